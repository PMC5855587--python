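# oligoforce

Analysis pipeline for single-molecule AFM force spectroscopy of
peptide–mineral adhesion: from raw force–distance curves to rupture-event
detection, most-probable-force (MPF) statistics, polymer peeling-work
quantification, and the configurational statistics of multivalent binding.

## The scientific problem

In AFM force mode, a ligand (an amino acid, a short oligopeptide, or a
polymer such as poly-L-lysine) is tethered to the cantilever tip through a
flexible PEG spacer and repeatedly brought into contact with a mineral
surface and retracted. When the ligand binds, the retract curve shows a
nonlinear tether-stretching ramp that ends in an abrupt rupture back to
baseline; the maximum force before the step is the unbinding force. The
questions such experiments answer — how strongly does each molecular
species bind, how often, and how does affinity grow with oligomer length —
bear on whether mineral surfaces can selectively concentrate longer
peptides, a step invoked in origins-of-life scenarios.

Getting from raw curves to those answers requires a chain of distinctly
unglamorous steps, each of which this package implements and tests:

* **curve I/O** (`oligoforce.curves`): delimited-text force curves with
  strict unit conventions (`F = k·d`; extension `x = Δz − |F|/k`),
* **tether model** (`oligoforce.wlc`): Marko–Siggia worm-like chain
  `F(x) = (k_BT/Lp)[1/(4(1−x/Lc)²) − 1/4 + x/Lc]`, its numerical inverse,
  and least-squares fitting,
* **event detection** (`oligoforce.detect`): baseline/contact estimation,
  rupture localisation, the 15–60 nm extension acceptance window that
  separates specific tether-mediated events from near-contact adhesion
  artefacts, and peeling-plateau recognition,
* **statistics** (`oligoforce.stats`): force histograms, the MPF as the
  mode of a Gaussian fitted locally around the tallest histogram peak,
  Gaussian-mixture decomposition of multi-modal histograms, Wilson binding
  frequencies, and z-intervals on MPF differences,
* **peeling work** (`oligoforce.peeling`): trapezoidal `∫F dx` over a
  plateau segment, converted to molar and per-residue adsorption energies,
* **multivalency** (`oligoforce.multivalency`): `W = 2ⁿ − 1` bound
  configurations of an n-site ligand and `ΔS = k_B ln W`,
* **calibration** (`oligoforce.calibration`): equipartition thermal-noise
  spring-constant estimation, `k = k_BT / var(d)`,
* **synthetic data** (`oligoforce.simulate`): a ground-truth-labelled
  generator of retract curves (specific / nonspecific / plateau /
  no-adhesion, with WLC ramps solved self-consistently with cantilever
  compliance) so every stage is testable without instrument data,
* **orchestration** (`oligoforce.pipeline`, CLI `oligoforce`): deterministic
  simulate → detect → stats → peel → compare runs from a YAML config.

See `docs/methods.md` for the models, parameter defaults, and numerical
choices, and `analysis/` for numbered end-to-end drivers.

## Worked example

Simulate a tri-Gly-like ensemble, detect events, and summarise:

```python
import dataclasses
from oligoforce import PipelineConfig, SimulationConfig, run_pipeline

sample = dataclasses.replace(SimulationConfig(), sample_label="tri-Gly",
                             n_curves=400, p_specific=0.085)
result = run_pipeline(PipelineConfig(samples=(sample,), outdir="out", seed=1))
print(result.summary.to_string(index=False))
```

```
 sample MPF_pN  relative_frequency_pct  n_specific  n_total
tri-Gly     53                     7.5          30      400
```

The fitted MPF (53 pN) is the mode of a Gaussian fitted around the tallest
10 pN histogram bin of the detected unbinding forces — here recovering the
generating rupture-force distribution N(55, 11) pN within the sampling
error of its 30 events — and the relative
frequency is the fraction of curves with an accepted specific event in the
15–60 nm extension window.

Comparing species by their fitted modes, spreads and event counts:

```python
from oligoforce.stats import MPFResult, compare_modes
penta = MPFResult(mode=76, sigma=10, amplitude=1, n_events=36, fit_window=(0, 200))
tri   = MPFResult(mode=55, sigma=11, amplitude=1, n_events=38, fit_window=(0, 200))
print(compare_modes(penta, tri, confidence=0.95).rounded())   # (21, 5)
```

i.e. the penta-Gly first peak exceeds the tri-Gly mode by 21 ± 5 pN at 95%
confidence. A constant 55 pN peeling plateau integrated over a 60 nm
segment gives 3300×10⁻²¹ J of work (55×10⁻²¹ J/nm ≈ 33×10³ J·nm⁻¹·mol⁻¹),
or 11.0 kJ/mol per residue at 3 residues/nm — the scale of a weak
non-covalent bond:

```python
import numpy as np
from oligoforce import peeling_work_from_series
x = np.linspace(0, 100, 1001)
r = peeling_work_from_series(x, np.full_like(x, 55.0), segment=(20, 80))
print(f"{r.work:.3g} J, {r.per_residue_energy:.1f} kJ/mol")  # 3.3e-18 J, 11.0 kJ/mol
```

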