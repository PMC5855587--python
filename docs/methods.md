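# Methods

`oligoforce` analyses single-molecule AFM force-spectroscopy experiments in
which an amino acid, oligopeptide or polymer is tethered to the cantilever
tip through a flexible PEG spacer and pulled off a mineral surface. This
note records the models implemented, the parameters that matter, what the
synthetic data do and do not emulate, and the numerical choices made where
the design was genuinely open.

## Force-curve model and conventions

A force curve is one approach/retract cycle of piezo position `z` (nm) and
cantilever deflection `d` (nm); the tip force is `F = k·d` with spring
constant `k` (nN/nm; 1 nN/nm = 1000 pN/nm). Adhesion during retraction
bends the cantilever toward the surface, giving negative deflection;
reported unbinding forces are positive magnitudes. The tether-extension axis
is `x = (z − z_contact) − |F|/k`: piezo travel past the contact point minus
the cantilever's own bending, so `x` is the tip–sample separation actually
imposed on the tether. Units are fixed package-wide (nm, pN, nN/nm, µm/s,
K); conversions happen only at I/O boundaries. Curves are stored as
tab-separated text with `#`-prefixed metadata and 17-significant-digit
floats, so write→read round trips are bit-identical.

## Tether elasticity

The PEG spacer is modelled as a worm-like chain with the Marko–Siggia
interpolation

    F(x) = (k_B T / Lp) · [ 1/(4(1 − x/Lc)²) − 1/4 + x/Lc ],

persistence length `Lp`, contour length `Lc`. The inverse is obtained by
bisection on `[0, Lc)` (round-trip accurate to 1e-9 relative). The exact
low-extension behaviour is `F = (3 k_B T / 2 Lp Lc)·x·(1 + x/2Lc + …)`; the
linear law is accurate to 1% only for `x/Lc ≲ 0.01` (the relative excess is
≈ x/2Lc), which is where the package's tests check it.

Two persistence lengths appear deliberately:

* **Validation fits** use `Lp = 0.1 nm` fixed, with `Lc` free — the
  convention used when such ramps are scored against "the" WLC curve in this
  kind of experiment. This value is sub-monomer and should be read as an
  effective fit parameter, not a structural length.
* **The synthetic generator** uses a literature-scale PEG persistence length
  of `Lp = 0.38 nm` for the tether it actually simulates. With `Lp = 0.1 nm`
  and `Lc = 35 nm`, a Marko–Siggia chain reaches 30–55 pN at only 12–18 nm
  extension, which would place a large fraction of true specific ruptures
  *below* the 15 nm acceptance window — inconsistent with ruptures observed
  at 25–40 nm extension for a PEG of MW ≈ 4000. With `Lp = 0.38 nm`,
  ruptures between 15 and 140 pN fall at 20–40 nm extension, inside the
  window, and detection sensitivity can meaningfully be scored.

WLC fits never reject events: experimental tether ramps deviate
systematically from the ideal WLC (e.g. excess force in the mid-region), so
the fit residual is stored as a plausibility score only.

## Synthetic data generator

The generator is the package's ground-truth oracle. Each curve is drawn
independently from a per-curve substream (`SeedSequence(seed, spawn_key=i)`),
so ensembles are byte-identical under a repeated seed and individual curves
are reproducible in isolation. Curve classes:

* **specific** — WLC tether ramp from the contact point, solved
  self-consistently with cantilever compliance (`z = x + F(x)/k`),
  terminating in a single-sample step to baseline at a rupture force drawn
  from a Gaussian or Gaussian mixture (per-curve contour length
  `Lc ~ N(35, 5) nm` for PEG MW heterogeneity). The final pre-rupture sample
  is pinned to the exact drawn force, so label = signal by construction.
* **nonspecific** — a near-contact adhesion well releasing below 15 nm
  extension (tip–surface adhesion artefact).
* **plateau** — a constant-force segment (peeling of an adsorbed polymer)
  ending in a terminal detachment step; force and detach length Gaussian.
* **no_adhesion** — baseline only.

All curves share a linear repulsive contact wall (30 pN/nm) for `z < 0`,
optional linear baseline drift (pN/µm), and white Gaussian force noise
(default sd 5 pN, matching a ~10 pN detection floor at 2× noise). Default
ensemble conditions: 0.75 µm retract span, 1500 samples/curve (0.5 nm
pitch), specific-binding probability 0.125 (the band reported for the
longest oligomer), nonspecific probability 0.10, rupture model N(55, 11) pN.

Deliberately **not** simulated: loading-rate (Bell–Evans) dependence of the
rupture force (all species are taken as measured at similar loading rates,
so forces are drawn directly from the stated distribution), hydrodynamic
drag, cantilever ringing, PEG conformational transitions, finite detachment
kinetics, and the unexplained mid-ramp force excess of real curves. Classes
are mutually exclusive per curve (a specific curve carries no additional
near-contact artefact). Passing tests therefore demonstrate that the
analysis recovers the truth of curves with exactly the structure the
analysis assumes — not robustness to every artefact of real data.

## Event detection

1. **Baseline**: straight line fitted to the final 20% of the retract trace
   (farthest from the surface); noise estimated robustly (1.4826·MAD of the
   residuals); the fit is then refined on all samples beyond 10% of the span
   with >3σ outliers (events) masked, which stabilises the drift slope. A
   slope above 2× noise per 100 nm raises a drift warning but the curve is
   still processed.
2. **Contact point**: the first downward baseline crossing of the smoothed
   force coming from the repulsive wall, where the wall is the *first*
   above-threshold smoothed run at the start of the trace (Savitzky–Golay
   overshoot at rupture cliffs can exceed the threshold later in the trace
   and must not be mistaken for the wall). No wall ⇒ no contact ⇒ the curve
   is classed `no_adhesion`.
3. **Rupture candidates**: smoothing (Savitzky–Golay, window 11, order 2) is
   used only to delimit event regions — contiguous stretches where smoothed
   adhesion exceeds the `min_force` floor (default 10 pN) until it releases
   back to within 2× noise of baseline. Within each region the rupture is
   located at the largest single-sample force drop, and the force is read
   from the *unsmoothed* sample just before it. This locator is unbiased to
   ≲0.2 pN, whereas reading at the smoothed maximum underestimates the
   force (smoothing shifts the peak off the cliff) and refining by a local
   unsmoothed argmax overestimates it by several pN (max-of-noise selection).
4. **Acceptance window**: events with rupture extension in [15, 60] nm
   (PEG-tether range allowing for MW heterogeneity) are accepted as
   specific; candidates confined below 15 nm mark the curve `nonspecific`
   — near-contact artefacts are excluded by position, not by discarding
   curves. The window filter is exact by construction. With several accepted
   events, the curve's headline unbinding force is the final rupture
   (largest extension; ties → larger force), per the single-tether
   interpretation.
5. **Plateaus**: the longest contiguous segment ≥ 20 nm whose smoothed
   adhesion stays ≥ `min_force` and within 2× noise of its own mean, ending
   in a terminal step to baseline. Smoothing-boundary samples at the segment
   edges are trimmed before the flatness test. Plateau classification takes
   precedence over rupture classification (the terminal detachment step of
   a peeling curve is not an unbinding event).

On the default 1000-curve labelled ensemble this yields sensitivity ≥ 0.98
(specific events with true force ≥ 30 pN), zero false positives, and a mean
detected-minus-true force bias below 0.5 pN.

## Force statistics

Unbinding-force histograms use left-closed 10 pN bins anchored at 0 pN (the
paper-scale decade binning; configurable). Because such histograms are
typically skewed, the most probable force (MPF) is the mode of a Gaussian
fitted by least squares to the bins within ±3 bins of the tallest bin — a
local fit around the main peak, not a global or skew-normal fit. Multi-modal
histograms are decomposed by Gaussian-mixture least squares, initialised at
the tallest bins at least 3 bins apart; adjacent fitted components closer
than their own width are a degenerate split of one peak and are merged back
to the single-peak fit with a warning.

Two MPFs are compared with the two-sided z-interval
`Δ ± z(conf)·√(σ₁²/n₁ + σ₂²/n₂)`, with the fitted Gaussian σ and the
accepted-event count n. At n ≈ 32–38 a t-interval would round to the same
whole-pN values; z is the declared contract. Rounding to the nearest pN
happens only at the reporting layer. Binding frequency is the fraction of
curves classified specific, with a Wilson 95% interval (statsmodels).

## Peeling work

For plateau curves the adhesion force is integrated trapezoidally over a
configurable extension segment (default 20–80 nm, skipping the complicated
initial region): `work = ∫F dx` with 1 pN·nm = 1e-21 J; per-nm work,
molar work (× Avogadro) and per-residue energy (÷ residue line density,
default 3 nm⁻¹, assuming every residue adsorbs) follow. A constant 55 pN
plateau over 60 nm gives 3300e-21 J, 55e-21 J/nm, 3.31e4 J/(nm·mol) and
11.0 kJ/mol per residue — the package reports the exact arithmetic value
(common rounding quotes "about 10 kJ/mol"). Segment endpoints are
interpolated onto the grid, so constant plateaus integrate exactly and grid
refinement is a no-op; the work from 0 to the segment end is reported only
when the curve actually covers it, never extrapolated. Noise jitters the
extension axis (σ_F/k ≈ 0.25 nm at defaults); the integrand keeps the
strictly-increasing subsequence (running maximum) of the axis.

## Multivalent binding statistics

An n-site ligand with identical, independent sites has `W = 2ⁿ − 1` bound
configurations (all non-empty site subsets; brute-force enumeration up to
n = 20 is the oracle for the closed form) and configurational entropy
`ΔS = k_B ln W`. The per-site predictor `P(bind) = 1 − (1 − p)ⁿ` is an
explicit extrapolation beyond the configurational count — W alone fixes no
frequency scale — and every result carries an `extrapolated` flag. It is
used to drive the synthetic length series (monotone binding frequency with
oligomer length).

## Spring-constant calibration

Plain equipartition: `k = k_B T / var(d)` from ≥10³ non-contact deflection
samples, with relative uncertainty `√(2/(n−1))` (chi-square sampling of a
variance); smaller samples are flagged insufficient. No spectral
(Lorentzian) fitting, optical-lever sensitivity calibration, or
cantilever-shape correction is applied; the shape correction would rescale
k by a known constant factor (≈0.97·1/0.817 ≈ 1.19 for the fundamental mode
of a rectangular lever read by an optical lever) and is out of scope for
the equipartition contract implemented here.

## Pipeline and problem sizes

`run_pipeline` derives per-sample simulation seeds from the master seed by
counter, so runs are deterministic end to end and a sample directory that
already holds a manifest is reused rather than re-simulated. The default
test ensemble is 1000 curves at 1500 samples/curve; the analysis drivers
use 400 curves per species at the same sampling pitch — large enough that
class frequencies and fitted modes sit well inside their sampling bands,
small enough to run interactively. MPF-recovery checks use the
experimental event counts themselves (n = 36 and 32) with 20 seeded
replicates summarised by the median.

## Known limitations

* The generator's class exclusivity and instantaneous ruptures idealise
  real curves; detection performance on real data will be bounded by
  artefacts not simulated here.
* The MPF local Gaussian fit is near-unbiased for Gaussian peaks but
  inherits the arbitrariness of bin anchoring at small n; sub-pN accuracy
  should not be over-interpreted at n ≈ 30.
* The frequency predictor `1 − (1−p)ⁿ` assumes site independence; rigidity
  or cooperative unbinding (invoked qualitatively to explain higher-force
  histogram peaks of longer oligomers) is not modelled.
* Vendor binary AFM formats are not read; curves enter as delimited text.
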