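"""End-to-end orchestration: simulate -> detect -> stats -> peel -> compare.

A pipeline run is driven by a :class:`PipelineConfig` (round-trippable
through YAML) and is deterministic for a fixed master seed: per-sample
simulation seeds are derived from the master seed by counter, so repeated
runs produce identical result bundles.  Stage outputs land in the output
directory (curves + labels per sample, an events TSV, per-sample results
JSON, and a summary table with one row per molecular species: MPF(s) and
relative binding frequency).  A sample directory that already contains a
manifest is not re-simulated, so partial re-runs resume from cached stage
outputs with identical results.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from oligoforce.curves import ForceCurve, read_curve, read_manifest
from oligoforce.detect import (
    DEFAULT_MIN_FORCE_PN,
    DEFAULT_WINDOW_NM,
    CurveClassification,
    classify_curve,
)
from oligoforce.multivalency import multivalency_result
from oligoforce.peeling import DEFAULT_RESIDUES_PER_NM, DEFAULT_SEGMENT_NM, PeelingResult, peeling_work
from oligoforce.simulate import PlateauModel, RuptureForceModel, SimulationConfig, write_ensemble
from oligoforce.stats import (
    DEFAULT_BIN_WIDTH_PN,
    MPFResult,
    binding_frequency,
    build_histogram,
    compare_modes,
    fit_mpf,
    fit_multi_mpf,
)
from oligoforce.wlc import WLCParams

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline", "length_series_samples"]

log = logging.getLogger("oligoforce")


@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters of one pipeline run.

    Every default equals the corresponding module-level default, so an empty
    config block reproduces library behaviour.
    """

    samples: tuple[SimulationConfig, ...] = ()
    outdir: str = "results"
    seed: int = 1
    min_force: float = DEFAULT_MIN_FORCE_PN
    window: tuple[float, float] = DEFAULT_WINDOW_NM
    bin_width: float = DEFAULT_BIN_WIDTH_PN
    confidence: float = 0.95
    n_peaks: dict = field(default_factory=dict)  # sample_label -> mixture components
    peeling_segment: tuple[float, float] = DEFAULT_SEGMENT_NM
    residues_per_nm: float = DEFAULT_RESIDUES_PER_NM
    validate_wlc: bool = True
    log_level: str = "INFO"

    # -- YAML round trip ---------------------------------------------------
    def to_dict(self) -> dict:
        def encode(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: encode(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, tuple):
                return [encode(v) for v in obj]
            if isinstance(obj, dict):
                return {k: encode(v) for k, v in obj.items()}
            return obj
        return encode(self)  # type: ignore[return-value]

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=False)

    @classmethod
    def from_dict(cls, payload: dict) -> "PipelineConfig":
        data = dict(payload)
        samples = []
        for s in data.pop("samples", []):
            s = dict(s)
            rfm = s.pop("rupture_force_model", None)
            if rfm is not None:
                s["rupture_force_model"] = RuptureForceModel(
                    means=tuple(rfm["means"]), sigmas=tuple(rfm["sigmas"]),
                    weights=tuple(rfm["weights"]),
                )
            tether = s.pop("tether", None)
            if tether is not None:
                s["tether"] = WLCParams(**tether)
            pm = s.pop("plateau_model", None)
            if pm is not None:
                s["plateau_model"] = PlateauModel(**pm)
            samples.append(SimulationConfig(**s))
        for key in ("window", "peeling_segment"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(samples=tuple(samples), **data)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(text))


@dataclass
class SampleStats:
    """Per-species results: histogram fit(s) and binding frequency."""

    sample_label: str
    n_total: int
    n_specific: int
    frequency: float
    frequency_ci: tuple[float, float]
    peaks: list[MPFResult]

    @property
    def mpf(self) -> Optional[MPFResult]:
        return self.peaks[0] if self.peaks else None

    def to_json_dict(self) -> dict:
        return {
            "sample_label": self.sample_label,
            "n_total": self.n_total,
            "n_specific": self.n_specific,
            "frequency": self.frequency,
            "frequency_ci95": list(self.frequency_ci),
            "MPF_pN": self.mpf.mode if self.mpf else None,
            "sigma_pN": self.mpf.sigma if self.mpf else None,
            "peaks": [
                {"mode_pN": p.mode, "sigma_pN": p.sigma, "amplitude": p.amplitude}
                for p in self.peaks
            ],
        }


@dataclass
class PipelineResult:
    """In-memory bundle of one pipeline run."""

    config: PipelineConfig
    classifications: dict[str, list[CurveClassification]]
    events: pd.DataFrame
    sample_stats: dict[str, SampleStats]
    summary: pd.DataFrame
    peeling: dict[str, list[PeelingResult]]
    comparisons: pd.DataFrame


def _derived_seed(master: int, index: int) -> int:
    return int(np.random.SeedSequence(master, spawn_key=(index,)).generate_state(1)[0] % 2**31)


def length_series_samples(
    base: SimulationConfig,
    per_site_probability: float,
    n_sites_by_label: dict[str, int],
) -> tuple[SimulationConfig, ...]:
    """Build a length-series of samples with multivalency-driven frequencies.

    Each sample's specific-binding probability is the (extrapolated)
    multi-site predictor ``1 - (1 - p)^n``, producing the monotone frequency
    ordering expected for progressively longer oligomers.
    """
    samples = []
    for label, n_sites in n_sites_by_label.items():
        mv = multivalency_result(n_sites, per_site_probability)
        samples.append(
            dataclasses.replace(base, sample_label=label,
                                p_specific=float(mv.predicted_binding_probability))
        )
    return tuple(samples)


def _simulate_stage(config: PipelineConfig, outdir: Path) -> dict[str, Path]:
    """Simulate each sample into outdir/curves/<label>/; resume if present."""
    manifests: dict[str, Path] = {}
    for i, sample in enumerate(config.samples):
        sample_dir = outdir / "curves" / sample.sample_label
        manifest_path = sample_dir / "manifest.json"
        if manifest_path.exists():
            log.info("simulate: %s cached (%s)", sample.sample_label, manifest_path)
        else:
            seeded = dataclasses.replace(sample, seed=_derived_seed(config.seed, i))
            write_ensemble(seeded, sample_dir)
            log.info("simulate: %s -> %d curves", sample.sample_label, sample.n_curves)
        manifests[sample.sample_label] = manifest_path
    return manifests


def _load_curves(manifest_path: Path) -> list[ForceCurve]:
    manifest = read_manifest(manifest_path)
    return [read_curve(p) for p in manifest.curve_paths(manifest_path.parent)]


def _detect_stage(
    config: PipelineConfig, curves_by_label: dict[str, list[ForceCurve]]
) -> tuple[dict[str, list[CurveClassification]], pd.DataFrame]:
    classifications: dict[str, list[CurveClassification]] = {}
    rows = []
    for label, curves in curves_by_label.items():
        cls_list = []
        for curve in curves:
            try:
                cls = classify_curve(curve, min_force=config.min_force,
                                     window=config.window, validate_wlc=config.validate_wlc)
            except ValueError as exc:
                raise RuntimeError(
                    f"detect stage failed on curve {curve.curve_id!r} (sample {label!r})"
                ) from exc
            cls_list.append(cls)
            head = cls.headline_event
            if head is not None:
                rows.append({
                    "curve_id": curve.curve_id, "sample_label": label,
                    "curve_class": cls.curve_class,
                    "rupture_force_pN": head.rupture_force,
                    "rupture_extension_nm": head.rupture_extension,
                    "wlc_Lc_nm": head.wlc_contour_length,
                    "wlc_residual_pN": head.wlc_residual,
                    "n_accepted_events": len(cls.accepted_events),
                })
        classifications[label] = cls_list
        counts = pd.Series([c.curve_class for c in cls_list]).value_counts().to_dict()
        log.info("detect: %s -> %s", label, counts)
    return classifications, pd.DataFrame(rows)


def _stats_stage(
    config: PipelineConfig, classifications: dict[str, list[CurveClassification]]
) -> tuple[dict[str, SampleStats], pd.DataFrame]:
    sample_stats: dict[str, SampleStats] = {}
    summary_rows = []
    for label, cls_list in classifications.items():
        forces = [c.headline_event.rupture_force for c in cls_list
                  if c.headline_event is not None]
        freq = binding_frequency(cls_list)
        peaks: list[MPFResult] = []
        if len(forces) >= 5:
            hist = build_histogram(forces, bin_width=config.bin_width)
            n_peaks = int(config.n_peaks.get(label, 1))
            try:
                peaks = fit_multi_mpf(hist, n_peaks) if n_peaks > 1 else [fit_mpf(hist)]
            except ValueError as exc:
                log.warning("stats: %s MPF fit skipped (%s)", label, exc)
        sample_stats[label] = SampleStats(
            sample_label=label, n_total=freq.n_total, n_specific=freq.n_specific,
            frequency=freq.fraction, frequency_ci=(freq.ci_low, freq.ci_high),
            peaks=peaks,
        )
        summary_rows.append({
            "sample": label,
            "MPF_pN": ", ".join(f"{p.mode:.0f}" for p in peaks) if peaks else "-",
            "relative_frequency_pct": 100.0 * freq.fraction,
            "n_specific": freq.n_specific, "n_total": freq.n_total,
        })
        log.info("stats: %s -> %d/%d specific (%.1f%%), MPF %s",
                 label, freq.n_specific, freq.n_total, 100 * freq.fraction,
                 summary_rows[-1]["MPF_pN"])
    return sample_stats, pd.DataFrame(summary_rows)


def _peel_stage(
    config: PipelineConfig,
    curves_by_label: dict[str, list[ForceCurve]],
    classifications: dict[str, list[CurveClassification]],
) -> dict[str, list[PeelingResult]]:
    peeling: dict[str, list[PeelingResult]] = {}
    for label, cls_list in classifications.items():
        plateau_ids = {c.curve_id for c in cls_list if c.curve_class == "plateau"}
        if not plateau_ids:
            continue
        results = []
        for curve in curves_by_label[label]:
            if curve.curve_id not in plateau_ids:
                continue
            try:
                results.append(peeling_work(curve, segment=config.peeling_segment,
                                            residues_per_nm=config.residues_per_nm))
            except ValueError as exc:
                log.warning("peel: %s skipped (%s)", curve.curve_id, exc)
        if results:
            peeling[label] = results
            log.info("peel: %s -> %d plateau curves, mean force %.1f pN",
                     label, len(results), np.mean([r.mean_force for r in results]))
    return peeling


def _compare_stage(config: PipelineConfig, sample_stats: dict[str, SampleStats]) -> pd.DataFrame:
    rows = []
    labels = [l for l, s in sample_stats.items() if s.mpf is not None and s.n_specific > 1]
    for i, l1 in enumerate(labels):
        for l2 in labels[i + 1:]:
            cmp_ = compare_modes(sample_stats[l1].mpf, sample_stats[l2].mpf,
                                 confidence=config.confidence)
            diff, half = cmp_.rounded()
            rows.append({
                "sample_1": l1, "sample_2": l2,
                "difference_pN": cmp_.difference, "half_width_pN": cmp_.half_width,
                "reported": f"{diff} ± {half} pN",
                "confidence": config.confidence, "significant": cmp_.significant,
            })
    return pd.DataFrame(rows)


def run_pipeline(
    config: PipelineConfig,
    curves_dir: Optional[str | Path] = None,
) -> PipelineResult:
    """Run all stages and write the result bundle to ``config.outdir``.

    With ``curves_dir`` given (a directory of per-sample subdirectories each
    holding a ``manifest.json``) the simulation stage is skipped and the run
    is analysis-only.
    """
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    if curves_dir is not None:
        root = Path(curves_dir)
        manifests = {p.parent.name: p for p in sorted(root.glob("*/manifest.json"))}
        if not manifests:
            raise FileNotFoundError(f"no */manifest.json under {root}")
    else:
        if not config.samples:
            raise ValueError("config defines no samples and no curves_dir was given")
        manifests = _simulate_stage(config, outdir)

    curves_by_label = {label: _load_curves(path) for label, path in manifests.items()}
    log.info("loaded %d samples, %d curves total",
             len(curves_by_label), sum(len(v) for v in curves_by_label.values()))

    classifications, events = _detect_stage(config, curves_by_label)
    events.to_csv(outdir / "events.tsv", sep="\t", index=False, float_format="%.3f")

    sample_stats, summary = _stats_stage(config, classifications)
    summary.to_csv(outdir / "summary.tsv", sep="\t", index=False)

    peeling = _peel_stage(config, curves_by_label, classifications)
    comparisons = _compare_stage(config, sample_stats)
    if not comparisons.empty:
        comparisons.to_csv(outdir / "mode_comparisons.tsv", sep="\t", index=False)

    class_counts = {
        label: pd.Series([c.curve_class for c in cls_list]).value_counts().to_dict()
        for label, cls_list in classifications.items()
    }
    results_json = {
        "samples": {l: s.to_json_dict() for l, s in sample_stats.items()},
        "class_counts": class_counts,
        "peeling": {
            l: [
                {"segment_nm": list(r.segment), "mean_force_pN": r.mean_force,
                 "work_J": r.work, "work_per_nm_J": r.work_per_nm,
                 "molar_work_per_nm_J": r.molar_work_per_nm,
                 "per_residue_energy_kJ_per_mol": r.per_residue_energy}
                for r in results
            ]
            for l, results in peeling.items()
        },
        "seed": config.seed,
    }
    (outdir / "results.json").write_text(json.dumps(results_json, indent=1, sort_keys=True) + "\n")
    (outdir / "pipeline_config.yaml").write_text(config.to_yaml())

    return PipelineResult(
        config=config, classifications=classifications, events=events,
        sample_stats=sample_stats, summary=summary, peeling=peeling,
        comparisons=comparisons,
    )
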