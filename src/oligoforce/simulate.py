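"""Ground-truth-labelled synthetic force curves.

The generator is an explicit forward model of what the analysis assumes a
retract curve contains, so every downstream stage can be scored against known
labels:

* **specific** curves: a WLC-shaped tether ramp starting at the contact point
  and terminating in an instantaneous force step to baseline at a rupture
  force drawn from a Gaussian (or Gaussian-mixture) distribution.  Cantilever
  compliance is honoured: at piezo displacement ``z`` past contact the tether
  extension ``x`` satisfies ``z = x + F(x)/k`` with ``F`` the WLC tension, so
  the recorded deflection and the tether state are mutually consistent.
* **nonspecific** curves: an adhesion well immediately after contact that
  releases at near-zero tether extension (< 15 nm), emulating tip-surface
  adhesion artefacts.
* **plateau** curves: a constant-force segment ending in a terminal detachment
  step, emulating the peeling of an adsorbed polymer chain.
* **no_adhesion** curves: baseline only.

All curves share a linear repulsive contact wall at negative piezo values, an
optional linear baseline drift, and white Gaussian force noise.  Rupture is
instantaneous (a single-sample step): the detected unbinding force of a
specific event is, by construction, the drawn rupture force.  Loading-rate
(Bell-Evans) physics is deliberately not simulated: all species are assumed
measured at similar loading rates, so rupture forces are drawn directly from
the stated distribution.

Randomness: one master seed; each curve uses an independent substream derived
from the master seed and the curve index, so individual curves are
reproducible and the ensemble is byte-identical under a repeated seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from oligoforce.curves import ExperimentManifest, ForceCurve, write_curve, write_manifest
from oligoforce.wlc import WLCParams, wlc_extension, wlc_force

__all__ = [
    "ConfigError",
    "RuptureForceModel",
    "PlateauModel",
    "SimulationConfig",
    "GroundTruthLabel",
    "simulate_retract_curve",
    "simulate_ensemble",
    "write_ensemble",
    "labels_to_frame",
]

#: Slope of the linear repulsive contact wall, pN per nm of indentation.
WALL_STIFFNESS_PN_PER_NM = 30.0

#: Piezo depth of the simulated contact region, nm.
WALL_DEPTH_NM = 15.0


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass(frozen=True)
class RuptureForceModel:
    """Gaussian or Gaussian-mixture rupture-force distribution (pN)."""

    means: tuple[float, ...] = (55.0,)
    sigmas: tuple[float, ...] = (11.0,)
    weights: tuple[float, ...] = (1.0,)

    def __post_init__(self) -> None:
        if not (len(self.means) == len(self.sigmas) == len(self.weights)):
            raise ConfigError("rupture_force_model: means, sigmas, weights must align")
        if any(s < 0 for s in self.sigmas):
            raise ConfigError("rupture_force_model: sigmas must be >= 0")
        if any(w < 0 for w in self.weights) or sum(self.weights) <= 0:
            raise ConfigError("rupture_force_model: weights must be non-negative, sum > 0")
        total = float(sum(self.weights))
        object.__setattr__(self, "weights", tuple(w / total for w in self.weights))

    def sample(self, rng: np.random.Generator) -> float:
        comp = int(rng.choice(len(self.means), p=self.weights))
        force = float(rng.normal(self.means[comp], self.sigmas[comp]))
        while force <= 1.0:  # rupture force is a positive magnitude
            force = float(rng.normal(self.means[comp], self.sigmas[comp]))
        return force


@dataclass(frozen=True)
class PlateauModel:
    """Peeling-plateau parameters: force and detachment length (Gaussian)."""

    force_mean: float = 55.0  # pN
    force_sd: float = 5.0
    detach_mean: float = 100.0  # nm
    detach_sd: float = 10.0


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one synthetic ensemble.

    Defaults emulate a tri-Gly-like experiment: a PEG tether of contour
    length 35 +/- 5 nm (maximally extended PEG of MW ~4000 is ~30-40 nm, with
    MW heterogeneity), ~5 pN baseline force noise, a 0.75 um retract span and
    a specific-binding probability in the band reported for short glycine
    oligomers.
    """

    n_curves: int = 500
    p_specific: float = 0.125
    p_nonspecific: float = 0.10
    p_plateau: float = 0.0
    rupture_force_model: RuptureForceModel = field(default_factory=RuptureForceModel)
    #: Tether default: PEG persistence length 0.38 nm (literature value for
    #: PEG in water), so ruptures at 30-140 pN occur at 20-40 nm extension,
    #: inside the specific-event acceptance window, as observed for a PEG
    #: spacer of MW ~4000.  The effective Lp = 0.1 nm used for WLC
    #: validation fits is a separate convention (see docs/methods.md).
    tether: WLCParams = field(default_factory=lambda: WLCParams(0.38, 35.0, 298.15))
    contour_length_jitter: float = 5.0  # nm, sd of per-curve contour length
    noise_sd: float = 5.0  # pN
    baseline_drift: float = 0.0  # pN per um of piezo travel
    curve_length_um: float = 0.75
    points_per_curve: int = 1500
    plateau_model: Optional[PlateauModel] = None
    spring_constant: float = 0.02  # nN/nm
    pulling_speed: float = 5.0  # um/s
    temperature: float = 298.15  # K
    sample_label: str = "synthetic"
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_specific", "p_nonspecific", "p_plateau"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1], got {p}")
        if self.p_specific + self.p_nonspecific + self.p_plateau > 1.0 + 1e-12:
            raise ConfigError("class probabilities must sum to at most 1")
        if self.n_curves < 1:
            raise ConfigError("n_curves must be >= 1")
        if self.noise_sd < 0 or self.contour_length_jitter < 0:
            raise ConfigError("noise_sd and contour_length_jitter must be >= 0")
        if self.points_per_curve < 50:
            raise ConfigError("points_per_curve must be >= 50")
        if self.p_plateau > 0:
            if self.plateau_model is None:
                raise ConfigError("p_plateau > 0 requires a plateau_model")
            pm = self.plateau_model
            if pm.detach_mean + 3 * pm.detach_sd > self.curve_length_nm:
                raise ConfigError(
                    "plateau detach length exceeds the curve length: "
                    f"{pm.detach_mean} + 3*{pm.detach_sd} nm vs {self.curve_length_nm} nm"
                )

    @property
    def curve_length_nm(self) -> float:
        return self.curve_length_um * 1000.0

    @property
    def spring_constant_pn_per_nm(self) -> float:
        return self.spring_constant * 1000.0


@dataclass(frozen=True)
class GroundTruthLabel:
    """Generator-side truth for one curve; the oracle for detection tests."""

    curve_id: str
    true_class: str  # no_adhesion | nonspecific | specific | plateau
    true_rupture_force: Optional[float] = None  # pN
    true_rupture_extension: Optional[float] = None  # nm
    true_plateau_force: Optional[float] = None  # pN
    true_contour_length: Optional[float] = None  # nm

    def __post_init__(self) -> None:
        if self.true_class not in {"no_adhesion", "nonspecific", "specific", "plateau"}:
            raise ValueError(f"unknown class {self.true_class!r}")
        if self.true_class == "specific" and (
            self.true_rupture_force is None or self.true_rupture_extension is None
        ):
            raise ValueError("specific label requires rupture force and extension")
        if self.true_class == "plateau" and self.true_plateau_force is None:
            raise ValueError("plateau label requires a plateau force")


def _curve_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(index,)))


def _tether_ramp(z: np.ndarray, params: WLCParams, rupture_force: float,
                 k_pn: float) -> tuple[np.ndarray, float, float]:
    """Adhesion force (pN, positive) on the piezo grid for a WLC tether.

    Solves ``z = x + F(x)/k`` per point and pins the final pre-rupture sample
    to the exact drawn rupture force.  Returns (adhesion array, rupture piezo
    position, rupture extension).
    """
    x_rupture = wlc_extension(rupture_force, params)
    z_rupture = x_rupture + rupture_force / k_pn
    adhesion = np.zeros_like(z)
    in_ramp = (z > 0) & (z < z_rupture)
    lc = params.contour_length

    def solve(zi: float) -> float:
        hi = min(zi, lc * (1.0 - 1e-12))
        g = lambda x: x + wlc_force(x, params) / k_pn - zi
        if g(hi) <= 0:  # force at hi still below what the piezo demands
            return hi
        return brentq(g, 0.0, hi, xtol=1e-12, maxiter=200)

    idx = np.flatnonzero(in_ramp)
    for i in idx:
        adhesion[i] = wlc_force(solve(float(z[i])), params)
    return adhesion, z_rupture, x_rupture


def simulate_retract_curve(
    config: SimulationConfig, index: int = 0,
    rng: Optional[np.random.Generator] = None,
) -> tuple[ForceCurve, GroundTruthLabel]:
    """Simulate one approach/retract cycle plus its ground-truth label.

    ``rng`` defaults to the per-curve substream derived from
    ``config.seed`` and ``index``.
    """
    if rng is None:
        rng = _curve_rng(config.seed, index)
    curve_id = f"curve_{index:05d}"
    k_pn = config.spring_constant_pn_per_nm
    n = config.points_per_curve
    z = np.linspace(-WALL_DEPTH_NM, config.curve_length_nm, n)

    u = rng.random()
    if u < config.p_specific:
        cls = "specific"
    elif u < config.p_specific + config.p_nonspecific:
        cls = "nonspecific"
    elif u < config.p_specific + config.p_nonspecific + config.p_plateau:
        cls = "plateau"
    else:
        cls = "no_adhesion"

    adhesion = np.zeros(n)  # positive = force pulling the tip surface-ward
    label_kwargs: dict = {}
    z = z.copy()

    if cls == "specific":
        lc = float(config.tether.contour_length
                   + config.contour_length_jitter * rng.standard_normal())
        lc = max(lc, 10.0)
        params = WLCParams(config.tether.persistence_length, lc, config.temperature)
        rupture_force = config.rupture_force_model.sample(rng)
        adhesion, z_rupture, x_rupture = _tether_ramp(z, params, rupture_force, k_pn)
        # pin the last pre-rupture sample to the exact rupture point
        i_after = int(np.searchsorted(z, z_rupture))
        if 0 < i_after <= n - 1:
            z[i_after - 1] = z_rupture
            adhesion[i_after - 1] = rupture_force
        label_kwargs = dict(true_rupture_force=rupture_force,
                            true_rupture_extension=x_rupture,
                            true_contour_length=lc)
    elif cls == "nonspecific":
        depth = float(rng.uniform(30.0, 250.0))
        z_peak = float(rng.uniform(2.0, 8.0))
        in_well = (z > 0) & (z <= z_peak)
        adhesion[in_well] = depth * z[in_well] / z_peak
    elif cls == "plateau":
        pm = config.plateau_model
        assert pm is not None  # enforced by config validation
        force = float(rng.normal(pm.force_mean, pm.force_sd))
        while force <= 1.0:
            force = float(rng.normal(pm.force_mean, pm.force_sd))
        detach = float(rng.normal(pm.detach_mean, pm.detach_sd))
        detach = min(max(detach, 25.0), config.curve_length_nm - 10.0)
        in_plateau = (z > 2.0) & (z <= detach)
        adhesion[in_plateau] = force
        label_kwargs = dict(true_plateau_force=force)

    wall = np.where(z < 0, -z * WALL_STIFFNESS_PN_PER_NM, 0.0)
    drift = config.baseline_drift * z / 1000.0
    force_retract = wall - adhesion + drift + rng.normal(0.0, config.noise_sd, n) \
        if config.noise_sd > 0 else wall - adhesion + drift
    # approach: mirror of wall + baseline, no adhesion, fresh noise
    z_app = z[::-1].copy()
    wall_app = np.where(z_app < 0, -z_app * WALL_STIFFNESS_PN_PER_NM, 0.0)
    drift_app = config.baseline_drift * z_app / 1000.0
    force_app = wall_app + drift_app + rng.normal(0.0, config.noise_sd, n) \
        if config.noise_sd > 0 else wall_app + drift_app

    curve = ForceCurve(
        curve_id=curve_id,
        piezo_approach=z_app,
        deflection_approach=force_app / k_pn,
        piezo_retract=z,
        deflection_retract=force_retract / k_pn,
        spring_constant=config.spring_constant,
        pulling_speed=config.pulling_speed,
        temperature=config.temperature,
        sample_label=config.sample_label,
    )
    label = GroundTruthLabel(curve_id=curve_id, true_class=cls, **label_kwargs)
    return curve, label


def simulate_ensemble(
    config: SimulationConfig,
) -> tuple[list[ForceCurve], list[GroundTruthLabel], ExperimentManifest]:
    """Simulate ``config.n_curves`` labelled curves plus a manifest."""
    curves: list[ForceCurve] = []
    labels: list[GroundTruthLabel] = []
    for i in range(config.n_curves):
        curve, label = simulate_retract_curve(config, index=i)
        curves.append(curve)
        labels.append(label)
    entries = [
        {"curve_id": c.curve_id, "file": f"{c.curve_id}.tsv",
         "sample_label": c.sample_label, "spring_constant_nN_per_nm": c.spring_constant,
         "pulling_speed_um_per_s": c.pulling_speed, "temperature_K": c.temperature}
        for c in curves
    ]
    manifest = ExperimentManifest(entries=entries, config={"seed": config.seed,
                                                           "n_curves": config.n_curves,
                                                           "sample_label": config.sample_label})
    return curves, labels, manifest


def labels_to_frame(labels: Sequence[GroundTruthLabel]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "curve_id": [l.curve_id for l in labels],
            "true_class": [l.true_class for l in labels],
            "true_rupture_force_pN": [
                math.nan if l.true_rupture_force is None else l.true_rupture_force for l in labels
            ],
            "true_rupture_extension_nm": [
                math.nan if l.true_rupture_extension is None else l.true_rupture_extension
                for l in labels
            ],
            "true_plateau_force_pN": [
                math.nan if l.true_plateau_force is None else l.true_plateau_force for l in labels
            ],
        }
    )


def write_ensemble(config: SimulationConfig, outdir: str | Path) -> Path:
    """Simulate and write curves, a labels TSV and a JSON manifest.

    Returns the manifest path.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    curves, labels, manifest = simulate_ensemble(config)
    for curve, entry in zip(curves, manifest.entries):
        write_curve(curve, outdir / entry["file"])
    labels_to_frame(labels).to_csv(outdir / "labels.tsv", sep="\t", index=False)
    return write_manifest(manifest, outdir / "manifest.json")
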