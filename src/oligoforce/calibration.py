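"""Thermal-noise (equipartition) spring-constant calibration.

A cantilever in thermal equilibrium fluctuates with deflection variance set
by equipartition, ``(1/2) k <d^2> = (1/2) k_B T``, so the spring constant
follows from baseline (non-contact) deflection samples as

    k = k_B T / var(d).

The sampling uncertainty of a variance estimate from ``n`` (independent,
Gaussian) samples gives a relative uncertainty of ``sqrt(2 / (n - 1))`` on
``k``; at least ~10^3 samples are needed for a meaningful estimate, and
estimates from fewer are flagged insufficient.  No spectral (Lorentzian)
fitting or cantilever-shape corrections are applied; those would rescale k by
a known constant factor (see the methods note) and are out of scope for the
plain equipartition contract implemented here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from oligoforce.units import thermal_energy_pn_nm

__all__ = ["CalibrationResult", "equipartition_k", "simulate_thermal_deflection"]

MIN_SAMPLES = 1000


@dataclass(frozen=True)
class CalibrationResult:
    """Equipartition spring-constant estimate."""

    k_estimate: float  # nN/nm
    n_samples: int
    temperature: float  # K
    relative_uncertainty: float  # sqrt(2/(n-1))
    sufficient: bool  # n_samples >= MIN_SAMPLES

    def __post_init__(self) -> None:
        if not self.k_estimate > 0:
            raise ValueError("k_estimate must be positive")


def equipartition_k(deflection_samples, temperature: float) -> CalibrationResult:
    """Estimate the spring constant from baseline deflection fluctuations.

    Parameters
    ----------
    deflection_samples : array-like, nm
        Non-contact cantilever deflection samples.
    temperature : float, K

    Returns
    -------
    CalibrationResult
        ``k_estimate`` in nN/nm with its chi-square relative uncertainty;
        flagged insufficient below 1000 samples.
    """
    d = np.asarray(deflection_samples, dtype=float)
    if d.size < 2:
        raise ValueError("need at least 2 deflection samples")
    variance = float(np.var(d, ddof=1))
    if variance <= 0:
        raise ValueError("zero deflection variance; cannot calibrate")
    k_pn_per_nm = thermal_energy_pn_nm(temperature) / variance
    return CalibrationResult(
        k_estimate=k_pn_per_nm / 1000.0,
        n_samples=int(d.size),
        temperature=temperature,
        relative_uncertainty=float(np.sqrt(2.0 / (d.size - 1))),
        sufficient=bool(d.size >= MIN_SAMPLES),
    )


def simulate_thermal_deflection(
    spring_constant: float, temperature: float, n_samples: int,
    rng: np.random.Generator | int | None = None,
) -> np.ndarray:
    """Draw Gaussian thermal deflection samples (nm) for a given k (nN/nm).

    The equipartition variance is ``k_B T / k``; used to validate the
    calibration estimator against a known ground truth.
    """
    if spring_constant <= 0:
        raise ValueError("spring_constant must be positive")
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    sd_nm = np.sqrt(thermal_energy_pn_nm(temperature) / (spring_constant * 1000.0))
    return rng.normal(0.0, sd_nm, n_samples)
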