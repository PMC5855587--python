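"""Worm-like-chain (WLC) elasticity of the PEG tether.

The PEG spacer linking the ligand to the tip stretches nonlinearly before a
specific rupture; its force-extension relation is modelled with the
Marko-Siggia interpolation

    F(x) = (k_B T / Lp) * [ 1 / (4 (1 - x/Lc)^2) - 1/4 + x/Lc ],

parameterised by persistence length ``Lp`` and contour length ``Lc``.  The
force vanishes at zero extension, rises linearly with slope
``3 k_B T / (2 Lp Lc)`` at small extension, and diverges as x -> Lc.  Fitting
the relation to the pre-rupture ramp of a retract curve gives the apparent
contour length and a residual used as a plausibility score for specific
(tether-mediated) events.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq, curve_fit, OptimizeWarning

from oligoforce.units import thermal_energy_pn_nm

__all__ = ["WLCParams", "WLCFit", "wlc_force", "wlc_extension", "fit_wlc"]

#: Default persistence length (nm) used when validating PEG tether events.
#: Deliberately sub-monomer; an effective parameter for PEG in water, not a
#: structural length.
DEFAULT_PERSISTENCE_LENGTH_NM = 0.1


@dataclass(frozen=True)
class WLCParams:
    """WLC parameters: persistence length, contour length (nm), temperature (K)."""

    persistence_length: float
    contour_length: float
    temperature: float

    def __post_init__(self) -> None:
        if not self.persistence_length > 0:
            raise ValueError(f"persistence_length must be > 0, got {self.persistence_length}")
        if not self.contour_length > 0:
            raise ValueError(f"contour_length must be > 0, got {self.contour_length}")
        if not self.temperature > 0:
            raise ValueError(f"temperature must be > 0, got {self.temperature}")

    @property
    def kbt(self) -> float:
        """Thermal energy k_B*T in pN*nm."""
        return thermal_energy_pn_nm(self.temperature)


def wlc_force(x, params: WLCParams):
    """Marko-Siggia WLC force (pN) at extension ``x`` (nm).

    Accepts a scalar or array; the domain is ``0 <= x < Lc``.
    """
    x_arr = np.asarray(x, dtype=float)
    if np.any(x_arr < 0):
        raise ValueError("extension must be non-negative")
    if np.any(x_arr >= params.contour_length):
        raise ValueError(
            f"extension must be below the contour length {params.contour_length} nm"
        )
    t = x_arr / params.contour_length
    f = (params.kbt / params.persistence_length) * (0.25 / (1.0 - t) ** 2 - 0.25 + t)
    return f if f.ndim else float(f)


def wlc_extension(force, params: WLCParams):
    """Invert the WLC relation: extension (nm) at tension ``force`` (pN).

    Monotone in force; bisection on ``[0, Lc)`` so the round trip
    ``wlc_force(wlc_extension(F)) == F`` holds to better than 1e-9 relative.
    """
    f_arr = np.atleast_1d(np.asarray(force, dtype=float))
    if np.any(f_arr < 0):
        raise ValueError("force must be non-negative")
    lc = params.contour_length
    out = np.empty_like(f_arr)
    for i, f in enumerate(f_arr):
        if f == 0.0:
            out[i] = 0.0
            continue
        hi = lc * (1.0 - 1e-14)
        out[i] = brentq(
            lambda x: wlc_force(x, params) - f, 0.0, hi, xtol=1e-13, rtol=1e-15, maxiter=200
        )
    return out if np.ndim(force) else float(out[0])


@dataclass(frozen=True)
class WLCFit:
    """Result of a least-squares WLC fit to a force ramp."""

    params: WLCParams
    residual_rms: float  # pN
    converged: bool
    persistence_length_fitted: bool


def fit_wlc(
    extension,
    force,
    temperature: float,
    persistence_length: float | None = DEFAULT_PERSISTENCE_LENGTH_NM,
) -> WLCFit:
    """Fit the WLC relation to an extension/force ramp.

    Parameters
    ----------
    extension, force : array-like
        Tether extension (nm) and tension magnitude (pN) of the pre-rupture
        ramp.
    temperature : float, K
    persistence_length : float or None
        Fix Lp at this value (default 0.1 nm) and fit only Lc, or pass
        ``None`` to fit both.

    Returns
    -------
    WLCFit
        Fitted parameters, residual RMS (pN) and a convergence flag.  A large
        residual signals model mismatch (e.g. a Hookean, non-tether ramp);
        the fit is flagged, not rejected, because real tether ramps deviate
        systematically from the ideal WLC.
    """
    x = np.asarray(extension, dtype=float)
    f = np.asarray(force, dtype=float)
    if x.size != f.size:
        raise ValueError("extension and force must have the same length")
    if x.size < 10:
        raise ValueError("need at least 10 points for a WLC fit")
    x_max = float(np.max(x))
    if x_max <= 0 or (np.max(x) - np.min(x)) < 0.3 * x_max:
        raise ValueError("segment must span at least 30% of the apparent contour length")

    def model_lc(xv, lc):
        p = WLCParams(persistence_length, lc, temperature)
        return wlc_force(np.clip(xv, 0.0, lc * (1 - 1e-9)), p)

    def model_lc_lp(xv, lc, lp):
        p = WLCParams(lp, lc, temperature)
        return wlc_force(np.clip(xv, 0.0, lc * (1 - 1e-9)), p)

    lc0 = x_max * 1.1
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", OptimizeWarning)
            if persistence_length is not None:
                popt, _ = curve_fit(
                    model_lc, x, f, p0=[lc0],
                    bounds=([x_max * (1 + 1e-6)], [x_max * 20]), maxfev=2000,
                )
                params = WLCParams(persistence_length, float(popt[0]), temperature)
                lp_fitted = False
            else:
                popt, _ = curve_fit(
                    model_lc_lp, x, f, p0=[lc0, DEFAULT_PERSISTENCE_LENGTH_NM],
                    bounds=([x_max * (1 + 1e-6), 1e-3], [x_max * 20, 50.0]), maxfev=5000,
                )
                params = WLCParams(float(popt[1]), float(popt[0]), temperature)
                lp_fitted = True
        resid = f - wlc_force(np.clip(x, 0.0, params.contour_length * (1 - 1e-9)), params)
        rms = float(np.sqrt(np.mean(resid**2)))
        return WLCFit(params=params, residual_rms=rms, converged=True,
                      persistence_length_fitted=lp_fitted)
    except RuntimeError:
        fallback = WLCParams(
            persistence_length if persistence_length is not None else DEFAULT_PERSISTENCE_LENGTH_NM,
            lc0,
            temperature,
        )
        return WLCFit(params=fallback, residual_rms=float("inf"), converged=False,
                      persistence_length_fitted=persistence_length is None)
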