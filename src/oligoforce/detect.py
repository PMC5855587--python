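"""Rupture-event detection and curve classification.

A retract curve is processed in three steps:

1. **Baseline and contact point.**  A linear baseline (offset + drift slope)
   is anchored on the final 20% of the retract trace, refined on the full
   far-from-surface region with event samples masked out, and the contact
   point is the position where the smoothed force crosses the baseline coming
   down from the repulsive contact wall.  The tether-extension axis is zeroed
   there: ``extension = (piezo - contact) - |force| / k``, subtracting the
   cantilever's own bending from the piezo travel.
2. **Rupture candidates.**  Local maxima of the (smoothed) adhesion force
   followed by a step of at least ``min_force`` back to within twice the
   noise of baseline.  Forces are read from the unsmoothed data at the
   located index so that smoothing cannot attenuate rupture heights.
3. **Acceptance window.**  Only events whose rupture extension falls inside
   the tether window (default 15-60 nm, the plausible extension range of a
   PEG spacer of MW ~4000 allowing for MW heterogeneity) are accepted as
   specific.  Adhesion confined below the window marks the curve nonspecific:
   near-contact adhesion artefacts are excluded by position, not by
   discarding the curve.  Steps smaller than ~10 pN are below the detection
   floor and are never counted as events.

Plateau (polymer peeling) curves are recognised separately as a long
constant-force segment ending in a terminal detachment step.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import savgol_filter

from oligoforce.curves import ForceCurve
from oligoforce.wlc import fit_wlc

__all__ = [
    "Baseline",
    "RuptureEvent",
    "PlateauSegment",
    "CurveClassification",
    "estimate_baseline_and_contact",
    "detect_ruptures",
    "detect_plateau",
    "classify_curve",
]

#: Detection floor (pN): tether tension below this escapes detection.
DEFAULT_MIN_FORCE_PN = 10.0

#: Acceptance window for specific (tether-mediated) events, nm of extension.
DEFAULT_WINDOW_NM = (15.0, 60.0)

#: Savitzky-Golay smoothing used only for peak localisation.
SMOOTH_WINDOW = 11
SMOOTH_POLYORDER = 2


@dataclass(frozen=True)
class Baseline:
    """Linear force baseline of a retract trace."""

    offset: float  # pN at piezo position 0
    slope: float  # pN per nm of piezo travel
    noise_sd: float  # pN, robust estimate from baseline residuals
    drift_warning: bool = False

    def at(self, z) -> np.ndarray:
        return self.offset + self.slope * np.asarray(z, dtype=float)


@dataclass(frozen=True)
class RuptureEvent:
    """One detected unbinding event."""

    curve_id: str
    rupture_force: float  # pN, magnitude above baseline
    rupture_extension: float  # nm, tether extension at rupture
    step_height: float  # pN, drop across the rupture
    wlc_contour_length: Optional[float] = None  # nm
    wlc_residual: Optional[float] = None  # pN RMS

    def __post_init__(self) -> None:
        if not self.rupture_force > 0:
            raise ValueError("rupture_force must be positive")
        if self.rupture_extension < 0:
            raise ValueError("rupture_extension must be non-negative")


@dataclass(frozen=True)
class PlateauSegment:
    """Constant-force (peeling) segment on the extension axis."""

    start: float  # nm
    end: float  # nm
    mean_force: float  # pN, magnitude above baseline

    @property
    def length(self) -> float:
        return self.end - self.start


@dataclass(frozen=True)
class CurveClassification:
    """Curve taxonomy: no_adhesion, nonspecific, specific or plateau."""

    curve_id: str
    curve_class: str
    accepted_events: tuple[RuptureEvent, ...] = ()
    rejected_events: tuple[RuptureEvent, ...] = ()
    plateau: Optional[PlateauSegment] = None
    contact_point: Optional[float] = None

    def __post_init__(self) -> None:
        if self.curve_class not in {"no_adhesion", "nonspecific", "specific", "plateau"}:
            raise ValueError(f"unknown class {self.curve_class!r}")
        if self.curve_class == "specific" and not self.accepted_events:
            raise ValueError("specific classification requires >= 1 accepted event")
        if self.curve_class == "plateau" and self.plateau is None:
            raise ValueError("plateau classification requires a plateau segment")

    @property
    def headline_event(self) -> Optional[RuptureEvent]:
        """The curve's unbinding force: the final rupture (largest extension).

        Under the single-tether interpretation the last rupture in the window
        is the tether detaching; ties on extension resolve to the larger
        force.
        """
        if not self.accepted_events:
            return None
        return max(self.accepted_events,
                   key=lambda e: (e.rupture_extension, e.rupture_force))


def _smooth(values: np.ndarray) -> np.ndarray:
    if values.size < SMOOTH_WINDOW:
        return values.copy()
    return savgol_filter(values, SMOOTH_WINDOW, SMOOTH_POLYORDER)


def _robust_sd(residuals: np.ndarray) -> float:
    mad = np.median(np.abs(residuals - np.median(residuals)))
    return float(1.4826 * mad)


def estimate_baseline_and_contact(
    curve: ForceCurve,
    baseline_fraction: float = 0.2,
) -> tuple[Baseline, Optional[float]]:
    """Estimate the force baseline and the contact point of a retract trace.

    The baseline is first fitted on the final ``baseline_fraction`` of the
    trace (farthest from the surface), then refined on all samples beyond a
    quarter of the span with >3-sigma outliers (events) masked, which
    stabilises the drift-slope estimate.  The contact point is the first
    downward crossing of the baseline by the smoothed force coming from the
    repulsive wall; ``None`` when no contact (no repulsive region) is found.
    """
    c = curve.retract_sorted()
    z = c.piezo_retract
    force = c.force_retract_pn()
    n = z.size
    if n < 50:
        raise ValueError(f"curve {curve.curve_id!r}: retract segment too short")

    tail = slice(int(n * (1.0 - baseline_fraction)), n)
    coeffs = np.polyfit(z[tail], force[tail], 1)
    noise = _robust_sd(force[tail] - np.polyval(coeffs, z[tail]))
    if noise == 0.0:
        noise = float(np.std(force[tail] - np.polyval(coeffs, z[tail])))

    # refine on the far region, masking event samples
    z_lo = z[0] + 0.10 * (z[-1] - z[0])
    far = z >= z_lo
    resid = force - np.polyval(coeffs, z)
    keep = far & (np.abs(resid) <= 3.0 * max(noise, 1e-12))
    if np.count_nonzero(keep) >= 10:
        coeffs = np.polyfit(z[keep], force[keep], 1)
    slope, offset = float(coeffs[0]), float(coeffs[1])

    drift_per_100nm = abs(slope) * 100.0
    baseline = Baseline(
        offset=offset, slope=slope, noise_sd=max(noise, 1e-12),
        drift_warning=bool(drift_per_100nm > 2.0 * noise),
    )
    if baseline.drift_warning:
        warnings.warn(
            f"curve {curve.curve_id!r}: baseline drift {drift_per_100nm:.2f} pN/100nm "
            f"exceeds 2x noise ({noise:.2f} pN); curve still processed",
            stacklevel=2,
        )

    corrected = force - baseline.at(z)
    smoothed = _smooth(corrected)
    wall_threshold = max(5.0 * baseline.noise_sd, 5.0)
    above = np.flatnonzero(smoothed >= wall_threshold)
    contact: Optional[float] = None
    if above.size:
        # the contact wall is the first above-threshold run at the start of
        # the trace; later excursions (smoothing overshoot at rupture steps)
        # must not be mistaken for it
        run_breaks = np.flatnonzero(np.diff(above) > 1)
        last_wall = above[run_breaks[0]] if run_breaks.size else above[-1]
        below = np.flatnonzero(smoothed[last_wall:] <= 0.0)
        if below.size:
            j = last_wall + below[0]
            # linear interpolation of the zero crossing
            if j > 0 and smoothed[j - 1] > smoothed[j]:
                frac = smoothed[j - 1] / (smoothed[j - 1] - smoothed[j])
                contact = float(z[j - 1] + frac * (z[j] - z[j - 1]))
            else:
                contact = float(z[j])
    return baseline, contact


def detect_ruptures(
    curve: ForceCurve,
    baseline: Baseline,
    contact: Optional[float],
    min_force: float = DEFAULT_MIN_FORCE_PN,
    window: tuple[float, float] = DEFAULT_WINDOW_NM,
    validate_wlc: bool = True,
) -> tuple[list[RuptureEvent], CurveClassification]:
    """Detect rupture candidates and classify the curve.

    Candidates are local maxima of the adhesion force (magnitude above
    baseline) followed by a step of at least ``min_force`` returning to
    within twice the noise of baseline.  Events inside the extension
    ``window`` are accepted (specific); adhesion confined outside it marks
    the curve nonspecific; no candidates at all means no adhesion.
    """
    c = curve.retract_sorted()
    z = c.piezo_retract
    force = c.force_retract_pn()
    k_pn = c.spring_constant_pn_per_nm
    if contact is None:
        cls = CurveClassification(curve_id=curve.curve_id, curve_class="no_adhesion",
                                  contact_point=None)
        return [], cls

    adhesion = -(force - baseline.at(z))  # positive = adhesive
    post = z > contact
    a = adhesion[post]
    zp = z[post]
    if a.size < SMOOTH_WINDOW + 2:
        cls = CurveClassification(curve_id=curve.curve_id, curve_class="no_adhesion",
                                  contact_point=contact)
        return [], cls
    sm = _smooth(a)
    noise = baseline.noise_sd
    release_level = 2.0 * noise

    events: list[RuptureEvent] = []
    n = sm.size
    # scan contiguous regions where the smoothed adhesion exceeds the floor,
    # tracking each until it releases back to within 2x noise of baseline
    above = sm >= min_force
    idx = 0
    while idx < n:
        if not above[idx]:
            idx += 1
            continue
        start = idx
        while idx < n and sm[idx] > release_level:
            idx += 1
        end = idx  # first index back at baseline (or n)
        returned = end < n  # trace actually came back to baseline
        if returned and end - start >= 2:
            # the rupture is the largest single-sample force drop in the
            # region; reading the unsmoothed sample just before it avoids
            # both smoothing attenuation and max-of-noise selection bias
            hi = min(end + 1, n)
            drops = np.diff(a[start:hi])
            i_step = start + int(np.argmin(drops))
            peak_force = float(a[i_step])
            after_level = float(sm[end])
            step = peak_force - after_level
            if step >= min_force and peak_force >= min_force:
                extension = float((zp[i_step] - contact) - peak_force / k_pn)
                if extension < 0:
                    extension = 0.0
                events.append(
                    RuptureEvent(curve_id=curve.curve_id, rupture_force=peak_force,
                                 rupture_extension=extension, step_height=float(step))
                )
        idx = end + 1

    lo_w, hi_w = window
    accepted = [e for e in events if lo_w <= e.rupture_extension <= hi_w]
    rejected = [e for e in events if not (lo_w <= e.rupture_extension <= hi_w)]

    if validate_wlc and accepted:
        accepted = [_with_wlc_fit(e, zp, a, contact, k_pn, c.temperature) for e in accepted]

    if accepted:
        curve_class = "specific"
    elif events:
        curve_class = "nonspecific"
    else:
        curve_class = "no_adhesion"
    cls = CurveClassification(
        curve_id=curve.curve_id, curve_class=curve_class,
        accepted_events=tuple(accepted), rejected_events=tuple(rejected),
        contact_point=contact,
    )
    return events, cls


def _with_wlc_fit(event: RuptureEvent, zp: np.ndarray, adhesion: np.ndarray,
                  contact: float, k_pn: float, temperature: float) -> RuptureEvent:
    """Attach a WLC plausibility fit to an accepted event (never rejects)."""
    extension = (zp - contact) - np.clip(adhesion, 0.0, None) / k_pn
    # ramp: samples before the rupture with meaningful tension
    x_rupture = event.rupture_extension
    mask = (extension >= 0) & (extension <= x_rupture) & (adhesion > 2.0)
    if np.count_nonzero(mask) < 10:
        return event
    x_seg = extension[mask]
    f_seg = adhesion[mask]
    try:
        fit = fit_wlc(x_seg, f_seg, temperature)
    except ValueError:
        return event
    if not fit.converged:
        return event
    return RuptureEvent(
        curve_id=event.curve_id, rupture_force=event.rupture_force,
        rupture_extension=event.rupture_extension, step_height=event.step_height,
        wlc_contour_length=fit.params.contour_length, wlc_residual=fit.residual_rms,
    )


def detect_plateau(
    curve: ForceCurve,
    baseline: Baseline,
    contact: Optional[float] = None,
    min_force: float = DEFAULT_MIN_FORCE_PN,
    min_length: float = 20.0,
) -> Optional[PlateauSegment]:
    """Find the longest constant-force (peeling) segment, if any.

    A plateau is a contiguous stretch of at least ``min_length`` nm whose
    smoothed adhesion stays at least ``min_force`` above baseline and within
    twice the noise of its own mean, terminated by a step back to baseline.
    A WLC ramp fails the flatness test; a bare baseline fails the force
    threshold.
    """
    c = curve.retract_sorted()
    z = c.piezo_retract
    force = c.force_retract_pn()
    k_pn = c.spring_constant_pn_per_nm
    if contact is None:
        _, contact = estimate_baseline_and_contact(curve)
        if contact is None:
            return None
    adhesion = -(force - baseline.at(z))
    post = z > contact
    a = adhesion[post]
    zp = z[post]
    if a.size < SMOOTH_WINDOW + 2:
        return None
    sm = _smooth(a)
    noise = baseline.noise_sd
    tol = max(2.0 * noise, 1e-9)

    above = sm >= min_force
    best: Optional[PlateauSegment] = None
    idx = 0
    n = sm.size
    while idx < n:
        if not above[idx]:
            idx += 1
            continue
        start = idx
        while idx < n and above[idx]:
            idx += 1
        end = idx
        # trim smoothing-boundary samples at both ends of the run
        trim = SMOOTH_WINDOW // 2
        s, e = start + trim, end - trim
        if e - s < 2:
            continue
        seg = sm[s:e]
        mean_sm = float(np.mean(seg))
        if np.max(np.abs(seg - mean_sm)) > tol:
            continue
        # terminal step back to baseline
        after = sm[end:end + SMOOTH_WINDOW]
        if after.size and float(np.min(after)) > 2.0 * noise:
            continue
        mean_force = float(np.mean(a[s:e]))
        x_start = float((zp[s] - contact) - mean_force / k_pn)
        x_end = float((zp[e - 1] - contact) - mean_force / k_pn)
        if x_end - x_start < min_length:
            continue
        if best is None or (x_end - x_start) > best.length:
            best = PlateauSegment(start=max(x_start, 0.0), end=x_end, mean_force=mean_force)
    return best


def classify_curve(
    curve: ForceCurve,
    min_force: float = DEFAULT_MIN_FORCE_PN,
    window: tuple[float, float] = DEFAULT_WINDOW_NM,
    validate_wlc: bool = True,
) -> CurveClassification:
    """Full per-curve pipeline: baseline, contact, plateau, ruptures, class.

    Plateau detection takes precedence: a curve with a qualifying peeling
    segment is classed ``plateau`` even though its terminal detachment step
    would otherwise register as a rupture candidate.
    """
    baseline, contact = estimate_baseline_and_contact(curve)
    if contact is None:
        return CurveClassification(curve_id=curve.curve_id, curve_class="no_adhesion",
                                   contact_point=None)
    plateau = detect_plateau(curve, baseline, contact, min_force=min_force)
    if plateau is not None:
        return CurveClassification(curve_id=curve.curve_id, curve_class="plateau",
                                   plateau=plateau, contact_point=contact)
    _, cls = detect_ruptures(curve, baseline, contact, min_force=min_force,
                             window=window, validate_wlc=validate_wlc)
    return cls
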