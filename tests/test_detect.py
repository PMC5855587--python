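"""Event detection: baseline/contact, ruptures, plateaus, classification."""

import dataclasses

import numpy as np
import pytest

from oligoforce.curves import ForceCurve
from oligoforce.detect import (
    classify_curve,
    detect_plateau,
    detect_ruptures,
    estimate_baseline_and_contact,
)
from oligoforce.simulate import (
    PlateauModel,
    RuptureForceModel,
    SimulationConfig,
    simulate_retract_curve,
)


def flat_curve(noise_sd=5.0, with_wall=True, drift=0.0, seed=0, n=1500):
    """Hand-built baseline curve, optionally without a contact wall."""
    rng = np.random.default_rng(seed)
    z = np.linspace(-15.0 if with_wall else 5.0, 735.0, n)
    force = np.where(z < 0, -z * 30.0, 0.0) + drift * z / 1000.0 + rng.normal(0, noise_sd, n)
    k = 0.02
    return ForceCurve(
        curve_id="flat", piezo_approach=z[::-1].copy(),
        deflection_approach=(force / (k * 1000))[::-1].copy(),
        piezo_retract=z, deflection_retract=force / (k * 1000),
        spring_constant=k, pulling_speed=5.0, temperature=298.0,
    )


@pytest.mark.parametrize("index", [0, 3, 5, 11])
def test_contact_point_within_2nm_of_truth(index):
    """The generator places contact at piezo = 0."""
    config = dataclasses.replace(SimulationConfig(), p_specific=0.5, p_nonspecific=0.25)
    curve, _ = simulate_retract_curve(config, index)
    _, contact = estimate_baseline_and_contact(curve)
    assert contact is not None
    assert abs(contact) <= 2.0


def test_pure_noise_curve_has_no_contact_and_no_adhesion():
    curve = flat_curve(with_wall=False)
    baseline, contact = estimate_baseline_and_contact(curve)
    assert abs(baseline.offset) < 2.0
    assert contact is None
    assert classify_curve(curve).curve_class == "no_adhesion"


def test_drift_slope_recovered_within_20_percent():
    """5 pN/um of baseline drift is recovered (mean over simulated curves)."""
    slopes = [estimate_baseline_and_contact(flat_curve(drift=5.0, seed=s))[0].slope * 1000.0
              for s in range(8)]
    assert np.mean(slopes) == pytest.approx(5.0, rel=0.2)


def test_strong_drift_raises_warning_but_processes():
    with pytest.warns(UserWarning, match="drift"):
        baseline, contact = estimate_baseline_and_contact(flat_curve(drift=150.0, seed=2))
    assert contact is not None


@pytest.mark.parametrize("index", [1, 3, 4, 8, 9])
def test_specific_event_force_and_extension_recovered(index):
    config = dataclasses.replace(SimulationConfig(), p_specific=1.0, p_nonspecific=0.0)
    curve, label = simulate_retract_curve(config, index)
    cls = classify_curve(curve)
    assert cls.curve_class == "specific"
    event = cls.headline_event
    assert event.rupture_force == pytest.approx(label.true_rupture_force,
                                                abs=2 * config.noise_sd)
    assert event.rupture_extension == pytest.approx(label.true_rupture_extension, abs=3.0)


def test_near_contact_rupture_classified_nonspecific():
    """Adhesion releasing below 15 nm extension is excluded by position."""
    config = dataclasses.replace(SimulationConfig(), p_specific=0.0, p_nonspecific=1.0)
    for index in range(4):
        curve, _ = simulate_retract_curve(config, index)
        cls = classify_curve(curve)
        assert cls.curve_class == "nonspecific"
        assert not cls.accepted_events


def test_8pN_rupture_below_detection_floor():
    """Tether tension below ~10 pN escapes detection entirely."""
    config = dataclasses.replace(
        SimulationConfig(), p_specific=1.0, p_nonspecific=0.0,
        rupture_force_model=RuptureForceModel(means=(8.0,), sigmas=(0.0,), weights=(1.0,)),
    )
    for index in range(4):
        curve, _ = simulate_retract_curve(config, index)
        cls = classify_curve(curve)
        assert not cls.accepted_events
        assert cls.curve_class != "specific"


def test_wlc_validation_attached_to_accepted_events():
    config = dataclasses.replace(SimulationConfig(), p_specific=1.0, p_nonspecific=0.0,
                                 noise_sd=2.0)
    curve, label = simulate_retract_curve(config, 3)
    cls = classify_curve(curve)
    event = cls.headline_event
    assert event.wlc_contour_length is not None
    # the fit uses the effective Lp = 0.1 nm convention, so the apparent
    # contour length differs from the generator tether's; it must still be
    # a plausible tether length beyond the rupture extension
    assert event.wlc_contour_length > event.rupture_extension


def plateau_config(force=55.0, detach=80.0, noise=5.0):
    return dataclasses.replace(
        SimulationConfig(), p_specific=0.0, p_nonspecific=0.0, p_plateau=1.0,
        noise_sd=noise,
        plateau_model=PlateauModel(force_mean=force, force_sd=0.0,
                                   detach_mean=detach, detach_sd=0.0),
    )


def test_plateau_detected_with_mean_within_2pN():
    """A 55 pN plateau out to 80 nm is found with its force recovered."""
    curve, label = simulate_retract_curve(plateau_config(), 1)
    baseline, contact = estimate_baseline_and_contact(curve)
    plateau = detect_plateau(curve, baseline, contact)
    assert plateau is not None
    assert plateau.mean_force == pytest.approx(55.0, abs=2.0)
    assert plateau.length >= 40.0
    assert classify_curve(curve).curve_class == "plateau"


def test_wlc_ramp_is_not_a_plateau():
    config = dataclasses.replace(SimulationConfig(), p_specific=1.0, p_nonspecific=0.0)
    curve, _ = simulate_retract_curve(config, 3)
    baseline, contact = estimate_baseline_and_contact(curve)
    assert detect_plateau(curve, baseline, contact) is None


def test_zero_force_curve_has_no_plateau():
    curve = flat_curve()
    baseline, contact = estimate_baseline_and_contact(curve)
    assert detect_plateau(curve, baseline, contact) is None


def test_multiple_candidates_headline_is_final_rupture():
    """With several accepted events the reported force is the last rupture."""
    from oligoforce.detect import CurveClassification, RuptureEvent

    events = (
        RuptureEvent("c", rupture_force=80.0, rupture_extension=20.0, step_height=80.0),
        RuptureEvent("c", rupture_force=55.0, rupture_extension=40.0, step_height=55.0),
    )
    cls = CurveClassification("c", "specific", accepted_events=events)
    assert cls.headline_event.rupture_extension == 40.0
    assert cls.headline_event.rupture_force == 55.0


def test_window_filter_is_exact(default_classifications):
    """No accepted event ever lies outside the 15-60 nm window."""
    for cls in default_classifications:
        for event in cls.accepted_events:
            assert 15.0 <= event.rupture_extension <= 60.0


def test_sensitivity_fpr_and_bias_on_labelled_ensemble(
    default_ensemble, default_classifications
):
    """Detection quality on 1000 labelled curves at default noise."""
    _, _, labels = default_ensemble
    pairs = list(zip(labels, default_classifications))
    strong = [(l, d) for l, d in pairs
              if l.true_class == "specific" and l.true_rupture_force >= 30.0]
    sensitivity = np.mean([d.curve_class == "specific" for _, d in strong])
    assert sensitivity >= 0.95

    negatives = [(l, d) for l, d in pairs if l.true_class != "specific"]
    fpr = np.mean([d.curve_class == "specific" for _, d in negatives])
    assert fpr <= 0.02

    errors = [d.headline_event.rupture_force - l.true_rupture_force
              for l, d in strong if d.curve_class == "specific"]
    assert abs(np.mean(errors)) <= 1.0
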