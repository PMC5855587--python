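"""Synthetic-curve generator: forward-model exactness, labels, determinism."""

import dataclasses

import numpy as np
import pytest
from scipy import stats as sps

from oligoforce.curves import read_curve
from oligoforce.simulate import (
    ConfigError,
    PlateauModel,
    RuptureForceModel,
    SimulationConfig,
    simulate_ensemble,
    simulate_retract_curve,
    write_ensemble,
)
from oligoforce.wlc import wlc_force


def noiseless_specific_config(**overrides):
    base = dict(p_specific=1.0, p_nonspecific=0.0, noise_sd=0.0,
                contour_length_jitter=0.0, baseline_drift=0.0)
    base.update(overrides)
    return dataclasses.replace(SimulationConfig(), **base)


def test_noiseless_ramp_matches_wlc_pointwise():
    """With zero noise the generator is an exact forward model of the WLC."""
    config = noiseless_specific_config()
    curve, label = simulate_retract_curve(config, 3)
    force = curve.force_retract_pn()
    z = curve.piezo_retract
    adhesion = -force
    k = curve.spring_constant_pn_per_nm
    in_ramp = (z > 0.5) & (adhesion > 0.5)
    x = z[in_ramp] - adhesion[in_ramp] / k
    params = dataclasses.replace(config.tether, contour_length=label.true_contour_length)
    np.testing.assert_allclose(adhesion[in_ramp], wlc_force(x, params), rtol=1e-6, atol=1e-6)


def test_label_equals_signal_at_rupture():
    """The labelled rupture force is the maximum tether force before the step."""
    config = noiseless_specific_config()
    curve, label = simulate_retract_curve(config, 3)
    adhesion = -curve.force_retract_pn()
    assert np.max(adhesion) == pytest.approx(label.true_rupture_force, rel=1e-12)
    # instantaneous step: one sample at the peak, next sample at baseline
    i = int(np.argmax(adhesion))
    assert adhesion[i + 1] == pytest.approx(0.0, abs=1e-9)


def test_rupture_extension_label_consistent_with_wlc():
    config = noiseless_specific_config()
    curve, label = simulate_retract_curve(config, 5)
    params = dataclasses.replace(config.tether, contour_length=label.true_contour_length)
    assert wlc_force(label.true_rupture_extension, params) == pytest.approx(
        label.true_rupture_force, rel=1e-9
    )


def test_all_no_adhesion_when_probabilities_zero():
    config = dataclasses.replace(SimulationConfig(), n_curves=50, p_specific=0.0,
                                 p_nonspecific=0.0, points_per_curve=200)
    _, labels, _ = simulate_ensemble(config)
    assert {l.true_class for l in labels} == {"no_adhesion"}


def test_specific_count_within_central_binomial_interval(default_ensemble):
    """n = 1000, p = 0.125: the specific count lies in the central 99% band."""
    config, _, labels = default_ensemble
    count = sum(1 for l in labels if l.true_class == "specific")
    lo = sps.binom.ppf(0.005, config.n_curves, config.p_specific)
    hi = sps.binom.ppf(0.995, config.n_curves, config.p_specific)
    assert lo <= count <= hi


def test_nonspecific_curves_release_below_window():
    config = dataclasses.replace(SimulationConfig(), n_curves=30, p_specific=0.0,
                                 p_nonspecific=1.0, noise_sd=0.0, points_per_curve=400)
    curves, labels, _ = simulate_ensemble(config)
    for curve in curves:
        adhesion = -curve.force_retract_pn()
        last = curve.piezo_retract[np.flatnonzero(adhesion > 1.0)[-1]]
        assert last < 15.0


def test_seed_repetition_is_byte_identical(tmp_path):
    config = dataclasses.replace(SimulationConfig(), n_curves=5, seed=77, points_per_curve=200)
    m1 = write_ensemble(config, tmp_path / "a")
    m2 = write_ensemble(config, tmp_path / "b")
    for e in [x["file"] for x in __import__("json").loads(m1.read_text())["curves"]]:
        assert (m1.parent / e).read_bytes() == (m2.parent / e).read_bytes()


def test_per_curve_substreams_reproducible():
    """Curve i is identical whether simulated alone or within the ensemble."""
    config = dataclasses.replace(SimulationConfig(), n_curves=8, seed=5, points_per_curve=200)
    curves, _, _ = simulate_ensemble(config)
    alone, _ = simulate_retract_curve(config, 6)
    assert alone == curves[6]


def test_mixture_reproduces_component_weights():
    """Rupture draws from a 70/110/140 pN mixture match the weights."""
    model = RuptureForceModel(means=(70.0, 110.0, 140.0), sigmas=(10.0,) * 3,
                              weights=(0.6, 0.25, 0.15))
    config = dataclasses.replace(
        SimulationConfig(), n_curves=400, p_specific=1.0, p_nonspecific=0.0,
        rupture_force_model=model, points_per_curve=200, curve_length_um=0.3, seed=21,
    )
    _, labels, _ = simulate_ensemble(config)
    forces = np.array([l.true_rupture_force for l in labels])
    edges = [90.0, 125.0]  # midpoints between the well-separated components
    counts = [np.sum(forces < edges[0]), np.sum((forces >= edges[0]) & (forces < edges[1])),
              np.sum(forces >= edges[1])]
    for count, w in zip(counts, model.weights):
        se = np.sqrt(400 * w * (1 - w))
        assert abs(count - 400 * w) <= 3.5 * se


def test_written_ensemble_reads_back(tmp_path):
    config = dataclasses.replace(SimulationConfig(), n_curves=3, points_per_curve=200)
    manifest = write_ensemble(config, tmp_path)
    curves, _, _ = simulate_ensemble(config)
    assert read_curve(tmp_path / "curve_00000.tsv") == curves[0]
    assert (tmp_path / "labels.tsv").exists() and manifest.exists()


@pytest.mark.parametrize(
    "overrides",
    [
        dict(p_specific=1.3),
        dict(p_specific=0.7, p_nonspecific=0.5),
        dict(n_curves=0),
        dict(noise_sd=-1.0),
        dict(p_plateau=0.5),  # plateau_model missing
    ],
)
def test_invalid_configs_rejected(overrides):
    with pytest.raises(ConfigError):
        dataclasses.replace(SimulationConfig(), **overrides)


def test_plateau_longer_than_curve_rejected():
    with pytest.raises(ConfigError, match="detach length"):
        dataclasses.replace(
            SimulationConfig(), p_plateau=0.5, p_specific=0.0, p_nonspecific=0.0,
            plateau_model=PlateauModel(detach_mean=900.0, detach_sd=50.0),
        )
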