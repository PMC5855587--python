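"""Histograms, MPF estimation, binding frequency, mode comparisons."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oligoforce.simulate import RuptureForceModel
from oligoforce.stats import (
    ForceHistogram,
    MPFResult,
    binding_frequency,
    build_histogram,
    compare_modes,
    fit_mpf,
    fit_multi_mpf,
)


def draw_forces(mean, sigma, n, seed):
    """Positive Gaussian rupture-force draws via the generator's model."""
    model = RuptureForceModel(means=(mean,), sigmas=(sigma,), weights=(1.0,))
    rng = np.random.default_rng(seed)
    return [model.sample(rng) for _ in range(n)]


# -- histograms ---------------------------------------------------------


def test_single_force_lands_in_its_bin():
    hist = build_histogram([55.0])
    assert hist.counts.sum() == 1
    i = int(np.argmax(hist.counts))
    assert (hist.bin_edges[i], hist.bin_edges[i + 1]) == (50.0, 60.0)


@given(forces=st.lists(st.floats(min_value=0.0, max_value=500.0), min_size=1, max_size=200),
       bin_width=st.floats(min_value=1.0, max_value=25.0))
def test_histogram_conserves_counts(forces, bin_width):
    hist = build_histogram(forces, bin_width=bin_width)
    assert int(hist.counts.sum()) == len(forces) == hist.n_events


def test_large_sample_modal_bin_contains_mean():
    forces = draw_forces(76.0, 10.0, 10_000, seed=1)
    hist = build_histogram(forces)
    i = int(np.argmax(hist.counts))
    assert hist.bin_edges[i] <= 76.0 < hist.bin_edges[i + 1]


def test_empty_input_rejected():
    with pytest.raises(ValueError):
        build_histogram([])


def test_inconsistent_histogram_rejected():
    with pytest.raises(ValueError):
        ForceHistogram(bin_edges=np.array([0.0, 10.0, 20.0]),
                       counts=np.array([1, 2]), n_events=5)


# -- single-peak MPF ----------------------------------------------------


def test_symmetric_three_bin_mode_is_center_midpoint():
    hist = ForceHistogram(bin_edges=np.array([0.0, 10, 20, 30.0]),
                          counts=np.array([1, 10, 1]), n_events=12)
    assert fit_mpf(hist).mode == pytest.approx(15.0, abs=1e-6)


def test_too_few_bins_advises_smaller_width():
    hist = build_histogram([55.0, 56.0, 57.0], bin_width=10.0)
    with pytest.raises(ValueError, match="bin width"):
        fit_mpf(hist)


@pytest.mark.parametrize("mean,sigma,n,tol", [(76.0, 10.0, 36, 4.0), (50.0, 18.0, 32, 6.0)])
def test_mpf_recovery_at_experimental_sample_sizes(mean, sigma, n, tol):
    """Local Gaussian fit recovers the generating mode at small n."""
    modes = []
    for k in range(20):
        rng_seed = int(np.random.SeedSequence(2024, spawn_key=(k,)).generate_state(1)[0] % 2**31)
        forces = draw_forces(mean, sigma, n, seed=rng_seed)
        modes.append(fit_mpf(build_histogram(forces)).mode)
    assert float(np.median(modes)) == pytest.approx(mean, abs=tol)


def test_mpf_estimator_approximately_unbiased():
    """Over 200 replicates (n = 36, sigma = 10) the mean fitted mode is true."""
    modes = []
    for k in range(200):
        forces = draw_forces(76.0, 10.0, 36, seed=10_000 + k)
        modes.append(fit_mpf(build_histogram(forces)).mode)
    assert abs(np.mean(modes) - 76.0) <= 1.0


# -- multi-peak ---------------------------------------------------------


def test_mixture_modes_recovered():
    """Three-component mixture (70/110/140 pN) decomposed within 5 pN."""
    rng = np.random.default_rng(3)
    comps = [(70.0, 0.6), (110.0, 0.25), (140.0, 0.15)]
    forces = np.concatenate([rng.normal(m, 10.0, int(500 * w)) for m, w in comps])
    hist = build_histogram(forces.clip(min=0.1))
    results = fit_multi_mpf(hist, 3)
    assert len(results) == 3
    for result, (mean, _) in zip(results, comps):
        assert result.mode == pytest.approx(mean, abs=5.0)


def test_single_component_equals_fit_mpf():
    hist = build_histogram(draw_forces(76.0, 10.0, 200, seed=5))
    assert fit_multi_mpf(hist, 1)[0] == fit_mpf(hist)


def test_degenerate_components_merge_with_warning():
    """Asking for two components of a single Gaussian merges them back."""
    hist = build_histogram(draw_forces(76.0, 10.0, 300, seed=6))
    with pytest.warns(UserWarning, match="degenerate"):
        results = fit_multi_mpf(hist, 2)
    assert len(results) == 1
    assert results[0].mode == pytest.approx(fit_mpf(hist).mode)


# -- binding frequency --------------------------------------------------


def test_zero_specific_wilson_upper_bound():
    freq = binding_frequency(n_specific=0, n_total=500)
    assert freq.fraction == 0.0
    assert freq.ci_low == pytest.approx(0.0, abs=1e-12)
    assert freq.ci_high == pytest.approx(0.0077, abs=2e-4)


def test_penta_gly_like_frequency():
    freq = binding_frequency(n_specific=125, n_total=1000)
    assert freq.fraction == pytest.approx(0.125)
    assert 0.10 <= freq.fraction <= 0.15  # the band reported for penta-Gly


def test_all_specific():
    freq = binding_frequency(n_specific=20, n_total=20)
    assert freq.fraction == 1.0
    assert freq.ci_high == pytest.approx(1.0)


def test_frequency_from_classification_objects(default_classifications):
    freq = binding_frequency(default_classifications)
    counted = sum(1 for c in default_classifications if c.curve_class == "specific")
    assert freq.n_specific == counted
    assert freq.n_total == len(default_classifications)


# -- mode comparisons ---------------------------------------------------


def mpf(mode, sigma, n):
    return MPFResult(mode=mode, sigma=sigma, amplitude=1.0, n_events=n, fit_window=(0, 200))


@pytest.mark.parametrize(
    "m1,m2,conf,expected_half,reported",
    [
        (mpf(76, 10, 36), mpf(55, 11, 38), 0.95, 4.7857, (21, 5)),
        (mpf(76, 10, 36), mpf(50, 18, 32), 0.95, 7.0403, (26, 7)),
        (mpf(55, 11, 38), mpf(50, 18, 32), 0.80, 4.6753, (5, 5)),
    ],
)
def test_mode_difference_half_widths(m1, m2, conf, expected_half, reported):
    """z-intervals reproduce the reported +/-5, +/-7, +/-5 pN after rounding."""
    cmp_ = compare_modes(m1, m2, confidence=conf)
    assert cmp_.half_width == pytest.approx(expected_half, abs=1e-3)
    assert cmp_.rounded() == reported


def test_identical_inputs_zero_difference():
    cmp_ = compare_modes(mpf(55, 10, 30), mpf(55, 10, 30))
    assert cmp_.difference == 0.0
    assert not cmp_.significant


def test_single_event_sample_rejected():
    with pytest.raises(ValueError):
        compare_modes(mpf(55, 10, 1), mpf(50, 10, 30))


def test_half_width_matches_parametric_bootstrap():
    """Closed-form z half-width vs brute-force resampling of two mean
    estimates (1e5 replicates), within 5%."""
    n1, s1, n2, s2 = 36, 10.0, 32, 18.0
    rng = np.random.default_rng(8)
    diffs = (rng.normal(76.0, s1, (100_000, n1)).mean(axis=1)
             - rng.normal(50.0, s2, (100_000, n2)).mean(axis=1))
    lo, hi = np.quantile(diffs, [0.025, 0.975])
    boot_half = (hi - lo) / 2
    closed = compare_modes(mpf(76, s1, n1), mpf(50, s2, n2)).half_width
    assert closed == pytest.approx(boot_half, rel=0.05)
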