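"""Force-curve I/O: unit conventions, round trips, format errors."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, strategies as st

from oligoforce.curves import (
    CurveFormatError,
    CurveValidationError,
    ExperimentManifest,
    ForceCurve,
    read_curve,
    read_manifest,
    write_curve,
    write_manifest,
)
from oligoforce.simulate import SimulationConfig, simulate_retract_curve


def make_curve(n=100, curve_id="c1", k=0.02, seed=0):
    rng = np.random.default_rng(seed)
    z = np.linspace(-10.0, 100.0, n)
    return ForceCurve(
        curve_id=curve_id,
        piezo_approach=z[::-1].copy(),
        deflection_approach=rng.normal(0, 0.1, n),
        piezo_retract=z,
        deflection_retract=rng.normal(0, 0.1, n),
        spring_constant=k,
        pulling_speed=5.0,
        temperature=298.0,
        sample_label="di-Gly",
    )


def test_force_is_spring_constant_times_deflection():
    """k = 0.02 nN/nm and d = 2.5 nm give 50 pN at that sample."""
    c = make_curve()
    d = c.deflection_retract.copy()
    d[37] = 2.5
    c = dataclasses.replace(c, deflection_retract=d)
    assert c.force_retract_pn()[37] == pytest.approx(50.0)


def test_force_conversion_is_linear():
    c = make_curve(seed=3)
    scaled = dataclasses.replace(c, deflection_retract=3.0 * c.deflection_retract)
    np.testing.assert_allclose(scaled.force_retract_pn(), 3.0 * c.force_retract_pn())


@pytest.mark.parametrize("index", [0, 5])
def test_round_trip_identity_on_generator_curves(tmp_path, index):
    curve, _ = simulate_retract_curve(SimulationConfig(points_per_curve=300, seed=9), index)
    path = write_curve(curve, tmp_path / "c.tsv")
    assert read_curve(path) == curve


@given(
    n=st.integers(min_value=2, max_value=40),
    k=st.floats(min_value=1e-3, max_value=1.0),
    seed=st.integers(min_value=0, max_value=2**16),
)
def test_round_trip_identity_property(tmp_path_factory, n, k, seed):
    """read(write(c)) reproduces every field bit-identically."""
    curve = make_curve(n=n, k=k, seed=seed)
    path = write_curve(curve, tmp_path_factory.mktemp("rt") / "c.tsv")
    back = read_curve(path)
    assert back == curve
    np.testing.assert_array_equal(back.deflection_retract, curve.deflection_retract)


def test_large_curve_single_file(tmp_path):
    curve = make_curve(n=100_000)
    path = write_curve(curve, tmp_path / "big.tsv")
    assert read_curve(path).piezo_retract.size == 100_000


def test_missing_deflection_column_is_format_error(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text(
        "# curve_id=x\n# sample_label=s\n# spring_constant_nN_per_nm=0.02\n"
        "# pulling_speed_um_per_s=5\n# temperature_K=298\n"
        "segment\tposition_nm\nretract\t1.0\n"
    )
    with pytest.raises(CurveFormatError):
        read_curve(path)


def test_missing_metadata_is_format_error(tmp_path):
    path = tmp_path / "bad.tsv"
    path.write_text("# curve_id=x\nsegment\tposition_nm\tdeflection_nm\nretract\t1.0\t0.1\n")
    with pytest.raises(CurveFormatError, match="missing required metadata"):
        read_curve(path)


def test_empty_retract_segment_refused():
    with pytest.raises(CurveValidationError, match="empty retract"):
        make_curve(n=0)


def test_non_monotone_position_names_curve_id():
    with pytest.raises(CurveValidationError, match="zigzag"):
        ForceCurve(
            curve_id="zigzag",
            piezo_approach=np.array([]), deflection_approach=np.array([]),
            piezo_retract=np.array([0.0, 2.0, 1.0]),
            deflection_retract=np.zeros(3),
            spring_constant=0.02, pulling_speed=5.0, temperature=298.0,
        )


@pytest.mark.parametrize("field,value", [("spring_constant", -0.02), ("temperature", 0.0)])
def test_nonpositive_metadata_rejected(field, value):
    with pytest.raises(CurveValidationError):
        dataclasses.replace(make_curve(), **{field: value})


def test_manifest_round_trip_and_validation(tmp_path):
    c1, c2 = make_curve(curve_id="a"), make_curve(curve_id="b")
    write_curve(c1, tmp_path / "a.tsv")
    write_curve(c2, tmp_path / "b.tsv")
    manifest = ExperimentManifest(entries=[
        {"curve_id": "a", "file": "a.tsv"}, {"curve_id": "b", "file": "b.tsv"},
    ])
    path = write_manifest(manifest, tmp_path / "manifest.json")
    back = read_manifest(path)
    assert [e["curve_id"] for e in back.entries] == ["a", "b"]

    dup = ExperimentManifest(entries=[{"curve_id": "a", "file": "a.tsv"}] * 2)
    with pytest.raises(CurveValidationError, match="duplicate"):
        dup.validate(tmp_path)
    missing = ExperimentManifest(entries=[{"curve_id": "z", "file": "z.tsv"}])
    with pytest.raises(CurveValidationError, match="missing"):
        missing.validate(tmp_path)
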