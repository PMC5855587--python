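"""Force-curve I/O: the single source of axis and unit conventions.

A force curve is one approach/retract cycle of an AFM cantilever against the
surface.  Each segment records piezo position (nm; increasing values move the
tip away from the surface) and cantilever deflection (nm).  Force follows from
Hooke's law, ``F = k * d``; adhesion during retraction gives negative
deflection, and downstream stages report unbinding forces as positive
magnitudes.

On disk a curve is a single tab-separated text file with ``#``-prefixed
metadata header lines followed by three columns (segment, position_nm,
deflection_nm).  Floats are written with 17 significant digits so that a
write/read round trip is bit-identical.  A set of curves is tied together by a
JSON manifest.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np

from oligoforce.units import spring_constant_pn_per_nm

__all__ = [
    "CurveFormatError",
    "CurveValidationError",
    "ForceCurve",
    "read_curve",
    "write_curve",
    "read_manifest",
    "write_manifest",
]

_META_KEYS = {
    "curve_id": str,
    "sample_label": str,
    "spring_constant_nN_per_nm": float,
    "pulling_speed_um_per_s": float,
    "temperature_K": float,
}

_FLOAT_FMT = "%.17g"


class CurveFormatError(ValueError):
    """Raised when a curve file does not have the expected layout."""


class CurveValidationError(ValueError):
    """Raised when curve contents violate a physical invariant."""


def _as_float_array(values, name: str, curve_id: str) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 1:
        raise CurveValidationError(f"curve {curve_id!r}: {name} must be 1-D")
    if not np.all(np.isfinite(arr)):
        raise CurveValidationError(f"curve {curve_id!r}: non-finite values in {name}")
    return arr


def _check_monotone(position: np.ndarray, segment: str, curve_id: str) -> None:
    if position.size < 2:
        return
    diffs = np.diff(position)
    if not (np.all(diffs > 0) or np.all(diffs < 0)):
        raise CurveValidationError(
            f"curve {curve_id!r}: piezo position not strictly monotone in {segment} segment"
        )


@dataclass(frozen=True)
class ForceCurve:
    """One approach/retract cycle with acquisition metadata.

    Parameters
    ----------
    curve_id : str
        Unique identifier within an experiment.
    piezo_approach, deflection_approach : ndarray, nm
        Approach segment (piezo decreasing toward the surface).
    piezo_retract, deflection_retract : ndarray, nm
        Retract segment (piezo increasing away from the surface).
    spring_constant : float, nN/nm
        Cantilever spring constant; shared by both segments.
    pulling_speed : float, um/s
    temperature : float, K
    sample_label : str
        Molecular species on the tip (e.g. ``"penta-Gly"``).
    """

    curve_id: str
    piezo_approach: np.ndarray
    deflection_approach: np.ndarray
    piezo_retract: np.ndarray
    deflection_retract: np.ndarray
    spring_constant: float
    pulling_speed: float
    temperature: float
    sample_label: str = ""

    def __post_init__(self) -> None:
        for name in ("piezo_approach", "deflection_approach", "piezo_retract", "deflection_retract"):
            arr = _as_float_array(getattr(self, name), name, self.curve_id)
            object.__setattr__(self, name, arr)
        if self.piezo_retract.size == 0:
            raise CurveValidationError(f"curve {self.curve_id!r}: empty retract segment")
        if self.piezo_retract.size != self.deflection_retract.size:
            raise CurveValidationError(f"curve {self.curve_id!r}: retract column length mismatch")
        if self.piezo_approach.size != self.deflection_approach.size:
            raise CurveValidationError(f"curve {self.curve_id!r}: approach column length mismatch")
        _check_monotone(self.piezo_approach, "approach", self.curve_id)
        _check_monotone(self.piezo_retract, "retract", self.curve_id)
        if not self.spring_constant > 0:
            raise CurveValidationError(f"curve {self.curve_id!r}: spring_constant must be > 0")
        if not self.temperature > 0:
            raise CurveValidationError(f"curve {self.curve_id!r}: temperature must be > 0")

    @property
    def spring_constant_pn_per_nm(self) -> float:
        return spring_constant_pn_per_nm(self.spring_constant)

    def force_retract_pn(self) -> np.ndarray:
        """Signed tip force along the retract segment, pN (adhesion negative)."""
        return self.spring_constant_pn_per_nm * self.deflection_retract

    def force_approach_pn(self) -> np.ndarray:
        return self.spring_constant_pn_per_nm * self.deflection_approach

    def retract_sorted(self) -> "ForceCurve":
        """Return a copy whose retract segment has ascending piezo position."""
        if self.piezo_retract.size < 2 or self.piezo_retract[1] > self.piezo_retract[0]:
            return self
        return replace(
            self,
            piezo_retract=self.piezo_retract[::-1].copy(),
            deflection_retract=self.deflection_retract[::-1].copy(),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ForceCurve):
            return NotImplemented
        return (
            self.curve_id == other.curve_id
            and self.sample_label == other.sample_label
            and self.spring_constant == other.spring_constant
            and self.pulling_speed == other.pulling_speed
            and self.temperature == other.temperature
            and np.array_equal(self.piezo_approach, other.piezo_approach)
            and np.array_equal(self.deflection_approach, other.deflection_approach)
            and np.array_equal(self.piezo_retract, other.piezo_retract)
            and np.array_equal(self.deflection_retract, other.deflection_retract)
        )


def write_curve(curve: ForceCurve, path: str | Path) -> Path:
    """Write a curve as delimited text with a ``#`` metadata header.

    Column order and numeric formatting are deterministic; floats carry full
    double precision with a locale-independent decimal point.
    """
    path = Path(path)
    lines: list[str] = []
    meta = {
        "curve_id": curve.curve_id,
        "sample_label": curve.sample_label,
        "spring_constant_nN_per_nm": _FLOAT_FMT % curve.spring_constant,
        "pulling_speed_um_per_s": _FLOAT_FMT % curve.pulling_speed,
        "temperature_K": _FLOAT_FMT % curve.temperature,
    }
    for key, value in meta.items():
        lines.append(f"# {key}={value}")
    lines.append("segment\tposition_nm\tdeflection_nm")
    for segment, pos, defl in (
        ("approach", curve.piezo_approach, curve.deflection_approach),
        ("retract", curve.piezo_retract, curve.deflection_retract),
    ):
        for p, d in zip(pos, defl):
            lines.append(f"{segment}\t{_FLOAT_FMT % p}\t{_FLOAT_FMT % d}")
    path.write_text("\n".join(lines) + "\n")
    return path


def _parse_header(lines: Iterator[str], path: Path) -> dict:
    meta: dict[str, str] = {}
    for raw in lines:
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
            continue
        # first non-comment line must be the column header
        cols = line.split("\t")
        if cols != ["segment", "position_nm", "deflection_nm"]:
            missing = {"segment", "position_nm", "deflection_nm"} - set(cols)
            raise CurveFormatError(f"{path}: missing or misnamed columns {sorted(missing)}")
        break
    else:
        raise CurveFormatError(f"{path}: no column header found")
    for key, conv in _META_KEYS.items():
        if key not in meta:
            raise CurveFormatError(f"{path}: missing required metadata key {key!r}")
        if conv is float:
            try:
                meta[key] = float(meta[key])  # type: ignore[assignment]
            except ValueError as exc:
                raise CurveFormatError(f"{path}: metadata {key!r} is not numeric") from exc
    return meta


def read_curve(path: str | Path) -> ForceCurve:
    """Read a curve file written by :func:`write_curve`.

    Raises
    ------
    CurveFormatError
        If columns or required metadata are missing.
    CurveValidationError
        If the parsed curve violates an invariant (naming the curve_id).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    lines = iter(path.read_text().splitlines())
    meta = _parse_header(lines, path)
    seg_data: dict[str, list[tuple[float, float]]] = {"approach": [], "retract": []}
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise CurveFormatError(f"{path}: expected 3 columns, got {len(parts)}: {line!r}")
        segment, pos, defl = parts
        if segment not in seg_data:
            raise CurveFormatError(f"{path}: unknown segment {segment!r}")
        try:
            seg_data[segment].append((float(pos), float(defl)))
        except ValueError as exc:
            raise CurveFormatError(f"{path}: non-numeric row {line!r}") from exc
    def _cols(rows: list[tuple[float, float]]) -> tuple[np.ndarray, np.ndarray]:
        if not rows:
            return np.empty(0), np.empty(0)
        arr = np.array(rows, dtype=float)
        return arr[:, 0], arr[:, 1]
    pa, da = _cols(seg_data["approach"])
    pr, dr = _cols(seg_data["retract"])
    return ForceCurve(
        curve_id=str(meta["curve_id"]),
        piezo_approach=pa,
        deflection_approach=da,
        piezo_retract=pr,
        deflection_retract=dr,
        spring_constant=float(meta["spring_constant_nN_per_nm"]),
        pulling_speed=float(meta["pulling_speed_um_per_s"]),
        temperature=float(meta["temperature_K"]),
        sample_label=str(meta["sample_label"]),
    )


@dataclass
class ExperimentManifest:
    """List of curve files plus per-curve metadata for one experiment."""

    entries: list[dict] = field(default_factory=list)
    config: dict = field(default_factory=dict)

    def curve_paths(self, root: str | Path) -> list[Path]:
        return [Path(root) / e["file"] for e in self.entries]

    def validate(self, root: str | Path) -> None:
        ids = [e["curve_id"] for e in self.entries]
        if len(ids) != len(set(ids)):
            raise CurveValidationError("manifest: duplicate curve_ids")
        for p in self.curve_paths(root):
            if not p.exists():
                raise CurveValidationError(f"manifest: referenced curve file missing: {p}")


def write_manifest(manifest: ExperimentManifest, path: str | Path) -> Path:
    path = Path(path)
    payload = {"curves": manifest.entries, "config": manifest.config}
    path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return path


def read_manifest(path: str | Path, validate: bool = True) -> ExperimentManifest:
    path = Path(path)
    payload = json.loads(path.read_text())
    manifest = ExperimentManifest(entries=payload["curves"], config=payload.get("config", {}))
    if validate:
        manifest.validate(path.parent)
    return manifest
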