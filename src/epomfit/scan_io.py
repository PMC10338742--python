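"""Reading, writing, validating, averaging and resampling water-tank depth scans.

A depth scan is either a relative depth-value curve (percentage depth dose or
percentage depth ionization) or a set of raw per-depth electrometer readings
(two polarizing voltages plus both polarities) awaiting recombination and
polarity correction.

Two plain-text dialects are supported:

* two-column ASCII: ``depth_cm  value`` per line (whitespace separated);
* headered CSV with columns ``depth_cm,value`` (curve) or
  ``depth_cm,m_v1,m_v2,m_pos,m_neg`` plus a ``# v1=... v2=...`` comment line
  (raw readings).

All depths are water depths in centimetres.  This module applies no
density or water-equivalent scaling and never extrapolates measured data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy.interpolate import PchipInterpolator


class Quantity(str, Enum):
    """What a relative depth curve measures."""

    DOSE = "dose"
    IONIZATION = "ionization"


class ScanValidationError(ValueError):
    """A scan violates a structural invariant (ordering, length, finiteness)."""


class ScanParseError(ValueError):
    """A scan file could not be parsed; carries the offending line number."""


@dataclass(frozen=True)
class DepthValueCurve:
    """A depth-ordered series of relative detector values.

    Parameters
    ----------
    depths : array of water depths in cm, strictly increasing, length >= 4.
    values : relative readings (dimensionless), finite and non-negative.
    quantity : whether the curve is dose or ionization; operations that need
        one must reject the other.
    meta : free-form provenance (detector, energy label, serial, session id).
    """

    depths: np.ndarray
    values: np.ndarray
    quantity: Quantity
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        depths = np.asarray(self.depths, dtype=float)
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "depths", depths)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "quantity", Quantity(self.quantity))
        if depths.ndim != 1 or values.shape != depths.shape:
            raise ScanValidationError("depths and values must be 1-d and equal length")
        if depths.size < 4:
            raise ScanValidationError(f"curve needs >= 4 points, got {depths.size}")
        if not np.all(np.isfinite(depths)) or not np.all(np.isfinite(values)):
            raise ScanValidationError("depths and values must be finite")
        if np.any(np.diff(depths) <= 0):
            bad = int(np.argmax(np.diff(depths) <= 0))
            raise ScanValidationError(
                f"depths must be strictly increasing (violated after index {bad},"
                f" depth {depths[bad]:g} cm)"
            )
        if np.any(values < 0) or values.max() <= 0:
            raise ScanValidationError("values must be non-negative with a positive maximum")

    def require(self, quantity: Quantity) -> "DepthValueCurve":
        quantity = Quantity(quantity)
        if self.quantity is not quantity:
            raise ScanValidationError(
                f"operation requires a {quantity.value} curve, got {self.quantity.value}"
            )
        return self

    def normalized(self, to: float = 100.0) -> "DepthValueCurve":
        """Return the curve rescaled so its maximum equals ``to`` (default 100)."""
        return DepthValueCurve(
            self.depths, self.values * (to / self.values.max()), self.quantity, dict(self.meta)
        )

    @property
    def span(self) -> tuple[float, float]:
        return float(self.depths[0]), float(self.depths[-1])


@dataclass(frozen=True)
class RawDepthReadings:
    """Raw electrometer readings at one depth, before kS/kpol correction.

    ``m_v1``/``m_v2`` are readings at polarizing voltages ``v1 > v2 > 0``;
    ``m_pos``/``m_neg`` are readings at positive and negative polarity.
    """

    depth: float
    m_v1: float
    m_v2: float
    m_pos: float
    m_neg: float
    v1: float
    v2: float

    def __post_init__(self) -> None:
        if not (self.v1 > self.v2 > 0):
            raise ScanValidationError(f"need v1 > v2 > 0, got v1={self.v1}, v2={self.v2}")
        for name in ("m_v1", "m_v2", "m_pos", "m_neg"):
            if getattr(self, name) == 0 or not np.isfinite(getattr(self, name)):
                raise ScanValidationError(f"reading {name} must be nonzero and finite")


_RAW_COLUMNS = ["depth_cm", "m_v1", "m_v2", "m_pos", "m_neg"]


def read_scan(
    path: str | Path, dialect: str | None = None, quantity: Quantity = Quantity.IONIZATION
) -> DepthValueCurve | list[RawDepthReadings]:
    """Read a depth scan from ``path``.

    ``dialect`` is ``"ascii"`` (two-column), ``"csv"`` (headered), or ``None``
    to sniff from the first non-comment line.  Curve files yield a
    :class:`DepthValueCurve` with the given ``quantity``; raw-reading CSVs
    yield a list of :class:`RawDepthReadings`.  A JSON sidecar
    ``<path>.meta.json``, when present, populates curve metadata.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    v1 = v2 = None
    body: list[tuple[int, str]] = []
    for i, line in enumerate(lines, start=1):
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            for tok in stripped.lstrip("#").split():
                if tok.startswith("v1="):
                    v1 = float(tok[3:])
                elif tok.startswith("v2="):
                    v2 = float(tok[3:])
            continue
        body.append((i, stripped))
    if not body:
        raise ScanParseError(f"{path}: empty scan file")

    if dialect is None:
        first = body[0][1]
        dialect = "csv" if any(c.isalpha() for c in first) or "," in first else "ascii"

    if dialect == "ascii":
        rows = []
        for lineno, line in body:
            parts = line.split()
            if len(parts) != 2:
                raise ScanParseError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            try:
                rows.append((float(parts[0]), float(parts[1])))
            except ValueError as exc:
                raise ScanParseError(f"{path}:{lineno}: {exc}") from None
        depths, values = map(np.asarray, zip(*rows))
        return DepthValueCurve(depths, values, quantity, _load_sidecar(path))

    if dialect != "csv":
        raise ValueError(f"unknown dialect {dialect!r}; use 'ascii' or 'csv'")

    header_line, header = body[0]
    columns = [c.strip() for c in header.split(",")]
    rows = []
    for lineno, line in body[1:]:
        parts = [p.strip() for p in line.split(",")]
        if len(parts) != len(columns):
            raise ScanParseError(
                f"{path}:{lineno}: expected {len(columns)} columns, got {len(parts)}"
            )
        try:
            rows.append([float(p) for p in parts])
        except ValueError as exc:
            raise ScanParseError(f"{path}:{lineno}: {exc}") from None
    if not rows:
        raise ScanParseError(f"{path}:{header_line}: header but no data rows")
    data = np.asarray(rows)

    if columns == ["depth_cm", "value"]:
        return DepthValueCurve(data[:, 0], data[:, 1], quantity, _load_sidecar(path))
    if columns == _RAW_COLUMNS:
        if v1 is None or v2 is None:
            raise ScanParseError(f"{path}: raw-reading CSV needs a '# v1=... v2=...' line")
        if np.any(np.diff(data[:, 0]) <= 0):
            raise ScanValidationError(f"{path}: depths must be strictly increasing")
        return [
            RawDepthReadings(row[0], row[1], row[2], row[3], row[4], v1, v2) for row in data
        ]
    raise ScanParseError(f"{path}:{header_line}: unrecognized columns {columns}")


def _load_sidecar(path: Path) -> dict:
    sidecar = path.with_name(path.name + ".meta.json")
    if sidecar.exists():
        return json.loads(sidecar.read_text())
    return {}


def write_scan(path: str | Path, curve: DepthValueCurve, sidecar: bool = False) -> None:
    """Write a curve as headered CSV at full precision; optionally a meta sidecar."""
    path = Path(path)
    lines = ["depth_cm,value"]
    lines += [f"{float(z)!r},{float(v)!r}" for z, v in zip(curve.depths, curve.values)]
    path.write_text("\n".join(lines) + "\n")
    if sidecar and curve.meta:
        path.with_name(path.name + ".meta.json").write_text(
            json.dumps(curve.meta, indent=1, sort_keys=True) + "\n"
        )


def write_raw(path: str | Path, readings: Sequence[RawDepthReadings]) -> None:
    """Write raw readings as headered CSV with the voltages in a comment line."""
    path = Path(path)
    r0 = readings[0]
    lines = [f"# v1={r0.v1:g} v2={r0.v2:g}", ",".join(_RAW_COLUMNS)]
    lines += [
        ",".join(repr(float(x)) for x in (r.depth, r.m_v1, r.m_v2, r.m_pos, r.m_neg))
        for r in readings
    ]
    path.write_text("\n".join(lines) + "\n")


def resample(curve: DepthValueCurve, new_depths: np.ndarray) -> np.ndarray:
    """Evaluate the curve at ``new_depths`` by monotone shape-preserving
    piecewise-cubic (PCHIP) interpolation.

    Exact at the knots and overshoot-free on monotone segments, which matters
    on the steep distal falloff where an ordinary cubic spline rings.
    Extrapolation is refused: scanning data outside its measured support is
    never meaningful.
    """
    new_depths = np.asarray(new_depths, dtype=float)
    lo, hi = curve.span
    if new_depths.size and (new_depths.min() < lo - 1e-12 or new_depths.max() > hi + 1e-12):
        raise ValueError(
            f"resample request [{new_depths.min():g}, {new_depths.max():g}] cm outside"
            f" measured support [{lo:g}, {hi:g}] cm; extrapolation is not allowed"
        )
    return PchipInterpolator(curve.depths, curve.values)(np.clip(new_depths, lo, hi))


def average_curves(curves: Sequence[DepthValueCurve]) -> DepthValueCurve:
    """Pointwise mean of several session curves of the same quantity.

    Depth grids may differ between sessions; each curve is resampled onto the
    union of all grids restricted to the depth interval common to every
    session (so no session is ever extrapolated), and the mean is taken
    pointwise.  Metadata records the session count.
    """
    if not curves:
        raise ValueError("need at least one curve")
    quantity = curves[0].quantity
    if any(c.quantity is not quantity for c in curves):
        raise ScanValidationError("cannot average curves of mixed quantities")
    lo = max(c.span[0] for c in curves)
    hi = min(c.span[1] for c in curves)
    if hi <= lo:
        raise ScanValidationError("curves share no common depth interval")
    grid = np.unique(np.concatenate([c.depths for c in curves]))
    grid = grid[(grid >= lo - 1e-12) & (grid <= hi + 1e-12)]
    if grid.size < 4:
        raise ScanValidationError("common depth interval holds fewer than 4 grid points")
    mean = np.mean([resample(c, grid) for c in curves], axis=0)
    meta = dict(curves[0].meta)
    meta["sessions"] = len(curves)
    return DepthValueCurve(grid, mean, quantity, meta)
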