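"""Ion-recombination and polarity corrections of raw chamber readings.

Both factors follow the standard dosimetry-protocol prescriptions.  The
polarity correction is

    kpol = (|M+| + |M-|) / (2 |M|),

with M the reading at the routinely used polarity, and the recombination
correction for pulsed beams comes from the two-voltage method,

    kS = a0 + a1 (M1/M2) + a2 (M1/M2)^2,

with the published quadratic coefficients tabulated per voltage ratio
V1/V2.  Because both factors vary slowly with depth in an electron beam,
they are evaluated depth by depth and applied multiplicatively to the
operating-voltage reading before normalization.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from .scan_io import DepthValueCurve, Quantity, RawDepthReadings

#: Pulsed-beam two-voltage quadratic coefficients (a0, a1, a2) keyed by V1/V2.
#: Each row satisfies a0 + a1 + a2 = 1 within 1e-3 (no recombination at M1 = M2).
TRS398_PULSED_KS: dict[float, tuple[float, float, float]] = {
    2.0: (2.337, -3.636, 2.299),
    2.5: (1.474, -1.587, 1.114),
    3.0: (1.198, -0.875, 0.677),
    3.5: (1.080, -0.542, 0.463),
    4.0: (1.022, -0.363, 0.341),
    5.0: (0.975, -0.188, 0.214),
}


def k_pol(m_pos: float, m_neg: float, m: float) -> float:
    """Polarity correction from readings at both polarities.

    ``m`` is the reading at the routinely used polarity (sign irrelevant:
    absolute values are taken throughout).
    """
    if m == 0:
        raise ZeroDivisionError("routine-polarity reading m must be nonzero")
    return (abs(m_pos) + abs(m_neg)) / (2.0 * abs(m))


def _lookup_coefficients(
    v1: float, v2: float, table: Mapping[float, tuple[float, float, float]]
) -> tuple[float, float, float]:
    ratio = v1 / v2
    for key, coeffs in table.items():
        if abs(ratio - key) < 1e-6:
            return coeffs
    supported = sorted(table)
    raise ValueError(
        f"voltage ratio V1/V2 = {ratio:g} unsupported; supported ratios: {supported}"
    )


def k_s_two_voltage(
    m1: float,
    m2: float,
    v1: float,
    v2: float,
    table: Mapping[float, tuple[float, float, float]] = TRS398_PULSED_KS,
) -> float:
    """Two-voltage recombination correction for pulsed beams.

    ``m1`` is the reading at the higher voltage ``v1``.  A reading ratio
    below 1 is nonphysical (collection should improve with voltage) and
    triggers a warning but still evaluates the quadratic.
    """
    if not (v1 > v2 > 0):
        raise ValueError(f"need v1 > v2 > 0, got {v1}, {v2}")
    if m1 <= 0 or m2 <= 0:
        raise ValueError("readings must be positive")
    a0, a1, a2 = _lookup_coefficients(v1, v2, table)
    r = m1 / m2
    if r < 1.0:
        warnings.warn(
            f"m1/m2 = {r:.5f} < 1 is nonphysical for recombination", stacklevel=2
        )
    return a0 + a1 * r + a2 * r * r


def two_voltage_ratio_for_ks(
    ks: float, v1: float, v2: float,
    table: Mapping[float, tuple[float, float, float]] = TRS398_PULSED_KS,
) -> float:
    """Invert the pulsed two-voltage quadratic: the reading ratio M1/M2 giving ``ks``.

    Takes the root on the physically increasing branch (M1/M2 >= 1 for
    kS >= 1); used by the synthetic generator to build consistent raw channels.
    """
    a0, a1, a2 = _lookup_coefficients(v1, v2, table)
    disc = a1 * a1 - 4.0 * a2 * (a0 - ks)
    if disc < 0:
        raise ValueError(f"kS = {ks:g} unreachable for V1/V2 = {v1 / v2:g}")
    return (-a1 + np.sqrt(disc)) / (2.0 * a2)


@dataclass(frozen=True)
class CorrectionProfile:
    """Per-depth kS and kpol actually applied to a scan, kept for reporting."""

    depth: np.ndarray
    ks: np.ndarray
    kpol: np.ndarray

    def to_csv(self, path: str | Path) -> None:
        lines = ["depth_cm,ks,kpol"]
        lines += [
            f"{float(z)!r},{float(s)!r},{float(p)!r}"
            for z, s, p in zip(self.depth, self.ks, self.kpol)
        ]
        Path(path).write_text("\n".join(lines) + "\n")


def correct_scan(
    readings: Sequence[RawDepthReadings],
    table: Mapping[float, tuple[float, float, float]] = TRS398_PULSED_KS,
) -> tuple[DepthValueCurve, CorrectionProfile]:
    """Apply depth-wise kS and kpol to raw readings and normalize.

    The corrected signal at each depth is ``m_v1 * kS * kpol`` with kS from
    the (m_v1, m_v2) pair and kpol from the polarity pair; the result is
    renormalized to 100 at its maximum and returned as an ionization curve
    together with the applied correction profile.
    """
    if len(readings) < 4:
        raise ValueError(f"need >= 4 depths, got {len(readings)}")
    depth = np.array([r.depth for r in readings])
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        ks = np.array(
            [k_s_two_voltage(abs(r.m_v1), abs(r.m_v2), r.v1, r.v2, table) for r in readings]
        )
    n_nonphys = sum("nonphysical" in str(w.message) for w in caught)
    if n_nonphys:
        warnings.warn(
            f"{n_nonphys}/{len(readings)} depths had m1/m2 < 1 (noise-dominated"
            " recombination signal)", stacklevel=2,
        )
    kpol = np.array([k_pol(r.m_pos, r.m_neg, r.m_v1) for r in readings])
    if np.any(ks < 1.0 - 0.005):
        warnings.warn("kS below 1 by more than 0.5%: recombination should lose charge")
    if np.any((kpol < 0.95) | (kpol > 1.05)):
        warnings.warn("kpol outside the [0.95, 1.05] sanity band")
    corrected = np.abs([r.m_v1 for r in readings]) * ks * kpol
    meta = {"v1": readings[0].v1, "v2": readings[0].v2}
    curve = DepthValueCurve(depth, corrected, Quantity.IONIZATION, meta).normalized()
    return curve, CorrectionProfile(depth, ks, kpol)
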