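"""Electron beam quality and ionization-to-dose conversion.

The beam quality specifier is R50, the water depth where the dose falls to
half its maximum on the distal side.  Percentage depth ionization (PDI)
measured with an air-filled chamber is converted to percentage depth dose
(PDD) by the depth-dependent water/air mean restricted mass collision
stopping-power ratio s_w,air(z, R50), here evaluated with the Burns
rational-function parameterization

    s_w,air(z, R50) = (a + b x + c x^2 + d y) / (1 + e x + f x^2 + g x^3 + h y)

with x = ln(R50 / cm) and y = z / R50, valid for 0.02 <= z/R50 <= 1.2 and
R50 roughly 1-20 cm.  Outside the validity window the fit is unreliable and
evaluation raises rather than extrapolating.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

from .scan_io import DepthValueCurve, Quantity, resample

#: R50 interval (cm) over which the study's EPOM shifts were established;
#: beams outside it only warn, they are not rejected.
R50_APPLICABILITY = (2.40, 8.82)


@dataclass(frozen=True)
class BeamSpec:
    """Electron beam metadata: nominal energy label, R50 (cm), SSD (cm), field size (cm)."""

    nominal_energy: str
    r50: float
    ssd: float = 100.0
    field_size: tuple[float, float] = (20.0, 20.0)

    def __post_init__(self) -> None:
        if self.r50 <= 0:
            raise ValueError("r50 must be positive")
        lo, hi = R50_APPLICABILITY
        if not (lo <= self.r50 <= hi):
            warnings.warn(
                f"R50 = {self.r50:g} cm is outside the validated range"
                f" [{lo:g}, {hi:g}] cm; EPOM shifts may not apply",
                stacklevel=2,
            )


class StoppingPowerRangeError(ValueError):
    """Requested depth lies outside the stopping-power fit's validity window."""


@dataclass(frozen=True)
class BurnsStoppingPower:
    """Burns rational-function fit of s_w,air(z, R50) with its validity window.

    Coefficients may be overridden (e.g. loaded from a config mapping) to
    swap in an alternative fit; the defaults are the published values.
    """

    num: tuple[float, float, float, float] = (1.0752, -0.50867, 0.08867, -0.08402)
    den: tuple[float, float, float, float] = (-0.42806, 0.064627, 0.003085, -0.12460)
    zr_min: float = 0.02
    zr_max: float = 1.2

    @classmethod
    def from_dict(cls, cfg: dict) -> "BurnsStoppingPower":
        return cls(
            num=tuple(cfg.get("num", cls.num)),
            den=tuple(cfg.get("den", cls.den)),
            zr_min=cfg.get("zr_min", cls.zr_min),
            zr_max=cfg.get("zr_max", cls.zr_max),
        )

    def in_window(self, z: np.ndarray | float, r50: float) -> np.ndarray | bool:
        y = np.asarray(z, dtype=float) / r50
        return (y >= self.zr_min) & (y <= self.zr_max)

    def ratio(self, z: np.ndarray | float, r50: float) -> np.ndarray | float:
        """s_w,air at depth ``z`` (cm) for beam quality ``r50`` (cm)."""
        if r50 <= 0:
            raise ValueError("r50 must be positive")
        z_arr = np.asarray(z, dtype=float)
        y = z_arr / r50
        if np.any(y < self.zr_min) or np.any(y > self.zr_max):
            bad = np.atleast_1d(z_arr)[~np.atleast_1d(self.in_window(z_arr, r50))]
            raise StoppingPowerRangeError(
                f"depth(s) {np.round(bad, 4).tolist()} cm give z/R50 outside the validity"
                f" window [{self.zr_min}, {self.zr_max}] for R50 = {r50:g} cm"
            )
        x = np.log(r50)
        a, b, c, d = self.num
        e, f, g, h = self.den
        value = (a + b * x + c * x**2 + d * y) / (1 + e * x + f * x**2 + g * x**3 + h * y)
        return float(value) if np.isscalar(z) else value


@dataclass(frozen=True)
class ConstantStoppingPower:
    """Depth-independent stopping-power stub (unit ratio by default).

    Useful for hand-checkable arithmetic: with a constant ratio the PDI→PDD
    conversion reduces to renormalization.
    """

    value: float = 1.0
    zr_min: float = -np.inf
    zr_max: float = np.inf

    def in_window(self, z, r50: float):
        return np.ones_like(np.asarray(z, dtype=float), dtype=bool)

    def ratio(self, z, r50: float):
        z_arr = np.asarray(z, dtype=float)
        out = np.full_like(z_arr, self.value)
        return float(out) if np.isscalar(z) else out


#: Default stopping-power model used throughout the pipeline.
BURNS = BurnsStoppingPower()


def stopping_power_ratio(z, r50: float, model: BurnsStoppingPower = BURNS):
    """s_w,air(z, R50) under the default Burns parameterization."""
    return model.ratio(z, r50)


def compute_r50(curve: DepthValueCurve) -> float:
    """Distal depth (cm) where a dose curve crosses 50% of its maximum.

    The curve is interpolated (PCHIP) and the first crossing beyond the dose
    maximum is located by root bracketing; scale-invariant by construction.
    """
    curve.require(Quantity.DOSE)
    half = 0.5 * curve.values.max()
    i_max = int(np.argmax(curve.values))
    below = np.nonzero(curve.values[i_max:] < half)[0]
    if below.size == 0:
        raise ValueError("dose curve has no distal 50% crossing within its support")
    j = i_max + below[0]
    lo, hi = curve.depths[j - 1], curve.depths[j]
    return float(brentq(lambda z: resample(curve, np.array([z]))[0] - half, lo, hi, xtol=1e-6))


def i50_to_r50(i50: float) -> float:
    """Protocol conversion from the ionization half-value depth I50 to R50 (cm).

    Linear in I50 with one expression up to 10 cm and one above.
    """
    if i50 <= 0:
        raise ValueError("i50 must be positive")
    if i50 <= 10.0:
        return 1.029 * i50 - 0.06
    return 1.059 * i50 - 0.37


def reference_depth(r50: float) -> float:
    """Protocol reference depth z_ref = 0.6 R50 - 0.1 (cm) for electron dosimetry."""
    z_ref = 0.6 * r50 - 0.1
    if z_ref <= 0:
        raise ValueError(f"reference depth nonpositive for r50 = {r50:g} cm")
    return z_ref


def pdi_to_pdd(
    curve: DepthValueCurve, r50: float, model: BurnsStoppingPower = BURNS
) -> DepthValueCurve:
    """Convert a percentage depth ionization curve to PDD.

    Each reading is multiplied by s_w,air at its own depth, then the result is
    renormalized to 100 at its maximum.  Depths outside the stopping-power
    validity window are an error (listed in the message), not silently dropped.
    """
    curve.require(Quantity.IONIZATION)
    ratios = model.ratio(curve.depths, r50)
    out = DepthValueCurve(curve.depths, curve.values * ratios, Quantity.DOSE, dict(curve.meta))
    return out.normalized()


def r50_from_ionization(
    curve: DepthValueCurve,
    model: BurnsStoppingPower = BURNS,
    tol: float = 0.001,
    max_iter: int = 20,
) -> float:
    """R50 for an ionization-only dataset by fixed-point iteration.

    Starts from the protocol I50→R50 estimate, converts PDI→PDD with it,
    recomputes R50 from the dose curve, and repeats until the change falls
    below ``tol`` cm (weak self-consistency of the conversion makes this a
    contraction in practice).
    """
    curve.require(Quantity.IONIZATION)
    as_dose = DepthValueCurve(curve.depths, curve.values, Quantity.DOSE, dict(curve.meta))
    i50 = compute_r50(as_dose)  # 50% crossing of the ionization curve
    r50 = i50_to_r50(i50)
    for _ in range(max_iter):
        r50_new = compute_r50(pdi_to_pdd(curve, r50, model))
        if abs(r50_new - r50) < tol:
            return r50_new
        r50 = r50_new
    warnings.warn(f"R50 fixed point not converged to {tol} cm in {max_iter} iterations")
    return r50
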