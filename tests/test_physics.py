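"""Beam quality, stopping-power ratios, and ionization-to-dose conversion."""

import numpy as np
import pytest

from epomfit import (
    BeamSpec,
    ConstantStoppingPower,
    DepthValueCurve,
    Quantity,
    StoppingPowerRangeError,
    compute_r50,
    i50_to_r50,
    make_reference_pdd,
    default_reference_grid,
    pdd_value,
    pdi_to_pdd,
    r50_from_ionization,
    reference_depth,
    stopping_power_ratio,
)
from epomfit.physics import BURNS
from scipy.optimize import brentq


def trs398_swair_at_zref(r50: float) -> float:
    """Published protocol closed form for s_w,air at the reference depth."""
    return 1.253 - 0.1487 * r50**0.214


class TestStoppingPowerRatio:
    def test_matches_published_reference_depth_form(self):
        """Anti-typo gate: the transcribed rational-fit coefficients must
        reproduce the published closed form for s_w,air(z_ref) across the
        full beam-quality range before anything downstream is trusted.  The
        two published parameterizations agree within 0.25% over the clinical
        range; a typo in any transcribed coefficient moves the ratio by far
        more than that."""
        for r50 in np.linspace(2.40, 8.82, 24):
            ours = stopping_power_ratio(reference_depth(r50), r50)
            assert ours == pytest.approx(trs398_swair_at_zref(r50), rel=2.5e-3)

    def test_range_error_outside_validity_window(self):
        with pytest.raises(StoppingPowerRangeError, match=r"\[0.02, 1.2\]"):
            stopping_power_ratio(1.3 * 4.0, 4.0)
        with pytest.raises(StoppingPowerRangeError):
            stopping_power_ratio(0.01 * 4.0, 4.0)

    def test_strictly_increasing_with_depth(self):
        for r50 in (2.40, 4.0, 8.82):
            z = np.linspace(0.02 * r50, 1.2 * r50, 200)
            s = stopping_power_ratio(z, r50)
            assert np.all(np.diff(s) > 0)
        assert stopping_power_ratio(3.0, 4.0) > stopping_power_ratio(1.0, 4.0)

    def test_continuous_in_r50(self):
        vals = [stopping_power_ratio(2.0, r50) for r50 in np.linspace(3.9, 4.1, 21)]
        assert np.max(np.abs(np.diff(vals))) < 5e-4


class TestComputeR50:
    def test_linear_crossing(self):
        depths = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 5.8]
        values = [100.0, 100.0, 100.0, 75.0, 50.0, 25.0, 5.0]
        curve = DepthValueCurve(depths, values, Quantity.DOSE)
        assert compute_r50(curve) == pytest.approx(4.0, abs=1e-5)

    def test_scale_invariant(self):
        depths = [0.0, 1.0, 2.0, 3.0, 4.0, 5.0, 5.8]
        values = np.array([100.0, 100.0, 100.0, 75.0, 50.0, 25.0, 5.0])
        a = compute_r50(DepthValueCurve(depths, values, Quantity.DOSE))
        b = compute_r50(DepthValueCurve(depths, 0.37 * values, Quantity.DOSE))
        assert a == pytest.approx(b, abs=1e-9)

    def test_sampled_curve_against_dense_root_oracle(self, beam12):
        """R50 from a 0.1 cm scan agrees with root-finding on the analytic
        curve to within 0.005 cm."""
        grid = np.arange(0.05, 1.3 * beam12.r50, 0.1)
        curve = DepthValueCurve(grid, pdd_value(beam12, grid), Quantity.DOSE)
        oracle = brentq(
            lambda z: pdd_value(beam12, z) - 50.0, beam12.zmax, beam12.rp, xtol=1e-6
        )
        assert compute_r50(curve) == pytest.approx(oracle, abs=0.005)

    def test_rejects_curve_without_crossing(self):
        curve = DepthValueCurve([1, 2, 3, 4], [100, 99, 98, 97], Quantity.DOSE)
        with pytest.raises(ValueError, match="50%"):
            compute_r50(curve)

    def test_rejects_ionization_curve(self):
        curve = DepthValueCurve([1, 2, 3, 4], [100, 80, 50, 20], Quantity.IONIZATION)
        with pytest.raises(ValueError, match="dose"):
            compute_r50(curve)


class TestI50ToR50:
    def test_protocol_formula_below_10cm(self):
        assert i50_to_r50(5.0) == pytest.approx(1.029 * 5.0 - 0.06, abs=1e-12)
        assert i50_to_r50(5.0) == pytest.approx(5.085, abs=1e-9)

    def test_branch_discontinuity_at_10cm_is_small(self):
        below = 1.029 * 10.0 - 0.06
        above = 1.059 * 10.0 - 0.37
        assert i50_to_r50(10.0) == pytest.approx(below, abs=1e-12)
        assert abs(above - below) < 0.01  # the two branches nearly meet

    def test_monotone(self):
        i50 = np.linspace(0.5, 15, 50)
        r50 = np.array([i50_to_r50(v) for v in i50])
        assert np.all(np.diff(r50) > 0)


class TestReferenceDepth:
    @pytest.mark.parametrize("r50, expected", [(4.0, 2.3), (2.40, 1.34)])
    def test_protocol_values(self, r50, expected):
        assert reference_depth(r50) == pytest.approx(expected, abs=1e-12)

    def test_affine_in_r50(self):
        assert reference_depth(6.0) - reference_depth(5.0) == pytest.approx(0.6, abs=1e-12)

    def test_rejects_nonpositive_result(self):
        with pytest.raises(ValueError):
            reference_depth(0.15)


class TestPdiToPdd:
    def test_unit_ratio_is_renormalized_identity(self):
        curve = DepthValueCurve([1, 2, 3, 4], [46, 50, 30, 10], Quantity.IONIZATION)
        out = pdi_to_pdd(curve, 4.0, model=ConstantStoppingPower(1.0))
        assert out.quantity is Quantity.DOSE
        np.testing.assert_allclose(out.values, [92, 100, 60, 20], rtol=1e-14)

    def test_hand_multiplication_on_toy_curve(self):
        depths = np.array([0.5, 1.0, 2.0, 3.0, 4.0])
        values = np.array([95.0, 100.0, 90.0, 55.0, 12.0])
        curve = DepthValueCurve(depths, values, Quantity.IONIZATION)
        r50 = 4.0
        out = pdi_to_pdd(curve, r50)
        manual = values * np.array([stopping_power_ratio(z, r50) for z in depths])
        manual = manual * 100.0 / manual.max()
        np.testing.assert_allclose(out.values, manual, rtol=1e-14)

    def test_dose_maximum_not_shallower_than_ionization_maximum(self, beam12):
        """The stopping-power ratio increases with depth, so conversion moves
        the maximum deeper (or leaves it in place)."""
        grid = np.arange(0.3, 1.15 * beam12.r50, 0.1)
        ion = pdd_value(beam12, grid) / stopping_power_ratio(grid, beam12.r50)
        curve = DepthValueCurve(grid, ion, Quantity.IONIZATION)
        out = pdi_to_pdd(curve, beam12.r50)
        z_ion = grid[np.argmax(curve.values)]
        z_dose = grid[np.argmax(out.values)]
        assert z_dose >= z_ion

    def test_invariant_to_prescaling(self, beam12):
        grid = np.arange(0.3, 1.15 * beam12.r50, 0.1)
        ion = pdd_value(beam12, grid) / stopping_power_ratio(grid, beam12.r50)
        a = pdi_to_pdd(DepthValueCurve(grid, ion, Quantity.IONIZATION), beam12.r50)
        b = pdi_to_pdd(DepthValueCurve(grid, 13.7 * ion, Quantity.IONIZATION), beam12.r50)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-12)

    def test_depth_outside_window_lists_offender(self):
        curve = DepthValueCurve([0.02, 1, 2, 3], [80, 100, 70, 30], Quantity.IONIZATION)
        with pytest.raises(StoppingPowerRangeError, match="0.02"):
            pdi_to_pdd(curve, 4.0)


class TestR50FixedPoint:
    def test_recovers_r50_from_ionization_only(self, beam12):
        grid = np.arange(0.15, 1.19 * beam12.r50, 0.05)
        ion = pdd_value(beam12, grid) / stopping_power_ratio(grid, beam12.r50)
        curve = DepthValueCurve(grid, ion, Quantity.IONIZATION)
        assert r50_from_ionization(curve) == pytest.approx(beam12.r50, abs=0.02)

    def test_weak_self_consistency_in_r50_guess(self, beam12):
        """compute_r50 after conversion is insensitive (<0.5%) to a +/-2%
        error in the R50 used for the conversion."""
        # keep all depths valid for every guess in the +/-2% band
        grid = np.arange(0.15, 1.15 * beam12.r50, 0.05)
        ion = pdd_value(beam12, grid) / stopping_power_ratio(grid, beam12.r50)
        curve = DepthValueCurve(grid, ion, Quantity.IONIZATION)
        base = compute_r50(pdi_to_pdd(curve, beam12.r50))
        for guess in (0.98 * beam12.r50, 1.02 * beam12.r50):
            perturbed = compute_r50(pdi_to_pdd(curve, guess))
            assert abs(perturbed - base) / base < 0.005


def test_beam_spec_warns_outside_validated_range():
    with pytest.warns(UserWarning, match="outside the validated range"):
        BeamSpec("4", r50=1.5)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error")
        BeamSpec("12", r50=4.93)  # inside the range: must not warn
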