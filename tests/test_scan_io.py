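"""Scan parsing, validation, resampling and session averaging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from epomfit import (
    DepthValueCurve,
    Quantity,
    RawDepthReadings,
    average_curves,
    make_reference_pdd,
    pdd_value,
    read_scan,
    resample,
    write_raw,
    write_scan,
)
from epomfit.scan_io import ScanParseError, ScanValidationError

from conftest import falloff_curve


class TestReadScan:
    def test_two_column_ascii(self, tmp_path):
        path = tmp_path / "scan.txt"
        path.write_text("0.1 98.2\n0.2 99.0\n0.3 99.6\n0.4 100.0\n")
        curve = read_scan(path, quantity=Quantity.DOSE)
        np.testing.assert_array_equal(curve.depths, [0.1, 0.2, 0.3, 0.4])
        np.testing.assert_array_equal(curve.values, [98.2, 99.0, 99.6, 100.0])
        assert curve.quantity is Quantity.DOSE

    def test_raw_csv(self, tmp_path):
        path = tmp_path / "scan.csv"
        path.write_text(
            "# v1=400 v2=200\n"
            "depth_cm,m_v1,m_v2,m_pos,m_neg\n"
            "0.1,10.0,9.96,10.0,-10.02\n"
            "0.2,10.2,10.16,10.2,-10.22\n"
            "0.3,10.1,10.06,10.1,-10.12\n"
            "0.4,9.9,9.86,9.9,-9.92\n"
        )
        readings = read_scan(path)
        assert len(readings) == 4
        assert isinstance(readings[0], RawDepthReadings)
        assert readings[0].v1 == 400 and readings[0].v2 == 200
        assert readings[1].m_v2 == 10.16

    def test_raw_csv_without_voltages_fails(self, tmp_path):
        path = tmp_path / "scan.csv"
        path.write_text(
            "depth_cm,m_v1,m_v2,m_pos,m_neg\n" + "0.1,1,1,1,-1\n" * 1
        )
        with pytest.raises(ScanParseError, match="v1"):
            read_scan(path)

    def test_malformed_row_reports_line_number(self, tmp_path):
        path = tmp_path / "scan.txt"
        path.write_text("0.1 98.2\n0.2 nine\n0.3 99.6\n0.4 100.0\n")
        with pytest.raises(ScanParseError, match=r":2"):
            read_scan(path)

    def test_non_increasing_depths_rejected(self, tmp_path):
        path = tmp_path / "scan.txt"
        path.write_text("0.1 98.0\n0.3 99.0\n0.2 99.5\n0.4 100.0\n")
        with pytest.raises(ScanValidationError, match="increasing"):
            read_scan(path)


class TestCurveInvariants:
    def test_too_short_curve_rejected(self):
        with pytest.raises(ScanValidationError, match=">= 4"):
            DepthValueCurve([0.1, 0.2, 0.3], [1, 2, 3], Quantity.DOSE)

    def test_quantity_gate(self):
        curve = DepthValueCurve([1, 2, 3, 4], [9, 10, 8, 6], Quantity.IONIZATION)
        with pytest.raises(ScanValidationError, match="requires a dose"):
            curve.require(Quantity.DOSE)


@given(
    depths=st.lists(
        st.floats(min_value=0.05, max_value=12.0, allow_nan=False),
        min_size=4, max_size=40, unique=True,
    ),
    data=st.data(),
)
@settings(max_examples=50, deadline=None)
def test_write_read_roundtrip_full_precision(tmp_path_factory, depths, data):
    """Writing a curve as CSV and reading it back reproduces it bit-for-bit."""
    depths = np.sort(np.asarray(depths, dtype=float))
    values = np.asarray(
        data.draw(
            st.lists(
                st.floats(min_value=1e-3, max_value=120.0, allow_nan=False),
                min_size=len(depths), max_size=len(depths),
            )
        )
    )
    curve = DepthValueCurve(depths, values, Quantity.DOSE)
    path = tmp_path_factory.mktemp("rt") / "c.csv"
    write_scan(path, curve)
    back = read_scan(path, quantity=Quantity.DOSE)
    np.testing.assert_array_equal(back.depths, curve.depths)
    np.testing.assert_array_equal(back.values, curve.values)


def test_write_read_roundtrip_raw(tmp_path):
    readings = [
        RawDepthReadings(0.1 * i, 10.0 + i / 7, 9.9 + i / 7, 10.0 + i / 7, -10.1 - i / 7, 400, 200)
        for i in range(1, 8)
    ]
    path = tmp_path / "raw.csv"
    write_raw(path, readings)
    back = read_scan(path)
    assert back == readings


class TestResample:
    def test_exact_at_knots(self):
        curve = falloff_curve()
        np.testing.assert_allclose(resample(curve, curve.depths), curve.values, rtol=1e-14)

    def test_reproduces_linear_data(self):
        curve = DepthValueCurve([1, 2, 3, 4, 5], [90, 80, 70, 60, 50], Quantity.DOSE)
        z = np.linspace(1, 5, 37)
        np.testing.assert_allclose(resample(curve, z), 100 - 10 * z, atol=1e-12)

    def test_against_dense_analytic_oracle(self, beam12):
        """A 0.1 cm sampled falloff interpolated at midpoints tracks the
        analytic curve it was sampled from."""
        grid = np.arange(0.1, 1.2 * beam12.r50, 0.1)
        curve = DepthValueCurve(grid, pdd_value(beam12, grid), Quantity.DOSE)
        mid = grid[:-1] + 0.05
        assert np.max(np.abs(resample(curve, mid) - pdd_value(beam12, mid))) < 0.25

    def test_refuses_extrapolation(self):
        curve = falloff_curve()
        with pytest.raises(ValueError, match="extrapolation"):
            resample(curve, np.array([2.5]))

    def test_overshoot_free_on_monotone_falloff(self):
        curve = falloff_curve()
        z = np.linspace(3.0, 4.4, 281)
        v = resample(curve, z)
        assert v.max() <= curve.values.max() + 1e-12
        assert v.min() >= curve.values.min() - 1e-12
        assert np.all(np.diff(v) <= 1e-12)  # shape preservation


class TestAverageCurves:
    def test_identity_on_identical_inputs(self, ref12):
        mean = average_curves([ref12, ref12, ref12])
        np.testing.assert_allclose(mean.values, ref12.values, rtol=1e-12)
        assert mean.meta["sessions"] == 3

    def test_arithmetic_mean_on_shared_grid(self):
        c1 = DepthValueCurve([1, 2, 3, 4], [10, 20, 16, 8], Quantity.DOSE)
        c2 = DepthValueCurve([1, 2, 3, 4], [30, 60, 48, 24], Quantity.DOSE)
        mean = average_curves([c1, c2])
        np.testing.assert_allclose(mean.values, [20, 40, 32, 16], rtol=1e-14)

    def test_offset_grids_against_dense_oracle(self, beam12):
        """Sessions on grids offset by 0.05 cm average to the dense-grid mean."""
        g1 = np.arange(0.5, 5.5, 0.1)
        g2 = g1 + 0.05
        c1 = DepthValueCurve(g1, pdd_value(beam12, g1), Quantity.DOSE)
        c2 = DepthValueCurve(g2, pdd_value(beam12, g2), Quantity.DOSE)
        mean = average_curves([c1, c2])
        # oracle: both sessions sampled from the same analytic curve, so the
        # mean must track that curve wherever both grids overlap
        inner = (mean.depths >= g2[0]) & (mean.depths <= g1[-1])
        oracle = pdd_value(beam12, mean.depths[inner])
        assert np.max(np.abs(mean.values[inner] - oracle)) < 0.25

    def test_mixed_quantities_rejected(self):
        c1 = DepthValueCurve([1, 2, 3, 4], [1, 2, 3, 4], Quantity.DOSE)
        c2 = DepthValueCurve([1, 2, 3, 4], [1, 2, 3, 4], Quantity.IONIZATION)
        with pytest.raises(ScanValidationError, match="mixed"):
            average_curves([c1, c2])

    def test_permutation_invariant(self, beam12):
        g = np.arange(0.5, 5.5, 0.1)
        curves = [
            DepthValueCurve(g + 0.02 * i, pdd_value(beam12, g + 0.02 * i), Quantity.DOSE)
            for i in range(3)
        ]
        a = average_curves(curves)
        b = average_curves(curves[::-1])
        np.testing.assert_array_equal(a.depths, b.depths)
        np.testing.assert_allclose(a.values, b.values, rtol=1e-14)
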