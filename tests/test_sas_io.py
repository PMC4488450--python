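import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from nanodisc_sas.sas_io import (
    CurveSegmentPair,
    SASCurve,
    SASParseError,
    SASValidationError,
    absolute_scale,
    merge_segments,
    read_sas_curve,
    write_sas_curve,
)


def write_rows(tmp_path, rows, name="curve.dat"):
    path = tmp_path / name
    path.write_text("# q I sigma\n" + "\n".join("  ".join(map(str, r)) for r in rows) + "\n")
    return path


class TestRead:
    def test_reads_simple_file(self, tmp_path):
        rows = [(0.01 * (i + 1), 1.0 - 0.1 * i, 0.1) for i in range(5)]
        curve = read_sas_curve(write_rows(tmp_path, rows), "xray")
        assert len(curve) == 5
        np.testing.assert_allclose(curve.q, [r[0] for r in rows])

    def test_zero_sigma_rejected(self, tmp_path):
        rows = [(0.01, 1.0, 0.1), (0.02, 0.9, 0.0), (0.03, 0.8, 0.1),
                (0.04, 0.7, 0.1), (0.05, 0.6, 0.1)]
        with pytest.raises(SASValidationError):
            read_sas_curve(write_rows(tmp_path, rows), "xray")

    def test_nonfinite_rows_dropped_and_counted(self, tmp_path, caplog):
        rows = [(0.001 * (i + 1), 1.0, 0.1) for i in range(1000)]
        for i in (100, 500, 900):
            rows[i] = (rows[i][0], "nan", 0.1)
        n_bad = sum("nan" in map(str, r) for r in rows)  # independent line scan
        with caplog.at_level("INFO"):
            curve = read_sas_curve(write_rows(tmp_path, rows), "neutron", 1.0)
        assert len(curve) == 1000 - n_bad
        assert curve.metadata["n_dropped_rows"] == n_bad
        assert any(str(n_bad) in rec.message for rec in caplog.records)

    def test_wrong_column_count_names_line(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("0.01 1.0 0.1\n0.02 0.9\n0.03 0.8 0.1\n0.04 0.7 0.1\n0.05 0.6 0.1\n")
        with pytest.raises(SASParseError, match=r":2:"):
            read_sas_curve(path, "xray")

    def test_non_monotone_q_rejected(self, tmp_path):
        rows = [(0.01, 1, 0.1), (0.03, 1, 0.1), (0.02, 1, 0.1), (0.04, 1, 0.1), (0.05, 1, 0.1)]
        with pytest.raises(SASValidationError, match="increasing"):
            read_sas_curve(write_rows(tmp_path, rows), "xray")

    def test_inverse_nm_conversion_is_explicit(self, tmp_path):
        rows = [(0.1 * (i + 1), 1.0, 0.1) for i in range(5)]
        path = write_rows(tmp_path, rows)
        in_nm = read_sas_curve(path, "xray", q_in_inverse_nm=True)
        in_a = read_sas_curve(path, "xray")
        np.testing.assert_allclose(in_nm.q, 0.1 * in_a.q)

    def test_write_read_round_trip_is_exact(self, tmp_path):
        rng = np.random.default_rng(42)
        q = np.sort(rng.uniform(0.01, 0.5, 50))
        curve = SASCurve(q, rng.lognormal(0, 1, 50), rng.lognormal(-3, 0.5, 50), "neutron", 1.0)
        path = tmp_path / "rt.dat"
        write_sas_curve(path, curve)
        back = read_sas_curve(path, "neutron", 1.0)
        assert np.array_equal(back.q, curve.q)
        assert np.array_equal(back.intensity, curve.intensity)
        assert np.array_equal(back.sigma, curve.sigma)
        assert (tmp_path / "rt.dat.yaml").exists()


class TestMerge:
    def segments(self, scale_high=1.0):
        q_low = np.linspace(0.01, 0.10, 30)
        # overlap points shared exactly, so the log-space least squares
        # scale is free of interpolation error
        q_high = np.concatenate([q_low[q_low >= 0.08], np.linspace(0.11, 0.30, 35)])
        i_low = 1.0 / (1.0 + (30 * q_low) ** 2)
        i_high = scale_high / (1.0 + (30 * q_high) ** 2)
        low = SASCurve(q_low, i_low, 0.01 * i_low, "neutron", 1.0, "low")
        high = SASCurve(q_high, i_high, 0.01 * i_high, "neutron", 1.0, "high")
        return CurveSegmentPair(low, high)

    def test_identical_segments_merge_to_input(self):
        pair = self.segments()
        c = pair.low_q_segment
        merged = merge_segments(CurveSegmentPair(c, c))
        assert merged.metadata["overlap_scale"] == pytest.approx(1.0)
        np.testing.assert_allclose(merged.q, c.q)
        np.testing.assert_allclose(merged.intensity, c.intensity)

    def test_doubled_high_segment_gives_half_scale(self):
        merged = merge_segments(self.segments(scale_high=2.0))
        assert merged.metadata["overlap_scale"] == pytest.approx(0.5, rel=1e-10)

    def test_disjoint_ranges_raise(self):
        low = SASCurve(np.linspace(0.01, 0.05, 10), np.ones(10), np.ones(10) * 0.1, "xray")
        high = SASCurve(np.linspace(0.10, 0.30, 10), np.ones(10), np.ones(10) * 0.1, "xray")
        with pytest.raises(SASValidationError, match="explicit scale"):
            merge_segments(CurveSegmentPair(low, high))

    def test_mixed_probe_pair_rejected(self):
        low = SASCurve(np.linspace(0.01, 0.05, 10), np.ones(10), np.ones(10) * 0.1, "xray")
        high = SASCurve(np.linspace(0.04, 0.30, 10), np.ones(10), np.ones(10) * 0.1, "neutron")
        with pytest.raises(SASValidationError, match="probe"):
            CurveSegmentPair(low, high)

    def test_merge_idempotent_on_merged_curve(self):
        merged = merge_segments(self.segments())
        # split the merged curve and merge again: nothing should change
        cut = len(merged) // 2
        low = SASCurve(merged.q[: cut + 5], merged.intensity[: cut + 5],
                       merged.sigma[: cut + 5], merged.probe, merged.solvent_d2o_fraction)
        high = SASCurve(merged.q[cut - 5:], merged.intensity[cut - 5:],
                        merged.sigma[cut - 5:], merged.probe, merged.solvent_d2o_fraction)
        again = merge_segments(CurveSegmentPair(low, high))
        np.testing.assert_allclose(again.q, merged.q)
        np.testing.assert_allclose(again.intensity, merged.intensity, rtol=1e-12)

    def test_scale_commutes_with_merge(self):
        pair = self.segments()
        a = absolute_scale(merge_segments(pair), 2.5)
        b = merge_segments(
            CurveSegmentPair(
                absolute_scale(pair.low_q_segment, 2.5),
                absolute_scale(pair.high_q_segment, 2.5),
            )
        )
        np.testing.assert_allclose(a.intensity, b.intensity, rtol=1e-12)


class TestAbsoluteScale:
    def test_factor_one_is_identity(self):
        c = SASCurve(np.linspace(0.01, 0.1, 10), np.ones(10), 0.1 * np.ones(10), "xray")
        out = absolute_scale(c, 1.0)
        np.testing.assert_array_equal(out.intensity, c.intensity)

    def test_factor_scales_intensity_and_sigma(self):
        c = SASCurve(np.linspace(0.01, 0.1, 10), np.ones(10), 0.1 * np.ones(10), "xray")
        out = absolute_scale(c, 2.0)
        np.testing.assert_allclose(out.intensity, 2.0)
        np.testing.assert_allclose(out.sigma, 0.2)
        assert out.metadata["calibration_factor"] == 2.0

    def test_nonpositive_factor_rejected(self):
        c = SASCurve(np.linspace(0.01, 0.1, 10), np.ones(10), 0.1 * np.ones(10), "xray")
        with pytest.raises(ValueError):
            absolute_scale(c, 0.0)

    @settings(deadline=None, max_examples=30, derandomize=True)
    @given(factor=st.floats(min_value=1e-6, max_value=1e6))
    def test_round_trip_recovers_original(self, factor):
        c = SASCurve(np.linspace(0.01, 0.1, 10), np.linspace(1, 0.1, 10),
                     0.1 * np.ones(10), "xray")
        back = absolute_scale(absolute_scale(c, factor), 1.0 / factor)
        np.testing.assert_allclose(back.intensity, c.intensity, rtol=1e-12)
        np.testing.assert_allclose(back.sigma, c.sigma, rtol=1e-12)
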