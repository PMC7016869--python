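"""Curve I/O, frame averaging, buffer subtraction and calibration."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from confensa import (ScatteringCurve, read_curve, write_curve,
                      average_frames, subtract_buffer, calibrate_intensity)
from confensa.curves import CurveFormatError, InsufficientDataError


def make_curve(n=60, i0=100.0, rg=20.0, rel_err=0.01, qmax=0.3, seed=None):
    q = np.linspace(0.01, qmax, n)
    inten = i0 * np.exp(-q ** 2 * rg ** 2 / 3)
    sig = rel_err * inten
    if seed is not None:
        rng = np.random.default_rng(seed)
        inten = inten + rng.normal(0, sig)
    return ScatteringCurve(q, inten, sig)


class TestScatteringCurve:
    def test_invariants_enforced(self):
        with pytest.raises(ValueError):
            ScatteringCurve([0.0, 0.1], [1, 1], [1, 1])       # q <= 0
        with pytest.raises(ValueError):
            ScatteringCurve([0.2, 0.1], [1, 1], [1, 1])       # not increasing
        with pytest.raises(ValueError):
            ScatteringCurve([0.1, 0.2], [1, 1], [1, 0.0])     # sigma <= 0
        with pytest.raises(ValueError):
            ScatteringCurve([0.1, 0.2], [1, 1, 1], [1, 1])    # ragged


class TestReadWrite:
    def test_direct_parse(self, tmp_path):
        text = "\n".join(f"{0.01 * (i + 1)} {100 - i} 1" for i in range(5))
        path = tmp_path / "toy.dat"
        path.write_text("# label: toy\n" + text + "\n")
        c = read_curve(path)
        assert len(c) == 5
        assert c.q[0] == pytest.approx(0.01)
        assert c.intensity[0] == pytest.approx(100)
        assert c.meta["label"] == "toy" or "toy" in str(c.meta["header"])

    def test_bad_rows_dropped_and_counted(self, tmp_path):
        rows = ["0.01 100 1", "-0.02 99 1", "0.03 98 0", "0.04 97 1",
                "0.05 96 1", "0.06 95 1", "0.07 94 1"]
        path = tmp_path / "d.dat"
        path.write_text("\n".join(rows) + "\n")
        c = read_curve(path)
        assert len(c) == 5
        assert c.meta["n_dropped"] == 2

    def test_format_error_names_line(self, tmp_path):
        path = tmp_path / "bad.dat"
        path.write_text("0.01 100 1\n0.02 oops 1\n")
        with pytest.raises(CurveFormatError, match="line 2"):
            read_curve(path)

    def test_too_few_rows(self, tmp_path):
        path = tmp_path / "short.dat"
        path.write_text("0.01 100 1\n0.02 99 1\n0.03 98 1\n")
        with pytest.raises(InsufficientDataError):
            read_curve(path)

    @settings(deadline=None, max_examples=25)
    @given(seed=st.integers(min_value=0, max_value=10_000))
    def test_round_trip_six_significant_digits(self, tmp_path_factory, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 40))
        q = np.sort(rng.uniform(1e-3, 0.7, n))
        q += np.arange(n) * 1e-6          # enforce strict increase
        c = ScatteringCurve(q, rng.uniform(1e-3, 1e5, n),
                            rng.uniform(1e-6, 1e3, n),
                            {"concentration": 0.5})
        path = tmp_path_factory.mktemp("rt") / "c.dat"
        write_curve(c, path)
        back = read_curve(path)
        np.testing.assert_allclose(back.q, c.q, rtol=1e-6)
        np.testing.assert_allclose(back.intensity, c.intensity, rtol=1e-6)
        np.testing.assert_allclose(back.sigma, c.sigma, rtol=1e-6)
        assert "0.5" in path.read_text()


class TestAverageFrames:
    def test_identical_frames_sigma_scales(self):
        frames = [make_curve() for _ in range(3)]
        avg, report = average_frames(frames)
        assert report["rejected"] == []
        np.testing.assert_allclose(avg.intensity, frames[0].intensity)
        np.testing.assert_allclose(avg.sigma, frames[0].sigma / np.sqrt(3))
        assert np.all(avg.sigma <= frames[0].sigma + 1e-15)

    def test_outlier_rejected(self):
        good = [make_curve(seed=1), make_curve(seed=2)]
        bad = make_curve(seed=3)
        bad = ScatteringCurve(bad.q, 2.0 * bad.intensity, bad.sigma)
        avg, report = average_frames(good + [bad])
        assert report["rejected"] == [2]

    def test_single_frame_unchanged(self):
        c = make_curve(seed=5)
        avg, report = average_frames([c])
        np.testing.assert_allclose(avg.intensity, c.intensity)
        assert report["rejected"] == []

    def test_grid_mismatch_raises(self):
        a = make_curve(n=50)
        b = make_curve(n=60)
        with pytest.raises(ValueError, match="grid"):
            average_frames([a, b])


class TestSubtractBuffer:
    @staticmethod
    def synthetic_pair(t=0.97, signal_scale=1e-5, seed=0, rel_err=0.002):
        """Sample/buffer pair where the signal is negligible (< 1% of
        buffer) inside the 0.1-0.7 fit window."""
        rng = np.random.default_rng(seed)
        q = np.linspace(0.012, 0.67, 280)
        buf = 5000 * np.exp(-q / 0.2) + 5000
        signal = signal_scale * 1e5 * np.exp(-q ** 2 * 33 ** 2 / 3)
        sig = rel_err * buf
        sample = ScatteringCurve(q, signal + t * buf + rng.normal(0, sig), sig)
        buffer = ScatteringCurve(q, buf + rng.normal(0, sig), sig)
        return sample, buffer, buf

    def test_identical_curves_give_t1_zero(self):
        c = make_curve(n=200, qmax=0.67)
        sub, t = subtract_buffer(c, c)
        assert t == pytest.approx(1.0, abs=1e-9)
        np.testing.assert_allclose(sub.intensity, 0.0, atol=1e-9)

    @pytest.mark.parametrize("t_true", [0.92, 0.97, 1.05])
    def test_recovers_planted_transmission(self, t_true):
        sample, buffer, _ = self.synthetic_pair(t=t_true)
        _, t = subtract_buffer(sample, buffer)
        assert t == pytest.approx(t_true, abs=0.01)

    def test_fixed_transmission_leaves_offset(self):
        sample, buffer, buf_ideal = self.synthetic_pair(t=0.97, rel_err=1e-6)
        sub, t = subtract_buffer(sample, buffer, transmission=1.0)
        assert t == 1.0
        win = (sub.q >= 0.1)
        # oversubtraction by ~0.03 * buffer across the window
        expect = -0.03 * np.interp(sub.q[win], sample.q, buf_ideal)
        np.testing.assert_allclose(sub.intensity[win], expect, rtol=0.05)

    def test_window_outside_range_raises(self):
        c = make_curve(qmax=0.08)
        with pytest.raises(ValueError, match="window"):
            subtract_buffer(c, c, q_window=(0.1, 0.7))


class TestCalibrate:
    def test_identity_and_linearity(self):
        c = make_curve()
        same = calibrate_intensity(c, 1.0, 1.0)
        np.testing.assert_allclose(same.intensity, c.intensity)
        half = calibrate_intensity(c, 2.0, 1.0)
        np.testing.assert_allclose(half.intensity, c.intensity / 2)
        assert half.meta["calibrated"]

    def test_i0_reads_as_molecular_weight(self):
        c = make_curve(i0=50.0)
        cal = calibrate_intensity(c, 0.5, 1000.0)   # x2000
        assert cal.intensity[0] == pytest.approx(
            50.0 * 2000 * np.exp(-c.q[0] ** 2 * 20 ** 2 / 3))

    def test_nonpositive_inputs_raise(self):
        c = make_curve()
        with pytest.raises(ValueError):
            calibrate_intensity(c, 0.0, 1.0)
        with pytest.raises(ValueError):
            calibrate_intensity(c, 1.0, -2.0)
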