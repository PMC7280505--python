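"""aEEG transform: filter response, envelope chain, segmentation, margins."""

import numpy as np
import pytest
from scipy import signal

from nvcwave import aeeg
from nvcwave.aeeg import (
    EPOCH_STEP_S,
    FilterSpec,
    GAIN_M1,
    GAIN_M2,
    M1_WINDOW_S,
    apply_fir,
    apply_gain,
    bandwidth,
    design_asymmetric_filter,
    envelope,
    epoch_count,
    epoch_geometry,
    extract_terminal_points,
    margins_m1,
    margins_m2,
    margins_m3,
    rectify,
    semilog_display,
)
from nvcwave.series import UniformSeries

RATE = 256.0


def series(values, rate=RATE):
    return UniformSeries(np.asarray(values, float), rate=rate, units="uV")


@pytest.fixture(scope="module")
def taps():
    return design_asymmetric_filter(RATE)


class TestAsymmetricFilter:
    def test_response_rises_12db_per_decade(self, taps):
        w, h = signal.freqz(taps, worN=8192, fs=RATE)
        mag = 20 * np.log10(np.abs(h) + 1e-12)

        def at(f):
            return mag[np.argmin(np.abs(w - f))]

        rise = at(15.0) - at(2.0)
        assert rise == pytest.approx(12 * np.log10(15 / 2), abs=0.8)

    def test_low_side_attenuation_floor(self, taps):
        w, h = signal.freqz(taps, worN=8192, fs=RATE)
        mag = 20 * np.log10(np.abs(h) + 1e-12)
        i05 = np.argmin(np.abs(w - 0.5))
        i2 = np.argmin(np.abs(w - 2.0))
        assert mag[i05] <= mag[i2] - 20.0

    def test_taps_symmetric_linear_phase(self, taps):
        assert np.allclose(taps, taps[::-1], atol=1e-12)

    def test_invalid_spec_rejected(self):
        with pytest.raises(ValueError):
            design_asymmetric_filter(RATE, FilterSpec(n_taps=400))
        with pytest.raises(ValueError):
            design_asymmetric_filter(20.0, FilterSpec())  # 15 Hz above Nyquist


class TestRectifyEnvelopeGain:
    def test_rectified_sine_nonnegative_with_mean_2_over_pi(self):
        t = np.arange(0, 60, 1 / RATE)
        r = rectify(series(np.sin(2 * np.pi * 10 * t)))
        assert np.all(r.values >= 0)
        assert r.values.mean() == pytest.approx(2 / np.pi, abs=1e-3)

    def test_rectify_zero_input(self):
        assert np.all(rectify(series(np.zeros(100))).values == 0)

    def test_envelope_dc_gain_unity(self):
        env = envelope(series(np.full(5000, 3.7)), cutoff_hz=1.0)
        assert env.values[2000:3000] == pytest.approx(3.7, rel=1e-6)

    def test_envelope_of_rectified_sine_near_its_mean(self):
        t = np.arange(0, 120, 1 / RATE)
        env = envelope(rectify(series(np.sin(2 * np.pi * 10 * t))), cutoff_hz=1.0)
        mid = env.values[len(env) // 4 : -len(env) // 4]
        assert mid.mean() == pytest.approx(2 / np.pi, rel=0.02)

    def test_envelope_zero_phase_preserves_symmetry(self):
        n = 8001
        pulse = np.exp(-0.5 * ((np.arange(n) - n // 2) / 200.0) ** 2)
        env = envelope(series(pulse), cutoff_hz=2.0).values
        assert np.allclose(env, env[::-1], atol=1e-8)

    def test_envelope_cutoff_above_nyquist_rejected(self):
        with pytest.raises(ValueError):
            envelope(series(np.ones(100)), cutoff_hz=200.0)

    def test_gain_values(self):
        x = series(np.ones(10))
        assert np.all(apply_gain(x, 1.0).values == x.values)
        assert np.all(apply_gain(x, GAIN_M1).values == 2.0)
        assert np.all(apply_gain(x, GAIN_M2).values == 1.631)


class TestTerminalPoints:
    def test_epoch_contains_1224_samples(self):
        geom = epoch_geometry(RATE)
        assert geom["epoch_samples"] == 1224
        assert geom["margin_rate_hz"] == pytest.approx(0.209, abs=0.209e-3)

    def test_constant_window_collapses_percentiles(self):
        tp = extract_terminal_points(series(np.full(4000, 5.0)), epoch_len_s=EPOCH_STEP_S, step_s=EPOCH_STEP_S)
        assert np.all(tp.utp == 5.0) and np.all(tp.ltp == 5.0)

    def test_ascending_window_matches_sort_interpolate_oracle(self):
        vals = np.arange(1.0, 1225.0)
        tp = extract_terminal_points(series(vals), epoch_len_s=EPOCH_STEP_S, step_s=EPOCH_STEP_S)
        # oracle: sort, then linear interpolation between order statistics
        srt = np.sort(vals)
        h = (len(srt) - 1) * 0.9
        expect = srt[int(h)] + (h - int(h)) * (srt[int(h) + 1] - srt[int(h)])
        assert tp.utp[0] == pytest.approx(expect, rel=1e-12)

    def test_random_windows_match_oracle(self, rng):
        """1000 random windows against an independent sort-and-interpolate oracle."""
        win = 97
        x = rng.standard_normal(1000 * win).clip(-5, 5) + 6.0
        tp = extract_terminal_points(series(x, rate=1.0), epoch_len_s=win, step_s=win)
        for i in range(0, 1000, 7):
            w = np.sort(x[i * win : (i + 1) * win])
            for q, got in ((0.9, tp.utp[i]), (0.1, tp.ltp[i])):
                h = (win - 1) * q
                lo = int(np.floor(h))
                expect = w[lo] + (h - lo) * (w[lo + 1] - w[lo])
                assert got == pytest.approx(expect, rel=1e-12)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            extract_terminal_points(series(np.ones(100)))


class TestMargins:
    def test_m1_window_overlap_and_rate(self):
        geom = epoch_geometry(RATE)
        assert geom["m1_overlap_s"] == pytest.approx(10.22, abs=0.01)
        x = series(np.abs(np.random.default_rng(0).standard_normal(256 * 120)))
        tr = margins_m1(x)
        assert tr.rate == pytest.approx(0.209, abs=0.209e-3)
        assert len(tr.uma) == epoch_count(256 * 120, 3840, 1224)

    def test_constant_envelope_collapses_margins(self):
        x = series(np.full(256 * 60, 4.0))
        for f in (margins_m1, margins_m2):
            tr = f(x)
            assert np.allclose(tr.uma.values, 4.0) and np.allclose(tr.lma.values, 4.0)
            assert np.allclose(bandwidth(tr).values, 0.0)

    def test_m2_equals_three_point_average_of_terminal_points(self, rng):
        x = series(np.abs(rng.standard_normal(256 * 60)))
        tp = extract_terminal_points(x, epoch_len_s=EPOCH_STEP_S, step_s=EPOCH_STEP_S)
        tr = margins_m2(x)
        # interior oracle: plain 3-point centered mean
        for i in range(1, len(tr.uma) - 1):
            assert tr.uma.values[i] == pytest.approx(tp.utp[i - 1 : i + 2].mean(), rel=1e-12)
            assert tr.lma.values[i] == pytest.approx(tp.ltp[i - 1 : i + 2].mean(), rel=1e-12)

    def test_m3_shares_m1_segmentation(self, rng):
        x = series(np.abs(rng.standard_normal(256 * 120)))
        m1 = margins_m1(x)
        m3 = margins_m3(x)
        assert np.array_equal(m1.uma.values, m3.uma.values)
        assert np.array_equal(m1.lma.values, m3.lma.values)
        assert m3.method == "M3"

    def test_m3_rejects_negative_input(self):
        with pytest.raises(ValueError, match="nonnegative"):
            margins_m3(series(np.linspace(-1, 1, 256 * 60)))

    def test_margin_ordering_invariant(self, rng):
        x = series(np.abs(rng.standard_normal(256 * 120)) * 20)
        for f in (margins_m1, margins_m2):
            tr = f(x)
            assert np.all(tr.uma.values >= tr.lma.values)
            assert np.all(tr.lma.values >= 0)

    @pytest.mark.parametrize("k", [0.5, 3.0])
    def test_scaling_equivariance_of_full_chain(self, k, taps, rng):
        """All stages are positively homogeneous: scaling EEG by k scales margins by k."""
        raw = series(rng.standard_normal(256 * 90) * 30)

        def chain(x):
            env = envelope(rectify(apply_fir(x, taps)), cutoff_hz=1.0)
            return margins_m1(apply_gain(env, GAIN_M1))

        a = chain(raw)
        b = chain(raw.with_values(k * raw.values))
        assert np.allclose(b.uma.values, k * a.uma.values, rtol=1e-9)
        assert np.allclose(bandwidth(b).values, k * bandwidth(a).values, rtol=1e-9, atol=1e-12)


class TestSemilogDisplay:
    @pytest.mark.parametrize("v,expect", [(5.0, 5.0), (10.0, 10.0), (100.0, 20.0), (0.0, 0.0)])
    def test_piecewise_values(self, v, expect):
        assert semilog_display(v) == pytest.approx(expect)

    def test_monotone_and_continuous(self):
        v = np.linspace(0, 120, 5000)
        d = semilog_display(v)
        assert np.all(np.diff(d) > 0)
        assert semilog_display(10.0 + 1e-9) == pytest.approx(10.0, abs=1e-6)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            semilog_display(-1.0)


class TestMethodInvariance:
    def test_m1_and_m2_bandwidth_share_modulation_peak(self, short_recording):
        """Slow amplitude dynamics survive both algorithms at the same period."""
        rec = short_recording  # 600 s modulation, strength 1
        taps = design_asymmetric_filter(rec.eeg.rate)
        env = envelope(rectify(apply_fir(rec.eeg, taps)), cutoff_hz=1.0)
        peaks = {}
        for name, f, g in (("M1", margins_m1, GAIN_M1), ("M2", margins_m2, GAIN_M2)):
            bw = bandwidth(f(apply_gain(env, g)))
            fr, p = signal.periodogram(bw.values - bw.values.mean(), fs=bw.rate)
            peaks[name] = 1.0 / fr[np.argmax(p)]
        assert peaks["M1"] == pytest.approx(600.0, rel=0.15)
        assert peaks["M1"] == pytest.approx(peaks["M2"], rel=0.1)
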