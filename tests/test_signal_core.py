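"""Signal primitives: filtering, envelopes, profiles, windowing, DFA."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocrit.datatypes import Band, TimeSeries
from neurocrit.signal_core import (
    DFA,
    amplitude_envelope,
    bandpass,
    dfa,
    signal_profile,
    split_windows,
)
from neurocrit.synthetic import fgn

from conftest import FS, tone

LOW_ALPHA = Band(8.3, 10.5)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        ts = tone(10.0, duration_s=20.0)
        out, edge = bandpass(ts, LOW_ALPHA)
        core = out.samples[0][edge:-edge]
        assert np.abs(core).max() == pytest.approx(1.0, abs=0.05)

    def test_out_of_band_tone_rejected(self):
        ts = tone(20.0, duration_s=20.0)
        out, edge = bandpass(ts, LOW_ALPHA)
        assert np.abs(out.samples[0][edge:-edge]).max() < 0.1

    def test_white_noise_variance_follows_parseval(self):
        rng = np.random.default_rng(0)
        ts = TimeSeries(rng.standard_normal(60 * int(FS)), FS)
        out, edge = bandpass(ts, LOW_ALPHA)
        expected = (LOW_ALPHA.f_hi - LOW_ALPHA.f_lo) / (FS / 2)
        ratio = out.samples[0][edge:-edge].var() / ts.samples[0].var()
        assert ratio == pytest.approx(expected, rel=0.2)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            bandpass(tone(10.0), Band(100.0, 130.0))


class TestAmplitudeEnvelope:
    def test_constant_tone(self):
        ts = tone(10.0, amp=0.7)
        env = amplitude_envelope(ts.samples[0])
        core = env[int(FS) : -int(FS)]
        assert np.allclose(core, 0.7, rtol=0.01)

    def test_am_identity(self):
        t = np.arange(int(30 * FS)) / FS
        a = 1 + 0.5 * np.sin(2 * np.pi * 0.2 * t)
        env = amplitude_envelope(a * np.sin(2 * np.pi * 10 * t))
        core = slice(int(FS), -int(FS))
        assert np.max(np.abs(env[core] - a[core]) / a[core]) < 0.05

    def test_matches_fft_half_spectrum_oracle(self):
        # analytic signal built explicitly: zero negative frequencies, double positive
        rng = np.random.default_rng(3)
        x = rng.standard_normal(4096)
        ts = TimeSeries(x, FS)
        filt, _ = bandpass(ts, LOW_ALPHA)
        y = filt.samples[0]
        spec = np.fft.fft(y)
        h = np.zeros(len(y))
        h[0] = 1
        h[1 : len(y) // 2] = 2
        h[len(y) // 2] = 1
        oracle = np.abs(np.fft.ifft(spec * h))
        assert np.allclose(amplitude_envelope(y), oracle, atol=1e-10)

    def test_sign_flip_invariance(self):
        ts = tone(10.0)
        filt, _ = bandpass(ts, LOW_ALPHA)
        e1 = amplitude_envelope(filt.samples[0])
        filt2, _ = bandpass(TimeSeries(-ts.samples[0], FS), LOW_ALPHA)
        e2 = amplitude_envelope(filt2.samples[0])
        assert np.allclose(e1, e2, atol=1e-12)


class TestSignalProfile:
    def test_hand_computed(self):
        assert np.allclose(signal_profile([1.0, 2.0, 3.0]), [-1.0, -1.0, 0.0])

    def test_constant_envelope_gives_zero_profile(self):
        assert np.allclose(signal_profile(np.full(100, 2.5)), 0.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            signal_profile(np.array([]))

    @given(st.integers(0, 2**31 - 1), st.integers(10, 400))
    @settings(max_examples=30, deadline=None)
    def test_endpoint_telescopes_to_zero(self, seed, n):
        a = np.random.default_rng(seed).uniform(0, 5, size=n)
        s = signal_profile(a)
        assert abs(s[-1]) < 1e-9 * n * max(a.max(), 1.0)


class TestSplitWindows:
    def test_example_grid(self):
        ws = split_windows(2000, 100.0, window_s=5.0, overlap=0.8)
        assert ws.n_windows == 16
        assert np.array_equal(ws.starts, np.arange(16) * 100)

    def test_single_window(self):
        ws = split_windows(500, 100.0, window_s=5.0, overlap=0.8)
        assert ws.n_windows == 1

    def test_disjoint_tiling(self):
        ws = split_windows(2000, 100.0, window_s=5.0, overlap=0.0)
        assert ws.n_windows == 4
        assert np.array_equal(ws.starts, [0, 500, 1000, 1500])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError, match="too short"):
            split_windows(400, 100.0, window_s=5.0)

    @given(
        n=st.integers(100, 5000),
        fs=st.sampled_from([100.0, 250.0]),
        window_s=st.sampled_from([1.0, 2.5, 5.0]),
        overlap=st.sampled_from([0.0, 0.5, 0.8]),
    )
    @settings(max_examples=60, deadline=None)
    def test_count_formula_exact(self, n, fs, window_s, overlap):
        n_per = int(round(window_s * fs))
        if n < n_per:
            return
        ws = split_windows(n, fs, window_s, overlap)
        step = max(int(round(n_per * (1 - overlap))), 1)
        assert ws.n_windows == (n - n_per) // step + 1
        assert ws.starts[-1] + n_per <= n


def _dfa_reference(env, fs, fit_range_s=(2.0, 20.0), n_sizes=10, overlap=0.5):
    """Naive loop implementation following the procedure literally."""
    env = np.asarray(env, dtype=float)
    profile = np.cumsum(env - env.mean())
    sizes = np.unique(np.round(np.geomspace(*fit_range_s, n_sizes) * fs).astype(int))
    sizes = sizes[(sizes >= 4) & (sizes <= env.size // 2)]
    flucts = []
    for n_per in sizes:
        step = max(int(round(n_per * (1 - overlap))), 1)
        rmss = []
        start = 0
        while start + n_per <= profile.size:
            seg = profile[start : start + n_per]
            t = np.arange(n_per, dtype=float)
            coef = np.polyfit(t, seg, 1)
            resid = seg - np.polyval(coef, t)
            rmss.append(np.sqrt(np.mean(resid**2)))
            start += step
        flucts.append(np.mean(rmss))
    slope, _ = np.polyfit(np.log10(sizes / fs), np.log10(flucts), 1)
    return slope


class TestDFA:
    def test_white_noise_envelope_near_half(self):
        # uncorrelated fluctuations: exponent at the theoretical 0.5
        exps = [
            dfa(np.random.default_rng(s).standard_normal(75000), FS).exponent
            for s in range(20)
        ]
        assert np.mean(exps) == pytest.approx(0.5, abs=0.05)

    def test_fgn_recovery(self):
        exps = [dfa(fgn(75000, 0.8, np.random.default_rng(s)), FS).exponent for s in range(20)]
        assert np.mean(exps) == pytest.approx(0.8, abs=0.07)

    def test_matches_naive_reference(self):
        env = np.abs(np.random.default_rng(5).standard_normal(2500)) + 0.1
        mine = dfa(env, FS, fit_range_s=(0.2, 2.0), n_sizes=6)
        ref = _dfa_reference(env, FS, fit_range_s=(0.2, 2.0), n_sizes=6)
        assert mine.exponent == pytest.approx(ref, abs=1e-10)

    @pytest.mark.parametrize("c", [0.3, 1.0, 250.0])
    def test_amplitude_scale_invariance(self, c):
        env = np.abs(np.random.default_rng(8).standard_normal(75000)) + 0.1
        assert dfa(c * env, FS).exponent == pytest.approx(dfa(env, FS).exponent, abs=1e-12)

    def test_monotone_in_hurst(self):
        means = []
        for h in (0.6, 0.7, 0.8):
            means.append(
                np.mean([dfa(fgn(75000, h, np.random.default_rng(s)), FS).exponent for s in range(20)])
            )
        assert means[0] < means[1] < means[2]

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="zero-variance"):
            dfa(np.ones(10000), FS)
        with pytest.raises(ValueError, match="fewer than 2"):
            dfa(np.random.default_rng(0).standard_normal(100), FS)

    def test_estimator_facade(self):
        env = np.abs(np.random.default_rng(2).standard_normal(75000)) + 0.1
        est = DFA(fs=FS).fit(env)
        assert est.exponent_ == pytest.approx(dfa(env, FS).exponent)
        assert est.get_params()["fit_range_s"] == (2.0, 20.0)
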