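"""Signal primitives: band-pass filtering, envelopes, profiles, windows, DFA.

These are the shared building blocks of both criticality biomarkers. The
filter is a zero-phase linear-phase FIR (Hamming-window design, 1 Hz
transition width) applied by convolution with explicit delay compensation,
so envelopes are not phase-distorted. Edge samples equal to the filter
half-length are contaminated by the convolution boundary and should be
trimmed before envelope statistics; :func:`bandpass` records that length.
"""

from __future__ import annotations

import numpy as np
from scipy import signal as sps
from sklearn.base import BaseEstimator

from .datatypes import Band, DfaResult, TimeSeries, WindowSet

__all__ = [
    "bandpass",
    "amplitude_envelope",
    "signal_profile",
    "split_windows",
    "dfa",
    "DFA",
    "design_fir",
]

#: FIR transition width in Hz used for all band-pass filters.
FIR_TRANSITION_HZ = 1.0


def design_fir(band: Band, fs: float, transition_hz: float = FIR_TRANSITION_HZ) -> np.ndarray:
    """Design an odd-length linear-phase band-pass FIR (Hamming window).

    The number of taps follows the Hamming-window rule of thumb
    ``N ~ 3.3 * fs / transition``, forced odd so the group delay is an
    integer number of samples.
    """
    band.validate_for_fs(fs)
    n_taps = int(np.ceil(3.3 * fs / transition_hz))
    n_taps += 1 - n_taps % 2  # force odd
    return sps.firwin(n_taps, [band.f_lo, band.f_hi], pass_zero=False, fs=fs, window="hamming")


def bandpass(ts: TimeSeries, band: Band) -> tuple[TimeSeries, int]:
    """Zero-phase band-pass filter every channel of ``ts``.

    Returns the filtered :class:`TimeSeries` (same length as the input) and
    the number of edge samples per side that are unreliable (half the filter
    length) and should be excluded from envelope-based statistics.
    """
    taps = design_fir(band, ts.fs)
    half = len(taps) // 2
    out = np.empty_like(ts.samples)
    for i in range(ts.n_channels):
        # 'same'-mode FFT convolution of a symmetric FIR == zero-phase filtering
        full = sps.fftconvolve(ts.samples[i], taps, mode="full")
        out[i] = full[half : half + ts.n_samples]
    return TimeSeries(out, ts.fs, list(ts.labels)), half


def amplitude_envelope(x: np.ndarray) -> np.ndarray:
    """Amplitude envelope of a narrow-band signal via the analytic signal.

    For an AM tone ``a(t) sin(2 pi f t)`` with slowly varying non-negative
    ``a(t)`` this recovers ``a(t)`` away from the signal edges.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    env = np.abs(sps.hilbert(x, axis=-1))
    return env[0] if env.shape[0] == 1 else env


def signal_profile(env: np.ndarray) -> np.ndarray:
    """Cumulative sum of the demeaned amplitude envelope.

    ``S(t) = sum_{k<=t} (A(k) - <A>)``; by construction the last sample is
    zero up to floating-point rounding.
    """
    env = np.asarray(env, dtype=float)
    if env.size == 0:
        raise ValueError("empty envelope")
    if not np.isfinite(env).all():
        raise ValueError("envelope contains non-finite values")
    return np.cumsum(env - env.mean())


def split_windows(n_samples: int, fs: float, window_s: float = 5.0, overlap: float = 0.8) -> WindowSet:
    """Maximal set of fully contained windows with the given size and overlap.

    The hop between consecutive window starts is
    ``round(window_s * fs * (1 - overlap))`` samples.
    """
    if not 0 <= overlap < 1:
        raise ValueError(f"overlap must be in [0, 1), got {overlap}")
    n_per = int(round(window_s * fs))
    if n_per < 2:
        raise ValueError(f"window of {window_s} s is shorter than 2 samples at fs={fs}")
    if n_samples < n_per:
        raise ValueError(
            f"signal too short: {n_samples} samples < one window of {n_per} samples"
        )
    step = int(round(n_per * (1 - overlap)))
    step = max(step, 1)
    starts = np.arange(0, n_samples - n_per + 1, step, dtype=int)
    return WindowSet(window_s=window_s, overlap=overlap, starts=starts, n_per_window=n_per, fs=fs)


def _detrended_rms(segments: np.ndarray) -> np.ndarray:
    """RMS of each row after removing its least-squares linear trend."""
    n = segments.shape[1]
    t = np.arange(n, dtype=float)
    t -= t.mean()
    # projection of each row onto [1, t]
    seg = segments - segments.mean(axis=1, keepdims=True)
    slope = seg @ t / (t @ t)
    resid = seg - slope[:, None] * t[None, :]
    return np.sqrt(np.mean(resid**2, axis=1))


def _log_spaced_sizes(fit_range_s: tuple[float, float], n_sizes: int, fs: float) -> np.ndarray:
    sizes = np.geomspace(fit_range_s[0], fit_range_s[1], n_sizes)
    # snap to whole samples, keep unique
    n_per = np.unique(np.round(sizes * fs).astype(int))
    return n_per[n_per >= 4]


def dfa(
    env: np.ndarray,
    fs: float,
    fit_range_s: tuple[float, float] = (2.0, 20.0),
    n_sizes: int = 10,
    overlap: float = 0.5,
) -> DfaResult:
    """Detrended fluctuation analysis of an amplitude envelope.

    For each log-spaced window size the demeaned-envelope profile is split
    into windows (``overlap`` fraction inside the DFA, default 50%), each
    window is linearly detrended, and the fluctuation for that size is the
    mean across windows of the per-window RMS. The scaling exponent is the
    least-squares slope of log10 fluctuation versus log10 window size.
    """
    env = np.asarray(env, dtype=float)
    if env.ndim != 1:
        raise ValueError("dfa expects a 1-D envelope")
    if env.std() == 0:
        raise ValueError("zero-variance envelope: DFA undefined")
    sizes_samples = _log_spaced_sizes(fit_range_s, n_sizes, fs)
    sizes_samples = sizes_samples[sizes_samples <= env.size // 2]
    if len(sizes_samples) < 2:
        raise ValueError(
            f"fewer than 2 usable window sizes for an envelope of {env.size} samples"
        )
    profile = signal_profile(env)
    fluct = np.empty(len(sizes_samples))
    for k, n_per in enumerate(sizes_samples):
        ws = split_windows(profile.size, fs, window_s=n_per / fs, overlap=overlap)
        fluct[k] = _detrended_rms(ws.segments(profile)).mean()
    sizes_s = sizes_samples / fs
    lx, ly = np.log10(sizes_s), np.log10(fluct)
    slope, intercept = np.polyfit(lx, ly, 1)
    pred = slope * lx + intercept
    ss_res = np.sum((ly - pred) ** 2)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return DfaResult(
        window_sizes_s=sizes_s,
        fluctuation=fluct,
        exponent=float(slope),
        fit_range_s=tuple(fit_range_s),
        r2=float(r2),
    )


class DFA(BaseEstimator):
    """Detrended fluctuation analysis as an estimator.

    Parameters
    ----------
    fs : float
        Sampling rate of the envelope in Hz.
    fit_range_s : tuple of float
        (min, max) window size in seconds for the log-log fit. The default
        2-20 s keeps the lower bound above two periods of the lowest alpha
        band edge, where filter-induced correlations would bias the slope.
    n_sizes : int
        Number of log-spaced window sizes.
    overlap : float
        Window overlap fraction inside the DFA.

    Attributes
    ----------
    exponent_ : float
        Fitted scaling exponent.
    result_ : DfaResult
        Full fluctuation function and fit diagnostics.
    """

    def __init__(
        self,
        fs: float = 250.0,
        fit_range_s: tuple[float, float] = (2.0, 20.0),
        n_sizes: int = 10,
        overlap: float = 0.5,
    ) -> None:
        self.fs = fs
        self.fit_range_s = fit_range_s
        self.n_sizes = n_sizes
        self.overlap = overlap

    def fit(self, X: np.ndarray, y=None) -> "DFA":
        """Compute the DFA of a 1-D amplitude envelope ``X``."""
        self.result_ = dfa(X, self.fs, self.fit_range_s, self.n_sizes, self.overlap)
        self.exponent_ = self.result_.exponent
        return self
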