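"""Functional excitation/inhibition ratio (fE/I).

The fE/I biomarker quantifies the covariance between the amplitude of a
narrow-band oscillation and the long-range-temporal-correlation structure of
its envelope: (1) band-pass the signal, (2) extract the amplitude envelope
A, (3) form the signal profile S (cumulative sum of the demeaned envelope)
and split it into overlapping windows, (4) divide each profile window by the
mean envelope of that window, (5) linearly detrend, (6) take the standard
deviation — the normalized fluctuation nF — and (7) correlate windowed
amplitude with nF across windows:

    fE/I = 1 - r(W_amp, W_nF)

fE/I = 1 indicates a critical network, < 1 a subcritical
(inhibition-dominated) one, > 1 a super-critical (excitation-dominated)
one. Because envelopes without long-range temporal correlations do not
carry this covariance, fE/I is only reported when the envelope's DFA
exponent exceeds a gate (default 0.6); gated results carry NaN.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator

from .datatypes import Band, FeiResult, TimeSeries, WindowSet, LOW_ALPHA, HIGH_ALPHA
from .signal_core import amplitude_envelope, bandpass, dfa, signal_profile, split_windows

__all__ = ["normalized_fluctuation", "compute_fei", "compute_fei_iaf", "FEI", "MIN_VALID_WINDOWS"]

#: minimum number of usable windows for a Pearson correlation we trust.
MIN_VALID_WINDOWS = 10


def normalized_fluctuation(env: np.ndarray, windows: WindowSet) -> tuple[np.ndarray, np.ndarray]:
    """Windowed amplitude and amplitude-normalized fluctuation of an envelope.

    Per window ``w``: ``amp_w`` is the mean envelope; the signal-profile
    segment for ``w`` is divided by ``amp_w``, linearly detrended, and
    ``nF_w`` is the standard deviation of the result. Windows with zero
    mean amplitude are dropped from both series (pairwise).
    """
    env = np.asarray(env, dtype=float)
    if windows.n_windows < 2:
        raise ValueError("need at least 2 windows")
    profile = signal_profile(env)
    amps = windows.segments(env).mean(axis=1)
    segs = windows.segments(profile)
    keep = amps != 0
    amps, segs = amps[keep], segs[keep]
    norm = segs / amps[:, None]
    n = norm.shape[1]
    t = np.arange(n, dtype=float)
    t -= t.mean()
    centered = norm - norm.mean(axis=1, keepdims=True)
    slope = centered @ t / (t @ t)
    resid = centered - slope[:, None] * t[None, :]
    nf = resid.std(axis=1)
    return amps, nf


def _fei_from_series(
    amps: np.ndarray, nf: np.ndarray, dfa_exponent: float, dfa_gate: float
) -> FeiResult:
    n = len(amps)
    base = dict(window_amplitudes=amps, window_nf=nf, n_windows=n, dfa_exponent=dfa_exponent)
    if n < MIN_VALID_WINDOWS:
        return FeiResult(fei=np.nan, r=np.nan, valid=False, reason="too few windows", **base)
    if amps.std() == 0 or nf.std() == 0:
        return FeiResult(fei=np.nan, r=np.nan, valid=False, reason="zero variance", **base)
    if not dfa_exponent > dfa_gate:
        return FeiResult(fei=np.nan, r=np.nan, valid=False, reason="dfa gate", **base)
    r = float(np.corrcoef(amps, nf)[0, 1])
    return FeiResult(fei=1.0 - r, r=r, valid=True, reason="", **base)


def compute_fei(
    ts: TimeSeries,
    band: Band,
    window_s: float = 5.0,
    overlap: float = 0.8,
    dfa_gate: float = 0.6,
    dfa_fit_range_s: tuple[float, float] = (2.0, 20.0),
    channel: int = 0,
) -> FeiResult:
    """fE/I of one channel in one band (steps 1-7 plus the DFA gate).

    The DFA gate is evaluated on the full-signal envelope of the same band
    (signal-level gating, not per window). When the exponent does not
    exceed ``dfa_gate`` the result is flagged invalid and fE/I is NaN.
    """
    filtered, edge = bandpass(ts, band)
    env = amplitude_envelope(filtered.samples[channel])
    env = env[edge : env.size - edge] if env.size > 2 * edge else env
    exponent = dfa(env, ts.fs, fit_range_s=dfa_fit_range_s).exponent
    windows = split_windows(env.size, ts.fs, window_s=window_s, overlap=overlap)
    amps, nf = normalized_fluctuation(env, windows)
    return _fei_from_series(amps, nf, exponent, dfa_gate)


def compute_fei_iaf(
    ts: TimeSeries,
    paf: float,
    window_s: float = 5.0,
    overlap: float = 0.8,
    dfa_gate: float = 0.6,
    channel: int = 0,
) -> tuple[FeiResult, FeiResult]:
    """fE/I on the two halves of the individualized alpha band.

    The IAF band is [paf - 2, paf + 2] Hz; each half-band ([paf - 2, paf]
    and [paf, paf + 2]) is processed independently by :func:`compute_fei`.
    A missing (NaN) peak alpha frequency yields two invalid results with
    reason "no alpha peak".
    """
    if not np.isfinite(paf):
        empty = np.array([])
        miss = FeiResult(
            fei=np.nan, r=np.nan, window_amplitudes=empty, window_nf=empty,
            n_windows=0, dfa_exponent=np.nan, valid=False, reason="no alpha peak",
        )
        return miss, miss
    if not 6 <= paf <= 14:
        raise ValueError(f"peak alpha frequency must be in [6, 14] Hz, got {paf}")
    low = Band(paf - 2.0, paf)
    high = Band(paf, paf + 2.0)
    return (
        compute_fei(ts, low, window_s, overlap, dfa_gate, channel=channel),
        compute_fei(ts, high, window_s, overlap, dfa_gate, channel=channel),
    )


class FEI(BaseEstimator):
    """fE/I as an estimator over a single-channel signal array.

    Parameters mirror :func:`compute_fei`; ``fit(X)`` accepts a 1-D sample
    array at ``fs`` Hz and exposes ``fei_``, ``r_``, ``dfa_exponent_``,
    ``valid_`` and the full ``result_``. Scaling the input by any positive
    constant leaves every fitted attribute unchanged.
    """

    def __init__(
        self,
        fs: float = 250.0,
        band: Band = LOW_ALPHA,
        window_s: float = 5.0,
        overlap: float = 0.8,
        dfa_gate: float = 0.6,
        dfa_fit_range_s: tuple[float, float] = (2.0, 20.0),
    ) -> None:
        self.fs = fs
        self.band = band
        self.window_s = window_s
        self.overlap = overlap
        self.dfa_gate = dfa_gate
        self.dfa_fit_range_s = dfa_fit_range_s

    def fit(self, X: np.ndarray, y=None) -> "FEI":
        ts = TimeSeries(np.asarray(X, dtype=float), self.fs)
        self.result_ = compute_fei(
            ts,
            self.band,
            window_s=self.window_s,
            overlap=self.overlap,
            dfa_gate=self.dfa_gate,
            dfa_fit_range_s=self.dfa_fit_range_s,
        )
        self.fei_ = self.result_.fei
        self.r_ = self.result_.r
        self.dfa_exponent_ = self.result_.dfa_exponent
        self.valid_ = self.result_.valid
        return self


# re-export the default analysis bands for convenience
FIXED_BANDS = (LOW_ALPHA, HIGH_ALPHA)
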