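"""Shared containers for signals, windows, and biomarker results.

Everything downstream (DFA, fE/I, spectral parameterization, network
aggregation) consumes or produces one of these lightweight dataclasses.
Arrays are always float64 numpy arrays; sampling rates are in Hz, window
and fit-range parameters in seconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "TimeSeries",
    "Band",
    "WindowSet",
    "DfaResult",
    "FeiResult",
    "SpectralFit",
]


@dataclass
class TimeSeries:
    """Sampled multichannel signal.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal amplitude in microvolts. A 1-D array is promoted to a
        single channel.
    fs : float
        Sampling rate in Hz, must be positive.
    labels : list of str
        One label per channel.
    """

    samples: np.ndarray
    fs: float
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim == 1:
            self.samples = self.samples[np.newaxis, :]
        if self.samples.ndim != 2:
            raise ValueError("samples must be 1-D or 2-D (channels x samples)")
        if not np.isfinite(self.samples).all():
            raise ValueError("samples contain non-finite values")
        if not (np.isfinite(self.fs) and self.fs > 0):
            raise ValueError(f"fs must be a positive finite number, got {self.fs}")
        if not self.labels:
            self.labels = [f"ch{i}" for i in range(self.samples.shape[0])]
        if len(self.labels) != self.samples.shape[0]:
            raise ValueError("number of labels must match number of channels")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D sample array for a channel by label."""
        try:
            idx = self.labels.index(label)
        except ValueError as err:
            raise KeyError(f"no channel labelled {label!r}") from err
        return self.samples[idx]


@dataclass(frozen=True)
class Band:
    """A frequency band [f_lo, f_hi] in Hz, f_lo < f_hi."""

    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not (0 < self.f_lo < self.f_hi):
            raise ValueError(f"need 0 < f_lo < f_hi, got ({self.f_lo}, {self.f_hi})")

    def validate_for_fs(self, fs: float) -> None:
        if self.f_hi >= fs / 2:
            raise ValueError(
                f"band upper edge {self.f_hi} Hz is at or above Nyquist ({fs / 2} Hz)"
            )

    @property
    def center(self) -> float:
        return 0.5 * (self.f_lo + self.f_hi)


# The two log-spaced alpha sub-bands used for the fixed-band analyses.
LOW_ALPHA = Band(8.3, 10.5)
HIGH_ALPHA = Band(10.5, 13.4)


@dataclass(frozen=True)
class WindowSet:
    """Deterministic segmentation of a signal into overlapping windows."""

    window_s: float
    overlap: float
    starts: np.ndarray  # sample offsets, int
    n_per_window: int
    fs: float

    @property
    def n_windows(self) -> int:
        return len(self.starts)

    def segments(self, x: np.ndarray) -> np.ndarray:
        """Stack windows of ``x`` into an (n_windows, n_per_window) matrix."""
        x = np.asarray(x)
        return np.stack([x[s : s + self.n_per_window] for s in self.starts])


@dataclass
class DfaResult:
    """Detrended fluctuation analysis output.

    ``exponent`` is the log-log slope of the fluctuation function over
    ``fit_range_s``; 0.5 means temporally uncorrelated fluctuations and
    values approaching 1 indicate strong long-range temporal correlations.
    """

    window_sizes_s: np.ndarray
    fluctuation: np.ndarray
    exponent: float
    fit_range_s: tuple[float, float]
    r2: float


@dataclass
class FeiResult:
    """Functional excitation/inhibition ratio for one channel and band.

    ``fei = 1 - r`` where ``r`` is the Pearson correlation between windowed
    oscillation amplitude and the amplitude-normalized fluctuation of the
    signal profile. ``fei`` is NaN when the result is not valid (DFA gate
    failed, too few windows, or degenerate variance); ``reason`` says why.
    """

    fei: float
    r: float
    window_amplitudes: np.ndarray
    window_nf: np.ndarray
    n_windows: int
    dfa_exponent: float
    valid: bool
    reason: str = ""

    def __post_init__(self) -> None:
        if self.valid and not np.isfinite(self.fei):
            raise ValueError("valid result must carry a finite fE/I value")


@dataclass
class SpectralFit:
    """Spectral parameterization: aperiodic component plus Gaussian peaks.

    ``beta`` is the aperiodic exponent of the 1/f^beta background (positive
    beta = decaying spectrum); ``peaks`` is a list of (center_hz,
    height_log10, width_hz) with heights measured above the aperiodic fit
    on a log10-power scale. ``paf``/``peak_height`` are set in broadband
    (peak-alpha) mode and NaN when no alpha peak is detected.
    """

    freqs: np.ndarray
    psd: np.ndarray
    offset: float
    beta: float
    peaks: list[tuple[float, float, float]]
    fit_range: tuple[float, float]
    r2: float
    paf: float = float("nan")
    peak_height: float = float("nan")

    @property
    def has_alpha_peak(self) -> bool:
        return np.isfinite(self.paf)
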