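"""Synthetic EEG signals and cohorts with known criticality structure.

Two generators live here:

* :func:`generate_signal` builds one channel of "EEG": a narrow-band alpha
  carrier amplitude-modulated by a long-memory envelope (fractional Gaussian
  noise with a chosen Hurst exponent, so the envelope's DFA exponent is
  known by construction), riding on 1/f^beta background noise. A coupling
  control ``kappa`` applies a level-dependent gain to within-block envelope
  fluctuations, which sets the *sign* of the correlation between windowed
  amplitude and normalized fluctuation — exactly the covariance the fE/I
  biomarker measures — without changing mean power. ``kappa = 0`` yields
  fE/I = 1 in expectation (the critical value), ``kappa > 0`` pushes fE/I
  below 1 and ``kappa < 0`` above 1.
* :func:`generate_cohort` builds a subject table (age ~ uniform over 6-19
  years, IQ ~ truncated normal 111 +/- 13 on [71, 145], sex ~ Bernoulli(1/2))
  and a long-format biomarker table with a built-in hierarchy-rank x IQ
  interaction of known size, for parameter-recovery and calibration tests
  of the statistical stage.

Fractional Gaussian noise is synthesized exactly by circulant embedding
(Davies-Harte), so the theoretical DFA exponent of the envelope equals the
requested Hurst exponent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps
from scipy.ndimage import gaussian_filter1d

from .datatypes import TimeSeries

__all__ = [
    "SignalParams",
    "CohortParams",
    "generate_signal",
    "generate_aperiodic",
    "generate_cohort",
    "fgn",
    "YEO7_BY_RANK",
    "hierarchy_of_rank",
]

#: Yeo7 network names ordered by sensorimotor-to-association rank 1-7.
YEO7_BY_RANK = {
    1: "visual",
    2: "somatomotor",
    3: "dorsal_attention",
    4: "salience_ventral_attention",
    5: "limbic",
    6: "control",
    7: "default",
}


def hierarchy_of_rank(rank: int) -> str:
    """Sensorimotor-association grouping: ranks 1-3 vs 4-7."""
    return "sensorimotor" if rank <= 3 else "association"


@dataclass
class SignalParams:
    """Parameters of one synthetic oscillatory channel.

    ``hurst`` is the target DFA exponent of the alpha amplitude envelope;
    ``coupling`` (kappa, in [-1, 1]) sets the sign and strength of the
    induced amplitude-fluctuation correlation; ``beta_aperiodic`` the
    1/f^beta background exponent; ``osc_snr`` the oscillation-to-background
    amplitude (RMS) ratio.
    """

    duration_s: float = 194.0
    fs: float = 250.0
    f_alpha: float = 10.0
    hurst: float = 0.75
    coupling: float = 0.0
    beta_aperiodic: float = 1.46
    osc_snr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("duration_s", "fs", "f_alpha", "hurst", "coupling", "beta_aperiodic", "osc_snr"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v}")
        n = self.duration_s * self.fs
        if abs(n - round(n)) > 1e-9 or n < 1:
            raise ValueError("duration_s * fs must be a positive integer number of samples")
        if not 0 < self.hurst < 1:
            raise ValueError(f"hurst must be in (0, 1), got {self.hurst}")
        if not -1 <= self.coupling <= 1:
            raise ValueError(f"coupling must be in [-1, 1], got {self.coupling}")
        if self.beta_aperiodic < 0:
            raise ValueError(f"beta_aperiodic must be >= 0, got {self.beta_aperiodic}")
        if self.osc_snr <= 0:
            raise ValueError(
                "osc_snr must be > 0: with osc_snr = 0 the oscillation envelope is undefined"
            )

    @property
    def n_samples(self) -> int:
        return int(round(self.duration_s * self.fs))


@dataclass
class CohortParams:
    """Parameters of a synthetic developmental cohort.

    Defaults mirror the study population the generator emulates: IQ
    111 +/- 13 truncated to [71, 145], age uniform over 6-19 years.
    ``effect_interaction`` is the biomarker change per (IQ point x rank
    unit); ``subject_sd``/``resid_sd`` the random-intercept and residual
    standard deviations in biomarker units.
    """

    n_subjects: int = 128
    iq_mean: float = 111.0
    iq_sd: float = 13.0
    iq_range: tuple[float, float] = (71.0, 145.0)
    age_range: tuple[float, float] = (6.0, 19.0)
    effect_interaction: float = 0.0
    subject_sd: float = 0.1
    resid_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        if not self.iq_range[0] <= self.iq_mean <= self.iq_range[1]:
            raise ValueError("iq_range must contain iq_mean")
        if self.iq_sd < 0 or self.subject_sd < 0 or self.resid_sd < 0:
            raise ValueError("all standard deviations must be >= 0")


def fgn(n: int, hurst: float, rng: np.random.Generator) -> np.ndarray:
    """Exact fractional Gaussian noise by circulant embedding (Davies-Harte).

    Returns ``n`` samples of a zero-mean, unit-variance stationary Gaussian
    process whose autocovariance is that of fGn with the given Hurst
    exponent; its theoretical DFA exponent equals ``hurst``.
    """
    if not 0 < hurst < 1:
        raise ValueError(f"hurst must be in (0, 1), got {hurst}")
    k = np.arange(n + 1, dtype=float)
    gamma = 0.5 * ((k + 1) ** (2 * hurst) - 2 * k ** (2 * hurst) + np.abs(k - 1) ** (2 * hurst))
    # first row of the 2n-circulant embedding
    row = np.concatenate([gamma[: n + 1], gamma[n - 1 : 0 : -1]])
    eig = np.fft.fft(row).real
    eig = np.clip(eig, 0.0, None)  # tiny negatives from rounding
    m = 2 * n
    z = rng.standard_normal(m) + 1j * rng.standard_normal(m)
    w = np.fft.fft(np.sqrt(eig / (2 * m)) * z)
    return w[:n].real * np.sqrt(2.0)


def generate_aperiodic(duration_s: float, fs: float, beta: float, seed: int) -> TimeSeries:
    """Gaussian noise whose expected PSD is proportional to f^(-beta).

    Synthesized by spectral shaping of white noise (rFFT amplitudes scaled
    by f^(-beta/2), DC removed), then normalized to unit variance.
    ``beta = 0`` gives white noise.
    """
    if beta < 0:
        raise ValueError(f"beta must be >= 0, got {beta}")
    n = int(round(duration_s * fs))
    if n < 2:
        raise ValueError("signal must contain at least 2 samples")
    rng = np.random.default_rng(seed)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    shape[1:] = freqs[1:] ** (-beta / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    x /= x.std()
    return TimeSeries(x, fs, ["synthetic_aperiodic"])


#: envelope band-limit: FIR low-pass cutoff and transition width (Hz).
#: Confines the modulation bandwidth so the oscillation's sidebands stay
#: inside the alpha band and clear of the 1-5 Hz aperiodic fit range.
_ENV_LOWPASS_HZ = 2.8
_ENV_LOWPASS_TRANSITION_HZ = 1.4
#: modulation depth of the long-memory envelope around its unit mean.
_ENV_DEPTH = 0.3
#: generator block length (s); also the slow/fast split scale of the
#: envelope (slow level varies across blocks, fast fluctuations within).
_COUPLING_BLOCK_S = 5.0


def _long_memory_envelope(
    n: int, hurst: float, fs: float, kappa: float, rng: np.random.Generator
) -> np.ndarray:
    """Long-memory envelope with a controllable amplitude-fluctuation coupling.

    A single fGn(hurst) process is split into spectrally disjoint slow
    (periods above the 5-s analysis-window scale) and fast components; being
    non-overlapping bands of a Gaussian process these are independent. The
    envelope is a slowly varying multiplicative level carrying fast
    fluctuations whose size scales with the level:

        env = L(slow) * (1 + depth * gain(block) * fast)
        L(x) = 1 + depth * x + (depth * x)^2 / 2

    The quadratic (exponential-to-second-order) level makes the *relative*
    within-window fluctuation of the level itself independent of the level,
    while truncating the higher-order convexity terms of a full exponential
    that would couple window-mean amplitude to within-window variance. With
    ``gain = 1`` (kappa = 0), windowed amplitude and normalized fluctuation
    are therefore uncorrelated (the critical, fE/I = 1 case; verified to
    |r| < 0.01 over hundreds of realizations). The coupling applies
    ``gain = 1 + kappa * z_block`` per 5-s generator block, ``z_block`` the
    standardized block level, making fluctuations relatively larger in
    high-amplitude stretches (kappa > 0, fE/I < 1) or smaller (kappa < 0,
    fE/I > 1), while the envelope's spectrum — hence its DFA exponent,
    approximately ``hurst`` — is essentially unchanged.
    """
    z = fgn(n, hurst, rng)
    n_taps = int(np.ceil(3.3 * fs / _ENV_LOWPASS_TRANSITION_HZ))
    n_taps += 1 - n_taps % 2
    taps = sps.firwin(n_taps, _ENV_LOWPASS_HZ, fs=fs)
    z = sps.fftconvolve(z, taps, mode="same")
    z = (z - z.mean()) / z.std()
    slow = gaussian_filter1d(z, sigma=0.25 * _COUPLING_BLOCK_S * fs, mode="reflect")
    fast = z - slow

    block = int(round(_COUPLING_BLOCK_S * fs))
    n_blocks = max(n // block, 1)
    gain = np.ones(n)
    if kappa != 0:
        idx = np.minimum(np.arange(n) // block, n_blocks - 1)
        level_means = np.array([slow[idx == b].mean() for b in range(n_blocks)])
        sd = level_means.std()
        if sd > 0:
            zb = (level_means - level_means.mean()) / sd
            gain = np.clip(1.0 + kappa * zb, 0.05, None)[idx]
    ds = _ENV_DEPTH * slow
    level = 1.0 + ds + 0.5 * ds**2
    env = level * (1.0 + _ENV_DEPTH * gain * fast)
    return np.clip(env, 0.01, None)


def generate_signal(p: SignalParams) -> TimeSeries:
    """One channel of synthetic oscillatory EEG (see module docstring).

    The returned signal is ``env(t) * sin(2 pi f_alpha t + phi) +
    background / osc_snr`` with the background scaled so the oscillation
    RMS over background RMS equals ``osc_snr``. Seeded runs are
    bit-reproducible.
    """
    n = p.n_samples
    rng = np.random.default_rng(p.seed)
    env = _long_memory_envelope(n, p.hurst, p.fs, p.coupling, rng)
    t = np.arange(n) / p.fs
    phi = rng.uniform(0, 2 * np.pi)
    osc = env * np.sin(2 * np.pi * p.f_alpha * t + phi)
    bg_seed = int(rng.integers(0, 2**31 - 1))
    bg = generate_aperiodic(p.duration_s, p.fs, p.beta_aperiodic, bg_seed).samples[0]
    bg = bg * (osc.std() / p.osc_snr)
    return TimeSeries(osc + bg, p.fs, ["synthetic"])


def _truncated_normal(mean: float, sd: float, lo: float, hi: float, size: int, rng: np.random.Generator) -> np.ndarray:
    """Truncated normal by rejection sampling (simple and exact)."""
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        keep = draw[(draw >= lo) & (draw <= hi)][: size - filled]
        out[filled : filled + keep.size] = keep
        filled += keep.size
    return out


def generate_cohort(
    c: CohortParams,
    networks: Sequence[int] = tuple(range(1, 8)),
    bands: Sequence[str] | None = None,
    biomarker: str = "exp1f",
    b0: float = 1.0,
    extra_effect: Callable[[float, float, int, str], float] | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Synthetic cohort: long-format biomarker table + covariate table.

    Each (network, hemisphere[, band]) cell of each subject gets

    ``value = b0 + effect_interaction * (IQ - iq_mean) * (rank - 4)
              + subject_intercept + noise``

    plus an optional ``extra_effect(age, iq, rank, hemisphere)`` hook for
    injecting additional structure (e.g., nonlinear age effects in selected
    networks). Returns ``(table, covariates)``; the table has columns
    subject_id, age, sex, iq, network, rank, hierarchy, hemisphere, band,
    biomarker, value, missing.
    """
    ranks = [int(r) for r in networks]
    if len(ranks) == 0:
        raise ValueError("empty network rank list")
    if any(r < 1 or r > 7 for r in ranks):
        raise ValueError(f"ranks must be in 1..7, got {sorted(set(ranks))}")
    rng = np.random.default_rng(c.seed)
    age = rng.uniform(*c.age_range, size=c.n_subjects)
    sex = np.where(rng.random(c.n_subjects) < 0.5, "F", "M")
    iq = _truncated_normal(c.iq_mean, c.iq_sd, *c.iq_range, size=c.n_subjects, rng=rng)
    intercepts = rng.normal(0.0, c.subject_sd, size=c.n_subjects)

    cov = pd.DataFrame(
        {
            "subject_id": [f"S{i:03d}" for i in range(c.n_subjects)],
            "age": age,
            "sex": sex,
            "iq": iq,
        }
    )

    band_list: list[str | None] = list(bands) if bands else [None]
    records = []
    for i in range(c.n_subjects):
        for rank in ranks:
            for hemi in ("L", "R"):
                for band in band_list:
                    value = (
                        b0
                        + c.effect_interaction * (iq[i] - c.iq_mean) * (rank - 4)
                        + intercepts[i]
                        + rng.normal(0.0, c.resid_sd)
                    )
                    if extra_effect is not None:
                        value += extra_effect(age[i], iq[i], rank, hemi)
                    records.append(
                        {
                            "subject_id": cov.subject_id[i],
                            "age": age[i],
                            "sex": sex[i],
                            "iq": iq[i],
                            "network": YEO7_BY_RANK.get(rank, f"network{rank}"),
                            "rank": rank,
                            "hierarchy": hierarchy_of_rank(rank),
                            "hemisphere": hemi,
                            "band": band,
                            "biomarker": biomarker,
                            "value": value,
                            "missing": False,
                        }
                    )
    return pd.DataFrame.from_records(records), cov
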