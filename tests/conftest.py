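"""Shared fixtures: short synthetic signals and cohort tables.

Everything is generated programmatically and seeded; module-scoped
fixtures cache the more expensive signals across tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from neurocrit.datatypes import Band, TimeSeries
from neurocrit.synthetic import CohortParams, SignalParams, generate_cohort, generate_signal

FS = 250.0
ALPHA = Band(8.0, 13.0)


@pytest.fixture(scope="session")
def critical_signal() -> TimeSeries:
    """300-s zero-coupling oscillation (H = 0.75): near-critical reference."""
    return generate_signal(SignalParams(duration_s=300.0, fs=FS, hurst=0.75, coupling=0.0, seed=11))


@pytest.fixture(scope="session")
def cohort_128() -> tuple[pd.DataFrame, pd.DataFrame]:
    """128-subject single-band cohort table (1/f-exponent shaped) + covariates."""
    return generate_cohort(CohortParams(n_subjects=128, seed=7), biomarker="exp1f", b0=1.46)


@pytest.fixture(scope="session")
def cohort_fei_128() -> tuple[pd.DataFrame, pd.DataFrame]:
    """128-subject two-band cohort (fE/I shaped) with a rank x IQ interaction."""
    return generate_cohort(
        CohortParams(n_subjects=128, effect_interaction=0.002, seed=13),
        bands=["low", "high"],
        biomarker="fei",
    )


def tone(freq: float, duration_s: float = 10.0, fs: float = FS, amp: float = 1.0) -> TimeSeries:
    t = np.arange(int(duration_s * fs)) / fs
    return TimeSeries(amp * np.sin(2 * np.pi * freq * t), fs)
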