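"""Readers and writers: EDF, flat binary + JSON sidecar, tidy CSV tables.

EDF reading goes through MNE (any standard EDF, channel selection by
label, samples returned in microvolts). Writing uses a minimal standard
16-bit EDF encoder (one data record per second, linear physical/digital
scaling), sufficient for round-tripping synthetic signals. The flat
binary format is float32 samples (channel-major) with a JSON sidecar
carrying the sampling rate and channel labels.
"""

from __future__ import annotations

import json
import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import TimeSeries

__all__ = ["read_edf", "write_edf", "read_flat", "write_flat", "read_table", "write_table"]


def read_edf(path, channels: list[str] | None = None) -> TimeSeries:
    """Read an EDF file into a TimeSeries (microvolts), via MNE."""
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    if channels is not None:
        missing = sorted(set(channels) - set(raw.ch_names))
        if missing:
            raise KeyError(f"channels not in {path}: {missing}")
        raw.pick(channels)
    data = raw.get_data(units="uV")
    return TimeSeries(data, float(raw.info["sfreq"]), list(raw.ch_names))


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii", errors="replace")[:width]
    return b + b" " * (width - len(b))


def write_edf(ts: TimeSeries, path) -> None:
    """Write a TimeSeries as 16-bit EDF (standard header, 1-s records).

    The sampling rate must be an integer; the signal is truncated to a
    whole number of seconds. Physical range is taken per channel from the
    data (widened slightly so quantization never clips).
    """
    fs = ts.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    fs = int(round(fs))
    n_records = ts.n_samples // fs
    if n_records < 1:
        raise ValueError("signal shorter than one 1-s EDF record")
    n_sig = ts.n_channels
    data = ts.samples[:, : n_records * fs]

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    span = np.maximum(phys_max - phys_min, 1e-6)
    phys_min = phys_min - 0.001 * span
    phys_max = phys_max + 0.001 * span
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _pad("0", 8),
            _pad("X X X X", 80),
            _pad("Startdate X X X X", 80),
            _pad("01.01.00", 8),
            _pad("00.00.00", 8),
            _pad(str(256 * (1 + n_sig)), 8),
            _pad("", 44),
            _pad(str(n_records), 8),
            _pad("1", 8),
            _pad(str(n_sig), 4),
        ]
    )

    def field(values, width):
        return b"".join(_pad(str(v), width) for v in values)

    header += field(ts.labels, 16)
    header += field([""] * n_sig, 80)
    header += field(["uV"] * n_sig, 8)
    header += field([f"{v:.6g}"[:8] for v in phys_min], 8)
    header += field([f"{v:.6g}"[:8] for v in phys_max], 8)
    header += field([dig_min] * n_sig, 8)
    header += field([dig_max] * n_sig, 8)
    header += field([""] * n_sig, 80)
    header += field([fs] * n_sig, 8)
    header += field([""] * n_sig, 32)

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    with open(path, "wb") as fh:
        fh.write(header)
        for rec in range(n_records):
            for ch in range(n_sig):
                seg = data[ch, rec * fs : (rec + 1) * fs]
                dig = np.round((seg - phys_min[ch]) * scale[ch] + dig_min).astype("<i2")
                fh.write(dig.tobytes())


def write_flat(ts: TimeSeries, path) -> None:
    """Write float32 samples (channel-major) + JSON sidecar (.json)."""
    path = Path(path)
    ts.samples.astype("<f4").tofile(path)
    sidecar = {
        "fs": ts.fs,
        "labels": list(ts.labels),
        "n_channels": ts.n_channels,
        "n_samples": ts.n_samples,
        "dtype": "<f4",
        "order": "channel-major",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar, indent=1))


def read_flat(path) -> TimeSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    data = np.fromfile(path, dtype=meta.get("dtype", "<f4"))
    data = data.reshape(meta["n_channels"], meta["n_samples"]).astype(float)
    return TimeSeries(data, float(meta["fs"]), list(meta["labels"]))


def write_table(table: pd.DataFrame, path) -> None:
    """Write a tidy biomarker table as CSV (lossless round trip)."""
    table.to_csv(path, index=False)


def read_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "missing" in df.columns:
        df["missing"] = df["missing"].astype(bool)
    if "band" in df.columns:
        df["band"] = df["band"].where(pd.notna(df["band"]), None)
    return df
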