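"""End-to-end orchestration: signals -> biomarkers -> tables -> models.

A :class:`PipelineConfig` (loadable from YAML) drives the run: read (or
simulate) multichannel signals and a covariate table, compute per-channel
fE/I (fixed alpha bands or individualized alpha), DFA, and spectral
parameters, aggregate into ranked-network tables, optionally impute
missing fE/I, fit the model ladder, and write every artifact as CSV plus
a plain-text run log with versions, the parameter echo, and per-stage
record counts. Per-subject failures are isolated: the subject is dropped
with a logged reason and the run continues.

Randomness fans out from the single config seed through counter-based
substreams per (subject, channel), so results do not depend on iteration
order or parallelism.
"""

from __future__ import annotations

import dataclasses
import json
import time
import traceback
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datatypes import Band, TimeSeries, LOW_ALPHA, HIGH_ALPHA
from .fei import MIN_VALID_WINDOWS, compute_fei_iaf, normalized_fluctuation, _fei_from_series
from .io import read_edf, read_flat, write_edf, write_table
from .networks import NetworkMap, aggregate_to_networks, collapse_hierarchy, default_1020_map, impute_missing_fei
from .signal_core import amplitude_envelope, bandpass, dfa, split_windows
from .spectral import fit_aperiodic_lowfreq, fit_periodic_broadband, welch_psd
from .stats_models import ModelResult, fit_gamm, fit_multilevel, fit_region_linear
from .synthetic import SignalParams, generate_signal

__all__ = ["PipelineConfig", "run_pipeline", "run_sensitivity_sweep", "simulate_cohort_signals"]

#: sweep sanity bounds: window sizes (s) and overlap fractions
SWEEP_WINDOW_BOUNDS = (3.0, 6.0)
SWEEP_OVERLAP_BOUNDS = (0.75, 0.85)


@dataclass
class PipelineConfig:
    """All knobs of one pipeline run (see module docstring)."""

    outdir: str = "neurocrit_out"
    signals_dir: str | None = None
    covariates: str | None = None
    network_map: str | None = None
    band_mode: str = "fixed"  # "fixed" (8.3-10.5, 10.5-13.4 Hz) or "iaf"
    window_s: float = 5.0
    overlap: float = 0.8
    dfa_gate: float = 0.6
    dfa_fit_range_s: tuple[float, float] = (2.0, 20.0)
    impute: bool = False
    models: tuple[str, ...] = ("linear", "multilevel", "gamm")
    sweep_windows: tuple[float, ...] = (3.0, 6.0)
    sweep_overlaps: tuple[float, ...] = (0.75, 0.85)
    seed: int = 0
    # simulation block (used when signals_dir is None)
    n_subjects: int = 32
    duration_s: float = 180.0
    fs: float = 250.0
    hurst: float = 0.75
    kappa_scale: float = 0.35
    beta_base: float = 1.46
    beta_effect: float = -0.15

    def __post_init__(self) -> None:
        if self.band_mode not in ("fixed", "iaf"):
            raise ValueError(f"band_mode must be 'fixed' or 'iaf', got {self.band_mode!r}")
        for w in self.sweep_windows:
            if not SWEEP_WINDOW_BOUNDS[0] <= w <= SWEEP_WINDOW_BOUNDS[1]:
                raise ValueError(f"sweep window {w} s outside bounds {SWEEP_WINDOW_BOUNDS}")
        for o in self.sweep_overlaps:
            if not SWEEP_OVERLAP_BOUNDS[0] <= o <= SWEEP_OVERLAP_BOUNDS[1]:
                raise ValueError(f"sweep overlap {o} outside bounds {SWEEP_OVERLAP_BOUNDS}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("dfa_fit_range_s", "models", "sweep_windows", "sweep_overlaps"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def _substream_seed(seed: int, *key: int) -> int:
    """Deterministic child seed below 2**31 from a counter key."""
    ss = np.random.SeedSequence([int(seed), *[int(k) for k in key]])
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def simulate_cohort_signals(
    cov: pd.DataFrame, net_map: NetworkMap, config: PipelineConfig
) -> dict[str, TimeSeries]:
    """Per-subject multichannel signals with a built-in rank x IQ structure.

    Each mapped channel gets an oscillatory signal whose coupling (hence
    fE/I) and background exponent depend on the subject's IQ and the
    channel's network rank:

        kappa = kappa_scale * z_iq * (rank - 4) / 3
        beta  = beta_base + beta_effect * z_iq * (rank - 4) / 3

    so high-IQ subjects drift toward fE/I < 1 (and flatter spectra) in
    high-rank association networks, the structure the moderation models
    are meant to detect.
    """
    signals: dict[str, TimeSeries] = {}
    iq_sd = max(float(cov["iq"].std(ddof=1)), 1e-9)
    iq_mean = float(cov["iq"].mean())
    excluded = sorted(net_map.exclude)
    labels = list(net_map.table["label"]) + excluded
    for i, row in cov.reset_index(drop=True).iterrows():
        z_iq = (row["iq"] - iq_mean) / iq_sd
        chans = []
        for j, mrow in net_map.table.iterrows():
            kappa = float(np.clip(config.kappa_scale * z_iq * (mrow["rank"] - 4) / 3.0, -0.9, 0.9))
            beta = float(max(config.beta_base + config.beta_effect * z_iq * (mrow["rank"] - 4) / 3.0, 0.3))
            p = SignalParams(
                duration_s=config.duration_s, fs=config.fs, hurst=config.hurst,
                coupling=kappa, beta_aperiodic=beta,
                seed=_substream_seed(config.seed, i, j),
            )
            chans.append(generate_signal(p).samples[0])
        # excluded (midline) electrodes: neutral channels, present in the
        # recording but dropped at aggregation
        for j, _ in enumerate(excluded):
            p = SignalParams(
                duration_s=config.duration_s, fs=config.fs, hurst=config.hurst,
                coupling=0.0, beta_aperiodic=config.beta_base,
                seed=_substream_seed(config.seed, i, 1000 + j),
            )
            chans.append(generate_signal(p).samples[0])
        signals[str(row["subject_id"])] = TimeSeries(np.vstack(chans), config.fs, labels)
    return signals


def _band_fei_all_channels(
    ts: TimeSeries, band: Band, window_s: float, overlap: float,
    dfa_gate: float, dfa_fit_range_s: tuple[float, float],
) -> list[dict]:
    """fE/I + DFA for every channel in one band (vectorized filtering)."""
    filtered, edge = bandpass(ts, band)
    envs = amplitude_envelope(filtered.samples)
    envs = np.atleast_2d(envs)
    if envs.shape[1] > 2 * edge:
        envs = envs[:, edge:-edge]
    rows = []
    for ch, label in enumerate(ts.labels):
        env = envs[ch]
        try:
            exponent = dfa(env, ts.fs, fit_range_s=dfa_fit_range_s).exponent
            windows = split_windows(env.size, ts.fs, window_s=window_s, overlap=overlap)
            amps, nf = normalized_fluctuation(env, windows)
            res = _fei_from_series(amps, nf, exponent, dfa_gate)
        except ValueError as err:
            rows.append({"label": label, "band_lo": band.f_lo, "band_hi": band.f_hi,
                         "fei": np.nan, "r": np.nan, "dfa": np.nan,
                         "n_windows": 0, "valid": False, "reason": str(err)})
            continue
        rows.append({"label": label, "band_lo": band.f_lo, "band_hi": band.f_hi,
                     "fei": res.fei, "r": res.r, "dfa": res.dfa_exponent,
                     "n_windows": res.n_windows, "valid": res.valid, "reason": res.reason})
    return rows


def compute_subject_biomarkers(ts: TimeSeries, config: PipelineConfig) -> pd.DataFrame:
    """Per-channel fE/I (per band) and spectral parameters for one subject.

    Returns a long frame: one row per channel x band for fE/I (band names
    "low"/"high"), plus the per-channel aperiodic exponent (``exp1f``),
    PAF and alpha peak height merged on.
    """
    spectral_rows = []
    for ch, label in enumerate(ts.labels):
        freqs, psd = welch_psd(ts, channel=ch)
        low = fit_aperiodic_lowfreq(freqs, psd)
        broad = fit_periodic_broadband(freqs, psd)
        spectral_rows.append({"label": label, "exp1f": low.beta, "offset": low.offset,
                              "paf": broad.paf, "peak_height": broad.peak_height})
    spec = pd.DataFrame(spectral_rows)

    fei_rows: list[dict] = []
    if config.band_mode == "fixed":
        for name, band in (("low", LOW_ALPHA), ("high", HIGH_ALPHA)):
            rows = _band_fei_all_channels(ts, band, config.window_s, config.overlap,
                                          config.dfa_gate, config.dfa_fit_range_s)
            for r in rows:
                r["band"] = name
            fei_rows.extend(rows)
    else:
        paf_by_label = dict(zip(spec["label"], spec["paf"]))
        for ch, label in enumerate(ts.labels):
            lo_res, hi_res = compute_fei_iaf(
                ts, paf_by_label[label], window_s=config.window_s,
                overlap=config.overlap, dfa_gate=config.dfa_gate, channel=ch,
            )
            for name, res in (("low", lo_res), ("high", hi_res)):
                fei_rows.append({"label": label, "band": name,
                                 "band_lo": np.nan, "band_hi": np.nan,
                                 "fei": res.fei, "r": res.r, "dfa": res.dfa_exponent,
                                 "n_windows": res.n_windows, "valid": res.valid,
                                 "reason": res.reason})
    out = pd.DataFrame(fei_rows).merge(spec, on="label", how="left")
    return out


def _signal_loaders(config: PipelineConfig, cov: pd.DataFrame):
    """Lazy per-subject loaders so a corrupt file only fails its subject."""
    sig_dir = Path(config.signals_dir)

    def make_loader(sid: str):
        def load() -> TimeSeries:
            edf = sig_dir / f"{sid}.edf"
            flat = sig_dir / f"{sid}.bin"
            if edf.exists():
                return read_edf(edf)
            if flat.exists():
                return read_flat(flat)
            raise FileNotFoundError(f"no signal file for subject {sid} in {sig_dir}")

        return load

    return {sid: make_loader(sid) for sid in cov["subject_id"].astype(str)}


def _network_tables(
    per_channel: pd.DataFrame, net_map: NetworkMap, cov: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Aggregate per-channel biomarkers into fE/I and 1/f network tables."""
    fei_chan = per_channel.rename(columns={"fei": "value"})[
        ["subject_id", "label", "band", "value"]
    ].copy()
    fei_chan["biomarker"] = "fei"
    fei_tab = aggregate_to_networks(fei_chan, net_map)

    exp_chan = per_channel[per_channel["band"] == "low"].rename(columns={"exp1f": "value"})[
        ["subject_id", "label", "value"]
    ].copy()
    exp_chan["biomarker"] = "exp1f"
    exp_tab = aggregate_to_networks(exp_chan, net_map)
    exp_tab["band"] = None

    cov_idx = cov.copy()
    cov_idx["subject_id"] = cov_idx["subject_id"].astype(str)
    fei_tab = fei_tab.merge(cov_idx, on="subject_id", how="left")
    exp_tab = exp_tab.merge(cov_idx, on="subject_id", how="left")
    return fei_tab, exp_tab


def _fit_models(
    fei_tab: pd.DataFrame, exp_tab: pd.DataFrame, config: PipelineConfig, log: list[str]
) -> dict[str, ModelResult]:
    results: dict[str, ModelResult] = {}
    fei_hier = collapse_hierarchy(fei_tab)
    exp_hier = collapse_hierarchy(exp_tab)
    for biomarker, net_tab, hier_tab in (("fei", fei_tab, fei_hier), ("exp1f", exp_tab, exp_hier)):
        if "linear" in config.models:
            for region in ("sensorimotor", "association"):
                key = f"linear_{biomarker}_{region}"
                results[key] = fit_region_linear(hier_tab, biomarker, region)
        if "multilevel" in config.models:
            results[f"multilevel_{biomarker}_hierarchy"] = fit_multilevel(hier_tab, biomarker, "hierarchy")
            results[f"multilevel_{biomarker}_network"] = fit_multilevel(net_tab, biomarker, "network")
        if "gamm" in config.models:
            results[f"gamm_{biomarker}_hierarchy"] = fit_gamm(hier_tab, biomarker, "hierarchy")
            results[f"gamm_{biomarker}_network"] = fit_gamm(net_tab, biomarker, "network")
    for key, res in results.items():
        log.append(f"model {key}: n_obs={res.n_obs} n_subjects={res.n_subjects} m={res.m}")
    return results


def run_pipeline(config: PipelineConfig) -> dict:
    """Run the full pipeline; returns the result bundle (also written to disk).

    Bundle keys: per_channel, fei_table, exp1f_table, fei_hierarchy,
    exp1f_hierarchy, models, failures, covariates.
    """
    t_start = time.time()
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log: list[str] = []
    import neurocrit
    import scipy
    log.append(f"neurocrit {neurocrit.__version__} numpy {np.__version__} scipy {scipy.__version__}")
    log.append(f"config: {dataclasses.asdict(config)}")

    net_map = (NetworkMap.from_csv(config.network_map) if config.network_map
               else default_1020_map())

    if config.covariates:
        cov = pd.read_csv(config.covariates)
    else:
        rng = np.random.default_rng(_substream_seed(config.seed, 0xC0))
        from .synthetic import _truncated_normal
        cov = pd.DataFrame({
            "subject_id": [f"S{i:03d}" for i in range(config.n_subjects)],
            "age": rng.uniform(6, 19, config.n_subjects),
            "sex": np.where(rng.random(config.n_subjects) < 0.5, "F", "M"),
            "iq": _truncated_normal(111, 13, 71, 145, config.n_subjects, rng),
        })
    cov["subject_id"] = cov["subject_id"].astype(str)

    if config.signals_dir:
        loaders = _signal_loaders(config, cov)
    else:
        sims = simulate_cohort_signals(cov, net_map, config)
        loaders = {sid: (lambda ts=ts: ts) for sid, ts in sims.items()}
    log.append(f"subjects: {len(loaders)}")

    frames = []
    failures: list[tuple[str, str]] = []
    for sid, load in loaders.items():
        try:
            ts = load()
            bm = compute_subject_biomarkers(ts, config)
            bm.insert(0, "subject_id", sid)
            frames.append(bm)
        except Exception as err:  # noqa: BLE001 - isolation is the contract
            failures.append((sid, f"{type(err).__name__}: {err}"))
            log.append(f"subject {sid} FAILED: {type(err).__name__}: {err}")
            log.append(traceback.format_exc(limit=2))
    if not frames:
        raise RuntimeError("all subjects failed biomarker computation")
    per_channel = pd.concat(frames, ignore_index=True)
    ok_ids = set(per_channel["subject_id"])
    cov_ok = cov[cov["subject_id"].isin(ok_ids)].reset_index(drop=True)
    log.append(f"per-channel records: {len(per_channel)}; failed subjects: {len(failures)}")

    fei_tab, exp_tab = _network_tables(per_channel, net_map, cov_ok)
    log.append(f"fei network records: {len(fei_tab)} (missing {int(fei_tab['missing'].sum())})")
    log.append(f"exp1f network records: {len(exp_tab)} (missing {int(exp_tab['missing'].sum())})")

    if config.impute and fei_tab["missing"].any():
        fei_tab = impute_missing_fei(fei_tab, seed=_substream_seed(config.seed, 0x1F))
        log.append(f"fei records after imputation: {len(fei_tab)} "
                   f"(imputed {int(fei_tab['imputed'].sum())})")

    models = _fit_models(fei_tab, exp_tab, config, log)
    fei_hier = collapse_hierarchy(fei_tab)
    exp_hier = collapse_hierarchy(exp_tab)
    log.append(f"fei hierarchy records: {len(fei_hier)}; exp1f hierarchy records: {len(exp_hier)}")

    write_table(per_channel, outdir / "per_channel.csv")
    write_table(fei_tab, outdir / "fei_network.csv")
    write_table(exp_tab, outdir / "exp1f_network.csv")
    write_table(fei_hier, outdir / "fei_hierarchy.csv")
    write_table(exp_hier, outdir / "exp1f_hierarchy.csv")
    cov_ok.to_csv(outdir / "covariates.csv", index=False)
    for key, res in models.items():
        res.terms.to_csv(outdir / f"model_{key}.csv", index=False)
    summary = {
        "n_subjects": len(cov_ok),
        "failures": failures,
        "models": {k: {"n_obs": v.n_obs, "m": v.m} for k, v in models.items()},
        "elapsed_s": round(time.time() - t_start, 2),
    }
    (outdir / "summary.json").write_text(json.dumps(summary, indent=1))
    log.append(f"elapsed: {summary['elapsed_s']} s")
    (outdir / "run.log").write_text("\n".join(log) + "\n")

    return {"per_channel": per_channel, "fei_table": fei_tab, "exp1f_table": exp_tab,
            "fei_hierarchy": fei_hier, "exp1f_hierarchy": exp_hier,
            "models": models, "failures": failures, "covariates": cov_ok}


def run_sensitivity_sweep(
    config: PipelineConfig,
    windows: tuple[float, ...] | None = None,
    overlaps: tuple[float, ...] | None = None,
) -> pd.DataFrame:
    """Recompute fE/I and the headline interaction over a parameter grid.

    For each (window size, overlap) cell the fE/I stage is rerun on the
    same signals and the network-level multilevel rank x IQ interaction is
    refit; the report carries the interaction estimate, its sign, p and
    Bonferroni-adjusted p per cell, so sign/significance stability can be
    read off directly.
    """
    windows = windows if windows is not None else config.sweep_windows
    overlaps = overlaps if overlaps is not None else config.sweep_overlaps
    if len(windows) == 0 or len(overlaps) == 0:
        raise ValueError("empty sweep grid")
    for w in windows:
        if not SWEEP_WINDOW_BOUNDS[0] <= w <= SWEEP_WINDOW_BOUNDS[1]:
            raise ValueError(f"sweep window {w} s outside bounds {SWEEP_WINDOW_BOUNDS}")
    for o in overlaps:
        if not SWEEP_OVERLAP_BOUNDS[0] <= o <= SWEEP_OVERLAP_BOUNDS[1]:
            raise ValueError(f"sweep overlap {o} outside bounds {SWEEP_OVERLAP_BOUNDS}")

    rows = []
    for w in windows:
        for o in overlaps:
            cell = dataclasses.replace(config, window_s=float(w), overlap=float(o),
                                       models=("multilevel",),
                                       outdir=str(Path(config.outdir) / f"sweep_w{w}_o{o}"))
            bundle = run_pipeline(cell)
            res = bundle["models"]["multilevel_fei_network"]
            term = res.term("rank_c:iq_c")
            rows.append({"window_s": w, "overlap": o,
                         "estimate": term["estimate"], "sign": float(np.sign(term["estimate"])),
                         "p": term["p"], "p_bonf": min(1.0, term["p"] * res.m),
                         "n_obs": res.n_obs})
    report = pd.DataFrame(rows)
    report.to_csv(Path(config.outdir) / "sweep_report.csv", index=False)
    return report
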