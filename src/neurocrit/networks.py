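"""Channel-to-network mapping, biomarker aggregation, and fE/I imputation.

Scalp channels (or source parcels) are mapped onto the seven canonical
resting-state functional networks, ranked 1-7 along the
sensorimotor-association cortical hierarchy:

    1 visual, 2 somatomotor, 3 dorsal attention,
    4 salience/ventral attention, 5 limbic, 6 control, 7 default

with ranks 1-3 grouped as "sensorimotor" and 4-7 as "association".
Biomarker values are averaged per (network, hemisphere[, band]) cell into a
long-format table, optionally collapsed further to the two broad hierarchy
regions. Missing fE/I cells (DFA-gated) can be imputed with a chained
random-forest imputer; aggregation means always ignore missing members.

The bundled default map places a standard 10-20 montage onto the seven
networks (a declared, editable convention; midline electrodes carry no
hemisphere and are excluded).
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor

from .synthetic import YEO7_BY_RANK, hierarchy_of_rank

__all__ = [
    "NetworkMap",
    "default_1020_map",
    "aggregate_to_networks",
    "collapse_hierarchy",
    "impute_missing_fei",
    "RandomForestImputer",
]

#: key columns identifying one biomarker cell
CELL_KEYS = ["network", "rank", "hierarchy", "hemisphere", "band"]


@dataclass
class NetworkMap:
    """Mapping from channel/parcel label to (network, rank, hierarchy, hemisphere).

    ``exclude`` lists labels deliberately dropped from aggregation (e.g.
    midline electrodes without a hemisphere).
    """

    table: pd.DataFrame  # columns: label, network, rank, hierarchy, hemisphere
    exclude: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        required = {"label", "network", "rank", "hierarchy", "hemisphere"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"NetworkMap table missing columns: {sorted(missing)}")
        bad_h = set(self.table["hierarchy"]) - {"sensorimotor", "association"}
        if bad_h:
            raise ValueError(f"invalid hierarchy values: {sorted(bad_h)}")
        bad_hemi = set(self.table["hemisphere"]) - {"L", "R"}
        if bad_hemi:
            raise ValueError(f"invalid hemisphere values: {sorted(bad_hemi)}")
        for net, grp in self.table.groupby("network"):
            if grp["hierarchy"].nunique() > 1 or grp["rank"].nunique() > 1:
                raise ValueError(f"network {net!r} has inconsistent rank/hierarchy")

    def lookup(self, label: str) -> pd.Series:
        rows = self.table[self.table["label"] == label]
        if rows.empty:
            raise KeyError(label)
        return rows.iloc[0]

    @property
    def labels(self) -> list[str]:
        return list(self.table["label"])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, exclude: set[str] | None = None) -> "NetworkMap":
        return cls(pd.read_csv(path), exclude=exclude or set())


_DEFAULT_1020 = """\
label,network,rank,hierarchy,hemisphere
O1,visual,1,sensorimotor,L
O2,visual,1,sensorimotor,R
C3,somatomotor,2,sensorimotor,L
C4,somatomotor,2,sensorimotor,R
P3,dorsal_attention,3,sensorimotor,L
P4,dorsal_attention,3,sensorimotor,R
F7,salience_ventral_attention,4,association,L
F8,salience_ventral_attention,4,association,R
T7,limbic,5,association,L
T8,limbic,5,association,R
F3,control,6,association,L
F4,control,6,association,R
Fp1,default,7,association,L
Fp2,default,7,association,R
P7,default,7,association,L
P8,default,7,association,R
"""


def default_1020_map() -> NetworkMap:
    """Sensor-space analog of the ranked seven-network parcellation.

    A declared convention for a 10-20-style montage: each network gets one
    or two lateral electrodes per hemisphere; the midline electrodes
    (Fz, Cz, Pz) carry no hemisphere and are excluded.
    """
    table = pd.read_csv(io.StringIO(_DEFAULT_1020))
    return NetworkMap(table, exclude={"Fz", "Cz", "Pz"})


def aggregate_to_networks(per_channel: pd.DataFrame, net_map: NetworkMap) -> pd.DataFrame:
    """Average per-channel biomarker values into network cells.

    ``per_channel`` needs columns (label, value) plus optional
    (subject_id, band, biomarker) carried through. Every label must be in
    the map or in its exclusion set. The mean per (network, hemisphere
    [, band]) ignores NaN members; a cell whose members are all NaN (e.g.
    all DFA-gated) is emitted with ``value = NaN, missing = True``.
    """
    unknown = sorted(
        set(per_channel["label"]) - set(net_map.labels) - set(net_map.exclude)
    )
    if unknown:
        raise KeyError(f"labels not in network map and not excluded: {unknown}")
    df = per_channel[~per_channel["label"].isin(net_map.exclude)].copy()
    df = df.merge(net_map.table, on="label", how="left")
    keys = [k for k in ("subject_id", "biomarker") if k in df.columns]
    keys += ["network", "rank", "hierarchy", "hemisphere"]
    if "band" in df.columns:
        keys.append("band")
    out = (
        df.groupby(keys, dropna=False, sort=True, observed=True)["value"]
        .agg(lambda v: v.mean(skipna=True))  # NaN only if no valid member
        .reset_index()
    )
    out["missing"] = ~np.isfinite(out["value"])
    return out


def collapse_hierarchy(table: pd.DataFrame) -> pd.DataFrame:
    """Average network cells into the two broad hierarchy regions.

    Per subject, the mean over that subject's networks within each
    (hierarchy, hemisphere[, band]) cell, ignoring missing members. The
    exact record-count identities (e.g. 2 regions x 2 hemispheres x N
    subjects) hold for complete data.
    """
    for col in ("hierarchy", "rank"):
        if col not in table.columns:
            raise ValueError(f"table lacks required column {col!r}")
    keys = [k for k in ("subject_id", "biomarker") if k in table.columns]
    keys += ["hierarchy", "hemisphere"]
    if "band" in table.columns:
        keys.append("band")
    carry = [c for c in ("age", "sex", "iq") if c in table.columns]
    agg = {"value": lambda v: v.mean(skipna=True)}
    agg.update({c: "first" for c in carry})
    out = table.groupby(keys, dropna=False, sort=True, observed=True).agg(agg).reset_index()
    out["missing"] = ~np.isfinite(out["value"])
    return out


class RandomForestImputer:
    """Chained random-forest imputation of missing fE/I cells.

    The long table is pivoted wide (one column per network cell); columns
    with missing entries are imputed in turn by regression forests trained
    on the complete covariates (age, sex, IQ) and the current state of the
    sibling cells, iterating until the mean out-of-bag error stops
    improving or ``max_iter`` passes. Seeded and deterministic. With a
    degenerate predictor matrix the imputer falls back to within-cell mean
    imputation (flagged in ``fallback_``).
    """

    def __init__(self, n_trees: int = 100, max_iter: int = 5, seed: int = 0) -> None:
        self.n_trees = n_trees
        self.max_iter = max_iter
        self.seed = seed
        self.fallback_ = False

    def impute(self, table: pd.DataFrame) -> pd.DataFrame:
        out = table.copy().reset_index(drop=True)
        out["imputed"] = False
        if not out["missing"].any():
            return out
        cell_cols = [c for c in CELL_KEYS if c in out.columns and out[c].nunique(dropna=False) > 1]
        cell_cols = cell_cols or ["network"]
        out["_cell"] = out[cell_cols].astype(str).agg("|".join, axis=1)
        wide = out.pivot_table(index="subject_id", columns="_cell", values="value", dropna=False)
        covs = out.groupby("subject_id").agg(age=("age", "first"), iq=("iq", "first"), sex=("sex", "first"))
        covs = covs.loc[wide.index]
        covs["sex"] = (covs["sex"] == "F").astype(float)
        X_cov = covs[["age", "sex", "iq"]].to_numpy(dtype=float)

        if not np.all(np.isfinite(X_cov)) or np.allclose(X_cov.std(axis=0), 0):
            self.fallback_ = True
            filled = wide.apply(lambda col: col.fillna(col.mean()))
        else:
            filled = self._chained_forest(wide, X_cov)

        long_fill = filled.stack(future_stack=True).rename("value_imp").reset_index()
        out = out.merge(long_fill, on=["subject_id", "_cell"], how="left")
        was_missing = out["missing"].to_numpy()
        out.loc[was_missing, "value"] = out.loc[was_missing, "value_imp"]
        out["imputed"] = was_missing & np.isfinite(out["value"])
        out["missing"] = ~np.isfinite(out["value"])
        return out.drop(columns=["_cell", "value_imp"])

    def _chained_forest(self, wide: pd.DataFrame, X_cov: np.ndarray) -> pd.DataFrame:
        rng = np.random.default_rng(self.seed)
        filled = wide.apply(lambda col: col.fillna(col.mean()))
        miss_cols = [c for c in wide.columns if wide[c].isna().any()]
        prev_oob = np.inf
        for _ in range(self.max_iter):
            oob_errs = []
            for col in miss_cols:
                obs = wide[col].notna().to_numpy()
                if obs.sum() < 5:
                    continue
                others = [c for c in filled.columns if c != col]
                X = np.column_stack([X_cov, filled[others].to_numpy(dtype=float)])
                y = filled[col].to_numpy(dtype=float)
                forest = RandomForestRegressor(
                    n_estimators=self.n_trees,
                    oob_score=True,
                    bootstrap=True,
                    random_state=int(rng.integers(0, 2**31 - 1)),
                    n_jobs=1,
                )
                forest.fit(X[obs], y[obs])
                oob_errs.append(1.0 - forest.oob_score_)
                pred = forest.predict(X[~obs])
                filled.loc[~obs, col] = pred
            if not oob_errs:
                break
            oob = float(np.mean(oob_errs))
            if oob >= prev_oob - 1e-4:
                break
            prev_oob = oob
        return filled


def impute_missing_fei(
    table: pd.DataFrame, n_trees: int = 100, max_iter: int = 5, seed: int = 0
) -> pd.DataFrame:
    """Impute missing fE/I values in a long biomarker table (see class docs)."""
    frac_missing = table["missing"].mean()
    if frac_missing >= 0.5:
        raise ValueError(f"missingness {frac_missing:.0%} >= 50%: refusing to impute")
    return RandomForestImputer(n_trees=n_trees, max_iter=max_iter, seed=seed).impute(table)
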