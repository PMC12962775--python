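"""Network mapping, aggregation, hierarchy collapse, and imputation."""

import numpy as np
import pandas as pd
import pytest

from neurocrit.networks import (
    NetworkMap,
    aggregate_to_networks,
    collapse_hierarchy,
    default_1020_map,
    impute_missing_fei,
)
from neurocrit.synthetic import CohortParams, generate_cohort


@pytest.fixture(scope="module")
def net_map():
    return default_1020_map()


def _per_channel_frame(net_map, n_subjects=4, value=1.0, bands=None, rng=None):
    rows = []
    for i in range(n_subjects):
        for label in net_map.labels:
            for band in bands or [None]:
                v = value if rng is None else rng.normal(value, 0.1)
                rows.append({"subject_id": f"S{i:03d}", "label": label, "band": band,
                             "value": v, "biomarker": "fei"})
    df = pd.DataFrame(rows)
    if bands is None:
        df = df.drop(columns=["band"])
    return df


class TestDefaultMap:
    def test_all_ranks_in_both_hemispheres(self, net_map):
        for hemi in ("L", "R"):
            ranks = set(net_map.table[net_map.table["hemisphere"] == hemi]["rank"])
            assert ranks == set(range(1, 8))

    def test_midline_excluded(self, net_map):
        assert {"Fz", "Cz", "Pz"} <= net_map.exclude

    def test_round_trip_csv(self, net_map, tmp_path):
        path = tmp_path / "map.csv"
        net_map.to_csv(path)
        again = NetworkMap.from_csv(path, exclude=net_map.exclude)
        pd.testing.assert_frame_equal(net_map.table, again.table)

    def test_inconsistent_hierarchy_rejected(self, net_map):
        bad = net_map.table.copy()
        bad.loc[bad.index[0], "rank"] = 5  # visual split across ranks
        with pytest.raises(ValueError, match="inconsistent"):
            NetworkMap(bad)


class TestAggregation:
    def test_record_count_identity_128(self, net_map):
        pc = _per_channel_frame(net_map, n_subjects=128)
        out = aggregate_to_networks(pc, net_map)
        assert len(out) == 1792  # 7 x 2 x 128

    def test_single_channel_identity(self, net_map):
        one = net_map.table.drop_duplicates(subset=["network", "hemisphere"])
        sub_map = NetworkMap(one.reset_index(drop=True))
        rng = np.random.default_rng(0)
        pc = _per_channel_frame(sub_map, n_subjects=2, rng=rng)
        out = aggregate_to_networks(pc, sub_map)
        merged = pc.merge(sub_map.table, on="label")
        for _, row in out.iterrows():
            src = merged[
                (merged["subject_id"] == row["subject_id"])
                & (merged["network"] == row["network"])
                & (merged["hemisphere"] == row["hemisphere"])
            ]["value"]
            assert row["value"] == pytest.approx(float(src.iloc[0]))

    def test_unknown_label_rejected_with_listing(self, net_map):
        pc = _per_channel_frame(net_map, n_subjects=1)
        pc.loc[len(pc)] = {"subject_id": "S000", "label": "XX9", "value": 1.0, "biomarker": "fei"}
        with pytest.raises(KeyError, match="XX9"):
            aggregate_to_networks(pc, net_map)

    def test_excluded_labels_dropped_silently(self, net_map):
        pc = _per_channel_frame(net_map, n_subjects=1)
        pc.loc[len(pc)] = {"subject_id": "S000", "label": "Cz", "value": 99.0, "biomarker": "fei"}
        out = aggregate_to_networks(pc, net_map)
        assert (out["value"] == 1.0).all()

    def test_missingness_locality(self, net_map):
        pc = _per_channel_frame(net_map, n_subjects=1)
        vis = net_map.table[net_map.table["network"] == "visual"]["label"]
        pc.loc[pc["label"].isin(vis), "value"] = np.nan
        out = aggregate_to_networks(pc, net_map)
        assert out[out["network"] == "visual"]["missing"].all()
        assert not out[out["network"] != "visual"]["missing"].any()

    def test_partial_nan_channels_ignored_in_mean(self, net_map):
        pc = _per_channel_frame(net_map, n_subjects=1, value=2.0)
        # default network has two channels per hemisphere; NaN one of them
        pc.loc[pc["label"] == "Fp1", "value"] = np.nan
        out = aggregate_to_networks(pc, net_map)
        cell = out[(out["network"] == "default") & (out["hemisphere"] == "L")]
        assert cell["value"].iloc[0] == pytest.approx(2.0)
        assert not cell["missing"].iloc[0]

    def test_permutation_invariance(self, net_map):
        rng = np.random.default_rng(5)
        pc = _per_channel_frame(net_map, n_subjects=3, rng=rng)
        out1 = aggregate_to_networks(pc, net_map)
        out2 = aggregate_to_networks(pc.sample(frac=1.0, random_state=1), net_map)
        pd.testing.assert_frame_equal(
            out1.reset_index(drop=True), out2.reset_index(drop=True)
        )


class TestCollapseHierarchy:
    def test_record_count_512(self, cohort_128):
        table, _ = cohort_128
        out = collapse_hierarchy(table)
        assert len(out) == 512  # 2 x 2 x 128

    def test_two_band_count_1024(self, cohort_fei_128):
        table, _ = cohort_fei_128
        out = collapse_hierarchy(table)
        assert len(out) == 1024  # 2 x 2 x 2 x 128

    def test_constant_subject_value_unchanged(self):
        table, _ = generate_cohort(
            CohortParams(n_subjects=4, subject_sd=0.5, resid_sd=0.0, seed=2), b0=1.0
        )
        out = collapse_hierarchy(table)
        merged = out.merge(
            table.groupby("subject_id")["value"].first().rename("per_sub"), on="subject_id"
        )
        # within a subject all cells share b0 + intercept, so collapse is identity
        assert np.allclose(merged["value"], merged["per_sub"])

    def test_missing_members_ignored(self, cohort_128):
        table, _ = cohort_128
        t = table.copy()
        mask = (t["subject_id"] == "S000") & (t["rank"] == 7)
        t.loc[mask, "value"] = np.nan
        t.loc[mask, "missing"] = True
        out = collapse_hierarchy(t)
        cell = out[(out["subject_id"] == "S000") & (out["hierarchy"] == "association")]
        assert np.isfinite(cell["value"]).all()


class TestImputation:
    def _masked_table(self, frac=0.1, seed=0):
        table, _ = generate_cohort(
            CohortParams(n_subjects=64, effect_interaction=0.003, seed=3),
            bands=["low", "high"], biomarker="fei",
        )
        rng = np.random.default_rng(seed)
        mask = rng.random(len(table)) < frac
        truth = table["value"].to_numpy().copy()
        table = table.copy()
        table.loc[mask, "value"] = np.nan
        table.loc[mask, "missing"] = True
        return table, truth, mask

    def test_complete_table_returned_unchanged(self, cohort_128):
        table, _ = cohort_128
        out = impute_missing_fei(table)
        assert not out["imputed"].any()
        assert np.allclose(out["value"], table["value"])

    def test_beats_mean_imputation(self):
        table, truth, mask = self._masked_table()
        out = impute_missing_fei(table, n_trees=50, seed=1)
        rf_rmse = np.sqrt(np.mean((out["value"].to_numpy()[mask] - truth[mask]) ** 2))
        mean_fill = table.groupby(["network", "hemisphere", "band"])["value"].transform(
            lambda v: v.fillna(v.mean())
        )
        mean_rmse = np.sqrt(np.mean((mean_fill.to_numpy()[mask] - truth[mask]) ** 2))
        assert rf_rmse < mean_rmse

    def test_seeded_determinism(self):
        table, _, _ = self._masked_table()
        a = impute_missing_fei(table, n_trees=30, seed=7)
        b = impute_missing_fei(table, n_trees=30, seed=7)
        assert np.allclose(a["value"], b["value"])

    def test_excessive_missingness_rejected(self):
        table, _, _ = self._masked_table(frac=0.6)
        with pytest.raises(ValueError, match="50%"):
            impute_missing_fei(table)
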