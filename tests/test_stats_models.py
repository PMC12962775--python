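"""Inferential suite: OLS, mixed models, Johnson-Neyman, subgroup tests."""

import shutil
import subprocess
import warnings
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from scipy import stats as spstats

from neurocrit.networks import collapse_hierarchy
from neurocrit.stats_models import (
    MixedInteractionModel,
    bonferroni,
    fit_gamm,
    fit_multilevel,
    fit_region_linear,
    johnson_neyman,
    predict_surface,
    subgroup_ttest,
    wilcoxon_age_groups,
)
from neurocrit.synthetic import CohortParams, generate_cohort


def _subject_table(n, beta_std, seed, region="association"):
    """Single-region per-subject table with a known standardized IQ slope."""
    rng = np.random.default_rng(seed)
    iq = rng.normal(111, 13, n)
    age = rng.uniform(6, 19, n)
    noise_sd = np.sqrt(max(1 - beta_std**2, 1e-9))
    y = beta_std * (iq - 111) / 13 + rng.normal(0, noise_sd, n)
    return pd.DataFrame(
        {"subject_id": [f"S{i}" for i in range(n)], "age": age,
         "sex": rng.choice(["F", "M"], n), "iq": iq, "value": y,
         "biomarker": "exp1f", "hierarchy": region,
         "hemisphere": "L", "rank": 5, "band": None, "missing": False}
    )


class TestRegionLinear:
    def test_null_calibration(self):
        # under the null at n=128 the standardized slope stays small and
        # non-significant in at least 90% of replicates
        calibrated = 0
        for seed in range(50):
            res = fit_region_linear(_subject_table(128, 0.0, seed), "exp1f", "association")
            ok = abs(res.extra["beta_std_iq"]) < 0.18 and res.term("iq")["p"] > 0.05
            calibrated += ok
        assert calibrated >= 45

    def test_injected_slope_recovered(self):
        betas = [
            fit_region_linear(_subject_table(128, -0.19, seed), "exp1f", "association").extra["beta_std_iq"]
            for seed in range(50)
        ]
        assert np.mean(betas) == pytest.approx(-0.19, abs=0.1)

    def test_collinear_design_rejected(self):
        df = _subject_table(60, 0.0, 1)
        df["age"] = df["iq"]  # perfect collinearity
        with pytest.raises(ValueError, match="rank-deficient"):
            fit_region_linear(df, "exp1f", "association")


class TestMultilevel:
    def test_interaction_recovery(self, cohort_fei_128):
        table, _ = cohort_fei_128
        res = fit_multilevel(table, "fei", "network")
        est = res.term("rank_c:iq_c")["estimate"]
        assert est == pytest.approx(0.002, rel=0.3)
        assert res.df_method == "satterthwaite"
        assert res.n_obs == 3584 and res.n_subjects == 128

    def test_zero_subject_variance_collapses_to_ols(self):
        import statsmodels.api as sm

        table, _ = generate_cohort(
            CohortParams(n_subjects=48, subject_sd=0.0, resid_sd=0.1, seed=9)
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", UserWarning)
            res = fit_multilevel(table, "exp1f", "network")
        # variance at (or chance-level above) zero
        assert res.random_intercept_var < 0.05 * res.resid_var
        # fixed effects equal OLS on the same design
        df = table.copy()
        df["iq_c"] = df["iq"] - df["iq"].mean()
        df["age_c"] = df["age"] - df["age"].mean()
        df["rank_c"] = df["rank"] - df["rank"].mean()
        X = pd.DataFrame({
            "age_c": df["age_c"], "sex": (df["sex"] == "M").astype(float),
            "hemi": (df["hemisphere"] == "R").astype(float),
            "rank_c": df["rank_c"], "iq_c": df["iq_c"], "x": df["rank_c"] * df["iq_c"],
        })
        ols = sm.OLS(df["value"], sm.add_constant(X)).fit()
        assert res.term("rank_c:iq_c")["estimate"] == pytest.approx(ols.params["x"], abs=1e-6)

    def test_balanced_anova_closed_form_reml(self):
        # balanced one-way random effects: REML variance components have
        # closed forms tau2 = (MSB - MSW)/n_per, sigma2 = MSW
        rng = np.random.default_rng(4)
        n_groups, n_per = 30, 6
        a = rng.normal(0, 0.3, n_groups)
        rows = []
        for g in range(n_groups):
            for j in range(n_per):
                rows.append({"subject_id": f"G{g}", "value": 1.0 + a[g] + rng.normal(0, 0.15),
                             "age": 10.0, "sex": "F", "hemisphere": "L", "iq": 100.0,
                             "rank": 4, "band": None, "biomarker": "x", "missing": False})
        df = pd.DataFrame(rows)
        res = fit_multilevel(df, "x", formula="value ~ 1")
        groups = df.groupby("subject_id")["value"]
        grand = df["value"].mean()
        msb = n_per * np.sum((groups.mean() - grand) ** 2) / (n_groups - 1)
        msw = np.sum((df["value"] - groups.transform("mean")) ** 2) / (n_groups * (n_per - 1))
        assert res.resid_var == pytest.approx(msw, abs=1e-6)
        assert res.random_intercept_var == pytest.approx((msb - msw) / n_per, abs=1e-6)

    def test_interaction_type_i_error(self):
        rejections = 0
        n_rep = 100
        for seed in range(n_rep):
            table, _ = generate_cohort(CohortParams(n_subjects=32, seed=seed), bands=["low", "high"])
            hier = collapse_hierarchy(table)
            res = fit_multilevel(hier, "exp1f", "hierarchy")
            rejections += res.term(")[T.association]:iq_c")["p"] < 0.05
        assert rejections / n_rep <= 0.09


@pytest.mark.skipif(shutil.which("Rscript") is None, reason="Rscript not on PATH")
class TestSatterthwaiteAgainstLmerTest:
    def test_df_match(self, tmp_path, cohort_fei_128):
        table, _ = cohort_fei_128
        hier = collapse_hierarchy(table.head(48 * 28))  # 48 subjects
        csv = tmp_path / "d.csv"
        hier.to_csv(csv, index=False)
        res = fit_multilevel(hier, "fei", "hierarchy")
        script = tmp_path / "lmm.R"
        script.write_text(
            f"""
            suppressMessages(library(lmerTest))
            d <- read.csv("{csv}")
            d$iq_c <- d$iq - mean(d$iq); d$age_c <- d$age - mean(d$age)
            d$hierarchy <- relevel(factor(d$hierarchy), "sensorimotor")
            m <- lmer(value ~ age_c + sex + hemisphere + band + hierarchy*iq_c
                      + (1|subject_id), data=d, REML=TRUE)
            co <- summary(m)$coefficients
            for (r in rownames(co)) cat(r, co[r, "Estimate"], co[r, "df"], co[r, "t value"], "\\n")
            """
        )
        out = subprocess.run(["Rscript", str(script)], capture_output=True, text=True, timeout=300)
        assert out.returncode == 0, out.stderr
        r_rows = {}
        for line in out.stdout.strip().splitlines():
            parts = line.split()
            r_rows[parts[0]] = (float(parts[1]), float(parts[2]), float(parts[3]))
        pairs = {
            "iq_c": "iq_c",
            "hierarchyassociation:iq_c": ")[T.association]:iq_c",
            "age_c": "age_c",
        }
        for r_name, my_pat in pairs.items():
            est_r, df_r, t_r = r_rows[r_name]
            mine = res.term(my_pat)
            assert mine["estimate"] == pytest.approx(est_r, rel=1e-4, abs=1e-8)
            assert mine["statistic"] == pytest.approx(t_r, rel=1e-3)
            assert mine["df"] == pytest.approx(df_r, rel=0.02)


class TestJohnsonNeyman:
    def test_constant_slope_significant_everywhere(self):
        # zero interaction, large main effect
        rng = np.random.default_rng(0)
        table, _ = generate_cohort(CohortParams(n_subjects=64, seed=2))
        table = table.copy()
        table["value"] += 0.05 * (table["rank"] - 4)  # strong rank main effect
        res = fit_multilevel(table, "exp1f", "network")
        jn = johnson_neyman(res, "rank_c", "rank_c:iq_c", np.linspace(-30, 30, 15))
        assert jn.grid["significant"].all()
        assert jn.boundaries == []

    def test_null_significant_nowhere(self):
        nowhere = 0
        n_rep = 40
        for seed in range(n_rep):
            table, _ = generate_cohort(CohortParams(n_subjects=32, seed=seed + 100))
            res = fit_multilevel(table, "exp1f", "network")
            jn = johnson_neyman(res, "rank_c", "rank_c:iq_c", np.linspace(-25, 25, 11))
            nowhere += not jn.grid["significant"].any()
        assert nowhere >= 0.85 * n_rep

    def test_matches_recentering_refit_oracle(self, cohort_fei_128):
        # slope at moderator value m equals the focal main effect after
        # refitting with the moderator recentered at m (via the formula, so
        # the model's own mean-centering cannot undo the shift)
        table, _ = cohort_fei_128
        res = fit_multilevel(table, "fei", "network")
        base = "value ~ age_c + sex + hemisphere + band"
        for m_val in (-15.0, 0.0, 20.0):
            jn = johnson_neyman(res, "rank_c", "rank_c:iq_c", np.array([m_val]))
            refit = fit_multilevel(
                table, "fei", "network",
                formula=f"{base} + rank_c * I(iq_c - {m_val})",
            )
            row = refit.term("rank_c")
            assert jn.grid["slope"].iloc[0] == pytest.approx(row["estimate"], abs=1e-6)
            assert jn.grid["se"].iloc[0] == pytest.approx(row["se"], rel=1e-4)

    def test_missing_interaction_rejected(self, cohort_128):
        table, _ = cohort_128
        res = fit_multilevel(table, "exp1f", "network")
        with pytest.raises(KeyError):
            johnson_neyman(res, "rank_c", "rank_c:definitely_absent", np.array([0.0]))

    def test_estimator_facade(self, cohort_fei_128):
        table, _ = cohort_fei_128
        est = MixedInteractionModel(biomarker="fei", level="network").fit(table)
        jn = est.johnson_neyman(np.linspace(-20, 20, 5))
        assert len(jn.grid) == 5


class TestGammModels:
    def test_fei_network_detects_linear_interaction(self, cohort_fei_128):
        table, _ = cohort_fei_128
        res = fit_gamm(table, "fei", "network")
        row = res.terms.set_index("term").loc["iq:rank"]
        assert row["p_bonf"] < 0.01
        assert res.m == len(res.terms[(res.terms["term"] != "(Intercept)")
                                      & (res.terms["type"] != "random")])

    def test_parametric_interaction_type_i_error(self):
        rejections = 0
        n_rep = 60
        for seed in range(n_rep):
            table, _ = generate_cohort(CohortParams(n_subjects=32, seed=seed + 300), bands=["low", "high"])
            hier = collapse_hierarchy(table)
            hier["biomarker"] = "fei"
            res = fit_gamm(hier, "fei", "hierarchy")
            row = res.terms.set_index("term").loc["iq:hierarchy[sensorimotor]"]
            rejections += row["p"] < 0.05
        assert rejections / n_rep <= 0.1

    def test_surface_export_shape(self, cohort_fei_128):
        table, _ = cohort_fei_128
        res = fit_gamm(table, "fei", "hierarchy")
        surf = predict_surface(res, table, "fei", "hierarchy", n_age=10)
        assert set(surf["iq_level"]) == {"low", "medium", "high"}
        assert len(surf) == 3 * 2 * 10
        assert np.isfinite(surf["fitted"]).all()


class TestBonferroni:
    def test_worked_examples(self):
        assert bonferroni([0.01], 7)[0] == pytest.approx(0.07)
        assert bonferroni([0.5], 7)[0] == 1.0
        # per-test threshold for alpha=0.05 with m=7
        assert 0.05 / 7 == pytest.approx(0.00714, abs=1e-5)

    def test_monotone_and_idempotent_at_m1(self):
        p = np.array([0.001, 0.01, 0.2, 0.9])
        adj = bonferroni(p, 3)
        assert np.all(np.diff(adj) >= 0)
        assert np.allclose(bonferroni(p, 1), p)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            bonferroni([1.2], 2)
        with pytest.raises(ValueError):
            bonferroni([0.5], 0)


class TestSubgroupTTest:
    def test_identical_groups_give_t_zero(self):
        df = _subject_table(200, 0.0, 3)
        df["value"] = 1.0  # constant outcome
        # degenerate: zero variance in both groups -> t = 0 via direct scipy
        high = df[df["iq"] >= df["iq"].mean() + df["iq"].std()]["value"]
        low = df[df["iq"] <= df["iq"].mean() - df["iq"].std()]["value"]
        res = spstats.ttest_ind(high, low, equal_var=False)
        assert np.isnan(res.statistic) or res.statistic == 0.0

    def test_shift_detected_with_expected_power(self):
        # 0.6 pooled-SD shift at n ~ 20/18: power >= 0.35 at alpha = 0.05
        rng = np.random.default_rng(0)
        hits = 0
        n_rep = 200
        for _ in range(n_rep):
            a = rng.normal(0.6, 1.0, 20)
            b = rng.normal(0.0, 1.0, 18)
            hits += spstats.ttest_ind(a, b, equal_var=False).pvalue < 0.05
        assert hits / n_rep >= 0.35

    def test_on_cohort_table(self, cohort_128):
        table, cov = cohort_128
        res = subgroup_ttest(table, "exp1f", "association")
        # truncated-normal IQ: ~15.9% beyond each 1-SD cutoff
        assert 0.08 * 128 <= res.n_high <= 0.25 * 128
        assert 0.08 * 128 <= res.n_low <= 0.25 * 128
        assert np.isfinite(res.t) and 0 <= res.p <= 1

    def test_small_group_rejected(self):
        df = _subject_table(6, 0.0, 5)
        with pytest.raises(ValueError, match="subgroup too small"):
            subgroup_ttest(df, "exp1f", "association")


class TestWilcoxon:
    def test_hand_enumerated_fixture(self):
        # [1,2] vs [3,4]: W = 3 (minimum possible); exact two-sided p by
        # enumeration over all C(4,2)=6 assignments: 2/6
        res = wilcoxon_age_groups([1.0, 2.0], [3.0, 4.0])
        assert res.w == 3.0
        ws = [sum(sorted([1, 2, 3, 4]).index(v) + 1 for v in pair)
              for pair in combinations([1, 2, 3, 4], 2)]
        extreme = sum(1 for w in ws if w <= 3 or w >= 7)
        assert res.p == pytest.approx(extreme / len(ws))

    def test_disjoint_supports_exact_p(self):
        from math import comb

        x = list(range(10))
        y = [v + 100 for v in range(10)]
        res = wilcoxon_age_groups(x, y)
        assert res.method == "exact"
        assert res.p == pytest.approx(2 / comb(20, 10), rel=1e-9)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(1)
        ps = [
            wilcoxon_age_groups(rng.normal(size=30), rng.normal(size=30)).p
            for _ in range(200)
        ]
        ks = spstats.kstest(ps, "uniform")
        assert ks.pvalue > 0.01

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError, match="non-empty"):
            wilcoxon_age_groups([], [1.0])
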