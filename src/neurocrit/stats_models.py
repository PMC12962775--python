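"""Inferential models relating criticality biomarkers to IQ, age, and
network hierarchy.

The suite mirrors a standard moderation-analysis ladder:

* region-level OLS of a biomarker on IQ with age and sex as covariates of
  no interest (standardized IQ coefficient reported);
* linear mixed models with random subject intercepts and a
  hierarchy x IQ (or rank x IQ) interaction, with Satterthwaite
  denominator degrees of freedom;
* Johnson-Neyman probing of the interaction: the IQ range over which the
  simple slope of the focal predictor is significant;
* GAMMs with tensor-product smooths (see :mod:`neurocrit.gamm`) for
  age x hierarchy/rank x IQ moderation;
* subgroup Welch t-tests (high-IQ >= mean + SD vs low-IQ <= mean - SD),
  Wilcoxon rank-sum comparisons across age groups, and Bonferroni
  correction sized by the number of fixed plus smooth effects per model.

Mixed models are estimated by REML through statsmodels' MixedLM; the
Satterthwaite approximation is computed here from the REML likelihood of
the random-intercept model (gradient-of-variance formula). When the
random-intercept variance collapses to zero the models degenerate to OLS
and degrees of freedom fall back to a labeled normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
import statsmodels.formula.api as smf
from scipy import stats as spstats
from sklearn.base import BaseEstimator

from .gamm import GAMM, RandomIntercept, TensorSmooth

__all__ = [
    "ModelResult",
    "JNInterval",
    "fit_region_linear",
    "fit_multilevel",
    "johnson_neyman",
    "fit_gamm",
    "bonferroni",
    "subgroup_ttest",
    "wilcoxon_age_groups",
    "RegionLinear",
    "MixedInteractionModel",
    "predict_surface",
]


@dataclass
class ModelResult:
    """Tidy summary of one fitted model.

    ``terms`` has one row per tested effect: estimate/se/df/statistic/p
    plus Bonferroni-adjusted p with the family size ``m`` recorded.
    """

    terms: pd.DataFrame
    n_obs: int
    n_subjects: int
    m: int
    model: str
    random_intercept_var: float = float("nan")
    resid_var: float = float("nan")
    df_method: str = ""
    params: pd.Series | None = None
    cov: pd.DataFrame | None = None
    extra: dict = field(default_factory=dict)

    def term(self, pattern: str) -> pd.Series:
        hits = self.terms[self.terms["term"].str.contains(pattern, regex=False)]
        if hits.empty:
            raise KeyError(f"no term matching {pattern!r}")
        return hits.iloc[0]


@dataclass
class JNInterval:
    """Johnson-Neyman probe of an interaction.

    ``grid`` carries the moderator values with the simple slope of the
    focal predictor, its SE, t and p at each point; ``significant`` flags
    p < alpha, and ``boundaries`` lists the moderator values (on the grid
    hull) where significance switches.
    """

    grid: pd.DataFrame
    alpha: float
    boundaries: list[float]

    @property
    def significant_range(self) -> tuple[float, float] | None:
        sig = self.grid[self.grid["significant"]]
        if sig.empty:
            return None
        return float(sig["moderator"].min()), float(sig["moderator"].max())


# ---------------------------------------------------------------------------
# region-level linear model (model i)
# ---------------------------------------------------------------------------


def _per_subject_region_mean(table: pd.DataFrame, biomarker: str, region: str) -> pd.DataFrame:
    df = table[(table["biomarker"] == biomarker) & (table["hierarchy"] == region)]
    if df.empty:
        raise ValueError(f"no rows for biomarker={biomarker!r}, region={region!r}")
    agg = (
        df.groupby("subject_id")
        .agg(value=("value", lambda v: v.mean(skipna=True)), age=("age", "first"),
             sex=("sex", "first"), iq=("iq", "first"))
        .reset_index()
    )
    return agg.dropna(subset=["value"])


def fit_region_linear(table: pd.DataFrame, biomarker: str, region: str) -> ModelResult:
    """OLS of the per-subject region-mean biomarker on IQ + age + sex.

    Hemispheres and bands are collapsed to one value per subject first.
    Reports the standardized IQ coefficient (biomarker and IQ z-scored).
    """
    df = _per_subject_region_mean(table, biomarker, region)
    X = pd.DataFrame(
        {
            "iq": df["iq"],
            "age": df["age"],
            "sex": (df["sex"] == "M").astype(float),
        }
    )
    if np.linalg.matrix_rank(sm.add_constant(X).to_numpy()) < X.shape[1] + 1:
        raise ValueError("rank-deficient design (collinear covariates)")
    fit = sm.OLS(df["value"].to_numpy(), sm.add_constant(X)).fit()
    beta_std = fit.params["iq"] * df["iq"].std(ddof=1) / df["value"].std(ddof=1)
    rows = []
    for name in ("iq", "age", "sex"):
        rows.append(
            {"term": name, "estimate": fit.params[name], "se": fit.bse[name],
             "df": fit.df_resid, "statistic": fit.tvalues[name], "p": fit.pvalues[name]}
        )
    terms = pd.DataFrame(rows)
    terms["p_bonf"] = np.minimum(1.0, terms["p"])
    return ModelResult(
        terms=terms, n_obs=int(fit.nobs), n_subjects=len(df), m=1,
        model=f"linear[{biomarker},{region}]", resid_var=float(fit.mse_resid),
        df_method="exact", params=fit.params, cov=pd.DataFrame(
            fit.cov_params(), index=fit.params.index, columns=fit.params.index),
        extra={"beta_std_iq": float(beta_std), "r2": float(fit.rsquared)},
    )


# ---------------------------------------------------------------------------
# multilevel models (models ii a/b) with Satterthwaite df
# ---------------------------------------------------------------------------


def _reml_loglik_random_intercept(
    theta: np.ndarray, y: np.ndarray, X: np.ndarray, codes: np.ndarray, n_groups: int
) -> float:
    """REML log-likelihood of y = X b + u_group + e at theta = (log s2, log t2)."""
    s2, t2 = np.exp(theta)
    n, p = X.shape
    counts = np.bincount(codes, minlength=n_groups).astype(float)
    shrink = t2 / (s2 + counts * t2)  # per group

    def vinv_dot(M: np.ndarray) -> np.ndarray:
        # V^-1 M with V = s2 I + t2 J per group (Woodbury)
        sums = np.zeros((n_groups, M.shape[1]))
        np.add.at(sums, codes, M)
        return (M - shrink[codes, None] * sums[codes]) / s2

    XtVinvX = X.T @ vinv_dot(X)
    XtVinvy = X.T @ vinv_dot(y[:, None])[:, 0]
    beta = np.linalg.solve(XtVinvX, XtVinvy)
    r = y - X @ beta
    quad = float(r @ vinv_dot(r[:, None])[:, 0])
    logdet_V = float(np.sum((counts - 1) * np.log(s2) + np.log(s2 + counts * t2)))
    sign, logdet_XVX = np.linalg.slogdet(XtVinvX)
    return -0.5 * (logdet_V + logdet_XVX + quad)


def _satterthwaite_dfs(
    y: np.ndarray, X: np.ndarray, codes: np.ndarray, n_groups: int,
    s2: float, t2: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-coefficient Satterthwaite df and SEs at the REML estimates.

    df_j = 2 f_j^2 / (g_j' A g_j) with f_j = Var(beta_j) as a function of
    the variance parameters, g_j its gradient (finite differences on the
    log scale), and A the inverse observed REML information.
    """
    theta = np.log([max(s2, 1e-10), max(t2, 1e-10)])

    def var_beta(th: np.ndarray) -> np.ndarray:
        s2_, t2_ = np.exp(th)
        counts = np.bincount(codes, minlength=n_groups).astype(float)
        shrink = t2_ / (s2_ + counts * t2_)
        sums = np.zeros((n_groups, X.shape[1]))
        np.add.at(sums, codes, X)
        VinvX = (X - shrink[codes, None] * sums[codes]) / s2_
        return np.diag(np.linalg.inv(X.T @ VinvX))

    h = 1e-4
    f0 = var_beta(theta)
    grads = np.empty((2, len(f0)))
    for k in range(2):
        tp, tm = theta.copy(), theta.copy()
        tp[k] += h
        tm[k] -= h
        grads[k] = (var_beta(tp) - var_beta(tm)) / (2 * h)

    def nll(th):
        return -_reml_loglik_random_intercept(th, y, X, codes, n_groups)

    H = np.empty((2, 2))
    for a in range(2):
        for b in range(2):
            ta = np.zeros(2); ta[a] = h
            tb = np.zeros(2); tb[b] = h
            H[a, b] = (
                nll(theta + ta + tb) - nll(theta + ta - tb)
                - nll(theta - ta + tb) + nll(theta - ta - tb)
            ) / (4 * h * h)
    try:
        A = np.linalg.inv(H)
        if np.any(np.diag(A) < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        return np.full(len(f0), np.inf), np.sqrt(f0)
    denom = np.einsum("kj,kl,lj->j", grads, A, grads)
    with np.errstate(divide="ignore", invalid="ignore"):
        dfs = 2 * f0**2 / denom
    dfs = np.where((denom <= 0) | ~np.isfinite(dfs), np.inf, dfs)
    return dfs, np.sqrt(f0)


def _multilevel_formula(biomarker: str, level: str) -> str:
    base = "value ~ age_c + sex + hemisphere"
    if biomarker == "fei":
        base += " + band"
    if level == "hierarchy":
        base += " + C(hierarchy, Treatment('sensorimotor')) * iq_c"
    elif level == "network":
        base += " + rank_c * iq_c"
    else:
        raise ValueError(f"level must be 'hierarchy' or 'network', got {level!r}")
    return base


def fit_multilevel(
    table: pd.DataFrame, biomarker: str = "fei", level: str = "hierarchy",
    formula: str | None = None,
) -> ModelResult:
    """Linear mixed model with random subject intercepts (REML).

    Fixed effects: age, sex, hemisphere, (band for fE/I), and the
    hierarchy x IQ (two-level factor) or rank x IQ (continuous) interaction,
    with IQ and rank centered at their sample means. Denominator df by the
    Satterthwaite approximation; if the random-intercept variance estimate
    is (near) zero the fit degenerates to OLS and df fall back to a
    normal approximation, labeled in ``df_method``.
    """
    df = table[(table["biomarker"] == biomarker) & np.isfinite(table["value"])].copy()
    if df.empty:
        raise ValueError(f"no usable rows for biomarker={biomarker!r}")
    df["iq_c"] = df["iq"] - df["iq"].mean()
    df["age_c"] = df["age"] - df["age"].mean()
    if "rank" in df.columns:
        df["rank_c"] = df["rank"] - df["rank"].mean()
    fml = formula or _multilevel_formula(biomarker, level)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        md = smf.mixedlm(fml, df, groups=df["subject_id"])
        fit = None
        last_err: Exception | None = None
        # the default optimizer can step through a singular covariance on
        # small samples; fall through a cascade of optimizers
        for method in ("lbfgs", "bfgs", "powell", "nm"):
            try:
                fit = md.fit(reml=True, method=method)
                break
            except (np.linalg.LinAlgError, ValueError, OverflowError) as err:
                last_err = err
        if fit is None:
            raise RuntimeError(f"mixed-model fit failed: {last_err}") from last_err
        if float(fit.cov_re.iloc[0, 0]) < 1e-8 * max(float(fit.scale), 1e-12):
            # lbfgs sometimes stops at the tau^2 = 0 boundary even when the
            # optimum is interior; cross-check with a derivative-free refit
            try:
                alt = md.fit(reml=True, method="powell")
                # a boundary fit may report a non-finite likelihood
                if np.isfinite(alt.llf) and (
                    not np.isfinite(fit.llf) or alt.llf > fit.llf + 1e-6
                ):
                    fit = alt
            except (np.linalg.LinAlgError, ValueError, OverflowError):
                pass

    s2 = float(fit.scale)
    t2 = float(fit.cov_re.iloc[0, 0])
    singular = t2 < 1e-8 * max(s2, 1e-12)

    X = md.exog
    y = md.endog
    codes = pd.Categorical(df["subject_id"]).codes.astype(int)
    n_groups = codes.max() + 1
    names = list(md.exog_names)

    if singular:
        dfs = np.full(len(names), np.inf)
        df_method = "normal-approx (singular random intercept, variance pinned at 0)"
        warnings.warn("singular random-intercept fit: variance pinned at 0", UserWarning)
    else:
        dfs, _ = _satterthwaite_dfs(y, X, codes, n_groups, s2, t2)
        df_method = "satterthwaite"

    params = fit.fe_params
    bse = fit.bse_fe
    rows = []
    for j, name in enumerate(names):
        t = params.iloc[j] / bse.iloc[j]
        d = dfs[j]
        p = 2 * (spstats.t.sf(abs(t), d) if np.isfinite(d) else spstats.norm.sf(abs(t)))
        rows.append({"term": name, "estimate": params.iloc[j], "se": bse.iloc[j],
                     "df": d, "statistic": t, "p": p})
    terms = pd.DataFrame(rows)
    m = len(names) - 1  # tested fixed effects, intercept excluded
    terms["p_bonf"] = np.minimum(1.0, terms["p"] * m)
    cov = pd.DataFrame(np.asarray(fit.cov_params())[: len(names), : len(names)],
                       index=names, columns=names)
    return ModelResult(
        terms=terms, n_obs=len(df), n_subjects=n_groups, m=m,
        model=f"multilevel[{biomarker},{level}]",
        random_intercept_var=0.0 if singular else t2, resid_var=s2,
        df_method=df_method, params=params, cov=cov,
        extra={"formula": fml, "iq_mean": float(df["iq"].mean()),
               "rank_mean": float(df["rank"].mean()) if "rank" in df.columns else np.nan},
    )


# ---------------------------------------------------------------------------
# Johnson-Neyman
# ---------------------------------------------------------------------------


def johnson_neyman(
    result: ModelResult, focal: str, interaction: str,
    moderator_values: np.ndarray, alpha: float = 0.05,
) -> JNInterval:
    """Simple slope of ``focal`` across the moderator, from the fitted
    coefficient covariance.

    ``focal`` / ``interaction`` are matched against coefficient names
    (substring). The moderator values must be on the same (centered) scale
    as the interaction's moderator column. Significance uses the t
    distribution with the focal term's denominator df.
    """
    names = list(result.params.index)

    def find(pat: str) -> int:
        if pat in names:
            return names.index(pat)
        hits = [i for i, n in enumerate(names) if pat in n]
        if not hits:
            raise KeyError(f"no coefficient matching {pat!r} in {names}")
        return hits[0]

    i_f = find(focal)
    i_x = find(interaction)
    if i_f == i_x:
        raise ValueError("focal and interaction patterns matched the same coefficient")
    b = result.params.to_numpy()
    V = result.cov.to_numpy()
    dfs = result.terms.set_index("term")["df"]
    dof = float(dfs.iloc[i_f]) if np.isfinite(dfs.iloc[i_f]) else np.inf
    tcrit = spstats.t.ppf(1 - alpha / 2, dof) if np.isfinite(dof) else spstats.norm.ppf(1 - alpha / 2)

    rows = []
    for mval in np.asarray(moderator_values, dtype=float):
        slope = b[i_f] + mval * b[i_x]
        var = V[i_f, i_f] + 2 * mval * V[i_f, i_x] + mval**2 * V[i_x, i_x]
        se = np.sqrt(var)
        t = slope / se
        p = 2 * (spstats.t.sf(abs(t), dof) if np.isfinite(dof) else spstats.norm.sf(abs(t)))
        rows.append({"moderator": mval, "slope": slope, "se": se, "t": t, "p": p,
                     "significant": abs(t) > tcrit})
    grid = pd.DataFrame(rows)
    sig = grid["significant"].to_numpy()
    boundaries = [float(grid["moderator"].iloc[i]) for i in range(1, len(sig)) if sig[i] != sig[i - 1]]
    return JNInterval(grid=grid, alpha=alpha, boundaries=boundaries)


# ---------------------------------------------------------------------------
# GAMMs (models iii a/b, iv a/b)
# ---------------------------------------------------------------------------

_GAMM_SPECS = {
    # (biomarker kind, level): (parametric terms, smooths)
    ("fei", "hierarchy"): (
        ["sex", "hemisphere", "band", "age", "iq", "hierarchy",
         "age:iq", "age:hierarchy", "iq:hierarchy", "age:iq:hierarchy"],
        [TensorSmooth(("age", "iq"), k=4, by="hierarchy")],
    ),
    ("fei", "network"): (
        ["sex", "hemisphere", "band", "age", "iq", "rank",
         "age:iq", "age:rank", "iq:rank", "age:iq:rank"],
        [TensorSmooth(("age", "rank", "iq"), k=4)],
    ),
    # age kept as a linear main effect only (no age interactions)
    ("exp1f", "hierarchy"): (
        ["sex", "hemisphere", "age", "iq", "hierarchy", "iq:hierarchy"],
        [TensorSmooth(("iq",), k=4, by="hierarchy")],
    ),
    ("exp1f", "network"): (
        ["sex", "hemisphere", "age", "iq", "rank", "iq:rank"],
        [TensorSmooth(("rank", "iq"), k=4)],
    ),
}


def fit_gamm(
    table: pd.DataFrame, biomarker: str = "fei", level: str = "hierarchy",
    select: bool = True,
) -> ModelResult:
    """Tensor-product GAMM for one biomarker at one spatial level.

    fE/I models include age in the linear and smooth interactions; the
    1/f-exponent models keep age as a linear covariate only. Rank (1-7)
    enters as a continuous predictor at network level; hierarchy as a
    ``by`` factor at region level. Bonferroni family size m = number of
    tested fixed plus smooth effects, computed from the model formula.
    """
    key = ("fei" if biomarker == "fei" else "exp1f", level)
    if key not in _GAMM_SPECS:
        raise ValueError(f"no GAMM specification for {key}")
    parametric, smooths = _GAMM_SPECS[key]
    df = table[(table["biomarker"] == biomarker) & np.isfinite(table["value"])].copy()
    if df.empty:
        raise ValueError(f"no usable rows for biomarker={biomarker!r}")
    parametric = [t for t in parametric
                  if all(v in df.columns and df[v.strip()].nunique() > 1 for v in t.split(":"))]
    model = GAMM(parametric=parametric, smooths=smooths,
                 random=RandomIntercept("subject_id"), select=select)
    model.fit(df, y="value")

    terms = model.summary_.rename(columns={"statistic": "statistic"})
    tested = terms[(terms["term"] != "(Intercept)") & (terms["type"] != "random")]
    m = len(tested)
    terms = terms.copy()
    terms["df"] = np.where(terms["type"] == "parametric", model.residual_df_, terms["edf"])
    terms["p_bonf"] = np.minimum(1.0, terms["p"] * m)
    re_row = terms[terms["type"] == "random"]
    re_var = float(re_row["estimate"].iloc[0]) if not re_row.empty else np.nan
    return ModelResult(
        terms=terms, n_obs=model.n_obs_, n_subjects=df["subject_id"].nunique(), m=m,
        model=f"gamm[{biomarker},{level}]", random_intercept_var=re_var,
        resid_var=model.sigma2_, df_method="penalized-regression approx",
        extra={"gamm": model, "edf_total": model.edf_total_},
    )


def predict_surface(
    result: ModelResult, table: pd.DataFrame, biomarker: str = "fei",
    level: str = "hierarchy", n_age: int = 25,
) -> pd.DataFrame:
    """GAMM prediction surface at IQ = mean - SD, mean, mean + SD.

    Returns a tidy frame (age, hierarchy/rank, iq_level, fitted, se) on an
    age grid, averaging over the non-focal covariates (reference levels).
    """
    model: GAMM = result.extra["gamm"]
    df = table[(table["biomarker"] == biomarker) & np.isfinite(table["value"])]
    iq_m, iq_s = df["iq"].mean(), df["iq"].std(ddof=1)
    ages = np.linspace(df["age"].min(), df["age"].max(), n_age)
    groups = sorted(df["hierarchy"].unique()) if level == "hierarchy" else sorted(df["rank"].unique())
    gcol = "hierarchy" if level == "hierarchy" else "rank"
    rows = []
    for iq_label, iq_val in (("low", iq_m - iq_s), ("medium", iq_m), ("high", iq_m + iq_s)):
        for g in groups:
            new = pd.DataFrame({"age": ages})
            new[gcol] = g
            new["iq"] = iq_val
            for col in ("sex", "hemisphere", "band"):
                if col in df.columns:
                    new[col] = df[col].mode().iloc[0]
            if gcol == "rank":
                new["hierarchy"] = "sensorimotor" if g <= 3 else "association"
            else:
                new["rank"] = 2 if g == "sensorimotor" else 5.5
            new["subject_id"] = "__new__"
            mu, se = model.predict(new, se=True)
            for a, f_, s_ in zip(ages, mu, se):
                rows.append({"age": a, gcol: g, "iq_level": iq_label, "iq": iq_val,
                             "fitted": f_, "se": s_})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# simple tests and multiplicity control
# ---------------------------------------------------------------------------


def bonferroni(pvals: np.ndarray, m: int) -> np.ndarray:
    """Bonferroni adjustment p_adj = min(1, p * m)."""
    p = np.asarray(pvals, dtype=float)
    if m < 1:
        raise ValueError(f"m must be >= 1, got {m}")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return np.minimum(1.0, p * m)


@dataclass
class TTestResult:
    t: float
    df: float
    p: float
    n_high: int
    n_low: int
    mean_high: float
    mean_low: float
    sd_high: float
    sd_low: float


def subgroup_ttest(table: pd.DataFrame, biomarker: str, region: str) -> TTestResult:
    """Welch t-test: high-IQ (>= mean + SD) vs low-IQ (<= mean - SD) subjects.

    Computed on per-subject region means; IQ cutoffs from the sample of
    subjects present in the table.
    """
    df = _per_subject_region_mean(table, biomarker, region)
    iq_m, iq_s = df["iq"].mean(), df["iq"].std(ddof=1)
    high = df[df["iq"] >= iq_m + iq_s]["value"]
    low = df[df["iq"] <= iq_m - iq_s]["value"]
    if len(high) < 2 or len(low) < 2:
        raise ValueError(f"subgroup too small: n_high={len(high)}, n_low={len(low)}")
    res = spstats.ttest_ind(high, low, equal_var=False)
    return TTestResult(
        t=float(res.statistic), df=float(res.df), p=float(res.pvalue),
        n_high=len(high), n_low=len(low),
        mean_high=float(high.mean()), mean_low=float(low.mean()),
        sd_high=float(high.std(ddof=1)), sd_low=float(low.std(ddof=1)),
    )


@dataclass
class RankSumResult:
    w: float
    p: float
    n1: int
    n2: int
    method: str


def wilcoxon_age_groups(
    x: np.ndarray, y: np.ndarray, exact_max_n: int = 20
) -> RankSumResult:
    """Wilcoxon rank-sum test (W = rank sum of the first sample, midranks
    for ties; exact null distribution for small samples, else normal
    approximation with tie correction)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be non-empty")
    method = "exact" if max(len(x), len(y)) <= exact_max_n else "asymptotic"
    res = spstats.mannwhitneyu(x, y, alternative="two-sided", method=method)
    w = float(res.statistic) + len(x) * (len(x) + 1) / 2.0  # U1 -> rank sum of x
    return RankSumResult(w=w, p=float(res.pvalue), n1=len(x), n2=len(y), method=method)


# ---------------------------------------------------------------------------
# estimator facades
# ---------------------------------------------------------------------------


class RegionLinear(BaseEstimator):
    """Region-level OLS (model i) as an estimator over a biomarker table."""

    def __init__(self, biomarker: str = "fei", region: str = "association") -> None:
        self.biomarker = biomarker
        self.region = region

    def fit(self, table: pd.DataFrame, y=None) -> "RegionLinear":
        self.result_ = fit_region_linear(table, self.biomarker, self.region)
        self.beta_std_iq_ = self.result_.extra["beta_std_iq"]
        return self


class MixedInteractionModel(BaseEstimator):
    """Multilevel hierarchy/rank x IQ interaction model (models ii a/b)."""

    def __init__(self, biomarker: str = "fei", level: str = "hierarchy") -> None:
        self.biomarker = biomarker
        self.level = level

    def fit(self, table: pd.DataFrame, y=None) -> "MixedInteractionModel":
        self.result_ = fit_multilevel(table, self.biomarker, self.level)
        return self

    def johnson_neyman(self, moderator_values: np.ndarray, alpha: float = 0.05) -> JNInterval:
        focal = ("C(hierarchy, Treatment('sensorimotor'))[T.association]"
                 if self.level == "hierarchy" else "rank_c")
        return johnson_neyman(self.result_, focal=focal, interaction=f"{focal}:iq_c",
                              moderator_values=moderator_values, alpha=alpha)
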