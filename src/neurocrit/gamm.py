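"""Generalized additive mixed models with tensor-product smooths.

A Gaussian additive model

    y = X_para beta + sum_t f_t(covariates) + b_subject + eps

where each smooth f_t is a (tensor-product) P-spline: cubic B-spline
marginal bases with second-order difference penalties, combined by
row-wise Kronecker products, sum-to-zero constrained, optionally
replicated per level of a ``by`` factor. Random subject intercepts enter
as an identity-penalized coefficient block (a random-effect "smooth").

Smoothing parameters are selected by REML using the generalized
Fellner-Schall update

    lambda_j <- sigma^2 * [tr(S_lambda^- S_j) - tr((X'X + S_lambda)^-1 S_j)]
                / (beta' S_j beta)

iterated to convergence. With ``select=True`` each smooth also receives a
null-space penalty (its own lambda), so smooths whose true shape lies in
the penalty null space — e.g. a purely linear interaction — can shrink to
zero effective degrees of freedom, mirroring double-penalty shrinkage
selection.

Inference mirrors the usual penalized-regression approximations: the
Bayesian posterior covariance sigma^2 (X'X + S)^-1 for coefficients,
t-tests for parametric terms on n - edf_total residual df, and Wald-type
F statistics on pseudo-inverted covariance blocks for smooth terms.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg as spla
from scipy import stats as spstats
from scipy.interpolate import BSpline
from sklearn.base import BaseEstimator

__all__ = ["TensorSmooth", "RandomIntercept", "GAMM", "bspline_basis", "build_parametric"]


def bspline_basis(x: np.ndarray, k: int, degree: int = 3,
                  xrange: tuple[float, float] | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Cubic B-spline basis with ``k`` functions on an even knot grid.

    Returns (basis matrix n x k, full knot vector). ``k`` must be at least
    degree + 1; the knot vector is clamped at the data range (or
    ``xrange``) so evaluation at the boundaries is exact.
    """
    x = np.asarray(x, dtype=float)
    if k < degree + 1:
        raise ValueError(f"k must be >= degree + 1 = {degree + 1}, got {k}")
    lo, hi = xrange if xrange is not None else (x.min(), x.max())
    if hi <= lo:
        hi = lo + 1.0
    inner = np.linspace(lo, hi, k - degree + 1)
    t = np.concatenate([[lo] * degree, inner, [hi] * degree])
    xc = np.clip(x, lo, hi)
    B = BSpline.design_matrix(xc, t, degree).toarray()
    return B, t


def _difference_penalty(k: int, order: int = 2) -> np.ndarray:
    D = np.diff(np.eye(k), n=order, axis=0)
    return D.T @ D


def _nullspace_transform(X: np.ndarray) -> np.ndarray:
    """Orthonormal basis Z of the null space of the column-mean constraint."""
    c = X.mean(axis=0, keepdims=True)
    # null space of the 1 x p matrix c
    _, _, vt = np.linalg.svd(c, full_matrices=True)
    return vt[1:].T  # p x (p-1)


@dataclass
class TensorSmooth:
    """Tensor-product P-spline smooth over one or more covariates.

    ``k`` basis functions per margin (scalar or per-variable tuple);
    ``by`` optionally replicates the smooth per level of a factor column,
    giving one independent smooth (and penalty set) per level.
    """

    variables: tuple[str, ...]
    k: int | tuple[int, ...] = 4
    by: str | None = None

    def label(self, level: str | None = None) -> str:
        base = f"te({','.join(self.variables)})"
        if level is not None:
            base += f":{self.by}={level}"
        return base


@dataclass
class RandomIntercept:
    """Random intercept per level of a grouping column (penalized block)."""

    column: str = "subject_id"

    def label(self) -> str:
        return f"s({self.column})"


class ParametricDesign:
    """Stateful parametric design builder.

    Factor levels (dummy coding, first level dropped) and numeric centers
    are learned from the training frame so prediction frames are encoded
    identically regardless of which levels or value ranges they contain.
    """

    def __init__(self, df: pd.DataFrame, terms: list[str]) -> None:
        self.terms = list(terms)
        self.levels_: dict[str, list[str]] = {}
        self.centers_: dict[str, float] = {}
        for term in self.terms:
            for name in term.split(":"):
                s = df[name]
                if s.dtype.kind in "OUSb" or isinstance(s.dtype, pd.CategoricalDtype):
                    self.levels_.setdefault(name, sorted(pd.unique(s.astype(str))))
                else:
                    self.centers_.setdefault(name, float(s.mean()))

    def _factor_columns(self, df: pd.DataFrame, name: str) -> list[tuple[str, np.ndarray]]:
        if name in self.levels_:
            s = df[name].astype(str)
            return [(f"{name}[{lv}]", (s == lv).to_numpy(float)) for lv in self.levels_[name][1:]]
        v = df[name].to_numpy(dtype=float)
        return [(name, v - self.centers_[name])]

    def build(self, df: pd.DataFrame) -> tuple[np.ndarray, list[str]]:
        cols: list[np.ndarray] = [np.ones(len(df))]
        names: list[str] = ["(Intercept)"]
        for term in self.terms:
            parts = [self._factor_columns(df, p) for p in term.split(":")]
            combos = parts[0]
            for nxt in parts[1:]:
                combos = [(f"{n1}:{n2}", v1 * v2) for n1, v1 in combos for n2, v2 in nxt]
            for name, v in combos:
                cols.append(v)
                names.append(name)
        return np.column_stack(cols), names


def build_parametric(df: pd.DataFrame, terms: list[str]) -> tuple[np.ndarray, list[str]]:
    """Design matrix for intercept + main/interaction parametric terms.

    Terms are column names or colon-joined products ("age:iq"); string or
    categorical columns are dummy-coded dropping the first level. Numeric
    columns are centered to keep interactions interpretable and the
    intercept stable.
    """
    return ParametricDesign(df, terms).build(df)


class _Block:
    """One coefficient block of the model: design columns + penalties."""

    def __init__(self, label: str, X: np.ndarray, penalties: list[np.ndarray], is_smooth: bool):
        self.label = label
        self.X = X
        self.penalties = penalties  # each p_block x p_block
        self.is_smooth = is_smooth
        self.sl: slice | None = None  # assigned at assembly


class GAMM(BaseEstimator):
    """Penalized-spline additive mixed model (see module docstring).

    Parameters
    ----------
    parametric : list of str
        Parametric terms (column names, ":"-joined for interactions);
        intercept always included.
    smooths : list of TensorSmooth
        Smooth terms.
    random : RandomIntercept or None
        Random intercept specification.
    select : bool
        Add null-space shrinkage penalties so uninformative smooths can
        shrink to ~0 effective degrees of freedom.
    max_iter : int
        Fellner-Schall iterations.

    Attributes
    ----------
    coef_ : ndarray
        Penalized coefficient estimates.
    summary_ : DataFrame
        Per-term estimates/tests: parametric rows carry (estimate, se, t,
        p), smooth rows (edf, F, p); the random intercept row its variance.
    edf_total_, sigma2_, lambdas_, cov_ : fit diagnostics.
    """

    def __init__(
        self,
        parametric: list[str] | None = None,
        smooths: list[TensorSmooth] | None = None,
        random: RandomIntercept | None = None,
        select: bool = True,
        max_iter: int = 100,
        tol: float = 1e-4,
    ) -> None:
        self.parametric = parametric or []
        self.smooths = smooths or []
        self.random = random
        self.select = select
        self.max_iter = max_iter
        self.tol = tol

    # -- design construction ------------------------------------------------

    def _marginal(self, df: pd.DataFrame, var: str, k: int) -> tuple[np.ndarray, np.ndarray, tuple]:
        x = df[var].to_numpy(dtype=float)
        n_unique = len(np.unique(x))
        k_eff = min(k, max(n_unique, 4))
        if k_eff < k:
            warnings.warn(
                f"smooth margin {var!r}: only {n_unique} unique values; basis reduced to k={k_eff}",
                UserWarning,
                stacklevel=2,
            )
        xrange = (x.min(), x.max())
        B, _ = bspline_basis(x, k_eff, xrange=xrange)
        return B, _difference_penalty(k_eff), (var, k_eff, xrange)

    def _tensor_block(self, df: pd.DataFrame, sm: TensorSmooth, rows: np.ndarray | None,
                      label: str, meta: list) -> _Block:
        ks = sm.k if isinstance(sm.k, tuple) else (sm.k,) * len(sm.variables)
        Bs, Ps, margins = [], [], []
        for var, k in zip(sm.variables, ks):
            B, P, m = self._marginal(df, var, k)
            Bs.append(B)
            Ps.append(P)
            margins.append(m)
        X = Bs[0]
        for B in Bs[1:]:
            X = (X[:, :, None] * B[:, None, :]).reshape(len(df), -1)
        dims = [B.shape[1] for B in Bs]
        pens = []
        for d, P in enumerate(Ps):
            mats = [np.eye(dim) for dim in dims]
            mats[d] = P
            S = mats[0]
            for M in mats[1:]:
                S = np.kron(S, M)
            pens.append(S)
        if rows is not None:
            X = X * rows[:, None]
        # sum-to-zero constraint (on the rows actually involved)
        Z = _nullspace_transform(X if rows is None else X[rows > 0])
        Xc = X @ Z
        pens = [Z.T @ S @ Z for S in pens]
        if self.select:
            total = sum(pens)
            eigval, eigvec = np.linalg.eigh(total)
            null = eigvec[:, eigval < 1e-8 * max(eigval.max(), 1e-300)]
            if null.shape[1] > 0:
                pens.append(null @ null.T)
        meta.append((sm, margins, Z, rows))
        return _Block(label, Xc, pens, is_smooth=True)

    def _assemble(self, df: pd.DataFrame) -> tuple[np.ndarray, list[_Block], list[str]]:
        self._para_design_ = ParametricDesign(df, self.parametric)
        Xp, names = self._para_design_.build(df)
        blocks: list[_Block] = []
        self._smooth_meta_: list = []
        for sm in self.smooths:
            if sm.by is None:
                blocks.append(self._tensor_block(df, sm, None, sm.label(), self._smooth_meta_))
            else:
                for level in sorted(pd.unique(df[sm.by].astype(str))):
                    ind = (df[sm.by].astype(str) == level).to_numpy(float)
                    blocks.append(
                        self._tensor_block(df, sm, ind, sm.label(level), self._smooth_meta_)
                    )
        if self.random is not None:
            groups = pd.Categorical(df[self.random.column].astype(str))
            Zre = np.eye(len(groups.categories))[groups.codes]
            blk = _Block(self.random.label(), Zre, [np.eye(Zre.shape[1])], is_smooth=False)
            blk.is_random = True
            blocks.append(blk)
        self._re_levels_ = (
            list(pd.Categorical(df[self.random.column].astype(str)).categories)
            if self.random is not None
            else []
        )
        return Xp, blocks, names

    # -- REML fitting -------------------------------------------------------

    def fit(self, df: pd.DataFrame, y: str | np.ndarray = "value") -> "GAMM":
        yv = df[y].to_numpy(dtype=float) if isinstance(y, str) else np.asarray(y, dtype=float)
        keep = np.isfinite(yv)
        df = df.loc[keep].reset_index(drop=True)
        yv = yv[keep]
        n = len(yv)

        Xp, blocks, para_names = self._assemble(df)
        mats = [Xp] + [b.X for b in blocks]
        offsets = np.cumsum([0] + [m.shape[1] for m in mats])
        p = offsets[-1]
        X = np.column_stack(mats)
        for b, lo, hi in zip(blocks, offsets[1:-1], offsets[2:]):
            b.sl = slice(lo, hi)
        self._para_sl_ = slice(0, offsets[1])

        # penalty list: (slice, S, lambda index)
        pen: list[tuple[slice, np.ndarray]] = []
        for b in blocks:
            for S in b.penalties:
                pen.append((b.sl, S))
        n_lam = len(pen)
        lam = np.full(n_lam, 1.0)

        XtX = X.T @ X
        Xty = X.T @ yv

        def total_S(lam_):
            S = np.zeros((p, p))
            for (sl, Sj), lj in zip(pen, lam_):
                S[sl, sl] += lj * Sj
            return S

        beta = np.zeros(p)
        sigma2 = np.var(yv)
        for _ in range(self.max_iter):
            A = XtX + total_S(lam)
            try:
                cf = spla.cho_factor(A + 1e-10 * np.eye(p))
            except np.linalg.LinAlgError:
                cf = spla.cho_factor(A + 1e-6 * np.eye(p))
            beta = spla.cho_solve(cf, Xty)
            Ainv = spla.cho_solve(cf, np.eye(p))
            edf = float(np.trace(Ainv @ XtX))
            rss = float(np.sum((yv - X @ beta) ** 2))
            sigma2 = rss / max(n - edf, 1.0)

            # per-block pseudo-inverse of the summed penalty
            new_lam = lam.copy()
            by_block: dict[int, list[int]] = {}
            for j, (sl, _) in enumerate(pen):
                by_block.setdefault(sl.start, []).append(j)
            for js in by_block.values():
                sl = pen[js[0]][0]
                Ssum = sum(lam[j] * pen[j][1] for j in js)
                eigval, eigvec = np.linalg.eigh(Ssum)
                pos = eigval > 1e-9 * max(eigval.max(), 1e-300)
                Spinv = (eigvec[:, pos] / eigval[pos]) @ eigvec[:, pos].T
                for j in js:
                    Sj = pen[j][1]
                    num = float(np.trace(Spinv @ Sj))
                    num -= float(np.trace(Ainv[sl, sl] @ Sj))
                    den = float(beta[sl] @ Sj @ beta[sl])
                    if den <= 1e-14 or num <= 0:
                        new_lam[j] = min(lam[j] * 10.0, 1e7)
                    else:
                        # multiplicative Fellner-Schall step; fixed point is
                        # the REML stationarity condition beta'Sb = s2*num
                        new_lam[j] = np.clip(lam[j] * sigma2 * num / den, 1e-7, 1e7)
            rel = np.max(np.abs(np.log(new_lam) - np.log(lam)))
            lam = new_lam
            if rel < self.tol:
                break

        A = XtX + total_S(lam)
        cf = spla.cho_factor(A + 1e-10 * np.eye(p))
        beta = spla.cho_solve(cf, Xty)
        Ainv = spla.cho_solve(cf, np.eye(p))
        F = Ainv @ XtX  # "hat" matrix in coefficient space
        edf_i = np.diag(F)
        edf = float(edf_i.sum())
        rss = float(np.sum((yv - X @ beta) ** 2))
        sigma2 = rss / max(n - edf, 1.0)
        Vb = sigma2 * Ainv

        self.coef_ = beta
        self.cov_ = Vb
        self.lambdas_ = lam
        self.sigma2_ = sigma2
        self.edf_total_ = edf
        self.n_obs_ = n
        self._blocks_ = blocks
        self._para_names_ = para_names
        self._X_shape_ = X.shape
        self.fitted_values_ = X @ beta
        self.residual_df_ = n - edf

        rows = []
        psl = self._para_sl_
        for i in range(psl.start, psl.stop):
            se = np.sqrt(Vb[i, i])
            t = beta[i] / se if se > 0 else np.nan
            pval = 2 * spstats.t.sf(abs(t), self.residual_df_)
            rows.append(
                {"term": para_names[i], "type": "parametric", "estimate": beta[i],
                 "se": se, "statistic": t, "edf": 1.0, "p": pval}
            )
        for b in blocks:
            if getattr(b, "is_random", False):
                var_re = float(np.mean(beta[b.sl] ** 2)) if b.sl.stop > b.sl.start else 0.0
                rows.append(
                    {"term": b.label, "type": "random", "estimate": var_re, "se": np.nan,
                     "statistic": np.nan, "edf": float(edf_i[b.sl].sum()), "p": np.nan}
                )
                continue
            bb = beta[b.sl]
            Vbb = Vb[b.sl, b.sl]
            edf_b = float(edf_i[b.sl].sum())
            r = max(1, int(round(min(edf_b, len(bb)))))
            eigval, eigvec = np.linalg.eigh(Vbb)
            order = np.argsort(eigval)[::-1]
            use = order[:r]
            good = eigval[use] > 1e-12 * max(eigval.max(), 1e-300)
            use = use[good]
            if len(use) == 0:
                stat, pval = 0.0, 1.0
            else:
                proj = eigvec[:, use].T @ bb
                x2 = float(np.sum(proj**2 / eigval[use]))
                stat = x2 / len(use)
                pval = spstats.f.sf(stat, len(use), self.residual_df_)
            rows.append(
                {"term": b.label, "type": "smooth", "estimate": np.nan, "se": np.nan,
                 "statistic": stat, "edf": edf_b, "p": pval}
            )
        self.summary_ = pd.DataFrame(rows)
        return self

    # -- prediction ---------------------------------------------------------

    def _design_for(self, df: pd.DataFrame) -> np.ndarray:
        Xp, _ = self._para_design_.build(df)
        mats = [Xp]
        meta_iter = iter(self._smooth_meta_)
        for b in self._blocks_:
            if getattr(b, "is_random", False):
                groups = df[self.random.column].astype(str)
                codes = pd.Categorical(groups, categories=self._re_levels_).codes
                Z = np.zeros((len(df), len(self._re_levels_)))
                ok = codes >= 0
                Z[np.arange(len(df))[ok], codes[ok]] = 1.0
                mats.append(Z)
                continue
            sm, margins, Zc, rows = next(meta_iter)
            Bs = []
            for var, k_eff, xrange in margins:
                B, _ = bspline_basis(df[var].to_numpy(dtype=float), k_eff, xrange=xrange)
                Bs.append(B)
            Xs = Bs[0]
            for B in Bs[1:]:
                Xs = (Xs[:, :, None] * B[:, None, :]).reshape(len(df), -1)
            if sm.by is not None:
                level = b.label.split("=")[-1]
                ind = (df[sm.by].astype(str) == level).to_numpy(float)
                Xs = Xs * ind[:, None]
            mats.append(Xs @ Zc)
        return np.column_stack(mats)

    def predict(self, df: pd.DataFrame, se: bool = False):
        """Fitted values for new data (unknown random-effect levels get 0)."""
        X = self._design_for(df.reset_index(drop=True))
        mu = X @ self.coef_
        if not se:
            return mu
        se_fit = np.sqrt(np.maximum(np.einsum("ij,jk,ik->i", X, self.cov_, X), 0))
        return mu, se_fit

    def term_pvalue(self, pattern: str) -> float:
        """Smallest p among summary rows whose term contains ``pattern``."""
        hits = self.summary_[self.summary_["term"].str.contains(pattern, regex=False)]
        if hits.empty:
            raise KeyError(f"no term matching {pattern!r}")
        return float(hits["p"].min())
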