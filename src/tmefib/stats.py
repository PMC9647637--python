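"""Classical inference used throughout the lesion/tumor/TLS-level analyses.

The module covers 2x2 contingency measures (odds ratios with Wald intervals,
Fisher's exact test), count transforms (Box-Cox with profile-likelihood lambda
selection, natural log with a documented zero shift), random-intercept linear
mixed models fitted by REML, Spearman correlation matrices, Mann-Whitney U and
t-tests.  Everything operates on plain numpy arrays / pandas objects.

The mixed model is the one of Laird & Ware with a single random intercept per
group: y = X beta + Z b + e, b ~ N(0, sg^2), e ~ N(0, se^2).  It is fitted by
profiling the REML criterion over the variance ratio theta = sg^2 / se^2,
which for this model reduces to a one-dimensional optimisation with all other
quantities available in closed form per candidate theta.  Fixed effects are
tested with Wald z statistics against the standard normal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats as sps

__all__ = [
    "OddsRatioResult",
    "MixedModelFit",
    "odds_ratio_wald",
    "fisher_exact_2x2",
    "boxcox_transform",
    "log_transform",
    "fit_random_intercept_lmm",
    "spearman_matrix",
    "mann_whitney_u",
    "two_sample_t",
    "shapiro_normality",
]


# ---------------------------------------------------------------------------
# contingency tables


@dataclass(frozen=True)
class OddsRatioResult:
    """Odds ratio ad/bc with a Wald confidence interval on the log scale."""

    odds_ratio: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    continuity_corrected: bool = False

    def __iter__(self):
        return iter((self.odds_ratio, self.ci_low, self.ci_high))


def odds_ratio_wald(a, b, c, d, level: float = 0.95) -> OddsRatioResult:
    """Wald odds ratio for the 2x2 table [[a, b], [c, d]].

    ``a`` counts exposed cases, ``b`` exposed non-cases, ``c`` referent cases,
    ``d`` referent non-cases; OR = ad / bc and the interval is
    exp(ln OR +- z * sqrt(1/a + 1/b + 1/c + 1/d)).  When any cell is zero the
    Haldane-Anscombe 0.5 correction is added to every cell and the result is
    flagged ``continuity_corrected``.
    """
    cells = np.asarray([a, b, c, d], dtype=float)
    if np.any(cells < 0):
        raise ValueError("contingency cells must be nonnegative")
    if cells.sum() == 0:
        raise ValueError("empty contingency table")
    corrected = bool(np.any(cells == 0))
    if corrected:
        cells = cells + 0.5
    a_, b_, c_, d_ = cells
    or_ = (a_ * d_) / (b_ * c_)
    se = np.sqrt((1.0 / cells).sum())
    z = sps.norm.ppf(0.5 + level / 2.0)
    lo, hi = np.exp(np.log(or_) + np.array([-1, 1]) * z * se)
    return OddsRatioResult(float(or_), float(lo), float(hi), level, corrected)


def fisher_exact_2x2(a, b, c, d) -> float:
    """Two-sided Fisher exact p for [[a, b], [c, d]] (margins fixed)."""
    _, p = sps.fisher_exact([[a, b], [c, d]], alternative="two-sided")
    return float(p)


# ---------------------------------------------------------------------------
# transforms


def _shifted(y, zero_shift):
    y = np.asarray(y, dtype=float)
    if np.any(~np.isfinite(y)):
        raise ValueError("non-finite values in response")
    if np.any(y <= 0):
        y = y + zero_shift
        if np.any(y <= 0):
            raise ValueError("values remain nonpositive after zero shift")
    return y


def boxcox_transform(y, lmbda: float | None = None, zero_shift: float = 0.5):
    """Box-Cox transform; lambda selected by profile likelihood when omitted.

    Counts of zero are handled by adding ``zero_shift`` to every value before
    transforming (applied only when the minimum is <= 0).  When ``lmbda`` is
    None the maximum profile-likelihood lambda is located on the grid
    [-2, 2] in steps of 0.01.

    Returns ``(transformed, lambda_hat)``.
    """
    y = _shifted(y, zero_shift)
    if lmbda is None:
        grid = np.round(np.arange(-2.0, 2.0 + 1e-9, 0.01), 2)
        llf = np.array([sps.boxcox_llf(l, y) for l in grid])
        lmbda = float(grid[int(np.argmax(llf))])
    z = np.log(y) if lmbda == 0 else (y**lmbda - 1.0) / lmbda
    return z, float(lmbda)


def log_transform(y, zero_shift: float = 0.5):
    """Natural log with the same zero-shift convention as boxcox_transform."""
    return np.log(_shifted(y, zero_shift))


# ---------------------------------------------------------------------------
# random-intercept linear mixed model


@dataclass
class MixedModelFit:
    """REML fit of a single-random-intercept linear mixed model."""

    params: pd.Series
    bse: pd.Series
    zvalues: pd.Series
    pvalues: pd.Series
    group_var: float
    resid_var: float
    n_obs: int
    n_groups: int
    group_name: str = "group"
    transform: str | None = None
    reml_criterion: float = float("nan")

    def wald_test(self, name):
        """(z, p) Wald test of a single fixed effect against zero."""
        return float(self.zvalues[name]), float(self.pvalues[name])

    def summary(self) -> str:
        rows = [
            f"Random-intercept LMM (REML), {self.n_obs} obs in "
            f"{self.n_groups} {self.group_name}s",
            f"group var {self.group_var:.5g}, residual var {self.resid_var:.5g}",
        ]
        for name in self.params.index:
            rows.append(
                f"  {name:>20s}  beta={self.params[name]: .4f}  "
                f"se={self.bse[name]:.4f}  z={self.zvalues[name]: .3f}  "
                f"p={self.pvalues[name]:.4g}"
            )
        return "\n".join(rows)


def _reml_pieces(theta, y, X, starts, counts):
    """Closed-form GLS pieces for V = I + theta * Z Z' (block diagonal)."""
    n, p = X.shape
    # group-wise sums via reduceat
    Xg = np.add.reduceat(X, starts, axis=0)  # (G, p)
    yg = np.add.reduceat(y, starts)  # (G,)
    cg = theta / (1.0 + theta * counts)  # (G,)
    XtVX = X.T @ X - (Xg * cg[:, None]).T @ Xg
    XtVy = X.T @ y - (Xg * cg[:, None]).T @ yg
    ytVy = y @ y - cg @ (yg**2)
    beta = np.linalg.solve(XtVX, XtVy)
    rss = max(float(ytVy - 2 * beta @ XtVy + beta @ (XtVX @ beta)), 1e-12)
    logdet_v = float(np.sum(np.log1p(theta * counts)))
    sign, logdet_xvx = np.linalg.slogdet(XtVX)
    if sign <= 0:
        raise np.linalg.LinAlgError("X'V^-1X not positive definite")
    crit = logdet_v + logdet_xvx + (n - p) * np.log(rss)
    return crit, beta, XtVX, rss


def fit_random_intercept_lmm(
    y,
    X,
    groups,
    group_name: str = "lesion",
    transform: str | None = None,
) -> MixedModelFit:
    """Fit y = X beta + b_group + e by REML (profile over sg^2/se^2).

    ``X`` may be a pandas DataFrame (column names kept) or 2-D array; an
    intercept column is NOT added automatically.  Requires >= 2 groups.
    """
    if isinstance(X, pd.DataFrame):
        names = list(X.columns)
        Xa = X.to_numpy(dtype=float)
    else:
        Xa = np.asarray(X, dtype=float)
        if Xa.ndim == 1:
            Xa = Xa[:, None]
        names = [f"x{i}" for i in range(Xa.shape[1])]
    y = np.asarray(y, dtype=float)
    groups = np.asarray(groups)
    if y.shape[0] != Xa.shape[0] or groups.shape[0] != y.shape[0]:
        raise ValueError("y, X and groups must have matching lengths")
    codes, _ = pd.factorize(groups)
    n_groups = int(codes.max()) + 1
    if n_groups < 2:
        raise ValueError("mixed model requires at least 2 groups")
    rank = np.linalg.matrix_rank(Xa)
    if rank < Xa.shape[1]:
        # name the collinear columns for the caller
        _, r = np.linalg.qr(Xa)
        bad = [names[j] for j in range(Xa.shape[1]) if abs(r[j, j]) < 1e-10]
        raise ValueError(f"singular fixed-effect design; collinear columns: {bad}")

    order = np.argsort(codes, kind="stable")
    ys, Xs, cs = y[order], Xa[order], codes[order]
    starts = np.flatnonzero(np.r_[1, np.diff(cs)])
    counts = np.diff(np.r_[starts, len(cs)]).astype(float)

    def crit(log_theta):
        return _reml_pieces(np.exp(log_theta), ys, Xs, starts, counts)[0]

    res = optimize.minimize_scalar(crit, bounds=(-12.0, 12.0), method="bounded")
    theta = float(np.exp(res.x))
    c0, *_ = _reml_pieces(1e-12, ys, Xs, starts, counts)
    if c0 <= res.fun:  # boundary: no group variance
        theta = 0.0
    best, beta, XtVX, rss = _reml_pieces(max(theta, 1e-12), ys, Xs, starts, counts)
    n, p = Xs.shape
    resid_var = rss / (n - p)
    group_var = theta * resid_var
    cov = np.linalg.inv(XtVX) * resid_var
    se = np.sqrt(np.diag(cov))
    zv = beta / se
    pv = 2.0 * sps.norm.sf(np.abs(zv))
    idx = pd.Index(names)
    return MixedModelFit(
        params=pd.Series(beta, idx),
        bse=pd.Series(se, idx),
        zvalues=pd.Series(zv, idx),
        pvalues=pd.Series(pv, idx),
        group_var=float(group_var),
        resid_var=float(resid_var),
        n_obs=int(n),
        n_groups=n_groups,
        group_name=group_name,
        transform=transform,
        reml_criterion=float(best),
    )


# ---------------------------------------------------------------------------
# rank statistics


def spearman_matrix(X: pd.DataFrame, y=None, alpha: float = 0.05):
    """Spearman rho among columns of X (optionally plus a response column).

    Pairwise-complete rows, average ranks on ties.  Returns
    ``(rho, pvalues, significant)`` DataFrames; the significance mask uses the
    unadjusted per-pair alpha, matching raw-p reporting.
    """
    df = X.copy()
    if y is not None:
        ser = pd.Series(np.asarray(y, dtype=float), index=df.index, name=getattr(y, "name", "y"))
        df = pd.concat([df, ser], axis=1)
    cols = list(df.columns)
    k = len(cols)
    rho = np.eye(k)
    pval = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = df[[cols[i], cols[j]]].dropna()
            if len(pair) < 3:
                r, p = np.nan, np.nan
            else:
                r, p = sps.spearmanr(pair.iloc[:, 0], pair.iloc[:, 1])
            rho[i, j] = rho[j, i] = r
            pval[i, j] = pval[j, i] = p
    rho = pd.DataFrame(rho, index=cols, columns=cols)
    pval = pd.DataFrame(pval, index=cols, columns=cols)
    sig = (pval < alpha) & ~np.eye(k, dtype=bool)
    return rho, pval, pd.DataFrame(sig, index=cols, columns=cols)


def mann_whitney_u(x, y, alternative: str = "two-sided"):
    """Mann-Whitney U with exact p for small tie-free samples.

    Exact enumeration when n_x + n_y <= 20 and there are no ties, otherwise
    the normal approximation with tie correction.  Returns ``(U, p)`` where U
    counts wins of ``x`` over ``y``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ties = len(np.unique(np.r_[x, y])) < len(x) + len(y)
    method = "exact" if (len(x) + len(y) <= 20 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)


def two_sample_t(x, y, welch: bool = False):
    """Student (pooled, default) or Welch two-sample t-test -> (t, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = sps.ttest_ind(x, y, equal_var=not welch)
    return float(res.statistic), float(res.pvalue)


def shapiro_normality(x, alpha: float = 0.05):
    """Shapiro-Wilk check used before t-tests; returns (is_normal, p)."""
    x = np.asarray(x, dtype=float)
    if len(x) < 3:
        return True, float("nan")
    _, p = sps.shapiro(x)
    return bool(p >= alpha), float(p)
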