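"""Permutation statistics for the two-session, two-chronotype design.

The design is a 2×2 mixed factorial: time of day (TOD; morning/evening,
within subject) crossed with chronotype (MT/ET, between subjects).  All
inference is by permutation:

* TOD main effect — mean of within-subject (evening − morning) differences,
  null built by random sign flips of each subject's difference;
* chronotype main effect — group mean difference of subject means, null by
  shuffling group labels;
* interaction — group mean difference of the within-subject differences,
  null by shuffling group labels.

Tests are two-sided on absolute statistics and use the add-one convention
p = (b + 1)/(n_perm + 1), so p ∈ [1/(n_perm+1), 1].  One-way permutation
tests fall back to exhaustive enumeration of label assignments when that
is cheaper than sampling, in which case the p-value is exact.
Benjamini–Hochberg FDR is applied per family.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


@dataclass
class StatResult:
    effect: str
    statistic: float
    p_perm: float
    n_perm: int
    seed: int | None = None
    p_fdr: float | None = None
    note: str | None = None


def _perm_p(obs, null_abs_ge_count, n_perm) -> float:
    return float((null_abs_ge_count + 1) / (n_perm + 1))


def _label_perms(rng: np.random.Generator, n_perm: int, n: int) -> np.ndarray:
    """(n_perm, n) independent random permutations of 0..n-1."""
    return np.argsort(rng.random((n_perm, n)), axis=1)


def _two_sample_null(v: np.ndarray, n_a: int, idx: np.ndarray) -> np.ndarray:
    """Group-mean differences of v under shuffled labels (rows of idx)."""
    perm = v[idx]  # (n_perm, n)
    return perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)


def perm_mixed_anova(
    morning,
    evening,
    group,
    n_perm: int = 30000,
    seed: int = 0,
) -> dict[str, StatResult]:
    """Permutation mixed-design ANOVA for one metric.

    ``morning``/``evening`` are per-subject values (aligned), ``group`` the
    chronotype labels.  Returns results for 'TOD', 'chronotype' and
    'interaction'.
    """
    morning = np.asarray(morning, float)
    evening = np.asarray(evening, float)
    group = np.asarray(group)
    n = len(morning)
    if len(evening) != n or len(group) != n:
        raise ValueError("morning, evening and group must be aligned per subject")
    groups = np.unique(group)
    if len(groups) != 2:
        raise ValueError("exactly two chronotype groups required")
    g_a = group == groups[0]
    n_a = int(g_a.sum())
    order = np.argsort(~g_a, kind="stable")  # group A first
    d = (evening - morning)[order]
    m = ((morning + evening) / 2)[order]
    rng = np.random.default_rng(seed)

    out: dict[str, StatResult] = {}
    note = None
    if np.ptp(morning) == 0 and np.ptp(evening) == 0:
        note = "constant metric"

    # TOD: sign-flip null on within-subject differences
    obs_t = d.mean()
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    null_t = (signs * d).mean(axis=1)
    p_t = _perm_p(obs_t, int((np.abs(null_t) >= abs(obs_t)).sum()), n_perm)
    out["TOD"] = StatResult("TOD", float(obs_t), p_t, n_perm, seed, note=note)

    # chronotype: label-shuffle null on subject means
    idx = _label_perms(rng, n_perm, n)
    obs_c = m[:n_a].mean() - m[n_a:].mean()
    null_c = _two_sample_null(m, n_a, idx)
    p_c = _perm_p(obs_c, int((np.abs(null_c) >= abs(obs_c)).sum()), n_perm)
    out["chronotype"] = StatResult("chronotype", float(obs_c), p_c, n_perm, seed, note=note)

    # interaction: label-shuffle null on difference scores
    idx2 = _label_perms(rng, n_perm, n)
    obs_i = d[:n_a].mean() - d[n_a:].mean()
    null_i = _two_sample_null(d, n_a, idx2)
    p_i = _perm_p(obs_i, int((np.abs(null_i) >= abs(obs_i)).sum()), n_perm)
    out["interaction"] = StatResult("interaction", float(obs_i), p_i, n_perm, seed, note=note)
    return out


def perm_mixed_anova_table(
    morning: np.ndarray,
    evening: np.ndarray,
    group: np.ndarray,
    n_perm: int = 30000,
    seed: int = 0,
    block: int = 64,
) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    """Vectorized mixed ANOVA over many variables at once.

    ``morning``/``evening`` are (n_subjects, n_vars).  Returns, per effect,
    ``(observed, p)`` arrays of length n_vars.  Variables are processed in
    blocks to bound memory at large permutation counts.
    """
    morning = np.atleast_2d(np.asarray(morning, float))
    evening = np.atleast_2d(np.asarray(evening, float))
    group = np.asarray(group)
    n, p = morning.shape
    groups = np.unique(group)
    g_a = group == groups[0]
    n_a = int(g_a.sum())
    order = np.argsort(~g_a, kind="stable")
    d = (evening - morning)[order]
    m = ((morning + evening) / 2)[order]
    rng = np.random.default_rng(seed)
    signs = rng.choice((-1.0, 1.0), size=(n_perm, n))
    idx_c = _label_perms(rng, n_perm, n)
    idx_i = _label_perms(rng, n_perm, n)

    obs = {
        "TOD": d.mean(axis=0),
        "chronotype": m[:n_a].mean(axis=0) - m[n_a:].mean(axis=0),
        "interaction": d[:n_a].mean(axis=0) - d[n_a:].mean(axis=0),
    }
    count = {k: np.zeros(p) for k in obs}
    for lo in range(0, p, block):
        sl = slice(lo, min(lo + block, p))
        db, mb = d[:, sl], m[:, sl]
        null = signs @ db / n  # (n_perm, blk)
        count["TOD"][sl] = (np.abs(null) >= np.abs(obs["TOD"][sl])).sum(axis=0)
        for eff, src, idx in (("chronotype", mb, idx_c), ("interaction", db, idx_i)):
            perm = src[idx]  # (n_perm, n, blk)
            null = perm[:, :n_a].mean(axis=1) - perm[:, n_a:].mean(axis=1)
            count[eff][sl] = (np.abs(null) >= np.abs(obs[eff][sl])).sum(axis=0)
    return {k: (obs[k], (count[k] + 1) / (n_perm + 1)) for k in obs}


def perm_oneway(
    x,
    y,
    n_perm: int = 30000,
    seed: int = 0,
    exact: bool | None = None,
) -> StatResult:
    """Two-sided permutation test on the difference of sample means.

    With ``exact=None`` the test enumerates all label assignments whenever
    there are no more than max(n_perm, 20000) of them (the p-value is then
    exact); otherwise it samples ``n_perm`` label shuffles.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both samples must be non-empty")
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    obs = x.mean() - y.mean()
    n_assign = comb(n, nx)
    if exact is None:
        exact = n_assign <= min(max(n_perm, 20000), 200000)
    if exact:
        tot = pooled.sum()
        count = 0
        for pick in combinations(range(n), nx):
            sx = pooled[list(pick)].sum()
            stat = sx / nx - (tot - sx) / (n - nx)
            if abs(stat) >= abs(obs) - 1e-12:
                count += 1
        return StatResult("oneway", float(obs), count / n_assign, n_assign, seed,
                          note="exact")
    rng = np.random.default_rng(seed)
    idx = _label_perms(rng, n_perm, n)
    null = _two_sample_null(pooled, nx, idx)
    p = _perm_p(obs, int((np.abs(null) >= abs(obs)).sum()), n_perm)
    return StatResult("oneway", float(obs), p, n_perm, seed)


def perm_identity_regression(
    x,
    y,
    n_perm: int = 30000,
    seed: int = 0,
) -> StatResult:
    """Does the least-squares line of y on x differ from the identity line?

    The statistic is the mean squared deviation of the fitted line from
    y = x evaluated at the observed x values.  The null swaps each pair's
    session assignment (x_i ↔ y_i) independently, under which the fitted
    line is exchangeable with the identity.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if n < 3 or len(y) != n:
        raise ValueError("need paired samples of length >= 3")
    if np.ptp(x) == 0:
        raise ValueError("x has zero variance; regression undefined")

    def stat(xv, yv):
        # xv, yv: (..., n)
        mx = xv.mean(axis=-1, keepdims=True)
        my = yv.mean(axis=-1, keepdims=True)
        vx = ((xv - mx) ** 2).mean(axis=-1)
        cxy = ((xv - mx) * (yv - my)).mean(axis=-1)
        b = cxy / vx
        a = (my - b[..., None] * mx)[..., 0]
        resid = a[..., None] + b[..., None] * xv - xv
        return (resid**2).mean(axis=-1)

    obs = float(stat(x, y))
    rng = np.random.default_rng(seed)
    flips = rng.random((n_perm, n)) < 0.5
    xs = np.where(flips, y, x)
    ys = np.where(flips, x, y)
    null = stat(xs, ys)
    p = _perm_p(obs, int((null >= obs).sum()), n_perm)
    return StatResult("identity_regression", obs, p, n_perm, seed)


def _residualize(v: np.ndarray, design: np.ndarray) -> np.ndarray:
    beta, *_ = np.linalg.lstsq(design, v, rcond=None)
    return v - design @ beta


def perm_partial_correlation(
    x,
    y,
    covariates=None,
    n_perm: int = 30000,
    seed: int = 0,
) -> StatResult:
    """Pearson correlation of covariate-residualized x and y, permutation p.

    Both variables are regressed (with intercept) on the covariates; the
    null permutes the y-residuals against the x-residuals.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n = len(x)
    if covariates is None:
        design = np.ones((n, 1))
        n_cov = 0
    else:
        c = np.asarray(pd.get_dummies(pd.DataFrame(covariates), drop_first=True), float)
        design = np.column_stack([np.ones(n), c])
        n_cov = c.shape[1]
        if np.linalg.matrix_rank(design) < design.shape[1]:
            raise ValueError("rank-deficient covariate matrix")
    if n <= n_cov + 2:
        raise ValueError("too few observations for the covariate count")
    rx = _residualize(x, design)
    ry = _residualize(y, design)
    sx, sy = rx.std(), ry.std()
    tol = 1e-10 * max(x.std(), y.std(), 1e-30)
    if sx <= tol or sy <= tol:
        raise ValueError("zero residual variance (covariate collinear with variable?)")
    rx = (rx - rx.mean()) / sx
    ry = (ry - ry.mean()) / sy
    obs = float(np.mean(rx * ry))
    rng = np.random.default_rng(seed)
    idx = _label_perms(rng, n_perm, n)
    null = (ry[idx] * rx).mean(axis=1)
    p = _perm_p(obs, int((np.abs(null) >= abs(obs)).sum()), n_perm)
    return StatResult("correlation", obs, p, n_perm, seed)


def bh_fdr(pvals, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up: (adjusted p, rejection flags at q)."""
    pvals = np.asarray(pvals, float)
    if pvals.size == 0:
        raise ValueError("empty p-value list")
    reject, p_adj, *_ = multipletests(pvals, alpha=q, method="fdr_bh")
    return p_adj, reject


def consolidate_thresholds(flags) -> bool:
    """Significant overall iff rejected at strictly more than half of the
    analysis densities."""
    flags = np.asarray(flags, bool)
    if flags.size == 0:
        raise ValueError("no per-density flags given")
    return bool(flags.sum() > flags.size / 2)


def cohort_tests(
    demographics: pd.DataFrame,
    group_col: str = "chronotype",
    categorical: tuple[str, ...] = ("sex",),
    interval: tuple[str, ...] = (),
    ordinal: tuple[str, ...] = ("age", "ME", "AM", "ESS"),
) -> pd.DataFrame:
    """Between-group cohort comparisons.

    Categorical variables get a Pearson chi-square on the contingency table
    (no continuity correction), interval variables a pooled-variance
    two-sample t-test, ordinal variables a two-sided Mann-Whitney U.
    One row per subject expected (deduplicate subject-session tables first).
    """
    groups = demographics[group_col].unique()
    if len(groups) != 2:
        raise ValueError("exactly two groups required")
    a = demographics[demographics[group_col] == groups[0]]
    b = demographics[demographics[group_col] == groups[1]]
    rows = []
    for var in categorical:
        tab = pd.crosstab(demographics[group_col], demographics[var])
        if (tab.to_numpy() == 0).any():
            raise ValueError(f"empty cell in contingency table for {var}")
        chi2, p, dof, _ = sps.chi2_contingency(tab, correction=False)
        rows.append(dict(variable=var, test="chi_square", statistic=chi2, df=dof, p=p))
    for var in interval:
        t, p = sps.ttest_ind(a[var], b[var], equal_var=True)
        rows.append(dict(variable=var, test="t", statistic=t,
                         df=len(a) + len(b) - 2, p=p))
    for var in ordinal:
        u, p = sps.mannwhitneyu(a[var], b[var], alternative="two-sided")
        rows.append(dict(variable=var, test="mann_whitney_u", statistic=u,
                         df=np.nan, p=p))
    return pd.DataFrame(rows)
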