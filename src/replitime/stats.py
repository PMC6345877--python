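"""Statistical kernel used across the package.

Small, explicit wrappers with exact small-sample behaviour:

* two-sided Fisher's exact test on 2x2 tables (probability-mass rule, the
  convention shared by R and scipy),
* Benjamini-Hochberg FDR,
* Mann-Whitney-Wilcoxon with exact enumeration for small samples and a
  tie- and continuity-corrected normal approximation otherwise,
* exact binomial tail tests,
* two-sample equal-proportions chi-square with Yates correction
  (R's ``prop.test`` default),
* empirical-Bayes moderated t for many parallel two-group comparisons,
* upper-tail hypergeometric over-representation with Bonferroni control.

All tests are two-sided unless stated otherwise and return a
:class:`TestResult` recording statistic, p, sidedness and effect size.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import special, stats as sps
from statsmodels.stats.multitest import multipletests

__all__ = [
    "TestResult",
    "fisher_exact_2x2",
    "bh_fdr",
    "mann_whitney",
    "binomial_exact",
    "equal_proportions",
    "moderated_t",
    "ModeratedTResult",
    "hypergeometric_overrepresentation",
    "two_sample_t",
]


@dataclass
class TestResult:
    statistic: float
    p: float
    sidedness: str
    method: str
    effect: float | None = None
    flags: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"p outside [0, 1]: {self.p}")


# --------------------------------------------------------------------- Fisher

def fisher_exact_2x2(
    a: int, b: int, c: int, d: int, sided: str = "two-sided"
) -> TestResult:
    """Fisher's exact test on the 2x2 table ((a, b), (c, d)).

    Two-sided p sums hypergeometric probabilities of tables (at fixed
    margins) no more probable than the observed one.  The effect is the
    sample odds ratio; a zero cell makes it 0 or inf.
    """
    for x in (a, b, c, d):
        if x < 0 or x != int(x):
            raise ValueError("cell counts must be non-negative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero table")
    alt = {"two-sided": "two-sided", "greater": "greater", "less": "less"}[sided]
    odds, p = sps.fisher_exact([[a, b], [c, d]], alternative=alt)
    return TestResult(float(odds), float(min(p, 1.0)), sided, "fisher_exact", float(odds))


def odds_ratio_haldane(a: int, b: int, c: int, d: int) -> tuple[float, bool]:
    """Sample OR; with any zero cell, the Haldane-Anscombe +0.5 estimate.

    Returns (odds_ratio, corrected_flag).
    """
    if min(a, b, c, d) == 0:
        a2, b2, c2, d2 = (x + 0.5 for x in (a, b, c, d))
        return (a2 * d2) / (b2 * c2), True
    return (a * d) / (b * c), False


# ------------------------------------------------------------------------ BH

def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (order preserving)."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ----------------------------------------------------------------------- MWW

_EXACT_MAX_N = 16


def _rank_sum_u(x: np.ndarray, y: np.ndarray) -> float:
    """U statistic for x (number of (x_i, y_j) pairs with x_i > y_j, ties 1/2)."""
    u = 0.0
    for xi in x:
        u += np.sum(xi > y) + 0.5 * np.sum(xi == y)
    return u


def mann_whitney(
    x, y, tail: str = "two-sided", exact_max_n: int = _EXACT_MAX_N
) -> TestResult:
    """Mann-Whitney-Wilcoxon rank-sum test.

    ``tail`` is 'two-sided', 'greater' (x tends larger) or 'less'.  For
    combined samples of at most ``exact_max_n`` the null distribution of U
    is enumerated exactly over all group assignments of the pooled values
    (valid with ties); larger samples use the normal approximation with tie
    and continuity corrections.  Fully tied data gives p = 1 with a flag.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("each group needs >= 1 observation")
    if tail not in ("two-sided", "greater", "less"):
        raise ValueError(f"unknown tail: {tail}")
    u_obs = _rank_sum_u(x, y)
    if np.unique(np.concatenate([x, y])).size == 1:
        return TestResult(u_obs, 1.0, tail, "mann_whitney", flags=["all-tied"])
    n1, n2 = x.size, y.size
    if n1 + n2 <= exact_max_n:
        pooled = np.concatenate([x, y])
        idx = np.arange(n1 + n2)
        us = np.array(
            [
                _rank_sum_u(pooled[list(comb)], np.delete(pooled, list(comb)))
                for comb in itertools.combinations(idx, n1)
            ]
        )
        eps = 1e-9
        p_ge = np.mean(us >= u_obs - eps)
        p_le = np.mean(us <= u_obs + eps)
        if tail == "greater":
            p = p_ge
        elif tail == "less":
            p = p_le
        else:
            p = min(1.0, 2.0 * min(p_ge, p_le))
        return TestResult(u_obs, float(p), tail, "mann_whitney_exact")
    res = sps.mannwhitneyu(x, y, alternative=tail, method="asymptotic")
    return TestResult(float(res.statistic), float(res.pvalue), tail, "mann_whitney_normal")


# ------------------------------------------------------------------ binomial

def binomial_exact(k: int, n: int, p0: float, tail: str = "ge") -> TestResult:
    """Exact binomial tail probability.

    ``tail='ge'`` gives P(X >= k | n, p0); ``'le'`` the lower tail;
    ``'two-sided'`` the minimum-likelihood two-sided test.
    """
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    if not (0.0 <= p0 <= 1.0):
        raise ValueError("p0 must lie in [0, 1]")
    alt = {"ge": "greater", "le": "less", "two-sided": "two-sided"}[tail]
    p = float(sps.binomtest(int(k), int(n), p0, alternative=alt).pvalue)
    return TestResult(float(k), min(p, 1.0), tail, "binomial_exact", effect=k / n if n else None)


# --------------------------------------------------------------- proportions

def equal_proportions(
    x1: int, n1: int, x2: int, n2: int, correction: bool = True
) -> TestResult:
    """Two-sample test of equal proportions (chi-square, Yates-corrected).

    Matches R's ``prop.test`` default; ``correction=False`` reproduces the
    uncorrected chi-square.  Effect is the difference of proportions.
    """
    if n1 <= 0 or n2 <= 0:
        raise ValueError("zero totals")
    if x1 > n1 or x2 > n2:
        raise ValueError("counts exceed totals")
    p1, p2 = x1 / n1, x2 / n2
    phat = (x1 + x2) / (n1 + n2)
    if phat in (0.0, 1.0):
        return TestResult(0.0, 1.0, "two-sided", "equal_proportions", p1 - p2)
    delta = abs(p1 - p2)
    if correction:
        delta = max(0.0, delta - (0.5 / n1 + 0.5 / n2))
    chi2 = delta**2 / (phat * (1 - phat) * (1 / n1 + 1 / n2))
    p = float(sps.chi2.sf(chi2, df=1))
    return TestResult(float(chi2), p, "two-sided", "equal_proportions", p1 - p2)


# --------------------------------------------------------------- moderated t

@dataclass
class ModeratedTResult:
    """Per-row moderated-t output for a two-group comparison."""

    logfc: np.ndarray          # group1 mean - group2 mean per row
    t: np.ndarray
    p: np.ndarray
    fdr: np.ndarray
    df_prior: float
    s2_prior: float
    df_total: float
    s2_post: np.ndarray
    flags: list[str] = field(default_factory=list)


def _fit_f_dist(s2: np.ndarray, df: float) -> tuple[float, float]:
    """Method-of-moments fit of the scaled-F prior on sample variances.

    Matches the standard empirical-Bayes approach: moments of log s^2,
    with the trigamma equation inverted by Newton iteration.  Returns
    (df_prior, s2_prior); df_prior = inf when variances are underdispersed
    relative to chi-square expectation.
    """
    s2 = np.asarray(s2, dtype=float)
    ok = s2 > 0
    if ok.sum() < 2:
        return math.inf, float(np.mean(s2)) if s2.size else 1.0
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2) + math.log(df / 2)
    emean = float(np.mean(e))
    n = z.size
    evar = float(np.mean((e - emean) ** 2) * n / (n - 1)) - float(special.polygamma(1, df / 2))
    if evar <= 0:
        s20 = math.exp(emean)
        return math.inf, s20
    # solve trigamma(d0/2) = evar for d0 by Newton on y = d0/2
    y = 0.5 + 1.0 / evar  # starting guess from trigamma(y) ~ 1/y
    for _ in range(50):
        f = float(special.polygamma(1, y)) - evar
        fp = float(special.polygamma(2, y))
        step = f / fp
        y_new = y - step
        if y_new <= 0:
            y_new = y / 2
        if abs(y_new - y) < 1e-12 * y:
            y = y_new
            break
        y = y_new
    d0 = 2 * y
    s20 = math.exp(emean + special.digamma(y) - math.log(y))
    return d0, s20


def moderated_t(
    group1: np.ndarray,
    group2: np.ndarray,
    df_prior: float | None = None,
    s2_prior: float | None = None,
) -> ModeratedTResult:
    """Empirical-Bayes moderated two-group t-statistics, row-wise.

    Rows are loci (or genes); columns are samples.  The posterior variance
    per row is ``s2_post = (d0 * s0^2 + d * s^2) / (d0 + d)`` with the prior
    ``(d0, s0^2)`` estimated across rows by method-of-moments on log sample
    variances; p-values use a t distribution with ``d0 + d`` degrees of
    freedom.  ``df_prior=0`` reproduces the ordinary two-sample t.

    With a single sample in either group the residual degrees of freedom
    vanish and the function falls back to an ordinary unequal-size t using
    the pooled across-row variance, with a warning.
    """
    g1 = np.atleast_2d(np.asarray(group1, dtype=float))
    g2 = np.atleast_2d(np.asarray(group2, dtype=float))
    if g1.shape[0] != g2.shape[0]:
        raise ValueError("groups must have the same number of rows")
    n1, n2 = g1.shape[1], g2.shape[1]
    flags: list[str] = []
    logfc = g1.mean(axis=1) - g2.mean(axis=1)
    df_resid = n1 + n2 - 2
    if df_resid < 1:
        raise ValueError("need >= 2 samples in total per group comparison")
    ss = np.zeros(g1.shape[0])
    if n1 > 1:
        ss += ((g1 - g1.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    if n2 > 1:
        ss += ((g2 - g2.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    s2 = ss / df_resid
    if min(n1, n2) == 1:
        flags.append("single-sample-group")
        warnings.warn(
            "a group has a single sample; falling back toward the pooled prior",
            stacklevel=2,
        )
    if df_prior is None or s2_prior is None:
        if np.all(s2 == 0):
            flags.append("degenerate-prior")
            warnings.warn("all residual variances are zero; prior is degenerate", stacklevel=2)
            d0, s20 = math.inf, float(np.mean(s2) + 1e-12)
        else:
            d0, s20 = _fit_f_dist(s2, df_resid)
        if df_prior is not None:
            d0 = df_prior
        if s2_prior is not None:
            s20 = s2_prior
    else:
        d0, s20 = df_prior, s2_prior
    if math.isinf(d0):
        s2_post = np.full_like(s2, s20)
        df_total = math.inf
    else:
        s2_post = (d0 * s20 + df_resid * s2) / (d0 + df_resid)
        df_total = d0 + df_resid
    se = np.sqrt(s2_post * (1 / n1 + 1 / n2))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, logfc / se, 0.0)
    if math.isinf(df_total):
        p = 2 * sps.norm.sf(np.abs(t))
    else:
        p = 2 * sps.t.sf(np.abs(t), df=df_total)
    return ModeratedTResult(
        logfc=logfc, t=t, p=p, fdr=bh_fdr(p),
        df_prior=d0, s2_prior=s20, df_total=df_total, s2_post=s2_post, flags=flags,
    )


# ------------------------------------------------------------- hypergeometric

def hypergeometric_overrepresentation(
    hits: int, set_size: int, universe: int, draws: int, n_sets: int = 1,
    correction: str = "bonferroni",
) -> TestResult:
    """Upper-tail hypergeometric over-representation test.

    P(X >= hits) for X ~ Hypergeom(universe, set_size, draws), with
    Bonferroni correction across ``n_sets`` scanned gene sets.
    """
    if hits > min(set_size, draws) or min(hits, set_size, draws) < 0:
        raise ValueError("inconsistent counts")
    if max(set_size, draws) > universe:
        raise ValueError("set or draw larger than universe")
    p = float(sps.hypergeom.sf(hits - 1, universe, set_size, draws))
    p = min(p, 1.0)
    if correction == "bonferroni":
        p_adj = min(1.0, p * n_sets)
    elif correction is None or correction == "none":
        p_adj = p
    else:
        raise ValueError(f"unknown correction: {correction}")
    return TestResult(float(hits), p_adj, "ge", "hypergeometric", effect=p)


# ------------------------------------------------------------------ plain t

def two_sample_t(x, y, equal_var: bool = True) -> TestResult:
    """Plain two-sample Student t (used for logFC group comparisons)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    res = sps.ttest_ind(x, y, equal_var=equal_var)
    return TestResult(
        float(res.statistic), float(res.pvalue), "two-sided", "student_t",
        effect=float(np.mean(x) - np.mean(y)),
    )
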