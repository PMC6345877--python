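"""The statistical kernel against brute-force enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps
from scipy.special import comb

from replitime import stats


# ----------------------------------------------------------- oracle helpers

def fisher_two_sided_oracle(a, b, c, d):
    """Sum hypergeometric probabilities of tables no more probable than
    the observed one, enumerating every table with the same margins."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(x):
        return (
            comb(r1, x, exact=True)
            * comb(r2, c1 - x, exact=True)
            / comb(n, c1, exact=True)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, c1 - r2), min(r1, c1) + 1):
        px = prob(x)
        if px <= p_obs * (1 + 1e-9):
            total += px
    return min(total, 1.0)


def mww_enumeration_oracle(x, y, tail):
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(a, b):
        return sum(np.sum(ai > b) + 0.5 * np.sum(ai == b) for ai in a)

    u_obs = u_stat(np.asarray(x, float), np.asarray(y, float))
    us = []
    for comb_idx in itertools.combinations(range(len(pooled)), n1):
        xa = pooled[list(comb_idx)]
        ya = np.delete(pooled, list(comb_idx))
        us.append(u_stat(xa, ya))
    us = np.array(us)
    p_ge = np.mean(us >= u_obs - 1e-9)
    p_le = np.mean(us <= u_obs + 1e-9)
    if tail == "greater":
        return p_ge
    if tail == "less":
        return p_le
    return min(1.0, 2 * min(p_ge, p_le))


# ------------------------------------------------------------------- Fisher

class TestFisher:
    def test_known_extreme_table(self):
        res = stats.fisher_exact_2x2(10, 0, 0, 10)
        assert res.p == pytest.approx(2 / comb(20, 10, exact=True), rel=1e-12)

    def test_symmetric_table_p_one(self):
        assert stats.fisher_exact_2x2(5, 5, 5, 5).p == pytest.approx(1.0)

    def test_exhaustive_small_tables_match_enumeration(self):
        # all tables with total <= 12
        for n in range(1, 13):
            for a in range(n + 1):
                for b in range(n - a + 1):
                    for c in range(n - a - b + 1):
                        d = n - a - b - c
                        got = stats.fisher_exact_2x2(a, b, c, d).p
                        want = fisher_two_sided_oracle(a, b, c, d)
                        assert got == pytest.approx(want, abs=1e-12), (a, b, c, d)

    def test_all_zero_rejected(self):
        with pytest.raises(ValueError):
            stats.fisher_exact_2x2(0, 0, 0, 0)

    def test_haldane_correction_flagged(self):
        odds, corrected = stats.odds_ratio_haldane(5, 0, 3, 7)
        assert corrected and np.isfinite(odds) and odds > 1


# ----------------------------------------------------------------------- BH

class TestBH:
    def test_hand_computed_example(self):
        got = stats.bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert got == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_single_and_ties(self):
        assert stats.bh_fdr([0.2]) == pytest.approx([0.2])
        assert stats.bh_fdr([0.5, 0.5, 0.5]) == pytest.approx([0.5, 0.5, 0.5])

    def test_step_up_oracle_random(self, rng):
        p = rng.random(50)
        got = stats.bh_fdr(p)
        # manual step-up with monotonicity enforcement
        order = np.argsort(p)
        n = len(p)
        adj = p[order] * n / np.arange(1, n + 1)
        adj = np.minimum.accumulate(adj[::-1])[::-1]
        want = np.empty(n)
        want[order] = np.minimum(adj, 1)
        assert got == pytest.approx(want, abs=1e-12)
        # monotone in sorted-p order and FDR >= p
        assert np.all(np.diff(got[order]) >= -1e-12)
        assert np.all(got >= p - 1e-12)


# ---------------------------------------------------------------------- MWW

class TestMannWhitney:
    def test_separated_triples(self):
        res = stats.mann_whitney([1, 2, 3], [4, 5, 6], tail="two-sided")
        assert res.p == pytest.approx(0.1)  # 2/20 arrangements as extreme
        res_less = stats.mann_whitney([1, 2, 3], [4, 5, 6], tail="less")
        assert res_less.p == pytest.approx(0.05)

    def test_identical_samples(self):
        res = stats.mann_whitney([2.0, 2.0], [2.0, 2.0])
        assert res.p == 1.0 and "all-tied" in res.flags

    @pytest.mark.parametrize("tail", ["two-sided", "greater", "less"])
    def test_exact_matches_enumeration_with_ties(self, rng, tail):
        for _ in range(25):
            n1 = int(rng.integers(1, 6))
            n2 = int(rng.integers(1, 6))
            x = rng.integers(0, 4, n1).astype(float)
            y = rng.integers(0, 4, n2).astype(float)
            if np.unique(np.concatenate([x, y])).size == 1:
                continue
            got = stats.mann_whitney(x, y, tail=tail).p
            want = mww_enumeration_oracle(x, y, tail)
            assert got == pytest.approx(want, abs=1e-12), (x, y, tail)

    def test_large_sample_uses_normal_approximation(self, rng):
        x = rng.normal(0, 1, 60)
        y = rng.normal(0.5, 1, 60)
        res = stats.mann_whitney(x, y)
        assert res.method == "mann_whitney_normal"
        ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue)


# ----------------------------------------------------------------- binomial

class TestBinomial:
    def test_summation_oracle(self):
        got = stats.binomial_exact(5, 10, 0.2, tail="ge").p
        want = sum(
            comb(10, j, exact=True) * 0.2**j * 0.8 ** (10 - j) for j in range(5, 11)
        )
        assert got == pytest.approx(want, abs=1e-12)
        assert got == pytest.approx(0.0328, abs=5e-5)

    @pytest.mark.parametrize("k,n,p0,expected", [(0, 10, 0.3, 1.0), (0, 5, 0.0, 1.0)])
    def test_trivial_tails(self, k, n, p0, expected):
        assert stats.binomial_exact(k, n, p0, tail="ge").p == pytest.approx(expected)

    def test_random_against_summation(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 12))
            k = int(rng.integers(0, n + 1))
            p0 = float(rng.random())
            got = stats.binomial_exact(k, n, p0, tail="ge").p
            want = sum(
                comb(n, j, exact=True) * p0**j * (1 - p0) ** (n - j)
                for j in range(k, n + 1)
            )
            assert got == pytest.approx(want, abs=1e-12)


# -------------------------------------------------------------- proportions

class TestEqualProportions:
    def test_identical_proportions(self):
        assert stats.equal_proportions(30, 100, 30, 100).p == pytest.approx(1.0)

    def test_hand_computed_corrected_chi_square(self):
        x1, n1, x2, n2 = 74, 100, 28, 100
        res = stats.equal_proportions(x1, n1, x2, n2)
        phat = (x1 + x2) / (n1 + n2)
        delta = abs(x1 / n1 - x2 / n2) - (0.5 / n1 + 0.5 / n2)
        want = delta**2 / (phat * (1 - phat) * (1 / n1 + 1 / n2))
        assert res.statistic == pytest.approx(want, rel=1e-12)
        assert res.effect == pytest.approx(0.46)

    def test_uncorrected_formula(self):
        res = stats.equal_proportions(74, 100, 28, 100, correction=False)
        phat = 102 / 200
        want = (0.46) ** 2 / (phat * (1 - phat) * 0.02)
        assert res.statistic == pytest.approx(want, rel=1e-12)


# -------------------------------------------------------------- moderated t

class TestModeratedT:
    def test_df_prior_zero_equals_ordinary_t(self, rng):
        for _ in range(100):
            n1, n2 = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            g1 = rng.normal(0, 1, (8, n1))
            g2 = rng.normal(0, 1, (8, n2))
            res = stats.moderated_t(g1, g2, df_prior=0.0, s2_prior=1.0)
            ref = sps.ttest_ind(g1, g2, axis=1)
            assert res.t == pytest.approx(ref.statistic, abs=1e-10)
            assert res.p == pytest.approx(ref.pvalue, abs=1e-10)

    def test_df_prior_inf_pools_variance(self, rng):
        g1 = rng.normal(0, 1, (20, 4))
        g2 = rng.normal(0, 1, (20, 4))
        s20 = 1.7
        res = stats.moderated_t(g1, g2, df_prior=math.inf, s2_prior=s20)
        want = (g1.mean(1) - g2.mean(1)) / np.sqrt(s20 * (1 / 4 + 1 / 4))
        assert res.t == pytest.approx(want, abs=1e-10)

    def test_moderated_between_limits(self, rng):
        g1 = rng.normal(0, 1, (200, 4))
        g2 = rng.normal(0, 1, (200, 4))
        res = stats.moderated_t(g1, g2)
        assert 0 < res.df_prior
        t0 = stats.moderated_t(g1, g2, df_prior=0.0, s2_prior=res.s2_prior).t
        tinf = stats.moderated_t(g1, g2, df_prior=math.inf, s2_prior=res.s2_prior).t
        lo = np.minimum(np.abs(t0), np.abs(tinf)) - 1e-9
        hi = np.maximum(np.abs(t0), np.abs(tinf)) + 1e-9
        between = (np.abs(res.t) >= lo) & (np.abs(res.t) <= hi)
        assert between.all()

    def test_single_sample_group_warns(self, rng):
        g1 = rng.normal(0, 1, (10, 1))
        g2 = rng.normal(0, 1, (10, 3))
        with pytest.warns(UserWarning, match="single sample"):
            res = stats.moderated_t(g1, g2)
        assert np.all(np.isfinite(res.p))


# ------------------------------------------------------------ hypergeometric

class TestHypergeometric:
    def test_full_overlap_enumeration(self):
        res = stats.hypergeometric_overrepresentation(10, 10, 20, 10)
        assert res.p == pytest.approx(1 / comb(20, 10, exact=True), rel=1e-12)

    @pytest.mark.parametrize(
        "hits,set_size,universe,draws,expected",
        [(5, 5, 5, 5, 1.0), (0, 4, 20, 6, 1.0)],
    )
    def test_trivial(self, hits, set_size, universe, draws, expected):
        res = stats.hypergeometric_overrepresentation(hits, set_size, universe, draws)
        assert res.p == pytest.approx(expected)

    def test_bonferroni(self):
        raw = stats.hypergeometric_overrepresentation(3, 5, 30, 6).p
        adj = stats.hypergeometric_overrepresentation(3, 5, 30, 6, n_sets=10).p
        assert adj == pytest.approx(min(1.0, raw * 10))

    def test_random_against_enumeration(self, rng):
        for _ in range(100):
            universe = int(rng.integers(2, 12))
            set_size = int(rng.integers(1, universe + 1))
            draws = int(rng.integers(1, universe + 1))
            hits = int(rng.integers(0, min(set_size, draws) + 1))
            if hits < max(0, set_size + draws - universe):
                continue
            got = stats.hypergeometric_overrepresentation(hits, set_size, universe, draws).p
            want = sum(
                comb(set_size, x, exact=True)
                * comb(universe - set_size, draws - x, exact=True)
                for x in range(hits, min(set_size, draws) + 1)
            ) / comb(universe, draws, exact=True)
            assert got == pytest.approx(min(want, 1.0), abs=1e-12)
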