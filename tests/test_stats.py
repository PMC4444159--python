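"""Case-control statistics vs brute-force enumeration oracles."""

import itertools
from math import comb

import numpy as np
import pytest

from rgikit.stats import (
    bh_fdr,
    compare_cohorts,
    fisher_exact_2x2,
    ks_two_sample,
    odds_curve,
    percentile_odds,
    wilcoxon_rank_sum,
)


# --------------------------------------------------------------------------
# Wilcoxon rank-sum vs enumeration
# --------------------------------------------------------------------------

def wilcoxon_oracle(x, y, sided):
    """Exact P by enumerating all C(n1+n2, n1) group assignments.

    Statistic: U = number of (x, y) pairs with x > y (+0.5 per tie).
    """
    pooled = np.concatenate([x, y])
    n1 = len(x)

    def u_stat(xs, ys):
        xs, ys = np.asarray(xs), np.asarray(ys)
        gt = (xs[:, None] > ys[None, :]).sum()
        eq = (xs[:, None] == ys[None, :]).sum()
        return gt + 0.5 * eq

    u_obs = u_stat(x, y)
    us = []
    for idx in itertools.combinations(range(len(pooled)), n1):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        us.append(u_stat(pooled[mask], pooled[~mask]))
    us = np.array(us)
    eps = 1e-12
    if sided == "greater":
        return np.mean(us >= u_obs - eps)
    center = len(x) * len(y) / 2
    return min(1.0, np.mean(np.abs(us - center) >= abs(u_obs - center) - eps))


class TestWilcoxon:
    @pytest.mark.parametrize(
        "x,y,sided",
        [
            ((1, 2), (3, 4), "greater"),
            ((1, 2, 3), (4, 5, 6), "two"),
            ((3, 1, 4, 1.5), (2.6, 5, 3.5), "two"),
            ((10, 12, 9), (8, 11, 13, 7), "greater"),
        ],
    )
    def test_exact_matches_enumeration(self, x, y, sided):
        _, p = wilcoxon_rank_sum(np.array(x), np.array(y), sided)
        assert p == pytest.approx(wilcoxon_oracle(np.array(x), np.array(y), sided), abs=1e-9)

    def test_known_small_values(self):
        # all 2/20 most extreme assignments of {1..6} into groups of 3
        _, p = wilcoxon_rank_sum([1, 2, 3], [4, 5, 6], "two")
        assert p == pytest.approx(0.1, abs=1e-12)

    def test_identical_groups_p_one(self):
        _, p = wilcoxon_rank_sum([1.0, 2.0, 3.0], [1.0, 2.0, 3.0], "two")
        assert p == pytest.approx(1.0)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            wilcoxon_rank_sum([], [1.0])

    def test_null_calibration_small(self, rng):
        """Two-sided rejection rate near alpha under the null (quick check)."""
        hits = sum(
            wilcoxon_rank_sum(rng.normal(size=30), rng.normal(size=30), "two")[1] < 0.05
            for _ in range(200)
        )
        # binomial(200, 0.05) central 99.9% region
        assert 1 <= hits <= 22


class TestKS:
    def test_identical_and_disjoint(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0 and p == pytest.approx(1.0)
        d, _ = ks_two_sample([1, 2, 3], [10, 11, 12])
        assert d == pytest.approx(1.0)

    def test_statistic_matches_ecdf_sup(self, rng):
        x, y = rng.normal(0, 1, 100), rng.normal(0.5, 1.2, 100)
        d, _ = ks_two_sample(x, y)
        grid = np.concatenate([x, y])
        ecdf_x = (x[None, :] <= grid[:, None]).mean(axis=1)
        ecdf_y = (y[None, :] <= grid[:, None]).mean(axis=1)
        assert d == pytest.approx(np.abs(ecdf_x - ecdf_y).max(), abs=1e-12)


class TestBH:
    def test_textbook_example(self):
        assert np.allclose(bh_fdr([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04])

    def test_single_and_flat(self):
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)
        assert np.allclose(bh_fdr([0.5] * 6), 0.5)

    def test_direct_formula_oracle(self, rng):
        p = rng.uniform(0, 1, 25)
        order = np.argsort(p)
        m = len(p)
        adj_sorted = np.minimum.accumulate((p[order] * m / np.arange(1, m + 1))[::-1])[::-1]
        expected = np.empty_like(p)
        expected[order] = np.minimum(adj_sorted, 1.0)
        assert np.allclose(bh_fdr(p), expected, atol=1e-12)

    def test_permutation_equivariance_and_dominance(self, rng):
        p = rng.uniform(0, 1, 12)
        perm = rng.permutation(12)
        assert np.allclose(bh_fdr(p)[perm], bh_fdr(p[perm]))
        assert (bh_fdr(p) >= p - 1e-15).all()
        assert (bh_fdr(p) <= 1.0).all()


# --------------------------------------------------------------------------
# Fisher's exact test
# --------------------------------------------------------------------------

def fisher_oracle_p(table):
    """Two-sided conditional P by hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(a_):
        return comb(c1, a_) * comb(n - c1, r1 - a_) / comb(n, r1)

    lo, hi = max(0, r1 - (n - c1)), min(r1, c1)
    p_obs = prob(a)
    return sum(prob(k) for k in range(lo, hi + 1) if prob(k) <= p_obs * (1 + 1e-12))


class TestFisher:
    def test_balanced_table(self):
        r = fisher_exact_2x2([[10, 10], [10, 10]])
        assert r.odds_ratio == pytest.approx(1.0)
        assert r.p_value == pytest.approx(1.0)
        assert not r.haldane_corrected

    def test_diagonal_table(self):
        r = fisher_exact_2x2([[5, 0], [0, 5]])
        assert r.p_value == pytest.approx(2 / comb(10, 5), abs=1e-12)
        assert r.haldane_corrected  # zero cells
        assert r.odds_ratio == pytest.approx(5.5 * 5.5 / 0.25)

    @pytest.mark.parametrize(
        "table", [[[20, 5], [5, 20]], [[3, 9], [12, 2]], [[7, 1], [2, 8]]]
    )
    def test_matches_enumeration(self, table):
        r = fisher_exact_2x2(table)
        assert r.p_value == pytest.approx(fisher_oracle_p(table), abs=1e-9)

    def test_rejects_bad_tables(self):
        with pytest.raises(ValueError):
            fisher_exact_2x2([[1, 2, 3], [4, 5, 6]])
        with pytest.raises(ValueError):
            fisher_exact_2x2([[-1, 2], [3, 4]])


# --------------------------------------------------------------------------
# percentile odds & odds curve
# --------------------------------------------------------------------------

class TestPercentileOdds:
    def test_null_or_near_one(self, rng):
        cases = rng.normal(1.0, 0.05, 2000)
        controls = rng.normal(1.0, 0.05, 2000)
        po = percentile_odds(cases, controls, percentile=90)
        assert 0.6 < po.odds_ratio < 1.6
        assert po.fisher_p > 0.01

    def test_zero_control_tail_flags_haldane(self):
        cases = np.linspace(2, 3, 50)
        controls = np.linspace(0, 1, 50)
        po = percentile_odds(cases, controls, percentile=80)
        assert po.haldane_corrected
        assert po.odds_ratio > 1

    def test_invalid_percentile(self):
        with pytest.raises(ValueError):
            percentile_odds([1.0], [1.0], percentile=100)
        with pytest.raises(ValueError):
            percentile_odds([1.0], [1.0], percentile=50)


class TestOddsCurve:
    def test_null_curve_pointwise_coverage(self):
        """Under the null the pointwise 95% band covers OR=1 at a fixed
        central grid point in ~95% of replicates (bands are pointwise, so
        somewhere-on-the-grid escapes are expected and not tested)."""
        covered = 0
        n_rep = 30
        for seed in range(n_rep):
            r = np.random.default_rng(seed)
            x = r.normal(1.0, 0.05, 400)
            y = r.normal(1.0, 0.05, 400)
            oc = odds_curve(x, y)
            assert not oc.separation
            j = int(np.argmin(np.abs(oc.grid - np.percentile(np.r_[x, y], 60))))
            covered += oc.ci_low[j] <= 1.0 <= oc.ci_high[j]
        assert covered >= 24  # binomial(30, 0.95) lower 0.1% tail

    def test_shifted_cases_monotone_central(self, rng):
        controls = rng.normal(1.0, 0.05, 500)
        cases = rng.normal(1.06, 0.05, 500)
        oc = odds_curve(cases, controls)
        k = len(oc.grid) // 20
        central = oc.log_or[k : len(oc.grid) - k]
        assert (np.diff(central) > -1e-9).all()
        assert central[-1] > central[0]

    def test_reference_anchor_is_unity(self, rng):
        controls = rng.normal(1.0, 0.05, 300)
        cases = rng.normal(1.03, 0.05, 300)
        oc = odds_curve(cases, controls)
        assert abs(np.interp(oc.reference_eil, oc.grid, oc.log_or)) < 0.05

    def test_separation_suppresses_intervals(self, rng):
        controls = rng.normal(0.0, 0.01, 80)
        cases = rng.normal(5.0, 0.01, 80)
        with pytest.warns(UserWarning, match="separation"):
            oc = odds_curve(cases, controls)
        assert oc.separation and oc.ci_low is None

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            odds_curve([], [1.0, 2.0])


class TestCompareCohorts:
    def test_battery_structure_and_adjustment(self, rng):
        groups = {
            "cases_a": rng.normal(1.05, 0.05, 150),
            "ctrl_a": rng.normal(1.0, 0.05, 150),
            "ctrl_b": rng.normal(1.0, 0.05, 150),
        }
        cmp_ = compare_cohorts(groups, ["cases_a"], percentile=90)
        for t in cmp_.tests:
            if t.p_adjusted is not None:
                assert t.p_adjusted >= t.p_value - 1e-15
                assert 0 <= t.p_adjusted <= 1
        names = [t.name for t in cmp_.tests]
        assert "ks:cases|controls" in names
        assert cmp_.percentile_or is not None
        d = cmp_.to_dict()
        assert set(d) >= {"groups", "tests", "percentile_or", "odds_curve"}

    def test_requires_case_and_control(self, rng):
        g = {"a": rng.normal(size=10), "b": rng.normal(size=10)}
        with pytest.raises(ValueError):
            compare_cohorts(g, ["a", "b"])
        with pytest.raises(ValueError):
            compare_cohorts(g, ["zzz"])
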