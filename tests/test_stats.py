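"""Statistical kernels against exact enumeration oracles."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from circscreen.stats import (ContingencyTable2x2, bh_adjust, chi_square_2x2,
                              colocalization_fraction, empirical_p, fisher_one_tailed,
                              go_enrichment, welch_t_test, wilcoxon_rank_sum)


def fisher_greater_oracle(a, b, c, d):
    """Enumerate the hypergeometric support at fixed margins."""
    r1, c1, n = a + b, a + c, a + b + c + d
    lo, hi = max(0, r1 + c1 - n), min(r1, c1)
    probs = {
        k: math.comb(c1, k) * math.comb(n - c1, r1 - k) / math.comb(n, r1)
        for k in range(lo, hi + 1)
    }
    return sum(p for k, p in probs.items() if k >= a)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [((2, 0, 0, 2), 1 / 6), ((0, 2, 2, 0), 1.0), ((5, 0, 0, 0), 1.0)],
    )
    def test_enumeration_examples(self, table, expected):
        assert fisher_one_tailed(ContingencyTable2x2(*table)) == pytest.approx(expected)

    def test_matches_enumeration_on_random_small_tables(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            a, b, c, d = rng.integers(0, 11, size=4)
            if a + b + c + d == 0 or a + b + c + d > 40:
                continue
            got = fisher_one_tailed(ContingencyTable2x2(int(a), int(b), int(c), int(d)))
            assert got == pytest.approx(fisher_greater_oracle(int(a), int(b), int(c), int(d)))


class TestChiSquare:
    def test_no_association(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(10, 10, 10, 10))
        assert stat == 0.0 and p == pytest.approx(1.0)

    def test_yates_hand_value(self):
        stat, _ = chi_square_2x2(ContingencyTable2x2(30, 70, 10, 90))
        assert stat == pytest.approx(11.28125)
        stat_plain, _ = chi_square_2x2(ContingencyTable2x2(30, 70, 10, 90), yates=False)
        assert stat_plain == pytest.approx(12.5)

    def test_row_swap_symmetry(self):
        s1, _ = chi_square_2x2(ContingencyTable2x2(7, 3, 2, 9))
        s2, _ = chi_square_2x2(ContingencyTable2x2(2, 9, 7, 3))
        assert s1 == pytest.approx(s2)

    def test_uncorrected_matches_closed_form(self):
        rng = np.random.default_rng(5)
        for _ in range(200):
            a, b, c, d = (int(x) for x in rng.integers(1, 30, size=4))
            stat, _ = chi_square_2x2(ContingencyTable2x2(a, b, c, d), yates=False)
            n = a + b + c + d
            closed = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert stat == pytest.approx(closed)

    def test_corrected_matches_independent_implementation(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            a, b, c, d = (int(x) for x in rng.integers(1, 31, size=4))
            stat, p = chi_square_2x2(ContingencyTable2x2(a, b, c, d))
            ref = sps.chi2_contingency([[a, b], [c, d]], correction=True)
            assert stat == pytest.approx(ref.statistic)
            assert p == pytest.approx(ref.pvalue)

    def test_zero_margin_is_na(self):
        stat, p = chi_square_2x2(ContingencyTable2x2(5, 0, 3, 0))
        assert math.isnan(stat) and math.isnan(p)


def wilcoxon_two_sided_oracle(x, y):
    """Exact two-sided p by enumerating every rank assignment (no ties)."""
    pooled = sorted(x + y)
    ranks = {v: i + 1 for i, v in enumerate(pooled)}
    obs = sum(ranks[v] for v in x)
    n, m = len(x), len(y)
    stats = [sum(c) for c in itertools.combinations(range(1, n + m + 1), n)]
    mean = n * (n + m + 1) / 2
    extreme = sum(1 for s in stats if abs(s - mean) >= abs(obs - mean) - 1e-9)
    return extreme / len(stats)


class TestWilcoxon:
    def test_enumeration_example(self):
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)
        assert wilcoxon_two_sided_oracle([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_matches_enumeration_small_samples(self):
        rng = np.random.default_rng(9)
        for _ in range(30):
            n, m = int(rng.integers(2, 6)), int(rng.integers(2, 6))
            vals = rng.permutation(50)[: n + m].tolist()  # distinct => no ties
            x, y = vals[:n], vals[n:]
            assert wilcoxon_rank_sum(x, y) == pytest.approx(wilcoxon_two_sided_oracle(x, y))

    def test_identical_samples(self):
        assert wilcoxon_rank_sum([2.0, 2.0], [2.0, 2.0, 2.0]) == 1.0

    def test_exact_and_approximate_agree_moderate_n(self):
        rng = np.random.default_rng(21)
        x = rng.normal(size=15)
        y = rng.normal(size=15)
        exact = sps.mannwhitneyu(x, y, method="exact").pvalue
        assert wilcoxon_rank_sum(x, y) == pytest.approx(exact, abs=0.01)


class TestWelch:
    def test_identical_groups(self):
        t, p = welch_t_test([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert t == pytest.approx(0.0) and p == pytest.approx(1.0)

    def test_sign_flip(self):
        x, y = [1.0, 2.0, 4.0], [2.0, 5.0, 6.0]
        t1, p1 = welch_t_test(x, y)
        t2, p2 = welch_t_test([-v for v in x], [-v for v in y])
        assert t2 == pytest.approx(-t1) and p2 == pytest.approx(p1)

    def test_agrees_with_permutation_oracle(self):
        rng = np.random.default_rng(33)
        x = rng.normal(size=10)
        y = rng.normal(size=10)
        _, p = welch_t_test(x, y)
        pooled = np.concatenate([x, y])
        obs = abs(np.mean(x) - np.mean(y))
        B = 4000
        hits = 0
        for _ in range(B):
            perm = rng.permutation(pooled)
            if abs(perm[:10].mean() - perm[10:].mean()) >= obs - 1e-12:
                hits += 1
        assert p == pytest.approx(hits / B, abs=0.04)

    def test_zero_variance(self):
        t, p = welch_t_test([1.0, 1.0], [2.0, 2.0])
        assert math.isnan(t) and math.isnan(p)


def bh_oracle(p, q):
    """Brute-force step-up: largest k with p_(k) <= k q / m defines rejections."""
    m = len(p)
    order = np.argsort(p)
    k_star = 0
    for k in range(1, m + 1):
        if p[order[k - 1]] <= k * q / m:
            k_star = k
    reject = np.zeros(m, dtype=bool)
    reject[order[:k_star]] = True
    return reject


class TestBH:
    def test_step_up_example(self):
        got = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(got, [0.04, 0.04, 0.04, 0.04])

    def test_single_value_unchanged(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(2)
        p = rng.random(20)
        perm = rng.permutation(20)
        assert np.allclose(bh_adjust(p)[perm], bh_adjust(p[perm]))

    def test_rejections_match_brute_force(self):
        rng = np.random.default_rng(8)
        for _ in range(100):
            p = rng.random(int(rng.integers(1, 40)))
            for q in (0.05, 0.1, 0.25):
                assert np.array_equal(bh_adjust(p) <= q, bh_oracle(p, q))

    def test_statsmodels_cross_check(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(14)
        p = rng.random(25)
        assert np.allclose(bh_adjust(p), multipletests(p, method="fdr_bh")[1])


class TestEmpiricalP:
    def test_plus_one_floor(self):
        assert empirical_p(10.0, np.zeros(100)) == pytest.approx(1 / 101)

    def test_all_ties(self):
        assert empirical_p(1.0, np.ones(100)) == 1.0


class TestGoEnrichment:
    def go_table(self):
        import pandas as pd

        return pd.DataFrame(
            [("R1", "T_small", "BP"), ("R1", "T_big", "BP"), ("R2", "T_big", "BP"),
             ("R3", "T_big", "BP"), ("R4", "T_solo", "MF")],
            columns=["rbp", "go_term", "domain"],
        )

    def test_single_rbp_term_excluded(self):
        out = go_enrichment({"R1"}, {"R1", "R2", "R3", "R4"}, self.go_table())
        assert "T_solo" not in set(out["go_term"])
        assert "T_small" not in set(out["go_term"])

    def test_fold_is_ratio_of_proportions(self):
        out = go_enrichment({"R1", "R2"}, {f"R{i}" for i in range(1, 5)}, self.go_table())
        row = out[out["go_term"] == "T_big"].iloc[0]
        # subset 2/2 annotated vs background 3/4
        assert row["fold"] == pytest.approx((2 / 2) / (3 / 4))

    def test_subset_equals_background_gives_fold_one(self):
        allr = {f"R{i}" for i in range(1, 5)}
        out = go_enrichment(allr, allr, self.go_table())
        assert np.allclose(out["fold"], 1.0)


class TestColocalization:
    def test_fraction(self):
        pct, resolved, unresolved = colocalization_fraction(
            [("c1", "R1"), ("c2", "R2"), ("c3", "R1"), ("c4", "R9")],
            {"c1": {"cytoplasm"}, "c2": {"cytoplasm"}, "c3": {"cytoplasm"}, "c4": {"cytoplasm"}},
            {"R1": {"nucleus", "cytoplasm"}, "R2": {"nucleus"}},
        )
        assert pct == pytest.approx(100 * 2 / 3)
        assert resolved == 3 and unresolved == 1
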