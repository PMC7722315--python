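"""Coverage math, enrichment ratios, expression-matched resampling."""

import math

import numpy as np
import pandas as pd
import pytest

from circscreen.coverage import (CoverageResult, covered_bases, exon_category_coverage,
                                 expression_bins, host_gene_enrichment, matched_resample,
                                 per_rbp_differential_binding, rbp_coverage)
from circscreen.intervals import GenomicInterval, IntervalSet
from circscreen.peaks import BindingSite

from conftest import base_set


def site(s, e, rbp="R1"):
    return BindingSite(rbp, "sim", GenomicInterval("chr1", s, e, "+"), 20, 0, 4.0)


class TestRbpCoverage:
    exon = IntervalSet.from_pairs("chr1", [(0, 100)])

    def test_merged_union_coverage(self):
        cov = rbp_coverage("f", self.exon, [site(10, 40), site(30, 60, "R2")])
        assert cov.covered_bp == 50 and cov.coverage_pct == pytest.approx(50.0)

    def test_no_sites_and_full_span(self):
        assert rbp_coverage("f", self.exon, []).coverage_pct == 0.0
        assert rbp_coverage("f", self.exon, [site(0, 100)]).coverage_pct == 100.0

    def test_split_site_invariance_and_monotonicity(self):
        whole = rbp_coverage("f", self.exon, [site(10, 60)]).covered_bp
        split = rbp_coverage("f", self.exon, [site(10, 35), site(35, 60)]).covered_bp
        assert whole == split
        more = rbp_coverage("f", self.exon, [site(10, 60), site(80, 95)]).covered_bp
        assert more >= whole

    def test_short_overlap_disregarded(self):
        # 3 bp of the site overlap the exon: below the 4 bp floor
        cov = rbp_coverage("f", self.exon, [site(97, 130)])
        assert cov.covered_bp == 0

    def test_empty_feature_rejected(self):
        with pytest.raises(ValueError):
            rbp_coverage("f", IntervalSet(), [site(0, 10)])
        with pytest.raises(ValueError):
            CoverageResult("f", 100, 101)


class TestCoveredBases:
    def test_matches_per_base_oracle(self):
        rng = np.random.default_rng(77)
        for _ in range(100):
            n = int(rng.integers(0, 12))
            starts = np.sort(rng.integers(0, 900, n))
            widths = rng.integers(2, 70, n)
            ends = starts + widths
            exons = [GenomicInterval("chr1", int(s), int(s) + int(w))
                     for s, w in zip(rng.integers(0, 900, 5), rng.integers(30, 120, 5))]
            got = covered_bases(exons, starts, ends, min_overlap=4)
            for exon, g in zip(exons, got):
                keep = [
                    (max(int(s), exon.start), min(int(e), exon.end))
                    for s, e in zip(starts, ends)
                    if min(int(e), exon.end) - max(int(s), exon.start) >= 4
                ]
                expected = len(base_set(keep) & base_set([exon]))
                assert g == expected


class TestHostGeneEnrichment:
    def cov(self, fid, pct):
        return CoverageResult(fid, 100, int(pct))

    def test_pseudocount_ratio(self):
        enr = host_gene_enrichment(self.cov("c", 93), [self.cov("e", 7)])
        assert enr.ratio == pytest.approx(94 / 8)  # ~11.75x, the highly covered circRNA case

    def test_uncovered_internal_exons_give_maximal_ratio(self):
        enr = host_gene_enrichment(self.cov("c", 100), [self.cov("e", 0)])
        assert enr.ratio == pytest.approx(101.0)

    def test_zero_internal_exons_is_na(self):
        enr = host_gene_enrichment(self.cov("c", 50), [])
        assert math.isnan(enr.ratio)

    def test_ratio_bounds(self):
        rng = np.random.default_rng(1)
        for _ in range(50):
            enr = host_gene_enrichment(
                self.cov("c", int(rng.integers(0, 101))),
                [self.cov("e", int(rng.integers(0, 101))) for _ in range(3)],
            )
            assert 1 / 101 <= enr.ratio <= 101


class TestExpressionBins:
    def test_equal_bins_distinct_fpkm(self):
        fpkm = {f"G{i:03d}": float(i + 1) for i in range(200)}
        bins = expression_bins(fpkm, n_bins=100)
        counts = pd.Series(bins).value_counts()
        assert set(counts) == {2}
        assert bins[max(fpkm, key=fpkm.get)] == 100

    def test_gene_id_tie_break_deterministic(self):
        fpkm = {"B": 1.0, "A": 1.0, "D": 1.0, "C": 1.0}
        bins = expression_bins(fpkm, n_bins=2)
        assert bins == {"A": 1, "B": 1, "C": 2, "D": 2}

    def test_unexpressed_genes_excluded_and_too_few_rejected(self):
        with pytest.raises(ValueError):
            expression_bins({"A": 0.0, "B": 1.0}, n_bins=2)


class TestMatchedResample:
    def make_pool(self, rng, n=200, n_bins=5):
        return pd.DataFrame({
            "bin": rng.integers(1, n_bins + 1, n),
            "coverage_pct": rng.random(n) * 100,
        })

    def test_empirical_p_floor_when_observed_exceeds_all(self):
        rng = np.random.default_rng(0)
        pool = self.make_pool(rng)
        res = matched_resample(np.array([1000.0]), [1], pool, iterations=100,
                               rng=np.random.default_rng(1))
        assert res.empirical_p == pytest.approx(1 / 101)

    def test_ties_count_toward_p(self):
        pool = pd.DataFrame({"bin": [1] * 10, "coverage_pct": [50.0] * 10})
        res = matched_resample(np.array([50.0]), [1], pool, iterations=100,
                               rng=np.random.default_rng(1))
        assert res.empirical_p == 1.0

    def test_draws_match_bin_histogram(self):
        rng = np.random.default_rng(5)
        pool = self.make_pool(rng, n=300)
        need = [1, 1, 2, 3, 3, 3]
        # shrink each bin's pool to unique values so draws are identifiable
        res = matched_resample(np.array([10.0]), need, pool, iterations=20,
                               rng=np.random.default_rng(2))
        assert len(res.resampled_means) == 20
        # mean of each draw is a mean of exactly len(need) values
        by_bin = {b: g["coverage_pct"].to_numpy() for b, g in pool.groupby("bin")}
        lo = np.mean([by_bin[b].min() for b in need])
        hi = np.mean([by_bin[b].max() for b in need])
        assert np.all(res.resampled_means >= lo - 1e-9)
        assert np.all(res.resampled_means <= hi + 1e-9)

    def test_empty_bin_raises(self):
        pool = pd.DataFrame({"bin": [1], "coverage_pct": [5.0]})
        with pytest.raises(ValueError):
            matched_resample(np.array([1.0]), [2], pool, iterations=5,
                             rng=np.random.default_rng(0))

    def test_small_bin_without_replacement_raises_when_disabled(self):
        pool = pd.DataFrame({"bin": [1, 1], "coverage_pct": [5.0, 6.0]})
        with pytest.raises(ValueError):
            matched_resample(np.array([1.0]), [1, 1, 1], pool, iterations=5,
                             rng=np.random.default_rng(0), allow_replacement=False)
        res = matched_resample(np.array([1.0]), [1, 1, 1], pool, iterations=5,
                               rng=np.random.default_rng(0))
        assert res.with_replacement_bins == [1]


class TestPerRbpDifferential:
    def table(self):
        rows = []
        for rbp, shift in (("Renr", 30.0), ("Rnull", 0.0), ("Rfew", 50.0)):
            for i in range(12):
                rows.append({"rbp": rbp, "category": "bsj_circ_exon",
                             "coverage_pct": 10.0 + shift + i})
            for i in range(12):
                rows.append({"rbp": rbp, "category": "non_circ_exon",
                             "coverage_pct": 10.0 + i})
        return pd.DataFrame(rows)

    def test_site_floor_and_fdr_call(self):
        out = per_rbp_differential_binding(
            self.table(), {"Renr": 25, "Rnull": 40, "Rfew": 19}
        )
        assert set(out["rbp"]) == {"Renr", "Rnull"}  # 19 sites excluded
        enr = out.set_index("rbp")
        assert bool(enr.loc["Renr", "significant"])
        assert not bool(enr.loc["Rnull", "significant"])

    def test_too_few_exons_skipped(self):
        df = pd.DataFrame([
            {"rbp": "R1", "category": "bsj_circ_exon", "coverage_pct": 5.0},
            {"rbp": "R1", "category": "non_circ_exon", "coverage_pct": 5.0},
        ])
        out = per_rbp_differential_binding(df, {"R1": 100})
        assert len(out) == 0


class TestExonCategoryCoverage:
    def test_consistent_with_rbp_coverage(self):
        from circscreen.catalog import ExonCategory, ExonRecord

        rng = np.random.default_rng(3)
        sites = [site(int(s), int(s) + int(w), f"R{i % 3}")
                 for i, (s, w) in enumerate(zip(rng.integers(0, 2000, 60),
                                                rng.integers(5, 60, 60)))]
        exons = [ExonRecord("G1", GenomicInterval("chr1", int(s), int(s) + 200),
                            ExonCategory.NON_CIRC_EXON, False, False)
                 for s in range(0, 1800, 300)]
        table = exon_category_coverage(exons, sites)
        for er in exons:
            ref = rbp_coverage(str(er.interval), IntervalSet([er.interval]), sites)
            got = table.loc[table["exon"] == str(er.interval), "covered_bp"].iloc[0]
            assert got == ref.covered_bp
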