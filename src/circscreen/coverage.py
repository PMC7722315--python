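"""RBP binding-site coverage of circRNAs and exon classes, enrichment ratios,
expression-matched resampling, and per-RBP differential binding.

Coverage of a feature is the percentage of its exonic bases overlapped by the
union of filtered binding sites. The host-gene enrichment ratio compares a
circRNA's coverage to the mean coverage of the internal non-circularizing
exons of its host gene, with a pseudocount of 1 on both sides so features
without any binding site stay in the analysis. The expression-matched
resampling draws internal non-circ-exons from genes not producing circRNAs,
matching the expression-bin histogram of circRNA-producing genes, and scores
the observed mean coverage with an add-one empirical p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .catalog import ExonCategory, ExonRecord
from .intervals import IntervalSet
from .peaks import BindingSite
from .stats import bh_adjust, empirical_p, wilcoxon_rank_sum


@dataclass
class CoverageResult:
    feature_id: str
    exonic_length: int
    covered_bp: int

    def __post_init__(self) -> None:
        if self.exonic_length <= 0:
            raise ValueError(f"feature {self.feature_id} has no exonic bases")
        if not 0 <= self.covered_bp <= self.exonic_length:
            raise ValueError(f"covered_bp out of range for {self.feature_id}")

    @property
    def coverage_pct(self) -> float:
        return 100.0 * self.covered_bp / self.exonic_length


@dataclass
class EnrichmentRatio:
    circ_id: str
    circ_coverage_pct: float
    mean_noncirc_coverage_pct: float | None  # None when the host gene has no internal non-circ-exons

    @property
    def ratio(self) -> float:
        if self.mean_noncirc_coverage_pct is None:
            return float("nan")
        return (self.circ_coverage_pct + 1) / (self.mean_noncirc_coverage_pct + 1)


@dataclass
class ResampleResult:
    observed_mean_coverage: float
    resampled_means: np.ndarray
    with_replacement_bins: list[int]

    @property
    def empirical_p(self) -> float:
        return empirical_p(self.observed_mean_coverage, self.resampled_means)


def rbp_coverage(
    feature_id: str,
    feature_exonic: IntervalSet,
    sites: list[BindingSite],
    merge_rbps: bool = True,
    min_overlap: int = 4,
) -> CoverageResult:
    """Coverage of a feature's exonic bases by (merged) binding sites.

    Sites whose overlap with the feature is below ``min_overlap`` bp are
    disregarded. With ``merge_rbps`` the union over all RBPs is taken before
    intersecting, so overlapping sites of different proteins are not double
    counted (they cannot inflate coverage past 100%).
    """
    if not feature_exonic:
        raise ValueError(f"feature {feature_id} has empty exonic set")
    kept = [s for s in sites if feature_exonic.overlap_length(s.interval) >= min_overlap]
    if not kept:
        return CoverageResult(feature_id, feature_exonic.total_length, 0)
    if not merge_rbps:
        raise NotImplementedError("per-RBP coverage is computed by the caller per RBP subset")
    site_union = IntervalSet(
        [s.interval for s in kept if s.interval.chrom == feature_exonic.chrom]
    )
    covered = feature_exonic.intersect(site_union).total_length
    return CoverageResult(feature_id, feature_exonic.total_length, covered)


def host_gene_enrichment(
    circ: CoverageResult, noncirc_exons: list[CoverageResult]
) -> EnrichmentRatio:
    """(circ coverage + 1) / (mean internal non-circ-exon coverage + 1), NA-safe.

    Callers must restrict ``noncirc_exons`` to internal (not first/last)
    non-circ-exons of the host gene; an empty list yields the NA case.
    """
    if not noncirc_exons:
        return EnrichmentRatio(circ.feature_id, circ.coverage_pct, None)
    mean_cov = float(np.mean([e.coverage_pct for e in noncirc_exons]))
    return EnrichmentRatio(circ.feature_id, circ.coverage_pct, mean_cov)


def expression_bins(
    fpkm_by_gene: dict[str, float], n_bins: int = 100
) -> dict[str, int]:
    """Assign expressed genes (FPKM > 0) to expression quantile bins 1..n_bins.

    Genes are sorted by (FPKM, gene_id) — the gene_id tie-break makes the
    assignment deterministic with identical FPKM values — and split into bins
    as equal as the remainder allows; the highest-expressed genes land in the
    top bin.
    """
    expressed = [(fpkm, gid) for gid, fpkm in fpkm_by_gene.items() if fpkm > 0]
    if len(expressed) < n_bins:
        raise ValueError(
            f"need at least {n_bins} expressed genes for {n_bins} bins, got {len(expressed)}"
        )
    expressed.sort()
    n = len(expressed)
    # np.array_split semantics: first (n % n_bins) bins get the extra gene
    sizes = [n // n_bins + (1 if i < n % n_bins else 0) for i in range(n_bins)]
    out: dict[str, int] = {}
    idx = 0
    for bin_no, size in enumerate(sizes, start=1):
        for _, gid in expressed[idx : idx + size]:
            out[gid] = bin_no
        idx += size
    return out


def matched_resample(
    observed_coverages: np.ndarray,
    circ_gene_bins: list[int],
    pool: pd.DataFrame,
    iterations: int = 100,
    rng: np.random.Generator | None = None,
    allow_replacement: bool = True,
) -> ResampleResult:
    """Expression-matched resampling of pool exons against an observed mean.

    ``observed_coverages`` are the per-exon coverage percentages of the
    observed group (e.g. BSJ circ-exons of circRNA-producing genes);
    ``circ_gene_bins`` is the expression-bin multiset of those genes; ``pool``
    has columns ``bin`` and ``coverage_pct`` for internal non-circ-exons of
    genes not producing circRNAs. Each iteration draws, per bin, as many pool
    exons as there are circ-genes in that bin (without replacement when the
    bin suffices, with replacement — flagged — otherwise) and records the mean
    coverage of the draw.
    """
    if rng is None:
        rng = np.random.default_rng()
    observed_mean = float(np.mean(observed_coverages))
    need = pd.Series(circ_gene_bins).value_counts().sort_index()
    pool_by_bin = {b: grp["coverage_pct"].to_numpy() for b, grp in pool.groupby("bin")}
    replacement_bins: list[int] = []
    for b, k in need.items():
        avail = pool_by_bin.get(b)
        if avail is None or len(avail) == 0:
            raise ValueError(f"expression bin {b} has no pool exons")
        if len(avail) < k:
            if not allow_replacement:
                raise ValueError(f"expression bin {b} has {len(avail)} pool exons, need {k}")
            replacement_bins.append(int(b))
    means = np.empty(iterations)
    for it in range(iterations):
        drawn: list[np.ndarray] = []
        for b, k in need.items():
            avail = pool_by_bin[b]
            replace = len(avail) < k
            drawn.append(rng.choice(avail, size=int(k), replace=replace))
        means[it] = float(np.mean(np.concatenate(drawn)))
    return ResampleResult(observed_mean, means, replacement_bins)


def per_rbp_differential_binding(
    exon_coverage: pd.DataFrame,
    site_counts: dict[str, int],
    min_sites: int = 20,
    fdr_threshold: float = 0.1,
) -> pd.DataFrame:
    """Per-RBP comparison of exon coverage, BSJ circ-exons vs non-circ-exons.

    ``exon_coverage`` has one row per (rbp, exon) with columns rbp, category,
    coverage_pct, restricted to exons of circRNA-producing genes. RBPs with
    fewer than ``min_sites`` distinct binding sites in total are excluded;
    RBPs with fewer than two exons in either category are skipped. Two-sided
    Wilcoxon rank-sum p-values are Benjamini-Hochberg adjusted and called
    significant at FDR < ``fdr_threshold``.
    """
    rows = []
    for rbp, grp in exon_coverage.groupby("rbp", sort=True):
        if site_counts.get(rbp, 0) < min_sites:
            continue
        bsj = grp.loc[grp["category"] == ExonCategory.BSJ_CIRC_EXON.value, "coverage_pct"].to_numpy()
        non = grp.loc[grp["category"] == ExonCategory.NON_CIRC_EXON.value, "coverage_pct"].to_numpy()
        if len(bsj) < 2 or len(non) < 2:
            continue
        p = wilcoxon_rank_sum(bsj, non, alternative="two-sided")
        rows.append(
            {
                "rbp": rbp,
                "n_sites": site_counts[rbp],
                "mean_coverage_bsj_circ_exon": float(np.mean(bsj)),
                "mean_coverage_non_circ_exon": float(np.mean(non)),
                "p": p,
            }
        )
    out = pd.DataFrame(rows, columns=["rbp", "n_sites", "mean_coverage_bsj_circ_exon",
                                      "mean_coverage_non_circ_exon", "p"])
    if len(out):
        out["fdr"] = bh_adjust(out["p"].to_numpy())
        out["significant"] = out["fdr"] < fdr_threshold
    else:
        out["fdr"] = pd.Series(dtype=float)
        out["significant"] = pd.Series(dtype=bool)
    return out


def covered_bases(
    intervals: list, site_starts: np.ndarray, site_ends: np.ndarray, min_overlap: int = 4
) -> np.ndarray:
    """Per-interval bases covered by sites overlapping it by >= min_overlap.

    ``site_starts``/``site_ends`` must be sorted by start (one chromosome).
    Equivalent to clipping the qualifying sites to the interval and taking the
    union length; vectorized for the resampling loops.
    """
    site_starts = np.asarray(site_starts, dtype=np.int64)
    site_ends = np.asarray(site_ends, dtype=np.int64)
    out = np.zeros(len(intervals), dtype=np.int64)
    if site_starts.size == 0:
        return out
    maxw = int((site_ends - site_starts).max())
    for i, iv in enumerate(intervals):
        lo = np.searchsorted(site_starts, iv.start - maxw)
        hi = np.searchsorted(site_starts, iv.end)
        if lo == hi:
            continue
        s = np.maximum(site_starts[lo:hi], iv.start)
        e = np.minimum(site_ends[lo:hi], iv.end)
        keep = (e - s) >= min_overlap
        if not keep.any():
            continue
        s, e = s[keep], e[keep]  # still sorted by clipped start
        cummax = np.maximum.accumulate(e)
        prev = np.concatenate(([iv.start - 1], cummax[:-1]))
        out[i] = int(np.maximum(0, e - np.maximum(s, prev)).sum())
    return out


def _site_arrays(sites: list[BindingSite]) -> dict[str, tuple[np.ndarray, np.ndarray]]:
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for s in sites:
        by_chrom.setdefault(s.interval.chrom, []).append((s.interval.start, s.interval.end))
    out = {}
    for chrom, pairs in by_chrom.items():
        arr = np.array(sorted(pairs), dtype=np.int64)
        out[chrom] = (arr[:, 0], arr[:, 1])
    return out


def exon_category_coverage(
    exons: list[ExonRecord],
    sites: list[BindingSite],
    min_overlap: int = 4,
    by_rbp: bool = False,
) -> pd.DataFrame:
    """Coverage table for categorized exons, merged over RBPs or per RBP."""
    groups: dict[str, list[BindingSite]]
    if by_rbp:
        groups = {}
        for s in sites:
            groups.setdefault(s.rbp_name, []).append(s)
    else:
        groups = {"ALL": sites}
    rows = []
    for rbp in sorted(groups):
        arrays = _site_arrays(groups[rbp])
        by_chrom: dict[str, list[ExonRecord]] = {}
        for er in exons:
            by_chrom.setdefault(er.interval.chrom, []).append(er)
        for chrom, ers in by_chrom.items():
            starts, ends = arrays.get(chrom, (np.array([], dtype=np.int64),) * 2)
            ivs = [er.interval for er in ers]
            covered = covered_bases(ivs, starts, ends, min_overlap=min_overlap)
            for er, cov in zip(ers, covered):
                rows.append(
                    {
                        "gene_id": er.gene_id,
                        "exon": str(er.interval),
                        "category": er.category.value,
                        "is_internal": er.is_internal,
                        "rbp": rbp,
                        "exon_length": er.interval.length,
                        "covered_bp": int(cov),
                        "coverage_pct": 100.0 * cov / er.interval.length,
                    }
                )
    return pd.DataFrame(
        rows,
        columns=["gene_id", "exon", "category", "is_internal", "rbp",
                 "exon_length", "covered_bp", "coverage_pct"],
    )
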