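"""Flanking-intron biogenesis analysis.

CircRNA biogenesis is promoted by factors binding the introns flanking the
circularized exons — either an RBP (such as KHSRP) bound in both flanks or
inverted *Alu* repeats (IRAlus) capable of pairing across the circle. This
module extracts the intronic bases within a fixed window on each side of a
feature, tests both-flank presence of binding sites or inverted Alu pairs,
compares circRNAs to non-circularizing exons by chi-square, and quantifies
knockdown effects on circRNA expression in reads-per-million.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .peaks import BindingSite
from .stats import ContingencyTable2x2, chi_square_2x2, welch_t_test, wilcoxon_rank_sum


@dataclass
class FlankPair:
    """Intronic bases within ``width`` bp on each side of a feature."""

    feature_id: str
    upstream_flank: IntervalSet
    downstream_flank: IntervalSet


def flank_pair(
    feature: GenomicInterval, introns: IntervalSet, width: int = 10_000
) -> FlankPair:
    """Windows [start-width, start) and [end, end+width) intersected with introns.

    "Upstream"/"downstream" are genomic (left/right of the feature); the
    windows are clipped at position 0 and are NOT truncated at neighboring
    genes — only the restriction to intronic bases applies.
    """
    up_start = max(0, feature.start - width)
    up = (
        IntervalSet([GenomicInterval(feature.chrom, up_start, feature.start)])
        if feature.start > 0
        else IntervalSet()
    )
    down = IntervalSet([GenomicInterval(feature.chrom, feature.end, feature.end + width)])
    return FlankPair(
        feature_id=str(feature),
        upstream_flank=up.intersect(introns) if up else IntervalSet(),
        downstream_flank=down.intersect(introns),
    )


def both_flank_presence(pair: FlankPair, sites: list[BindingSite]) -> bool:
    """True iff at least one site overlaps (>= 1 bp) each flank's intronic bases."""
    def hits(flank: IntervalSet) -> bool:
        return any(flank.overlap_length(s.interval) > 0 for s in sites)

    return hits(pair.upstream_flank) and hits(pair.downstream_flank)


def iralu_both_flanks(pair: FlankPair, alus: pd.DataFrame) -> bool:
    """True iff the two flanks contain Alu elements on OPPOSITE strands.

    ``alus`` is a BED6-style frame (chrom, start, end, name, score, strand).
    An upstream Alu and a downstream Alu in inverted orientation can base-pair
    across the feature; the test is symmetric under swapping all strands.
    """
    def flank_strands(flank: IntervalSet) -> set[str]:
        strands: set[str] = set()
        for row in alus.itertuples(index=False):
            if flank.chrom is not None and row.chrom != flank.chrom:
                continue
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
            if flank.overlap_length(iv) > 0:
                strands.add(row.strand)
        return strands

    up = flank_strands(pair.upstream_flank)
    down = flank_strands(pair.downstream_flank)
    return ("+" in up and "-" in down) or ("-" in up and "+" in down)


def flank_enrichment_test(
    group_a_flags: np.ndarray, group_b_flags: np.ndarray
) -> tuple[float, float, float]:
    """Fold and Yates-corrected chi-square for both-flank presence, A vs B.

    Group A is circRNAs; group B is internal non-circ-exons of expressed genes
    with first/last exons and circRNA exons removed (the caller enforces the
    group-B restriction). Returns (fold, chi2, p); p is NaN when a margin is
    zero, fold is NaN when group B has no positives.
    """
    a = np.asarray(group_a_flags, dtype=bool)
    b = np.asarray(group_b_flags, dtype=bool)
    table = ContingencyTable2x2(
        int(a.sum()), int((~a).sum()), int(b.sum()), int((~b).sum())
    )
    chi2, p = chi_square_2x2(table, yates=True)
    prop_a = a.mean() if a.size else float("nan")
    prop_b = b.mean() if b.size else float("nan")
    fold = prop_a / prop_b if prop_b > 0 else float("nan")
    return float(fold), chi2, p


def rpm_normalize(counts: pd.DataFrame, library_sizes: pd.Series) -> pd.DataFrame:
    """counts[c, s] * 1e6 / library_size[s] for every sample column s."""
    missing = set(counts.columns) - set(library_sizes.index)
    if missing:
        raise ValueError(f"missing library sizes for samples {sorted(missing)}")
    sizes = library_sizes[counts.columns].astype(float)
    if (sizes <= 0).any():
        raise ValueError("library sizes must be positive")
    return counts * 1e6 / sizes


def kd_group_compare(
    rpm: pd.DataFrame,
    conditions: pd.Series,
    subset: list[str],
    test: str = "t",
) -> dict:
    """Compare total circRNA expression (RPM) between KD and control samples.

    ``rpm`` is circ_id x sample; ``conditions`` maps sample -> {"KD",
    "control"}. The per-sample total RPM over ``subset`` is compared by Welch
    t-test or Wilcoxon rank-sum; the per-circRNA mean RPM is reported
    alongside. Relative change = (mean_KD - mean_control) / mean_control.
    """
    if not subset:
        raise ValueError("empty circRNA subset")
    missing = set(subset) - set(rpm.index)
    if missing:
        raise ValueError(f"subset circRNAs absent from the matrix: {sorted(missing)[:3]}")
    sub = rpm.loc[subset]
    totals = sub.sum(axis=0)
    kd_samples = conditions[conditions == "KD"].index
    ctrl_samples = conditions[conditions == "control"].index
    kd = totals[kd_samples].to_numpy(dtype=float)
    ctrl = totals[ctrl_samples].to_numpy(dtype=float)
    if test == "t":
        _, p = welch_t_test(kd, ctrl)
    elif test == "wilcoxon":
        p = wilcoxon_rank_sum(kd, ctrl, alternative="two-sided")
    else:
        raise ValueError(f"unknown test {test!r}")
    mean_kd, mean_ctrl = float(kd.mean()), float(ctrl.mean())
    return {
        "n_circ": len(subset),
        "mean_kd_total_rpm": mean_kd,
        "mean_control_total_rpm": mean_ctrl,
        "mean_kd_per_circ_rpm": mean_kd / len(subset),
        "mean_control_per_circ_rpm": mean_ctrl / len(subset),
        "relative_change": (mean_kd - mean_ctrl) / mean_ctrl if mean_ctrl else float("nan"),
        "p": float(p),
        "test": test,
    }
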