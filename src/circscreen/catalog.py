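"""Consensus circRNA catalog, top-percentile sets, and exon categorization.

Two backsplice-junction callers are reconciled on exact junction coordinates;
a junction is kept only when both callers support it with at least two
BSJ-spanning reads. Expression (BSJ and linear read counts) is always taken
from caller A, the CIRI2-role caller.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .intervals import GenomicInterval, IntervalSet, GeneModel, MergedExon, gene_merged_exons


class ExonCategory(str, Enum):
    BSJ_CIRC_EXON = "bsj_circ_exon"
    CIRC_EXON = "circ_exon"
    NON_CIRC_EXON = "non_circ_exon"


@dataclass
class CircRNACall:
    """A backsplice junction with two-caller read support."""

    chrom: str
    start: int
    end: int
    strand: str
    bsj_reads_a: int
    bsj_reads_b: int
    linear_reads: int
    host_gene: str | None = None

    def __post_init__(self) -> None:
        if min(self.bsj_reads_a, self.bsj_reads_b, self.linear_reads) < 0:
            raise ValueError(f"negative read count for {self.circ_id}")

    @property
    def circ_id(self) -> str:
        return f"{self.chrom}:{self.start}-{self.end}"

    @property
    def interval(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand)


@dataclass
class ExonRecord:
    """A merged per-gene exon with its category relative to the circRNA catalog."""

    gene_id: str
    interval: GenomicInterval
    category: ExonCategory
    is_first: bool
    is_last: bool

    @property
    def in_any_circ(self) -> bool:
        return self.category in (ExonCategory.BSJ_CIRC_EXON, ExonCategory.CIRC_EXON)

    @property
    def is_internal(self) -> bool:
        return not (self.is_first or self.is_last)


def read_caller_table(
    path: str | os.PathLike, coords: str = "bed"
) -> pd.DataFrame:
    """Read a caller TSV (chrom, start, end, strand, bsj_reads, linear_reads[, gene_id]).

    ``coords`` declares the caller dialect: "bed" (0-based half-open) or
    "ciri" (1-based closed, converted on read).
    """
    if coords not in ("bed", "ciri"):
        raise ValueError(f"unknown coordinate dialect {coords!r}")
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = {"chrom", "start", "end", "strand", "bsj_reads", "linear_reads"}
    if not required <= set(df.columns):
        raise ValueError(f"caller table missing columns {sorted(required - set(df.columns))}")
    df = df.copy()
    if coords == "ciri":
        df["start"] = df["start"].astype(int) - 1
    if (df["start"] >= df["end"]).any():
        raise ValueError("caller table contains empty/inverted junction spans; "
                         "check the coordinate dialect flag")
    return df


def consensus_catalog(
    calls_a: pd.DataFrame, calls_b: pd.DataFrame, min_reads: int = 2
) -> list[CircRNACall]:
    """Junctions supported by >= min_reads BSJ reads in BOTH callers.

    Callers are matched on exact (chrom, start, end); expression fields come
    from caller A.
    """
    key = ["chrom", "start", "end"]
    b_counts = calls_b.set_index(key)["bsj_reads"]
    if b_counts.index.has_duplicates:
        raise ValueError("duplicate junctions in caller B table")
    out: list[CircRNACall] = []
    seen: set[tuple] = set()
    for row in calls_a.itertuples(index=False):
        k = (row.chrom, row.start, row.end)
        if k in seen:
            raise ValueError(f"duplicate junction in caller A table: {k}")
        seen.add(k)
        if k not in b_counts.index:
            continue
        reads_b = int(b_counts.loc[k])
        if row.bsj_reads < min_reads or reads_b < min_reads:
            continue
        out.append(
            CircRNACall(
                chrom=row.chrom,
                start=int(row.start),
                end=int(row.end),
                strand=row.strand,
                bsj_reads_a=int(row.bsj_reads),
                bsj_reads_b=reads_b,
                linear_reads=int(row.linear_reads),
                host_gene=getattr(row, "gene_id", None),
            )
        )
    return out


def top_percentile(catalog: list[CircRNACall], fraction: float = 0.01) -> list[CircRNACall]:
    """The ceil(fraction * N) most highly expressed circRNAs (caller-A reads).

    Ties at the boundary are resolved deterministically: all tied junctions are
    ranked by circ_id lexicographically and the list truncated to size.
    """
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if not catalog:
        raise ValueError("empty catalog")
    n_keep = math.ceil(fraction * len(catalog))
    ranked = sorted(catalog, key=lambda c: (-c.bsj_reads_a, c.circ_id))
    return ranked[:n_keep]


def top_percentile_size(n: int, fraction: float = 0.01) -> int:
    """Set size under the ceiling rule, without materializing a catalog."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    if n < 1:
        raise ValueError("catalog size must be >= 1")
    return math.ceil(fraction * n)


def relative_ratio(bsj_reads: int, linear_reads: int) -> float:
    """Relative circular-to-linear ratio (2c) / (2c + l).

    A BSJ read arises from both ends of the circular junction but is counted
    once, while linear reads come from one end; doubling the circular count
    puts the two on the same footing. Undefined (NaN) when both counts are 0.
    """
    if bsj_reads < 0 or linear_reads < 0:
        raise ValueError("negative read count")
    if bsj_reads == 0 and linear_reads == 0:
        return float("nan")
    return 2 * bsj_reads / (2 * bsj_reads + linear_reads)


def assign_host_genes(
    catalog: list[CircRNACall],
    genes: list[GeneModel],
    merged_exons: dict[str, list[MergedExon]] | None = None,
) -> None:
    """Assign each circRNA the gene whose merged exons it overlaps most.

    Overlap is counted in exonic bases; candidates are strand-matched when the
    circRNA strand is known ('+'/'-'). Calls with no exonic overlap keep
    host_gene = None. Ties break by gene_id.
    """
    if merged_exons is None:
        merged_exons = {g.gene_id: gene_merged_exons(g) for g in genes}
    gene_by_id = {g.gene_id: g for g in genes}
    exon_sets = {
        gid: IntervalSet([me.interval for me in mes]) for gid, mes in merged_exons.items()
    }
    for circ in catalog:
        best: tuple[int, str] | None = None
        for gid, exset in exon_sets.items():
            gene = gene_by_id[gid]
            if gene.chrom != circ.chrom:
                continue
            if circ.strand in "+-" and gene.strand in "+-" and gene.strand != circ.strand:
                continue
            ov = exset.overlap_length(circ.interval)
            if ov > 0 and (best is None or ov > best[0] or (ov == best[0] and gid < best[1])):
                best = (ov, gid)
        circ.host_gene = best[1] if best else None


def categorize_exons(
    merged_exons: list[MergedExon], catalog: list[CircRNACall], boundary_tolerance: int = 0
) -> list[ExonRecord]:
    """Categorize merged exons relative to the circRNA catalog.

    BSJ circ-exon: an exon boundary coincides (within ``boundary_tolerance``,
    default exact) with a backsplice coordinate of any same-gene circRNA.
    Circ-exon: fully inside a circRNA span but never boundary-matched.
    Non-circ-exon: everything else. BSJ circ-exon takes precedence: an exon
    internal to one circle but boundary-matched in another is a BSJ circ-exon.
    """
    by_gene: dict[str | None, list[CircRNACall]] = {}
    for circ in catalog:
        by_gene.setdefault(circ.host_gene, []).append(circ)
    out: list[ExonRecord] = []
    for me in merged_exons:
        circs = by_gene.get(me.gene_id, [])
        category = ExonCategory.NON_CIRC_EXON
        for circ in circs:
            iv = me.interval
            boundary = (
                abs(iv.start - circ.start) <= boundary_tolerance
                or abs(iv.end - circ.end) <= boundary_tolerance
            )
            if boundary:
                category = ExonCategory.BSJ_CIRC_EXON
                break
            if circ.start <= iv.start and iv.end <= circ.end:
                category = ExonCategory.CIRC_EXON
        out.append(
            ExonRecord(
                gene_id=me.gene_id,
                interval=me.interval,
                category=category,
                is_first=me.is_first,
                is_last=me.is_last,
            )
        )
    return out


def circ_exonic_parts(
    circ: CircRNACall, merged_exons: list[MergedExon]
) -> tuple[IntervalSet, bool]:
    """Exonic parts of a circRNA: its span intersected with host-gene merged exons.

    Returns (interval set, has_annotated_exons). circRNAs without annotated
    exons are flagged and excluded from coverage analyses upstream.
    """
    host_exons = IntervalSet(
        [me.interval for me in merged_exons if me.gene_id == circ.host_gene]
    ) if circ.host_gene else IntervalSet()
    if not host_exons:
        return IntervalSet(), False
    span = IntervalSet([circ.interval])
    parts = span.intersect(host_exons)
    return parts, bool(parts)


def catalog_table(
    catalog: list[CircRNACall], merged_exons: dict[str, list[MergedExon]]
) -> pd.DataFrame:
    """Per-circRNA summary mirroring the published supplementary schema."""
    rows = []
    for circ in catalog:
        mes = merged_exons.get(circ.host_gene, []) if circ.host_gene else []
        parts, has_exons = circ_exonic_parts(circ, mes)
        rows.append(
            {
                "circRNA_ID": circ.circ_id,
                "chrom": circ.chrom,
                "start": circ.start,
                "end": circ.end,
                "strand": circ.strand,
                "host_gene": circ.host_gene if circ.host_gene else "NA",
                "BSJ_reads": circ.bsj_reads_a,
                "BSJ_reads_caller_B": circ.bsj_reads_b,
                "linear_reads": circ.linear_reads,
                "relative_ratio": relative_ratio(circ.bsj_reads_a, circ.linear_reads),
                "exonic_length": parts.total_length,
                "N_exons": len(parts),
                "has_annotated_exons": has_exons,
            }
        )
    return pd.DataFrame(rows)
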