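"""Genomic interval arithmetic and gene models.

All coordinates are 0-based half-open (BED convention). GTF input, which is
1-based closed, is converted on read and back on write (see :mod:`circscreen.io`).
Set algebra (merge / intersect / subtract) ignores strand: it is applied
per gene, where strand is uniform; strand matters only for first/last-exon
orientation and inverted-repeat orientation downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Sequence

import numpy as np

VALID_STRANDS = ("+", "-", ".")


@dataclass(frozen=True)
class GenomicInterval:
    """A stranded genomic interval, 0-based half-open."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start < 0:
            raise ValueError(f"negative start: {self.start}")
        if self.start >= self.end:
            raise ValueError(f"empty or inverted interval: [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"invalid strand {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    def overlap_length(self, other: "GenomicInterval") -> int:
        if self.chrom != other.chrom:
            return 0
        return max(0, min(self.end, other.end) - max(self.start, other.start))

    def __str__(self) -> str:  # chrom:start-end, BED-style coordinates
        return f"{self.chrom}:{self.start}-{self.end}"


class IntervalSet:
    """A merged, sorted set of disjoint intervals on one chromosome.

    Construction merges overlapping and bookended (distance-0) intervals,
    matching ``bedtools merge`` defaults. Stored as two int64 arrays.
    """

    __slots__ = ("chrom", "starts", "ends")

    def __init__(self, intervals: Iterable[GenomicInterval] = ()):
        ivs = list(intervals)
        chroms = {iv.chrom for iv in ivs}
        if len(chroms) > 1:
            raise ValueError(f"intervals span multiple chromosomes: {sorted(chroms)}")
        self.chrom: str | None = chroms.pop() if chroms else None
        starts = np.array([iv.start for iv in ivs], dtype=np.int64)
        ends = np.array([iv.end for iv in ivs], dtype=np.int64)
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        # single pass merge; touching intervals ([a,b) + [b,c)) coalesce
        m_starts: list[int] = []
        m_ends: list[int] = []
        for s, e in zip(starts, ends):
            if m_ends and s <= m_ends[-1]:
                if e > m_ends[-1]:
                    m_ends[-1] = int(e)
            else:
                m_starts.append(int(s))
                m_ends.append(int(e))
        self.starts = np.array(m_starts, dtype=np.int64)
        self.ends = np.array(m_ends, dtype=np.int64)

    @classmethod
    def _from_arrays(cls, chrom: str | None, starts: np.ndarray, ends: np.ndarray) -> "IntervalSet":
        out = cls.__new__(cls)
        out.chrom = chrom
        out.starts = np.asarray(starts, dtype=np.int64)
        out.ends = np.asarray(ends, dtype=np.int64)
        return out

    @classmethod
    def from_pairs(cls, chrom: str, pairs: Iterable[tuple[int, int]], strand: str = ".") -> "IntervalSet":
        return cls(GenomicInterval(chrom, s, e, strand) for s, e in pairs)

    def __len__(self) -> int:
        return len(self.starts)

    def __bool__(self) -> bool:
        return len(self.starts) > 0

    def __iter__(self) -> Iterator[tuple[int, int]]:
        return iter(zip(self.starts.tolist(), self.ends.tolist()))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IntervalSet):
            return NotImplemented
        return (
            len(self) == len(other)
            and (not self or self.chrom == other.chrom)
            and bool(np.array_equal(self.starts, other.starts))
            and bool(np.array_equal(other.ends, self.ends))
        )

    def __repr__(self) -> str:
        body = ",".join(f"[{s},{e})" for s, e in self)
        return f"IntervalSet({self.chrom}: {body})"

    @property
    def total_length(self) -> int:
        return int((self.ends - self.starts).sum())

    def intervals(self, strand: str = ".") -> list[GenomicInterval]:
        return [GenomicInterval(self.chrom, int(s), int(e), strand) for s, e in self]

    def _check_chrom(self, other: "IntervalSet") -> str | None:
        if self.chrom is not None and other.chrom is not None and self.chrom != other.chrom:
            raise ValueError(f"chromosome mismatch: {self.chrom} vs {other.chrom}")
        return self.chrom or other.chrom

    def intersect(self, other: "IntervalSet") -> "IntervalSet":
        """Base-level intersection (half-open adjacency does not overlap)."""
        chrom = self._check_chrom(other)
        starts: list[int] = []
        ends: list[int] = []
        i = j = 0
        while i < len(self) and j < len(other):
            s = max(self.starts[i], other.starts[j])
            e = min(self.ends[i], other.ends[j])
            if s < e:
                starts.append(int(s))
                ends.append(int(e))
            if self.ends[i] <= other.ends[j]:
                i += 1
            else:
                j += 1
        return IntervalSet._from_arrays(chrom if starts else None, np.array(starts), np.array(ends))

    def subtract(self, other: "IntervalSet") -> "IntervalSet":
        """Bases in self and not in other."""
        chrom = self._check_chrom(other)
        starts: list[int] = []
        ends: list[int] = []
        j = 0
        for s, e in self:
            cur = s
            while j < len(other) and other.ends[j] <= cur:
                j += 1
            k = j
            while k < len(other) and other.starts[k] < e:
                if other.starts[k] > cur:
                    starts.append(cur)
                    ends.append(int(other.starts[k]))
                cur = max(cur, int(other.ends[k]))
                k += 1
            if cur < e:
                starts.append(cur)
                ends.append(e)
        return IntervalSet._from_arrays(chrom if starts else None, np.array(starts), np.array(ends))

    def union(self, other: "IntervalSet") -> "IntervalSet":
        chrom = self._check_chrom(other)
        starts = np.concatenate([self.starts, other.starts])
        ends = np.concatenate([self.ends, other.ends])
        ivs = [GenomicInterval(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
        return IntervalSet(ivs)

    def overlap_length(self, interval: GenomicInterval) -> int:
        if self.chrom is not None and interval.chrom != self.chrom:
            return 0
        ov = np.minimum(self.ends, interval.end) - np.maximum(self.starts, interval.start)
        return int(ov[ov > 0].sum())

    def contains_interval(self, interval: GenomicInterval) -> bool:
        """True iff every base of ``interval`` is in the set."""
        return self.overlap_length(interval) == interval.length


def merge_intervals(intervals: Sequence[GenomicInterval]) -> IntervalSet:
    """Merge intervals into disjoint sorted blocks (``bedtools merge`` semantics)."""
    return IntervalSet(intervals)


def intersect(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.intersect(b)


def subtract(a: IntervalSet, b: IntervalSet) -> IntervalSet:
    return a.subtract(b)


@dataclass
class TranscriptModel:
    """One transcript isoform: ordered exons on a single chromosome/strand."""

    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: list[GenomicInterval] = field(default_factory=list)

    def sorted_exons(self) -> list[GenomicInterval]:
        """Exons in transcription order (5'->3' on the transcript strand)."""
        ex = sorted(self.exons, key=lambda iv: iv.start)
        return ex[::-1] if self.strand == "-" else ex

    def validate(self) -> None:
        if not self.exons:
            raise ValueError(f"transcript {self.transcript_id} has no exons")
        if any(iv.chrom != self.chrom for iv in self.exons):
            raise ValueError(f"transcript {self.transcript_id} spans chromosomes")
        ex = sorted(self.exons, key=lambda iv: iv.start)
        for a, b in zip(ex, ex[1:]):
            if b.start < a.end:
                raise ValueError(f"overlapping exons in transcript {self.transcript_id}")


@dataclass
class GeneModel:
    """A gene with its isoforms and an expression value (FPKM)."""

    gene_id: str
    chrom: str
    strand: str
    transcripts: list[TranscriptModel] = field(default_factory=list)
    fpkm: float = 0.0
    expression_percentile: int | None = None

    def validate(self) -> None:
        if not self.transcripts:
            raise ValueError(f"gene {self.gene_id} has no transcripts")
        if self.fpkm < 0:
            raise ValueError(f"gene {self.gene_id} has negative FPKM")
        for tx in self.transcripts:
            if tx.chrom != self.chrom or tx.strand != self.strand:
                raise ValueError(
                    f"gene {self.gene_id}: transcript {tx.transcript_id} on a different "
                    "chromosome or strand"
                )
            tx.validate()

    def all_exons(self) -> list[GenomicInterval]:
        return [iv for tx in self.transcripts for iv in tx.exons]

    def exon_union(self) -> IntervalSet:
        return IntervalSet(self.all_exons())

    def span(self) -> GenomicInterval:
        """The exon hull: from the first to the last exonic base."""
        union = self.exon_union()
        return GenomicInterval(self.chrom, int(union.starts[0]), int(union.ends[-1]), self.strand)


@dataclass
class MergedExon:
    """A per-gene merged exon with its position-in-gene flags."""

    gene_id: str
    interval: GenomicInterval
    is_first: bool
    is_last: bool


def gene_merged_exons(gene: GeneModel) -> list[MergedExon]:
    """Merge exons across isoforms into one interval per exon per gene.

    The 5'-most merged exon is flagged ``is_first`` on the + strand; the
    orientation is reversed on the - strand. A single-exon gene is both.
    """
    gene.validate()
    union = gene.exon_union()
    n = len(union)
    out = []
    for idx, (s, e) in enumerate(union):
        genomic_first = idx == 0
        genomic_last = idx == n - 1
        if gene.strand == "-":
            genomic_first, genomic_last = genomic_last, genomic_first
        out.append(
            MergedExon(
                gene_id=gene.gene_id,
                interval=GenomicInterval(gene.chrom, int(s), int(e), gene.strand),
                is_first=genomic_first,
                is_last=genomic_last,
            )
        )
    return out


def intronic_regions(gene: GeneModel) -> IntervalSet:
    """Purely intronic bases: the exon hull minus exons of ALL isoforms.

    A region that is intronic in one isoform but exonic in another is not
    intronic here.
    """
    gene.validate()
    union = gene.exon_union()
    span = IntervalSet([gene.span()])
    return span.subtract(union)
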