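"""Backsplice-junction reference construction and junction-spanning read mapping.

A backsplice junction joins the 3' end (donor) of a downstream exon to the
5' end (acceptor) of an upstream exon of the same transcript. For every
transcript and every ordered exon pair (acceptor index i <= donor index j in
transcript order, including i = j for single-exon circles) a pseudo-reference
is built: the last k bases of exon j followed by the first k bases of exon i,
both in transcript orientation (k = 30 by default, 60 bp total). Short eCLIP
reads are aligned to these references ungapped with a small mismatch budget;
a read counts only when it spans the junction by at least ``min_span`` bases
on BOTH sides. PCR duplicates are collapsed on (barcode, junction, offset).
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .intervals import TranscriptModel
from .peaks import compute_log2fc

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


class SampleRole(str, Enum):
    IP_REP1 = "IP_rep1"
    IP_REP2 = "IP_rep2"
    INPUT = "input"


@dataclass(frozen=True)
class EclipRead:
    read_id: str
    barcode: str
    sequence: str
    role: SampleRole


@dataclass
class BsjReference:
    """One junction pseudo-sequence; duplicates share a record via junction_ids."""

    junction_ids: list[str]  # transcript_id:donor_exon_index:acceptor_exon_index
    sequence: str
    junction_offset: int  # donor side occupies [0, junction_offset)
    truncated: bool = False

    @property
    def junction_id(self) -> str:
        return self.junction_ids[0]


@dataclass(frozen=True)
class JunctionHit:
    read_id: str
    barcode: str
    role: SampleRole
    junction_id: str
    offset: int
    orientation: str  # "+" read as-is, "-" reverse complement
    mismatches: int


def exon_sequence(tx: TranscriptModel, genome: dict[str, str], exon_index: int) -> str:
    """Sequence of the exon at transcript-order ``exon_index`` (0-based), 5'->3'."""
    iv = tx.sorted_exons()[exon_index]
    seq = genome[iv.chrom][iv.start : iv.end].upper()
    return revcomp(seq) if tx.strand == "-" else seq


def build_bsj_reference(
    transcripts: list[TranscriptModel],
    genome: dict[str, str],
    k: int = 30,
) -> list[BsjReference]:
    """All possible exonic backsplice junctions within each transcript.

    For n exons there are n(n+1)/2 junctions before sequence collapsing.
    Exons shorter than k contribute their full length on that side (no padding
    into introns); such references are flagged truncated. References with
    identical (sequence, junction offset) are collapsed, keeping every source
    junction id.
    """
    by_key: dict[tuple[str, int], BsjReference] = {}
    order: list[tuple[str, int]] = []
    for tx in transcripts:
        n = len(tx.exons)
        seqs = [exon_sequence(tx, genome, idx) for idx in range(n)]
        for i in range(n):  # acceptor
            for j in range(i, n):  # donor
                donor_side = seqs[j][-k:]
                acceptor_side = seqs[i][:k]
                truncated = len(donor_side) < k or len(acceptor_side) < k
                seq = donor_side + acceptor_side
                jid = f"{tx.transcript_id}:{j + 1}:{i + 1}"
                key = (seq, len(donor_side))
                ref = by_key.get(key)
                if ref is None:
                    by_key[key] = BsjReference([jid], seq, len(donor_side), truncated)
                    order.append(key)
                else:
                    ref.junction_ids.append(jid)
    return [by_key[key] for key in order]


def _scan(
    seq: str, ref: BsjReference, max_mismatches: int, min_span: int
) -> list[tuple[int, int]]:
    """(offset, mismatches) for every spanning ungapped placement of seq on ref."""
    L, R = len(seq), len(ref.sequence)
    out = []
    # spanning constraint: offset + L >= junction_offset + min_span and
    # offset <= junction_offset - min_span
    lo = max(0, ref.junction_offset + min_span - L)
    hi = min(R - L, ref.junction_offset - min_span)
    for off in range(lo, hi + 1):
        window = ref.sequence[off : off + L]
        mm = sum(a != b for a, b in zip(seq, window))
        if mm <= max_mismatches:
            out.append((off, mm))
    return out


def map_read(
    read: EclipRead,
    references: list[BsjReference],
    max_mismatches: int = 2,
    min_span: int = 5,
) -> list[JunctionHit]:
    """Ungapped full-read alignment against every reference, both orientations.

    A hit requires the read to cover at least ``min_span`` bases on each side
    of the junction with at most ``max_mismatches`` substitutions. Reads
    shorter than 2*min_span can never span and yield no hits. A read hitting
    several collapsed references is counted once per distinct junction id.
    """
    seq = read.sequence.upper()
    if len(seq) < 2 * min_span:
        return []
    hits: list[JunctionHit] = []
    seen: set[tuple[str, int, str]] = set()
    for orientation, s in (("+", seq), ("-", revcomp(seq))):
        for ref in references:
            for off, mm in _scan(s, ref, max_mismatches, min_span):
                for jid in ref.junction_ids:
                    key = (jid, off, orientation)
                    if key in seen:
                        continue
                    seen.add(key)
                    hits.append(
                        JunctionHit(read.read_id, read.barcode, read.role, jid, off, orientation, mm)
                    )
    return hits


def dedup_reads(hits: list[JunctionHit]) -> list[JunctionHit]:
    """Collapse PCR duplicates: one hit per (role, barcode, junction, offset).

    The representative is the first by read_id order, making the operation
    order-insensitive and idempotent.
    """
    best: dict[tuple, JunctionHit] = {}
    for h in hits:
        key = (h.role, h.barcode, h.junction_id, h.offset, h.orientation)
        cur = best.get(key)
        if cur is None or h.read_id < cur.read_id:
            best[key] = h
    return sorted(best.values(), key=lambda h: (h.junction_id, h.role.value, h.offset, h.read_id))


def junction_counts(dedup: list[JunctionHit]) -> pd.DataFrame:
    """Deduplicated read counts per junction per sample role."""
    rows = [
        {"junction_id": h.junction_id, "role": h.role.value} for h in dedup
    ]
    if not rows:
        return pd.DataFrame(columns=["junction_id", "IP_rep1", "IP_rep2", "input"])
    df = pd.DataFrame(rows)
    counts = df.groupby(["junction_id", "role"]).size().unstack(fill_value=0)
    for role in ("IP_rep1", "IP_rep2", "input"):
        if role not in counts.columns:
            counts[role] = 0
    return counts[["IP_rep1", "IP_rep2", "input"]].reset_index()


def call_junction_sites(
    counts: pd.DataFrame,
    min_reads: int = 10,
    min_log2fc: float = 3.0,
    pseudocount: int = 1,
) -> pd.DataFrame:
    """Junction-level binding calls from deduplicated counts.

    A junction is called when each IP replicate has >= min_reads reads and
    log2((IP_rep + 1) / (input + 1)) >= min_log2fc for BOTH replicates.
    """
    required = {"junction_id", "IP_rep1", "IP_rep2", "input"}
    if not required <= set(counts.columns):
        raise ValueError(f"counts table missing columns {sorted(required - set(counts.columns))}")
    out = counts.copy()
    out["log2fc_rep1"] = [
        compute_log2fc(r, i, pseudocount) for r, i in zip(out["IP_rep1"], out["input"])
    ]
    out["log2fc_rep2"] = [
        compute_log2fc(r, i, pseudocount) for r, i in zip(out["IP_rep2"], out["input"])
    ]
    out["called"] = (
        (out["IP_rep1"] >= min_reads)
        & (out["IP_rep2"] >= min_reads)
        & (out["log2fc_rep1"] >= min_log2fc)
        & (out["log2fc_rep2"] >= min_log2fc)
    )
    return out


def read_fastq_reads(path: str, role: SampleRole) -> list[EclipRead]:
    """FASTQ reader; the barcode is the field after the last ':' in the name."""
    from Bio import SeqIO

    reads = []
    for rec in SeqIO.parse(path, "fastq"):
        barcode = rec.id.rsplit(":", 1)[-1]
        reads.append(EclipRead(rec.id, barcode, str(rec.seq).upper(), role))
    return reads


def references_to_fasta(references: list[BsjReference]) -> dict[str, str]:
    return {ref.junction_id: ref.sequence for ref in references}
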