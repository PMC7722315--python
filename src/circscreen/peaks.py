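"""eCLIP peak filtering into high-confidence RBP binding sites.

A peak survives when it is supported by at least 10 IP reads, its IP/input
log2 fold change is at least 3 (an 8-fold linear enrichment over the
size-matched input), and it is at least 4 bp wide. When the peak table
carries a precomputed log2 fold change it is trusted; otherwise the fold
change is computed from the read counts with a pseudocount of 1.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .intervals import GenomicInterval, IntervalSet
from .io import read_bed6


@dataclass(frozen=True)
class BindingSite:
    rbp_name: str
    cell_line: str
    interval: GenomicInterval
    ip_reads: int
    input_reads: int
    log2fc: float


class SiteLocation(str, Enum):
    EXONIC = "exonic"
    INTRONIC = "intronic"
    EXON_INTRON_BOUNDARY = "exon_intron_boundary"
    OTHER = "other"


def compute_log2fc(
    ip_reads: float,
    input_reads: float,
    pseudocount: float = 1,
    ip_library_size: float | None = None,
    input_library_size: float | None = None,
) -> float:
    """log2((ip + pc) / (input + pc)).

    Counts are scaled to reads-per-million first when library sizes are
    supplied; otherwise raw counts are compared directly.
    """
    if ip_reads < 0 or input_reads < 0:
        raise ValueError("negative read count")
    if (ip_library_size is None) != (input_library_size is None):
        raise ValueError("supply both library sizes or neither")
    if ip_library_size is not None:
        ip_reads = ip_reads * 1e6 / ip_library_size
        input_reads = input_reads * 1e6 / input_library_size
    return math.log2((ip_reads + pseudocount) / (input_reads + pseudocount))


def read_peak_table(path: str | os.PathLike, cell_line: str = "sim") -> pd.DataFrame:
    """BED6+ peak table: chrom start end rbp score strand ip_reads input_reads [log2fc]."""
    first = open(path).readline().rstrip("\n").split("\t")
    extra = ["ip_reads", "input_reads"] + (["log2fc"] if len(first) >= 9 else [])
    df = read_bed6(path, extra_columns=extra)
    df = df.rename(columns={"name": "rbp"})
    df["cell_line"] = cell_line
    return df


def filter_sites(
    peaks: pd.DataFrame,
    min_ip: int = 10,
    min_log2fc: float = 3.0,
    min_width: int = 4,
    cell_line: str = "sim",
) -> list[BindingSite]:
    """Apply the three independent thresholds; output is a subset of the input.

    ``peaks`` rows must carry ip_reads/input_reads or a precomputed log2fc.
    """
    has_fc = "log2fc" in peaks.columns
    has_counts = {"ip_reads", "input_reads"} <= set(peaks.columns)
    if not has_fc and not has_counts:
        raise ValueError("peak table needs ip_reads/input_reads or log2fc")
    out: list[BindingSite] = []
    for row in peaks.itertuples(index=False):
        ip = int(getattr(row, "ip_reads", 0))
        inp = int(getattr(row, "input_reads", 0))
        if has_fc and not pd.isna(getattr(row, "log2fc")):
            fc = float(getattr(row, "log2fc"))
        elif has_counts:
            fc = compute_log2fc(ip, inp)
        else:
            raise ValueError(f"peak {row.chrom}:{row.start}-{row.end} has neither counts nor log2fc")
        width = int(row.end) - int(row.start)
        if ip < min_ip or fc < min_log2fc or width < min_width:
            continue
        out.append(
            BindingSite(
                rbp_name=str(row.rbp),
                cell_line=getattr(row, "cell_line", cell_line),
                interval=GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand),
                ip_reads=ip,
                input_reads=inp,
                log2fc=fc,
            )
        )
    return out


def site_feature_overlaps(
    sites: list[BindingSite],
    features: dict[str, IntervalSet],
    min_overlap: int = 4,
) -> pd.DataFrame:
    """One row per (site, feature) pair overlapping by >= min_overlap bp.

    Short overlaps (< 4 bp by default) are disregarded, as are the sites and
    features they would connect.
    """
    rows = []
    for site in sites:
        for feat_id, featset in features.items():
            ov = featset.overlap_length(site.interval)
            if ov >= min_overlap:
                rows.append(
                    {
                        "rbp": site.rbp_name,
                        "site": str(site.interval),
                        "feature_id": feat_id,
                        "overlap_bp": ov,
                    }
                )
    return pd.DataFrame(rows, columns=["rbp", "site", "feature_id", "overlap_bp"])


def classify_site_location(
    site: BindingSite,
    exons: IntervalSet,
    introns: IntervalSet,
) -> SiteLocation:
    """Locate a binding site relative to a gene's exonic and intronic bases."""
    iv = site.interval
    in_exon = exons.overlap_length(iv) > 0
    in_intron = introns.overlap_length(iv) > 0
    if in_exon and in_intron:
        return SiteLocation.EXON_INTRON_BOUNDARY
    if in_exon:
        return SiteLocation.EXONIC
    if in_intron:
        return SiteLocation.INTRONIC
    return SiteLocation.OTHER


def sites_table(sites: list[BindingSite]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": s.interval.chrom,
                "start": s.interval.start,
                "end": s.interval.end,
                "rbp": s.rbp_name,
                "score": 0,
                "strand": s.interval.strand,
                "ip_reads": s.ip_reads,
                "input_reads": s.input_reads,
                "log2fc": s.log2fc,
                "cell_line": s.cell_line,
            }
            for s in sites
        ]
    )
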