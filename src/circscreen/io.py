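"""Readers and writers for the standard formats the pipeline consumes.

GTF is 1-based closed on disk and converted to 0-based half-open in memory;
BED and all internal coordinates stay 0-based half-open. Tables are
tab-delimited with a header line.
"""

from __future__ import annotations

import os
from typing import Iterable, Mapping

import gffutils
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import GenomicInterval, GeneModel, TranscriptModel

SCHEMA_VERSION = "1"

BED6_COLUMNS = ["chrom", "start", "end", "name", "score", "strand"]


def read_gtf(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models from a GTF file (``exon`` features only).

    Requires gene_id and transcript_id attributes on exon records. Genes whose
    exons fall on more than one chromosome or strand are rejected.
    """
    transcripts: dict[str, TranscriptModel] = {}
    tx_order: list[str] = []
    for feat in gffutils.DataIterator(str(path)):
        if feat.featuretype != "exon":
            continue
        gene_ids = feat.attributes.get("gene_id")
        tx_ids = feat.attributes.get("transcript_id")
        if not gene_ids or not tx_ids:
            raise ValueError(f"exon record without gene_id/transcript_id at {feat.seqid}:{feat.start}")
        gene_id, tx_id = gene_ids[0], tx_ids[0]
        iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        tx = transcripts.get(tx_id)
        if tx is None:
            tx = TranscriptModel(tx_id, gene_id, feat.seqid, feat.strand, [])
            transcripts[tx_id] = tx
            tx_order.append(tx_id)
        tx.exons.append(iv)

    genes: dict[str, GeneModel] = {}
    gene_order: list[str] = []
    for tx_id in tx_order:
        tx = transcripts[tx_id]
        gene = genes.get(tx.gene_id)
        if gene is None:
            gene = GeneModel(tx.gene_id, tx.chrom, tx.strand, [])
            genes[tx.gene_id] = gene
            gene_order.append(tx.gene_id)
        if tx.chrom != gene.chrom or tx.strand != gene.strand:
            raise ValueError(
                f"gene {tx.gene_id} has transcripts on multiple chromosomes or strands"
            )
        gene.transcripts.append(tx)
    out = [genes[g] for g in gene_order]
    for gene in out:
        gene.validate()
    return out


def write_gtf(genes: Iterable[GeneModel], path: str | os.PathLike, source: str = "circscreen") -> None:
    """Write gene/transcript/exon records, converting back to 1-based closed."""
    with open(path, "w") as fh:
        for gene in genes:
            span = gene.span()
            fh.write(
                f"{gene.chrom}\t{source}\tgene\t{span.start + 1}\t{span.end}\t.\t"
                f'{gene.strand}\t.\tgene_id "{gene.gene_id}";\n'
            )
            for tx in gene.transcripts:
                exs = sorted(tx.exons, key=lambda iv: iv.start)
                fh.write(
                    f"{gene.chrom}\t{source}\ttranscript\t{exs[0].start + 1}\t{exs[-1].end}\t.\t"
                    f'{gene.strand}\t.\tgene_id "{gene.gene_id}"; transcript_id "{tx.transcript_id}";\n'
                )
                for iv in exs:
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{iv.start + 1}\t{iv.end}\t.\t"
                        f'{gene.strand}\t.\tgene_id "{gene.gene_id}"; '
                        f'transcript_id "{tx.transcript_id}";\n'
                    )


def read_bed6(path: str | os.PathLike, extra_columns: list[str] | None = None) -> pd.DataFrame:
    """Read BED6 (plus optional extra columns) into a DataFrame.

    Accepts files with or without a header line starting with the column names.
    """
    cols = BED6_COLUMNS + (extra_columns or [])
    first = open(path).readline()
    header = 0 if first.split("\t")[0] == "chrom" else None
    df = pd.read_csv(path, sep="\t", header=header, names=cols, dtype={"chrom": str})
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    if (df["start"] >= df["end"]).any():
        bad = df[df["start"] >= df["end"]].iloc[0]
        raise ValueError(f"invalid BED interval {bad['chrom']}:{bad['start']}-{bad['end']}")
    return df


def write_bed6(df: pd.DataFrame, path: str | os.PathLike) -> None:
    cols = [c for c in df.columns if c in BED6_COLUMNS] + [
        c for c in df.columns if c not in BED6_COLUMNS
    ]
    df[cols].to_csv(path, sep="\t", index=False)


def write_table(df: pd.DataFrame, path: str | os.PathLike) -> None:
    """Tab-delimited table with a schema-version comment and a header line."""
    with open(path, "w") as fh:
        fh.write(f"# circscreen table schema_version={SCHEMA_VERSION}\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def read_table(path: str | os.PathLike) -> pd.DataFrame:
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#"):
            version = dict(
                kv.split("=") for kv in first.lstrip("# ").split() if "=" in kv
            ).get("schema_version")
            if version != SCHEMA_VERSION:
                raise ValueError(f"unknown table schema version {version!r}")
            return pd.read_csv(fh, sep="\t")
    return pd.read_csv(path, sep="\t")


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(seqs: Mapping[str, str], path: str | os.PathLike) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    SeqIO.write(records, str(path), "fasta")


def read_expression_table(path: str | os.PathLike) -> dict[str, float]:
    """gene_id -> FPKM."""
    df = read_table(path)
    if not {"gene_id", "fpkm"} <= set(df.columns):
        raise ValueError("expression table must have gene_id and fpkm columns")
    return dict(zip(df["gene_id"], df["fpkm"].astype(float)))
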