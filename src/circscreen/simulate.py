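"""Synthetic data generator with known ground truth.

Every pipeline input is emulated at desk scale: a random genome with
multi-isoform gene models, two circRNA caller tables with a consensus subset
and a planted highly-expressed subset, eCLIP peak tables with planted
coverage enrichment in circularizing exons, a flank-binding RBP (KHSRP-role)
with sites planted in both introns flanking a target circRNA subset,
inverted-Alu placements, knockdown/control count matrices with a planted
expression decrease on the flanked subset, junction-spanning eCLIP reads,
and localization/GO tables with one planted enriched term.

Planted effect sizes mirror the biology the screen is designed to detect: a
3x binding-site density multiplier in circularizing exons, a 0.85x (15%
decrease) knockdown effect on flanked circRNAs, and 20-25 bp junction reads.
All draws flow from one seeded generator; a fixed seed gives byte-identical
output files.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .bsjmap import BsjReference, EclipRead, SampleRole
from .intervals import GenomicInterval, GeneModel, TranscriptModel, gene_merged_exons, intronic_regions

BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for the synthetic screen. Defaults are the conditions
    all tests and analyses run under; sizes are desk-scale."""

    seed: int = 0
    chrom: str = "chrS"
    n_genes: int = 80
    exons_per_gene: tuple[int, int] = (4, 7)
    exon_length: tuple[int, int] = (150, 350)
    intron_length: tuple[int, int] = (300, 1500)
    intergenic_length: tuple[int, int] = (500, 2000)
    isoform2_fraction: float = 0.5  # genes with a second, exon-skipping isoform
    fpkm_sigma: float = 2.3  # log-normal sd in ln units: ~4 orders of magnitude span
    # circRNAs
    n_circ_genes: int = 20
    circ_top_fraction: float = 0.25  # consensus circRNAs planted as highly expressed
    n_discordant_calls: int = 6  # calls failing the 2-read consensus in exactly one caller
    # eCLIP
    n_rbps: int = 8
    enriched_rbps: tuple[str, ...] | None = None  # None = first half of the non-flank RBPs
    baseline_exon_density: float = 1.5  # sites per kb per RBP
    baseline_intron_density: float = 0.15
    circ_exon_multiplier: float = 3.0
    site_width: tuple[int, int] = (20, 60)
    filter_fail_fraction: float = 0.15  # sites emitted below an eCLIP filter threshold
    # flanking biogenesis
    flank_rbp: str = "KHSRP"
    flank_target_fraction: float = 0.6  # of consensus circRNAs get both-flank sites
    flank_background_rate: float = 0.02  # intronic background density of the flank RBP (per kb)
    iralu_fraction: float = 0.4  # of flanked circRNAs get an inverted Alu pair
    alu_background_per_gene: float = 1.0
    # knockdown
    kd_effect: float = 0.85  # 15% decrease on the flanked subset
    kd_samples: int = 3
    kd_mean_count: float = 400.0
    kd_dispersion: float = 0.005  # low dispersion: var = mu + disp * mu^2
    library_size: float = 1.0e6
    # BSJ reads
    bsj_k: int = 30
    read_length: tuple[int, int] = (20, 25)
    junction_ip_reads: tuple[int, int] = (15, 31)  # floor passes >=10 reads and log2((15+1)/(1+1))=3
    junction_input_reads: tuple[int, int] = (0, 2)
    n_planted_junctions: int = 6
    n_subthreshold_junctions: int = 3
    duplicate_rate: float = 0.3
    error_rate: float = 0.0
    # GO / localization
    n_go_terms: int = 6
    planted_go_term: str = "GO:RNA_STAB"  # regulation of mRNA stability role

    def __post_init__(self) -> None:
        if not 0 < self.kd_effect <= 1:
            raise ValueError("kd_effect must be in (0, 1]")
        if self.circ_exon_multiplier <= 0:
            raise ValueError("multiplier must be positive")

    def rbp_names(self) -> list[str]:
        names = [f"RBP{i + 1:02d}" for i in range(self.n_rbps - 1)]
        return names + [self.flank_rbp]

    def enriched(self) -> set[str]:
        if self.enriched_rbps is None:
            non_flank = [r for r in self.rbp_names() if r != self.flank_rbp]
            return set(non_flank[: self.n_rbps // 2])
        return set(self.enriched_rbps)


@dataclass
class GroundTruth:
    circ_gene_ids: list[str] = field(default_factory=list)
    consensus_circ_ids: list[str] = field(default_factory=list)
    top_circ_ids: list[str] = field(default_factory=list)
    enriched_rbps: list[str] = field(default_factory=list)
    flanked_circ_ids: list[str] = field(default_factory=list)
    iralu_circ_ids: list[str] = field(default_factory=list)
    kd_effect: float = 1.0
    planted_go_term: str = ""
    planted_junction_ids: list[str] = field(default_factory=list)
    subthreshold_junction_ids: list[str] = field(default_factory=list)


@dataclass
class SimulatedDataset:
    config: SimulationConfig
    genes: list[GeneModel]
    genome: dict[str, str] | None
    fpkm: dict[str, float]
    calls_a: pd.DataFrame
    calls_b: pd.DataFrame
    peaks: pd.DataFrame
    alus: pd.DataFrame
    kd_counts: pd.DataFrame
    kd_library_sizes: pd.Series
    kd_conditions: pd.Series
    localization_circ: dict[str, set[str]]
    localization_rbp: dict[str, set[str]]
    go_annotations: pd.DataFrame
    truth: GroundTruth


def simulate_annotation(
    config: SimulationConfig, rng: np.random.Generator, with_sequence: bool = True
) -> tuple[list[GeneModel], dict[str, str] | None, dict[str, float]]:
    """Random non-overlapping multi-isoform gene models plus log-normal FPKM."""
    genes: list[GeneModel] = []
    pos = int(rng.integers(*config.intergenic_length))
    for g in range(config.n_genes):
        gene_id = f"G{g + 1:03d}"
        strand = "+" if rng.random() < 0.5 else "-"
        n_exons = int(rng.integers(config.exons_per_gene[0], config.exons_per_gene[1] + 1))
        exons = []
        for e in range(n_exons):
            length = int(rng.integers(*config.exon_length))
            exons.append(GenomicInterval(config.chrom, pos, pos + length, strand))
            pos += length
            if e < n_exons - 1:
                pos += int(rng.integers(*config.intron_length))
        tx1 = TranscriptModel(f"{gene_id}.T1", gene_id, config.chrom, strand, list(exons))
        if strand == "-":
            tx1.exons = list(exons)  # genomic order kept; sorted_exons handles orientation
        transcripts = [tx1]
        if n_exons >= 4 and rng.random() < config.isoform2_fraction:
            skip = int(rng.integers(1, n_exons - 1))  # skip one internal exon
            tx2_exons = [iv for k, iv in enumerate(exons) if k != skip]
            transcripts.append(
                TranscriptModel(f"{gene_id}.T2", gene_id, config.chrom, strand, tx2_exons)
            )
        gene = GeneModel(gene_id, config.chrom, strand, transcripts)
        genes.append(gene)
        pos += int(rng.integers(*config.intergenic_length))

    fpkm = {
        g.gene_id: float(np.exp(rng.normal(1.0, config.fpkm_sigma))) for g in genes
    }
    for g in genes:
        g.fpkm = fpkm[g.gene_id]

    genome = None
    if with_sequence:
        genome = {config.chrom: "".join(rng.choice(BASES, size=pos + 100))}
    return genes, genome, fpkm


def simulate_circ_calls(
    config: SimulationConfig,
    genes: list[GeneModel],
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Two caller tables with a consensus subset and planted top expression.

    One circRNA is placed per circ-gene, spanning internal merged exons so
    both flanking introns exist; a known subset gets BSJ counts above the
    top-percentile boundary; ``n_discordant_calls`` extra junctions fail the
    2-read floor in exactly one caller.
    """
    truth = GroundTruth(kd_effect=config.kd_effect, planted_go_term=config.planted_go_term)
    eligible = [g for g in genes if len(gene_merged_exons(g)) >= 4]
    circ_genes = list(rng.choice(len(eligible), size=config.n_circ_genes, replace=False))
    rows_a, rows_b = [], []
    consensus: list[tuple[str, int]] = []
    for gi in circ_genes:
        gene = eligible[gi]
        mes = gene_merged_exons(gene)
        internal = [me for me in mes if not (me.is_first or me.is_last)]
        i = int(rng.integers(0, len(internal)))
        j = int(rng.integers(i, len(internal)))
        start = internal[i].interval.start
        end = internal[j].interval.end
        circ_id = f"{gene.chrom}:{start}-{end}"
        truth.circ_gene_ids.append(gene.gene_id)
        consensus.append((circ_id, gi))
        rows_a.append(
            {"chrom": gene.chrom, "start": start, "end": end, "strand": gene.strand,
             "bsj_reads": 0, "linear_reads": int(rng.poisson(30)), "gene_id": gene.gene_id}
        )
        rows_b.append({"chrom": gene.chrom, "start": start, "end": end,
                       "strand": gene.strand, "bsj_reads": 0, "linear_reads": 0})

    # counts: planted top subset sits strictly above the rest
    n_top = max(1, int(np.ceil(config.circ_top_fraction * len(rows_a))))
    order = rng.permutation(len(rows_a))
    top_idx = set(order[:n_top].tolist())
    for idx, row in enumerate(rows_a):
        if idx in top_idx:
            reads = int(rng.integers(400, 1000))
        else:
            reads = int(rng.integers(2, 60))
        row["bsj_reads"] = reads
        rows_b[idx]["bsj_reads"] = max(2, int(rng.binomial(reads, 0.8)))
        cid = f"{row['chrom']}:{row['start']}-{row['end']}"
        truth.consensus_circ_ids.append(cid)
        if idx in top_idx:
            truth.top_circ_ids.append(cid)

    # discordant calls: drop below the consensus floor in exactly one caller
    other = [g for g in genes if g.gene_id not in set(truth.circ_gene_ids)]
    for d in range(config.n_discordant_calls):
        gene = other[int(rng.integers(0, len(other)))]
        mes = gene_merged_exons(gene)
        me = mes[int(rng.integers(0, len(mes)))]
        row = {"chrom": gene.chrom, "start": me.interval.start, "end": me.interval.end,
               "strand": gene.strand, "linear_reads": int(rng.poisson(10)),
               "gene_id": gene.gene_id}
        if any(r["start"] == row["start"] and r["end"] == row["end"] for r in rows_a):
            continue
        fail_in_a = d % 2 == 0
        rows_a.append({**row, "bsj_reads": 1 if fail_in_a else int(rng.integers(2, 20))})
        rows_b.append({"chrom": row["chrom"], "start": row["start"], "end": row["end"],
                       "strand": row["strand"], "linear_reads": 0,
                       "bsj_reads": int(rng.integers(2, 20)) if fail_in_a else 1})

    # choose the flanked target subset here so downstream generators
    # (peaks, knockdown) agree on it without depending on each other
    n_target = int(round(config.flank_target_fraction * len(truth.consensus_circ_ids)))
    target_order = rng.permutation(len(truth.consensus_circ_ids))
    truth.flanked_circ_ids = sorted(
        np.asarray(truth.consensus_circ_ids)[target_order[:n_target]].tolist()
    )

    calls_a = pd.DataFrame(rows_a)
    calls_b = pd.DataFrame(rows_b)
    return calls_a, calls_b, truth


def _poisson_sites(
    rng: np.random.Generator,
    region: GenomicInterval,
    density_per_kb: float,
    width_range: tuple[int, int],
) -> list[tuple[int, int]]:
    n = rng.poisson(density_per_kb * region.length / 1000.0)
    out = []
    for _ in range(n):
        w = int(rng.integers(*width_range))
        s = int(rng.integers(region.start, max(region.start + 1, region.end - w // 2)))
        out.append((s, s + w))
    return out


def simulate_eclip_peaks(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Peak table with planted circ-exon enrichment and both-flank sites.

    Sites follow a Poisson process at the baseline density on exons and
    introns; on exons inside circRNA spans of circ-genes the density is
    multiplied by ``circ_exon_multiplier`` for enriched RBPs. The flank RBP
    additionally gets a site planted in each intronic flank of the target
    circRNA subset. A ``filter_fail_fraction`` of sites is emitted below one
    of the eCLIP thresholds and must be removed by filtering.
    """
    circ_spans: dict[str, list[tuple[int, int]]] = {}
    for cid, gid in zip(truth.consensus_circ_ids, truth.circ_gene_ids):
        start, end = map(int, cid.split(":")[1].split("-"))
        circ_spans.setdefault(gid, []).append((start, end))

    enriched = config.enriched()
    truth.enriched_rbps = sorted(enriched)
    rows = []

    def emit(rbp: str, s: int, e: int, strand: str, force_pass: bool = False) -> None:
        failing = (not force_pass) and rng.random() < config.filter_fail_fraction
        if failing:
            mode = rng.integers(0, 3)
            if mode == 0:
                ip, inp = int(rng.integers(1, 10)), 0  # IP-read floor
            elif mode == 1:
                ip, inp = int(rng.integers(20, 40)), int(rng.integers(10, 20))  # fold change
            else:
                ip, inp = int(rng.integers(15, 40)), int(rng.integers(0, 2))
                e = s + int(rng.integers(2, 4))  # width floor
        else:
            ip = int(rng.integers(15, 60))
            inp = int(rng.integers(0, 2))
        rows.append({"chrom": config.chrom, "start": s, "end": e, "rbp": rbp,
                     "score": 0, "strand": strand, "ip_reads": ip, "input_reads": inp})

    for gene in genes:
        mes = gene_merged_exons(gene)
        introns = intronic_regions(gene)
        spans = circ_spans.get(gene.gene_id, [])
        for rbp in config.rbp_names():
            for me in mes:
                in_circ = any(
                    cs <= me.interval.start and me.interval.end <= ce for cs, ce in spans
                ) or any(
                    me.interval.start == cs or me.interval.end == ce for cs, ce in spans
                )
                mult = config.circ_exon_multiplier if (in_circ and rbp in enriched) else 1.0
                for s, e in _poisson_sites(
                    rng, me.interval, config.baseline_exon_density * mult, config.site_width
                ):
                    emit(rbp, s, e, gene.strand)
            density = (
                config.baseline_intron_density
                if rbp != config.flank_rbp
                else config.flank_background_rate
            )
            for iv in introns.intervals(gene.strand):
                for s, e in _poisson_sites(rng, iv, density, config.site_width):
                    emit(rbp, s, e, gene.strand)

    # planted both-flank sites of the flank RBP on the target subset
    targets = truth.flanked_circ_ids
    gene_by_id = {g.gene_id: g for g in genes}
    gid_by_cid = dict(zip(truth.consensus_circ_ids, truth.circ_gene_ids))
    for cid in targets:
        start, end = map(int, cid.split(":")[1].split("-"))
        gene = gene_by_id[gid_by_cid[cid]]
        introns = intronic_regions(gene)
        for flank_side in ("up", "down"):
            window = (
                GenomicInterval(config.chrom, max(0, start - 10_000), start)
                if flank_side == "up"
                else GenomicInterval(config.chrom, end, end + 10_000)
            )
            candidates = [
                (max(s, window.start), min(e, window.end))
                for s, e in introns
                if min(e, window.end) - max(s, window.start) >= 80
            ]
            if not candidates:
                continue
            s0, e0 = candidates[int(rng.integers(0, len(candidates)))]
            w = int(rng.integers(*config.site_width))
            s = int(rng.integers(s0, max(s0 + 1, e0 - w)))
            emit(config.flank_rbp, s, s + w, gene.strand, force_pass=True)

    df = pd.DataFrame(rows).sort_values(["start", "end", "rbp"], kind="stable")
    return df.reset_index(drop=True)


def simulate_alus(
    config: SimulationConfig,
    genes: list[GeneModel],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Alu BED6: background intronic Alus plus planted inverted pairs.

    A configurable fraction of the flanked circRNA subset gets an Alu in each
    flanking intron on opposite strands (the inverted-repeat configuration).
    """
    rows = []
    gene_by_id = {g.gene_id: g for g in genes}
    gid_by_cid = dict(
        zip(truth.consensus_circ_ids, truth.circ_gene_ids)
    )
    n_iralu = int(round(config.iralu_fraction * len(truth.flanked_circ_ids)))
    iralu_ids = truth.flanked_circ_ids[:n_iralu]
    truth.iralu_circ_ids = list(iralu_ids)
    alu_no = 0
    for cid in iralu_ids:
        start, end = map(int, cid.split(":")[1].split("-"))
        gene = gene_by_id[gid_by_cid[cid]]
        introns = intronic_regions(gene)
        up_strand = "+" if rng.random() < 0.5 else "-"
        for window, strand in (
            (GenomicInterval(config.chrom, max(0, start - 10_000), start), up_strand),
            (GenomicInterval(config.chrom, end, end + 10_000), "-" if up_strand == "+" else "+"),
        ):
            candidates = [
                (max(s, window.start), min(e, window.end))
                for s, e in introns
                if min(e, window.end) - max(s, window.start) >= 350
            ]
            if not candidates:
                continue
            s0, e0 = candidates[int(rng.integers(0, len(candidates)))]
            s = int(rng.integers(s0, e0 - 300))
            alu_no += 1
            rows.append({"chrom": config.chrom, "start": s, "end": s + 300,
                         "name": f"AluY_{alu_no}", "score": 0, "strand": strand})
    for gene in genes:
        for iv in intronic_regions(gene).intervals():
            if iv.length < 350 or rng.random() > config.alu_background_per_gene / 4:
                continue
            s = int(rng.integers(iv.start, iv.end - 300))
            alu_no += 1
            rows.append({"chrom": config.chrom, "start": s, "end": s + 300,
                         "name": f"AluSx_{alu_no}", "score": 0,
                         "strand": "+" if rng.random() < 0.5 else "-"})
    return pd.DataFrame(rows).sort_values(["start", "end"], kind="stable").reset_index(drop=True)


def simulate_kd_counts(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    """Negative-binomial KD/control counts; the flanked subset is scaled by
    ``kd_effect`` in KD samples only."""
    circ_ids = truth.consensus_circ_ids
    flanked = set(truth.flanked_circ_ids)
    base_mu = config.kd_mean_count * np.exp(rng.normal(0.0, 0.25, size=len(circ_ids)))
    samples = [f"KD_{i + 1}" for i in range(config.kd_samples)] + [
        f"ctrl_{i + 1}" for i in range(config.kd_samples)
    ]
    conditions = pd.Series(
        ["KD"] * config.kd_samples + ["control"] * config.kd_samples, index=samples
    )
    lib = pd.Series(
        config.library_size * np.exp(rng.normal(0.0, 0.05, size=len(samples))), index=samples
    )
    disp = config.kd_dispersion
    r = 1.0 / disp
    data = {}
    for s in samples:
        mu = base_mu.copy() * (lib[s] / config.library_size)
        if conditions[s] == "KD":
            mask = np.array([cid in flanked for cid in circ_ids])
            mu[mask] *= config.kd_effect
        p = r / (r + mu)
        data[s] = rng.negative_binomial(r, p)
    counts = pd.DataFrame(data, index=pd.Index(circ_ids, name="circ_id"))
    return counts, lib, conditions


def simulate_bsj_reads(
    config: SimulationConfig,
    references: list[BsjReference],
    truth: GroundTruth,
    rng: np.random.Generator,
) -> list[EclipRead]:
    """Junction-spanning eCLIP reads for both IP replicates and the input.

    Planted junctions get per-replicate deduplicated counts inside
    ``junction_ip_reads`` with near-zero input, so they pass the calling
    thresholds; sub-threshold junctions get < 10 reads per replicate. PCR
    duplicates are emitted at ``duplicate_rate`` on top of the unique reads.
    """
    usable = [
        ref
        for ref in references
        if not ref.truncated and len(ref.sequence) == 2 * config.bsj_k
    ]
    order = rng.permutation(len(usable))
    n_planted = min(config.n_planted_junctions, len(usable))
    planted = [usable[i] for i in order[:n_planted]]
    sub = [
        usable[i]
        for i in order[n_planted : n_planted + config.n_subthreshold_junctions]
    ]
    truth.planted_junction_ids = [ref.junction_id for ref in planted]
    truth.subthreshold_junction_ids = [ref.junction_id for ref in sub]

    reads: list[EclipRead] = []
    counter = 0

    def emit_reads(ref: BsjReference, role: SampleRole, n: int) -> None:
        nonlocal counter
        min_span = 5
        for _ in range(n):
            counter += 1
            L = int(rng.integers(config.read_length[0], config.read_length[1] + 1))
            lo = max(0, ref.junction_offset + min_span - L)
            hi = min(len(ref.sequence) - L, ref.junction_offset - min_span)
            off = int(rng.integers(lo, hi + 1))
            seq = ref.sequence[off : off + L]
            if config.error_rate > 0:
                chars = list(seq)
                for k in range(len(chars)):
                    if rng.random() < config.error_rate:
                        chars[k] = str(rng.choice([b for b in "ACGT" if b != chars[k]]))
                seq = "".join(chars)
            barcode = "".join(rng.choice(BASES, size=8))
            rid = f"read{counter:06d}:{barcode}"
            reads.append(EclipRead(rid, barcode, seq, role))
            if rng.random() < config.duplicate_rate:
                counter += 1
                reads.append(EclipRead(f"read{counter:06d}:{barcode}", barcode, seq, role))

    for ref in planted:
        for role in (SampleRole.IP_REP1, SampleRole.IP_REP2):
            emit_reads(ref, role, int(rng.integers(*config.junction_ip_reads)))
        emit_reads(ref, SampleRole.INPUT, int(rng.integers(*config.junction_input_reads)))
    for ref in sub:
        for role in (SampleRole.IP_REP1, SampleRole.IP_REP2):
            emit_reads(ref, role, int(rng.integers(2, 9)))
        emit_reads(ref, SampleRole.INPUT, int(rng.integers(0, 2)))
    return reads


def simulate_localization(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> tuple[dict[str, set[str]], dict[str, set[str]]]:
    """Subcellular compartments: circRNAs all cytoplasmic (a known property of
    circRNAs), a subset also nuclear; RBPs mostly in both compartments, a
    small fraction nucleus-only (the source of non-colocalized pairs)."""
    circ_loc = {}
    for cid in truth.consensus_circ_ids:
        comps = {"cytoplasm"}
        if rng.random() < 0.6:
            comps.add("nucleus")
        circ_loc[cid] = comps
    rbp_loc = {}
    for rbp in config.rbp_names():
        u = rng.random()
        if u < 0.60:
            rbp_loc[rbp] = {"cytoplasm", "nucleus"}
        elif u < 0.94:
            rbp_loc[rbp] = {"cytoplasm"}
        else:
            rbp_loc[rbp] = {"nucleus"}
    return circ_loc, rbp_loc


def simulate_go_annotations(
    config: SimulationConfig, truth: GroundTruth, rng: np.random.Generator
) -> pd.DataFrame:
    """GO table (rbp, go_term, domain) with one planted enriched term.

    The planted term annotates every enriched RBP (plus at most one
    background RBP); the other terms are spread uniformly.
    """
    rbps = config.rbp_names()
    enriched = sorted(truth.enriched_rbps) if truth.enriched_rbps else sorted(
        config.enriched()
    )
    rows = [
        {"rbp": rbp, "go_term": config.planted_go_term, "domain": "BP"}
        for rbp in enriched
    ]
    background = [r for r in rbps if r not in set(enriched)]
    if background:
        rows.append({"rbp": background[0], "go_term": config.planted_go_term, "domain": "BP"})
    for t in range(config.n_go_terms - 1):
        term = f"GO:TERM{t + 1:02d}"
        domain = ["BP", "MF", "CC"][t % 3]
        for rbp in rbps:
            if rng.random() < 0.35:
                rows.append({"rbp": rbp, "go_term": term, "domain": domain})
    return pd.DataFrame(rows).sort_values(["go_term", "rbp"], kind="stable").reset_index(drop=True)


def simulate_all(config: SimulationConfig, with_sequence: bool = True) -> SimulatedDataset:
    """Run every generator off one seeded stream and bundle the dataset."""
    rng = np.random.default_rng(config.seed)
    genes, genome, fpkm = simulate_annotation(config, rng, with_sequence=with_sequence)
    calls_a, calls_b, truth = simulate_circ_calls(config, genes, rng)
    peaks = simulate_eclip_peaks(config, genes, truth, rng)
    alus = simulate_alus(config, genes, truth, rng)
    kd_counts, kd_lib, kd_cond = simulate_kd_counts(config, truth, rng)
    circ_loc, rbp_loc = simulate_localization(config, truth, rng)
    go = simulate_go_annotations(config, truth, rng)
    return SimulatedDataset(
        config=config,
        genes=genes,
        genome=genome,
        fpkm=fpkm,
        calls_a=calls_a,
        calls_b=calls_b,
        peaks=peaks,
        alus=alus,
        kd_counts=kd_counts,
        kd_library_sizes=kd_lib,
        kd_conditions=kd_cond,
        localization_circ=circ_loc,
        localization_rbp=rbp_loc,
        go_annotations=go,
        truth=truth,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | os.PathLike) -> dict[str, str]:
    """Write every input file a pipeline run consumes; returns name -> path."""
    from . import io as cio

    outdir = os.fspath(outdir)
    os.makedirs(outdir, exist_ok=True)
    paths = {}

    def p(name: str) -> str:
        paths[name] = os.path.join(outdir, name)
        return paths[name]

    cio.write_gtf(ds.genes, p("annotation.gtf"))
    if ds.genome is not None:
        cio.write_fasta(ds.genome, p("genome.fa"))
    cio.write_table(
        pd.DataFrame(
            {"gene_id": list(ds.fpkm), "fpkm": [ds.fpkm[g] for g in ds.fpkm]}
        ),
        p("expression.tsv"),
    )
    ds.calls_a.to_csv(p("caller_a.tsv"), sep="\t", index=False)
    ds.calls_b.to_csv(p("caller_b.tsv"), sep="\t", index=False)
    cio.write_bed6(ds.peaks.rename(columns={"rbp": "name"}), p("eclip_peaks.tsv"))
    cio.write_bed6(ds.alus, p("alu.bed"))
    ds.kd_counts.to_csv(p("kd_counts.tsv"), sep="\t")
    pd.DataFrame(
        {"sample": ds.kd_library_sizes.index,
         "library_size": ds.kd_library_sizes.values,
         "condition": ds.kd_conditions[ds.kd_library_sizes.index].values}
    ).to_csv(p("kd_samples.tsv"), sep="\t", index=False)
    loc_rows = [
        {"entity": cid, "kind": "circRNA", "compartments": ",".join(sorted(c))}
        for cid, c in ds.localization_circ.items()
    ] + [
        {"entity": rbp, "kind": "RBP", "compartments": ",".join(sorted(c))}
        for rbp, c in ds.localization_rbp.items()
    ]
    pd.DataFrame(loc_rows).to_csv(p("localization.tsv"), sep="\t", index=False)
    ds.go_annotations.to_csv(p("go_annotations.tsv"), sep="\t", index=False)
    with open(p("ground_truth.json"), "w") as fh:
        json.dump(dataclasses.asdict(ds.truth), fh, indent=1, sort_keys=True)
    return paths
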