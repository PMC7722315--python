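"""Pipeline orchestration: staged runs over a run directory with manifests.

Each stage reads its inputs from the run directory, writes its outputs there,
and records a manifest (config hash, seed, input checksums, package version).
Reruns with identical inputs and seed are byte-identical. Threshold defaults
are the screen's published operating points; the desk-scale helper tightens
only the scale parameters (bin count, top fraction) to match the synthetic
dataset size.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import os
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import __version__
from . import io as cio
from .bsjmap import (SampleRole, build_bsj_reference, call_junction_sites, dedup_reads,
                     junction_counts, map_read, read_fastq_reads, references_to_fasta)
from .catalog import (CircRNACall, ExonCategory, assign_host_genes, catalog_table,
                      categorize_exons, circ_exonic_parts, consensus_catalog,
                      read_caller_table, top_percentile)
from .coverage import (exon_category_coverage, expression_bins, host_gene_enrichment,
                       matched_resample, per_rbp_differential_binding, rbp_coverage)
from .flanking import (both_flank_presence, flank_enrichment_test, flank_pair,
                       iralu_both_flanks, kd_group_compare, rpm_normalize)
from .intervals import IntervalSet, gene_merged_exons, intronic_regions
from .peaks import filter_sites, read_peak_table, sites_table
from .simulate import SimulationConfig, simulate_all, simulate_bsj_reads, write_dataset
from .stats import colocalization_fraction, go_enrichment

log = logging.getLogger("circscreen")

STAGES = ("simulate", "catalog", "coverage", "flanks", "bsjmap", "enrich", "report")


@dataclass(frozen=True)
class PipelineConfig:
    """Thresholds default to the screen's published operating points."""

    seed: int = 0
    consensus_min_reads: int = 2
    top_fraction: float = 0.01
    min_ip_reads: int = 10
    min_log2fc: float = 3.0
    min_site_width: int = 4
    min_overlap: int = 4
    flank_width: int = 10_000
    n_bins: int = 100
    iterations: int = 100
    bsj_k: int = 30
    max_mismatches: int = 2
    min_span: int = 5
    min_rbp_sites: int = 20
    fdr: float = 0.1
    caller_a_coords: str = "bed"
    caller_b_coords: str = "bed"

    def __post_init__(self) -> None:
        if not 0 < self.top_fraction <= 1:
            raise ValueError(f"top_fraction must be in (0, 1], got {self.top_fraction}")
        if self.consensus_min_reads < 0 or self.min_ip_reads < 0:
            raise ValueError("read thresholds must be non-negative")
        if self.n_bins < 1 or self.iterations < 1:
            raise ValueError("n_bins and iterations must be positive")
        if self.min_span < 1 or self.bsj_k < self.min_span:
            raise ValueError("need 1 <= min_span <= bsj_k")
        if not 0 < self.fdr < 1:
            raise ValueError("fdr must be in (0, 1)")


def desk_scale_config(seed: int = 0, **overrides) -> PipelineConfig:
    """Published thresholds with scale parameters sized for the synthetic data:
    10 expression bins over 80 genes and a 25% top fraction over ~20 circRNAs."""
    defaults = dict(seed=seed, n_bins=10, top_fraction=0.25)
    defaults.update(overrides)
    return PipelineConfig(**defaults)


def config_hash(cfg) -> str:
    payload = json.dumps(dataclasses.asdict(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _checksum(path: str) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def _require(rundir: str, *names: str) -> list[str]:
    paths = []
    for name in names:
        path = os.path.join(rundir, name)
        if not os.path.exists(path):
            raise FileNotFoundError(f"stage input missing: {path}")
        paths.append(path)
    return paths


def _write_manifest(rundir: str, stage: str, cfg: PipelineConfig, inputs: list[str],
                    outputs: list[str]) -> None:
    manifest = {
        "stage": stage,
        "version": __version__,
        "seed": cfg.seed,
        "config_hash": config_hash(cfg),
        "inputs": {os.path.basename(p): _checksum(p) for p in sorted(inputs)},
        "outputs": {os.path.basename(p): _checksum(p) for p in sorted(outputs)},
    }
    with open(os.path.join(rundir, f"manifest_{stage}.json"), "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def stage_simulate(cfg: PipelineConfig, rundir: str,
                   sim_config: SimulationConfig | None = None) -> dict[str, str]:
    """Generate every pipeline input under the run directory."""
    os.makedirs(rundir, exist_ok=True)
    sim = sim_config or SimulationConfig(seed=cfg.seed)
    ds = simulate_all(sim)
    paths = write_dataset(ds, rundir)
    # junction-spanning reads for the circ-gene transcripts
    circ_genes = [g for g in ds.genes if g.gene_id in set(ds.truth.circ_gene_ids)]
    transcripts = [g.transcripts[0] for g in circ_genes[:4]]
    refs = build_bsj_reference(transcripts, ds.genome, k=sim.bsj_k)
    rng = np.random.default_rng(sim.seed + 1)
    reads = simulate_bsj_reads(sim, refs, ds.truth, rng)
    cio.write_fasta(references_to_fasta(refs), os.path.join(rundir, "bsj_reference.fa"))
    for role in SampleRole:
        path = os.path.join(rundir, f"eclip_reads_{role.value}.fastq")
        with open(path, "w") as fh:
            for r in reads:
                if r.role == role:
                    fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{'I' * len(r.sequence)}\n")
        paths[os.path.basename(path)] = path
    with open(os.path.join(rundir, "ground_truth.json"), "w") as fh:
        json.dump(dataclasses.asdict(ds.truth), fh, indent=1, sort_keys=True)
    _write_manifest(rundir, "simulate", cfg, [], sorted(paths.values()))
    log.info("simulate: %d genes, %d caller-A calls", len(ds.genes), len(ds.calls_a))
    return paths


def _load_catalog(cfg: PipelineConfig, rundir: str) -> tuple[list[CircRNACall], list]:
    gtf, ca, cb = _require(rundir, "annotation.gtf", "caller_a.tsv", "caller_b.tsv")
    genes = cio.read_gtf(gtf)
    fpkm = cio.read_expression_table(os.path.join(rundir, "expression.tsv"))
    for g in genes:
        g.fpkm = fpkm.get(g.gene_id, 0.0)
    calls_a = read_caller_table(ca, coords=cfg.caller_a_coords)
    calls_b = read_caller_table(cb, coords=cfg.caller_b_coords)
    catalog = consensus_catalog(calls_a, calls_b, min_reads=cfg.consensus_min_reads)
    assign_host_genes(catalog, genes)
    return catalog, genes


def stage_catalog(cfg: PipelineConfig, rundir: str) -> pd.DataFrame:
    """Consensus catalog + top-percentile set."""
    catalog, genes = _load_catalog(cfg, rundir)
    merged = {g.gene_id: gene_merged_exons(g) for g in genes}
    table = catalog_table(catalog, merged)
    top = top_percentile(catalog, cfg.top_fraction)
    table["in_top_set"] = table["circRNA_ID"].isin({c.circ_id for c in top})
    out = os.path.join(rundir, "catalog.tsv")
    cio.write_table(table, out)
    _write_manifest(rundir, "catalog", cfg,
                    _require(rundir, "caller_a.tsv", "caller_b.tsv"), [out])
    log.info("catalog: %d consensus circRNAs, %d in top set", len(table), len(top))
    return table


def stage_coverage(cfg: PipelineConfig, rundir: str) -> dict[str, pd.DataFrame]:
    """Coverage of circRNAs and exon categories, enrichment ratios,
    expression-matched resampling, per-RBP differential binding."""
    catalog, genes = _load_catalog(cfg, rundir)
    peaks_path = _require(rundir, "eclip_peaks.tsv")[0]
    peaks = read_peak_table(peaks_path)
    sites = filter_sites(peaks, cfg.min_ip_reads, cfg.min_log2fc, cfg.min_site_width)

    merged = {g.gene_id: gene_merged_exons(g) for g in genes}
    top = top_percentile(catalog, cfg.top_fraction)
    exons = categorize_exons([me for mes in merged.values() for me in mes], catalog)

    # per-circRNA coverage + host-gene enrichment (supplementary-table schema)
    merged_cov = exon_category_coverage(exons, sites, min_overlap=cfg.min_overlap)
    cov_by_exon = dict(zip(merged_cov["exon"], merged_cov["coverage_pct"]))
    rows = []
    for circ in top:
        parts, has_exons = circ_exonic_parts(circ, merged.get(circ.host_gene, []))
        if not has_exons:
            rows.append({"circRNA_ID": circ.circ_id, "host_gene": circ.host_gene or "NA",
                         "exonic_length": 0, "RBP_overlap_bp": 0, "RBP_coverage": np.nan,
                         "N_non_circ_exon_host_gene": 0,
                         "mean_RBP_coverage_non_circ_exons": np.nan,
                         "Ratio_RBP_coverage_circRNA_non_circ_exons": np.nan})
            continue
        cov = rbp_coverage(circ.circ_id, parts, sites, min_overlap=cfg.min_overlap)
        host_noncirc = [
            er for er in exons
            if er.gene_id == circ.host_gene and er.is_internal
            and er.category is ExonCategory.NON_CIRC_EXON
        ]
        noncirc_cov = [
            rbp_coverage(str(er.interval), IntervalSet([er.interval]), sites,
                         min_overlap=cfg.min_overlap)
            for er in host_noncirc
        ]
        enr = host_gene_enrichment(cov, noncirc_cov)
        rows.append({
            "circRNA_ID": circ.circ_id,
            "host_gene": circ.host_gene or "NA",
            "exonic_length": cov.exonic_length,
            "RBP_overlap_bp": cov.covered_bp,
            "RBP_coverage": cov.coverage_pct,
            "N_non_circ_exon_host_gene": len(host_noncirc),
            "mean_RBP_coverage_non_circ_exons": (
                enr.mean_noncirc_coverage_pct if enr.mean_noncirc_coverage_pct is not None
                else np.nan
            ),
            "Ratio_RBP_coverage_circRNA_non_circ_exons": enr.ratio,
        })
    circ_table = pd.DataFrame(rows)

    # expression-matched resampling of BSJ circ-exon coverage
    fpkm = {g.gene_id: g.fpkm for g in genes}
    bins = expression_bins(fpkm, n_bins=cfg.n_bins)
    circ_gene_ids = {c.host_gene for c in catalog if c.host_gene}
    top_gene_ids = {c.host_gene for c in top if c.host_gene}
    obs = merged_cov[
        (merged_cov["category"] == ExonCategory.BSJ_CIRC_EXON.value)
        & merged_cov["gene_id"].isin(top_gene_ids)
        & merged_cov["gene_id"].map(lambda g: g in bins)
    ]
    pool = merged_cov[
        (merged_cov["category"] == ExonCategory.NON_CIRC_EXON.value)
        & merged_cov["is_internal"]
        & ~merged_cov["gene_id"].isin(circ_gene_ids)
        & merged_cov["gene_id"].map(lambda g: g in bins)
    ].copy()
    pool["bin"] = pool["gene_id"].map(bins)
    rng = np.random.default_rng(cfg.seed + 17)
    res = matched_resample(
        obs["coverage_pct"].to_numpy(),
        [bins[g] for g in obs["gene_id"]],
        pool,
        iterations=cfg.iterations,
        rng=rng,
    )
    resample_table = pd.DataFrame({
        "iteration": np.arange(1, cfg.iterations + 1),
        "resampled_mean_coverage": res.resampled_means,
    })
    resample_summary = pd.DataFrame([{
        "observed_mean_coverage": res.observed_mean_coverage,
        "empirical_p": res.empirical_p,
        "n_observed_exons": len(obs),
        "with_replacement_bins": ",".join(map(str, res.with_replacement_bins)) or "none",
    }])

    # per-RBP differential binding within circ-genes
    per_rbp_cov = exon_category_coverage(
        [er for er in exons if er.gene_id in circ_gene_ids],
        sites, min_overlap=cfg.min_overlap, by_rbp=True,
    )
    site_counts = pd.Series([s.rbp_name for s in sites]).value_counts().to_dict()
    diff = per_rbp_differential_binding(
        per_rbp_cov, site_counts, min_sites=cfg.min_rbp_sites, fdr_threshold=cfg.fdr
    )

    outputs = {}
    for name, df in (("circ_coverage.tsv", circ_table),
                     ("resampling.tsv", resample_table),
                     ("resampling_summary.tsv", resample_summary),
                     ("rbp_differential_binding.tsv", diff),
                     ("filtered_sites.tsv", sites_table(sites))):
        path = os.path.join(rundir, name)
        cio.write_table(df, path)
        outputs[name] = path
    _write_manifest(rundir, "coverage", cfg, [peaks_path], sorted(outputs.values()))
    log.info("coverage: %d filtered sites, resampling p=%.4f",
             len(sites), res.empirical_p)
    return {"circ_coverage": circ_table, "resampling_summary": resample_summary,
            "rbp_differential_binding": diff}


def stage_flanks(cfg: PipelineConfig, rundir: str) -> dict[str, pd.DataFrame]:
    """Both-flank RBP and inverted-Alu enrichment; knockdown comparison."""
    catalog, genes = _load_catalog(cfg, rundir)
    peaks_path, alu_path, counts_path, samples_path = _require(
        rundir, "eclip_peaks.tsv", "alu.bed", "kd_counts.tsv", "kd_samples.tsv")
    peaks = read_peak_table(peaks_path)
    sites = filter_sites(peaks, cfg.min_ip_reads, cfg.min_log2fc, cfg.min_site_width)
    alus = cio.read_bed6(alu_path)

    merged = {g.gene_id: gene_merged_exons(g) for g in genes}
    introns = {g.gene_id: intronic_regions(g) for g in genes}
    exons = categorize_exons([me for mes in merged.values() for me in mes], catalog)
    circ_gene_ids = {c.host_gene for c in catalog if c.host_gene}

    # flank pairs: circRNAs, and internal non-circ-exons of expressed circ-producing genes
    expressed = {g.gene_id for g in genes if g.fpkm > 0}
    circ_pairs = [
        (c.circ_id, flank_pair(c.interval, introns[c.host_gene], cfg.flank_width))
        for c in catalog if c.host_gene
    ]
    # control group: internal non-circ-exons of all expressed genes; first/last
    # exons (not intron-flanked on both sides) and circRNA exons are excluded
    exon_pairs = [
        (str(er.interval), flank_pair(er.interval, introns[er.gene_id], cfg.flank_width))
        for er in exons
        if er.is_internal and er.category is ExonCategory.NON_CIRC_EXON
        and er.gene_id in expressed
    ]
    sites_by_rbp: dict[str, list] = {}
    for s in sites:
        sites_by_rbp.setdefault(s.rbp_name, []).append(s)

    rbp_rows = []
    flag_tables: dict[str, pd.DataFrame] = {}
    for rbp in sorted(sites_by_rbp):
        ssites = sites_by_rbp[rbp]
        circ_flags = np.array([both_flank_presence(p, ssites) for _, p in circ_pairs])
        exon_flags = np.array([both_flank_presence(p, ssites) for _, p in exon_pairs])
        fold, chi2, p = flank_enrichment_test(circ_flags, exon_flags)
        rbp_rows.append({
            "rbp": rbp,
            "circ_both_flank_fraction": float(circ_flags.mean()) if len(circ_flags) else np.nan,
            "non_circ_exon_both_flank_fraction": float(exon_flags.mean()) if len(exon_flags) else np.nan,
            "fold": fold, "chi2": chi2, "p": p,
        })
        flag_tables[rbp] = pd.DataFrame({
            "feature_id": [fid for fid, _ in circ_pairs],
            "both_flanks": circ_flags,
        })
    flank_table = pd.DataFrame(rbp_rows)

    iralu_flags = pd.DataFrame({
        "circ_id": [fid for fid, _ in circ_pairs],
        "iralu_both_flanks": [iralu_both_flanks(p, alus) for _, p in circ_pairs],
    })

    # knockdown comparison in RPM, split on the flank RBP's both-flank status
    counts = pd.read_csv(counts_path, sep="\t", index_col=0)
    samples = pd.read_csv(samples_path, sep="\t")
    lib = pd.Series(samples["library_size"].values, index=samples["sample"])
    conditions = pd.Series(samples["condition"].values, index=samples["sample"])
    rpm = rpm_normalize(counts, lib)
    flank_rbp = flank_table.sort_values("fold", ascending=False)["rbp"].iloc[0] \
        if len(flank_table) else None
    kd_rows = []
    if flank_rbp is not None:
        flags = flag_tables[flank_rbp].set_index("feature_id")["both_flanks"]
        flagged = [c for c in rpm.index if flags.get(c, False)]
        unflagged = [c for c in rpm.index if not flags.get(c, False)]
        for label, subset in (("all", list(rpm.index)),
                              (f"{flank_rbp}_both_flanks", flagged),
                              ("complement", unflagged)):
            if not subset:
                continue
            for test in ("t", "wilcoxon"):
                result = kd_group_compare(rpm, conditions, subset, test=test)
                kd_rows.append({"subset": label, **result})
    kd_table = pd.DataFrame(kd_rows)

    outputs = {}
    for name, df in (("flank_enrichment.tsv", flank_table),
                     ("iralu_flags.tsv", iralu_flags),
                     ("kd_comparison.tsv", kd_table)):
        path = os.path.join(rundir, name)
        cio.write_table(df, path)
        outputs[name] = path
    _write_manifest(rundir, "flanks", cfg,
                    [peaks_path, alu_path, counts_path], sorted(outputs.values()))
    return {"flank_enrichment": flank_table, "iralu_flags": iralu_flags,
            "kd_comparison": kd_table}


def stage_bsjmap(cfg: PipelineConfig, rundir: str) -> pd.DataFrame:
    """Map junction-spanning reads against the BSJ reference and call sites."""
    fa, gtf = _require(rundir, "genome.fa", "annotation.gtf")
    genome = cio.read_fasta(fa)
    ref_path = os.path.join(rundir, "bsj_reference.fa")
    if os.path.exists(ref_path):
        # reuse the emitted reference set (keeps mapping consistent with simulation)
        ref_seqs = cio.read_fasta(ref_path)
        from .bsjmap import BsjReference
        refs = [BsjReference([jid], seq, cfg.bsj_k) for jid, seq in ref_seqs.items()]
    else:
        genes = cio.read_gtf(gtf)
        transcripts = [tx for g in genes for tx in g.transcripts]
        refs = build_bsj_reference(transcripts, genome, k=cfg.bsj_k)
    hits = []
    inputs = [fa, gtf]
    for role in SampleRole:
        path = os.path.join(rundir, f"eclip_reads_{role.value}.fastq")
        if not os.path.exists(path):
            raise FileNotFoundError(f"stage input missing: {path}")
        inputs.append(path)
        for read in read_fastq_reads(path, role):
            hits.extend(map_read(read, refs, cfg.max_mismatches, cfg.min_span))
    dedup = dedup_reads(hits)
    counts = junction_counts(dedup)
    calls = call_junction_sites(counts, min_reads=cfg.min_ip_reads,
                                min_log2fc=cfg.min_log2fc)
    out = os.path.join(rundir, "bsj_junction_calls.tsv")
    cio.write_table(calls, out)
    _write_manifest(rundir, "bsjmap", cfg, inputs, [out])
    log.info("bsjmap: %d dedup hits, %d called junctions", len(dedup), int(calls["called"].sum()))
    return calls


def stage_enrich(cfg: PipelineConfig, rundir: str) -> dict[str, pd.DataFrame]:
    """GO enrichment of differentially binding RBPs + co-localization."""
    diff_path, go_path, loc_path, cov_path = _require(
        rundir, "rbp_differential_binding.tsv", "go_annotations.tsv",
        "localization.tsv", "filtered_sites.tsv")
    diff = cio.read_table(diff_path)
    go = pd.read_csv(go_path, sep="\t")
    loc = pd.read_csv(loc_path, sep="\t")
    sites = cio.read_table(cov_path)
    catalog, genes = _load_catalog(cfg, rundir)
    merged = {g.gene_id: gene_merged_exons(g) for g in genes}

    all_rbps = set(sites["rbp"])
    subset = set(diff.loc[diff["significant"] & (
        diff["mean_coverage_bsj_circ_exon"] > diff["mean_coverage_non_circ_exon"]), "rbp"])
    go_table = go_enrichment(subset, all_rbps, go) if subset else pd.DataFrame()

    # interactions: top circRNA x RBP pairs with a >= min_overlap site overlap
    top = top_percentile(catalog, cfg.top_fraction)
    interactions = []
    for circ in top:
        parts, has_exons = circ_exonic_parts(circ, merged.get(circ.host_gene, []))
        if not has_exons:
            continue
        for row in sites.itertuples(index=False):
            from .intervals import GenomicInterval
            iv = GenomicInterval(row.chrom, int(row.start), int(row.end), row.strand)
            if parts.overlap_length(iv) >= cfg.min_overlap:
                interactions.append((circ.circ_id, row.rbp))
    interactions = sorted(set(interactions))
    circ_loc = {r.entity: set(str(r.compartments).split(","))
                for r in loc.itertuples(index=False) if r.kind == "circRNA"}
    rbp_loc = {r.entity: set(str(r.compartments).split(","))
               for r in loc.itertuples(index=False) if r.kind == "RBP"}
    pct, resolved, unresolved = colocalization_fraction(interactions, circ_loc, rbp_loc)
    coloc = pd.DataFrame([{
        "n_interactions": len(interactions), "n_resolved": resolved,
        "n_unresolved": unresolved, "colocalized_pct": pct,
    }])

    outputs = {}
    for name, df in (("go_enrichment.tsv", go_table), ("colocalization.tsv", coloc)):
        path = os.path.join(rundir, name)
        cio.write_table(df, path)
        outputs[name] = path
    _write_manifest(rundir, "enrich", cfg, [diff_path, go_path, loc_path],
                    sorted(outputs.values()))
    return {"go_enrichment": go_table, "colocalization": coloc}


def stage_report(cfg: PipelineConfig, rundir: str) -> dict:
    """Gather the headline numbers of a run into report.json."""
    report: dict = {"seed": cfg.seed, "config_hash": config_hash(cfg)}
    catalog = cio.read_table(os.path.join(rundir, "catalog.tsv"))
    report["n_consensus_circRNAs"] = int(len(catalog))
    report["n_top_set"] = int(catalog["in_top_set"].sum())
    rs = cio.read_table(os.path.join(rundir, "resampling_summary.tsv"))
    report["resampling_empirical_p"] = float(rs["empirical_p"].iloc[0])
    report["observed_mean_bsj_exon_coverage"] = float(rs["observed_mean_coverage"].iloc[0])
    diff = cio.read_table(os.path.join(rundir, "rbp_differential_binding.tsv"))
    report["n_rbps_differential"] = int(diff["significant"].sum()) if len(diff) else 0
    flank = cio.read_table(os.path.join(rundir, "flank_enrichment.tsv"))
    if len(flank):
        best = flank.sort_values("fold", ascending=False).iloc[0]
        report["top_flank_rbp"] = str(best["rbp"])
        report["top_flank_fold"] = float(best["fold"])
        report["top_flank_p"] = float(best["p"])
    kd = cio.read_table(os.path.join(rundir, "kd_comparison.tsv"))
    for row in kd.itertuples(index=False):
        if row.test == "t":
            report[f"kd_relative_change_{row.subset}"] = float(row.relative_change)
            report[f"kd_p_{row.subset}"] = float(row.p)
    calls = cio.read_table(os.path.join(rundir, "bsj_junction_calls.tsv"))
    report["n_bsj_junctions_called"] = int(calls["called"].sum()) if len(calls) else 0
    coloc = cio.read_table(os.path.join(rundir, "colocalization.tsv"))
    report["colocalized_pct"] = float(coloc["colocalized_pct"].iloc[0])
    go = cio.read_table(os.path.join(rundir, "go_enrichment.tsv"))
    if len(go):
        top_term = go.sort_values(["p", "go_term"]).iloc[0]
        report["top_go_term"] = str(top_term["go_term"])
        report["top_go_fold"] = float(top_term["fold"])
    with open(os.path.join(rundir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True)
    return report


def run_stage(stage: str, cfg: PipelineConfig, rundir: str):
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    fn = {
        "simulate": stage_simulate,
        "catalog": stage_catalog,
        "coverage": stage_coverage,
        "flanks": stage_flanks,
        "bsjmap": stage_bsjmap,
        "enrich": stage_enrich,
        "report": stage_report,
    }[stage]
    return fn(cfg, rundir)


def run_all(cfg: PipelineConfig, rundir: str,
            sim_config: SimulationConfig | None = None) -> dict:
    stage_simulate(cfg, rundir, sim_config)
    for stage in STAGES[1:-1]:
        run_stage(stage, cfg, rundir)
    return stage_report(cfg, rundir)
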