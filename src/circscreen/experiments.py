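"""In-memory planted-effect experiments over the synthetic screen.

These functions run single-seed replicates of the screen's core statistical
procedures directly on in-memory simulated data (no files), so calibration
and power studies over many generator seeds stay cheap. They are used by the
analysis drivers and the acceptance checks alike.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .catalog import (ExonCategory, assign_host_genes, categorize_exons,
                      consensus_catalog, top_percentile)
from .coverage import exon_category_coverage, expression_bins, matched_resample
from .flanking import both_flank_presence, flank_enrichment_test, flank_pair, kd_group_compare, rpm_normalize
from .intervals import gene_merged_exons, intronic_regions
from .peaks import filter_sites
from .simulate import (SimulationConfig, simulate_annotation, simulate_circ_calls,
                       simulate_eclip_peaks, simulate_kd_counts)


def _sim_config(seed: int, **overrides) -> SimulationConfig:
    base = SimulationConfig(seed=seed)
    return dataclasses.replace(base, **overrides) if overrides else base


def _catalog_and_exons(config, genes, calls_a, calls_b):
    catalog = consensus_catalog(calls_a, calls_b)
    assign_host_genes(catalog, genes)
    merged = [me for g in genes for me in gene_merged_exons(g)]
    exons = categorize_exons(merged, catalog)
    return catalog, exons


def resampling_experiment(
    seed: int,
    multiplier: float = 3.0,
    n_bins: int = 10,
    iterations: int = 100,
    **sim_overrides,
) -> dict:
    """One replicate of the expression-matched resampling screen.

    The multiplier is applied for every RBP (the experiment's condition is the
    circ-exon site density relative to the pool); the observed statistic is
    the mean merged-RBP coverage of BSJ circ-exons of genes producing highly
    expressed circRNAs, resampled against internal non-circ-exons of genes
    not producing circRNAs, matched on expression bin.
    """
    config = _sim_config(seed, circ_exon_multiplier=multiplier, **sim_overrides)
    config = dataclasses.replace(config, enriched_rbps=tuple(config.rbp_names()))
    rng = np.random.default_rng(config.seed)
    genes, _, fpkm = simulate_annotation(config, rng, with_sequence=False)
    calls_a, calls_b, truth = simulate_circ_calls(config, genes, rng)
    peaks = simulate_eclip_peaks(config, genes, truth, rng)
    sites = filter_sites(peaks)
    catalog, exons = _catalog_and_exons(config, genes, calls_a, calls_b)
    cov = exon_category_coverage(exons, sites)

    bins = expression_bins(fpkm, n_bins=n_bins)
    top = top_percentile(catalog, config.circ_top_fraction)
    top_genes = {c.host_gene for c in top if c.host_gene}
    circ_genes = {c.host_gene for c in catalog if c.host_gene}
    obs = cov[
        (cov["category"] == ExonCategory.BSJ_CIRC_EXON.value)
        & cov["gene_id"].isin(top_genes)
        & cov["gene_id"].isin(bins)
    ]
    pool = cov[
        (cov["category"] == ExonCategory.NON_CIRC_EXON.value)
        & cov["is_internal"]
        & ~cov["gene_id"].isin(circ_genes)
        & cov["gene_id"].isin(bins)
    ].copy()
    pool["bin"] = pool["gene_id"].map(bins)
    res = matched_resample(
        obs["coverage_pct"].to_numpy(),
        [bins[g] for g in obs["gene_id"]],
        pool,
        iterations=iterations,
        rng=np.random.default_rng(config.seed + 1_000_003),
    )
    return {
        "seed": seed,
        "multiplier": multiplier,
        "observed_mean_coverage": res.observed_mean_coverage,
        "null_mean_coverage": float(res.resampled_means.mean()),
        "empirical_p": res.empirical_p,
        "n_observed_exons": int(len(obs)),
        "n_pool_exons": int(len(pool)),
    }


def kd_experiment(seed: int, **sim_overrides) -> dict:
    """One replicate of the knockdown comparison on ground-truth subsets.

    Both-flank (truth-flanked) circRNAs carry the planted expression decrease
    in KD samples; the complement is a true null. Welch t-test on per-sample
    total RPM over each subset.
    """
    config = _sim_config(seed, **sim_overrides)
    rng = np.random.default_rng(config.seed)
    genes, _, _ = simulate_annotation(config, rng, with_sequence=False)
    _, _, truth = simulate_circ_calls(config, genes, rng)
    counts, lib, conditions = simulate_kd_counts(config, truth, rng)
    rpm = rpm_normalize(counts, lib)
    flanked = truth.flanked_circ_ids
    complement = [c for c in truth.consensus_circ_ids if c not in set(flanked)]
    out = {"seed": seed, "effect": config.kd_effect}
    for label, subset in (("flanked", flanked), ("complement", complement)):
        res = kd_group_compare(rpm, conditions, subset, test="t")
        out[f"{label}_relative_change"] = res["relative_change"]
        out[f"{label}_p"] = res["p"]
        out[f"{label}_n"] = res["n_circ"]
    return out


def flank_experiment(seed: int, flank_width: int = 10_000, **sim_overrides) -> dict:
    """One replicate of the both-flank chi-square enrichment for the flank RBP.

    Group A: consensus circRNAs; group B: internal non-circ-exons of expressed
    genes (first/last and circRNA exons excluded).
    """
    config = _sim_config(seed, **sim_overrides)
    rng = np.random.default_rng(config.seed)
    genes, _, _ = simulate_annotation(config, rng, with_sequence=False)
    calls_a, calls_b, truth = simulate_circ_calls(config, genes, rng)
    peaks = simulate_eclip_peaks(config, genes, truth, rng)
    sites = [s for s in filter_sites(peaks) if s.rbp_name == config.flank_rbp]
    catalog, exons = _catalog_and_exons(config, genes, calls_a, calls_b)
    introns = {g.gene_id: intronic_regions(g) for g in genes}

    circ_flags = np.array([
        both_flank_presence(
            flank_pair(c.interval, introns[c.host_gene], flank_width), sites
        )
        for c in catalog if c.host_gene
    ])
    exon_flags = np.array([
        both_flank_presence(
            flank_pair(er.interval, introns[er.gene_id], flank_width), sites
        )
        for er in exons
        if er.is_internal and er.category is ExonCategory.NON_CIRC_EXON
    ])
    fold, chi2, p = flank_enrichment_test(circ_flags, exon_flags)
    flagged = {
        c.circ_id
        for c, f in zip([c for c in catalog if c.host_gene], circ_flags)
        if f
    }
    truth_flanked = set(truth.flanked_circ_ids)
    return {
        "seed": seed,
        "fold": fold,
        "chi2": chi2,
        "p": p,
        "circ_both_flank_fraction": float(circ_flags.mean()),
        "exon_both_flank_fraction": float(exon_flags.mean()),
        "recall_planted": len(flagged & truth_flanked) / len(truth_flanked),
        "n_false_flagged": len(flagged - truth_flanked),
    }


def type_i_error_study(seed: int = 0, n_reps: int = 2000, alpha: float = 0.05) -> dict:
    """Null rejection rates for the four shared test kernels.

    Instances are sized so the discrete tests operate in their asymptotic
    regime (binomial n=200 margins for the 2x2 tests, 30 per group for the
    rank test, 10 per group for the t-test): at toy sizes the Yates-corrected
    chi-square and the one-tailed Fisher are conservative by construction and
    their rejection rate says nothing about implementation correctness.
    """
    from .stats import (ContingencyTable2x2, chi_square_2x2, fisher_one_tailed,
                        welch_t_test, wilcoxon_rank_sum)

    rng = np.random.default_rng(seed)
    n_tab = 200
    a = rng.binomial(n_tab, 0.3, n_reps)
    c = rng.binomial(n_tab, 0.3, n_reps)
    rej_chi = rej_fisher = 0
    for ai, ci in zip(a, c):
        table = ContingencyTable2x2(int(ai), n_tab - int(ai), int(ci), n_tab - int(ci))
        if chi_square_2x2(table)[1] < alpha:
            rej_chi += 1
        if fisher_one_tailed(table) < alpha:
            rej_fisher += 1
    xw = rng.normal(size=(n_reps, 30))
    yw = rng.normal(size=(n_reps, 30))
    rej_wilcoxon = sum(wilcoxon_rank_sum(x, y) < alpha for x, y in zip(xw, yw))
    xt = rng.normal(size=(n_reps, 10))
    yt = rng.normal(size=(n_reps, 10))
    rej_welch = sum(welch_t_test(x, y)[1] < alpha for x, y in zip(xt, yt))
    return {
        "n_reps": n_reps,
        "alpha": alpha,
        "chi_square_2x2": rej_chi / n_reps,
        "fisher_one_tailed": rej_fisher / n_reps,
        "wilcoxon_rank_sum": rej_wilcoxon / n_reps,
        "welch_t_test": rej_welch / n_reps,
    }
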