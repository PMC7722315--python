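# Methods

## Scope and model

`circscreen` treats a circRNA as a backsplice junction: an interval on a
chromosome whose start is the acceptor and whose end is the donor coordinate,
supported by reads spanning the non-colinear junction. All genomic
arithmetic is done in 0-based half-open coordinates (BED convention); GTF
input is converted on read and back on write. Interval set algebra (merge /
intersect / subtract) follows `bedtools` semantics — bookended intervals
merge at distance 0, half-open adjacency does not intersect — and is
verified against a per-base set oracle on random instances. Strand is
carried but ignored by the set algebra, which is only ever applied within a
gene; it matters for first/last-exon orientation, host-gene assignment, and
inverted-*Alu* orientation.

Gene structure is reduced to merged exons: exons of all isoforms of a gene
are unioned into one interval per exon per gene, and intronic bases are the
gene's exon hull minus that union — a region exonic in any isoform is never
intronic. The exon hull (first to last exonic base) is used as the gene span
for intron derivation; annotation `gene` features can extend beyond exons
and would otherwise contribute spurious "introns" at the gene ends. The
5′-most merged exon is the first exon on the + strand, the 3′-most on −;
first/last status is decided after isoform merging, since the downstream
exclusion rules are phrased per gene, not per transcript.

Exons are categorized against the circRNA catalog with a precedence rule:
an exon whose boundary coincides exactly (tolerance 0 by default; callers
report splice-site-exact coordinates) with a backsplice coordinate of any
same-gene circRNA is a BSJ circ-exon even if it is internal to some other
circRNA; an exon fully inside a circRNA span is a circ-exon; everything
else is a non-circ-exon. Host genes are assigned by maximal exonic base
overlap, strand-matched when the circRNA strand is known, ties broken by
gene id.

## Thresholds and parameters

All operating points default to the screen's published values and are
collected in `PipelineConfig`:

| parameter | default | meaning |
|---|---|---|
| consensus_min_reads | 2 | BSJ reads required in each caller |
| top_fraction | 0.01 | highly expressed set, size ⌈f·N⌉ |
| min_ip_reads | 10 | eCLIP peak IP-read floor (pooled) |
| min_log2fc | 3.0 | IP vs size-matched input, 8-fold linear |
| min_site_width / min_overlap | 4 / 4 bp | site and site–feature floors |
| flank_width | 10,000 bp | window on each side of a feature |
| n_bins / iterations | 100 / 100 | expression bins, resampling repeats |
| bsj_k / max_mismatches / min_span | 30 bp / 2 / 5 bp | junction reference and mapping |
| min_rbp_sites | 20 | per-RBP differential-binding floor |
| fdr | 0.1 | Benjamini–Hochberg significance level |

Ambiguities resolved as package choices: the ≥10-read floor for genomic
peaks is applied to the pooled count (the per-replicate rule is enforced
only in the junction-read procedure, where it is explicit); ties at the
top-percentile boundary are broken by including all tied junctions and
truncating in lexicographic circ-id order; "spanning by ≥ 5 bp" means ≥ 5 bp
on *each* side of the junction, so every counted read genuinely crosses it;
the junction fold-change condition is applied per IP replicate against the
single input; flank windows are not truncated at neighboring genes — only
the restriction to intronic bases applies; an inverted-*Alu* pair is an
*Alu* in each flank on opposite strands (the standard inverted-repeat
criterion; the flag is symmetric under a global strand swap); "total
expression" of a circRNA subset is the per-sample sum of RPM over the
subset (the per-circRNA mean is emitted alongside); per-category "mean
coverage" averages per-exon percentages rather than pooling base counts.
The chi-square control group is internal non-circularizing exons of all
expressed genes, with first/last exons (not intron-flanked on both sides)
and exons found in circRNAs removed.

## Statistical kernels

The 2×2 chi-square uses the Yates continuity correction with the |O−E|−0.5
term capped at zero (matching R's default behavior for 2×2 tables, under
which the original analysis was run), df = 1. Fisher's exact test is
one-tailed on the hypergeometric support. The Wilcoxon rank-sum p-value is
exact when min(n) ≤ 25 and there are no ties, otherwise the normal
approximation with tie and continuity corrections. The t-test is Welch's,
with Satterthwaite degrees of freedom. Benjamini–Hochberg adjustment is the
step-up rule, capped at 1 and monotone. The empirical p-value uses the
add-one estimator p = (1 + #{resampled ≥ observed})/(1 + B), which cannot
reach 0 with finite resamples (floor 1/101 at B = 100). Every kernel is
tested against an independent enumeration or closed-form oracle, and their
type-I error is checked at α = 0.05 over 2,000 null replicates. The null
instances for that calibration are deliberately moderately sized (binomial
n = 200 margins for the 2×2 tests, 30 per group for the rank test, 10 per
group for the t-test): discrete tests are conservative by construction at
toy sizes, and a rejection rate near nominal is only informative in the
asymptotic regime.

Expression-matched resampling draws, per expression bin, as many pool exons
as the observed group contributes to that bin, so each draw reproduces the
observed bin histogram and the observed and resampled means average the
same number of exons. Draws are without replacement within a bin when the
pool suffices, with replacement (flagged in the output) otherwise. Bins are
quantile bins over expressed genes (FPKM > 0) with a gene-id tie-break, so
the assignment is deterministic under ties.

## Junction-spanning read mapping

The reference set contains one 2k-mer per transcript exon pair (i ≤ j,
including i = j for single-exon circles): the last k bases of the donor
exon followed by the first k bases of the acceptor exon, in transcript
orientation. Exons shorter than k contribute their full length (no padding
into introns) and the reference is flagged truncated. Identical (sequence,
junction-offset) references are collapsed, retaining all source junction
ids. Alignment is ungapped — at 20–25 bp reads with a 2-mismatch budget,
indel alignments are not meaningful — full-read, both orientations, and a
read hitting several collapsed references counts once per distinct
junction id. Deduplication keeps one read per (sample, barcode, junction,
offset, orientation), first by read id, which makes it idempotent and
order-insensitive. Counts are raw deduplicated counts; no library-size
normalization is applied at this stage.

## Synthetic data

The generator emulates every input of the screen at desk scale with known
ground truth: 80 non-overlapping genes (4–7 exons of 150–350 bp, introns
300–1500 bp) on one synthetic chromosome, half of them with an
exon-skipping second isoform; log-normal FPKM spanning over four orders of
magnitude; 20 circRNA-producing genes with one circRNA each placed on
internal merged-exon boundaries, a planted top quartile of highly expressed
circRNAs, and six discordant calls that fail the two-read consensus in
exactly one caller. Eight RBPs place binding sites as a Poisson process
(1.5 sites/kb/RBP on exons, chosen so the planted 3× multiplier is
recoverable per RBP at this exon count; 0.15/kb in introns), with the
multiplier applied to circularizing exons for the enriched subset (default:
half the RBPs; the resampling calibration/power experiments set all RBPs
enriched, since their condition is the overall circ-exon density relative
to the pool). A KHSRP-role flank RBP gets a site planted in each intronic
flank of a 60% target subset of circRNAs over a low 0.02/kb intronic
background; 40% of those also get an opposite-strand *Alu* pair.
Knockdown counts are negative binomial (variance μ + 0.005 μ², "low
dispersion") with the flanked subset scaled by 0.85 in KD samples only —
a 15% decrease, the biogenesis effect size the screen is designed to
detect — in 3 + 3 samples at ~10⁶ library size. Junction reads are 20–25 bp
copies of reference sequence with spans ≥ 5 bp, random 8-mer barcodes, a
0.3 PCR-duplicate rate, and per-replicate deduplicated counts drawn from
[15, 31) against input ≤ 1, the minimum that passes the calling thresholds
by construction; sub-threshold junctions get < 10 reads. Localization
tables make all circRNAs cytoplasmic (60% also nuclear) and RBPs mostly
dual-compartment with a small nucleus-only fraction, and the GO table
annotates one planted term on the enriched RBPs.

All draws flow from a single seeded `numpy` generator; a fixed seed gives
byte-identical output files, which the pipeline's manifests (config hash,
seed, input/output checksums) make checkable per stage.

What the generator does *not* emulate — realistic sequence composition and
motifs, crosslink-position biases, overlapping genes, isoform-level
expression, dispersion heterogeneity, batch effects — bounds what passing
tests show: they demonstrate that the screen's statistics are implemented
correctly, calibrated under their nulls, and able to recover planted
effects of the stated sizes at desk scale, not that the screen would make
the same calls on real ENCODE-scale data.

## Desk-scale analysis settings

The analysis drivers and the end-to-end pipeline runs use the published
thresholds with two scale parameters sized to the synthetic data
(`desk_scale_config`): 10 expression bins over 80 genes (100 bins require
more genes than the simulation carries) and a 0.25 top fraction over ~20
consensus circRNAs (so the highly expressed set contains 5 circRNAs rather
than 1). With only ~7 BSJ circ-exons in the observed group, the
default-configuration resampling has moderate power — individual seeds can
miss — whereas the all-RBPs-enriched condition used in the calibration and
power studies detects the 3× density in ≈99/100 seeds while keeping the
null fraction of p ≤ 0.1 near 10%.

## Known limitations

Exact-coordinate consensus matching will under-merge callers that round
splice sites differently (a tolerance knob exists but defaults to 0).
Host-gene assignment picks a single gene; fusion or read-through contexts
are out of scope. The per-RBP differential-binding test treats exons as
independent sampling units, ignoring within-gene correlation. The
knockdown comparison is a group-mean test in RPM, not a dispersion-modeling
differential expression analysis. The junction mapper is exhaustive rather
than indexed and is intended for reference sets of up to a few thousand
junctions.
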