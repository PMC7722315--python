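# circscreen

A transcriptome-wide screen for circular RNA (circRNA) – RNA-binding protein
(RBP) interactions, built as a tested Python library with a staged pipeline
and a set of numbered analysis drivers.

Circular RNAs arise when a downstream splice donor joins an upstream splice
acceptor (backsplicing), producing a covalently closed transcript whose
backsplice junction (BSJ) is its only unique sequence. Abundant circRNAs that
are densely covered by RBP binding sites can act as protein sponges, and RBPs
bound in the introns flanking circularized exons (or inverted *Alu* pairs
there) can promote circularization. `circscreen` implements the full
computational screen connecting these ideas: consensus circRNA cataloguing
from two callers, eCLIP peak filtering, binding-site coverage statistics
with expression-matched resampling, flanking-intron biogenesis tests,
knockdown response quantification, and junction-spanning read mapping — all
exercisable end to end on synthetic data with planted ground truth.

It is aimed at computational biologists who work with circRNA quantification
(CIRI2/CIRCexplorer-style callers) and ENCODE-style eCLIP peak sets, and at
methods developers who need a reference implementation of the screen's
statistics with exact oracle tests.

## The statistics at the core

* **Consensus catalog** — a junction is kept when both callers support it
  with ≥ 2 BSJ-spanning reads; expression always comes from caller A. The
  highly expressed set is the top fraction by BSJ reads with a ceiling rule:
  |top| = ⌈f·N⌉ (f = 0.01 gives 161 of 16,033 and 147 of 14,648).
* **Circular-to-linear ratio** — r = 2c / (2c + l) for c BSJ reads and l
  linearly spliced reads across the same junction: a BSJ read is generated
  from two ends of the circular junction but counted once.
* **Binding sites** — eCLIP peaks pass with ≥ 10 IP reads, log2(FC) ≥ 3
  against the size-matched input (an 8-fold linear enrichment), and width
  ≥ 4 bp; site–feature overlaps under 4 bp are disregarded.
* **Coverage and enrichment** — coverage is the percentage of a feature's
  exonic bases under the union of filtered sites; host-gene enrichment is
  (coverage + 1) / (mean internal non-circ-exon coverage + 1), NA when the
  host gene has no internal non-circ-exons.
* **Expression-matched resampling** — genes are split into expression
  quantile bins; internal non-circ-exons of genes without circRNAs are drawn
  matching the bin histogram of circRNA-producing genes (100 iterations);
  the observed mean coverage gets an add-one empirical p-value,
  p = (1 + #{resampled ≥ observed}) / (1 + B), with floor 1/101.
* **Flanking biogenesis** — intronic bases within 10 kb on each side of a
  feature; both-flank RBP presence is compared between circRNAs and internal
  non-circ-exons by Yates-corrected chi-square; inverted *Alu* pairs are
  opposite-strand *Alu*s across the two flanks; knockdown response is the
  relative change of total reads-per-million with a Welch t-test.
* **BSJ read mapping** — for every transcript, every exon pair (i ≤ j) gives
  a 60 bp pseudo-reference (last 30 bp of exon j + first 30 bp of exon i);
  ~20–25 bp reads are aligned ungapped with ≤ 2 mismatches, must span the
  junction by ≥ 5 bp on each side, are deduplicated on (barcode, junction,
  offset), and a junction is called with ≥ 10 reads in both IP replicates
  and log2((IP+1)/(input+1)) ≥ 3 in both.
* **Differential binding and GO** — per-RBP Wilcoxon rank-sum on exon
  coverage (BSJ circ-exons vs non-circ-exons, RBPs with ≥ 20 sites),
  Benjamini–Hochberg FDR < 0.1; GO terms with ≥ 2 annotated RBPs tested by
  one-tailed Fisher's exact test.

## Worked example

The whole screen on a simulated dataset, from one command:

```
circscreen screen --rundir run0 --seed 0 --top-fraction 0.25 --n-bins 10
```

or stage by stage through the numbered drivers (each prints what it found
and copies its tables into `results/`):

```
PYTHONPATH=analysis python analysis/01_simulate.py
PYTHONPATH=analysis python analysis/02_catalog.py
...
PYTHONPATH=analysis python analysis/07_calibration_power.py
```

At seed 0 the drivers print, among other things:

```
20 consensus circRNAs; top set of 5 (min 483 BSJ reads)
strongest both-flank enrichment: KHSRP (10.4x, chi-square p = 1.2e-13)
           subset     test  n_circ  relative_change        p
KHSRP_both_flanks        t      12        -0.153371 0.009049
       complement        t       8        -0.027413 0.346747
6/11 junctions called (>=10 dedup reads per IP replicate, log2FC >= 3 vs input)
100.0% of 19 resolved circRNA-RBP interactions share a subcellular compartment
```

Reading this: the consensus filter kept 20 junctions and the ⌈0.25·20⌉ = 5
most expressed form the high-confidence set; KHSRP is the RBP most enriched
for binding sites in both introns flanking circRNAs (10.4× over
non-circularizing exons); circRNAs with KHSRP sites in both flanks drop 15%
in expression upon knockdown (t-test p = 0.009) while the remaining
circRNAs do not change; six backsplice junctions attract enough
deduplicated junction-spanning eCLIP reads to be called bound; and every
resolved circRNA–RBP interaction is compartment-compatible. The calibration
driver (07) additionally reports that the expression-matched resampling
detects a planted 3× circ-exon site density with p ≤ 0.01 in 99/100 seeds
while staying calibrated under the null, and that all four statistical
kernels hold their nominal 5% type-I error.

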