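# Methods

## Detection model

A NUMT insertion that is absent from the reference genome leaves read-pair
evidence: pairs in which one mate maps to the mitochondrial contig and the
other to a nuclear chromosome. `numtquant` quantifies exactly this signal.
No split-read or assembly step is attempted; the nuclear mate's leftmost
mapped coordinate stands in for the integration breakpoint, which is
adequate at window/cytoband resolution because the mate separation of the
targeted libraries is short (~150 bp). Two consequences follow:

* germline NUMTs that are present in both members of a matched pair cancel
  in the tumor/normal contrast, so the metric reads out *somatic* excess
  without explicitly genotyping germline insertions;
* NUMTs already embedded in the reference produce no chimeric pairs and are
  invisible to this method.

Pairs are reconstructed from either mate via the SAM mate fields and
deduplicated by query name, so a chimeric pair survives even when one of
its records is removed by filtering. Secondary and supplementary alignments
are excluded by default (they would double-count pairs); duplicate-flagged
records are dropped by default, with an internal coordinate-signature
marker available for unflagged inputs. No MAPQ threshold is applied by
default — `min_mapq` is exposed, and raising it trades repeat-mediated
false chimeras against sensitivity. Counting is pair-wise for N (one pair =
one insertion observation) and read-wise for M; counting mates individually
would only rescale every proportion by ≈2.

## The abundance metric

Per sample and interval, `P = N/M` normalizes the chimeric-pair count to
local mapped depth, which matters because local representation is not
constant across tumor genomes (CNV, aneuploidy). The paired contrast is
summarized by the rescaled fold-change `R′ = R^S · S` with
`S = sign(ΔP)`: it maps R = 2 to +2 and R = 0.5 to −2, collapsing no-change
to 0. Conventions at the edges:

* ΔP = 0 → S = 0 and R′ = 0 (the sign formula is 0/0 there; collapsing
  no-change to zero is the metric's stated intent).
* Exactly one of P_t, P_h zero → the ratio (or its reciprocal) is
  undefined; the interval is omitted from ratio tables and logged. This
  keeps the antisymmetry property (swapping tumor and healthy negates R′)
  exact on the retained rows.
* Genome level: M excludes sex-chromosome reads while N keeps pairs landing
  there, so genome N equals the sum of chromosome N but genome M equals the
  autosomal sum only.

For sub-genomic partitions the matched healthy baseline is unreliable
(healthy samples may have zero pairs in a short interval), so `pooled` mode
replaces P_ih with the plate-mean healthy proportion (zeros included) and
pools tumor counts before normalization (ΣN/ΣM per plate). Without a plate
column the pool is global, with a warning.

## Partitions

Nuclear: whole genome, chromosome, arm, cytoband, sliding window (default
2.5 Mbp, step = size). Mitochondrial: whole genome, replication strand,
gene. All internal coordinates are 0-based half-open; SAM input is
converted on ingest and all BED/TSV output stays 0-based half-open.
Default window step equals window size: disjoint tiling makes window
counts sum exactly to chromosome counts, which the conservation checks and
pooled normalization rely on; an overlapping mode (step < size) is
retained and counts each window independently. Arms derive from cytoband
name prefixes (p/q), with centromeric bands belonging to the arm their
prefix names. Stain-stratified summaries use exactly the five groups
gneg/gpos25/gpos50/gpos75/gpos100; acen, gvar and stalk bands are
excluded. The bundled mitochondrial gene table follows the human rCRS
layout (13 protein genes, 2 rRNAs, d-loop; 16,569 bp) with three gene
starts nudged past their upstream neighbours to keep intervals disjoint;
the d-loop wraps the origin of the circular genome and is stored as two
arcs sharing one id, counted as a single bin. Strand `+` maps to "heavy"
by the bundled table's convention and the mapping is configurable. GC per
interval is (G+C)/(A+C+G+T), case-insensitive, ambiguity codes excluded;
intervals with no unambiguous bases are omitted.

## Cohort statistics

All tests delegate to standard scipy routines behind a thin result layer:
paired t on log differences (any log base gives identical t and p; the
one-tailed alternative is tumor > healthy), Welch's t with
Welch–Satterthwaite df, Mann–Whitney U (exact for min(n) ≤ 8 without ties,
tie-corrected normal approximation otherwise), OLS for the log2
tumor-on-blood regression and the arm-level R′-vs-mapped-reads regression,
Pearson + Spearman for the window-level R′-vs-GC association. Zero-variance
inputs return a flagged degenerate result instead of infinities (the
paired-t degeneracy cut is sd ≤ 1e-12·|mean|, i.e. numerically constant
log-fold). No multiple-testing correction is applied by default; a
Benjamini–Hochberg helper exists for window-level scans. Per-sample fold
change in stratified summaries means genome-level R (tumor over matched
healthy); entry points accepting raw proportions exist where a contrast is
better run on those. The cohort-level fold change is reported as the mean
of per-sample R_gen (the median is printed alongside).

## Hotspots

Breakpoint histograms count each pair's mtDNA-side coordinate into the
gene partition (or fixed-size bins), with an explicit `unannotated`
catch-all so totals always conserve. Hotspots are ranked by count with
ties broken by genomic order. Tumor-unique regions require zero healthy
pairs cohort-wide and at least `k_min = 2` tumor pairs — one pair is weak
evidence, and the threshold is configurable.

## Synthetic cohorts

The simulator emulates the data structure the analysis assumes: per
sample, background concordant pairs uniform over the nuclear toy genome
(mate gap ~ Normal(150, 30) truncated at 0), concordant mitochondrial
background pairs (mtDNA is high-copy, so real genomes have deep chrM
coverage; default 2,000 pairs), and chimeric pairs implanted at
Poisson(rate × 2 × background_pairs). Defaults:

* toy genome: three autosomes (5 + 4 + 3.5 Mbp), chrX (2 Mbp), chrM
  (16,569 bp) — large enough for ~580 25-kbp GC windows, small enough that
  a full cohort simulates in seconds;
* healthy chimera rate 5·10⁻⁴ pairs per mapped read, chosen so a
  100,000-background-pair genome carries ~100 healthy chimeric pairs —
  the same order as a deep-coverage human genome, keeping per-sample ratio
  estimates meaningful at toy scale;
* tumor/healthy rate ratio 4.42, the cohort-level excess the pipeline is
  designed to measure, with optional per-sex overrides;
* mtDNA breakpoint mixture 50% ND1 + 30% COX1 + 20% uniform, reflecting
  the observed concentration of donor sites in complex I/IV genes;
  tumor-only hotspot genes take a configurable share of tumor breakpoints
  with the shared mixture rescaled to the complement, so healthy genomes
  never draw from them;
* nuclear landing windows weighted ∝ length · exp(β · GC); β defaults to
  0 and GC-bias experiments set it explicitly (tests use β = 4, about a
  3.3× weight range across the GC span 0.30–0.60, which yields a clearly
  detectable but not overwhelming correlation at ~580 windows).

Per-window GC targets are drawn once from the root seed (uniform
0.30–0.60) and shared between FASTA emission and landing weights, so
GC-bias recovery is testable without any external reference. Each sample's
draws come from an RNG substream keyed by a stable hash of its id:
changing cohort composition does not reshuffle other samples, and output
is byte-identical under a fixed config.

Two fidelities exist. The file-level path writes a complete workspace
(SAM per sample, FASTA + index, cytoband table, mito gene BED, metadata,
truth table) and exercises the whole I/O stack. The count-level path skips
read records, allocating background pairs multinomially over the fine
window grid and returning the chimeric truth table directly; the two share
the same truth model, and cohort-scale statistical experiments
(ratio-recovery across thousands of genomes, test calibration over 2,000
cohorts) use the count-level path so run time is spent on the statistics
rather than on file I/O. Problem sizes in the validation suite — 20
participants × 100,000 background pairs for ratio recovery, 2,000 cohorts
of 20 for calibration, 50 replicates for hotspot recovery — were chosen as
the smallest scales at which the Monte-Carlo error bands are informative.

What the simulator does **not** model: sequencing error and base
qualities, alignment ambiguity and mapping error (every record has MAPQ
60), CNV-structured background depth, reference-embedded NUMTs, and
chimera-artifact pairs from library preparation. Passing recovery tests
therefore demonstrates correctness of the counting, normalization and
statistics on cleanly aligned data, not robustness to alignment artifacts
— on real data the MAPQ filter and duplicate handling are the operative
defenses, and their trade-offs are the user's.

## Known limitations

* Breakpoints are proxied, not resolved; sub-kilobase localization and
  junction sequence are out of scope.
* The matched contrast absorbs germline NUMT signal but cannot separate a
  germline insertion lost in the tumor from a somatic one gained in blood.
* `pooled` mode mixes per-plate tumor pools with plate-mean healthy
  baselines; with very few healthy samples per plate the baseline is
  noisy, and intervals without any healthy baseline are dropped.
* The Mann–Whitney vital-status comparison is only as good as the group
  sizes; with the cohort composition this targets (a handful of deceased
  samples) it is descriptive.
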