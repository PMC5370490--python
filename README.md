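# numtquant

Quantification of somatic **NUMTs** — nuclear insertions of mitochondrial
DNA — from matched tumor / blood-derived-normal paired-end whole-genome
alignments.

Mitochondrial DNA fragments transfer into the nuclear genome ("numtogenesis"),
and tumors appear to acquire such insertions at an elevated rate. `numtquant`
detects the read-pair evidence for these events, quantifies their abundance
relative to sequencing depth, and contrasts tumor against matched normal over
nested genomic partitions, from whole genome down to 2.5-Mbp windows and down
the mitochondrial genome to individual genes.

## The metric

A NUMT-supporting (chimeric) read pair has one mate mapped to the
mitochondrial contig and the other to a nuclear chromosome; since the exact
integration breakpoint is not resolved, the nuclear mate's coordinate is the
insertion-site proxy (mate separation is ~150 bp). For sample *j* ∈ {t, h}
(tumor, healthy) and genomic interval *i*:

```
P_ij = N_ij / M_ij                  NUMT proportion (pairs per mapped read)
ΔP_i = P_it − P_ih                  paired difference
R_i  = P_it / P_ih                  fold-ratio (asymmetric about 1)
S_i  = ΔP_i / |ΔP_i|                direction indicator (0 at no change)
R′_i = R_i^{S_i} · S_i              rescaled fold-change
```

R′ symmetrizes the ratio: a doubling in tumor maps to +2, a halving to −2,
and no change collapses to 0, so |R′| ≥ 1 or R′ = 0 and swapping tumor with
healthy flips the sign. At genome scale the mapped-read denominator excludes
sex chromosomes (length-linked representation bias); for short intervals,
where a matched normal may carry no NUMTs at all, the matched baseline P_ih
is replaced by the plate-pooled healthy mean P̄_ih and tumor samples are
pooled before normalization.

On top of the metric the package provides the cohort statistics (paired t on
log proportions, Welch and Mann–Whitney group contrasts, log2 tumor-on-blood
regression, arm-level aneuploidy regression, window-level GC association,
Giemsa-stain-group summaries), mitochondrial fragile-site histograms with
tumor-unique region calling, and a synthetic cohort simulator with complete
ground truth.

## Worked example

Simulate a small matched cohort, then run the pipeline end to end:

```sh
numtquant simulate --out ws --seed 7 --participants 6 \
    --background-pairs 20000 --healthy-rate 0.002
numtquant extract  --alignments ws/alignments --metadata ws/metadata.tsv --out ws/extract
numtquant quantify --extract-dir ws/extract --metadata ws/metadata.tsv \
    --reference ws/reference.fa --out ws/quant
numtquant cohort   --quantify-dir ws/quant --metadata ws/metadata.tsv --out ws/cohort
numtquant hotspots --extract-dir ws/extract --mito-bed ws/mito_genes.bed --out ws/hotspots
```

which prints:

```
wrote 12 alignment files under ws
2587 chimeric pairs -> ws/extract/numt_pairs.tsv
ratio tables -> ws/quant
paired t (log2), two-tailed: t=37.86 p=2.422e-07 n=6
log2 regression tumor~blood: slope=0.06205 R2=0.04955 p=0.6716
cohort fold change: mean=4.559 median=4.469 n=6
sex: Welch t stat=0.145 p=0.8964
vital_status: Mann-Whitney U (exact) stat=1 p=0.6667
top fragile sites: ND1, COX1, RNR2, ND5, ND2
```

The simulator implanted chimeric pairs at a 4.42-fold tumor excess; the
recovered cohort mean fold change is 4.56 with a decisively significant
paired test, and the implanted ND1/COX1 donor hotspots head the
fragile-site ranking. `ws/quant/ratios_gen.tsv` holds the per-participant
records, e.g.

```
participant  interval_id  p_t       p_h       delta_p   ratio  direction  rescaled  baseline_kind
P0001        gen          1.05e-02  2.23e-03  8.29e-03  4.72   1          4.72      matched
```

The same operations are available as a library (`numtquant.extract_numt_pairs`,
`numtquant.ratio_table`, `numtquant.simulate_counts`, ...); see the module
docstrings and `docs/methods.md`.

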