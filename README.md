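# epimem

Windowed differential-methylation analysis for MeDIP-chip probe signals,
with a seeded synthetic-data generator, cross-experiment epigenetic
signature comparison, and global-methylation (%mC) genotype-by-environment
statistics.

The core pipeline:

1. **Reference model** — per chromosome and condition, the "base level"
   methylation mean is estimated from a random 20% probe subset
   (stratified within chromosomes); a two-component Gaussian mixture
   fitted by EM characterizes the bimodal signal distribution and offers a
   mixture-weighted alternative reference.
2. **Window scoring** — consecutive 50 kb windows are built from the
   remaining 80% of probes (midpoint containment, 0-based half-open
   coordinates, last window truncated at the chromosome end). Each
   window's signals are tested against the reference mean with a one-sample
   Wilcoxon signed-rank test (exact null by enumeration for n ≤ 25 without
   ties, otherwise normal approximation with tie/continuity corrections).
   P-values are FDR-adjusted at α = 5% (Benjamini–Hochberg by default, or
   a tail-area local-FDR estimator) and each window gets a ternary score:
   −1 (significantly below the reference), 0, +1 (significantly above).
3. **DMR calling** — a DMR is a window whose score differs between the
   favorable and unfavorable conditions, classified by direction
   (hyper/hypo under unfavorable conditions) and intensity (mild = one-step
   change, strong = −1 ↔ +1), annotated with probe categories
   (BODY / PROMOTER / TE / BODY+TE / PROM+TE / INTERGENIC) and overlapped
   genes. Summary ratios are displayed floored to one decimal.
4. **Comparison** — common DMRs across experiments, conserved vs inversed
   direction classes, and upper-tail hypergeometric over-representation
   tests (overlap, direction, and DMR-gene × DEG overlap).
5. **%mC statistics** — %mC = mC/(C+mC)×100 from nucleoside quantities,
   technical-replicate aggregation, type-II two-way ANOVA with Tukey post
   hoc and Shapiro–Wilk checks, and normality-gated Pearson/Spearman
   correlations against biomass.

The `epimem.simulate` module generates seeded toy genomes, 5-probes-per-gene
designs, bimodal signals with planted whole-window DMRs, and
nucleoside/biomass tables with G×E structure — every stage is testable
offline.

## CLI

```sh
epimem simulate  --config sim.yaml  --out sim_out       # synthetic experiment
epimem reference --config run.yaml                      # reference.tsv
epimem score     --config run.yaml [--plot]             # windows.tsv (+ Manhattan)
epimem call-dmr  --config run.yaml                      # dmrs.bed/tsv, summary.tsv
epimem compare   --dmrs exp1 a/dmrs.tsv --dmrs exp2 b/dmrs.tsv \
                 --universe a/windows.tsv --out cmp     # common_dmrs.tsv, enrichment.tsv
epimem hplc      --config hplc.yaml --out hplc_out      # %mC + G×E statistics
```

Configs are YAML; a resolved copy is written next to every run's outputs.
Analysis commands read input paths from the config's `paths:` mapping
(`probes`, `signals`, `samples`, `chromosome_lengths`, optionally `genes`).
Exit code 2 signals a validation error. All tables are TSV with a header;
all coordinates are 0-based half-open (BED-native).

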