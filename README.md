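# nestedvar

Variance decomposition and concordance analysis for **nested parallel
gene-expression experiments** — the study design in which the same RNA
samples are profiled by both two-channel microarrays and RNA-seq under a
balanced 2×2×2×2 nesting: two conditions (e.g. yeast grown on glucose, G,
vs ethanol, E), two biological replicates per condition, two library or
labelling preparations per biological replicate, and two chips (arrays)
or lanes (sequencing) per preparation — 16 profiles per platform on
identical designs.

The central question such a design answers is *where the variance comes
from*, and in particular how each platform's technical noise depends on a
gene's **intensity** (fluorescence for arrays, read depth for
sequencing).  The package is aimed at statisticians and genomicists who
want to study or teach those operating characteristics with full control
of the ground truth: every analysis stage runs on synthetic paired
experiments whose per-gene effects and per-stage variances are known.

## What it computes

**Per-gene nested ANOVA.**  For each gene's 16-sample profile, three
nested fixed-effects models are fit — condition means (p = 2),
biological-replicate means (p = 4), preparation means (p = 8) — and each
stage's share of variance is the increment in adjusted R²,

    adjR² = 1 − (1 − R²)(n − 1)/(n − p),

    condition   = adjR²(M1)
    biological  = adjR²(M2) − adjR²(M1)
    preparation = adjR²(M3) − adjR²(M2)
    chip/lane   = 1 − adjR²(M3)          (residual stratum)

with negative increments clipped at zero and the vector renormalized.  A
count-data variant replaces sums of squares with Poisson deviances
(library-size offsets, deviance R² = 1 − D(M)/D(0)) so that the
discreteness of read counts can be ruled out as a confounder.  Fractions
are smoothed over intensity quantiles by local quadratic regression
(LOESS) with 95% bands, and platform differences are tested in ten
shared-intensity bins by paired Wilcoxon signed-rank tests.

**Differential expression.**  Counts are pooled (and array ratios
averaged) to biological replicates to avoid pseudoreplication, placed on
the log2-CPM scale with voom-style precision weights from the fitted
mean–variance trend, normalized between samples (TMM, RLE or quantile),
and tested gene-wise with empirical-Bayes moderated t-statistics;
FDR by Benjamini–Hochberg or Storey q-values.

**Concordance and validation.**  Genes are ordered by *min quantile*
(the lower of the two platforms' intensity quantiles); log2(G/E)
agreement is tracked by 500-gene rolling Pearson/Spearman windows,
within-platform chip-vs-chip and lane-vs-lane fold-change divergence by
LOESS tracks, and low-intensity genes whose platform estimates disagree
by ≥ 1 log2 unit can be arbitrated against simulated replicate qPCR
(one PCR cycle = one log2 unit).

**Enrichment.**  Gene sets are tested by Wilcoxon rank-sum against
either signed fold changes (two-sided) or DE p-values (one-sided), with
a five-bin median-intensity diagnostic that exposes how the p-value
ranking is conservative for weakly expressed gene sets.

## Worked example

```python
import nestedvar as nv

params = nv.SimulationParams(seed=1)          # 5000 genes, 16+16 samples
truth, counts, arrays = nv.simulate_experiment(params)

logc  = nv.normalized_log_matrix(counts, "tmm")
dec_rs = nv.decompose_matrix(counts, params.design, variant="gaussian", values=logc)
dec_ma = nv.decompose_matrix(arrays, params.design, variant="gaussian")

print(dec_rs[nv.COMPONENTS].mean().round(3))   # RNA-seq
print(dec_ma[nv.COMPONENTS].mean().round(3))   # microarray

mq   = nv.min_quantile(counts.intensity + 0.5, arrays.intensity)
bins = nv.bin_platform_test(dec_rs, dec_ma, mq["min_quantile"])
print(bins[["n_genes", "median_diff", "p"]].round(4))
```

prints

```
condition      0.116        condition      0.149
biological     0.122        biological     0.157
preparation    0.141        preparation    0.169
residual       0.621        residual       0.525

     n_genes  median_diff       p
bin
1        500       0.2693  0.0000
2        500       0.2353  0.0000
3        500       0.1559  0.0000
4        500       0.1059  0.0000
5        500       0.0877  0.0000
6        500       0.0422  0.0001
7        500       0.0334  0.0049
8        500       0.0401  0.0059
9        500       0.0171  0.1584
10       500       0.0094  0.9946
```

The residual (chip/lane) fraction averages 0.62 for sequencing against
0.53 for arrays, and the binned tests show where that excess lives: the
median per-gene difference falls from +0.27 in the lowest-depth decile
to ~0.01 at the top, where the platforms are statistically
indistinguishable — sequencing noise is strongly depth-dependent while
chip noise is flat, exactly the contrast the nested design isolates.

A subcommand CLI wraps the same pipeline for shell use:

```sh
nestedvar simulate --seed 1 --out-dir run/
nestedvar de --matrix run/counts.tsv --design run/design.tsv --platform counts --out run/de_rs.tsv
nestedvar decompose --matrix run/counts.tsv --design run/design.tsv --platform counts --out-dir run/dec
nestedvar report --dir run/dec
```

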