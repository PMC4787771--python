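# Methods

## The design and the estimand

The experiment layout is a balanced binary nesting of depth four:
condition (2 levels, G vs E), biological replicate (2 per condition),
preparation (2 per biological replicate), and chip or lane (2 per
preparation), giving 16 samples per platform.  The condition and
biological stages are shared between platforms; preparation and
chip/lane are technology-specific.  For each gene the estimand is the
fraction of across-sample variance attributable to each stage, and its
dependence on the gene's intensity (mean cy5 fluorescence for arrays,
total mapped reads for sequencing).

## Nested-ANOVA decomposition

Three nested fixed-effects models are fit per gene: condition means
(p=2), biological means (p=4), preparation means (p=8).  The chip/lane
stage is deliberately left as the residual stratum: parameterizing it
would saturate the model (16 parameters for 16 observations, zero
residual df).  Stage fractions are increments of adjusted R² with the
standard Wherry-style correction `1 − (1 − R²)(n − 1)/(n − p)`; the
correction makes the increments approximately unbiased for the
underlying variance fractions at the cost of occasional small negative
values, which are clipped at zero with the four components renormalized
to sum to one.  Unadjusted R² is monotone under nesting, which the test
suite asserts; the adjusted increments are not, which is why clipping is
needed.  The adjustment formula is isolated in one function
(`decompose.adjusted_r2`) so an alternative penalty can be swapped in.

Genes with zero total variance (or zero total count) are flagged
degenerate, excluded from smoothing and binned testing, and reported
with NaN fractions rather than aborting the matrix.

### Count-data variant

To rule out count discreteness as the source of any platform contrast,
the same three models are refit as Poisson log-linear models with
log-library-size offsets.  Group-mean Poisson MLEs are closed-form
(group rate = group count sum / group library sum), the deviance is
`D = 2 Σ[y log(y/μ) − (y − μ)]` with `0·log 0 = 0`, deviance R² is
`1 − D(M)/D(0)`, and the same df adjustment, clipping and
renormalization are applied.  A deviance-based (rather than
KL-divergence-based) count R² was chosen for its direct GLM
interpretation; at high depth and modest dispersion the two variants
agree to well under 0.02 per component, which the suite verifies.

## Smoothing and binned comparison

Per-gene fractions are smoothed over intensity quantiles (average ranks
scaled to (0,1]) by locally weighted quadratic regression with tricube
weights, span 0.75 by default, evaluated on a 100-point grid.  The 95%
band is analytic (local weighted-residual variance times the squared
norm of the smoother row) or a 200-replicate gene-resampling bootstrap.
Local quadratic fitting reproduces polynomial trends exactly on the
interior, which anchors the unit tests.

Cross-platform comparisons bin genes into 10 equal-size bins by the
shared *min quantile* — the lower of a gene's two platform quantiles, so
a gene weakly measured on either platform is treated as weakly measured
— and compare per-gene residual fractions with a paired two-sided
Wilcoxon signed-rank test per bin (an unpaired rank-sum alternative is
available), BH-adjusted across bins.  Bins with fewer than 10 usable
genes are flagged untested.

## Normalization and differential expression

Two data paths are kept strictly separate.  The decomposition path uses
the full unpooled 16-sample matrices, since the replicate structure is
the signal.  The DE path first collapses replicates to the biological
level — counts summed, array log-ratios averaged — because preparation
and chip/lane replicates are not biological replicates, and treating
them as such would be pseudoreplication that understates within-group
variance.  That leaves a 2-vs-2 comparison with 2 residual df per gene;
the package warns that empirical-Bayes moderation dominates in this
regime, which is faithful to the design being modeled.

Counts become log2-CPM (`log2((y + 0.5)/(L + 1) × 1e6)`), with TMM
(doubly trimmed 30%/5%, precision-weighted, factors rescaled to
geometric mean 1), RLE (median-of-ratios), or quantile normalization
between samples; the default DE path uses TMM, which removes the
library-composition drift that otherwise biases fold-change estimates
by a few hundredths of a log2 unit.  Precision weights follow the voom
recipe: gene-wise condition-mean fits to log2-CPM, a lowess trend (span
0.5) of sqrt(residual sd) on mean log2 count, observation weights equal
to the predicted fourth inverse power at the fitted log-count, floored
at 1e-6.  Moderated t-statistics use the standard moment estimation of
the scaled-F prior on log variances, with a Newton trigamma inverse
(tolerance ~1e-10); the implementation is cross-checked against the
Bioconductor reference (limma/edgeR via Rscript) in the test suite.
FDR is Storey q-values (cubic smoother for π0 over λ ∈ {0.05, …, 0.95},
evaluated at λ = 0.95) or Benjamini–Hochberg; forcing π0 = 1 recovers
BH exactly.

Array dye-swap structure is not modeled; a common-reference
single-contrast layout is assumed throughout.

## The simulator: what it emulates, and what it does not

On the log2 scale, gene g in sample s has signal
`a_g + c_s β_g/2 + b_(g,bio) + p_(g,prep) + e_gs`, with `c_s = ±1`, so
the G-vs-E contrast is exactly `β_g` (log2(G/E)).  Defaults, chosen
once to emulate the phenomenology of a yeast carbon-source experiment
at desk scale:

| parameter | default | meaning |
|---|---|---|
| `n_genes` | 5000 | ~yeast-genome scale |
| `baseline_log_abundance` | N(4, 2.5) | several orders of magnitude of expression |
| `prop_de` | 0.2 | fraction of genes with condition effect |
| `de_logfc` | N(0, 1) | effect sizes (log2) |
| `sigma_bio`, `sigma_prep` | 0.2, 0.2 | intensity-flat stage noise (log2 sd) |
| `array_sigma_unit` | 0.305 | intensity-flat chip noise (may be a function of abundance) |
| `seq_extra_sigma_unit` | 0.30 | flat lane factor before read sampling |
| `seq_total_reads` | 1,000,000 | reads per lane-share |

Counts are Poisson draws (multinomial optional) around per-lane expected
proportions `∝ 2^signal+lane-factor`; the lane factor is a per-gene
lognormal overdispersion knob interpolating between pure-Poisson and
array-like behavior.  Array log-ratios subtract a common reference
modeled as the mean of the condition means plus small per-gene noise
(so technical replicates of a preparation are identical when chip noise
is switched off), with intensity reported as rescaled 2^a.

Two calibration choices deserve explanation, since the paired-platform
contrast is the package's headline result and both were fixed by
delta-method calculation before verification, not by tuning:

* **Depth.**  At 1M reads per lane the Poisson sampling variance on the
  log2 scale, ≈ 1/(μ ln²2), dominates the flat lane factor for the
  bottom half of genes and becomes negligible in the top decile, so the
  boundary where the platforms become statistically indistinguishable
  falls near the 80th intensity percentile — the same *proportional*
  boundary as in a full-scale experiment.  At a much lower depth the
  sampling regime would extend through the top decile and the platforms
  would differ everywhere, which is not the phenomenon being emulated.
* **Chip floor.**  The chip noise sd (0.305) sits fractionally above the
  lane flat component (0.30): the difference in variance, ≈ 0.003,
  equals the median residual sampling variance of the top depth decile
  at this scale, making the two platforms' *total* unit noise equivalent
  for strongly measured genes, as observed in real parallel data.

The simulator also provides: an intensity-*dependent* chip-noise option
(`intensity_dependent_array_sigma`, floor 0.15 + 0.5·2^(−a/2)) for
studies of within-platform divergence, since real chips are somewhat
noisier at low fluorescence; a low-intensity bias injector (13 genes in
the bottom 20% of abundance given ±(1.5 + |N(0, 0.5)|) log2-FC offsets
on one platform, drawn preferentially from genes with true condition
effects so validation panels carry genuine fold changes); replicate
qPCR tables (Ct = const − log2 abundance, per-run plate offsets,
3 replicates × 4 RNA samples); and intensity-coherent enrichment-null
gene sets.

What the simulator does **not** model: read-level artifacts (mapping,
GC/length bias), probe-sequence cross-hybridization (bias is injected
phenomenologically), dye-swap or spatial array effects, and any
correlation between expression level and effect size.  Consequently,
passing tests demonstrate the *statistical machinery* and the
qualitative intensity phenomenology; they do not certify behavior on
real data with those additional artifacts.

## qPCR normalization

Each Ct is centered by the all-gene mean Ct of its biological
replicate, which removes per-run plate/loading offsets; the per-gene
fold change is the difference of centered means between conditions,
with one cycle equal to one log2 unit and lower Ct meaning higher
abundance.  A consequence worth knowing: centering across the measured
panel subtracts the panel-mean condition effect, so recovered fold
changes equal `β_g − mean(β_panel)`.  This constant cancels in the
correlation comparisons the rule is used for, and is exactly zero for
sign-balanced panels (which the round-trip test uses).

## Enrichment ranking modes

`logfc` mode tests signed fold changes two-sided, reporting direction
separately.  `pvalue` mode tests one-sided for the in-set p-values
being *smaller* than background ("is this set more significant than the
genome?").  The sidedness choice is deliberate: statistical power falls
with intensity, so weakly expressed sets are systematically *less*
significant than background, and the one-sided test then produces
p-values piling up near 1 — the conservativeness that the five-bin
median-intensity diagnostic makes visible, and the reason fold-change
ranking is preferable when set expression level correlates with
membership.  At desk scale this conservativeness is a real but modest
effect; the diagnostic study therefore uses a GO-collection-like design
(300 sets of 40–100 genes) for adequate power of the KS uniformity
check, and remains a seed-sensitive, qualitative reproduction.

## Problem sizes and numerical choices

Reproduction studies run at 5000 genes per experiment; oracle
equivalence uses 100 random 16-sample profiles (tolerances 1e-10
Gaussian, 1e-8 count); bootstrap bands use B = 200; rolling windows
default to 500 genes, stride configurable (edge windows are dropped,
not shrunk).  Ties in ranks are averaged everywhere.  The Mann-Whitney
set test uses the exact null when the smaller group has ≤ 8 members and
no ties, otherwise the tie- and continuity-corrected normal
approximation.  All simulation streams derive from a single user seed
via independent substreams, so every table is bit-reproducible at a
given seed.
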