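# Methods

## Overview

`zincsig` implements a three-stage analysis for estimating tissue zinc status
from bulk expression data:

1. **Derivation** — a consensus list of zinc-stimulated genes (ZSGs) is
   assembled from many small, heterogeneous two-group treatment experiments
   by vote counting, cleaned of stress-response transcripts, and validated
   against zinc-depletion experiments.
2. **Scoring** — a per-sample *zinc signature score*: the equal-weighted
   arithmetic mean of the signature genes' normalized log2 expression
   (log2 counts-per-million for sequencing data, log2 intensity for arrays).
3. **Association** — disease-vs-control LOG2 fold change of the score,
   quartile stratification, correlation of the score with clinical
   covariates, genome-wide score–gene correlation, cross-cohort consensus of
   the top correlated genes, and pre-ranked gene set enrichment on the
   correlation-ranked list.

## Differential expression engine

Both platform types are reduced to one moderated two-sample t engine.

*Intensity (array-like) data.* Matrices whose maximum exceeds 50 are treated
as linear-scale and log2-transformed (an optional offset handles zeros);
matrices already below that ceiling pass through. Samples are then quantile
normalized: each column's sorted values are replaced by the across-column
mean of sorted values, with ties receiving the mean of the quantile values
they span. Quantile normalization is applied unconditionally by default (a
config flag disables it) — a deterministic operationalization of
normalize-as-required.

*Count (RNA-seq) data.* Counts are converted to CPM, genes are kept when
CPM ≥ 1 in at least *k* samples (*k* defaults to the smaller group size),
and values become log2(CPM + 0.5). This log-CPM + moderated-t route is a
deliberate approximation of a quasi-likelihood count model: the consensus
vote downstream consumes only (log2 fold change, p), which is robust to the
testing engine. The approximation is visible as a mild conservativeness of
raw p-values on simulated negative-binomial counts (null p<0.05 rate
≈ 0.045 at n = 4 vs 4, dispersion 0.1).

*Moderation.* Gene-wise residual variances s²_g on d_g degrees of freedom
are shrunk toward a scaled inverse-chi-square prior (d0, s0²) fitted by
moment matching on log variances: the observed variance of log s²_g in
excess of trigamma(d_g/2) determines d0 through trigamma inversion (Newton
iteration), and the mean of log s²_g determines s0². When the observed
spread does not exceed the sampling spread, d0 = ∞ and s0² is the mean
variance. The posterior variance (d0·s0² + d_g·s²_g)/(d0 + d_g) replaces the
pooled variance in the t statistic, referred to t on d0 + d_g degrees of
freedom (standard normal in the d0 = ∞ limit; the ordinary pooled t is the
d0 = 0 limit). With gene standard deviations drawn uniformly (not from the
conjugate prior) the null p<0.05 rate measures ≈ 0.052 — a small, known
anti-conservativeness from prior misspecification that the replicate-level
Monte-Carlo band in the tests accommodates.

*Calls.* A gene is called up-regulated when log2FC ≥ log2(1.5) **and**
raw p < 0.05 (fold boundary inclusive, significance boundary strict);
down-regulation mirrors this. BH-adjusted values are always reported, and a
config flag switches the significance gate to FDR; raw p is the default
because the signature-definition rule is stated on p.

## Consensus rule and filters

A gene enters the preliminary signature with up-votes in ≥ 5 datasets,
an **absolute** threshold out of the total panel (default 11). Five rather
than a strict majority of six accommodates genes missing from some
platforms; missingness is carried as reduced opportunity to vote, never
imputed. A relative mode (votes / datasets-measured) is available behind a
flag. Ordering: votes desc, mean log2FC desc, symbol asc.

Stress filtering is membership-based: preliminary genes occurring in any
configured stress set (shipped default: a small heat-shock/DNA-damage GMT
with HSPA6, DDIT3, DNAJB1, …) are removed. Each dataset's full up-list is
additionally ORA-tested (upper-tail hypergeometric, BH across sets) against
the stress sets and flagged stress-confounded at q < 0.05 — report only;
votes are not retroactively removed, since dose-driven stress co-induction
does not invalidate a dataset's zinc calls. The judgment-guided, annotation
based removal that a human analyst would perform is not mechanically
reproducible; set membership is the declared convention.

Depletion validation labels each signature gene *validated* (down-called in
≥ 1 depletion dataset, up-called in none), *discordant* (up-called anywhere
under depletion — seen in practice with non-specific chelators), or
*unmeasured*. Discordant genes are retained by default (removal is a config
option), matching how discordant-but-established zinc transporters are
handled in practice.

## Scoring and cohort statistics

Scores are comparable only within one dataset/platform; no cross-platform
calibration exists, so cross-dataset statements use each cohort's own
controls (LOG2FC = difference of group mean scores, which on log2 data is a
log2 fold change). At least half the signature genes must be measured
(configurable); the mean is over the measured members.

Quartiles: samples sorted by score descending, ties broken by sample id;
descending rank r (1-based) maps to quartile ⌊4(r−1)/n⌋+1, so sizes differ
by at most one and quartile 1 holds the highest scores. Top-vs-bottom
quartile comparisons use the unpaired Wilcoxon–Mann–Whitney rank-sum test —
exact by ties-aware enumeration of rank assignments when n₁+n₂ ≤ 12, the
normal approximation with tie correction otherwise. (Figure legends in this
literature sometimes cite the *signed-rank* test for such comparisons; that
is a paired test, and no pairing structure exists between quartiles, so the
unpaired rank-sum is the implemented default.) Covariate association uses
Pearson r with the t-transform p on n−2 df and pairwise deletion of missing
values.

## Association analysis

*Batch merging.* Cohorts are intersected on common genes (≥ 100 required),
quantile normalized per cohort, then each gene is standardized within each
batch to the pooled per-gene mean and variance. This location–scale
adjustment is deliberately simpler than empirical-Bayes batch correction:
the downstream consumers are correlations and ranks, which are insensitive
to the difference, and the simpler form is exactly invertible and
deterministic. Genes with zero within-batch variance receive a
location-only shift.

*Genome-wide correlation.* Pearson r between the score vector and every
gene, vectorized; zero-variance genes are reported missing. Ranking is r
descending with ties broken by symbol for determinism.

*Consensus top genes.* Genes ranked in every cohort are ordered by mean
rank; the signature's own genes can be excluded (they correlate with the
score by construction).

*Pre-ranked GSEA.* Walking-sum statistic: at set members the sum rises by
|r|^p normalized by the total hit weight (default p = 1; p = 0 reproduces
the unweighted Kolmogorov–Smirnov-like statistic), elsewhere it falls by
1/(N−m); ES is the signed extremum. The null permutes gene labels — random
m-gene sets on the fixed list — because the ranked list is a correlation
vector, not a sample-level statistic; each set gets its own freshly drawn
null (vectorized, seeded), which keeps permutation p-values independent
across sets. NES = ES / mean |null ES| of matching sign;
p = (1 + #{null at least as extreme, same sign}) / (1 + #{null same sign});
BH across tested sets. Set-size bounds (≥ 5 ranked members, ≤ half the
list) are configurable. With n_perm = 0 only ES is reported.

## Synthetic data generator

The generator produces the statistical structure the pipeline assumes, not
the biology of any real cohort:

- **Treatment panels** (default 11 datasets: 6 intensity, 5 counts; 2,000
  genes; 4 vs 4): intensity values are Gaussian on the log2 scale
  (gene means U(4,12), gene SDs U(0.2,0.6), emitted on the linear scale so
  the pipeline exercises log detection); counts are negative binomial with
  log-normal baseline means and dispersion 0.1 (a typical bulk RNA-seq
  magnitude). Nine planted zinc genes gain +1.5 log2 in treated samples
  wherever measured; six stress genes gain +2.0 log2 only in three
  designated high-dose datasets. Each gene is independently unmeasured per
  dataset with probability 0.15, with planted genes kept measured in ≥ 8
  datasets.
- **Depletion datasets** shift the planted genes −1.0 log2 in depleted
  samples (6 vs 6); listed discordant genes shift +1.0 instead.
- **Disease cohorts** (41 disease vs 10 healthy) are driven by a latent
  per-sample zinc level z ~ N(0, latent_sd²), shifted −1.0 log2 in disease.
  Signature genes are baseline + z + N(0, 0.2); a 20-gene module is coupled
  to z so its cohort-level correlation is ≈ 0.7 (the coupling is rescaled by
  the realized variance of z including its between-group component);
  covariates are linear in z (AST slope −30, ALB slope +4) plus Gaussian
  noise.

**Choice of latent spread.** The latent level enters every signature gene
coherently, so the within-group latent SD — not per-gene measurement noise
— bounds how precisely a cohort's score LOG2FC can recover the planted
shift: the group-mean difference carries latent noise of SD
latent_sd·√(1/41 + 1/10) ≈ 0.35·latent_sd. The default latent_sd = 0.15
log2 units keeps that recovery error within ±0.15 at the default sample
sizes while leaving the covariate and module correlations strong; it is a
generator parameter, stated once here, and models a population whose
biological zinc variation is subordinate to the disease effect. Real
cohorts with larger biological spread will recover the shift more noisily
than the synthetic benchmark suggests — a limitation of the benchmark, not
of the scoring formula.

What the generator does **not** emulate: probe-level artifacts, platform-
specific intensity distributions, correlated background genes (beyond the
planted module), library-size outliers, or covariate distributions of any
real clinical cohort. Passing the synthetic benchmarks therefore
demonstrates correctness of the machinery and its operating characteristics
under the stated model, not performance on any particular GEO cohort.

## Numerical conventions

- Trigamma inversion by Newton iteration from the 0.5 + 1/x start, 50-step
  cap, 1e-10 relative tolerance.
- p-values clipped into (0, 1]; two-sided throughout.
- All tie-breaks are deterministic (symbol order, sample-id order); all
  randomness flows from a single integer seed through
  `numpy.random.default_rng`; derived seeds stay below 2³¹.
- Duplicate probe rows collapse to the row with the highest mean — a
  declared convention where no standard exists.
- TSV output uses `%.10g` so repeated runs are byte-identical.

## Problem sizes used in the benchmark suite

The replicated benchmarks run at the generator defaults (2,000 genes,
11 datasets, 4 vs 4; cohorts 41 vs 10) with 20 replicate seeds for recovery
experiments, 50 for null calibration, 1,000 permutations and 200 random
sets for the enrichment checks — sizes at which every experiment's
Monte-Carlo error is far below the margins being asserted, and the full
suite completes in well under a minute per experiment.

## Known limitations

- The count path approximates a count model on the log-CPM scale (above).
- Stress filtering is only as good as the supplied stress sets.
- The moderated-t prior assumes exchangeable gene variances; strong
  mean-variance trends (counts at low depth) violate it mildly.
- The batch adjustment assumes batch effects are per-gene location/scale;
  it will not remove interaction-structured batch effects.
- Scores are means of log expression: a single extreme signature gene can
  dominate; the equal-weight convention is intentional (robust across
  tissues where individual members drop out) but not optimal for any one
  tissue.
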