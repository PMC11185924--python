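# Methods

## Overview

`drugsense` predicts which drugs a tumor is likely to respond to from its
bulk expression profile alone, by exploiting a pharmacogenomic cell-line
panel in which both baseline expression and drug response (AUC of the
dose–growth-inhibition curve; higher AUC = more resistant) are measured.

The method has two phases:

1. **Training.** For every (gene, drug) pair, the Pearson correlation
   coefficient (PCC) between the gene's expression and the drug's AUC is
   computed across cell lines. Sorting genes by PCC in descending order
   gives the drug–gene correlation profile (DGCP): genes at the top are
   putative resistance biomarkers (expression rises with resistance), genes
   at the bottom putative sensitivity biomarkers.
2. **Scoring.** A tumor profile is compared with each drug's DGCP through
   four directional gene-set enrichment (GSEA) tests, each yielding a
   one-sided empirical p-value against a permutation null; the geometric
   mean of the four p-values is the drug's G-score. Smaller G-score =
   predicted more sensitive. Drugs are ranked per sample by ascending
   G-score.

Downstream, per-patient rankings are merged into subtype-level consensus
lists by Cross-Entropy Monte Carlo rank aggregation, and predictions are
benchmarked with percentile-binned normalized positive-predictive-value
(PPV) curves.

## Training

Correlations use a pairwise-complete-observation policy: for each gene,
only cell lines with both a finite expression value and a finite AUC enter
the computation. Genes with fewer than `min_pairs` (default 10) complete
pairs, or zero variance on either side, are dropped per drug; a drug with
fewer than `min_pairs` usable cell lines is skipped with a warning. The
`min_pairs` filter is a configurable guess at why some drugs fail training
on sparse panels; it is the natural minimum-sample rule but is not imposed
by any external convention. PCC ties are broken by gene id (stable sort) so
training is bit-for-bit deterministic. A library's gene universe is the
intersection of the genes retained by every surviving DGCP, and every DGCP
is restricted to it.

Lineage stratification (e.g. training separately on solid-tumor and
liquid-tumor panels) is deliberately the caller's responsibility: pass the
already-filtered cell-line subset and a `lineage_label`. Gene identifiers
are matched exactly and case-sensitively; inputs must share one namespace
(no alias mapping is attempted, since any mapping is data-dependent).

## The four enrichment tests

Genes shared by the tumor profile and the DGCP form the working universe of
size N. With set size m (default 250, per the reference protocol):

| test | ranking            | gene set                     | expected direction |
|------|--------------------|------------------------------|--------------------|
| 1    | DGCP (desc. PCC)   | tumor's m most expressed     | bottom (ES → −1)   |
| 2    | DGCP (desc. PCC)   | tumor's m least expressed    | top (ES → +1)      |
| 3    | tumor (desc. expr) | DGCP bottom-m (sensitivity)  | top (ES → +1)      |
| 4    | tumor (desc. expr) | DGCP top-m (resistance)      | bottom (ES → −1)   |

The enrichment score is the classic Kolmogorov–Smirnov running-sum
statistic: walking down the ranking, hits increment the sum by
|r_i|^w / Σ_hits |r_j|^w (with weight w = 0 this is 1/m) and misses
decrement it by 1/(N − m); the ES is the signed maximum deviation from
zero, in [−1, 1]. The weight exponent defaults to 0 (unweighted) and is
exposed as a parameter; the set-size robustness checks in the test suite
cover the sweep. One-sided directions are fixed as in the table — the four
tests state intents ("sensitivity biomarkers are up-regulated"), and the
sign conventions above realize them.

## Permutation null and p-values

The null randomizes the tumor profile: each permutation selects
⌈shuffle_fraction·N⌉ positions of the ranked gene-label vector uniformly at
random (default fraction 0.25) and cyclically deranges the labels among
them, so every selected label actually moves while the expression values
and their ordering stay put. The ES of each test is recomputed on the
randomized profile, and the one-sided empirical p-value uses the add-one
rule p = (1 + #extreme) / (1 + n_perm), so p ≥ 1/(n_perm + 1). The default
n_perm is 10,000; the bundled tests and the acceptance script use 500–1,000
to keep runs in the minutes range, at the cost of a coarser p floor.

Interpretation choices the protocol leaves open, fixed here: the shuffled
subset is resampled independently every permutation, and one ensemble of
randomized profiles drives all four tests (and all drugs, and all samples
whose working universe has the same size). The single ensemble mirrors the
idea of randomizing the tumor profile itself, makes scoring reproducible
and identical inputs give identical outputs, and provides the joint null
needed to estimate the covariance for Brown's method. Marginally, each
test's null distribution is unaffected by the sharing; only the coupling
between tests is introduced, which is exactly what Brown's correction
consumes. With `shuffle_fraction = 1` the derangement spans the whole
vector (a uniform random cycle), and empirical p-values are uniform within
Kolmogorov–Smirnov tolerance (verified in the acceptance suite).

## Combining p-values

The G-score is the geometric mean (p1 p2 p3 p4)^(1/4), strictly monotone in
each p and permutation-invariant. Because the four tests are correlated, a
Brown-combined p-value is available as an alternative: with
X = −2 Σ ln p_i, Brown's method fits a scaled chi-square with
c = var(X)/(2 E[X]) and df = 2 E[X]²/var(X), where E[X] = 8 and
var(X) = 16 + 2 Σ_{i<j} cov(−2 ln p_i, −2 ln p_j). The covariance is
estimated empirically from the shared permutation ensemble (null ES →
within-null empirical p → −2 ln p → 4×4 covariance). A degenerate
covariance falls back to Fisher's method (df 8) with a warning. Since X is
a monotone transform of the geometric mean, the two rankings agree almost
perfectly (Spearman ≈ 0.998 in the acceptance run); only the absolute
p-values differ.

Ranks are 1-based, ascending in G-score, with ties broken by drug id.

## Consensus rank aggregation

Per-patient ranked drug lists are aggregated into one ordered top-k list by
minimizing the mean Spearman footrule distance: for each input list, sum
|position in candidate − position in the input's top-k| over the union of
the two k-lists, with absent items at position k+1, and average over
patients. The Cross-Entropy Monte Carlo optimizer maintains a
(universe × k) column-stochastic probability matrix (initialized uniform),
samples `n_samples` candidate k-lists without replacement per iteration
(default 10·|universe|), re-estimates the matrix from the elite fraction
(default 0.1) of candidates, smooths with weight 0.7 against the previous
matrix, and stops after 15 iterations without improvement or 200 iterations.
These defaults follow the common settings of the rank-aggregation
literature; the exact settings used in the original analysis are not
reported, so they are exposed as parameters. The item universe is sorted
lexicographically so the result is invariant to the order the patient lists
arrive in; an exhaustive enumerator (guarded at 10^6 candidates) serves as
the exact oracle on small instances. The "worst drugs" consensus reverses
every input list and aggregates with the same machinery. A weighted
(G-score-magnitude) variant of the footrule is deliberately excluded.

## Validation metric

Scored (sample, drug) pairs with a sensitive/resistant label are sorted by
ascending G-score (ties stably by sample then drug) and binned into
percentiles. At each percentile the cumulative PPV = TP/(TP+FP) is
computed and divided by the prevalence of sensitive pairs — the PPV a
random ordering attains — so the curve ends at exactly 1 and a perfect
scorer reaches 1/prevalence at the percentile equal to 100·prevalence.
Pairs with unknown labels are excluded rather than counted as false
positives. A per-bin (non-cumulative) variant is available behind a flag.

Gold standards come from either (a) AUC values, calling a pair sensitive
below the per-drug q-quantile (default q = 0.05; the exact calling rule of
the reference cell-line resource is not recoverable, so the rule is
configurable and recorded in `rule_provenance`), or (b) categorical
response calls, mapping complete/partial response to sensitive and
stable/progressive disease to resistant.

## Synthetic benchmark

The generator plants per-drug biomarkers with a shared-latent-factor model.
For drug d, a latent factor t_c ~ N(0,1) per cell line drives both the
response, AUC = μ + β·t + ε with ε ~ N(0, σ²) and μ = 10 (clipped at 0),
and the planted genes' expression, z = (∓t + η)/√2 with η ~ N(0,1) —
minus for the n sensitivity biomarkers, plus for the n resistance
biomarkers (n = 50 per direction by default). Every planted gene then has a
standard-normal marginal and per-gene expected correlation
∓β/√(2(β² + σ²)) with the AUC (≈ ∓0.63 at the default β/σ = 2), which is
what makes per-gene correlation ranking able to recover the planted sets.
A purely additive design in which the AUC is a noisy sum of 2n i.i.d.
biomarker expressions cannot produce recoverable per-gene signal — each
gene's correlation is then bounded by 1/√(2n) ≈ 0.1, below the null
sampling noise at 60 cell lines — so the latent-factor construction is
used instead. When planted sets overlap across drugs (unavoidable at the
default 2,000 genes × 30 drugs × 100 planted genes each), a gene serving k
drugs sums its k factors and is renormalized to unit variance, diluting
each per-drug correlation by √((1+k)/2); within a drug, sensitivity and
resistance sets never overlap. Fully cross-drug-disjoint planting is
available (`cross_drug_disjoint=True`) when the gene pool allows it.

Background expression is i.i.d. standard normal rather than a realistic
RNA-seq marginal: the method is rank- and correlation-based, so marginal
shape is immaterial, and the simplification keeps the analytic expectations
exact. The generator does not emulate lineage structure, batch effects or
realistic dose–response shapes; passing tests therefore demonstrate the
method's statistical machinery, not its performance on real cohorts.

Tumor cohorts add `shift` (default +2) to the sensitivity biomarkers — and
−shift to the resistance biomarkers — of each subtype's designated drugs
(two subtypes, 12 patients and 5 designated drugs each by default, loosely
mirroring a two-subtype cohort with subtype-specific vulnerabilities) on an
i.i.d. normal background. The implied gold standard labels a (patient,
drug) pair sensitive iff the drug is designated for the patient's subtype.

## Problem sizes used in the bundled checks

The acceptance suite trains on the default benchmark (2,000 genes, 60 cell
lines, 30 drugs, 50 planted biomarkers per direction, β/σ = 2) and scores
40 tumors at n_perm = 1,000 for the matched-versus-shuffled-library
comparison; the set-size robustness sweep re-scores 30 of the training
lines at n_perm = 500; the subtype-recovery property runs 100 reduced-scale
pipelines (300 genes, 40 lines, 6 drugs, n_perm = 100). These sizes are the
package's chosen desk-scale study conditions; they keep every permutation
p-value resolvable at its floor while the statistics of interest (recall,
normalized PPV, consensus recovery) remain well separated from their
negative controls.

One caveat quantified during development: with 1,200 labeled pairs
clustered in 40 tumors, the first-decile normalized PPV of the
label-shuffled control is an honest-but-noisy statistic (mean ≈ 1.0,
sd ≈ 0.27 over independent replicates), because whole tumors enter or
leave the decile together. Interpret single-seed control values
accordingly.

## Numerical and degenerate-input choices

- ES extremum: the running-sum value of largest magnitude, first occurrence
  on exact ties; positive chosen when |max| = |min|.
- `rank_profile` breaks expression ties by gene id; an all-equal profile
  degenerates to lexicographic order with a warning.
- Duplicate gene rows in expression input are collapsed by mean (warned).
- Missing AUC entries are excluded pairwise at training; missing expression
  drops the gene from that sample's ranking (warned).
- Biomarker requests larger than the DGCP are clamped with a warning.
- `empirical_p` uses the add-one floor so p = 0 never occurs; G-score
  inputs are validated to (0, 1].
- AUC values are validated non-negative; the synthetic generator clips at 0
  (a > 5σ event at default parameters).
- CE aggregation columns that lose all probability mass fall back to a
  uniform draw over the remaining items.

## Known limitations

- The permutation null conditions on the observed profile and moves only
  25% of labels by default, so p-values are under-dispersed relative to a
  full relabeling; they are calibrated for ranking, not for absolute
  error-rate control (the method ranks drugs and applies no FDR across
  drugs by design).
- Exact-string gene matching means mismatched identifier namespaces
  silently shrink the working universe; the minimum-overlap guard
  (2·set_size shared genes) is the only protection.
- The synthetic cohort's subtype signal is additive and axis-aligned;
  real subtype differences are broader transcriptional programs.
- `exhaustive_aggregate` is an oracle for tests, not a production path;
  beyond ~10^6 candidate lists only the stochastic optimizer applies.
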