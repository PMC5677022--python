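# Methods

## The analysis model

The package operationalises a causal chain: deficiency of the DNA damage
response (DDR), and of homologous recombination (HR) in particular, lets
somatic mutations accumulate (genome instability), shifts the expression
of miRNAs that regulate DDR genes, sensitises tumours to platinum agents,
and improves survival under platinum-based chemotherapy. Mutation burden —
the per-sample count of somatic mutation records, deduplicated on
(sample, chromosome, position, alternate allele) — is used as the
instability index. Burden is a raw count, not per-megabase: the cohorts
this targets are profiled on a common exome footprint, and only the
ranks of the counts enter any statistic. Silent variants are counted by
default (the least-filtered reading of "somatic mutation frequency"); an
`exclude_classes` policy drops them when a non-silent count is wanted.

### The screen

For each miRNA the cohort is split at the median of its expression: high
strictly above, low strictly below, exact ties set aside. Mutation counts
of the two halves are compared with the Mann-Whitney U test and both
one-sided p-values are computed; the smaller is reported together with its
direction (positive: high expression accompanies higher burden). A miRNA
is flagged when that smaller one-sided p falls below a raw alpha (default
0.01), with no multiple-testing correction. **This doubled one-sided rule
is a directional screen with effective size up to 2-alpha**: under the
null, P(min of the two one-sided p-values < alpha) is at most 2-alpha
(slightly less under discreteness). The null calibration test measures
the realised size (~0.0175 at alpha 0.01 on the default generator) and
checks it against the [alpha, 2-alpha] band. A `bh=True` option applies
Benjamini-Hochberg instead, as an extension beyond the raw rule.

### The score

A signed signature (positive set P, negative set N, k = |P| + |N|) scores
each sample by counting positive-direction miRNAs strictly above their
cohort median plus negative-direction miRNAs strictly below it. Medians
are recomputed within each scored dataset; a `compute_scores` call on a
pooled tumour+normal matrix scores normals against pooled medians, which
is the default for tumour-vs-normal comparisons (scoring normals against
frozen tumour medians is possible by scoring the tumour matrix first and
reusing its breakdown). Samples missing a signature miRNA's value earn no
point for it and are flagged. Groups are high (score >= cutoff) versus
low; the default cutoff is floor(k/2)+1, i.e. 6 for the 10-miRNA
signature.

The score–burden association is Spearman's rho over the (score level,
median burden at that level) pairs — 11 points for k = 10 — with
average-rank ties; an exhaustive permutation p-value is used up to 8
levels, the t-approximation beyond. This level-median formulation follows
the score's intended read-out (does the *typical* burden rise with the
score?) and is insensitive to the very long burden tails; a per-sample
Spearman is available through `truth_report` for synthetic cohorts.
Response trends are Pearson correlations of the per-level response rate
against the level (Spearman by option).

### Defect evidence

`brca_defect` = BRCA1 mutated or methylated, or BRCA2 mutated;
`hr_defect` additionally admits EMSY amplification, PTEN homozygous
deletion, or alteration (mutation or deletion) of a configurable core-HR
gene set (canonical HR effectors plus the Fanconi anaemia genes).
Epigenetic silencing is called per gene by z-scoring methylation and
expression, clustering with 2-means over 25 seeded restarts, taking the
majority assignment, and labelling a cluster silenced only when it is both
hyper-methylated and down-expressed; if no cluster satisfies the
conjunction — or either feature is constant — nothing is called.

### Survival and matching

Kaplan-Meier curves, the log-rank test and Cox proportional-hazards
regression are delegated to lifelines; Cox fitting uses the partial
likelihood with Efron handling of tied event times, Wald 95% intervals,
and a brute-force grid maximisation of the hand-written partial
likelihood as the test oracle. Multivariate fits encode FIGO stage and
histological grade as ordinal numerics and debulking as a suboptimal
indicator. Non-convergence and separation are reported on the fit, never
silent.

Matched-group selection sorts both groups together by the balancing
covariate (ascending, ties broken by sample identifier so the scan is
deterministic) and keeps every adjacent pair of opposite labels, one to
each output group; everything unpaired is discarded. Pairs are accepted
in either label order: a one-directional scan discards roughly half of an
interleaved cohort for no benefit, while the either-order scan retains it
almost completely (the strict variant remains available via
`strict_order`). Kept groups are equal-sized by construction and their
covariate distributions compare as null under a two-sided Mann-Whitney
test (balance p, median ~0.99 on default synthetic cohorts).

## Exact-test conventions

- `fisher_exact_2x2`: two-sided p sums hypergeometric probabilities of all
  tables with the observed margins whose probability does not exceed the
  observed table's, with a 1e-7 *relative* tolerance on the comparison to
  absorb floating-point noise in the pmf; odds ratio ad/bc (infinite when
  bc = 0 with ad > 0); a zero margin returns p = 1 with a warning.
- Mann-Whitney: exact null enumeration for untied pools when both groups
  have <= 12 observations; exhaustive permutation enumeration (average
  ranks, two-sided = twice the smaller one-sided, capped at 1) for tied
  pools of <= 16 observations; tie-corrected normal approximation with
  continuity correction otherwise.
- `chi2_2x2`: Pearson statistic with 1 df, Yates correction off by
  default; an expected cell below 1 warns but still returns; a zero margin
  returns (0, 1) with a warning.
- Degenerate associations (constant level medians, constant response
  rates) report a coefficient of 0 with p = 1 and a degenerate flag rather
  than NaN.

## The synthetic generator

`SimulationConfig` encodes the causal chain with a latent per-tumour
deficiency D:

| parameter | default | meaning |
|---|---|---|
| `n_tumours`, `n_normals`, `n_mirnas` | 400, 8, 100 | cohort dimensions |
| `deficiency_model`, `deficiency_p` | bernoulli, 0.5 | D ~ Bernoulli(0.5); beta(a,b) gives graded deficiency |
| `planted_positive`, `planted_negative` | 6, 4 | miRNAs coupled to D, matching the 6/4 signature |
| `effect_size_sd` | 1.0 | expression shift per unit D, in noise-SD units |
| `mutation_mean_base`, `mutation_mean_slope` | 10, 50 | NB mean 10 (intact) to 60 (deficient) mutations |
| `mutation_dispersion` | 2.0 | NB size; variance mu + mu^2/size (over-dispersed burden) |
| `hazard_base` | 0.22 /year | intact-tumour hazard (median OS ~3.2 years) |
| `log_hr_deficiency` | log 0.55 | protective deficiency hazard ratio |
| `censor_rate` | 0.05 /year | independent exponential censoring (~15-20% censored) |
| `response_intercept`, `response_slope` | -1.4, 2.8 | platinum sensitivity/CR from ~20% (intact) to ~80% (deficient) |
| `defect_prob_intercept`, `defect_prob_slope` | -2.0, 4.0 | defect-evidence union probability ~12% to ~88% |

The defect model carries an intercept so that non-deficient tumours keep a
realistic ~12% baseline evidence rate; the union probability is split
evenly over six independent evidence channels (BRCA1 mutation/methylation,
BRCA2 mutation, EMSY amplification, PTEN deletion, core-HR alteration).
Normal controls are drawn at D = 0 with no mutations. All sampling comes
from one `numpy.random.default_rng(seed)` stream consumed in a fixed
order, so equal seeds give byte-identical output files.

What the generator emulates: signed expression shifts against independent
Gaussian noise, over-dispersed burden, proportional-hazards survival,
logistic response, binary defect evidence. What it does not: inter-miRNA
correlation, batch structure, platform effects, copy-number segments,
methylation mixtures beyond the two-cluster silencing fixture, or
covariate-outcome confounding (age/stage/grade are independent of D).
Passing recovery tests therefore certify the *machinery* — that each stage
recovers what its generative assumption plants — not performance on real
cohorts, where effect sizes, correlation structure and confounding are
unknown.

A known behaviour worth stating plainly: with the default binary
deficiency, the 11 score-level burden medians form a step, not a ramp —
within the low (0-5) and high (6-10) halves the medians are equal in
expectation — so their Spearman rho is high (median ~0.85 at n = 400) but
seed-noisy, reaching 0.8 in roughly three quarters of replicates; a graded
(beta) deficiency makes the level medians monotone and the rho uniformly
high. Relatedly, a Cox fit of survival generated from latent D on the
*score group* covariate is attenuated toward the null by group
misclassification (fitted ~0.63-0.65 for a generative 0.55 at the default
1-SD expression effect); `truth_report` reports this as the bias against
exp(log_hr x dD), where dD is the deficiency gap between the fitted
groups. Hazard-ratio *recovery* is therefore checked by regenerating
survival with the known ratio on the assigned group, which the Cox
machinery recovers without bias (median 0.549 over 20 replicates).

## Problem sizes used in tests

Recovery experiments use 50 replicates at n = 400 (screen, association,
matching) and n = 1000 (Cox); null calibration uses 10 replicates of 200
null miRNAs; moment checks use n = 10,000 and n = 5,000 draws; the exact
Fisher comparison enumerates every 2x2 table with total <= 40. The
acceptance script uses 20 replicates for each recovery quantity and 8 for
the null rate. These sizes put Monte-Carlo error comfortably below the
asserted margins while keeping the default suite quick.

## Limitations

- The packaged DDR network edge list is a synthetic stand-in: nine edges
  are literature-documented, the remainder deterministic filler
  reproducing the published shape (142 edges, 75 miRNAs, 55 genes). It
  exercises the code paths; it is not a curation.
- LOH fraction, total aberration index and altered-genome fraction are
  pass-through columns only; the package computes no copy-number summary.
- The screen's raw-alpha rule is reproduced deliberately; treat flagged
  sets as candidates, not discoveries, or use the BH option.
- Cox fits assume proportional hazards; no diagnostics beyond convergence
  and separation warnings are provided.
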