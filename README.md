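# mirgi — miRNA expression scoring of tumour genome instability

Ovarian tumours with deficient homologous recombination (HR) accumulate
somatic mutations and respond better to platinum chemotherapy, but direct
genomic read-outs of HR deficiency (BRCA1/2 mutation or methylation, EMSY
amplification, PTEN deletion) miss tumours inactivated post-
transcriptionally. `mirgi` implements a miRNA-expression route to the same
phenotype: it screens miRNAs for association with somatic mutation burden,
summarises a signed miRNA set into an integer score that tracks HR
deficiency, and evaluates that score against defect annotations, platinum
response and survival. It is written for computational biologists analysing
matched miRNA-expression / somatic-mutation / clinical cohorts, and ships a
ground-truth synthetic cohort generator so every stage is testable without
any data download.

## The score

For a signed signature with positive set *P* and negative set *N*
(k = |P| + |N|), each sample *s* receives

```
score(s) = Σ_{j∈P} 1[x_js > m_j]  +  Σ_{j∈N} 1[x_js < m_j]
```

where `x_js` is the expression of miRNA *j* in sample *s* and `m_j` the
cohort median of miRNA *j*. Inequalities are strict: ties at the median
earn no point. The score is integer-valued in [0, k], weightless by design
(no fitted coefficients), and invariant to any monotone transformation of a
miRNA's expression. The shipped default is a 10-miRNA signature
(6 positive: miR-151, miR-301b, miR-505\*, miR-324, miR-502, miR-421;
4 negative: let-7a\*, miR-320, miR-146a\*, miR-193a), grouped high/low at a
cutoff of 6.

Around the score, the package provides:

- **data_io** — TSV readers/validators for expression matrices, MAF-lite
  mutation tables, clinical tables, defect-evidence tables and miRNA–gene
  network edge lists, aligned on a shared sample universe;
- **instability** — per-sample mutation counts, a 2-means consensus caller
  for epigenetic silencing, and HR-defect annotation;
- **screen** — the median-split Mann-Whitney screen plus Fisher exact,
  chi-squared and hypergeometric enrichment statistics;
- **score** — signature scoring, grouping, and score–burden /
  score–response associations;
- **outcome** — Kaplan-Meier, log-rank, Cox regression (via lifelines) and
  an adjacent-pair matched-group selection algorithm;
- **synthetic** — the cohort generator with known ground truth;
- **pipeline** — `GenomeInstabilityModel` / `PipelineResults`, a
  statsmodels-style model/results pair running the whole sequence.

## Worked example

```python
from mirgi import GenomeInstabilityModel, simulate_cohort

cohort = simulate_cohort(seed=1)          # 400 tumours, 100 miRNAs, 10 planted
results = GenomeInstabilityModel(cohort.bundle).fit()
print(results.summary())
```

prints

```
Genome-instability miRNA score pipeline
=======================================================
samples: 400   signature: screen-derived (k=11)
provenance: 9f0d2d5df12f0f58

screen: 11/100 miRNAs significant (alpha=0.01)
score groups: high=196, low=204 (cutoff 6)
score-burden association: rho=0.911, p=3.85e-05 over 12 levels
platinum_sensitive trend: r=0.886, p=0.000127
complete_response trend: r=0.857, p=0.000363
defect enrichment [hr_defect]: table=(156, 40, 46, 158), p=1.26e-31
defect enrichment [brca_defect]: table=(116, 80, 27, 177), p=1.55e-22
defect enrichment [emsy_amplified]: table=(58, 138, 11, 193), p=5.14e-11
defect enrichment [pten_deleted]: table=(55, 141, 7, 197), p=2.58e-12
log-rank high vs low: chi2=27.167, p=1.87e-07
Cox univariate: HR=0.538 [0.43-0.68], p=2.79e-07
Cox multivariate: HR=0.538 [0.42-0.68], p=3.05e-07
matched groups (balanced on burden): 77+77 kept, 246 discarded, balance p=0.994, matched log-rank p=0.0006

  [network_enrichment] SKIPPED: no network provided
```

(no network edge list was attached to the bundle, so that stage reports
itself skipped; pass `mirgi.read_network_edges(...)` output into
`assemble_cohort` to enable it).

Reading the output: the screen flagged 11 miRNAs (the 10 planted plus one
false positive); the score tracks mutation burden across its levels
(Spearman rho 0.91 over the level medians); HR-defect evidence concentrates
in the high-score group; high-score patients live longer (hazard ratio
0.54, protective as planted), and they remain prognostic even after
matching the two score groups to near-identical mutation-burden
distributions (balance p 0.99), which is the point of the matched-group
design: the expression signature carries survival information beyond the
raw mutation count.

The same stages are available from the shell:

```bash
mirgi simulate --seed 1 --outdir cohort/
mirgi run --expr cohort/expr.tsv --maf cohort/muts.maf.tsv \
          --clinical cohort/clin.tsv --defects cohort/defects.tsv \
          --signature cohort/signature.tsv --out report/
```

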