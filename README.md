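# painrhythm

Circadian pain-rhythmicity phenotyping for chronic low back pain (CLBP)
cohorts, with the downstream biopsychosocial and blood-transcriptomic
analyses that the phenotypes feed into — and a seeded synthetic-cohort
generator so that every stage can be exercised and validated against known
ground truth without access to participant-level data.

It is written for biostatisticians and computational biologists working with
ecological momentary assessment (EMA) symptom diaries and paired
day/night bulk RNA-seq from the same participants.

## What it computes

**Phenotyping.** Participants rate pain (0–10 numeric rating scale) three
times a day (08:00, 14:00, 20:00) for seven days; entries more than ±1 h from
a slot are discarded. Within-day variability is the mean over days of the
within-day sample SD. The cohort is split at the median of this metric:

- low-variability participants are split again at the median of mean pain
  intensity into **constant_low** and **constant_high**;
- high-variability participants with a relative change
  (s₂₀ − s₀₈)/s₀₈ ≥ 0.30 on ≥ 4 of the 7 scheduled days are
  **rhythmic_up** (≤ −0.30 gives **rhythmic_down**); the rest are **mixed**.

**Cohort statistics.** Multinomial logistic regression of phenotype
membership on biopsychosocial covariates with rhythmic_up as reference
(OR = e^β, 95 % CI = e^(β±1.96·se)), with explicit quasi-complete-separation
handling (an exposure absent from the reference class drives β → ∞; the fit
stops at a divergence guard and flags the OR as a bounded sentinel).
Fisher's exact test including the Freeman–Halton r×c extension by exact
enumeration, Kruskal–Wallis and one-way ANOVA + Tukey HSD, Spearman
correlation, day→night percent change, and 2^−ΔΔCt qPCR fold changes.

**Transcriptomics.** TMM library-size normalization, top-30 % MAD filtering,
three-metric sample-outlier triage (inter-sample distance sum, KS statistic,
Hoeffding's D), median log-ratio batch centering, log-CPM transform;
per-transcript negative-binomial GLMs (Var = μ + αμ², Cox–Reid adjusted
profile-likelihood dispersions, likelihood-ratio contrasts, Bonferroni
control); signed weighted coexpression networks
(a_ij = ((1+r_ij)/2)^β, topological overlap, average-linkage clustering with
an adaptive tree cut, module eigengenes, iterative merging at |r| ≥ 0.30,
eigengene–phenotype GLMs); hypergeometric over-representation and
running-sum (GSEA-style) gene-set enrichment with a seeded permutation null.

**Replication arm.** A two-visit cohort is modelled as
`~ age + sex + RIN + smoker + resolved + time + opioids + time:opioids`;
genes are ranked by the interaction Wald statistic (positive = expression in
opioid users lingered or rose over time) and tested for enrichment of a
designated gene set. A logistic model gives the opioid → pain-chronicity OR.

## Worked example

```python
import pandas as pd
from painrhythm import CohortConfig, gen_diaries, phenotype_cohort
from painrhythm.cohort_stats import fisher_exact

diary, truth = gen_diaries(CohortConfig(seed=7))   # 62-participant cohort
diary["timestamp"] = pd.to_datetime(diary["timestamp"])
labels = phenotype_cohort(diary, scale="pain")
print(labels["label"].value_counts().to_dict())
print(fisher_exact([[1, 9], [2, 15], [8, 11], [8, 6]]))
```

prints

```
{'mixed': 21, 'constant_low': 16, 'constant_high': 15, 'rhythmic_up': 8, 'rhythmic_down': 2}
0.01602901370600392
```

The first line is the phenotype composition recovered from a synthetic
cohort generated at the study's group sizes (17/14/10/2/19 plus
classification noise). The second is the exact Freeman–Halton p-value for a
4×2 antidepressant-use-by-phenotype table — antidepressant use differs
across phenotypes at p ≈ 0.016, with only 2 of 17 (11.8 %) constant-low
participants reporting use.

The full pipeline (simulate → phenotype → cohort stats → preprocessing →
differential expression → network → enrichment → replication) runs from one
YAML config:

```bash
painrhythm run config.yaml     # see painrhythm --help for the subcommands
```

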