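# Methods

This note documents the statistical models implemented in `painrhythm`,
their assumptions, the parameters that matter, what the synthetic-data
generator does and does not emulate, and the numerical choices made where
the procedure left room.

## Pain-rhythmicity phenotyping

Diary entries are retained only if time-stamped within ±60 min of a
scheduled slot (08:00/14:00/20:00); when several entries compete for one
slot the entry closest to the slot time wins (exact ties go to the earliest).
Day 0 is the participant's first diary date; the protocol window is 7 days.

The participant-level variability metric is the **mean over days of the
within-day sample SD** (n−1 denominator; a day needs ≥ 2 of its 3 slots).
A pooled-SD variant (`variability_mode="pooled"`) is available: the phrase
"daily pain score SD" admits both readings, and the mean-of-daily-SDs form
was chosen as default because both the metric and the 12-h change rule
concern within-day structure. The cohort is split at the 50th percentile
(linear-interpolation median); ties go to the low-variability side so the
partition is deterministic and order-free. The constant-low/high split uses
the median of mean intensity **within the low-variability subset** (a
whole-cohort variant would shift the cut when the subsets' intensity
distributions differ; the subset median is the default).

A day qualifies as increasing when (s₂₀ − s₀₈)/s₀₈ ≥ 0.30, with the morning
score as denominator; a zero morning score with a positive evening score
counts as an increase, two zeros as no change, and a day missing either
terminal entry can never qualify — while the "≥ 4 of 7" denominator stays
the 7 scheduled days (the conservative reading). The threshold is inclusive
(≥ 30 %) and exposed as a knob. Decreasing days use the same formula at
≤ −0.30. Participants are `unclassifiable` only when no day has two slots.

**Assumption to note:** splitting at the cohort median presumes roughly half
the cohort is low-variability, which held in the motivating cohort (31/60
constant). In a cohort dominated by variable patterns the median split will
push genuinely variable participants into the constant branch; recovery
benchmarks therefore use compositions balanced between the two branches.

## Cohort statistics

The multinomial logit is fitted by Newton–Raphson with step-halving (the
log-likelihood is monotone across iterations); Wald CIs come from the
inverse observed information. Quasi-complete separation — e.g. an exposure
absent from the reference phenotype — drives the affected coefficient to
infinity; iteration stops when any |β| crosses 15 (OR ≈ 3×10⁶) and the
result is reported with a `separated` flag: the OR is then a bounded
sentinel, not an MLE, mirroring how such cohort data behave rather than
hiding them. An optional L2 (`ridge`) penalty provides a stabilized fit;
it is off by default.

Freeman–Halton r×c exact tests enumerate all tables with the observed
margins (two-sided rule: total probability of tables no more probable than
the observed, with a 1e-7 relative log-probability tolerance for ties);
tables whose enumeration is infeasible fall back to seeded Monte-Carlo
sampling from the fixed-margins null (Patefield draws, 1e5 by default).
Kruskal–Wallis uses the tie-corrected H; the ANOVA path is the ordinary
(pooled-variance) F with Tukey HSD via the studentized range.

## Expression preprocessing

TMM factors follow the weighted trimmed-mean-of-M-values recipe (30 % M
trim, 5 % A trim, delta-method weights, reference = library whose
upper-quartile relative abundance is closest to the cohort mean, factors
rescaled to geometric mean 1); the implementation agrees with edgeR's
`calcNormFactors` to ~1e-7 on composition-biased matrices. Note that a
depth-only change leaves TMM factors at 1 — depth lives in the library
size; factors correct composition.

The variance-flattening transform is log₂ CPM with prior count 0.5 on
TMM-effective library sizes — a deliberate, documented stand-in for a
variance-stabilizing transform: monotone, near-logarithmic where counts are
large, sufficient for the filtering and network stages that consume it.
Batch adjustment is per-gene median log-ratio centering (each gene's
per-batch median is moved to its grand median on the log scale, counts
re-rounded); the full empirical-Bayes NB location/scale model is out of
scope, and batch additionally enters the DE design directly, so the
centering only needs to protect the correlation-based network stage.
MAD filtering keeps the top 30 % of transcripts by MAD of the transformed
values (configurable to raw/normalized counts), ties broken by transcript id.

Sample triage computes three scores per sample — sum of mean absolute
differences to the other samples, the KS statistic of the sample's value
distribution against the pooled distribution, and Hoeffding's D between A
and M of the sample's MA-plot against the median pseudo-reference — twice:
on raw log₂ counts (depth included) and on normalized log-CPM. A sample is
removed only when flagged both before and after normalization, or by ≥ 2
metrics after. Flags use Tukey's far-out fence (Q3 + 3·IQR): with cohorts
of 10–60 samples the inner 1.5·IQR fence flags several percent of samples
per metric under pure-noise nulls, which would make removals routine where
they should be rare; the far-out fence keeps the false-removal rate of the
whole two-clause rule at ~3 % per cohort while still catching gross shifts.

## Differential expression

Per-transcript counts are NB with Var = μ + αμ² and log link; offsets are
log TMM-effective library sizes. Per-gene α maximizes the Cox–Reid adjusted
profile likelihood (bounded scalar search over log₁₀ α ∈ [−8, 1.7]); genes
whose estimate fails fall back to the median of successful estimates. No
empirical-Bayes trend shrinkage is applied — the validation surface here is
calibration and recovery, not bit-parity with any particular tool. Contrasts
use likelihood-ratio tests (χ², df = number of dropped columns); Bonferroni
controls the tested family (the whole matrix, or the candidate-set subset
for candidate DE). All-zero transcripts are dropped and reported. Under null
simulations at 2000 genes the raw-p rejection rate at α = 0.05 falls in
[0.03, 0.07] (recomputed by `scripts/acceptance.py`).

The replication model ranks genes by the Wald statistic of the
opioid × time interaction (Wald chosen over LRT for ranking: one fit per
gene, and the sign is the interpretable quantity — positive means users'
expression lingered or rose relative to nonusers). Participants with a
single visit are excluded with a log entry.

## Coexpression networks

Signed adjacency ((1+r)/2)^β on the batch-adjusted, transformed matrix.
β is the smallest candidate (1–20) whose connectivity distribution fits a
scale-free form (signed R² ≥ 0.80 of the binned log-log degree regression),
with two guards: candidates whose mean connectivity falls below 2 are
ineligible (at high powers a near-empty network fits a line spuriously
well), and when no candidate reaches the target the best-fitting eligible
one is used. On correlation matrices estimated from a few dozen samples the
0.80 target is rarely attainable — the fallback path is the norm at this
scale, and it reliably lands in the β range where planted structure is
preserved.

Topological overlap uses the standard form
TOM_ij = (Σ_u a_iu a_uj + a_ij)/(min(k_i,k_j) + 1 − a_ij). Modules are
branches of the average-linkage dendrogram of 1−TOM: the tree is severed at
92 % of the root merge height, clusters of ≥ `min_module_size` leaves whose
mean internal dissimilarity is below 90 % of the cut height become modules
(the coherence check rejects loose aggregates of unconnected transcripts),
and unassigned transcripts join the nearest module when close enough to its
core — a simplified form of dynamic-hybrid branch cutting; a plain static
cut is available. Fragments of one true module that the cut oversplits are
recombined by the merge stage. A matrix whose every transcript belongs to a
single module is a known blind spot of the coherence check (nothing is
left to be "far"); it does not arise in matrices that passed a variability
filter.

Eigengenes are the first principal component of the module's z-scored
member profiles, unit norm, sign-anchored to correlate positively with the
module mean profile. Modules merge iteratively while any two eigengenes
correlate at |r| ≥ 0.30 — an unusually aggressive threshold kept as quoted
from the motivating procedure (the common convention is ~0.75); it is a
config knob, and |r| (not signed r) is the default reading. Associations
with the rhythmic-increasing phenotype use a logistic GLM on the eigengene
(binary) or the baseline-category multinomial GLM (multilevel), with the
same separation guard as the cohort models.

## Enrichment

ORA: hypergeometric upper tail on sets intersected with the background and
filtered to sizes 10–500, Benjamini–Hochberg adjustment (with a Bonferroni
option). The graph-aware multiple-testing correction used by some web
services depends on the live ontology structure and is deliberately not
re-derived; adjusted values are therefore not comparable to that scheme.

GSEA: classic weighted running sum (hit increments ∝ |stat|^w, w = 1;
positive extremum wins magnitude ties, to a 1e-12 tolerance, so results do
not depend on summation order). The null redraws the set's positions among
the ranked genes — exact enumeration over all C(n,k) placements when that
count does not exceed `n_perm`, seeded draws otherwise; the p-value is
one-sided on the observed sign with the +1 correction for sampled nulls;
NES divides by the mean same-sign null |ES|. Gene permutation ignores
inter-gene correlation: when an entire set's statistics shift coherently
(as with a shared exposure mislabelling), enrichment attenuates rather than
vanishes — the package's tests check attenuation against the true-label
p-value for exactly this reason.

## Synthetic cohorts

Diary archetypes (NRS units): constant-low 2.5, constant-high 7.0, rhythmic
up morning 3.5 with multiplicative morning→evening growth of +60 %
(evening = morning × 1.6, well past the 30 % rule so classification errors
reflect noise, not the rule boundary), rhythmic-down 5.5 at −45 %, and
mixed 5.0 with dominant day-to-day variation (SD 2.2) plus within-day SD
1.3 — an "unpredictable" pattern must stay noisy, so low-noise benchmark
configurations damp only the four structured archetypes (to 0.2/0.3). Slot
noise is Gaussian, then rounded half-away-from-zero and clipped to 0–10;
this is a stand-in, not an inference about real diary noise. Missingness is
slot-wise Bernoulli (default 10 %); timestamps jitter with SD 10 min,
truncated at ±55 min. Default group sizes are the study's (17/14/10/2/19).
Mood and fatigue track the day's pain with extra noise, giving the positive
cross-scale rank correlations without a diurnal signature.

Covariates: PROMIS-style t-scores Normal(50, 10) plus configured phenotype
shifts; opioid probability exactly 0 for rhythmic-up and 0.44 elsewhere
(the observed non-rhythmic rate); antidepressant probabilities at the
observed group rates.

Counts: paired day/night NB matrices (Var = μ + αμ², α = 0.15, matching the
DE model so recovery tests are self-consistent). One planted module of 50
of 600 transcripts shares a latent factor (loadings ≈ 0.8 on the log scale,
giving member correlations ~0.6–0.8 as in real modules); the factor's
per-sample mean drops by `module_effect` in rhythmic-up participants, so
the planted eigengene is negatively associated with that phenotype.
Per-gene batch (two batches, SD 0.30), sex (0.10) and time (0.20) effects
are multiplicative on the mean. Library sizes 0.8–1.6×10⁵ and 600
transcripts are scaled-down problem sizes chosen so the full pipeline and
its tests run in seconds; they preserve the count regime (tens to hundreds
per transcript) in which the NB machinery operates.

Replication: 45 users / 52 nonusers, two visits; a designated 40-gene set
gets a +0.5 log-unit opioid × time interaction; chronicity is Bernoulli
from a logistic model with opioid coefficient log(2.6). At n = 97 a single
OR estimate is noisy (CI width several-fold); parameter-recovery checks
therefore average over replicate cohorts generated at inflated n.

**What passing tests show, and what they do not.** The generator produces
independent NB counts given its latent structure, Gaussian diary noise,
ignorable missingness, and exactly two sequencing batches. Real diaries
have autocorrelated, non-Gaussian, informatively missing entries; real
expression has correlated gene families, outlier samples and library
artifacts beyond multiplicative batch shifts. Recovery and calibration
results certify the pipeline's statistical machinery under its own model
assumptions — not the biology of any cohort.

## Seeds and determinism

Every generator takes a mandatory seed; the pipeline expands one global
seed into fixed per-stage substreams (SeedSequence with stage tags), so a
stage can be rerun alone without perturbing the rest, and reruns are
byte-identical. All derived seeds stay below 2³¹.
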