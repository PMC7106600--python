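# Methods

This note documents the models, conventions and numerical choices behind
`pvqnet`, and what the synthetic study conditions do and do not establish.

## Instrument schema and scoring

Records carry raw *answer positions* exactly as the instrument prints them;
all keying is a scoring concern. The OQ composite reverses items 13, 24 and
31 (`score = 4 - answer`) because their printed scales run 4..0, and averages
them with item 3; item 8 is the ideation screen and stays its own ordinal
variable. The RFL composite averages 13 of the 14 items; item 25 ("I'm too
stable to kill myself") has standalone signal and stays separate. No RFL
items are reversed (all are protective-direction). The reversal set ships in
the serialized transforms so an alternative keying needs no code change.

Age is ingested as a band, not an integer. Two published band codings exist
for this instrument -- the form's own (18-28 .. >78) and the validation
sample's descriptive coding (14-19 .. 60+) -- and they disagree; both are
supported (`age_bands="instrument" | "study"`) and neither is asserted as
canonical. Bands are left-closed. Missing item responses reject the record
(listwise) by default; there is no imputation.

## DEQ principal components

PCA is computed on the correlation matrix of the six DEQ items: columns are
standardized by training mean and sd (ddof=1) and the components are right
singular vectors of the standardized matrix. Exactly two components are
retained, regardless of explained variance, matching the instrument's fixed
design. Sign indeterminacy is resolved by orienting each component so the
loading of DEQ item 19 ("I become scared when I feel lonely") is
non-negative; item 19 loads positively on both published components, so this
convention reproduces the published orientation without data-dependent
flips. The quadrant code thresholds both scores at 0 -- scores are centered
by construction, and the published quadrant shares are all near 25%.

Continuous composites enter the network as ordinal levels from k=3
training-quantile bins (left-closed, ends clamped). k is configurable; 3 is
the default because the discrete network needs small cardinalities at
n ~ 650 and terciles keep every CPT row populated.

## Network engine

*Scores.* BIC (default) and BDeu are both decomposable; BIC's local term is
the maximized multinomial log-likelihood minus `0.5 ln(N) q (r-1)`. The BDeu
equivalent sample size and the CPT-estimation prior weight are separate
knobs that default to 1.

*Search.* Hill-climbing applies the single best improving
addition/deletion/reversal; tabu search continues past local optima with the
best non-tabu move (FIFO tabu list of inverses, default length 10, escape
budget 10) and returns the best DAG visited, so its score never falls below
hill-climbing's. Ties between moves break lexicographically by (child,
parent, add < delete < reverse), making both searches deterministic.
Whitelisted arcs seed the start graph and are never deleted or reversed;
blacklisted arcs are never added (a reversal counts as adding the opposite
arc). The five constraint-based algorithms historically compared against
these (Grow-Shrink, IAMB variants, MMPC) are registered by name but raise
`UnsupportedAlgorithmError`; the selection harness compares the two
score-based searches.

*Parameters.* CPT rows are Dirichlet posterior means,
`(n_jk + ess/(rq)) / (n_j + ess/q)`; an unobserved parent configuration
yields the uniform row. Parent axes are stored in sorted order so tables
from different construction paths are directly comparable.

*Inference.* Exact variable elimination with a min-degree heuristic
(lexicographic ties). Evidence with zero probability raises
`InconsistentEvidenceError` rather than returning NaNs. Risk prediction
thresholds the posterior at 0.5, boundary to the positive class.

*Equivalence.* Learned and true structures are compared as CPDAGs
(v-structures plus Meek rules R1-R3) under structural Hamming distance, so
score-equivalent orientations are never counted as errors.

*Expert graph.* The originally published initial graph and blacklist exist
only as figures, so constraints are data, not code: a JSON
whitelist/blacklist file. The shipped default
(`evaluation.default_constraints`) is the package's own illustrative
stand-in -- trait/state variables feed the SB node, demographics are
exogenous, the SB label causes nothing upstream -- and is editable.

## Cross-validation

Every fold refits the full chain (PCA, discretizer edges, structure, CPTs)
on training cases only; per-record composites (a record's own item mean)
are fold-independent and precomputed. LOOCV pools all N single-case
predictions into one confusion matrix and reports the 11-metric summary;
"accuracy" in repeated k-fold is (tp+tn)/N pooled per repeat. Folds are
stratified by group (balanced groups, stable composition); assignments come
from seeded `StratifiedKFold` and are shared across algorithms during
selection so the comparison is paired. A fixed-structure mode (structure
learned once on the full cohort, CPTs refit per fold) exists because the
original analysis is ambiguous about what was refit per fold; the honest
per-fold refit is the default. The classification threshold (0.5) is
configurable.

Undefined metric ratios (zero denominators) are reported as NaN with a
warning, never silently as 0.

## Descriptive statistics

Categorical group comparisons use Pearson's chi-squared test with the Yates
continuity correction on 2x2 tables only -- the convention that reproduces
the validation sample's published statistics from its printed integer counts
(e.g. gender 0.001583, education 2.473); correction can be disabled.
Summary-level mean comparisons use the two-sample t-test, pooled df by
default with Welch as an option (for the published age comparison the two
are indistinguishable: 4.0417 vs 4.0418). Reproduction from printed rounded
summaries carries a +-0.01 tolerance on t; exact assertions are reserved for
statistics computed from integer counts. The published 9x2 diagnosis table
supports its printed statistic only to 4 significant figures (74.12); the
recomputed value is 74.1207.

## Synthetic study conditions

The generator samples feature-level truth first (ancestral sampling from a
ground-truth network), then renders items, so the preprocessing stage
provably inverts the rendering up to channel noise. Defaults emulate the
validation sample: n=650; near-balanced groups; age-band, gender, diagnosis
and severity marginals from the published tables (fields with only aggregate
summaries published -- children, schooling detail, cohabitation detail --
use shares chosen to match those aggregates); OQ/RFL blocks with one shared
factor and strong level separation (mean pairwise RFL correlation ~0.95);
DEQ items with the published loading matrix (its columns are unit-norm and
orthogonal as printed), component sds 1.452/1.131, and independent noise
(sd 0.95) giving mean absolute inter-item correlation ~0.22.

The default truth network is `age_band -> {deq_quadrant, rfl_level}`,
`{deq_quadrant, rfl_level, oq_level} -> sb_group -> oq8`. Two deliberate
choices:

* **oq8 is a child (symptom) of the SB state**, not a parent. Substantively
  the ideation item is the most direct expression of the state; numerically,
  a fourth SB parent would multiply the SB table to 180 parent
  configurations, leaving ~111 observations per row at n=20,000 -- parameter
  recovery within 0.05 would then be statistically unattainable (binomial sd
  alone ~0.047). With 36 configurations each row keeps ~555 observations.
* **SB rows are strong and bounded away from 0, 0.5 and 1**: 0.95/0.05 when
  distress and reasons-for-living disagree, 0.85/0.15 decided by the
  self-esteem digit of the DEQ quadrant when they balance. This keeps the
  Bayes decision unambiguous in every configuration, CPT estimation robust
  at LOOCV fold sizes, and every arc detectable by BIC at n=20,000. The
  age tilts on quadrant and RFL level are centered under the age marginal so
  both variables stay exactly uniform -- the quantile discretizer bins into
  equal shares, and a tilted marginal would cut bin edges inside a level
  cluster.

The analytic Bayes-optimal balanced accuracy of these conditions (full-joint
enumeration) is 0.931; the end-to-end pipeline at n=500 typically lands
0.02-0.04 below it, the gap being the composite/quadrant channel noise plus
CPT estimation error.

What passing these conditions does *not* show: real questionnaire data has
no crisp level structure, its inter-item correlations are weaker and
patterned, labels are noisy, and demographics correlate with everything.
The synthetic conditions establish that the machinery is correct and that
the pipeline recovers what is recoverable -- not that real-data accuracy
will approach these numbers. Accordingly, no attempt is made to forge a
cohort reproducing the validation study's published cross-validated fit
(~0.70), which depends on the controlled-access data.

## Problem sizes

Defaults used by the test suite and the acceptance script: inference checks
on 200 random networks of <= 8 nodes against full-joint enumeration (1e-9);
search checks on 100 3-node datasets against exhaustive enumeration of all
25 DAGs; parameter and structure recovery at n=20,000 (20 seeds); end-to-end
LOOCV at n=500; null-cohort LOOCV at n=200. These sizes keep the full suite
under a minute of compute while leaving the statistical margins analyzed
above.

## Known limitations

* Only the score-based searches are implemented; the constraint-based
  algorithm names exist for configuration compatibility only.
* No continuous or hybrid networks, no latent-variable learning, no MCMC --
  exact inference is feasible at this scale by design.
* No ROC/AUC machinery and no nested hyperparameter tuning.
* The leave-one-answer-out factor strengths are a local explanation of the
  posterior, not a causal attribution.
* The shipped expert constraints and truth network are illustrative; real
  deployments should supply their own constraint file.
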