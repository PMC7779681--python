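# Methods

This note records the modelling assumptions, parameter choices and
numerical conventions behind `koaprog`, and what the synthetic-data
validation does and does not establish.

## Synthetic cohort generator

The generator emulates an OAI-style longitudinal study: annual visits,
a KL grade per visit, and mixed continuous/ordinal covariates tied
together by a structural causal model.

**Structural equations.** Continuous nodes are linear-Gaussian
(`value = intercept + Σ coef·parent + N(0, σ)`); ordinal nodes are
ordered-logit (`level = #{thresholds below intercept + Σ coef·parent +
Logistic(0,1)}`).  These families were chosen so that the Fisher-z and
G² conditional-independence tests used downstream are well matched to
the generating process.  Age and BMI are truncated to enrollment-style
ranges ([45, 79.5] years, [12, 55] kg/m²) so that the published binning
schemes cover every generated value.

**Default causal structure.** A latent anatomical factor `u_align`
confounds `left_alignment` and `right_alignment`; observed
tibiofemoral/patellofemoral angles are additional parents of the two
alignments; both alignments cause joint-space narrowing (`jsn`); `jsn`,
BMI and age raise the progression hazard; the current KL grade causes
four ordinal symptom items and a continuous pain score, and nothing
flows from symptoms back into progression.  The observed angle parents
matter for identification: they create the v-structures
(`angle *→ alignment ←* alignment`) from which FCI can prove the
alignment pair latently confounded (bidirected edge); without observed
parents of the alignments, the PAG marks on that edge would remain
circles and the confounder claim would be undecidable from data.
Coefficient magnitudes (0.8 on alignment paths, 0.6 into `jsn`, 1.2 per
grade into symptoms, 1.5 into pain) are package constants chosen to
give moderate, realistic correlations (pairwise |r| roughly 0.3–0.6).

**KL dynamics.** The grade follows a first-order Markov chain over
grades 0–4.  Only the at-risk row is a literature value — an at-risk
knee (KL = 1) maintains with probability 0.78 and advances with
probability 0.17 over one year; its remaining 0.05 regresses to KL = 0.
All other rows are package constants chosen to be near-absorbing for
established OA (stay ≥ 0.90), to allow no upward jump of more than one
grade per visit, and to keep backward transitions at or below the 0.05
regression rate.  The hazard score
`0.8·jsn/1.46 + 0.4·(bmi−28)/5 + 0.4·(age−62)/8` (each term one
standardized unit per coefficient) shifts the advance probability on
the logit scale, with the change compensated on the stay entry so rows
remain stochastic.  Baseline KL is drawn from the configured initial
distribution (default 0.35/0.30/0.20/0.10/0.05) through the same
logistic shift, so the baseline cross-section carries the covariate
dependences the causal analysis should find; with modulation disabled
the baseline marginal is exactly the configured distribution and the
chain is exactly the supplied matrix (this is the configuration the
Markov recovery checks use).

**Randomness.** One integer seed; every (node, visit) slot draws from
its own `SeedSequence([seed, ...])` substream, vectorized across
patients, so cohorts are bit-reproducible and adding visits never
perturbs earlier columns.  Missingness is MCAR only — each non-key
covariate cell is masked independently; the KL grade and keys are never
masked.  Real-cohort missingness is unlikely to be MCAR; passing
imputation tests here shows correctness of the mechanics, not
robustness to informative missingness.

## Preprocessing

**Predictive-mean imputation** is implemented as predictive-mean
*matching*: a linear predictor of the target covariate is fitted on the
cohort's fully observed covariates, and each missing cell receives a
seeded draw from the `k = 5` observed rows with nearest predicted mean
(modal donor value for ordinal variables).  Matching preserves the
observed support, which keeps downstream ordinal encodings valid; plain
conditional-mean filling is available via `method="mean"`.

**Binning.** BMI bins close the gaps in the conventional group limits
as half-open intervals `[10,20) [20,26) [26,35) [35,40) [40,∞)`, with
the obese range split at 40 because the odds-ratio table distinguishes
obese from morbidly obese.  Age uses 5-year bins from 45 to 79 with
`[45,50)` as the reference.  Values outside a scheme raise an error
listing the offending rows rather than silently clipping.

**Index knee.** The knee with the strictly higher KL grade; ties go to
the right knee (the retained questionnaire items are dominated by
right-knee items).

**Cross-cohort matching** runs at baseline: donor patients with the
same (age bin, BMI bin) supply missing clinical variables — copied
verbatim for a unique match, averaged (continuous) or taken modal
(ordinal) for multiple matches, left missing and logged for none.
Borrowed values are held constant across a patient's visits.

**Denoisers** operate on column-standardized inputs (mixed units).
PCA is the SVD of the standardized matrix, deterministic up to
component sign.  The autoencoder is one tanh hidden layer with a linear
decoder, trained by full-batch gradient descent (default 300 epochs,
lr 0.05) on squared reconstruction error with the loss history
recorded.

## Logistic selection

IRLS with convergence when the maximum absolute coefficient change
falls below `tol = 1e-10`; Wald standard errors from the inverse Fisher
information at the optimum; 95% intervals `exp(β ± 1.959964·SE)`;
per-variable likelihood-ratio p-values from refits without the
variable, `df = ` number of dropped columns.  Separation is handled by
capping |β| at 15 with a warning rather than penalizing — the reported
odds-ratio tables this mirrors contain unpenalized extreme ratios — so
capped terms carry a flag and their intervals are not trustworthy.  The
default fit uses the baseline visit only (`visit="pooled"` treats every
row as an observation; neither accounts for within-patient
correlation).  `remove_weak_predictors` drops a variable only when its
LRT p-value *and* all its per-level Wald p-values exceed `alpha`
(default 0.5): this codifies a removal rule of the right kind without
claiming any specific published criterion, and the threshold is
exposed as configuration.

## Markov estimation

Transitions are counted between consecutive visits within a patient; a
missing intermediate grade breaks the pair (bridging two non-adjacent
visits would bias toward long-range jumps).  The MLE is row-wise
`(count + s) / (row + 5s)` with pseudo-count `s ≥ 0`; an unobserved row
at `s = 0` becomes an identity row (the grade is treated as
self-maintaining in the absence of evidence).

## Attention-LSTM

A (visits × features) score matrix `A`, all ones at initialization, is
row-normalized at use time (dividing by the row sum, so initialization
is uniform; softmax normalization is available as a flag), multiplied
elementwise into the visit's feature vector, and fed to a standard
LSTM cell (forget/input/output gates, cell candidate, hidden size 32 by
default).  The hidden state maps to a 5-class softmax; KL is treated as
categorical rather than ordinal, matching per-grade one-vs-rest AUC
reporting.  Training is full-batch gradient descent (default lr 0.5) on
masked mean cross-entropy — positions without an observed next-visit
grade are excluded — with all parameters including `A` updated every
epoch and `A` clipped at 1e-6 to stay positive.  Gradients are
analytic BPTT and are verified against central finite differences to
1e-4 relative error in the test suite.  Argmax ties in prediction break
toward the lower grade (the clinically conservative call and NumPy's
first-maximum convention).  Plain gradient descent was chosen over
adaptive optimizers to keep the training trajectory deterministic and
auditable; it needs more epochs (150–400 on the bundled fixtures) than
an adaptive method would.

## FCI

Fisher-z partial correlations (from the inverse of the correlation
submatrix; the plain correlation when the conditioning set is empty)
for continuous data, G² over stratified contingency tables for discrete
data; ordinal variables entering a Fisher-z analysis are converted to
ranks — a documented approximation that attenuates but preserves
monotone dependence.  Defaults `alpha = 0.01`, `max_depth = 3` are
standard constraint-based practice at n ≈ 500–5,000 and both are
exposed.  The skeleton search is PC-style with conditioning sets drawn
from current adjacencies in lexicographic order over the canonically
sorted variable names, which makes the output invariant to input
column order; after provisional v-structure orientation, every
remaining edge is retested against subsets (up to `max_depth`) of the
Possible-D-SEP sets of its endpoints, as full FCI requires under latent
confounding.  Orientation applies Zhang's R1–R4 to a fixed point;
directed consequences of Y-structures emerge from R1.  Marks are
monotone (circle → arrowhead/tail, never back); conflicting requests
keep the arrowhead and emit a warning — finite-sample tests can
contradict each other and silent resolution would hide it.  The
default analysis runs on the baseline visit (one row per patient);
which cross-section a published analysis used is generally unstated,
and pooling visits would violate the tests' i.i.d. assumption.

## Evaluation

Folds are patient-level, stratified by final KL grade, dealt
round-robin so sizes differ by at most one; every visit of a patient
shares a fold, so no leakage is possible by construction.  AUC is
computed as the Mann-Whitney statistic with ties counting one half;
the ROC curve sweeps unique score thresholds.  "Mean decrease in
accuracy" permutes one feature column at a time (default 5 repeats)
against a fixed prediction contract.  The RF/SVM/naive-Bayes
comparators are scikit-learn estimators — they are reference baselines,
not a contribution — evaluated on the flattened one-step-ahead task
(penultimate-visit features, final-visit grade) with this package's own
fold and ROC machinery.

## Problem sizes used in validation

Markov recovery uses 100,000 simulated transitions out of KL = 1
(binomial SE ≈ 0.13 percentage points on the 17% entry, comfortably
inside the ±0.5-point check).  FCI recovery uses 10 cohorts of 10,000
patients; the oracle-equivalence check enumerates all 543 DAGs on four
nodes against a brute-force d-separation reference.  Logistic recovery
uses n = 20,000; LSTM fixtures use 150–250 patients over 3–5 visits.

## Known limitations

- MCAR missingness and single imputation only; no pooling across
  imputations, no MNAR sensitivity.
- The logistic model treats repeated visits cross-sectionally; no GEE
  or mixed-effects correction.
- The Markov chain is time-homogeneous and unadjusted for calendar
  time; the simulator's hazard modulation is the only
  covariate-dependent transition mechanism.
- FCI output is a Markov equivalence class: circles are genuinely
  undecidable from observational data, and the rank approximation for
  ordinal variables can cost power at small n (at 518 patients the
  default cohort yields the correct skeleton but few orientations).
- Synthetic validation shows the estimators recover the structures
  they were built for under the stated generating families; it cannot
  certify behaviour on real cohorts with nonlinearities, informative
  missingness, or measurement error.
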