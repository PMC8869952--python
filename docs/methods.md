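# Methods

## The model

`admoe` discovers Alzheimer's disease (AD) subtypes from region-of-interest
(ROI) gray-matter morphometry — voxel-based density summed within 116
AAL-style regions, or cortical thickness averaged within 68
Desikan-Killiany-style parcels — and measures how consistently two such
morphological measures define the same subtypes.

The core is a semi-supervised mixture-of-experts (MOE): K sparse linear
discriminants ("experts"), each separating AD from cognitively normal (CN)
controls, are coupled to a fuzzy-c-means (FCM) clustering of the AD
subjects.  With residualized feature vectors `x_i`, labels `y_i = +1` (AD)
/ `-1` (CN), expert weights `w_k` (intercept appended, excluded from the
penalty), centroids `d_k` and memberships `m_ik` on the K-simplex, the
joint objective is

    J = sum_k [ 1/2 ||w_k||_1
                + C ( sum_{i in AD} m_ik h_ik(w_k) + s_CN sum_{j in CN} h_jk(w_k) )
                + t sum_{i in AD} m_ik^2 ||x_i - d_k||^2 ],

where `h_ik = max(0, 1 - y_i w_k^T [x_i; 1])^2` is the squared hinge, `C`
penalizes misclassification, and `t` trades the discriminative term
against the clustering term.  A subject's memberships tie the experts
together: each expert is trained mostly on "its" patients, so the experts
specialize into one-subtype-vs-CN discriminants while the FCM term keeps
the subtypes compact.

Modeling assumptions worth stating explicitly:

* **CN participation.**  The membership-weighted hinge runs over AD
  subjects only; every expert additionally sees the full CN group with a
  fixed per-subject weight `cn_weight` (default 1.0).  Without the CN term
  an expert's hinge would be degenerate (one-class).  `cn_weight` is
  exposed because the balance between the shared CN pull and the
  subtype-specific AD pull controls how much the experts differentiate.
* **Fuzzification exponent.**  The centroid update uses exponent `alpha`
  while the scatter term uses `m^2`.  The default `alpha = 2` makes the
  centroid step the exact minimizer of the stated objective; other values
  are accepted but then the centroid step is a heuristic rather than an
  exact block minimization.
* **Linear experts.**  No kernels; K is fixed (default 4), not selected.

## Optimization

Alternating block minimization; every block update is non-increasing in J,
so the objective trace is monotone and this is asserted in the tests:

1. **Centroids** — closed form `d_k = sum_i m_ik^a x_i / sum_i m_ik^a`
   (exact minimizer for `a = 2`).
2. **Experts** — each `w_k` solves `1/2 ||w||_1 + C sum_i s_i h_i(w)^2`
   with weights `s_i = m_ik` (AD) or `cn_weight` (CN), by proximal
   gradient descent (ISTA) with step `1/L`, `L = 2C lambda_max(X^T S X)`,
   plus backtracking: a step is accepted only if the composite objective
   does not increase, so the solve never leaves the warm start worse than
   it found it.  Exactness is not required for the outer monotonicity —
   only this descent contract is.
3. **Memberships** — per subject, the minimizer of
   `sum_k [C m_k h_k + t m_k^2 D_k]` on the simplex has the KKT form
   `m_k = max(0, (lambda - C h_k) / (2 t D_k))`; the active set and
   `lambda` are found exactly by water-filling over the h-sorted experts
   (no iterative root-finding).  Squared distances are floored at
   `d_floor = 1e-12` so the update is defined when a point coincides with
   a centroid.

Convergence: stop when `|J_prev - J| <= tol (1 + |J_prev|)` (default
`tol = 1e-6`) or after `max_iter = 100` outer iterations.  If an expert's
total membership mass collapses below 1e-8, its memberships are re-seeded
on the most ambiguous subjects (the `max(1, N/(2K))` subjects with the
smallest maximum membership get 0.9 on the empty expert); at most three
such restarts, after which the fit errors out.  A re-seed is a jump, not a
descent step, so the objective trace restarts with it — the recorded trace
is always the monotone tail of the run.

Initialization (`init="kmeans"`, default) runs K-means on the AD residuals
and smooths the crisp labels to 0.9 / uniform-rest; `"random"` draws
flat-Dirichlet rows.  Both are reproducible from the seed, and the whole
fit is deterministic given its configuration.

Hard labels are `argmax_k m_ik`, ties to the lowest expert index.
Diagnosis prediction uses the expert max rule: AD iff
`max_k w_k^T [x; 1] > 0`, which is invariant to expert reordering.

## Residualization

Nuisance effects (age, sex, education, intracranial volume) are estimated
on CN subjects only — ordinary least squares per ROI on the design
`[1, age, sex(F=0/M=1), education, icv]` — and the fitted prediction is
subtracted from every subject, CN and AD.  We read the control-referenced
regression as a standard multiple regression with separate coefficients
per covariate per ROI; a single shared scalar coefficient across
covariates with different units would not be meaningfully estimable.
Covariates are not standardized before fitting.  Residuals are z-scored
per ROI using CN mean/SD before entering the MOE (`standardize_residuals`,
default on) so that the SVM margins and FCM distances weigh all ROIs
comparably; the fitted model stores the transform and applies it at
prediction time.  Whether to z-score is genuinely open — it is a flag, not
a hard-coded truth.

## Hyperparameter selection

`(C, t)` are scored on a powers-of-two grid (default `2^-3 .. 2^10`, 14
values per axis, 196 cells) with three indicators, each summarized as mean
and SD over stratified ten-fold cross-validation:

* **ACC** — held-out diagnostic accuracy (%) of the expert max rule;
* **BPC** — Bezdek partition coefficient `(1/N) sum_ik m_ik^2`, 1 for a
  crisp partition, 1/K for a uniform one;
* **W_r** — the largest pairwise |cosine| between expert weight vectors,
  intercept excluded.  We normalize to cosine because the raw inner
  product is contaminated by the arbitrary scale of each expert.

No scalar criterion combines the three, so selection is a documented
lexicographic rule — maximize ACC; ties within 0.5 percentage points go to
the higher BPC, then the lower W_r, then grid order — and the full ranked
grid is always returned so a human can overrule it.  Folds are stratified
by diagnosis only (the latent subtype is unknown at selection time), and
each grid cell is independently re-seeded from the master seed.

## Concordance of two subtype solutions

Solutions from the two measures label the same patients with arbitrary
cluster indices.  On the subjects common to both solutions we build the
K x K contingency table, pair subtypes by maximizing total overlap
(optimal bipartite assignment — deterministic, and it coincides with
matching by visual atrophy pattern whenever the patterns align), and score
each matched pair with the Dice coefficient
`2|A ∩ B| / (|A| + |B|)`.  Subjects seen by only one modality are
excluded; two empty matched sets define Dice 0 with a warning.  When
generator truth is available the report adds each solution's adjusted Rand
index (ARI) against its modality's effective latent subtype.

## Subtype characterization

* **Atrophy maps** are ROI-wise (the pipeline operates on ROI tables, not
  voxel images): Welch two-sample t per ROI on residualized values,
  subtype vs CN, with Benjamini-Hochberg FDR control across the ROIs of
  one map and significance at `q < 0.05`; Cohen's d (pooled SD) is
  reported per ROI.  An uncorrected variant (`correction="none"`)
  reproduces raw-p maps.  ROIs with zero variance in both groups are
  untestable and excluded from the FDR family with a warning.
* **Qualitative variables** (APOE carrier status, CSF abnormality flags):
  Pearson chi-square without continuity correction, minimum expected count
  reported and warned below 5; zero-margin tables are returned as
  untestable rather than given a statistic.
* **Quantitative variables**: one-way ANOVA across subtypes plus
  many-to-one comparisons of each subtype against an explicit reference
  group via Welch t with Bonferroni correction over the K-1 comparisons.
  This is a deliberately conservative substitute for the exact many-to-one
  multivariate-t procedure: it preserves the comparison structure and
  controls the family-wise error from above.  The reference group is a
  required argument — there is no defensible default.
* **CSF abnormality**: amyloid-beta 1-42 abnormal below 192 ng/L, total
  tau above 93, phosphorylated tau above 23; ties at the cutoff are
  normal (standard biomarker convention); missing values produce missing
  flags and shrink the reported denominator, never a sentinel value.

## The synthetic cohort generator

Real subject-level data for this problem is access-restricted, so the
generator is first-class, tested code that emulates the study's structure
with known ground truth.

CN values: per-ROI baseline (fixed given the atlas: density 2.5-4.5
unitless, thickness 2.2-2.9 mm) plus linear covariate effects (age slope
-0.005 density / -0.003 mm per year; small sex, education and ICV effects;
covariates age ~ N(75, 5) yr, sex ~ Bernoulli(0.5), education ~ N(15, 3)
yr, ICV ~ N(1.5e6, 1.5e5) mm^3) plus N(0, noise_sd) noise,
`noise_sd = 0.1`.  AD subjects additionally lose
`effect_size * severity_i * loading_p(z_i)`.

The four templates are built from the atlas's lobe/hemisphere tags: DAD
loads every cortical and subcortical ROI (1.0; cerebellar 0.5); MAD loads
only subcortical ROIs (0.3) and is therefore near-indistinguishable from
CN in a cortex-only thickness atlas — which is the clinically reported
character of that subtype; LTAD loads exactly the left temporal and
parietal ROIs; OSAD loads everything except the occipital lobe, with full
cerebellar (posterior fossa) involvement.  Because severity multiplies the
whole template, a uniformly weaker template would be indistinguishable
from a milder patient of the stronger one; templates therefore differ in
pattern, not magnitude.

Key calibrations, chosen once:

* `effect_size = 0.3` with `noise_sd = 0.1` puts a fully loaded ROI 3 CN
  standard deviations below the healthy expectation — severe but
  realistic atrophy, and comfortably separable.
* `severity ~ LogNormal(0, 0.15)`.  Severity moves subjects along their
  subtype's ray in feature space; its spread must stay below the
  between-template contrasts or the subtype patterns become
  unidentifiable *in principle* for any variance-based clustering (the
  clustering objective then strictly prefers splitting by severity — we
  verified this numerically at sigma = 0.3, where the severity split
  scores 33925 against 37169 for the true partition).  Sigma 0.15 keeps
  patients heterogeneous (5th-95th percentile roughly 0.78-1.28 of median
  severity) while leaving the patterns recoverable.
* `kappa = 0.8`: the probability that a subject expresses the same latent
  subtype in the thickness table as in the density table (the density
  table always carries the true subtype; discordant subjects re-draw
  uniformly among the other K-1).  Expected matched Dice at perfect
  clustering is approximately kappa, so 0.8 places the generated
  concordance in the 70-85% band reported for real dual-measure cohorts.
* Default cohort size 200 CN / 180 AD, equal subtype proportions
  (configurable).

Phenotypes: cognitive scores linear in severity plus noise (MMSE and the
composite scores decline, CDR-SB/ADAS rise); APOE carrier flags Bernoulli
with per-subtype probabilities (defaults give MAD and LTAD elevated
epsilon-2 fractions and DAD the highest epsilon-4 fraction); CSF markers
from two truncated normals strictly on either side of the clinical
cutoffs, mixed by per-subtype abnormal fractions (DAD/OSAD high, MAD
lowest).  A `missing_csf_fraction` knob (default 0) reproduces the heavy
CSF missingness of real cohorts when wanted.

**What the generator does not emulate** — and therefore what passing tests
do not show about real data: ROI values are conditionally independent
given subtype and severity (no inter-regional covariance structure, no
covarying atrophy networks); noise is homoscedastic and Gaussian; there
are no site/scanner effects, no MCI continuum between CN and AD, no
longitudinal drift, and subtype expression discordance is a single
uniform re-draw rather than a structured modality difference.  Recovery
results on these cohorts certify the pipeline's correctness, not its
behavior under real-data confounds.

## Observed behavior on synthetic cohorts

Two fitted quantities behave differently here than on real cohorts, for
understood reasons.  Memberships are fairly fuzzy (BPC near 0.4 at K=4)
because in 68-116 dimensions squared distances concentrate — every subject
is roughly equidistant from all centroids, and the FCM update (membership
proportional to 1/D at alpha=2) then spreads mass, even while the argmax
is decisively correct (ARI near 1).  Relatedly, with `cn_weight = 1.0`
the shared CN hinge dominates each expert's subproblem when memberships
are fuzzy, so expert weight vectors can converge to nearly the same
AD-vs-CN discriminant and W_r approaches 1.  Both are properties of the
synthetic geometry plus the default CN weighting, not optimization
failures; lowering `cn_weight` differentiates the experts.

## Problem sizes used in the shipped analyses

The test suite exercises cohorts up to 200 CN / 400 AD and the
end-to-end analysis script uses 200 CN / 180 AD with ten-fold
cross-validation per modality; the grid-search operation is exercised on
small sub-grids, with the full 196-cell grid left to explicit user runs.
These sizes match the scale of the cohort the pipeline models while
keeping every shipped computation reproducible in minutes on one CPU.

## Known limitations

* Dunnett's exact many-to-one test is not implemented; the Bonferroni
  Welch-t stand-in is conservative.
* K is fixed, not selected; no kernel experts; no nested CV, so grid ACC
  is a selection signal, not an unbiased performance estimate.
* The optimal-assignment subtype matching breaks exact ties by the
  assignment solver's deterministic order, which may differ from a
  visual-pattern match in degenerate cases.
* ISTA solves the expert subproblem to a tolerance, not exactly; the
  outer loop only relies on its descent guarantee.
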