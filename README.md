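# admoe

Semi-supervised subtype discovery for Alzheimer's disease (AD) from ROI
gray-matter morphometry, and concordance analysis of subtype solutions
produced from two different morphological measures.

## Who this is for

Neuroimaging and biostatistics researchers who have subjects x ROI tables
of gray-matter measures — voxel-based density summed within AAL-style
regions, or FreeSurfer cortical thickness averaged within
Desikan-Killiany parcels — for a case/control cohort, and who want to
(1) partition the patients into atrophy subtypes with a discriminative
clustering model, and (2) ask whether two measures of the same anatomy
define the same subtypes.  Because the motivating cohort data is
access-restricted, the package ships a fully specified synthetic cohort
generator with known ground truth; every stage is developed and tested
against it.

## The model

After control-referenced residualization (per-ROI OLS of each feature on
`[1, age, sex, education, ICV]` fitted on CN subjects only, subtracted
from everyone), subtypes are found by a joint mixture-of-experts: K
L1-regularized squared-hinge linear SVMs, each separating AD (`y = +1`)
from CN (`y = -1`), coupled to fuzzy-c-means clustering of the AD
subjects through memberships `m_ik` on the K-simplex:

```
min_{w, m}  Σ_k [ ½‖w_k‖₁ + C ( Σ_{i∈AD} m_ik max(0, 1 − y_i w_kᵀx_i)²
                                + Σ_{j∈CN} max(0, 1 − y_j w_kᵀx_j)² )
                  + t Σ_{i∈AD} m_ik² ‖x_i − d_k‖² ]
s.t.  Σ_k m_ik = 1,  m_ik ∈ [0, 1],   d_k = Σ_i m_ik² x_i / Σ_i m_ik²
```

Optimization alternates exact centroid and membership updates with
warm-started monotone proximal-gradient SVM solves, so the objective is
non-increasing by construction.  Hyperparameters `(C, t)` are scored on a
powers-of-two grid by ten-fold cross-validated accuracy (ACC), the Bezdek
partition coefficient (BPC) and the maximum pairwise expert cosine (W_r).
Subtype solutions from two measures are paired by optimal assignment on
their contingency table and scored with Dice coefficients
`2|A∩B|/(|A|+|B|)`; discovered subtypes are profiled with ROI-wise
Welch-t atrophy maps under Benjamini-Hochberg FDR control, chi-square
tests for carrier-type variables, ANOVA with many-to-one pairwise
comparisons, and CSF biomarker abnormality at the clinical cutoffs
(Aβ1-42 < 192, T-tau > 93, P-tau > 23 ng/L).

See `docs/methods.md` for the full model account, numerical choices and
limitations.

## Worked example

`examples/` contains one narrative script per capability (simulation,
residualization, fitting, selection, concordance, characterization).  The
concordance example generates a 200 CN / 180 AD dual-modality cohort in
which each AD subject expresses the same latent subtype in both tables
with probability κ = 0.8, fits the K=4 model independently per modality,
and matches the solutions:

```
$ python examples/05_concordance.py
subtype pairing (density -> ct): {1: 4, 2: 3, 3: 2, 4: 1}
  matched pair 1: Dice = 79.5%
  matched pair 2: Dice = 89.5%
  matched pair 3: Dice = 79.5%
  matched pair 4: Dice = 78.7%
mean Dice 81.8% (range 78.7-89.5%)
ARI vs truth: density 1.000, ct 0.984
```

Reading this: both modality fits recover the generator's latent subtypes
essentially exactly (adjusted Rand index ≈ 1), so the matched Dice
scores of ~80% reflect the built-in κ = 0.8 modality disagreement, not
clustering error — the same reading one would give imperfect Dice overlap
between density-based and thickness-based subtypes in a real cohort.

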