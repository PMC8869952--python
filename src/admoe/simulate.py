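"""Synthetic dual-modality cohort generator with known ground truth.

Real subject-level data from the cohort this pipeline targets is
access-restricted, so every downstream stage is exercised on generated
cohorts that emulate its structure: cognitively normal (CN) controls whose
ROI values are a per-ROI baseline plus linear age/sex/education/ICV effects
plus Gaussian noise, and AD patients who additionally lose signal according
to one of four latent atrophy subtypes:

* DAD  — diffuse atrophy: loading on essentially every region;
* MAD  — minimal atrophy: no cortical loading, sporadic subcortical loading;
* LTAD — left temporal-parietal dominant atrophy;
* OSAD — atrophy everywhere except the occipital lobe.

Each AD subject carries one latent subtype ``z`` and a positive severity
scalar shared by both modalities.  The *density* table always expresses
``z``; the *ct* table expresses ``z`` with probability ``kappa`` and
otherwise a uniformly re-drawn other subtype.  ``kappa`` is therefore a
single interpretable knob that maps directly onto the expected Dice overlap
of subtype solutions recovered from the two tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import RoiSpec, aal116_atlas, dk68_atlas, validate_atlas
from .io import PHENOTYPE_COLUMNS, FeatureTable, PhenotypeTable

SUBTYPE_NAMES = ("DAD", "MAD", "LTAD", "OSAD")

# CSF biomarker abnormality cutoffs (ng/L): amyloid-beta 1-42 below,
# total tau and phosphorylated tau above.
ABETA_CUTOFF = 192.0
TTAU_CUTOFF = 93.0
PTAU_CUTOFF = 23.0

# Linear covariate effects on CN ROI values: [age, sex(M=1), education, icv].
# Units: feature-units per year / per category / per year / per mm^3.
COVARIATE_EFFECTS = {
    "density": np.array([-0.005, -0.05, 0.002, 2.0e-7]),
    "ct": np.array([-0.003, -0.03, 0.001, 1.0e-7]),
}

_BASELINE_SEED = 20220187  # fixed: baselines depend on the atlas, not the cohort seed


@dataclass
class AtrophyTemplate:
    """Fractional atrophy loading per ROI for one subtype, values in [0, 1]."""

    subtype_name: str
    roi_loadings: np.ndarray

    def __post_init__(self) -> None:
        self.roi_loadings = np.asarray(self.roi_loadings, dtype=float)
        if self.subtype_name not in SUBTYPE_NAMES:
            raise ValueError(f"unknown subtype name {self.subtype_name!r}")
        if ((self.roi_loadings < 0) | (self.roi_loadings > 1)).any():
            raise ValueError("template loadings must lie in [0, 1]")


def make_atrophy_templates(atlas_spec: list[RoiSpec]) -> list[AtrophyTemplate]:
    """Build the four subtype templates from an atlas's lobe/hemisphere tags.

    Deterministic given the atlas.  Construction rules:

    * DAD: 1.0 on every cortical and subcortical ROI, 0.5 cerebellar.
    * MAD: 0.3 on subcortical ROIs only (zero wherever the atlas has no
      subcortical regions, as in a cortex-only thickness atlas).
    * LTAD: 1.0 exactly where hemisphere is L and lobe is temporal or
      parietal.
    * OSAD: zero on occipital ROIs, 1.0 on other cortical/subcortical ROIs
      and 1.0 cerebellar — occipital sparing with prominent posterior-fossa
      involvement.

    The loading magnitudes keep the four template rays mutually
    distinguishable under per-subject severity scaling: because severity
    multiplies the whole template, a weaker copy of a template is
    indistinguishable from a milder patient of the stronger one, so
    templates that differ must differ in *pattern* (support or relative
    regional emphasis), not merely in overall magnitude.

    Raises ``ValueError`` when the atlas cannot define a template (no
    left-temporal ROI for LTAD, no occipital ROI for OSAD).
    """
    validate_atlas(atlas_spec)
    lobes = np.array([r.lobe for r in atlas_spec])
    hemis = np.array([r.hemisphere for r in atlas_spec])
    cerebellar = lobes == "cerebellar"
    subcortical = lobes == "subcortical"
    occipital = lobes == "occipital"

    dad = np.where(cerebellar, 0.5, 1.0)

    mad = np.where(subcortical, 0.3, 0.0)

    ltad_mask = (hemis == "L") & np.isin(lobes, ["temporal", "parietal"])
    if not ltad_mask.any():
        raise ValueError("atlas has no left temporal/parietal ROI: LTAD undefinable")
    ltad = np.where(ltad_mask, 1.0, 0.0)

    if not occipital.any():
        raise ValueError("atlas has no occipital ROI: OSAD undefinable")
    osad = np.where(occipital, 0.0, 1.0)

    return [
        AtrophyTemplate("DAD", dad),
        AtrophyTemplate("MAD", mad),
        AtrophyTemplate("LTAD", ltad),
        AtrophyTemplate("OSAD", osad),
    ]


def roi_baselines(atlas_spec: list[RoiSpec], modality: str) -> np.ndarray:
    """Healthy-control baseline value per ROI.

    Drawn once from a fixed internal stream so baselines depend only on the
    atlas and modality, never on the cohort seed: density baselines span
    2.5-4.5 (unitless summed density), thickness baselines 2.2-2.9 mm.
    """
    rng = np.random.default_rng([_BASELINE_SEED, len(atlas_spec)])
    u = rng.uniform(size=len(atlas_spec))
    if modality == "density":
        return 2.5 + 2.0 * u
    if modality == "ct":
        return 2.2 + 0.7 * u
    raise ValueError(f"unknown modality {modality!r}")


@dataclass
class SyntheticTruth:
    """Ground-truth latent state of the AD subjects of a generated cohort.

    ``df`` columns: subject_id, z (latent subtype index 1..K), severity,
    z_effective_density, z_effective_ct.  ``kappa`` is the concordance
    probability that was used; ``subtype_names[z-1]`` names subtype ``z``.
    """

    df: pd.DataFrame
    kappa: float
    subtype_names: tuple[str, ...] = SUBTYPE_NAMES

    @property
    def subject_ids(self) -> pd.Series:
        return self.df["subject_id"]

    def labels(self, modality: str = "density") -> np.ndarray:
        col = {"density": "z_effective_density", "ct": "z_effective_ct"}[modality]
        return self.df[col].to_numpy(dtype=int)


def _draw_covariates(rng: np.random.Generator, n: int) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "age": rng.normal(75.0, 5.0, size=n),
            "sex": np.where(rng.random(n) < 0.5, "F", "M"),
            "education": rng.normal(15.0, 3.0, size=n),
            "icv": rng.normal(1.5e6, 1.5e5, size=n),
        }
    )


def _modality_values(
    rng: np.random.Generator,
    covariates: pd.DataFrame,
    diagnosis: np.ndarray,
    z_effective: np.ndarray,
    severity: np.ndarray,
    templates: list[AtrophyTemplate],
    atlas: list[RoiSpec],
    modality: str,
    effect_size: float,
    noise_sd: float,
) -> np.ndarray:
    n = len(covariates)
    base = roi_baselines(atlas, modality)
    betas = COVARIATE_EFFECTS[modality]
    sex01 = (covariates["sex"] == "M").to_numpy(dtype=float)
    design = np.column_stack(
        [
            covariates["age"].to_numpy(),
            sex01,
            covariates["education"].to_numpy(),
            covariates["icv"].to_numpy(),
        ]
    )
    values = base[None, :] + (design @ betas)[:, None]  # (n, P) via broadcasting
    ad_rows = np.flatnonzero(diagnosis == "AD")
    loadings = np.stack([t.roi_loadings for t in templates])  # K x P
    for i in ad_rows:
        values[i] -= effect_size * severity[i] * loadings[z_effective[i] - 1]
    values += rng.normal(0.0, noise_sd, size=values.shape)
    return values


def generate_cohort(
    n_cn: int,
    n_ad: int,
    *,
    effect_size: float = 0.3,
    kappa: float = 0.8,
    noise_sd: float = 0.1,
    severity_sigma: float = 0.15,
    seed: int,
    proportions: list[float] | None = None,
    atlas_density: list[RoiSpec] | None = None,
    atlas_ct: list[RoiSpec] | None = None,
    templates_density: list[AtrophyTemplate] | None = None,
    templates_ct: list[AtrophyTemplate] | None = None,
    phenotype_config: "PhenotypeConfig | None" = None,
) -> tuple[FeatureTable, FeatureTable, SyntheticTruth, PhenotypeTable]:
    """Generate a paired density/thickness cohort with known ground truth.

    Covariates are drawn once per subject (age ~ N(75, 5) years, sex
    Bernoulli(0.5), education ~ N(15, 3) years, ICV ~ N(1.5e6, 1.5e5) mm^3)
    and shared by both modalities, as are the latent subtype ``z`` (default
    equal proportions) and severity ~ LogNormal(0, severity_sigma).  The
    thickness table re-draws each AD subject's expressed subtype uniformly
    among the other K-1 with probability 1 - kappa.  Fully reproducible
    from ``seed``.

    Severity multiplies the whole atrophy template, so its spread moves
    subjects *along* their subtype's direction in feature space.  The
    default severity_sigma = 0.15 keeps that within-subtype spread smaller
    than the between-template contrasts; much larger values make subtype
    patterns unidentifiable in principle for any variance-based clustering,
    because a severe occipital-sparing patient becomes indistinguishable
    from a mild diffuse one.
    """
    if severity_sigma < 0:
        raise ValueError("severity_sigma must be >= 0")
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    if effect_size < 0:
        raise ValueError("effect_size must be >= 0")
    if atlas_density is None:
        atlas_density = aal116_atlas()
    if atlas_ct is None:
        atlas_ct = dk68_atlas()
    if templates_density is None:
        templates_density = make_atrophy_templates(atlas_density)
    if templates_ct is None:
        templates_ct = make_atrophy_templates(atlas_ct)
    K = len(templates_density)
    if len(templates_ct) != K:
        raise ValueError("template lists must have equal length")
    if n_cn < K or n_ad < K:
        raise ValueError(f"n_cn and n_ad must each be >= K={K}")
    if proportions is None:
        proportions = [1.0 / K] * K
    proportions = np.asarray(proportions, dtype=float)
    if len(proportions) != K or (proportions < 0).any():
        raise ValueError("proportions must be K nonnegative values")
    proportions = proportions / proportions.sum()

    ss = np.random.SeedSequence([int(seed), 0])
    (
        rng_cov,
        rng_z,
        rng_sev,
        rng_kappa,
        rng_density,
        rng_ct,
        rng_phen,
    ) = [np.random.default_rng(s) for s in ss.spawn(7)]

    n = n_cn + n_ad
    subject_ids = [f"S{i + 1:04d}" for i in range(n)]
    diagnosis = np.array(["CN"] * n_cn + ["AD"] * n_ad)
    covariates = _draw_covariates(rng_cov, n)

    z = rng_z.choice(np.arange(1, K + 1), size=n_ad, p=proportions)
    severity = rng_sev.lognormal(mean=0.0, sigma=severity_sigma, size=n_ad)

    # density expresses the true subtype; thickness flips with prob 1-kappa
    z_eff_density = z.copy()
    z_eff_ct = z.copy()
    flip = rng_kappa.random(n_ad) >= kappa
    for i in np.flatnonzero(flip):
        others = [k for k in range(1, K + 1) if k != z[i]]
        z_eff_ct[i] = others[rng_kappa.integers(len(others))]

    z_full = np.zeros(n, dtype=int)
    sev_full = np.zeros(n)
    z_eff_d_full = np.zeros(n, dtype=int)
    z_eff_c_full = np.zeros(n, dtype=int)
    z_full[n_cn:] = z
    sev_full[n_cn:] = severity
    z_eff_d_full[n_cn:] = z_eff_density
    z_eff_c_full[n_cn:] = z_eff_ct

    tables = {}
    for modality, atlas, templates, rng_mod, z_eff in (
        ("density", atlas_density, templates_density, rng_density, z_eff_d_full),
        ("ct", atlas_ct, templates_ct, rng_ct, z_eff_c_full),
    ):
        values = _modality_values(
            rng_mod, covariates, diagnosis, z_eff, sev_full,
            templates, atlas, modality, effect_size, noise_sd,
        )
        df = pd.DataFrame(
            {
                "subject_id": subject_ids,
                "diagnosis": diagnosis,
                "age": covariates["age"],
                "sex": covariates["sex"],
                "education": covariates["education"],
                "icv": covariates["icv"],
            }
        )
        roi_df = pd.DataFrame(values, columns=[r.name for r in atlas], index=df.index)
        tables[modality] = FeatureTable(pd.concat([df, roi_df], axis=1), modality)

    truth = SyntheticTruth(
        pd.DataFrame(
            {
                "subject_id": np.array(subject_ids)[n_cn:],
                "z": z,
                "severity": severity,
                "z_effective_density": z_eff_density,
                "z_effective_ct": z_eff_ct,
            }
        ),
        kappa=kappa,
        subtype_names=tuple(t.subtype_name for t in templates_density),
    )
    phenotypes = generate_phenotypes(
        truth,
        config=phenotype_config,
        seed=rng_phen.integers(2**31),
        ages=pd.Series(covariates["age"].to_numpy()[n_cn:], index=truth.df.index),
    )
    return tables["density"], tables["ct"], truth, phenotypes


def _per_subtype(value, subtype_names) -> dict[str, float]:
    if isinstance(value, dict):
        return {s: float(value[s]) for s in subtype_names}
    return {s: float(value) for s in subtype_names}


@dataclass
class PhenotypeConfig:
    """Parameters of the synthetic clinical phenotype model.

    Cognitive scores are linear in the latent severity scalar plus Gaussian
    noise (MMSE and composites decline with severity; CDR-SB and ADAS
    rise).  APOE carrier flags are Bernoulli with per-subtype probabilities;
    CSF markers are drawn from a two-component model: with the subtype's
    abnormal fraction, from a truncated normal strictly on the abnormal
    side of the clinical cutoff (A-beta < 192, T-tau > 93, P-tau > 23
    ng/L), otherwise from the normal side.
    """

    mmse_intercept: float = 29.0
    mmse_severity_slope: float = 5.0
    mmse_sd: float = 1.5
    duration_mean: float = 2.5
    duration_sd: float = 1.0
    apoe_e2: dict | float = field(
        default_factory=lambda: {"DAD": 0.04, "MAD": 0.15, "LTAD": 0.12, "OSAD": 0.05}
    )
    apoe_e4: dict | float = field(
        default_factory=lambda: {"DAD": 0.70, "MAD": 0.45, "LTAD": 0.55, "OSAD": 0.65}
    )
    abnormal_abeta: dict | float = field(
        default_factory=lambda: {"DAD": 0.92, "MAD": 0.55, "LTAD": 0.70, "OSAD": 0.90}
    )
    abnormal_ttau: dict | float = field(
        default_factory=lambda: {"DAD": 0.75, "MAD": 0.40, "LTAD": 0.55, "OSAD": 0.80}
    )
    abnormal_ptau: dict | float = field(
        default_factory=lambda: {"DAD": 0.85, "MAD": 0.45, "LTAD": 0.60, "OSAD": 0.70}
    )
    missing_csf_fraction: float = 0.0


def _truncated_normal(rng, mean, sd, low, high, size):
    a = (low - mean) / sd
    b = (high - mean) / sd
    return stats.truncnorm.rvs(a, b, loc=mean, scale=sd, size=size, random_state=rng)


def generate_phenotypes(
    truth: SyntheticTruth,
    config: PhenotypeConfig | None = None,
    seed: int = 0,
    ages: pd.Series | None = None,
) -> PhenotypeTable:
    """Draw clinical phenotypes for the AD subjects of a synthetic cohort."""
    if config is None:
        config = PhenotypeConfig()
    names = truth.subtype_names
    probs = {
        key: _per_subtype(getattr(config, key), names)
        for key in ("apoe_e2", "apoe_e4", "abnormal_abeta", "abnormal_ttau", "abnormal_ptau")
    }
    for key, by_subtype in probs.items():
        for s, p in by_subtype.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{key}[{s}] = {p} outside [0, 1]")
    if not 0.0 <= config.missing_csf_fraction <= 1.0:
        raise ValueError("missing_csf_fraction outside [0, 1]")

    rng = np.random.default_rng(seed)
    n = len(truth.df)
    sev = truth.df["severity"].to_numpy()
    subtype = np.array([names[z - 1] for z in truth.df["z"]])
    if ages is None:
        ages = pd.Series(rng.normal(75.0, 5.0, size=n))
    ages = np.asarray(ages, dtype=float)

    duration = np.maximum(
        0.3, rng.normal(config.duration_mean, config.duration_sd, size=n)
    )
    mmse = np.clip(
        config.mmse_intercept
        - config.mmse_severity_slope * sev
        + rng.normal(0.0, config.mmse_sd, size=n),
        0.0,
        30.0,
    )
    cdrsb = np.clip(1.0 + 4.0 * sev + rng.normal(0.0, 1.0, size=n), 0.0, 18.0)
    adas11 = np.clip(5.0 + 12.0 * sev + rng.normal(0.0, 2.5, size=n), 0.0, 70.0)
    adas13 = np.clip(8.0 + 15.0 * sev + rng.normal(0.0, 3.0, size=n), 0.0, 85.0)
    adni_mem = 0.2 - 1.0 * sev + rng.normal(0.0, 0.3, size=n)
    adni_ef = 0.1 - 0.8 * sev + rng.normal(0.0, 0.35, size=n)
    adni_lan = 0.1 - 0.7 * sev + rng.normal(0.0, 0.35, size=n)
    adni_vs = 0.0 - 0.6 * sev + rng.normal(0.0, 0.4, size=n)

    def bern(key):
        p = np.array([probs[key][s] for s in subtype])
        return (rng.random(n) < p).astype(int)

    apoe_e2 = bern("apoe_e2")
    apoe_e4 = bern("apoe_e4")

    abn_abeta = rng.random(n) < np.array([probs["abnormal_abeta"][s] for s in subtype])
    abn_ttau = rng.random(n) < np.array([probs["abnormal_ttau"][s] for s in subtype])
    abn_ptau = rng.random(n) < np.array([probs["abnormal_ptau"][s] for s in subtype])

    abeta = np.where(
        abn_abeta,
        _truncated_normal(rng, 145.0, 25.0, 20.0, ABETA_CUTOFF - 1e-9, n),
        _truncated_normal(rng, 235.0, 30.0, ABETA_CUTOFF, 450.0, n),
    )
    ttau = np.where(
        abn_ttau,
        _truncated_normal(rng, 135.0, 35.0, TTAU_CUTOFF + 1e-9, 400.0, n),
        _truncated_normal(rng, 60.0, 15.0, 5.0, TTAU_CUTOFF, n),
    )
    ptau = np.where(
        abn_ptau,
        _truncated_normal(rng, 40.0, 12.0, PTAU_CUTOFF + 1e-9, 120.0, n),
        _truncated_normal(rng, 15.0, 4.5, 2.0, PTAU_CUTOFF, n),
    )

    if config.missing_csf_fraction > 0:
        miss = rng.random(n) < config.missing_csf_fraction
        abeta = np.where(miss, np.nan, abeta)
        ttau = np.where(miss, np.nan, ttau)
        ptau = np.where(miss, np.nan, ptau)

    df = pd.DataFrame(
        {
            "subject_id": truth.df["subject_id"].to_numpy(),
            "onset_age": ages - duration,
            "duration": duration,
            "mmse": mmse,
            "cdrsb": cdrsb,
            "adas11": adas11,
            "adas13": adas13,
            "adni_mem": adni_mem,
            "adni_ef": adni_ef,
            "adni_lan": adni_lan,
            "adni_vs": adni_vs,
            "apoe_e2": apoe_e2,
            "apoe_e4": apoe_e4,
            "abeta": abeta,
            "ttau": ttau,
            "ptau": ptau,
        },
        columns=PHENOTYPE_COLUMNS,
    )
    return PhenotypeTable(df)
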