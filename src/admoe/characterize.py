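"""Subtype characterization: atrophy maps, group tests, CSF flags.

Given a subtype solution, each subtype is profiled three ways:

* ROI-wise atrophy map vs CN — a Welch two-sample t-test per ROI on the
  residualized values, with Benjamini-Hochberg FDR control across the ROIs
  of one map (q < 0.05 by default) and Cohen's d effect sizes.  Maps are
  per-ROI rather than per-voxel because the pipeline operates on ROI
  tables; an uncorrected-p variant is available via ``correction="none"``.
* Qualitative variables (APOE carrier status, sex, CSF abnormality flags) —
  Pearson chi-square without continuity correction on the 2x2 table, with
  the minimum expected count reported and a warning below 5.
* Quantitative variables (cognitive scores, demographics) — one-way ANOVA
  across subtypes plus many-to-one pairwise comparisons of each group
  against a chosen reference group via Welch t-tests with Bonferroni
  correction over the K-1 comparisons (a conservative stand-in for the
  exact many-to-one multivariate-t procedure, with the same comparison
  structure).

CSF abnormality follows the standard biomarker convention: amyloid-beta
1-42 is abnormal *below* its cutoff, total and phosphorylated tau *above*
theirs; values exactly at the cutoff count as normal.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import PhenotypeTable
from .residualize import ResidualTable
from .simulate import ABETA_CUTOFF, PTAU_CUTOFF, TTAU_CUTOFF

ATROPHY_MAP_COLUMNS = ["roi", "t", "p", "q", "cohens_d", "significant"]


@dataclass
class GroupComparison:
    """Result of one group-difference test."""

    variable: str
    test: str  # chi-square | anova | pairwise
    statistic: float | None
    p: float | None
    status: str = "ok"  # ok | untestable
    detail: dict = field(default_factory=dict)
    group_summaries: dict = field(default_factory=dict)


def _cohens_d(a: np.ndarray, b: np.ndarray) -> float:
    na, nb = len(a), len(b)
    pooled = np.sqrt(
        ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    )
    if pooled == 0:
        return 0.0
    return float((a.mean() - b.mean()) / pooled)


def roi_atrophy_map(
    subtype_members: set,
    cn_subjects: set,
    residuals: ResidualTable,
    q_threshold: float = 0.05,
    correction: str = "bh",
) -> pd.DataFrame:
    """ROI-wise subtype-vs-CN difference map on residualized features.

    Returns a DataFrame with one row per ROI: Welch t, raw p, BH-adjusted q
    (or q = p when ``correction="none"``), Cohen's d, and the significance
    flag at ``q < q_threshold``.  ROIs with zero variance in both groups
    are untestable: they get NaN statistics, are excluded from the FDR
    family, and a warning is emitted.
    """
    if correction not in ("bh", "none"):
        raise ValueError("correction must be 'bh' or 'none'")
    ids = residuals.subject_ids
    mask_sub = ids.isin(subtype_members).to_numpy()
    mask_cn = ids.isin(cn_subjects).to_numpy()
    if mask_sub.sum() < 3 or mask_cn.sum() < 3:
        raise ValueError("both groups need at least 3 subjects")
    A = residuals.values[mask_sub]
    B = residuals.values[mask_cn]
    P = A.shape[1]
    testable = (A.var(axis=0, ddof=1) > 0) | (B.var(axis=0, ddof=1) > 0)
    tvals = np.full(P, np.nan)
    pvals = np.full(P, np.nan)
    dvals = np.full(P, np.nan)
    if testable.any():
        t, p = stats.ttest_ind(A[:, testable], B[:, testable], equal_var=False, axis=0)
        tvals[testable] = t
        pvals[testable] = p
        na, nb = len(A), len(B)
        pooled = np.sqrt(
            (
                (na - 1) * A[:, testable].var(axis=0, ddof=1)
                + (nb - 1) * B[:, testable].var(axis=0, ddof=1)
            )
            / (na + nb - 2)
        )
        with np.errstate(invalid="ignore", divide="ignore"):
            d = (A[:, testable].mean(axis=0) - B[:, testable].mean(axis=0)) / pooled
        dvals[testable] = np.where(pooled > 0, d, 0.0)
    if not testable.all():
        warnings.warn(
            f"{(~testable).sum()} ROI(s) with zero variance in both groups "
            "excluded from the FDR family",
            stacklevel=2,
        )
    qvals = np.full(P, np.nan)
    if correction == "bh":
        if testable.any():
            _, q, _, _ = multipletests(pvals[testable], method="fdr_bh")
            qvals[testable] = q
    else:
        qvals[testable] = pvals[testable]
    significant = np.zeros(P, dtype=bool)
    significant[testable] = qvals[testable] < q_threshold
    return pd.DataFrame(
        {
            "roi": residuals.roi_names,
            "t": tvals,
            "p": pvals,
            "q": qvals,
            "cohens_d": dvals,
            "significant": significant,
        },
        columns=ATROPHY_MAP_COLUMNS,
    )


def compare_qualitative(
    group_a: set,
    group_b: set,
    flag_variable: str,
    phenotypes: PhenotypeTable,
) -> GroupComparison:
    """Pearson chi-square (no continuity correction) of flag x group.

    Subjects with a missing flag are dropped (count reported in
    ``detail["n_missing"]``).  A zero margin — all carriers or none, or an
    empty group — makes the table untestable; the result then carries
    ``status="untestable"`` and no statistic.
    """
    df = phenotypes.df.set_index("subject_id")
    table = np.zeros((2, 2))
    n_missing = 0
    summaries = {}
    for gi, members in enumerate((group_a, group_b)):
        present = [s for s in members if s in df.index]
        flags = df.loc[present, flag_variable]
        n_missing += int(flags.isna().sum())
        flags = flags.dropna()
        table[gi, 0] = float((flags == 0).sum())
        table[gi, 1] = float((flags != 0).sum())
        summaries[f"group_{'ab'[gi]}"] = {
            "n": int(len(flags)),
            "carriers": int((flags != 0).sum()),
        }
    detail = {"table": table.tolist(), "n_missing": n_missing}
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        return GroupComparison(
            variable=flag_variable, test="chi-square", statistic=None, p=None,
            status="untestable", detail=detail, group_summaries=summaries,
        )
    chi2, p, dof, expected = stats.chi2_contingency(table, correction=False)
    detail["dof"] = int(dof)
    detail["min_expected"] = float(expected.min())
    if expected.min() < 5:
        warnings.warn(
            f"chi-square for {flag_variable!r}: minimum expected count "
            f"{expected.min():.2f} < 5",
            stacklevel=2,
        )
    return GroupComparison(
        variable=flag_variable, test="chi-square",
        statistic=float(chi2), p=float(p),
        detail=detail, group_summaries=summaries,
    )


def compare_quantitative(
    groups: list[set],
    variable: str,
    phenotypes: PhenotypeTable,
    reference_index: int,
) -> list[GroupComparison]:
    """One-way ANOVA plus many-to-one pairwise comparisons.

    ``groups`` is a list of subject-id sets; ``reference_index`` selects the
    reference group every other group is compared against (Welch t with
    Bonferroni correction over the K-1 comparisons).  Groups with fewer
    than 2 non-missing values are dropped with a warning.  Returns the
    ANOVA result first, then one pairwise result per non-reference group.
    """
    df = phenotypes.df.set_index("subject_id")
    samples: list[np.ndarray | None] = []
    for members in groups:
        present = [s for s in members if s in df.index]
        vals = df.loc[present, variable].dropna().to_numpy(dtype=float)
        if len(vals) < 2:
            warnings.warn(
                f"group with <2 usable values dropped for {variable!r}",
                stacklevel=2,
            )
            samples.append(None)
        else:
            samples.append(vals)
    usable = [s for s in samples if s is not None]
    if len(usable) < 2:
        raise ValueError(f"fewer than 2 usable groups for {variable!r}")
    if samples[reference_index] is None:
        raise ValueError("reference group has too few usable values")

    summaries = {
        f"group_{i}": {
            "n": 0 if s is None else int(len(s)),
            "mean": None if s is None else float(s.mean()),
            "sd": None if s is None else float(s.std(ddof=1)),
        }
        for i, s in enumerate(samples)
    }
    F, p = stats.f_oneway(*usable)
    results = [
        GroupComparison(
            variable=variable, test="anova", statistic=float(F), p=float(p),
            group_summaries=summaries,
        )
    ]
    ref = samples[reference_index]
    n_comparisons = sum(
        1 for i, s in enumerate(samples) if i != reference_index and s is not None
    )
    for i, s in enumerate(samples):
        if i == reference_index or s is None:
            continue
        t, p_raw = stats.ttest_ind(s, ref, equal_var=False)
        p_adj = min(1.0, float(p_raw) * n_comparisons)
        results.append(
            GroupComparison(
                variable=variable, test="pairwise",
                statistic=float(t), p=p_adj,
                detail={
                    "group": i,
                    "reference": reference_index,
                    "p_raw": float(p_raw),
                    "bonferroni_m": n_comparisons,
                },
            )
        )
    return results


def csf_abnormality(phenotypes: PhenotypeTable) -> pd.DataFrame:
    """Per-subject abnormality flags for the three CSF biomarkers.

    Abnormal iff abeta < 192, ttau > 93, ptau > 23 (ng/L); values at the
    cutoff are normal.  Missing values yield NA flags and are excluded from
    any downstream proportion's denominator.  Negative concentrations are
    a validation error.
    """
    df = phenotypes.df
    out = pd.DataFrame({"subject_id": df["subject_id"]})
    for col, cutoff, direction in (
        ("abeta", ABETA_CUTOFF, "below"),
        ("ttau", TTAU_CUTOFF, "above"),
        ("ptau", PTAU_CUTOFF, "above"),
    ):
        vals = df[col]
        if (vals.dropna() < 0).any():
            raise ValueError(f"negative {col} concentration")
        if direction == "below":
            flag = vals < cutoff
        else:
            flag = vals > cutoff
        out[f"abnormal_{col}"] = flag.where(vals.notna(), other=pd.NA)
    return out


def abnormal_proportions(flags: pd.DataFrame) -> pd.DataFrame:
    """Abnormal fraction per biomarker with the non-missing denominator."""
    rows = []
    for col in ("abnormal_abeta", "abnormal_ttau", "abnormal_ptau"):
        usable = flags[col].dropna()
        rows.append(
            {
                "biomarker": col.removeprefix("abnormal_"),
                "n_usable": int(len(usable)),
                "proportion_abnormal": (
                    float(usable.mean()) if len(usable) else np.nan
                ),
            }
        )
    return pd.DataFrame(rows)
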