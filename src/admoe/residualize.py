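"""Control-referenced covariate residualization of ROI features.

Nuisance effects of age, sex, education and intracranial volume are
estimated by ordinary least squares on the CN subjects only — one
regression per ROI with design ``[1, age, sex, education, icv]`` — and the
fitted linear predictor is then subtracted from *every* subject's values,
CN and AD alike.  Fitting on controls only keeps disease-related atrophy
out of the covariate coefficients, so AD residuals retain the disease
signal relative to the healthy-aging expectation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import FeatureTable

DESIGN_COLUMNS = ["intercept", "age", "sex", "education", "icv"]


@dataclass
class CovariateModel:
    """Per-ROI OLS coefficients fitted on CN subjects.

    ``beta`` is P x 5 (columns: intercept, age, sex, education, icv);
    ``roi_names`` fixes the ROI order the model applies to.
    """

    beta: np.ndarray
    roi_names: list[str]
    n_cn_fit: int
    modality: str

    def __post_init__(self) -> None:
        self.beta = np.asarray(self.beta, dtype=float)
        if self.beta.shape != (len(self.roi_names), len(DESIGN_COLUMNS)):
            raise ValueError("beta must be P x 5 matching roi_names")
        if not np.isfinite(self.beta).all():
            raise ValueError("beta contains non-finite entries")
        if self.n_cn_fit < 6:
            raise ValueError("need at least 6 CN subjects to fit 5 coefficients")


@dataclass
class ResidualTable:
    """Residualized features; same subjects and ROI order as the source."""

    df: pd.DataFrame  # subject_id, diagnosis, then ROI residual columns
    modality: str

    @property
    def roi_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in ("subject_id", "diagnosis")]

    @property
    def subject_ids(self) -> pd.Series:
        return self.df["subject_id"]

    @property
    def diagnosis(self) -> pd.Series:
        return self.df["diagnosis"]

    @property
    def values(self) -> np.ndarray:
        return self.df[self.roi_names].to_numpy(dtype=float)

    def subset(self, mask_or_index) -> "ResidualTable":
        idx = np.asarray(mask_or_index)
        sub = self.df.loc[idx] if idx.dtype == bool else self.df.iloc[idx]
        return ResidualTable(sub.reset_index(drop=True), self.modality)


def _check_design_rank(X: np.ndarray) -> None:
    """Raise naming the collinear column(s) when the CN design is deficient."""
    for j, name in enumerate(DESIGN_COLUMNS[1:], start=1):
        if np.ptp(X[:, j]) == 0.0:
            raise ValueError(
                f"rank-deficient CN design: covariate {name!r} is constant"
            )
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # identify a column whose removal restores full rank
        for j, name in enumerate(DESIGN_COLUMNS):
            reduced = np.delete(X, j, axis=1)
            if np.linalg.matrix_rank(reduced) == rank:
                raise ValueError(
                    f"rank-deficient CN design: column {name!r} is collinear"
                )
        raise ValueError("rank-deficient CN design")


def fit_cn_covariate_model(table: FeatureTable) -> CovariateModel:
    """OLS fit of the covariate model on the CN rows of ``table``.

    Requires at least 6 CN subjects and a full-rank CN design matrix.
    """
    cn_mask = (table.diagnosis == "CN").to_numpy()
    n_cn = int(cn_mask.sum())
    if n_cn < 6:
        raise ValueError(f"need at least 6 CN subjects, found {n_cn}")
    X = table.covariate_design()[cn_mask]
    _check_design_rank(X)
    Y = table.values[cn_mask]
    beta, *_ = np.linalg.lstsq(X, Y, rcond=None)  # 5 x P
    return CovariateModel(
        beta=beta.T,
        roi_names=table.roi_names,
        n_cn_fit=n_cn,
        modality=table.modality,
    )


def residualize(table: FeatureTable, model: CovariateModel) -> ResidualTable:
    """Subtract the CN-fitted covariate prediction from every subject."""
    if table.modality != model.modality:
        raise ValueError(
            f"modality mismatch: table {table.modality!r} vs model {model.modality!r}"
        )
    if table.roi_names != model.roi_names:
        for a, b in zip(table.roi_names, model.roi_names):
            if a != b:
                raise ValueError(f"ROI mismatch: table {a!r} vs model {b!r}")
        raise ValueError("ROI lists differ in length")
    X = table.covariate_design()
    residuals = table.values - X @ model.beta.T
    df = pd.DataFrame(
        {"subject_id": table.subject_ids, "diagnosis": table.diagnosis}
    )
    out = pd.concat(
        [df, pd.DataFrame(residuals, columns=model.roi_names, index=df.index)],
        axis=1,
    )
    return ResidualTable(out, table.modality)


def residualize_pipeline(table: FeatureTable) -> tuple[ResidualTable, CovariateModel]:
    """Convenience: fit on CN then residualize all subjects of ``table``."""
    model = fit_cn_covariate_model(table)
    return residualize(table, model), model


def residual_table_from_feature_table(
    table: FeatureTable, residuals: np.ndarray
) -> ResidualTable:
    """Package an externally computed residual matrix with table metadata."""
    df = pd.DataFrame({"subject_id": table.subject_ids, "diagnosis": table.diagnosis})
    out = pd.concat(
        [df, pd.DataFrame(residuals, columns=table.roi_names, index=df.index)], axis=1
    )
    return ResidualTable(out, table.modality)


def write_residual_table(table: ResidualTable, path) -> None:
    table.df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_residual_table(path, modality: str) -> ResidualTable:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    if "subject_id" not in df.columns or "diagnosis" not in df.columns:
        raise ValueError("residual CSV must have subject_id and diagnosis columns")
    return ResidualTable(df, modality)
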