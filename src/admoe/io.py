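"""Feature-table and phenotype-table containers and CSV I/O.

The canonical feature CSV layout is::

    subject_id,diagnosis,age,sex,education,icv,<roi_1>,...,<roi_P>

with ``diagnosis`` in {CN, AD}, ``sex`` in {F, M}, ``age``/``education`` in
years, ``icv`` (intracranial volume) in mm^3, and one numeric column per ROI.
Real ADNI exports ('uaspmvbm.csv'-like VBM density tables, 'ucsffx.csv'-like
FreeSurfer thickness tables) carry idiosyncratic headers; they are expected
to be renamed to this canonical dialect before loading.

Missing ROI values are a load error: morphometry exports are complete by
construction, so a hole indicates a broken extraction, not data to impute.
Phenotype fields, by contrast, may legitimately be missing (CSF markers in
particular) and are kept as explicit NA values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

MANDATORY_COLUMNS = ["subject_id", "diagnosis", "age", "sex", "education", "icv"]

PHENOTYPE_COLUMNS = [
    "subject_id",
    "onset_age",
    "duration",
    "mmse",
    "cdrsb",
    "adas11",
    "adas13",
    "adni_mem",
    "adni_ef",
    "adni_lan",
    "adni_vs",
    "apoe_e2",
    "apoe_e4",
    "abeta",
    "ttau",
    "ptau",
]

MODALITIES = ("density", "ct")


class FormatError(ValueError):
    """A table violates the canonical column/value contract."""


@dataclass
class FeatureTable:
    """Subjects x ROI morphometry values for one modality.

    ``df`` holds the six mandatory columns followed by the ROI columns in
    their original order.  ``modality`` is ``"density"`` (unitless summed
    gray-matter density) or ``"ct"`` (cortical thickness in mm).
    """

    df: pd.DataFrame
    modality: str

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise FormatError(f"unknown modality {self.modality!r}")
        cols = list(self.df.columns)
        for name in MANDATORY_COLUMNS:
            if name not in cols:
                raise FormatError(f"missing mandatory column: {name}")
        if cols[: len(MANDATORY_COLUMNS)] != MANDATORY_COLUMNS:
            raise FormatError(
                "mandatory columns must come first in canonical order "
                f"{MANDATORY_COLUMNS}"
            )
        if len(self.df) == 0:
            raise FormatError("feature table has no subjects")
        if self.df["subject_id"].duplicated().any():
            dup = self.df["subject_id"][self.df["subject_id"].duplicated()].iloc[0]
            raise FormatError(f"duplicate subject_id: {dup!r}")
        bad_dx = set(self.df["diagnosis"]) - {"CN", "AD"}
        if bad_dx:
            raise FormatError(f"diagnosis values outside {{CN, AD}}: {sorted(bad_dx)}")
        bad_sex = set(self.df["sex"]) - {"F", "M"}
        if bad_sex:
            raise FormatError(f"sex values outside {{F, M}}: {sorted(bad_sex)}")
        if len(self.roi_names) < 2:
            raise FormatError("feature table needs at least 2 ROI columns")
        vals = self.df[self.roi_names]
        for col in self.roi_names + ["age", "education", "icv"]:
            if not pd.api.types.is_numeric_dtype(self.df[col]):
                raise FormatError(f"non-numeric column: {col}")
        arr = vals.to_numpy(dtype=float)
        if not np.isfinite(arr).all():
            i, j = np.argwhere(~np.isfinite(arr))[0]
            raise FormatError(
                f"missing/non-finite ROI value at row {i} column {self.roi_names[j]!r}"
            )

    @property
    def roi_names(self) -> list[str]:
        return [c for c in self.df.columns if c not in MANDATORY_COLUMNS]

    @property
    def subject_ids(self) -> pd.Series:
        return self.df["subject_id"]

    @property
    def diagnosis(self) -> pd.Series:
        return self.df["diagnosis"]

    @property
    def values(self) -> np.ndarray:
        """Subjects x P matrix of ROI values."""
        return self.df[self.roi_names].to_numpy(dtype=float)

    @property
    def n_subjects(self) -> int:
        return len(self.df)

    @property
    def n_roi(self) -> int:
        return len(self.roi_names)

    def covariate_design(self) -> np.ndarray:
        """Design matrix [1, age, sex(F=0/M=1), education, icv] per subject."""
        sex01 = (self.df["sex"] == "M").to_numpy(dtype=float)
        return np.column_stack(
            [
                np.ones(len(self.df)),
                self.df["age"].to_numpy(dtype=float),
                sex01,
                self.df["education"].to_numpy(dtype=float),
                self.df["icv"].to_numpy(dtype=float),
            ]
        )

    def subset(self, mask_or_index) -> "FeatureTable":
        idx = np.asarray(mask_or_index)
        sub = self.df.loc[idx] if idx.dtype == bool else self.df.iloc[idx]
        return FeatureTable(sub.reset_index(drop=True), self.modality)


@dataclass
class PhenotypeTable:
    """Per-subject clinical phenotypes; score and CSF fields may be NA."""

    df: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.df.columns)
        if cols != PHENOTYPE_COLUMNS:
            raise FormatError(
                f"phenotype table must have columns {PHENOTYPE_COLUMNS}, got {cols}"
            )
        if self.df["subject_id"].duplicated().any():
            raise FormatError("duplicate subject_id in phenotype table")

    @property
    def subject_ids(self) -> pd.Series:
        return self.df["subject_id"]


def read_feature_table(path, modality: str) -> FeatureTable:
    """Read a canonical feature CSV, validating the column contract.

    Raises :class:`FormatError` naming the offending column/row on a missing
    mandatory column, a non-numeric or missing ROI cell, or a duplicated
    subject_id.
    """
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    for name in MANDATORY_COLUMNS:
        if name not in df.columns:
            raise FormatError(f"missing mandatory column: {name}")
    roi_cols = [c for c in df.columns if c not in MANDATORY_COLUMNS]
    for col in roi_cols + ["age", "education", "icv"]:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            row = int(np.argmax(bad.to_numpy()))
            raise FormatError(
                f"non-numeric or missing value at row {row} column {col!r}"
            )
        df[col] = numeric
    return FeatureTable(df, modality)


def write_feature_table(table: FeatureTable, path) -> None:
    """Write a feature table in the canonical CSV dialect.

    Floats are written with Python's shortest round-trippable repr, so a
    write/read cycle reproduces the table exactly.
    """
    table.df.to_csv(path, index=False, float_format=lambda x: repr(float(x)))


def read_phenotype_table(path) -> PhenotypeTable:
    df = pd.read_csv(path, dtype={"subject_id": str}, float_precision="round_trip")
    return PhenotypeTable(df)


def write_phenotype_table(table: PhenotypeTable, path) -> None:
    """Write phenotypes; missing values become empty fields, never sentinels."""
    table.df.to_csv(path, index=False, na_rep="", float_format=lambda x: repr(float(x)))
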