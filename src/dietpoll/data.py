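"""Household table container, CSV I/O and validation.

A :class:`HouseholdTable` wraps a pandas ``DataFrame`` with one row per
surveyed household/child together with the :class:`~dietpoll.codebook.VariableCodebook`
describing its coded columns.  Reserved columns:

``id``
    unique record identifier (text).
``weight``
    non-negative observation mass ``w_s``; survey sampling weights or 1.
``diet_class``
    1 = inadequate dietary diversity (the *treated* state), 0 = adequate.
``stunting``
    1 = height-for-age more than 2 SD below the reference mean.
``child_age_months``, ``interview_day``
    integer age and day-of-fieldwork index.

All other columns must be declared in the codebook (role ``covariate`` or
``item-flag``) and hold consecutive non-negative integer codes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .codebook import VariableCodebook

logger = logging.getLogger(__name__)

RESERVED = ("id", "weight", "diet_class", "stunting", "child_age_months", "interview_day")

#: default analysis window in months: children under 6 months are presumed
#: breast-/bottle-fed and excluded from diet-diversity analysis; the survey
#: covers children up to 25 months.
DEFAULT_AGE_WINDOW = (6, 25)


@dataclass
class HouseholdTable:
    """Validated household-level sample with observation masses."""

    df: pd.DataFrame
    codebook: VariableCodebook

    def __post_init__(self) -> None:
        self.df = self.df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def total_mass(self) -> float:
        return float(self.df["weight"].sum())

    @property
    def weights(self) -> np.ndarray:
        return self.df["weight"].to_numpy(dtype=float)

    def column(self, name: str) -> np.ndarray:
        return self.df[name].to_numpy()

    def copy(self) -> "HouseholdTable":
        return HouseholdTable(self.df.copy(), self.codebook)

    # ------------------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            raise ValueError("household table is empty")
        if "id" not in df.columns:
            raise ValueError("missing required column 'id'")
        if df["id"].duplicated().any():
            dup = df.loc[df["id"].duplicated(), "id"].iloc[0]
            raise ValueError(f"duplicate household id {dup!r}")
        if "weight" not in df.columns:
            raise ValueError("missing 'weight' column (call load_households to default)")
        if (df["weight"] < 0).any():
            row = int(np.flatnonzero(df["weight"].to_numpy() < 0)[0])
            raise ValueError(f"negative weight in row {row}")
        if self.total_mass <= 0:
            raise ValueError("total mass must be positive")
        for col in ("diet_class", "stunting"):
            if col in df.columns:
                vals = df[col].dropna().unique()
                bad = [v for v in vals if v not in (0, 1)]
                if bad:
                    raise ValueError(f"column {col!r} must be binary, found {bad[0]!r}")
        for name in self.codebook.names():
            if name not in df.columns:
                continue
            var = self.codebook[name]
            codes = df[name].to_numpy()
            invalid = (codes < 0) | (codes >= var.n_categories)
            if invalid.any():
                row = int(np.flatnonzero(invalid)[0])
                raise ValueError(
                    f"row {row}: code {codes[row]} invalid for variable "
                    f"{name!r} ({var.n_categories} categories)"
                )

    def write_csv(self, path) -> None:
        self.df.to_csv(path, index=False)


def load_households(path, codebook: VariableCodebook) -> HouseholdTable:
    """Load and validate a household CSV against ``codebook``.

    Covariate and item-flag columns may contain either integer codes or
    category labels; labels are translated through the codebook and unknown
    labels raise with the offending row, column and label.  A missing
    ``weight`` column defaults every mass to 1 with a logged warning.
    """
    df = pd.read_csv(path, dtype={"id": str})
    if len(df) == 0:
        raise ValueError(f"{path}: file has no data rows")

    if "weight" not in df.columns:
        logger.warning("%s: no 'weight' column; defaulting all %d weights to 1", path, len(df))
        df["weight"] = 1.0
    else:
        n_missing = int(df["weight"].isna().sum())
        if n_missing:
            logger.warning("%s: %d missing weights defaulted to 1", path, n_missing)
            df["weight"] = df["weight"].fillna(1.0)

    coded = [n for n in codebook.names() if n in df.columns]
    for name in coded:
        var = codebook[name]
        col = df[name]
        if col.isna().any():
            row = int(np.flatnonzero(col.isna().to_numpy())[0])
            raise ValueError(f"row {row}, column {name!r}: missing value")
        if not pd.api.types.is_numeric_dtype(col):
            known = {lab: i for i, lab in enumerate(var.labels)}
            unknown = ~col.astype(str).isin(known)
            if unknown.any():
                row = int(np.flatnonzero(unknown.to_numpy())[0])
                raise ValueError(
                    f"row {row}, column {name!r}: label {col.iloc[row]!r} "
                    f"not in codebook"
                )
            df[name] = col.astype(str).map(known).astype(int)
        else:
            if not np.allclose(col.to_numpy(dtype=float) % 1, 0):
                row = int(np.flatnonzero(col.to_numpy(dtype=float) % 1 != 0)[0])
                raise ValueError(f"row {row}, column {name!r}: non-integer code {col.iloc[row]}")
            df[name] = col.astype(int)

    table = HouseholdTable(df, codebook)
    table.validate()
    return table


def filter_age_window(
    table: HouseholdTable,
    min_months: int = DEFAULT_AGE_WINDOW[0],
    max_months: int = DEFAULT_AGE_WINDOW[1],
) -> HouseholdTable:
    """Keep records with ``min_months <= child_age_months <= max_months``.

    The default window drops under-6-month children (still breast-/bottle-fed,
    so diet diversity is not meaningfully measured) and those above 25 months
    (outside the recall instrument's reach).
    """
    if min_months > max_months:
        raise ValueError(f"min_months {min_months} exceeds max_months {max_months}")
    age = table.df["child_age_months"]
    keep = (age >= min_months) & (age <= max_months)
    n_drop = int((~keep).sum())
    if keep.sum() == 0:
        raise ValueError(
            f"no records in age window [{min_months}, {max_months}] months; "
            "check the window against the data"
        )
    if n_drop:
        logger.info("age filter [%d, %d]: dropped %d of %d records",
                    min_months, max_months, n_drop, len(table))
    return HouseholdTable(table.df.loc[keep].reset_index(drop=True), table.codebook)
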