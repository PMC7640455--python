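"""Child Dietary Diversity Score (CDDS) construction and adequacy classing.

The 24-h recall instrument asks about 13 individual food items; these
collapse onto 7 food groups (grains/roots/tubers, vitamin-A rich foods,
other fruits and vegetables, meat/poultry/fish, eggs, pulses/legumes/nuts,
milk products).  A group scores 1 whenever at least one of its items was
consumed, the CDDS is the number of groups scored (0-7), and a child with
CDDS strictly above the adequacy threshold (default 3) has an *adequate*
diet.  ``diet_class = 1 - adequate`` is the treatment state used downstream:
treated means inadequate diversity.

The survey is fielded over several months, so measured diversity can carry
an artificial seasonal trend from non-random interview timing;
:func:`detrend_interview_timing` removes the linear day trend from the
adequacy indicator by within-day re-thresholding of the score.
"""

from __future__ import annotations

import importlib.resources
import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .data import HouseholdTable

logger = logging.getLogger(__name__)

N_GROUPS = 7
DEFAULT_ADEQUACY_THRESHOLD = 3


@dataclass(frozen=True)
class CddsMapping:
    """Item -> food-group map with group labels indexed 1..7."""

    item_to_class: dict[str, int]
    class_labels: dict[int, str]

    def __post_init__(self) -> None:
        classes = set(self.item_to_class.values())
        if not classes <= set(self.class_labels):
            raise ValueError("item mapped to unlabelled food group")
        if set(self.class_labels) != set(range(1, N_GROUPS + 1)):
            raise ValueError(f"class labels must index 1..{N_GROUPS}")
        if len(classes) != N_GROUPS:
            missing = sorted(set(self.class_labels) - classes)
            raise ValueError(f"food groups {missing} unreachable from any item")

    @property
    def items(self) -> list[str]:
        return list(self.item_to_class)

    @classmethod
    def default(cls) -> "CddsMapping":
        """The shipped 13-item survey mapping."""
        ref = importlib.resources.files("dietpoll") / "data" / "cdds_mapping.yaml"
        spec = yaml.safe_load(ref.read_text())
        return cls(
            item_to_class={str(k): int(v) for k, v in spec["items"].items()},
            class_labels={int(k): str(v) for k, v in spec["class_labels"].items()},
        )

    @classmethod
    def from_yaml(cls, path) -> "CddsMapping":
        with open(path) as fh:
            spec = yaml.safe_load(fh)
        return cls(
            item_to_class={str(k): int(v) for k, v in spec["items"].items()},
            class_labels={int(k): str(v) for k, v in spec["class_labels"].items()},
        )


def map_items_to_groups(
    item_flags: Mapping[str, int] | pd.DataFrame, mapping: CddsMapping | None = None
) -> np.ndarray:
    """Collapse item flags to 7 group flags (group = 1 iff any item in it is 1).

    Accepts a single record as a mapping or a DataFrame of records; returns
    shape (7,) or (n, 7) arrays of 0/1 flags ordered by group index 1..7.
    """
    mapping = mapping or CddsMapping.default()
    if isinstance(item_flags, pd.DataFrame):
        frame = item_flags
        single = False
    else:
        unknown = set(item_flags) - set(mapping.item_to_class)
        if unknown:
            raise KeyError(f"unknown item(s): {sorted(unknown)}")
        frame = pd.DataFrame([item_flags])
        single = True

    missing = [it for it in mapping.items if it not in frame.columns]
    if missing:
        raise KeyError(f"missing item flag(s): {missing}")

    groups = np.zeros((len(frame), N_GROUPS), dtype=int)
    for item, cls in mapping.item_to_class.items():
        flags = frame[item].to_numpy(dtype=int)
        if not np.isin(flags, (0, 1)).all():
            raise ValueError(f"item {item!r} flags must be 0/1")
        groups[:, cls - 1] |= flags
    return groups[0] if single else groups


def compute_cdds(group_flags: Sequence[int] | np.ndarray) -> np.ndarray | int:
    """Dietary diversity score: the number of food groups consumed (0-7)."""
    arr = np.asarray(group_flags, dtype=int)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError("group flags must be binary")
    if arr.shape[-1] != N_GROUPS:
        raise ValueError(f"expected {N_GROUPS} group flags, got {arr.shape[-1]}")
    score = arr.sum(axis=-1)
    return int(score) if score.ndim == 0 else score


def classify_adequacy(cdds, threshold: int = DEFAULT_ADEQUACY_THRESHOLD):
    """Adequate diversity iff CDDS exceeds ``threshold`` (strictly).

    Returns 0/1 with the same shape as ``cdds``.  The complement,
    ``diet_class = 1 - adequate``, marks the treated (inadequate) state.
    """
    if not 0 <= threshold <= N_GROUPS:
        raise ValueError(f"threshold must lie in 0..{N_GROUPS}, got {threshold}")
    arr = np.asarray(cdds, dtype=int)
    if (arr < 0).any() or (arr > N_GROUPS).any():
        raise ValueError("CDDS values must lie in 0..7")
    adequate = (arr > threshold).astype(int)
    return int(adequate) if adequate.ndim == 0 else adequate


def score_table(
    table: HouseholdTable,
    mapping: CddsMapping | None = None,
    threshold: int = DEFAULT_ADEQUACY_THRESHOLD,
) -> HouseholdTable:
    """Compute ``cdds`` and ``diet_class`` columns from a table's item flags."""
    mapping = mapping or CddsMapping.default()
    groups = map_items_to_groups(table.df, mapping)
    score = compute_cdds(groups)
    df = table.df.copy()
    df["cdds"] = score
    df["diet_class"] = 1 - classify_adequacy(score, threshold)
    return HouseholdTable(df, table.codebook)


def detrend_interview_timing(
    table: HouseholdTable, method: str = "none"
) -> HouseholdTable:
    """Remove the linear interview-day trend from the adequacy indicator.

    ``method="none"`` returns the table unchanged.  ``method="day-regression"``
    fits a linear-probability regression of the adequacy indicator on the
    interview-day index and re-thresholds within each day so that each day's
    adequate count is moved by exactly the fitted linear component: day *d*
    with observed adequacy rate ``p_d`` is re-targeted to
    ``p_d - b1 * (d - mean(day))``.  Within a day, records are ranked by CDDS
    (higher scores stay adequate; ties broken by current class, then id) so
    the adjustment flips the marginal diets first.  Non-linear day-to-day
    variation is deliberately preserved — only the fitted linear trend is
    removed.
    """
    if method == "none":
        return table
    if method != "day-regression":
        raise ValueError(f"unknown detrend method {method!r}")

    df = table.df.copy()
    day = df["interview_day"].to_numpy(dtype=float)
    if np.ptp(day) == 0:
        logger.warning("interview_day is constant; detrending skipped")
        return table
    adequate = 1 - df["diet_class"].to_numpy(dtype=int)
    day_c = day - day.mean()
    b1 = float(np.dot(day_c, adequate) / np.dot(day_c, day_c))

    rank_score = df["cdds"].to_numpy(dtype=float) if "cdds" in df.columns else np.zeros(len(df))
    # tie-break: keep the current classification, then id order
    order_key = pd.DataFrame({
        "day": df["interview_day"].to_numpy(),
        "score": -rank_score,
        "keep": -adequate,
        "id": df["id"].to_numpy(),
    })

    adjusted = np.zeros(len(df), dtype=int)
    n_flips = 0
    for d, idx in df.groupby("interview_day").groups.items():
        idx = np.asarray(idx)
        n_d = len(idx)
        p_d = adequate[idx].mean()
        target = float(np.clip(p_d - b1 * (float(d) - day.mean()), 0.0, 1.0))
        k_d = int(round(n_d * target))
        sub = order_key.loc[idx].sort_values(["score", "keep", "id"])
        chosen = sub.index[:k_d]
        adjusted[chosen] = 1
        n_flips += int((adjusted[idx] != adequate[idx]).sum())

    if n_flips:
        logger.info("interview-timing detrend flipped %d of %d adequacy labels",
                    n_flips, len(df))
    df["diet_class"] = 1 - adjusted
    return HouseholdTable(df, table.codebook)
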