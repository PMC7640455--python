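"""Univariate screening of candidate profiling variables.

Each candidate covariate is regressed (probit, matching the treatment
model family) against the binary outcome on its category indicators; the
variable's p-value is the joint Wald test that all its category effects
are zero.  Candidates are ranked by ascending p-value and the top-k kept
for profile enumeration and matching.  Ties are broken lexicographically
by variable name so the selection is reproducible and independent of the
candidate list order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .data import HouseholdTable
from .matching import build_design, _find_separating_column

logger = logging.getLogger(__name__)

DEFAULT_TOP_K = 10


@dataclass
class ScreenResult:
    variable: str
    statistic: float
    p_value: float
    rank: int
    note: str = ""


def _single_variable_pvalue(table: HouseholdTable, candidate: str, outcome: str):
    y = table.df[outcome].to_numpy(dtype=float)
    if table.df[candidate].nunique() < 2:
        return np.nan, 1.0, "single observed category"
    X = build_design(table, [candidate])
    X = X.loc[:, (X != 0).any() | (X.columns == "const")]  # drop empty categories
    slopes = [c for c in X.columns if c != "const"]

    sep = _find_separating_column(X, y)
    if sep is None:
        try:
            res = sm.Probit(y, X).fit(disp=0, maxiter=100, method="newton")
            if res.mle_retvals.get("converged", False):
                constraint = " = ".join(slopes) + " = 0" if len(slopes) > 1 else f"{slopes[0]} = 0"
                wald = res.wald_test(constraint, scalar=True)
                return float(wald.statistic), float(wald.pvalue), ""
        except np.linalg.LinAlgError:
            pass

    # separation or non-convergence: fall back to a linear-probability F test,
    # which stays defined when the probit likelihood diverges
    ols = sm.OLS(y, X).fit()
    fres = ols.f_test(np.eye(len(X.columns))[1:])
    note = f"separation on {sep}; LPM fallback" if sep else "probit fallback to LPM"
    logger.warning("screening %s: %s", candidate, note)
    return float(fres.statistic), float(fres.pvalue), note


def univariate_screen(
    table: HouseholdTable,
    candidates: list[str],
    outcome: str = "diet_class",
    k: int = DEFAULT_TOP_K,
) -> list[ScreenResult]:
    """Rank candidates by univariate p-value; return the top-k.

    A candidate with a single observed category is uninformative and gets
    p = 1 with a warning.
    """
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} candidates")
    vals = set(np.unique(table.df[outcome].to_numpy()))
    if not vals <= {0, 1}:
        raise ValueError(f"outcome {outcome!r} must be binary")

    scored = []
    for cand in sorted(candidates):
        stat, p, note = _single_variable_pvalue(table, cand, outcome)
        if note == "single observed category":
            logger.warning("screening %s: single observed category, p set to 1", cand)
        scored.append((cand, stat, p, note))

    # ascending p, ties by name (already name-sorted; stable sort preserves it)
    scored.sort(key=lambda t: t[2])
    results = [
        ScreenResult(variable=c, statistic=s, p_value=p, rank=i + 1, note=note)
        for i, (c, s, p, note) in enumerate(scored)
    ]
    return results[:k]
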