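"""Polling: exhaustive non-parametric profiling of a target group.

A *profile* fixes a subset of the coded covariates at specific values and
thereby defines a population subgroup.  For a relevant group (here:
children with inadequate diet diversity, ``diet_class == 1``) and profile
``x`` the engine computes, from observation masses ``w_s``:

- ``coverage`` — mass of group members inside the profile over total group
  mass,
- exclusion error ``lambda = 1 - coverage`` — the group mass the profile
  misses,
- inclusion error ``mu`` — the share of the profile's mass that is *not* in
  the group,
- ``psi(alpha) = lambda**alpha * mu**(1 - alpha)`` — the weighted geometric
  mean of the two errors, minimised over profiles to pick a *winning*
  profile per weight ``alpha``.

Enumeration is exhaustive over every value assignment of every k-subset of
the candidate variables; no greedy search is involved.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .codebook import VariableCodebook
from .data import HouseholdTable

logger = logging.getLogger(__name__)

DEFAULT_ALPHA_GRID = tuple(np.round(np.arange(0.0, 1.0 + 1e-9, 0.1), 10))


@dataclass(frozen=True)
class Profile:
    """A subset of covariates fixed at specific codes."""

    variables: tuple[str, ...]
    values: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.variables) != len(self.values):
            raise ValueError("variables and values must align")
        if len(set(self.variables)) != len(self.variables):
            raise ValueError(f"repeated variable in profile {self.variables}")

    @property
    def key(self) -> tuple:
        """Deterministic sort key (lexicographic on variable/value pairs)."""
        return tuple(sorted(zip(self.variables, self.values)))

    def mask(self, table: HouseholdTable) -> np.ndarray:
        """Boolean membership vector over the table's records."""
        m = np.ones(len(table), dtype=bool)
        for var, val in zip(self.variables, self.values):
            m &= table.df[var].to_numpy() == val
        return m

    def describe(self, codebook: VariableCodebook | None = None) -> str:
        parts = []
        for var, val in zip(self.variables, self.values):
            label = codebook[var].label_of(val) if codebook else str(val)
            parts.append(f"{var}={label}")
        return ", ".join(parts)


@dataclass
class PollingMetrics:
    """Mass-based need metrics for one profile."""

    profile: Profile
    mass: float              # m_gc: group mass inside the profile
    group_mass: float        # total mass of the relevant group
    profile_mass: float      # total mass inside the profile
    coverage: float
    lambda_polling: float
    mu_polling: float
    n_members: int = 0
    estimable: bool = True

    def psi(self, alpha: float) -> float:
        return psi(self.lambda_polling, self.mu_polling, alpha)


@dataclass
class WinningProfile:
    alpha: float
    profile: Profile
    psi_value: float
    ties: list[Profile] = field(default_factory=list)


def n_variable_subsets(n_variables: int, k: int) -> int:
    """Number of k-subsets of the candidate variables (C(n, k))."""
    if k <= 0:
        raise ValueError(f"profile size k must be positive, got {k}")
    if k > n_variables:
        raise ValueError(f"k={k} exceeds the {n_variables} candidate variables")
    return math.comb(n_variables, k)


def enumerate_profiles(
    variables: Sequence[str], k: int, codebook: VariableCodebook
) -> list[Profile]:
    """Every value assignment of every k-subset of ``variables``."""
    n_subsets = n_variable_subsets(len(variables), k)
    unknown = [v for v in variables if v not in codebook]
    if unknown:
        raise KeyError(f"variables not in codebook: {unknown}")
    profiles: list[Profile] = []
    for subset in itertools.combinations(variables, k):
        value_ranges = [codebook[v].codes for v in subset]
        for values in itertools.product(*value_ranges):
            profiles.append(Profile(tuple(subset), tuple(int(v) for v in values)))
    logger.info("enumerated %d profiles over %d variable subsets (k=%d)",
                len(profiles), n_subsets, k)
    return profiles


def polling_metrics(
    profile: Profile, table: HouseholdTable, group: int = 1,
    group_var: str = "diet_class",
) -> PollingMetrics:
    """Coverage and inclusion/exclusion errors of one profile."""
    w = table.weights
    in_group = table.df[group_var].to_numpy() == group
    group_mass = float(w[in_group].sum())
    if group_mass <= 0:
        raise ValueError(f"group {group_var}=={group} has no mass")
    member = profile.mask(table)
    mass = float(w[member & in_group].sum())
    profile_mass = float(w[member].sum())
    coverage = mass / group_mass
    if profile_mass > 0:
        mu = 1.0 - mass / profile_mass
        estimable = True
    else:
        mu = float("nan")
        estimable = False
    return PollingMetrics(
        profile=profile,
        mass=mass,
        group_mass=group_mass,
        profile_mass=profile_mass,
        coverage=coverage,
        lambda_polling=1.0 - coverage,
        mu_polling=mu,
        n_members=int(member.sum()),
        estimable=estimable,
    )


def polling_metrics_all(
    profiles: Iterable[Profile], table: HouseholdTable, group: int = 1,
    group_var: str = "diet_class", min_members: int = 0,
) -> list[PollingMetrics]:
    """Metrics for many profiles, sharing per-(variable, value) masks.

    Profiles with fewer than ``min_members`` records are marked inestimable
    and excluded from any subsequent ranking.
    """
    w = table.weights
    in_group = table.df[group_var].to_numpy() == group
    group_mass = float(w[in_group].sum())
    if group_mass <= 0:
        raise ValueError(f"group {group_var}=={group} has no mass")
    cell_masks: dict[tuple[str, int], np.ndarray] = {}

    def cell(var: str, val: int) -> np.ndarray:
        key = (var, val)
        if key not in cell_masks:
            cell_masks[key] = table.df[var].to_numpy() == val
        return cell_masks[key]

    out: list[PollingMetrics] = []
    w_group = w * in_group
    for i, prof in enumerate(profiles):
        member = cell(prof.variables[0], prof.values[0]).copy()
        for var, val in zip(prof.variables[1:], prof.values[1:]):
            member &= cell(var, val)
        mass = float(w_group[member].sum())
        profile_mass = float(w[member].sum())
        n_members = int(member.sum())
        coverage = mass / group_mass
        estimable = profile_mass > 0 and n_members >= min_members
        mu = 1.0 - mass / profile_mass if profile_mass > 0 else float("nan")
        out.append(PollingMetrics(
            profile=prof, mass=mass, group_mass=group_mass,
            profile_mass=profile_mass, coverage=coverage,
            lambda_polling=1.0 - coverage, mu_polling=mu,
            n_members=n_members, estimable=estimable,
        ))
        if (i + 1) % 1000 == 0:
            logger.debug("polling metrics: %d profiles done", i + 1)
    return out


def psi(lam: float, mu: float, alpha: float) -> float:
    """Weighted geometric mean of errors, ``lam**alpha * mu**(1 - alpha)``.

    ``0**0`` is taken as 1, so a profile with a zero error scores 0 at the
    matching boundary alpha.
    """
    for name, v in (("lambda", lam), ("mu", mu), ("alpha", alpha)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {v}")
    return float(lam ** alpha) * float(mu ** (1.0 - alpha))


def winning_profiles(
    metrics: Sequence[PollingMetrics],
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    tie_tol: float = 1e-12,
) -> list[WinningProfile]:
    """The psi-minimising profile per alpha; ties reported, not hidden.

    The primary winner among exact ties is the lexicographically smallest
    profile key, so results do not depend on enumeration order.
    """
    usable = [m for m in metrics if m.estimable and np.isfinite(m.mu_polling)]
    if not usable:
        raise ValueError("no estimable profiles to rank")
    winners = []
    for alpha in alpha_grid:
        vals = np.array([m.psi(alpha) for m in usable])
        best = float(vals.min())
        tied = [usable[i].profile for i in np.flatnonzero(vals <= best + tie_tol)]
        tied.sort(key=lambda p: p.key)
        winners.append(WinningProfile(
            alpha=float(alpha), profile=tied[0], psi_value=best, ties=tied,
        ))
        if len(tied) > 1:
            logger.info("alpha=%.2f: %d tied winning profiles", alpha, len(tied))
    return winners


def metrics_frame(metrics: Sequence[PollingMetrics],
                  codebook: VariableCodebook | None = None) -> pd.DataFrame:
    """Flat table of polling metrics for export."""
    rows = []
    for m in metrics:
        rows.append({
            "profile": m.profile.describe(codebook),
            "n_members": m.n_members,
            "mass": m.mass,
            "profile_mass": m.profile_mass,
            "coverage": m.coverage,
            "lambda": m.lambda_polling,
            "mu": m.mu_polling,
            "estimable": m.estimable,
        })
    return pd.DataFrame(rows)
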