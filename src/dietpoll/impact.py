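"""Impact profiling: who benefits most from fixing inadequate diet diversity.

Need-based profiling (the polling engine) finds subgroups where inadequate
diet diversity is concentrated; impact profiling instead scores each
profile ``x`` by the stunting reduction an intervention there would buy:

    impact(x) = ATT(x) * Pr[treated | x] * Pr[x]

where ``ATT(x)`` is the kernel-matching treatment effect estimated within
the profile (reusing the propensity scores fitted once on the full
sample), ``Pr[treated | x]`` the treated share inside the profile and
``Pr[x]`` the profile's population mass share.  The *impact coverage* of a
profile is its impact as a fraction of the total impact over the profile
universe; because profiles overlap, the denominator can divide each
household's mass by the number of profiles containing it (the
overlap-adjusted total).  Exclusion and inclusion errors and the
psi-minimising winning profile mirror the polling definitions:

    lambda_impact = 1 - impact coverage
    mu_impact     = 1 - Pr[treated | x]
    psi_impact    = lambda_impact**alpha * mu_impact**(1 - alpha)

Because every enumerated profile yields an ATT estimate, sampling
variation produces spurious discoveries; the module therefore also
provides the anti-fishing diagnostics — profile-ATT distributions by
minimum treated sample size, and a permutation-null estimate of the false
discovery rate over a (minimum n, t threshold) grid.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import HouseholdTable
from .matching import AttEstimate, SupportMask, kernel_att, DEFAULT_BANDWIDTH
from .polling import (
    DEFAULT_ALPHA_GRID,
    PollingMetrics,
    Profile,
    WinningProfile,
    psi,
)

logger = logging.getLogger(__name__)

DEFAULT_MIN_TREATED_N = 100
DEFAULT_T_THRESHOLD = 1.645
DEFAULT_MIN_N_THRESHOLDS = (50, 75, 100, 125, 150)


@dataclass
class ImpactMetrics:
    """Per-profile treatment-effect and targeting metrics."""

    profile: Profile
    att: float
    se: float
    t: float
    pr_x: float                   # profile mass share of the population
    pr_treated_given_x: float     # treated share within the profile
    ate_x: float                  # att * pr_treated_given_x
    impact: float                 # att * pr_treated_given_x * pr_x
    n_treated_in_profile: int
    n_comparison_in_profile: int
    estimable: bool = True
    impact_coverage: float = float("nan")
    lambda_impact: float = float("nan")
    mu_impact: float = float("nan")

    def psi_impact(self, alpha: float) -> float:
        return psi(self.lambda_impact, self.mu_impact, alpha)

    @property
    def rankable(self) -> bool:
        """psi is defined only when both errors lie in [0, 1]."""
        return (
            self.estimable
            and np.isfinite(self.lambda_impact)
            and 0.0 <= self.lambda_impact <= 1.0
            and 0.0 <= self.mu_impact <= 1.0
        )


def impact(att: float, pr_treated_given_x: float, pr_x: float) -> tuple[float, float]:
    """Profile impact and ATE(x).

    Returns ``(impact, ate_x)`` with ``ate_x = att * pr_treated_given_x``
    and ``impact = ate_x * pr_x``.
    """
    for name, p in (("pr_treated_given_x", pr_treated_given_x), ("pr_x", pr_x)):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1], got {p}")
    ate_x = att * pr_treated_given_x
    return ate_x * pr_x, ate_x


def profile_att(
    profile: Profile,
    table: HouseholdTable,
    scores: np.ndarray,
    bandwidth: float = DEFAULT_BANDWIDTH,
    outcome: str = "stunting",
    treat_var: str = "diet_class",
) -> AttEstimate:
    """Kernel ATT restricted to a profile's members.

    The propensity scores are the ones fitted on the full sample; common
    support is re-checked within the profile.
    """
    member = profile.mask(table)
    treat = table.df[treat_var].to_numpy().astype(bool)
    if not (member & treat).any() or not (member & ~treat).any():
        return AttEstimate(
            att=np.nan, se=np.nan, t=np.nan, mean_treated=np.nan,
            mean_matched_comparison=np.nan,
            n_treated=int((member & treat).sum()),
            n_comparison=int((member & ~treat).sum()),
            unmatched_diff=np.nan, unmatched_se=np.nan, estimable=False,
        )
    comp_scores = scores[member & ~treat]
    lo, hi = comp_scores.min(), comp_scores.max()
    on = np.ones(len(table), dtype=bool)
    on[treat & ((scores < lo) | (scores > hi))] = False
    support = SupportMask(
        on_support=on,
        share_treated_off=float((treat & member & ~on).sum() / (treat & member).sum()),
        comparison_min=float(lo), comparison_max=float(hi),
    )
    return kernel_att(
        table, scores, mask=support, outcome=outcome, bandwidth=bandwidth,
        treat_var=treat_var, subset=member,
    )


def compute_impact_metrics(
    profiles: Sequence[Profile],
    table: HouseholdTable,
    scores: np.ndarray,
    bandwidth: float = DEFAULT_BANDWIDTH,
    outcome: str = "stunting",
    treat_var: str = "diet_class",
    min_treated_n: int = 0,
) -> list[ImpactMetrics]:
    """ATT and impact components for every profile.

    Profiles with fewer than ``min_treated_n`` treated members, or with no
    treated or no comparison members at all, are marked inestimable and
    excluded from rankings (their metrics stay NaN).
    """
    w = table.weights
    total_mass = w.sum()
    treat = table.df[treat_var].to_numpy().astype(bool)
    out: list[ImpactMetrics] = []
    for i, prof in enumerate(profiles):
        member = prof.mask(table)
        profile_mass = float(w[member].sum())
        pr_x = profile_mass / total_mass
        treated_mass = float(w[member & treat].sum())
        pr_t = treated_mass / profile_mass if profile_mass > 0 else np.nan
        n_tr = int((member & treat).sum())
        est = profile_att(prof, table, scores, bandwidth, outcome, treat_var)
        estimable = est.estimable and n_tr >= min_treated_n
        if estimable:
            imp, ate_x = impact(est.att, pr_t, pr_x)
            out.append(ImpactMetrics(
                profile=prof, att=est.att, se=est.se, t=est.t, pr_x=pr_x,
                pr_treated_given_x=pr_t, ate_x=ate_x, impact=imp,
                n_treated_in_profile=n_tr,
                n_comparison_in_profile=est.n_comparison, estimable=True,
            ))
        else:
            out.append(ImpactMetrics(
                profile=prof, att=np.nan, se=np.nan, t=np.nan, pr_x=pr_x,
                pr_treated_given_x=pr_t if profile_mass > 0 else np.nan,
                ate_x=np.nan, impact=np.nan, n_treated_in_profile=n_tr,
                n_comparison_in_profile=int((member & ~treat).sum()),
                estimable=False,
            ))
        if (i + 1) % 1000 == 0:
            logger.info("impact metrics: %d/%d profiles", i + 1, len(profiles))
    return out


# ----------------------------------------------------------------------
# impact coverage with overlap adjustment
# ----------------------------------------------------------------------
@dataclass
class ProfileUniverse:
    """The profile set defining the total-impact denominator.

    ``overlap_count[s]`` is the number of universe profiles containing
    household ``s``; the overlap-adjusted mass of a profile divides each
    member's weight by its count, so overlapping profiles do not double
    count households in the total.
    """

    profiles: list[Profile]
    overlap_count: np.ndarray
    adjusted_pr: dict[tuple, float] = field(default_factory=dict)


def build_universe(profiles: Sequence[Profile], table: HouseholdTable) -> ProfileUniverse:
    w = table.weights
    total_mass = w.sum()
    count = np.zeros(len(table), dtype=int)
    masks = []
    for prof in profiles:
        m = prof.mask(table)
        masks.append(m)
        count += m
    safe = np.where(count > 0, count, 1)
    adj = {}
    for prof, m in zip(profiles, masks):
        adj[prof.key] = float(np.sum(w[m] / safe[m]) / total_mass)
    return ProfileUniverse(profiles=list(profiles), overlap_count=count, adjusted_pr=adj)


def impact_coverage(
    metrics: Sequence[ImpactMetrics],
    universe: ProfileUniverse | None = None,
    overlap_adjust: bool = True,
    table: HouseholdTable | None = None,
) -> list[ImpactMetrics]:
    """Fill impact coverage, lambda and mu on each estimable metric.

    Without adjustment the denominator is the plain sum of profile impacts;
    with adjustment each profile's denominator term uses the
    overlap-adjusted mass share from ``universe`` (built from ``metrics``'
    estimable profiles if not supplied, which requires ``table``).
    Coverage is undefined (and logged) when the total impact is zero.
    """
    est = [m for m in metrics if m.estimable and np.isfinite(m.impact)]
    if not est:
        raise ValueError("no estimable profile impacts")
    if overlap_adjust:
        if universe is None:
            if table is None:
                raise ValueError("need a universe or a table to build one")
            universe = build_universe([m.profile for m in est], table)
        denom = sum(
            m.att * m.pr_treated_given_x * universe.adjusted_pr[m.profile.key]
            for m in est if m.profile.key in universe.adjusted_pr
        )
    else:
        denom = sum(m.impact for m in est)

    if denom == 0:
        logger.warning("total impact is zero; impact coverage undefined")
        return list(metrics)
    for m in metrics:
        if m.estimable and np.isfinite(m.impact):
            m.impact_coverage = m.impact / denom
            m.lambda_impact = 1.0 - m.impact_coverage
            m.mu_impact = 1.0 - m.pr_treated_given_x
    return list(metrics)


def winning_impact_profiles(
    metrics: Sequence[ImpactMetrics],
    alpha_grid: Sequence[float] = DEFAULT_ALPHA_GRID,
    tie_tol: float = 1e-12,
) -> list[WinningProfile]:
    """psi_impact-minimising profile per alpha (ties reported).

    Profiles whose errors fall outside [0, 1] (possible when some profile
    impacts are negative) cannot enter the geometric mean and are skipped.
    """
    usable = [m for m in metrics if m.rankable]
    if not usable:
        raise ValueError("no rankable profiles (compute impact_coverage first)")
    winners = []
    for alpha in alpha_grid:
        vals = np.array([m.psi_impact(alpha) for m in usable])
        best = float(vals.min())
        tied = [usable[i].profile for i in np.flatnonzero(vals <= best + tie_tol)]
        tied.sort(key=lambda p: p.key)
        winners.append(WinningProfile(alpha=float(alpha), profile=tied[0],
                                      psi_value=best, ties=tied))
    return winners


# ----------------------------------------------------------------------
# sampling-variation diagnostics
# ----------------------------------------------------------------------
def att_distribution_by_min_n(
    metrics: Sequence[ImpactMetrics],
    thresholds: Sequence[int] = DEFAULT_MIN_N_THRESHOLDS,
) -> pd.DataFrame:
    """Profile-ATT distribution summaries by minimum treated sample size.

    For each threshold, the profiles with strictly more treated members
    enter; the summary reports the centre, spread, skewness and the share
    of negative ATTs.  Under a global null the distributions centre on
    zero at every threshold; a real positive effect pulls the centre up
    and shrinks the negative share as the threshold grows.
    """
    rows = []
    for thr in thresholds:
        atts = np.array([
            m.att for m in metrics
            if m.estimable and np.isfinite(m.att) and m.n_treated_in_profile > thr
        ])
        if len(atts) == 0:
            logger.warning("min-n threshold %d leaves no profiles", thr)
            rows.append({"min_n": thr, "n_profiles": 0, "mean": np.nan,
                         "median": np.nan, "sd": np.nan, "skew": np.nan,
                         "share_negative": np.nan})
            continue
        rows.append({
            "min_n": thr,
            "n_profiles": len(atts),
            "mean": float(atts.mean()),
            "median": float(np.median(atts)),
            "sd": float(atts.std(ddof=1)) if len(atts) > 1 else np.nan,
            "skew": float(stats.skew(atts)) if len(atts) > 2 else np.nan,
            "share_negative": float((atts < 0).mean()),
        })
    return pd.DataFrame(rows)


def att_values_by_min_n(
    metrics: Sequence[ImpactMetrics],
    thresholds: Sequence[int] = DEFAULT_MIN_N_THRESHOLDS,
) -> pd.DataFrame:
    """Long-format profile ATTs per threshold, for density plots."""
    rows = []
    for thr in thresholds:
        for m in metrics:
            if m.estimable and np.isfinite(m.att) and m.n_treated_in_profile > thr:
                rows.append({"min_n": thr, "att": m.att})
    return pd.DataFrame(rows, columns=["min_n", "att"])


@dataclass
class FdrTradeoff:
    """Significant-profile counts and permutation-null FDR per grid cell."""

    table: pd.DataFrame     # columns: min_n, t_threshold, n_significant,
                            # expected_null, fdr
    null_replicates: int


def fdr_tradeoff(
    table: HouseholdTable,
    profiles: Sequence[Profile],
    regressors: Sequence[str],
    observed: Sequence[ImpactMetrics],
    n_grid: Sequence[int] = (50, 75, 100, 125, 150),
    t_grid: Sequence[float] = (1.0, 1.645, 2.0, 2.5),
    null_replicates: int = 20,
    seed: int = 20151104,
    bandwidth: float = DEFAULT_BANDWIDTH,
    outcome: str = "stunting",
    treat_var: str = "diet_class",
) -> FdrTradeoff:
    """FDR over a (minimum treated n, t threshold) grid via a permutation null.

    Treatment labels are permuted across households (breaking any true
    effect and any confounding), the propensity model is re-fitted, and
    profile ATTs recomputed; the expected number of one-sided discoveries
    under this null, divided by the observed discovery count, estimates
    the FDR for each cell.  Cells with zero observed discoveries report an
    undefined (NaN) FDR.
    """
    from .matching import fit_propensity

    rng = np.random.default_rng(seed)
    null_counts = {(n, t): [] for n in n_grid for t in t_grid}
    for rep in range(null_replicates):
        perm = table.copy()
        perm.df[treat_var] = rng.permutation(perm.df[treat_var].to_numpy())
        try:
            pm = fit_propensity(perm, list(regressors), treat_var=treat_var)
        except ValueError:
            logger.warning("permutation %d: propensity fit failed, skipped", rep)
            continue
        null_metrics = compute_impact_metrics(
            profiles, perm, pm.scores, bandwidth=bandwidth, outcome=outcome,
            treat_var=treat_var,
        )
        for n_min in n_grid:
            for t_min in t_grid:
                cnt = sum(
                    1 for m in null_metrics
                    if m.estimable and np.isfinite(m.t)
                    and m.n_treated_in_profile >= n_min and m.t >= t_min
                )
                null_counts[(n_min, t_min)].append(cnt)

    rows = []
    for n_min in n_grid:
        for t_min in t_grid:
            n_sig = sum(
                1 for m in observed
                if m.estimable and np.isfinite(m.t)
                and m.n_treated_in_profile >= n_min and m.t >= t_min
            )
            null_mean = float(np.mean(null_counts[(n_min, t_min)])) if null_counts[(n_min, t_min)] else np.nan
            fdr = min(null_mean / n_sig, 1.0) if n_sig > 0 and np.isfinite(null_mean) else np.nan
            rows.append({"min_n": n_min, "t_threshold": t_min,
                         "n_significant": n_sig, "expected_null": null_mean,
                         "fdr": fdr})
    return FdrTradeoff(table=pd.DataFrame(rows), null_replicates=null_replicates)


# ----------------------------------------------------------------------
# need vs impact
# ----------------------------------------------------------------------
def need_vs_impact(
    polling: Sequence[PollingMetrics],
    impacts: Sequence[ImpactMetrics],
    t_threshold: float = DEFAULT_T_THRESHOLD,
    min_n: int = DEFAULT_MIN_TREATED_N,
) -> tuple[pd.DataFrame, float]:
    """Pair need coverage with impact coverage over qualifying profiles.

    Qualifying profiles have a positive profile ATT significant at the
    one-sided ``t_threshold`` and at least ``min_n`` treated members.
    Returns the paired table and the Pearson correlation (NaN, with a
    warning, when fewer than 3 profiles qualify).
    """
    poll_by_key = {m.profile.key: m for m in polling}
    rows = []
    for m in impacts:
        if not (m.estimable and np.isfinite(m.t)):
            continue
        if m.att <= 0 or m.t < t_threshold or m.n_treated_in_profile < min_n:
            continue
        pm = poll_by_key.get(m.profile.key)
        if pm is None:
            continue
        rows.append({
            "profile": m.profile.describe(),
            "coverage": pm.coverage,
            "impact_coverage": m.impact_coverage,
            "att": m.att, "t": m.t,
            "n_treated": m.n_treated_in_profile,
        })
    frame = pd.DataFrame(rows, columns=["profile", "coverage", "impact_coverage",
                                        "att", "t", "n_treated"])
    if len(frame) < 3:
        logger.warning("only %d qualifying profiles; correlation undefined", len(frame))
        return frame, float("nan")
    r = float(np.corrcoef(frame["coverage"], frame["impact_coverage"])[0, 1])
    return frame, r


def profile_characteristics(
    metrics: Sequence[ImpactMetrics],
    t_threshold: float = DEFAULT_T_THRESHOLD,
    min_n: int = DEFAULT_MIN_TREATED_N,
    codebook=None,
) -> pd.DataFrame:
    """Share of significant profiles containing each (variable, value).

    Mirrors a characteristics-frequency table: among profiles with positive
    ATT, one-sided t at or above the threshold and at least ``min_n``
    treated members, the percentage containing each covariate value.
    """
    sig = [
        m for m in metrics
        if m.estimable and np.isfinite(m.t) and m.att > 0
        and m.t >= t_threshold and m.n_treated_in_profile >= min_n
    ]
    counts: dict[tuple[str, int], int] = {}
    for m in sig:
        for var, val in zip(m.profile.variables, m.profile.values):
            counts[(var, val)] = counts.get((var, val), 0) + 1
    rows = []
    for (var, val), c in sorted(counts.items(), key=lambda kv: -kv[1]):
        label = codebook[var].label_of(val) if codebook else str(val)
        rows.append({"variable": var, "value": label,
                     "n_profiles": c,
                     "pct_of_profiles": 100.0 * c / len(sig) if sig else np.nan})
    return pd.DataFrame(rows, columns=["variable", "value", "n_profiles",
                                       "pct_of_profiles"])
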