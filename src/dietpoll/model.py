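"""Model-style front end: profilers built from data, with fit() -> results.

``PollingProfiler`` wraps the exhaustive need-profiling engine;
``ImpactProfiler`` runs the full impact-profiling analysis (screening,
propensity estimation, common support, global kernel ATT, per-profile
ATTs, impact coverage, winning profiles and the need-vs-impact
comparison).  Both return results objects carrying estimates,
uncertainties and diagnostics with a ``summary()``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

import importlib

impact_mod = importlib.import_module(".impact", __package__)
polling_mod = importlib.import_module(".polling", __package__)
from .data import HouseholdTable
from .matching import (
    AttEstimate,
    BalanceReport,
    DEFAULT_BANDWIDTH,
    PropensityModel,
    balance_report,
    common_support,
    fit_propensity,
    kernel_att,
)
from .screening import ScreenResult, univariate_screen

logger = logging.getLogger(__name__)

DEFAULT_PROFILE_SIZE = 5


# ----------------------------------------------------------------------
# polling
# ----------------------------------------------------------------------
@dataclass
class PollingResults:
    metrics: list[polling_mod.PollingMetrics]
    winners: list[polling_mod.WinningProfile]
    group_mass: float
    n_profiles: int
    n_variable_subsets: int

    def metrics_frame(self, codebook=None) -> pd.DataFrame:
        return polling_mod.metrics_frame(self.metrics, codebook)

    def winners_frame(self, codebook=None) -> pd.DataFrame:
        rows = []
        for w in self.winners:
            m = next(m for m in self.metrics if m.profile.key == w.profile.key)
            rows.append({
                "alpha": w.alpha,
                "profile": w.profile.describe(codebook),
                "lambda": m.lambda_polling,
                "mu": m.mu_polling,
                "psi": w.psi_value,
                "n_ties": len(w.ties),
            })
        return pd.DataFrame(rows)

    def summary(self, codebook=None) -> str:
        lines = [
            "Polling profiler results",
            "========================",
            f"profiles enumerated: {self.n_profiles} "
            f"({self.n_variable_subsets} variable subsets)",
            f"relevant-group mass: {self.group_mass:.4g}",
            "",
            "Winning profiles by alpha (exclusion-error weight):",
            self.winners_frame(codebook).to_string(index=False,
                                                   float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class PollingProfiler:
    """Exhaustive need profiling of a binary target group.

    Parameters
    ----------
    table:
        Validated household table with the group indicator column.
    variables:
        Candidate covariates; defaults to every codebook covariate present
        in the table.
    k:
        Number of variables fixed in each profile (profiles are enumerated
        over every value assignment of every k-subset).
    group, group_var:
        The relevant group (default: ``diet_class == 1``, inadequate diet
        diversity).
    min_members:
        Profiles with fewer records are excluded from rankings.
    """

    def __init__(self, table: HouseholdTable, variables: list[str] | None = None,
                 k: int = DEFAULT_PROFILE_SIZE, group: int = 1,
                 group_var: str = "diet_class",
                 alpha_grid=polling_mod.DEFAULT_ALPHA_GRID,
                 min_members: int = 0):
        self.table = table
        self.variables = variables or [
            v for v in table.codebook.covariates if v in table.df.columns
        ]
        self.k = k
        self.group = group
        self.group_var = group_var
        self.alpha_grid = alpha_grid
        self.min_members = min_members

    def fit(self) -> PollingResults:
        profiles = polling_mod.enumerate_profiles(self.variables, self.k,
                                                  self.table.codebook)
        metrics = polling_mod.polling_metrics_all(
            profiles, self.table, group=self.group, group_var=self.group_var,
            min_members=self.min_members,
        )
        winners = polling_mod.winning_profiles(metrics, self.alpha_grid)
        return PollingResults(
            metrics=metrics, winners=winners,
            group_mass=metrics[0].group_mass if metrics else 0.0,
            n_profiles=len(profiles),
            n_variable_subsets=polling_mod.n_variable_subsets(len(self.variables), self.k),
        )


# ----------------------------------------------------------------------
# impact profiling
# ----------------------------------------------------------------------
@dataclass
class ImpactProfilerResults:
    screen: list[ScreenResult] | None
    selected_variables: list[str]
    propensity: PropensityModel
    support_share_off: float
    global_att: AttEstimate
    balance: BalanceReport
    polling: PollingResults
    impact_metrics: list[impact_mod.ImpactMetrics]
    winners_impact: list[polling_mod.WinningProfile]
    need_impact_table: pd.DataFrame
    need_impact_corr: float
    bandwidth: float
    min_treated_n: int
    t_threshold: float
    _codebook: object = field(default=None, repr=False)

    def impact_frame(self) -> pd.DataFrame:
        cb = self._codebook
        rows = []
        for m in self.impact_metrics:
            rows.append({
                "profile": m.profile.describe(cb),
                "n_treated": m.n_treated_in_profile,
                "n_comparison": m.n_comparison_in_profile,
                "att": m.att, "se": m.se, "t": m.t,
                "pr_x": m.pr_x, "pr_treated_given_x": m.pr_treated_given_x,
                "ate_x": m.ate_x, "impact": m.impact,
                "impact_coverage": m.impact_coverage,
                "lambda_impact": m.lambda_impact, "mu_impact": m.mu_impact,
                "estimable": m.estimable,
            })
        return pd.DataFrame(rows)

    def winners_impact_frame(self) -> pd.DataFrame:
        cb = self._codebook
        by_key = {m.profile.key: m for m in self.impact_metrics}
        rows = []
        for w in self.winners_impact:
            m = by_key[w.profile.key]
            rows.append({
                "alpha": w.alpha, "profile": w.profile.describe(cb),
                "lambda_impact": m.lambda_impact, "mu_impact": m.mu_impact,
                "psi_impact": w.psi_value, "n_ties": len(w.ties),
            })
        return pd.DataFrame(rows)

    def characteristics_frame(self) -> pd.DataFrame:
        return impact_mod.profile_characteristics(
            self.impact_metrics, t_threshold=self.t_threshold,
            min_n=self.min_treated_n, codebook=self._codebook,
        )

    @property
    def n_significant_profiles(self) -> int:
        return int(sum(
            1 for m in self.impact_metrics
            if m.estimable and np.isfinite(m.t) and m.att > 0
            and m.t >= self.t_threshold
            and m.n_treated_in_profile >= self.min_treated_n
        ))

    def summary(self) -> str:
        g = self.global_att
        lines = [
            "Impact profiler results",
            "=======================",
            f"n = {self.propensity.n_obs} records; "
            f"selected variables: {', '.join(self.selected_variables)}",
            f"treated off support: {100 * self.support_share_off:.2f}%",
            "",
            "Global kernel-matching ATT of inadequate diet diversity "
            f"(bandwidth {self.bandwidth}):",
            f"  unmatched difference: {g.unmatched_diff:+.4f} "
            f"(se {g.unmatched_se:.4f}, t {g.unmatched_diff / g.unmatched_se:+.2f})"
            if g.unmatched_se and g.unmatched_se > 0 else
            f"  unmatched difference: {g.unmatched_diff:+.4f}",
            f"  ATT: {g.att:+.4f} (se {g.se:.4f}, t {g.t:+.2f}); "
            f"treated mean {g.mean_treated:.3f}, matched comparison "
            f"{g.mean_matched_comparison:.3f}",
            "",
            f"profiles: {self.polling.n_profiles} enumerated, "
            f"{sum(m.estimable for m in self.impact_metrics)} with estimable ATT, "
            f"{self.n_significant_profiles} significant "
            f"(t >= {self.t_threshold}, n_treated >= {self.min_treated_n})",
            f"need vs impact coverage correlation: {self.need_impact_corr:.3f}"
            if np.isfinite(self.need_impact_corr) else
            "need vs impact coverage correlation: undefined (too few profiles)",
            "",
            "Winning impact profiles by alpha:",
            self.winners_impact_frame().to_string(
                index=False, float_format=lambda v: f"{v:.4f}"),
        ]
        return "\n".join(lines)


class ImpactProfiler:
    """Full impact-profiling analysis on a household table.

    The propensity score is fitted once on the whole sample; every
    enumerated profile then gets a kernel ATT restricted to its members,
    an impact score ``ATT(x) * Pr[treated|x] * Pr[x]``, and the
    overlap-adjusted impact coverage used to pick winning profiles.
    """

    def __init__(self, table: HouseholdTable,
                 candidates: list[str] | None = None,
                 top_k_screen: int | None = None,
                 k: int = DEFAULT_PROFILE_SIZE,
                 bandwidth: float = DEFAULT_BANDWIDTH,
                 min_treated_n: int = impact_mod.DEFAULT_MIN_TREATED_N,
                 t_threshold: float = impact_mod.DEFAULT_T_THRESHOLD,
                 alpha_grid=polling_mod.DEFAULT_ALPHA_GRID,
                 outcome: str = "stunting",
                 treat_var: str = "diet_class",
                 overlap_adjust: bool = True):
        self.table = table
        self.candidates = candidates or [
            v for v in table.codebook.covariates if v in table.df.columns
        ]
        self.top_k_screen = top_k_screen
        self.k = k
        self.bandwidth = bandwidth
        self.min_treated_n = min_treated_n
        self.t_threshold = t_threshold
        self.alpha_grid = alpha_grid
        self.outcome = outcome
        self.treat_var = treat_var
        self.overlap_adjust = overlap_adjust

    def fit(self) -> ImpactProfilerResults:
        table = self.table
        screen = None
        selected = list(self.candidates)
        if self.top_k_screen is not None and self.top_k_screen < len(self.candidates):
            screen = univariate_screen(table, self.candidates,
                                       outcome=self.treat_var, k=self.top_k_screen)
            selected = [s.variable for s in screen]

        prop = fit_propensity(table, selected, treat_var=self.treat_var)
        treat = table.df[self.treat_var].to_numpy().astype(bool)
        support = common_support(prop.scores, treat)
        global_att = kernel_att(table, prop.scores, mask=support,
                                outcome=self.outcome, bandwidth=self.bandwidth,
                                treat_var=self.treat_var)
        balance = balance_report(table, selected, global_att,
                                 treat_var=self.treat_var)

        poller = PollingProfiler(table, variables=selected, k=self.k,
                                 group=1, group_var=self.treat_var,
                                 alpha_grid=self.alpha_grid)
        polling_res = poller.fit()
        profiles = [m.profile for m in polling_res.metrics]

        # every profile with at least one treated and one comparison member
        # gets an ATT; min_treated_n applies to the significance filters
        # (discovery counts, characteristics, need-vs-impact), not here
        metrics = impact_mod.compute_impact_metrics(
            profiles, table, prop.scores, bandwidth=self.bandwidth,
            outcome=self.outcome, treat_var=self.treat_var, min_treated_n=0,
        )
        metrics = impact_mod.impact_coverage(
            metrics, overlap_adjust=self.overlap_adjust, table=table,
        )
        winners = impact_mod.winning_impact_profiles(metrics, self.alpha_grid)
        ni_table, ni_corr = impact_mod.need_vs_impact(
            polling_res.metrics, metrics,
            t_threshold=self.t_threshold, min_n=self.min_treated_n,
        )
        return ImpactProfilerResults(
            screen=screen, selected_variables=selected, propensity=prop,
            support_share_off=support.share_treated_off, global_att=global_att,
            balance=balance, polling=polling_res, impact_metrics=metrics,
            winners_impact=winners, need_impact_table=ni_table,
            need_impact_corr=ni_corr, bandwidth=self.bandwidth,
            min_treated_n=self.min_treated_n, t_threshold=self.t_threshold,
            _codebook=table.codebook,
        )
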