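"""Propensity-score estimation and Epanechnikov kernel matching.

Treatment is *inadequate child diet diversity* (``diet_class == 1``); the
outcome is stunting.  The propensity score is the probit probability
``Prob[treated | x] = F(x'b)`` fitted by maximum likelihood on category
indicators (first category omitted).  Treated records outside the
comparison group's score range are dropped (common support), and each
remaining treated record is matched to a kernel-weighted average of
comparison outcomes with Epanechnikov weights ``K(u) = 0.75 (1 - u^2)`` on
``|u| < 1``, ``u = (p_j - p_i) / h``.

The ATT standard error uses the analytic approximation valid under
independent observations, fixed kernel weights, homoscedastic outcomes
within the treated and within the comparison group, and outcome variance
unrelated to the propensity score:

    Var(ATT) = s2_T * sum_i om_i^2  +  s2_C * sum_j W_j^2

where ``om_i`` are the normalised treated masses and ``W_j`` the total
matched mass each comparison receives.

Kernel sums are evaluated with sorted prefix sums (O(n log n) rather than
the O(n^2) double loop), exploiting that the Epanechnikov kernel is a
quadratic polynomial in the score inside its window.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.nonparametric.smoothers_lowess import lowess

from .data import HouseholdTable

logger = logging.getLogger(__name__)

DEFAULT_BANDWIDTH = 0.06
_SCORE_EPS = 1e-9


# ----------------------------------------------------------------------
# design matrix helpers
# ----------------------------------------------------------------------
def build_design(table: HouseholdTable, regressors: list[str]) -> pd.DataFrame:
    """Indicator design matrix with the first category of each coded
    variable omitted; columns not in the codebook enter as-is (continuous)."""
    cols = {}
    for name in regressors:
        if name in table.codebook:
            var = table.codebook[name]
            codes = table.df[name].to_numpy()
            for c in range(1, var.n_categories):
                cols[f"{name}[{var.label_of(c)}]"] = (codes == c).astype(float)
        else:
            cols[name] = table.df[name].to_numpy(dtype=float)
    X = pd.DataFrame(cols, index=table.df.index)
    X.insert(0, "const", 1.0)
    return X


def _find_separating_column(X: pd.DataFrame, y: np.ndarray) -> str | None:
    for col in X.columns:
        if col == "const":
            continue
        v = X[col].to_numpy()
        if len(np.unique(v)) > 2:
            continue
        hi = v == v.max()
        if len(np.unique(y[hi])) < 2 or len(np.unique(y[~hi])) < 2:
            return col
    return None


@dataclass
class PropensityModel:
    """Fitted probit treatment model with scores for every record."""

    result: object                      # statsmodels BinaryResults
    regressors: list[str]
    coefficients: pd.Series
    std_errors: pd.Series
    marginal_effects: pd.DataFrame      # dF/dx at the regressor means
    scores: np.ndarray                  # fitted P(treated | x), in (0, 1)
    converged: bool
    n_obs: int

    def summary_frame(self) -> pd.DataFrame:
        """Coefficients, marginal effects and significance stars."""
        me = self.marginal_effects
        out = pd.DataFrame({
            "coef": self.coefficients,
            "se_coef": self.std_errors,
        })
        out = out.join(me[["dy/dx", "se", "p"]], how="left")
        out["stars"] = out["p"].map(
            lambda p: "***" if p < 0.01 else "**" if p < 0.05 else "*" if p < 0.10 else ""
        ).fillna("")
        return out


def fit_propensity(
    table: HouseholdTable,
    regressors: list[str],
    treat_var: str = "diet_class",
    maxiter: int = 100,
    tol: float = 1e-8,
) -> PropensityModel:
    """Maximum-likelihood probit of treatment on category indicators.

    Marginal effects are evaluated at the regressor means.  Raises on
    non-convergence (with the optimizer trace) and on perfect separation
    (naming the separating column).
    """
    y = table.df[treat_var].to_numpy(dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError(f"{treat_var} does not vary: cannot fit a treatment model")
    X = build_design(table, regressors)

    sep = _find_separating_column(X, y)
    if sep is not None:
        raise ValueError(f"perfect separation: column {sep!r} fully predicts treatment")

    model = sm.Probit(y, X)
    try:
        res = model.fit(disp=0, maxiter=maxiter, tol=tol, method="newton")
    except np.linalg.LinAlgError as err:
        raise ValueError(f"probit fit failed (singular design): {err}") from err
    if not res.mle_retvals.get("converged", False):
        raise ValueError(
            "probit did not converge after "
            f"{res.mle_retvals.get('iterations', maxiter)} iterations; "
            f"trace: {res.mle_retvals}"
        )
    margeff = res.get_margeff(at="mean")
    me_frame = margeff.summary_frame()
    me_frame.columns = ["dy/dx", "se", "z", "p", "ci_low", "ci_high"]
    scores = np.clip(res.predict(X), _SCORE_EPS, 1.0 - _SCORE_EPS)
    return PropensityModel(
        result=res,
        regressors=list(regressors),
        coefficients=res.params,
        std_errors=res.bse,
        marginal_effects=me_frame,
        scores=np.asarray(scores, dtype=float),
        converged=True,
        n_obs=len(y),
    )


# ----------------------------------------------------------------------
# common support
# ----------------------------------------------------------------------
@dataclass
class SupportMask:
    """Per-record on-support flags after min/max trimming of the treated."""

    on_support: np.ndarray          # bool, full length
    share_treated_off: float
    comparison_min: float
    comparison_max: float


def common_support(scores: np.ndarray, treat: np.ndarray) -> SupportMask:
    """Two-sided min/max support rule.

    Treated records with propensity score above the comparison-group maximum
    or below its minimum have no comparable untreated record and are dropped
    from the ATT; all comparison records are retained (the kernel assigns
    them zero weight if they are far from every treated score).
    """
    treat = np.asarray(treat).astype(bool)
    scores = np.asarray(scores, dtype=float)
    if not treat.any():
        raise ValueError("no treated records")
    if treat.all():
        raise ValueError("no comparison records")
    comp_scores = scores[~treat]
    lo, hi = float(comp_scores.min()), float(comp_scores.max())
    on = np.ones(len(scores), dtype=bool)
    off_treated = treat & ((scores < lo) | (scores > hi))
    on[off_treated] = False
    n_treated = int(treat.sum())
    share_off = float(off_treated.sum() / n_treated)
    if share_off == 1.0:
        raise ValueError("every treated record lies outside the comparison support")
    if off_treated.any():
        logger.info("common support dropped %d of %d treated (%.1f%%)",
                    off_treated.sum(), n_treated, 100 * share_off)
    return SupportMask(
        on_support=on, share_treated_off=share_off,
        comparison_min=lo, comparison_max=hi,
    )


# ----------------------------------------------------------------------
# Epanechnikov kernel machinery (prefix-sum evaluation)
# ----------------------------------------------------------------------
def _windowed_poly_sums(p_sorted: np.ndarray, values: np.ndarray,
                        centers: np.ndarray, h: float) -> np.ndarray:
    """``0.75 * sum_j v_j (1 - ((p_j - c)/h)^2)`` over ``|p_j - c| < h``.

    ``p_sorted`` must be ascending with ``values`` aligned.  Evaluated with
    prefix sums of v, v*p and v*p^2.
    """
    c0 = np.concatenate(([0.0], np.cumsum(values)))
    c1 = np.concatenate(([0.0], np.cumsum(values * p_sorted)))
    c2 = np.concatenate(([0.0], np.cumsum(values * p_sorted ** 2)))
    lo = np.searchsorted(p_sorted, centers - h, side="right")
    hi = np.searchsorted(p_sorted, centers + h, side="left")
    s0 = c0[hi] - c0[lo]
    s1 = c1[hi] - c1[lo]
    s2 = c2[hi] - c2[lo]
    return 0.75 * (s0 - (s2 - 2.0 * centers * s1 + centers ** 2 * s0) / h ** 2)


@dataclass
class AttEstimate:
    """Kernel-matching ATT with the analytic standard error."""

    att: float
    se: float
    t: float
    mean_treated: float
    mean_matched_comparison: float
    n_treated: int
    n_comparison: int
    unmatched_diff: float
    unmatched_se: float
    n_treated_unmatched: int = 0        # treated with empty kernel window
    estimable: bool = True
    # full-length arrays for diagnostics (balance, local ATT curves)
    treated_mask: np.ndarray | None = field(default=None, repr=False)
    comparison_weights: np.ndarray | None = field(default=None, repr=False)
    treated_scores: np.ndarray | None = field(default=None, repr=False)
    treated_diffs: np.ndarray | None = field(default=None, repr=False)


def kernel_att(
    table: HouseholdTable,
    scores: np.ndarray,
    mask: SupportMask | None = None,
    outcome: str = "stunting",
    bandwidth: float = DEFAULT_BANDWIDTH,
    treat_var: str = "diet_class",
    subset: np.ndarray | None = None,
) -> AttEstimate:
    """ATT of treatment on ``outcome`` by Epanechnikov kernel matching.

    ``subset`` optionally restricts both treated and comparison records to a
    profile's members (scores stay the globally fitted ones).  Treated
    records with no comparison inside the bandwidth window are dropped and
    counted in ``n_treated_unmatched``.
    """
    if bandwidth <= 0:
        raise ValueError(f"bandwidth must be positive, got {bandwidth}")
    scores = np.asarray(scores, dtype=float)
    treat = table.df[treat_var].to_numpy().astype(bool)
    y = table.df[outcome].to_numpy(dtype=float)
    w = table.weights
    keep = np.ones(len(table), dtype=bool) if mask is None else mask.on_support.copy()
    if subset is not None:
        keep &= np.asarray(subset, dtype=bool)

    t_idx = np.flatnonzero(keep & treat)
    c_idx = np.flatnonzero(keep & ~treat)
    if len(t_idx) == 0 or len(c_idx) == 0:
        return AttEstimate(
            att=np.nan, se=np.nan, t=np.nan, mean_treated=np.nan,
            mean_matched_comparison=np.nan, n_treated=len(t_idx),
            n_comparison=len(c_idx), unmatched_diff=np.nan, unmatched_se=np.nan,
            estimable=False,
        )

    order = np.argsort(scores[c_idx], kind="stable")
    c_idx = c_idx[order]
    p_c, y_c, w_c = scores[c_idx], y[c_idx], w[c_idx]
    p_t, y_t, w_t = scores[t_idx], y[t_idx], w[t_idx]

    den = _windowed_poly_sums(p_c, w_c, p_t, bandwidth)
    num = _windowed_poly_sums(p_c, w_c * y_c, p_t, bandwidth)
    matched = den > 0
    n_unmatched = int((~matched).sum())
    if n_unmatched:
        logger.info("%d treated had no comparison within bandwidth %.3g and were dropped",
                    n_unmatched, bandwidth)
    if not matched.any():
        return AttEstimate(
            att=np.nan, se=np.nan, t=np.nan, mean_treated=np.nan,
            mean_matched_comparison=np.nan, n_treated=0,
            n_comparison=len(c_idx), unmatched_diff=np.nan, unmatched_se=np.nan,
            n_treated_unmatched=n_unmatched, estimable=False,
        )

    t_idx, p_t, y_t, w_t = t_idx[matched], p_t[matched], y_t[matched], w_t[matched]
    den, num = den[matched], num[matched]
    cf = num / den
    om = w_t / w_t.sum()
    diffs = y_t - cf
    att = float(np.dot(om, diffs))
    mean_t = float(np.dot(om, y_t))
    mean_cf = float(np.dot(om, cf))

    # total matched mass each comparison receives: W_j = w_j * sum_i (om_i/den_i) K_ij
    t_order = np.argsort(p_t, kind="stable")
    W = w_c * _windowed_poly_sums(
        p_t[t_order], (om / den)[t_order], p_c, bandwidth
    )

    s2_t = float(np.var(y_t, ddof=1)) if len(y_t) > 1 else 0.0
    s2_c = float(np.var(y_c, ddof=1)) if len(y_c) > 1 else 0.0
    var_att = s2_t * float(np.sum(om ** 2)) + s2_c * float(np.sum(W ** 2))
    se = float(np.sqrt(var_att))

    # raw (unmatched) difference in means over the same support
    om_c = w_c / w_c.sum()
    raw_diff = mean_t - float(np.dot(om_c, y_c))
    raw_se = float(np.sqrt(s2_t * np.sum(om ** 2) + s2_c * np.sum(om_c ** 2)))

    full_w = np.zeros(len(table))
    full_w[c_idx] = W
    full_t = np.zeros(len(table), dtype=bool)
    full_t[t_idx] = True

    return AttEstimate(
        att=att, se=se, t=att / se if se > 0 else np.nan,
        mean_treated=mean_t, mean_matched_comparison=mean_cf,
        n_treated=len(t_idx), n_comparison=len(c_idx),
        unmatched_diff=raw_diff, unmatched_se=raw_se,
        n_treated_unmatched=n_unmatched,
        treated_mask=full_t, comparison_weights=full_w,
        treated_scores=p_t, treated_diffs=diffs,
    )


# ----------------------------------------------------------------------
# diagnostics
# ----------------------------------------------------------------------
@dataclass
class BalanceReport:
    table: pd.DataFrame        # per design column: std diff / var ratio, before & after


def balance_report(
    table: HouseholdTable,
    regressors: list[str],
    att: AttEstimate,
    treat_var: str = "diet_class",
) -> BalanceReport:
    """Standardised differences and variance ratios before/after matching.

    Before-matching statistics use all treated vs all comparison records;
    after-matching uses matched treated vs the kernel-weighted comparison
    sample.  Standardised differences are scaled by the pooled
    before-matching standard deviation, as is conventional, so before and
    after are on one scale.
    """
    if att.treated_mask is None or att.comparison_weights is None:
        raise ValueError("ATT estimate carries no matching weights; rerun kernel_att")
    X = build_design(table, regressors).drop(columns="const")
    treat = table.df[treat_var].to_numpy().astype(bool)
    Wc = att.comparison_weights
    mt = att.treated_mask

    rows = []
    for col in X.columns:
        v = X[col].to_numpy(dtype=float)
        m_t, m_c = v[treat].mean(), v[~treat].mean()
        v_t = float(np.var(v[treat], ddof=1)) if treat.sum() > 1 else 0.0
        v_c = float(np.var(v[~treat], ddof=1)) if (~treat).sum() > 1 else 0.0
        pooled = np.sqrt((v_t + v_c) / 2.0)
        sd_before = (m_t - m_c) / pooled if pooled > 0 else 0.0

        m_t_a = v[mt].mean() if mt.any() else np.nan
        wsum = Wc.sum()
        m_c_a = float(np.dot(Wc, v) / wsum) if wsum > 0 else np.nan
        sd_after = (m_t_a - m_c_a) / pooled if pooled > 0 else 0.0
        if wsum > 0:
            v_c_a = float(np.dot(Wc, (v - m_c_a) ** 2) / wsum)
        else:
            v_c_a = np.nan
        v_t_a = float(np.var(v[mt], ddof=1)) if mt.sum() > 1 else 0.0
        rows.append({
            "variable": col,
            "std_diff_before": sd_before,
            "std_diff_after": sd_after,
            "var_ratio_before": v_t / v_c if v_c > 0 else np.nan,
            "var_ratio_after": v_t_a / v_c_a if v_c_a and v_c_a > 0 else np.nan,
        })
    return BalanceReport(table=pd.DataFrame(rows).set_index("variable"))


def matched_density_data(
    table: HouseholdTable,
    att: AttEstimate,
    columns: tuple[str, ...] = ("child_age_months", "interview_day"),
    treat_var: str = "diet_class",
    n_grid: int = 64,
) -> pd.DataFrame:
    """Gaussian-KDE density curves before and after matching, for export.

    One row per (column, group, grid point); ``group`` is treated,
    comparison, or matched_comparison (kernel-weighted).
    """
    from scipy.stats import gaussian_kde

    treat = table.df[treat_var].to_numpy().astype(bool)
    Wc = att.comparison_weights
    rows = []
    for col in columns:
        v = table.df[col].to_numpy(dtype=float)
        grid = np.linspace(v.min(), v.max(), n_grid)
        specs = [
            ("treated", v[treat], None),
            ("comparison", v[~treat], None),
            ("matched_comparison", v, Wc),
        ]
        for name, vals, wts in specs:
            if wts is not None:
                sel = wts > 0
                vals, wts = v[sel], wts[sel]
            if len(np.unique(vals)) < 2:
                continue
            kde = gaussian_kde(vals, weights=wts)
            dens = kde(grid)
            rows.extend({"column": col, "group": name, "x": g, "density": d}
                        for g, d in zip(grid, dens))
    return pd.DataFrame(rows)


def att_by_pscore_curve(att: AttEstimate, span: float = 0.8) -> pd.DataFrame:
    """Locally weighted regression of per-treated outcome gaps on the score.

    Returns the lowess fit of ``y_i - counterfactual_i`` against ``p_i`` as a
    (score, local_att) table — the local treatment-effect curve across the
    propensity distribution.
    """
    if att.treated_scores is None or att.treated_diffs is None:
        raise ValueError("ATT estimate carries no per-treated gaps; rerun kernel_att")
    p, d = att.treated_scores, att.treated_diffs
    if len(p) < 10:
        raise ValueError(f"need at least 10 matched treated records, have {len(p)}")
    if np.ptp(p) == 0:
        logger.warning("no variation in treated propensity scores; single-point curve")
        return pd.DataFrame({"score": [float(p[0])], "local_att": [float(d.mean())],
                             "degenerate": [True]})
    fit = lowess(d, p, frac=span, return_sorted=True)
    return pd.DataFrame({"score": fit[:, 0], "local_att": fit[:, 1],
                         "degenerate": False})
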