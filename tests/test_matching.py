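"""Propensity model, common support, kernel ATT and balance diagnostics."""

import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from dietpoll import (
    SyntheticConfig,
    Variable,
    VariableCodebook,
    att_by_pscore_curve,
    balance_report,
    common_support,
    fit_propensity,
    generate,
    kernel_att,
)
from dietpoll.matching import _windowed_poly_sums, build_design

from conftest import make_table, naive_kernel_att, naive_kernel_counterfactuals, \
    stratified_att


def _probit_table(rng, n, beta0, betas, codebook=None):
    """Treatment from a known probit on two 3-category covariates."""
    cb = codebook or VariableCodebook.from_variables([
        Variable("x1", ("a", "b", "c"), "covariate"),
        Variable("x2", ("a", "b", "c"), "covariate"),
    ])
    x1 = rng.integers(0, 3, n)
    x2 = rng.integers(0, 3, n)
    idx = beta0 + betas["x1"][x1] + betas["x2"][x2]
    treated = (idx + rng.standard_normal(n) > 0).astype(int)
    t = make_table(pd.DataFrame({
        "x1": x1, "x2": x2, "diet_class": treated,
        "stunting": rng.integers(0, 2, n),
    }), cb)
    return t, idx


BETAS = {"x1": np.array([0.0, 0.5, -0.4]), "x2": np.array([0.0, -0.6, 0.3])}


class TestPropensity:
    def test_monte_carlo_coefficient_recovery(self):
        """Estimates cover the true probit coefficients at the 2-SE level."""
        rng = np.random.default_rng(0)
        true = np.array([0.2, 0.5, -0.4, -0.6, 0.3])  # const + 4 slopes
        reps, n = 60, 4000
        hits = np.zeros(len(true))
        for _ in range(reps):
            t, _ = _probit_table(rng, n, 0.2, BETAS)
            pm = fit_propensity(t, ["x1", "x2"])
            est, se = pm.coefficients.to_numpy(), pm.std_errors.to_numpy()
            hits += np.abs(est - true) <= 2 * se
        assert (hits / reps >= 0.90).all()

    def test_null_marginal_effects_near_zero(self):
        rng = np.random.default_rng(1)
        t, _ = _probit_table(rng, 8000, 0.0, {"x1": np.zeros(3), "x2": np.zeros(3)})
        pm = fit_propensity(t, ["x1", "x2"])
        me = pm.marginal_effects
        assert (np.abs(me["dy/dx"]) <= 2 * me["se"]).all()

    def test_scores_match_normal_cdf_of_index(self):
        rng = np.random.default_rng(2)
        t, _ = _probit_table(rng, 20000, 0.2, BETAS)
        pm = fit_propensity(t, ["x1", "x2"])
        X = build_design(t, ["x1", "x2"])
        manual = norm.cdf(X.to_numpy() @ pm.coefficients.to_numpy())
        assert np.allclose(pm.scores, manual, atol=1e-9)
        assert ((pm.scores > 0) & (pm.scores < 1)).all()

    def test_all_treated_rejected(self, simple_codebook):
        t = make_table(pd.DataFrame({
            "region": [0, 1, 0], "wealth": [0, 0, 1], "diet_class": [1, 1, 1],
        }), simple_codebook)
        with pytest.raises(ValueError, match="vary"):
            fit_propensity(t, ["region", "wealth"])

    def test_perfect_separation_named(self, simple_codebook):
        t = make_table(pd.DataFrame({
            "region": [0, 0, 1, 1] * 10, "wealth": [0, 1, 0, 1] * 10,
            "diet_class": [0, 0, 1, 1] * 10,
        }), simple_codebook)
        with pytest.raises(ValueError, match="separation.*region"):
            fit_propensity(t, ["region", "wealth"])


class TestCommonSupport:
    def test_full_overlap_drops_nothing(self):
        scores = np.array([0.4, 0.5, 0.2, 0.8])
        treat = np.array([1, 1, 0, 0])
        m = common_support(scores, treat)
        assert m.on_support.all() and m.share_treated_off == 0.0

    def test_upper_tail_treated_dropped(self):
        scores = np.array([0.99, 0.5, 0.2, 0.90])
        treat = np.array([1, 1, 0, 0])
        m = common_support(scores, treat)
        assert not m.on_support[0]
        assert m.share_treated_off == 0.5

    def test_matches_brute_force_scan(self):
        rng = np.random.default_rng(3)
        scores = rng.random(5000)
        treat = rng.integers(0, 2, 5000)
        scores[treat == 1] += 0.2  # disjoint upper tail
        scores = np.clip(scores, 0, 1.5)
        m = common_support(scores, treat)
        comp_max, comp_min = scores[treat == 0].max(), scores[treat == 0].min()
        brute = sum(1 for s, tr in zip(scores, treat)
                    if tr and (s > comp_max or s < comp_min))
        assert int((~m.on_support).sum()) == brute
        assert m.share_treated_off == pytest.approx(brute / treat.sum())

    def test_one_sided_sample_rejected(self):
        with pytest.raises(ValueError):
            common_support(np.array([0.5, 0.5]), np.array([1, 1]))


class TestKernelAtt:
    def test_prefix_sums_match_direct_double_loop(self):
        rng = np.random.default_rng(4)
        p = np.sort(rng.random(300))
        v = rng.random(300)
        centers = rng.random(50)
        h = 0.07
        fast = _windowed_poly_sums(p, v, centers, h)
        for c, f in zip(centers, fast):
            u = (p - c) / h
            direct = np.sum(np.where(np.abs(u) < 1, 0.75 * (1 - u ** 2), 0) * v)
            assert f == pytest.approx(direct, abs=1e-10)

    def test_att_matches_naive_oracle(self, simple_codebook):
        rng = np.random.default_rng(5)
        n = 400
        t = make_table(pd.DataFrame({
            "region": rng.integers(0, 2, n), "wealth": rng.integers(0, 2, n),
            "diet_class": rng.integers(0, 2, n),
            "stunting": rng.integers(0, 2, n),
            "weight": rng.uniform(0.5, 2, n),
        }), simple_codebook)
        scores = rng.uniform(0.05, 0.95, n)
        est = kernel_att(t, scores, bandwidth=0.06)
        treat = t.df["diet_class"].to_numpy().astype(bool)
        oracle = naive_kernel_att(
            scores[treat], t.df["stunting"].to_numpy(float)[treat],
            t.weights[treat], scores[~treat],
            t.df["stunting"].to_numpy(float)[~treat], t.weights[~treat], 0.06)
        assert est.att == pytest.approx(oracle, abs=1e-12)

    def test_identical_outcomes_give_zero_att(self, simple_codebook):
        rng = np.random.default_rng(6)
        n = 200
        t = make_table(pd.DataFrame({
            "region": rng.integers(0, 2, n), "wealth": rng.integers(0, 2, n),
            "diet_class": rng.integers(0, 2, n), "stunting": 1,
        }), simple_codebook)
        est = kernel_att(t, rng.uniform(0.2, 0.8, n))
        assert est.att == pytest.approx(0.0, abs=1e-12)
        assert est.se == 0.0

    def test_matches_stratified_oracle_on_discrete_covariate(self, simple_codebook):
        """With one binary covariate, scores take two values; a bandwidth
        smaller than their gap makes kernel matching exactly stratification."""
        rng = np.random.default_rng(7)
        n = 2000
        x = rng.integers(0, 2, n)
        treated = (rng.random(n) < np.where(x == 1, 0.7, 0.4)).astype(int)
        y = (rng.random(n) < 0.2 + 0.1 * x + 0.05 * treated).astype(int)
        t = make_table(pd.DataFrame({
            "region": x, "wealth": 0, "diet_class": treated, "stunting": y,
        }), simple_codebook)
        pm = fit_propensity(t, ["region"])
        gap = abs(np.diff(np.unique(np.round(pm.scores, 12)))).min()
        est = kernel_att(t, pm.scores, bandwidth=gap / 2)
        tr = treated.astype(bool)
        oracle = stratified_att(x[tr], y[tr].astype(float), t.weights[tr],
                                x[~tr], y[~tr].astype(float), t.weights[~tr])
        assert est.att == pytest.approx(oracle, abs=1e-10)

    def test_matched_weights_sum_to_one(self, simple_codebook):
        rng = np.random.default_rng(8)
        n = 500
        t = make_table(pd.DataFrame({
            "region": rng.integers(0, 2, n), "wealth": rng.integers(0, 2, n),
            "diet_class": rng.integers(0, 2, n),
            "stunting": rng.integers(0, 2, n),
        }), simple_codebook)
        est = kernel_att(t, rng.uniform(0.3, 0.7, n))
        assert est.comparison_weights.sum() == pytest.approx(1.0, abs=1e-9)

    def test_outcome_shift_invariance(self, simple_codebook):
        rng = np.random.default_rng(9)
        n = 300
        df = pd.DataFrame({
            "region": rng.integers(0, 2, n), "wealth": rng.integers(0, 2, n),
            "diet_class": rng.integers(0, 2, n),
            "stunting": rng.integers(0, 2, n),
        })
        scores = rng.uniform(0.2, 0.8, n)
        t1 = make_table(df, simple_codebook)
        # shift all outcomes by +5 (as a separate float column)
        t2 = make_table(df.assign(shifted=df["stunting"] + 5.0), simple_codebook)
        a1 = kernel_att(t1, scores)
        a2 = kernel_att(t2, scores, outcome="shifted")
        assert a1.att == pytest.approx(a2.att, abs=1e-10)

    def test_infinite_bandwidth_gives_comparison_mean(self, simple_codebook):
        rng = np.random.default_rng(10)
        n = 400
        y = rng.integers(0, 2, n)
        treat = rng.integers(0, 2, n)
        t = make_table(pd.DataFrame({
            "region": rng.integers(0, 2, n), "wealth": 0,
            "diet_class": treat, "stunting": y,
        }), simple_codebook)
        est = kernel_att(t, rng.uniform(0.3, 0.7, n), bandwidth=10.0)
        # with the kernel window covering everything, the counterfactual is
        # close to (but, kernel-weighted, not exactly) the comparison mean;
        # at h=10 the weights are near-uniform
        comp_mean = y[treat == 0].mean()
        assert est.mean_matched_comparison == pytest.approx(comp_mean, abs=5e-4)

    def test_unmatched_treated_dropped_and_counted(self, simple_codebook):
        t = make_table(pd.DataFrame({
            "region": [0, 0, 1, 1], "wealth": [0, 0, 0, 0],
            "diet_class": [1, 1, 0, 0], "stunting": [1, 0, 1, 0],
        }), simple_codebook)
        scores = np.array([0.9, 0.3, 0.31, 0.32])
        est = kernel_att(t, scores, bandwidth=0.05)
        assert est.n_treated_unmatched == 1
        assert est.n_treated == 1

    def test_se_positive_when_outcomes_vary(self, simple_codebook):
        rng = np.random.default_rng(11)
        n = 300
        t = make_table(pd.DataFrame({
            "region": rng.integers(0, 2, n), "wealth": 0,
            "diet_class": rng.integers(0, 2, n),
            "stunting": rng.integers(0, 2, n),
        }), simple_codebook)
        est = kernel_att(t, rng.uniform(0.3, 0.7, n))
        assert est.se > 0
        assert est.t == pytest.approx(est.att / est.se)

    def test_bad_bandwidth_rejected(self, toy):
        with pytest.raises(ValueError, match="bandwidth"):
            kernel_att(toy, np.full(12, 0.5), bandwidth=0.0)


class TestBalance:
    def test_randomized_treatment_is_balanced_before_matching(self):
        reps, ok = 20, 0
        for seed in range(reps):
            cfg = SyntheticConfig(
                n=5000, include_items=False, treatment_intercept=0.0,
                treatment_coefs={},
            )
            tab = generate(cfg, seed=300 + seed)
            pm = fit_propensity(tab, ["wealth_quintile", "location"])
            est = kernel_att(tab, pm.scores)
            rep = balance_report(tab, ["wealth_quintile", "location"], est)
            if (rep.table["std_diff_before"].abs() < 0.1).all():
                ok += 1
        assert ok / reps >= 0.95

    def test_matching_reduces_confounder_imbalance(self):
        reps, ok = 20, 0
        for seed in range(reps):
            tab = generate(SyntheticConfig(n=4000, include_items=False),
                           seed=400 + seed)
            regs = list(tab.codebook.covariates)
            pm = fit_propensity(tab, regs)
            est = kernel_att(tab, pm.scores)
            rep = balance_report(tab, ["mother_education"], est)
            row = rep.table.loc[rep.table.index.str.startswith("mother_education")]
            if (row["std_diff_after"].abs() <= row["std_diff_before"].abs()).all():
                ok += 1
        assert ok / reps >= 0.90

    def test_constant_covariate_scores_zero_difference(self, simple_codebook):
        rng = np.random.default_rng(12)
        n = 200
        t = make_table(pd.DataFrame({
            "region": rng.integers(0, 2, n), "wealth": 1,
            "diet_class": rng.integers(0, 2, n),
            "stunting": rng.integers(0, 2, n),
        }), simple_codebook)
        est = kernel_att(t, rng.uniform(0.3, 0.7, n))
        rep = balance_report(t, ["wealth"], est)
        assert rep.table.loc["wealth[rich]", "std_diff_before"] == 0.0
        assert rep.table.loc["wealth[rich]", "std_diff_after"] == 0.0


class TestLocalAttCurve:
    def _planted(self, seed, n, tau_fn):
        rng = np.random.default_rng(seed)
        x = rng.random(n)                       # latent driver of the score
        treated = (rng.random(n) < 0.5).astype(int)
        scores = 0.2 + 0.6 * x
        y0 = rng.random(n) < 0.3
        y = np.where(treated == 1, rng.random(n) < 0.3 + tau_fn(scores), y0)
        cb = VariableCodebook.from_variables([
            Variable("region", ("north", "south"), "covariate"),
            Variable("wealth", ("poor", "rich"), "covariate"),
        ])
        t = make_table(pd.DataFrame({
            "region": rng.integers(0, 2, n), "wealth": rng.integers(0, 2, n),
            "diet_class": treated, "stunting": y.astype(int),
        }), cb)
        return t, scores

    def test_constant_effect_yields_flat_curve(self):
        t, scores = self._planted(13, 20000, lambda p: 0.15)
        est = kernel_att(t, scores)
        curve = att_by_pscore_curve(est)
        inner = curve[(curve.score > 0.3) & (curve.score < 0.7)]
        assert np.abs(inner.local_att - 0.15).max() < 0.05

    def test_declining_effect_yields_negative_slope(self):
        neg = 0
        reps = 20
        for seed in range(reps):
            t, scores = self._planted(500 + seed, 8000,
                                      lambda p: 0.35 - 0.4 * p)
            est = kernel_att(t, scores)
            curve = att_by_pscore_curve(est)
            slope = np.polyfit(curve.score, curve.local_att, 1)[0]
            neg += slope < 0
        assert neg >= int(0.9 * reps)

    def test_too_few_treated_rejected(self, simple_codebook):
        t = make_table(pd.DataFrame({
            "region": [0, 1] * 4, "wealth": [0, 0, 1, 1] * 2,
            "diet_class": [1, 0] * 4, "stunting": [0, 1] * 4,
        }), simple_codebook)
        est = kernel_att(t, np.linspace(0.4, 0.6, 8))
        with pytest.raises(ValueError, match="at least 10"):
            att_by_pscore_curve(est)

    def test_degenerate_score_distribution_flagged(self, simple_codebook):
        rng = np.random.default_rng(14)
        n = 100
        t = make_table(pd.DataFrame({
            "region": rng.integers(0, 2, n), "wealth": 0,
            "diet_class": rng.integers(0, 2, n),
            "stunting": rng.integers(0, 2, n),
        }), simple_codebook)
        est = kernel_att(t, np.full(n, 0.5))
        curve = att_by_pscore_curve(est)
        assert len(curve) == 1 and curve.degenerate.all()
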