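# Methods

This note documents the models, estimators, numerical choices and known
limitations behind `dietpoll`. It states nothing the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model

A household table holds one row per surveyed child: an observation mass
`w_s` (sampling weight, default 1 — masses only ever enter as ratios, so
all polling quantities are invariant to rescaling all weights), a vector
of integer-coded categorical covariates validated against a codebook
(consecutive codes from 0; the first category of each variable is the
omitted reference in every regression), the treatment state
`diet_class` (1 = inadequate dietary diversity), the binary stunting
outcome (height-for-age more than 2 SD below the reference mean), child
age in months and the interview-day index. Records with missing
covariate values are rejected at load with the offending row and column
named; a missing weight column defaults to unit masses with a logged
warning.

The default analysis window keeps children aged 6–25 months inclusive:
younger infants are presumed breast- or bottle-fed (diet diversity is
not meaningfully measured) and the recall instrument does not reach
older children.

## CDDS construction

Thirteen 24-h recall items collapse onto 7 food groups
(grains/roots/tubers; vitamin-A rich; other fruits and vegetables;
meat/poultry/fish; eggs; pulses/legumes/nuts; milk products) — a group
scores 1 when any of its items does. The instrument has no oil/fat item,
so the eighth conventional group is unreachable and the score range is
0–7. Adequacy requires a score strictly above the threshold (default 3);
the threshold is a parameter so the 4-of-8 variant remains available.

### Interview-timing detrend

Fieldwork spans months, so measured diversity can carry a seasonal
artifact. `detrend_interview_timing(method="day-regression")` removes
the *linear* day trend of the adequacy indicator. A note on the design:
simply residualising the 0/1 indicator on day and re-thresholding is an
identity for any realistic trend — the fitted shift (a few points of
probability) never bridges the 0-to-1 gap, so no label can flip. The
implementation therefore re-thresholds **within days**: each day's
adequate count is moved by exactly the fitted linear component
(`target rate = observed rate − b̂₁·(day − mean day)`), with records
ranked by CDDS so the marginal diets flip first (ties broken by current
class, then record id — fully deterministic). Non-linear day-to-day
variation is deliberately preserved. Under a no-trend data-generating
process fewer than 1% of labels move (rounding noise only); under a
planted linear trend the post-adjustment slope is zero up to Monte-Carlo
error (both verified in the suite). The default remains `none` so the
core pipeline never silently depends on this approximation.

## Variable screening

Each candidate covariate is screened by a univariate probit of the
treatment state on its category indicators; the variable's p-value is
the joint Wald test of all its category effects, and the top-k (default
10) lowest p-values are kept. Probit keeps the screen internally
consistent with the propensity model. On perfect separation or
non-convergence the p-value falls back to a linear-probability OLS
F test, flagged in the result. Ties in p-value break lexicographically
by variable name, so the selection is deterministic and independent of
the candidate ordering.

## Polling

Profiles are enumerated exhaustively: every value assignment of every
k-subset of the selected variables (k = 5 by default; 10 variables give
252 subsets). For relevant group g and profile x with mass
`m_gc = Σ_{s∈S_gc} w_s`:

- coverage `= m_gc / Σ_c m_gc`, exclusion error `λ = 1 − coverage`,
- inclusion error `μ = 1 − m_gc / Σ_g m_gc`,
- `ψ(α) = λ^α μ^(1−α)`, with `0⁰ := 1` so a zero error wins outright at
  the boundary weightings.

Zero-mass profiles have undefined μ and are excluded from ranking. The
winner per α is the ψ-argmin; exact ties (within 1e-12) are all
reported, with the lexicographically smallest profile key as the primary
pick, making results independent of enumeration order.

## Propensity-score kernel matching

The treatment model is a maximum-likelihood probit of `diet_class` on
category indicators (Newton, tolerance 1e-8, max 100 iterations;
deterministic). Marginal effects are evaluated at the regressor means.
Perfect separation is detected up front and reported with the offending
column; fitted scores are clipped into (1e-9, 1 − 1e-9).

**Common support.** Treated records with scores outside the comparison
group's [min, max] are dropped and counted. The rule is two-sided for
symmetry even though, with treatment the majority state, drops occur in
practice only at the upper end.

**ATT.** For treated i, the counterfactual is the Epanechnikov-weighted
comparison mean, `K(u) = 0.75(1 − u²)` on `|u| < 1`, `u = (p_j − p_i)/h`.
The default bandwidth h = 0.06 follows the convention of widely used
kernel-matching implementations (the choice is exposed; sensitivity
sweeps over {0.02, 0.06, 0.1} showed no material bias difference in the
generator's designs). Treated records with an empty kernel window are
dropped and counted rather than rescued by nearest-neighbour matching.
Kernel weights normalise to 1 per treated record whenever the window is
non-empty.

Because the kernel is a quadratic polynomial inside its window, all
kernel sums are evaluated with sorted prefix sums of `v`, `v·p`, `v·p²`
(O(n log n) instead of the O(n²) double loop); the suite cross-checks
this against a direct double-loop oracle at 1e-10 and against an exact
stratification oracle when a single discrete covariate makes the score
discrete.

**Standard error.** With normalised treated masses ω_i and total matched
mass W_j received by comparison j, the ATT is
`Σ ω_i y_i − Σ W_j y_j`, and under the stated assumption set
(independent observations, fixed kernel weights, homoscedastic outcomes
within the treated and within the comparison group, outcome variance
unrelated to the score):

    Var(ATT) = s²_T · Σ_i ω_i²  +  s²_C · Σ_j W_j²

with s² the within-group sample variances. The null-calibration test
confirms the implied one-sided t ≥ 1.645 discovery rate sits at ~5%.
This variance ignores the estimation of the propensity score itself
(as the assumption set implies); under randomisation that omission is
conservative.

**Diagnostics.** Balance is reported as standardised differences and
variance ratios before/after matching, both scaled by the pooled
*before*-matching SD so the two columns share a scale; density curves of
child age and interview day (before/after) use a Gaussian KDE. The local
treatment-effect curve is a lowess fit (default span 0.8) of the
per-treated outcome gap `y_i − counterfactual_i` on `p_i`.

## Impact profiling

Scores are fitted once on the full sample; each profile's ATT restricts
both treated and comparison to profile members and re-checks support
within the profile. Then

    impact(x) = ATT(x) · Pr[treated | x] · Pr[x],

impact coverage is the profile's share of total impact, and
`λ_impact = 1 − impact coverage`, `μ_impact = 1 − Pr[treated | x]`,
`ψ_impact = λ^α μ^(1−α)` minimised as in polling. When profiles overlap,
the total-impact denominator divides each household's mass by the number
of universe profiles containing it (`Σ_{s∈S_x} w_s / c_s`); on a
disjoint universe this reduces exactly to the plain sum (asserted in the
suite). When some profile impacts are negative a coverage can leave
[0, 1]; such profiles cannot enter the geometric mean and are skipped in
the winner ranking (their metrics are still reported).

**Minimum-sample semantics.** Every profile with at least one treated
and one comparison member receives an ATT and enters the impact-coverage
universe; the minimum-treated-n rule (default 100) and the one-sided
t ≥ 1.645 threshold apply to the significance-based outputs — discovery
counts, the characteristics table and the need-vs-impact comparison.
Gating *estimability* on the minimum-n rule instead would empty the
universe entirely at survey scale (≈1600 households, 5-variable
profiles), which is why the model layer separates the two roles.

**Anti-fishing diagnostics.** With ~10⁵ profile ATTs, sampling variation
alone produces significant-looking effects. The package reports (a)
profile-ATT distribution summaries (centre, skew, share negative) by
minimum treated sample size — under a global null these centre on zero
at every threshold, while a real effect shifts them and shrinks the
negative share as the threshold grows; and (b) a false-discovery-rate
estimate per (minimum n, t threshold) cell: treatment labels are
permuted, the propensity model re-fitted and profile ATTs recomputed;
the expected null discovery count over the observed count estimates the
FDR (undefined when nothing is observed; capped at 1).

**Need vs impact.** Over profiles with positive ATT significant at the
one-sided threshold and enough treated members, the Pearson correlation
of polling coverage with impact coverage measures how far targeting need
aligns with targeting impact. Both coverages share the profile-mass
factor, so even strongly divergent effect landscapes leave substantial
positive correlation; the informative comparison is which profiles *win*
under each criterion. Fewer than 3 qualifying profiles leave the
correlation undefined (flagged).

## Synthetic data generator

The generator emulates the target survey, not any particular microdata
release. Defaults (the fixed study conditions of the test suite):
n = 1613 children aged 6–25 months; ten covariates with the category
distributions in `SyntheticConfig`; a probit treatment model whose
coefficient pattern follows the usual gradients (inadequate diversity
more likely for younger children, children with young siblings,
non-working and less-educated mothers, poorer, rural households),
intercept 2.0 giving a treated share near 0.7; baseline stunting risk
0.20 with mild covariate gradients (education, wealth, location, age)
that confound treatment and outcome; unit masses (a lognormal option
exists); no treatment effect unless profiles with τ_x are planted.
Stunting is drawn Bernoulli at `baseline + covariate terms +
τ_x·treated`, clipped to [0, 1] with a logged count and an error if more
than 5% of records clip. Recall item flags are drawn consistently with
the assigned diet class (treated children receive CDDS ≤ 3), so passing
the table back through the CDDS module reproduces `diet_class` exactly.

What the generator does **not** emulate: within-cluster correlation of
survey design, spatially structured covariates, measurement error in the
recall, misreported ages, or effect heterogeneity beyond the planted
profile map. Passing tests therefore demonstrate the estimators'
correctness under selection-on-observables with independent
observations, not robustness to those real-data features.

## Problem sizes in the suite and acceptance script

Monte-Carlo checks use: constant-effect recovery τ = 0.10 at n = 5000
over 200 replicates (script: 50); profile-effect recovery τ = 0.15 at
n = 20000 over 100 replicates (script: 20) plus 50 replicates for the
rank-correlation check across a five-level effect gradient; null
calibration over 100 replicates of n = 4000 with five disjoint profiles
each (script: 80). The replicate counts were set for Monte-Carlo
standard errors an order of magnitude below the planted effects. The
study-scale pipeline run uses the generator defaults (n = 1613, k = 5,
97 088 enumerated profiles).

## Known limitations

- Identification is selection-on-observables; nothing here licenses
  causal claims when unobserved confounders move both diet diversity and
  stunting.
- The analytic SE ignores propensity-estimation uncertainty and
  within-cluster correlation; bootstrap SEs are deliberately out of
  scope.
- The interview-timing correction removes only a linear day trend and
  needs the CDDS column for a meaningful within-day ranking.
- Exhaustive enumeration is exponential in k through the category
  counts; k = 5 over 10 variables (~10⁵ profiles) is comfortable, much
  larger universes are not the design point.
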