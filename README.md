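# dietpoll

Polling and impact profiling of child dietary diversity: who *lacks* a
diverse diet, and who would *benefit most* from fixing that.

## The problem

Nutrition surveys with a 24-h food recall let us score each child's
dietary diversity (the CDDS: the number of distinct food groups, 0–7,
eaten the previous day) and flag children with an inadequate diet
(CDDS ≤ 3). Programmes then have to decide *whom to target*. Two answers
compete:

- **Need** — target the subgroups where inadequate diversity is most
  concentrated.
- **Impact** — target the subgroups where improving diversity would
  reduce stunting the most. These need not coincide: the same diversity
  score can hide very different diets, and diet interacts with disease
  burden, water, sanitation and local agriculture.

`dietpoll` implements both answers for household survey data with
integer-coded covariates (child age band, sibling presence, mother's work
and education, wealth quintile, urban/rural, land use, growing period,
farming system, slope).

## The method

**Polling (need).** A *profile* x fixes k covariates at specific values
(default k = 5, enumerated exhaustively over every value assignment of
every k-subset — 10 variables in groups of 5 give C(10,5) = 252 subsets).
With observation masses w_s, group g (inadequate diversity) and
m_gc = Σ_{s∈S_gc} w_s:

    coverage    = m_gc / Σ_c m_gc          (share of the group captured)
    λ           = 1 − coverage              (exclusion error)
    μ           = 1 − m_gc / Σ_g m_gc       (inclusion error)
    ψ(α)        = λ^α · μ^(1−α)

The *winning profile* per α minimises ψ. Everything is non-parametric:
no functional form, just masses.

**Impact profiling.** The propensity of inadequate diversity is fitted
once by probit, Prob[treated | x] = Φ(x'β); treated children outside the
comparison group's score range are dropped (common support) and each
remaining treated child is matched to an Epanechnikov-kernel-weighted
average of comparison outcomes, K(u) = 0.75(1 − u²) on |u| < 1 with
u = (p_j − p_i)/h (default h = 0.06). For each profile x, the ATT of
inadequate diversity on stunting is re-estimated within the profile
(reusing the global scores), and

    impact(x)        = ATT(x) · Pr[treated | x] · Pr[x]
    impact coverage  = impact(x) / Σ_x' impact(x')
    λ_impact = 1 − impact coverage,  μ_impact = 1 − Pr[treated | x]
    ψ_impact(α) = λ_impact^α · μ_impact^(1−α)

Overlapping profiles share households, so the total-impact denominator
can divide each household's mass by the number of profiles containing it.
Because thousands of profile ATTs invite spurious findings, the package
ships anti-fishing diagnostics: profile-ATT distributions by minimum
treated sample size, and a permutation-null false-discovery-rate
estimate over a (minimum n, t threshold) grid.

No public microdata ships with the package; a synthetic-data generator
emulates the survey (known probit treatment model, additive stunting
risk, plantable profile-specific effects τ_x), so every stage is testable
against known truth.

## Worked example

```python
import dietpoll as dp

# simulate a survey-scale table with a planted urban effect
cfg = dp.SyntheticConfig(n=20000, include_items=False,
                         effects=((dp.Profile(("location",), (1,)), 0.10),))
table = dp.generate(cfg, seed=1)

res = dp.ImpactProfiler(table, k=2).fit()
print(res.summary())
```

prints (abridged):

```
Impact profiler results
=======================
n = 20000 records; selected variables: child_age_band, ..., slope
treated off support: 1.01%

Global kernel-matching ATT of inadequate diet diversity (bandwidth 0.06):
  unmatched difference: +0.0320 (se 0.0066, t +4.84)
  ATT: +0.0193 (se 0.0078, t +2.47); treated mean 0.259, matched comparison 0.240

profiles: 512 enumerated, 512 with estimable ATT, 101 significant (t >= 1.645, n_treated >= 100)
need vs impact coverage correlation: 0.615

Winning impact profiles by alpha:
 alpha                                                 profile  lambda_impact  mu_impact  psi_impact
0.0000 land_use=cultivated, farming_system=commercial_pastoral         0.9552     0.1099      0.1099
0.2000                   child_age_band=13-25m, location=urban         0.0003     0.3906      0.0928
0.5000                   child_age_band=13-25m, location=urban         0.0003     0.3906      0.0107
1.0000                   child_age_band=13-25m, location=urban         0.0003     0.3906      0.0003
```

Read it as: the raw stunting gap between inadequately- and
adequately-fed children (+3.2 points) shrinks to +1.9 points after
matching on observables; the effect was planted in urban households, and
the winning impact profile for most error weightings is exactly the
urban/older-children subgroup, even though that group has comparatively
*low* need (μ_impact = 0.39 means 39% of its members already eat
adequately). The need-vs-impact correlation of 0.615 quantifies how far
targeting the neediest diverges from targeting the highest impact.

A command-line pipeline wraps the same machinery:

```bash
dietpoll simulate --seed 7 --out table.csv --codebook-out cb.yaml
dietpoll report --config run.yaml --out runs/demo
```

writing polling metrics, the propensity model, balance diagnostics,
figure-data CSVs and a machine-readable manifest.

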