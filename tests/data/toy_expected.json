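{
  "comment": "Hand-computed expectations for the 12-record toy fixture (total mass 15, treated mass 10). Impact numbers assume a constant propensity score for every record, so each counterfactual is the weighted comparison mean within the profile. Fractions: mu north = 3/7, att north = 1/12, impact north = 1/45, att poor = -5/7, impact poor = -1/3, att south = 1/6, impact south = 1/15.",
  "total_mass": 15.0,
  "treated_mass": 10.0,
  "polling": {
    "region=north": {
      "mass": 4.0,
      "profile_mass": 7.0,
      "coverage": 0.4,
      "lambda": 0.6,
      "mu": 0.42857142857142855,
      "psi_alpha_0.5": 0.5070925528371099
    },
    "wealth=poor": {
      "mass": 7.0,
      "profile_mass": 8.0,
      "coverage": 0.7,
      "lambda": 0.3,
      "mu": 0.125
    },
    "region=north,wealth=poor": {
      "mass": 2.0,
      "profile_mass": 3.0,
      "coverage": 0.2,
      "lambda": 0.8,
      "mu": 0.3333333333333333
    }
  },
  "impact": {
    "region=north": {
      "att": 0.08333333333333333,
      "pr_x": 0.4666666666666667,
      "pr_treated_given_x": 0.5714285714285714,
      "ate_x": 0.047619047619047616,
      "impact": 0.022222222222222223
    },
    "region=south": {
      "att": 0.16666666666666666,
      "pr_x": 0.5333333333333333,
      "pr_treated_given_x": 0.75,
      "ate_x": 0.125,
      "impact": 0.06666666666666667
    },
    "wealth=poor": {
      "att": -0.7142857142857143,
      "pr_x": 0.5333333333333333,
      "pr_treated_given_x": 0.875,
      "ate_x": -0.625,
      "impact": -0.3333333333333333
    }
  },
  "impact_coverage_region_partition": {
    "region=north": 0.25,
    "region=south": 0.75,
    "lambda_impact_north": 0.75,
    "mu_impact_north": 0.42857142857142855
  }
}
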