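# Synthetic-cohort spec with NON-NULL covariate effects (illustrative only;
# these effect sizes are this package's invention, not estimates from any
# real cohort). Useful for exercising the change-in-estimate confounder
# screen. Run with:
#   sepsisthresh simulate --spec examples/confounded.yaml --out confounded.csv
n_patients: 2000
seed: 7
# intercept lowered to offset the mean covariate contribution to the logit,
# keeping marginal 28-day mortality near 6%
intercept: -4.0
covariate_specs:
  - name: age
    dist: normal
    params: {loc: 66.7, scale: 15.2, lo: 18, hi: 89}
    effect: 0.02          # log-odds per year
  - name: sofa
    dist: lognormal
    params: {mu: 1.05, sigma: 0.65}
    effect: 0.15          # log-odds per SOFA point
  - name: septic_shock
    dist: bernoulli
    params: {p: 0.583}
    effect: 0.4
  - name: lactate
    dist: lognormal
    params: {mu: 0.64, sigma: 0.60}
    effect: 0.1           # log-odds per mmol/L
missing_rates:
  lactate: 0.283
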