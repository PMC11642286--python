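# bcfa — Bayesian CFA validation for Likert questionnaires

`bcfa` implements the Bayesian structural equation modelling (BSEM) workflow
used to validate patient-reported instruments such as the 12-item Partners in
Health (PIH) scale, which scores four self-management domains (Knowledge,
Partnership, Management of symptoms, Coping) on an 8-point Likert scale.

Classical confirmatory factor analysis (CFA) forces every cross-loading and
residual covariance to exactly zero — an assumption almost never literally
true, and a common source of apparent misfit.  The BSEM alternative replaces
exact zeros with informative small-variance priors: cross-loadings get
Normal(0, v) priors with tiny v, and the residual covariance matrix Θ gets an
Inverse-Wishart prior IW(dD, d) whose degrees of freedom d control how close
Θ is held to the diagonal matrix D.  The model is

    y = ν + Λη + ε,   η ~ N(0, Φ),   ε ~ N(0, Θ),

with factor variances fixed to 1 (Φ a correlation matrix) and standardized
indicators.  Estimation is by blocked Gibbs sampling with 8 independent
chains, monitored by the Gelman–Rubin potential scale reduction (PSR < 1.1).
Model fit is assessed with the posterior predictive p-value (PPP) built on
the ML chi-square discrepancy, the DIC with its effective parameter count
pD, and Bayesian versions of RMSEA/CFI/TLI.  Subscale reliability uses
McDonald's omega, ω = (Σλ)² / [(Σλ)² + Σθ], with 95% credible intervals.

The package covers the full sensitivity-search ladder: plain CFA → sweep of
cross-loading prior variances (0.001 … 0.03) → residual-covariance df grid
(d = 50 … 400), selecting the largest d whose PPP still exceeds 0.05.  A
synthetic-data generator parameterised from the published standardized
solution makes every step testable end to end.

## Worked example

```python
import bcfa

# 2000 synthetic respondents from the published BSEM solution
data = bcfa.generate_continuous(bcfa.bsem_generating_model(), 2000, seed=0)
std = bcfa.standardize(data)

spec = bcfa.with_crossloading_priors(bcfa.pih_cfa_spec(), 0.005)
draws = bcfa.run_mcmc(spec, std, chains=4, min_iterations=5000,
                      max_iterations=20000, seed=7)
print(draws.converged, round(max(draws.psr.values()), 3))

sol = bcfa.standardized_solution(draws)
print(round(sol.loadings[6, 2], 3))          # item 7 on Management
for name, est in bcfa.omega_posterior(draws).items():
    print(name, round(est.point, 2), (round(est.lower, 2), round(est.upper, 2)))
```

Output:

```
True 1.099
0.9
Knowledge 0.85 (0.81, 0.88)
Partnership 0.78 (0.73, 0.82)
Management 0.89 (0.86, 0.91)
Coping 0.84 (0.82, 0.87)
```

The fit converges (all PSR below 1.1); the recovered standardized loading of
item 7 on the Management factor is close to the generating value 0.906, and
each subscale's omega falls in the 0.70–0.95 band regarded as good internal
consistency, matching the reliabilities implied by the generating solution.

A CLI mirrors the library: `bcfa simulate`, `bcfa fit`, `bcfa sweep`,
`bcfa pipeline` (see `bcfa --help`).

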