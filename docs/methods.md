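# Methods

## Model and identification

The measurement model for p standardized indicators and m factors is
y = ν + Λη + ε with η ~ N(0, Φ) and ε ~ N(0, Θ).  Factor variances are
fixed at 1, so Φ is a correlation matrix and the solution is reported on the
standardized scale; this is required because all loadings — including
cross-loadings — are estimated in the BSEM specifications, leaving no
marker-indicator constraint available.  Indicators are treated as continuous
after column standardization (mean 0, sample sd 1); the 8-point Likert
response format is emulated by the generator's optional discretization step
but the estimator itself fits the linear model, matching the
standardize-and-fit treatment of the validation study design this package
operationalises.

Free parameters are counted as: estimated loadings (p majors, plus p·m − p
crosses when freed) + p intercepts + residual entries (p for diagonal Θ,
p(p+1)/2 for full Θ) + m(m−1)/2 factor correlations.  For the 12-item,
4-factor instrument this gives 42 (CFA), 78 (crosses freed) and 144 (full
Θ).  Intercepts are estimated rather than fixed at zero — standardization
makes them nearly zero, but counting them is what reproduces the
42/78/144 ladder of the reference software.

## Priors

* Major loadings and intercepts: Normal(0, 10) — effectively diffuse on
  standardized data.  (The source analysis does not state these; with
  n ≥ 200 their influence is negligible.)
* Cross-loadings: Normal(0, v) with v swept over
  {0.001, 0.005, 0.01, 0.015, 0.02, 0.03}.  v = 0.005 (prior sd ≈ 0.07)
  states that cross-loadings are believed close to zero without forcing
  them there.
* Residual covariance, diagonal specs: independent inverse-gamma IG(2, 0.5)
  per variance (prior mean 0.5, infinite variance).  A proper prior keeps
  prior-only sampling well defined; at the sample sizes used its posterior
  influence is a shift of order 1/n.
* Residual covariance, full specs: Θ ~ IW(dD, d) with D the diagonal of the
  posterior-mean Θ from the immediately preceding cross-loading fit (the
  natural reading of "residual variances from the BCFA model"; prior mean
  dD/(d − p − 1), which requires d > p + 1).  Larger d pulls Θ harder
  toward diagonality.
* Factor correlations: the marginally uniform projected Inverse-Wishart
  prior induced by W ~ IW(I, m+1), Φ = cor(W) — each correlation is
  marginally uniform on (−1, 1).

## Sampler

Blocked Gibbs with exact full conditionals:

1. factor scores η_i | · ~ N(VΛ'Θ⁻¹(y_i − ν), V), V = (Φ⁻¹ + Λ'Θ⁻¹Λ)⁻¹;
2. the free entries of the coefficient matrix [ν, Λ] jointly from the
   normal full conditional with precision (Θ⁻¹ ⊗ X'X) restricted to free
   entries plus the diagonal prior precision (X = [1, η]);
3. Θ | · from IW(dD + E'E, d + n) (full) or per-item inverse-gamma
   (diagonal), E the residual matrix;
4. Φ | · by exact parameter expansion (marginal data augmentation): draw
   the expansion scales d_j² ~ IG((m+1)/2, (Φ⁻¹)_jj/2), rescale the factor
   scores, update the expanded covariance W conjugately from
   IW(I + ξ'ξ, m + 1 + n), and project back to Φ = cor(W).  Because the
   expansion is exact for the projected-IW prior, no Metropolis correction
   is needed — the step is a plain Gibbs move with acceptance probability 1,
   which is why a parameter-expanded Metropolis variant was not used.

After every iteration each factor is sign-aligned so its summed major
loadings are positive; this relabelling leaves the likelihood invariant and
removes the reflection ambiguity from summaries.  Inverse-Wishart draws use
the Bartlett decomposition.  A single integer seed spawns one independent
stream per chain, so runs are bit-reproducible regardless of scheduling.

Chains start overdispersed (majors jittered in 0.3–1.1, residual variances
in e^[−1, 0.2]).  The first half of every chain is discarded as burn-in.
Convergence uses the classic Gelman–Rubin PSR on the retained halves,
PSR = sqrt([(T−1)/T·W + B/T]/W) (floored at 1 so identical chains report
exactly 1), checked at the minimum iteration count and every 1000 iterations
thereafter until PSR < 1.1 for every monitored parameter or the maximum is
reached; non-convergence sets a flag rather than raising.

## Fit assessment

The discrepancy is the chi-square-scaled ML fit function with a mean term:
D = n[ln|Σ| − ln|S| + tr(SΣ⁻¹) − p + (ȳ−μ)'Σ⁻¹(ȳ−μ)], with S the
divisor-n sample covariance (the SEM ML convention, recorded in output
metadata).  PPP is the share of retained draws whose replicated-data
discrepancy (fresh n-row dataset simulated from the draw) exceeds the
observed-data discrepancy; the 2.5/97.5 percentiles of D_obs − D_rep give
the reported interval.  Replicate seeds derive from the run seed plus the
draw index.

DIC uses the multivariate-normal deviance: pD = mean deviance minus
deviance at the posterior mean, DIC = D(θ̄) + 2pD; negative pD is reported
as-is with a warning, and a non-PD posterior-mean Σ is repaired to the
nearest PD matrix (eigenvalue floor) with a warning.

The named approximate fit indices are not given closed forms in most BSEM
reports; this package computes, per draw, the chi-square excess over the
free-parameter count p*: BRMSEA = sqrt(max(0, D − p*)/(p*·n)); BCFI = 1 −
excess/excess_baseline; BTLI the same with df-normalised excesses (df =
moments − free parameters, moments = p(p+3)/2).  The baseline is the
independence model (per-item means and variances, conjugate posterior
sampled exactly).  Indices are capped at their logical bounds, summarised
by the posterior median with equal-tailed 90% intervals, and labelled
against the conventional cut-offs RMSEA < 0.06, CFI/TLI > 0.95.  The exact
variant is recorded in the output so comparisons are self-describing.

## Sensitivity ladder

"Substantial reduction" of the discrepancy-difference interval is
operationalised as ≥ 30% shrinkage of its upper bound relative to the CFA
row (configurable); "not sacrificing convergence speed" as convergence
within twice the minimum iterations.  The residual-df rule keeps the
largest d with PPP > 0.05 — the model closest to the CFA that still fits.
On the published PPP-by-d map this rule selects d = 300; because reports in
this literature sometimes adopt a smaller d on qualitative grounds, the
pipeline accepts explicit overrides for both the cross-loading variance and
d.

## Synthetic data generator

`bsem_generating_model()` reproduces the published standardized BSEM
solution (majors, small crosses, factor correlations 0.409–0.662) with
diagonal Θ chosen so every indicator has unit implied variance;
`cfa_generating_model()` does the same for the zero-cross CFA solution.
Residual covariances in the presets are diagonal — the three significant
residual correlations in the source analysis were below 0.14 and deemed
ignorable — but a user-supplied Θ with off-diagonals is accepted to
exercise the IW machinery.  Rows are i.i.d. multivariate normal;
discretization to k Likert categories uses per-item equal-probability
(empirical-quantile) cuts or explicit thresholds.  The generator emulates
the covariance structure the analysis assumes, not survey artefacts
(no skew/floor effects, no missingness, no acquiescence styles), so passing
recovery tests demonstrates correctness of the estimator under its own
assumptions rather than robustness to real questionnaire data.

## Problem sizes and numerical choices

The test suite and acceptance script run recovery at n = 2000 (4–8 chains,
5,000–15,000 minimum iterations), oracle comparisons at n = 2000, and the
PPP calibration study at n = 200 with 200 generate-and-refit replicates on
a reduced budget (2 chains × 800 iterations) — sizes chosen to keep the
full suite in the tens of minutes on one CPU while leaving Monte-Carlo
error well inside the tested tolerances.  Matrix inversions go through
Cholesky factorizations with symmetrisation of accumulating products;
the ML-CFA oracle (scipy L-BFGS-B on the Wishart fit function, Φ through
normalised Cholesky rows, log-variances) uses jittered multi-starts.

## Known limitations

* Ordinal data are treated as continuous; no polychoric/probit variant.
* The PX update targets the marginally uniform correlation prior only; no
  user-specified Φ prior.
* A two-indicator subscale (Knowledge, Management) identifies its factor
  mainly through cross-factor covariances; at n ≈ 2000 the split of the two
  loadings within such a pair carries posterior sd ≈ 0.05–0.08 under
  small-variance cross-loading priors, so point recovery of an individual
  loading is intrinsically noisier there than for four-indicator factors.
* Full-Θ (IW) models with d close to p + 2 put substantial mass on strong
  residual correlations; the sampler handles this, but PPP-based selection
  should be interpreted as the design intends (closeness to the CFA), not
  as evidence the residual structure is real.
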