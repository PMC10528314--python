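# Methods

## Model family

The package composes the unit truncated Lindley (UTL) law with a parent cdf
G. The UTL cdf and pdf on [0, 1] are

    F(y) = C_θ [1 + θ − (1 + θ + θy) e^{−θy}],
    f(y) = θ² C_θ (1 + y) e^{−θy},
    C_θ  = 1 / D(θ),   D(θ) = 1 + θ − e^{−θ} − 2θ e^{−θ},

for any θ ≠ 0 (D > 0 on both half-lines). The composed family has cdf
F∘G and density θ² C_θ g (1 + G) e^{−θG}; with a Weibull(k, λ) parent every
distribution function is closed-form (the TLW model). θ → 0 is a removable
singularity: D ~ (3/2)θ², and the density degenerates continuously to
(2/3)(1 + G(x)) g(x). All code treats θ = 0 as the formal exclusion it is,
but evaluates the limit stably, so optimizers may cross the origin.

Quantiles invert the UTL cdf through the Lambert W function. Writing the
defining equation in `w e^w` form gives `w = −(1 + θ + θy)`; for θ > 0 this
is below −1 (branch −1), for θ < 0 above −1 (principal branch). The
implementation selects the branch by sign(θ), applies one Newton polish in
the stable cdf, and falls back to bracketed Brent root-finding whenever the
Lambert argument is ill-conditioned (|θ| < 0.01, where the argument collides
with the branch point −1/e) or overflows (θ below about −700).

## Numerical policy

* **Never exponentiate −θ alone.** For θ ≤ −30 all ratios are rescaled by
  e^θ (e.g. log D = −θ + log[(1+θ)e^θ − (1+2θ)]); likelihoods, survival
  functions and scores stay finite for θ of order −50, the regime real
  lifetime data favour.
* **Cancellation-free small-θ forms.** D and the cdf numerator are evaluated
  through `expm1`-based rewrites whose leading O(1) terms cancel
  analytically, plus short power series for |θ| < 0.05 where even those
  lose digits (log(θ²C_θ) and its θ-derivative are evaluated as series of
  the ratio, finite at θ = 0).
* **Survival function.** S = C_θ e^{−θ}[(1+2θ)·expm1(s) − s e^s] with
  s = θe^{−z}, exact for both θ signs; for |s| < 1e−6 a log-space asymptote
  (log S = log 2θ² − z − θ − log D) avoids underflow in the deep right tail.
* **Quadrature.** Moments, the mgf, mean deviations and entropies integrate
  in the probability scale y = G(x) against the UTL density
  (adaptive Gauss–Kronrod, absolute tolerance 1e−10, limit 400). The
  exponentiated-G series expansion of the density is implemented only as a
  cross-check; it is alternating and useful for |θ| ≲ 3 at order ~40.
* **mgf sign.** The generating function uses e^{+tQ_G(y)} in the integrand
  so that M(0) = 1 and M′(0) equals the mean (both verified by tests).

## Shape classification

Stationary points of the TLW density solve A(z) = B(z) in z = (x/λ)^k
space, with A = −z e^{−z} and B = (2/θ)·z(1−e^{−z})/(2−e^{−z}) + τ\*,
τ\* = (1−k)/(kθ). Roots are located by 4000 log-spaced sign probes on
z ∈ (1e−10, max(50, 10/|θ|)) with Brent refinement, and labelled min/max
from the density derivative. `classify_shape` reports this exact analysis
as `shape`, alongside the coarse decision-table prediction
(`table_shape`) by sign(θ) and the position of τ\* relative to −1/e and 0.
The two coincide except for θ < 0 with τ\* ∈ (−1/e, 0) at small |θ|,
where the (2/θ) term dominates B and the density is simply decreasing —
the decision table is valid only where that term is subordinate.
Boundary cases (τ\* within 1e−10 of −1/e or 0) are delegated to a
2000-point monotonicity scan and flagged.

## Estimation

The TLW log-likelihood (with z_i = (x_i/λ)^k)

    ℓ = n[2log|θ| + log C_θ + log k − k log λ] + (k−1)Σ log x_i
        + Σ log(2 − e^{−z_i}) − Σ z_i − θ Σ (1 − e^{−z_i})

is maximised in (θ, log k, log λ) by L-BFGS-B with the analytic score
(re-derived by direct differentiation and verified against central finite
differences to 1e−6 relative). The surface is typically bimodal across the
sign of θ, so the default multistart bank is θ ∈ ±{0.5, 2, 10, 40} with
(k, λ) seeded from the closed-form-profile Weibull baseline fit. Standard
errors come from the inverse numeric Hessian in the original
parameterisation, with an outer-product-of-scores fallback (flagged in the
result) when the Hessian is not positive definite; 95% intervals are
estimate ± 1.96·SE. Convergence requires the optimizer's own criterion
(ftol 1e−12) plus a small scaled gradient norm.

The censored regression shares θ across observations and links both Weibull
parameters, λᵢ = exp(vᵢ'β₁), kᵢ = exp(vᵢ'β₂). Failure times contribute the
log density, right-censored times log S; the analytic gradient chains the
per-observation (θ, log k, log λ) derivatives through the design matrices.
Wald p-values use the standard normal reference (the large-sample
distribution; a t reference would require an effective-df convention the
model does not supply).

A note on the packaged-temperature fit: the likelihood is extremely flat
along a ridge in (θ, k, λ) near the optimum (SE(θ̂) ≈ 26). Our multistart
fit converges to −ℓ = 252.5614 at (−27.654, 3.4814, 12.822); the
previously circulated point (−28.449, 3.4545, 12.756) lies on the same
ridge 4·10⁻⁴ log-likelihood units lower, i.e. it is the same optimum
reported at a looser convergence tolerance. The −ℓ values our evaluation
produces for the TLW fits (252.562 and 56.983 on the two packaged
datasets) are what the likelihood above actually takes at those points;
the package reports only quantities it computes.

## Boundary behaviour of the family

As θ → ±∞ with λ^k/|θ| held fixed, the TLW law converges to a plain
Weibull distribution: the family contains its own parent on the boundary
of the parameter space. Consequently, for data whose best description is
(close to) Weibull, the likelihood increases along an escape ridge with
θ and λ diverging together, and the global maximiser need not exist in the
interior. This matters for simulation studies (below) and explains the
flat θ ridges seen in real-data fits.

## Monte Carlo studies

`run_tlw_study` and `run_regression_study` simulate at known true values by
inverse transform, refit every replicate, and report the average estimate
(AE), |AE − truth|, the mean absolute error, the MSE, and the Monte Carlo
standard error of the AE; both absolute-bias conventions are reported
because published recovery tables in this literature typically print
|AE − truth|. Failed replicates are redrawn up to three times, then
dropped and counted. A single integer seed drives a SeedSequence spawn per
replicate, so reports are bit-reproducible.

Two refit protocols exist. The default, `protocol="local"`, runs one
quasi-Newton ascent initialised at the generating values and therefore
measures recovery of the likelihood branch the data were generated from.
This is a deliberate design choice: because of the Weibull boundary limit,
the *global* maximiser escapes along the θ-ridge for a material share of
replicates (pilot at truth (0.5, 0.5, 0.5), n = 300: mean θ̂ of order 10³),
so global-MLE recovery moments are dominated by those excursions; an
information-matrix calculation likewise shows that the tight recovery
published for this design is unattainable by any unconstrained global
estimator. `protocol="multistart"` is available for studying exactly that
behaviour. Default cell sizes follow the published designs (replicates are
configurable; the acceptance script uses 500 for the distribution cell and
200 for the regression cell).

Censoring in the regression study uses cᵢ ~ Uniform(0, γ) with γ calibrated
by Brent root-finding so the expected censoring fraction (averaged over the
binary-covariate patterns, survival integrated by quadrature) matches the
requested target; realized fractions land within ~1 percentage point of
the 10%/30% targets.

## Synthetic data generators

The simulation designs emulate the structure of real censored survival
studies: one binary covariate (Bernoulli(0.5)) entering both link
functions, uniform non-informative censoring, true values
(β₁₀, β₁₁, β₂₀, β₂₁, θ) = (0.3, 0.4, 0.2, 0.5, 0.6) and sample sizes
100–500. They do not emulate covariate-dependent or informative censoring,
continuous covariates, ties from coarse measurement, or model
misspecification — passing recovery tests therefore demonstrates
correctness of the estimation machinery under the assumed model, not
robustness on messy real data.

## Entropies

The Shannon entropy is computed exactly as −E[log f(X)] by quadrature in
the probability scale. A closed-form shortcut
(−log(θ²C_θ) + η_G + 1 − 2log2 + θ/2, with η_G the parent entropy) is also
exposed: it treats G(X) as uniform, whereas under this family G(X) follows
the UTL law, so it is only approximate (exact in the θ → 0 limit); both
values are available so the gap can be inspected. The Rényi entropy
integrates f^τ directly in x.

## Known limitations

* Standard errors for θ̂ on ridge-shaped likelihoods are Wald approximations
  of limited meaning; profile or bootstrap intervals would be better and are
  not implemented.
* The exponentiated-G series oracle diverges numerically for |θ| ≳ 10 and is
  not a production path.
* `quantile_residuals` is defined only for fully observed samples;
  randomized quantile residuals for censored data are not implemented.
* The Kaplan–Meier helper handles right censoring only (no left truncation).
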