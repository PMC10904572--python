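# Methods

## Model and assumptions

The package works at the identification level: populations are described by
exact joint distributions, not samples, so there is no sampling uncertainty
anywhere and no confidence intervals are produced. The causal assumptions
are the standard ones for attributable-fraction identification:

* **Conditional exchangeability.** Within each stratum of the measured
  confounder, exposure is as-if randomised. This licenses the
  counterfactual standardization used by the population oracle: the
  counterfactual risk of a cell under exposure level `t` is the observed
  risk of the cell at level `t` in the same confounder stratum.
* **Reference level.** Exposure codes are integers with 0 fixed as the
  reference (the minimum-risk exposure value, MREV). For continuous
  exposures the MREV must coincide with a grid node; shifting or
  interpolating exposure scales is out of scope.
* **Consistency/positivity.** Every stratum must contain a reference cell
  (a hard error otherwise, since the counterfactual is undefined); a
  stratum may lack a non-reference level, contributing no exposed mass.

Definitions, for a binary exposure X, disease Y, confounder C:

* definition PAF = (P(Y=1) − P(Y₀=1)) / P(Y=1);
* unadjusted RR, RR_U = P(Y=1|X=1)/P(Y=1|X=0);
* marginal causal RR, RR_C = P(Y₁=1)/P(Y₀=1), standardized over the
  population confounder distribution;
* causal RR among the exposed, RR_e = P(Y₁=1|X=1)/P(Y₀=1|X=1),
  standardized over the confounder distribution of the exposed;
* confounding ratio C = RR_C/RR_U (C = 1 ⇔ no confounding in risk ratio).

Exact identities implemented and verified by property tests:

* the case-weighted stratum decomposition
  PAF = E_{C|Y=1}[P(X=1|C,Y=1)·(RR_C(C)−1)/RR_C(C)] (and its multi-level
  double-expectation form) equals the definition PAF for *every* valid
  population, including under effect modification;
* π_c·(RR_e−1)/RR_e equals the definition PAF always;
* Miettinen's two forms (case-prevalence and three-variable) equal the
  definition PAF whenever the stratum causal RRs are constant;
* Levin's formula equals the definition PAF when exposure is independent
  of the confounder;
* the marginal causal RR and RR_e are both weighted averages of the
  stratum causal RRs, hence bracketed by their extremes.

## Bias of Levin's formula

With no effect modification the truth is the three-variable Miettinen form,
and the relative bias has the closed form
`PAF_L/PAF = C(1+π(RR_U−1))/(1+π(C·RR_U−1))`. Limits are reported
analytically, never by grid extrapolation: the relative bias rises to
`1+(1−π)/(π·RR_U)` as C→∞, takes the continuous-extension value
`(1+π(RR_U−1))/RR_U` at C = 1/RR_U (where both PAFs vanish), and tends to 0
as C→0; the absolute bias vanishes at C = 1 and C = 1/RR_U and tends to
`1−πRR_U/(1+π(RR_U−1))` for large C. The absolute bias is evaluated as a
single fraction whose numerator bracket cancels bitwise when RR_C equals
RR_U, so the curve is exactly 0 at C = 1 rather than within rounding.

The default confounding grid is 200 log-spaced points on [0.2, 5] — log
spacing because C acts multiplicatively, and a range that spans substantial
confounding in both directions while keeping the four-panel figure
readable; both endpoints and the resolution are configurable. The figure
reproduces the standard presentation (absolute/relative bias, with and
without the restriction RR_C ≥ 1, adjusted Levin in blue, unadjusted in
red, analytic limit lines); styling is not bit-matched to any publication.

The "unadjusted" Levin variant plugs RR_U in place of RR_C. Its estimate is
constant in C while the truth moves, so its relative bias is negative
wherever RR_C < 1 < RR_U — the estimator flips the sign of the PAF — which
the property suite checks.

## General exposure distributions

Multi-category exposures use mass-weighted sums; continuous exposures use
composite trapezoid quadrature on the user-supplied grid. No adaptive
refinement is attempted because inputs are typically tabulated summaries
rather than callable functions; instead a warning fires when the RR ratio
between adjacent support nodes exceeds 1.5 (the grid is then probably too
coarse) and the convergence test in the suite checks that halving the grid
spacing of a smooth profile (lognormal density, log-linear RR) moves
results by less than 1e-6. Continuous densities are renormalized to
integrate to exactly 1, with a warning when the raw integral is off by more
than 1e-3. Category masses must sum to 1 exactly (to 1e-9); they are never
silently rescaled.

The case-conditional density is related to the population density by Bayes'
rule, π_c(x) ∝ RR_U(x)·π(x); `ExposureProfile.case_profile()` applies this,
and the suite confirms numerically that the case-density estimator and the
population-density estimator agree on random gridded profiles, and that
every estimator collapses to its binary closed form on two-point profiles.

## Synthetic generator

Randomness lives only in the `synthetic` module; everything else is
deterministic. The generator mirrors the worked example's mechanism: a
confounder shifts both baseline risk and exposure probability, so cell
proportions are `stratum_weight × exposure probability` and exposed-cell
risks are `baseline × stratum RR`. Random specs draw stratum weights from a
Dirichlet(2,…,2) (moderately even strata), baseline risks uniformly below a
cap of 0.95/max(RR, 1) so every product stays a valid probability, stratum
RRs uniform on [0.5, 3] (protective through strong harmful effects), and
per-stratum exposure prevalences uniform on [0.05, 0.95] so both exposed
and unexposed cells always carry mass. Defaults are chosen to exercise the
estimators across realistic epidemiological ranges rather than to emulate
any particular disease.

`sweep_confounding` fixes the overall prevalence and a constant causal RR
and solves for the exposure split between a low- and a high-baseline-risk
stratum that realises a requested confounding ratio. The realised C is
monotone in the split, so bisection (Brent's method, |C − target| < 1e-6)
suffices; targets outside the achievable range raise an error reporting
that range. The worked example's geometry (π = 0.45, RR_C = 1.5,
C = 9/11) is recovered by this mechanism and tied to the closed-form bias
ratio in the tests.

The continuous-profile generator produces a lognormal-shaped density
truncated to [0, x_max] (renormalized up front) with log-linear RR_C and a
log-linear confounding function, which keeps RR_U(0) = 1 exactly.

What the generator does **not** emulate: finite samples and measurement
error, unmeasured confounding, non-transportable relative risks, and
exposure misclassification. Passing tests therefore demonstrate the
algebraic correctness of the estimators at the identification level, not
robustness to the data problems of real studies.

## Numerical choices

* All computation is double precision; rounding to printed precision
  happens only in report formatting (3 significant figures for human
  output, full precision in machine output).
* Estimates may be negative (protective exposure) and are never clamped;
  an estimate of exactly 1 is rejected as a domain violation.
* Zero observed risk, a zero reference risk where a ratio is needed, and a
  missing reference cell are hard errors naming the offending quantity or
  stratum.
* When both π_c and (π, RR_U) are supplied, the redundant pair is
  cross-checked to 1e-6 and a warning is emitted on mismatch (published
  inputs are often rounded); the explicitly supplied value wins.
* Identity-style property tests assert agreement to 1e-12 absolute — the
  identities are exact, so only accumulation error is tolerated; oracle
  comparisons that pass through the bisection-based generator use 1e-8.

## Known limitations

* Confidence intervals and estimation from individual-level records are
  out of scope by design; the package quantifies identification bias only.
* Estimating the MREV from data, transportability adjustments across
  populations, and distributional-shift impact fractions are not
  implemented.
* The near-constant-confounding error approximation for continuous
  exposures is not implemented.
* The acceptance/report pipeline uses the packaged desk-scale tables
  (4 cells each); property suites run on randomly generated populations of
  up to a few strata, which is where the identities live — they are
  dimension-free, so small populations are fully informative.
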