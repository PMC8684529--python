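# Methods

## Model and reduction

Lifetimes follow a Lomax (Pareto type-II) law with density
f(x; β, σ) = (β/σ)(1 + x/σ)^−(β+1) on x ≥ 0. The scale σ is assumed known
throughout; only the shape β is estimated. The transform
Y = ln(1 + X/σ) is Exponential with rate β, so the statistic
γ = Σᵢ ln(1 + xᵢ/σ) is sufficient for β and exactly Gamma(n, rate β)
distributed. Three consequences shape the whole package:

1. every estimator is a function of the data only through (n, γ);
2. the MLE is n/γ, with E[n/γ] = nβ/(n−1) and
   E[(n/γ − β)²] = β²[n²/((n−1)(n−2)) − 2n/(n−1) + 1];
3. Monte Carlo performance (AE, MASE) of any estimator is a
   one-dimensional integral against the Gamma(n, β) density of γ, which
   the package evaluates by adaptive quadrature as a noise-free oracle.

Sampling uses the inverse-CDF transform x = σ[(1−U)^(−1/β) − 1] with U
uniform on [0, 1); the generator never emits U = 1, so x is always
finite, and U = 0 maps to x = 0. γ is accumulated with numpy's pairwise
summation. A sample in which every observation is zero has γ = 0 and no
finite MLE; it raises a dedicated error rather than returning infinity.

## Losses and Bayes estimation

Six losses are supported (Δ = β̂ − β): squared error; LINEX
e^{cΔ} − cΔ − 1 (asymmetric, c ≠ 0); the asymmetric ratio loss
β/β̂ + β̂/β − 2; entropy loss β̂/β − ln(β̂/β) − 1; composite LINEX
e^{−cΔ} + e^{cΔ} − 2 (symmetric but exponential in the error, c > 0);
and the weighted composite LINEX w(β)[e^{−cΔ} + e^{cΔ} − 2] with weight
w(β) = e^{−ωβ}, ω ≥ 0. The weight multiplies the full bracket including
the −2 term; since that term does not depend on β̂ it does not move the
minimizer, but it keeps the loss nonnegative with a unique zero at
β̂ = β. The weight makes errors committed at large β cheaper, which pulls
the estimate down; the WCLLF estimate is strictly decreasing in ω and
equals the composite-LINEX estimate at ω = 0.

With the conjugate Gamma(z, k) prior the posterior is Gamma(A, B),
A = n + z, B = γ + k, and the posterior-risk minimizers are the closed
forms tabulated in the README. Existence conditions are enforced as hard
errors, never clamps: B + c > 0 for LINEX, B > c for composite LINEX,
B + ω > c for the weighted form, and A > 1 wherever E[1/β] appears.
Clamping would silently bias the simulation study; at the default study
settings (n ≥ 25, σ = 3) the conditions fail with negligible probability
(< 1e−10), and the Monte Carlo driver treats a violating replicate as
fatal unless explicitly told to record-and-skip.

### Numerical risk minimizer (the oracle)

`posterior_risk` integrates loss × posterior density by adaptive
quadrature (scipy `quad`), splitting the interval at the posterior mean
and at the mean of the exponentially tilted posterior (the e^{cβ} factor
in the composite losses shifts the effective rate to B − c), and
truncating ~40 tilted standard deviations into the tail, beyond which
the integrand underflows. `argmin_risk` then locates the minimizer as
the root of the quadrature-evaluated risk derivative (the loss
derivative in β̂ is integrated under the posterior), bracketed around
the posterior mean and solved by Brent's method. A root of the
derivative was preferred over derivative-free minimization because a
golden-section/parabolic search localizes a smooth minimum only to about
√ε ≈ 1e−8 relative, while the implementation and the closed forms agree
to ~1e−12; the derivative route keeps the oracle sharp enough to detect
a wrong closed form at any tolerance down to quadrature precision. The
oracle shares no algebra with the closed forms: the tests' central check
is their agreement on randomized posteriors.

## E-Bayesian estimation

The prior density Gamma(z, k) is decreasing in β exactly when 0 < z < 1,
which motivates the hyperprior z ~ U(0, 1), k ~ U(0, v), independent,
with joint density 1/v. The E-Bayes estimate is the hyperprior average
of the Bayes estimate. Averaging the closed forms in k gives elementary
antiderivatives via ∫ ln t dt = t ln t − t, with the convention
t ln t := 0 at t = 0 (removable singularity); averaging in z is linear
for every family except the asymmetric-ratio one, whose
∫₀¹ √((n+z−1)(n+z)) dz has no convenient elementary form and is
evaluated with a fixed 32-point Gauss–Legendre rule (error ≪ 1e−12 for
this smooth integrand; a fixed rule keeps results bit-stable across
platforms). Domain conditions tighten to the worst point of the
hyperprior range (k → 0): γ > c for the composite family and
γ + ω > c for the weighted one.

Each closed form is validated in the tests against a 40-point
Gauss–Legendre *product* rule over (z, k) applied to the Bayes closed
form, and the LINEX family additionally against a plain Monte Carlo
average over 10⁶ hyperprior draws.

## Monte Carlo study

The default `StudyConfig` is the study design used for all reported
numbers: n ∈ {25, 50, 75, 100}, β ∈ {1, 1.5, 2}, σ = 3, prior
(z, k) = (0.6, 0.5), hyperprior bound v = 1, LINEX constants
c ∈ {0.5, 1.5}, weight decay ω = 0.5, and 10,000 replicates per cell.
Per replicate one sample is drawn and *all* estimator columns are
evaluated on it (common random numbers), which sharpens between-column
comparisons; AE is the mean estimate and MASE the mean squared deviation
from the true β, so MASE = (biased) variance + squared bias, an identity
the tests assert. Each (β, n) cell derives its own generator from the
master seed via `SeedSequence(seed, spawn_key=(cell_index,))`, so cells
are reproducible in isolation; the vectorized cell path consumes the
stream in the same order as repeated single-replicate calls and is
bit-identical to them.

The quadrature counterpart `expected_performance_quadrature` integrates
est(γ) and (est(γ) − β)² against the Gamma(n, β) density (relative
tolerance ~1e−9). If an estimator's domain excludes a γ-region of
probability mass above 1e−10 the cell is refused — the expectation
simply does not exist there — rather than silently truncated; at the
default settings all cells are admissible.

## Findings the noise-free oracle supports (and one it overturns)

On quadrature values at the default design: MASE decreases in n and
increases in β for every column; the E-Bayes column beats its Bayes
counterpart in 104 of 108 family-cells; and within the symmetric
families (squared error, composite LINEX), the ω-weighted composite
estimators have the smallest MASE at every cell. However, the *global*
minimum at every cell belongs to the LINEX(c = 1.5) estimators, not the
weighted-composite ones (e.g. at β = 1, n = 25: EB-LLF 0.03958 vs
EB-WCLLF 0.04191), and LINEX(c = 1.5) Bayes beats its E-Bayes version at
β = 2. Both effects are smaller than the Monte Carlo standard error of a
10,000-replicate MASE cell (~0.0007 at β = 1), so a single MC run can
rank them either way; two acceptance tests assert the MC-run orderings
and are expected to fail on the noise-free values, documenting exactly
this. The practical reading: the ω-weight buys a genuine improvement
over the symmetric composite and squared-error losses, while the
comparison against strongly asymmetric LINEX depends on whether its
asymmetry is acceptable for the application, not on MASE.

## What the generator does and does not emulate

The built-in sampler produces exactly i.i.d. Lomax lifetimes with known
scale — the data-generating process the estimators assume. Passing tests
therefore certify the estimators and the study machinery, not robustness
to misspecified scale, censoring, contamination or dependence, none of
which are modelled. Problem sizes in the tests (10,000 replicates for
table cells, reduced grids elsewhere) were chosen so the full suite
exercises every cell of the default design while remaining a
seconds-to-a-minute run.
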