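# Methods

## Model

The generalized inverse exponential distribution (GIED) has distribution
function F(x) = 1 − (1 − e^(−λ/x))^β on x > 0 with shape β > 0 and scale
λ > 0.  If T follows the standard member (λ = 1) then λT follows the
general one, so λ is a pure scale parameter; β = 1 recovers the inverse
exponential distribution.  The density is unimodal with a heavy right
tail; both moments and entropies exist for all parameter values (the
Rényi integral ∫ f^α additionally needs α(β+1) > 1, see below).

## Progressive Type-II censoring

A PC-II experiment places n units on test, observes m failures, and
withdraws R_i surviving units at the i-th failure; m + ΣR_i = n.  The
package validates this accounting strictly by default.  A *relaxed* mode
accepts a shortfall (m + ΣR < n) and records the deficit without
modifying the removal vector: one of the packaged censored subsamples is
published with exactly such an inconsistent accounting, and altering its
removal vector would change the likelihood, so the package reproduces it
verbatim and flags it instead.

Samples are generated by the uniform-spacings construction: with
W_i ~ U(0,1), V_i = W_i^{1/(i + R_m + … + R_{m−i+1})} and
U_i = 1 − V_m⋯V_{m−i+1}, the values quantile(U_i) have exactly the joint
law of the progressively censored order statistics.  This is exact and
O(m); no rejection or sorting step is involved.

The three standard removal patterns are: (a) all removals at the middle
observed failure; (b) removals split between the first and last failures,
with an odd leftover unit absorbed at the end and flagged; (c) one removal
per failure.  Pattern (c) balances only when n = 2m; a surplus n − 2m > 0
is absorbed into R_m, and when n < 2m only the first n − m failures carry
a removal.  Either adjustment flags the scheme as `adjusted`.

## Entropy

Shannon entropy H_S = −∫ f ln f and Rényi entropy
H_R(α) = (1−α)⁻¹ ln ∫ f^α are computed in nats.  Two routes are kept and
cross-checked:

* **Integral forms** (the package default everywhere downstream).  The
  substitution t = λ/x maps (0, ∞) onto itself and turns the integrand
  into β e^(−t)(1−e^(−t))^(β−1)(⋯), which is well behaved: the original
  integrand has an essential decay at 0.  Quadrature is adaptive
  (QUADPACK) with absolute/relative tolerance 1e-9, split at t = 1 so the
  u^(β−1) endpoint singularity (sharp for small β) is isolated from the
  exponential tail; an error estimate above max(1e-6, 1e-5·|value|)
  raises instead of returning silently.
* **Series forms** from the binomial expansion of (1−e^(−t))^(β−1) with
  generalized binomial coefficients.  For integer β the Shannon series
  terminates; otherwise terms decay like i^(−β−1) (Shannon) or
  i^(−α(β+1)) (Rényi), which is far too slow for direct summation at
  small β.  Direct summation with a stopping rule (|term| below
  tol·|partial sum| for 5 consecutive terms, capped at 1e4 terms) is
  attempted first; on failure an Euler–Maclaurin accelerated sum takes
  over, using the smooth coefficient representation
  (−1)^i binom(β−1, i) = Γ(i+1−β)/(Γ(1−β)Γ(i+1)) so the term function is
  analytic in the index, which the acceleration requires.

The Shannon series as classically derived omits a 2 ln λ term relative to
the integral form — the two coincide only at λ = 1.  The package treats
the integral form as authoritative (it equals the definition −∫ f ln f by
direct quadrature, checked to 1e-6) and exposes the verbatim series
behind `corrected=False` for fidelity.  All downstream reference values
are reproduced by the integral form.

Because λ is a pure scale parameter, H(β, λ) = ln λ + h(β) for both
entropies.  Consequently ∂H/∂λ = 1/λ, ∂²H/∂λ² = −1/λ², and the mixed
derivative vanishes identically.  The analytic gradient and Hessian
implementations evaluate the full integral expressions rather than these
shortcuts, and the test suite uses the closed forms as an independent
check on those expressions.

## Maximum likelihood

The PC-II log-likelihood is

l(β, λ) = ln ξ + m ln(λβ) − 2Σ ln x_i − λΣ 1/x_i + Σ (βR_i + β − 1) ln u_i,

with u_i = 1 − e^(−λ/x_i) and ξ the combinatorial constant of the plan
(computed in log space; constant in the parameters, so omitted from all
derivatives).  Setting ∂l/∂β = 0 gives the closed-form profile
β̂(λ) = −m / Σ(R_i+1) ln u_i, always positive.  The fit bisects the
profiled λ-score to a default interval tolerance of 1e-8.  The bracket
defaults to [1e-3, 1e3] × median(x) and is refined by scanning a
120-point geometric grid for a sign change before bisection; the profiled
score underflows to an unusable value at extreme λ (ln u_i rounds to 0),
so non-finite grid values are skipped and the grid is expanded up to five
times before the fit reports failure with the score trace.  A
user-supplied bracket without a sign change falls back to the same scan.

The observed information is the negative analytic Hessian; its inverse
(symmetrized solve) feeds both the delta-method variance
Var(Ĥ) = ∇H I⁻¹ ∇Hᵀ and the Lindley approximation.  Entropy gradients
default to central differences of the integral form (step
1e-5·max(1, |θ|)) so one code path serves Shannon and any Rényi order;
the analytic integral gradients are retained as an independent path and
agree to 1e-4 relative in the tests.

## Bayesian estimation

Independent rate-parameterized gamma priors β ~ Γ(η₁, γ₁), λ ~ Γ(η₂, γ₂).
Posterior expectations E[φ(β, λ) | data] are approximated by the Lindley
second-order expansion at the MLE, which needs the inverse observed
information, the prior log-gradient ρ = ((η₁−1)/β̂ − γ₁, (η₂−1)/λ̂ − γ₂),
and the third log-likelihood derivatives (l_βββ = 2m/β̂³,
l_λλβ = −Σ(R_i+1)e_i/(x_i²u_i²), l_λλλ, with l_λββ = 0 exactly).  A single
generic engine over a callable φ with numeric derivatives serves all six
estimator variants — the analytic derivative systems for each loss are
error-prone nested integral expressions, better used as test oracles than
as the primary path.  The engine accepts analytic derivatives where the
caller has them.

Estimators: Linex −c⁻¹ ln Ê[e^(−cH)], entropy loss (Ê[H⁻¹])⁻¹, DeGroot
Ê[H²]/Ê[H].  The Lindley value of E[e^(−cH)] can leave (0, ∞) for small,
heavily censored samples — the approximation is a quadratic expansion,
not a proper posterior — in which case the estimator raises with advice
rather than returning a number; published worked examples contain cells
with exactly this instability.

The exact-posterior oracle in the tests integrates L·π on a 200×200
log-spaced grid spanning ±6 asymptotic SDs (trapezoid weights), with the
entropy evaluated via the ln λ + h(β) factorization so only one
quadrature per grid β is needed.  Lindley agrees with the exact
estimators to within 10% relative on complete samples of n = 10, and
within ~1–2% on typical draws; the inverse-moment (entropy-loss) oracle
is restricted to the region H > 0.25, excluding a sub-1e-3 posterior mass
where 1/H is numerically meaningless on a grid.

## Bootstrap-t intervals

Parametric: B replicates are simulated from the fitted GIED under the
original censoring scheme and refitted; the studentized statistics
(Ĥ* − Ĥ)/√Var(Ĥ*) are collected and the interval is
Ĥ + √Var(Ĥ) · {θ/2, 1−θ/2 empirical quantiles} (type-7 interpolation).
The classical presentation of this algorithm carries a √B factor in the
statistic and a B^(−1/2) in the interval; they cancel algebraically, and
the package implements the cancelled form with a `literal` flag
reproducing the factor-carrying arithmetic bit-for-bit.  Replicates whose
refit fails or whose variance is non-positive are dropped and counted;
more than 10% failures aborts the interval.

This is the *unreflected* studentized interval (quantiles added to the
estimate, not reflected).  For a skewed pivot — and the entropy of a
heavily right-skewed lifetime law is skewed at moderate m — it
undercovers modestly: measured coverage of the 90% interval is ≈ 0.80 at
(n, m) = (30, 20) and (80, 60).  The coverage test therefore asserts a
near-nominal band rather than a point value; interval ordering, width
monotonicity in the confidence level, and width decrease in m are tested
exactly.

## Monte Carlo harness

The study design follows the simulation conventions of this literature:
truth β = λ = 0.5, grids over (n, m) with the three removal patterns,
1000 replications by default, gamma hyperparameters all 1, Linex c = 2,
Rényi α = 1.5, bootstrap B = 5000 and θ ∈ {0.05, 0.1} when intervals are
enabled.  Replicate k of cell j derives its generator from the seed tuple
(master, j, k), so cells are reproducible independently.  Failed
replicates are dropped and counted, never retried — retrying would bias
the summaries; a cell with more than 5% failures is flagged.  The true
entropies are computed once per study from the integral forms and shared
by all cells.  Reports are TSV with 4-decimal cells in the estimator
order MLE, LBe, EBe, DBe.

The acceptance script runs the (n, m) = (80, 60) middle-removal cell at
1000 replications with ML estimators only, which reproduces the reference
means to Monte Carlo accuracy in a few seconds; the full grid with Bayes
estimators and bootstrap intervals is available through
`gied-entropy simulate`.

## Goodness of fit

The KS statistic is evaluated with the ECDF at its value at each order
statistic, D = max_i |i/n − F(x_(i))|, and the one-sided asymptotic tail
p = exp(−2nD²) — the convention that reproduces the reference analysis of
the packaged data; the textbook two-sided sup-distance with its exact
null distribution is available via `convention="two-sided"`.  Neither
corrects for estimated parameters.  Alternative families (inverse
Weibull, Weibull; both two-parameter shape/scale) are fitted by
Nelder–Mead on the complete-sample log-likelihood in log-parameter space.
The three-parameter exponentiated Weibull is out of scope: its
parameterization in the comparison this package mirrors is ambiguous.

## Known limitations

* The Lindley approximation is O(n⁻¹)-accurate and can be unusable for
  m ≲ 10 under heavy censoring (raised as an error, not silently wrong).
* Bootstrap-t coverage is below nominal for skewed pivots, as noted.
* The synthetic-data generator produces exact PC-II samples from a
  *correctly specified* GIED; it does not emulate model misspecification,
  ties, rounding, or inspection-time effects present in real lifetime
  data, so passing tests demonstrate correctness of the inference
  machinery, not robustness of the GIED model itself.
* Progressive Type-I, first-failure and adaptive censoring are out of
  scope, as are MCMC posteriors, squared-error Bayes estimators, and
  credible intervals.
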