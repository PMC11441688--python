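# gied-entropy

Entropy inference for the **generalized inverse exponential distribution
(GIED)** under **progressive Type-II (PC-II) censoring**.

Lifetime data from reliability tests and survival studies are rarely
observed completely: units are withdrawn from test at intermediate failure
times (progressive censoring), and only `m` of the `n` units on test are
observed to fail.  This package estimates the *uncertainty* of the fitted
lifetime law — its Shannon entropy H_S = −∫ f ln f and Rényi entropy
H_R(α) = (1−α)⁻¹ ln ∫ f^α — from such censored samples, for the GIED

    f(x; λ, β) = λβ x⁻² e^(−λ/x) (1 − e^(−λ/x))^(β−1),
    F(x; λ, β) = 1 − (1 − e^(−λ/x))^β,        x > 0, λ, β > 0,

which reduces to the inverse exponential distribution at β = 1.  It is
aimed at reliability engineers and statisticians working with censored
lifetime data who need point estimates, variances, and intervals for
entropy functionals rather than only for the parameters.

## What it does

* **Maximum likelihood** — the shape β has a closed-form profile
  β̂(λ) = −m / Σ (Rᵢ+1) ln(1−e^(−λ/xᵢ)), so the fit reduces to a
  one-dimensional bisection on the profiled score in λ.  The observed
  Fisher information supplies delta-method variances
  Var(Ĥ) = T I⁻¹ Tᵀ for the plug-in entropy estimates.
* **Bayesian estimation** — independent Gamma(η, γ) priors on β and λ;
  posterior expectations approximated with the Lindley second-order
  expansion around the MLE (no posterior sampling); Bayes estimators of
  H under the Linex (−c⁻¹ ln E[e^(−cH)]), entropy ((E[H⁻¹])⁻¹) and
  DeGroot (E[H²]/E[H]) losses.
* **Bootstrap-t intervals** — parametric studentized bootstrap under the
  original censoring scheme.
* **Simulation harness** — PC-II sample generation by the exact
  uniform-spacings construction, the three standard removal patterns
  (middle / ends / uniform), and AE / MSE / AW / CP summary tables.
* **Model comparison** — Kolmogorov–Smirnov goodness of fit of the GIED
  against inverse Weibull and Weibull alternatives on complete samples.

## Worked example

The packaged dataset is the survival time in months of 15 Hodgkin's
disease patients under nitrogen-mustard treatment.  Fit the GIED and
estimate its entropy:

```sh
$ gied-entropy fixtures --dir data
$ gied-entropy fit --data data/hodgkin_survival.txt
{
  "beta": 1.2225264156812754,
  "lam": 6.0790347644562335,
  ...
}
```

β̂ ≈ 1.2225 (shape > 1: an interior mode) and λ̂ ≈ 6.079 months.  The KS
comparison ranks the GIED first among the candidate families:

```sh
$ gied-entropy gof --data data/hodgkin_survival.txt
model   shape   scale   KS      P
GIED    1.2225  6.0790  0.0878  0.7934
IWD     1.0070  5.3113  0.1190  0.6540
WD      1.1852  13.9465 0.1468  0.5239
```

On the progressively censored subsample I (m = 7 of n = 15, eight units
withdrawn at the fourth failure), the plug-in and Bayes entropy
estimates are:

```sh
$ gied-entropy entropy --data data/hodgkin_pc2_I.txt --kind renyi --alpha 1.5 \
      --n 15 --m 7 --R 0,0,0,8,0,0,0
{
  "H": 3.718127033292034,
  "var": 0.37100677073629673,
  ...
}
$ gied-entropy bayes --data data/hodgkin_pc2_I.txt --n 15 --m 7 --R 0,0,0,8,0,0,0
{
  "shannon_linex": 4.5229562691589695,
  "renyi_degroot": 4.105657679108923,
  ...
}
```

A Rényi entropy of 3.72 nats (α = 1.5) quantifies the spread of the
fitted lifetime law; the Bayes estimates under asymmetric losses shift
the plug-in value according to the posterior curvature around the MLE —
the DeGroot estimator always sits above the posterior mean.

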