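"""The generalized inverse exponential distribution (GIED).

A positive random variable X follows the GIED with shape ``beta`` and scale
``lam`` when

.. math::

    f(x) = \\lambda \\beta x^{-2} e^{-\\lambda/x}
           (1 - e^{-\\lambda/x})^{\\beta - 1},
    \\qquad
    F(x) = 1 - (1 - e^{-\\lambda/x})^{\\beta},
    \\qquad x > 0.

At ``beta = 1`` the family collapses to the inverse exponential distribution
(IED).  The module also carries the two-parameter inverse Weibull and Weibull
families used for goodness-of-fit comparison on complete samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import optimize

__all__ = [
    "GIEDParams",
    "AltFamily",
    "pdf",
    "logpdf",
    "cdf",
    "sf",
    "quantile",
    "rvs",
    "alt_cdf",
    "fit_alt",
]


@dataclass(frozen=True)
class GIEDParams:
    """Parameter pair of the GIED.

    Attributes
    ----------
    beta : float
        Shape parameter, dimensionless, > 0.
    lam : float
        Scale parameter, in the units of the time data, > 0.
    """

    beta: float
    lam: float

    def __post_init__(self) -> None:
        if not (np.isfinite(self.beta) and self.beta > 0):
            raise ValueError(f"shape beta must be positive, got {self.beta}")
        if not (np.isfinite(self.lam) and self.lam > 0):
            raise ValueError(f"scale lam must be positive, got {self.lam}")


_ALT_FAMILIES = ("IWD", "WD")


@dataclass(frozen=True)
class AltFamily:
    """A two-parameter alternative lifetime family: inverse Weibull or Weibull.

    ``params`` is (shape, scale), both positive.
    """

    name: str
    params: tuple[float, float]

    def __post_init__(self) -> None:
        if self.name not in _ALT_FAMILIES:
            raise ValueError(f"unknown family {self.name!r}; expected one of {_ALT_FAMILIES}")
        shape, scale = self.params
        if not (shape > 0 and scale > 0):
            raise ValueError(f"family parameters must be positive, got {self.params}")


def _check_x(x):
    x = np.asarray(x, dtype=float)
    if np.any(x <= 0) or np.any(~np.isfinite(x)):
        raise ValueError("x must be positive and finite")
    return x


def logpdf(x, p: GIEDParams):
    """Log-density of the GIED, stable for both tails.

    The factor (1-e^(-lam/x))^(beta-1) is evaluated as
    exp((beta-1)*log1p(-e^(-lam/x))) so precision survives large x, and the
    e^(-lam/x) factor drives the result to -inf (pdf 0) as x -> 0+.
    """
    x = _check_x(x)
    t = p.lam / x
    with np.errstate(divide="ignore"):
        out = (
            np.log(p.lam * p.beta)
            - 2.0 * np.log(x)
            - t
            + (p.beta - 1.0) * np.log1p(-np.exp(-t))
        )
    return out if out.ndim else float(out)


def pdf(x, p: GIEDParams):
    """Density f(x) = lam*beta*x^-2*exp(-lam/x)*(1-exp(-lam/x))^(beta-1)."""
    out = np.exp(logpdf(x, p))
    return out if np.ndim(out) else float(out)


def cdf(x, p: GIEDParams):
    """Distribution function F(x) = 1 - (1-exp(-lam/x))^beta."""
    x = _check_x(x)
    u = -np.expm1(-p.lam / x)  # 1 - e^(-lam/x), accurate for large x
    out = -np.expm1(p.beta * np.log(u))
    return out if out.ndim else float(out)


def sf(x, p: GIEDParams):
    """Survival function 1 - F(x) = (1-exp(-lam/x))^beta."""
    x = _check_x(x)
    out = np.exp(p.beta * np.log1p(-np.exp(-p.lam / x)))
    return out if out.ndim else float(out)


def quantile(q, p: GIEDParams):
    """Inverse cdf: x = -lam / log(1 - (1-q)^(1/beta)), strictly increasing in q."""
    q = np.asarray(q, dtype=float)
    if np.any(q <= 0) or np.any(q >= 1):
        raise ValueError("q must lie strictly inside (0, 1)")
    out = -p.lam / np.log1p(-np.exp(np.log1p(-q) / p.beta))
    return out if out.ndim else float(out)


def rvs(p: GIEDParams, size: int, rng: np.random.Generator):
    """Inverse-transform sampling: quantile(U) with U ~ uniform(0,1).

    ``size`` must be at least 1; reproducible for a seeded generator.
    """
    if size < 1:
        raise ValueError("size must be >= 1")
    u = rng.uniform(size=size)
    # clip away exact endpoints, which have probability zero anyway
    u = np.clip(u, 1e-300, 1.0 - 1e-16)
    return quantile(u, p)


def alt_cdf(x, fam: AltFamily):
    """Distribution function of an alternative family.

    IWD(shape k, scale s): F(x) = exp(-(s/x)^k).
    WD(shape k, scale s):  F(x) = 1 - exp(-(x/s)^k).
    """
    x = _check_x(x)
    k, s = fam.params
    if fam.name == "IWD":
        out = np.exp(-((s / x) ** k))
    else:
        out = -np.expm1(-((x / s) ** k))
    return out if out.ndim else float(out)


def _alt_logpdf(x, name, k, s):
    if name == "IWD":
        return np.log(k) + k * np.log(s) - (k + 1) * np.log(x) - (s / x) ** k
    return np.log(k) - np.log(s) + (k - 1) * (np.log(x) - np.log(s)) - (x / s) ** k


def fit_alt(x, name: str) -> AltFamily:
    """Complete-sample ML fit of an alternative family by 2-D optimization.

    Optimizes the log-likelihood in log-parameter space (Nelder-Mead), which
    keeps both parameters positive without constraints.
    """
    if name not in _ALT_FAMILIES:
        raise ValueError(f"unknown family {name!r}; expected one of {_ALT_FAMILIES}")
    x = _check_x(np.asarray(x, dtype=float))

    def nll(theta):
        k, s = np.exp(theta)
        return -np.sum(_alt_logpdf(x, name, k, s))

    x0 = np.log([1.0, float(np.median(x))])
    res = optimize.minimize(nll, x0, method="Nelder-Mead",
                            options={"xatol": 1e-10, "fatol": 1e-12, "maxiter": 5000})
    k, s = np.exp(res.x)
    return AltFamily(name=name, params=(float(k), float(s)))
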