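"""Shannon and Renyi entropy of the GIED.

Both entropies are available in two forms that are kept and cross-checked
against each other:

* an *integral* form evaluated by adaptive quadrature after the substitution
  t = lam/x, which maps (0, inf) onto itself with a well-behaved integrand
  (the raw integrand decays essentially at 0);
* a *series* form obtained by binomial expansion of (1-e^(-t))^(beta-1),
  summed with generalized binomial coefficients.

The integral form is the package default everywhere downstream (plug-in MLE,
Lindley approximation, delta-method gradients).  The Shannon series as
written in its source omits a 2*ln(lam) term relative to the integral form
(the two coincide only at lam = 1); ``corrected=True`` (default) adds it so
that the series and the integral agree.  The Renyi series needs no such
correction.

Shannon:  H_S = -integral f ln f
Renyi:    H_R(alpha) = (1-alpha)^-1 * ln integral f^alpha, alpha > 0, != 1,
          finite for the GIED iff alpha*(beta+1) > 1.

All values are in nats.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import integrate, special

from .model import GIEDParams

__all__ = [
    "EntropySpec",
    "EntropyValue",
    "QuadratureError",
    "SeriesConvergenceError",
    "shannon_integral",
    "shannon_direct",
    "shannon_series",
    "renyi_integral",
    "renyi_direct",
    "renyi_series",
    "entropy",
    "shannon_gradient",
    "renyi_gradient",
    "shannon_hessian",
    "renyi_hessian",
]

_EULER = float(np.euler_gamma)  # gamma_E = -Gamma'(1); psi(1) = -gamma_E
_QUAD_TOL = 1e-9
_MAX_TERMS = 10_000


class QuadratureError(RuntimeError):
    """Adaptive quadrature did not reach the requested tolerance."""


class SeriesConvergenceError(RuntimeError):
    """A series form did not converge within the term budget."""


@dataclass(frozen=True)
class EntropySpec:
    """Which entropy is being estimated: Shannon, or Renyi of order alpha."""

    kind: str
    alpha: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("shannon", "renyi"):
            raise ValueError(f"kind must be 'shannon' or 'renyi', got {self.kind!r}")
        if self.kind == "renyi":
            if self.alpha is None:
                raise ValueError("Renyi entropy requires an order alpha")
            if not (self.alpha > 0) or self.alpha == 1:
                raise ValueError(f"Renyi order must satisfy alpha > 0, alpha != 1, got {self.alpha}")
        elif self.alpha is not None:
            raise ValueError("alpha is only meaningful for kind='renyi'")


@dataclass(frozen=True)
class EntropyValue:
    """An entropy value (nats) together with how it was computed."""

    value: float
    method: str  # 'integral', 'series' or 'series_corrected'
    truncation_terms: int | None = None

    def __float__(self) -> float:
        return self.value


def _quad(f) -> float:
    # split at t = 1: isolates the endpoint singularity of u^(beta-1) at 0
    # from the exponential tail, which QUADPACK otherwise trades off badly
    # for extreme shape values
    v1, e1 = integrate.quad(f, 0.0, 1.0, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=400)
    v2, e2 = integrate.quad(f, 1.0, np.inf, epsabs=_QUAD_TOL, epsrel=_QUAD_TOL, limit=400)
    val, err = v1 + v2, e1 + e2
    if not np.isfinite(val) or err > max(1e-6, 1e-5 * abs(val)):
        raise QuadratureError(f"quadrature unreliable: value={val}, error estimate={err}")
    return val


def shannon_integral(p: GIEDParams) -> EntropyValue:
    """Shannon entropy by quadrature of the reduced integral form.

    After t = lam/x the form reads
    H_S = -ln(lam*beta) + 2*int_0^inf beta e^-t (1-e^-t)^(beta-1) ln(lam/t) dt
          + psi(beta+1) - psi(1) + (beta-1)/beta.
    """
    b, lam = p.beta, p.lam
    lnl = np.log(lam)

    def f(t):
        return b * np.exp(-t) * (-np.expm1(-t)) ** (b - 1.0) * (lnl - np.log(t))

    val = (
        -np.log(lam * b)
        + 2.0 * _quad(f)
        + special.digamma(b + 1.0)
        + _EULER
        + (b - 1.0) / b
    )
    return EntropyValue(value=float(val), method="integral")


def shannon_direct(p: GIEDParams) -> EntropyValue:
    """Shannon entropy straight from the definition -integral f ln f.

    Independent of :func:`shannon_integral` up to the common t = lam/x
    substitution; used as a cross-check of the reduced form.
    """
    b, lam = p.beta, p.lam

    def f(t):
        u = -np.expm1(-t)
        lnf = np.log(lam * b) + 2.0 * (np.log(t) - np.log(lam)) - t + (b - 1.0) * np.log(u)
        return -b * np.exp(-t) * u ** (b - 1.0) * lnf

    return EntropyValue(value=float(_quad(f)), method="integral")


def _log_binom_signed(a: float, i: int) -> float:
    """(-1)^i * binom(a, i) for real a, via the reflection identity.

    For non-integer a this equals Gamma(i-a) / (Gamma(-a) * Gamma(i+1)),
    which is smooth in i — the property the accelerated tail sum relies on.
    """
    return special.gamma(i - a) / (special.gamma(-a) * special.gamma(i + 1))


def _sum_series(term, tol: float):
    """Direct summation with the consecutive-small-term stopping rule.

    Stops once |term| < tol*|partial sum| for 5 consecutive terms; returns
    (sum, nterms) or (None, None) when the budget of 1e4 terms is exhausted.
    """
    s = 0.0
    small = 0
    for i in range(_MAX_TERMS):
        t = term(i)
        s += t
        if abs(t) < tol * max(abs(s), 1e-300):
            small += 1
            if small >= 5:
                return s, i + 1
        else:
            small = 0
    return None, None


def _sum_em(term_mp):
    """Euler-Maclaurin accelerated tail sum (mpmath) for slowly decaying series."""
    import mpmath as mp

    return float(mp.nsum(term_mp, [0, mp.inf], method="e"))


def shannon_series(p: GIEDParams, tol: float = 1e-10, corrected: bool = True) -> EntropyValue:
    """Shannon entropy by the binomial series expansion.

    ``corrected=False`` returns the series exactly as derived, which differs
    from the integral form by -2*ln(lam); ``corrected=True`` (default) adds
    2*ln(lam) so the two forms agree for every lam.

    For integer beta the series terminates after beta terms.  Otherwise the
    terms decay like i^(-beta-1); direct summation is attempted first and an
    Euler-Maclaurin accelerated sum takes over when the direct rule does not
    converge within the term budget.
    """
    b, lam = p.beta, p.lam

    if float(b).is_integer():
        nb = int(b)
        s = sum(
            special.binom(b - 1.0, i) * (-1) ** i * (np.log(1.0 + i) + _EULER) / (1.0 + i)
            for i in range(nb)
        )
        nterms = nb
        method = "series_corrected" if corrected else "series"
    else:
        def term(i):
            return _log_binom_signed(b - 1.0, i) * (np.log(1.0 + i) + _EULER) / (1.0 + i)

        s, nterms = _sum_series(term, tol)
        if s is None:
            import mpmath as mp

            def term_mp(i):
                c = mp.gamma(i + 1 - b) / (mp.gamma(1 - b) * mp.gamma(i + 1))
                return c * (mp.log(1 + i) + mp.euler) / (1 + i)

            s = _sum_em(term_mp)
            nterms = None
        method = "series_corrected" if corrected else "series"

    val = (
        -np.log(lam * b)
        + 2.0 * b * s
        + special.digamma(b + 1.0)
        + _EULER
        + (b - 1.0) / b
    )
    if corrected:
        val += 2.0 * np.log(lam)
    return EntropyValue(value=float(val), method=method, truncation_terms=nterms)


def _check_renyi(p: GIEDParams, spec: EntropySpec) -> float:
    if spec.kind != "renyi":
        raise ValueError("spec.kind must be 'renyi'")
    a = float(spec.alpha)
    if a * (p.beta + 1.0) <= 1.0:
        raise ValueError(
            f"integral of f^alpha diverges: need alpha*(beta+1) > 1, "
            f"got alpha={a}, beta={p.beta}"
        )
    return a


def _renyi_reduced_integral(p: GIEDParams, a: float) -> float:
    """int_0^inf t^(2a-2) e^(-a t) (1-e^-t)^(a(beta-1)) dt  (t = lam/x form)."""
    b = p.beta

    def f(t):
        return t ** (2.0 * a - 2.0) * np.exp(-a * t) * (-np.expm1(-t)) ** (a * (b - 1.0))

    return _quad(f)


def renyi_integral(p: GIEDParams, spec: EntropySpec) -> EntropyValue:
    """Renyi entropy (1-alpha)^-1 * ln integral f^alpha by quadrature."""
    a = _check_renyi(p, spec)
    I = _renyi_reduced_integral(p, a)
    val = (a * np.log(p.lam * p.beta) + (1.0 - 2.0 * a) * np.log(p.lam) + np.log(I)) / (1.0 - a)
    return EntropyValue(value=float(val), method="integral")


def renyi_direct(p: GIEDParams, spec: EntropySpec) -> EntropyValue:
    """Renyi entropy straight from the definition, as a cross-check."""
    a = _check_renyi(p, spec)
    b, lam = p.beta, p.lam

    def f(t):
        # f(x)^alpha * dx with t = lam/x: (lam b)^a (t/lam)^(2a) e^(-at) u^(a(b-1)) * lam/t^2 dt
        u = -np.expm1(-t)
        return np.exp(
            a * np.log(lam * b)
            + (2.0 * a - 2.0) * np.log(t)
            + (1.0 - 2.0 * a) * np.log(lam)
            - a * t
            + a * (b - 1.0) * np.log(u)
        )

    return EntropyValue(value=float(np.log(_quad(f)) / (1.0 - a)), method="integral")


def renyi_series(p: GIEDParams, spec: EntropySpec, tol: float = 1e-10) -> EntropyValue:
    """Renyi entropy by the binomial series.

    Requires alpha > 1/2 so that Gamma(2*alpha - 1) is finite.  The terms
    decay like i^(-alpha*(beta+1)); the same direct-then-accelerated strategy
    as :func:`shannon_series` is used.
    """
    a = _check_renyi(p, spec)
    if a <= 0.5:
        raise ValueError(f"series form needs alpha > 1/2 (Gamma(2*alpha-1) finite), got {a}")
    b, lam = p.beta, p.lam
    ab = a * (b - 1.0)
    g2a = special.gamma(2.0 * a - 1.0)

    if float(ab).is_integer() and ab >= 0:
        s = sum(
            special.binom(ab, i) * (-1) ** i * g2a / (a + i) ** (2.0 * a - 1.0)
            for i in range(int(ab) + 1)
        )
        nterms = int(ab) + 1
    else:
        def term(i):
            return _log_binom_signed(ab, i) * g2a / (a + i) ** (2.0 * a - 1.0)

        s, nterms = _sum_series(term, tol)
        if s is None:
            import mpmath as mp

            def term_mp(i):
                c = mp.gamma(i - ab) / (mp.gamma(-ab) * mp.gamma(i + 1))
                return c * mp.gamma(2 * a - 1) / (a + i) ** (2 * a - 1)

            s = _sum_em(term_mp)
            nterms = None

    if s <= 0:
        raise SeriesConvergenceError(f"series sum non-positive ({s}); cannot take log")
    val = ((1.0 - a) * np.log(lam) + a * np.log(b) + np.log(s)) / (1.0 - a)
    return EntropyValue(value=float(val), method="series", truncation_terms=nterms)


def entropy(p: GIEDParams, spec: EntropySpec, method: str = "integral") -> EntropyValue:
    """Dispatch to the requested entropy and evaluation method."""
    if spec.kind == "shannon":
        if method == "integral":
            return shannon_integral(p)
        if method == "series":
            return shannon_series(p, corrected=True)
        if method == "series_verbatim":
            return shannon_series(p, corrected=False)
    else:
        if method == "integral":
            return renyi_integral(p, spec)
        if method in ("series", "series_verbatim"):
            return renyi_series(p, spec)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Analytic gradients (delta-method / Lindley oracles)
# ---------------------------------------------------------------------------

def shannon_gradient(p: GIEDParams) -> tuple[float, float]:
    """Analytic (dH_S/dbeta, dH_S/dlam) from the reduced integral expressions."""
    b, lam = p.beta, p.lam
    lnl = np.log(lam)

    def fb(t):
        u = -np.expm1(-t)
        return np.exp(-t) * u ** (b - 1.0) * (lnl - np.log(t)) * (1.0 + b * np.log(u))

    db = -1.0 / b + 2.0 * _quad(fb) + special.polygamma(1, b + 1.0) + 1.0 / b ** 2

    def fl(t):
        u = -np.expm1(-t)
        return t * np.exp(-t) * u ** (b - 2.0) * (lnl - np.log(t)) * (u / t + b - b * u - 1.0)

    dl = -1.0 / lam + (2.0 * b / lam) * _quad(fl)
    return float(db), float(dl)


def renyi_gradient(p: GIEDParams, alpha: float) -> tuple[float, float]:
    """Analytic (dH_R/dbeta, dH_R/dlam) from the reduced integral expressions."""
    spec = EntropySpec(kind="renyi", alpha=alpha)
    a = _check_renyi(p, spec)
    b, lam = p.beta, p.lam

    def w(t):
        return t ** (2.0 * a - 2.0) * np.exp(-a * t) * (-np.expm1(-t)) ** (a * (b - 1.0))

    I0 = _renyi_reduced_integral(p, a)

    def nb(t):
        return w(t) * np.log(-np.expm1(-t))

    db = a / (b * (1.0 - a)) + a * _quad(nb) / ((1.0 - a) * I0)

    def nl(t):
        u = -np.expm1(-t)
        return t ** (2.0 * a - 1.0) * np.exp(-a * t) * u ** (a * (b - 1.0) - 1.0) * (b * u - b + 1.0)

    dl = a / (lam * (1.0 - a)) - a * _quad(nl) / (lam * (1.0 - a) * I0)
    return float(db), float(dl)


def shannon_hessian(p: GIEDParams) -> tuple[float, float, float]:
    """Analytic (d2H_S/dbeta2, d2H_S/dbetadlam, d2H_S/dlam2).

    Evaluated from the closed integral expressions.  Because lam is a pure
    scale parameter, H_S(beta, lam) = ln(lam) + h(beta), so the mixed
    derivative is identically 0 and the lam-lam entry is -1/lam^2; the
    integral forms reproduce both, which the test suite uses as a check on
    the whole derivative block.
    """
    b, lam = p.beta, p.lam
    lnl = np.log(lam)

    def fbb(t):
        u = -np.expm1(-t)
        return np.exp(-t) * u ** (b - 1.0) * np.log(u) * (lnl - np.log(t)) * (2.0 + b * np.log(u))

    h_bb = 1.0 / b ** 2 + 2.0 * _quad(fbb) + special.polygamma(2, b + 1.0) - 2.0 / b ** 3

    def fll2(t):
        u = -np.expm1(-t)
        e = np.exp(-t)
        return (t * t * e * u ** (b - 2.0) * (lnl - np.log(t))
                * (u / t + b - b * u - 1.0) * (1.0 - (b - 2.0) * e / u))

    def fll3(t):
        u = -np.expm1(-t)
        e = np.exp(-t)
        return t * e * u ** (b - 2.0) * (lnl - np.log(t)) * (e + b - b * u - b * t * e - 1.0)

    h_ll = 1.0 / lam ** 2 - (2.0 * b / lam ** 2) * _quad(fll2) + (2.0 * b / lam ** 2) * _quad(fll3)

    def fbl1(t):
        u = -np.expm1(-t)
        return np.exp(-t) * u ** (b - 1.0) * (lnl - np.log(t)) * (1.0 + b * np.log(u)) * (1.0 - t)

    def fbl2(t):
        u = -np.expm1(-t)
        lnu = np.log(u)
        return (t * np.exp(-2.0 * t) * u ** (b - 2.0) * (lnl - np.log(t))
                * (2.0 * b + b * b * lnu - b * lnu - 1.0))

    h_bl = (2.0 / lam) * _quad(fbl1) + (2.0 / lam) * _quad(fbl2)
    return float(h_bb), float(h_bl), float(h_ll)


def renyi_hessian(p: GIEDParams, alpha: float) -> tuple[float, float, float]:
    """Analytic (d2H_R/dbeta2, d2H_R/dbetadlam, d2H_R/dlam2) from the integral forms.

    The same scale-parameter structure as :func:`shannon_hessian` applies:
    the integral expressions must evaluate to 0 (mixed) and -1/lam^2 (lam-lam).
    """
    spec = EntropySpec(kind="renyi", alpha=alpha)
    a = _check_renyi(p, spec)
    b, lam = p.beta, p.lam

    def u(t):
        return -np.expm1(-t)

    def w(t):
        return t ** (2.0 * a - 2.0) * np.exp(-a * t) * u(t) ** (a * (b - 1.0))

    J0 = _quad(w)
    J1 = _quad(lambda t: w(t) * np.log(u(t)))
    J2 = _quad(lambda t: w(t) * np.log(u(t)) ** 2)
    K1 = _quad(lambda t: t ** (2 * a - 1) * np.exp(-a * t) * u(t) ** (a * (b - 1) - 1)
               * (b * u(t) - b + 1.0))
    K1b = _quad(lambda t: t ** (2 * a - 1) * np.exp(-a * t) * u(t) ** (a * (b - 1) - 1)
                * np.log(u(t)) * (b * u(t) - b + 1.0))
    K1c = _quad(lambda t: t ** (2 * a - 1) * np.exp(-(a + 1.0) * t) * u(t) ** (a * (b - 1) - 1))
    L1 = _quad(lambda t: t ** (2 * a) * np.exp(-a * t) * u(t) ** (a * (b - 1) - 2)
               * (b * u(t) - b + 1.0) * (a * b * u(t) - a * b + a - u(t) + 1.0))
    L2 = _quad(lambda t: t ** (2 * a) * np.exp(-(a + 1.0) * t) * u(t) ** (a * (b - 1) - 1))

    h_bb = (-a / (b * b * (1 - a)) + a * a * J2 / ((1 - a) * J0)
            - a * a * J1 * J1 / ((1 - a) * J0 * J0))
    h_ll = (-a / (lam * lam * (1 - a)) + a * L1 / ((1 - a) * lam * lam * J0)
            - a * b * L2 / ((1 - a) * lam * lam * J0)
            - a * a * K1 * K1 / ((1 - a) * lam * lam * J0 * J0))
    h_bl = (-a * a * K1b / ((1 - a) * lam * J0) + a * K1c / ((1 - a) * lam * J0)
            + a * a * J1 * K1 / ((1 - a) * lam * J0 * J0))
    return float(h_bb), float(h_bl), float(h_ll)
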