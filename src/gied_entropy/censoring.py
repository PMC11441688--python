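"""Progressive Type-II (PC-II) censoring schemes and sample generation.

A PC-II life test places ``n`` units on test and observes ``m`` failures.  At
the i-th observed failure, ``R_i`` of the surviving units are withdrawn, so
that ``m + R_1 + ... + R_m = n``.  This module builds the three standard
removal patterns used in simulation studies (removals concentrated in the
middle, split between the ends, or spread uniformly), draws PC-II samples
from any continuous lifetime distribution via the uniform-spacings
construction, and progressively censors an existing complete dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "CensoringScheme",
    "ProgressiveSample",
    "make_scheme",
    "sample_pc2",
    "censor_dataset",
]


@dataclass(frozen=True)
class CensoringScheme:
    """A PC-II removal plan (n, m, R_1..R_m).

    Strict validation requires m + sum(R) == n.  With ``relaxed=True`` a
    shortfall (m + sum(R) < n) is tolerated and recorded in ``deficit``; the
    removal vector is kept verbatim.  ``adjusted`` marks schemes whose removal
    vector was modified by :func:`make_scheme` to absorb a remainder.
    """

    n: int
    m: int
    R: tuple[int, ...]
    relaxed: bool = False
    adjusted: bool = field(default=False, compare=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "R", tuple(int(r) for r in self.R))
        if not (1 <= self.m <= self.n):
            raise ValueError(f"need 1 <= m <= n, got m={self.m}, n={self.n}")
        if len(self.R) != self.m:
            raise ValueError(f"removal vector has length {len(self.R)}, expected m={self.m}")
        if any(r < 0 for r in self.R):
            raise ValueError("removal counts must be nonnegative")
        total = self.m + sum(self.R)
        if total > self.n:
            raise ValueError(f"m + sum(R) = {total} exceeds n = {self.n}")
        if total != self.n and not self.relaxed:
            raise ValueError(
                f"m + sum(R) = {total} != n = {self.n}; use relaxed=True to allow a deficit"
            )

    @property
    def deficit(self) -> int:
        """Units unaccounted for by the removal plan (0 for a strict scheme)."""
        return self.n - self.m - sum(self.R)

    @classmethod
    def parse(cls, n: int, m: int, r_text: str, relaxed: bool = False) -> "CensoringScheme":
        """Build a scheme from a comma-separated removal vector, e.g. "4,0,0,0,0,0,4"."""
        R = tuple(int(tok) for tok in r_text.split(","))
        return cls(n=n, m=m, R=R, relaxed=relaxed)

    def serialize(self) -> str:
        return ",".join(str(r) for r in self.R)


@dataclass(frozen=True)
class ProgressiveSample:
    """Ordered observed failure times x_{1:m:n} < ... < x_{m:m:n} with their scheme."""

    times: tuple[float, ...]
    scheme: CensoringScheme

    def __post_init__(self) -> None:
        t = tuple(float(v) for v in self.times)
        object.__setattr__(self, "times", t)
        if len(t) != self.scheme.m:
            raise ValueError(f"{len(t)} times for a scheme with m={self.scheme.m}")
        arr = np.asarray(t)
        if np.any(arr <= 0):
            raise ValueError("observed times must be positive")
        if np.any(np.diff(arr) <= 0):
            raise ValueError("observed times must be strictly increasing")

    @property
    def x(self) -> np.ndarray:
        return np.asarray(self.times)

    @property
    def removals(self) -> np.ndarray:
        return np.asarray(self.scheme.R, dtype=float)


def make_scheme(kind: str, n: int, m: int) -> CensoringScheme:
    """Construct removal pattern a, b or c.

    a: all removals at the middle observed failure (index (m+1)/2 for odd m,
       m/2 for even m), R there equal to n-m.
    b: removals split between the first and last failures; when n-m is odd the
       two ends get (n-m-1)/2 each and the leftover unit is absorbed into R_m
       (scheme flagged ``adjusted``).
    c: one removal at each failure.  Requires n = 2m to balance exactly; a
       surplus n-2m > 0 is absorbed into R_m, and when n < 2m only the first
       n-m failures carry a removal.  Either departure flags ``adjusted``.
    """
    if not (1 <= m <= n):
        raise ValueError(f"need 1 <= m <= n, got m={m}, n={n}")
    R = [0] * m
    adjusted = False
    if kind == "a":
        mid = (m + 1) // 2 if m % 2 else m // 2
        R[mid - 1] = n - m
    elif kind == "b":
        if m == 1:
            R[0] = n - m
        elif (n - m) % 2 == 0:
            R[0] = R[-1] = (n - m) // 2
        else:
            R[0] = (n - m - 1) // 2
            R[-1] = (n - m - 1) // 2 + 1  # leftover unit absorbed at the end
            adjusted = True
    elif kind == "c":
        k = min(m, n - m)
        for i in range(k):
            R[i] = 1
        if n - 2 * m > 0:
            R[-1] += n - 2 * m
        adjusted = n != 2 * m
    else:
        raise ValueError(f"unknown scheme kind {kind!r}; expected 'a', 'b' or 'c'")
    return CensoringScheme(n=n, m=m, R=tuple(R), adjusted=adjusted)


def sample_pc2(
    quantile_fn: Callable[[np.ndarray], np.ndarray],
    scheme: CensoringScheme,
    rng: np.random.Generator,
) -> ProgressiveSample:
    """Draw one PC-II sample via the uniform-spacings construction.

    With W_i ~ U(0,1) set V_i = W_i^{1/(i + R_m + ... + R_{m-i+1})} and
    U_i = 1 - V_m V_{m-1} ... V_{m-i+1}; then x_i = quantile_fn(U_i) has
    exactly the joint law of the progressively censored order statistics for
    the given scheme.  Exact and O(m).
    """
    m = scheme.m
    R = np.asarray(scheme.R, dtype=float)
    W = rng.uniform(size=m)
    expo = np.arange(1, m + 1) + np.cumsum(R[::-1])
    V = W ** (1.0 / expo)
    U = 1.0 - np.cumprod(V[::-1])
    U = np.clip(U, 1e-300, 1.0 - 1e-16)
    x = np.asarray(quantile_fn(U), dtype=float)
    return ProgressiveSample(times=tuple(x), scheme=scheme)


def censor_dataset(
    sorted_times: Sequence[float],
    scheme: CensoringScheme,
    rng: np.random.Generator | None = None,
    removal: str = "random",
) -> ProgressiveSample:
    """Run the PC-II experiment on an existing complete dataset.

    At each stage the smallest remaining value is observed and R_i survivors
    are withdrawn.  ``removal='random'`` withdraws uniformly at random without
    replacement (the textbook mechanism, requires ``rng``);
    ``removal='smallest'`` deterministically withdraws the R_i smallest
    survivors, which is the variant consistent with published worked examples.
    """
    x = np.sort(np.asarray(sorted_times, dtype=float))
    if len(x) != scheme.n:
        raise ValueError(f"dataset has {len(x)} values but scheme expects n={scheme.n}")
    if removal not in ("random", "smallest"):
        raise ValueError("removal must be 'random' or 'smallest'")
    if removal == "random" and rng is None:
        raise ValueError("removal='random' requires a seeded generator")
    remaining = list(x)
    observed = []
    for r in scheme.R:
        observed.append(remaining.pop(0))
        r = min(r, len(remaining))
        if removal == "smallest":
            del remaining[:r]
        elif r:
            drop = rng.choice(len(remaining), size=r, replace=False)
            remaining = [v for j, v in enumerate(remaining) if j not in set(drop)]
    return ProgressiveSample(times=tuple(observed), scheme=scheme)
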