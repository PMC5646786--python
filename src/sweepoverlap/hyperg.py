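"""Exact distribution of the intersection size of two random gene draws.

Model: two sets of sizes ``a`` and ``b`` are drawn independently, uniformly,
and without replacement from a universe of ``n`` distinct genes, and
``V = |A ∩ B|`` is the intersection size. Conditioning on the first draw
(whose identity is irrelevant by exchangeability) reduces V to the standard
hypergeometric law

    P(V = v) = C(a, v) * C(n - a, b - v) / C(n, b),

so the "both draws random" formulation and the fixed-first-set formulation
coincide. The upper tail P(V >= v) is the significance measure for an
observed overlap: small values mean the two candidate lists share more genes
than independent draws from a common genome would.

All binomial coefficients are evaluated in log space (log-gamma), so the
paper-scale regime (n ~ 2e4, a, b ~ 700) is exact to double precision.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from fractions import Fraction
from itertools import combinations

import numpy as np
from scipy.special import gammaln


class ParameterError(ValueError):
    """Raised when (n, a, b, v) violate the distribution's parameter bounds."""


@dataclass(frozen=True)
class HypergParams:
    """Parameters of one intersection test: universe and draw sizes plus v."""

    n: int
    a: int
    b: int
    v: int

    def __post_init__(self) -> None:
        _check_nab(self.n, self.a, self.b)
        if self.v < 0:
            raise ParameterError(f"v must be non-negative, got {self.v}")


@dataclass(frozen=True)
class HypergResult:
    """Exact tail probability and moments for one intersection test."""

    params: HypergParams
    p_tail: float
    mean: float
    variance: float


def _check_nab(n: int, a: int, b: int) -> None:
    if n < 0:
        raise ParameterError(f"universe size must be non-negative, got n={n}")
    if not (0 <= a <= n):
        raise ParameterError(f"draw size a={a} outside [0, n={n}]")
    if not (0 <= b <= n):
        raise ParameterError(f"draw size b={b} outside [0, n={n}]")


def support(n: int, a: int, b: int) -> tuple[int, int]:
    """Inclusive support bounds of the intersection size: [max(0, a+b-n), min(a, b)]."""
    return max(0, a + b - n), min(a, b)


def _log_choose(n, k):
    n = np.asarray(n, dtype=float)
    k = np.asarray(k, dtype=float)
    return gammaln(n + 1.0) - gammaln(k + 1.0) - gammaln(n - k + 1.0)


def _log_pmf_vector(n: int, a: int, b: int, v: np.ndarray) -> np.ndarray:
    # canonical argument order makes the a<->b symmetry exact in floats
    a, b = min(a, b), max(a, b)
    return _log_choose(a, v) + _log_choose(n - a, b - v) - _log_choose(n, b)


def intersection_pmf(n: int, a: int, b: int, v: int) -> float:
    """P(V = v); zero outside the support."""
    _check_nab(n, a, b)
    lo, hi = support(n, a, b)
    if v < lo or v > hi:
        return 0.0
    return float(math.exp(_log_pmf_vector(n, a, b, np.asarray([v]))[0]))


def intersection_tail_ge(n: int, a: int, b: int, v: int) -> float:
    """Upper tail P(V >= v), the significance of an observed overlap of v.

    The smaller of the two tails is summed directly (in ordinary floats via
    exact-rounded summation); the result is clamped to [0, 1].
    """
    _check_nab(n, a, b)
    lo, hi = support(n, a, b)
    if v <= lo:
        return 1.0
    if v > hi:
        return 0.0
    upper = np.arange(v, hi + 1)
    lower = np.arange(lo, v)
    if len(upper) <= len(lower):
        p = math.fsum(np.exp(_log_pmf_vector(n, a, b, upper)).tolist())
    else:
        p = 1.0 - math.fsum(np.exp(_log_pmf_vector(n, a, b, lower)).tolist())
    return min(1.0, max(0.0, p))


def intersection_moments(n: int, a: int, b: int) -> tuple[float, float]:
    """Closed-form mean a*b/n and variance of the intersection size."""
    _check_nab(n, a, b)
    if n < 2:
        if a or b:
            raise ParameterError("moments need n >= 2 when draws are non-empty")
        return 0.0, 0.0
    mean = a * b / n
    variance = mean * (1.0 - a / n) * (n - b) / (n - 1.0)
    return mean, variance


def intersection_test(n: int, a: int, b: int, v: int) -> HypergResult:
    """Bundle the exact tail probability with the null moments."""
    params = HypergParams(n, a, b, v)
    mean, variance = intersection_moments(n, a, b)
    return HypergResult(
        params=params,
        p_tail=intersection_tail_ge(n, a, b, v),
        mean=mean,
        variance=variance,
    )


# enumeration cap: C(14,7)^2 ~ 1.2e7 subset pairs is the largest full
# enumeration that stays interactive
_BRUTE_FORCE_CAP = 14


def brute_force_intersection_pmf(n: int, a: int, b: int) -> list[Fraction]:
    """Exact pmf by enumerating every (A, B) subset pair; test oracle only.

    Returns the pmf over v = 0..min(a, b) as exact rationals. Subsets are
    encoded as bitmasks and intersections counted with a vectorized popcount,
    but every one of the C(n,a)*C(n,b) pairs is visited: nothing is shared
    with the closed-form path.
    """
    _check_nab(n, a, b)
    if n > _BRUTE_FORCE_CAP:
        raise ParameterError(
            f"brute-force enumeration refused for n={n} > {_BRUTE_FORCE_CAP}"
        )
    masks_a = np.array(
        [sum(1 << i for i in comb) for comb in combinations(range(n), a)],
        dtype=np.uint64,
    )
    masks_b = np.array(
        [sum(1 << i for i in comb) for comb in combinations(range(n), b)],
        dtype=np.uint64,
    )
    sizes = np.bitwise_count(masks_a[:, None] & masks_b[None, :]).ravel()
    counts = np.bincount(sizes, minlength=min(a, b) + 1)
    total = int(counts.sum())
    return [Fraction(int(c), total) for c in counts]
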