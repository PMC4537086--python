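"""Closed-form and exact-recursion references for validating the simulator.

All quantities are expressed in 4*N0-generation units (the ms time scale), in
which k lineages coalesce at rate k*(k-1). The monophyly oracle covers the
single-outgroup sampling design: n_in exchangeable ingroup lineages plus one
lineage from a sister population that merges into the ingroup's ancestor at
the join time.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.linalg import expm

from .errors import InvalidParameterError

__all__ = [
    "LineageCountDistribution",
    "expected_tmrca",
    "expected_total_length",
    "expected_segsites",
    "lineage_count_distribution",
    "monophyly_probability",
]


@dataclass(frozen=True)
class LineageCountDistribution:
    """P(j ancestral lineages at time t | n sampled at time 0), j = 1..n."""

    n: int
    t: float
    probabilities: np.ndarray  # index 0 is j=1

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=float)
        if p.shape != (self.n,):
            raise InvalidParameterError("probability vector must have length n")
        if np.any(p < -1e-15) or abs(p.sum() - 1.0) > 1e-12:
            raise InvalidParameterError("probabilities must be non-negative and sum to 1")
        object.__setattr__(self, "probabilities", np.clip(p, 0.0, 1.0))

    def prob(self, j: int) -> float:
        if not 1 <= j <= self.n:
            raise InvalidParameterError(f"j must be in 1..{self.n}, got {j}")
        return float(self.probabilities[j - 1])


def expected_tmrca(n: int) -> float:
    """E[TMRCA] of n panmictic lineages: sum_{k=2..n} 1/(k(k-1)) = 1 - 1/n."""
    if n < 2:
        raise InvalidParameterError(f"n must be >= 2, got {n}")
    return 1.0 - 1.0 / n


def expected_total_length(n: int) -> float:
    """E[total branch length] = H_{n-1} = sum_{i=1..n-1} 1/i."""
    if n < 2:
        raise InvalidParameterError(f"n must be >= 2, got {n}")
    return float(sum(1.0 / i for i in range(1, n)))


def expected_segsites(n: int, theta: float) -> float:
    """Watterson expectation E[S] = theta * H_{n-1}."""
    if theta < 0:
        raise InvalidParameterError(f"theta must be >= 0, got {theta}")
    return theta * expected_total_length(n)


def lineage_count_distribution(n: int, t: float) -> LineageCountDistribution:
    """Exact distribution of the ancestral lineage count of the pure-death chain.

    The chain steps j -> j-1 at rate j*(j-1). The distribution is computed as
    a matrix exponential of the (n x n) generator, which is numerically stable
    for the sample sizes used here, rather than via the classical alternating
    series (which loses all precision at small t for moderate n).
    """
    if n < 1:
        raise InvalidParameterError(f"n must be >= 1, got {n}")
    if t < 0:
        raise InvalidParameterError(f"t must be >= 0, got {t}")
    if n == 1 or t == 0.0:
        p = np.zeros(n)
        p[n - 1] = 1.0
        return LineageCountDistribution(n=n, t=float(t), probabilities=p)

    # Generator over states j = 1..n (index j-1); absorbing at j = 1.
    q = np.zeros((n, n))
    for j in range(2, n + 1):
        rate = j * (j - 1)
        q[j - 1, j - 1] = -rate
        q[j - 1, j - 2] = rate
    p0 = np.zeros(n)
    p0[n - 1] = 1.0
    p = p0 @ expm(q * t)
    p = np.clip(p, 0.0, None)
    p /= p.sum()
    return LineageCountDistribution(n=n, t=float(t), probabilities=p)


def _q_monophyly(j: int) -> float:
    """P(j exchangeable lineages fully coalesce before any joins a lone outgroup).

    With k ingroup lineages plus the outgroup present, the next coalescence is
    ingroup-internal with probability C(k,2)/C(k+1,2) = (k-1)/(k+1); the
    product over k = j..2 telescopes to 2/(j*(j+1)).
    """
    return 2.0 / (j * (j + 1))


def monophyly_probability(n_in: int, t_join: float) -> float:
    """Exact probability the ingroup is monophyletic in the single-outgroup design.

    Conditions on the number j of ingroup lineages surviving to the join:
    P(mono) = sum_j P(j at t_join) * q(j), with q(1) = 1 and
    q(j) = 2/(j*(j+1)).
    """
    if n_in < 1:
        raise InvalidParameterError(f"n_in must be >= 1, got {n_in}")
    dist = lineage_count_distribution(n_in, t_join)
    return float(sum(dist.prob(j) * _q_monophyly(j) for j in range(1, n_in + 1)))
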