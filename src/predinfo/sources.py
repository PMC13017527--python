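"""Source distributions over meanings used by the simulations and pipelines.

A source is a probability table over meanings; meanings here are tuples over
feature variables (coin flips, grammatical features, digit features) or
atoms. Constructors cover: products of weighted coins, a mixture that ties
two coins together with tunable mutual information, Zipfian sources, a
hierarchically coupled six-variable source, and empirical count tables with
optional add-constant smoothing.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .process_model import Source, mutual_information


@dataclass(frozen=True)
class FeatureSpec:
    """Named feature variables M_1..M_k with their cardinalities."""

    variables: tuple[str, ...]
    cardinalities: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.variables) < 1:
            raise ValueError("need at least one variable")
        if len(self.variables) != len(self.cardinalities):
            raise ValueError("variables and cardinalities differ in length")
        if any(c < 2 for c in self.cardinalities):
            raise ValueError("cardinalities must be >= 2")

    @property
    def k(self) -> int:
        return len(self.variables)

    def meanings(self) -> tuple[tuple[int, ...], ...]:
        """All value tuples, in lexicographic order."""
        return tuple(itertools.product(*(range(c) for c in self.cardinalities)))


@dataclass(frozen=True)
class CountTable:
    """Nonnegative counts over feature tuples, with a smoothing constant."""

    counts: Mapping[tuple, float]
    smoothing: float = 0.5

    def __post_init__(self) -> None:
        if not any(c > 0 for c in self.counts.values()):
            raise ValueError("count table needs at least one positive count")
        if any(c < 0 for c in self.counts.values()):
            raise ValueError("counts must be nonnegative")


def _bernoulli(q: float) -> np.ndarray:
    if not 0.0 <= q <= 1.0:
        raise ValueError(f"Bernoulli parameter {q} outside [0, 1]")
    return np.array([1.0 - q, q])


COINFLIP_SPEC = FeatureSpec(("M1", "M2", "M3"), (2, 2, 2))


def product_bernoulli_source(epsilon: float = 0.05) -> Source:
    """Three independent weighted coins: Bernoulli(2/3) x Bernoulli(2/3+eps)
    x Bernoulli(2/3+2*eps), over meanings (i, j, k) in {0,1}^3."""
    p1 = _bernoulli(2 / 3)
    p2 = _bernoulli(2 / 3 + epsilon)
    p3 = _bernoulli(2 / 3 + 2 * epsilon)
    meanings = COINFLIP_SPEC.meanings()
    probs = np.array([p1[i] * p2[j] * p3[k] for i, j, k in meanings])
    return Source(meanings, probs)


def correlated_mixture_source(epsilon: float = 0.05, alpha: float = 0.0) -> Source:
    """The coin-flip source with coins 2 and 3 tied together.

    p_a(ijk) = p1(i) * [(1-a) p2(j) p3(k) + (a/2) delta_jk]; the mixture
    weight ``alpha`` moves I[M2:M3] from 0 (independent) up to at most 1 bit
    (fully tied).
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must be in [0, 1]")
    p1 = _bernoulli(2 / 3)
    p2 = _bernoulli(2 / 3 + epsilon)
    p3 = _bernoulli(2 / 3 + 2 * epsilon)
    meanings = COINFLIP_SPEC.meanings()
    probs = np.array(
        [
            p1[i] * ((1 - alpha) * p2[j] * p3[k] + (alpha / 2) * (j == k))
            for i, j, k in meanings
        ]
    )
    return Source(meanings, probs)


def tied_pair_mi(source: Source) -> float:
    """I[M2:M3] of a three-feature source (marginalizing M1)."""
    joint: dict = {}
    for (i, j, k), p in source.items():
        joint[(j, k)] = joint.get((j, k), 0.0) + p
    return mutual_information(joint)


def zipf_probs(n: int, exponent: float = 1.0) -> np.ndarray:
    """p_i ∝ (i+1)^(-exponent) for i = 0..n-1, normalized."""
    if n < 1:
        raise ValueError("n must be >= 1")
    p = (np.arange(1, n + 1, dtype=float)) ** (-exponent)
    return p / p.sum()


def zipfian_source(n: int, exponent: float = 1.0) -> Source:
    """A Zipfian distribution over ``n`` atomic meanings 0..n-1."""
    return Source(tuple(range(n)), zipf_probs(n, exponent))


HIERARCHY_SPEC = FeatureSpec(
    ("M1", "M2", "M3", "M4", "M5", "M6"), (5, 5, 5, 5, 5, 5)
)


def hierarchical_source(
    alpha: float = 0.01, beta: float = 0.20, gamma: float = 0.99
) -> Source:
    """Six five-valued variables with nested coupling.

    p(M) = a*q(M1..M6) + (1-a) * g(M1,M2,M3) * g(M4,M5,M6), where
    g(X,Y,Z) = b*q(X,Y,Z) + (1-b) * [c*q(X,Y) + (1-c)*q(X)q(Y)] * q(Z),
    and every q(.) is a Zipfian distribution over its (lexicographically
    ordered) domain. Defaults make (M1,M2) and (M4,M5) highly correlated
    pairs, weakly coupled to M3 and M6 respectively, with only very weak
    coupling across the two triples.
    """
    for name, v in (("alpha", alpha), ("beta", beta), ("gamma", gamma)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name} must be in [0, 1]")
    q1 = zipf_probs(5)
    q2 = zipf_probs(25).reshape(5, 5)
    q3 = zipf_probs(125).reshape(5, 5, 5)
    q6 = zipf_probs(5**6).reshape((5,) * 6)
    pair = gamma * q2 + (1 - gamma) * np.outer(q1, q1)
    triple = beta * q3 + (1 - beta) * pair[:, :, None] * q1[None, None, :]
    probs = (
        alpha * q6
        + (1 - alpha)
        * triple[:, :, :, None, None, None]
        * triple[None, None, None, :, :, :]
    )
    return Source(HIERARCHY_SPEC.meanings(), probs.ravel())


def group_mutual_information(
    source: Source, left: tuple[int, ...], right: tuple[int, ...]
) -> float:
    """I between two disjoint groups of feature positions of a tuple source."""
    if set(left) & set(right):
        raise ValueError("groups must be disjoint")
    joint: dict = {}
    for m, p in source.items():
        key = (tuple(m[i] for i in left), tuple(m[i] for i in right))
        joint[key] = joint.get(key, 0.0) + p
    return mutual_information(joint)


def empirical_source(
    counts: Mapping[tuple, float] | CountTable, smoothing: float = 0.5
) -> Source:
    """Source proportional to empirical counts.

    With ``smoothing`` s > 0, probability ∝ count + s over the *full
    cross-product* of the feature values attested in the table (so unseen
    feature combinations receive mass); with s = 0, probability ∝ count over
    the observed tuples only.
    """
    if isinstance(counts, CountTable):
        smoothing = counts.smoothing
        counts = counts.counts
    if smoothing < 0:
        raise ValueError("smoothing must be >= 0")
    items = list(counts.items())
    if not items:
        raise ValueError("empty count table")
    if smoothing > 0:
        k = len(items[0][0]) if isinstance(items[0][0], tuple) else None
        if k is not None:
            values = [sorted({m[i] for m, _ in items}) for i in range(k)]
            meanings = tuple(itertools.product(*values))
            probs = np.array(
                [counts.get(m, 0.0) + smoothing for m in meanings], dtype=float
            )
        else:
            meanings = tuple(m for m, _ in items)
            probs = np.array([c + smoothing for _, c in items], dtype=float)
    else:
        meanings = tuple(m for m, _ in items)
        probs = np.array([c for _, c in items], dtype=float)
        if probs.sum() <= 0:
            raise ValueError("all-zero count table with zero smoothing")
    return Source(meanings, probs / probs.sum())
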