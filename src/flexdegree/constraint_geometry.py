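"""Measures of synaptic-weight configuration spaces under net-weight constraints.

A neuron with ``K`` synaptic partners and total connection strength budget
``Jbar`` occupies a point in the non-negative orthant of ``R^K``.  Two
constraints are considered:

* **bounded**: ``sum_i J_i <= Jbar`` — the allowed configurations fill the
  *volume* under a regular ``K-1`` simplex, ``V(K) = Jbar^K / K!``.
* **fixed**: ``sum_i J_i == Jbar`` — the allowed configurations lie on the
  simplex *surface*, whose ``K-1``-dimensional Hausdorff measure depends on
  the norm of the weight space: ``A(K) = Jbar^{K-1} sqrt(K) / (K-1)!`` for the
  Euclidean norm, with ``sqrt(K)`` replaced by ``K`` under the 1-norm (weights
  potentiate/depress independently, so the inner radius is ``Jbar/K`` rather
  than ``Jbar/sqrt(K)``).

The budget may scale with the degree, ``Jbar * K**p``; ``p = 0`` recovers a
degree-independent budget.  All factorial/Gamma arithmetic is done in log
space and exponentiated only at the interface, since ``K`` can reach several
hundred in real connectomes.

The discrete counterpart — ``M`` indivisible units of synaptic weight split
among ``K`` partners — is counted exactly by a binomial coefficient and
converges to the continuum volume for large ``M``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Sequence

import numpy as np
from scipy.special import gammaln

__all__ = [
    "ConstraintKind",
    "Norm",
    "DiscreteResourceModel",
    "ConstraintSpec",
    "WeightConfiguration",
    "MonteCarloEstimate",
    "count_configurations",
    "log_simplex_volume",
    "simplex_volume",
    "log_simplex_area",
    "simplex_area",
    "monte_carlo_measure",
]


class ConstraintKind(str, Enum):
    BOUNDED = "bounded"
    FIXED = "fixed"


class Norm(str, Enum):
    EUCLIDEAN = "euclidean"
    MANHATTAN = "manhattan"


@dataclass(frozen=True)
class DiscreteResourceModel:
    """``n_units`` indivisible synaptic-weight units of size ``unit_weight``
    to be distributed among ``degree`` synaptic partners."""

    n_units: int
    degree: int
    unit_weight: float = 1.0

    def __post_init__(self) -> None:
        if self.n_units < 1:
            raise ValueError(f"n_units must be >= 1, got {self.n_units}")
        if self.degree < 1:
            raise ValueError(f"degree must be >= 1, got {self.degree}")
        if self.unit_weight <= 0:
            raise ValueError("unit_weight must be positive")

    @property
    def net_weight(self) -> float:
        return self.n_units * self.unit_weight


@dataclass(frozen=True)
class ConstraintSpec:
    """Constraint on the net synaptic weight.

    The effective budget at degree ``K`` is ``net_weight * K**scaling_exponent``.
    """

    kind: ConstraintKind = ConstraintKind.BOUNDED
    net_weight: float = 1.0
    scaling_exponent: float = 0.0
    norm: Norm = Norm.EUCLIDEAN

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", ConstraintKind(self.kind))
        object.__setattr__(self, "norm", Norm(self.norm))
        if self.net_weight < 0:
            raise ValueError("net_weight must be non-negative")

    def budget(self, degree: int) -> float:
        """Effective net-weight budget ``Jbar * K**p`` at the given degree."""
        return self.net_weight * float(degree) ** self.scaling_exponent


@dataclass(frozen=True)
class WeightConfiguration:
    """A single vector of non-negative connection strengths."""

    weights: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.weights) == 0:
            raise ValueError("a configuration needs at least one weight")
        if any(w < 0 for w in self.weights):
            raise ValueError("synaptic weights must be non-negative")

    @property
    def degree(self) -> int:
        return len(self.weights)

    def satisfies(self, spec: ConstraintSpec, rtol: float = 1e-9) -> bool:
        budget = spec.budget(self.degree)
        total = sum(self.weights)
        if spec.kind is ConstraintKind.BOUNDED:
            return total <= budget * (1.0 + rtol)
        return math.isclose(total, budget, rel_tol=rtol, abs_tol=rtol)


def count_configurations(model: DiscreteResourceModel) -> int:
    """Exact number of ways to place ``K`` connections among ``M`` weight units.

    This is the binomial coefficient ``C(M, K)``; defined only for
    ``1 <= K <= M``.  Integer arithmetic throughout, so there is no overflow.
    """
    m, k = model.n_units, model.degree
    if k > m:
        raise ValueError(f"degree K={k} exceeds the number of weight units M={m}")
    return math.comb(m, k)


def _check_degree(K: int) -> int:
    if K < 1 or int(K) != K:
        raise ValueError(f"degree K must be an integer >= 1, got {K!r}")
    return int(K)


def log_simplex_volume(K: int, spec: ConstraintSpec) -> float:
    """``ln V(K)`` with ``V = (Jbar K^p)^K / K!`` (bounded constraint)."""
    K = _check_degree(K)
    if spec.kind is not ConstraintKind.BOUNDED:
        raise ValueError("simplex volume is the measure of the *bounded* constraint")
    b = spec.budget(K)
    if b == 0.0:
        return -math.inf
    return K * math.log(b) - float(gammaln(K + 1))


def simplex_volume(K: int, spec: ConstraintSpec) -> float:
    return math.exp(log_simplex_volume(K, spec))


def log_simplex_area(K: int, spec: ConstraintSpec) -> float:
    """``ln A(K)`` of the simplex surface (fixed constraint).

    Euclidean norm: ``A = (Jbar K^p)^{K-1} sqrt(K) / (K-1)!``; the 1-norm
    replaces ``sqrt(K)`` by ``K``.  ``A(1) = 1`` in both norms (a single
    point carries unit counting measure).
    """
    K = _check_degree(K)
    if spec.kind is not ConstraintKind.FIXED:
        raise ValueError("simplex area is the measure of the *fixed* constraint")
    b = spec.budget(K)
    if K == 1:
        return 0.0
    if b == 0.0:
        return -math.inf
    w = 0.5 if spec.norm is Norm.EUCLIDEAN else 1.0
    return (K - 1) * math.log(b) + w * math.log(K) - float(gammaln(K))


def simplex_area(K: int, spec: ConstraintSpec) -> float:
    return math.exp(log_simplex_area(K, spec))


@dataclass(frozen=True)
class MonteCarloEstimate:
    estimate: float
    standard_error: float
    n_samples: int


def monte_carlo_measure(
    K: int,
    spec: ConstraintSpec,
    n_samples: int,
    seed: int | np.random.Generator | None = 0,
) -> MonteCarloEstimate:
    """Monte-Carlo oracle for the simplex volume / surface area.

    bounded: hit-or-miss in the cube ``[0, budget]^K`` (fraction of points
    whose coordinates sum below the budget, times the cube volume).

    fixed: the surface ``{J >= 0, sum J = budget}`` is the graph of
    ``J_K = budget - sum_{i<K} J_i`` over the ``K-1``-dimensional bounded
    simplex; its area element is a constant factor times the base volume —
    ``sqrt(K)`` for the Euclidean norm (the graph's normal is
    ``(1,...,1)/sqrt(K)``), ``K`` for the 1-norm.  The base volume is
    estimated by hit-or-miss, so the estimator shares no closed form with
    :func:`simplex_area` beyond the projection factor.
    """
    K = _check_degree(K)
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    b = spec.budget(K)

    if spec.kind is ConstraintKind.BOUNDED:
        dim, box_measure = K, b**K
    else:
        if K == 1:
            return MonteCarloEstimate(1.0, 0.0, n_samples)
        factor = math.sqrt(K) if spec.norm is Norm.EUCLIDEAN else float(K)
        dim, box_measure = K - 1, factor * b ** (K - 1)

    hits = 0
    remaining = n_samples
    while remaining > 0:
        chunk = min(remaining, 1_000_000)
        pts = rng.random((chunk, dim))
        hits += int(np.count_nonzero(pts.sum(axis=1) <= 1.0))
        remaining -= chunk
    p = hits / n_samples
    est = p * box_measure
    se = box_measure * math.sqrt(max(p * (1.0 - p), 0.0) / n_samples)
    return MonteCarloEstimate(est, se, n_samples)
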