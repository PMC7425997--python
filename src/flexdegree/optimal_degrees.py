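"""Optimally flexible degrees: the K that maximizes the configuration measure.

Closed forms (asymptotic in ``1/K*``), in terms of the effective budget
``b = alpha * Sbar`` at the optimum and the budget-scaling exponent ``p``:

* bounded (volume):  ``K* = b e^p - 1/2``  — equivalently the mode of the
  zero-truncated Poisson at ``p = 0``; the ratio route gives
  ``K* = b e^p + p - 1``.
* fixed (area):      ``K* = b e^p + 2 - p`` (real-K differentiation route)
  or ``K* = b e^p - p + 1/2`` (ratio route).  The two routes differ at
  O(1), which is inside the honest error band of either.

The discrete optimum is treated as ground truth.  It is located from the
ratio criterion: successive measure ratios ``m(K+1)/m(K)`` are written with
the local identification ``Jbar K^p = alpha Sbar`` (the measured synapse
count absorbs the degree scaling), giving a single log-concave sequence
whose argmax is found exactly.  At ``p = 0`` the substitution is vacuous and
the sequence *is* the log measure itself.  This formulation stays well-posed
through ``p = 1``, where maximizing the raw measure at fixed ``Jbar``
degenerates (the log measure becomes convex/linear in ``K``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np

from .constraint_geometry import ConstraintKind, Norm

__all__ = [
    "OptimalDegreeResult",
    "log_measure_sequence",
    "brute_force_argmax",
    "optimal_degree_bounded",
    "optimal_degree_fixed",
]


@dataclass(frozen=True)
class OptimalDegreeResult:
    kind: ConstraintKind
    continuous_estimate: float
    continuous_estimate_ratio: float
    discrete_argmax: tuple[int, ...]
    scaling_exponent: float
    norm: Norm | None = None

    @property
    def discrete(self) -> int:
        """Smallest maximizer (ties reported in full in ``discrete_argmax``)."""
        return self.discrete_argmax[0]


def log_measure_sequence(budget: float, p: float, kind: ConstraintKind,
                         norm: Norm = Norm.EUCLIDEAN,
                         K_max: int | None = None) -> np.ndarray:
    """Log configuration measure over K = 1..K_max (index 0 <-> K = 1).

    Built by accumulating log ratios of successive measures with
    ``Jbar K^p = budget`` substituted locally; for ``p = 0`` this equals the
    exact ``ln V`` / ``ln A`` up to the K = 1 anchor.
    """
    if budget <= 0:
        raise ValueError("budget must be positive")
    if K_max is None:
        K_max = max(10, int(math.ceil(4.0 * budget * math.exp(p))))
    j = np.arange(1, K_max, dtype=float)  # ratio m(j+1)/m(j)
    if kind is ConstraintKind.BOUNDED:
        log_r = math.log(budget) + p * (j + 1.0) * np.log1p(1.0 / j) - np.log(j + 1.0)
        anchor = math.log(budget)  # V(1) = Jbar
    else:
        w = 0.5 if norm is Norm.EUCLIDEAN else 1.0
        log_r = math.log(budget) + (p * j + w) * np.log1p(1.0 / j) - np.log(j)
        anchor = 0.0  # A(1) = 1 in both norms
    out = np.empty(K_max, dtype=float)
    out[0] = anchor
    np.cumsum(log_r, out=out[1:])
    out[1:] += anchor
    return out


def brute_force_argmax(log_measure: np.ndarray | Callable[[np.ndarray], np.ndarray],
                       K_range: Sequence[int] | None = None,
                       rel_tol: float = 1e-12) -> tuple[int, ...]:
    """All maximizers of a log measure over a degree range, ties included.

    Ties are detected at relative tolerance ``rel_tol`` on the log scale so
    that exact ties (e.g. the bounded family at integer budgets) are
    reported rather than silently broken.
    """
    if callable(log_measure):
        if K_range is None or len(K_range) == 0:
            raise ValueError("K_range must be non-empty")
        Ks = np.asarray(list(K_range), dtype=int)
        vals = np.asarray(log_measure(Ks), dtype=float)
    else:
        vals = np.asarray(log_measure, dtype=float)
        Ks = np.arange(1, len(vals) + 1) if K_range is None else np.asarray(list(K_range), dtype=int)
        if len(Ks) != len(vals):
            raise ValueError("K_range does not match the measure sequence")
    if len(vals) == 0:
        raise ValueError("K_range must be non-empty")
    best = vals.max()
    tol = rel_tol * max(1.0, abs(best))
    return tuple(int(k) for k in Ks[vals >= best - tol])


def optimal_degree_bounded(alpha_sbar: float, p: float = 0.0,
                           K_max: int | None = None) -> OptimalDegreeResult:
    """Optimal degree under a bounded net weight with effective budget ``alpha_sbar``."""
    if alpha_sbar <= 0:
        raise ValueError("effective budget must be positive")
    seq = log_measure_sequence(alpha_sbar, p, ConstraintKind.BOUNDED, K_max=K_max)
    ties = brute_force_argmax(seq)
    cont = alpha_sbar * math.exp(p) - 0.5
    cont_ratio = alpha_sbar * math.exp(p) + p - 1.0
    return OptimalDegreeResult(ConstraintKind.BOUNDED, cont, cont_ratio, ties, p)


def optimal_degree_fixed(alpha_sbar: float, p: float = 0.0,
                         norm: Norm | str = Norm.EUCLIDEAN,
                         K_max: int | None = None) -> OptimalDegreeResult:
    """Optimal degree under a fixed net weight with effective budget ``alpha_sbar``."""
    norm = Norm(norm)
    if alpha_sbar <= 0:
        raise ValueError("effective budget must be positive")
    seq = log_measure_sequence(alpha_sbar, p, ConstraintKind.FIXED, norm=norm, K_max=K_max)
    ties = brute_force_argmax(seq)
    cont = alpha_sbar * math.exp(p) + 2.0 - p
    cont_ratio = alpha_sbar * math.exp(p) - p + 0.5
    return OptimalDegreeResult(ConstraintKind.FIXED, cont, cont_ratio, ties, p, norm)
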