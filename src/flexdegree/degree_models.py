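"""Conditional degree-distribution families derived from weight constraints.

Each family gives the probability that a neuron has ``K >= 1`` synaptic
partners, conditioned on its total synapse count ``Sbar`` through the
effective budget ``x = alpha * Sbar`` (``alpha`` converts synapse counts to
net synaptic weight):

* ``bounded_volume`` — p(K) proportional to the simplex volume, which
  normalizes exactly to a zero-truncated Poisson:
  ``p(K) = x^K / ((e^x - 1) K!)``.
* ``fixed_area`` — p(K) proportional to the simplex surface area,
  ``p(K) = x^{K-1} sqrt(K) / (K-1)! / Z_A(x)``; ``Z_A`` has no closed form
  and is summed numerically with a certified tail bound.
* ``fixed_area_1norm`` — as above with ``K`` in place of ``sqrt(K)``; here
  ``Z_1(x) = (1 + x) e^x`` exactly.
* ``binomial`` — a random-wiring null model: zero-truncated binomial with
  ``N`` potential partners connecting independently with probability ``q``
  (does not depend on ``Sbar``).

The degenerate budget ``x = 0`` is treated as its analytic limit (a point
mass at ``K = 1``) so that optimizers can explore the boundary.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.special import gammaln, logsumexp

from .constraint_geometry import Norm

__all__ = [
    "Family",
    "DegreeModel",
    "DegreePMF",
    "pmf_bounded",
    "pmf_fixed",
    "pmf_binomial",
    "conditional_pmf",
    "marginal_pmf",
    "sample_degree",
    "log_z_bounded",
    "fixed_weight_normalizer",
]

_TAIL_TOL = 1e-12


class Family(str, Enum):
    BOUNDED_VOLUME = "bounded_volume"
    FIXED_AREA = "fixed_area"
    FIXED_AREA_1NORM = "fixed_area_1norm"
    BINOMIAL = "binomial"


_FAMILY_NORM = {Family.FIXED_AREA: Norm.EUCLIDEAN, Family.FIXED_AREA_1NORM: Norm.MANHATTAN}


@dataclass(frozen=True)
class DegreeModel:
    """A degree-distribution family with its parameters.

    ``alpha`` is used by the three constraint families; ``(N, q)`` by the
    binomial family.
    """

    family: Family
    alpha: float | None = None
    N: int | None = None
    q: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "family", Family(self.family))
        if self.family is Family.BINOMIAL:
            if self.N is None or self.q is None:
                raise ValueError("binomial family requires N and q")
            if self.N < 1:
                raise ValueError("N must be >= 1")
            if not (0.0 < self.q <= 1.0):
                raise ValueError("q must lie in (0, 1]")
        else:
            if self.alpha is None or self.alpha < 0:
                raise ValueError("constraint families require alpha >= 0")


@dataclass(frozen=True)
class DegreePMF:
    """A normalized degree distribution on the truncated support 1..K_max."""

    support: np.ndarray
    probs: np.ndarray
    log_Z: float
    truncation_tail: float

    def __post_init__(self) -> None:
        total = float(self.probs.sum())
        if not (1.0 - 1e-9 <= total <= 1.0 + 1e-9):
            raise ValueError(f"pmf does not sum to 1 (sum={total!r})")

    def prob(self, K: int) -> float:
        i = int(K) - int(self.support[0])
        if i < 0 or i >= len(self.support):
            return 0.0
        return float(self.probs[i])

    def mean(self) -> float:
        return float(np.dot(self.support, self.probs))


# ---------------------------------------------------------------------------
# normalizers


def log_z_bounded(x: float) -> float:
    """``ln(e^x - 1)``, stable for both tiny and large ``x``."""
    if x <= 0:
        raise ValueError("requires x > 0")
    if x > 30.0:
        return x + math.log1p(-math.exp(-x))
    return math.log(math.expm1(x))


def _fixed_weight_k_max(x: np.ndarray, sbar: np.ndarray, K_max: int | None) -> int:
    if K_max is not None:
        return int(K_max)
    # default: twice the largest synapse count, padded so the Poisson-like
    # bulk (mean ~ x) plus many standard deviations is always covered
    hi = float(np.max(x))
    auto = max(2.0 * float(np.max(sbar)), hi + 12.0 * math.sqrt(hi) + 30.0)
    return int(math.ceil(auto))


def fixed_weight_normalizer(
    x: np.ndarray | float,
    norm: Norm | str = Norm.EUCLIDEAN,
    K_max: int | None = None,
    *,
    with_moments: bool = False,
):
    """Log normalizer of the fixed-weight family, by certified summation.

    Sums ``ln Z(x) = ln sum_{K=1..K_max} x^{K-1} K^w / (K-1)!`` (``w = 1/2``
    Euclidean, ``w = 1`` 1-norm) and bounds the omitted tail by a geometric
    series; the range is doubled until ``tail/Z < 1e-12``.

    Returns ``(log_Z, tail_bound)`` or, with ``with_moments=True``,
    ``(log_Z, tail_bound, m1, v)`` where ``m1 = E[K-1]`` and
    ``v = E[(K-1)(K-2)] - E[K-1]^2`` under the tilted weights; these give the
    first two derivatives of ``ln Z`` with respect to ``ln x``-like
    quantities used by the evidence module:
    ``d ln Z/dx = m1/x`` and ``d^2 ln Z/dx^2 = v/x^2``.
    """
    norm = Norm(norm)
    x_arr = np.atleast_1d(np.asarray(x, dtype=float))
    if np.any(x_arr < 0):
        raise ValueError("x = alpha*Sbar must be non-negative")
    w = 0.5 if norm is Norm.EUCLIDEAN else 1.0
    k_hi = _fixed_weight_k_max(np.maximum(x_arr, 1.0), np.maximum(x_arr, 1.0), K_max)

    while True:
        K = np.arange(1, k_hi + 1, dtype=float)
        with np.errstate(divide="ignore"):
            logx = np.where(x_arr > 0, np.log(np.where(x_arr > 0, x_arr, 1.0)), -np.inf)
        lt = (K - 1.0)[None, :] * logx[:, None] + (w * np.log(K) - gammaln(K))[None, :]
        log_Z = logsumexp(lt, axis=1)
        # tail: for K > k_hi the term ratio is <= x * ((K+1)/K)^w / K
        ratio = x_arr * (1.0 + 1.0 / k_hi) ** w / k_hi
        with np.errstate(divide="ignore", invalid="ignore"):
            log_next = k_hi * logx + w * math.log(k_hi + 1) - gammaln(k_hi + 1)
            log_tail = np.where(
                ratio < 0.9, log_next - np.log1p(-np.minimum(ratio, 0.9)), np.inf
            )
        tail = np.exp(log_tail - log_Z)
        if K_max is not None or np.all(tail < _TAIL_TOL):
            break
        k_hi *= 2

    if with_moments:
        weights = np.exp(lt - log_Z[:, None])
        m1 = weights @ (K - 1.0)
        m2 = weights @ ((K - 1.0) * (K - 2.0))
        v = m2 - m1**2
        if np.isscalar(x) or np.asarray(x).ndim == 0:
            return float(log_Z[0]), float(tail[0]), float(m1[0]), float(v[0])
        return log_Z, tail, m1, v
    if np.isscalar(x) or np.asarray(x).ndim == 0:
        return float(log_Z[0]), float(tail[0])
    return log_Z, tail


# ---------------------------------------------------------------------------
# conditional pmfs


def pmf_bounded(K, alpha: float, sbar: float):
    """Zero-truncated Poisson pmf ``x^K / ((e^x - 1) K!)`` at ``x = alpha*sbar``."""
    if alpha < 0 or sbar < 0:
        raise ValueError("alpha and sbar must be non-negative")
    K_arr = np.atleast_1d(np.asarray(K))
    if np.any(K_arr < 1):
        raise ValueError("degree K must be >= 1")
    x = alpha * sbar
    if x == 0.0:
        out = np.where(K_arr == 1, 1.0, 0.0)
    else:
        lz = log_z_bounded(x)
        out = np.exp(K_arr * math.log(x) - gammaln(K_arr + 1.0) - lz)
    return float(out[0]) if np.isscalar(K) else out


def pmf_fixed(K, alpha: float, sbar: float, norm: Norm | str = Norm.EUCLIDEAN,
              K_max: int | None = None):
    """Simplex-area pmf ``x^{K-1} K^w / (K-1)! / Z_A`` at ``x = alpha*sbar``.

    ``K_max`` truncates the normalizing sum (default: twice ``sbar``); the
    sum is extended automatically whenever the certified tail bound exceeds
    1e-12.  Probabilities for ``K > K_max`` are treated as out of support.
    """
    norm = Norm(norm)
    if alpha < 0 or sbar < 0:
        raise ValueError("alpha and sbar must be non-negative")
    K_arr = np.atleast_1d(np.asarray(K))
    if np.any(K_arr < 1):
        raise ValueError("degree K must be >= 1")
    x = alpha * sbar
    k_hi = K_max if K_max is not None else _fixed_weight_k_max(
        np.atleast_1d(max(x, 1.0)), np.atleast_1d(max(sbar, 1.0)), None)
    if np.any(K_arr > k_hi):
        raise ValueError(f"K exceeds the truncation bound K_max={k_hi}")
    if x == 0.0:
        out = np.where(K_arr == 1, 1.0, 0.0)
    else:
        w = 0.5 if norm is Norm.EUCLIDEAN else 1.0
        log_Z, _ = fixed_weight_normalizer(x, norm, K_max)
        out = np.exp((K_arr - 1.0) * math.log(x) + w * np.log(K_arr)
                     - gammaln(K_arr.astype(float)) - log_Z)
    return float(out[0]) if np.isscalar(K) else out


def pmf_binomial(K, N: int, q: float):
    """Zero-truncated binomial pmf ``C(N,K) q^K (1-q)^{N-K} / (1 - (1-q)^N)``."""
    if q <= 0.0 or q > 1.0:
        raise ValueError("q must lie in (0, 1]")
    if N < 1:
        raise ValueError("N must be >= 1")
    K_arr = np.atleast_1d(np.asarray(K))
    if np.any(K_arr < 1):
        raise ValueError("degree K must be >= 1")
    out = np.zeros(K_arr.shape, dtype=float)
    ok = K_arr <= N
    if q == 1.0:
        out[ok] = (K_arr[ok] == N).astype(float)
    else:
        Kf = K_arr[ok].astype(float)
        log_trunc = math.log(-math.expm1(N * math.log1p(-q)))
        lp = (gammaln(N + 1.0) - gammaln(Kf + 1.0) - gammaln(N - Kf + 1.0)
              + Kf * math.log(q) + (N - Kf) * math.log1p(-q) - log_trunc)
        out[ok] = np.exp(lp)
    return float(out[0]) if np.isscalar(K) else out


def conditional_pmf(model: DegreeModel, sbar: float | None = None,
                    K_max: int | None = None) -> DegreePMF:
    """Tabulate the conditional degree pmf of ``model`` for one neuron."""
    if model.family is Family.BINOMIAL:
        support = np.arange(1, model.N + 1)
        probs = pmf_binomial(support, model.N, model.q)
        log_Z = math.log(-math.expm1(model.N * math.log1p(-model.q))) if model.q < 1 else 0.0
        return DegreePMF(support, probs, log_Z, 0.0)
    if sbar is None or sbar < 0:
        raise ValueError("constraint families require sbar >= 0")
    x = model.alpha * sbar
    if model.family is Family.BOUNDED_VOLUME:
        if K_max is None:
            K_max = int(math.ceil(max(2.0 * sbar, x + 12.0 * math.sqrt(max(x, 1.0)) + 30.0)))
        support = np.arange(1, K_max + 1)
        if x == 0.0:
            probs = np.where(support == 1, 1.0, 0.0).astype(float)
            return DegreePMF(support, probs, -math.inf, 0.0)
        log_Z = log_z_bounded(x)
        probs = pmf_bounded(support, model.alpha, sbar)
        tail = max(0.0, 1.0 - float(probs.sum()))
        return DegreePMF(support, probs / probs.sum(), log_Z, tail)
    norm = _FAMILY_NORM[model.family]
    if x == 0.0:
        support = np.arange(1, (K_max or 2) + 1)
        probs = np.where(support == 1, 1.0, 0.0).astype(float)
        return DegreePMF(support, probs, 0.0, 0.0)
    log_Z, tail_b = fixed_weight_normalizer(x, norm, K_max)
    if K_max is None:
        K_max = _fixed_weight_k_max(np.atleast_1d(max(x, 1.0)), np.atleast_1d(max(sbar, 1.0)), None)
    support = np.arange(1, K_max + 1)
    probs = pmf_fixed(support, model.alpha, sbar, norm, K_max=K_max)
    # renormalize within the tabulated support; the omitted mass is recorded
    total = probs.sum()
    return DegreePMF(support, probs / total, log_Z, max(float(tail_b), 1.0 - float(total)))


def marginal_pmf(model: DegreeModel, sbar_list: Sequence[float],
                 K_max: int | None = None) -> DegreePMF:
    """Marginal degree distribution ``p(K) = mean_i p(K | alpha, Sbar_i)``.

    This integrates the synapse count out against its empirical distribution,
    which is how fitted models are compared with observed degree histograms.
    """
    sbar_arr = np.asarray(list(sbar_list), dtype=float)
    if sbar_arr.size == 0:
        raise ValueError("sbar_list must be non-empty")
    if model.family is Family.BINOMIAL:
        return conditional_pmf(model)
    if K_max is None:
        hi = model.alpha * float(sbar_arr.max())
        K_max = int(math.ceil(max(2.0 * float(sbar_arr.max()),
                                  hi + 12.0 * math.sqrt(max(hi, 1.0)) + 30.0)))
    support = np.arange(1, K_max + 1)
    acc = np.zeros(K_max, dtype=float)
    tail = 0.0
    for s in sbar_arr:
        pmf = conditional_pmf(model, float(s), K_max=K_max)
        acc += pmf.probs
        tail = max(tail, pmf.truncation_tail)
    acc /= len(sbar_arr)
    return DegreePMF(support, acc / acc.sum(), math.nan, tail)


@lru_cache(maxsize=4096)
def _cached_cdf(model: DegreeModel, sbar: float | None) -> tuple[np.ndarray, np.ndarray]:
    pmf = conditional_pmf(model, sbar)
    return pmf.support, np.cumsum(pmf.probs)


def sample_degree(model: DegreeModel, sbar: float | None, rng: np.random.Generator) -> int:
    """Draw one degree by exact inverse-CDF sampling on the truncated support."""
    if model.family is not Family.BINOMIAL:
        if sbar is None or sbar <= 0:
            raise ValueError("constraint families require sbar > 0 for sampling")
    support, cdf = _cached_cdf(model, None if model.family is Family.BINOMIAL else float(sbar))
    u = rng.random()
    idx = int(np.searchsorted(cdf, u * cdf[-1], side="left"))
    return int(support[min(idx, len(support) - 1)])
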