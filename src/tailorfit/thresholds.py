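"""Category thresholds matching target moments of the response distribution.

Ordinal indicators are produced by cutting a standard-normal latent response
at K−1 thresholds.  The study design does not prescribe the thresholds
directly but the *moments* of the resulting categorical score distribution
(scores 1..K): skewness 0 for symmetric response distributions, 0.65 for
asymmetric ones, with excess kurtosis ≈ −0.80 throughout.  We therefore
parameterize the K category probabilities directly (softmax over free
log-weights, with a mirror-symmetry constraint when the target skewness is
zero), minimize the squared deviation of the implied skewness and excess
kurtosis from their targets, and recover thresholds as normal quantiles of
the cumulative probabilities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import ndtri, softmax

__all__ = ["ThresholdSet", "categorical_moments", "solve_thresholds"]

#: design targets per distribution label
TARGET_MOMENTS = {
    "symmetric": (0.00, -0.80),
    "asymmetric": (0.65, -0.80),
}


def categorical_moments(probs: Sequence[float]) -> tuple[float, float, float, float]:
    """Exact mean, variance, skewness and excess kurtosis of scores ``1..K``.

    Serves as the independent oracle for the threshold solver: it involves
    nothing but the definition of the moments of a finite distribution.
    """
    p = np.asarray(probs, dtype=float)
    if p.ndim != 1 or p.size < 1 or np.any(p < -1e-12) or abs(p.sum() - 1.0) > 1e-8:
        raise ValueError("probs must be a probability vector")
    scores = np.arange(1, p.size + 1, dtype=float)
    mean = float(p @ scores)
    d = scores - mean
    var = float(p @ d**2)
    if var == 0.0:
        return mean, 0.0, 0.0, 0.0
    skew = float(p @ d**3) / var**1.5
    exkurt = float(p @ d**4) / var**2 - 3.0
    return mean, var, skew, exkurt


@dataclass(frozen=True)
class ThresholdSet:
    """K−1 increasing standard-normal cutpoints and their implied categories."""

    n_options: int
    thresholds: tuple[float, ...]
    implied_probs: tuple[float, ...]
    target_skew: float
    target_excess_kurtosis: float

    def __post_init__(self) -> None:
        if len(self.thresholds) != self.n_options - 1:
            raise ValueError("need K-1 thresholds for K options")
        if np.any(np.diff(self.thresholds) <= 0):
            raise ValueError("thresholds must be strictly increasing")

    @property
    def moments(self) -> tuple[float, float, float, float]:
        return categorical_moments(self.implied_probs)

    def to_json(self) -> str:
        return json.dumps(
            {
                "n_options": self.n_options,
                "thresholds": list(self.thresholds),
                "implied_probs": list(self.implied_probs),
                "target_skew": self.target_skew,
                "target_excess_kurtosis": self.target_excess_kurtosis,
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "ThresholdSet":
        d = json.loads(text)
        return cls(
            n_options=d["n_options"],
            thresholds=tuple(d["thresholds"]),
            implied_probs=tuple(d["implied_probs"]),
            target_skew=d["target_skew"],
            target_excess_kurtosis=d["target_excess_kurtosis"],
        )


def _probs_from_free(free: np.ndarray, K: int, symmetric: bool) -> np.ndarray:
    if symmetric:
        # mirror-symmetric probabilities: p_j = p_{K+1-j} by construction
        half = (K + 1) // 2
        w = np.empty(K)
        w[:half] = free
        w[K - half :] = free[::-1]
        return softmax(w)
    w = np.concatenate([free, [0.0]])
    return softmax(w)


def solve_thresholds(
    K: int,
    target_skew: float,
    target_excess_kurtosis: float = -0.80,
    *,
    tol: float = 1e-6,
) -> ThresholdSet:
    """Thresholds whose categorical score distribution matches target moments.

    Symmetric targets (skew 0) are enforced exactly by construction; the
    optimizer then only matches the kurtosis target.  Raises if the best
    attainable moments deviate from the targets by more than ``tol`` in
    squared error (suggesting the kurtosis target is not attainable for K).
    """
    if K < 2:
        raise ValueError("need at least two response options")
    symmetric = target_skew == 0.0
    if K == 2:
        # variance-only distribution: skewness 0, excess kurtosis fixed by p
        if symmetric:
            probs = np.array([0.5, 0.5])
            return ThresholdSet(2, (0.0,), tuple(probs), target_skew, target_excess_kurtosis)
    n_free = (K + 1) // 2 if symmetric else K - 1

    def objective(free: np.ndarray) -> float:
        p = _probs_from_free(free, K, symmetric)
        _, _, skew, exkurt = categorical_moments(p)
        val = (exkurt - target_excess_kurtosis) ** 2
        if not symmetric:
            val += (skew - target_skew) ** 2
        return val

    best = None
    rng = np.random.default_rng(12345)  # fixed: solver must be deterministic
    starts = [np.zeros(n_free)] + [rng.normal(scale=s, size=n_free) for s in (0.5, 1.0, 2.0)]
    for x0 in starts:
        res = minimize(objective, x0, method="Nelder-Mead",
                       options={"xatol": 1e-10, "fatol": 1e-14, "maxiter": 20000})
        if best is None or res.fun < best.fun:
            best = res
        if best.fun < 1e-16:
            break
    assert best is not None
    if best.fun > tol:
        raise RuntimeError(
            f"threshold solver did not reach the moment targets for K={K} "
            f"(residual {best.fun:.2e}); consider relaxing the kurtosis target"
        )
    probs = _probs_from_free(best.x, K, symmetric)
    cum = np.cumsum(probs)[:-1]
    tau = ndtri(np.clip(cum, 1e-12, 1 - 1e-12))
    if symmetric:
        tau = (tau - tau[::-1]) / 2.0  # exact mirror symmetry
    return ThresholdSet(
        n_options=K,
        thresholds=tuple(float(t) for t in tau),
        implied_probs=tuple(float(p) for p in probs),
        target_skew=target_skew,
        target_excess_kurtosis=target_excess_kurtosis,
    )
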