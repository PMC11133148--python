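"""Vectorized standard bivariate normal probabilities.

Rectangle probabilities of the standard bivariate normal underpin both the
polychoric likelihood and its asymptotic covariance.  The CDF uses Genz's
numerical integration scheme (Gauss–Legendre on a transformed correlation
integral, with a dedicated high-|rho| branch), vectorized over arrays of
integration limits at a fixed correlation; absolute accuracy is ~1e-14.
"""

from __future__ import annotations

import numpy as np
from numpy.polynomial.legendre import leggauss
from scipy.special import ndtr

__all__ = ["bvn_cdf", "bvn_pdf", "rectangle_probs"]

_CLIP = 8.5  # |Phi^{-1}| beyond this is numerically 0/1

_RULES = {n: leggauss(n) for n in (6, 12, 20)}


def bvn_pdf(h: np.ndarray, k: np.ndarray, rho: float) -> np.ndarray:
    """Standard bivariate normal density at (h, k); zero at infinite limits."""
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    om = 1.0 - rho * rho
    z = (h * h - 2.0 * rho * h * k + k * k) / om
    return np.exp(-z / 2.0) / (2.0 * np.pi * np.sqrt(om))


def _bvn_upper(h: np.ndarray, k: np.ndarray, r: float) -> np.ndarray:
    """P(X > h, Y > k) for standard bivariate normal, correlation r (Genz)."""
    h = np.array(h, dtype=float, copy=True)
    k = np.array(k, dtype=float, copy=True)
    if abs(r) < 0.925:
        n = 6 if abs(r) < 0.3 else (12 if abs(r) < 0.75 else 20)
        x, w = _RULES[n]
        asr = np.arcsin(r)
        sn = np.sin(asr * (x + 1.0) / 2.0)  # nodes on (0, asin r)
        hk = h * k
        hs = (h * h + k * k) / 2.0
        f = np.exp((sn[:, None] * hk[None, :] - hs[None, :]) / (1.0 - sn[:, None] ** 2))
        bvn = asr * (w / 2.0) @ f / (2.0 * np.pi)
        return bvn + ndtr(-h) * ndtr(-k)
    # high-correlation branch
    twopi = 2.0 * np.pi
    if r < 0.0:
        k = -k
    hk = h * k
    bvn = np.zeros_like(h)
    if abs(r) < 1.0:
        as_ = (1.0 - r) * (1.0 + r)
        a = np.sqrt(as_)
        bs = (h - k) ** 2
        c = (4.0 - hk) / 8.0
        d = (12.0 - hk) / 16.0
        asr = -(bs / as_ + hk) / 2.0
        m = asr > -100.0
        bvn = np.where(
            m,
            a * np.exp(asr) * (1.0 - c * (bs - as_) * (1.0 - d * bs / 5.0) / 3.0
                               + c * d * as_ * as_ / 5.0),
            0.0,
        )
        m = -hk < 100.0
        b = np.sqrt(bs)
        with np.errstate(over="ignore"):
            term = (np.exp(-hk / 2.0) * np.sqrt(twopi) * ndtr(-b / a) * b
                    * (1.0 - c * bs * (1.0 - d * bs / 5.0) / 3.0))
        bvn = bvn - np.where(m, term, 0.0)
        a2 = a / 2.0
        x, w = _RULES[20]
        for xi, wi in zip(x, w):
            xs = (a2 * (xi + 1.0)) ** 2
            rs = np.sqrt(1.0 - xs)
            asr1 = -(bs / xs + hk) / 2.0
            m = asr1 > -100.0
            sp = 1.0 + c * xs * (1.0 + d * xs)
            ep = np.exp(-hk * (1.0 - rs) / (2.0 * (1.0 + rs))) / rs
            bvn = bvn + np.where(m, a2 * wi * np.exp(asr1) * (ep - sp), 0.0)
        bvn = -bvn / twopi
    if r > 0.0:
        return bvn + ndtr(-np.maximum(h, k))
    return -bvn + np.maximum(0.0, ndtr(-h) - ndtr(-k))


def bvn_cdf(h, k, rho: float):
    """P(X <= h, Y <= k), vectorized over equal-shaped ``h`` and ``k``."""
    h = np.clip(np.asarray(h, dtype=float), -_CLIP, _CLIP)
    k = np.clip(np.asarray(k, dtype=float), -_CLIP, _CLIP)
    shape = np.broadcast_shapes(h.shape, k.shape)
    hb = np.broadcast_to(h, shape).ravel()
    kb = np.broadcast_to(k, shape).ravel()
    # P(X <= h, Y <= k) = P(-X >= -h, -Y >= -k) and (-X,-Y) has the same rho
    out = _bvn_upper(-hb, -kb, float(rho))
    return np.clip(out, 0.0, 1.0).reshape(shape)


def rectangle_probs(tau_row: np.ndarray, tau_col: np.ndarray, rho: float) -> np.ndarray:
    """Cell probabilities of the discretized bivariate normal.

    ``tau_row``/``tau_col`` are the finite threshold vectors (K−1 values); the
    returned matrix is K_row × K_col and sums to 1.
    """
    a = np.concatenate([[-np.inf], tau_row, [np.inf]])
    b = np.concatenate([[-np.inf], tau_col, [np.inf]])
    cdf = bvn_cdf(a[:, None], b[None, :], rho)
    probs = np.diff(np.diff(cdf, axis=0), axis=1)
    return np.clip(probs, 0.0, 1.0)
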