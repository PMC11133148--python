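"""Two-step polychoric correlations with their asymptotic covariance matrix.

Step one estimates each indicator's thresholds as normal quantiles of the
cumulative category proportions.  Step two maximizes, for each indicator
pair, the bivariate-normal likelihood of the observed contingency table in
the correlation alone, thresholds held fixed.

The asymptotic covariance of the estimated correlations (needed for the
diagonal weight matrix of DWLS and for the mean-and-variance adjustment of
the WLSMV test statistic) is assembled from per-observation influence
functions of the two-step estimator: the raw likelihood score for the
correlation plus the propagated influence of the estimated thresholds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar
from scipy.special import ndtr, ndtri

from .bvn import bvn_cdf, bvn_pdf, rectangle_probs
from .population import OrdinalDataset

__all__ = ["PolychoricSummary", "estimate_polychorics", "polychoric_pair", "pair_order"]

_RHO_BOUND = 0.999
_PROB_FLOOR = 1e-12


def pair_order(p: int) -> list[tuple[int, int]]:
    """Canonical ordering of indicator pairs: (0,1), (0,2), ..., (p-2,p-1)."""
    return [(i, j) for i in range(p) for j in range(i + 1, p)]


@dataclass(frozen=True)
class PolychoricSummary:
    """Thresholds, correlation matrix and asymptotic covariance for one dataset.

    ``gamma`` is the estimated asymptotic covariance of sqrt(N) times the
    correlation vector (in :func:`pair_order` order); ``boundary`` flags
    correlations that hit the search bound.
    """

    thresholds: tuple[np.ndarray, ...]
    rho_matrix: np.ndarray
    gamma: np.ndarray
    n: int
    boundary: tuple[bool, ...]

    @property
    def n_indicators(self) -> int:
        return self.rho_matrix.shape[0]

    @property
    def correlations(self) -> np.ndarray:
        """Correlation vector in pair order (the moment vector fitted by DWLS)."""
        idx = pair_order(self.n_indicators)
        return np.array([self.rho_matrix[i, j] for i, j in idx])


def _column_thresholds(codes: np.ndarray, K: int) -> tuple[np.ndarray, np.ndarray]:
    counts = np.bincount(codes, minlength=K + 1)[1:]
    if np.any(counts == 0):
        empty = int(np.argmin(counts)) + 1
        raise ValueError(
            f"empty category {empty}: thresholds are undefined for unobserved "
            "response options (upstream resampling enforces >= 5 per cell)"
        )
    cum = np.cumsum(counts)[:-1] / codes.size
    return ndtri(cum), counts


def _neg_loglik(rho: float, table: np.ndarray, tau_i: np.ndarray, tau_j: np.ndarray) -> float:
    probs = np.maximum(rectangle_probs(tau_i, tau_j, rho), _PROB_FLOOR)
    return -float((table * np.log(probs)).sum())


def polychoric_pair(
    table: np.ndarray, tau_i: np.ndarray, tau_j: np.ndarray
) -> tuple[float, bool]:
    """ML estimate of one polychoric correlation with thresholds fixed.

    Returns the estimate and a flag marking a solution at the search bound.
    """
    table = np.asarray(table, dtype=float)
    res = minimize_scalar(
        _neg_loglik,
        bounds=(-_RHO_BOUND, _RHO_BOUND),
        args=(table, tau_i, tau_j),
        method="bounded",
        options={"xatol": 1e-8},
    )
    rho = float(res.x)
    return rho, bool(abs(rho) >= _RHO_BOUND - 1e-6)


def _pair_cell_quantities(tau_i: np.ndarray, tau_j: np.ndarray, rho: float):
    """Model cell probabilities and their derivatives w.r.t. rho and thresholds."""
    Ki, Kj = tau_i.size + 1, tau_j.size + 1
    a = np.concatenate([[-np.inf], tau_i, [np.inf]])
    b = np.concatenate([[-np.inf], tau_j, [np.inf]])
    probs = np.maximum(rectangle_probs(tau_i, tau_j, rho), _PROB_FLOOR)
    # d pi / d rho: the bivariate density at the four cell corners
    dens = np.zeros((Ki + 1, Kj + 1))
    dens[1:-1, 1:-1] = bvn_pdf(tau_i[:, None], tau_j[None, :], rho)
    dpi_drho = np.diff(np.diff(dens, axis=0), axis=1)
    s = np.sqrt(1.0 - rho * rho)
    # d pi / d tau_i[a']: phi(tau) * [conditional Phi differences]; the
    # threshold tau_i[a'] borders cells (a', b) [+] and (a'+1, b) [-]
    dpi_dti = np.zeros((Ki - 1, Ki, Kj))
    phi_i = np.exp(-0.5 * tau_i**2) / np.sqrt(2 * np.pi)
    cond_j = ndtr((b[None, :] - rho * tau_i[:, None]) / s)  # (Ki-1, Kj+1)
    edge_i = phi_i[:, None] * np.diff(cond_j, axis=1)  # (Ki-1, Kj)
    for t in range(Ki - 1):
        dpi_dti[t, t, :] = edge_i[t]
        dpi_dti[t, t + 1, :] = -edge_i[t]
    dpi_dtj = np.zeros((Kj - 1, Ki, Kj))
    phi_j = np.exp(-0.5 * tau_j**2) / np.sqrt(2 * np.pi)
    cond_i = ndtr((a[None, :] - rho * tau_j[:, None]) / s)  # (Kj-1, Ki+1)
    edge_j = phi_j[:, None] * np.diff(cond_i, axis=1)  # (Kj-1, Ki)
    for t in range(Kj - 1):
        dpi_dtj[t, :, t] = edge_j[t]
        dpi_dtj[t, :, t + 1] = -edge_j[t]
    return probs, dpi_drho, dpi_dti, dpi_dtj


def _pair_influence(
    tau_i: np.ndarray, tau_j: np.ndarray, rho: float
) -> np.ndarray:
    """Per-cell influence values of the two-step correlation estimate.

    Element (a, b) is the influence an observation falling in cell (a, b)
    exerts on sqrt(N)(rho_hat - rho); the propagated threshold influence uses
    the closed-form influence of normal quantiles of cumulative proportions.
    """
    probs, dpi_drho, dpi_dti, dpi_dtj = _pair_cell_quantities(tau_i, tau_j, rho)
    score_rho = dpi_drho / probs
    info_rho = float((dpi_drho**2 / probs).sum())
    g = score_rho.copy()
    Ki, Kj = probs.shape
    # threshold influence: delta_t(category c) = (1{c <= t} - Phi(tau_t)) / phi(tau_t)
    for tau, dpi, axis in ((tau_i, dpi_dti, 0), (tau_j, dpi_dtj, 1)):
        K = tau.size + 1
        phi = np.exp(-0.5 * tau**2) / np.sqrt(2 * np.pi)
        cdf = ndtr(tau)
        for t in range(K - 1):
            info_cross = float((dpi_drho * dpi[t] / probs).sum())
            delta = ((np.arange(1, K + 1) <= t + 1).astype(float) - cdf[t]) / phi[t]
            if axis == 0:
                g -= info_cross * delta[:, None]
            else:
                g -= info_cross * delta[None, :]
    return g / info_rho


def estimate_polychorics(data: OrdinalDataset) -> PolychoricSummary:
    """Thresholds, pairwise correlations and their asymptotic covariance."""
    values = data.values
    n, p = values.shape
    K = data.n_options
    taus = []
    for j in range(p):
        tau, _ = _column_thresholds(values[:, j], K)
        taus.append(tau)
    pairs = pair_order(p)
    rho = np.eye(p)
    boundary = []
    influence = np.empty((n, len(pairs)))
    for idx, (i, j) in enumerate(pairs):
        table = np.zeros((K, K))
        np.add.at(table, (values[:, i] - 1, values[:, j] - 1), 1.0)
        r, at_bound = polychoric_pair(table, taus[i], taus[j])
        rho[i, j] = rho[j, i] = r
        boundary.append(at_bound)
        cell_infl = _pair_influence(taus[i], taus[j], r)
        influence[:, idx] = cell_infl[values[:, i] - 1, values[:, j] - 1]
    influence -= influence.mean(axis=0, keepdims=True)
    gamma = influence.T @ influence / n
    return PolychoricSummary(
        thresholds=tuple(taus),
        rho_matrix=rho,
        gamma=gamma,
        n=n,
        boundary=tuple(boundary),
    )
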