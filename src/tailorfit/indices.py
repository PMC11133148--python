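"""Goodness-of-fit indices: chi-square ratio, CFI, RMSEA, SRMR.

All five indices are computed from the estimator-reported test statistic
(robustified for MLR, mean-and-variance adjusted for WLSMV, applied to the
target and the independence baseline alike) and from the sample/implied
moment matrices for SRMR.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

__all__ = ["GofRecord", "compute_cfi", "compute_rmsea", "compute_srmr", "gof_record"]


def compute_cfi(T: float, df: float, T_b: float, df_b: float) -> float:
    """Comparative fit index with the standard non-negativity guards."""
    if min(T, T_b) < 0 or df < 0 or df_b < df:
        raise ValueError("need T, T_b >= 0 and df_b >= df >= 0")
    num = max(T - df, 0.0)
    den = max(T_b - df_b, T - df, 0.0)
    if den == 0.0:
        return 1.0
    return 1.0 - num / den


def compute_rmsea(T: float, df: float, n: int) -> float:
    """Root mean square error of approximation; NaN when df = 0."""
    if df <= 0:
        return float("nan")
    if n <= 1:
        raise ValueError("need n > 1")
    return float(np.sqrt(max(T - df, 0.0) / (df * n)))


def compute_srmr(
    sample_matrix: np.ndarray,
    implied_matrix: np.ndarray,
    scale: np.ndarray | None = None,
) -> float:
    """Standardized root mean square residual over the lower triangle.

    The mean includes the p(p+1)/2 diagonal elements; for correlation-matrix
    inputs (categorical fits) the diagonal residuals are zero by construction.
    ``scale`` supplies the standardizing SDs; by default the square roots of
    the sample diagonal.
    """
    S = np.asarray(sample_matrix, dtype=float)
    Sig = np.asarray(implied_matrix, dtype=float)
    if S.shape != Sig.shape or S.shape[0] != S.shape[1]:
        raise ValueError("matrices must be square and conformable")
    if scale is None:
        scale = np.sqrt(np.diag(S))
    if np.any(scale <= 0):
        raise ValueError("zero or negative standardizing SD")
    resid = (S - Sig) / np.outer(scale, scale)
    rows, cols = np.tril_indices(S.shape[0])
    return float(np.sqrt(np.mean(resid[rows, cols] ** 2)))


@dataclass(frozen=True)
class GofRecord:
    """The five indices for one replication of one scenario."""

    chi2: float
    chi2_df: float
    cfi: float
    rmsea: float
    srmr: float
    df: int
    estimator: str
    scenario_id: str = ""
    replication: int = 0
    converged: bool = True
    scaling_factor: float = 1.0
    factor_corr_est: float = float("nan")
    resampled: int = 0

    def to_dict(self) -> dict:
        return asdict(self)


def gof_record(
    fit,
    baseline=None,
    n: int | None = None,
    *,
    scenario_id: str = "",
    replication: int = 0,
    resampled: int = 0,
) -> GofRecord:
    """Assemble a :class:`GofRecord` from a target fit and its baseline.

    ``fit``/``baseline`` are :class:`~tailorfit.model.CFAResults`-like objects;
    the baseline defaults to the one attached to the fit.
    """
    if baseline is None:
        baseline = fit.baseline
    if baseline is None:
        raise ValueError("a baseline (independence) fit is required for CFI")
    if n is None:
        n = fit.nobs
    if fit.estimator != baseline.estimator:
        raise ValueError("target and baseline must use the same estimator")
    T, df = fit.statistic, fit.df
    fc = fit.factor_correlation
    return GofRecord(
        chi2=T,
        chi2_df=T / df if df > 0 else float("nan"),
        cfi=compute_cfi(T, df, baseline.statistic, baseline.df) if fit.converged else float("nan"),
        rmsea=compute_rmsea(T, df, n),
        srmr=compute_srmr(fit.sample_matrix, fit.implied_matrix),
        df=df,
        estimator=fit.estimator,
        scenario_id=scenario_id,
        replication=replication,
        converged=fit.converged,
        scaling_factor=fit.scaling_factor,
        factor_corr_est=float("nan") if fc is None else fc,
        resampled=resampled,
    )
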