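"""Confirmatory factor analysis under ML, MLR, DWLS and WLSMV.

The fitted structures are one- or two-factor measurement models without
cross-loadings, identified by fixing the first loading of each factor to
unity.  ML treats the ordinal codes as numeric and minimizes the normal-theory
discrepancy on the sample covariance matrix; MLR rescales the ML test
statistic with the Satorra–Bentler/Yuan–Bentler correction built from the
fourth-moment (asymptotically distribution-free) covariance of the sample
covariances.  DWLS fits the polychoric correlation vector by diagonally
weighted least squares under the theta parameterization (latent-response
residual variances fixed at one, the implied matrix rescaled to a
correlation matrix); WLSMV applies the mean-and-variance-adjusted
(scaled-and-shifted) correction to the DWLS statistic using the full
asymptotic covariance of the polychorics.

Usage follows the Model/Results convention::

    model = CFAModel(dataset, n_factors=1)
    res = model.fit(estimator="WLSMV")
    res.cfi, res.rmsea, res.summary()
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import least_squares, minimize

from . import indices as _indices
from .design import Scenario
from .polychoric import PolychoricSummary, estimate_polychorics, pair_order
from .population import OrdinalDataset

__all__ = ["ModelSpec", "CFAModel", "CFAResults"]

Estimator = Literal["ML", "MLR", "DWLS", "WLSMV"]
_CATEGORICAL = ("DWLS", "WLSMV")


# ---------------------------------------------------------------------------
# analysis model specification


@dataclass(frozen=True)
class ModelSpec:
    """Structure of the fitted model: factor membership and correlation mode.

    Analysis models never contain cross-loadings; misfit in the simulation
    arises purely from their omission.  ``correlation_mode`` is ``absent``
    for one factor, otherwise ``estimated`` or ``fixed_zero``.
    """

    n_factors: int
    assignment: tuple[int, ...]
    correlation_mode: Literal["estimated", "fixed_zero", "absent"] = "absent"

    def __post_init__(self) -> None:
        if self.n_factors not in (1, 2):
            raise ValueError("only one- and two-factor analysis models are supported")
        if set(self.assignment) != set(range(self.n_factors)):
            raise ValueError("every factor needs at least one indicator")
        if (self.correlation_mode == "absent") != (self.n_factors == 1):
            raise ValueError("correlation_mode is 'absent' iff the model has one factor")
        counts = np.bincount(self.assignment, minlength=self.n_factors)
        if counts.min() < 3:
            raise ValueError("each factor needs at least three indicators")

    @property
    def n_indicators(self) -> int:
        return len(self.assignment)

    @classmethod
    def one_factor(cls, p: int) -> "ModelSpec":
        return cls(1, tuple([0] * p), "absent")

    @classmethod
    def two_factor(cls, p: int, correlated: bool = True) -> "ModelSpec":
        half = p // 2
        assignment = tuple([0] * half + [1] * (p - half))
        return cls(2, assignment, "estimated" if correlated else "fixed_zero")

    @classmethod
    def for_scenario(cls, s: Scenario) -> "ModelSpec":
        """The analysis model the design prescribes for a cell."""
        if s.n_analysis_factors == 1:
            return cls.one_factor(s.n_indicators)
        return cls.two_factor(s.n_indicators, correlated=s.correlation_estimated)

    # indices of the first indicator of each factor (loading fixed to 1)
    @property
    def fixed_indicators(self) -> tuple[int, ...]:
        first = []
        for f in range(self.n_factors):
            first.append(int(np.argmax(np.asarray(self.assignment) == f)))
        return tuple(first)

    @property
    def free_loading_indicators(self) -> tuple[int, ...]:
        fixed = set(self.fixed_indicators)
        return tuple(j for j in range(self.n_indicators) if j not in fixed)


# ---------------------------------------------------------------------------
# parameter bookkeeping

_EPS_VAR = 1e-6


class _Parameterization:
    """Mapping between the internal optimizer vector and raw parameters.

    Internal coordinates: free loadings (raw), log factor variances, an
    atanh-scale factor correlation (guaranteeing |r| < 1), and — for ML —
    log residual variances.  Raw parameters: loadings, factor (co)variances,
    residual variances.
    """

    def __init__(self, spec: ModelSpec, with_residuals: bool):
        self.spec = spec
        self.with_residuals = with_residuals
        self.p = spec.n_indicators
        self.m = spec.n_factors
        self.n_load = len(spec.free_loading_indicators)
        self.has_corr = spec.correlation_mode == "estimated"
        self.n_internal = (
            self.n_load + self.m + int(self.has_corr) + (self.p if with_residuals else 0)
        )

    def split(self, u: np.ndarray):
        i = self.n_load
        load = u[:i]
        psi = np.exp(np.clip(u[i : i + self.m], -30, 30))
        i += self.m
        if self.has_corr:
            z = u[i]
            i += 1
            r = np.tanh(z)
        else:
            z, r = None, 0.0
        resid = np.exp(np.clip(u[i:], -30, 30)) if self.with_residuals else None
        return load, psi, z, r, resid

    def matrices(self, u: np.ndarray):
        load, psi, z, r, resid = self.split(u)
        lam = np.zeros((self.p, self.m))
        for j, f in zip(self.spec.fixed_indicators, range(self.m)):
            lam[j, f] = 1.0
        assign = np.asarray(self.spec.assignment)
        for val, j in zip(load, self.spec.free_loading_indicators):
            lam[j, assign[j]] = val
        phi = np.diag(psi)
        if self.m == 2:
            cov = r * np.sqrt(psi[0] * psi[1])
            phi[0, 1] = phi[1, 0] = cov
        return lam, phi, resid

    def raw_derivative_matrices(self, u: np.ndarray) -> list[np.ndarray]:
        """dSigma*/d(raw param) for loadings, psi_f, psi_12, residuals.

        Sigma* = Lam Phi Lam' (+ diag(resid) added by the caller).  The raw
        order is: free loadings, factor variances, factor covariance (if
        estimated), residual variances (if present).
        """
        lam, phi, resid = self.matrices(u)
        lp = lam @ phi  # p x m
        mats = []
        assign = np.asarray(self.spec.assignment)
        for j in self.spec.free_loading_indicators:
            f = assign[j]
            d = np.zeros((self.p, self.p))
            d[j, :] += lp[:, f]
            d[:, j] += lp[:, f]
            mats.append(d)
        for f in range(self.m):
            col = lam[:, f]
            mats.append(np.outer(col, col))
        if self.has_corr:
            d = np.outer(lam[:, 0], lam[:, 1])
            mats.append(d + d.T)
        if self.with_residuals:
            for j in range(self.p):
                d = np.zeros((self.p, self.p))
                d[j, j] = 1.0
                mats.append(d)
        return mats

    def chain(self, u: np.ndarray, grad_raw: np.ndarray) -> np.ndarray:
        """Pull a raw-parameter gradient back to the internal coordinates."""
        load, psi, z, r, resid = self.split(u)
        g = np.zeros(self.n_internal)
        i = self.n_load
        g[:i] = grad_raw[: self.n_load]
        k = self.n_load
        # factor variances (log scale); the factor covariance depends on them
        if self.has_corr:
            cov = r * np.sqrt(psi[0] * psi[1])
            g_cov = grad_raw[k + self.m]
        for f in range(self.m):
            g[i + f] = grad_raw[k + f] * psi[f]
            if self.has_corr:
                g[i + f] += 0.5 * cov * g_cov
        i += self.m
        if self.has_corr:
            g[i] = (1.0 - r * r) * np.sqrt(psi[0] * psi[1]) * g_cov
            i += 1
        if self.with_residuals:
            n_head = self.n_load + self.m + int(self.has_corr)
            g[i:] = grad_raw[n_head:] * resid
        return g

    def start(self, sample: np.ndarray) -> np.ndarray:
        """Moment-informed starting point on the internal scale."""
        assign = np.asarray(self.spec.assignment)
        u = []
        u.extend([0.5] * self.n_load)
        psis = []
        for f in range(self.m):
            idx = np.where(assign == f)[0]
            off = sample[np.ix_(idx, idx)][np.triu_indices(idx.size, 1)]
            psis.append(float(np.clip(np.mean(off), 0.05, 2.0)))
        u.extend(np.log(psis))
        if self.has_corr:
            u.append(0.0)
        if self.with_residuals:
            u.extend(np.log(np.clip(0.5 * np.diag(sample), 0.05, None)))
        return np.asarray(u)


# ---------------------------------------------------------------------------
# results


@dataclass
class CFAResults:
    """Estimates, test statistic and fit indices for one fitted CFA.

    ``statistic`` is the estimator-reported chi-square statistic (robustified
    for MLR, mean-and-variance adjusted for WLSMV); ``statistic_unscaled``
    the uncorrected one.  ``baseline`` holds the matching independence-model
    fit used by the comparative fit index.
    """

    model: "CFAModel"
    estimator: str
    spec: ModelSpec
    converged: bool
    loadings: np.ndarray
    factor_cov: np.ndarray
    residual_variances: np.ndarray | None
    statistic: float
    statistic_unscaled: float
    df: int
    scaling_factor: float
    shift: float
    implied_matrix: np.ndarray
    sample_matrix: np.ndarray
    nobs: int
    baseline: "CFAResults | None" = None
    heywood: bool = False
    extras: dict = field(default_factory=dict)

    # -- derived quantities -------------------------------------------------
    @property
    def factor_correlation(self) -> float | None:
        if self.spec.n_factors != 2:
            return None
        psi = np.diag(self.factor_cov)
        return float(self.factor_cov[0, 1] / np.sqrt(psi[0] * psi[1]))

    @property
    def standardized_loadings(self) -> np.ndarray:
        sd_f = np.sqrt(np.diag(self.factor_cov))
        common = np.diag(self.loadings @ self.factor_cov @ self.loadings.T)
        if self.residual_variances is not None:
            var_y = common + self.residual_variances
        else:
            var_y = common + 1.0  # theta parameterization: unit latent residuals
        return self.loadings * sd_f[None, :] / np.sqrt(var_y)[:, None]

    @property
    def chi2(self) -> float:
        return self.statistic

    @property
    def chi2_df(self) -> float:
        return self.statistic / self.df if self.df > 0 else np.nan

    @property
    def cfi(self) -> float:
        if self.baseline is None:
            raise ValueError("no baseline fit attached")
        return _indices.compute_cfi(
            self.statistic, self.df, self.baseline.statistic, self.baseline.df
        )

    @property
    def rmsea(self) -> float:
        return _indices.compute_rmsea(self.statistic, self.df, self.nobs)

    @property
    def srmr(self) -> float:
        return _indices.compute_srmr(self.sample_matrix, self.implied_matrix)

    @property
    def params(self) -> pd.Series:
        entries = {}
        assign = np.asarray(self.spec.assignment)
        for j in range(self.spec.n_indicators):
            f = assign[j]
            entries[f"lambda_{j + 1}_F{f + 1}"] = self.loadings[j, f]
        for f in range(self.spec.n_factors):
            entries[f"psi_F{f + 1}"] = self.factor_cov[f, f]
        if self.spec.n_factors == 2:
            entries["psi_F1F2"] = self.factor_cov[0, 1]
        if self.residual_variances is not None:
            for j, v in enumerate(self.residual_variances):
                entries[f"theta_{j + 1}"] = v
        return pd.Series(entries)

    def summary(self) -> str:
        lines = [
            "Confirmatory factor analysis",
            f"  estimator: {self.estimator}   n = {self.nobs}   converged: {self.converged}",
            f"  chi2({self.df}) = {self.statistic:.3f}"
            + (
                f"   (unscaled {self.statistic_unscaled:.3f}, "
                f"scaling {self.scaling_factor:.3f}, shift {self.shift:.3f})"
                if self.estimator in ("MLR", "WLSMV")
                else ""
            ),
        ]
        if self.baseline is not None and self.df > 0:
            lines.append(
                f"  chi2/df = {self.chi2_df:.3f}   CFI = {self.cfi:.3f}   "
                f"RMSEA = {self.rmsea:.3f}   SRMR = {self.srmr:.3f}"
            )
        lines.append("  parameter estimates:")
        for name, value in self.params.items():
            lines.append(f"    {name:>14s} = {value: .4f}")
        if self.spec.n_factors == 2:
            lines.append(f"  standardized factor correlation = {self.factor_correlation:.4f}")
        if self.heywood:
            lines.append("  note: residual variance at the admissibility bound (Heywood)")
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "estimator": self.estimator,
            "converged": self.converged,
            "statistic": self.statistic,
            "statistic_unscaled": self.statistic_unscaled,
            "df": self.df,
            "scaling_factor": self.scaling_factor,
            "shift": self.shift,
            "params": self.params.to_dict(),
            "heywood": self.heywood,
        }


# ---------------------------------------------------------------------------
# vech helpers (ML robustification)


def _vech(mat: np.ndarray) -> np.ndarray:
    return mat[np.tril_indices(mat.shape[0])]


def _duplication(p: int) -> np.ndarray:
    rows, cols = np.tril_indices(p)
    D = np.zeros((p * p, rows.size))
    for m, (i, j) in enumerate(zip(rows, cols)):
        D[j * p + i, m] = 1.0
        D[i * p + j, m] = 1.0
    return D


def _adf_gamma(values: np.ndarray) -> np.ndarray:
    """Fourth-moment asymptotic covariance of sqrt(N) vech(S), divisor N."""
    z = values - values.mean(axis=0, keepdims=True)
    n, p = z.shape
    rows, cols = np.tril_indices(p)
    d = z[:, rows] * z[:, cols]
    d -= d.mean(axis=0, keepdims=True)
    return d.T @ d / n


# ---------------------------------------------------------------------------
# the model


class CFAModel:
    """A CFA measurement model attached to one ordinal dataset.

    Parameters
    ----------
    data
        An :class:`OrdinalDataset`, a DataFrame or an integer array of
        category codes 1..K (rows = observations).
    n_factors
        One or two; with two factors the indicators split into contiguous
        halves unless ``assignment`` says otherwise.
    correlated_factors
        Whether a two-factor model frees the inter-factor covariance.
    """

    def __init__(
        self,
        data: OrdinalDataset | pd.DataFrame | np.ndarray,
        n_factors: int = 1,
        *,
        assignment: Sequence[int] | None = None,
        correlated_factors: bool = True,
        spec: ModelSpec | None = None,
    ):
        if isinstance(data, OrdinalDataset):
            self.data = data
        elif isinstance(data, pd.DataFrame):
            self.data = OrdinalDataset.from_frame(data)
        else:
            self.data = OrdinalDataset.from_frame(pd.DataFrame(np.asarray(data)))
        p = self.data.n_indicators
        if spec is not None:
            self.spec = spec
        elif assignment is not None:
            mode = "absent" if n_factors == 1 else ("estimated" if correlated_factors else "fixed_zero")
            self.spec = ModelSpec(n_factors, tuple(assignment), mode)
        elif n_factors == 1:
            self.spec = ModelSpec.one_factor(p)
        else:
            self.spec = ModelSpec.two_factor(p, correlated=correlated_factors)
        if self.spec.n_indicators != p:
            raise ValueError("model specification does not match the data width")
        self._polychorics: PolychoricSummary | None = None

    @classmethod
    def from_dataframe(cls, frame: pd.DataFrame, n_factors: int = 1, **kwargs) -> "CFAModel":
        return cls(frame, n_factors=n_factors, **kwargs)

    @classmethod
    def from_scenario(cls, scenario: Scenario, data: OrdinalDataset) -> "CFAModel":
        return cls(data, spec=ModelSpec.for_scenario(scenario))

    # -- public API ---------------------------------------------------------
    def fit(self, estimator: Estimator = "ML", *, include_baseline: bool = True) -> CFAResults:
        if estimator in ("ML", "MLR"):
            res = self._fit_ml(robust=(estimator == "MLR"), include_baseline=include_baseline)
        elif estimator in _CATEGORICAL:
            res = self._fit_categorical(
                adjusted=(estimator == "WLSMV"), include_baseline=include_baseline
            )
        else:
            raise ValueError(f"unknown estimator: {estimator!r}")
        return res

    @property
    def polychorics(self) -> PolychoricSummary:
        if self._polychorics is None:
            self._polychorics = estimate_polychorics(self.data)
        return self._polychorics

    # -- maximum likelihood -------------------------------------------------
    def _sample_cov(self) -> np.ndarray:
        z = self.data.values - self.data.values.mean(axis=0, keepdims=True)
        return z.T @ z / self.data.n  # divisor N, matching T = N * F

    def _fit_ml(self, robust: bool, include_baseline: bool) -> CFAResults:
        spec = self.spec
        S = self._sample_cov()
        n, p = self.data.n, spec.n_indicators
        sign, logdet_S = np.linalg.slogdet(S)
        if sign <= 0:
            raise ValueError("singular sample covariance matrix")
        par = _Parameterization(spec, with_residuals=True)

        def sigma_of(u):
            lam, phi, resid = par.matrices(u)
            sigma = lam @ phi @ lam.T
            sigma[np.diag_indices(p)] += resid
            return sigma, lam, phi, resid

        def objective(u):
            sigma, *_ = sigma_of(u)
            sign_m, logdet = np.linalg.slogdet(sigma)
            if sign_m <= 0:
                return 1e10, np.zeros_like(u)
            sigma_inv = np.linalg.inv(sigma)
            f = logdet + float(np.sum(sigma_inv * S)) - logdet_S - p
            A = sigma_inv - sigma_inv @ S @ sigma_inv
            grad_raw = np.array(
                [float(np.sum(A * dm)) for dm in par.raw_derivative_matrices(u)]
            )
            return f, par.chain(u, grad_raw)

        best = None
        starts = [self._spec_start(par), par.start(S)]
        for u0 in starts:
            res = minimize(objective, u0, jac=True, method="L-BFGS-B",
                           options={"maxiter": 500, "gtol": 1e-8, "ftol": 1e-12})
            if best is None or (res.fun < best.fun):
                best = res
            if best.success and best.fun < 1e9:
                break
        assert best is not None
        grad_norm = float(np.max(np.abs(best.jac)))
        converged = bool(best.fun < 1e9 and (best.success or grad_norm < 1e-4))
        u_hat = best.x
        sigma_hat, lam, phi, resid = sigma_of(u_hat)
        f_min = max(float(best.fun), 0.0)
        T = n * f_min
        q = par.n_internal
        df = p * (p + 1) // 2 - q
        scaling, shift, T_rep = 1.0, 0.0, T
        extras = {}
        if robust and converged:
            if df == 0:
                warnings.warn("df = 0: the robust scaling factor is undefined; "
                              "returning the unscaled statistic")
            else:
                gamma = _adf_gamma(self.data.values.astype(float))
                delta = self._delta_vech(par, u_hat)
                scaling = _sb_scaling(sigma_hat, gamma, delta, df)
                T_rep = T / scaling
                extras["gamma_trace"] = float(np.trace(gamma))
        res = CFAResults(
            model=self,
            estimator="MLR" if robust else "ML",
            spec=spec,
            converged=converged,
            loadings=lam,
            factor_cov=phi,
            residual_variances=resid,
            statistic=T_rep,
            statistic_unscaled=T,
            df=df,
            scaling_factor=scaling,
            shift=shift,
            implied_matrix=sigma_hat,
            sample_matrix=S,
            nobs=n,
            heywood=bool(resid is not None and np.min(resid) < 1e-3),
            extras=extras,
        )
        if include_baseline:
            res.baseline = self._baseline_ml(robust=robust)
        return res

    def _spec_start(self, par: _Parameterization) -> np.ndarray:
        """Documented default starts: loadings .5, variances 1, correlation 0."""
        u = np.zeros(par.n_internal)
        u[: par.n_load] = 0.5
        return u

    def _delta_vech(self, par: _Parameterization, u: np.ndarray) -> np.ndarray:
        rows = [_vech(dm) for dm in par.raw_derivative_matrices(u)]
        return np.column_stack(rows)

    def _baseline_ml(self, robust: bool) -> CFAResults:
        """Independence model: free variances, all covariances zero."""
        S = self._sample_cov()
        n, p = self.data.n, self.spec.n_indicators
        sd = np.sqrt(np.diag(S))
        R = S / np.outer(sd, sd)
        sign, logdet_R = np.linalg.slogdet(R)
        T = -n * logdet_R
        df = p * (p - 1) // 2
        sigma_b = np.diag(np.diag(S))
        scaling, T_rep = 1.0, T
        if robust:
            gamma = _adf_gamma(self.data.values.astype(float))
            delta = np.zeros((p * (p + 1) // 2, p))
            rows, cols = np.tril_indices(p)
            for j in range(p):
                delta[(rows == j) & (cols == j), j] = 1.0
            scaling = _sb_scaling(sigma_b, gamma, delta, df)
            T_rep = T / scaling
        return CFAResults(
            model=self,
            estimator="MLR" if robust else "ML",
            spec=self.spec,
            converged=True,
            loadings=np.zeros((p, self.spec.n_factors)),
            factor_cov=np.eye(self.spec.n_factors),
            residual_variances=np.diag(S),
            statistic=T_rep,
            statistic_unscaled=T,
            df=df,
            scaling_factor=scaling,
            shift=0.0,
            implied_matrix=sigma_b,
            sample_matrix=S,
            nobs=n,
        )

    # -- categorical (DWLS / WLSMV) -----------------------------------------
    def _fit_categorical(self, adjusted: bool, include_baseline: bool) -> CFAResults:
        spec = self.spec
        poly = self.polychorics
        n, p = self.data.n, spec.n_indicators
        s = poly.correlations
        w = np.diag(poly.gamma).copy()
        if np.any(w <= 0):
            raise ValueError("non-positive diagonal in the polychoric asymptotic covariance")
        sqrt_w = np.sqrt(w)
        pairs = pair_order(p)
        par = _Parameterization(spec, with_residuals=False)

        def implied(u):
            lam, phi, _ = par.matrices(u)
            sigma_star = lam @ phi @ lam.T + np.eye(p)  # theta parameterization
            d = np.sqrt(np.diag(sigma_star))
            corr = sigma_star / np.outer(d, d)
            return corr, sigma_star, lam, phi

        def corr_vec(u):
            corr, *_ = implied(u)
            return np.array([corr[i, j] for i, j in pairs])

        def residuals(u):
            return (s - corr_vec(u)) / sqrt_w

        def jac(u):
            return -self._delta_corr(par, u, pairs) / sqrt_w[:, None]

        best = None
        for u0 in (self._spec_start(par), par.start(poly.rho_matrix)):
            res = least_squares(residuals, u0, jac=jac, method="lm", xtol=1e-12, ftol=1e-12)
            if best is None or res.cost < best.cost:
                best = res
            if best.success:
                break
        assert best is not None
        converged = bool(best.success)
        u_hat = best.x
        corr_hat, sigma_star, lam, phi = implied(u_hat)
        F = float(2.0 * best.cost)  # sum of squared weighted residuals
        T = n * F
        q = par.n_internal
        df = p * (p - 1) // 2 - q
        scaling, shift, T_rep = 1.0, 0.0, T
        if adjusted and converged and df > 0:
            delta = self._delta_corr(par, u_hat, pairs)
            V = np.diag(1.0 / w)
            VD = V @ delta
            U = V - VD @ np.linalg.solve(delta.T @ VD, VD.T)
            M = U @ poly.gamma
            a = np.sqrt(df / float(np.trace(M @ M)))
            shift = df - a * float(np.trace(M))
            scaling = 1.0 / a
            T_rep = max(a * T + shift, 0.0)
        res = CFAResults(
            model=self,
            estimator="WLSMV" if adjusted else "DWLS",
            spec=spec,
            converged=converged,
            loadings=lam,
            factor_cov=phi,
            residual_variances=None,
            statistic=T_rep,
            statistic_unscaled=T,
            df=df,
            scaling_factor=scaling,
            shift=shift,
            implied_matrix=corr_hat,
            sample_matrix=poly.rho_matrix,
            nobs=n,
        )
        if include_baseline:
            res.baseline = self._baseline_categorical(adjusted=adjusted)
        return res

    def _delta_corr(self, par, u, pairs) -> np.ndarray:
        """Jacobian of the implied correlation vector w.r.t. internal params."""
        lam, phi, _ = par.matrices(u)
        p = par.p
        sigma_star = lam @ phi @ lam.T + np.eye(p)
        d2 = np.diag(sigma_star)
        d = np.sqrt(d2)
        corr = sigma_star / np.outer(d, d)
        raw_mats = par.raw_derivative_matrices(u)
        cols = []
        for dm in raw_mats:
            dcorr = dm / np.outer(d, d) - 0.5 * corr * (
                (np.diag(dm) / d2)[:, None] + (np.diag(dm) / d2)[None, :]
            )
            cols.append([dcorr[i, j] for i, j in pairs])
        raw_jac = np.array(cols).T  # n_pairs x n_raw
        # chain rule column-by-column via the same pull-back as gradients
        out = np.empty((raw_jac.shape[0], par.n_internal))
        for k in range(raw_jac.shape[0]):
            out[k] = par.chain(u, raw_jac[k])
        return out

    def _baseline_categorical(self, adjusted: bool) -> CFAResults:
        """Independence model on polychorics: all correlations zero."""
        poly = self.polychorics
        n, p = self.data.n, self.spec.n_indicators
        s = poly.correlations
        w = np.diag(poly.gamma)
        T = n * float(np.sum(s * s / w))
        df = p * (p - 1) // 2
        scaling, shift, T_rep = 1.0, 0.0, T
        if adjusted:
            M = np.diag(1.0 / w) @ poly.gamma
            a = np.sqrt(df / float(np.trace(M @ M)))
            shift = df - a * float(np.trace(M))
            scaling = 1.0 / a
            T_rep = max(a * T + shift, 0.0)
        return CFAResults(
            model=self,
            estimator="WLSMV" if adjusted else "DWLS",
            spec=self.spec,
            converged=True,
            loadings=np.zeros((p, self.spec.n_factors)),
            factor_cov=np.eye(self.spec.n_factors),
            residual_variances=None,
            statistic=T_rep,
            statistic_unscaled=T,
            df=df,
            scaling_factor=scaling,
            shift=shift,
            implied_matrix=np.eye(p),
            sample_matrix=poly.rho_matrix,
            nobs=n,
        )


def _sb_scaling(sigma_hat: np.ndarray, gamma: np.ndarray, delta: np.ndarray, df: int) -> float:
    """Satorra–Bentler scaling factor c = tr(U Gamma) / df for ML fits."""
    p = sigma_hat.shape[0]
    D = _duplication(p)
    sigma_inv = np.linalg.inv(sigma_hat)
    W = 0.5 * D.T @ np.kron(sigma_inv, sigma_inv) @ D
    WD = W @ delta
    U = W - WD @ np.linalg.solve(delta.T @ WD, WD.T)
    return float(np.trace(U @ gamma)) / df
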