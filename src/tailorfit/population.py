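"""Population models and ordinal data generation.

Population models are standardized: factors and continuous latent responses
have unit variance, so each indicator's residual variance is
``1 − (λ_F1² + λ_F2² + 2 λ_F1 λ_F2 Cov(F1,F2))``.  Continuous responses are
discretized by the moment-matched thresholds; a whole dataset is regenerated
(from a fresh random substream) whenever any response option of any indicator
is observed fewer than five times, since threshold estimation requires every
category to be populated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from .design import Scenario, scenario_id
from .thresholds import ThresholdSet

__all__ = [
    "PopulationModel",
    "OrdinalDataset",
    "build_population_model",
    "simulate_dataset",
]

MIN_CELL_COUNT = 5


@dataclass(frozen=True)
class PopulationModel:
    """Standardized loading matrix, factor correlation and residual variances."""

    loadings: np.ndarray  # (p, m) standardized loadings, cross-loadings included
    factor_correlation: float | None  # None for a single factor
    residual_variances: np.ndarray  # (p,) theta_eps, all > 0

    @property
    def n_indicators(self) -> int:
        return self.loadings.shape[0]

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    @property
    def factor_cov(self) -> np.ndarray:
        m = self.n_factors
        phi = np.eye(m)
        if m == 2 and self.factor_correlation is not None:
            phi[0, 1] = phi[1, 0] = self.factor_correlation
        return phi

    def correlation_matrix(self) -> np.ndarray:
        """Population correlation matrix of the continuous responses."""
        sigma = self.loadings @ self.factor_cov @ self.loadings.T
        sigma[np.diag_indices_from(sigma)] += self.residual_variances
        return sigma


def build_population_model(s: Scenario) -> PopulationModel:
    """Realize the scenario's topology: loadings, correlation, residuals."""
    p, lam = s.n_indicators, s.loading
    if s.n_population_factors == 1:
        loadings = np.full((p, 1), lam)
        r = None
    else:
        loadings = np.zeros((p, 2))
        half = p // 2
        loadings[:half, 0] = lam
        loadings[half:, 1] = lam
        r = s.factor_correlation
        # unmodeled cross-loadings: the first k indicators of factor 2
        # additionally load on factor 1
        k = s.n_cross_loadings
        if k:
            loadings[half : half + k, 0] = s.misspec_magnitude
    theta = implied_residual_variances(loadings, r)
    return PopulationModel(loadings=loadings, factor_correlation=r, residual_variances=theta)


def implied_residual_variances(
    loadings: np.ndarray, factor_correlation: float | None
) -> np.ndarray:
    """Residual variances forcing unit indicator variance; raises if <= 0."""
    loadings = np.atleast_2d(np.asarray(loadings, dtype=float))
    phi_r = 0.0 if factor_correlation is None else factor_correlation
    l1 = loadings[:, 0]
    l2 = loadings[:, 1] if loadings.shape[1] > 1 else np.zeros_like(l1)
    theta = 1.0 - (l1**2 + l2**2 + 2.0 * l1 * l2 * phi_r)
    if np.any(theta <= 0):
        bad = int(np.argmin(theta))
        raise ValueError(
            f"non-positive residual variance ({theta[bad]:.4f}) for indicator "
            f"{bad + 1}; loadings/correlation imply variance > 1"
        )
    return theta


@dataclass(frozen=True)
class OrdinalDataset:
    """N × p integer matrix of category codes 1..K plus provenance."""

    values: np.ndarray
    n_options: int
    provenance: dict[str, Any] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def n_indicators(self) -> int:
        return self.values.shape[1]

    @property
    def resample_count(self) -> int:
        return int(self.provenance.get("resamples", 0))

    def to_frame(self) -> pd.DataFrame:
        cols = [f"y{j + 1}" for j in range(self.n_indicators)]
        return pd.DataFrame(self.values, columns=cols)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, n_options: int | None = None) -> "OrdinalDataset":
        values = frame.to_numpy()
        if not np.issubdtype(values.dtype, np.integer):
            as_int = values.astype(int)
            if not np.array_equal(as_int, values):
                raise ValueError("ordinal data must be integer category codes")
            values = as_int
        if n_options is None:
            n_options = int(values.max())
        if values.min() < 1 or values.max() > n_options:
            raise ValueError("category codes must lie in 1..K")
        return cls(values=values, n_options=n_options)

    @classmethod
    def from_csv(cls, path, n_options: int | None = None) -> "OrdinalDataset":
        return cls.from_frame(pd.read_csv(path), n_options=n_options)


def _draw_continuous(model: PopulationModel, n: int, rng: np.random.Generator) -> np.ndarray:
    chol = np.linalg.cholesky(model.factor_cov)
    factors = rng.standard_normal((n, model.n_factors)) @ chol.T
    resid = rng.standard_normal((n, model.n_indicators)) * np.sqrt(model.residual_variances)
    return factors @ model.loadings.T + resid


def simulate_dataset(
    model: PopulationModel,
    thresholds: ThresholdSet,
    n: int,
    seed: int | np.random.SeedSequence | np.random.Generator,
    *,
    scenario: Scenario | None = None,
    max_resamples: int = 1000,
) -> OrdinalDataset:
    """Simulate one ordinal dataset, re-simulating until all cells have >= 5.

    The full dataset is regenerated from the next random substream on every
    failed attempt (the sparsity rule is a dataset-level acceptance rule, not
    a per-column patch), and the number of regenerations is recorded.
    """
    if isinstance(seed, np.random.Generator):
        rng = seed
    else:
        rng = np.random.default_rng(seed)
    tau = np.asarray(thresholds.thresholds)
    K = thresholds.n_options
    for attempt in range(max_resamples + 1):
        ystar = _draw_continuous(model, n, rng)
        codes = np.searchsorted(tau, ystar) + 1  # monotone: larger y* => larger code
        counts = np.stack([(codes == c).sum(axis=0) for c in range(1, K + 1)])
        if counts.min() >= MIN_CELL_COUNT:
            prov = {
                "resamples": attempt,
                "n": n,
            }
            if scenario is not None:
                prov["scenario_id"] = scenario_id(scenario)
            return OrdinalDataset(values=codes.astype(np.int64), n_options=K, provenance=prov)
    cat, col = np.unravel_index(np.argmin(counts), counts.shape)
    raise RuntimeError(
        f"exceeded {max_resamples} resampling attempts: category {cat + 1} of "
        f"indicator {col + 1} stays below {MIN_CELL_COUNT} observations at N={n}"
    )
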