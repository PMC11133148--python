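"""Descriptive and inferential analyses of GOF sensitivity and susceptibility.

*Sensitivity* is the (desired) response of a fit index to model
misspecification; *susceptibility* its (undesired) dependence on other data
and analysis characteristics.  Both are quantified by Kendall tau-b
associations and by per-index least-squares regressions on the
characteristics with quadratic terms (for characteristics with more than two
levels) and all two-way interactions.  Before regression, chi-square,
chi-square/df, RMSEA and SRMR are multiplied by −1 so that for every index a
lower value means worse fit.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cutoffs import GOF_NAMES
from .engine import SimulationResult

__all__ = [
    "SusceptibilitySummary",
    "kendall_tau_b",
    "susceptibility_regression",
    "median_profiles",
    "recode_gofs",
]

#: indices recoded by −1 so that lower always means worse fit
_NEGATED = ("chi2", "chi2_df", "rmsea", "srmr")


def kendall_tau_b(x, y) -> float:
    """Kendall rank correlation with tie correction in both margins.

    Returns NaN when either margin is entirely tied (tau-b undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need two equal-length vectors of length >= 2")
    if np.unique(x).size < 2 or np.unique(y).size < 2:
        return float("nan")
    return float(stats.kendalltau(x, y, variant="b").statistic)


def recode_gofs(records: pd.DataFrame) -> pd.DataFrame:
    """Multiply chi2, chi2/df, RMSEA and SRMR by −1 (lower = worse for all)."""
    out = records.copy()
    for gof in _NEGATED:
        out[gof] = -out[gof]
    return out


@dataclass(frozen=True)
class SusceptibilitySummary:
    """Tau-b matrix, per-GOF regression coefficients/R², or grouped medians."""

    tau_b: pd.DataFrame | None = None
    regression: pd.DataFrame | None = None
    r_squared: pd.Series | None = None
    median_profiles: pd.DataFrame | None = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# characteristic coding


def _characteristics(records: pd.DataFrame) -> pd.DataFrame:
    """Numeric characteristic columns with the reference levels of the study.

    ML, symmetric and uncorrelated are reference categories; sample size is
    divided by 1000 to keep coefficients comparable with the cutoff
    regression convention.
    """
    X = pd.DataFrame(index=records.index)
    present = set(records["estimator"])
    if len(present) < 2:
        raise ValueError("characteristic 'estimator' has fewer than two levels")
    for est in ("MLR", "DWLS", "WLSMV"):
        if est in present:
            X[est.lower()] = (records["estimator"] == est).astype(float)
    X["indicators"] = records["n_indicators"].astype(float)
    X["options"] = records["n_options"].astype(float)
    X["asymmetric"] = (records["distribution"] == "asymmetric").astype(float)
    X["loading"] = records["loading"].astype(float)
    X["n"] = records["sample_size"].astype(float) / 1000.0
    family = records["family"].iloc[0]
    if family == "dim_misspec":
        # misspecification magnitude = parameter difference 1 − r
        X["misspec_magnitude"] = 1.0 - records["factor_correlation"].astype(float)
    elif family.startswith("cross"):
        X["correlated"] = (records["factor_correlation"] > 0).astype(float)
        if family == "cross_misspec":
            X["misspec_magnitude"] = records["misspec_magnitude"].astype(float)
            X["misspec_proportion"] = records["misspec_proportion"].astype(float)
    return X


def _design_with_interactions(X: pd.DataFrame) -> pd.DataFrame:
    """Linear terms, quadratics for >2-level characteristics, 2-way products.

    The estimator dummies form one categorical characteristic: their mutual
    products are structurally zero and are not included, and no higher-order
    interactions enter.
    """
    quads = {}
    for col in X.columns:
        if X[col].nunique() > 2:
            quads[col + "2"] = X[col] ** 2
    full = pd.concat([X, pd.DataFrame(quads, index=X.index)], axis=1)
    est_cols = {"mlr", "dwls", "wlsmv"}
    char_of = {c: ("estimator" if c.rstrip("2") in est_cols else c.rstrip("2"))
               for c in full.columns}
    inter = {}
    cols = list(full.columns)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            if char_of[a] == char_of[b]:
                continue  # same characteristic: no self-interactions
            inter[f"{a}:{b}"] = full[a] * full[b]
    out = pd.concat([full, pd.DataFrame(inter, index=X.index)], axis=1)
    out.insert(0, "intercept", 1.0)
    return out


def susceptibility_regression(
    result: SimulationResult, family_subset: str
) -> SusceptibilitySummary:
    """Per-GOF least squares on characteristics, quadratics and interactions.

    ``family_subset`` selects one scenario family; recoded indices are the
    responses.  Raises on an aliased design, naming the offending terms.
    """
    records = result.converged_records()
    records = records[records["family"] == family_subset]
    if records.empty:
        raise ValueError(f"no converged records in family {family_subset!r}")
    X_chars = _characteristics(records)
    constant = [c for c in X_chars.columns if X_chars[c].nunique() < 2]
    if constant:
        warnings.warn(
            f"characteristics held constant in these records are excluded: {constant}"
        )
        X_chars = X_chars.drop(columns=constant)
    if X_chars.empty:
        raise ValueError("no characteristic varies across the records")
    recoded = recode_gofs(records)
    design = _design_with_interactions(X_chars)
    Xmat = design.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(Xmat)
    if rank < Xmat.shape[1]:
        aliased = _aliased(Xmat, list(design.columns))
        raise ValueError(f"aliased design; drop terms: {aliased}")
    coef = pd.DataFrame(index=design.columns, columns=list(GOF_NAMES), dtype=float)
    r2 = pd.Series(index=pd.Index(GOF_NAMES), dtype=float)
    tau = pd.DataFrame(index=X_chars.columns, columns=list(GOF_NAMES), dtype=float)
    for gof in GOF_NAMES:
        y = recoded[gof].to_numpy(dtype=float)
        ok = np.isfinite(y)
        beta, *_ = np.linalg.lstsq(Xmat[ok], y[ok], rcond=None)
        coef[gof] = beta
        resid = y[ok] - Xmat[ok] @ beta
        ss_tot = float(np.sum((y[ok] - y[ok].mean()) ** 2))
        r2[gof] = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else np.nan
        for char in X_chars.columns:
            xv = X_chars[char].to_numpy(dtype=float)[ok]
            tau.loc[char, gof] = kendall_tau_b(xv, y[ok]) if ok.sum() >= 2 else np.nan
    return SusceptibilitySummary(
        tau_b=tau, regression=coef, r_squared=r2,
        meta={"family": family_subset, "n_records": int(len(records))},
    )


def _aliased(X: np.ndarray, names: list[str]) -> list[str]:
    kept: list[int] = []
    out = []
    for j in range(X.shape[1]):
        if np.linalg.matrix_rank(X[:, kept + [j]]) == len(kept) + 1:
            kept.append(j)
        else:
            out.append(names[j])
    return out


def median_profiles(
    result: SimulationResult,
    condition_on: list[str],
    response: str,
) -> SusceptibilitySummary:
    """Grouped medians of a fit index or parameter estimate.

    ``response`` is one of the GOF columns or ``factor_corr_est``;
    empty groups yield NaN rows rather than errors.
    """
    records = result.converged_records()
    for col in condition_on:
        if col not in records.columns:
            raise KeyError(f"unknown conditioning factor {col!r}")
    if response not in records.columns:
        raise KeyError(f"unknown response {response!r}")
    grouped = (
        records.groupby(condition_on, dropna=False)[response]
        .median()
        .rename("median")
        .reset_index()
    )
    return SusceptibilitySummary(
        median_profiles=grouped, meta={"response": response, "by": condition_on}
    )
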