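"""Tailored cutoffs: Type-I-error-controlling quantiles and their predictors.

A tailored cutoff for a goodness-of-fit index is the empirical quantile of
that index over replications of a *correctly specified* model in a given
scenario: the 95% quantile for chi-square, chi-square/df, RMSEA and SRMR
(which grow with misfit) and the 5% quantile for CFI (which shrinks).
Judging a model against these cutoffs fixes the Type-I error rate at the
nominal alpha.

The equation-based predictor regresses scenario cutoffs on the data/analysis
characteristics, their quadratic terms and all two-way interactions; the
published coefficient set for the full-scale simulation ships with the
package and :func:`predict_cutoffs` evaluates it for a user's setting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

from .design import parse_scenario_id
from .engine import SimulationResult

__all__ = [
    "GOF_NAMES",
    "CutoffTable",
    "CutoffRegression",
    "derive_cutoffs",
    "rejection_rates",
    "fit_cutoff_regression",
    "predict_cutoffs",
    "published_regression",
    "ScenarioFeatures",
]

GOF_NAMES = ("chi2", "chi2_df", "cfi", "rmsea", "srmr")
#: indices whose cutoff is an upper quantile (larger = worse fit)
UPPER_TAIL = ("chi2", "chi2_df", "rmsea", "srmr")
CORRECT_FAMILIES = ("dim_correct", "cross_correct")

_DATA_FILE = "cutoff_regression_coefficients.csv"


# ---------------------------------------------------------------------------
# scenario characteristics as predictor features


@dataclass(frozen=True)
class ScenarioFeatures:
    """Raw, uncentered characteristics entering the cutoff regression.

    Sample size is divided by 1000 before use; the estimator enters as
    dummies against the ML reference; whether factors correlate enters only
    through its interaction with the number of factors.
    """

    estimator: str
    n_indicators: int
    n_options: int
    asymmetric: bool
    loading: float
    sample_size: float
    n_factors: int
    correlated: bool = False

    def __post_init__(self) -> None:
        if self.estimator not in ("ML", "MLR", "DWLS", "WLSMV"):
            raise ValueError(f"unknown estimator: {self.estimator!r}")
        if self.n_factors not in (1, 2):
            raise ValueError("the predictor supports one or two factors only")

    @classmethod
    def from_scenario_id(cls, sid: str) -> "ScenarioFeatures":
        s = parse_scenario_id(sid)
        return cls(
            estimator=s.estimator,
            n_indicators=s.n_indicators,
            n_options=s.n_options,
            asymmetric=s.distribution == "asymmetric",
            loading=s.loading,
            sample_size=s.sample_size,
            n_factors=s.n_analysis_factors,
            correlated=bool(s.factor_correlation) and s.n_analysis_factors == 2,
        )

    def base_terms(self, estimator: str | None = None) -> dict[str, float]:
        est = estimator or self.estimator
        n = self.sample_size / 1000.0
        return {
            "mlr": float(est == "MLR"),
            "dwls": float(est == "DWLS"),
            "wlsmv": float(est == "WLSMV"),
            "indicators": float(self.n_indicators),
            "options": float(self.n_options),
            "options2": float(self.n_options**2),
            "asymmetric": float(self.asymmetric),
            "loading": float(self.loading),
            "loading2": float(self.loading**2),
            "n": n,
            "n2": n * n,
            "factors": float(self.n_factors),
            "correlated": float(self.correlated),
        }


_MAIN_TERMS = [
    "mlr", "dwls", "wlsmv", "indicators", "options", "options2",
    "asymmetric", "loading", "loading2", "n", "n2", "factors",
]
_INTERACTION_PARTNERS = [
    "indicators", "options", "options2", "asymmetric",
    "loading", "loading2", "n", "n2", "factors",
]


def regression_terms() -> list[str]:
    """The full term list of the cutoff regression, in its canonical order."""
    terms = ["intercept", *_MAIN_TERMS]
    for est in ("mlr", "dwls", "wlsmv"):
        terms += [f"{est}:{t}" for t in _INTERACTION_PARTNERS]
    bases = ["indicators", "options", "options2", "asymmetric",
             "loading", "loading2", "n", "n2"]
    for i, left in enumerate(bases):
        partners = [t for t in _INTERACTION_PARTNERS if t not in bases[: i + 1]]
        # squared terms never interact with their own linear term
        if left == "options":
            partners = [t for t in partners if t != "options2"]
        if left == "loading":
            partners = [t for t in partners if t != "loading2"]
        if left == "n":
            partners = [t for t in partners if t != "n2"]
        terms += [f"{left}:{t}" for t in partners]
    terms += ["factors:correlated"]
    return terms


def _term_value(term: str, base: dict[str, float]) -> float:
    if term == "intercept":
        return 1.0
    out = 1.0
    for part in term.split(":"):
        out *= base[part]
    return out


def design_row(features: ScenarioFeatures, estimator: str | None = None) -> np.ndarray:
    base = features.base_terms(estimator)
    return np.array([_term_value(t, base) for t in regression_terms()])


# ---------------------------------------------------------------------------
# cutoff tables


@dataclass(frozen=True)
class CutoffTable:
    """Per-scenario quantile cutoffs at a nominal Type-I error rate."""

    table: pd.DataFrame  # indexed by scenario_id; columns GOF_NAMES + n_effective
    alpha: float

    def cutoff(self, sid: str, gof: str) -> float:
        return float(self.table.loc[sid, gof])

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index_label="scenario_id")


def derive_cutoffs(
    result: SimulationResult, alpha: float = 0.05, *, min_reps: int = 50
) -> CutoffTable:
    """Empirical (1−alpha) quantiles (alpha for CFI) over converged replications.

    Only correctly specified scenarios define Type-I-error cutoffs; records
    from misspecified families raise.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    records = result.converged_records()
    bad = set(records["family"]) - set(CORRECT_FAMILIES)
    if bad:
        raise ValueError(
            f"cutoffs are defined on correctly specified models; found {sorted(bad)}"
        )
    if records.empty:
        raise ValueError("no converged records")
    rows = {}
    for sid, group in records.groupby("scenario_id"):
        if len(group) < min_reps:
            warnings.warn(f"only {len(group)} converged replications for {sid}")
        row = {}
        for gof in GOF_NAMES:
            vals = group[gof].dropna().to_numpy()
            if vals.size == 0:
                row[gof] = np.nan
                continue
            q = (1.0 - alpha) if gof in UPPER_TAIL else alpha
            row[gof] = float(np.quantile(vals, q))  # linear interpolation
        row["n_effective"] = len(group)
        rows[sid] = row
    table = pd.DataFrame.from_dict(rows, orient="index")
    table.index.name = "scenario_id"
    return CutoffTable(table=table, alpha=alpha)


def _reject(values: pd.Series, gof: str, cutoff: float) -> pd.Series:
    if gof in UPPER_TAIL:
        return values > cutoff
    return values < cutoff


def _correct_twin(sid: str) -> str:
    """Scenario id of the correctly specified twin of a misspecified cell."""
    s = parse_scenario_id(sid)
    if s.family == "dim_misspec":
        twin = type(s)(
            family="dim_correct", estimator=s.estimator,
            n_indicators=s.n_indicators, n_options=s.n_options,
            distribution=s.distribution, loading=s.loading,
            sample_size=s.sample_size,
        )
    elif s.family == "cross_misspec":
        twin = type(s)(
            family="cross_correct", estimator=s.estimator,
            n_indicators=s.n_indicators, n_options=s.n_options,
            distribution=s.distribution, loading=s.loading,
            sample_size=s.sample_size, factor_correlation=s.factor_correlation,
        )
    else:
        return sid
    from .design import scenario_id as _sid

    return _sid(twin)


def rejection_rates(result: SimulationResult, table: CutoffTable) -> pd.DataFrame:
    """Per-scenario Type-I (correct cells) and Type-II (misspecified) rates.

    Correct-specification records are scored against their own cutoffs
    (rejection fraction = Type-I error); misspecified records against the
    cutoffs of the correctly specified twin cell that shares all
    non-misspecification characteristics (acceptance fraction = Type-II).
    """
    records = result.converged_records()
    if records.empty:
        raise ValueError("no converged records")
    rows = []
    for sid, group in records.groupby("scenario_id"):
        correct = group["family"].iloc[0] in CORRECT_FAMILIES
        ref = sid if correct else _correct_twin(sid)
        if ref not in table.table.index:
            raise KeyError(f"no cutoff available for scenario {ref}")
        row: dict = {"scenario_id": sid, "kind": "type_i" if correct else "type_ii",
                     "n": len(group)}
        for gof in GOF_NAMES:
            cut = table.cutoff(ref, gof)
            rej = _reject(group[gof].dropna(), gof, cut)
            rate = float(rej.mean()) if len(rej) else np.nan
            row[gof] = rate if correct else 1.0 - rate
        rows.append(row)
    return pd.DataFrame(rows).set_index("scenario_id")


# ---------------------------------------------------------------------------
# the cutoff regression


@dataclass(frozen=True)
class CutoffRegression:
    """Per-GOF coefficients of the cutoff-prediction regression.

    ``coefficients`` is indexed by term name (see :func:`regression_terms`);
    the SRMR column has no MLR/WLSMV terms because SRMR is identical under
    ML/MLR and under DWLS/WLSMV.
    """

    coefficients: pd.DataFrame
    r_squared: pd.Series
    n_cells: pd.Series

    def terms_for(self, gof: str) -> pd.Series:
        col = self.coefficients[gof]
        return col.dropna()


def published_regression() -> CutoffRegression:
    """The shipped coefficient set estimated on the full-scale simulation."""
    with resources.files("tailorfit.data").joinpath(_DATA_FILE).open() as fh:
        raw = pd.read_csv(fh, index_col="term")
    coef = raw.drop(index=["r_squared", "n_cells"])
    expected = regression_terms()
    if list(coef.index) != expected:
        raise RuntimeError("shipped coefficient table does not match the term structure")
    return CutoffRegression(
        coefficients=coef,
        r_squared=raw.loc["r_squared"],
        n_cells=raw.loc["n_cells"].astype(int),
    )


def fit_cutoff_regression(
    table: CutoffTable, features: dict[str, ScenarioFeatures] | None = None
) -> CutoffRegression:
    """OLS of scenario cutoffs on the characteristics term structure.

    ``features`` maps scenario id -> characteristics; by default they are
    parsed from the scenario ids.  For SRMR only ML/DWLS cells enter (the
    index is identical under the robustified statistics).
    """
    sids = list(table.table.index)
    if features is None:
        features = {sid: ScenarioFeatures.from_scenario_id(sid) for sid in sids}
    terms = regression_terms()
    X_full = np.array([design_row(features[sid]) for sid in sids])
    coef = pd.DataFrame(index=pd.Index(terms, name="term"), columns=GOF_NAMES, dtype=float)
    r2 = pd.Series(index=pd.Index(GOF_NAMES), dtype=float)
    n_cells = pd.Series(index=pd.Index(GOF_NAMES), dtype=int)
    for gof in GOF_NAMES:
        y = table.table[gof].to_numpy(dtype=float)
        X = X_full
        use_terms = terms
        keep = np.isfinite(y)
        if gof == "srmr":
            ml_dwls = np.array(
                [features[sid].estimator in ("ML", "DWLS") for sid in sids]
            )
            keep &= ml_dwls
            use_terms = [t for t in terms if "mlr" not in t and "wlsmv" not in t]
            cols = [terms.index(t) for t in use_terms]
            X = X_full[:, cols]
        Xk, yk = X[keep], y[keep]
        if Xk.shape[0] <= Xk.shape[1]:
            raise ValueError(
                f"underdetermined cutoff regression for {gof}: "
                f"{Xk.shape[0]} cells for {Xk.shape[1]} terms"
            )
        rank = np.linalg.matrix_rank(Xk)
        if rank < Xk.shape[1]:
            aliased = _aliased_terms(Xk, use_terms)
            raise ValueError(f"rank-deficient design for {gof}; aliased terms: {aliased}")
        beta, *_ = np.linalg.lstsq(Xk, yk, rcond=None)
        fittedv = Xk @ beta
        ss_res = float(np.sum((yk - fittedv) ** 2))
        ss_tot = float(np.sum((yk - yk.mean()) ** 2))
        coef.loc[use_terms, gof] = beta
        r2[gof] = 1.0 - ss_res / ss_tot if ss_tot > 0 else np.nan
        n_cells[gof] = int(keep.sum())
    return CutoffRegression(coefficients=coef, r_squared=r2, n_cells=n_cells)


def _aliased_terms(X: np.ndarray, terms: list[str]) -> list[str]:
    aliased = []
    kept: list[int] = []
    for j in range(X.shape[1]):
        cand = X[:, kept + [j]]
        if np.linalg.matrix_rank(cand) == len(kept) + 1:
            kept.append(j)
        else:
            aliased.append(terms[j])
    return aliased


_SIMULATED_RANGES = {
    "n_indicators": (6, 12),
    "n_options": (3, 7),
    "loading": (0.40, 0.80),
    "sample_size": (200, 2000),
}

CHI2_CAVEAT = (
    "predicted chi-square cutoffs depend on the model degrees of freedom and "
    "are barely useful for models different from the simulated ones"
)


def predict_cutoffs(
    features: ScenarioFeatures,
    regression: CutoffRegression | None = None,
) -> pd.Series:
    """Evaluate the cutoff-prediction formulae for one empirical setting.

    For SRMR the MLR setting maps to ML and WLSMV to DWLS (the index is
    identical under the robustified statistics).  Warns on extrapolation
    beyond the simulated characteristic ranges and always attaches the
    caveat that chi-square predictions are model-specific.
    """
    if regression is None:
        regression = published_regression()
    for name, (lo, hi) in _SIMULATED_RANGES.items():
        val = getattr(features, name)
        if not lo <= val <= hi:
            warnings.warn(
                f"{name}={val} lies outside the simulated range [{lo}, {hi}]; "
                "the predicted cutoffs are extrapolations"
            )
    warnings.warn(CHI2_CAVEAT)
    out = {}
    terms = regression.coefficients.index.to_list()
    row = pd.Series(design_row(features), index=terms)
    srmr_est = {"MLR": "ML", "WLSMV": "DWLS"}.get(features.estimator, features.estimator)
    srmr_row = pd.Series(design_row(features, estimator=srmr_est), index=terms)
    for gof in GOF_NAMES:
        coefs = regression.terms_for(gof)
        x = srmr_row if gof == "srmr" else row
        out[gof] = float((coefs * x[coefs.index]).sum())
    return pd.Series(out)
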