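"""Crossed simulation design for the fit-index calibration study.

The study crosses four scenario *families* — correctly specified and
misspecified factor dimensionality, and correctly specified and misspecified
(unmodeled) cross-loadings — with six data/analysis characteristics:
estimator, number of indicators, number of response options, response
distribution shape, standardized loading magnitude and sample size.  Two-factor
families additionally vary the factor correlation, and the misspecified
cross-loading family varies the magnitude and proportion of cross-loadings.

Enumerating the full default design yields 6048 cells
(432 + 1296 + 864 + 3456).
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, fields as dc_fields
from typing import Iterable, Mapping, Sequence

import pandas as pd

__all__ = [
    "Scenario",
    "FAMILIES",
    "ESTIMATORS",
    "DEFAULT_DESIGN",
    "enumerate_scenarios",
    "scenario_id",
    "parse_scenario_id",
    "cross_loading_count",
    "grid_to_frame",
]

FAMILIES = ("dim_correct", "dim_misspec", "cross_correct", "cross_misspec")
ESTIMATORS = ("ML", "MLR", "DWLS", "WLSMV")

# Documented level sets of the crossed design.
_LEVELS = {
    "estimator": ESTIMATORS,
    "n_indicators": (6, 12),
    "n_options": (3, 5, 7),
    "distribution": ("symmetric", "asymmetric"),
    "loading": (0.40, 0.60, 0.80),
    "sample_size": (200, 500, 2000),
}
# factor correlation levels: population correlation in the misspecified
# dimensionality family induces the misspecification (fit as one factor);
# cross-loading families use uncorrelated/correlated (.00/.30).
_CORR_LEVELS = {
    "dim_correct": (None,),
    "dim_misspec": (0.70, 0.50, 0.30),
    "cross_correct": (0.00, 0.30),
    "cross_misspec": (0.00, 0.30),
}
_MAGNITUDE_LEVELS = (0.20, 0.30)
_PROPORTION_LEVELS = (0.17, 0.33)


@dataclass(frozen=True, order=True)
class Scenario:
    """One cell of the simulation design.

    ``factor_correlation`` is the population inter-factor correlation: absent
    for the one-factor family, the misspecification driver (.70/.50/.30) in
    the misspecified-dimensionality family, and .00/.30 in the cross-loading
    families.  ``misspec_magnitude``/``misspec_proportion`` describe the
    cross-loadings present in the population but omitted from the analysis
    model; they exist only in the ``cross_misspec`` family.
    """

    family: str
    estimator: str
    n_indicators: int
    n_options: int
    distribution: str
    loading: float
    sample_size: int
    factor_correlation: float | None = None
    misspec_magnitude: float | None = None
    misspec_proportion: float | None = None

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(f"unknown family: {self.family!r}")
        for name, levels in _LEVELS.items():
            value = getattr(self, name)
            if value not in levels:
                raise ValueError(f"invalid level for {name!r}: {value!r}")
        if self.family == "dim_correct":
            if self.factor_correlation is not None:
                raise ValueError("dim_correct has no factor correlation")
        elif self.factor_correlation is None:
            raise ValueError(f"{self.family} requires a factor correlation")
        if self.family == "cross_misspec":
            if self.misspec_magnitude is None or self.misspec_proportion is None:
                raise ValueError("cross_misspec requires misspecification fields")
        elif self.misspec_magnitude is not None or self.misspec_proportion is not None:
            raise ValueError(f"{self.family} has no misspecification fields")

    # -- derived structure -------------------------------------------------
    @property
    def n_population_factors(self) -> int:
        return 1 if self.family == "dim_correct" else 2

    @property
    def n_analysis_factors(self) -> int:
        """Factors in the fitted model (one in both dimensionality families)."""
        return 2 if self.family.startswith("cross") else 1

    @property
    def correlation_estimated(self) -> bool:
        """Whether the two-factor analysis model frees the factor correlation."""
        return self.n_analysis_factors == 2 and self.factor_correlation != 0.0

    @property
    def n_cross_loadings(self) -> int:
        return cross_loading_count(self.n_indicators, self.misspec_proportion)


def cross_loading_count(n_indicators: int, proportion: float | None) -> int:
    """Number of indicators carrying a population cross-loading.

    The design states the proportion (17% or 33%) of all indicators; with six
    indicators that corresponds to one or two cross-loadings, with twelve to
    two or four.
    """
    if proportion is None:
        return 0
    return int(round(proportion * n_indicators))


# ---------------------------------------------------------------------------
# enumeration

DEFAULT_DESIGN: dict[str, dict[str, Sequence]] = {
    family: {
        "estimator": _LEVELS["estimator"],
        "n_indicators": _LEVELS["n_indicators"],
        "n_options": _LEVELS["n_options"],
        "distribution": _LEVELS["distribution"],
        "loading": _LEVELS["loading"],
        "sample_size": _LEVELS["sample_size"],
        "factor_correlation": _CORR_LEVELS[family],
        **(
            {
                "misspec_magnitude": _MAGNITUDE_LEVELS,
                "misspec_proportion": _PROPORTION_LEVELS,
            }
            if family == "cross_misspec"
            else {}
        ),
    }
    for family in FAMILIES
}

_FACTOR_ORDER = (
    "estimator",
    "n_indicators",
    "n_options",
    "distribution",
    "loading",
    "sample_size",
    "factor_correlation",
    "misspec_magnitude",
    "misspec_proportion",
)


def _validate_levels(family: str, factor: str, levels: Sequence) -> None:
    if factor in _LEVELS:
        allowed = _LEVELS[factor]
    elif factor == "factor_correlation":
        allowed = _CORR_LEVELS[family]
    elif factor == "misspec_magnitude":
        allowed = _MAGNITUDE_LEVELS
    elif factor == "misspec_proportion":
        allowed = _PROPORTION_LEVELS
    else:
        raise ValueError(f"unknown design factor: {factor!r}")
    if len(levels) == 0:
        raise ValueError(f"empty level set for {factor!r}")
    for lev in levels:
        if lev not in allowed:
            warnings.warn(
                f"level {lev!r} of {factor!r} extends the documented design",
                stacklevel=3,
            )


def enumerate_scenarios(
    config: Mapping[str, Mapping[str, Sequence]] | None = None,
) -> list[Scenario]:
    """Enumerate the Cartesian product of design levels, family by family.

    ``config`` maps family name -> {factor -> level list}; omitted factors
    default to the full documented level set.  The order is deterministic:
    families in their declared order, then the lexicographic product over
    (estimator, indicators, options, distribution, loading, sample size,
    correlation, magnitude, proportion) in the order the levels are given.
    """
    if config is None:
        config = DEFAULT_DESIGN
    scenarios: list[Scenario] = []
    for family in config:
        if family not in FAMILIES:
            raise ValueError(f"unknown family: {family!r}")
    for family in FAMILIES:
        if family not in config:
            continue
        spec = dict(config[family])
        factors: dict[str, Sequence] = {}
        for factor in _FACTOR_ORDER:
            if factor in spec:
                levels = spec.pop(factor)
            elif factor in DEFAULT_DESIGN[family]:
                levels = DEFAULT_DESIGN[family][factor]
            else:
                continue
            _validate_levels(family, factor, levels)
            factors[factor] = levels
        if spec:
            raise ValueError(f"unknown design factor(s): {sorted(spec)!r}")
        names = list(factors)
        for combo in itertools.product(*factors.values()):
            scenarios.append(Scenario(family=family, **dict(zip(names, combo))))
    return scenarios


# ---------------------------------------------------------------------------
# identifiers

_FAMILY_CODE = {
    "dim_correct": "dc",
    "dim_misspec": "dm",
    "cross_correct": "cc",
    "cross_misspec": "cm",
}
_FAMILY_FROM_CODE = {v: k for k, v in _FAMILY_CODE.items()}
_DIST_CODE = {"symmetric": "sym", "asymmetric": "asym"}
_DIST_FROM_CODE = {v: k for k, v in _DIST_CODE.items()}


def _pct(x: float) -> str:
    return f"{int(round(100 * x)):02d}"


def scenario_id(s: Scenario) -> str:
    """Stable, filesystem-safe, injective identifier for a design cell."""
    parts = [
        _FAMILY_CODE[s.family],
        s.estimator,
        f"i{s.n_indicators}",
        f"k{s.n_options}",
        _DIST_CODE[s.distribution],
        f"l{_pct(s.loading)}",
        f"n{s.sample_size}",
    ]
    if s.factor_correlation is not None:
        parts.append(f"r{_pct(s.factor_correlation)}")
    if s.misspec_magnitude is not None:
        parts.append(f"m{_pct(s.misspec_magnitude)}")
        parts.append(f"p{_pct(s.misspec_proportion)}")
    return "_".join(parts)


def parse_scenario_id(sid: str) -> Scenario:
    """Inverse of :func:`scenario_id`."""
    parts = sid.split("_")
    if len(parts) < 7:
        raise ValueError(f"malformed scenario id: {sid!r}")
    family = _FAMILY_FROM_CODE.get(parts[0])
    if family is None:
        raise ValueError(f"malformed scenario id: {sid!r}")
    kwargs: dict = {
        "family": family,
        "estimator": parts[1],
        "n_indicators": int(parts[2][1:]),
        "n_options": int(parts[3][1:]),
        "distribution": _DIST_FROM_CODE[parts[4]],
        "loading": int(parts[5][1:]) / 100,
        "sample_size": int(parts[6][1:]),
    }
    for extra in parts[7:]:
        key, value = extra[0], int(extra[1:]) / 100
        if key == "r":
            kwargs["factor_correlation"] = value
        elif key == "m":
            kwargs["misspec_magnitude"] = value
        elif key == "p":
            kwargs["misspec_proportion"] = value
        else:
            raise ValueError(f"malformed scenario id: {sid!r}")
    return Scenario(**kwargs)


def grid_to_frame(scenarios: Iterable[Scenario]) -> pd.DataFrame:
    """One row per scenario: all design fields plus the stable id."""
    rows = []
    for s in scenarios:
        row = {f.name: getattr(s, f.name) for f in dc_fields(s)}
        row["scenario_id"] = scenario_id(s)
        rows.append(row)
    return pd.DataFrame(rows)
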