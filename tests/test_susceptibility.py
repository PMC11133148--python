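"""Sensitivity/susceptibility analyses: tau-b, regressions, median profiles."""

import numpy as np
import pandas as pd
import pytest

from tailorfit.design import Scenario
from tailorfit.engine import SimulationResult, run_grid
from tailorfit.susceptibility import (
    kendall_tau_b,
    median_profiles,
    recode_gofs,
    susceptibility_regression,
)


class TestKendallTauB:
    def test_perfect_concordance(self):
        assert kendall_tau_b([1, 2, 3, 4], [10, 20, 30, 40]) == pytest.approx(1.0)

    def test_perfect_discordance(self):
        assert kendall_tau_b([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_independence_near_zero(self, rng):
        x = rng.normal(size=5000)
        y = rng.normal(size=5000)
        assert abs(kendall_tau_b(x, y)) < 0.03

    def test_all_tied_margin_undefined(self):
        assert np.isnan(kendall_tau_b([1, 1, 1], [1, 2, 3]))

    def test_matches_pairwise_enumeration_oracle(self):
        """Heavily tied vectors against the O(n^2) concordance count."""
        x = np.array([1, 1, 2, 2, 2, 3, 3, 1, 2, 3])
        y = np.array([2, 1, 2, 3, 2, 3, 1, 1, 3, 3])
        n = len(x)
        conc = disc = tx = ty = 0
        for i in range(n):
            for j in range(i + 1, n):
                dx, dy = x[i] - x[j], y[i] - y[j]
                if dx == 0 and dy == 0:
                    continue
                elif dx == 0:
                    tx += 1
                elif dy == 0:
                    ty += 1
                elif dx * dy > 0:
                    conc += 1
                else:
                    disc += 1
        n0 = n * (n - 1) // 2
        oracle = (conc - disc) / np.sqrt((n0 - _ties(x)) * (n0 - _ties(y)))
        assert kendall_tau_b(x, y) == pytest.approx(oracle, abs=1e-12)


def _ties(v):
    _, counts = np.unique(v, return_counts=True)
    return int(sum(c * (c - 1) // 2 for c in counts))


def _fake_result(records: pd.DataFrame) -> SimulationResult:
    return SimulationResult(records, 1.0, 0.0, 0, "x")


def _grid_records(rng, family="dim_correct", n_per_cell=6) -> pd.DataFrame:
    rows = []
    rep = 0
    for est in ("ML", "DWLS"):
        for load in (0.4, 0.6, 0.8):
            for n in (200, 500, 2000):
                for k in (3, 5, 7):
                    for dist in ("symmetric", "asymmetric"):
                        for ind in (6, 12):
                            for _ in range(n_per_cell):
                                chi2 = rng.chisquare(9)
                                rows.append({
                                    "scenario_id": f"{est}_{load}_{n}_{k}_{dist}_{ind}",
                                    "family": family, "estimator": est,
                                    "n_indicators": ind, "n_options": k,
                                    "distribution": dist, "loading": load,
                                    "sample_size": n,
                                    "factor_correlation": np.nan,
                                    "misspec_magnitude": np.nan,
                                    "misspec_proportion": np.nan,
                                    "replication": rep, "converged": True,
                                    "chi2": chi2, "df": 9, "chi2_df": chi2 / 9,
                                    "cfi": 1 - rng.uniform(0, .1),
                                    "rmsea": rng.uniform(0, .1),
                                    "srmr": rng.uniform(0, .1),
                                    "scaling_factor": 1.0,
                                    "factor_corr_est": np.nan, "resampled": 0,
                                })
                                rep += 1
    return pd.DataFrame(rows)


class TestSusceptibilityRegression:
    def test_recovers_planted_sample_size_effect(self, rng):
        rec = _grid_records(rng)
        # plant: recoded pseudo-GOF depends linearly on n/1000 with slope +2
        rec["srmr"] = -(2.0 * rec["sample_size"] / 1000.0 + rng.normal(0, 1e-6, len(rec)))
        summary = susceptibility_regression(_fake_result(rec), "dim_correct")
        assert summary.regression.loc["n", "srmr"] == pytest.approx(2.0, abs=1e-3)
        assert summary.r_squared["srmr"] > 0.999

    def test_recoding_flips_fitted_signs(self, rng):
        rec = _grid_records(rng)
        rec["rmsea"] = 0.05 * rec["loading"]
        summary = susceptibility_regression(_fake_result(rec), "dim_correct")
        flipped = rec.copy()
        recoded = recode_gofs(flipped)
        assert np.allclose(recoded["rmsea"], -rec["rmsea"])
        # fitted loading effect has the sign of the recoded response
        assert summary.regression.loc["loading", "rmsea"] < 0

    def test_misspec_magnitude_negative_for_all_gofs(self):
        """Dimensionality misspecification worsens every (recoded) index."""
        scenarios = [
            Scenario("dim_misspec", est, 6, 5, "symmetric", load, 200,
                     factor_correlation=r)
            for est in ("ML", "DWLS")
            for load in (0.4, 0.8)
            for r in (0.70, 0.50, 0.30)
        ]
        res = run_grid(scenarios, 8, 77)
        summary = susceptibility_regression(res, "dim_misspec")
        for gof in ("chi2", "chi2_df", "cfi", "rmsea", "srmr"):
            # recoded responses: lower = worse, so the association is negative
            assert summary.tau_b.loc["misspec_magnitude", gof] < 0, gof

    def test_single_level_characteristic_rejected(self, rng):
        rec = _grid_records(rng)
        rec = rec[rec["estimator"] == "ML"]
        with pytest.raises(ValueError, match="fewer than two levels"):
            susceptibility_regression(_fake_result(rec), "dim_correct")


class TestMedianProfiles:
    def test_constant_response(self, rng):
        rec = _grid_records(rng)
        rec["cfi"] = 0.9
        prof = median_profiles(_fake_result(rec), ["estimator"], "cfi")
        assert (prof.median_profiles["median"] == 0.9).all()

    def test_groupby_levels(self, rng):
        rec = _grid_records(rng)
        prof = median_profiles(_fake_result(rec), ["estimator", "loading"], "rmsea")
        assert len(prof.median_profiles) == 6

    def test_unknown_factor_or_response(self, rng):
        rec = _grid_records(rng)
        with pytest.raises(KeyError):
            median_profiles(_fake_result(rec), ["bogus"], "cfi")
        with pytest.raises(KeyError):
            median_profiles(_fake_result(rec), ["estimator"], "bogus")

    def test_rmsea_increases_as_population_correlation_drops(self):
        """More severe dimensionality misspecification raises median RMSEA."""
        scenarios = [
            Scenario("dim_misspec", "ML", 6, 5, "symmetric", 0.8, 500,
                     factor_correlation=r)
            for r in (0.70, 0.50, 0.30)
        ]
        res = run_grid(scenarios, 10, 13)
        prof = median_profiles(res, ["factor_correlation"], "rmsea")
        med = prof.median_profiles.set_index("factor_correlation")["median"]
        assert med[0.30] > med[0.50] > med[0.70]
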