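"""Tailored cutoffs: quantile derivation, error rates, and the predictor."""

import hashlib
from importlib import resources

import numpy as np
import pandas as pd
import pytest

from tailorfit.cutoffs import (
    CutoffTable,
    GOF_NAMES,
    ScenarioFeatures,
    derive_cutoffs,
    design_row,
    fit_cutoff_regression,
    predict_cutoffs,
    published_regression,
    regression_terms,
    rejection_rates,
)
from tailorfit.design import Scenario, enumerate_scenarios, scenario_id
from tailorfit.engine import SimulationResult, run_scenario

COEF_SHA256 = "2325487c4a78984bdc0d5ab071f103407b6b1df3fcc5ab44f69933a72172a714"


def _result_from(records: pd.DataFrame) -> SimulationResult:
    return SimulationResult(records, 1.0, 0.0, 0, "test")


def _synthetic_records(sid: str, family: str, estimator: str, n: int, rng,
                       **field_overrides) -> pd.DataFrame:
    base = {
        "scenario_id": sid, "family": family, "estimator": estimator,
        "n_indicators": 6, "n_options": 5, "distribution": "symmetric",
        "loading": 0.6, "sample_size": 200, "factor_correlation": np.nan,
        "misspec_magnitude": np.nan, "misspec_proportion": np.nan,
        "df": 9, "converged": True, "scaling_factor": 1.0,
        "factor_corr_est": np.nan, "resampled": 0,
    }
    base.update(field_overrides)
    chi2 = rng.chisquare(9, size=n)
    rows = pd.DataFrame({
        **{k: [v] * n for k, v in base.items()},
        "replication": np.arange(n),
        "chi2": chi2,
        "chi2_df": chi2 / 9,
        "cfi": 1 - rng.uniform(0, 0.2, size=n),
        "rmsea": rng.uniform(0, 0.1, size=n),
        "srmr": rng.uniform(0, 0.1, size=n),
    })
    return rows


class TestDeriveCutoffs:
    def test_constant_gof_gives_constant_cutoff(self, rng):
        rec = _synthetic_records("s1", "dim_correct", "ML", 100, rng)
        for gof in GOF_NAMES:
            rec[gof] = 0.123
        table = derive_cutoffs(_result_from(rec), alpha=0.05, min_reps=10)
        for gof in GOF_NAMES:
            assert table.cutoff("s1", gof) == pytest.approx(0.123)

    def test_alpha_monotonicity(self, rng):
        rec = _synthetic_records("s1", "dim_correct", "ML", 500, rng)
        res = _result_from(rec)
        strict = derive_cutoffs(res, alpha=0.01)
        lax = derive_cutoffs(res, alpha=0.05)
        assert strict.cutoff("s1", "chi2") > lax.cutoff("s1", "chi2")
        assert strict.cutoff("s1", "cfi") < lax.cutoff("s1", "cfi")

    def test_misspecified_family_rejected(self, rng):
        rec = _synthetic_records("bad", "dim_misspec", "ML", 50, rng,
                                 factor_correlation=0.5)
        with pytest.raises(ValueError, match="correctly specified"):
            derive_cutoffs(_result_from(rec))

    def test_low_replication_warning(self, rng):
        rec = _synthetic_records("s1", "dim_correct", "ML", 20, rng)
        with pytest.warns(UserWarning, match="converged replications"):
            derive_cutoffs(_result_from(rec))


class TestRejectionRates:
    def test_type_i_self_consistency(self, rng):
        rec = _synthetic_records("s1", "dim_correct", "ML", 400, rng)
        res = _result_from(rec)
        table = derive_cutoffs(res, alpha=0.05)
        rates = rejection_rates(res, table)
        for gof in GOF_NAMES:
            assert rates.loc["s1", gof] == pytest.approx(0.05, abs=1 / 400)

    def test_type_ii_uses_correct_twin(self, rng):
        correct_sid = scenario_id(
            Scenario("dim_correct", "ML", 6, 5, "symmetric", 0.6, 200))
        mis_sid = scenario_id(
            Scenario("dim_misspec", "ML", 6, 5, "symmetric", 0.6, 200,
                     factor_correlation=0.30))
        correct = _synthetic_records(correct_sid, "dim_correct", "ML", 300, rng)
        mis = _synthetic_records(mis_sid, "dim_misspec", "ML", 300, rng,
                                 factor_correlation=0.30)
        mis["chi2"] += 60  # grossly misfitting
        mis["chi2_df"] = mis["chi2"] / 9
        mis["cfi"] -= 0.5
        res = _result_from(pd.concat([correct, mis], ignore_index=True))
        table = derive_cutoffs(_result_from(correct))
        rates = rejection_rates(res, table)
        assert rates.loc[mis_sid, "kind"] == "type_ii"
        assert rates.loc[mis_sid, "chi2"] < 0.05  # nearly always rejected

    def test_missing_twin_raises(self, rng):
        mis = _synthetic_records("dm_ML_i6_k5_sym_l60_n200_r30", "dim_misspec",
                                 "ML", 50, rng, factor_correlation=0.30)
        correct = _synthetic_records("s0", "dim_correct", "ML", 50, rng)
        table = derive_cutoffs(_result_from(correct))
        with pytest.raises(KeyError, match="no cutoff"):
            rejection_rates(_result_from(mis), table)

    def test_zero_converged_records(self, rng):
        rec = _synthetic_records("s1", "dim_correct", "ML", 10, rng)
        rec["converged"] = False
        table = CutoffTable(pd.DataFrame(), alpha=0.05)
        with pytest.raises(ValueError, match="no converged"):
            rejection_rates(_result_from(rec), table)


class TestCutoffRegression:
    def _full_feature_table(self):
        """Cutoff cells spanning all correct-specification scenarios (ML..WLSMV)."""
        grid = enumerate_scenarios(
            {"dim_correct": {}, "cross_correct": {"factor_correlation": [0.0, 0.3]}}
        )
        return {scenario_id(s): ScenarioFeatures.from_scenario_id(scenario_id(s))
                for s in grid}

    def test_recovers_planted_linear_model(self):
        features = self._full_feature_table()
        sids = list(features)
        terms = regression_terms()
        rng = np.random.default_rng(8)
        beta = rng.normal(size=len(terms))
        rows = {}
        for sid in sids:
            x = design_row(features[sid])
            val = float(x @ beta)
            rows[sid] = {g: val for g in GOF_NAMES}
            rows[sid]["n_effective"] = 1000
        table = CutoffTable(pd.DataFrame.from_dict(rows, orient="index"), 0.05)
        reg = fit_cutoff_regression(table, features)
        got = reg.coefficients["cfi"].to_numpy(dtype=float)
        assert np.allclose(got, beta, atol=1e-8)
        assert reg.r_squared["cfi"] == pytest.approx(1.0)
        # SRMR column fits on the ML/DWLS subset with the reduced term set
        assert reg.n_cells["srmr"] == len(sids) // 2

    def test_single_row_table_underdetermined(self):
        features = self._full_feature_table()
        sid = next(iter(features))
        table = CutoffTable(
            pd.DataFrame.from_dict(
                {sid: {g: 0.5 for g in GOF_NAMES} | {"n_effective": 10}},
                orient="index",
            ),
            0.05,
        )
        with pytest.raises(ValueError, match="underdetermined"):
            fit_cutoff_regression(table, {sid: features[sid]})


class TestPublishedPredictor:
    def test_shipped_table_checksum(self):
        data = (
            resources.files("tailorfit.data")
            .joinpath("cutoff_regression_coefficients.csv")
            .read_bytes()
        )
        assert hashlib.sha256(data).hexdigest() == COEF_SHA256

    def test_embedded_values_match_published_digits(self):
        reg = published_regression()
        assert reg.coefficients.loc["intercept", "cfi"] == -0.53129
        assert reg.coefficients.loc["loading", "cfi"] == 4.12967
        assert reg.coefficients.loc["dwls", "srmr"] == 0.03774
        assert pd.isna(reg.coefficients.loc["mlr", "srmr"])
        assert reg.r_squared.min() >= 0.810
        assert reg.n_cells["srmr"] == 648

    def test_prediction_matches_term_by_term_oracle(self):
        """Independent hand summation of coefficient x characteristic products."""
        reg = published_regression()
        est, ind, opt, asym, load, n, fac, corr = "ML", 6, 5, 0.0, 0.6, 0.2, 1, 0.0
        vals = {
            "intercept": 1.0, "mlr": 0.0, "dwls": 0.0, "wlsmv": 0.0,
            "indicators": ind, "options": opt, "options2": opt**2,
            "asymmetric": asym, "loading": load, "loading2": load**2,
            "n": n, "n2": n**2, "factors": fac, "correlated": corr,
        }
        expected = {}
        for gof in GOF_NAMES:
            total = 0.0
            for term, coef in reg.coefficients[gof].dropna().items():
                prod = coef
                for part in term.split(":"):
                    prod *= vals.get(part, 1.0) if part != "intercept" else 1.0
                total += prod
            expected[gof] = total
        feats = ScenarioFeatures("ML", 6, 5, False, 0.6, 200, 1, False)
        with pytest.warns(UserWarning, match="chi-square"):
            got = predict_cutoffs(feats, reg)
        for gof in GOF_NAMES:
            assert got[gof] == pytest.approx(expected[gof], abs=1e-10)

    def test_srmr_wlsmv_equals_dwls(self):
        reg = published_regression()
        base = dict(n_indicators=6, n_options=5, asymmetric=False,
                    loading=0.6, sample_size=200, n_factors=1)
        with pytest.warns(UserWarning):
            p_wlsmv = predict_cutoffs(ScenarioFeatures("WLSMV", **base), reg)
            p_dwls = predict_cutoffs(ScenarioFeatures("DWLS", **base), reg)
            p_mlr = predict_cutoffs(ScenarioFeatures("MLR", **base), reg)
            p_ml = predict_cutoffs(ScenarioFeatures("ML", **base), reg)
        assert p_wlsmv["srmr"] == p_dwls["srmr"]
        assert p_mlr["srmr"] == p_ml["srmr"]
        assert p_wlsmv["cfi"] != p_dwls["cfi"]

    def test_cfi_cutoff_increases_with_loading(self):
        reg = published_regression()
        cuts = []
        for load in (0.4, 0.6, 0.8):
            feats = ScenarioFeatures("ML", 6, 7, True, load, 200, 1, False)
            with pytest.warns(UserWarning):
                cuts.append(predict_cutoffs(feats, reg)["cfi"])
        assert cuts[0] < cuts[1] < cuts[2]

    def test_extrapolation_warning_and_estimator_validation(self):
        with pytest.raises(ValueError, match="estimator"):
            ScenarioFeatures("ULS", 6, 5, False, 0.6, 200, 1)
        with pytest.raises(ValueError, match="factors"):
            ScenarioFeatures("ML", 6, 5, False, 0.6, 200, 3)
        feats = ScenarioFeatures("ML", 30, 5, False, 0.6, 200, 1)
        with pytest.warns(UserWarning, match="outside the simulated range"):
            predict_cutoffs(feats)

    def test_all_predictions_within_sane_ranges(self):
        """Predicted cutoffs across the design grid stay on each index's scale."""
        reg = published_regression()
        rng = np.random.default_rng(0)
        for _ in range(50):
            feats = ScenarioFeatures(
                estimator=str(rng.choice(["ML", "MLR", "DWLS", "WLSMV"])),
                n_indicators=int(rng.choice([6, 12])),
                n_options=int(rng.choice([3, 5, 7])),
                asymmetric=bool(rng.choice([False, True])),
                loading=float(rng.choice([0.4, 0.6, 0.8])),
                sample_size=int(rng.choice([200, 500, 2000])),
                n_factors=int(rng.choice([1, 2])),
                correlated=bool(rng.choice([False, True])),
            )
            if feats.n_factors == 1 and feats.correlated:
                continue
            with pytest.warns(UserWarning):
                pred = predict_cutoffs(feats, reg)
            assert 0.5 < pred["cfi"] <= 1.05
            assert -0.02 <= pred["rmsea"] < 0.2
            assert 0.0 < pred["srmr"] < 0.2


class TestEndToEndCutoffs:
    def test_derived_cutoffs_control_type_i_on_fresh_run(self):
        s = Scenario("dim_correct", "ML", 6, 5, "symmetric", 0.8, 500)
        res = run_scenario(s, 200, 31)
        table = derive_cutoffs(res, alpha=0.05)
        rates = rejection_rates(res, table)
        sid = scenario_id(s)
        for gof in GOF_NAMES:
            assert rates.loc[sid, gof] == pytest.approx(0.05, abs=1 / 200)
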