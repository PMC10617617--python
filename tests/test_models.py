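"""Outlier filtering, forward selection, consensus and evaluation."""

import numpy as np
import pandas as pd
import pytest

from whiskmorph.models import (
    CoefficientSet,
    ModelEquation,
    consensus_model,
    diagnostics,
    evaluate,
    forward_select,
    load_coefficient_set,
    remove_outliers,
)


def obs_table(theta, phi, y, response="theta_w", animal="m1"):
    return pd.DataFrame(
        {
            "animal_id": animal,
            "row": 3,
            "col": np.arange(len(theta)) % 7 + 1,
            "theta_bp": theta,
            "phi_bp": phi,
            response: y,
        }
    )


class TestRemoveOutliers:
    def _grouped(self, groups):
        rows = []
        for (r, c), values in groups.items():
            for v in values:
                rows.append({"row": r, "col": c, "S": v})
        return pd.DataFrame(rows)

    def test_identical_values_none_removed(self):
        table = self._grouped({(1, 1): [5.0] * 8})
        out, rep = remove_outliers(table, "S")
        assert rep["n_removed"] == 0
        assert out["S"].notna().all()

    def test_single_gross_outlier_removed(self):
        table = self._grouped({(1, 1): [0.0] * 9 + [100.0]})
        out, rep = remove_outliers(table, "S")
        assert rep["n_removed"] == 1
        assert out["S"].isna().sum() == 1
        assert np.isnan(out.loc[out.index[-1], "S"])

    def test_small_groups_pass_through(self):
        table = self._grouped({(2, 2): [0.0, 100.0]})
        out, rep = remove_outliers(table, "S")
        assert rep["n_removed"] == 0

    def test_matches_zscore_oracle(self, rng):
        vals = rng.normal(10, 2, 40)
        vals[3] += 15.0
        table = self._grouped({(3, 3): list(vals)})
        out, rep = remove_outliers(table, "S")
        z = np.abs(vals - vals.mean()) / vals.std(ddof=1)
        assert rep["n_removed"] == int((z > 2).sum())

    def test_single_pass_report_arithmetic(self, rng):
        # 14 planted spikes among 357 values -> 3.92% removed, 343 survive
        groups = {}
        for g in range(14):
            groups[(g % 5 + 1, g % 7 + 1)] = [float(g)] * 9 + [float(g) + 100.0]
        filler = [10.0 + 0.01 * k for k in range(217)]
        rows = []
        for (r, c), values in groups.items():
            rows += [{"row": r, "col": c, "S": v} for v in values]
        # spread the filler across distinct clean groups
        for k, v in enumerate(filler):
            rows.append({"row": 5, "col": k % 7 + 1, "S": v})
        table = pd.DataFrame(rows)
        assert len(table) == 357
        out, rep = remove_outliers(table, "S")
        assert rep["n_before"] == 357
        assert rep["n_removed"] == 14
        assert rep["n_after"] == 343
        assert np.isclose(rep["pct_removed"], 100 * 14 / 357)


class TestForwardSelect:
    def test_recovers_single_linear_signal(self, rng):
        theta = rng.uniform(-60, 60, 60)
        phi = rng.uniform(-35, 35, 60)
        y = 3.0 * theta + rng.normal(0, 2.0, 60)
        eq = forward_select(obs_table(theta, phi, y), "theta_w")
        assert set(eq.predictor_terms) == {"theta_bp"}
        assert abs(eq.terms["theta_bp"] - 3.0) < 0.05

    def test_pure_noise_mostly_intercept_only(self):
        admitted = 0
        reps = 60
        for seed in range(reps):
            r = np.random.default_rng(seed)
            theta = r.uniform(-60, 60, 40)
            phi = r.uniform(-35, 35, 40)
            y = r.normal(0, 1, 40)
            eq = forward_select(obs_table(theta, phi, y), "theta_w")
            admitted += bool(eq.predictor_terms)
        # two independent univariate screens at alpha = 0.05
        assert admitted / reps < 0.25

    def test_quadratic_gated_by_aic(self, rng):
        theta = rng.uniform(-60, 60, 120)
        phi = rng.uniform(-35, 35, 120)
        strong = 0.01 * theta**2 + 0.5 * theta + rng.normal(0, 1.0, 120)
        eq = forward_select(obs_table(theta, phi, strong), "theta_w")
        assert "theta_bp^2" in eq.terms
        weak = 0.5 * theta + rng.normal(0, 5.0, 120)
        eq2 = forward_select(obs_table(theta, phi, weak), "theta_w")
        assert "theta_bp^2" not in eq2.terms

    def test_final_model_terms_all_significant(self, rng):
        import statsmodels.api as sm

        theta = rng.uniform(-60, 60, 80)
        phi = rng.uniform(-35, 35, 80)
        y = 1.2 * theta + 0.4 * phi + rng.normal(0, 4.0, 80)
        eq = forward_select(obs_table(theta, phi, y), "theta_w")
        data = {"theta_bp": theta, "phi_bp": phi}
        X = np.column_stack(
            [np.ones_like(theta)]
            + [data[t] if not t.endswith("^2") else data[t[:-2]] ** 2
               for t in eq.predictor_terms]
        )
        refit = sm.OLS(y, X).fit()
        assert np.all(refit.pvalues[1:] <= 0.05)

    def test_log_branch_returns_both_fits(self, rng):
        theta = rng.uniform(-60, 60, 50)
        phi = rng.uniform(-35, 35, 50)
        y = 11.7 * np.exp(-0.0165 * theta) * np.exp(rng.normal(0, 0.1, 50))
        out = forward_select(obs_table(theta, phi, y, response="S"), "S", allow_log=True)
        assert set(out) == {"raw", "log"}
        assert out["log"].log_response and not out["raw"].log_response
        assert abs(out["log"].terms["theta_bp"] + 0.0165) < 0.003

    def test_too_few_observations_raise(self):
        with pytest.raises(ValueError):
            forward_select(obs_table([1.0] * 5, [1.0] * 5, [1.0] * 5), "theta_w")


class TestConsensus:
    def _animals(self, rng, n_animals=8, n=40, fn=None, response="theta_w"):
        models, frames = [], []
        for a in range(n_animals):
            theta = rng.uniform(-60, 60, n)
            phi = rng.uniform(-35, 35, n)
            y = fn(theta, phi) + rng.normal(0, 2.0, n)
            tab = obs_table(theta, phi, y, response=response, animal=f"m{a}")
            models.append(forward_select(tab, response))
            frames.append(tab)
        return models, pd.concat(frames, ignore_index=True)

    def test_shared_true_model_recovered(self, rng):
        fn = lambda t, p: 0.6 * t + 85.0
        models, pooled = self._animals(rng, fn=fn)
        eq = consensus_model(models, pooled, "theta_w")
        assert set(eq.predictor_terms) == {"theta_bp"}
        assert abs(eq.terms["theta_bp"] - 0.6) < 0.02
        assert abs(eq.terms["1"] - 85.0) < 1.0

    def test_low_support_term_excluded(self, rng):
        # phi appears in only 3 of 8 per-animal models: it must not enter
        # the consensus even though it is real (and pooled-significant)
        models = []
        for a in range(8):
            terms = {"1": 85.0, "theta_bp": 0.6}
            if a < 3:
                terms["phi_bp"] = 0.5
            models.append(ModelEquation("theta_w", terms, n=40))
        theta = rng.uniform(-60, 60, 300)
        phi = rng.uniform(-35, 35, 300)
        y = 0.6 * theta + 0.5 * phi + rng.normal(0, 1.0, 300)
        pooled = obs_table(theta, phi, y)
        eq = consensus_model(models, pooled, "theta_w")
        assert "phi_bp" not in eq.terms

    def test_order_capped_by_support(self, rng):
        # squared term unsupported across animals -> consensus stays linear
        models = [
            ModelEquation("theta_w", {"1": 0.0, "theta_bp": 0.6}, n=40)
            for _ in range(8)
        ]
        theta = rng.uniform(-60, 60, 400)
        phi = rng.uniform(-35, 35, 400)
        y = 0.6 * theta + 0.02 * theta**2 + rng.normal(0, 0.5, 400)
        eq = consensus_model(models, obs_table(theta, phi, y), "theta_w")
        assert all(not t.endswith("^2") for t in eq.terms)

    def test_log_branch_chosen_for_exponential_response(self, rng):
        fn = None
        models, frames = [], []
        for a in range(8):
            theta = rng.uniform(-60, 60, 40)
            phi = rng.uniform(-35, 35, 40)
            y = 11.7 * np.exp(-0.0165 * theta) * np.exp(rng.normal(0, 0.1, 40))
            tab = obs_table(theta, phi, y, response="S", animal=f"m{a}")
            models.append(forward_select(tab, "S", allow_log=True))
            frames.append(tab)
        pooled = pd.concat(frames, ignore_index=True)
        eq = consensus_model(models, pooled, "S")
        assert eq.log_response
        assert abs(eq.terms["theta_bp"] + 0.0165) / 0.0165 < 0.1


class TestEvaluateAndDiagnostics:
    def test_linearity(self):
        eq = ModelEquation("theta_bp", {"1": -66.817, "col": 19.0})
        d1 = evaluate(eq, {"col": 3.0}) - evaluate(eq, {"col": 2.0})
        d2 = evaluate(eq, {"col": 7.0}) - evaluate(eq, {"col": 6.0})
        assert np.isclose(d1, 19.0) and np.isclose(d2, 19.0)

    def test_log_response_back_transforms(self):
        eq = ModelEquation("S", {"1": np.log(11.7), "theta_bp": -0.0165},
                           log_response=True)
        assert np.isclose(evaluate(eq, {"theta_bp": 0.0}), 11.7)

    def test_perfect_fit_r2_one(self):
        eq = ModelEquation("theta_w", {"1": 2.0, "theta_bp": 3.0})
        tab = obs_table(np.arange(20.0), np.zeros(20), 3.0 * np.arange(20.0) + 2.0)
        assert np.isclose(diagnostics(eq, tab)["r2"], 1.0)

    def test_r2_matches_sse_sst_oracle(self, rng):
        theta = rng.uniform(-60, 60, 50)
        y = 0.5 * theta + rng.normal(0, 3.0, 50)
        eq = ModelEquation("theta_w", {"1": 0.1, "theta_bp": 0.48})
        tab = obs_table(theta, np.zeros(50), y)
        out = diagnostics(eq, tab)
        pred = 0.1 + 0.48 * theta
        oracle = 1 - np.sum((y - pred) ** 2) / np.sum((y - y.mean()) ** 2)
        assert np.isclose(out["r2"], oracle)

    def test_noise_fit_r2_near_zero(self, rng):
        theta = rng.uniform(-60, 60, 2000)
        y = rng.normal(0, 1, 2000)
        eq = ModelEquation("theta_w", {"1": float(y.mean())})
        out = diagnostics(eq, tab := obs_table(theta, np.zeros(2000), y))
        assert abs(out["r2"]) < 0.01


class TestCoefficientSets:
    def test_mouse_set_complete(self, mouse_coeffs):
        for name in CoefficientSet.REQUIRED_MOUSE:
            assert name in mouse_coeffs.equations, name

    def test_checksum_guard(self, mouse_coeffs):
        d = mouse_coeffs.to_dict()
        d["equations"]["theta_bp_from_col"]["terms"]["col"] = 99.0
        with pytest.raises(ValueError):
            CoefficientSet.from_dict(d)

    def test_round_trip_through_json(self, tmp_path, mouse_coeffs):
        p = tmp_path / "set.json"
        mouse_coeffs.save(p)
        again = load_coefficient_set(p)
        assert again.species == "mouse"
        assert again.equations.keys() == mouse_coeffs.equations.keys()

    def test_zeta_low_confidence_preset(self, mouse_coeffs):
        assert mouse_coeffs.zeta_is_low_confidence(1, 2)  # A row
        assert mouse_coeffs.zeta_is_low_confidence(3, 7)  # rostral-most
        assert not mouse_coeffs.zeta_is_low_confidence(3, 2)
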