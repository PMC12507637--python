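"""Panel VAR: ADF screening, lag selection, estimation, Granger, IRF."""

import numpy as np
import pandas as pd
import pytest

from vetcoord import montecarlo as mc
from vetcoord import pvar as pv
from vetcoord import simulate as sim


class TestADF:
    def test_size_under_random_walk(self):
        """Rejection rate on pure random walks stays near the nominal 5%."""
        rng = np.random.default_rng(42)
        rejections = 0
        B = 500
        for _ in range(B):
            rw = np.cumsum(rng.standard_normal(500))
            _, _, reject, _ = pv.adf_unit(rw, max_lag=2)
            rejections += reject
        assert 0.02 <= rejections / B <= 0.09

    def test_power_on_strong_ar1(self):
        rng = np.random.default_rng(43)
        rejections = 0
        B = 200
        for _ in range(B):
            eps = rng.standard_normal(500)
            ar = np.zeros(500)
            for t in range(1, 500):
                ar[t] = 0.2 * ar[t - 1] + eps[t]
            _, _, reject, _ = pv.adf_unit(ar, max_lag=2)
            rejections += reject
        assert rejections / B > 0.95

    def test_constant_series_degenerate(self):
        with pytest.warns(UserWarning, match="constant"):
            stat, pval, reject, lags = pv.adf_unit(np.full(20, 3.0))
        assert reject

    def test_too_short_series_names_minimum(self):
        with pytest.raises(ValueError, match="at least"):
            pv.adf_unit(np.arange(4.0), max_lag=2)


class TestPanelStationarity:
    def test_proportion_arithmetic_25_of_31(self):
        summary = pv.summarize_stationarity(
            {"VHR": [True] * 25 + [False] * 6})
        assert summary.proportions["VHR"] == 80.6
        assert summary.verdicts["VHR"]

    def test_proportion_arithmetic_19_of_31(self):
        summary = pv.summarize_stationarity(
            {"PAAW": [True] * 19 + [False] * 12})
        assert summary.proportions["PAAW"] == 61.3
        assert summary.verdicts["PAAW"]

    def test_below_majority_not_stationary(self):
        summary = pv.summarize_stationarity(
            {"VHR": [True] * 15 + [False] * 16})
        assert summary.proportions["VHR"] == 48.4
        assert not summary.verdicts["VHR"]

    def test_exact_half_fails_strict_majority(self):
        summary = pv.summarize_stationarity({"X": [True] * 5 + [False] * 5})
        assert not summary.verdicts["X"]

    def test_panel_screen_runs_and_counts(self, uni_panel):
        from vetcoord.entropy import score_panel
        panel, _ = uni_panel
        _, scores = score_panel(panel)
        summary = pv.panel_stationarity(scores)
        assert summary.n_units == 31
        assert len(summary.records) == 62
        frame = summary.to_frame()
        assert set(frame["subsystem"]) == {"VHR", "PAAW"}
        assert frame["proportion_pct"].between(0, 100).all()

    def test_error_carries_unit_id(self):
        vals = [0.5, 0.62, 0.41, 0.73]  # too short for ADF with max_lag=2
        rows = []
        for u in ("A", "B", "C"):
            for y, v in enumerate(vals):
                rows.append((u, 2014 + y, "VHR", v))
                rows.append((u, 2014 + y, "PAAW", 1.0 - v))
        scores = pd.DataFrame(rows, columns=["unit", "year", "subsystem",
                                             "score"])
        with pytest.raises(ValueError, match="unit 'A'"):
            pv.panel_stationarity(scores, max_lag=2)


class TestRounding:
    @pytest.mark.parametrize("x,expect", [
        (80.645161, 80.6), (61.290322, 61.3), (48.387096, 48.4),
        (0.25, 0.3), (-0.25, -0.3), (2.0, 2.0),
    ])
    def test_half_away_from_zero(self, x, expect):
        assert pv.round_half_away(x, 1) == pytest.approx(expect)


class TestLagSelection:
    def test_recovers_var2_order(self):
        """AIC/BIC/HQIC consensus finds p = 2 on a long VAR(2) panel in the
        large majority of replicates."""
        hits = 0
        B = 30
        for r in range(B):
            spec = sim.preset_regimes("unidirectional_vhr_to_paaw",
                                      n_periods=30, seed=500 + r)
            truth = sim.simulate_latent(spec)
            sel = pv.select_lag(truth.latent, max_p=4)
            hits += sel.consensus == 2
        assert hits / B > 0.5

    def test_consensus_tie_breaks_to_smaller(self):
        assert pv.consensus_lag({"AIC": 3, "BIC": 1, "HQIC": 2}) == 1
        assert pv.consensus_lag({"AIC": 2, "BIC": 2, "HQIC": 1}) == 2

    def test_max_p_bounds(self, uni_panel):
        from vetcoord.entropy import score_panel
        panel, _ = uni_panel
        _, scores = score_panel(panel)
        sel = pv.select_lag(scores, max_p=2)
        assert sel.consensus in (1, 2)
        with pytest.raises(ValueError, match="too short"):
            pv.select_lag(scores, max_p=8)

    def test_criteria_table_shape(self, uni_panel):
        from vetcoord.entropy import score_panel
        panel, _ = uni_panel
        _, scores = score_panel(panel)
        sel = pv.select_lag(scores, max_p=3)
        assert list(sel.criteria["p"]) == [1, 2, 3]
        assert {"AIC", "BIC", "HQIC"} <= set(sel.criteria.columns)


class TestEstimation:
    def test_quick_parameter_recovery(self):
        """FOD-IV estimates centre on the true null-regime coefficients."""
        mean_A = mc.coefficient_means("null", n_reps=50, seed=3,
                                      n_periods=50)
        assert abs(mean_A[0][0, 1]) < 0.05
        assert abs(mean_A[0][1, 0]) < 0.05
        assert np.allclose(np.diag(mean_A[0]), 0.4, atol=0.05)

    def test_determinism(self, uni_panel):
        from vetcoord.entropy import score_panel
        panel, _ = uni_panel
        _, scores = score_panel(panel)
        m1 = pv.fit_pvar(scores, p=2)
        m2 = pv.fit_pvar(scores, p=2)
        assert np.array_equal(m1.A, m2.A)
        assert np.array_equal(m1.eq_cov, m2.eq_cov)

    def test_constant_panel_is_singular(self):
        Y = np.full((5, 12, 2), 0.5)
        with pytest.raises(ValueError, match="singular"):
            pv.fit_panel_var(Y, p=2)

    def test_within_matches_statsmodels_var_without_effects(self):
        """On a long panel with no fixed effects, the pooled within
        estimator agrees with per-unit statsmodels VAR fits."""
        from statsmodels.tsa.api import VAR
        spec = sim.DGPSpec(
            n_units=3, n_periods=800, unit_effect_sd=0.0, time_effect_sd=0.0,
            A1=np.array([[0.45, 0.1], [0.3, 0.35]]),
            A2=np.array([[0.05, 0.0], [0.1, 0.05]]), seed=7)
        truth = sim.simulate_latent(spec)
        model = pv.fit_panel_var(truth.latent, p=2, method="within",
                                 time_effects=False)
        sm_A1 = np.mean(
            [VAR(truth.latent[i]).fit(2, trend="c").coefs[0]
             for i in range(3)], axis=0)
        assert np.allclose(model.A[0], sm_A1, atol=0.05)

    def test_both_estimators_run_at_study_dimensions(self, uni_panel):
        from vetcoord.entropy import score_panel
        panel, _ = uni_panel
        _, scores = score_panel(panel)
        for method in ("fod_iv", "within"):
            model = pv.fit_pvar(scores, p=2, method=method)
            assert model.A.shape == (2, 2, 2)
            assert np.all(np.linalg.eigvalsh(model.sigma_u) >= -1e-12)

    def test_bias_shrinks_with_panel_length(self):
        """Absolute bias of the own-lag coefficient decreases from T=10
        to T=50 to T=200 on the same regime and seeds."""
        biases = []
        for T in (10, 50, 200):
            mean_A = mc.coefficient_means("null", n_reps=30, seed=11,
                                          n_periods=T)
            biases.append(abs(mean_A[0][0, 0] - 0.4))
        assert biases[0] > biases[2]
        assert biases[1] < 0.05 and biases[2] < 0.02


class TestGranger:
    def _zero_cross_model(self):
        A = np.array([[[0.4, 0.0], [0.0, 0.3]], [[0.1, 0.0], [0.0, 0.1]]])
        eq_coefs = np.array([[0.4, 0.0, 0.1, 0.0], [0.0, 0.3, 0.0, 0.1]])
        eq_cov = np.stack([np.eye(4) * 0.01] * 2)
        return pv.PVARModel(
            order=2, subsystems=("VHR", "PAAW"), A=A, eq_coefs=eq_coefs,
            eq_cov=eq_cov, sigma_u=np.eye(2), method="fod_iv",
            time_demeaned=True, n_units=31, n_periods=10, nobs=217,
            n_clusters=31)

    def test_zero_cross_lags_give_zero_statistic(self):
        res = pv.granger(self._zero_cross_model()).to_frame()
        assert np.allclose(res["wald"], 0.0)
        assert np.allclose(res["wald_p"], 1.0)
        assert np.allclose(res["F_p"], 1.0)
        assert not res["reject"].any()

    def test_statistics_nonnegative_pvalues_in_unit_interval(self, uni_panel):
        from vetcoord.entropy import score_panel
        panel, _ = uni_panel
        _, scores = score_panel(panel)
        res = pv.granger(pv.fit_pvar(scores, p=2)).to_frame()
        assert (res["wald"] >= 0).all()
        assert res["wald_p"].between(0, 1).all()
        assert res["F_p"].between(0, 1).all()
        assert set(zip(res["cause"], res["effect"])) == \
            {("VHR", "PAAW"), ("PAAW", "VHR")}

    def test_unidirectional_pattern_in_majority_of_replicates(self):
        """Scoring + PVAR on the unidirectional regime at 31 x 10 mostly
        rejects VHR->PAAW while failing to reject PAAW->VHR."""
        B = 60
        rng = np.random.default_rng(77)
        seeds = rng.integers(0, 2 ** 31 - 1, size=B)
        pattern = 0
        for s in seeds:
            spec = sim.preset_regimes("unidirectional_vhr_to_paaw",
                                      seed=int(s))
            Y = mc.scored_array(spec)
            res = pv.granger(pv.fit_panel_var(Y, p=2)).to_frame()
            d = res.set_index(["cause", "effect"])["reject"]
            pattern += d[("VHR", "PAAW")] and not d[("PAAW", "VHR")]
        assert pattern / B > 0.5


class TestIRF:
    def test_analytic_oracle_companion_powers(self):
        """Module IRFs equal J F^h J' L computed from the companion matrix."""
        A1 = np.array([[0.5, 0.0], [0.3, 0.4]])
        A2 = np.array([[0.05, 0.0], [0.1, 0.02]])
        sigma = np.array([[1.0, 0.3], [0.3, 0.8]])
        H = 12
        resp = pv.analytic_irf(np.array([A1, A2]), sigma, H)
        F = sim.companion_matrix(A1, A2)
        J = np.hstack([np.eye(2), np.zeros((2, 2))])
        L = np.linalg.cholesky(sigma)
        for h in range(H + 1):
            oracle = J @ np.linalg.matrix_power(F, h) @ J.T @ L
            assert np.allclose(resp[h], oracle, atol=1e-10)

    def test_known_coefficients_horizon_one(self):
        """Response of PAAW to a VHR shock at horizon 1 equals A1[1,0]."""
        A1 = np.array([[0.5, 0.0], [0.3, 0.4]])
        resp = pv.analytic_irf(A1[None], np.eye(2), 3)
        assert resp[1, 1, 0] == pytest.approx(0.3)

    def test_horizon_zero_is_cholesky_factor(self, uni_panel):
        from vetcoord.entropy import score_panel
        panel, _ = uni_panel
        _, scores = score_panel(panel)
        model = pv.fit_pvar(scores, p=2)
        irf = pv.impulse_response(model, horizon=4)
        assert np.allclose(irf.responses[0],
                           np.linalg.cholesky(model.sigma_u), atol=1e-12)

    def test_decoupled_system_zero_cross_responses(self):
        A1 = np.diag([0.5, 0.4])
        resp = pv.analytic_irf(A1[None], np.eye(2), 10)
        assert np.allclose(resp[:, 0, 1], 0.0)
        assert np.allclose(resp[:, 1, 0], 0.0)

    def test_explosive_model_rejected(self):
        model = pv.PVARModel(
            order=1, subsystems=("VHR", "PAAW"),
            A=np.array([[[1.05, 0.0], [0.0, 0.5]]]),
            eq_coefs=np.zeros((2, 2)), eq_cov=np.stack([np.eye(2)] * 2),
            sigma_u=np.eye(2), method="fod_iv", time_demeaned=True,
            n_units=31, n_periods=10, nobs=217, n_clusters=31)
        with pytest.raises(ValueError, match="spectral radius"):
            pv.impulse_response(model, horizon=5)

    def test_negative_horizon_rejected(self, uni_panel):
        from vetcoord.entropy import score_panel
        panel, _ = uni_panel
        _, scores = score_panel(panel)
        model = pv.fit_pvar(scores, p=2)
        with pytest.raises(ValueError, match="horizon"):
            pv.impulse_response(model, horizon=-1)

    def test_ordering_flip_changes_contemporaneous_block(self, uni_panel):
        from vetcoord.entropy import score_panel
        panel, _ = uni_panel
        _, scores = score_panel(panel)
        model = pv.fit_pvar(scores, p=2)
        a = pv.impulse_response(model, horizon=2, ordering=("VHR", "PAAW"))
        b = pv.impulse_response(model, horizon=2, ordering=("PAAW", "VHR"))
        # VHR-first: VHR shock may move PAAW at h=0, not vice versa
        assert a.responses[0, 0, 1] == pytest.approx(0.0, abs=1e-12)
        assert b.responses[0, 1, 0] == pytest.approx(0.0, abs=1e-12)

    def test_bootstrap_bands_bracket_point_estimate(self, uni_panel):
        from vetcoord.entropy import score_panel
        panel, _ = uni_panel
        _, scores = score_panel(panel)
        model = pv.fit_pvar(scores, p=2)
        irf = pv.impulse_response(model, horizon=5, n_boot=25, seed=5)
        assert irf.lower.shape == irf.responses.shape
        frac_inside = np.mean((irf.lower <= irf.responses)
                              & (irf.responses <= irf.upper))
        assert frac_inside > 0.8
        frame = irf.to_frame()
        assert {"lower", "upper"} <= set(frame.columns)
        # deterministic given the seed
        irf2 = pv.impulse_response(model, horizon=5, n_boot=25, seed=5)
        assert np.array_equal(irf.lower, irf2.lower)
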