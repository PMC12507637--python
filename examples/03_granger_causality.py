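"""Stationarity screen, lag selection and Granger causality on scores.

Runs per-province ADF tests with the majority rule, picks the lag order
by AIC/BIC/HQIC consensus, fits the fixed-effects panel VAR (forward
orthogonal deviations + lagged-level instruments) and tests Granger
causality in both directions.
"""

from vetcoord import (preset_regimes, simulate_panel, score_panel,
                      panel_stationarity, select_lag, fit_pvar, granger)

spec = preset_regimes("unidirectional_vhr_to_paaw", seed=7)
panel, _ = simulate_panel(spec)
_, scores = score_panel(panel, index_spec=spec.index_spec())

summary = panel_stationarity(scores)
print("per-province ADF screen (share of provinces rejecting a unit root):")
print(summary.to_frame().to_string(index=False))
print("With only 10 annual observations per province the ADF test has low "
      "power, so small shares are expected on synthetic stationary data.\n")

sel = select_lag(scores, max_p=4)
print("lag-order criteria (smaller is better):")
print(sel.to_frame().round(3).to_string(index=False))
print(f"consensus lag order: {sel.consensus}\n")

model = fit_pvar(scores, p=2)
print("estimated lag matrices (true DGP: A1[PAAW,VHR]=0.40, "
      "A2[PAAW,VHR]=0.20, reverse cross-lags 0; entropy scoring rescales "
      "the units, the sign pattern is what carries over):")
print("A1 =\n", model.A[0].round(3))
print("A2 =\n", model.A[1].round(3))

res = granger(model).to_frame()
print("\nGranger causality (cluster-robust Wald, F form):")
print(res[["hypothesis", "F", "F_p", "reject"]].round(4).to_string(index=False))
print("\nThe workforce->attention null is rejected while the reverse is "
      "not: the estimated pattern matches the one-way regime that "
      "generated the data.")
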