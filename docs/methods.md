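# Methods

`vetcoord` analyses the coordination between two subsystems of an animal
health governance system observed as a balanced province-by-year panel:
**VHR** (veterinary human resources — the service-supply side, measured by
workforce indicators of township animal husbandry and veterinary stations)
and **PAAW** (public attention to animal welfare — the demand side,
measured by search-interest indices for animal-health keywords).  The
chain has four stages: entropy-weight composite scoring, a per-province
stationarity screen, fixed-effects panel-VAR causality analysis, and
coupling-coordination / relative-development classification.  A synthetic
generator with a fully known latent process provides ground truth for
validating every stage.

## Entropy-weight scoring

Within each (year, subsystem) cross-section of raw indicators `X[u, j]`
(u = province, j = indicator):

1. **Min–max normalisation.** Benefit indicators map to
   `(x − min)/(max − min)`, cost indicators to `(max − x)/(max − min)`.
   Exact zeros after mapping are replaced by a **0.01 floor** so every
   province contributes minimally; values that are merely small are left
   untouched.  A zero-variance indicator cannot be scaled and is set to
   the floor everywhere (with a logged warning).
2. **Entropy.** Each indicator's column is turned into proportions
   `P[u] = Y[u]/Σ_u Y[u]`, and `e_j = −(1/ln n) Σ_u P[u] ln P[u]` with
   n the number of provinces.  `e_j ∈ [0, 1]`; `e_j = 1` iff the
   indicator spreads all provinces identically (no information).
3. **Weights.** `w_j = (1 − e_j)/Σ_k (1 − e_k)` — weight grows with
   cross-sectional information content.  A constant indicator gets weight
   exactly 0; if *every* indicator is constant the weights fall back to
   equal with a warning.
4. **Scores.** `U[u] = Σ_j w_j Y[u, j] ∈ (0, 1]`.

Weights are computed **separately for each year**, so distributional
drift across periods cannot leak into a year's weighting.  The summation
axis is deliberate: proportions and entropy run *across provinces within
one year*, which is the only reading consistent with per-year weights.
An optional pooled normalisation (min/max over all years) is provided but
off by default, because it changes cross-year comparability of the
scores; entropy and weights remain per-year even then.

The scoring floor, normalisation and weight simplex guarantee scale and
shift invariance (affine transforms of any raw indicator leave scores
unchanged) and monotonicity (raising a province's benefit-indicator value
never lowers its score).  Both are enforced by property tests, and the
whole chain is checked against an independent brute-force evaluation on
random cross-sections to 1e-10.

## Stationarity screen

Each province's score series is tested by an ADF regression with a
constant (no trend — scores are bounded in (0, 1] and trendless by
construction), lag length chosen by AIC up to `max_lag` (default:
`min(2, T // 6)`, i.e. 1 for a 10-year panel).  A subsystem counts as
panel-stationary when the share of provinces rejecting the unit root at
the 5% level **strictly exceeds 50%** (both configurable).  Shares are
printed as percentages rounded half away from zero to one decimal
(25/31 → 80.6, 19/31 → 61.3).  A constant series is degenerate and is
flagged stationary with a warning rather than crashing the screen.
Homogeneous-panel and heterogeneous-panel pooled unit-root tests are
intentionally not implemented; the screen is the per-province ADF +
majority-rule procedure only.

Note that with ten annual observations per province the ADF test has
little power: on synthetic stationary panels of that length the rejection
share is typically well below 50%.  The screen is reported and warned
about, but it does not block estimation.

## Fixed-effects panel VAR

Model for `Y[i,t] = (VHR, PAAW)'`:

    Y[i,t] = A1 Y[i,t−1] + … + Ap Y[i,t−p] + μ[i] + λ[t] + ε[i,t]

**Year effects** λ[t] are removed by subtracting the cross-section mean
of each period.  **Province effects** μ[i] are removed by one of:

- `fod_iv` (default) — forward orthogonal deviations (Helmert
  transform): each observation is replaced by its scaled deviation from
  the mean of that unit's *future* observations.  The transform is
  applied jointly to the dependent rows and the already-built lagged
  regressors, and the untransformed lagged levels serve as instruments.
  With exactly p lags of instruments the system is just-identified, so
  the GMM estimator reduces to per-equation IV, `β = (Z'X̃)⁻¹ Z'ỹ`.
  This avoids the O(1/T) Nickell bias of demeaning, which matters at the
  study's T = 10.  Effective sample: n(T − p − 1) rows.
- `within` — within-unit demeaning + pooled OLS.  Simple, efficient for
  long T, biased for short T; it is also what the Gaussian lag-order
  criteria are computed on (likelihood criteria are not defined for the
  IV objective), and it is cross-checked against per-unit VAR fits from
  statsmodels on long no-effects panels.

Coefficient covariances are cluster-robust by province with the
`G/(G−1) · (N−1)/(N−k)` small-sample factor.  The innovation covariance
is estimated from the transformed residuals (the Helmert transform is
orthonormal, so it preserves the innovation covariance).

**Lag order** is chosen on a common sample (implied by `max_p`) by AIC,
BIC and HQIC in the `ln det Σ̂ + penalty` form; each criterion's
minimiser and the modal consensus are reported, all ties breaking toward
the smaller order.  On 10-period panels criteria computed over orders
above 2 can overfit (and the resulting fit may even be explosive), so
pipeline users with very short panels should cap `max_lag` near 2 — the
order the study design targets.

**Granger causality**: for each direction, a Wald test that all p
cross-lag coefficients from the candidate cause into the effect equation
are jointly zero, using the cluster-robust covariance.  Both the χ²(q)
form and the `F(q, G−1)` form are reported; rejection is decided on the F
form, the appropriate small-sample reference with ~31 clusters.  Under
the no-cross-lag synthetic regime at 31 × 10 the empirical size of this
test at the nominal 5% level is about 4–5%, and under the unidirectional
regime its power exceeds 60% while the reverse direction stays at size —
both verified by 500-replicate Monte Carlo in the acceptance suite.

**Impulse responses** are orthogonalised by Cholesky.  The default
ordering puts VHR first — consistent with the estimated direction of
causality (workforce shocks may move attention contemporaneously, not
vice versa) — and is configurable; both orderings are exposed.  Responses
come from the moving-average recursion `Φ_h = Σ_l Φ_{h−l} A_l`,
`Θ_h = Φ_h L`, verified against the companion-matrix power form to
1e-10.  Percentile confidence bands (default 95%) come from a
residual-resampling bootstrap: panels are rebuilt from the estimated
coefficients, estimated unit effects and residuals resampled with
replacement within each unit, then re-estimated; explosive bootstrap
draws fall back to the point estimate.  An estimated model with companion
spectral radius ≥ 1 refuses to produce IRFs.

## Coupling coordination and relative development

Per (province, year) with subsystem scores `U_V`, `U_A`:

- coupling degree `C = 2·√(U_V·U_A/(U_V+U_A)²) ∈ [0, 1]`, equal to 1 at
  parity; defined as 0 when both scores are 0 (the limit is
  indeterminate and 0 keeps the downstream label coherent);
- coordination index `T = α·U_V + β·U_A` with `α = β = 0.5` by default
  (the two subsystems are treated as equally important);
- coupling coordination degree `D = √(C·T)`, binned into **ten levels**
  over half-open deciles `[0, 0.1), …, [0.8, 0.9)` with a **closed top
  bin** `[0.9, 1.0]` ("Perfectly coordinated"; `D = 0.9` belongs to it);
- relative development `R = U_V/U_A`, classified as **VHR lag**
  (`R < 0.9`), **VHR-PAAW synchronization** (`0.9 ≤ R ≤ 1.1`, bounds
  closed) or **PAAW lag** (`R > 1.1`).  `U_A = 0` raises an error rather
  than returning infinity: the scoring floor makes it unreachable, so
  hitting it means corrupted input.

C measures balance only — `C = 1` at `U_V = U_A = 0.05` — whereas D folds
in the joint level: that example yields `D ≈ 0.224`, "Moderately
uncoordinated".  The identity `D² = C·T` holds to 1e-12 and the ten bins
form a total, disjoint cover of [0, 1]; both are asserted on large random
samples.

## Synthetic data generator

The generator emulates the structure the analysis assumes, not the
marginal distributions of real yearbook or search-index data.  Latent
subsystem levels follow the fixed-effects VAR(2) above with Gaussian unit
effects (sd 0.5), time effects (sd 0.3) and innovations (identity
covariance); the intercept `(I − A1 − A2)·offset` pins the stationary
mean at the level offset (10 per channel) so latent levels stay positive.
Fifty burn-in periods are discarded to remove initialisation transients.
Observable indicators are linear readouts — 4 workforce-like and 8
attention-like columns, loadings spread over 0.7–1.5, measurement-noise
sd 0.15 (about 10% of the latent fluctuation scale) — clipped at 1e-6 for
strict positivity.  Cost-type indicators are reflected about twice the
level offset, a sign flip of the fluctuation that keeps the observed
scale positive; all default indicators are benefit-type, matching the
published index system.  Gaussian innovations are an assumption of the
generator (chosen for tractable closed-form checks, e.g. the AR(1)
stationary variance `1/(1−a²)`), as is the linear indicator-measurement
model: the published index system states no measurement relationship, so
this is the simplest structure under which entropy scoring is a sensible
aggregator.

Named regimes: `null` (A1 = diag(0.4, 0.4), A2 = 0 — no cross-lags, for
test size), `unidirectional_vhr_to_paaw` (PAAW-equation loads on lagged
VHR with 0.40 at lag 1 and 0.20 at lag 2; zero reverse cross-lags;
companion spectral radius 0.613 — encodes the study's qualitative
finding, and its true-coefficient IRF peaks at horizon 2 then decays),
`bidirectional`, and `unit_root` (spectral radius exactly 1, carries
`stationary=False`; specs flagged stationary refuse lag matrices with
spectral radius ≥ 1, naming the radius).

What passing tests on this generator do **not** show: robustness to the
heavy tails, zero-inflation and cross-sectional dependence of real search
indices, to unbalanced panels, or to non-linear indicator-latent
relationships.  They do show that the implementation recovers known
dynamics, holds its nominal test size, and classifies coordination
exactly as defined.

## Problem sizes and numerical choices

Monte-Carlo studies use 500 replicates for size/power at the study
dimensions (31 × 10) and 200 replicates at 31 × 50 for estimator
recovery; lag-order recovery uses 31 × 30 panels.  These sizes give
Monte-Carlo standard errors below one percentage point on rejection rates
while keeping the full suite fast.  Recovery studies feed the estimator
the latent scores directly, since entropy scoring rescales the series and
hence the coefficient units; size/power studies run the *entire* chain
including scoring.  Other numerics: weights sum to 1 within 1e-12; the
singular-design guard triggers at condition number 1e12 and names the
offending columns; `C` is clamped at 1 to absorb float error at parity;
decile binning uses comparisons against the stored bin edges rather than
multiplication by 10, so boundary values classify exactly.

## Known limitations

- The FOD-IV estimator is just-identified by construction; no
  overidentifying-restriction diagnostics (nothing to test) and no
  two-step efficient GMM.
- No cointegration/VECM path, cross-sectional-dependence tests, or
  forecast-error variance decomposition.
- The stationarity screen is a robustness heuristic, not a pooled panel
  unit-root test; its low power at T = 10 is inherent.
- Grouped (regional) summaries are presentational averages only; no
  spatial statistics or cartography are computed, though the wide
  year × unit matrices are export-ready for mapping tools.
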