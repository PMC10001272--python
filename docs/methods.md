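# Methods

This note documents the models implemented in `tvlc`, the estimation and
tuning procedures, the synthetic data used to validate them, and the
numerical and design choices a user should know about.

## 1. The Lee–Carter core

For `N` ages observed over `T` consecutive years the log central death
rate is modelled as `ln m_{x,t} = a_x + b_x k_t + ε_{x,t}` under the
identification constraints `Σ_t k_t = 0`, `Σ_x b_x = 1`.  Estimation is
by SVD: `a_x` is the row mean of the log rates, and `(b, k)` the leading
singular pair of the row-centred matrix, rescaled to the constraints.
The sign is fixed by requiring the raw leading age vector to sum to a
positive number before rescaling, which makes the decomposition
deterministic.  Row-centring makes every right singular vector
orthogonal to the constant vector, so `Σ k_t = 0` holds to machine
precision by construction.

The period index follows a random walk with drift.  The drift is the
mean first difference, `d = (k_T − k_1)/(T−1)`; its innovation s.d. uses
denominator `T−2` because one degree of freedom is spent on the drift.
Mean forecasts are `k̂_{T+h} = k_T + h d`.

**Poisson drift adjustment.**  Treating the rates as death counts per
unit exposure (exposures may be supplied when available), each `k_t` is
re-estimated by one-dimensional Newton ascent of the Poisson
log-likelihood with `a, b` held fixed; the likelihood is concave in
`k_t`, so convergence is quadratic from the SVD value.  The re-estimated
index is re-centred to sum to zero and the centring constant absorbed
into `a` (`a ← a + b·mean(k)`), so fitted rates — and therefore the
Poisson likelihood — are unchanged by the re-centring.  The drift and
innovation s.d. are then refitted from the adjusted index.  This
adjustment is applied in every fitted model variant (the `lc` tag
included), reflecting the practice of adjusting the drift throughout.

**Fitting-period selection** (the second BMS-style adjustment, used by
the `bms` and `LL-BMS` variants): for each candidate start year the
model is refitted and the ratio of the mean squared deviation of `k_t`
about its linear trend to the squared trend increment is computed; the
earliest start within 5% of the minimum ratio is chosen, favouring
longer samples.  The exact criterion behind this selection is a design
choice of this package, isolated in one method so it can be swapped.

## 2. Time-varying loadings by kernel smoothing

Calendar time is rescaled to `τ = t/T ∈ (0, 1]`.  For a target year `t`
the loadings solve a locally weighted version of the Lee–Carter problem:
the columns of the centred log-rate matrix are scaled by `sqrt(w_s)`
with `w_s = K_b(τ_s − τ)`, and the leading left singular vector of the
weighted matrix — oriented to correlate positively with the static
loadings, rescaled to sum to 1 — is `b_{·,t}`.  Centring uses the
full-sample `a_x`: weighting the *uncentred* rates would conflate the
age level into the loadings.  The `sqrt`-weighting makes the weighted
Gram matrix match the Nadaraya–Watson local least-squares objective.

Kernels: Gaussian `K_b(u) = exp(−(u/b)²/2)/(√(2π) b)` and Epanechnikov
`K_b(u) = (0.75/b)(1 − (u/b)²)₊`.  The overall kernel height is
irrelevant (the SVD direction is scale-free); only the bandwidth
matters.  Near the sample ends the same truncated one-sided weights are
used with no boundary correction; the local-constant estimator is
therefore biased towards the interior near the boundaries, which is why
recovery checks in the test-suite evaluate the central half of the
years.  Bandwidths are expressed on the `τ` scale with an unconstrained
positive grid, so both sub-unit and effectively-uniform (`b ≫ 1`)
regimes are reachable.

## 3. Age-coherent loading forecasts

Age coherence requires that no two ages' log-rate forecasts diverge as
`h → ∞`.  Since the long-run mortality improvement at age `x` is
`b̂_{x,T+h}·d`, coherence forces every `b̂_{x,T+h}` to a common limit,
which the constraint `Σ_x b = 1` pins at `1/N`.  The centred loadings
`b* = b − 1/N` are therefore modelled as a zero-mean stationary process
with a banded-coefficient VAR(1): age `i` loads on its own lag (`α_i`),
the same cohort one age younger (`β_i`) and two ages younger (`γ_i`),
with edge equations for the first two ages.

Estimation minimises the squared-error loss plus cross-age roughness
penalties on each coefficient sequence.  The penalties couple
neighbouring ages, so all `3N−3` coefficients are found in a single
symmetric positive-definite solve (Cholesky); with all penalties zero
the system decouples into per-age OLS.  A singular system (e.g.
time-constant loadings with zero penalties, where the three lag
regressors are collinear) raises an error advising positive penalties.
The second edge equation enters the loss squared, like every other term
— the objective is a quadratic form throughout.

Forecasts iterate the fitted recursion with zero innovations, add back
`1/N` and rescale each horizon's vector multiplicatively to sum exactly
to 1 (add-back first, then rescale).  Stationarity is *reported*, not
enforced: the companion matrix's spectral radius is computed and a
non-stationary fit attaches a warning to the results and forecasts while
forecasting proceeds.  On rare simulated draws the tuned fit is mildly
explosive and long-horizon forecasts diverge; summaries across
replicates therefore use medians.

**Diagnostics.**  Per age, stationarity of `b*` is screened by the
augmented Dickey–Fuller test (constant, no trend, AIC lag selection up
to 4); failing to reject at the 5% level counts as a failure.  Adequacy
of a single lag is screened by an F-test of the lag-2 block (own age and
the two next-younger ages) added to the constrained lag-1 regressors.
Counts out of `N` are tabulated per test.

## 4. Tuning

The bandwidth and penalty triple are selected on a hold-out sample: with
the 1-based boundary `⌊2T/3⌋`, years `1..boundary−1` train and
`boundary..T` test (for `T = 70`: 45 training, 25 test years).  For each
grid point the loadings are kernel-estimated on the training years, the
VAR fitted, the loadings forecast across the test window, log rates
assembled with the full-sample `a`, the full-sample `k` at the training
boundary and the full-sample drift, and scored by RMSFE on the logged
scale.  This "paper" leakage mode is the literal 5-step procedure; a
"strict" mode that refits `a, k, d` on the training years only is
available for users who want tuning fully blind to the hold-out window.
Expanding-window cross-validation is deliberately not offered: the
models target long-horizon accuracy, which short-step expanding windows
do not measure.

Defaults: bandwidth grid `{0.05, 0.1, 0.2, 0.4, 0.8, 1.6, 3.2, 6.4,
12.8}`; penalty grid `{0, 0.01, 0.1, 1, 10, 100}` searched with
`λ_α = λ_β = λ_γ` first, then one pass of per-penalty coordinate
refinement.  Grid points that fail to fit are skipped with a logged
reason.  Exact ties are broken towards the larger bandwidth, then larger
penalties — the smoother model.  Given identical inputs and grids the
selection and forecasts are deterministic.

After tuning, the kernel loadings and the VAR are refitted on the full
sample at the selected values, and forecasts follow
`ln m̂_{x,T+h} = â_x + b̂_{x,T+h}(k̂_T + h d)` with `â, k̂_T, d` from the
full-sample (drift-adjusted) static fit.

## 5. Life tables and prediction intervals

A year's rate schedule converts to a period life table with
`q_x = m_x/(1 + 0.5 m_x)` (deaths spread uniformly in the year of age,
`a_x = 0.5`, no separate infant correction), `L_x = l_x − 0.5 d_x`, and
the open age group closed by exposure, `L = l/m`.  Under a constant rate
`m` this telescopes exactly to `e0 = 1/m`, which the tests use as a
closed-form anchor (m = 0.02 → 50, m = 0.01 → 100).

Prediction intervals simulate only the innovation uncertainty of the
period index: `n ≥ 1000` Gaussian shock paths accumulate into `k` paths,
each mapped through the model's (static or forecast) loading path to
log rates and `e0`; the band is the empirical percentile interval.
Drift-estimation and loading uncertainty are deliberately excluded, so
with estimated parameters the realised coverage sits a few points off
nominal — below when drift error dominates, above when measurement
noise inflates the estimated innovation s.d.  The calibration test
builds the interval at known true parameters, where coverage is nominal
up to Monte-Carlo noise; the acceptance script reports the fitted-model
coverage alongside as a diagnostic.  With the same seed the intervals
are bit-reproducible; with `σ_e = 0` they degenerate to the point path.

## 6. Multi-population extensions

The Li–Lee model adds a common factor: `ln m_{x,t,j} = a_{x,j} + B_x K_t
+ b_{x,j} k_{t,j} + ε`.  The common pair `(B, K)` is the chosen
single-population fit (LC, BMS, LC-E or LC-G) on the log rates averaged
across populations (geometric mean of rates); tuning for the
time-varying variants happens on the averaged population only.  Each
population's residual matrix — its log rates minus its own age means and
the common component (`B_x K_t`, or `B_{x,t} K_t` for the time-varying
variants, whose in-sample common loadings are time-indexed) — is
decomposed by one SVD factor with `Σ_x b_{x,j} = 1`; the residual index
`k_j` is *not* re-centred, since the residual level belongs to it.  Each
`k_j` follows an AR(1) with intercept (least squares), so population
deviations mean-revert: forecasts are population-coherent.  A
non-stationary fitted AR(1) is flagged and used as-is.  Forecasts add
`a_{x,j}`, the variant's common term, and the AR(1) mean recursion;
population loadings `b_{x,j}` stay static in every variant.  Plain LL is
not age-coherent (its static `B_x` times the drifting `K` separates
ages linearly in `h`); LL-E/LL-G inherit age coherence from the
constrained VAR on the averaged population.

## 7. Synthetic data

The generator produces surfaces with known truth:
`ln m_{x,t} = a_x + b_{x,t} k_t + ε`, with a piecewise-linear bathtub
baseline (infant log-rate −4 falling to a childhood minimum −9.5 near
age 10, then near-Gompertz increase of 0.085 per year of age), loadings
interpolating from `b_start ∝ exp(−x/25)` (young-age-heavy declines,
matching the historical pattern) towards the flat `1/N`, and a
random-walk-with-drift period index started at 0, centred to sum to
zero after simulation so the static fit's constraint is attainable
exactly in noiseless tests.

Defaults are one population of `N = 101` ages × `T = 70` years — the
scale of a single-country 1950–2019 extract — with drift `d = −1.5`/yr,
innovation s.d. `σ_e = 0.4`, cell noise `σ_eps = 0.02` (log scale), and
a logistic rotation schedule centred mid-sample with scale `0.15·T`.
The mid-sample midpoint matters: observed low-mortality populations show
the rotation well underway *within* recent sample windows, and a
generator whose rotation only begins at the sample end would make the
in-sample loadings a pure trend with near-unit-root fitted dynamics — a
different regime from the mean-reverting loading dynamics the coherent
VAR targets.  A small profile (`N = 20, T = 30`) serves fast tests.
Panels add a shared common factor weighted by `common_share` plus
independent stationary AR(1) population factors.

What the generator does **not** emulate: cohort effects, sex-specific
structure, demographically calibrated rate levels (the bathtub is
stylised; synthetic `e0` levels are arbitrary), heteroscedastic
old-age sampling noise, and mortality shocks (wars, pandemics).
Passing tests therefore demonstrate correctness of the estimation and
forecasting machinery under the model's own assumptions plus smooth
rotation — not forecast accuracy on any real population.

## 8. Numerical choices and limitations

- SVD sign convention: positive sum of the raw leading age vector;
  loading columns in the kernel fit are oriented by positive correlation
  with the static loadings.
- The PLS system is solved by Cholesky; singularity raises with advice
  to use positive penalties.  Conditioning degrades when neighbouring
  ages' loading series are nearly collinear and penalties are near zero.
- Hold-out scoring shares the full-sample `a, k, d` across all grid
  points ("paper" mode), so bandwidth differences are judged purely on
  the loading forecasts.
- The hold-out boundary uses integer floor arithmetic.
- Missing cells survive reading (as NaN, never zero) but every model
  constructor rejects incomplete surfaces; imputation is out of scope.
- Five-year age grouping averages *log* rates with equal weights;
  death-weighted grouping would require exposures.
- The open age group is stored under its lower bound (e.g. "110+" → 110).
- Forecast rescaling guards against a vanishing loading sum and raises
  rather than returning unbounded loadings.
- Known limitations: no parameter-uncertainty intervals (innovation-only
  by design); no cohort terms; no stochastic simulation of loading paths
  (loadings are forecast deterministically); stationarity of the fitted
  VAR is diagnosed, not imposed; single-sex (total) analysis only.
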