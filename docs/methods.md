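# Methods

This note records the models implemented in `cocoflux`, the choices made
where the design was genuinely open, and what the synthetic-data-based
tests do and do not demonstrate.

## Design and data model

The experimental object is a two-factor face-centered central composite
design (axial points at α = 1): pressure 50–200 kPa and temperature
20–40 °C, coded so that (low, center, high) → (−1, 0, +1). The embedded
pilot dataset holds 9 unique conditions and 29 samples: the five
individual center replicates are stored as measured, while the eight
non-center conditions carry their published condition mean with
multiplicity three, because the individual replicate values were never
published. This mean-filling preserves every condition sum, hence every
least-squares fit on the full sample set — all reduced-model
coefficients and predictions are exact — but it deflates the pure-error
sum of squares at non-center conditions, so sample-level error metrics
computed on the fixture (AAD, MSE, R²) are only approximate. Replicate
standard deviations are carried as condition metadata.

Coded space is canonical internally; actual units appear only at I/O
boundaries (CSV design tables, CLI flags, surrogate scalers).

## Quadratic response surfaces

The full model is the six-term polynomial in the coded factors, fitted
by OLS over all individual samples, which is equivalent to a weighted
fit on unique conditions with replicate-count weights (asserted
numerically in the tests). The reproduction pipeline ("paper" preset)
is: fit the full model, drop every non-intercept term with *p* ≥ 0.05
(two-sided *t* test on the full-model coefficients; ties at *p* = α
retain the term), refit the reduced model. On the pilot data this drops
the pressure linear term for flux and the temperature linear plus
pressure quadratic terms for the fouling index, and reproduces all
published model predictions to ±0.01 — with one exception: the
published flux prediction at the (−1, −1) corner (347.53) is
inconsistent with the value implied by every other row (347.73); the
package treats this as a typo in the source table and asserts the
recomputed value.

Because the design is balanced, the pressure-linear column is
orthogonal to all other columns: dropping it changes no other flux
coefficient, and the center prediction equals the intercept in both
the full and the reduced model.

ANOVA follows the classical RSM decomposition: SS_total =
SS_regression + SS_residual, with SS_residual split into lack-of-fit
and pure error from within-condition replicate scatter; F_cal =
MS_regression/MS_residual is compared against the F quantile at
α = 0.05 with (df_regression, df_residual). Prediction uncertainty is
the standard error of the fitted mean response from the reduced-model
coefficient covariance; no wider intervals are reported by default.

Surface optimization over the coded box is exact: the interior
stationary point (when the Hessian is nonsingular and the point lies
inside), the four edge-wise 1-D stationary points, and the four corners
are enumerated and compared. On the pilot flux surface the analytic
maximum is ≈(126.9 kPa, 32.8 °C) at ≈671.9 L h⁻¹ m⁻²; evaluating the
surface at the externally reported optimum (128.5 kPa, 32.90 °C)
reproduces 671.84. The fouling minimum lies on the low-pressure edge of
the box (the pressure coefficient is positive), so no interior fouling
optimum exists; the package reports the boundary point and flags it.

## Neural surrogate

Architecture is fixed at 2-5-2: tansig hidden layer
(2/(1+e^(−2n)) − 1; a commonly garbled rendering of this formula was
normalized to the standard form), purelin output. Inputs and outputs
are min–max scaled to [−1, 1]; scalers are fitted on all 29 samples by
default (configurable to training-subset-only; the original fitting
basis is unstated). Constant variables map to 0 and invert to the
constant.

Training minimizes perf = (1−λ)·MSE_scaled + λ·MSW with λ = 0.10, where
MSW is the mean squared weight/bias — the convention of the toolbox
"regularization parameter". The optimizer is damped Gauss–Newton
(Levenberg–Marquardt) on the augmented residual vector
[√((1−λ)/N)·e; √(λ/27)·θ] with analytic Jacobian: μ₀ = 10⁻³, ×10 on a
rejected step, ÷10 on acceptance, μ_max = 10¹⁰, at most 1000 epochs.
The objective is non-increasing across accepted steps by construction.
Early stopping monitors the validation MSE with a patience of 6
consecutive failures and restores the best-validation weights.

Samples are split 70/15/15 at the sample level by largest-remainder
apportionment with remainder ties resolved test > validation > train,
giving 20/4/5 at n = 29. `select_best` runs N restarts (default 20),
each with a **fresh random split and fresh uniform [−0.5, 0.5] weight
initialization** drawn from one seed sequence, and keeps the restart
with the lowest validation MSE. Re-drawing the split per restart
mirrors toolbox practice (data are re-divided on every training call)
and matters statistically: selecting 20 restarts against a single
4-sample validation subset overfits the selection, occasionally
producing networks with excellent validation MSE but poor overall fit;
with per-restart splits the best-of-20 all-sample pooled R² is
typically ≈0.97–0.98 on the pilot data.

The exact network predictions of the original study depend on
unrecorded random initializations and are treated as reference points,
not regression targets: tests assert stochastic envelopes (center-point
flux within ±5% of 659.19; setpoint flux within [590, 680]).

## Genetic algorithm

A seeded, bounded, single-objective GA in the minimization convention
(flux runs use fitness = −J_p, so best-fitness values are negative).
Operators — the original study's solver defaults are not fully
specified, so a documented, testable set is used: tournament selection
of size 2, blend (BLX-0.5) crossover on 80% of non-elite offspring,
Gaussian mutation with linearly decaying step size (initial σ = 15% of
each factor span) resampled until feasible, elites (5% of 120) copied
unchanged. Termination: 50 generations or 8 stall generations with
best-fitness improvement below 10⁻⁶. Elitism makes the best-fitness
trajectory non-increasing for every seed. Against the closed-form
stationary point of the reduced flux surface the GA lands within
0.01 kPa / 0.01 °C at the default budget.

## Model comparison and cross-validation

The metric suite operates at the sample level. R² uses the
conventional denominator Σ(X_A − X_M)² around the experimental mean;
printed variants of these formulas that use the predicted-value
denominator or omit the RMSE_CV square root are reachable behind a
`literal_denominator` flag but are not the default, because the
interpretation of negative Q² ("worse than predicting the mean")
requires the conventional forms. MPE normalizes by the prediction and
is flagged unreliable when any prediction is zero.

LOCO CV holds out all replicates of one condition per fold and refits
the model factory on the remainder; pooled held-out predictions give
Q² and RMSE_CV. The default is 9 condition-folds (true grouping, no
replicate leakage); a "row" scheme treats each design-table row as a
fold (13 on the pilot data, splitting the center replicates into
singleton folds) for compatibility with descriptions that count 13
conditions. On the pilot data the quadratic surface attains Q² ≈ 0.36
(flux) and ≈ 0.79 (fouling index), while the neural surrogate's flux
Q² is negative — the surrogate generalizes worse than the experimental
mean across held-out conditions — matching the qualitative finding of
the source study; exact Q² values are not reproducible because the
original replicate values and network seeds are unpublished.

## Fouling analysis

Resistance-in-series bookkeeping uses SI units internally
(1 L h⁻¹ m⁻² = 2.7778·10⁻⁷ m s⁻¹) and water viscosity 1.0 mPa s.
The four stage permeances (clean membrane, post-process, post-physical
clean, post-chemical clean) partition the total resistance through
reciprocal differences; the telescoping identity R_M + R_C + R_R + R_I
= 1/(µ_w·Lp₁) holds to machine precision by construction and is
property-tested on random staircases. The permeance-based fouling
index 100·(1 − Lp₁/Lp₀) is the design response; the in-run relative
flux decline 100·(1 − J_end/J₀) is a different quantity (it includes
fully reversible polarization) and is exposed as a separate helper.

Hermia fits regress each law's linearized transform (ln J, J^(−1/2),
J^(−1), J^(−2)) on time by OLS; mechanisms are ranked by the R² of the
linearized fit, the original comparison criterion. A "mixed regime"
note is attached when the top two R² differ by less than 0.01, and an
optional burn-in parameter (default 0) excludes the initial
polarization-dominated decline. The decomposition of the decay
constants into physical blocking coefficients (K·v₀ products) is not
estimated: flux data alone cannot identify those factors.

## Techno-economics

The baseline scenario: 1 t of green coconut per batch, 1346 batches
over 300 days (1,346,000 kg/year feed), whole-fruit composition
33.6/16.5/30.4/19.5% (husk/shell/albumen/water), products priced
US$16.80 per 10×1 L case of coconut water and US$11.20 per 10×0.4 kg
case of pulp, discount rate 13%, inflation 4%, 20 operating years,
30-month construction, 4-month startup. CAPEX (US$959,000) and OPEX
(US$1,178,000) line items are scenario inputs, not recomputed — their
derivation belongs to a proprietary flowsheet simulator. The published
coconut-water case count (2574.21/year) is inconsistent with the
published water revenue (US$432,468 at US$16.80/case); the implied
25,742.1 cases/year is used, with the printed string preserved in
scenario metadata.

Cash-flow timing is deliberately simple and fully stated: CAPEX spreads
over construction years by calendar overlap, operating flows accrue
pro-rata from the end of startup, all flows inflate from year 0 and are
summed at year-end, and NPV discounts flow t by (1+rate)^t. Taxes,
depreciation schedules and working-capital release are not modeled, so
the headline NPV/IRR/payback of the source analysis are **not**
reproduction targets; the package targets the accounting identities
(demand, prices, revenue components, sensitivity price grid) and
self-consistency properties (npv(flows, irr(flows)) = 0; NPV monotone
in the price multiplier; the −20% price scenario is loss-making). Gross
margin (revenue − OPEX)/revenue evaluates to 25.85% with the rounded
published OPEX versus the printed 25.88%; the gap is documented, not
asserted.

## Synthetic data

Generators are pure functions of spec + seed. FCD generation adds
Gaussian replicate noise to a known quadratic (defaults: the
pilot-refit flux/fouling coefficients, SD 15 and 1 respectively,
matching the pilot replicate scatter); flux-decline generation
multiplies a closed-form decay by lognormal noise with the first point
exact (default: intermediate law, J₀ = 600 L h⁻¹ m⁻², 2-min sampling
over 2 h, decay constant set by exact inversion to the pilot's ≈91%
in-run decline); permeance staircases are constructed by inverting the
telescoping identity for requested resistance shares.

What passing tests show: the estimators recover known truth under the
noise structure they assume (Gaussian replicates, lognormal decay
noise), at the pilot's magnitudes. What they do not show: robustness to
feed variability between batches, non-stationary fouling kinetics,
temperature-dependent viscosity, or model misspecification beyond the
four blocking laws — real coconut-water runs contain all of these.

## Problem sizes and numerical choices

The test suite trains best-of-20 networks on 29 samples (a few seconds
per selection), runs GA searches at the full 120×50 budget, and uses
200-seed simulation studies for the stochastic recovery claims
(mechanism selection top-1 rate, 2-SE coefficient coverage) — sizes
chosen so the whole suite completes in well under a minute while
keeping binomial fluctuations small against the asserted rates.
Degenerate inputs are handled explicitly: constant responses
(degenerate Hermia ranking in fixed law order; constant-variable
scalers), flat surfaces (flagged optimum), non-finite GA fitness
(candidate assigned +∞ and counted), rank-deficient designs (explicit
singular-fit error), and fold failures in cross-validation (reported
per fold, never fatal).
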