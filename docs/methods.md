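# Methods

This note records the models implemented in `mabvisc`, the numerical
choices behind them, what the synthetic-data generators do and do not
emulate, and the design decisions taken where more than one defensible
option existed.

## Concentration–viscosity models

Four parametric curves are fitted to per-molecule profiles of dynamic
viscosity η (cP) against concentration c (mg/mL):

| model | equation | free parameters |
|---|---|---|
| exponential growth | η = Y₀·e^{kc} | Y₀ (cP), k (mL/mg) |
| three-parameter exponential | η = e^{a₁ + a₂c + a₃/T} | a₁, a₂ (mL/mg), a₃ (K) |
| modified Ross–Minton | η = η₀·exp([η]c/(1 − κ_ν[η]c)) | [η] (mL/mg), κ_ν = k/v |
| Tomar | η = η₀·e^{lnA + Bc} | lnA, B (mL/mg) |

η₀ is the formulation-buffer viscosity, fixed at 1.13 cP by default. The
Ross–Minton curve has a pole at c = 1/(κ_ν[η]); admissible parameters keep
it beyond the data range.

**Estimation.** Bound-constrained nonlinear least squares
(`scipy.optimize.least_squares`) from a deterministic multi-start grid
seeded by the log-linear regression of ln η on c. This replaces
spreadsheet-style generalized-reduced-gradient solving with a reproducible
procedure that is insensitive to a single bad starting point. The
Ross–Minton fit runs in the reparametrisation (x₁, x₂) = ([η], κ_ν[η]), so
the singularity constraint 1 − κ_ν[η]c > 0 over the data becomes the box
bound x₂ < 1/c_max and the optimizer can never step across the pole.
Convergence tolerances are 1e−14 on parameters, cost and gradient.

**Identifiability.** At a single temperature a₁ and a₃/T enter the
three-parameter model only through their sum, so the fit estimates the
combined intercept (reported as a₁) and pins a₃ = 0, with residual degrees
of freedom counted for two free parameters. a₃ is meaningful only with
multi-temperature data, which the containers carry but the study design
does not exercise.

**Uncertainty.** Parameter covariance comes from the linearized Jacobian
at the optimum. The default is the HC1 heteroscedasticity-consistent
sandwich estimator, (JᵀJ)⁻¹Jᵀdiag(r²)J(JᵀJ)⁻¹·n/(n−p): viscometer noise
scales with the reading while the fit is deliberately unweighted (no
weighting scheme is part of the protocol), and the classic homoscedastic
σ²(JᵀJ)⁻¹ then understates prediction uncertainty at the high-viscosity end
— in seeded simulations at 5% proportional noise its 95% prediction
intervals cover the truth only ~88–90% of the time, versus ~92–93% for the
sandwich form. `cov_type="classic"` restores the textbook estimator.
Prediction intervals use the first-order delta method with a Student-t
quantile at n − p degrees of freedom; a rank-deficient Jacobian flags the
covariance unavailable rather than failing.

**Goodness of fit.** R² = 1 − SS_res/SS_tot about the observed mean, also
for the nonlinear models — convenient and comparable across models, though
not a likelihood-based criterion.

**Knee.** The knee is the root of dη/dc = 1 cP·mL/mg (units are part of
the definition). Closed forms exist for three models —
c = ln(1/(Y₀k))/k (growth), c = (ln(1/a₂) − a₁ − a₃/T)/a₂ (3-parameter),
c = ln(1/(Bη₀A))/B (Tomar) — and the Ross–Minton knee is bracketed and
solved by Brent's method on dη/dc − 1 = η[η]/(1 − κ_ν[η]c)² − 1 to
|Δc| < 1e−9 (residuals in practice < 1e−10). When the slope already
exceeds 1 at c = 0 the status is `slope_exceeds_one_at_zero`; a curve whose
slope never reaches 1 before the pole reports `no_root_in_range`. Knees
averaged across models use only `ok` statuses and report how many models
contributed.

**Regimes.** c ≤ 120 mg/mL is the high-concentration regime; the
ultra-high regime (≤260 mg/mL) includes the high-range data by default,
with `ultra_inclusive=False` giving the strictly-above-cutoff variant. The
regime contrast at a query concentration is the symmetric percent
difference 100·(η_ultra − η_high)/mean(η_ultra, η_high), bounded by ±200%
and antisymmetric under regime exchange; the sign convention is
ultra minus high. Cross-regime rank agreement uses Spearman correlation
with average ranks for ties.

## Dilute-solution viscometry

Within the 5–50 mg/mL window (configurable; an optional drop-top-k
parameter excludes the highest concentrations rather than any silent
curvature heuristic) the analysis computes η_rel = η/η₀, η_sp = η_rel − 1
and η_red = η_sp/c. Concentrations are converted to g/mL for the linear
extrapolations so [η] is in mL/g and k_H is dimensionless.

* Huggins: OLS of η_red on c; intercept [η]_H, slope x = k_H[η]².
* Logarithmic route: OLS of ln(η_rel)/c on c; intercept [η]_K. The two
  intercepts are averaged, [η]_avg = ([η]_H + [η]_K)/2, and
  k_H = x/[η]_avg².
* Polynomial route: zero-intercept least squares of η_rel − 1 on (c, c²);
  [η]_v = k₁ (reported in mL/g).
* Exponential coefficient: η_rel = e^{k_exp·c} by nonlinear least squares,
  with the zero-intercept log-linear regression available as an option (the
  two coincide exactly on noiseless exponential data).

The k_H uncertainty follows the propagation expression
σ_kH = k_H·sqrt((σ_x/x)² + (σ_{[η]²}/[η]²)² − 2σ_{[η]²}σ_x/([η]²x)) with
σ_{[η]²} = 2[η]σ_{[η]}. The cross term as written assumes fully correlated
slope and intercept errors; because that correlation is a modelling
convention rather than an estimated quantity, an independent-errors variant
(no cross term) is available behind `include_cross_term=False`.

DLS series are fitted by OLS as D_app = D₀(1 + k_D·c) on the 1–20 mg/mL
window; k_D = slope/D₀ with a ratio-delta-method standard error from the
full OLS covariance. A non-positive intercept (D₀ ≤ 0) is an error, not a
result.

## Hydrodynamics

r_h = (3[η]M_w/(10πN_A))^{1/3} with [η] converted to nm³/g; the 10π
constant embeds the rigid-sphere Einstein coefficient. φ(c) =
(cN_A/M_w)(4/3)πr_h³ with c in g/nm³; φ ≥ 0.74 (random close packing)
triggers a crowding warning instead of an error, since extrapolated φ is
routinely inspected beyond validity. The shape ratio ρ = R_g/r_h is ~0.775
for globular proteins (solid uniform sphere: sqrt(3/5) ≈ 0.7746). The
shape coefficient Ψ = SASA/V^{2/3} is scale-invariant (sphere: ≈4.836) and
maps to the shape factor via the empirical line Ψ = 1.454v + 7.085,
implemented verbatim; note the line assigns a sphere a negative v, so only
comparative use across similar molecules is meaningful. R_g, SASA, V and
M_w are external-tool inputs — no structure computation is done here.

## Sequence descriptors and predictors

The hydrophobic index HI = −Σn_iE_i / Σn_jE_j partitions the alphabet into
hydrophobic {A,C,F,I,L,P,V,G,W,Y} and hydrophilic {D,E,H,K,M,N,Q,R,S,T}
residues (M deliberately on the hydrophilic side, as the index is defined)
and scores both sums with the embedded Eisenberg (1984) normalized
consensus scale. Net charges use a Henderson–Hasselbalch sum over D, E, C,
Y, H, K, R and the free termini with a named pKa table (EMBOSS values by
default, Grimsley–Scholtz–Pace selectable) at formulation pH 6.0; the
sequence pI is the bisection zero of that monotone function. FvCSP is the
product of the VH and VL net charges — a convention, since the charge
model behind published FvCSP values is tool-dependent. Structure-derived
descriptors (pI3D, WALTZ/TANGO scores, ensemble charge, patch counts) are
always inputs.

Viscosity banding: green ≤ 20 cP, amber strictly between 20 and 30 cP,
red ≥ 30 cP; the binary acceptability threshold is 30 cP, with both
boundary values resolved to the stricter band (20 → green, 30 → red). The
ensemble-charge rule predicts low viscosity iff ens_charge ≥ +2
(inclusive), scored as a 2×2 confusion matrix with "low" as the positive
class and accuracy in percent.

The three empirical predictors are applied with their published
coefficients, never refitted. The Sharma log₁₀-linear equation is
typeset ambiguously in circulation; the default reading uses coefficients
(0.15, 1.26, −0.043, −0.02) — the interleaved 0.6/0.015 fragments are
treated as uncertainty values — and every coefficient is exposed in a
configuration mapping so another parse can be swapped in. The anchor
sharma(0,0,0) = 10^0.15 holds under any parse. The Tomar predictor shares
its functional form with the Tomar curve model (lnA = −0.58,
B = −0.0044·pI3D + 0.056), so predictions and curve evaluations agree by
construction; its c = 0 value falls below η₀, which is preserved with a
warning rather than clamped — the model is only used at high
concentration.

## PLS knee regression

NIPALS with autoscaled X and y (autoscaling chosen because descriptors mix
scales by orders of magnitude; `scale=False` is available), component
weights normalized to unit length, deflation after each component, and an
inner-iteration tolerance of 1e−10 (for a univariate response the weight
update converges in one pass). Coefficients are returned on the original
descriptor scale. Component count is selected by leave-one-out
cross-validation: PRESS(a) = Σ(yᵢ − ŷ₋ᵢ(a))², Q² = 1 − PRESS/SS_tot, the
minimum-PRESS count wins and ties go to fewer components (parsimony).
An optional pre-filter keeps descriptors with |Pearson r| > 0.5 against
the response. With all components on full-rank X the fit equals OLS — the
suite checks this against a normal-equations oracle and against an
independent PLS implementation. Test-set evaluation reports R² about the
test mean, RMSE and Pearson R; constant predictions are flagged degenerate
(R undefined) rather than silently returning a correlation.

## Synthetic data: what it does and does not emulate

Generators draw from `numpy.random.SeedSequence`-spawned streams so a
single spec-level seed reproduces every input byte-for-byte. Defaults
mirror the study conditions: viscosity profiles on a 20–260 mg/mL grid in
duplicate (N = 2) with 5% proportional Gaussian noise (typical
microfluidic-viscometer repeatability), replicates averaged with their
standard deviation recorded; dilute series with exact Huggins structure on
5–50 mg/mL; DLS series linear in c on 1–20 mg/mL; mutant panels as
validated single-residue substitutions of a base Fv; descriptor matrices
as correlated Gaussians (pairwise r = 0.3) with a known linear response.

The generators do not emulate shear-rate dependence (profiles are assumed
Newtonian), cluster formation or other non-Huggins curvature, instrument
drift, or non-Gaussian error tails. Passing tests therefore demonstrate
estimator correctness and calibration under the assumed noise model, not
robustness of the science to real-data pathologies such as the
low-concentration DLS artifacts or charge-screening effects that genuine
panels exhibit.

For the PLS sanity envelope, a 9-molecule, 5-descriptor panel with
response noise at a quarter of the coefficient scale yields training R² in
the 0.6–0.9 band across seeds — an order-of-magnitude check, not a
reproduction of any particular dataset, since raw descriptor and knee
values for real panels are not published.

## Problem sizes and numerical conventions

Acceptance-style checks use 100-draw parameter sweeps for knee
consistency, 500 seeded repetitions for interval coverage, 200 for the
null-model Q² expectation, and 300 for dilute-estimator calibration —
sizes at which the Monte-Carlo standard error is comfortably below each
asserted margin. All concentrations are mg/mL internally; intrinsic
viscosities are reported in mL/g (×1000 from mL/mg); N_A is the SI-exact
6.02214076e23. Degenerate inputs fail loudly: fewer than three points,
non-positive viscosities, zero-variance descriptor columns, empty regime
segments and Ross–Minton grids crossing the singularity are all errors
naming the offending quantity.

## Known limitations

* The three-parameter exponential's a₃ is unidentifiable from
  single-temperature data and is reported only as part of the combined
  intercept.
* Delta-method intervals are first-order; strongly nonlinear parameter
  posteriors (e.g., Ross–Minton near its pole) are approximated, not
  captured.
* The Sharma coefficient reading and the FvCSP charge convention are
  documented choices; predictions should be compared across molecules, not
  taken as absolute calibrated viscosities.
* R² about the mean can be negative for poor nonlinear fits and is not a
  model-selection criterion across different regimes' data.
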