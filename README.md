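# mabvisc

Analysis toolkit for the solution viscosity of therapeutic monoclonal
antibodies (mAbs). Subcutaneous dosing pushes formulations to high
(≤120 mg/mL) and ultra-high (≤260 mg/mL) protein concentrations, where
viscosity grows pseudo-exponentially and becomes a manufacturability and
injectability risk. `mabvisc` implements the quantitative machinery used to
characterise and predict that behaviour:

* **Concentration–viscosity curve models** fitted to measured profiles, with
  confidence intervals, regime comparison and the curve "knee":
  - exponential growth: η = Y₀·e^{kc}
  - three-parameter exponential: η = e^{a₁ + a₂c + a₃/T}
  - modified Ross–Minton: η = η₀·exp([η]c / (1 − (k/v)[η]c))
  - Tomar (log-linear): ln(η/η₀) = lnA + Bc

  The knee is the concentration where dη/dc reaches 1 cP·mL/mg — a
  model-agnostic marker for the onset of steep viscosity growth. Predictions
  from the two concentration regimes are contrasted with the symmetric
  percent difference 100·(η_ultra − η_high)/((η_ultra + η_high)/2) and by
  Spearman rank agreement across molecules.

* **Dilute-solution viscometry** (5–50 mg/mL): relative/specific/reduced
  viscosities, intrinsic viscosity by Huggins (η_red = [η] + k_H[η]²c),
  logarithmic (ln(η_rel)/c) and quadratic polynomial (η_rel = 1 + k₁c + k₂c²)
  extrapolations, the Huggins coefficient k_H with propagated uncertainty,
  the exponential coefficient k_exp, and the DLS diffusion interaction
  parameter k_D from D_app = D₀(1 + k_D·c).

* **Hydrodynamics**: r_h = (3[η]M_w/(10πN_A))^{1/3}, effective volume
  fraction φ(c), shape ratio ρ = R_g/r_h and the geometric shape coefficient
  Ψ = SASA/V^{2/3} with its empirical shape-factor line Ψ = 1.454v + 7.085.

* **Sequence descriptors and empirical predictors**: Eisenberg-scale
  hydrophobic index, Henderson–Hasselbalch net charges and sequence pI, the
  Fv charge symmetry parameter (FvCSP), traffic-light viscosity banding
  (green ≤20 cP, amber 20–30 cP, red ≥30 cP), the ensemble-charge ≥ +2
  low-viscosity rule, and the Li, Sharma and Tomar regression predictors
  that map descriptors directly to viscosity at 150 or 180 mg/mL.

* **Knee regression**: NIPALS partial least squares of the model-averaged
  knee on molecular descriptors, with leave-one-out PRESS/Q² component
  selection and test-set evaluation.

* **Synthetic data**: seeded generators for every input (noisy duplicate
  viscosity profiles, Huggins-structured dilute series, linear DLS series,
  point-mutant Fv panels, correlated descriptor tables), so the full
  pipeline runs and is testable without instrument data.

## Worked example

```python
import mabvisc as mv

# a synthetic Ross-Minton molecule measured in duplicate with 5% noise
truth = mv.ModelSpec("ross_minton",
                     {"intrinsic_viscosity": 0.0063, "crowding_ratio": 0.3})
profile = mv.gen_viscosity_profile(truth, mv.SyntheticSpec(seed=7, sd_value=0.05),
                                   molecule_id="mAb-1")

high, ultra = mv.segment_regimes(profile)        # <=120 vs <=260 mg/mL
res = mv.fit_model(ultra, "ross_minton")
print(res.summary())
```

```
Model: ross_minton   molecule: mAb-1
Regime: ultra_high   n = 13   R^2 = 0.9997   SSE = 0.2117 cP^2
Parameters:
     intrinsic_viscosity =  0.00644452  (se 7.66e-05)
          crowding_ratio =  0.284367  (se 0.00718)
Knee (d eta/dc = 1): c = 273.42 mg/mL [ok]
```

The fit recovers the generating intrinsic viscosity (0.0063 mL/mg) and
crowding ratio (0.3) within their standard errors; the knee near 273 mg/mL
says the curve only turns steep beyond the measured range. Prediction with
a 95% confidence interval, and the high- vs ultra-high-regime contrast at
180 mg/mL:

```python
eta, ci = res.predict_with_ci(180.0)             # 6.38 cP, (6.25, 6.51)
res_h = mv.fit_model(high, "ross_minton")
mv.compare_regimes(res_h.predict(180.0), res.predict(180.0))   # -7.7 %
```

Dilute-regime analysis of the same molecule:

```python
series = mv.gen_dilute_series(6.3, 0.40, spec=mv.SyntheticSpec(seed=3, sd_value=0.005),
                              molecule_id="mAb-1")
print(mv.DiluteViscometry(series).fit().summary())
```

```
Dilute viscometry: mAb-1  (n = 6)
  [eta]_H   =    5.645 +/- 0.408 mL/g
  [eta]_K   =    5.665 +/- 0.396 mL/g
  [eta]_avg =    5.655 +/- 0.284 mL/g
  [eta]_v   =    6.271 mL/g (k1 = 0.0062712 mL/mg, k2 = 1.6632e-05)
  k_H       =   1.0467 +/- 0.3151
  k_exp     =  0.00611 mL/mg
  Huggins R^2 = 0.6079
```

[η]_H and [η]_K are the two linear-extrapolation estimates of intrinsic
viscosity (mL/g), averaged into [η]_avg; [η]_v is the quadratic-fit
alternative. With only six points at 0.5% noise the Huggins slope — and
hence k_H, the pair-interaction coefficient — is the least certain output,
which the propagated ±0.32 makes explicit.

A command-line layer mirrors the library
(`mabvisc fit|dilute|kd|hydro|descriptors|predict|pls|simulate|run`):

```bash
mabvisc simulate profile --seed 5 --out data/
mabvisc fit --input data/profiles.csv --model all --predict-at 180 --out results/
```

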