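# cocoflux

Process-modeling toolkit for crossflow microfiltration of green coconut
water, covering the full analysis chain of a membrane-clarification
optimization study and the techno-economics of the associated coconut
biorefinery.

## What it does

Fresh coconut water is highly perishable; crossflow microfiltration
through a 0.2 µm silicon-carbide membrane is a "cold" clarification
route whose performance hinges on two operating factors — transmembrane
pressure *P* (kPa) and temperature *T* (°C) — and on membrane fouling.
`cocoflux` models that trade-off end to end:

- **`cocoflux.doe`** — two-factor face-centered central composite design
  (FCD, α = 1): factor coding, CSV/JSON design tables, and the embedded
  29-sample pilot dataset (9 unique conditions; non-center points in
  triplicate, center point in quintuplicate) with permeate flux
  *J_p* (L h⁻¹ m⁻²) and fouling index F.I. (%) responses.
- **`cocoflux.rsm`** — replicate-weighted quadratic response surfaces

  *Y* = β₀ + β₁x₁ + β₂x₂ + β₁₁x₁² + β₂₂x₂² + β₁₂x₁x₂,

  fitted by OLS over all samples, pruned at *p* < 0.05 and refitted;
  ANOVA with lack-of-fit/pure-error split; closed-form box-constrained
  surface optimization with prediction standard errors.
- **`cocoflux.ann`** — a compact 2-5-2 tansig/purelin surrogate trained by
  Levenberg–Marquardt with L2 weight decay
  (perf = (1−λ)·MSE + λ·MSW, λ = 0.10), random 70/15/15 splits,
  validation early stopping, and best-of-N restart selection.
- **`cocoflux.ga`** — seeded genetic algorithm (population 120,
  50 generations, 5% elitism, stall limit 8) for setpoint search on
  either surrogate; flux maximization uses fitness = −*J_p*.
- **`cocoflux.compare`** — AAD/MSE/RMSE/MPE/NMSE/NRMSE/R² metric suite and
  grouped leave-one-condition-out cross-validation (Q², RMSE_CV).
- **`cocoflux.membrane`** — flux, VRR, transmission/rejection, permeance
  coefficients and the resistance-in-series partition
  R_T = R_M + R_C + R_F with fouling index 100·(1 − Lp₁/Lp₀).
- **`cocoflux.hermia`** — constant-pressure Hermia blocking laws
  (complete n = 2, standard n = 1.5, intermediate n = 1, cake n = 0):
  closed-form decay simulators, linearized fits, mechanism ranking by R².
- **`cocoflux.tea`** — six-tenths-rule cost scaling, batch mass balance,
  revenue, nominal discounted cash flows (NPV, IRR, payback) and
  price-sensitivity scenarios for the 1 t/batch biorefinery.
- **`cocoflux.synth`** — seeded generators for FCD datasets, Hermia-type
  flux-decline series and permeance staircases.

## Worked example

```python
from cocoflux import table1, prune_by_significance
from cocoflux.rsm import optimize_surface

ds = table1()                                   # 29 samples, 9 conditions
flux = prune_by_significance(ds, "flux")        # drops the P linear term
print(flux.included_terms)
# ('1', 'x2', 'x1^2', 'x2^2', 'x1:x2')
print(flux.predict((0.0, 0.0)))                 # center point
# (660.5867567567567, 12.206680451593277)
print(flux.predict_actual(75.0, 30.0))          # validation setpoint
# (611.4827327327326, 10.095084269859624)
opt = optimize_surface(flux, "max")
print(opt.actual, round(opt.value, 2))
# (126.8602559582628, 32.831704053692704) 671.89
```

The center prediction 660.59 ± 12.21 and the 75 kPa / 30 °C prediction
611.48 ± 10.10 L h⁻¹ m⁻² are the model's fitted mean responses with
their standard errors; the analytic surface maximum sits at
≈127 kPa / 32.8 °C, predicting ≈672 L h⁻¹ m⁻².

The same chain runs from the shell:

```bash
cocoflux fit-rsm --response flux --out flux.json
cocoflux predict --model flux.json --pressure 75 --temperature 30
cocoflux train-ann --restarts 20 --seed 7 --out ann.json
cocoflux optimize --model ann.json --response flux --direction max
cocoflux crossval --model rsm --response fouling_index
cocoflux tea run
cocoflux paper-preset --out bundle/   # the whole pipeline, one seed block
```

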