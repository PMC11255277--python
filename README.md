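# cherrydiff

Modelling and estimation toolkit for dye diffusion in pitted spherical
fruit. Candied (Bing-type) cherries are stained by immersing them in a
stirred hypertonic dye bath; the CIELAB redness coordinate a\* read at
radial positions inside the flesh is a linear proxy for local dye
concentration. `cherrydiff` turns those colour kinetics — and the
matching UV–VIS solution-phase kinetics of dye egress — into effective
diffusivities of the dye in cherry flesh and skin, with the statistical
comparisons needed to contrast dyes, temperatures and bath
concentrations.

## The model

A pitted cherry is a hollow sphere: cavity radius `r_A` (left by the
stone), flesh radius `r0`, and a thin skin of thickness `r_s − r0`
(0.4 mm). In dimensionless variables

```
Θ = D_F t / r0²,   R = r / r0,   a* = (a(t) − a_s) / (a_i − a_s)
```

radial Fickian diffusion reads

```
∂a*/∂Θ = ∂²a*/∂R² + (2/R) ∂a*/∂R ,      A = r_A/r0 ≤ R ≤ 1
a*(R, 0) = 1
a*(A, Θ) = 0                             (cavity wall takes the bath value)
∂a*/∂R + H a* = 0  at R = 1,  H = (D_S/D_F) · r0/(r_s − r0)
```

The skin acts as a thin resistive layer with its own effective
diffusivity `D_S`, collapsed into the Robin factor `H` (double
flesh–skin diffusion boundary; the well-stirred bath keeps the skin's
outer face at the bath concentration — large mass Biot number).
Separation of variables gives eigenfunctions `φ_n(R) = sin(λ_n(R−A))/R`
with `λ_n` the positive roots of
`λ cos(λ(1−A)) + (H−1) sin(λ(1−A)) = 0`, and the volume-average redness

```
a*_V(Θ) = 3/(1−A³) · Σ_n { c_n²/b_n − W·A₀/(λ_n²−A₁)·[e^{(λ_n²−A₁)Θ} − 1]·c_n } e^{−λ_n²Θ}
```

with norms `b_n = ∫ R²φ_n² dR`, coefficients `c_n = ∫ R²φ_n dR` and an
optional exponential boundary forcing `(W, A₀, A₁)` (off by default).
The truncated series (220 terms) is cross-checked against an
independent method-of-lines finite-difference solver.

Diffusivities are estimated by multi-start nonlinear least squares over
`(log₁₀D_F, log₁₀D_S)` followed by a minimum-χ² refinement; cumulative
window refits give the time-resolved diffusivity curve and its
first-hour mean ± SD; one-way ANOVA with Tukey–Kramer HSD (studentized
range CDF by direct quadrature) and Scheffé contrasts produce the
compact letter display across study conditions.

A seeded synthetic-data generator emulates the study design — radial
stations at 2.63/5.26/10.53 mm plus the fruit exterior, n = 5 then n = 3
replicates, uptake and release runs over the 18-condition grid of
2 dyes × {40, 50, 60 °C} × {119, 238, 357 ppm}, multiplicative
measurement noise — so the full pipeline runs and is validated without
laboratory data.

## Worked example

```python
from cherrydiff import (Geometry, StudyDesign, DyeCondition,
                        generate_uptake, normalize, fit_diffusivities,
                        time_resolved_diffusivity)

geom = Geometry.cherry()                       # 27 mm calibre, 0.4 mm skin
cond = DyeCondition("red_gardenia", 60.0, 357.0)
design = StudyDesign(conditions=(cond,), noise_sigma=0.02, seed=42)
series = normalize(generate_uptake(design, geom=geom).series[0])

fit = fit_diffusivities(series, geom)
print(f"D_flesh = {fit.D_flesh_hat:.3e} m^2/s")
print(f"D_skin  = {fit.D_skin_hat:.3e} m^2/s")
tr = time_resolved_diffusivity(series, geom)
print(f"first-hour D_flesh = {tr.mean_D_flesh:.3e} +/- {tr.sd_D_flesh:.1e} (n={tr.n_windows_60min})")
```

prints

```
D_flesh = 3.881e-08 m^2/s
D_skin  = 7.016e-09 m^2/s
first-hour D_flesh = 3.875e-08 +/- 8.7e-11 (n=4)
```

i.e. the estimator recovers the generator's true red-gardenia values
(3.89e−08 and 6.61e−09 m²/s) from 2 %-noise colour readings: the flesh
diffusivity to 0.2 %, the skin diffusivity — seen only through the
boundary condition — to about 6 %. The first-hour summary is the mean
over the four cumulative-window refits ending within 60 min.

The same pipeline runs from a shell:

```bash
cherrydiff run-all --seed 0 --out results/
cherrydiff surfaces red_gardenia_60C_357ppm --out results/
```

`run-all` writes `summary.csv` (one row per condition and tissue with
D mean ± SD, n, R², RMSE, χ² and significance letters),
`comparisons.csv` (pairwise Tukey–Kramer results) and `fits.json`;
`surfaces` exports the redness surface a(r, t) on the 15-node
presentation mesh over the 12 mm flesh span and [0, 60] min.

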