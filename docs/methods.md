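# Methods

## Physical model and assumptions

The fruit is treated as a hollow sphere of homogeneous, isotropic flesh:
an inner cavity of radius `r_A` (the pitted stone, default 1.1 mm), an
outer flesh radius `r0` (default 13.1 mm from a 27 mm calibre minus the
skin) and a skin of thickness `δ = r_s − r0` (default 0.4 mm). Dye moves
by radial Fickian diffusion with a constant effective diffusivity `D_F`
in the flesh. Convective transport inside the tissue and chemical
generation are neglected. The bath is stirred strongly enough that the
external film resistance vanishes (large mass Biot number): the outer
face of the skin takes the bath concentration instantly, and the cavity
wall — reached by the bath through the stem channel — is held at the
bath value (an inner Dirichlet condition). The skin itself is a thin
layer with its own effective diffusivity `D_S`; because `δ ≪ r0` its
capacitance is neglected and it enters only as the Robin condition
`∂a*/∂R + H a* = 0` at `R = 1`, with `H = (D_S/D_F)·r0/δ`.

Redness is assumed linear in local dye concentration (checked by the
straight-line calibration utility), so the normalised redness
`a* = (a − a_s)/(a_i − a_s)` obeys the same diffusion equation as
concentration and both staining (uptake) and de-staining (release) runs
reduce to the same dimensionless decay problem: `a* = 1` initially,
relaxing to 0.

`A = 0` (unpitted fruit) is supported: the eigenfunctions
`sin(λR)/R` are regular at the origin and the inner condition becomes
boundedness (numerically, a symmetry/no-flux node at `R = 0`).

Not modelled: finite external film (convective boundary), anisotropy or
2-D/3-D tissue structure, sugar co-diffusion, pH-driven pigment
precipitation, tortuosity evolving during candying.

## Series solution

Separation of variables gives `φ_n(R) = sin(λ_n(R − A))/R` with `λ_n`
the positive roots of `λ cos(λL) + (H−1) sin(λL) = 0`, `L = 1 − A`.
This family is the unique one satisfying the interior equation, the
inner Dirichlet condition and the Robin skin condition; it is gated in
the test-suite on agreement with the independent finite-difference
solver (max-abs ≤ 1e-3 on refined meshes) rather than trusted on
derivation alone.

Roots are bracketed by a sign-change scan at 8 points per asymptotic
half-period `π/L` (doubled automatically if a gap larger than `2π/L`
between consecutive roots signals a miss), refined by bisection to
machine precision and polished with two guarded Newton steps. Norms
`b_n = ∫_A^1 R²φ_n² dR = L/2 − sin(2λL)/(4λ)` and coefficients
`c_n = ∫_A^1 R²φ_n dR` use closed forms, validated against adaptive
quadrature at 1e-12 in the tests. The eigenvalue residual is asserted
at ≤ 1e-10 on the scaled form `|g(λ)|/max(1, λ)` for all 220 modes (and
absolutely for the first 50): at `λ ≈ 800` the absolute residual of an
exactly rounded double root already sits at ~1e-10, the floor of double
precision.

The truncated series keeps 220 terms by default. The point-wise profile
carries visible truncation ripples at `Θ = 0` (a jump between the unit
initial state and the inner boundary); the volume average reconstructs
`a*_V(0) = 1` to within 2e-3 and is used where the initial instant
matters.

The optional boundary forcing `(W, A₀, A₁)` parameterises an
exponentially decaying boundary value. The forcing bracket
`e^{(λ²−A₁)Θ} − 1` times the overall `e^{−λ²Θ}` is evaluated in the
equivalent overflow-safe form `e^{−A₁Θ} − e^{−λ²Θ}` (net forcing decay
`e^{−A₁Θ}`). `W = 0` — a constant boundary — is the shipped default;
`A₁` within 1e-9 of any `λ_n²` raises a singularity error. The forced
profile and volume average are kept mutually consistent (the
volume-average of the forced profile equals the forced series), but only
the `W = 0` case is gated on the numerical oracle.

Eigen-systems are memoised on the exact `(A, H, n_terms)` triple with
LRU eviction, so a cache hit is bit-identical to a cold computation and
repeated runs are byte-reproducible. Serialised systems use a
12-significant-digit key convention.

## Finite-difference backend

The same problem in the conservative coefficient form
`∂u/∂t = x^{−m} ∂_x(x^m D ∂_x u)` (m = 2, spherical) is discretised by
second-order central differences; Robin and Dirichlet boundaries use
ghost-node stencils, no-flux boundaries use finite-volume half-cells
whose face flux is exactly zero, making the discrete weighted mass
`Σ w_i x_i^m u_i` conserved to the time-integrator tolerance (the
`discrete_mass` helper exposes the matching weights). Time integration
is implicit (BDF) with rtol 1e-8 / atol 1e-10 and a tridiagonal Jacobian
sparsity pattern.

The 15-node mesh on the 12 mm flesh span with output on [0, 60] min is
the *presentation* default (it reproduces the documented study
configuration and the surface plots); every verification comparison uses
≥ 301 nodes, since a convergence study flags the 15-node mesh as coarse.
Radial coordinates of dimensional grids are measured from where the
flesh begins (flesh-origin convention, cavity wall at 0 mm), recorded
explicitly in the grid metadata.

## Estimation

Fits run over `(log₁₀D_F, log₁₀D_S)` inside the box [1e-14, 1e-6] m²/s,
which spans the observed flesh/skin range (≈ 6.6e-12 … 3.9e-8 m²/s)
with margin; the log parameterisation handles the four
orders-of-magnitude spread. A 5×5 log-spaced start grid is screened on
residual sum of squares; the best starts are refined by damped
Gauss–Newton (finite-difference Jacobian, step-halving safeguard,
gradient tolerance 1e-10, ≤ 200 iterations, projection onto the box).
By default 4 starts are refined for per-position fits and 8 for
volume-average ones: the volume-average objective has a genuine
competing local optimum — an almost impermeable skin with a larger
flesh diffusivity, draining through the cavity — that shallow
multi-start depth can mistake for the solution. A subsequent
minimum-χ² pass (Pearson weighting by the model prediction, floored at
1e-6) refines the least-squares optimum and is guarded never to
increase the χ² it minimises; both objectives are reported. A
sum-of-squares χ² alias (`SSR/(n−p)`) is provided for comparability
with reports that use that convention.

Two observation operators are available, and the default ("auto") picks
the one matching the data actually present:

* **per_position** — residuals between the radial-profile series and the
  normalised colour readings at the measurement stations (2.63, 5.26,
  10.53 mm from the flesh origin, exterior ↦ R = 1). Colour rows at
  t = 0 are excluded: the initial condition is imposed, not fitted, and
  the truncated profile ripples there.
* **volume_average** — residuals between `a*_V(Θ)` and the fruit content
  inferred from solution-phase (UV–VIS) kinetics,
  `a*_V = 1 − c(t)/c_equil`. The t = 0 bath reading is kept: an egress
  bath genuinely starts dye-free, the volume-average series is
  ripple-free at Θ = 0, and without the curve's origin, conditions that
  saturate within the first sampling interval leave only noise-floor
  observations.

Fitting the volume-average series directly against a plain mean of
three radial stations would be a biased observation operator (the
stations under-weight the outer shell that dominates the `R²`-weighted
volume integral), which is why per-position is the default for radial
scans rather than the volume-average curve.

Standard errors on the log-diffusivities are curvature-based
(Gauss–Newton `(JᵀJ)⁻¹` at the optimum). The headline mean ± SD per
condition instead comes from window-to-window dispersion: cumulative
windows `[0, t_j]` for each sampling time from the third onward, with
the first-hour summary the mean ± SD of windows ending within 60 min
(n = 4 under the default schedule). Cumulative windows are
deterministic and use all data up to `t_j`; sliding windows were
considered and rejected as noisier for the same cost. Estimates pinned
at a box bound are flagged (`at_bounds`) and marked unconverged.

Uptake and release runs are fitted separately.

## Statistics

One-way ANOVA uses the standard between/within decomposition with
unequal n; F-tail probabilities go through the regularized incomplete
beta function. Tukey–Kramer q statistics use the pairwise harmonic
standard error `√((MSE/2)(1/nᵢ + 1/nⱼ))`; p-values come from the
studentized range distribution evaluated by direct double quadrature of
its CDF (outer integral over the pooled-SD chi density, inner over the
normal range probability; absolute tolerance ~1e-6), cross-checked in
the tests against an independent library implementation and the
classical critical value q(0.05, 3, 10) = 3.877. Scheffé contrasts
refer the pairwise contrast F to `(k−1)·F_{k−1,ν}`; for k = 2 they
reduce to the ANOVA F test, and their p-values are never smaller than
Tukey–Kramer's. The compact letter display uses insert-and-absorb:
start from one letter covering all groups, split on each significant
pair, absorb subsets, and patch so that two groups share a letter iff
their pairwise p ≥ α (non-transitive patterns simply yield more
letters).

Diffusivities are compared on the log₁₀ scale: their SDs are of the
same order as their means, so the log transform stabilises variance.
Raw-scale comparison remains available for literal reproduction.

## Synthetic data generator

The generator emulates the study design, not any particular laboratory
dataset: the 18-condition grid (2 dyes × 40/50/60 °C × 119/238/357 ppm),
radial stations plus exterior, five replicates at the first two sampling
times then three (early external colour variability), both uptake and
release runs, and per-condition true diffusivities set to the reference
flesh/skin magnitudes for erythrosine and red gardenia (6.6e-12 …
3.9e-8 m²/s, skin below flesh everywhere). Sampling defaults to
0–240 min with dense coverage of the first hour, where the main
molecular movement occurs. Noise is multiplicative Gaussian
(`a_obs = a_true(1+ε)`, σ = 2 % by default) because colour and
absorbance readings scale with signal; an additive variant is a
one-line design change. Raw redness references default to `a_i = 5`
(bleached, desulphited fruit) and a dye-saturated boundary value scaled
linearly with bath concentration up to 35 at 357 ppm — arbitrary but
documented, since raw a\* magnitudes are dataset-specific. Release
solution concentrations follow the mass balance
`c(t) = c_equil (1 − a*_V)` with a capacity proportional to the
staining-bath concentration.

Every noise draw is seeded from the master seed hashed (CRC32) with the
record key, so subsetting the design never reshuffles noise and
regeneration is byte-identical.

What passing tests on this generator do **not** show about real data:
the generator draws from the same model family the estimator fits (no
model misfit), noise is independent across records (no fruit-level
random effects, no drift), the redness–concentration relation is exactly
linear, and the true diffusivities are time-constant — whereas real
time-resolved estimates decrease as the matrix saturates. Recovery
accuracy reported here is therefore a self-consistency statement, not a
field accuracy claim.

## Problem sizes and numerical choices

Default problem sizes: 220 series terms (440 used once in a convergence
check), 301-node meshes for oracle comparisons, 15 nodes for
presentation grids, 50 replicate datasets for recovery studies, 2,000
simulations for the ANOVA null calibration, and the full 18-condition
grid for end-to-end runs. Quadrature tolerances: 1e-12 absolute for
eigen-integrals (closed forms validated against quadrature), ~1e-6 for
the studentized-range CDF. Degenerate inputs are rejected with named
errors: `a_i = a_s` (undefined normalisation), constant concentrations
(rank-deficient calibration), zero observation variance (undefined R²),
forcing rate on an eigenvalue (series singularity), non-monotone meshes.

## Known limitations

* The skin is a boundary condition, not a resolved layer; `D_S` is
  identified only through `H` and is the harder parameter (its recovery
  tolerance is accordingly wider).
* The volume-average objective is nearly degenerate along an
  impermeable-skin ridge; multi-start depth handles it for the study
  conditions, but pathological designs (no early sampling) can still
  select the wrong branch.
* Slow conditions (D ~ 1e-11 m²/s) barely move the radial profile within
  240 min; their per-position fits are dominated by the exterior station
  and window-to-window estimates scatter widely — visible as large SDs
  in the summary table.
* No Arrhenius temperature model is fitted; temperatures are treated as
  unordered factors in the statistics.
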