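# Methods

This note documents the models, algorithms, numerical choices and known
limitations of `skinaniso`.

## Measurement model and data layout

A profile is a set of (angle, arrival time) readings on a uniform angular
grid. The protocol grid is 36 angles at 10° steps; 360° coincides with 0°,
so the grid is stored as 0°–350° and the endpoint reading is not
duplicated. Arrival times are strictly positive RRT units. Repeats (three
per subject and configuration) are averaged per angle with a plain
arithmetic mean before any fitting; no half-turn symmetry correction is
applied. The raw-data Langer rule returns the angle of the minimum reading
reduced modulo 180°, with ties broken toward the smallest angle so the
result is deterministic.

## Ellipse fitting

Profiles are mapped to Cartesian points (x, y) = r(cos φ, sin φ) and a
conic Ax² + Bxy + Cy² + Dx + Ey + F = 0 is fitted by minimising the sum of
squared algebraic distances subject to the ellipse-specificity constraint
4AC − B² = 1. The constrained eigenproblem is solved with the stable block
decomposition of the scatter matrix (quadratic block eliminated against
the linear block), which avoids the near-singularity of the original
single 6×6 eigen-formulation for low-noise and near-circular data. Before
solving, each point cloud is centered on its mean and rescaled by its RMS
radius; the conic is mapped back to the original frame afterwards and
normalised to unit coefficient norm.

Numerical details:

- The admissible eigenvector is the one with 4ac − b² > 0; if none exists
  (collinear or otherwise degenerate data, including conics whose minor
  axis collapses below 10⁻⁷ of the major axis), the fit raises a
  degenerate-fit error — or is counted and excluded inside the Monte-Carlo
  driver.
- Geometric parameters come from the conic: center from the gradient
  stationary point, axis lengths from −F₀/λᵢ with λᵢ the eigenvalues of
  the quadratic-form matrix, tilt from the major-axis eigenvector using
  whichever of its two algebraic forms is better conditioned (the other
  degenerates for axis-aligned ellipses).
- Tilt is axial and reported in [0°, 180°); axes are swapped (tilt rotated
  90°) if extraction orders them minor-first. A numerically circular fit
  reports tilt 0 for determinism.
- The solver accepts a leading batch dimension, so the simulation study
  fits 10,000 replicates through the very same code path in one vectorised
  call (`numpy.linalg.eig` on stacked 3×3 matrices).
- The printed eccentricity definition with a²/b² inside the root is
  imaginary for a > b; the package uses the standard e = √(1 − b²/a²),
  which matches every numeric use of eccentricity in the source analysis.
- `rms_residual` is the RMS algebraic distance under the unit-norm conic —
  a diagnostic only, not a geometric distance.

Exactness: on noiseless 36-point profiles the fit recovers a, b, center
and tilt to better than 10⁻⁶ relative error across aspect ratios up to 10
(property-tested), and the fit is equivariant under rotation and scaling.

## Anisotropy measures

- Eccentricity e = √(1 − b²/a²), area A = πab, Langer direction
  (tilt + 90°) mod 180°.
- Anisotropic ratio AR = max/min of the raw readings. On a noiseless
  gridded profile whose axes align with the grid, AR = a/b = 1/√(1 − e²)
  exactly; with the axes mid-grid (worst case 5° off), the grid misses the
  extremes and AR underestimates a/b by up to 0.55% at e = 0.7 and 1.9% at
  e = 0.9. The 0.5%-tolerance identity is therefore asserted for e ≤ 0.65
  at arbitrary tilt and exactly on-grid otherwise.

## Calibration

v = √(E/(3.284ρ)) for an unstressed incompressible isotropic solid; one
RRT corresponds to (gap/v)/meanRRT microseconds. The transducer gap
defaults to 2 mm and is exposed as a parameter. The bundled reference
table (three elastomers) reproduces conversions 0.322, 0.249, 0.282 µs;
their unrounded mean is 0.2846 µs. Density units are kg/m³.

## Monte-Carlo robustness study

Each cell of the (e, σ) grid draws `n_reps` profiles: true polar radius of
the scenario ellipse at each grid angle plus independent N(0, σ²) radial
noise, non-positive radii redrawn (probability is negligible on the study
grid, where the smallest radius is 160 RRT and σ ≤ 30). Noise is applied
to the polar radius — matching the geometry of a device that measures one
arrival time per orientation — rather than per Cartesian coordinate; the
point count and noise geometry are configurable. Tilt is fixed at 0° for
the grid; rotation equivariance of the estimator is tested separately, so
this loses no generality. Defaults replicate the study conditions: b = 160
RRT, e ∈ {0.5, 0.7, 0.9}, σ ∈ {1, 10, 20, 30}, 10,000 replicates, 36
angles. Everything is reproducible from the scenario seed; each grid cell
receives an independent child seed.

The outlier demonstration displaces the readings nearest the major axis
outward and those nearest the minor axis inward on a noiseless profile,
showing that AR (a function of the two extremes only) inflates by a far
larger factor than the fitted eccentricity.

## Synthetic cohorts

`generate_outcomes` draws, per subject, age ~ Uniform(3, 93) years and
gender ~ Bernoulli(41/78 male), and emits both configurations with
outcome vector α + **B**x + MVN(0, Σ). Defaults:

- **B** is set near the coefficient magnitudes the trivariate model is
  designed to detect (age→log e 0.007 per year, config→b −26.8 RRT, etc.),
  so synthetic cohorts have realistic effect sizes. These are generator
  settings for recovery testing, not reproductions of any estimate.
- α = (−1.15, 120, 180) and residual SDs (0.09, 12, 10) with correlations
  (log e, A) = 0.4, (log e, b) = −0.3, (A, b) = 0.6. The log-eccentricity
  intercept and SD were chosen together so that eccentricities lie mostly
  in 0.4–0.7 while exp(log e) ≥ 1 has worst-case probability ≈ 10⁻⁴,
  below the 10⁻³ configuration gate; the gate is evaluated analytically at
  the worst covariate combination and violating parameter sets are
  rejected at construction.
- Profile-level generation treats (e, b) as the free shape parameters,
  derives a = b/√(1 − e²) and recomputes the area from the realised
  ellipse, because the three outcomes are algebraically redundant given
  one ellipse (A = πb²/√(1 − e²)). The drawn area outcome is therefore
  overwritten at profile level; its regression structure arises implicitly
  through (e, b). Out-of-range outcome draws are redrawn and counted.
- Tilts come from the circular model below; per-reading radial noise
  defaults to 10 RRT, the "low noise" level of the robustness grid.
- Errors are drawn independently for the two configurations of a subject —
  a known simplification; real repeated measures are likely positively
  correlated within subject, which the regression models here do not
  absorb (no subject random effect).

Pipeline closure holds by construction: at zero reading noise, fitting the
generated profiles returns the generated (e, b, tilt) to 10⁻⁶.

## Bayesian multivariate regression

Model: yᵢ = α + **B**xᵢ + εᵢ, εᵢ ~ N₃(0, Σ), with x = (age in years,
uncentered; gender 0 = female, 1 = male; configuration 0 = natural,
1 = stretched), and outcomes (log e, A/1000, b) using the natural log.
Priors are conjugate and weakly informative: stacked coefficients
Γ = (α; **B**ᵀ) ~ MatrixNormal(0, τ²I ⊗ Σ) with τ = 100, and
Σ ~ InverseWishart(ν = 4, I₃). The Gibbs sampler alternates the exact
conditionals

- Γ | Σ, Y ~ MN(Vₙ XᵀY, Vₙ, Σ), Vₙ = (XᵀX + τ⁻²I)⁻¹,
- Σ | Γ, Y ~ IW(ν + n + p, I + EᵀE + τ⁻²ΓᵀΓ).

Defaults: 4 chains, 2,000 iterations, first half discarded as warm-up.
Split-R̂ and bulk ESS (via arviz) are attached to every fit; R̂ > 1.01 or
ESS < 400 raises a warning and flags the posterior, never silently.
Significance is exactly the 0-outside-the-0.95-HPDI rule with no
multiple-testing correction. The HPDI is the narrowest window of
⌈0.95n⌉ consecutive sorted draws, appropriate for unimodal posteriors.
Sensitivity: scaling the prior SD ×10 moves posterior means by < 5% on
default synthetic cohorts (tested). With Σ fixed, the draws are iid from
the matrix-normal conditional and the posterior mean equals the ridge
solution (XᵀX + τ⁻²I)⁻¹XᵀY — used as an analytic correctness oracle.

## Circular tilt regression

The ellipse tilt is axial, so angles are doubled onto [0°, 360°) before
fitting and results halved back — an explicit modelling choice, since the
original handling of axial tilt is not documented. The doubled angle
follows a projected normal: θᵢ = atan2(uᵢ₂, uᵢ₁) with latent
uᵢ ~ N₂(μᵢ, I), μᵢ = γ₀ + γ₁·configᵢ. The Gibbs sampler augments with the
latent lengths rᵢ: writing bᵢ = μᵢᵀ(cos θᵢ, sin θᵢ), the conditional
density of rᵢ ∝ r·exp(−(r − bᵢ)²/2) on r > 0 is handled by a second
augmentation wᵢ | rᵢ ~ Uniform(0, rᵢ), after which
rᵢ | wᵢ ~ N(bᵢ, 1) truncated below at wᵢ — every conditional is exact
(no Metropolis step). Coefficients get independent N(0, τ²) priors per
latent coordinate.

Posterior circular means per configuration are atan2 of the fitted latent
mean; their HPDIs are computed on the circle by unwrapping the draws
around their circular mean. The significance rule is interval overlap:
overlapping 0.95 HPDIs of the two configurations' circular means indicate
no configuration effect on the tilt. With a single configuration the
model degenerates gracefully to a baseline mean; an all-identical-angles
input warns and returns a degenerate posterior.

## Problem sizes and seeds

Default study sizes follow the protocol: 78 subjects × 2 configurations ×
3 repeats × 36 angles; 10,000 Monte-Carlo replicates per grid cell
(vectorised, ≈ 0.3 s per cell). Test-suite model fits use 2 chains of
800–1,500 iterations, which the attached diagnostics show is ample for
this conjugate sampler (R̂ < 1.01 at a few hundred draws); HPDI-coverage
calibration uses 100 replications and the fixed-Σ oracle comparison uses
90,000 iid draws so Monte-Carlo error sits below the 10⁻³ tolerance. Every
stochastic component takes an explicit integer seed; grid cells, pipeline
stages and chains derive independent child streams from it.

## Known limitations

- The Rayleigh relation assumes an unstressed, incompressible, isotropic,
  linear-elastic half-space; skin is none of these, so converted moduli
  are effective values, and no acoustoelastic (pre-stress) correction is
  attempted.
- The repeat-averaging step uses a plain per-angle mean; if the original
  acquisition applied a symmetry correction between half-turns, results
  on real data could differ slightly.
- The generator draws configuration errors independently within subject
  and models tilt concentration as homogeneous; passing recovery tests
  therefore demonstrates correctness of the estimators under the assumed
  generative structure, not robustness to within-subject correlation or
  heteroscedasticity in real cohorts.
- No robust or weighted ellipse fitting: the least-squares fit is the
  object of study, and its documented sensitivity to gross outliers is a
  feature being measured, not corrected.
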