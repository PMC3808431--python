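# Methods

This document records the equation systems, parameter semantics, numerical
conventions and known limitations of the package.

## 1. Parameterization conventions

* Both surface parameters `u` and `v` live on the closed default domain
  `[0, 2π]`; angles are radians everywhere. A custom rectangular domain can
  be supplied, but whorl count is carried by the winding coefficient `b`
  rather than by an extended domain.
* `s = u / 2π` denotes the fraction of the u-sweep (0 = aperture end,
  1 = apex) and `ρ = v / 2π` the radial fraction used by cap-like forms
  (limpets, bivalves, cones).
* All generators are homogeneous of degree 1 in their radii
  (`R`, `r`, `R_max`, `r_max`): multiplying every radius by `c` multiplies
  the surface, its Jacobian summary, and its Hessian elements by exactly `c`.
* The reference point for Jacobian and Hessian evaluation defaults to
  `(u, v) = (0, 0)` and is configurable per analysis.

## 2. Equation systems

All systems derive from the ring torus
`x = (R + r cos v) cos u`, `y = (R + r cos v) sin u`, `z = r sin v`.
Only sines, cosines, hyperbolic secants/tangents, exponentials and
polynomials of `u`, `v` appear, so every expression is smooth and
symbolically differentiable on the whole domain.

### 2.1 Helical gastropods (System 1, turritellids, *Vermicularia*, spirals)

With whorl taper `w(s) = exp(−k b s) sech(l s)` and aperture taper
`exp(−m s)`:

```
x = a · w(s) · (R_max + r_max e^{−m s} cos v) · cos(b u)
y = a · w(s) · (R_max + r_max e^{−m s} cos v) · sin(b u)
z = −c j b R_max s + c · w(s) · r_max e^{−m s} sin v + q R_max s²
```

* `b` — whorl (winding) count; `j` — spire pitch; `k`, `l`, `m` — whorl and
  aperture taper; `a`, `c` — overall width/height scaling; `q` — whorl
  separation (the *Vermicularia* uncoiling term, squared in `s`).
* With `l = m = 0` the taper is a pure logarithmic spiral (growth factor
  `e^{−k}` per whorl), which makes whorl series self-similar — the
  turritellid isometric-growth case. At the reference point the Jacobian
  elements are affine in `b`, so the turritellid whorl series (b = 5…12)
  traces an exactly linear, monotone morphospace trajectory.
* A turritellid equals a *Vermicularia* with positive `b` and `q = 0`
  pointwise; spiral "curves" use an aperture radius near, but never exactly,
  zero (default `r_max = 1e-3`).
* Registered recipes (printed coefficient values): cone shell
  (`k=0.7, l=m=3, c=1, R_max=1.5, r_max=2`), volute (`k=1, l=m=0,
  R_max=1.5, r_max=2`), olive (`k=1, l=2, m=0, R_max=1, r_max=2`),
  *Melampus* (`l=1.5, m=2.3, R_max=0.7, r_max=2.4`), sundial
  (`a=b=2, l=m=0, R_max=1.3, r_max=1`), bubble (`k=1, l=1, m=0,
  R_max=1, r_max=2`). Coefficients not fixed by a recipe take the package
  defaults `a=1, b=3, c=1, j=0.45`.

### 2.2 System 2 (globose gastropods)

```
x = a (R_max e^{−k b s} + r_max cos v) cos(b u)
y = a (R_max e^{−k b s} + r_max cos v) sin(b u)
z = −c j b R_max s + c r_max sin v
```

The whorl centerline spirals inward while the aperture stays full-sized,
producing low-spired, globose shells (registered exemplar: `moon_snail`).

### 2.3 Uncoiled forms

* **Limpet** — radial fan with a sech height profile:
  `x = a R ρ cos u`, `y = a R ρ sin u`, `z = c r sech(k ρ)`.
* **Clam** — elliptical outline (length `j`), umbo height `b`:
  `x = j R ρ cos u`, `y = R ρ sin u`, `z = r sech(a ρ) + b r (1 − ρ)`.
* **Oyster** — `x = c R ρ cos u`, `y = R ρ sin u`, `z = r sech(c ρ)`.
* **Scallop** — auricles via `a R ρ sech(b sin(u/2))` added to `y`, `j` ribs
  of depth `c` in `z`, outline width `m`, convexity `l`.
* **Scaphopod** — circular-arc centerline (bend `a`) carrying a tapering
  tube of width `k` (taper 1/5 + 4s/5).
* **Echinoid** — a spindle torus whose hole (`a R`, with `a = 0.05`) almost
  disappears, flattened by `−c r tanh(b sin v)` with a small
  `sin²(5u) sin³(v)` sculpture term (amplitude coefficient stored in the `q`
  slot, default 0.02). The registered echinoid uses `R = r = 2`, reflecting
  whorl and aperture radii of comparable magnitude.

### 2.4 Ammonites and the pleat-phase degeneracy

```
g(s) = exp(l (s − 1))
x = g (R + r cos v) cos(l u)
y = g (R + r cos v) sin(l u)
z = g r (sin v + 0.2 sin(q (v + σ_v)) (1 − cos(l (u + σ_u))))
```

`l` controls the degree of coiling, `q` the pleat frequency, and the fixed
pleat amplitude is 0.2 of the aperture radius. The pleat wave vanishes to
first order at `(0, 0)` for every v-phase `σ_v`, so two ammonites differing
only in `σ_v` have **bit-identical Jacobian summaries** while their second
u-derivatives differ (for `l = 3, r = 1, σ_v = π/16, q = 8` the `∂²z/∂u²`
gap is `0.2 l² e^{−l} r sin(q σ_v) ≈ 0.0896`). This is the degenerate pair
that motivates Hessian post-processing. An optional `z_offset` coefficient
adds `z_offset · v · r` to any system's z-equation, the augmentation that
splits such pairs at the Jacobian level by altering `∂z/∂v`.

Known limitation: because the pleat term also vanishes to second order in
`v` at the reference point, ammonites sharing `l` but differing only in `q`
coincide through second order at `(0, 0)`; the `ammonite_grid` collection
therefore flags within-`l` pairs as degenerate. This is intrinsic to any
pleat design whose wave vanishes to first order at the reference point.

### 2.5 Basic geometric forms

Torus (`R = 2, r = 1` canonical), cylinder (`z = R(v/π − 1)`), cone
(`x = r ρ cos u`, `z = R(1 − ρ)`), dome (`cos(v/4)/sin(v/4)` cap), sphere
and ellipsoid. The sphere/ellipsoid/dome use an equator-first
parameterization (`cos(v/2)` radial, `z = ∓ a r sin(v/2)`) so the reference
point is metrically regular and an ellipsoid's elongation is visible in
`∂z/∂v = −a r / 2`; a pole-first parameterization would make the sphere and
all ellipsoids spuriously Jacobian-degenerate.

## 3. Jacobian and Hessian conventions

* Matrix orientation: rows `(x, y, z)`, columns `(u, v)`; flattening order
  `(∂x/∂u, ∂x/∂v, ∂y/∂u, ∂y/∂v, ∂z/∂u, ∂z/∂v)` everywhere a summary
  becomes a table row.
* Derivatives are exact symbolic partials (sympy), compiled once per model
  and cached; `numeric_jacobian` provides an independent central-difference
  oracle (default step `1e-6`) that bypasses the domain check so it can step
  past the boundary.
* Two summaries count as identical when their maximum absolute difference is
  below `1e-9`; table assembly flags such pairs and logs a warning.
* The default Hessian subset is the six u-dominant elements
  `{∂²x/∂u², ∂²y/∂u², ∂²z/∂u², ∂²x/∂u∂v, ∂²y/∂u∂v, ∂²z/∂u∂v}`; all nine
  named second partials are available on request. Mixed partials are
  symmetric for all registry models.
* Surface normal convention: `principal_curvatures` orients the normal so
  the classical torus values are positive (`κ_parallel = cos v/(R + r cos v)`,
  `κ_meridian = 1/r`); frame and curvature signs are conventions, and
  sign-sensitive comparisons should be made up to sign.

## 4. Measurement reduction

Measured maximum whorl and aperture radii (`R_max`, `r_max`, cm) are divided
by the smaller member (*actual proportion*, reported to 3 decimals, rounding
half away from zero), then rounded half-up to the nearest integers and
reduced by their gcd (*integer proportion*). Half-up rounding resolves the
single tie in the published measurement table upward (1.5 → 2). Two
published cells deviate from this rule by print precision — 1.6875 printed
as 1.687, and 2.667 printed as 2.7 — and are checked at loosened tolerances
(±0.001 and ±0.05) rather than guessed at. Integer proportions parameterize
generalized "blank" models; raw actual proportions remain available for
refined models.

## 5. Ordination conventions

* Correlation-matrix PCA: columns standardized to zero mean and unit
  variance with `ddof = 1`, so per-PC score variances equal the eigenvalues
  and the eigenvalue sum equals the retained variable count.
* Constant columns (sample standard deviation ≤ 1e-12) are dropped with a
  warning; e.g. the turritellid series retains 3 of 6 variables because
  `∂x/∂v`, `∂y/∂v` and `∂z/∂u`-adjacent elements do not vary within the
  family.
* Variable–PC correlations are eigenvector elements times the square root of
  the eigenvalue; PC signs are fixed so each PC's largest-magnitude variable
  correlation is positive. Eigenvectors of numerically zero eigenvalues are
  arbitrary (null-space directions), so correlations on variance-free PCs
  are not comparable across runs.
* Axes carry no built-in meaning; the morphospace is empirical and
  interpreted a posteriori from the correlation structure.
* Trajectory collinearity is the fraction of the path points' variance lying
  on their first principal (SVD) direction: 1 for a perfect line or a
  degenerate single point.

## 6. Generator realism and limitations

The generators reproduce the qualitative form classes (high-spired and
globose gastropods, planispiral ammonites, bivalve valves, limpets, tusk
shells, echinoid tests) and the quantitative behaviors the analyses rest on
(homogeneity, self-similar whorl series, pleat-phase degeneracy). They are
not fitted to specimens: coefficient values for forms without printed
recipes (winding `b`, pitch `j`, the bivalve/scallop shape constants, the
echinoid flattening) are package choices selected for visual plausibility
and well-conditioned derivatives, and are documented in the registry. The
published ordination's exact model population is unknown, so the frozen
fixture collections (`mollusk_echinoid`, `basic_forms`,
`turritellid_series`, `ammonite_grid`) approximate it and downstream numbers
are reproducible within this package rather than against published
eigenvalues.

## 7. Numerical choices and problem sizes

* Symbolic derivatives are evaluated through numpy-compiled callables with
  real-valued `sech`/`csch` overrides (the default printer would route them
  through complex exponentials).
* Geodesic torsion uses a central difference of the unit normal with step
  `1e-5`; finite-difference Jacobians use step `1e-6` (relative agreement
  with the symbolic path is ~1e-10 on registry models).
* Typical sizes: collections of 8–17 models, 6 variables, grids up to a few
  thousand points; the full test suite runs in well under a minute.
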