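# Methods

## Scope and model

`savrelease` analyses in-vitro dissolution of 3D-printed (FDM) tablets in
which the surface-area-to-volume ratio (SA/V, mm⁻¹) of the printed object is
the single release-controlling design variable for a fixed formulation.  The
pipeline has four stages:

1. **Geometry.**  Tablets are idealised as exact solids (cuboid, cylinder,
   hollow cylinder, right square pyramid) with closed-form surface area and
   volume; print-layer roughness is ignored.  The dose follows from the
   volume, the filament drug-load fraction and the filament density
   (`dose = V · ρ · w`); no default density is shipped because densities are
   formulation-specific.  The inverse problem (dimensions for a target SA/V,
   optionally also a target dose) is solved in closed form where SA/V
   decomposes additively — cuboid `2/a + 2/b + 2/c`, cylinder `2/r + 2/h`,
   hollow cylinder `2/(R−r) + 2/h` — and by bracketed Brent root search on a
   log-spaced grid (10⁻⁵–10⁶ mm) otherwise.  Infeasible targets report the
   attainable bound (e.g. a cylinder with fixed radius r can never go below
   SA/V = 2/r).

2. **Release kinetics.**  Seven classical equations are fitted to cumulative
   release curves (0–100 % scale, minutes): Korsmeyer–Peppas `k·tⁿ`,
   Peppas–Sahlin `k₁tⁿ + k₂t²ⁿ`, Higuchi `k_H·√t`, Lapidus–Lordi
   `200·(SA/V)·√(Dt/π)`, Hixson–Crowell cube-root, Hopfenberg erosion and the
   empirical Weibull `100·(1 − exp(−((t−T_i)/a)^b))`.  For Higuchi,
   Lapidus–Lordi, Hixson–Crowell and Hopfenberg only a rate ratio is
   identifiable from a percent-release curve, so fitting uses the collapsed
   forms (W₀ = 100 and c₀ = a₀ = 1 by convention).  The erosion bracket of
   the cube-root and Hopfenberg laws is floored at zero so release holds at
   100 % after complete erosion; this keeps raw curves monotone and
   physical.  The Weibull scale parameter a multiplies the shifted time
   *inside* the exponent — with that reading the tabulated PZQ constants at
   SA/V = 1 give MDT = a·Γ(1 + 1/b) ≈ 73.4 min, consistent with the MDT
   power law of that formulation (coefficient 73.487), which fixes the
   otherwise ambiguous exponent grouping.

3. **Summary statistics.**  MDT is the trapezoid-increment statistic
   `Σ (c_{i+1}−c_i)(t_i+t_{i+1})/2 / c∞`; a (0, 0) point is prepended when
   absent, points are used only up to the first sample reaching c∞ (that
   sample clamped to c∞), and noisy backward steps enter signed (a warning
   fires above 2 %).  Replicates are averaged point-wise on their common
   schedule before MDT by default.  RMSEP is the plain root mean squared
   prediction error.  f2 follows regulatory practice: measurement points
   only (t = 0 excluded), truncation one point after the reference passes
   85 %, warning below 12 points; identical curves give exactly 100.

4. **SA/V correlation.**  MDT and the fitted constants follow power laws
   `A·(SA/V)^p`, estimated by ordinary least squares after natural-log
   transformation of both axes (this matches how such data are linearised
   and reported; no weighting, no original-scale refit).  R² is reported in
   log space.  Prediction inverts trivially (`sav = (target/A)^{1/p}`),
   supporting the inverse-design use case, and a two-point calibration
   (lowest and highest SA/V) yields the exact law through those points.
   Full profiles are predicted by evaluating each constant's law at the
   target SA/V and inserting the constants into the model equation with the
   series-wide shared diffusion exponent n̄ (Peppas–Sahlin) or directly
   (Weibull); predicted curves are clipped to [0, 100].

## Fitting details

Bounded nonlinear least squares (`scipy.optimize.least_squares`,
xtol = ftol = gtol = 1e-14, ≤ 10⁴ evaluations) seeded by log-linearisation,
with a handful of perturbed multi-starts; constants are constrained ≥ 0 and
diffusion exponents to (0, 2].  The free-exponent Peppas–Sahlin fit profiles
the SSR over n with exact non-negative least squares (NNLS) inner solves for
(k₁, k₂) before polishing, which makes the noise-free round trip exact to
machine precision for all seven families.  Each family carries a fit cap —
points above it do not enter the fit — of 60 % released for the power-law
models valid only early (Korsmeyer–Peppas, Higuchi, Lapidus–Lordi) and 98 %
for the full-curve models; both are user-settable.  R² is computed strictly
over the fitted points.  Model ranking is by descending R², ties below 10⁻⁶
broken toward fewer free parameters.

The shared-exponent estimator is deliberately simple: pass 1 fits n freely
per profile, n̄ is the arithmetic mean, pass 2 refits the rate constants at
n̄.  A caveat discovered while validating it: n is weakly identified in the
two-term power model (a smaller n with a larger relaxational term fits
almost as well), so with 1 % measurement noise single-profile free
exponents scatter with sd ≈ 0.1–0.2 and n̄ over nine profiles can deviate
from truth by ~0.1.  Downstream predictions are insensitive to this because
the pass-2 constants re-adapt to whatever n̄ is used; end-to-end holdout
profile RMSEP stays near 1 % regardless.

## Transport classification

The diffusion exponent maps to a mechanism per geometry class with
thresholds (thin film / cylinder / sphere): Fickian diffusion at
0.50/0.45/0.43, Case-II transport at 1.00/0.89/0.85 (each within a 0.005
tolerance), anomalous transport strictly between, and sub-Fickian /
super-Case-II outside.

## Synthetic studies

The generator emulates the basket-method dissolution experiment the
analysis expects.  Sampling times follow the apparatus schedule — every
5 min to 30 min, every 10 min to 120 min, every 20 min to 240 min, every
30 min beyond — truncated when the truth curve passes 99.5 % (cap 600 min).
Three archetype formulations are shipped, with constants taken from the
reference tables in `savrelease.reference`:

| archetype | matrix | model | n̄ |
|---|---|---|---|
| PVA-PDM | water-soluble hydrocolloid | Peppas–Sahlin | 0.79 |
| EVA-LD  | inert                      | Peppas–Sahlin | 0.66 |
| PVA-PZQ | hydrocolloid, BCS II drug  | Weibull       | — |

On-grid SA/V values use the tabulated constants exactly; off-grid values
come from log-log interpolating laws fitted privately inside the generator,
so generator and analysis share no regression code path and recovery tests
cannot self-confirm.  Noise is additive Gaussian on cumulative % (default
sd 1.5 %, a realistic magnitude for UV-Vis sampling; constant over time, no
autocorrelation), independent per point and replicate, clipped to [0, 102];
truth curves are capped at 100.  Defaults are 3 replicates per design.  The
truth record stores the generating constants plus two MDTs: the dense-grid
model MDT and the MDT of the noise-free schedule-sampled curve
(`mdt_sampled`).  Recovery comparisons use the latter, because it applies
the same measurement operator the analysis sees — with zero noise the
pipeline then reproduces the generating exponent to 10⁻⁶, so any deviation
under noise is attributable to noise alone.

What the generator does *not* emulate: apparatus hydrodynamics, the pH
shift mid-run for poorly soluble drugs, content-uniformity variation
between tablets, and autocorrelated drift in the detector.  Passing
recovery tests therefore demonstrate statistical soundness of the
estimation chain under the assumed noise model, not robustness to every
laboratory artefact.

A structural note: the fast-release designs (SA/V ≥ 3.3 of the PVA-PDM
archetype) complete within two or three schedule samples, leaving too few
points below the 98 % cap for a free three-parameter fit.  The pipeline
treats these levels as partial results (they still enter the MDT law, which
needs no curve fit) — the same limitation a real experiment on that
schedule would face.

## Problem sizes

Simulated studies in the test suite use 9 SA/V levels × 3 replicates with
1 % noise, repeated over 10 seeds for the stochastic recovery checks; the
dense MDT-oracle grids use 0.05-min steps.  These sizes give stable
statistics while keeping the full suite fast.

## Known limitations

* Log-space OLS is maximum-likelihood only under multiplicative log-normal
  errors; for strongly heteroscedastic responses a weighted fit would
  differ.  The package follows the linearised-presentation convention.
* The Hopfenberg shape index is selected by exhaustive refit over
  {1, 2, 3}; it is a discrete model choice, not a continuous parameter.
* Replicate averaging requires a common time grid (schedules are
  intersected); irregular per-vessel schedules would need interpolation,
  which is intentionally not done.
* Extrapolation beyond the calibrated SA/V domain is permitted but warns;
  validation of the approach covers interior points only.
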