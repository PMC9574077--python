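# Methods

This note documents the models implemented in `healthdea`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the known limitations.

## Panel and indicators

The unit of analysis is a province-year.  The indicator panel carries one
initial input (I1, per-capita health expenditure, currency), three
intermediate outputs (M1–M3: institutions, technicians, beds, each per
thousand population) and five final outputs (F1 diagnoses, F2 bed
utilization in percent, F3 class-A/B infectious-disease incidence, F4
maternal mortality, F5 perinatal mortality).  F3–F5 are negative-direction
indicators and are positivized by taking reciprocals; a zero rate is a hard
error because the reciprocal is undefined.  Reciprocals are *not* rescaled
afterwards: constant-returns DEA efficiency is invariant to the units of
any single column (tested), so the scale is immaterial.  Panels must be
complete and balanced; no imputation is offered, because the methodology
this package implements assumes a complete panel and silent imputation
would change the frontier.

The 31 provincial units and the eastern (11) / central (8) / western (12)
region partition are shipped as package constants, as is a first-order
contiguity pair list.  Hainan is an island; it is linked to Guangdong, its
nearest mainland neighbor, because an unlinked island has an undefined
row-standardized weight row.  The policy is explicit
(`CHINA_ISLAND_LINKS`) and can be disabled.

## Two-stage network DEA

All efficiency programs are multiplier-form linear programs after the
Charnes–Cooper normalization (weighted input of the evaluated unit = 1),
solved with HiGHS at 1e-9 feasibility tolerances.  The relational model
shares one multiplier system across stages, giving the exact product
identity `E = E1·E2`.  Design choices:

* **Non-Archimedean ε.**  Default 1e-6, configurable.  The bound is
  applied *relative to the column scale* (multiplier ≥ ε / column max):
  this keeps every score strictly positive, makes the units-invariance
  property exact rather than approximate, and leaves the score independent
  of the units the indicators happen to be recorded in.  A fitted model
  flags scores within 10·ε·(total dimension) of a bound as ε-sensitive.
* **Returns to scale.**  Constant returns throughout; no variable-returns
  option is in scope.
* **Frontier definition.**  Per-year cross-sectional frontiers; multi-year
  results are averages of year scores, not a pooled frontier.
* **Decomposition non-uniqueness.**  The overall optimum is unique but its
  stage split may not be.  The split is computed by pinning the overall
  score (as an equality with a 1e-9 slack band, avoiding spurious
  infeasibility) and then maximizing the stage-1 score (`stage1_first`,
  the default) or minimizing it (`stage2_first`, which maximizes stage 2).
  Both orders are always computed; units whose splits differ by more than
  1e-6 are flagged `nonunique_`.  The exact bounds `E ≤ E1 ≤ 1` are
  enforced by clamping within solver tolerance (1e-6); violations beyond
  tolerance raise instead of being repaired silently.

## Moran's I

The statistic is implemented for arbitrary nonnegative weight matrices;
the default weights are binary contiguity, row-standardized (the
convention of the GeoDa lineage of spatial analysis).  Inference defaults
to a seeded permutation test with 999 shuffles and a one-sided
(positive-autocorrelation) p-value `(1 + #{I_perm ≥ I_obs}) / (B + 1)`;
the closed-form randomization moments give the normal-approximation
alternative, whose empirical size at n = 25 sits inside [0.03, 0.08] in
the acceptance run.

## Spatial Durbin panel model

Two-way fixed effects are absorbed by exact double demeaning (idempotent,
absorbs any additive unit and period effects).  The spatial lag of y is
computed per period before demeaning; demeaning and the lag commute up to
the absorbed effects.  Estimation concentrates the likelihood on ρ:
coefficients and σ² are profiled out by least squares at each ρ, the
log-determinant term `T·log|I − ρW|` is evaluated from the eigenvalues of
W (computed once; real for row-standardized symmetric-origin weights), and
ρ is found by bounded derivative-free scalar minimization on the
invertibility interval intersected with (−0.999, 0.999) — the same
bracketed, derivative-free class as golden-section search, with faster
convergence.  Hitting the interval boundary is reported, never clamped
silently.

The covariance matrix comes from the analytic information matrix of
(coefficients, ρ, σ²).  A degrees-of-freedom correction
`σ² · nT / ((n−1)(T−1))` compensates the means absorbed by the within
transformation (Lee–Yu style); it is on by default and recorded in
`meta_`.  The dependent variable is the efficiency score untransformed;
covariates are log-transformed before fitting.

**Effects.**  Direct/indirect/total effects use the reduced-form impact
matrix `S_r(W) = (I − ρW)⁻¹(Iβ_r + Wη_r)`; additivity direct + indirect =
total is exact by construction.  Dispersion comes from seeded draws
(default 1000) from the asymptotic normal of (ρ, β, η), with the
covariance eigen-clipped to positive semidefinite before sampling.

**Test battery.**  The LM and robust-LM statistics for spatial lag/error
are computed on the residuals of the non-spatial two-way within
regression, with the panel trace term `T·tr(W′W + WW)`.  The residual
variance uses the degrees-of-freedom-corrected estimator (subtracting the
absorbed unit and period means); the ML-style `e′e/N` over-rejects
noticeably in panels of this size.  LR tests refit the spatial-lag and
spatial-error models by ML (`H0: η = 0` and the common-factor restriction
`H0: η + ρβ = 0` respectively, both χ²(k)); Wald tests use the delta
method on the full fit.  The Hausman test is the classical (non-spatial)
one-way panel variant — within FE against Swamy–Arora feasible GLS —
flagged as such in its result; the RE covariance uses the within-based σ̂²
(the GLS transform whitens the composite error to that variance by
construction; using RE residuals would inflate it exactly when the null is
false and break the positive-definiteness of the covariance difference).

## Natural breaks and aggregation

The five-class efficiency map tables use the exact Fisher–Jenks dynamic
program (minimal within-class sum of squares over contiguous partitions of
the sorted values), not the iterative heuristic; it matches exhaustive
enumeration at n = 31, k = 5.  Classification defaults to per-year breaks;
regional trends are unweighted arithmetic means per region-year, so the
national mean is the province-count-weighted average of the regional
means.

## Synthetic generators

The DEA generator plants ground truth by construction.  Per year it draws
a price system (a, b) defining one facet of each stage's CRS frontier;
frontier units receive profiles on the facet, other units receive convex
combinations of frontier profiles (which remain on the facet) with the
initial input inflated by f1 ~ U(1, 3) and final outputs deflated by
f2 ~ U(1, 1.8).  With a single initial input, the true stage-1 efficiency
is exactly 1/f1 (radial distance to the common facet) — the LP reproduces
it to solver precision.  Stage 2 has multiple inputs, so 1/f2 is only a
bound: it is attainable at the generator's own price system, hence the LP
stage-2 score is ≥ 1/f2, and exact stage-2 truth is taken from the LP
itself on small instances.  The asymmetric inefficiency ranges reflect the
published provincial pattern in this setting: service operation
(stage 2, provincial averages ranging roughly 0.57–1.00) is substantially
more efficient than resource allocation (0.26–0.98).  Indicator magnitudes
are scaled to typical provincial values (expenditure ≈ 900, institutions /
technicians / beds ≈ 0.75 / 5.9 / 5.0 per thousand, incidence ≈ 0.005,
maternal mortality ≈ 0.1, perinatal mortality ≈ 2), and F3–F5 are emitted
as reciprocals of the generated benefit outputs so positivization restores
them exactly.  An optional spatially autocorrelated latent field
(`spatial_rho` with a weight matrix) drives f1 through a centered tanh
map, with the frontier assigned to the efficient end of the field, so the
planted clustering survives into the measured efficiency surface.

The SDM generator simulates the Durbin process exactly: log-normal
covariates (so the logged regressors used in estimation are Gaussian),
drawn unit and time effects, spherical noise (default σ = 0.1, matching an
error variance of ~0.01 on an efficiency-scaled outcome), and the reduced
form solved with `(I − ρW)⁻¹`.  Default design: n = 49 (7×7 rook grid) or
n = 31 (shipped contiguity), T = 12, ρ = 0.4, β = (−0.6, 0.3),
η = (1.2, −0.5).

All randomness flows from one seed through named substreams, so panels are
byte-identical under a fixed seed and adding a draw site never shifts
existing draws.

**What the generators do not emulate:** real provinces' actual indicator
values, serial correlation of efficiency within a province, measurement
error in yearbook statistics, or any real spatial pattern of Chinese
health efficiency.  Passing tests therefore demonstrate correctness of the
measurement machinery under a known data-generating process, not agreement
with any particular published efficiency table — published tables derive
from undeposited source data and enter only as inputs to arithmetic
consistency checks.

## Problem sizes

The test and acceptance runs use deliberately compact designs: 50 random
instances with n ≤ 6 and dimensions ≤ 2 for oracle agreement (a fine grid
over normalized multiplier vectors is exhaustive there), 15–31 units for
truth recovery, 500 replicates for test size, 200 for estimator recovery
and coverage, and 100 for reduction-test power.  These sizes give
Monte-Carlo standard errors comfortably inside the asserted bands.

## Known limitations

* ε is not identified by the methodology itself; third-decimal agreement
  with any published efficiency table is not a meaningful contract even
  with the same data, since ε, the solver, and the decomposition priority
  all move the third decimal.
* The decomposition reports both priority orders but cannot resolve true
  non-uniqueness; it only flags it.
* The Hausman test is the classical panel variant, not a spatial one.
* The SEM used in the LR battery omits Durbin terms by construction; it
  exists to test the reduction, not as a recommended model.
* The sampling-based effect standard errors assume the asymptotic normal
  of the ML estimator is a good finite-sample approximation; at n = 31,
  T = 12 this is adequate for sign and magnitude, not for fine-grained
  inference.
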