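# Methods

`frapmap` turns sparse FRAP point measurements of intracellular diffusion
into whole-cell diffusion maps with per-pixel uncertainty.  This note
records the models, the estimation choices, and the synthetic study
conditions in enough detail to reproduce or challenge them.

## FRAP recovery model

After photobleaching a ~3 um circular region, the radial fluorescence
profile around the spot center relaxes as

    F(r, t) = A1 - A2 / (4 D t + rho^2) * exp(-r^2 / (4 D t + rho^2)),

the free-diffusion solution for a Gaussian initial bleach profile: D is
the diffusion coefficient (um^2/s), A1 the recovered plateau, A2 the
bleach depth scale (intensity x um^2), rho the initial bleach radius (um).
We fit all four parameters by bounded least squares *jointly* over every
post-bleach frame and radial bin, rather than frame-by-frame: the joint
fit uses the full spatiotemporal information and behaves better when
individual frames are noisy.  Time is measured from the end of the bleach
phase, with the first recovery frame at t = half a frame interval by
default (the bleach occurs during the preceding interval); this origin is
configurable and a misestimate of order one frame interval perturbs D by
roughly Delta-t / t_typical.

Initialization: A1 from the bright quantile of the data, rho from the
median sampled radius, A2 from the central dip depth, D from rho^2 / (4
t_half) with t_half the time for the central intensity to recover halfway.

Binning: `radial_profile` reports one-pixel-wide radial bins for display,
with each bin's abscissa the *mean radius of its pixels* — using nominal
bin centers instead biases fits at the curved profile core.  `fit_all_spots`
fits on quarter-pixel bins, where each bin spans a nearly constant radius
and aggregation adds no curvature bias; on noiseless forward-modeled
stacks D is recovered to ~1e-4 relative.

A fit is flagged non-identifiable when its fitted central bleach depth at
the earliest frame is below 0.1% of the plateau: such "fits" track
background structure, not a bleach, and their D is meaningless.
Non-converged or non-identifiable spots are excluded from the point set
with a warning, never silently.

Photobleaching correction is the simple-ratio method: every frame is
multiplied by ref(0)/ref(t), the reference being a user-supplied
non-bleached region.  This removes a global multiplicative decay exactly
and is the simplest documented mode of the standard correction tools.

## Spatial structure: semivariogram

The spatial statistics operate on the point set {(u_k, D_k)}.  Pairwise
semivariances gamma_ij = (D_i - D_j)^2 / 2 at lags h_ij form the variogram
cloud, summarized by the exponential model

    gamma(h) = b + (c - b)(1 - exp(-h/a)),  h > 0;  gamma(0) = 0,

with range a, nugget b, sill c.  The pipeline default fits the full cloud
(every pair, unbinned) by bounded nonlinear least squares with a
constrained to at most the maximum observed lag — ranges beyond the data
are unresolvable, and without the bound the estimator's heavy tail (cloud
semivariances are scaled chi-square with one degree of freedom) produces
occasional runaway fits.  For parameter-recovery studies we use
`fit_exponential_binned`: 20 equal-width bins to half the maximum lag,
weighted by pair counts.  On 200-point samples of simulated fields
(a = 20 um, c = 1, 160 um domain) it recovers the range within ~25% and
the sill within ~15% on average; the raw-cloud fit is unbiased in the
median but too heavy-tailed to average.

Degenerate inputs: a perfectly flat cloud returns b = c = mean semivariance
with a warning; a sill of zero disables simulation downstream (flagged as a
numerical degeneracy, since the conditional distributions collapse).

## Ordinary kriging

The estimate at u_o is Z* = sum_k w_k Z(u_k) with weights from the
semivariogram-form system

    sum_k w_k gamma(h_jk) + mu = gamma(h_jo),   sum_k w_k = 1,

and prediction variance sigma^2 = sum_k w_k gamma(h_ko) + mu (clamped at
zero against round-off).  Coincident data positions are averaged before
assembly so the system stays nonsingular.  For the right-hand side we use
the continuous limit gamma -> b as h -> 0+: a prediction point collocated
with a datum is treated as a distinct location, so a positive nugget
filters measurement noise while b = 0 keeps kriging an exact interpolator
— both behaviors are asserted in the tests.  Measured-data kriging uses
the global neighborhood (all points; n is ~30 in this application).

Cross-validation reports accuracy = 100 (1 - mean_k |pred_k - obs_k| /
|obs_k|), floored at zero, alongside MAE and RMSE.  The percentage form is
a documented convention of this package (the relative-error mean is the
natural summary when diffusivities span a decade); observations equal to
zero are excluded from it with a warning.  Two leave-one-out predictors
are provided: plain ordinary kriging, and the SGS ensemble mean evaluated
at the held-out location (small target-collocated grid, normal-score
transform and score-space variogram fitted once on the full dataset, as
in the mapping pipeline).  On transformed-Gaussian synthetic fields the
two are nearly tied under this accuracy definition, with kriging ahead by
a fraction of a point — the ensemble mean approximates the conditional
mean, which the relative-error metric does not reward over the best
linear predictor on these fields; see the direction test in the
acceptance suite for the measured comparison.

## Sequential Gaussian simulation

One realization: (1) normal-score transform the data (rank-based, plotting
position (k - 1/2)/n, averaged ties); (2) fit the variogram on the scores
(standard simulation practice; fitting in raw space is available via a
flag); (3) visit grid nodes in a uniformly random order; (4) at each node,
ordinary kriging from the k = 24 nearest conditioning points (measured
plus previously simulated) gives a conditional mean and variance, a draw
from that normal is assigned and appended to the conditioning set; (5)
back-transform the realization to original units — linear interpolation in
the score table, linear tail extrapolation, floored at zero for
diffusivities.  The ensemble default is 100 realizations, each with a
fresh random path and fresh draws (per-realization seeds spawned from the
master seed via `numpy` SeedSequence, reduced below 2^31); re-randomizing
the path per realization averages out path-dependent artifacts.  The
ensemble mean in original units is the map estimate and the per-node SD
the spread (uncertainty) map; back-transforming *before* aggregation keeps
the summary in physical units.

Properties verified in the tests: with full conditioning the sequential
kriging surface reproduces global ordinary kriging to machine precision,
and the 500-realization ensemble mean is an unbiased Monte-Carlo estimate
of it (>= 99% of nodes within 3 standard errors).  The k = 24 local
neighborhood — the production default, needed because full conditioning
scales as the cube of the conditioning set — introduces a small bias
relative to global kriging (typical node deviation ~0.05, max ~0.25
standard-score units on a 35x35 cell grid); the running-mean stabilization
diagnostic (below) is insensitive to it.  Spread maps are larger far from
the data, concentrating uncertainty at the cell periphery where
measurement density is lowest.

The grid is built by block moving-average downsampling of the
full-resolution cell mask (default target 70x70); a node is kept when at
least half its source pixels are intracellular.  Node positions are block
centers in image coordinates (x = column x pixel size, origin at the
top-left pixel center).

Convergence diagnostic: realizations are added in batches of 10 and the
running mean map compared between successive checkpoints; the ensemble is
declared stable when the maximum per-node relative change drops below 2%.
This is a strict criterion — the maximum over ~500 nodes is dominated by
the least favorable node (typically a low-valued node with moderate
ensemble spread, where the same absolute wobble is a larger relative one)
— and on the synthetic conditioned simulations it first triggers at
roughly 110-130 realizations, slightly above the 100-realization default.
Typical nodes stabilize far earlier; users who need the strict criterion
met should raise `n_realizations` accordingly (cost is linear).

## Moran's I diagnostic

Spatial autocorrelation — the method's premise — is tested before mapping.
Weights are inverse squared distance truncated at the mean pairwise
distance, with a zero diagonal (the printed weight rule would give
infinite self-weights; self-pair exclusion is the universal convention),
and the denominator of I uses the squared deviations (the standard form).
The analytic null uses E[I] = -1/(n-1) and the closed-form
normality-assumption variance; an assumption-free permutation mode is the
cross-check, and the two agree in z to within a few percent on fixed
datasets.  p-values are two-sided; p < 0.01 is the significance
convention, and the mapping pipeline completes but warns when the premise
fails.  Power is worth knowing: on exponential-variogram fields sampled at
30 points, the test rejects in roughly 80-90% of draws even when the
correlation range far exceeds the cell — exponential fields are rough at
short lags, so some draws genuinely carry weak within-window structure.

## Synthetic study conditions

The generators define the study conditions; their defaults are fixed and
the tests inherit them.

- **Cell geometries**: a round ellipse (semiaxes 27 x 24 um on a 140x140
  raster at 0.5 um/px; equivalent radius R_cell ~ 25.5 um) and an
  elongated crescent (33 x 14 um body with a lobe carved out).  These are
  synthetic stand-ins for the two experimentally derived morphologies the
  sampling study calls for; the round one is genuinely round so that
  elongation effects are isolated in the crescent.
- **Ground-truth fields**: a radial gradient, linear in normalized
  distance from the mask centroid, from D = 0.5 at the center to 2.0
  um^2/s at the rim (matching the observed intracellular range); and a
  stepwise concentric field with discrete ring levels at equal radial
  quantiles.
- **Sampling patterns**: 30 points per cell (the experimental design
  point), drawn from an isotropic Gaussian of width sigma at the centroid
  and rejection-sampled into the mask, or a square lattice anchored at the
  centroid.  Sweeps enforce a minimum spacing of one grid pitch (2 um at
  35x35) — enough to keep points on distinct nodes; the experimental ~10
  um spacing cannot hold 30 points at narrow sigma and is a protocol
  constraint, not a simulation one.
- **Random fields**: Gaussian random fields with exponential covariance
  C(h) = (c - b) exp(-h/a) by dense Cholesky (grids <= 5000 nodes; the
  jitter-and-retry ladder handles marginal positive-definiteness), nugget
  realized as i.i.d. node noise.  FRAP stacks are forward-modeled from the
  recovery profile; FCS curves from the two-component model.
- **Sweep scale**: sampling sweeps run on a 35x35 grid (70x70 available
  via flag) with 50 realizations per reconstruction and 20 repeats per
  sweep value.

What the synthetic data do *not* emulate: optical blur and detector noise
beyond additive Gaussian, anisotropic or non-stationary spatial structure,
binding/immobile fractions in the recovery curves, and cell-to-cell
variability of the D distribution.  Passing tests therefore demonstrate
the statistical machinery under its own assumptions, not robustness to
every property of real microscopy data.

## Sampling-design findings (as measured by this package)

On the radial-gradient round cell, reconstruction error falls steeply as
the Gaussian pattern widens — mean MAE roughly halves from sigma/R_cell =
0.2 to 0.3 and halves again by ~0.5 — then flattens; narrow patterns
starve the periphery of measurements, and the normal-score back-transform
cannot reach rim values far outside the sampled range.  The plateau-onset
statistic (smallest sweep value whose mean MAE is within 10% of the sweep
minimum) is one operationalization of "where widening stops paying";
because it chases a noisy minimum it carries sampling variability of about
one 0.1 grid step at 20 repeats.

## FCS cross-check

The intensity ACF G(tau) = <dF(t) dF(t+tau)> / <F>^2 is computed directly
at a multi-tau-style quasi-logarithmic lag grid, and fitted with the
two-component 3-D diffusion model in log-parameters (positivity for free),
components ordered fast-first; D_i = w_xy^2 / (4 tau_Di) with calibration
constants w_xy = 0.21 um and S = 2.67 by default.  No triplet term is
included, and fit weights are uniform (1/G weighting available).

## Numerical conventions

- Units are fixed: um, s, um^2/s.  No unit auto-detection anywhere.
- Kriging variances and ensemble SDs are clamped at zero against
  round-off; weight sums are checked to 1e-10 in tests.
- All stochastic components (paths, draws, patterns, noise) derive from
  explicit seeds; every CLI run writes a provenance JSON with the seeds
  used.  The SGS inner loop is JIT-compiled (numba) with an identical pure
  NumPy fallback selected automatically at import.
- Duplicate measurement positions are averaged; sub-resolution duplicates
  inside the SGS conditioning search are skipped to keep systems
  nonsingular.

## Known limitations

- Isotropic variograms only; anisotropy in elongated cells is folded into
  the isotropic fit.
- The k-nearest SGS neighborhood biases node means slightly toward local
  data relative to global kriging (quantified above); increase
  `k_neighbors` where unbiasedness matters more than speed.
- The accuracy percentage is sensitive to near-zero observations; MAE and
  RMSE are always reported alongside.
- LOO cross-validation with the SGS-mean predictor is Monte-Carlo noisy at
  small realization counts; its comparison against kriging should be read
  at the ensemble-size used.
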