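# frapmap

**Whole-cell diffusion maps from sparse FRAP measurements, with
uncertainty.**

FRAP (fluorescence recovery after photobleaching) measures molecular
diffusion at the handful of spots you can afford to bleach — typically a
few tens per cell before photodamage ends the experiment.  Yet the
quantity of interest is the diffusion landscape of the *whole* cell.
`frapmap` closes that gap with geostatistics: it treats the per-spot
diffusion coefficients as a spatially correlated random field, models
their spatial structure with a semivariogram, and reconstructs the full
intracellular map — with a per-pixel uncertainty estimate — by ordinary
kriging and sequential Gaussian simulation (SGS).

It is written for quantitative cell biologists and microscopists who have
FRAP image stacks (or already-fitted point tables) and want statistically
grounded diffusion maps, and for methods developers who want to study how
photobleach-point placement affects reconstruction quality.

## The model

Per bleach spot, the radial fluorescence profile recovers as

    F(r, t) = A1 − A2 / (4 D t + ρ²) · exp(−r² / (4 D t + ρ²)),

fitted jointly over all post-bleach frames by least squares to give the
local diffusion coefficient D (µm²/s).  The point set {(u_k, D_k)} is then
summarized by the exponential semivariogram

    γ(h) = b + (c − b)(1 − e^(−h/a)),   γ(0) = 0,

(range a, nugget b, sill c), fitted on the variogram cloud.  Ordinary
kriging predicts D at unobserved locations u_o as Σ_k ω_k D(u_k) with
weights solving

    Σ_k ω_k γ(h_jk) + µ = γ(h_jo),   Σ_k ω_k = 1,

and SGS turns the single kriging surface into an ensemble: grid nodes are
visited in random order, each simulated from its local kriging
conditional N(mean, error variance) in normal-score space, conditioning
all later nodes; 100 such realizations are back-transformed and averaged
into a mean map, their spread giving the uncertainty map.  Moran's I
(inverse-square-distance weights truncated at the mean pairwise distance)
tests the spatial-autocorrelation premise before any interpolation is
trusted.

## Worked example

Thirty synthetic FRAP measurements on an elliptical cell, mapped to a
35×35 grid:

```python
import numpy as np
from frapmap import (DiffusionMap, VariogramModel, build_grid,
                     gaussian_sampling, make_radial_field,
                     sample_points_from_field, equivalent_radius)
from frapmap.sampling import ellipse_mask

mask = ellipse_mask()                         # 140×140 px, 0.5 µm/px
grid = build_grid(mask, pixel_size=0.5, target_shape=(35, 35))
field = make_radial_field(grid, D_center=0.5, D_edge=2.0)   # ground truth
pattern = gaussian_sampling(grid, sigma=0.56 * equivalent_radius(grid),
                            n_points=30, seed=7, min_spacing=2.0)
points = sample_points_from_field(field.values, grid, pattern.positions)

model = DiffusionMap(points, grid=grid)
res = model.fit(n_realizations=100, seed=7)
print(res.summary())
```

prints

```
Whole-cell diffusion map (variogram + sequential Gaussian simulation)
======================================================================
measurement points        30
grid nodes (in cell)      511  shape (35, 35), pitch 2 um
realizations              100  (master seed 7)

Spatial structure (exponential variogram, normal-score space)
  range a                 10.82 um
  nugget b                3.928e-10
  sill c                  1.272

Spatial autocorrelation (Moran's I, inverse-square weights)
  I                       0.8354
  E[I] under null         -0.0345
  z                       6.799
  p (analytic)          1.06e-11  *significant*

Mapped diffusivity (um^2/s)
  data   min/median/max   0.612 / 1.33 / 1.98
  map    min/median/max   0.64 / 1.4 / 1.94
  spread mean             0.274

Leave-one-out cross-validation (ok)
  accuracy                93.2%
  MAE / RMSE              0.0841 / 0.114
```

Reading it: the measured diffusion coefficients are strongly spatially
autocorrelated (Moran's I = 0.84 against a null expectation of −0.03,
p ≈ 1e-11), so interpolation is justified; their spatial correlation
decays over a ~11 µm range with essentially no nugget; the SGS mean map
spans the measured 0.6–2.0 µm²/s range; and leaving each point out in
turn, kriging predicts it to within ~7% on average (accuracy 93%).
`res.mean_map` and `res.spread_map` are the (35, 35) maps (NaN outside
the cell), and `res.plot()` renders them with the measurement points
overlaid.

The same pipeline is scriptable from the shell (`frapmap sgs --points
points.csv --mask cell.tif --pixel-size 0.5 --n-real 100 --seed 7
--out-prefix cellA`), along with `fit-frap` (stacks → point tables),
`variogram`, `moran`, `krige`, `fcs`, `simulate-sampling`, `synth` and
`summarize-regions` subcommands; every run writes a JSON provenance
record with all seeds.

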