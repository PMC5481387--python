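# Methods

This note documents the statistical models implemented in `bayescluster3d`,
the meaning and defaults of every user-facing parameter, the scope of the
synthetic-data generator, and the numerical choices that make results exact
and reproducible. All lengths are nanometres.

## Overview

The analysis of one region of interest (ROI) proceeds in three stages:

1. **Proposal generation.** For each probe radius `r` on a grid, compute a
   localized 3D Ripley's L value per point, keep points whose neighbour
   count exceeds a complete-spatial-randomness (CSR) significance
   threshold, find the modes of the resulting L field on the r-neighbour
   graph, and merge or delete modes whose topographic prominence falls
   below a threshold `T` (also swept on a grid). Every `(r, T)` pair yields
   a candidate partition of the points into clusters plus background.
2. **Bayesian scoring.** Each candidate partition receives a log posterior
   score under a generative model with Gaussian clusters, per-point
   anisotropic localization error, a histogram prior over cluster radius,
   and a (possibly non-uniform) axial background law.
3. **MAP selection and description.** The highest-scoring partition is
   reported, along with per-cluster and per-ROI descriptors and an axial
   profile of the clustered fraction.

## Localized 3D Ripley's L

For point *j*, let `c_j` be the number of other points strictly within
distance `r` under the **toroidal** metric (the ROI is treated as a 3-torus,
the standard edge correction for rectangular ROIs). The linearised local L
statistic is

```
L3D(r)_j = ( 3 V c_j / (4 (n-1) π) )^(1/3)
```

with `V` the ROI volume and `n` the number of points. Under CSR the
expectation of `c_j` is `(n-1) p` with `p = (4πr³/3)/V`, and `E[L] ≈ r`
when the mean count is large. (For small mean counts the cube root
introduces a Jensen bias; the calibration test therefore uses a probe
radius large enough that the mean count is ≈ 12.)

**CSR eligibility.** A point may seed or join a cluster proposal only if
`c_j > c* = (n-1)p + sqrt((n-1)p(1-p))` — one binomial standard deviation
above the CSR mean. The linearised value of `c*` is the "sea level" `L*`
used by the island rule below.

Neighbour search uses `scipy.spatial.cKDTree` with `boxsize` equal to the
ROI lengths, which implements the periodic metric natively; an O(n²)
brute-force counter is kept as a test oracle. `r` must be below half the
smallest ROI side for the toroidal metric to be well defined.

## Mode finding and topographic prominence

On the graph connecting eligible points within distance `r`, each point
climbs to its steepest-ascent neighbour, where "higher" means
lexicographically larger `(L, index)` (the index breaks exact ties
deterministically). Climbing terminates at modes; each mode owns a basin.

Modes are then processed in descending `(L, index)` order with a
union-find, ToMATo-style persistence merge:

- when the basin of a lower mode first touches the basin of a higher mode,
  the lower mode's prominence is `L(mode) − L(saddle)`, where the saddle is
  the contact point; if the prominence is below `T`, the two basins merge,
  otherwise the lower mode becomes a separate cluster;
- **island rule**: a mode whose basin never meets a higher basin has
  prominence `L(mode) − L*` (its height above the CSR sea level); if that
  is below `T`, its points drop to background. This rule makes `T` act
  uniformly on isolated and connected modes.

Clusters smaller than `min_cluster_size` (default **5**) are relabelled as
background. With the Bernoulli labelling prior below, any 2–4 point
aggregate of background points within ~100 nm gains a few log-posterior
units when labelled a cluster, so without a minimum size the MAP partition
on clustered data carries dozens of spurious micro-clusters and the CSR
false-positive rate rises severalfold. Five is the smallest size at which
this failure mode disappears in our measurements.

The sweep grid defaults are `r ∈ {20, 30, …, 200}` and
`T ∈ {0, 10, …, 200}`. `T` lives on the same scale as `L` (local maxima on
typical data reach 200–400 nm and `L*` is 80–220 nm), which is why its
range matches the `r`-scale rather than being a small fraction of it.
Duplicate partitions arising at different `(r, T)` are deduplicated by a
canonical signature, and the all-background partition is always included
as a baseline candidate.

## Generative model and scoring

Each localization is background with prior probability `p_bg` (default
0.5, i.e. a neutral labelling prior) or a member of a cluster.

**Clusters.** Molecular positions in a cluster follow an isotropic
Gaussian of standard deviation `s` (the cluster "radius") about an unknown
centre `μ`. The radius carries a histogram prior with bin centres
`{5, 10, …, 60}` nm by default and uniform weights. The support is
deliberately restricted to the sub-diffraction nanocluster regime (up to
about twice the typical 30 nm localization precision): if the support
extends to ~100 nm, broad Poisson density fluctuations spanning
150–250 nm in completely random data get absorbed as maximal-radius
"clusters", destroying specificity. Users studying larger structures can
pass their own `RadiusPrior`.

**Observation error.** Localization *i* is observed through independent
Gaussian noise with per-dimension standard deviation `(σx, σy, σz)_i`, so
its observation variance in dimension *d* at radius `s` is
`v_id = s² + σ_id²`.

**Centre integral.** Given `s`, the likelihood factorises per dimension
and the integral over `μ_d` has the closed form

```
∫ Π_i N(x_i; μ, v_i) dμ
  = exp( -½ [ (m−1) ln 2π + Σ ln v_i + ln Σ 1/v_i
              + Σ x_i²/v_i − (Σ x_i/v_i)² / Σ 1/v_i ] )
```

(equal to 1 for a single point). The centre prior — uniform in x and y,
Beta in z (see below) — is evaluated at the precision-weighted mean centre
and multiplied in, rather than integrated, which is exact for the flat x/y
directions and a sharp-peak approximation in z. The cluster marginal is
the log-sum-exp over radius bins of these per-bin terms plus log bin
weights.

**Background.** Background positions are uniform in x and y and follow a
`Beta(α, β)` law on `z/Lz`; `Beta(1, 1)` is the uniform model. With
`z_mode="fit-beta"` (default) the Beta law is fitted to the ROI's own z
density by maximum likelihood (`scipy.stats.beta.fit` with location and
scale fixed; method-of-moments fallback on non-convergence; uniform below
10 points, where the fit is unidentifiable). The same law serves as the
z prior for cluster centres, so an axially skewed ROI penalises cluster
centres in depleted z slabs as well as background there.

**Score.** For a partition with background set B and clusters C₁…C_K,

```
score = Σ_k log m(C_k)  +  Σ_{i∈B} log f_bg(x_i)
        + |B| log p_bg + (n − |B|) log(1 − p_bg)
```

where `m(·)` is the cluster marginal and `f_bg` the background density
(per nm³). At `p_bg = 0.5` the Bernoulli term is a constant `n log ½`, so
ranking is labelling-independent; the scoring is deliberately neutral by
default. The MAP partition maximises the score; exact ties are broken
toward fewer clusters, then smaller `r`, then smaller `T`.

## Descriptors

Per cluster: point count; MAP radius (the radius bin maximising the
per-bin marginal term plus log weight); precision-weighted centroid
(weights `1/v` at the MAP radius); RMS radius
`sqrt(Σ‖x−centroid‖² / 3m)`, which estimates `sqrt(s² + σ²)` and is
therefore larger than the MAP radius.

Per ROI: number of clusters K, percent of localizations in clusters, mean
localizations per cluster, mean MAP radius, the winning `(r, T)` and
score. The axial profile bins the ROI into 30 nm z slabs and reports, per
slab, localization count, clustered percentage, and the fraction of
clusters (by centroid) in the slab. Batch summaries report per-ROI rows
plus mean and standard-error rows (the SEM row is flagged undefined for a
single ROI).

## Synthetic-data generator

`SimulationSpec` describes one condition; named constructors cover the
validation suite:

- **Standard Condition**: 3000 × 3000 × 600 nm ROI, 10 Gaussian clusters
  of radius 30 nm with 50 molecules each, plus 50% uniform background —
  1000 localizations total.
- Variants: total counts 100–2000 (cluster size scales with the total),
  background fractions 0.1–0.9, CSR (no clusters), membrane-proximal
  `Beta(2,5)` / `Beta(2,20)` axial laws, hard-sphere (uniform-ball) and
  ellipsoidal clusters (axis ratio 1:1:2, random principal axis).
- Cluster centres are placed uniformly at least `3s` from every face; when
  an axial Beta law is given it applies to background **and** cluster
  centres (rejection sampling within the margin), since a slab-shaped
  background with uniformly deep clusters would make the single-Beta
  background fit badly mis-specified.
- Each molecule receives its own localization precision drawn from a
  Gamma law (shape 4, mean 30 nm), applied isotropically, and is observed
  through Gaussian noise of that scale.
- Noise can push a position outside the ROI; positions are **reflected**
  at the faces rather than wrapped. Wrapping would teleport
  membrane-proximal molecules to the opposite face and visibly corrupt
  the axial law the condition is defined by; reflection preserves counts
  and locality.

Ground truth (labels, centres, true radius, molecular positions) is
returned with each table, and helpers score recovery: an *artificial*
cluster is a detected cluster whose centroid lies farther than three true
radii from every true centre.

Scope: the generator covers rectangular ROIs with independent molecules
and isotropic per-point precision. It does not model repeated blinking of
one fluorophore, drift, or anisotropic (z-inflated) precision — real SMLM
data have all three, and the localized-L + Bayesian machinery does not by
itself distinguish overcounting artifacts from true clustering.

## Numerical choices

- All probabilistic computation is in log space; mixtures use
  `scipy.special.logsumexp`.
- Beta log densities clamp their argument to `[1e-6, 1 − 1e-6]` to avoid
  infinities at the faces.
- Neighbour relations use strict inequality (`d < r`), matching the
  brute-force oracle exactly; KD-tree and brute-force counts are asserted
  equal in the test suite.
- CSV output uses `%.17g` and reading uses round-trip float parsing, so a
  write/read cycle is bit-exact and re-running an analysis on the same
  inputs is byte-identical.
- All tie-breaks (mode ordering, MAP selection) are deterministic; the
  entire pipeline contains no random number generation outside the
  simulator, whose draws all derive from a single integer seed.

## Known limitations

- The Bernoulli labelling prior is *per point*, not a prior over
  partitions: it pays no "look-elsewhere" cost for introducing an extra
  cluster. Specificity therefore rests on the minimum cluster size and the
  radius-prior support rather than on the prior itself, and the benefit of
  fitting the axial Beta law (versus assuming uniform z) is small in our
  measurements — the fitted law shifts scores by a few log units, which
  rarely crosses the decision boundary for the ≥5-point aggregates that
  survive the size filter.
- The centre prior in z is evaluated at the weighted mean centre (sharp
  peak approximation) rather than integrated against the Beta law.
- The toroidal edge correction assumes the process continues statistically
  beyond the ROI; features touching the boundary are wrapped, not
  truncated.
- The sweep considers whole partitions generated by the prominence
  machinery only; the scorer never moves individual points between
  clusters and background.
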