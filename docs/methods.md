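# Methods

## Model and estimation procedure

The Interaction Factor treats the segmented clusters of a two-color image
as rigid objects and asks how much the observed cluster-level overlap
exceeds what uniform random placement inside the ROI would produce.

**Null model.**  Every cluster is translated to an anchor drawn uniformly
from its *valid-anchor set* — all positions at which the entire cluster
lies inside the ROI.  Shapes never rotate or deform (rotation changes
overlap statistics only marginally for compact clusters and would break
shape conservation), and same-color clusters may overlap one another: the
null must not impose an exclusion interaction that the data do not.

**Interacting placement.**  A reference cluster is placed with interaction
factor f by: (1) draw a random position; (2) keep it if f = 0; (3) keep it
if it overlaps (shares ≥ 1 pixel with) the other color; (4) otherwise keep
it with probability 1 − f, else retry from (1).  The overlap probability of
cluster k across retry iterations is the geometric series
p_k(0) · Σ_i [(1 − p_k(0)) f]^i = p_k(0) / (1 − (1 − p_k(0)) f).  The mean
of this expression over clusters is the analytic overlap curve P(f); the
estimator inverts it at the observed overlap fraction.  The same placement
rule run generatively produces validation scenes whose true f is known.

**Estimation.**  p_k(0) is the fraction of `n_sims` null randomizations in
which cluster k overlapped the other channel, so each p_k(0) and the
empirical p-value are exact multiples of 1/n_sims (0.02 at the default
n_sims = 50).  The observed overlap fraction is always measured on the
original, non-randomized scene.  Both reference directions are estimated
independently; interaction can be genuinely asymmetric, and the two
estimates agree only for symmetric scenes.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `scale` | 20 nm/px | physical pixel pitch of the rendered image |
| `min_area` | 4 px | clusters strictly smaller are excluded (segmentation and generator alike) |
| `connectivity` | 8 | pixel connectivity for components and overlap-region counting |
| `n_sims` | 50 | null randomizations per direction; probability precision 1/n_sims |
| `randomize_both` | True | randomize both colors; False keeps the other color fixed (e.g. membrane-bound species) |
| `max_attempts_per_cluster` | 10 000 | cap on the accept/retry loop; exhaustions are counted and warned, never fatal |

Mask rule is strictly `value > threshold`.  Overlap area converts as
(pixel count) × (scale/1000)² µm².  Pixel (0, 0) is top-left; polygon ROI
vertices are [x, y] in pixel coordinates and a pixel belongs to the ROI
when its center is inside or on the boundary (simple, non-self-intersecting
polygons are assumed; rasterization uses shapely's point-in-polygon test).

## Numerical choices

* **Inversion** is by bisection on [0, 1] (≤ 60 iterations, interval
  tolerance 1e-9): P(f) is strictly increasing whenever some
  p_k(0) ∈ (0, 1), making bisection branch-free and robust.  Observed
  overlap ≤ P(0) clamps to f̂ = 0 (below-chance co-localization is not
  distinguished further); ≥ P(1) clamps to 1.  A profile whose p_k(0) are
  all 0 or 1 has a flat curve; the clamps handle every observable input,
  and a non-invertibility error guards the (unreachable) interior case.
* **p_k(0) ∈ {0, 1}** enter the curve by their limits: a cluster with
  p_k(0) = 0 contributes 0 at every f including f = 1; p_k(0) > 0
  contributes exactly 1 at f = 1 (computed as the limit, avoiding p0/p0
  round-off).
* **Uniform anchor draws** use rejection sampling from the ROI bounding
  box, which is exactly uniform over the valid-anchor set and requires no
  per-shape precomputation.  If 5 000 proposals fail (ROIs occupying a tiny
  fraction of their bounding box), the valid-anchor set is enumerated
  exhaustively once, cached per (ROI, shape), and sampled directly; an
  empty enumeration raises a placement error.  The enumeration is also the
  brute-force oracle used in tests.
* **Determinism.**  One integer seed is fanned out into named substreams
  (generation, per-direction profiles, experiment cells) via
  `numpy.random.SeedSequence` spawn keys, so identical seeds give
  bit-identical results and enlarging one stage never perturbs another.

## Synthetic scenes

`SceneSpec` defaults define the validation conditions: a 512×512 grid at
20 nm/px with an elliptical ROI (semi-axes 230×179 px, ≈ 52 µm² — the scale
of a cell nucleus filling half the field of view), 100 reference (green)
and 100 other (red) clusters.  Clusters are filled rotated ellipses with
log-normal semi-axes (μ = ln 3.4, σ = 0.3, orientation uniform), giving a
mean area ≈ 40 px — diffraction-scale protein clusters at this pixel size.
Sub-4-px rasterizations are resampled so generated counts are exact and
every cluster survives the segmentation filter.  Red cluster number and
size multipliers are the density knobs of the validation experiments.

What the generator does *not* emulate: localization noise, blinking
artifacts and rendering PSFs of raw SMLM data; intensity variation within
clusters (scenes are binary); spatial inhomogeneity of cluster density
(placement is uniform); cluster-shape families beyond ellipses.  Passing
validation therefore demonstrates correctness of the estimator given
segmented clusters, not robustness of segmentation to imaging artifacts —
on real data the segmentation choices (threshold method, ROI) remain the
user's responsibility.

## Validation experiments (desk scale)

`experiments` reruns the estimator's validation studies with tidy-table
outputs, at problem sizes chosen so the full suite completes in minutes on
one CPU (larger grids are a config change away):

* **density_sweep** — the headline property: across red-cluster counts at
  fixed true IF, the regression slope of f̂ on count is statistically flat
  while the raw overlap fraction strictly increases.
* **accuracy_grid** — R² of estimated vs true IF per (size, count) cell,
  both per-image and on cell means; accuracy degrades for sparse/small
  red clusters, where p_k(0) is small and the overlap curve flat.
* **significance_grid** — mean two-sample p-value for distinguishing
  image groups at IF pairs (Bartlett pre-test, Welch t-test on unequal
  variances, Student otherwise), as a sample-size planning guide.
* **repeatability** — run-to-run spread of f̂ for a fixed scene.  Spread
  shrinks as 1/√n_sims and is widest near the random level, where the
  curve is flattest; a random scene whose observed overlap falls below its
  null mean is clamped to 0 in every repeat, so repeatability at a level is
  summarized over several scenes.
* **if_curve** — Monte-Carlo overlap of scenes regenerated across f
  against the analytic curve.  The analytic overlay uses 200 null
  randomizations (not the estimation default 50): p_k(f) is convex in
  p_k(0), so noisy profile estimates bias the high-f curve upward, and the
  overlay is meant to represent the curve itself.

Multi-group comparisons follow the same variance-pretest scheme
(Kruskal–Wallis on unequal variances, one-way ANOVA otherwise).

## Known limitations

* 2D only; overlap in projected images overstates 3D co-localization.
* The null places clusters uniformly; organelle-scale spatial structure
  (excluded volumes, compartments) inflates apparent interaction unless
  captured by the ROI or the fixed-channel option.
* Estimates for scenes near the random level have high variance and a
  point mass at 0 from clamping; conclusions there need many images.
* Rigid translation without rotation slightly misstates the null for
  highly anisotropic clusters in anisotropic ROIs.
* Channel registration, drift correction and localization-list rendering
  are upstream of this package.
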