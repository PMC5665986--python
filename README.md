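# ifactor

Density-invariant quantification of cluster co-localization in two-color
(super-resolution) fluorescence microscopy images.

## The problem

Fluorescence microscopy experiments frequently ask whether two labeled
molecular species interact, using spatial overlap of their segmented
clusters as a surrogate for interaction.  Raw overlap measures — percentage
of overlapping clusters, overlap area, Manders M1/M2, Pearson r — all grow
with cluster density: add more red clusters and more green clusters overlap
by chance alone, even with no interaction.  Comparing conditions that also
change expression level or clustering is then confounded.

The **Interaction Factor (IF)** removes this confound.  It is a probability
in [0, 1]: 0 means the observed overlap is fully attributable to random
placement, 1 means complete co-localization.  It is estimated per image by
comparing observed overlap against a stochastic null model built from the
image's own clusters.

## The model

Segment both channels (Otsu threshold, connected components, clusters with
fewer than 4 px excluded) inside a region of interest (e.g. a nucleus
outline).  Two clusters co-localize when they share at least one pixel.
Repeatedly re-place all clusters uniformly at random inside the ROI
(rigidly — translated, never rotated or deformed) to estimate, for every
reference-color cluster *k*, its random-overlap probability *p_k*(0).
Under placement with interaction factor *f* (clusters that miss the other
color are re-placed with probability *f*), the overlap probability of
cluster *k* follows a geometric series with closed form

    p_k(f) = p_k(0) / (1 − (1 − p_k(0)) · f)

and the expected fraction of overlapping reference clusters is

    P(f) = (1/n) Σ_k  p_k(0) / (1 − (1 − p_k(0)) · f)

*P*(f) is continuous and strictly increasing in *f*, so the estimate `f̂`
is obtained by bisection from the observed overlap fraction; observed
overlap at or below the random level maps to 0.  An empirical p-value
reports the proportion of null randomizations whose overlap fraction
reached the observed one.  Interaction can be asymmetric, so the IF is
always reported in both reference directions (R-G IF: green reference;
G-R IF: red reference).

The package also generates fully synthetic two-color ellipse-cluster scenes
at any prescribed IF (the same accept/retry placement run forward), which
is how the estimator is validated end to end without any experimental data.

## Worked example

Simulate one two-color image at a known IF of 0.85 and re-estimate it:

```sh
ifactor simulate --n-ref 100 --n-other 100 --if 0.85 --seed 11 --out-dir demo
ifactor estimate --image demo/sim_000.tif --roi demo/roi.tif --seed 11 --out-dir demo_est
```

prints

```json
{
  "forward": {
    "f_hat": 0.887952568475157,
    "p_value": 0.0,
    "percent_overlap": 47.674418604651166
  },
  "reverse": {
    "f_hat": 0.8772632726468146,
    "p_value": 0.0,
    "percent_overlap": 44.565217391304344
  }
}
```

47.7% of green clusters overlap a red cluster, and the null randomizations
never reached that overlap (p = 0.0, i.e. < 1/50): the co-localization is
far above chance.  Inverting the overlap curve gives an IF of ≈ 0.89 with
green as reference (≈ 0.88 with red), recovering the simulated 0.85 within
the single-image spread.  `demo_est/if_result.json` additionally records
the symmetric overlap statistics (42 overlap regions, 0.24 µm² total at
20 nm/px, M1 = 0.17, M2 = 0.15, Pearson r = 0.13).

The same estimate runs on real data: a TIFF/PNG with the two channels
selected by `--channels` (R/G/B name or page index), an optional ROI as a
mask image or JSON polygon, and `--scale` in nm/pixel.  `ifactor metrics`
computes only the classical overlap/Manders/Pearson measures, and
`ifactor validate {density,accuracy,significance,repeatability,curve}`
runs the desk-scale validation experiments (see `docs/methods.md`).

## Library use

```python
import numpy as np
from ifactor import SceneSpec, generate_scene, compute_if

scene = generate_scene(SceneSpec(n_ref=100, n_other=25, f=0.9),
                       np.random.default_rng(1))
forward, reverse = compute_if(scene, n_sims=50, seed=1)
print(forward.f_hat, forward.percent_overlap, forward.p_value)
```

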