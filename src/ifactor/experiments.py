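"""Desk-scale validation studies of the IF estimator.

Each experiment generates synthetic ellipse scenes at known interaction
factors, runs the estimator, and summarizes how well and how reproducibly
the true IF is recovered:

* :func:`density_sweep` — the headline property: the estimated IF stays flat
  while the raw overlap fraction climbs with other-color cluster density.
* :func:`accuracy_grid` — R² of estimated vs true IF over size/count cells.
* :func:`significance_grid` — mean t-test p-values for distinguishing groups
  of images at different IF levels and sample sizes.
* :func:`repeatability` — run-to-run spread of the estimate for one scene.
* :func:`if_curve` — Monte-Carlo overlap versus the analytic overlap curve.

All outputs are tidy DataFrames reproducible bit-for-bit from (config, seed).
Estimates here use the forward direction (scene reference color as
reference, i.e. the R-G IF for green-reference scenes).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import substream
from .core import Scene
from .clusters import measure_overlap
from .estimator import (
    DEFAULT_N_SIMS,
    estimate_direction,
    estimate_profile,
    forward_overlap,
)
from .randomize import PlacementConfig, randomize_scene
from .simulate import SceneSpec, generate_scene


def r_squared(true_values, estimates) -> float:
    """Coefficient of determination of the regression estimate ~ true.

    Returns NaN when either side has zero variance (undefined R²).
    """
    x = np.asarray(true_values, dtype=float)
    y = np.asarray(estimates, dtype=float)
    if x.size < 2 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)


def _two_group_p(a: np.ndarray, b: np.ndarray) -> float:
    """Two-sample test p-value: Bartlett pre-test, Welch on unequal variances."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.std() == 0 and b.std() == 0:
        return 1.0 if a.mean() == b.mean() else 0.0
    with np.errstate(divide="ignore"):
        bart = stats.bartlett(a, b).pvalue
    unequal = (not np.isfinite(bart)) or bart < 0.05
    return float(stats.ttest_ind(a, b, equal_var=not unequal).pvalue)


def _multi_group_p(groups: list[np.ndarray]) -> tuple[str, float]:
    """k-group test: Kruskal-Wallis on unequal variances, else one-way ANOVA."""
    with np.errstate(divide="ignore"):
        bart = stats.bartlett(*groups).pvalue
    unequal = (not np.isfinite(bart)) or bart < 0.05
    if unequal:
        return "kruskal", float(stats.kruskal(*groups).pvalue)
    return "anova", float(stats.f_oneway(*groups).pvalue)


@dataclass
class SweepResult:
    """Per-image results plus summaries of a density sweep."""

    images: pd.DataFrame
    summary: pd.DataFrame
    regression: pd.DataFrame
    group_test: pd.DataFrame


def density_sweep(
    true_f: list[float],
    n_other_levels: list[int],
    images_per_cell: int,
    base_spec: SceneSpec | None = None,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
) -> SweepResult:
    """Vary other-color cluster count at fixed IF levels.

    For every (f, level) cell, ``images_per_cell`` scenes are generated and
    estimated.  Per IF level the summary includes a linear regression of the
    estimate on the cluster count (whose slope should be indistinguishable
    from 0) and the multi-group test on the estimates across counts.
    """
    if not true_f or not n_other_levels:
        raise ValueError("true_f and n_other_levels must be non-empty")
    base = base_spec if base_spec is not None else SceneSpec()
    rows = []
    for f in true_f:
        for level in n_other_levels:
            spec = replace(base, f=f, n_other=int(level))
            for rep in range(images_per_cell):
                scene = generate_scene(spec, substream(seed, "sweep-gen", f, level, rep))
                res = estimate_direction(
                    scene, n_sims, rng=substream(seed, "sweep-est", f, level, rep), seed=seed
                )
                rows.append(
                    {"f_true": f, "n_other": level, "rep": rep,
                     "f_hat": res.f_hat, "observed_P": res.observed_P,
                     "p_value": res.p_value}
                )
    images = pd.DataFrame(rows)
    summary = (
        images.groupby(["f_true", "n_other"])
        .agg(mean_f_hat=("f_hat", "mean"), sd_f_hat=("f_hat", "std"),
             mean_P=("observed_P", "mean"), sd_P=("observed_P", "std"),
             n=("f_hat", "size"))
        .reset_index()
    )
    reg_rows, test_rows = [], []
    for f in true_f:
        sub = images[images.f_true == f]
        if len(n_other_levels) >= 2 and len(sub) >= 3:
            fit = stats.linregress(sub.n_other, sub.f_hat)
            reg_rows.append({"f_true": f, "slope": fit.slope,
                             "intercept": fit.intercept, "p_slope": fit.pvalue})
        groups = [sub[sub.n_other == lv].f_hat.to_numpy() for lv in n_other_levels]
        if len(groups) >= 2 and all(g.size >= 2 for g in groups):
            name, p = _multi_group_p(groups)
            test_rows.append({"f_true": f, "test": name, "p": p})
    return SweepResult(images, summary, pd.DataFrame(reg_rows), pd.DataFrame(test_rows))


@dataclass
class AccuracyResult:
    """Per-image recoveries plus R² tables over (size, count) cells."""

    images: pd.DataFrame
    r2_per_image: pd.DataFrame
    r2_cell_means: pd.DataFrame


def accuracy_grid(
    sizes: list[float],
    counts: list[int],
    f_levels: list[float],
    images_per_cell: int,
    base_spec: SceneSpec | None = None,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
) -> AccuracyResult:
    """R² of estimated vs true IF for each other-color (size, count) cell.

    R² is computed twice per cell, pooling over the IF levels: from all
    individual images and from the per-level means (the per-image table is
    the stricter of the two).
    """
    if len(f_levels) < 2:
        raise ValueError("need at least two IF levels for R²")
    base = base_spec if base_spec is not None else SceneSpec()
    rows = []
    for size in sizes:
        for count in counts:
            for f in f_levels:
                spec = replace(base, f=f, n_other=int(count), size_scale_other=size)
                for rep in range(images_per_cell):
                    scene = generate_scene(spec, substream(seed, "acc-gen", size, count, f, rep))
                    res = estimate_direction(
                        scene, n_sims,
                        rng=substream(seed, "acc-est", size, count, f, rep), seed=seed,
                    )
                    rows.append({"size": size, "n_other": count, "f_true": f,
                                 "rep": rep, "f_hat": res.f_hat,
                                 "observed_P": res.observed_P})
    images = pd.DataFrame(rows)
    per_image, cell_means = [], []
    for size in sizes:
        for count in counts:
            cell = images[(images["size"] == size) & (images.n_other == count)]
            per_image.append({"size": size, "n_other": count,
                              "r2": r_squared(cell.f_true, cell.f_hat)})
            means = cell.groupby("f_true").f_hat.mean()
            cell_means.append({"size": size, "n_other": count,
                               "r2": r_squared(means.index, means.to_numpy())})
    return AccuracyResult(
        images,
        pd.DataFrame(per_image).pivot(index="size", columns="n_other", values="r2"),
        pd.DataFrame(cell_means).pivot(index="size", columns="n_other", values="r2"),
    )


def significance_grid(
    f_levels: list[float],
    images_per_group: int,
    repeats: int,
    base_spec: SceneSpec | None = None,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
) -> pd.DataFrame:
    """Mean two-sample p-value for every pair of IF levels.

    For each (f1, f2) pair, two groups of ``images_per_group`` scenes are
    generated and their estimates compared (Bartlett pre-test, then Welch or
    Student t-test); the comparison is repeated ``repeats`` times and the
    p-values averaged.
    """
    if images_per_group < 2:
        raise ValueError("images_per_group must be >= 2")
    base = base_spec if base_spec is not None else SceneSpec()

    def group(f: float, tag: object) -> np.ndarray:
        out = np.empty(images_per_group)
        spec = replace(base, f=f)
        for i in range(images_per_group):
            scene = generate_scene(spec, substream(seed, "sig-gen", tag, f, i))
            out[i] = estimate_direction(
                scene, n_sims, rng=substream(seed, "sig-est", tag, f, i), seed=seed
            ).f_hat
        return out

    rows = []
    for i, f1 in enumerate(f_levels):
        for f2 in f_levels[i:]:
            ps = [
                _two_group_p(group(f1, (r, "a")), group(f2, (r, "b")))
                for r in range(repeats)
            ]
            rows.append({"f1": f1, "f2": f2,
                         "mean_p": float(np.mean(ps)),
                         "n_per_group": images_per_group})
    return pd.DataFrame(rows)


@dataclass
class RepeatabilityResult:
    f_hats: np.ndarray
    range: float
    sd: float
    observed_P: float


def repeatability(
    scene: Scene,
    n_repeats: int = 20,
    n_sims: int = DEFAULT_N_SIMS,
    seed: int = 0,
) -> RepeatabilityResult:
    """Run-to-run spread of the IF estimate for a single fixed scene.

    The observed overlap is fixed; only the random-overlap profile is
    re-estimated with an independent substream per repeat.  The reported
    range (max - min) shrinks as n_sims grows and is widest for scenes near
    the random level, where the overlap curve is flattest.
    """
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    f_hats = np.empty(n_repeats)
    observed = measure_overlap(scene).fraction_ref_overlapping
    for i in range(n_repeats):
        res = estimate_direction(scene, n_sims, rng=substream(seed, "repeat", i), seed=seed)
        f_hats[i] = res.f_hat
    return RepeatabilityResult(
        f_hats, float(f_hats.max() - f_hats.min()), float(f_hats.std(ddof=1)), observed
    )


@dataclass
class CurveResult:
    """Monte-Carlo overlap fractions vs the analytic overlap curve."""

    table: pd.DataFrame
    max_abs_dev: float


def if_curve(
    scene: Scene,
    f_grid: list[float],
    sims_per_f: int = 20,
    n_sims_profile: int = 200,
    seed: int = 0,
) -> CurveResult:
    """Overlap fraction of simulations at each IF vs the analytic prediction.

    The analytic curve is the mean of p_k(0) / (1 - (1 - p_k(0)) f) over the
    scene's clusters, with p_k(0) estimated once from ``n_sims_profile``
    randomizations; the simulated points are the mean overlap fraction of
    ``sims_per_f`` scenes regenerated at each f.
    """
    profile = estimate_profile(scene, n_sims_profile, rng=substream(seed, "curve-profile"))
    rows = []
    for f in f_grid:
        fractions = np.empty(sims_per_f)
        for i in range(sims_per_f):
            sim = randomize_scene(
                scene, PlacementConfig(f=f), substream(seed, "curve-sim", f, i)
            )
            fractions[i] = measure_overlap(sim).fraction_ref_overlapping
        analytic = forward_overlap(profile, f)
        rows.append({"f": f, "sim_mean": fractions.mean(),
                     "sim_sd": fractions.std(ddof=1),
                     "sim_se": fractions.std(ddof=1) / np.sqrt(sims_per_f),
                     "analytic": analytic})
    table = pd.DataFrame(rows)
    return CurveResult(table, float((table.sim_mean - table.analytic).abs().max()))


def plot_heatmap(matrix: pd.DataFrame, path, title: str = "", cmap: str = "viridis") -> None:
    """Write a heat-map PNG for a pivoted result table (side-effect free
    otherwise; matplotlib is imported lazily)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.0 + 0.6 * matrix.shape[1], 1.0 + 0.6 * matrix.shape[0]))
    im = ax.imshow(matrix.to_numpy(), cmap=cmap, aspect="auto")
    ax.set_xticks(range(matrix.shape[1]), [str(c) for c in matrix.columns])
    ax.set_yticks(range(matrix.shape[0]), [str(i) for i in matrix.index])
    ax.set_xlabel(str(matrix.columns.name or ""))
    ax.set_ylabel(str(matrix.index.name or ""))
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
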