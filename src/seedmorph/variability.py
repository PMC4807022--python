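"""Sampling procedures: per-individual sample-size stabilization and the
rarefaction dispersion statistic for intraspecific variability.

Stabilization asks how many seeds must be measured before the running mean
of a size parameter stops fluctuating: for each subset size k an
independent random k-subset is drawn and its mean recorded; the stable
size is the smallest k from which every mean stays inside a relative
tolerance band around the full-sample mean.

Rarefaction dispersion quantifies intraspecific variability comparably
across species with unequal sampling: in a PCA space fitted once on all
seeds, each species' dispersion is the mean variance-weighted squared
distance of a fixed-size random seed subset from the species centroid,
averaged over replicates.  Note the distances are *sums of squares*
(weighted by each component's explained-variance fraction, no square
root), so the units are quadratic in score units.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .stats_suite import pca, tukey_hsd_letters

__all__ = ["StabilizationResult", "DispersionResult", "stabilization_analysis", "rarefaction_dispersion"]

SIZE_PARAMETERS = ("length", "width", "thickness", "surface")


def stable_subset_size(means, full_mean: float, epsilon: float) -> int:
    """The band rule: smallest k such that the means of all subset sizes
    >= k lie within ``+/- epsilon * full_mean`` of the full mean.  Falls
    back to the largest size when even that one is outside the band."""
    means = np.asarray(means, dtype=float)
    inside = np.abs(means - full_mean) <= epsilon * abs(full_mean)
    n_stable = len(means)
    for k in range(len(means), 0, -1):
        if inside[k - 1]:
            n_stable = k
        else:
            break
    return n_stable


@dataclass
class StabilizationResult:
    sample_id: str
    parameter: str
    cumulative_means: np.ndarray  # mean of a random k-subset, k = 1..n_max
    n_stable: int
    epsilon: float
    full_mean: float
    n_max: int
    truncated: bool = False  # n_max lowered to the available seed count


def stabilization_analysis(
    dataset,
    sample_id: str,
    parameter: str,
    n_max: int = 30,
    epsilon: float = 0.025,
    seed: int | np.random.Generator = 0,
) -> StabilizationResult:
    """Sample-size stabilization for one accession and one size parameter.

    Draws an independent random k-subset for each k = 1..n_max (subsets are
    not nested) and reports the smallest k such that the means of all
    subsets of size >= k lie within ``+/- epsilon * full-sample mean`` of
    the full-sample mean.  Deterministic under a fixed seed.
    """
    if parameter not in SIZE_PARAMETERS:
        raise ValueError(f"parameter must be one of {SIZE_PARAMETERS}")
    m = dataset.measures
    values = m.loc[m["sample_id"] == sample_id, parameter].dropna().to_numpy()
    if len(values) == 0:
        raise KeyError(f"unknown or empty sample_id {sample_id!r}")
    truncated = len(values) < n_max
    n_max_eff = min(n_max, len(values))
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    means = np.array(
        [rng.choice(values, size=k, replace=False).mean() for k in range(1, n_max_eff + 1)]
    )
    # when n_max_eff == sample size the last subset is the whole sample,
    # so means[-1] equals the full mean exactly
    full = values.mean()
    n_stable = stable_subset_size(means, full, epsilon)
    return StabilizationResult(
        sample_id=sample_id,
        parameter=parameter,
        cumulative_means=means,
        n_stable=n_stable,
        epsilon=epsilon,
        full_mean=float(full),
        n_max=n_max_eff,
        truncated=truncated,
    )


@dataclass
class DispersionResult:
    species: str
    mean_dispersion: float
    sd_dispersion: float
    n_seeds: int
    n_draw: int
    n_replicates: int
    space: str
    tukey_group: str = ""
    small_sample: bool = False  # fewer seeds than n_draw, exhaustive draw used


def rarefaction_dispersion(
    dataset,
    space: str,
    n_draw: int = 20,
    n_replicates: int = 100,
    seed: int | np.random.Generator = 0,
    allow_small: bool = False,
    fixed_centroid: bool = True,
    standardize: bool = True,
    alpha: float = 0.05,
) -> list[DispersionResult]:
    """Rarefied intraspecific dispersion per species.

    ``space`` is "size" (the four size parameters) or "shape" (the 64
    retained coefficients).  A single PCA is fitted on all seeds of all
    species; each species' centroid is the mean score vector of all its
    seeds (``fixed_centroid=False`` recomputes it per draw).  The per-seed
    distance is the explained-variance-weighted sum of squared score
    deviations over all components.  Species represented by a single sample
    are excluded; species with fewer than ``n_draw`` seeds raise unless
    ``allow_small`` (then all seeds are used, flagged).  Tukey letters over
    the replicate values are attached.
    """
    if space == "size":
        X = dataset.size_matrix()
    elif space == "shape":
        X = dataset.shape_matrix()
    else:
        raise ValueError("space must be 'size' or 'shape'")
    labels = dataset.labels_for(X.index, "species").to_numpy()
    samples = dataset.labels_for(X.index, "sample_id")
    space_pca = pca(X, standardize=standardize)
    scores = space_pca.scores
    w = space_pca.explained_fraction
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    results: list[DispersionResult] = []
    replicate_values: dict[str, np.ndarray] = {}
    for sp in sorted(pd.unique(labels)):
        sel = labels == sp
        if samples[sel].nunique() < 2:
            continue  # single-sample species: intraspecific variability undefined
        S = scores[sel]
        n_sp = S.shape[0]
        small = n_sp < n_draw
        if small and not allow_small:
            raise ValueError(
                f"species {sp!r} has {n_sp} seeds < n_draw={n_draw}; pass allow_small=True"
            )
        k = min(n_draw, n_sp)
        centroid = S.mean(axis=0)
        reps = np.empty(n_replicates)
        for r in range(n_replicates):
            idx = rng.choice(n_sp, size=k, replace=False)
            sub = S[idx]
            c = centroid if fixed_centroid else sub.mean(axis=0)
            d = ((sub - c) ** 2 * w).sum(axis=1)
            reps[r] = d.mean()
        replicate_values[sp] = reps
        results.append(
            DispersionResult(
                species=sp,
                mean_dispersion=float(reps.mean()),
                sd_dispersion=float(reps.std(ddof=1)),
                n_seeds=n_sp,
                n_draw=k,
                n_replicates=n_replicates,
                space=space,
                small_sample=small,
            )
        )
    if len(replicate_values) >= 2:
        vals = np.concatenate(list(replicate_values.values()))
        grp = np.concatenate([[sp] * len(v) for sp, v in replicate_values.items()])
        grouping = tukey_hsd_letters(vals, grp, alpha=alpha)
        for res in results:
            res.tukey_group = grouping.letters.get(res.species, "")
    return results
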