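"""Linear discriminant analysis of species and of the cultivated-vs-wild
domestication axis, with leave-one-out validation and projection of
supplementary (unknown-status) individuals.

The classifier is the classical Gaussian LDA with a pooled within-class
covariance: discriminant axes diagonalize the between-class scatter in the
within-class metric (reported with their proportion-of-trace variance
fractions), priors default to class frequencies, and posteriors follow the
usual linear discriminant scores.  Leave-one-out refits the model without
each seed, using exact downdates of the class sums for speed; a brute-force
refit loop gives the same allocations and is kept as the test oracle.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg as sla

from .stats_suite import nested_anova, nested_manova, pca, student_test, tukey_hsd_letters

__all__ = [
    "LDAModel",
    "LDAResult",
    "SupplementaryProjection",
    "lda_fit",
    "loocv_allocation",
    "project_supplementary",
    "domestication_pipeline",
]


@dataclass
class LDAModel:
    """Fitted pooled-covariance linear discriminant model."""

    classes: np.ndarray
    means: np.ndarray              # class x variable
    pooled_cov: np.ndarray
    priors: np.ndarray
    axes: np.ndarray               # variable x axis (within-cov normalized)
    axis_fractions: np.ndarray     # proportion of between-class trace per axis
    grand_mean: np.ndarray
    ridge: float = 0.0
    n_per_class: np.ndarray | None = None

    def scores(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, dtype=float) - self.grand_mean) @ self.axes

    def _discriminants(self, X: np.ndarray) -> np.ndarray:
        Winv_mu = np.linalg.solve(self.pooled_cov, self.means.T)  # p x K
        lin = X @ Winv_mu
        const = -0.5 * np.einsum("kp,pk->k", self.means, Winv_mu) + np.log(self.priors)
        return lin + const

    def posterior(self, X: np.ndarray) -> np.ndarray:
        d = self._discriminants(np.asarray(X, dtype=float))
        d -= d.max(axis=1, keepdims=True)
        e = np.exp(d)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.classes[np.argmax(self._discriminants(np.asarray(X, dtype=float)), axis=1)]


@dataclass
class LDAResult:
    model: LDAModel
    training_scores: np.ndarray
    labels: np.ndarray
    confusion: pd.DataFrame | None = None
    per_class_correct: pd.Series | None = None
    mean_correct_unweighted: float | None = None
    mean_correct_weighted: float | None = None
    perfect_separation: bool = False


@dataclass
class SupplementaryProjection:
    seed_id: str
    scores: np.ndarray
    posterior: dict
    predicted: str


def _fit_from_sums(classes, sums, sqsum, counts, n, p, prior_mode, ridge_scale=1e-8):
    means = sums / counts[:, None]
    # pooled within-class scatter: sum over classes of sum(xx^T) - n_c mu mu^T
    Sw = sqsum.copy()
    for k in range(len(classes)):
        Sw -= counts[k] * np.outer(means[k], means[k])
    W = Sw / (n - len(classes))
    ridge = 0.0
    try:
        sla.cholesky(W)
    except sla.LinAlgError:
        grand_tmp = (counts @ means) / n
        total = sqsum / n - np.outer(grand_tmp, grand_tmp)
        base = np.trace(W) / p
        if base <= 0:
            base = max(np.trace(total) / p, 1.0)
        ridge = ridge_scale * base
        W = W + ridge * np.eye(p)
        warnings.warn("singular pooled covariance; applying ridge regularization")
    priors = counts / n if prior_mode == "proportional" else np.full(len(classes), 1.0 / len(classes))
    grand = (counts @ means) / n
    B = np.zeros((p, p))
    for k in range(len(classes)):
        d = means[k] - grand
        B += counts[k] * np.outer(d, d)
    # sphere by W^{-1/2} and diagonalize the between scatter there
    evals_w, evecs_w = sla.eigh(W)
    evals_w = np.clip(evals_w, np.finfo(float).tiny, None)
    Wm12 = evecs_w @ np.diag(evals_w**-0.5) @ evecs_w.T
    M = Wm12 @ B @ Wm12
    lam, U = sla.eigh(M)
    order = np.argsort(lam)[::-1]
    r = min(len(classes) - 1, p)
    lam = np.clip(lam[order][:r], 0.0, None)
    axes = Wm12 @ U[:, order][:, :r]
    # deterministic sign: largest-|loading| entry positive
    flip = np.sign(axes[np.abs(axes).argmax(axis=0), np.arange(axes.shape[1])])
    flip[flip == 0] = 1.0
    axes *= flip
    fractions = lam / lam.sum() if lam.sum() > 0 else np.zeros_like(lam)
    return LDAModel(
        classes=np.asarray(classes), means=means, pooled_cov=W, priors=priors,
        axes=axes, axis_fractions=fractions, grand_mean=grand, ridge=ridge,
        n_per_class=counts.astype(int),
    )


def lda_fit(features, labels, priors: str = "proportional") -> LDAResult:
    """Fit the discriminant model.  ``priors`` is "proportional" (class
    frequencies, the default of the original analysis software) or
    "uniform"."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    if X.ndim != 2 or len(X) != len(y):
        raise ValueError("features must be 2-D and aligned with labels")
    classes, idx = np.unique(y, return_inverse=True)
    counts = np.bincount(idx).astype(float)
    if (counts < 2).any():
        small = classes[counts < 2]
        raise ValueError(f"every class needs >= 2 seeds; too small: {list(small)}")
    p = X.shape[1]
    sums = np.zeros((len(classes), p))
    np.add.at(sums, idx, X)
    sqsum = X.T @ X
    model = _fit_from_sums(classes, sums, sqsum, counts, len(y), p, priors)
    scores = model.scores(X)
    within_trace = np.trace(model.pooled_cov) - p * model.ridge
    return LDAResult(
        model=model, training_scores=scores, labels=y,
        perfect_separation=bool(within_trace < 1e-12 * (np.abs(X).max() ** 2 + 1)),
    )


def loocv_allocation(features, labels, priors: str = "proportional"):
    """Leave-one-out allocation: each seed classified by a model fitted
    without it.  Returns ``(per_class_correct_%, confusion, mean_unweighted,
    mean_weighted, predictions)``; the "Mean" convention of the species
    table is the unweighted average over classes."""
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels)
    classes, idx = np.unique(y, return_inverse=True)
    counts_all = np.bincount(idx).astype(float)
    if (counts_all < 2).any():
        raise ValueError("every class needs >= 2 seeds for leave-one-out")
    n, p = X.shape
    sums_all = np.zeros((len(classes), p))
    np.add.at(sums_all, idx, X)
    sqsum_all = X.T @ X
    preds = np.empty(n, dtype=object)
    for i in range(n):
        k = idx[i]
        if counts_all[k] - 1 < 1:
            preds[i] = None  # fold would empty the class; skipped
            continue
        sums = sums_all.copy()
        sums[k] -= X[i]
        counts = counts_all.copy()
        counts[k] -= 1
        sqsum = sqsum_all - np.outer(X[i], X[i])
        model = _fit_from_sums(classes, sums, sqsum, counts, n - 1, p, priors)
        preds[i] = model.predict(X[i : i + 1])[0]
    confusion = pd.crosstab(
        pd.Series(y, name="true"), pd.Series(preds, name="predicted"), dropna=False
    ).reindex(index=classes, columns=classes, fill_value=0)
    correct = pd.Series(np.diag(confusion), index=classes) / confusion.sum(axis=1) * 100.0
    mean_unweighted = float(correct.mean())
    mean_weighted = float((preds == y).mean() * 100.0)
    return correct, confusion, mean_unweighted, mean_weighted, preds


def project_supplementary(model_or_result, features_sup, seed_ids=None) -> list[SupplementaryProjection]:
    """Project seeds that did not participate in the model onto its
    discriminant axes and return scores, Gaussian posteriors and the
    predicted class for each."""
    model = model_or_result.model if isinstance(model_or_result, LDAResult) else model_or_result
    X = np.asarray(features_sup, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"supplementary features must have {model.means.shape[1]} columns, got {X.shape}"
        )
    if seed_ids is None:
        seed_ids = [str(i) for i in range(len(X))]
    scores = model.scores(X)
    post = model.posterior(X)
    pred = model.predict(X)
    return [
        SupplementaryProjection(
            seed_id=str(sid),
            scores=scores[i],
            posterior=dict(zip(model.classes, post[i])),
            predicted=str(pred[i]),
        )
        for i, sid in enumerate(seed_ids)
    ]


def _features(dataset, which: str):
    """Aligned (feature matrix, seed index) for size, shape or both."""
    shape = dataset.shape_matrix()
    size = dataset.size_matrix()
    if which == "size":
        return size.to_numpy(), size.index
    if which == "shape":
        return shape.to_numpy(), shape.index
    if which == "both":
        ids = shape.index.intersection(size.index)
        ids = [s for s in shape.index if s in set(ids)]
        both = np.hstack([size.loc[ids].to_numpy(), shape.loc[ids].to_numpy()])
        return both, pd.Index(ids)
    raise ValueError("features must be 'size', 'shape' or 'both'")


def species_discrimination(dataset, which: str = "both", priors: str = "proportional"):
    """One species-level LDA with leave-one-out validation."""
    X, ids = _features(dataset, which)
    y = dataset.labels_for(ids, "species").to_numpy()
    result = lda_fit(X, y, priors=priors)
    correct, confusion, mean_u, mean_w, preds = loocv_allocation(X, y, priors=priors)
    result.per_class_correct = correct
    result.confusion = confusion
    result.mean_correct_unweighted = mean_u
    result.mean_correct_weighted = mean_w
    return result


def domestication_pipeline(
    dataset,
    priors: str = "proportional",
    pca_standardize: bool = True,
    seed: int = 0,
) -> dict:
    """The cultivated-versus-wild analysis.

    Orchestrates (1) four-group size comparisons (nested ANOVA + Tukey
    letters per parameter), (2) seedling-vs-cultivar pooled t-tests,
    (3) a nested MANOVA on the first five shape PCs with status as the
    explanatory variable, (4) the two-group LDA (cultivated vs wild
    reference) with leave-one-out validation, and (5) projection of feral
    and unknown-status seeds as supplementary individuals.  Returns one
    structured report dict.
    """
    m = dataset.measures
    statuses = set(m["status"].unique())
    if "cultivated" not in statuses or "wild_reference" not in statuses:
        raise ValueError(
            "domestication analysis needs both cultivated and wild_reference seeds"
        )
    report: dict = {}

    # (1) size by status group
    size = dataset.size_matrix()
    meta = dataset.labels_for(size.index, "status")
    acc = dataset.labels_for(size.index, "sample_id")
    size_tables = {}
    for param in size.columns:
        anova = nested_anova(size[param].to_numpy(), meta.to_numpy(), acc.to_numpy())
        tukey = tukey_hsd_letters(size[param].to_numpy(), meta.to_numpy())
        size_tables[param] = {
            "anova": anova,
            "tukey_letters": tukey.letters,
            "group_means": tukey.means.to_dict(),
            "p_species_vs_residual": float(anova.loc[anova["term"] == "species", "p_residual"].iloc[0]),
        }
    report["size_by_status"] = size_tables

    # (2) seedlings vs cultivars (within cultivated)
    if "role" in m.columns and (m["role"] == "seedling").any():
        t_tests = {}
        for param in size.columns:
            roles = dataset.labels_for(size.index, "role")
            a = size.loc[roles == "seedling", param]
            b = size.loc[roles == "cultivar", param]
            t, p = student_test(a, b)
            t_tests[param] = {"t": t, "p": p}
        report["seedling_vs_cultivar"] = t_tests

    # (3) shape MANOVA on first five PCs, status as factor
    shape = dataset.shape_matrix()
    shape_pca = pca(shape, standardize=pca_standardize)
    st = dataset.labels_for(shape.index, "status").to_numpy()
    sa = dataset.labels_for(shape.index, "sample_id").to_numpy()
    report["shape_pca_first5_explained"] = float(shape_pca.explained_fraction[:5].sum())
    report["shape_manova"] = nested_manova(shape_pca.scores[:, :5], st, sa)

    # (4) two-group LDA on size + shape, excluding feral / unknown status
    X, ids = _features(dataset, "both")
    status = dataset.labels_for(ids, "status")
    train = status.isin(["cultivated", "wild_reference"]).to_numpy()
    y = np.where(status[train] == "cultivated", "cultivated", "wild")
    result = lda_fit(X[train], y, priors=priors)
    correct, confusion, mean_u, mean_w, _ = loocv_allocation(X[train], y, priors=priors)
    report["two_group"] = {
        "per_class_correct": correct.to_dict(),
        "confusion": confusion,
        "mean_correct_unweighted": mean_u,
        "mean_correct_weighted": mean_w,
        "axis_fraction": result.model.axis_fractions.tolist(),
    }

    # (5) supplementary projection of feral and unknown-status seeds
    projections = {}
    for grp in ("feral", "uncultivated_unknown"):
        sel = (status == grp).to_numpy()
        if sel.any():
            projections[grp] = project_supplementary(result, X[sel], ids[sel])
    report["projections"] = projections
    for grp, projs in projections.items():
        n_c = sum(pr.predicted == "cultivated" for pr in projs)
        report[f"{grp}_assigned_cultivated"] = n_c
        report[f"{grp}_assigned_wild"] = len(projs) - n_c
        report[f"{grp}_n"] = len(projs)
    report["model"] = result
    return report
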