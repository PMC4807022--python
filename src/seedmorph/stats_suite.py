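"""The inferential toolbox the pipeline calls.

Pearson correlations, Shapiro-Wilk / Bartlett assumption checks, nested
ANOVA (accession within species), Tukey post-hoc grouping with a compact
letter display, a nested MANOVA (Pillai trace), pooled two-sample t-tests
and PCA.  Only the designs the seed pipeline needs are implemented; nested
sums of squares are computed directly from group means (sequential,
species-first decomposition), which for a purely nested design coincides
with the usual sequential ANOVA table.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "PCASpace",
    "TukeyGrouping",
    "pca",
    "pearson_correlations",
    "assumption_checks",
    "nested_anova",
    "tukey_hsd_letters",
    "nested_manova",
    "student_test",
]


# ---------------------------------------------------------------------------
# PCA

@dataclass
class PCASpace:
    """Centered (optionally standardized) principal component space."""

    loadings: np.ndarray          # variables x components, orthonormal columns
    explained_fraction: np.ndarray
    scores: np.ndarray            # observations x components
    center: np.ndarray
    scale: np.ndarray
    columns: list | None = None

    def transform(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, dtype=float) - self.center) / self.scale
        return Z @ self.loadings


def pca(matrix, standardize: bool = True) -> PCASpace:
    """PCA by SVD of the centered (and by default unit-variance scaled)
    data.  Sign convention: the largest-magnitude entry of each loading
    vector is positive."""
    columns = list(matrix.columns) if isinstance(matrix, pd.DataFrame) else None
    X = np.asarray(matrix, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("pca needs a 2-D matrix with >= 2 rows and columns")
    if np.isnan(X).any():
        raise ValueError("pca input contains missing cells")
    center = X.mean(axis=0)
    if standardize:
        scale = X.std(axis=0, ddof=1)
        if np.any(scale == 0):
            bad = int(np.flatnonzero(scale == 0)[0])
            name = columns[bad] if columns else bad
            raise ValueError(f"constant column {name!r} cannot be standardized")
    else:
        scale = np.ones(X.shape[1])
    Z = (X - center) / scale
    _, s, vt = np.linalg.svd(Z, full_matrices=False)
    loadings = vt.T
    # deterministic sign: largest |entry| of each loading positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings *= flip
    lam = s**2
    return PCASpace(
        loadings=loadings,
        explained_fraction=lam / lam.sum(),
        scores=Z @ loadings,
        center=center,
        scale=scale,
        columns=columns,
    )


# ---------------------------------------------------------------------------
# Correlations and simple tests

def pearson_correlations(data, variables=None, subset_filter=None):
    """Pairwise Pearson r and two-sided p-values.

    ``data`` is a DataFrame (or a Dataset, whose size matrix is used);
    ``subset_filter`` is an optional boolean mask or callable applied to the
    rows first.  Returns ``(r, p)`` DataFrames.
    """
    if hasattr(data, "size_matrix"):
        data = data.size_matrix()
    df = pd.DataFrame(data)
    if subset_filter is not None:
        df = df[subset_filter(df) if callable(subset_filter) else subset_filter]
    if variables is not None:
        df = df[list(variables)]
    df = df.dropna()
    if len(df) < 3:
        raise ValueError("need at least 3 complete records")
    cols = list(df.columns)
    r = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    p = pd.DataFrame(np.zeros((len(cols), len(cols))), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for b in cols[i + 1 :]:
            x, y = df[a].to_numpy(), df[b].to_numpy()
            if x.std() == 0 or y.std() == 0:
                raise ValueError(f"zero-variance variable in pair ({a}, {b})")
            res = sps.pearsonr(x, y)
            r.loc[a, b] = r.loc[b, a] = res.statistic
            p.loc[a, b] = p.loc[b, a] = res.pvalue
    return r, p


def assumption_checks(values, groups) -> pd.DataFrame:
    """Shapiro-Wilk normality per group plus a Bartlett homoscedasticity
    test across groups.  Returns a tidy frame of raw p-values; groups with
    constant values are flagged (NaN p)."""
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    rows = []
    samples = []
    for g in pd.unique(groups):
        x = values[groups == g]
        samples.append(x)
        if len(x) < 3 or np.ptp(x) == 0:
            rows.append({"test": "shapiro", "group": g, "statistic": np.nan, "p": np.nan})
        else:
            st = sps.shapiro(x)
            rows.append({"test": "shapiro", "group": g, "statistic": st.statistic, "p": st.pvalue})
    usable = [x for x in samples if len(x) >= 2 and np.ptp(x) > 0]
    if len(usable) >= 2:
        bt = sps.bartlett(*usable)
        rows.append({"test": "bartlett", "group": "all", "statistic": bt.statistic, "p": bt.pvalue})
    else:
        rows.append({"test": "bartlett", "group": "all", "statistic": np.nan, "p": np.nan})
    return pd.DataFrame(rows)


def student_test(values_a, values_b):
    """Two-sample pooled-variance t-test, two-sided.  Returns (t, p);
    (0.0, 1.0) with a flag if the pooled variance is zero."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("both samples need n >= 2")
    if np.ptp(np.concatenate([a, b])) == 0:
        return 0.0, 1.0
    res = sps.ttest_ind(a, b, equal_var=True)
    return float(res.statistic), float(res.pvalue)


# ---------------------------------------------------------------------------
# Nested ANOVA / MANOVA

def _check_nesting(species: np.ndarray, accession: np.ndarray) -> None:
    tab = pd.DataFrame({"s": species, "a": accession}).drop_duplicates()
    bad = tab.groupby("a")["s"].nunique()
    if (bad > 1).any():
        acc = bad.index[bad > 1][0]
        raise ValueError(f"accession {acc!r} appears under more than one species")


def nested_anova(response, species, accession) -> pd.DataFrame:
    """Nested ANOVA: species, accession-within-species, residual.

    Sequential sums of squares from group means (exact for the purely
    nested design).  The species effect is tested two ways: against the
    residual mean square (``F_residual``, the common software default) and
    against the accession mean square (``F_accession``, the hierarchical
    test).  Returns a tidy table with one row per term.
    """
    y = np.asarray(response, dtype=float)
    species = np.asarray(species)
    accession = np.asarray(accession)
    _check_nesting(species, accession)
    if len(pd.unique(species)) < 2:
        raise ValueError("need at least two species")
    grand = y.mean()
    df = pd.DataFrame({"y": y, "s": species, "a": accession})
    sp = df.groupby("s")["y"].agg(["mean", "size"])
    acc = df.groupby(["s", "a"])["y"].agg(["mean", "size"])
    ss_species = float((sp["size"] * (sp["mean"] - grand) ** 2).sum())
    acc_sp_mean = acc.join(sp["mean"].rename("sp_mean"), on="s")
    ss_acc = float((acc["size"] * (acc_sp_mean["mean"] - acc_sp_mean["sp_mean"]) ** 2).sum())
    fitted = df.join(acc["mean"].rename("a_mean"), on=["s", "a"])["a_mean"].to_numpy()
    ss_res = float(((y - fitted) ** 2).sum())
    df_species = len(sp) - 1
    df_acc = len(acc) - len(sp)
    df_res = len(y) - len(acc)
    ms_species = ss_species / df_species
    ms_acc = ss_acc / df_acc if df_acc > 0 else np.nan
    ms_res = ss_res / df_res if df_res > 0 else np.nan

    def _f(ms_num, ms_den, d1, d2):
        if not (ms_den and ms_den > 0) or d2 <= 0:
            return np.nan, np.nan
        f = ms_num / ms_den
        return f, float(sps.f.sf(f, d1, d2))

    f_sp_res, p_sp_res = _f(ms_species, ms_res, df_species, df_res)
    f_sp_acc, p_sp_acc = _f(ms_species, ms_acc, df_species, df_acc)
    f_acc, p_acc = _f(ms_acc, ms_res, df_acc, df_res)
    return pd.DataFrame(
        [
            {
                "term": "species", "df": df_species, "ss": ss_species, "ms": ms_species,
                "F_residual": f_sp_res, "p_residual": p_sp_res,
                "F_accession": f_sp_acc, "p_accession": p_sp_acc,
            },
            {
                "term": "accession", "df": df_acc, "ss": ss_acc, "ms": ms_acc,
                "F_residual": f_acc, "p_residual": p_acc,
                "F_accession": np.nan, "p_accession": np.nan,
            },
            {
                "term": "residual", "df": df_res, "ss": ss_res, "ms": ms_res,
                "F_residual": np.nan, "p_residual": np.nan,
                "F_accession": np.nan, "p_accession": np.nan,
            },
        ]
    )


@dataclass
class TukeyGrouping:
    """Tukey post-hoc result with a compact letter display."""

    means: pd.Series                 # group -> mean, sorted descending
    p_adjusted: pd.DataFrame         # group x group adjusted p-values
    letters: dict                    # group -> letter string
    alpha: float
    excluded: list = field(default_factory=list)


def _compact_letters(groups_sorted, significant) -> dict:
    """Insert-and-absorb compact letter display.

    ``significant(a, b)`` says whether two groups differ; groups sharing a
    letter are not significantly different, and the display is minimal in
    the insert-absorb sense.
    """
    columns: list[set] = [set(groups_sorted)]
    for i, a in enumerate(groups_sorted):
        for b in groups_sorted[i + 1 :]:
            if not significant(a, b):
                continue
            for col in [c for c in columns if a in c and b in c]:
                columns.remove(col)
                columns.extend([col - {a}, col - {b}])
            # absorb: drop columns contained in another
            columns = [
                c for c in columns
                if c and not any(c < other for other in columns if other is not c)
            ]
    # deduplicate while preserving insertion structure, then order columns by
    # the best (highest-mean) group they contain for a stable display
    uniq = []
    for c in columns:
        if c not in uniq:
            uniq.append(c)
    order = {g: i for i, g in enumerate(groups_sorted)}
    uniq.sort(key=lambda c: min(order[g] for g in c))
    letters = {g: "" for g in groups_sorted}
    for i, col in enumerate(uniq):
        letter = chr(ord("a") + i) if i < 26 else f"z{i}"
        for g in col:
            letters[g] += letter
    return {g: "".join(sorted(v)) for g, v in letters.items()}


def tukey_hsd_letters(
    values,
    groups,
    alpha: float = 0.05,
    error_ms: float | None = None,
    error_df: float | None = None,
    method: str = "harmonic",
) -> TukeyGrouping:
    """Tukey HSD over group means with a compact letter display.

    Pairwise p-values use the studentized-range distribution.  With
    ``method="harmonic"`` (the convention of the original analysis for
    unbalanced designs) a common standard error based on the harmonic mean
    group size is used; ``method="tukey-kramer"`` uses per-pair sizes.  The
    error mean square defaults to the one-way within-group MS but can be
    supplied (e.g. the residual MS of a nested ANOVA).  Singleton groups are
    excluded with a warning entry.
    """
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    sizes = pd.Series(groups).value_counts()
    excluded = sorted(sizes.index[sizes < 2])
    keep = ~pd.Series(groups).isin(excluded).to_numpy()
    values, groups = values[keep], groups[keep]
    names = pd.unique(groups)
    if len(names) < 2:
        raise ValueError("need at least two groups with >= 2 values")
    means = pd.Series({g: values[groups == g].mean() for g in names}).sort_values(ascending=False)
    ns = {g: int((groups == g).sum()) for g in names}
    k = len(names)
    if error_ms is None:
        ss_within = sum(((values[groups == g] - means[g]) ** 2).sum() for g in names)
        error_df = len(values) - k
        error_ms = ss_within / error_df
    elif error_df is None:
        raise ValueError("error_df must accompany error_ms")
    n_harm = k / sum(1.0 / ns[g] for g in names)
    padj = pd.DataFrame(np.ones((k, k)), index=means.index, columns=means.index)
    for i, a in enumerate(means.index):
        for b in means.index[i + 1 :]:
            if method == "harmonic":
                se = np.sqrt(error_ms / n_harm)
            else:
                se = np.sqrt(error_ms / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            q = abs(means[a] - means[b]) / se
            pv = float(sps.studentized_range.sf(q, k, error_df))
            padj.loc[a, b] = padj.loc[b, a] = min(1.0, pv)
    letters = _compact_letters(
        list(means.index), lambda a, b: padj.loc[a, b] < alpha
    )
    return TukeyGrouping(means=means, p_adjusted=padj, letters=letters, alpha=alpha, excluded=excluded)


def nested_manova(scores, species, accession=None) -> dict:
    """Nested MANOVA on a small score matrix (typically 5 PCs): Pillai
    trace for the species term with accession (optionally) nested.

    The hypothesis matrix comes from the species means (sequential,
    species first); the error matrix is the residual cross-product after
    removing accession means (or species means when no accession factor is
    given).  Returns Pillai's trace with its approximate F test; a
    rank-deficient error matrix is flagged and handled by pseudo-inverse.
    """
    Y = np.asarray(scores, dtype=float)
    if Y.ndim != 2:
        raise ValueError("scores must be 2-D")
    species = np.asarray(species)
    if len(pd.unique(species)) < 2:
        raise ValueError("need at least two species")
    if accession is None:
        accession = species
    accession = np.asarray(accession)
    _check_nesting(species, accession)
    n, p = Y.shape
    grand = Y.mean(axis=0)
    H = np.zeros((p, p))
    for g in pd.unique(species):
        m = Y[species == g].mean(axis=0) - grand
        H += (species == g).sum() * np.outer(m, m)
    resid = Y.copy()
    for a in pd.unique(accession):
        sel = accession == a
        resid[sel] -= Y[sel].mean(axis=0)
    E = resid.T @ resid
    df_h = len(pd.unique(species)) - 1
    df_e = n - len(pd.unique(accession))
    rank_deficient = np.linalg.matrix_rank(E) < p
    HE = (np.linalg.pinv if rank_deficient else np.linalg.inv)(E + H) @ H
    pillai = float(np.trace(HE))
    s = min(p, df_h)
    m = (abs(df_h - p) - 1) / 2.0
    nn = (df_e - p - 1) / 2.0
    df1 = s * (2 * m + s + 1)
    df2 = s * (2 * nn + s + 1)
    F = (df2 / df1) * pillai / (s - pillai) if s > pillai else np.inf
    pval = float(sps.f.sf(F, df1, df2)) if np.isfinite(F) else 0.0
    return {
        "pillai": pillai, "F": float(F), "df1": float(df1), "df2": float(df2),
        "p": pval, "df_hypothesis": df_h, "df_error": df_e,
        "rank_deficient": bool(rank_deficient),
    }
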