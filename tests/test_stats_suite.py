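"""Inferential toolbox against independent oracles (direct formulas,
statsmodels, sklearn) and under null/alternative simulations."""
import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from seedmorph.stats_suite import (
    assumption_checks,
    nested_anova,
    nested_manova,
    pca,
    pearson_correlations,
    student_test,
    tukey_hsd_letters,
)


# ---------------------------------------------------------------------------
# correlations

def test_pearson_matches_direct_formula(rng):
    df = pd.DataFrame(rng.normal(size=(50, 4)), columns=list("abcd"))
    r, p = pearson_correlations(df)
    for i, a in enumerate("abcd"):
        for b in "abcd"[i + 1:]:
            x, y = df[a].to_numpy(), df[b].to_numpy()
            want = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
                np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
            )
            assert r.loc[a, b] == pytest.approx(want, abs=1e-12)
            assert 0 <= p.loc[a, b] <= 1


def test_pearson_perfect_and_errors(rng):
    x = rng.normal(size=20)
    df = pd.DataFrame({"x": x, "y": 2 * x})
    r, _ = pearson_correlations(df)
    assert r.loc["x", "y"] == pytest.approx(1.0, abs=1e-12)
    with pytest.raises(ValueError):
        pearson_correlations(pd.DataFrame({"x": x, "c": np.ones(20)}))
    with pytest.raises(ValueError):
        pearson_correlations(df.iloc[:2])


# ---------------------------------------------------------------------------
# PCA

def test_pca_collinear_single_component(rng):
    x = rng.normal(size=60)
    space = pca(np.column_stack([x, 3 * x]), standardize=False)
    assert space.explained_fraction[0] == pytest.approx(1.0, abs=1e-12)


def test_pca_matches_eigensolver_oracle(rng):
    X = rng.normal(size=(80, 6)) @ rng.normal(size=(6, 6))
    space = pca(X, standardize=True)
    Z = (X - X.mean(0)) / X.std(0, ddof=1)
    lam = np.sort(np.linalg.eigvalsh(Z.T @ Z))[::-1]
    assert np.allclose(space.explained_fraction, lam / lam.sum(), atol=1e-10)
    # orthonormal loadings, scores consistent
    assert np.allclose(space.loadings.T @ space.loadings, np.eye(6), atol=1e-10)
    assert np.allclose(space.scores, Z @ space.loadings, atol=1e-10)


def test_pca_reconstruction_with_all_components(rng):
    X = rng.normal(size=(40, 5))
    space = pca(X, standardize=True)
    back = space.scores @ space.loadings.T * space.scale + space.center
    assert np.abs(back - X).max() < 1e-8


def test_pca_matches_sklearn(rng):
    from sklearn.decomposition import PCA as SkPCA

    X = rng.normal(size=(50, 4))
    space = pca(X, standardize=False)
    sk = SkPCA().fit(X)
    assert np.allclose(space.explained_fraction, sk.explained_variance_ratio_, atol=1e-10)


def test_pca_errors(rng):
    with pytest.raises(ValueError, match="const"):
        pca(pd.DataFrame({"a": rng.normal(size=10), "const": np.ones(10)}))
    with pytest.raises(ValueError):
        pca(np.full((5, 3), np.nan))


# ---------------------------------------------------------------------------
# nested ANOVA

def _nested_data(rng, k_species=3, k_acc=2, n=10, sp_effect=1.0, acc_effect=0.5):
    rows = []
    for s in range(k_species):
        for a in range(k_acc):
            mu = sp_effect * s + acc_effect * rng.normal()
            for _ in range(n):
                rows.append((f"s{s}", f"a{a}", f"s{s}a{a}", mu + rng.normal()))
    df = pd.DataFrame(rows, columns=["species", "accw", "acc", "y"])
    return df


def test_nested_anova_matches_statsmodels(rng):
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = _nested_data(rng)
    tab = nested_anova(df["y"], df["species"], df["acc"])
    # proper nested coding: accession-within-species as an interaction term
    fit = smf.ols("y ~ C(species) + C(species):C(accw)", data=df).fit()
    want = sm.stats.anova_lm(fit, typ=1)
    assert tab.loc[0, "ss"] == pytest.approx(want.loc["C(species)", "sum_sq"], rel=1e-10)
    assert tab.loc[1, "ss"] == pytest.approx(want.loc["C(species):C(accw)", "sum_sq"], rel=1e-10)
    assert tab.loc[2, "ss"] == pytest.approx(want.loc["Residual", "sum_sq"], rel=1e-10)
    assert tab.loc[0, "F_residual"] == pytest.approx(want.loc["C(species)", "F"], rel=1e-10)
    assert tab.loc[0, "p_residual"] == pytest.approx(want.loc["C(species)", "PR(>F)"], abs=1e-12)


def test_nested_anova_additivity_and_hierarchical_f(rng):
    df = _nested_data(rng, k_species=4, k_acc=3, n=8)
    tab = nested_anova(df["y"], df["species"], df["acc"])
    total = ((df["y"] - df["y"].mean()) ** 2).sum()
    assert tab["ss"].sum() == pytest.approx(total, rel=1e-8)
    # hierarchical F = MS_species / MS_accession
    assert tab.loc[0, "F_accession"] == pytest.approx(
        tab.loc[0, "ms"] / tab.loc[1, "ms"], rel=1e-12
    )


def test_nested_anova_degenerate_and_errors():
    species = ["a"] * 4 + ["b"] * 4
    acc = ["a1", "a1", "a2", "a2", "b1", "b1", "b2", "b2"]
    tab = nested_anova(np.ones(8), species, acc)
    assert tab["ss"].sum() == pytest.approx(0.0, abs=1e-12)
    assert np.isnan(tab.loc[0, "F_residual"])
    with pytest.raises(ValueError, match="more than one species"):
        nested_anova(np.arange(8.0), species, ["x1"] * 4 + ["x1"] * 4)


# ---------------------------------------------------------------------------
# Tukey + compact letters

def test_tukey_fully_separated_and_identical(rng):
    g = np.repeat(["a", "b", "c"], 20)
    y = np.concatenate([rng.normal(0, 0.1, 20), rng.normal(10, 0.1, 20), rng.normal(20, 0.1, 20)])
    res = tukey_hsd_letters(y, g)
    assert len({res.letters[k] for k in "abc"}) == 3
    y2 = np.concatenate([rng.normal(0, 1, 20), rng.normal(0, 1, 20)])
    res2 = tukey_hsd_letters(y2, np.repeat(["u", "v"], 20))
    assert res2.letters["u"] == res2.letters["v"]


def test_tukey_pvalues_match_statsmodels(rng):
    from statsmodels.stats.multicomp import pairwise_tukeyhsd

    g = np.repeat(["a", "b", "c", "d"], 15)
    y = rng.normal(0, 1, 60) + np.repeat([0.0, 0.5, 1.0, 1.5], 15)
    res = tukey_hsd_letters(y, g, method="tukey-kramer")
    sm_res = pairwise_tukeyhsd(y, g)
    table = pd.DataFrame(sm_res.summary().data[1:], columns=sm_res.summary().data[0])
    for _, row in table.iterrows():
        assert res.p_adjusted.loc[row["group1"], row["group2"]] == pytest.approx(
            float(row["p-adj"]), abs=2e-3
        )


def test_tukey_letters_invariant_to_relabeling(rng):
    g = np.repeat(["a", "b", "c"], 12)
    y = rng.normal(0, 1, 36) + np.repeat([0, 3, 3.1], 12)
    res = tukey_hsd_letters(y, g)
    relabel = {"a": "z", "b": "y", "c": "x"}
    res2 = tukey_hsd_letters(y, np.array([relabel[v] for v in g]))
    for old, new in relabel.items():
        # same sharing structure under renaming
        partners_old = {o for o in "abc" if set(res.letters[o]) & set(res.letters[old])}
        partners_new = {o for o in "xyz" if set(res2.letters[o]) & set(res2.letters[new])}
        assert {relabel[o] for o in partners_old} == partners_new


def test_tukey_singleton_excluded(rng):
    g = np.array(["a"] * 10 + ["b"] * 10 + ["solo"])
    y = np.concatenate([rng.normal(0, 1, 10), rng.normal(5, 1, 10), [99.0]])
    res = tukey_hsd_letters(y, g)
    assert res.excluded == ["solo"]
    assert "solo" not in res.letters


# ---------------------------------------------------------------------------
# assumption checks and t-test

def test_bartlett_null_and_alternative():
    hits = 0
    for i in range(100):
        r = np.random.default_rng(1000 + i)
        out = assumption_checks(
            np.concatenate([r.normal(0, 1, 200), r.normal(0, 1, 200)]),
            np.repeat(["a", "b"], 200),
        )
        if out.loc[out["test"] == "bartlett", "p"].iloc[0] > 0.05:
            hits += 1
    assert hits >= 90
    r = np.random.default_rng(7)
    out = assumption_checks(
        np.concatenate([r.normal(0, 1, 200), r.normal(0, 5, 200)]),
        np.repeat(["a", "b"], 200),
    )
    assert out.loc[out["test"] == "bartlett", "p"].iloc[0] < 1e-3


def test_shapiro_power_against_uniform():
    hits = sum(
        assumption_checks(np.random.default_rng(i).uniform(size=500), np.repeat("g", 500))
        .loc[lambda d: d["test"] == "shapiro", "p"]
        .iloc[0]
        < 0.05
        for i in range(40)
    )
    assert hits >= int(0.95 * 40)


def test_student_test_oracle(rng):
    a, b = rng.normal(0, 1, 12), rng.normal(1, 1, 15)
    t, p = student_test(a, b)
    na, nb = len(a), len(b)
    sp2 = ((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2)
    t_want = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / na + 1 / nb))
    assert t == pytest.approx(t_want, abs=1e-12)
    assert p == pytest.approx(2 * sps.t.sf(abs(t_want), na + nb - 2), abs=1e-12)
    assert student_test(a, a) == (0.0, 1.0) or student_test(a, a)[1] == pytest.approx(1.0)
    t0, p0 = student_test(np.ones(5), np.ones(5))
    assert (t0, p0) == (0.0, 1.0)


# ---------------------------------------------------------------------------
# nested MANOVA

def test_manova_null_and_power_simulations():
    null_hits = power_hits = 0
    for i in range(100):
        r = np.random.default_rng(2000 + i)
        Y = r.normal(size=(200, 5))
        g = np.repeat(["a", "b"], 100)
        if nested_manova(Y, g)["p"] > 0.05:
            null_hits += 1
        Y2 = Y.copy()
        Y2[100:, 0] += 2.0  # 2 sd shift on one coordinate
        if nested_manova(Y2, g)["p"] < 0.01:
            power_hits += 1
    assert null_hits >= 90
    assert power_hits >= 95


def test_manova_matches_statsmodels_pillai(rng):
    from statsmodels.multivariate.manova import MANOVA

    Y = rng.normal(size=(60, 3))
    g = np.repeat(["a", "b", "c"], 20)
    Y[20:40] += [0.5, 0.0, -0.3]
    ours = nested_manova(Y, g)
    df = pd.DataFrame(Y, columns=["y1", "y2", "y3"])
    df["g"] = g
    mv = MANOVA.from_formula("y1 + y2 + y3 ~ g", data=df).mv_test()
    stat = mv.results["g"]["stat"]
    assert ours["pillai"] == pytest.approx(float(stat.loc["Pillai's trace", "Value"]), rel=1e-8)
    assert ours["p"] == pytest.approx(float(stat.loc["Pillai's trace", "Pr > F"]), rel=1e-6, abs=1e-12)


def test_manova_errors(rng):
    with pytest.raises(ValueError):
        nested_manova(rng.normal(size=(10, 3)), np.repeat("only", 10))
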