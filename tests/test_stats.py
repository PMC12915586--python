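"""Community statistics against closed forms, independent oracles, and the
established library implementations (scipy / scikit-bio) used purely as
cross-checks."""
import numpy as np
import pandas as pd
import pytest
import scipy.linalg
import scipy.spatial.distance
import scipy.stats
import skbio.stats.distance
import skbio.stats.ordination
from skbio.stats.distance import DistanceMatrix

import amplitrait as at
from amplitrait.stats import expand_formula

from _oracles import (
    oracle_kruskal_h,
    oracle_mantel_enumeration,
    oracle_oneway_permanova_f,
    oracle_spearman,
)


def _table(rows, ids=None):
    ids = ids or [f"s{i}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=ids, columns=[f"o{j}" for j in range(len(rows[0]))])


# ---------------------------------------------------------------------------
# rarefaction


def test_rarefy_keeps_exact_depth_and_drops_shallow():
    table = _table([[1000, 1000], [900, 600], [3000, 1000]])
    rare, dropped = at.rarefy(table, depth=2000, seed=0)
    assert dropped == ["s1"]
    assert (rare.sum(axis=1) == 2000).all()
    # a sample at exactly the target depth passes through unchanged
    assert (rare.loc["s0"] == [1000, 1000]).all()


def test_rarefy_expected_proportions():
    """Hypergeometric subsampling preserves proportions in expectation."""
    table = _table([[1000, 2000, 1000]])
    totals = np.zeros(3)
    n_seeds = 100
    for seed in range(n_seeds):
        rare, _ = at.rarefy(table, depth=2000, seed=seed)
        totals += rare.iloc[0].to_numpy()
    expected = np.array([500, 1000, 500]) * n_seeds
    chi2 = ((totals - expected) ** 2 / expected).sum()
    assert scipy.stats.chi2.sf(chi2, df=2) > 0.01


def test_rarefy_rejects_bad_depth():
    with pytest.raises(ValueError):
        at.rarefy(_table([[5, 5]]), depth=0)


# ---------------------------------------------------------------------------
# alpha diversity


@pytest.mark.parametrize(
    "counts,expected_h,expected_s",
    [
        ([7, 0, 0], 0.0, 1),
        ([5, 5, 5, 5], np.log(4), 4),
        ([2, 1, 1], 1.5 * np.log(2), 3),
    ],
)
def test_shannon_and_richness_closed_forms(counts, expected_h, expected_s):
    assert at.shannon(np.array(counts)) == pytest.approx(expected_h, abs=1e-12)
    assert at.richness(np.array(counts)) == expected_s


def test_shannon_rejects_zero_total():
    with pytest.raises(ValueError):
        at.shannon(np.array([0, 0]))


# ---------------------------------------------------------------------------
# Bray-Curtis


def test_bray_curtis_worked_cases():
    dm = at.bray_curtis(_table([[2, 0, 1], [0, 2, 1], [2, 0, 1], [0, 3, 0]]))
    assert dm["s0", "s1"] == pytest.approx(4 / 6, abs=1e-12)
    assert dm["s0", "s2"] == 0.0
    assert dm["s0", "s3"] == 1.0  # disjoint OTUs


def test_bray_curtis_matches_scipy_on_random_counts():
    rng = np.random.default_rng(0)
    table = _table(rng.integers(0, 50, size=(6, 12)))
    dm = at.bray_curtis(table)
    ref = scipy.spatial.distance.squareform(
        scipy.spatial.distance.pdist(table.to_numpy(), metric="braycurtis")
    )
    assert np.allclose(dm.data, ref, atol=1e-12)


# ---------------------------------------------------------------------------
# PCoA


def test_pcoa_two_samples():
    dm = DistanceMatrix([[0.0, 0.6], [0.6, 0.0]], ids=["a", "b"])
    res = at.pcoa(dm)
    assert np.allclose(np.abs(res.coordinates[:, 0]), 0.3, atol=1e-12)


def test_pcoa_recovers_planar_configuration():
    rng = np.random.default_rng(4)
    points = rng.normal(size=(10, 2))
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(points))
    res = at.pcoa(DistanceMatrix(d, ids=[str(i) for i in range(10)]), n_axes=2)
    a = points - points.mean(axis=0)
    b = res.coordinates
    rot, _ = scipy.linalg.orthogonal_procrustes(b, a)
    assert np.abs(b @ rot - a).max() < 1e-8


def test_pcoa_matches_skbio_eigenvalues(rarefied):
    dm = at.bray_curtis(rarefied.iloc[:25])
    ours = at.pcoa(dm)
    ref = skbio.stats.ordination.pcoa(skbio.stats.distance.DistanceMatrix(dm.data, dm.ids))
    assert np.allclose(ours.eigenvalues[:5], ref.eigvals.to_numpy()[:5], atol=1e-8)


# ---------------------------------------------------------------------------
# PERMANOVA


def _random_distance(rng, n):
    x = rng.normal(size=(n, 4))
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(x))
    return DistanceMatrix(d, ids=[f"s{i}" for i in range(n)])


def test_formula_expansion():
    assert expand_formula("a*b+c") == ["a", "b", "a:b", "c"]
    assert expand_formula("a + b") == ["a", "b"]


def test_permanova_r2_partition_sums_to_one(rarefied, metadata):
    dm = at.bray_curtis(rarefied)
    res = at.permanova(dm, metadata, "time_point*compartment+treatment", n_perm=9, seed=0)
    terms = res[~res["term"].isin(["Total"])]
    assert terms["R2"].sum() == pytest.approx(1.0, abs=1e-10)
    ss = res.set_index("term")["SS"]
    assert ss.drop("Total").sum() == pytest.approx(ss["Total"], rel=1e-10)
    pvals = res["p"].dropna()
    assert ((pvals >= 1 / 10) & (pvals <= 1)).all()


def test_permanova_single_factor_matches_definitional_f():
    """Pseudo-F for a two-level factor on 6 samples equals the definitional
    (SS_between/df) / (SS_within/df) computed directly from distances."""
    rng = np.random.default_rng(9)
    dm = _random_distance(rng, 6)
    meta = pd.DataFrame(
        {"group": ["x", "x", "x", "y", "y", "y"]}, index=[f"s{i}" for i in range(6)]
    )
    res = at.permanova(dm, meta, "group", n_perm=99, seed=1)
    f_oracle = oracle_oneway_permanova_f(dm.data.tolist(), list(meta["group"]))
    assert res.loc[res["term"] == "group", "F"].iloc[0] == pytest.approx(f_oracle, rel=1e-10)


def test_permanova_single_factor_matches_skbio():
    rng = np.random.default_rng(19)
    dm = _random_distance(rng, 12)
    labels = ["a"] * 6 + ["b"] * 6
    meta = pd.DataFrame({"group": labels}, index=list(dm.ids))
    ours = at.permanova(dm, meta, "group", n_perm=9, seed=0)
    ref = skbio.stats.distance.permanova(
        skbio.stats.distance.DistanceMatrix(dm.data, dm.ids),
        labels,
        permutations=9,
    )
    assert ours.loc[ours["term"] == "group", "F"].iloc[0] == pytest.approx(
        ref["test statistic"], rel=1e-10
    )


def test_permanova_strong_separation_minimal_p():
    # three well-separated groups of unequal size: only a permutation
    # reproducing all three groups exactly could tie the observed F
    rng = np.random.default_rng(2)
    x = np.vstack(
        [
            rng.normal(0, 0.01, size=(5, 3)),
            rng.normal(50, 0.01, size=(6, 3)),
            rng.normal(-50, 0.01, size=(9, 3)),
        ]
    )
    d = scipy.spatial.distance.squareform(scipy.spatial.distance.pdist(x))
    dm = DistanceMatrix(d, ids=[f"s{i}" for i in range(20)])
    meta = pd.DataFrame({"group": ["a"] * 5 + ["b"] * 6 + ["c"] * 9, }, index=list(dm.ids))
    res = at.permanova(dm, meta, "group", n_perm=99, seed=0)
    row = res[res["term"] == "group"].iloc[0]
    assert row["R2"] > 0.99
    assert row["p"] == pytest.approx(1 / 100)


def test_permanova_rejects_single_level_factor():
    rng = np.random.default_rng(3)
    dm = _random_distance(rng, 6)
    meta = pd.DataFrame({"group": ["x"] * 6}, index=list(dm.ids))
    with pytest.raises(ValueError, match="single level"):
        at.permanova(dm, meta, "group", n_perm=9)


# ---------------------------------------------------------------------------
# Mantel & temporal distance


def test_mantel_identity_r_one():
    rng = np.random.default_rng(5)
    dm = _random_distance(rng, 9)
    res = at.mantel(dm, dm, n_perm=99, seed=0)
    assert res.statistic == pytest.approx(1.0, abs=1e-12)


def test_mantel_exhaustive_matches_enumeration_oracle():
    rng = np.random.default_rng(6)
    d1 = _random_distance(rng, 5)
    d2 = _random_distance(rng, 5)
    res = at.mantel(d1, d2, n_perm=99, seed=0)
    assert res.exhaustive and res.n_permutations == 120
    r_oracle, p_oracle = oracle_mantel_enumeration(d1.data.tolist(), d2.data.tolist())
    assert res.statistic == pytest.approx(r_oracle, abs=1e-12)
    assert res.p_value == p_oracle


def test_mantel_statistic_matches_skbio():
    rng = np.random.default_rng(7)
    d1 = _random_distance(rng, 12)
    d2 = _random_distance(rng, 12)
    res = at.mantel(d1, d2, n_perm=9, seed=0)
    r_ref = skbio.stats.distance.mantel(
        skbio.stats.distance.DistanceMatrix(d1.data, d1.ids),
        skbio.stats.distance.DistanceMatrix(d2.data, d2.ids),
        permutations=0,
    )[0]
    assert res.statistic == pytest.approx(r_ref, abs=1e-12)


def test_mantel_rejects_mismatched_ids():
    rng = np.random.default_rng(8)
    d1 = _random_distance(rng, 5)
    d2 = DistanceMatrix(d1.data, ids=["x0", "x1", "x2", "x3", "x4"])
    with pytest.raises(ValueError, match="different samples"):
        at.mantel(d1, d2)


def test_temporal_distance_and_triangle_inequality():
    meta = pd.DataFrame({"time_point": [1, 1, 7, 4]}, index=["a", "b", "c", "d"])
    dm = at.temporal_distance(meta)
    assert dm["a", "b"] == 0.0
    assert dm["a", "c"] == 6.0
    d = dm.data
    n = d.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                assert d[i, j] <= d[i, k] + d[k, j] + 1e-12


# ---------------------------------------------------------------------------
# Spearman / Kruskal-Wallis / Bonferroni


def test_spearman_worked_cases():
    assert at.spearman_trend(np.arange(5), np.arange(5) ** 2).rho == pytest.approx(1.0, abs=1e-12)
    res = at.spearman_trend(np.arange(1, 6), np.array([2, 1, 4, 3, 5]))
    assert res.rho == pytest.approx(0.8, abs=1e-12)


def test_spearman_matches_oracle_and_scipy_on_ties():
    rng = np.random.default_rng(10)
    for _ in range(20):
        x = rng.integers(0, 5, size=12).astype(float)
        y = rng.integers(0, 5, size=12).astype(float)
        if np.all(x == x[0]) or np.all(y == y[0]):
            continue
        res = at.spearman_trend(x, y)
        assert res.rho == pytest.approx(oracle_spearman(x, y), abs=1e-12)
        ref = scipy.stats.spearmanr(x, y)
        assert res.rho == pytest.approx(ref.statistic, abs=1e-12)
        assert res.p_value == pytest.approx(ref.pvalue, abs=1e-9)


def test_spearman_exact_permutation_small_n():
    x = np.arange(1.0, 6.0)
    y = np.array([2.0, 1.0, 4.0, 3.0, 5.0])
    res = at.spearman_trend(x, y, exact=True)
    assert res.method == "exact"
    assert 0 < res.p_value <= 1


def test_spearman_rejects_constant_vector():
    with pytest.raises(ValueError, match="constant"):
        at.spearman_trend(np.arange(5.0), np.ones(5))


def test_kruskal_wallis_worked_case():
    h, p = at.kruskal_wallis(np.array([1.0, 2, 3]), np.array([4.0, 5, 6]))
    assert h == pytest.approx(12 / 42 * (36 / 3 + 225 / 3) - 21, abs=1e-12)
    assert h == pytest.approx(oracle_kruskal_h([[1, 2, 3], [4, 5, 6]]), abs=1e-12)


def test_kruskal_wallis_all_ties_is_zero():
    h, p = at.kruskal_wallis(np.ones(4), np.ones(3))
    assert h == 0.0 and p == 1.0


def test_kruskal_wallis_matches_scipy():
    rng = np.random.default_rng(12)
    a, b, c = rng.normal(size=8), rng.normal(1, 1, size=6), rng.integers(0, 3, size=7).astype(float)
    h, p = at.kruskal_wallis(a, b, c)
    ref = scipy.stats.kruskal(a, b, c)
    assert h == pytest.approx(ref.statistic, abs=1e-10)
    assert p == pytest.approx(ref.pvalue, abs=1e-10)


def test_bonferroni():
    adj = at.bonferroni([0.02, 0.5, 0.9])
    assert adj[0] == pytest.approx(0.06)
    assert adj[1] == 1.0 and adj[2] == 1.0
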