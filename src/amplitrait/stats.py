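"""Community-level statistics implemented from their definitions.

Covers the temporal-analysis toolkit for rarefied OTU tables: rarefaction
to uniform depth, Shannon diversity and richness, Bray-Curtis
dissimilarity, principal coordinates analysis, PERMANOVA with sequential
(Type I) sums of squares and permutation p-values, Mantel tests against
temporal distance, Spearman rank trend tests, and Kruskal-Wallis with
Bonferroni correction.

Distance matrices are carried as :class:`skbio.stats.distance.DistanceMatrix`
(which enforces symmetry and a zero diagonal); every statistic on them is
computed here from first principles.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.stats
from skbio.stats.distance import DistanceMatrix


# ---------------------------------------------------------------------------
# rarefaction and alpha diversity


def rarefy(
    table: pd.DataFrame,
    depth: int = 2000,
    seed: int | np.random.Generator | None = None,
    prune_empty: bool = True,
) -> tuple[pd.DataFrame, list[str]]:
    """Subsample every sample without replacement to exactly ``depth`` reads.

    Samples whose total falls below ``depth`` are dropped and returned in
    the second element. Subsampling is multivariate hypergeometric, so the
    expected retained count of OTU i is ``depth * n_i / total``. A sample
    totalling exactly ``depth`` is returned unchanged for any seed.
    """
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    rng = np.random.default_rng(seed)
    values = table.to_numpy(dtype=np.int64)
    totals = values.sum(axis=1)
    keep = totals >= depth
    dropped = [str(s) for s in table.index[~keep]]
    kept = values[keep]
    out = np.empty_like(kept)
    for row in range(kept.shape[0]):
        if totals[keep][row] == depth:
            out[row] = kept[row]
        else:
            out[row] = rng.multivariate_hypergeometric(kept[row], depth)
    result = pd.DataFrame(out, index=table.index[keep], columns=table.columns)
    if prune_empty:
        result = result.loc[:, result.sum(axis=0) > 0]
    return result, dropped


def shannon(counts: np.ndarray) -> float:
    """Shannon entropy H = -sum p_i ln p_i over OTUs with positive counts."""
    counts = np.asarray(counts, dtype=float)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    total = counts.sum()
    if total <= 0:
        raise ValueError("sample has zero total reads")
    p = counts[counts > 0] / total
    return float(-(p * np.log(p)).sum())


def richness(counts: np.ndarray) -> int:
    """Number of OTUs with at least one read."""
    counts = np.asarray(counts)
    if np.any(counts < 0):
        raise ValueError("negative counts")
    return int((counts > 0).sum())


# ---------------------------------------------------------------------------
# beta diversity


def bray_curtis(table: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity d(a,b) = sum|a_i-b_i| / sum(a_i+b_i)."""
    values = table.to_numpy(dtype=float)
    if values.shape[0] < 2:
        raise ValueError("need at least two samples")
    totals = values.sum(axis=1)
    if np.any(totals == 0):
        raise ValueError("sample with zero total reads")
    n = values.shape[0]
    d = np.zeros((n, n))
    for i in range(n - 1):
        diff = np.abs(values[i] - values[i + 1 :]).sum(axis=1)
        denom = totals[i] + totals[i + 1 :]
        d[i, i + 1 :] = diff / denom
        d[i + 1 :, i] = d[i, i + 1 :]
    return DistanceMatrix(d, ids=[str(s) for s in table.index])


@dataclass
class PCoAResult:
    sample_ids: list[str]
    coordinates: np.ndarray  # samples x axes, scaled by sqrt(eigenvalue)
    eigenvalues: np.ndarray  # all eigenvalues, descending (negatives retained)
    proportion_explained: np.ndarray  # per positive axis, rel. to sum of positives


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d**2
    row = a.mean(axis=0, keepdims=True)
    col = a.mean(axis=1, keepdims=True)
    return a - row - col + a.mean()


def pcoa(dm: DistanceMatrix, n_axes: int | None = None) -> PCoAResult:
    """Principal coordinates: eigendecomposition of the Gower-centred matrix.

    Negative eigenvalues (Bray-Curtis is non-Euclidean) are reported but
    excluded from the variance-explained denominator; no Cailliez/Lingoes
    correction is applied.
    """
    g = _gower_center(dm.data)
    eigvals, eigvecs = scipy.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals = eigvals[order]
    eigvecs = eigvecs[:, order]
    positive = eigvals > 1e-10 * max(abs(eigvals[0]), 1.0)
    n_pos = int(positive.sum())
    k = n_pos if n_axes is None else min(n_axes, n_pos)
    coords = eigvecs[:, :k] * np.sqrt(eigvals[:k])
    pos_sum = eigvals[:n_pos].sum()
    prop = eigvals[:k] / pos_sum if pos_sum > 0 else np.zeros(k)
    return PCoAResult(list(dm.ids), coords, eigvals, prop)


# ---------------------------------------------------------------------------
# PERMANOVA


def expand_formula(formula: str) -> list[str]:
    """Expand a formula like ``"a*b+c"`` into ordered terms
    ``["a", "b", "a:b", "c"]``; ``:`` denotes an interaction."""
    terms: list[str] = []
    for part in formula.replace(" ", "").split("+"):
        if not part:
            continue
        if "*" in part:
            factors = part.split("*")
            for r in range(1, len(factors) + 1):
                for combo in itertools.combinations(factors, r):
                    t = ":".join(combo)
                    if t not in terms:
                        terms.append(t)
        elif part not in terms:
            terms.append(part)
    return terms


def _term_dummies(metadata: pd.DataFrame, term: str) -> np.ndarray:
    factors = term.split(":")
    for f in factors:
        if f not in metadata.columns:
            raise ValueError(f"formula references unknown metadata column {f!r}")
        if metadata[f].nunique() < 2:
            raise ValueError(f"factor {f!r} has a single level")
    labels = metadata[factors[0]].astype(str)
    for f in factors[1:]:
        labels = labels + "\x1f" + metadata[f].astype(str)
    return pd.get_dummies(labels).to_numpy(dtype=float)


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Projection matrix onto the column space of x, and its rank."""
    u, sv, _ = np.linalg.svd(x, full_matrices=False)
    tol = sv.max() * max(x.shape) * np.finfo(float).eps if sv.size else 0.0
    rank = int((sv > tol).sum())
    u = u[:, :rank]
    return u @ u.T, rank


def permanova(
    dm: DistanceMatrix,
    metadata: pd.DataFrame,
    formula: str,
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    strata: str | None = None,
) -> pd.DataFrame:
    """PERMANOVA with sequential (Type I) sums of squares, adonis-style.

    Terms are fitted in formula order through projection (hat) matrices of
    the cumulative dummy-coded model; pseudo-F per term uses the residual
    mean square of the full model; p-values permute sample rows (within
    ``strata`` groups when given), with p = (1 + exceedances) / (1 + n_perm).
    Returns a tidy frame with term, df, SS, F, R2 and p rows plus Residual
    and Total.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    ids = list(dm.ids)
    meta = metadata.loc[ids]
    n = len(ids)
    terms = expand_formula(formula)
    if not terms:
        raise ValueError("empty formula")

    g = _gower_center(dm.data)
    x = np.ones((n, 1))
    hats: list[np.ndarray] = []
    dfs: list[int] = []
    prev_hat, prev_rank = _hat(x)
    for term in terms:
        x = np.hstack([x, _term_dummies(meta, term)])
        hat, rank = _hat(x)
        hats.append(hat - prev_hat)
        dfs.append(rank - prev_rank)
        prev_hat, prev_rank = hat, rank
    resid_proj = np.eye(n) - prev_hat
    df_resid = n - prev_rank
    if df_resid <= 0:
        raise ValueError("model leaves no residual degrees of freedom")
    if any(df == 0 for df in dfs):
        bad = terms[dfs.index(0)]
        raise ValueError(f"term {bad!r} adds no degrees of freedom (aliased)")

    def stats_for(gmat: np.ndarray) -> tuple[np.ndarray, float]:
        ss_terms = np.array([np.sum(h * gmat) for h in hats])
        ss_resid = float(np.sum(resid_proj * gmat))
        return ss_terms, ss_resid

    ss_terms, ss_resid = stats_for(g)
    ss_total = float(np.trace(g))
    f_obs = (ss_terms / np.array(dfs)) / (ss_resid / df_resid)

    rng = np.random.default_rng(seed)
    if strata is not None:
        groups = meta[strata].to_numpy()
        blocks = [np.flatnonzero(groups == gval) for gval in pd.unique(groups)]
    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = np.arange(n)
            for idx in blocks:
                perm[idx] = idx[rng.permutation(len(idx))]
        gp = g[np.ix_(perm, perm)]
        ss_p, ss_r = stats_for(gp)
        f_p = (ss_p / np.array(dfs)) / (ss_r / df_resid)
        exceed += f_p >= f_obs
    pvals = (1.0 + exceed) / (1.0 + n_perm)

    rows = []
    for term, df, ss, f, p in zip(terms, dfs, ss_terms, f_obs, pvals):
        rows.append({"term": term, "df": df, "SS": ss, "F": f, "R2": ss / ss_total, "p": p})
    rows.append(
        {
            "term": "Residual",
            "df": df_resid,
            "SS": ss_resid,
            "F": np.nan,
            "R2": ss_resid / ss_total,
            "p": np.nan,
        }
    )
    rows.append(
        {"term": "Total", "df": n - 1, "SS": ss_total, "F": np.nan, "R2": 1.0, "p": np.nan}
    )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Mantel


@dataclass
class MantelResult:
    statistic: float
    p_value: float
    n_permutations: int
    method: str
    exhaustive: bool
    n_samples: int


def _tri(d: np.ndarray) -> np.ndarray:
    i, j = np.tril_indices(d.shape[0], k=-1)
    return d[i, j]


def mantel(
    dm1: DistanceMatrix,
    dm2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
    max_exhaustive: int = 10_000,
) -> MantelResult:
    """Mantel correlation between two distance matrices.

    R is the chosen correlation over strictly-lower-triangle entries; the
    one-sided p-value (R_perm >= R_obs) permutes the rows and columns of the
    second matrix simultaneously. When the number of relabelings n! does not
    exceed ``max_exhaustive``, all of them are enumerated and the p-value is
    exact (#{R_perm >= R_obs} / n!, the identity included).
    """
    if set(dm1.ids) != set(dm2.ids):
        raise ValueError("distance matrices cover different samples")
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    order = [dm2.ids.index(i) for i in dm1.ids]
    a = dm1.data
    b = dm2.data[np.ix_(order, order)]
    n = a.shape[0]
    xa = _tri(a)
    if method == "spearman":
        xa = scipy.stats.rankdata(xa)
    if np.all(xa == xa[0]):
        raise ValueError("first matrix has constant off-diagonal entries")
    if np.all(_tri(b) == _tri(b)[0]):
        raise ValueError("second matrix has constant off-diagonal entries")

    def corr(bd: np.ndarray) -> float:
        xb = _tri(bd)
        if method == "spearman":
            xb = scipy.stats.rankdata(xb)
        elif method != "pearson":
            raise ValueError(f"unknown correlation method {method!r}")
        return float(np.corrcoef(xa, xb)[0, 1])

    r_obs = corr(b)
    if math.factorial(n) <= max_exhaustive:
        count = 0
        total = 0
        for perm in itertools.permutations(range(n)):
            idx = np.array(perm)
            if corr(b[np.ix_(idx, idx)]) >= r_obs:
                count += 1
            total += 1
        return MantelResult(r_obs, count / total, total, method, True, n)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        idx = rng.permutation(n)
        if corr(b[np.ix_(idx, idx)]) >= r_obs:
            exceed += 1
    return MantelResult(r_obs, (1 + exceed) / (1 + n_perm), n_perm, method, False, n)


def temporal_distance(metadata: pd.DataFrame, time_col: str = "time_point") -> DistanceMatrix:
    """Pairwise absolute time-point differences d(a,b) = |t_a - t_b|."""
    t = metadata[time_col]
    if t.isna().any():
        bad = metadata.index[t.isna()][0]
        raise ValueError(f"missing time value for sample {bad!r}")
    tv = t.to_numpy(dtype=float)
    d = np.abs(tv[:, None] - tv[None, :])
    return DistanceMatrix(d, ids=[str(i) for i in metadata.index])


# ---------------------------------------------------------------------------
# trend and group tests


@dataclass
class TrendResult:
    rho: float
    p_value: float
    n: int
    method: str = "t"


def spearman_trend(x: np.ndarray, y: np.ndarray, exact: bool = False) -> TrendResult:
    """Spearman rank correlation of y against x with a two-sided p-value.

    Ranks use averages for ties; rho is the Pearson correlation of the
    ranks. The default p comes from the t-distribution approximation with
    n-2 degrees of freedom; ``exact=True`` (n <= 9) enumerates all
    permutations of y's ranks instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be equal-length 1-D vectors")
    n = len(x)
    if n < 3:
        raise ValueError("need at least three observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("constant vector: correlation undefined")
    rx = scipy.stats.rankdata(x)
    ry = scipy.stats.rankdata(y)
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if exact:
        if n > 9:
            raise ValueError("exact permutation p limited to n <= 9")
        count = 0
        total = 0
        for perm in itertools.permutations(ry):
            r = np.corrcoef(rx, np.asarray(perm))[0, 1]
            if abs(r) >= abs(rho) - 1e-12:
                count += 1
            total += 1
        return TrendResult(rho, count / total, n, method="exact")
    if abs(rho) >= 1.0:
        return TrendResult(rho, 0.0, n)
    t = rho * math.sqrt((n - 2) / (1 - rho**2))
    p = 2.0 * scipy.stats.t.sf(abs(t), df=n - 2)
    return TrendResult(rho, float(p), n)


def kruskal_wallis(*groups: np.ndarray) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-square p (g-1 df).

    With every observation identical the tie correction degenerates; H is
    reported as 0 with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    arrays = [np.asarray(g, dtype=float) for g in groups]
    if any(a.size == 0 for a in arrays):
        raise ValueError("empty group")
    pooled = np.concatenate(arrays)
    n = pooled.size
    if n < 3:
        raise ValueError("need at least three observations in total")
    ranks = scipy.stats.rankdata(pooled)
    h = 0.0
    start = 0
    for a in arrays:
        r = ranks[start : start + a.size]
        h += r.sum() ** 2 / a.size
        start += a.size
    h = 12.0 / (n * (n + 1)) * h - 3.0 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - (tie_counts**3 - tie_counts).sum() / (n**3 - n)
    if correction == 0.0:
        return 0.0, 1.0
    h /= correction
    p = float(scipy.stats.chi2.sf(h, df=len(arrays) - 1))
    return float(h), p


def bonferroni(pvalues: np.ndarray) -> np.ndarray:
    """Bonferroni adjustment: p_adj = min(1, m * p)."""
    p = np.asarray(pvalues, dtype=float)
    return np.minimum(1.0, p * p.size)
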