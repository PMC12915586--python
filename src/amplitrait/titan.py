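"""Threshold indicator taxa analysis along a temporal gradient.

For each taxon the gradient (time points) is split at every candidate
change point — the midpoints between consecutive distinct gradient values
with at least ``min_side`` samples on each side. At each split the
Dufrene-Legendre indicator value IndVal = 100 * A * B is computed for both
sides (A: relative mean abundance of the side, B: occurrence frequency in
the side) and the partition takes the larger side. A permutation z-score
standardises the observed IndVal against gradient-shuffled replicates; the
taxon's change point is the split maximising z, its direction is the side
achieving the maximum there (increaser when the high-gradient side wins),
and its p-value is the permutation exceedance probability at that split.

Bootstrap resampling of samples yields purity (fraction of bootstraps
agreeing with the observed direction) and reliability (fraction with
permutation p <= 0.05); taxa are retained when both reach their thresholds
(default 0.95, the conventional screen).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from .annotate import TraitAssignment
from .stats import kruskal_wallis


@dataclass(frozen=True)
class ChangePointResult:
    change_point: float
    indval_max: float
    z_score: float
    direction: str  # "increaser" | "decreaser"
    p_value: float


@dataclass(frozen=True)
class IndicatorResult:
    otu_id: str
    direction: str
    change_point: float
    indval_max: float
    z_score: float
    p_value: float
    purity: float
    reliability: float
    retained: bool
    n_boot_valid: int


def indval(abund: np.ndarray, in_group_a: np.ndarray) -> tuple[float, str]:
    """Indicator value of one taxon for a binary partition.

    Returns ``(max IndVal over the two sides, side)`` where side is "A" or
    "B". IndVal_g = 100 * A_g * B_g with A_g the group mean abundance
    divided by the sum of both group means and B_g the occurrence frequency
    within the group.
    """
    abund = np.asarray(abund, dtype=float)
    mask = np.asarray(in_group_a, dtype=bool)
    if mask.all() or not mask.any():
        raise ValueError("both groups must be non-empty")
    if not np.any(abund > 0):
        raise ValueError("taxon absent from all samples")
    iv_a, iv_b = _indval_rows(abund[None, :], mask)
    if iv_a[0] >= iv_b[0]:
        return float(iv_a[0]), "A"
    return float(iv_b[0]), "B"


def _indval_rows(rows: np.ndarray, low_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised IndVal for both sides over many abundance rows."""
    low = rows[:, low_mask]
    high = rows[:, ~low_mask]
    m_low = low.mean(axis=1)
    m_high = high.mean(axis=1)
    denom = m_low + m_high
    safe = np.where(denom > 0, denom, 1.0)
    a_low = np.where(denom > 0, m_low / safe, 0.0)
    a_high = np.where(denom > 0, m_high / safe, 0.0)
    b_low = (low > 0).mean(axis=1)
    b_high = (high > 0).mean(axis=1)
    return 100.0 * a_low * b_low, 100.0 * a_high * b_high


def _candidate_splits(gradient: np.ndarray, min_side: int) -> list[tuple[float, np.ndarray]]:
    values = np.unique(gradient)
    splits = []
    for lo, hi in zip(values[:-1], values[1:]):
        cp = 0.5 * (lo + hi)
        mask = gradient < cp
        if mask.sum() >= min_side and (~mask).sum() >= min_side:
            splits.append((float(cp), mask))
    return splits


def taxon_change_point(
    abund: np.ndarray,
    gradient: np.ndarray,
    n_perm: int = 250,
    seed: int | np.random.Generator | None = None,
    min_side: int = 3,
) -> ChangePointResult:
    """Locate one taxon's change point by maximising the permutation z-score.

    ``abund`` should hold per-sample relative abundances. Permutations
    shuffle the gradient labels (equivalently the abundance vector); the
    same permuted replicates score every candidate split, and the split
    with the largest z wins (ties resolved toward the smallest change
    point). p = (1 + #{IndVal_perm >= IndVal_obs at the chosen split}) /
    (1 + n_perm).
    """
    abund = np.asarray(abund, dtype=float)
    gradient = np.asarray(gradient, dtype=float)
    if abund.shape != gradient.shape:
        raise ValueError("abundance and gradient lengths differ")
    if not np.any(abund > 0):
        raise ValueError("taxon absent from all samples")
    if np.unique(gradient).size < 2:
        raise ValueError("gradient is degenerate (single value)")
    splits = _candidate_splits(gradient, min_side)
    if not splits:
        raise ValueError("no candidate split satisfies the minimum side size")
    rng = np.random.default_rng(seed)
    n = abund.size
    perms = rng.permuted(np.tile(abund, (n_perm, 1)), axis=1)

    best = None  # (z, cp, obs_iv, direction, p)
    for cp, low_mask in splits:
        iv_low, iv_high = _indval_rows(abund[None, :], low_mask)
        obs = max(iv_low[0], iv_high[0])
        direction = "decreaser" if iv_low[0] >= iv_high[0] else "increaser"
        p_low, p_high = _indval_rows(perms, low_mask)
        perm_iv = np.maximum(p_low, p_high)
        sd = perm_iv.std(ddof=1)
        z = (obs - perm_iv.mean()) / sd if sd > 0 else 0.0
        p = (1.0 + np.count_nonzero(perm_iv >= obs)) / (1.0 + n_perm)
        if best is None or z > best[0]:
            best = (z, cp, obs, direction, p)
    z, cp, obs, direction, p = best
    return ChangePointResult(cp, obs, float(z), direction, float(p))


def titan_screen(
    table: pd.DataFrame,
    gradient: np.ndarray | pd.Series,
    n_perm: int = 250,
    n_boot: int = 500,
    purity_min: float = 0.95,
    reliability_min: float = 0.95,
    occupancy_min: int = 3,
    min_side: int = 3,
    seed: int | np.random.Generator | None = None,
) -> pd.DataFrame:
    """Screen every sufficiently occupied taxon for a temporal change point.

    ``table`` is a samples x taxa table of counts or relative abundances;
    rows are converted to relative abundances before analysis. Returns one
    row per analysed taxon with change point, direction, z, permutation p,
    bootstrap purity and reliability, and the retention flag
    (purity >= purity_min and reliability >= reliability_min).
    """
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if table.empty:
        raise ValueError("empty abundance table")
    if not (0 < purity_min <= 1) or not (0 < reliability_min <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    gradient = np.asarray(pd.Series(gradient).loc[table.index] if isinstance(gradient, pd.Series) else gradient, dtype=float)
    if gradient.size != table.shape[0]:
        raise ValueError("gradient length does not match sample count")
    values = table.to_numpy(dtype=float)
    rel = values / values.sum(axis=1, keepdims=True)
    occupancy = (rel > 0).sum(axis=0)
    keep = occupancy >= occupancy_min
    taxa = [str(c) for c, k in zip(table.columns, keep) if k]
    rel = rel[:, keep]

    rng = np.random.default_rng(seed)
    n = rel.shape[0]
    boot_idx = rng.integers(0, n, size=(n_boot, n))

    rows = []
    for t, taxon in enumerate(taxa):
        abund = rel[:, t]
        obs = taxon_change_point(abund, gradient, n_perm=n_perm, seed=rng, min_side=min_side)
        agree = 0
        significant = 0
        valid = 0
        for b in range(n_boot):
            idx = boot_idx[b]
            g_b = gradient[idx]
            a_b = abund[idx]
            if np.unique(g_b).size < 2 or not np.any(a_b > 0):
                continue
            if not _candidate_splits(g_b, min_side):
                continue
            res = taxon_change_point(a_b, g_b, n_perm=n_perm, seed=rng, min_side=min_side)
            valid += 1
            agree += res.direction == obs.direction
            significant += res.p_value <= 0.05
        purity = agree / valid if valid else 0.0
        reliability = significant / valid if valid else 0.0
        rows.append(
            IndicatorResult(
                otu_id=taxon,
                direction=obs.direction,
                change_point=obs.change_point,
                indval_max=obs.indval_max,
                z_score=obs.z_score,
                p_value=obs.p_value,
                purity=purity,
                reliability=reliability,
                retained=purity >= purity_min and reliability >= reliability_min,
                n_boot_valid=valid,
            )
        )
    return pd.DataFrame([r.__dict__ for r in rows])


@dataclass
class TraitContrast:
    n_increasers: int
    n_decreasers: int
    genome_size_mean_increasers: float
    genome_size_mean_decreasers: float
    rrn_mean_increasers: float
    rrn_mean_decreasers: float
    genome_size_diff_mb: float
    rrn_diff: float
    genome_size_p: float
    rrn_p: float

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([self.__dict__])


def indicator_trait_contrast(
    indicators: pd.DataFrame, assignments: Mapping[str, TraitAssignment]
) -> TraitContrast:
    """Compare mean genome size and RRN between retained increasers and
    decreasers (unweighted means over trait-assigned taxa; Kruskal-Wallis p
    per trait). Differences are increaser minus decreaser."""
    retained = indicators[indicators["retained"]]
    groups: dict[str, dict[str, list[float]]] = {
        "increaser": {"gs": [], "rrn": []},
        "decreaser": {"gs": [], "rrn": []},
    }
    for row in retained.itertuples(index=False):
        a = assignments.get(row.otu_id)
        if a is None or not a.assigned:
            continue
        if a.genome_size_mb is not None:
            groups[row.direction]["gs"].append(a.genome_size_mb)
        if a.rrn is not None:
            groups[row.direction]["rrn"].append(float(a.rrn))
    inc, dec = groups["increaser"], groups["decreaser"]

    def mean(vals: list[float]) -> float:
        return float(np.mean(vals)) if vals else float("nan")

    def kw_p(a: list[float], b: list[float]) -> float:
        if not a or not b or len(a) + len(b) < 3:
            return float("nan")
        return kruskal_wallis(np.array(a), np.array(b))[1]

    return TraitContrast(
        n_increasers=len(inc["gs"]),
        n_decreasers=len(dec["gs"]),
        genome_size_mean_increasers=mean(inc["gs"]),
        genome_size_mean_decreasers=mean(dec["gs"]),
        rrn_mean_increasers=mean(inc["rrn"]),
        rrn_mean_decreasers=mean(dec["rrn"]),
        genome_size_diff_mb=mean(inc["gs"]) - mean(dec["gs"]),
        rrn_diff=mean(inc["rrn"]) - mean(dec["rrn"]),
        genome_size_p=kw_p(inc["gs"], dec["gs"]),
        rrn_p=kw_p(inc["rrn"], dec["rrn"]),
    )
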