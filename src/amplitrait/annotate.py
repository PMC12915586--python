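"""Trait annotation of OTUs and abundance-weighted community trait means.

Each OTU representative sequence is matched against the trait reference;
the best hit (highest score, ties broken by higher identity and then by
lexicographically smallest accession) is retained only if both percent
identity and query coverage reach their thresholds (default 95/95). Genome
size (Mb) and rRNA operon copy number are then propagated from the matched
reference, and per-sample community-weighted means are computed over the
assigned read fraction.

An exact k-mer prescreen (default k=11) limits the subjects each query is
aligned against; queries sharing no k-mer with any reference fall back to a
full scan, so the prescreen can never change a best hit for queries that
share at least one k-mer with their best subject.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .align import AlignmentHit, align_pair, kmer_candidates, kmer_index
from .reference import TraitReferenceSet


@dataclass(frozen=True)
class TraitAssignment:
    """Match outcome for one OTU: best hit plus traits, or unassigned."""

    otu_id: str
    status: str  # "assigned" | "unassigned"
    accession: str | None = None
    identity_pct: float = float("nan")
    query_coverage_pct: float = float("nan")
    genome_size_mb: float | None = None
    rrn: int | None = None

    @property
    def assigned(self) -> bool:
        return self.status == "assigned"


def best_hit(
    query_id: str,
    query: str,
    reference: TraitReferenceSet,
    candidates: Iterable[str] | None = None,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
) -> AlignmentHit:
    """Best-scoring reference for one query, with deterministic tie-breaks."""
    accs = sorted(candidates) if candidates is not None else sorted(reference.accessions)
    best: AlignmentHit | None = None
    for acc in accs:
        hit = align_pair(
            query,
            reference[acc].sequence,
            match=match,
            mismatch=mismatch,
            gap=gap,
            query_id=query_id,
            subject_accession=acc,
        )
        if (
            best is None
            or hit.score > best.score
            or (hit.score == best.score and hit.identity_pct > best.identity_pct)
        ):
            # accessions are visited in lexicographic order, so on a full
            # score+identity tie the earlier (smaller) accession is kept
            best = hit
    assert best is not None
    return best


def assign_traits(
    otus: Sequence[tuple[str, str]],
    reference: TraitReferenceSet,
    min_identity_pct: float = 95.0,
    min_coverage_pct: float = 95.0,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    prescreen_k: int | None = 11,
) -> dict[str, TraitAssignment]:
    """Assign genome size and RRN to each OTU by best reference hit.

    ``otus`` is a sequence of ``(otu_id, sequence)`` pairs (as returned by
    :func:`amplitrait.io.read_fasta`).
    """
    if not (0 < min_identity_pct <= 100) or not (0 < min_coverage_pct <= 100):
        raise ValueError("thresholds must lie in (0, 100]")
    ids = [otu_id for otu_id, _ in otus]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate OTU ids")
    index = (
        kmer_index({r.accession: r.sequence for r in reference}, k=prescreen_k)
        if prescreen_k
        else None
    )
    assignments: dict[str, TraitAssignment] = {}
    for otu_id, seq in otus:
        candidates = None
        if index is not None:
            found = kmer_candidates(seq.upper(), index, k=prescreen_k)
            if found:
                candidates = found
        hit = best_hit(
            otu_id, seq, reference, candidates, match=match, mismatch=mismatch, gap=gap
        )
        passed = (
            hit.identity_pct >= min_identity_pct
            and hit.query_coverage_pct >= min_coverage_pct
        )
        if passed:
            ref = reference[hit.subject_accession]
            assignments[otu_id] = TraitAssignment(
                otu_id=otu_id,
                status="assigned",
                accession=hit.subject_accession,
                identity_pct=hit.identity_pct,
                query_coverage_pct=hit.query_coverage_pct,
                genome_size_mb=ref.genome_size_mb,
                rrn=ref.rrn,
            )
        else:
            assignments[otu_id] = TraitAssignment(
                otu_id=otu_id,
                status="unassigned",
                accession=hit.subject_accession,
                identity_pct=hit.identity_pct,
                query_coverage_pct=hit.query_coverage_pct,
            )
    return assignments


def assignments_to_frame(assignments: Mapping[str, TraitAssignment]) -> pd.DataFrame:
    rows = []
    for a in assignments.values():
        rows.append(
            {
                "otu_id": a.otu_id,
                "status": a.status,
                "accession": a.accession or "",
                "identity_pct": a.identity_pct,
                "coverage_pct": a.query_coverage_pct,
                "genome_size_mb": a.genome_size_mb if a.genome_size_mb is not None else np.nan,
                "rrn": a.rrn if a.rrn is not None else np.nan,
            }
        )
    return pd.DataFrame(rows)


def frame_to_assignments(frame: pd.DataFrame) -> dict[str, TraitAssignment]:
    out: dict[str, TraitAssignment] = {}
    for row in frame.itertuples(index=False):
        gs = None if pd.isna(row.genome_size_mb) else float(row.genome_size_mb)
        rrn = None if pd.isna(row.rrn) else int(row.rrn)
        out[str(row.otu_id)] = TraitAssignment(
            otu_id=str(row.otu_id),
            status=str(row.status),
            accession=str(row.accession) or None,
            identity_pct=float(row.identity_pct),
            query_coverage_pct=float(row.coverage_pct),
            genome_size_mb=gs,
            rrn=rrn,
        )
    return out


def community_weighted_traits(
    counts: pd.DataFrame, assignments: Mapping[str, TraitAssignment]
) -> pd.DataFrame:
    """Per-sample abundance-weighted mean genome size and RRN.

    For each trait, mean = sum(n_i * t_i) / sum(n_i) over OTUs assigned for
    that trait; ``assigned_fraction_*`` is the read fraction those OTUs
    carry. Means are NaN when the assigned fraction is zero. Genome size and
    RRN are treated independently: an OTU may carry one trait and not the
    other.
    """
    missing = [c for c in counts.columns if c not in assignments]
    if missing:
        raise ValueError(f"OTUs without assignment records: {missing[:5]}")
    values = counts.to_numpy(dtype=float)
    if np.any(values < 0):
        raise ValueError("negative counts")
    totals = values.sum(axis=1)
    if np.any(totals == 0):
        bad = counts.index[totals == 0][0]
        raise ValueError(f"sample {bad!r} has zero total reads")

    gs = np.array(
        [
            a.genome_size_mb if (a.assigned and a.genome_size_mb is not None) else np.nan
            for a in (assignments[c] for c in counts.columns)
        ]
    )
    rrn = np.array(
        [
            float(a.rrn) if (a.assigned and a.rrn is not None) else np.nan
            for a in (assignments[c] for c in counts.columns)
        ]
    )

    def weighted(trait: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        mask = ~np.isnan(trait)
        assigned_reads = values[:, mask].sum(axis=1)
        frac = assigned_reads / totals
        with np.errstate(invalid="ignore"):
            mean = np.where(
                assigned_reads > 0,
                values[:, mask] @ trait[mask] / np.where(assigned_reads > 0, assigned_reads, 1.0),
                np.nan,
            )
        return mean, frac

    mean_gs, frac_gs = weighted(gs)
    mean_rrn, frac_rrn = weighted(rrn)
    return pd.DataFrame(
        {
            "mean_genome_size_mb": mean_gs,
            "mean_rrn": mean_rrn,
            "assigned_fraction_gs": frac_gs,
            "assigned_fraction_rrn": frac_rrn,
        },
        index=counts.index.copy(),
    )


def coverage_report(
    profiles: pd.DataFrame,
    groups: pd.Series | None = None,
    warn_below: float = 0.5,
) -> pd.DataFrame:
    """Min/median/max assigned fraction per group and trait, with warnings.

    ``groups`` maps sample id -> group label (e.g. compartment); with no
    grouping all samples form one group. Samples whose assigned fraction
    falls below ``warn_below`` are listed in the ``flagged`` column.
    """
    if profiles.empty:
        raise ValueError("no trait profiles supplied")
    if groups is None:
        groups = pd.Series("all", index=profiles.index)
    groups = groups.reindex(profiles.index)
    rows = []
    for trait, col in (("genome_size", "assigned_fraction_gs"), ("rrn", "assigned_fraction_rrn")):
        for label, sub in profiles.groupby(groups, sort=True):
            frac = sub[col]
            flagged = sorted(frac.index[frac < warn_below])
            rows.append(
                {
                    "group": label,
                    "trait": trait,
                    "n_samples": len(sub),
                    "min": float(frac.min()),
                    "median": float(frac.median()),
                    "max": float(frac.max()),
                    "flagged": ";".join(flagged),
                }
            )
    return pd.DataFrame(rows)
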