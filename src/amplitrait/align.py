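"""Semi-global pairwise alignment of short amplicon sequences.

Matches an amplicon query against a reference 16S region the way a
BLAST-style best hit would be interpreted downstream:

* overlap ("glocal") alignment — gaps at either end of either sequence are
  free, so a query may align into an interior window of the subject and a
  low-quality query end may be left unaligned;
* linear gap cost (default match +1, mismatch -1, gap -2 per column);
* identity = identical columns / alignment columns, with interior gap
  columns counted in the denominator (the "identities / alignment length"
  convention);
* query coverage = query residues inside the aligned span / query length;
* ``N`` never counts as a match.

Ties are resolved deterministically: the alignment end cell is the first
maximum encountered scanning the final DP row (subject positions ascending)
then the final column (query positions ascending), and traceback prefers
diagonal, then a gap in the subject, then a gap in the query. The same
conventions define the brute-force oracle used in the test suite.

The forward pass is vectorised row by row: with a linear gap penalty the
within-row dependency ``H[i,j] = max(candidate[j], H[i,j-1] + gap)`` unrolls
to a running maximum of ``candidate[k] - gap*k``, i.e. a prefix-max.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

_VALID = frozenset("ACGTN")


@dataclass(frozen=True)
class AlignmentHit:
    """Best-alignment summary for one query/subject pair."""

    query_id: str
    subject_accession: str
    score: float
    identity_pct: float
    query_coverage_pct: float
    alignment_length: int


def _check_sequence(seq: str, label: str) -> str:
    if not seq:
        raise ValueError(f"{label} sequence is empty")
    seq = seq.upper()
    bad = set(seq) - _VALID
    if bad:
        raise ValueError(f"{label} sequence contains invalid symbols {sorted(bad)}")
    return seq


def _dp_matrix(q: np.ndarray, s: np.ndarray, match: float, mismatch: float, gap: float) -> np.ndarray:
    m, n = len(q), len(s)
    H = np.zeros((m + 1, n + 1))
    j_idx = np.arange(n + 1)
    gap_ramp = gap * j_idx
    n_code = ord("N")
    for i in range(1, m + 1):
        qi = q[i - 1]
        if qi == n_code:
            sub = np.full(n, mismatch)
        else:
            sub = np.where((s == qi) & (s != n_code), match, mismatch)
        cand = np.empty(n + 1)
        cand[0] = 0.0  # free leading gap in the subject
        cand[1:] = np.maximum(H[i - 1, :-1] + sub, H[i - 1, 1:] + gap)
        H[i] = np.maximum.accumulate(cand - gap_ramp) + gap_ramp
    return H


def _end_cell(H: np.ndarray) -> tuple[int, int]:
    """First strict maximum over the last row (j ascending) then last column."""
    m = H.shape[0] - 1
    n = H.shape[1] - 1
    best_i, best_j = m, 0
    best = H[m, 0]
    for j in range(1, n + 1):
        if H[m, j] > best:
            best, best_i, best_j = H[m, j], m, j
    for i in range(m):
        if H[i, n] > best:
            best, best_i, best_j = H[i, n], i, n
    return best_i, best_j


def align_pair(
    query: str,
    subject: str,
    match: float = 1.0,
    mismatch: float = -1.0,
    gap: float = -2.0,
    query_id: str = "query",
    subject_accession: str = "subject",
) -> AlignmentHit:
    """Optimal overlap alignment of ``query`` against ``subject``.

    Returns the score, BLAST-like percent identity, query coverage, and
    alignment length of the best-scoring alignment under the deterministic
    tie-break conventions documented in the module docstring.
    """
    for p in (match, mismatch, gap):
        if not np.isfinite(p):
            raise ValueError("scoring parameters must be finite")
    query = _check_sequence(query, "query")
    subject = _check_sequence(subject, "subject")
    q = np.frombuffer(query.encode("ascii"), dtype=np.uint8).astype(np.int16)
    s = np.frombuffer(subject.encode("ascii"), dtype=np.uint8).astype(np.int16)
    H = _dp_matrix(q, s, match, mismatch, gap)

    i, j = _end_cell(H)
    score = float(H[i, j])
    end_i = i
    columns = 0
    matches = 0
    n_code = ord("N")
    # Traceback: diagonal > gap-in-subject (up) > gap-in-query (left).
    while i > 0 and j > 0:
        here = H[i, j]
        qi, sj = q[i - 1], s[j - 1]
        sub = match if (qi == sj and qi != n_code) else mismatch
        if here == H[i - 1, j - 1] + sub:
            if qi == sj and qi != n_code:
                matches += 1
            i -= 1
            j -= 1
        elif here == H[i - 1, j] + gap:
            i -= 1
        else:
            j -= 1
        columns += 1
    aligned_query = end_i - i
    qlen = len(query)
    if columns == 0:
        identity = 0.0
        coverage = 0.0
    else:
        identity = 100.0 * matches / columns
        coverage = 100.0 * aligned_query / qlen
    return AlignmentHit(
        query_id=query_id,
        subject_accession=subject_accession,
        score=score,
        identity_pct=identity,
        query_coverage_pct=coverage,
        alignment_length=columns,
    )


def kmer_index(sequences: dict[str, str], k: int = 11) -> dict[str, set[str]]:
    """Exact k-mer -> accession index used as an alignment prescreen."""
    index: dict[str, set[str]] = {}
    for acc, seq in sequences.items():
        for pos in range(len(seq) - k + 1):
            index.setdefault(seq[pos : pos + k], set()).add(acc)
    return index


def kmer_candidates(query: str, index: dict[str, set[str]], k: int = 11) -> set[str]:
    hits: set[str] = set()
    for pos in range(len(query) - k + 1):
        hits |= index.get(query[pos : pos + k], set())
    return hits
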