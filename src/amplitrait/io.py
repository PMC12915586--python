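"""Readers and writers for the plain-text formats the pipeline exchanges:
FASTA, tab-separated count tables / metadata / trait tables, and square
distance matrices.

All tables are tab-separated with a header row; count tables have samples
as rows and OTU identifiers as columns. Round trips are stable (write then
read yields identical content).
"""
from __future__ import annotations

from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from skbio.stats.distance import DistanceMatrix


class SchemaError(ValueError):
    """An input file is missing required columns or violates its contract."""


METADATA_COLUMNS = ("sample_id", "compartment", "time_point", "treatment", "site")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, sequence)`` pairs, enforcing unique IDs."""
    records = [(rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(str(path), "fasta")]
    if not records:
        raise SchemaError(f"{path}: FASTA contains no records")
    ids = [rid for rid, _ in records]
    if len(set(ids)) != len(ids):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise SchemaError(f"{path}: duplicate FASTA ids {dupes}")
    for rid, seq in records:
        if not seq:
            raise SchemaError(f"{path}: empty sequence for {rid!r}")
    return records


def write_fasta(path: str | Path, records: Iterable[tuple[str, str]]) -> None:
    seqrecs = [
        SeqRecord(Seq(seq), id=rid, description="") for rid, seq in records
    ]
    SeqIO.write(seqrecs, str(path), "fasta")


def read_count_table(path: str | Path) -> pd.DataFrame:
    """Read a samples x OTUs count table; validates non-negative integers."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    return validate_count_table(table, name=str(path))


def validate_count_table(table: pd.DataFrame, name: str = "count table") -> pd.DataFrame:
    if table.index.duplicated().any():
        raise SchemaError(f"{name}: duplicate sample ids")
    if table.columns.duplicated().any():
        raise SchemaError(f"{name}: duplicate OTU ids")
    values = table.to_numpy()
    if values.size and not np.issubdtype(values.dtype, np.number):
        raise SchemaError(f"{name}: non-numeric entries")
    if np.any(values < 0):
        i, j = np.argwhere(values < 0)[0]
        raise SchemaError(
            f"{name}: negative count at sample {table.index[i]!r}, OTU {table.columns[j]!r}"
        )
    if np.any(values != np.floor(values)):
        i, j = np.argwhere(values != np.floor(values))[0]
        raise SchemaError(
            f"{name}: non-integer count at sample {table.index[i]!r}, OTU {table.columns[j]!r}"
        )
    out = table.astype(np.int64)
    out.index = out.index.astype(str)
    out.columns = out.columns.astype(str)
    out.index.name = "sample_id"
    return out


def write_count_table(path: str | Path, table: pd.DataFrame) -> None:
    out = table.copy()
    out.index.name = "sample_id"
    out.to_csv(path, sep="\t")


def read_metadata(path: str | Path, required: Sequence[str] = METADATA_COLUMNS) -> pd.DataFrame:
    meta = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    missing = [c for c in required if c not in meta.columns]
    if missing:
        raise SchemaError(f"{path}: metadata missing columns {missing}")
    if meta["sample_id"].duplicated().any():
        raise SchemaError(f"{path}: duplicate sample ids in metadata")
    meta = meta.set_index("sample_id", drop=False)
    meta.index.name = None
    return meta


def write_metadata(path: str | Path, meta: pd.DataFrame) -> None:
    meta.to_csv(path, sep="\t", index=False)


def read_distance_matrix(path: str | Path) -> DistanceMatrix:
    frame = pd.read_csv(path, sep="\t", index_col=0)
    if list(frame.index) != list(frame.columns):
        raise SchemaError(f"{path}: row and column sample ids differ")
    return DistanceMatrix(frame.to_numpy(dtype=float), ids=[str(i) for i in frame.index])


def write_distance_matrix(path: str | Path, dm: DistanceMatrix) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")
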