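"""Trait reference records: 16S sequences keyed by genome accession, with
genome size (Mb) and rRNA operon copy number (RRN).

The on-disk representation is a FASTA of reference 16S regions plus a
tab-separated metadata table (accession, genome_size_mb, rrn), so that a
user can substitute a real genome-derived reference for the synthetic one.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd

from .io import read_fasta, write_fasta, SchemaError

_ALPHABET = frozenset("ACGT")


@dataclass(frozen=True)
class TraitReference:
    """One reference taxon: accession, 16S region sequence, and traits."""

    accession: str
    sequence: str
    genome_size_mb: float
    rrn: int

    def __post_init__(self) -> None:
        if not self.accession:
            raise ValueError("accession must be non-empty")
        if not self.sequence or set(self.sequence) - _ALPHABET:
            raise ValueError(
                f"{self.accession}: sequence must be non-empty and over A/C/G/T"
            )
        if not self.genome_size_mb > 0:
            raise ValueError(f"{self.accession}: genome_size_mb must be positive")
        if self.rrn < 1:
            raise ValueError(f"{self.accession}: rrn must be >= 1")


class TraitReferenceSet:
    """Accession-indexed collection of :class:`TraitReference` records."""

    def __init__(self, records: Iterable[TraitReference]):
        self._records: dict[str, TraitReference] = {}
        for rec in records:
            if rec.accession in self._records:
                raise ValueError(f"duplicate accession {rec.accession!r}")
            self._records[rec.accession] = rec
        if not self._records:
            raise ValueError("reference set must contain at least one record")

    def __len__(self) -> int:
        return len(self._records)

    def __iter__(self) -> Iterator[TraitReference]:
        return iter(self._records.values())

    def __getitem__(self, accession: str) -> TraitReference:
        return self._records[accession]

    def __contains__(self, accession: str) -> bool:
        return accession in self._records

    @property
    def accessions(self) -> list[str]:
        return list(self._records)

    def to_metadata_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "accession": [r.accession for r in self],
                "genome_size_mb": [r.genome_size_mb for r in self],
                "rrn": [r.rrn for r in self],
            }
        )

    def write(self, fasta_path: str | Path, metadata_path: str | Path) -> None:
        write_fasta(fasta_path, [(r.accession, r.sequence) for r in self])
        self.to_metadata_frame().to_csv(metadata_path, sep="\t", index=False)

    @classmethod
    def read(cls, fasta_path: str | Path, metadata_path: str | Path) -> "TraitReferenceSet":
        seqs = dict(read_fasta(fasta_path))
        meta = pd.read_csv(metadata_path, sep="\t")
        missing = {"accession", "genome_size_mb", "rrn"} - set(meta.columns)
        if missing:
            raise SchemaError(f"trait metadata missing columns: {sorted(missing)}")
        records = []
        for row in meta.itertuples(index=False):
            acc = str(row.accession)
            if acc not in seqs:
                raise SchemaError(f"accession {acc!r} has metadata but no sequence")
            records.append(
                TraitReference(acc, seqs[acc], float(row.genome_size_mb), int(row.rrn))
            )
        return cls(records)
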