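"""Synthetic study generator: trait references, amplicon sequences, and
trait-structured count tables for an air/leaf/root x time x N-treatment
seedling design.

The community model plants the fast-to-slow succession signal the analysis
is meant to detect. Taxa belong to guilds:

* ``late_slow`` — large genomes, low rRNA operon copy number (RRN), log-
  abundance rising with time in roots (anchored by an exemplar at
  8.817 Mb / RRN 2);
* ``early_fast`` — small genomes, high RRN, declining in roots and
  suppressed under N addition (anchor 5.778 Mb / RRN 3);
* ``background`` — intermediate traits, temporally flat, partly lacking a
  reference match so that annotation coverage is realistic rather than
  complete.

Per sample, expected relative abundances follow log-linear guild
trajectories (compartment- and treatment-specific) with a multiplicative
log-normal site effect, are perturbed by Dirichlet compositional noise, and
counts are drawn multinomially at a per-sample depth. Air communities are
flat in time, leaves trend weakly, roots strongly — so rarefaction,
annotation, trend tests, Mantel contrasts, and the indicator screen all
have planted structure to recover.

All randomness flows from one master seed through named substreams
(reference / amplicons / counts), so each stage is reproducible on its own.
"""
from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .io import write_count_table, write_fasta, write_metadata
from .reference import TraitReference, TraitReferenceSet

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def substream(seed: int, name: str) -> np.random.Generator:
    """Independent generator derived from the master seed and a stream name."""
    name_key = zlib.crc32(name.encode()) & 0x7FFFFFFF
    return np.random.default_rng(np.random.SeedSequence([seed, name_key]))


@dataclass(frozen=True)
class GuildSpec:
    """Trait distribution and temporal behaviour of one guild."""

    name: str
    fraction: float  # share of taxa allocated to this guild
    genome_size_mean_mb: float
    genome_size_sd_mb: float
    rrn_choices: tuple[int, ...]
    slopes: Mapping[str, float] = field(default_factory=dict)  # compartment -> log slope / TP
    treatment_factor: float = 1.0  # multiplies relative abundance under non-control treatment
    unmatched_fraction: float = 0.0  # taxa whose OTU sequence has no reference match
    base_log_mean: float = 0.0
    anchor: tuple[float, int] | None = None  # (genome_size_mb, rrn) for the guild's first taxon

    def slope(self, compartment: str) -> float:
        return float(self.slopes.get(compartment, 0.0))


@dataclass(frozen=True)
class TurnoverSpec:
    """Guild definitions plus noise structure for the generator."""

    guilds: tuple[GuildSpec, ...]
    dirichlet_concentration: float | None = 200.0  # None disables compositional noise
    site_sd: float = 0.15  # log-sd of the per-(site, guild) random effect
    base_log_sd: float = 1.0

    def __post_init__(self) -> None:
        if not self.guilds:
            raise ValueError("turnover spec needs at least one guild")
        by_name = {g.name: g for g in self.guilds}
        late, early = by_name.get("late_slow"), by_name.get("early_fast")
        if late is not None and early is not None:
            if not (
                late.genome_size_mean_mb > early.genome_size_mean_mb
                and np.mean(late.rrn_choices) < np.mean(early.rrn_choices)
            ):
                raise ValueError(
                    "late_slow guild must have larger genomes and lower RRN than early_fast"
                )


def default_turnover() -> TurnoverSpec:
    """Study-default guild structure: strong monotone turnover in roots,
    weak in leaves, none in air; N addition suppresses the fast guild."""
    return TurnoverSpec(
        guilds=(
            GuildSpec(
                name="late_slow",
                fraction=0.15,
                genome_size_mean_mb=8.0,
                genome_size_sd_mb=0.5,
                rrn_choices=(1, 2),
                slopes={"root": 0.35, "leaf": 0.08, "air": 0.0},
                base_log_mean=-0.7,
                anchor=(8.817, 2),
            ),
            GuildSpec(
                name="early_fast",
                fraction=0.15,
                genome_size_mean_mb=4.0,
                genome_size_sd_mb=0.5,
                rrn_choices=(5, 6, 7),
                slopes={"root": -0.35, "leaf": -0.08, "air": 0.0},
                treatment_factor=0.7,
                base_log_mean=0.7,
                anchor=(5.778, 3),
            ),
            GuildSpec(
                name="background",
                fraction=0.70,
                genome_size_mean_mb=5.5,
                genome_size_sd_mb=0.8,
                rrn_choices=(2, 3, 4, 5),
                unmatched_fraction=0.25,
            ),
        )
    )


@dataclass(frozen=True)
class StudyDesign:
    """Sampling layout: compartments x time points x treatments x sites."""

    compartments: tuple[str, ...] = ("air", "leaf", "root")
    n_time_points: int = 7
    treatments: tuple[str, ...] = ("control", "N_addition")  # first is the reference level
    n_sites: int = 3
    replicates: int = 2  # per (compartment, time, treatment, site) cell
    depth_range: tuple[int, int] = (1500, 6000)
    missing_cells: tuple[tuple[str, int, str, int], ...] = ()  # (compartment, tp, treatment, site)

    def __post_init__(self) -> None:
        if self.n_time_points < 2:
            raise ValueError("need at least two time points")
        if self.depth_range[0] < 1:
            raise ValueError("minimum sequencing depth must be at least 1 read")
        if self.depth_range[1] < self.depth_range[0]:
            raise ValueError("depth range is inverted")
        if self.replicates < 1 or self.n_sites < 1:
            raise ValueError("replicates and sites must be positive")


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return rng.choice(_BASES, size=length).tobytes().decode("ascii")


def _allocate(n_taxa: int, guilds: Sequence[GuildSpec]) -> list[int]:
    if n_taxa < len(guilds):
        raise ValueError("n_taxa must be at least the number of guilds")
    raw = np.array([g.fraction for g in guilds], dtype=float)
    raw = raw / raw.sum() * n_taxa
    counts = np.maximum(1, np.floor(raw).astype(int))
    while counts.sum() < n_taxa:
        counts[np.argmax(raw - counts)] += 1
    while counts.sum() > n_taxa:
        over = np.where(counts > 1)[0]
        counts[over[np.argmin((raw - counts)[over])]] -= 1
    return counts.tolist()


def simulate_reference(
    n_taxa: int, turnover: TurnoverSpec, seed: int
) -> tuple[TraitReferenceSet, dict[str, str]]:
    """Generate the trait reference and the accession -> guild map.

    The first taxon of a guild carrying an ``anchor`` receives the anchor's
    exact genome size and RRN; other taxa draw from the guild distribution.
    """
    if n_taxa <= 0:
        raise ValueError("n_taxa must be positive")
    rng = substream(seed, "reference")
    counts = _allocate(n_taxa, turnover.guilds)
    records: list[TraitReference] = []
    guild_map: dict[str, str] = {}
    idx = 1
    for guild, k in zip(turnover.guilds, counts):
        for j in range(k):
            acc = f"REF_{idx:03d}"
            length = int(rng.integers(250, 261))
            seq = _random_sequence(rng, length)
            if j == 0 and guild.anchor is not None:
                gs, rrn = guild.anchor
            else:
                gs = max(0.5, float(rng.normal(guild.genome_size_mean_mb, guild.genome_size_sd_mb)))
                rrn = int(rng.choice(guild.rrn_choices))
            records.append(TraitReference(acc, seq, float(gs), int(rrn)))
            guild_map[acc] = guild.name
            idx += 1
    return TraitReferenceSet(records), guild_map


def otu_id_for(accession: str) -> str:
    return accession.replace("REF", "OTU")


def simulate_amplicons(
    reference: TraitReferenceSet,
    identity_targets: Mapping[str, float] | float,
    unrelated: Sequence[str] = (),
    seed: int = 0,
) -> tuple[list[tuple[str, str]], dict[str, str | None]]:
    """OTU representative sequences with controlled best-hit identities.

    Each reference taxon yields one OTU: its sequence mutated by
    ``round((1 - target) * L)`` substitutions at random positions (so the
    realised ungapped identity is within one substitution of the target),
    or — for accessions listed in ``unrelated`` — a fresh random sequence
    with no reference counterpart, expected to fall below any sensible
    identity threshold. Returns the records and an OTU -> source accession
    map (None for unrelated OTUs).
    """
    rng = substream(seed, "amplicons")
    unrelated_set = set(unrelated)
    records: list[tuple[str, str]] = []
    otu_map: dict[str, str | None] = {}
    for ref in reference:
        otu = otu_id_for(ref.accession)
        if ref.accession in unrelated_set:
            records.append((otu, _random_sequence(rng, len(ref.sequence))))
            otu_map[otu] = None
            continue
        target = (
            identity_targets
            if isinstance(identity_targets, float)
            else identity_targets.get(ref.accession, 1.0)
        )
        if not (0.5 <= target <= 1.0):
            raise ValueError(f"target identity {target} outside [0.5, 1.0]")
        length = len(ref.sequence)
        n_sub = int(round((1.0 - target) * length))
        seq = np.frombuffer(ref.sequence.encode("ascii"), dtype=np.uint8).copy()
        if n_sub:
            positions = rng.choice(length, size=n_sub, replace=False)
            for pos in positions:
                options = _BASES[_BASES != seq[pos]]
                seq[pos] = rng.choice(options)
        records.append((otu, seq.tobytes().decode("ascii")))
        otu_map[otu] = ref.accession
    return records, otu_map


def simulate_counts(
    design: StudyDesign,
    turnover: TurnoverSpec,
    guild_map: Mapping[str, str],
    seed: int = 0,
    column_ids: Mapping[str, str] | None = None,
    return_expected: bool = False,
):
    """Draw the count table and sample metadata for the full design.

    Expected relative abundances per sample come from log-linear guild
    trajectories (slope per compartment, multiplicative treatment factor on
    non-control samples, log-normal site x guild effect), renormalised to a
    composition, optionally perturbed by Dirichlet noise, then realised as
    a multinomial draw at a uniform-integer depth.
    """
    rng = substream(seed, "counts")
    taxa = list(guild_map)
    guilds = {g.name: g for g in turnover.guilds}
    for name in set(guild_map.values()):
        if name not in guilds:
            raise ValueError(f"guild map references unknown guild {name!r}")
    guild_of = [guilds[guild_map[t]] for t in taxa]
    n_taxa = len(taxa)

    base = np.array(
        [g.base_log_mean + rng.normal(0.0, turnover.base_log_sd) for g in guild_of]
    )
    site_eff = {
        (s, g.name): rng.normal(0.0, turnover.site_sd)
        for s in range(1, design.n_sites + 1)
        for g in {id(g): g for g in guild_of}.values()
    }
    missing = set(design.missing_cells)

    rows, meta_rows, expected_rows, sample_ids = [], [], [], []
    for comp in design.compartments:
        slopes = np.array([g.slope(comp) for g in guild_of])
        log_factor = np.array(
            [np.log(g.treatment_factor) if g.treatment_factor > 0 else -np.inf for g in guild_of]
        )
        for tp in range(1, design.n_time_points + 1):
            for trt in design.treatments:
                treated = trt != design.treatments[0]
                for site in range(1, design.n_sites + 1):
                    if (comp, tp, trt, site) in missing:
                        continue
                    s_eff = np.array([site_eff[(site, g.name)] for g in guild_of])
                    logw = base + slopes * (tp - 1) + s_eff
                    if treated:
                        logw = logw + log_factor
                    w = np.exp(logw - logw.max())
                    p = w / w.sum()
                    for rep in range(1, design.replicates + 1):
                        if turnover.dirichlet_concentration is not None:
                            probs = rng.dirichlet(turnover.dirichlet_concentration * p)
                        else:
                            probs = p
                        depth = int(rng.integers(design.depth_range[0], design.depth_range[1] + 1))
                        counts = rng.multinomial(depth, probs)
                        sid = f"{comp}.TP{tp}.{trt}.S{site}.R{rep}"
                        sample_ids.append(sid)
                        rows.append(counts)
                        expected_rows.append(p)
                        meta_rows.append(
                            {
                                "sample_id": sid,
                                "compartment": comp,
                                "time_point": tp,
                                "treatment": trt,
                                "site": site,
                            }
                        )
    columns = [column_ids.get(t, t) if column_ids else t for t in taxa]
    table = pd.DataFrame(np.array(rows, dtype=np.int64), index=sample_ids, columns=columns)
    table.index.name = "sample_id"
    metadata = pd.DataFrame(meta_rows).set_index("sample_id", drop=False)
    metadata.index.name = None
    if return_expected:
        expected = pd.DataFrame(np.array(expected_rows), index=sample_ids, columns=columns)
        return table, metadata, expected
    return table, metadata


@dataclass
class StudyBundle:
    """Everything one synthetic study run produces, plus the ground truth."""

    reference: TraitReferenceSet
    guild_map: dict[str, str]
    otus: list[tuple[str, str]]
    otu_map: dict[str, str | None]
    counts: pd.DataFrame
    metadata: pd.DataFrame
    truth: pd.DataFrame  # per-OTU: accession, guild, traits, matched flag, target identity

    def write(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.reference.write(out / "reference.fasta", out / "reference_traits.tsv")
        write_fasta(out / "otus.fasta", self.otus)
        write_count_table(out / "counts.tsv", self.counts)
        write_metadata(out / "metadata.tsv", self.metadata)
        self.truth.to_csv(out / "truth.tsv", sep="\t", index=False)


def simulate_study(
    design: StudyDesign | None = None,
    turnover: TurnoverSpec | None = None,
    n_taxa: int = 60,
    seed: int = 0,
    identity_range: tuple[float, float] = (0.96, 1.0),
) -> StudyBundle:
    """Run the full generator: reference, amplicons, counts, truth table."""
    design = design or StudyDesign()
    turnover = turnover or default_turnover()
    reference, guild_map = simulate_reference(n_taxa, turnover, seed)

    rng = substream(seed, "study")
    guild_accs: dict[str, list[str]] = {}
    for acc, g in guild_map.items():
        guild_accs.setdefault(g, []).append(acc)
    unrelated: list[str] = []
    for g in turnover.guilds:
        accs = guild_accs.get(g.name, [])
        k = int(round(g.unmatched_fraction * len(accs)))
        if k:
            unrelated.extend(sorted(rng.choice(accs, size=k, replace=False)))
    lo, hi = identity_range
    targets = {acc: float(rng.uniform(lo, hi)) for acc in guild_map}

    otus, otu_map = simulate_amplicons(reference, targets, unrelated, seed=seed)
    column_ids = {acc: otu_id_for(acc) for acc in guild_map}
    counts, metadata = simulate_counts(design, turnover, guild_map, seed=seed, column_ids=column_ids)

    truth = pd.DataFrame(
        {
            "otu_id": [otu_id_for(acc) for acc in guild_map],
            "accession": list(guild_map),
            "guild": [guild_map[acc] for acc in guild_map],
            "genome_size_mb": [reference[acc].genome_size_mb for acc in guild_map],
            "rrn": [reference[acc].rrn for acc in guild_map],
            "matched": [acc not in set(unrelated) for acc in guild_map],
            "target_identity": [targets[acc] for acc in guild_map],
        }
    )
    return StudyBundle(reference, guild_map, otus, otu_map, counts, metadata, truth)
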