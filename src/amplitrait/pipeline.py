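"""End-to-end orchestration: simulate (or load) -> rarefy -> annotate ->
community traits -> temporal statistics -> indicator screen, with every
intermediate persisted as a plain tab-separated file so any stage can be
audited or re-run in isolation.

Stage order is fixed: rarefaction first, and all downstream analyses (trait
means, ordination, trends, indicators) run on the rarefied table. One
master seed drives named substreams per stage, so two runs with the same
configuration are byte-identical.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .annotate import (
    assign_traits,
    assignments_to_frame,
    community_weighted_traits,
    coverage_report,
)
from .io import (
    read_count_table,
    read_fasta,
    read_metadata,
    write_count_table,
    write_distance_matrix,
    write_metadata,
)
from .reference import TraitReferenceSet
from .simulate import StudyDesign, simulate_study, substream
from .stats import bray_curtis, mantel, pcoa, permanova, rarefy, spearman_trend, temporal_distance
from .titan import indicator_trait_contrast, titan_screen


class PipelineError(RuntimeError):
    """A stage failed; the message names the stage and the offending input."""


@dataclass
class RunConfig:
    """Paths, parameters and stage toggles for one pipeline run."""

    out_dir: str = "amplitrait_run"
    seed: int = 0
    # input source: synthetic by default, or explicit paths
    simulate: bool = True
    n_taxa: int = 60
    counts_path: str | None = None
    otus_path: str | None = None
    reference_fasta: str | None = None
    reference_traits: str | None = None
    metadata_path: str | None = None
    # rarefaction
    rarefaction_depth: int = 2000
    # annotation
    min_identity_pct: float = 95.0
    min_coverage_pct: float = 95.0
    match: float = 1.0
    mismatch: float = -1.0
    gap: float = -2.0
    warn_coverage_below: float = 0.5
    # community statistics
    formula: str = "time_point*compartment+treatment"
    permutations: int = 999
    mantel_permutations: int = 999
    strata: str | None = None
    # indicator screen
    titan_permutations: int = 250
    titan_bootstraps: int = 500
    titan_compartments: tuple[str, ...] = ("root",)
    titan_occupancy_min: int = 3
    # stage toggles
    run_annotation: bool = True
    run_stats: bool = True
    run_indicators: bool = True

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        unknown = set(raw) - {f for f in cls.__dataclass_fields__}
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "titan_compartments" in raw:
            raw["titan_compartments"] = tuple(raw["titan_compartments"])
        cfg = cls(**raw)
        return replace(cfg, **overrides) if overrides else cfg

    def digest(self) -> str:
        """Hash of the analysis parameters (file locations excluded, so the
        same analysis written to two directories shares a digest)."""
        params = asdict(self)
        for key in (
            "out_dir",
            "counts_path",
            "otus_path",
            "reference_fasta",
            "reference_traits",
            "metadata_path",
        ):
            params.pop(key)
        blob = json.dumps(params, sort_keys=True, default=str).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def trend_panel(
    profiles: pd.DataFrame, metadata: pd.DataFrame, min_n: int = 3
) -> pd.DataFrame:
    """Spearman trend (rho, p) of each community trait against time within
    every compartment x treatment cell, plus a least-squares slope for
    plotting parity. Cells below ``min_n`` samples are reported but skipped."""
    meta = metadata.loc[profiles.index]
    rows = []
    for (comp, trt), sub in meta.groupby(["compartment", "treatment"], sort=True):
        prof = profiles.loc[sub.index]
        for trait in ("mean_genome_size_mb", "mean_rrn"):
            y = prof[trait].to_numpy(dtype=float)
            t = sub["time_point"].to_numpy(dtype=float)
            ok = ~np.isnan(y)
            row = {
                "compartment": comp,
                "treatment": trt,
                "trait": trait,
                "n": int(ok.sum()),
            }
            if ok.sum() < min_n or np.all(y[ok] == y[ok][0]) or np.all(t[ok] == t[ok][0]):
                row.update({"rho": np.nan, "p": np.nan, "slope": np.nan, "skipped": True})
            else:
                res = spearman_trend(t[ok], y[ok])
                slope = float(np.polyfit(t[ok], y[ok], 1)[0])
                row.update({"rho": res.rho, "p": res.p_value, "slope": slope, "skipped": False})
            rows.append(row)
    return pd.DataFrame(rows)


def _mantel_panel(dm, metadata: pd.DataFrame, n_perm: int, seed: int) -> pd.DataFrame:
    """Mantel R between Bray-Curtis and temporal distance, per compartment
    (treatments pooled) and per compartment x treatment cell."""
    rows = []
    groups: list[tuple[str, str, pd.DataFrame]] = []
    for comp, sub in metadata.groupby("compartment", sort=True):
        groups.append((comp, "pooled", sub))
        for trt, cell in sub.groupby("treatment", sort=True):
            groups.append((comp, trt, cell))
    for comp, trt, sub in groups:
        ids = [s for s in dm.ids if s in set(sub.index)]
        row = {"compartment": comp, "treatment": trt, "n": len(ids)}
        if len(ids) < 4 or sub.loc[ids, "time_point"].nunique() < 2:
            row.update({"mantel_r": np.nan, "p": np.nan, "skipped": True})
        else:
            sub_dm = dm.filter(ids)
            tdm = temporal_distance(sub.loc[ids])
            rng = substream(seed, f"mantel:{comp}:{trt}")
            res = mantel(sub_dm, tdm, n_perm=n_perm, seed=rng)
            row.update({"mantel_r": res.statistic, "p": res.p_value, "skipped": False})
        rows.append(row)
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages and return the run report (also written
    to ``<out_dir>/report.json`` with all intermediate tables alongside)."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {
        "provenance": {
            "version": __version__,
            "seed": config.seed,
            "config_digest": config.digest(),
        }
    }
    with open(out / "config.yaml", "w") as fh:
        yaml.safe_dump(asdict(config), fh, sort_keys=True)

    # ---- inputs -----------------------------------------------------------
    stage = "inputs"
    try:
        if config.simulate:
            bundle = simulate_study(
                design=StudyDesign(), n_taxa=config.n_taxa, seed=config.seed
            )
            inputs = out / "inputs"
            bundle.write(inputs)
            counts, metadata, otus = bundle.counts, bundle.metadata, bundle.otus
            reference = bundle.reference
        else:
            if config.counts_path is None or config.metadata_path is None:
                raise ValueError("counts_path and metadata_path are required when simulate=false")
            counts = read_count_table(config.counts_path)
            metadata = read_metadata(config.metadata_path)
            otus = read_fasta(config.otus_path) if config.otus_path else None
            reference = (
                TraitReferenceSet.read(config.reference_fasta, config.reference_traits)
                if config.reference_fasta and config.reference_traits
                else None
            )
        missing = set(counts.index) - set(metadata.index)
        if missing:
            raise ValueError(f"samples without metadata: {sorted(missing)[:5]}")
        report["inputs"] = {"n_samples": int(counts.shape[0]), "n_otus": int(counts.shape[1])}
    except Exception as exc:  # noqa: BLE001 - stage context for any failure
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # ---- rarefaction ------------------------------------------------------
    stage = "rarefy"
    try:
        rare, dropped = rarefy(
            counts, depth=config.rarefaction_depth, seed=substream(config.seed, "rarefy")
        )
        write_count_table(out / "rarefied_counts.tsv", rare)
        (out / "dropped_samples.txt").write_text("\n".join(dropped) + ("\n" if dropped else ""))
        metadata = metadata.loc[rare.index]
        write_metadata(out / "rarefied_metadata.tsv", metadata)
        report["rarefy"] = {
            "depth": config.rarefaction_depth,
            "n_retained": int(rare.shape[0]),
            "n_dropped": len(dropped),
        }
    except Exception as exc:
        raise PipelineError(f"stage {stage}: {exc}") from exc

    # ---- annotation + community traits ------------------------------------
    assignments = None
    profiles = None
    if config.run_annotation:
        stage = "annotate"
        try:
            if otus is None or reference is None:
                raise ValueError("annotation requires OTU sequences and a trait reference")
            assignments = assign_traits(
                otus,
                reference,
                min_identity_pct=config.min_identity_pct,
                min_coverage_pct=config.min_coverage_pct,
                match=config.match,
                mismatch=config.mismatch,
                gap=config.gap,
            )
            frame = assignments_to_frame(assignments)
            frame.to_csv(out / "assignments.tsv", sep="\t", index=False)
            profiles = community_weighted_traits(rare, assignments)
            profiles.to_csv(out / "trait_profiles.tsv", sep="\t")
            cov = coverage_report(
                profiles, metadata["compartment"], warn_below=config.warn_coverage_below
            )
            cov.to_csv(out / "coverage_report.tsv", sep="\t", index=False)
            report["annotate"] = {
                "n_assigned": int((frame["status"] == "assigned").sum()),
                "n_unassigned": int((frame["status"] == "unassigned").sum()),
                "assigned_fraction_gs_min": float(profiles["assigned_fraction_gs"].min()),
                "assigned_fraction_gs_max": float(profiles["assigned_fraction_gs"].max()),
            }
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    # ---- community statistics ---------------------------------------------
    if config.run_stats:
        stage = "stats"
        try:
            dm = bray_curtis(rare)
            write_distance_matrix(out / "bray_curtis.tsv", dm)
            ord_res = pcoa(dm, n_axes=2)
            pd.DataFrame(
                ord_res.coordinates,
                index=ord_res.sample_ids,
                columns=[f"PCo{i+1}" for i in range(ord_res.coordinates.shape[1])],
            ).to_csv(out / "pcoa_coordinates.tsv", sep="\t")
            perm = permanova(
                dm,
                metadata,
                config.formula,
                n_perm=config.permutations,
                seed=substream(config.seed, "permanova"),
                strata=config.strata,
            )
            perm.to_csv(out / "permanova.tsv", sep="\t", index=False)
            mant = _mantel_panel(dm, metadata, config.mantel_permutations, config.seed)
            mant.to_csv(out / "mantel.tsv", sep="\t", index=False)
            report["stats"] = {
                "permanova": {
                    r["term"]: {"R2": float(r["R2"]), "p": float(r["p"])}
                    for _, r in perm.iterrows()
                    if r["term"] not in ("Residual", "Total")
                },
                "mantel": {
                    f'{r["compartment"]}:{r["treatment"]}': float(r["mantel_r"])
                    for _, r in mant.iterrows()
                    if not r["skipped"]
                },
            }
            if profiles is not None:
                trends = trend_panel(profiles, metadata)
                trends.to_csv(out / "trait_trends.tsv", sep="\t", index=False)
                report["stats"]["trends"] = {
                    f'{r["compartment"]}:{r["treatment"]}:{r["trait"]}': {
                        "rho": float(r["rho"]),
                        "p": float(r["p"]),
                    }
                    for _, r in trends.iterrows()
                    if not r["skipped"]
                }
                summary = (
                    profiles.join(metadata[["compartment"]])
                    .groupby("compartment")[["mean_genome_size_mb", "mean_rrn"]]
                    .agg(["mean", "sem"])
                )
                summary.columns = ["_".join(c) for c in summary.columns]
                summary.to_csv(out / "trait_summary.tsv", sep="\t")
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    # ---- indicator screen --------------------------------------------------
    if config.run_indicators:
        stage = "indicators"
        try:
            report["indicators"] = {}
            for comp in config.titan_compartments:
                sub = metadata[metadata["compartment"] == comp]
                if sub.empty:
                    raise ValueError(f"no samples in compartment {comp!r}")
                table = rare.loc[sub.index]
                table = table.loc[:, table.sum(axis=0) > 0]
                ind = titan_screen(
                    table,
                    sub["time_point"],
                    n_perm=config.titan_permutations,
                    n_boot=config.titan_bootstraps,
                    occupancy_min=config.titan_occupancy_min,
                    seed=substream(config.seed, f"titan:{comp}"),
                )
                ind.to_csv(out / f"indicators_{comp}.tsv", sep="\t", index=False)
                entry = {
                    "n_tested": int(ind.shape[0]),
                    "n_retained": int(ind["retained"].sum()),
                    "n_increasers": int(((ind["direction"] == "increaser") & ind["retained"]).sum()),
                    "n_decreasers": int(((ind["direction"] == "decreaser") & ind["retained"]).sum()),
                }
                if assignments is not None:
                    contrast = indicator_trait_contrast(ind, assignments)
                    contrast.to_frame().to_csv(
                        out / f"trait_contrast_{comp}.tsv", sep="\t", index=False
                    )
                    entry["trait_contrast"] = {
                        "genome_size_diff_mb": contrast.genome_size_diff_mb,
                        "rrn_diff": contrast.rrn_diff,
                    }
                report["indicators"][comp] = entry
        except Exception as exc:
            raise PipelineError(f"stage {stage}: {exc}") from exc

    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True, default=_jsonable)
        fh.write("\n")
    return report
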