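"""End-to-end orchestration: simulate/load -> diff -> classify -> context ->
branchpoints, with persisted stage tables and a run summary."""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import (
    branchpoint,
    diffsplice,
    event_classification,
    junction_io,
    seq_context,
)

__all__ = ["RunConfig", "ConfigError", "validate_config", "run_pipeline"]

log = logging.getLogger("bpshift")


class ConfigError(ValueError):
    def __init__(self, errors: list[str]):
        self.errors = errors
        super().__init__("; ".join(errors))


@dataclass
class RunConfig:
    junctions: str = ""
    samples: str = ""
    genome: str = ""
    annotation: str = ""
    catalogue: str | None = None
    outdir: str = "bpshift_out"
    p_threshold: float = diffsplice.DEFAULT_P_THRESHOLD
    lfc_threshold: float = diffsplice.DEFAULT_LFC_THRESHOLD
    min_total: int = 10
    distance_window: tuple[int, int] = (-50, -1)
    bp_window_ag: tuple[int, int] = (-44, -16)
    bpprime_window: tuple[int, int] = (-18, -9)
    min_dist: int = 6
    max_dist: int = 100
    intron_flank: int = 50
    exon_flank: int = 50
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError([f"unknown config keys: {sorted(unknown)}"])
        for key in ("distance_window", "bp_window_ag", "bpprime_window"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)


def validate_config(config: RunConfig) -> RunConfig:
    """Check a run configuration, reporting every problem at once."""
    errors = []
    for name in ("junctions", "samples", "genome", "annotation"):
        value = getattr(config, name)
        if not value:
            errors.append(f"missing required path: {name}")
        elif not Path(value).exists():
            errors.append(f"{name} path does not exist: {value}")
    if config.catalogue and not Path(config.catalogue).exists():
        errors.append(f"catalogue path does not exist: {config.catalogue}")
    if not 0.0 < config.p_threshold <= 1.0:
        errors.append(f"p_threshold must lie in (0, 1], got {config.p_threshold}")
    if config.lfc_threshold < 0:
        errors.append(f"lfc_threshold must be >= 0, got {config.lfc_threshold}")
    if config.min_dist < 0 or config.max_dist <= config.min_dist:
        errors.append("need 0 <= min_dist < max_dist")
    for key in ("distance_window", "bp_window_ag", "bpprime_window"):
        lo, hi = getattr(config, key)
        if lo > hi:
            errors.append(f"{key}: window start {lo} exceeds end {hi}")
    if errors:
        raise ConfigError(errors)
    for f in fields(config):
        log.info("config %s = %r", f.name, getattr(config, f.name))
    return config


def _read_annotation_ids(path: str | Path) -> set[str]:
    ids = set()
    for j in junction_io.read_junction_bed(path, dialect="intron-bed6"):
        ids.add(j.id)
    return ids


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the summary dict (also written to disk).

    Stage outputs are persisted as they complete, so a failure in a later
    stage leaves earlier tables on disk; the raised error names the stage.
    """
    validate_config(config)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(outdir / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)

    summary: dict = {"seed": config.seed}
    stage = "load"
    try:
        sheet = junction_io.read_sample_sheet(config.samples)
        juncs = junction_io.read_junction_bed(
            config.junctions, dialect="intron-bed6", sample_sheet=sheet
        )
        table = junction_io.junctions_to_frame(juncs, sheet)
        annotation = _read_annotation_ids(config.annotation)
        genome = junction_io.read_fasta(config.genome)
        summary["n_junctions"] = len(table)
        summary["n_samples"] = sheet.n

        stage = "diff"
        diff = diffsplice.run_diffsplice(
            table, sheet,
            min_total=config.min_total,
            p_threshold=config.p_threshold,
            lfc_threshold=config.lfc_threshold,
        )
        diff.to_csv(outdir / "differential.tsv", sep="\t", index=False)
        selected_ids = list(diff.loc[diff["selected"], "id"])
        summary["n_selected"] = len(selected_ids)

        stage = "classify"
        events = event_classification.build_pairs(selected_ids, table, annotation)
        ev_frame = event_classification.events_to_frame(events)
        ev_frame.to_csv(outdir / "events.tsv", sep="\t", index=False)
        ev_summary = event_classification.summarize_events(events, config.distance_window)
        summary["class_counts"] = ev_summary.class_counts
        summary["n_within_window"] = ev_summary.n_within_window
        summary["inframe_fraction"] = ev_summary.inframe_fraction
        summary["inframe_p"] = ev_summary.inframe_p
        summary["novel_fraction"] = ev_summary.novel_fraction
        hist = pd.DataFrame(
            sorted(ev_summary.distance_histogram.items()), columns=["distance", "count"]
        )
        hist.to_csv(outdir / "distance_histogram.tsv", sep="\t", index=False)

        stage = "context"
        alt3 = [e for e in events if e.event_class == "alt3"]
        summary["plus_one"] = {}
        if alt3:
            agp_sites = [e.alternative_site for e in alt3]
            ag_sites = [e.canonical_site for e in alt3]
            for name, sites in (("ag_prime", agp_sites), ("ag", ag_sites)):
                comp = seq_context.plus_one_composition(sites, genome)
                summary["plus_one"][name] = comp
            matrix = seq_context.build_matrix(
                agp_sites, genome, config.intron_flank, config.exon_flank
            )
            matrix.to_frame().to_csv(outdir / "agprime_matrix.tsv", sep="\t")

        stage = "branchpoints"
        assignments = []
        for e in alt3:
            assignments.append(
                branchpoint.assign_branchpoints(
                    e, genome,
                    bp_window_ag=config.bp_window_ag,
                    bpprime_window=config.bpprime_window,
                    min_dist=config.min_dist,
                    max_dist=config.max_dist,
                )
            )
        rows = []
        for a in assignments:
            rows.append(
                {
                    "event_id": a.event_id,
                    "bp_offset": a.bp.offset if a.bp else np.nan,
                    "bp_heptamer": a.bp.heptamer if a.bp else "",
                    "bp_pairing": a.bp.pairing_score if a.bp else np.nan,
                    "bpprime_offset": a.bp_prime.offset if a.bp_prime else np.nan,
                    "bpprime_heptamer": a.bp_prime.heptamer if a.bp_prime else "",
                    "bpprime_pairing": a.bp_prime.pairing_score if a.bp_prime else np.nan,
                }
            )
        pd.DataFrame(
            rows,
            columns=[
                "event_id", "bp_offset", "bp_heptamer", "bp_pairing",
                "bpprime_offset", "bpprime_heptamer", "bpprime_pairing",
            ],
        ).to_csv(outdir / "branchpoints.tsv", sep="\t", index=False)
        dist = branchpoint.bp_distance_distribution(assignments)
        summary["bp_distance_modes"] = {k: v["mode"] for k, v in dist.items()}

        if config.catalogue:
            stage = "catalogue"
            catalogue = junction_io.read_branchpoint_catalogue(config.catalogue)
            agp_a = [
                (e.alternative_site.chrom, e.alternative_site.genomic(-2),
                 e.alternative_site.strand)
                for e in alt3
            ]
            summary["catalogue_overlap"] = branchpoint.overlap_with_catalogue(
                agp_a, catalogue
            )
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()

    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
    return summary
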