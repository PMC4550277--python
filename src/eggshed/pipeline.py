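"""End-to-end orchestration: simulate → assign → stats → transport.

A single flat config (YAML or constructed in code) drives all stages;
one global seed fans out to per-stage seeds by fixed offsets so each
stage is independently reproducible.  Every run writes a manifest
recording versions, seeds, input digests and output paths.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import barcode_id, community_stats, io_formats, synthetic_data, transport

__all__ = ["RunConfig", "validate_config", "run_pipeline", "SEED_OFFSETS"]

# fixed fan-out so stages are independently reproducible from one seed
SEED_OFFSETS = {"sequences": 1, "reads": 2, "field": 3, "collections": 4, "transport": 5}


@dataclass
class RunConfig:
    """Declarative description of one pipeline run (simulation mode)."""

    out_dir: str = "results/run"
    seed: int = 0
    stages: tuple[str, ...] = ("simulate", "assign", "stats", "transport")
    simulate: bool = True
    # non-simulation input paths
    reads_fasta: str | None = None
    db_fasta: str | None = None
    db_meta: str | None = None
    collections_table: str | None = None
    temps_table: str | None = None
    field_path: str | None = None
    # simulation parameters
    n_reads: int = 300
    seq: synthetic_data.SeqSimParams = field(default_factory=synthetic_data.SeqSimParams)
    fieldsim: synthetic_data.FieldSimParams = field(
        default_factory=lambda: synthetic_data.FieldSimParams(n_hours=120)
    )
    collections: synthetic_data.CollectionSimParams = field(
        default_factory=synthetic_data.CollectionSimParams
    )
    # transport settings
    epsilon: float = 5.0
    release_rate: int = 50
    hindcast_days: float = 3.0
    forecast_days: float = 0.0  # 0 disables the forecast stage
    source: tuple[float, float] | None = None
    # assignment thresholds
    thresholds: barcode_id.Thresholds = field(default_factory=barcode_id.Thresholds)


def validate_config(config: RunConfig) -> list[str]:
    """Return a list of problems; empty iff the config is runnable."""
    problems = []
    if config.epsilon < 0:
        problems.append("epsilon: must be >= 0")
    if config.release_rate < 1:
        problems.append("release_rate: must be >= 1")
    if config.n_reads < 1:
        problems.append("n_reads: must be >= 1")
    if config.hindcast_days <= 0:
        problems.append("hindcast_days: must be positive")
    unknown = set(config.stages) - {"simulate", "assign", "stats", "transport"}
    if unknown:
        problems.append(f"stages: unknown stage(s) {sorted(unknown)}")
    if not config.simulate:
        for name in ("reads_fasta", "db_fasta", "db_meta", "collections_table", "field_path"):
            p = getattr(config, name)
            if "assign" in config.stages and name in ("reads_fasta", "db_fasta", "db_meta"):
                if p is None or not Path(p).exists():
                    problems.append(f"{name}: missing input path")
            if "stats" in config.stages and name == "collections_table":
                if p is None or not Path(p).exists():
                    problems.append(f"{name}: missing input path")
            if "transport" in config.stages and name == "field_path":
                if p is None or not Path(p).exists():
                    problems.append(f"{name}: missing input path")
    if "transport" in config.stages and config.simulate:
        span_h = config.fieldsim.n_hours
        needed = config.hindcast_days * 24 + config.forecast_days * 24
        if needed > span_h:
            problems.append(
                "hindcast/forecast window: exceeds the simulated field span "
                f"({needed:.0f} h needed, {span_h} h available)"
            )
    return problems


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()[:16]


def run_pipeline(config: RunConfig, log=lambda msg: print(msg, file=sys.stderr)) -> dict:
    """Execute the configured stages in dependency order; returns the manifest."""
    problems = validate_config(config)
    if problems:
        raise ValueError("invalid config: " + "; ".join(problems))
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "eggshed_version": __version__,
        "seed": config.seed,
        "seed_offsets": SEED_OFFSETS,
        "stages": list(config.stages),
        "outputs": {},
        "inputs": {},
    }

    db = truth = reads = read_truth = events = temps = fieldobj = None

    if "simulate" in config.stages and config.simulate:
        log("[simulate] generating reference DB, reads, collections, current field")
        seq_params = dataclasses.replace(config.seq, seed=config.seed + SEED_OFFSETS["sequences"])
        db, truth = synthetic_data.gen_reference_db(seq_params)
        reads, read_truth = synthetic_data.gen_egg_reads(
            db,
            truth,
            n_reads=config.n_reads,
            error_rate=seq_params.read_error_rate,
            truncation_range=seq_params.truncation_range,
            seed=config.seed + SEED_OFFSETS["reads"],
        )
        coll_params = dataclasses.replace(
            config.collections, seed=config.seed + SEED_OFFSETS["collections"]
        )
        events, temps = synthetic_data.gen_collections(coll_params)
        field_params = dataclasses.replace(
            config.fieldsim, seed=config.seed + SEED_OFFSETS["field"]
        )
        fieldobj = synthetic_data.gen_current_field(field_params)

        io_formats.write_reference_db(db, out / "refs.fasta", out / "refs.tsv")
        io_formats.write_fasta([(r.read_id, r.sequence) for r in reads], out / "reads.fasta")
        read_truth.to_csv(out / "reads_truth.tsv", sep="\t", index=False)
        truth.to_csv(out / "diagnostics_truth.tsv", sep="\t", index=False)
        io_formats.write_collections(events, out / "collections.tsv")
        io_formats.write_temperature_series(temps, out / "temps.tsv")
        io_formats.write_current_field(fieldobj, out / "field.nc")
        for name in (
            "refs.fasta", "refs.tsv", "reads.fasta", "reads_truth.tsv",
            "diagnostics_truth.tsv", "collections.tsv", "temps.tsv", "field.nc",
        ):
            manifest["outputs"][name] = str(out / name)

    if not config.simulate:
        if "assign" in config.stages:
            db = io_formats.read_reference_db(config.db_fasta, config.db_meta)
            raw = io_formats.read_fasta(config.reads_fasta)
            reads = [
                io_formats.EggRead(rid, "unknown", io_formats.Locus.COI, seq)
                for rid, seq in raw
            ]
            manifest["inputs"]["db_fasta"] = _digest(Path(config.db_fasta))
            manifest["inputs"]["reads_fasta"] = _digest(Path(config.reads_fasta))
        if "stats" in config.stages:
            events = io_formats.read_collections(config.collections_table)
            if config.temps_table:
                temps = io_formats.read_temperature_series(config.temps_table)
        if "transport" in config.stages:
            fieldobj = io_formats.read_current_field(config.field_path)

    if "assign" in config.stages:
        log("[assign] assigning reads to species")
        diagnostics = _diagnostic_sets(db)
        assignments = barcode_id.assign_all(reads, db, diagnostics, config.thresholds)
        table = barcode_id.assignments_table(assignments)
        table.to_csv(out / "assignments.tsv", sep="\t", index=False)
        manifest["outputs"]["assignments.tsv"] = str(out / "assignments.tsv")
        manifest["assigned_fraction"] = float(
            (table["status"] == "assigned").mean()
        )

    if "stats" in config.stages:
        log("[stats] phenology and community statistics")
        report_dir = out / "report"
        report_dir.mkdir(exist_ok=True)
        sw = community_stats.sliding_window_mean(events)
        sw.rename_axis("window_center").reset_index().to_csv(
            report_dir / "sliding_window.tsv", sep="\t", index=False
        )
        tests: dict = {}
        try:
            tests["temperature_split"] = community_stats.temperature_split_test(events)
        except ValueError as e:
            tests["temperature_split"] = {"error": str(e)}
        try:
            anova = community_stats.seasonal_anova(events)
            tests["seasonal_anova"] = {
                k: v for k, v in anova.items() if k != "tukey"
            }
            if anova["tukey"] is not None:
                anova["tukey"].to_csv(report_dir / "tukey.tsv", sep="\t", index=False)
        except ValueError as e:
            tests["seasonal_anova"] = {"error": str(e)}
        mm = community_stats.monthly_mean_matrix(events).log1p()
        D = community_stats.bray_curtis(mm)
        pd.DataFrame(D, index=mm.data.index, columns=mm.data.index).to_csv(
            report_dir / "bray_curtis.tsv", sep="\t"
        )
        month_labels = [lab.split("-")[1] for lab in mm.data.index]
        if len(set(month_labels)) >= 2 and min(
            pd.Series(month_labels).value_counts()
        ) >= 2:
            f, p = community_stats.permanova(
                D, month_labels, n_perm=999, seed=config.seed + 17
            )
            tests["permanova_months"] = {"pseudo_F": f, "p": p}
        coords, stress, conv = community_stats.nmds(D, seed=config.seed + 23)
        pd.DataFrame(coords, index=mm.data.index, columns=["nmds1", "nmds2"]).to_csv(
            report_dir / "nmds.tsv", sep="\t"
        )
        tests["nmds_stress"] = stress
        presence = community_stats.monthly_presence(events)
        presence.bins.map(lambda b: b.value).to_csv(
            report_dir / "presence_bins.tsv", sep="\t"
        )
        with open(report_dir / "tests.json", "w") as fh:
            json.dump(tests, fh, indent=2, default=float)
        manifest["outputs"]["report"] = str(report_dir)

    if "transport" in config.stages:
        log("[transport] hindcast/forecast exposure kernels")
        source = config.source or (
            float(fieldobj.x[0] + fieldobj.dx), float(np.mean(fieldobj.y))
        )
        params = transport.TransportParams(
            source=source,
            epsilon=config.epsilon,
            release_rate=config.release_rate,
            seed=config.seed + SEED_OFFSETS["transport"],
        )
        t_collection = pd.Timestamp(fieldobj.times[0]) + pd.Timedelta(
            hours=config.hindcast_days * 24
        )
        kernel = transport.hindcast_spawning(
            fieldobj, t_collection, source, params, days=config.hindcast_days
        )
        io_formats.write_kernel(kernel, out / "kernel_bit.nc")
        manifest["outputs"]["kernel_bit.nc"] = str(out / "kernel_bit.nc")
        if config.forecast_days > 0:
            kernel_fit = transport.forecast_larvae(
                fieldobj, t_collection, source, params, days=config.forecast_days
            )
            io_formats.write_kernel(kernel_fit, out / "kernel_fit.nc")
            manifest["outputs"]["kernel_fit.nc"] = str(out / "kernel_fit.nc")

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    manifest["manifest_path"] = str(out / "manifest.json")
    return manifest


def _diagnostic_sets(db) -> list[barcode_id.DiagnosticSet]:
    """Derive diagnostic sets for every highly similar congener pair in a DB."""
    import itertools as it

    sets = []
    by_species: dict[str, list[str]] = {}
    for r in db:
        by_species.setdefault(r.species, []).append(r.sequence)
    for (sa, seqs_a), (sb, seqs_b) in it.combinations(sorted(by_species.items()), 2):
        ident, _ = barcode_id.pairwise_identity(seqs_a[0], seqs_b[0])
        if ident >= 0.99:
            ds = barcode_id.find_diagnostic_sites(seqs_a, seqs_b, (sa, sb))
            if ds is not None:
                sets.append(ds)
    return sets


def load_config(path: str | Path) -> RunConfig:
    """Load a flat YAML config; nested parameter blocks map to dataclasses."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    kwargs = dict(raw)
    if "seq" in kwargs:
        kwargs["seq"] = synthetic_data.SeqSimParams(**kwargs["seq"])
    if "fieldsim" in kwargs:
        kwargs["fieldsim"] = synthetic_data.FieldSimParams(**kwargs["fieldsim"])
    if "collections" in kwargs:
        coll = dict(kwargs["collections"])
        if "species_profiles" in coll:
            coll["species_profiles"] = tuple(
                synthetic_data.SpeciesProfile(**p) for p in coll["species_profiles"]
            )
        kwargs["collections"] = synthetic_data.CollectionSimParams(**coll)
    if "thresholds" in kwargs:
        kwargs["thresholds"] = barcode_id.Thresholds(**kwargs["thresholds"])
    if "stages" in kwargs:
        kwargs["stages"] = tuple(kwargs["stages"])
    if "source" in kwargs and kwargs["source"] is not None:
        kwargs["source"] = tuple(kwargs["source"])
    return RunConfig(**kwargs)
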