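"""End-to-end pipeline stages behind the CLI.

Each stage reads files, writes files, and records a manifest of every
parameter that affected its output, so a run is reproducible from its
outputs alone: (config, seed) → byte-identical tables.
"""

from __future__ import annotations

import hashlib
import json
import logging
import os
from dataclasses import dataclass, field, asdict
from typing import Any, Mapping

import yaml

from . import discriminate, genotyper, panel as panel_mod, synthetic, variant_io
from .errors import ConfigError, ConsistencyError

log = logging.getLogger("clonemarker")


def _manifest(outdir: str, stage: str, params: Mapping[str, Any]) -> None:
    canon = json.dumps(params, sort_keys=True, default=str)
    payload = {
        "stage": stage,
        "parameters": params,
        "manifest_sha256": hashlib.sha256(canon.encode()).hexdigest(),
    }
    with open(os.path.join(outdir, f"manifest_{stage}.json"), "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")


@dataclass
class PipelineConfig:
    """Flat key-value configuration shared by all stages.

    Paths are validated lazily per stage: a discovery run does not require a
    counts table and vice versa.
    """

    outdir: str = "out"
    seed: int = 0
    # discovery inputs
    reference: str | None = None
    vcf: str | None = None  # joint multi-sample VCF
    vcfs: list[str] = field(default_factory=list)  # or per-sample VCFs
    design_table: str | None = None
    quality_threshold: float = 100.0
    strict_missing: bool = False
    absent_as: str = "missing"
    window: int = 100_000
    cultivar: str = "NA"
    # marker constraints
    min_amplicon_len: int = 141
    max_amplicon_len: int = 487
    target_amplicon_len: int = 200
    min_edge_distance: int = 30
    # identification inputs
    panel: str | None = None
    counts: str | None = None
    min_depth: int = 20
    min_minor_fraction: float = 0.20
    max_minor_for_hom: float = 0.05
    # simulation (CohortDesign mirror)
    n_clones: int = 4
    replicates: int = 3
    clone_specific: int = 1000
    genome_length: int = 1_000_000
    n_contigs: int = 2
    gc_fraction: float = 0.345
    background_het_rate: float = 0.005
    indel_fraction: float = 0.258
    tstv_ratio: float = 2.1
    het_fraction_specific: float = 0.94
    dropout_rate: float = 0.05
    false_positive_rate: float = 1e-5

    @classmethod
    def from_file(cls, path: str, **overrides) -> "PipelineConfig":
        if not os.path.exists(path):
            raise ConfigError(f"config file not found: {path}")
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a flat key-value mapping")
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"{path}: unknown config keys {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ConfigError(str(exc)) from exc

    def require(self, *names: str) -> None:
        for name in names:
            value = getattr(self, name)
            if value in (None, [], ""):
                raise ConfigError(f"config key {name!r} is required for this stage")
            if name in ("reference", "vcf", "design_table", "panel", "counts"):
                if not os.path.exists(value):
                    raise ConfigError(f"{name}: path does not exist: {value}")
            if name == "vcfs":
                for p in value:
                    if not os.path.exists(p):
                        raise ConfigError(f"vcfs: path does not exist: {p}")

    def marker_constraints(self) -> panel_mod.MarkerConstraints:
        return panel_mod.MarkerConstraints(
            min_len=self.min_amplicon_len,
            max_len=self.max_amplicon_len,
            target_len=self.target_amplicon_len,
            min_edge_distance=self.min_edge_distance,
        )

    def genotype_thresholds(self) -> genotyper.GenotypeThresholds:
        return genotyper.GenotypeThresholds(
            min_depth=self.min_depth,
            min_minor_fraction=self.min_minor_fraction,
            max_minor_for_hom=self.max_minor_for_hom,
        )


# ---------------------------------------------------------------------------
# Stages


def run_simulate(config: PipelineConfig) -> synthetic.TruthTable:
    """Generate a reference, a clonal cohort and noisy calls under ``outdir``."""
    os.makedirs(config.outdir, exist_ok=True)
    design = synthetic.make_design(
        n_clones=config.n_clones,
        replicates=config.replicates,
        clone_specific=config.clone_specific,
        genome_length=config.genome_length,
        n_contigs=config.n_contigs,
        gc_fraction=config.gc_fraction,
        background_het_rate=config.background_het_rate,
        indel_fraction=config.indel_fraction,
        tstv_ratio=config.tstv_ratio,
        het_fraction_specific=config.het_fraction_specific,
        dropout_rate=config.dropout_rate,
        false_positive_rate=config.false_positive_rate,
        seed=config.seed,
    )
    reference = synthetic.generate_reference(
        design.genome_length, design.n_contigs, design.gc_fraction, seed=config.seed
    )
    truth = synthetic.plant_cohort(design, reference)
    samples, records = synthetic.simulate_calls(truth, design)
    out = config.outdir
    synthetic.write_fasta(reference, os.path.join(out, "reference.fasta"))
    truth.write_tsv(os.path.join(out, "truth.tsv"))
    synthetic.write_calls_vcf(os.path.join(out, "calls.vcf"), truth, samples, records)
    s2c = design.sample_to_clone()
    with open(os.path.join(out, "design_table.tsv"), "w") as fh:
        fh.write("sample_id\tclone_id\tcultivar\n")
        for s in samples:
            fh.write(f"{s}\t{s2c[s]}\t{config.cultivar}\n")
    _manifest(out, "simulate", design.to_dict())
    log.info("simulated %d variants over %d samples", len(truth.records), len(samples))
    return truth


def run_discovery(config: PipelineConfig) -> dict[str, Any]:
    """Quality filter → genotype matrix → exclusivity → summaries → candidates.

    Writes per-clone exclusive VCF subsets, summary and window-density
    tables, PCA coordinates, candidate marker table/BED, and a manifest.
    """
    config.require("design_table")
    if not config.vcf and not config.vcfs:
        raise ConfigError("discovery needs 'vcf' (joint) or 'vcfs' (per sample)")
    config.require("vcf" if config.vcf else "vcfs")
    os.makedirs(config.outdir, exist_ok=True)

    design = variant_io.read_design_table(config.design_table)
    s2c = dict(zip(design["sample_id"], design["clone_id"]))

    paths = [config.vcf] if config.vcf else list(config.vcfs)
    call_sets = []
    for p in paths:
        samples, records = variant_io.read_vcf(p)
        records = variant_io.quality_filter(records, config.quality_threshold)
        samples = [s for s in samples if s in s2c]  # excluded samples dropped
        call_sets.append((samples, records))
    matrix = variant_io.build_matrix(call_sets, s2c, absent_as=config.absent_as)

    sets = discriminate.clone_exclusive(matrix, strict_missing=config.strict_missing)
    all_records = [r for _, recs in call_sets for r in recs]
    by_key = {r.key: r for r in all_records}

    reference = (
        synthetic.read_fasta(config.reference) if config.reference else None
    )
    genome_length = (
        sum(len(s) for s in reference.values())
        if reference
        else max((r.pos for r in all_records), default=1)
    )
    stats = discriminate.summarize(
        all_records, genome_length=genome_length, window=config.window
    )
    consistent_union = sorted(set().union(*sets.consistent.values()) or set())
    coords, ratios = discriminate.pca_clones(
        matrix, sites=consistent_union or None
    )

    out = config.outdir
    for clone, keys in sorted(sets.exclusive.items()):
        recs = [by_key[k] for k in sorted(keys) if k in by_key]
        variant_io.write_vcf(
            os.path.join(out, f"exclusive_{clone}.vcf"),
            matrix.clone_samples(clone),
            recs,
            contig_lengths=(
                {c: len(s) for c, s in reference.items()} if reference else None
            ),
        )
    summary_rows = [
        ("n_snv", stats.n_snv),
        ("n_indel", stats.n_indel),
        ("het_fraction_pct", stats.het_fraction_pct),
        ("snv_per_kbp", stats.snv_per_kbp),
        ("indel_per_kbp", stats.indel_per_kbp),
        ("tstv_ratio", stats.tstv_ratio),
    ] + [
        (f"n_exclusive_{clone}", len(keys))
        for clone, keys in sorted(sets.exclusive.items())
    ]
    with open(os.path.join(out, "summary.tsv"), "w") as fh:
        fh.write("statistic\tvalue\n")
        for k, v in summary_rows:
            fh.write(f"{k}\t{'' if v is None else v}\n")
    stats.window_densities.to_csv(
        os.path.join(out, "window_density.tsv"), sep="\t", index=False
    )
    coords.assign(clone=[s2c[s] for s in coords.index]).to_csv(
        os.path.join(out, "pca.tsv"), sep="\t", index_label="sample_id"
    )

    markers: list[panel_mod.MarkerDefinition] = []
    skipped: list = []
    if reference is not None:
        markers, skipped = panel_mod.select_candidates(
            sets,
            matrix,
            all_records,
            reference,
            constraints=config.marker_constraints(),
            cultivar=config.cultivar,
        )
        panel_mod.write_marker_table(markers, os.path.join(out, "candidates.tsv"))
        panel_mod.write_candidates_bed(markers, os.path.join(out, "candidates.bed"))
        with open(os.path.join(out, "candidates_skipped.tsv"), "w") as fh:
            fh.write("contig\tpos\tref\talt\treason\n")
            for key, reason in skipped:
                fh.write("\t".join(map(str, key)) + f"\t{reason}\n")

    _manifest(
        out,
        "discover",
        {
            "vcf": paths,
            "design_table": config.design_table,
            "reference": config.reference,
            "quality_threshold": config.quality_threshold,
            "strict_missing": config.strict_missing,
            "absent_as": config.absent_as,
            "window": config.window,
            "constraints": asdict(config.marker_constraints()),
            "seed": config.seed,
        },
    )
    log.info(
        "discovery: %d sites, exclusive per clone: %s, %d candidate markers",
        len(matrix.sites),
        {c: len(k) for c, k in sorted(sets.exclusive.items())},
        len(markers),
    )
    return {
        "matrix": matrix,
        "sets": sets,
        "stats": stats,
        "pca_coords": coords,
        "pca_ratios": ratios,
        "markers": markers,
        "skipped": skipped,
    }


def run_identification(config: PipelineConfig) -> list[genotyper.IdentificationResult]:
    """Panel + counts table → per-sample clone identification report."""
    config.require("panel", "counts")
    os.makedirs(config.outdir, exist_ok=True)
    markers = panel_mod.load_marker_table(config.panel)
    counts = genotyper.read_counts_table(config.counts)
    known = {m.marker_id for m in markers}
    for sample, cs in counts.items():
        for c in cs:
            if c.marker_id not in known:
                raise ConsistencyError(
                    f"sample {sample}: unknown marker {c.marker_id!r} in counts"
                )
    thresholds = config.genotype_thresholds()
    results = [
        genotyper.identify_clone(sample, cs, markers, thresholds)
        for sample, cs in counts.items()
    ]
    out = config.outdir
    genotyper.write_report(
        results,
        os.path.join(out, "report.tsv"),
        os.path.join(out, "report.json"),
    )
    tally = {"assigned": 0, "unassigned": 0, "ambiguous": 0}
    for r in results:
        if r.assigned_clone in ("unassigned", "ambiguous"):
            tally[r.assigned_clone] += 1
        else:
            tally["assigned"] += 1
    _manifest(
        out,
        "identify",
        {
            "panel": config.panel,
            "counts": config.counts,
            "thresholds": asdict(thresholds),
            "seed": config.seed,
        },
    )
    log.info("identification: %s", tally)
    return results
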