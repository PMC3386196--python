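"""Full-analysis orchestration: QC -> distances -> OT -> entities -> ranks.

The pipeline mirrors the standard integrated-barcoding workflow: screen the
alignment, build a labelled *reference* dataset (minus configured species
exclusions), optimise the identification threshold on it, identify unknown
queries against it, then rebuild the *comprehensive* dataset, partition it
into molecular entities at the OT, detect divergent intraspecific lineages
and assign taxonomic ranks.  Every stochastic stage consumes an explicit
seed from the config, and the run log records every parameter in effect, so
two runs with equal config produce identical outputs (timestamps aside).
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
import yaml

from . import __version__
from .classify import (
    AssignmentResult,
    TaxonomicEntity,
    assign_ranks,
    assignment_report,
    entity_report,
    identify_queries,
    partition_entities,
)
from .distances import DistanceMatrix, distance_matrix, divergence_summary
from .seq_qc import (
    UNKNOWN,
    BarcodeAlignment,
    base_composition,
    merge_metadata,
    numt_screen,
    read_fasta,
    read_metadata,
    trim_to_common_window,
    trim_to_shortest,
)
from .threshold import (
    OTResult,
    ThresholdScan,
    error_curve_report,
    optimum_threshold,
    threshold_scan,
)
from .trees import LineageSet, SupportTree, bootstrap_support, detect_lineages

logger = logging.getLogger("barcodetax")


@dataclass(frozen=True)
class PipelineConfig:
    fasta: str
    metadata: str | None = None
    output_dir: str = "barcodetax_out"
    trim_start: int | None = None          # None -> trim to shortest
    trim_end: int | None = None
    genetic_code: int = 2                  # vertebrate mitochondrial
    grid_step_pct: float = 0.1
    tie_rule: str = "midpoint"
    ucs_low_pct: float = 2.0
    cryptic_pct: float = 5.0
    min_support: float = 95.0
    bootstrap_replicates: int = 1000
    seed: int = 0
    exclusions: tuple[str, ...] = ()       # species kept out of the OT reference
    two_pass_unknowns: bool = True         # re-enter assigned queries
    fail_on_qc: bool = True
    run_tree: bool = True

    def __post_init__(self) -> None:
        if not self.ucs_low_pct < self.cryptic_pct:
            raise ValueError("need ucs_low_pct < cryptic_pct")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        """Load a flat key:value YAML config; keyword overrides win."""
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "exclusions" in raw and isinstance(raw["exclusions"], list):
            raw["exclusions"] = tuple(raw["exclusions"])
        raw.update(overrides)
        return cls(**raw)


@dataclass
class PipelineResult:
    config: PipelineConfig
    alignment: BarcodeAlignment
    qc_frame_used: int
    base_frequencies: dict[str, float]
    matrix: DistanceMatrix
    scan: ThresholdScan
    ot: OTResult
    summary: object
    assignments: list[AssignmentResult]
    entities: list[TaxonomicEntity]
    lineages: LineageSet
    tree: SupportTree | None

    def rank_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for e in self.entities:
            counts[e.rank] = counts.get(e.rank, 0) + 1
        return counts


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = [
        f"barcodetax {__version__}",
        "parameters:",
    ]
    for f in dataclasses.fields(config):
        log_lines.append(f"  {f.name} = {getattr(config, f.name)!r}")

    def stage(name):
        logger.info("stage: %s", name)
        log_lines.append(f"stage: {name}")

    try:
        stage("qc")
        records = read_fasta(config.fasta)
        if config.metadata:
            records = merge_metadata(records, read_metadata(config.metadata))
        if config.trim_start is not None and config.trim_end is not None:
            alignment = trim_to_common_window(
                records, config.trim_start, config.trim_end
            )
        else:
            alignment = trim_to_shortest(records)
        qc = numt_screen(alignment, config.genetic_code)
        qc.to_tsv(outdir / "qc_report.tsv")
        if not qc.all_passed:
            msg = f"QC failures (NUMT suspects): {qc.failed_ids()}"
            if config.fail_on_qc:
                raise ValueError(msg)
            logger.warning(msg)
            keep = {r.sample_id for r in qc.records if r.passed}
            alignment = BarcodeAlignment(
                tuple(r for r in alignment.records if r.sample_id in keep)
            )
        freqs = base_composition(alignment)
        log_lines.append(f"alignment: {len(alignment)} x {alignment.length}")
        log_lines.append(f"frame_used: {qc.frame_used}")
        log_lines.append(
            "base_frequencies: "
            + " ".join(f"{b}={freqs[b]:.4f}" for b in "ACGT")
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("qc", exc) from exc

    try:
        stage("reference_dataset")
        excluded = set(config.exclusions)
        reference_records = tuple(
            r for r in alignment.records
            if r.species_label != UNKNOWN and r.species_label not in excluded
        )
        query_records = tuple(
            r for r in alignment.records if r.species_label == UNKNOWN
        )
        reference = BarcodeAlignment(reference_records)
        log_lines.append(
            f"reference: {len(reference)} labelled samples "
            f"({len(query_records)} unknown queries, "
            f"{len(alignment) - len(reference) - len(query_records)} excluded)"
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("reference_dataset", exc) from exc

    try:
        stage("optimum_threshold")
        ref_matrix = distance_matrix(reference)
        scan = threshold_scan(
            ref_matrix, reference.species_labels, step_pct=config.grid_step_pct
        )
        ot = optimum_threshold(scan, tie_rule=config.tie_rule)
        error_curve_report(scan, outdir / "threshold_scan.tsv")
        log_lines.append(
            f"OT = {ot.ot_pct:.2f}%  MCE = {ot.mce_pct:.4f}%  "
            f"optimal interval = {ot.optimal_interval_pct}"
        )
    except Exception as exc:  # noqa: BLE001
        raise StageError("optimum_threshold", exc) from exc

    try:
        stage("identify_unknowns")
        assignments: list[AssignmentResult] = []
        if query_records:
            queries = BarcodeAlignment(query_records)
            assignments = identify_queries(queries, reference, ot.ot_pct)
            assignment_report(assignments, outdir / "assignments.tsv")
    except Exception as exc:  # noqa: BLE001
        raise StageError("identify_unknowns", exc) from exc

    try:
        stage("comprehensive_dataset")
        assigned_label = {
            a.sample_id: a.assigned
            for a in assignments
            if a.assigned not in ("UNASSIGNED", "AMBIGUOUS")
        }
        comprehensive_records = []
        for r in alignment.records:
            if r.species_label == UNKNOWN and config.two_pass_unknowns:
                label = assigned_label.get(r.sample_id)
                if label is not None:
                    comprehensive_records.append(
                        dataclasses.replace(r, species_label=label)
                    )
                # unassigned/ambiguous queries stay out of the partition
            elif r.species_label != UNKNOWN:
                comprehensive_records.append(r)
        comprehensive = BarcodeAlignment(tuple(comprehensive_records))
        matrix = distance_matrix(comprehensive)
        matrix.to_tsv(outdir / "distance_matrix.tsv")
        summary = divergence_summary(matrix, comprehensive.species_labels)
    except Exception as exc:  # noqa: BLE001
        raise StageError("comprehensive_dataset", exc) from exc

    tree: SupportTree | None = None
    if config.run_tree and len(comprehensive) >= 3:
        try:
            stage("tree")
            tree = bootstrap_support(
                comprehensive,
                replicates=config.bootstrap_replicates,
                seed=config.seed,
            )
            (outdir / "tree.nwk").write_text(tree.to_newick() + "\n")
        except Exception as exc:  # noqa: BLE001
            raise StageError("tree", exc) from exc

    try:
        stage("lineages_and_ranks")
        lineages = detect_lineages(
            matrix,
            comprehensive.species_labels,
            comprehensive.locality_groups,
            min_divergence_pct=config.ucs_low_pct,
            support_tree=tree,
            min_support=config.min_support,
        )
        partition = partition_entities(matrix, ot.ot_pct)
        entities = assign_ranks(
            partition,
            matrix,
            comprehensive.species_labels,
            comprehensive.locality_groups,
            ot.ot_pct,
            ucs_low_pct=config.ucs_low_pct,
            cryptic_pct=config.cryptic_pct,
            lineages=lineages,
        )
        entity_report(entities, outdir / "entities.tsv")
        counts: dict[str, int] = {}
        for e in entities:
            counts[e.rank] = counts.get(e.rank, 0) + 1
        log_lines.append(f"entities: {len(entities)}  ranks: {counts}")
    except Exception as exc:  # noqa: BLE001
        raise StageError("lineages_and_ranks", exc) from exc

    (outdir / "run_log.txt").write_text("\n".join(log_lines) + "\n")
    return PipelineResult(
        config=config,
        alignment=alignment,
        qc_frame_used=qc.frame_used,
        base_frequencies=freqs,
        matrix=matrix,
        scan=scan,
        ot=ot,
        summary=summary,
        assignments=assignments,
        entities=entities,
        lineages=lineages,
        tree=tree,
    )
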