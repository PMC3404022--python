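"""Result aggregation and end-to-end pipeline orchestration.

`run_pipeline` chains read -> screen -> cascade -> novelty -> blocks -> tree
-> reconcile -> place -> summarize, writing every artifact plus a run log.
All non-log outputs are byte-deterministic for fixed inputs.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd
import yaml

from . import __version__
from .core import (
    ConfigError,
    GenotypeMatrix,
    PipelineError,
    Variant,
    natural_key,
)
from .filters import (
    FilterOutcome,
    FilterReport,
    ScreenResult,
    annotate_novelty,
    orient_by_controls,
    run_filters,
    screen_samples,
)
from .tree import (
    CladeTree,
    PlacementRecord,
    build_tree,
    clade_sample_sets,
    equivalence_blocks,
    export_newick,
    place_samples,
    possibly_equivalent_pairs,
    read_scaffold,
    reconcile_scaffold,
)
from .variant_io import (
    read_known_list,
    read_sample_metadata,
    read_vcf,
    write_variant_table,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "PipelineResult",
    "format_percent",
    "summarize",
    "recovery_metrics",
    "run_pipeline",
]


def format_percent(count: int, total: int) -> str:
    """One-decimal percentage, round half away from zero; em dash when the
    denominator is empty."""
    if total == 0:
        return "—"
    pct = Decimal(100 * count) / Decimal(total)
    return str(pct.quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


def summarize(
    tree: CladeTree,
    placements: dict[str, PlacementRecord],
    sample_meta: dict[str, str],
    variants_by_key: Optional[dict[tuple[str, int], Variant]] = None,
) -> pd.DataFrame:
    """One row per tree node: attachment and subtree counts, per-population
    subtree composition, and known/novel variant counts for the node's block."""
    known_placed = set(placements)
    unknown = known_placed - set(tree.case_samples)
    if unknown:
        raise ConfigError(f"placements contain unknown samples: {sorted(unknown)}")

    pops = sorted({sample_meta.get(s, "NA") for s in tree.case_samples})
    rows = []
    for node in tree.nodes:
        subtree = node.subtree_samples()
        row: dict[str, object] = {
            "label": node.label,
            "n_attached": len(node.attached),
            "n_subtree": len(subtree),
        }
        for pop in pops:
            n = sum(1 for s in subtree if sample_meta.get(s, "NA") == pop)
            row[f"pop_{pop}_n"] = n
            row[f"pop_{pop}_pct"] = format_percent(n, len(subtree))
        if node.block is not None:
            row["n_known"] = sum(1 for v in node.block.variants if v.known)
            row["n_novel"] = sum(1 for v in node.block.variants if not v.known)
        else:
            row["n_known"] = 0
            row["n_novel"] = 0
        rows.append(row)
    return pd.DataFrame(rows)


def recovery_metrics(truth, report: FilterReport, tree: CladeTree) -> dict:
    """Degradation metrics against simulated ground truth.

    ``true_branch_assignment_fraction`` is the fraction of simulated branch
    variants that were retained and whose tree node recovers the true
    carrier set exactly (restricted to screened case samples, so the metric
    measures assignment rather than anchor-screening loss);
    ``control_contamination`` counts branch variants lost to a
    (noise-induced) derived control call.
    """
    node_of_key = {}
    for node in tree.block_nodes:
        for v in node.block.variants:
            node_of_key[v.key] = node
    case_set = set(tree.case_samples)

    n_branch = 0
    n_correct = 0
    n_control_contaminated = 0
    for branch, keys in truth.branch_variants.items():
        true_set = truth.tip_samples(branch) & case_set
        for key in keys:
            n_branch += 1
            rec = report.record(key)
            if rec.outcome == FilterOutcome.FAIL_CONTROL_DERIVED:
                n_control_contaminated += 1
            if rec.outcome != FilterOutcome.RETAINED:
                continue
            node = node_of_key.get(key)
            if node is not None and set(node.effective_set) == true_set:
                n_correct += 1
    return {
        "n_branch_variants": n_branch,
        "n_assigned_true_branch": n_correct,
        "true_branch_assignment_fraction": (
            n_correct / n_branch if n_branch else float("nan")
        ),
        "control_contamination": n_control_contaminated,
    }


@dataclass(frozen=True)
class PipelineConfig:
    """Flat run configuration (mirrors the YAML file)."""

    vcf: str
    anchor: str
    samples: Optional[str] = None
    known_variants: Optional[str] = None
    scaffold: Optional[str] = None
    max_ambiguous: int = 0
    ancestral_policy: str = "info-anc"
    ambiguity_threshold_reads: int = 2

    @classmethod
    def from_yaml(cls, path: Path | str) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**data)


@dataclass
class PipelineResult:
    matrix: GenotypeMatrix
    screen: ScreenResult
    report: FilterReport
    tree: CladeTree
    placements: dict[str, PlacementRecord]
    summary: pd.DataFrame
    manifest: dict


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except PipelineError as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
            except OSError as exc:
                raise PipelineError(f"stage {name}: {exc}") from exc
        return wrapper
    return deco


def _write_screen(screen: ScreenResult, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tclass\n")
        for s in sorted(screen.cases):
            fh.write(f"{s}\tcase\n")
        for s in sorted(screen.controls):
            fh.write(f"{s}\tcontrol\n")
        for s in sorted(screen.excluded):
            fh.write(f"{s}\texcluded\n")


def _write_conflicts(report: FilterReport, path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("variant_a\tvariant_b\n")
        for a, b in report.conflict_edges:
            fh.write(f"{a}\t{b}\n")


def _write_blocks(tree: CladeTree, flags: list[tuple[str, str]], path: Path) -> None:
    flagged: dict[str, list[str]] = {}
    for a, b in flags:
        flagged.setdefault(a, []).append(b)
        flagged.setdefault(b, []).append(a)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(
            "label\tparent\tn_variants\tn_carriers\tcarriers\t"
            "possibly_equivalent_with\n"
        )
        for node in tree.block_nodes:
            parent = node.parent.label if node.parent is not None else ""
            fh.write(
                "\t".join(
                    [
                        node.label,
                        parent,
                        str(len(node.block.variants)),
                        str(len(node.block.derived_cases)),
                        ",".join(sorted(node.block.derived_cases)),
                        "; ".join(sorted(flagged.get(node.label, []))),
                    ]
                )
                + "\n"
            )


def _write_placements(placements: dict[str, PlacementRecord], path: Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("sample\tnode\tpath\tdiagnostics\n")
        for s in sorted(placements):
            rec = placements[s]
            fh.write(
                f"{s}\t{rec.node_label}\t{' > '.join(rec.path)}\t"
                f"{'; '.join(rec.diagnostics)}\n"
            )


def run_pipeline(
    config: PipelineConfig, out_dir: Path | str, truth=None
) -> PipelineResult:
    """Execute the whole pipeline and write all artifacts to ``out_dir``.

    When simulated ``truth`` is supplied, recovery metrics are added to the
    manifest. Raises :class:`PipelineError` with a stage-named message on
    failure; the CLI converts that into a nonzero exit status.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root_logger = logging.getLogger("yphylo")
    root_logger.addHandler(handler)
    root_logger.setLevel(logging.INFO)

    try:
        logger.info("yphylo %s | python %s", __version__, sys.version.split()[0])
        logger.info("config: %s", dataclasses.asdict(config))

        sample_meta = (
            _stage("read")(read_sample_metadata)(config.samples)
            if config.samples
            else {}
        )
        matrix = _stage("read")(read_vcf)(
            config.vcf,
            ancestral_policy=config.ancestral_policy,
            ambiguity_threshold_reads=config.ambiguity_threshold_reads,
            sample_metadata=sample_meta,
        )
        screen = _stage("screen")(screen_samples)(matrix, config.anchor)
        if not screen.controls:
            logger.warning(
                "no control samples at anchor %s: F1 is vacuous", config.anchor
            )

        unusable: set = set()
        if config.ancestral_policy == "control-majority":
            matrix, unusable, flipped = _stage("screen")(orient_by_controls)(
                matrix, screen
            )
            logger.info(
                "control-majority orientation: flipped %d sites, %d unusable",
                len(flipped), len(unusable),
            )

        candidates = [v for v in matrix.variants if v.key != screen.anchor.key]
        if config.known_variants:
            known = _stage("novelty")(read_known_list)(config.known_variants)
            candidates = annotate_novelty(candidates, known)

        filter_report = _stage("filter")(run_filters)(
            matrix,
            screen,
            candidates=candidates,
            max_ambiguous=config.max_ambiguous,
            unusable_keys=unusable,
        )

        retained = [
            v for v in candidates if v.key in filter_report.retained_keys
        ]
        blocks = _stage("build")(equivalence_blocks)(
            matrix, retained, sorted(screen.cases)
        )
        flags = possibly_equivalent_pairs(matrix, blocks)
        tree = _stage("build")(build_tree)(blocks, sorted(screen.cases))
        tree.root_names.add(config.anchor)

        reconciliation = None
        if config.scaffold:
            scaffold = _stage("build")(read_scaffold)(config.scaffold)
            tree.root_names.add(scaffold.root)
            reconciliation = _stage("build")(reconcile_scaffold)(tree, scaffold)

        placements = _stage("place")(place_samples)(tree, matrix)
        summary = _stage("report")(summarize)(
            tree, placements, matrix.populations or sample_meta
        )

        branch_assignment = {}
        for node in tree.block_nodes:
            for v in node.block.variants:
                branch_assignment[v.key] = node.label

        paths = {
            "screen": out / "screen.tsv",
            "variant_table": out / "variant_table.tsv",
            "conflict_graph": out / "conflict_graph.tsv",
            "blocks": out / "blocks.tsv",
            "tree": out / "tree.nwk",
            "reconciliation": out / "reconciliation.tsv",
            "placements": out / "placements.tsv",
            "summary": out / "summary.tsv",
        }
        writer = _stage("write")
        writer(_write_screen)(screen, paths["screen"])
        writer(write_variant_table)(
            candidates, filter_report, paths["variant_table"], branch_assignment
        )
        writer(_write_conflicts)(filter_report, paths["conflict_graph"])
        writer(_write_blocks)(tree, flags, paths["blocks"])
        writer(export_newick)(tree, paths["tree"])
        with open(paths["reconciliation"], "w", encoding="utf-8") as fh:
            fh.write("marker\tstatus\told_parent\tnew_parent\n")
            if reconciliation is not None:
                for row in reconciliation.rows():
                    fh.write("\t".join(row) + "\n")
        writer(_write_placements)(placements, paths["placements"])
        summary.to_csv(paths["summary"], sep="\t", index=False)

        manifest = {
            "outputs": {k: str(p.name) for k, p in paths.items()},
            "n_samples": matrix.n_samples,
            "n_variants": matrix.n_variants,
            "n_cases": len(screen.cases),
            "n_controls": len(screen.controls),
            "n_excluded": len(screen.excluded),
            "outcome_counts": {
                o.name: n for o, n in filter_report.outcome_counts().items()
            },
            "n_blocks": len(blocks),
        }
        if truth is not None:
            manifest["recovery"] = recovery_metrics(truth, filter_report, tree)
        (out / "pipeline_manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        logger.info("pipeline complete: %s", manifest["outcome_counts"])
        return PipelineResult(
            matrix=matrix,
            screen=screen,
            report=filter_report,
            tree=tree,
            placements=placements,
            summary=summary,
            manifest=manifest,
        )
    finally:
        root_logger.removeHandler(handler)
        handler.close()
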