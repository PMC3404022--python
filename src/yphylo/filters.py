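"""Anchor-SNP screening and the four-stage variant filter cascade.

Cascade order is F1 (controls all ancestral) -> F2 (at least two derived
cases) -> F3 (no heterozygous-looking calls) -> F4 (pairwise rooted
compatibility), with first-fail attribution. MISSING and AMBIGUOUS calls are
never treated as evidence: F1 quantifies over observed control calls only and
F2 counts observed derived case calls only.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional, Sequence

import numpy as np

from .core import (
    CallState,
    ConfigError,
    GenotypeMatrix,
    KnownVariantList,
    Variant,
)

__all__ = [
    "FilterOutcome",
    "ScreenResult",
    "VariantRecord",
    "FilterReport",
    "screen_samples",
    "orient_by_controls",
    "filter_control_ancestral",
    "filter_non_singleton",
    "filter_ambiguous",
    "compatible",
    "filter_consistent",
    "annotate_novelty",
    "run_filters",
]


class FilterOutcome(Enum):
    RETAINED = "RETAINED"
    FAIL_CONTROL_DERIVED = "FAIL_CONTROL_DERIVED"
    FAIL_SINGLETON = "FAIL_SINGLETON"
    FAIL_AMBIGUOUS = "FAIL_AMBIGUOUS"
    FAIL_INCONSISTENT = "FAIL_INCONSISTENT"
    UNUSABLE = "UNUSABLE"


@dataclass
class ScreenResult:
    """Case/control/excluded partition of the samples at the anchor SNP."""

    anchor: Variant
    cases: frozenset[str]
    controls: frozenset[str]
    excluded: frozenset[str]

    def __post_init__(self) -> None:
        if self.cases & self.controls or self.cases & self.excluded or (
            self.controls & self.excluded
        ):
            raise ConfigError("screen partition has overlapping classes")


@dataclass
class VariantRecord:
    """Per-variant cascade outcome plus the counts that justify it."""

    key: tuple[str, int]
    outcome: FilterOutcome
    derived_cases: int = 0
    observed_controls: int = 0
    ambiguous_calls: int = 0
    conflict_partners: list[str] = field(default_factory=list)
    notes: list[str] = field(default_factory=list)


class FilterReport:
    """Outcome records for every candidate variant, in input order."""

    def __init__(self) -> None:
        self._records: dict[tuple[str, int], VariantRecord] = {}
        self.conflict_edges: list[tuple[str, str]] = []

    def add(self, record: VariantRecord) -> None:
        self._records[record.key] = record

    def record(self, key: tuple[str, int]) -> VariantRecord:
        return self._records[key]

    def __len__(self) -> int:
        return len(self._records)

    def outcome_counts(self) -> dict[FilterOutcome, int]:
        counts = {o: 0 for o in FilterOutcome}
        for rec in self._records.values():
            counts[rec.outcome] += 1
        return counts

    def keys_with(self, outcome: FilterOutcome) -> set[tuple[str, int]]:
        return {k for k, r in self._records.items() if r.outcome == outcome}

    @property
    def retained_keys(self) -> set[tuple[str, int]]:
        return self.keys_with(FilterOutcome.RETAINED)


def screen_samples(matrix: GenotypeMatrix, anchor_name: str) -> ScreenResult:
    """Partition samples by their call state at the anchor SNP.

    DERIVED -> case, ANCESTRAL -> control, MISSING/AMBIGUOUS -> excluded
    (excluded samples take no further part in filtering but are reported).
    """
    anchor = matrix.find_variant(anchor_name)
    if anchor is None:
        raise ConfigError(f"anchor variant {anchor_name!r} not found in matrix")
    col = matrix.column(anchor)
    samples = np.array(matrix.samples)
    cases = frozenset(samples[col == CallState.DERIVED])
    controls = frozenset(samples[col == CallState.ANCESTRAL])
    excluded = frozenset(samples) - cases - controls
    return ScreenResult(anchor=anchor, cases=cases, controls=controls, excluded=excluded)


def orient_by_controls(
    matrix: GenotypeMatrix, screen: ScreenResult
) -> tuple[GenotypeMatrix, set[tuple[str, int]], set[tuple[str, int]]]:
    """Re-derive ancestral orientation from the control cohort.

    For each non-anchor variant the majority observed control allele becomes
    ancestral; columns read in the opposite orientation are flipped (states
    and alleles swapped). An exact nonzero tie makes the site unusable.
    Returns (reoriented matrix, unusable keys, flipped keys).
    """
    control_idx = [matrix.sample_index(s) for s in sorted(screen.controls)]
    calls = matrix.calls.copy()
    ad = matrix.ad.copy() if matrix.ad is not None else None
    variants = list(matrix.variants)
    unusable: set[tuple[str, int]] = set()
    flipped: set[tuple[str, int]] = set()

    for j, v in enumerate(variants):
        if v.key == screen.anchor.key:
            continue
        col = matrix.calls[control_idx, j] if control_idx else np.array([], dtype=np.int8)
        n_anc = int(np.count_nonzero(col == CallState.ANCESTRAL))
        n_der = int(np.count_nonzero(col == CallState.DERIVED))
        if n_der > n_anc:
            flipped.add(v.key)
            anc_mask = matrix.calls[:, j] == CallState.ANCESTRAL
            der_mask = matrix.calls[:, j] == CallState.DERIVED
            calls[anc_mask, j] = CallState.DERIVED
            calls[der_mask, j] = CallState.ANCESTRAL
            if ad is not None:
                ad[:, j] = ad[:, j, ::-1]
            variants[j] = Variant(
                contig=v.contig,
                position=v.position,
                ancestral_allele=v.derived_allele,
                derived_allele=v.ancestral_allele,
                name=v.name,
                known=v.known,
                rs_id=v.rs_id,
            )
        elif n_der == n_anc and n_der > 0:
            unusable.add(v.key)

    out = GenotypeMatrix(
        matrix.samples, variants, calls, populations=matrix.populations, ad=ad
    )
    return out, unusable, flipped


def _class_masks(
    matrix: GenotypeMatrix, screen: ScreenResult
) -> tuple[np.ndarray, np.ndarray]:
    case_mask = np.array([s in screen.cases for s in matrix.samples])
    control_mask = np.array([s in screen.controls for s in matrix.samples])
    return case_mask, control_mask


def filter_control_ancestral(
    matrix: GenotypeMatrix, screen: ScreenResult
) -> dict[tuple[str, int], bool]:
    """F1: fail iff any control has an observed DERIVED call.

    MISSING/AMBIGUOUS controls are uninformative; a variant with zero
    observed control calls passes vacuously (annotated downstream).
    """
    _, control_mask = _class_masks(matrix, screen)
    sub = matrix.calls[control_mask]
    derived_any = (sub == CallState.DERIVED).any(axis=0)
    return {v.key: not bool(derived_any[j]) for j, v in enumerate(matrix.variants)}


def filter_non_singleton(
    matrix: GenotypeMatrix, screen: ScreenResult
) -> dict[tuple[str, int], bool]:
    """F2: fail iff at most one case sample has an observed DERIVED call."""
    case_mask, _ = _class_masks(matrix, screen)
    sub = matrix.calls[case_mask]
    n_derived = (sub == CallState.DERIVED).sum(axis=0)
    return {v.key: int(n_derived[j]) >= 2 for j, v in enumerate(matrix.variants)}


def filter_ambiguous(
    matrix: GenotypeMatrix, screen: ScreenResult, max_ambiguous: int = 0
) -> dict[tuple[str, int], bool]:
    """F3: fail iff AMBIGUOUS calls among cases+controls exceed the cap."""
    case_mask, control_mask = _class_masks(matrix, screen)
    sub = matrix.calls[case_mask | control_mask]
    n_amb = (sub == CallState.AMBIGUOUS).sum(axis=0)
    return {v.key: int(n_amb[j]) <= max_ambiguous for j, v in enumerate(matrix.variants)}


def compatible(
    v1_derived_cases: frozenset[str] | set[str],
    v2_derived_cases: frozenset[str] | set[str],
    jointly_observed: frozenset[str] | set[str],
) -> bool:
    """Rooted pairwise compatibility with known ancestral state.

    TRUE iff, restricted to jointly observed samples, the derived sets are
    nested or disjoint; equivalently FALSE iff all three carrier patterns
    (1,0), (0,1) and (1,1) occur among jointly observed samples.
    """
    d1 = set(v1_derived_cases) & set(jointly_observed)
    d2 = set(v2_derived_cases) & set(jointly_observed)
    return not (d1 - d2 and d2 - d1 and d1 & d2)


def _conflict_graph(
    matrix: GenotypeMatrix,
    screen: ScreenResult,
    variants: Sequence[Variant],
) -> dict[tuple[str, int], set[tuple[str, int]]]:
    """Pairwise incompatibility over case samples, vectorised.

    For variants i, j the three patterns are counted over jointly observed
    case samples via boolean matrix products (derived implies observed, so
    D @ D.T counts (1,1), D @ A.T counts (1,0) with A = observed ancestral).
    """
    case_mask, _ = _class_masks(matrix, screen)
    cols = [matrix.variant_index(v) for v in variants]
    sub = matrix.calls[case_mask][:, cols]
    D = (sub == CallState.DERIVED).T.astype(np.int32)
    A = (sub == CallState.ANCESTRAL).T.astype(np.int32)
    n11 = D @ D.T
    n10 = D @ A.T
    conflict = (n11 > 0) & (n10 > 0) & (n10.T > 0)
    np.fill_diagonal(conflict, False)
    graph: dict[tuple[str, int], set[tuple[str, int]]] = {
        v.key: set() for v in variants
    }
    for i, j in zip(*np.nonzero(conflict)):
        graph[variants[i].key].add(variants[j].key)
    return graph


def filter_consistent(
    matrix: GenotypeMatrix,
    screen: ScreenResult,
    survivors: Sequence[Variant],
) -> tuple[
    dict[tuple[str, int], bool],
    dict[tuple[str, int], set[tuple[str, int]]],
]:
    """F4: greedily remove maximum-conflict-degree variants until the
    pairwise incompatibility graph is empty.

    Ties are broken toward fewer observed derived case calls, then higher
    position, so removal order — and therefore every outcome — is invariant
    under input order. Returns (pass map, original conflict graph).
    """
    graph = _conflict_graph(matrix, screen, survivors)
    case_mask, _ = _class_masks(matrix, screen)
    by_key = {v.key: v for v in survivors}
    n_derived = {
        v.key: int(
            np.count_nonzero(
                matrix.calls[case_mask][:, matrix.variant_index(v)] == CallState.DERIVED
            )
        )
        for v in survivors
    }

    degree = {k: len(nbrs) for k, nbrs in graph.items()}
    alive = set(graph)
    removed: set[tuple[str, int]] = set()
    live_graph = {k: set(nbrs) for k, nbrs in graph.items()}
    while True:
        conflicted = [k for k in alive if degree[k] > 0]
        if not conflicted:
            break
        victim = min(
            conflicted,
            key=lambda k: (-degree[k], n_derived[k], -by_key[k].position),
        )
        removed.add(victim)
        alive.discard(victim)
        for nbr in live_graph[victim]:
            live_graph[nbr].discard(victim)
            degree[nbr] -= 1
        degree[victim] = 0
        live_graph[victim] = set()
    passes = {v.key: v.key not in removed for v in survivors}
    return passes, graph


def annotate_novelty(
    variants: Sequence[Variant], known_list: KnownVariantList
) -> list[Variant]:
    """Flag variants found in the known list; copy names from the list."""
    out = []
    for v in variants:
        name = known_list.name_of(v)
        if name is not None:
            out.append(v.with_name(name, known=True))
        else:
            out.append(v)
    return out


def run_filters(
    matrix: GenotypeMatrix,
    screen: ScreenResult,
    candidates: Optional[Sequence[Variant]] = None,
    max_ambiguous: int = 0,
    unusable_keys: Optional[set[tuple[str, int]]] = None,
) -> FilterReport:
    """Apply the cascade F1 -> F2 -> F3 -> F4 with first-fail attribution.

    ``candidates`` defaults to every variant except the anchor (the anchor
    defines the root clade and is not itself a discovery candidate).
    Outcome-class counts always sum to the number of candidates.
    """
    if candidates is None:
        candidates = [v for v in matrix.variants if v.key != screen.anchor.key]
    unusable_keys = unusable_keys or set()

    case_mask, control_mask = _class_masks(matrix, screen)
    f1 = filter_control_ancestral(matrix, screen)
    f2 = filter_non_singleton(matrix, screen)
    f3 = filter_ambiguous(matrix, screen, max_ambiguous)

    report = FilterReport()
    survivors: list[Variant] = []
    for v in candidates:
        j = matrix.variant_index(v)
        col_cases = matrix.calls[case_mask, j]
        col_controls = matrix.calls[control_mask, j]
        col_both = matrix.calls[case_mask | control_mask, j]
        rec = VariantRecord(
            key=v.key,
            outcome=FilterOutcome.RETAINED,
            derived_cases=int(np.count_nonzero(col_cases == CallState.DERIVED)),
            observed_controls=int(
                np.count_nonzero(
                    (col_controls == CallState.ANCESTRAL)
                    | (col_controls == CallState.DERIVED)
                )
            ),
            ambiguous_calls=int(np.count_nonzero(col_both == CallState.AMBIGUOUS)),
        )
        observed_both = (col_both == CallState.ANCESTRAL) | (
            col_both == CallState.DERIVED
        )
        derived_both = col_both == CallState.DERIVED
        if observed_both.any() and bool((derived_both == observed_both).all()):
            rec.notes.append("all observed calls derived (possible reference artefact)")
        if rec.observed_controls == 0:
            rec.notes.append("no informative controls")

        if v.key in unusable_keys:
            rec.outcome = FilterOutcome.UNUSABLE
            rec.notes.append("control-majority orientation tie")
        elif not f1[v.key]:
            rec.outcome = FilterOutcome.FAIL_CONTROL_DERIVED
        elif not f2[v.key]:
            rec.outcome = FilterOutcome.FAIL_SINGLETON
        elif not f3[v.key]:
            rec.outcome = FilterOutcome.FAIL_AMBIGUOUS
        else:
            survivors.append(v)
        report.add(rec)

    f4, graph = filter_consistent(matrix, screen, survivors)
    label_of = {v.key: v.label for v in candidates}
    for v in survivors:
        rec = report.record(v.key)
        partners = sorted(label_of[k] for k in graph[v.key])
        if not f4[v.key]:
            rec.outcome = FilterOutcome.FAIL_INCONSISTENT
            rec.conflict_partners = partners
        elif partners:
            rec.conflict_partners = partners
    for a, nbrs in graph.items():
        for b in nbrs:
            if label_of[a] < label_of[b]:
                report.conflict_edges.append((label_of[a], label_of[b]))
    report.conflict_edges.sort()
    return report
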