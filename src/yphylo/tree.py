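"""Equivalent-marker blocks, perfect-phylogeny construction, scaffold
reconciliation and sample placement.

The clade tree is the rooted-tree form of a laminar family of derived-carrier
sets: every non-root node carries one marker block, and every case sample
attaches to the most derived node containing it. With missing data the
observed carrier sets need not be perfectly laminar even after the
compatibility filter; partial overlaps are resolved deterministically during
construction (majority-inside descent with recorded expansions/trims), which
reduces to plain superset insertion on complete data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import dendropy

from .core import (
    CallState,
    FormatError,
    GenotypeMatrix,
    PipelineError,
    Variant,
    natural_key,
)

__all__ = [
    "MarkerBlock",
    "CladeNode",
    "CladeTree",
    "ScaffoldTree",
    "ReconciliationReport",
    "PlacementRecord",
    "equivalence_blocks",
    "possibly_equivalent_pairs",
    "build_tree",
    "read_scaffold",
    "reconcile_scaffold",
    "place_samples",
    "export_newick",
    "clade_sample_sets",
]

LABEL_SEP = ", "


@dataclass(frozen=True)
class MarkerBlock:
    """An equivalence class of variants sharing one observed derived set."""

    variants: tuple[Variant, ...]
    derived_cases: frozenset[str]

    def __post_init__(self) -> None:
        if not self.variants:
            raise PipelineError("a marker block needs at least one variant")
        if not self.derived_cases:
            raise PipelineError("a marker block needs a nonempty derived set")

    @property
    def label(self) -> str:
        return LABEL_SEP.join(
            sorted((v.label for v in self.variants), key=natural_key)
        )

    @property
    def names(self) -> set[str]:
        return {v.name for v in self.variants if v.name}


class CladeNode:
    """One tree node: a marker block (root: none) plus attached samples."""

    def __init__(
        self,
        block: Optional[MarkerBlock],
        effective_set: frozenset[str],
        parent: Optional["CladeNode"] = None,
    ) -> None:
        self.block = block
        self.effective_set = effective_set
        self.parent = parent
        self.children: list["CladeNode"] = []
        self.attached: set[str] = set()

    @property
    def label(self) -> str:
        return self.block.label if self.block else "ROOT"

    def sort_children(self) -> None:
        self.children.sort(key=lambda c: natural_key(c.label))

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()

    def subtree_samples(self) -> set[str]:
        out = set()
        for n in self.walk():
            out |= n.attached
        return out


class CladeTree:
    """Rooted clade tree; the root stands for the anchor clade."""

    def __init__(self, root: CladeNode, case_samples: Sequence[str]) -> None:
        self.root = root
        self.case_samples = list(case_samples)
        self.root_names: set[str] = set()
        self.diagnostics: list[tuple[str, ...]] = []

    @property
    def nodes(self) -> list[CladeNode]:
        return list(self.root.walk())

    @property
    def block_nodes(self) -> list[CladeNode]:
        return [n for n in self.root.walk() if n.block is not None]

    def node_of_name(self, marker_name: str) -> Optional[CladeNode]:
        for n in self.block_nodes:
            if marker_name in n.block.names:
                return n
        return None

    def assert_laminar(self) -> None:
        """Hard postcondition: node sets pairwise nested or disjoint."""
        sets = [n.effective_set for n in self.block_nodes]
        for i, a in enumerate(sets):
            for b in sets[i + 1:]:
                inter = a & b
                if inter and not (a <= b or b <= a):
                    raise PipelineError(
                        "internal consistency error: node sets are not laminar"
                    )


def _observed_derived_cases(
    matrix: GenotypeMatrix, variant: Variant, case_samples: Sequence[str]
) -> frozenset[str]:
    derived = matrix.samples_in_state(variant, CallState.DERIVED)
    return frozenset(derived & set(case_samples))


def equivalence_blocks(
    matrix: GenotypeMatrix,
    retained_variants: Sequence[Variant],
    case_samples: Sequence[str],
) -> list[MarkerBlock]:
    """Group variants whose observed derived case sets are identical.

    Identical observed sets make any observed contradiction between members
    impossible, so set identity is the whole equivalence rule. Blocks are
    returned sorted by descending carrier count, then label.
    """
    groups: dict[frozenset[str], list[Variant]] = {}
    for v in retained_variants:
        d = _observed_derived_cases(matrix, v, case_samples)
        if not d:
            continue  # no observed carriers: nothing to place
        groups.setdefault(d, []).append(v)
    blocks = [
        MarkerBlock(
            variants=tuple(sorted(vs, key=lambda v: natural_key(v.label))),
            derived_cases=d,
        )
        for d, vs in groups.items()
    ]
    blocks.sort(key=lambda b: (-len(b.derived_cases), natural_key(b.label)))
    return blocks


def possibly_equivalent_pairs(
    matrix: GenotypeMatrix, blocks: Sequence[MarkerBlock]
) -> list[tuple[str, str]]:
    """Block pairs separated only by unobserved calls.

    Two blocks are flagged when every sample in the symmetric difference of
    their derived sets has no observed call at any variant of the block it is
    missing from — such blocks may represent one true branch split by
    missing data.
    """

    def unobserved_at(sample: str, block: MarkerBlock) -> bool:
        for v in block.variants:
            if matrix.state(sample, v) in (CallState.ANCESTRAL, CallState.DERIVED):
                return False
        return True

    flagged = []
    for i, b1 in enumerate(blocks):
        for b2 in blocks[i + 1:]:
            d1, d2 = b1.derived_cases, b2.derived_cases
            if d1 == d2:
                continue
            only1, only2 = d1 - d2, d2 - d1
            if not (only1 or only2):
                continue
            if all(unobserved_at(s, b2) for s in only1) and all(
                unobserved_at(s, b1) for s in only2
            ):
                flagged.append(tuple(sorted((b1.label, b2.label))))
    return sorted(flagged)


def build_tree(blocks: Sequence[MarkerBlock], case_samples: Sequence[str]) -> CladeTree:
    """Insert blocks by descending carrier count into a laminar tree.

    Each block descends from the root: into a containing child when one
    exists, else into the maximum-overlap child when the majority of its
    remaining carriers lie inside (expanding that child's effective set and
    recording the expansion), trimming away minority overlaps otherwise.
    On complete, compatible data no expansion or trim ever fires and the
    result is the unique perfect phylogeny of the blocks. Input order does
    not affect the result. Laminarity is asserted before returning.
    """
    case_set = frozenset(case_samples)
    root = CladeNode(block=None, effective_set=case_set)
    tree = CladeTree(root, case_samples)

    ordered = sorted(
        blocks, key=lambda b: (-len(b.derived_cases), natural_key(b.label))
    )
    for block in ordered:
        if not block.derived_cases <= case_set:
            raise PipelineError(
                f"block {block.label!r} contains non-case samples"
            )
        b_eff = set(block.derived_cases)
        node = root
        while b_eff:
            overlapping = [c for c in node.children if c.effective_set & b_eff]
            if not overlapping:
                break
            container = next(
                (c for c in overlapping if c.effective_set >= b_eff), None
            )
            if container is not None:
                node = container
                continue
            best = min(
                overlapping,
                key=lambda c: (
                    -len(c.effective_set & b_eff),
                    natural_key(c.label),  # ties: earliest label wins
                ),
            )
            for other in overlapping:
                if other is best:
                    continue
                lost = sorted(b_eff & other.effective_set)
                b_eff -= other.effective_set
                tree.diagnostics.append(
                    ("trim", block.label, other.label, ",".join(lost))
                )
            inside = b_eff & best.effective_set
            outside = b_eff - best.effective_set
            if len(inside) >= len(outside):
                if outside:
                    _expand(best, frozenset(outside))
                    tree.diagnostics.append(
                        ("expand", best.label, block.label, ",".join(sorted(outside)))
                    )
                node = best
            else:
                tree.diagnostics.append(
                    ("trim", block.label, best.label, ",".join(sorted(inside)))
                )
                b_eff -= best.effective_set
        if not b_eff:
            tree.diagnostics.append(("unplaced", block.label))
            continue
        new = CladeNode(block=block, effective_set=frozenset(b_eff), parent=node)
        moved = [c for c in node.children if c.effective_set <= new.effective_set]
        for c in moved:
            node.children.remove(c)
            c.parent = new
            new.children.append(c)
        node.children.append(new)
        new.sort_children()
        node.sort_children()

    _attach_samples(tree)
    tree.assert_laminar()
    return tree


def _expand(node: CladeNode, extra: frozenset[str]) -> None:
    node.effective_set = frozenset(node.effective_set | extra)


def _attach_samples(tree: CladeTree) -> None:
    for s in tree.case_samples:
        node = tree.root
        while True:
            nxt = next(
                (c for c in node.children if s in c.effective_set), None
            )
            if nxt is None:
                break
            node = nxt
        node.attached.add(s)
    total = sum(len(n.attached) for n in tree.nodes)
    if total != len(tree.case_samples):
        raise PipelineError("sample attachment is not a partition of the cases")


class ScaffoldTree:
    """Prior hierarchy of named markers (name -> parent-name table)."""

    def __init__(self, parent: dict[str, Optional[str]]) -> None:
        roots = [n for n, p in parent.items() if p is None]
        if len(roots) != 1:
            raise FormatError(
                f"scaffold must have exactly one root, found {len(roots)}"
            )
        self.root = roots[0]
        self.parent = dict(parent)
        for name, p in parent.items():
            if p is not None and p not in parent:
                raise FormatError(f"scaffold parent {p!r} of {name!r} is undefined")
        # cycle check: every node must reach the root
        for name in parent:
            seen = set()
            cur: Optional[str] = name
            while cur is not None:
                if cur in seen:
                    raise FormatError(f"scaffold contains a cycle through {cur!r}")
                seen.add(cur)
                cur = self.parent[cur]

    @property
    def names(self) -> set[str]:
        return set(self.parent)

    def ancestors(self, name: str) -> list[str]:
        """Proper ancestors, nearest first."""
        out = []
        cur = self.parent[name]
        while cur is not None:
            out.append(cur)
            cur = self.parent[cur]
        return out


def read_scaffold(path: Path | str) -> ScaffoldTree:
    """Read the scaffold TSV (marker_name, parent_name; root row blank)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = {"marker_name", "parent_name"} - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    parent: dict[str, Optional[str]] = {}
    for row in df.itertuples(index=False):
        name = str(row.marker_name)
        if name in parent:
            raise FormatError(f"{path}: duplicate scaffold marker {name!r}")
        p = str(row.parent_name)
        parent[name] = p if p else None
    return ScaffoldTree(parent)


@dataclass
class ReconciliationReport:
    """Per-scaffold-marker status after comparison with the built tree."""

    status: dict[str, str] = field(default_factory=dict)
    old_parent: dict[str, str] = field(default_factory=dict)
    new_parent: dict[str, str] = field(default_factory=dict)

    def rows(self) -> list[tuple[str, str, str, str]]:
        return [
            (
                m,
                self.status[m],
                self.old_parent.get(m, ""),
                self.new_parent.get(m, ""),
            )
            for m in sorted(self.status, key=natural_key)
        ]


def reconcile_scaffold(tree: CladeTree, scaffold: ScaffoldTree) -> ReconciliationReport:
    """Compare data-derived marker placements with the scaffold.

    A marker is CONFIRMED when its tree parent's block carries its scaffold
    parent or any scaffold ancestor of it; otherwise it is REPOSITIONED and
    the data-derived parent is kept (data wins), with both placements
    reported. Markers absent from the tree are UNPLACED.
    """
    report = ReconciliationReport()
    for marker in scaffold.names:
        if marker == scaffold.root:
            if marker in tree.root_names or tree.node_of_name(marker) is not None:
                report.status[marker] = "CONFIRMED"
            else:
                report.status[marker] = "UNPLACED"
            continue
        node = tree.node_of_name(marker)
        if node is None:
            report.status[marker] = "UNPLACED"
            continue
        scaffold_parent = scaffold.parent[marker]
        acceptable = {scaffold_parent, *scaffold.ancestors(scaffold_parent)}
        parent = node.parent
        parent_names = (
            tree.root_names if parent is tree.root or parent is None
            else parent.block.names
        )
        if parent is tree.root or parent is None:
            parent_names = set(parent_names) | {scaffold.root}
        report.old_parent[marker] = scaffold_parent or ""
        if parent_names & acceptable:
            report.status[marker] = "CONFIRMED"
        else:
            report.status[marker] = "REPOSITIONED"
            report.new_parent[marker] = (
                parent.label if parent is not None else "ROOT"
            )
    return report


@dataclass
class PlacementRecord:
    sample: str
    node_label: str
    path: list[str]
    diagnostics: list[str] = field(default_factory=list)


def place_samples(tree: CladeTree, matrix: GenotypeMatrix) -> dict[str, PlacementRecord]:
    """Report each case sample's terminal node, root path and call caveats.

    Diagnostics cover the boundary of the placement: path nodes the sample
    passed through without an observed derived call (passage inferred from
    deeper calls), and child blocks of the terminal node where the sample's
    calls are MISSING or AMBIGUOUS (its true position may be deeper).
    """

    def observed_states(sample: str, block: MarkerBlock) -> list[CallState]:
        return [CallState(matrix.state(sample, v)) for v in block.variants]

    out: dict[str, PlacementRecord] = {}
    for sample in tree.case_samples:
        node = tree.root
        path_nodes: list[CladeNode] = []
        while True:
            nxt = next((c for c in node.children if sample in c.effective_set), None)
            if nxt is None:
                break
            node = nxt
            path_nodes.append(node)
        diagnostics = []
        for n in path_nodes:
            states = observed_states(sample, n.block)
            if CallState.DERIVED not in states:
                diagnostics.append(
                    f"undetermined at {n.block.label} (passage inferred)"
                )
        for child in node.children:
            states = observed_states(sample, child.block)
            if CallState.DERIVED in states or CallState.ANCESTRAL in states:
                continue
            diagnostics.append(f"undetermined at {child.block.label}")
        out[sample] = PlacementRecord(
            sample=sample,
            node_label=node.label,
            path=[n.label for n in path_nodes],
            diagnostics=diagnostics,
        )
    return out


def _to_dendropy(tree: CladeTree) -> dendropy.Tree:
    dtree = dendropy.Tree()
    taxa = dtree.taxon_namespace

    def convert(node: CladeNode, dnode: dendropy.Node) -> None:
        dnode.label = node.label
        for child in node.children:
            dchild = dnode.new_child()
            convert(child, dchild)
        for s in sorted(node.attached):
            leaf = dnode.new_child()
            leaf.taxon = taxa.new_taxon(label=s)

    convert(tree.root, dtree.seed_node)
    return dtree


def export_newick(tree: CladeTree, path: Path | str) -> None:
    """Serialise the clade tree: internal labels = block labels, leaves =
    attached sample ids. Re-parsing reproduces topology and labels."""
    dtree = _to_dendropy(tree)
    text = dtree.as_string(
        schema="newick",
        suppress_rooting=True,
        suppress_internal_node_labels=False,
    )
    Path(path).write_text(text if text.endswith("\n") else text + "\n", encoding="utf-8")


def clade_sample_sets(tree: CladeTree) -> set[frozenset[str]]:
    """Subtree sample sets, one per non-root node (the rooted-RF currency)."""
    return {frozenset(n.subtree_samples()) for n in tree.block_nodes}
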