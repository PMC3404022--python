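"""Synthetic haploid call-set generator with known ground truth.

Emulates the low-coverage (2-4x) discovery regime: a rooted clade tree below
an anchor marker, branch-private derived alleles under infinite sites,
uncatalogued singletons, recurrent artefacts spanning two unrelated branches
(the duplicated-region failure mode), Poisson read depth, per-read error that
produces heterozygous-looking calls, and missing data.

Randomness is split into fixed per-stage substreams derived from the single
configured seed, so adding a later stage never perturbs an earlier one.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import yaml

from .core import (
    CallState,
    ConfigError,
    GenerationError,
    GenotypeMatrix,
    Variant,
)

__all__ = [
    "SimConfig",
    "TruthTree",
    "SimTruth",
    "simulate_tree",
    "simulate_mutations",
    "simulate_calls",
    "simulate_dataset",
    "write_fixture_set",
]

# Fixed substream tags: rng for stage k is default_rng([_STAGE_*, seed]).
_STAGE_TREE = 11
_STAGE_MUTATIONS = 12
_STAGE_CALLS = 13
_STAGE_POPULATIONS = 14

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SimConfig:
    """Parameters of one synthetic dataset. The seed fully determines output."""

    n_case_samples: int = 30
    n_control_samples: int = 20
    n_clades: int = 8
    variants_per_branch: int = 3
    singleton_count: int = 5
    recurrent_count: int = 2
    mean_coverage: float = 3.0
    per_read_error: float = 0.01
    missing_rate: float = 0.02
    ambiguity_threshold_reads: int = 2
    populations: tuple[tuple[str, float], ...] = (
        ("P1", 0.4),
        ("P2", 0.35),
        ("P3", 0.25),
    )
    seed: int = 0
    anchor_name: str = "A1"
    control_private_count: int = 0
    contig: str = "chrY"
    position_max: int = 60_000_000

    def __post_init__(self) -> None:
        counts = {
            "n_case_samples": self.n_case_samples,
            "n_control_samples": self.n_control_samples,
            "variants_per_branch": self.variants_per_branch,
            "singleton_count": self.singleton_count,
            "recurrent_count": self.recurrent_count,
            "ambiguity_threshold_reads": self.ambiguity_threshold_reads,
            "control_private_count": self.control_private_count,
        }
        for k, v in counts.items():
            if v < 0:
                raise ConfigError(f"{k} must be >= 0, got {v}")
        if self.n_clades < 1:
            raise ConfigError(f"n_clades must be >= 1, got {self.n_clades}")
        for k in ("per_read_error", "missing_rate"):
            v = getattr(self, k)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{k} must be in [0, 1], got {v}")
        if self.mean_coverage <= 0:
            raise ConfigError(f"mean_coverage must be > 0, got {self.mean_coverage}")
        if not self.populations:
            raise ConfigError("populations must be non-empty")
        total = sum(w for _, w in self.populations)
        if total <= 0:
            raise ConfigError("population weights must sum to a positive value")

    def to_yaml(self, path: Path | str) -> None:
        data = dataclasses.asdict(self)
        data["populations"] = {label: w for label, w in self.populations}
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True), encoding="utf-8")

    @classmethod
    def from_yaml(cls, path: Path | str) -> "SimConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(data) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        if "populations" in data:
            pops = data["populations"]
            if isinstance(pops, dict):
                data["populations"] = tuple(sorted(pops.items()))
            else:
                data["populations"] = tuple((str(a), float(b)) for a, b in pops)
        return cls(**data)


class TruthTree:
    """Rooted clade tree: an anchor root plus named internal clade nodes."""

    ROOT = "ROOT"

    def __init__(self) -> None:
        self.parent: dict[str, Optional[str]] = {self.ROOT: None}
        self.children: dict[str, list[str]] = {self.ROOT: []}
        self.nodes: list[str] = [self.ROOT]

    def add_node(self, node: str, parent: str) -> None:
        if node in self.parent:
            raise ConfigError(f"duplicate node {node!r}")
        if parent not in self.parent:
            raise ConfigError(f"unknown parent {parent!r}")
        self.parent[node] = parent
        self.children[node] = []
        self.children[parent].append(node)
        self.nodes.append(node)

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    def subtree_nodes(self, node: str) -> list[str]:
        out, stack = [], [node]
        while stack:
            n = stack.pop()
            out.append(n)
            stack.extend(reversed(self.children[n]))
        return out

    def is_ancestor_or_self(self, a: str, b: str) -> bool:
        """True if ``a`` lies on the root path of ``b`` (inclusive)."""
        cur: Optional[str] = b
        while cur is not None:
            if cur == a:
                return True
            cur = self.parent[cur]
        return False

    def to_newick(self, attached: Optional[dict[str, list[str]]] = None) -> str:
        attached = attached or {}

        def render(node: str) -> str:
            parts = [render(c) for c in self.children[node]]
            parts.extend(sorted(attached.get(node, [])))
            if parts:
                return "(" + ",".join(parts) + ")" + node
            return node

        return render(self.ROOT) + ";"


@dataclass
class SimTruth:
    """Ground truth for one simulated dataset.

    ``branch_variants`` maps each non-root tree node to the (contig, position)
    keys of its branch-private variants; singleton, artefact and control-side
    variants are tracked separately and the four classes are disjoint.
    """

    true_tree: TruthTree
    branch_variants: dict[str, set[tuple[str, int]]]
    sample_tip: dict[str, str]
    artefact_variants: set[tuple[str, int]] = field(default_factory=set)
    singleton_variants: set[tuple[str, int]] = field(default_factory=set)
    artefact_branches: dict[tuple[str, int], tuple[str, str]] = field(default_factory=dict)
    singleton_carrier: dict[tuple[str, int], str] = field(default_factory=dict)
    control_variants: dict[tuple[str, int], frozenset[str]] = field(default_factory=dict)
    anchor_key: Optional[tuple[str, int]] = None
    case_samples: list[str] = field(default_factory=list)
    control_samples: list[str] = field(default_factory=list)
    populations: dict[str, str] = field(default_factory=dict)

    def variant_branch(self, key: tuple[str, int]) -> Optional[str]:
        cache = self.__dict__.get("_branch_of")
        if cache is None or len(cache) != sum(
            len(ks) for ks in self.branch_variants.values()
        ):
            cache = {
                k: branch
                for branch, keys in self.branch_variants.items()
                for k in keys
            }
            self.__dict__["_branch_of"] = cache
        return cache.get(key)

    def tip_samples(self, node: str) -> set[str]:
        """Case samples whose tip lies in ``node``'s subtree."""
        cache = self.__dict__.setdefault("_tip_cache", {})
        if node not in cache:
            sub = set(self.true_tree.subtree_nodes(node))
            cache[node] = {s for s, tip in self.sample_tip.items() if tip in sub}
        return cache[node]

    def carriers(self, key: tuple[str, int]) -> set[str]:
        """All true derived carriers of one variant."""
        if key == self.anchor_key:
            return set(self.case_samples)
        if key in self.singleton_carrier:
            return {self.singleton_carrier[key]}
        if key in self.artefact_branches:
            a, b = self.artefact_branches[key]
            return self.tip_samples(a) | self.tip_samples(b)
        if key in self.control_variants:
            return set(self.control_variants[key])
        branch = self.variant_branch(key)
        if branch is None:
            raise KeyError(f"unknown variant key {key}")
        return self.tip_samples(branch)

    def is_derived(self, sample: str, key: tuple[str, int]) -> bool:
        """Truth-implied carrier state for one cell."""
        return sample in self.carriers(key)

    def truth_matrix(self, variants: Sequence[Variant]) -> np.ndarray:
        """0/1 carrier matrix (samples x variants), cases then controls."""
        samples = self.case_samples + self.control_samples
        index = {s: i for i, s in enumerate(samples)}
        out = np.zeros((len(samples), len(variants)), dtype=np.int8)
        for j, v in enumerate(variants):
            rows = [index[s] for s in self.carriers(v.key)]
            out[rows, j] = 1
        return out


def simulate_tree(n_clades: int, seed: int) -> TruthTree:
    """Grow a random rooted clade tree with ``n_clades`` nodes below the root.

    Each new node attaches uniformly to a previously created node, which
    yields the nested-subclade shapes seen in real haplogroup trees.
    """
    if n_clades < 1:
        raise ConfigError(f"n_clades must be >= 1, got {n_clades}")
    rng = np.random.default_rng([_STAGE_TREE, seed])
    tree = TruthTree()
    for i in range(1, n_clades + 1):
        parent = tree.nodes[int(rng.integers(0, len(tree.nodes)))]
        tree.add_node(f"C{i}", parent)
    return tree


def _draw_positions(rng: np.random.Generator, n: int, position_max: int) -> list[int]:
    if n > position_max:
        raise GenerationError(
            f"cannot draw {n} unique positions from 1..{position_max}"
        )
    # Sampling without replacement over the full range is cheap at this scale.
    pos = rng.choice(position_max, size=n, replace=False) + 1
    return [int(p) for p in pos]


def _draw_alleles(rng: np.random.Generator, n: int) -> list[tuple[str, str]]:
    anc_idx = rng.integers(0, 4, size=n)
    shift = rng.integers(1, 4, size=n)
    der_idx = (anc_idx + shift) % 4
    return [(str(_BASES[a]), str(_BASES[d])) for a, d in zip(anc_idx, der_idx)]


def _assign_tips(
    tree: TruthTree, case_samples: list[str], rng: np.random.Generator
) -> dict[str, str]:
    """Attach case samples to tree nodes.

    Every non-root node gets two directly attached samples first (while the
    supply lasts) so that parent and child clades always differ in membership
    and every branch is supported by at least two carriers; the remainder is
    spread uniformly over all nodes including the root.
    """
    order = list(case_samples)
    rng.shuffle(order)
    tips: dict[str, str] = {}
    non_root = [n for n in tree.nodes if n != TruthTree.ROOT]
    i = 0
    for _ in range(2):
        for node in non_root:
            if i >= len(order):
                break
            tips[order[i]] = node
            i += 1
    while i < len(order):
        tips[order[i]] = tree.nodes[int(rng.integers(0, tree.n_nodes))]
        i += 1
    return tips


def _artefact_pairs(
    tree: TruthTree, truth: SimTruth, rng: np.random.Generator, count: int
) -> list[tuple[str, str]]:
    """Pick branch pairs with disjoint tip sets for recurrent artefacts.

    At least one node of each pair must have an ancestor strictly between
    itself and the pair's lowest common ancestor: that intermediate branch's
    own variants partially overlap the artefact's derived set, so the
    compatibility filter is guaranteed to see a conflict. (If both nodes were
    direct children of their LCA the union of their tip sets would nest
    cleanly inside it and be compatible with every true branch.)
    """

    def ancestors(node: str) -> list[str]:
        out = []
        cur: Optional[str] = node
        while cur is not None:
            out.append(cur)
            cur = tree.parent[cur]
        return out

    non_root = [n for n in tree.nodes if n != TruthTree.ROOT]
    candidates = []
    for i, a in enumerate(non_root):
        for b in non_root[i + 1:]:
            if tree.is_ancestor_or_self(a, b) or tree.is_ancestor_or_self(b, a):
                continue
            tips_a, tips_b = truth.tip_samples(a), truth.tip_samples(b)
            if not tips_a or not tips_b or tips_a & tips_b:
                continue
            anc_a, anc_b = ancestors(a), ancestors(b)
            lca = next(x for x in anc_a if x in set(anc_b))
            if tree.parent[a] == lca and tree.parent[b] == lca:
                continue
            candidates.append((a, b))
    if not candidates:
        raise GenerationError(
            "tree topology offers no disjoint branch pair for recurrent artefacts"
        )
    replace = count > len(candidates)
    idx = rng.choice(len(candidates), size=count, replace=replace)
    return [candidates[int(i)] for i in idx]


def simulate_mutations(tree: TruthTree, config: SimConfig) -> tuple[list[Variant], SimTruth]:
    """Place variants on the tree and build the ground truth.

    Output order: anchor, branch variants (tree order), singletons, artefacts,
    control-side variants. Each branch gets exactly ``variants_per_branch``
    private variants so that every clade is detectable downstream.
    """
    rng = np.random.default_rng([_STAGE_MUTATIONS, config.seed])
    pop_rng = np.random.default_rng([_STAGE_POPULATIONS, config.seed])

    case_samples = [f"S{i:04d}" for i in range(1, config.n_case_samples + 1)]
    control_samples = [f"K{i:04d}" for i in range(1, config.n_control_samples + 1)]

    truth = SimTruth(
        true_tree=tree,
        branch_variants={},
        sample_tip=_assign_tips(tree, case_samples, rng),
        case_samples=case_samples,
        control_samples=control_samples,
    )

    non_root = [n for n in tree.nodes if n != TruthTree.ROOT]
    n_branch = len(non_root) * config.variants_per_branch
    n_total = (
        1  # anchor
        + n_branch
        + config.singleton_count
        + config.recurrent_count
        + config.control_private_count
    )
    positions = _draw_positions(rng, n_total, config.position_max)
    alleles = _draw_alleles(rng, n_total)
    cursor = 0

    def next_variant(name: Optional[str] = None) -> Variant:
        nonlocal cursor
        anc, der = alleles[cursor]
        v = Variant(
            contig=config.contig,
            position=positions[cursor],
            ancestral_allele=anc,
            derived_allele=der,
            name=name,
        )
        cursor += 1
        return v

    variants: list[Variant] = []

    anchor = next_variant(config.anchor_name)
    truth.anchor_key = anchor.key
    variants.append(anchor)

    # First variant on each branch carries a stable marker-style name so the
    # fixture scaffold and known-variant list have something to reference.
    for node in non_root:
        keys: set[tuple[str, int]] = set()
        for j in range(config.variants_per_branch):
            name = f"M{node[1:]}" if j == 0 else None
            v = next_variant(name)
            variants.append(v)
            keys.add(v.key)
        truth.branch_variants[node] = keys

    if config.singleton_count and not case_samples:
        raise GenerationError("singletons requested but there are no case samples")
    for _ in range(config.singleton_count):
        v = next_variant()
        carrier = case_samples[int(rng.integers(0, len(case_samples)))]
        truth.singleton_variants.add(v.key)
        truth.singleton_carrier[v.key] = carrier
        variants.append(v)

    if config.recurrent_count:
        pairs = _artefact_pairs(tree, truth, rng, config.recurrent_count)
        for pair in pairs:
            v = next_variant()
            truth.artefact_variants.add(v.key)
            truth.artefact_branches[v.key] = pair
            variants.append(v)

    if config.control_private_count:
        if len(control_samples) < 2:
            raise GenerationError(
                "control-side variants need at least two control samples"
            )
        for _ in range(config.control_private_count):
            v = next_variant()
            size = int(rng.integers(2, len(control_samples) + 1))
            chosen = rng.choice(len(control_samples), size=size, replace=False)
            truth.control_variants[v.key] = frozenset(
                control_samples[int(i)] for i in chosen
            )
            variants.append(v)

    # Population labels are i.i.d. by weight and only ever affect reporting.
    labels = [p for p, _ in config.populations]
    weights = np.array([w for _, w in config.populations], dtype=float)
    weights /= weights.sum()
    all_samples = case_samples + control_samples
    draws = pop_rng.choice(len(labels), size=len(all_samples), p=weights)
    truth.populations = {s: labels[int(d)] for s, d in zip(all_samples, draws)}

    return variants, truth


def simulate_calls(
    variants: Sequence[Variant], truth: SimTruth, config: SimConfig
) -> GenotypeMatrix:
    """Simulate per-cell calls from read draws.

    Depth is Poisson(mean_coverage); each read reports the true allele with
    probability ``1 - per_read_error``. A cell is MISSING on dropout or zero
    depth, AMBIGUOUS when both alleles reach the read-support threshold (or
    tie with no majority), else the majority allele.
    """
    rng = np.random.default_rng([_STAGE_CALLS, config.seed])
    samples = truth.case_samples + truth.control_samples
    n_s, n_v = len(samples), len(variants)
    shape = (n_s, n_v)

    truth_mat = truth.truth_matrix(variants)
    depth = rng.poisson(config.mean_coverage, size=shape)
    dropout = rng.random(size=shape) < config.missing_rate
    true_reads = rng.binomial(depth, 1.0 - config.per_read_error)
    wrong_reads = depth - true_reads

    der_reads = np.where(truth_mat == 1, true_reads, wrong_reads)
    anc_reads = depth - der_reads
    der_reads = np.where(dropout, 0, der_reads)
    anc_reads = np.where(dropout, 0, anc_reads)
    eff_depth = anc_reads + der_reads

    thr = config.ambiguity_threshold_reads
    calls = np.full(shape, CallState.MISSING, dtype=np.int8)
    observed = eff_depth > 0
    both_supported = (anc_reads >= thr) & (der_reads >= thr)
    tied = observed & (anc_reads == der_reads)
    ambiguous = observed & (both_supported | tied)
    calls[observed & (der_reads > anc_reads)] = CallState.DERIVED
    calls[observed & (anc_reads > der_reads)] = CallState.ANCESTRAL
    calls[ambiguous] = CallState.AMBIGUOUS

    ad = np.stack([anc_reads, der_reads], axis=-1).astype(np.int32)
    populations = getattr(truth, "populations", {})
    return GenotypeMatrix(samples, list(variants), calls, populations=populations, ad=ad)


def simulate_dataset(config: SimConfig) -> tuple[GenotypeMatrix, SimTruth]:
    """Convenience wrapper: tree -> mutations -> calls."""
    tree = simulate_tree(config.n_clades, config.seed)
    variants, truth = simulate_mutations(tree, config)
    matrix = simulate_calls(variants, truth, config)
    return matrix, truth


def write_fixture_set(config: SimConfig, out_dir: Path | str) -> dict:
    """Write a complete fixture set and return its manifest.

    Emits the pipeline inputs (VCF, sample metadata, known-variant list,
    scaffold) plus the three ground-truth files, and a ``manifest.json``
    recording all of them.
    """
    from . import variant_io  # local import to avoid a cycle

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_dataset(config)
    tree = truth.true_tree

    paths = {
        "vcf": out / "calls.vcf",
        "samples": out / "samples.tsv",
        "known_variants": out / "known_variants.tsv",
        "scaffold": out / "scaffold.tsv",
        "truth_tree": out / "truth_tree.nwk",
        "truth_variants": out / "truth_variants.tsv",
        "truth_tips": out / "truth_tips.tsv",
    }

    variant_io.write_vcf(matrix, paths["vcf"])
    variant_io.write_sample_metadata(matrix.samples, matrix.populations, paths["samples"])

    # Known list: the anchor plus every named branch marker.
    with open(paths["known_variants"], "w", encoding="utf-8") as fh:
        fh.write("name\tcontig\tposition\tderived\n")
        for v in matrix.variants:
            if v.name:
                fh.write(f"{v.name}\t{v.contig}\t{v.position}\t{v.derived_allele}\n")

    # Scaffold: named branch markers in their true parent-child relation.
    node_marker = {TruthTree.ROOT: config.anchor_name}
    for node in tree.nodes:
        if node == TruthTree.ROOT:
            continue
        node_marker[node] = f"M{node[1:]}"
    with open(paths["scaffold"], "w", encoding="utf-8") as fh:
        fh.write("marker_name\tparent_name\n")
        fh.write(f"{config.anchor_name}\t\n")
        for node in tree.nodes:
            if node == TruthTree.ROOT:
                continue
            fh.write(f"{node_marker[node]}\t{node_marker[tree.parent[node]]}\n")

    attached: dict[str, list[str]] = {}
    for s, tip in truth.sample_tip.items():
        attached.setdefault(tip, []).append(s)
    paths["truth_tree"].write_text(tree.to_newick(attached) + "\n", encoding="utf-8")

    with open(paths["truth_variants"], "w", encoding="utf-8") as fh:
        fh.write("contig\tposition\tclass\tbranch\tdetail\n")
        for v in matrix.variants:
            key = v.key
            if key == truth.anchor_key:
                cls, branch, detail = "anchor", TruthTree.ROOT, v.name or ""
            elif key in truth.singleton_variants:
                cls, branch, detail = "singleton", "", truth.singleton_carrier[key]
            elif key in truth.artefact_variants:
                a, b = truth.artefact_branches[key]
                cls, branch, detail = "artefact", "", f"{a}+{b}"
            elif key in truth.control_variants:
                cls, branch = "control", ""
                detail = ",".join(sorted(truth.control_variants[key]))
            else:
                cls, branch, detail = "branch", truth.variant_branch(key) or "", v.name or ""
            fh.write(f"{v.contig}\t{v.position}\t{cls}\t{branch}\t{detail}\n")

    with open(paths["truth_tips"], "w", encoding="utf-8") as fh:
        fh.write("sample\ttip\n")
        for s in truth.case_samples:
            fh.write(f"{s}\t{truth.sample_tip[s]}\n")

    manifest = {
        "config": {
            **{
                k: (list(map(list, v)) if k == "populations" else v)
                for k, v in dataclasses.asdict(config).items()
            }
        },
        "files": {k: str(p.name) for k, p in paths.items()},
        "n_samples": matrix.n_samples,
        "n_variants": matrix.n_variants,
    }
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return manifest
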