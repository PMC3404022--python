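"""Unit and property tests for blocks, tree building, reconciliation,
placement and Newick export."""

import itertools

import dendropy
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from yphylo.core import CallState, PipelineError, Variant
from yphylo.filters import FilterOutcome, run_filters, screen_samples
from yphylo.simulate import simulate_dataset
from yphylo.tree import (
    MarkerBlock,
    ScaffoldTree,
    build_tree,
    clade_sample_sets,
    equivalence_blocks,
    export_newick,
    place_samples,
    possibly_equivalent_pairs,
    read_scaffold,
    reconcile_scaffold,
)

from conftest import A, D, M, U, make_matrix, noiseless_config


def mkvariant(pos, name=None):
    return Variant("chrY", pos, "A", "G", name=name)


def mkblock(samples, *variants):
    return MarkerBlock(variants=tuple(variants), derived_cases=frozenset(samples))


class TestEquivalenceBlocks:
    def test_identical_sets_share_one_block(self):
        matrix = make_matrix(
            ["s1", "s2", "s3", "s4"],
            [(100, "v1"), (200, "v2")],
            [[D, D], [D, D], [D, D], [A, A]],
        )
        blocks = equivalence_blocks(matrix, matrix.variants, matrix.samples)
        assert len(blocks) == 1
        assert blocks[0].label == "v1, v2"
        assert blocks[0].derived_cases == {"s1", "s2", "s3"}

    def test_nested_sets_stay_separate(self):
        matrix = make_matrix(
            ["s1", "s2", "s3"],
            [(100, "v1"), (200, "v2")],
            [[D, D], [D, D], [A, D]],
        )
        blocks = equivalence_blocks(matrix, matrix.variants, matrix.samples)
        assert len(blocks) == 2

    def test_label_natural_order(self):
        matrix = make_matrix(
            ["s1", "s2"],
            [(100, "Z10"), (200, "Z9"), (300, "Z100")],
            [[D, D, D], [D, D, D]],
        )
        blocks = equivalence_blocks(matrix, matrix.variants, matrix.samples)
        assert blocks[0].label == "Z9, Z10, Z100"

    def test_noiseless_one_block_per_branch_of_size_3(self):
        config = noiseless_config(variants_per_branch=3)
        matrix, truth = simulate_dataset(config)
        screen = screen_samples(matrix, config.anchor_name)
        report = run_filters(matrix, screen)
        retained = [v for v in matrix.variants if v.key in report.retained_keys]
        blocks = equivalence_blocks(matrix, retained, sorted(screen.cases))
        assert len(blocks) == config.n_clades
        assert all(len(b.variants) == 3 for b in blocks)

    def test_possibly_equivalent_flag(self):
        # v2 differs from v1 only where its call is unobserved
        matrix = make_matrix(
            ["s1", "s2", "s3"],
            [(100, "v1"), (200, "v2")],
            [[D, D], [D, D], [D, M]],
        )
        blocks = equivalence_blocks(matrix, matrix.variants, matrix.samples)
        assert len(blocks) == 2
        assert possibly_equivalent_pairs(matrix, blocks) == [("v1", "v2")]


class TestBuildTree:
    def test_chain_nesting(self):
        b1 = mkblock({"a", "b", "c", "d"}, mkvariant(100, "top"))
        b2 = mkblock({"a", "b"}, mkvariant(200, "mid"))
        b3 = mkblock({"a"}, mkvariant(300, "low"))
        tree = build_tree([b1, b2, b3], ["a", "b", "c", "d", "e"])
        chain = []
        node = tree.root
        while node.children:
            assert len(node.children) == 1
            node = node.children[0]
            chain.append(node.label)
        assert chain == ["top", "mid", "low"]
        # sample c attaches at the top block's node
        labels = {n.label: n for n in tree.nodes}
        assert "c" in labels["top"].attached
        assert "a" in labels["low"].attached
        assert "e" in tree.root.attached

    def test_disjoint_blocks_are_siblings(self):
        b1 = mkblock({"a", "b"}, mkvariant(100, "x"))
        b2 = mkblock({"c", "d"}, mkvariant(200, "y"))
        tree = build_tree([b1, b2], ["a", "b", "c", "d", "e"])
        assert sorted(c.label for c in tree.root.children) == ["x", "y"]
        assert tree.root.attached == {"e"}

    def test_input_order_invariance(self):
        blocks = [
            mkblock({"a", "b", "c", "d"}, mkvariant(100, "p")),
            mkblock({"a", "b"}, mkvariant(200, "q")),
            mkblock({"c", "d"}, mkvariant(300, "r")),
            mkblock({"a"}, mkvariant(400, "s")),
        ]
        ref = None
        for perm in itertools.permutations(blocks):
            tree = build_tree(list(perm), list("abcde"))
            shape = [
                (n.label, sorted(n.attached), sorted(c.label for c in n.children))
                for n in tree.nodes
            ]
            if ref is None:
                ref = shape
            assert shape == ref

    def test_incompatible_blocks_resolved_deterministically(self):
        # {a,b,c} vs {c,d}: genuinely crossing sets; builder must stay
        # laminar via its trim rule rather than crash
        b1 = mkblock({"a", "b", "c"}, mkvariant(100, "x"))
        b2 = mkblock({"c", "d"}, mkvariant(200, "y"))
        tree = build_tree([b1, b2], list("abcde"))
        tree.assert_laminar()
        assert any(d[0] in ("trim", "expand") for d in tree.diagnostics)

    def test_attachment_conservation(self):
        config = noiseless_config(seed=9)
        matrix, _ = simulate_dataset(config)
        screen = screen_samples(matrix, config.anchor_name)
        report = run_filters(matrix, screen)
        retained = [v for v in matrix.variants if v.key in report.retained_keys]
        blocks = equivalence_blocks(matrix, retained, sorted(screen.cases))
        tree = build_tree(blocks, sorted(screen.cases))
        assert sum(len(n.attached) for n in tree.nodes) == len(screen.cases)

    def test_noiseless_recovery_matches_truth(self):
        config = noiseless_config(seed=4)
        matrix, truth = simulate_dataset(config)
        screen = screen_samples(matrix, config.anchor_name)
        report = run_filters(matrix, screen)
        retained = [v for v in matrix.variants if v.key in report.retained_keys]
        blocks = equivalence_blocks(matrix, retained, sorted(screen.cases))
        tree = build_tree(blocks, sorted(screen.cases))
        truth_clades = {
            frozenset(truth.tip_samples(n))
            for n in truth.true_tree.nodes
            if n != "ROOT"
        }
        assert clade_sample_sets(tree) == truth_clades

    @settings(max_examples=60, deadline=None)
    @given(
        st.lists(
            st.frozensets(st.sampled_from(list("abcdefghij")), min_size=1),
            min_size=1,
            max_size=12,
            unique=True,
        )
    )
    def test_arbitrary_block_sets_always_yield_laminar_tree(self, carrier_sets):
        blocks = [
            mkblock(s, mkvariant(100 + i, f"v{i}"))
            for i, s in enumerate(carrier_sets)
        ]
        tree = build_tree(blocks, list("abcdefghij"))
        tree.assert_laminar()
        assert sum(len(n.attached) for n in tree.nodes) == 10


class TestPlaceSamples:
    def test_single_block_path_length_one(self):
        matrix = make_matrix(["s1", "s2"], [(100, "x")], [[D], [A]])
        blocks = equivalence_blocks(matrix, matrix.variants, matrix.samples)
        tree = build_tree(blocks, matrix.samples)
        placements = place_samples(tree, matrix)
        assert placements["s1"].path == ["x"]
        assert placements["s2"].node_label == "ROOT"

    def test_missing_at_parent_placed_at_child_with_diagnostic(self):
        # s3 is MISSING at parent block X but DERIVED at child block Y;
        # X's parenthood is supported by s4/s5, so laminarity forces s3's
        # passage through X
        matrix = make_matrix(
            ["s1", "s2", "s3", "s4", "s5", "s6"],
            [(100, "X"), (200, "Y")],
            [
                [D, D],
                [D, D],
                [M, D],
                [D, A],
                [D, A],
                [A, A],
            ],
        )
        blocks = equivalence_blocks(matrix, matrix.variants, matrix.samples)
        tree = build_tree(blocks, matrix.samples)
        placements = place_samples(tree, matrix)
        assert placements["s3"].node_label == "Y"
        assert placements["s3"].path == ["X", "Y"]
        assert "undetermined at X (passage inferred)" in placements["s3"].diagnostics

    def test_missing_at_boundary_child_is_reported(self):
        matrix = make_matrix(
            ["s1", "s2", "s3"],
            [(100, "X"), (200, "Y")],
            [
                [D, D],
                [D, M],
                [A, A],
            ],
        )
        blocks = equivalence_blocks(matrix, matrix.variants, matrix.samples)
        tree = build_tree(blocks, matrix.samples)
        placements = place_samples(tree, matrix)
        assert placements["s2"].node_label == "X"
        assert "undetermined at Y" in placements["s2"].diagnostics

    def test_noiseless_placements_match_truth(self):
        config = noiseless_config(seed=12)
        matrix, truth = simulate_dataset(config)
        screen = screen_samples(matrix, config.anchor_name)
        report = run_filters(matrix, screen)
        retained = [v for v in matrix.variants if v.key in report.retained_keys]
        blocks = equivalence_blocks(matrix, retained, sorted(screen.cases))
        tree = build_tree(blocks, sorted(screen.cases))
        placements = place_samples(tree, matrix)
        label_to_node = {n.label: n for n in tree.nodes}
        for sample, tip in truth.sample_tip.items():
            node = label_to_node[placements[sample].node_label]
            if tip == "ROOT":
                assert node is tree.root
            else:
                assert set(node.effective_set) == truth.tip_samples(tip)


class TestReconcile:
    def scaffold(self, rows):
        parent = {}
        for name, p in rows:
            parent[name] = p
        return ScaffoldTree(parent)

    def build_named(self, spec, samples):
        """spec: list of (name, carrier set)."""
        blocks = [
            mkblock(s, mkvariant(100 + i, name)) for i, (name, s) in enumerate(spec)
        ]
        tree = build_tree(blocks, samples)
        tree.root_names.add("ANCH")
        return tree

    def test_concordant_marker_confirmed(self):
        tree = self.build_named(
            [("L21x", {"a", "b", "c"}), ("DF13x", {"a", "b"})], list("abcd")
        )
        scaffold = self.scaffold(
            [("ANCH", None), ("L21x", "ANCH"), ("DF13x", "L21x")]
        )
        report = reconcile_scaffold(tree, scaffold)
        assert report.status == {
            "ANCH": "CONFIRMED", "L21x": "CONFIRMED", "DF13x": "CONFIRMED",
        }

    def test_marker_below_new_intermediate_is_repositioned(self):
        # scaffold: M below A (i.e. below the root); data: M below C below root
        tree = self.build_named(
            [("Cnew", {"a", "b", "c"}), ("Mold", {"a", "b"})], list("abcd")
        )
        scaffold = self.scaffold([("ANCH", None), ("Mold", "ANCH")])
        report = reconcile_scaffold(tree, scaffold)
        assert report.status["Mold"] == "REPOSITIONED"
        assert report.new_parent["Mold"] == "Cnew"
        assert report.old_parent["Mold"] == "ANCH"

    def test_grandparent_ancestor_still_confirmed(self):
        # scaffold parent absent from data; tree parent carries an ancestor
        tree = self.build_named(
            [("TOPx", {"a", "b", "c"}), ("Mx", {"a", "b"})], list("abcd")
        )
        scaffold = self.scaffold(
            [("ANCH", None), ("TOPx", "ANCH"), ("MIDx", "TOPx"), ("Mx", "MIDx")]
        )
        report = reconcile_scaffold(tree, scaffold)
        # Mx's tree parent TOPx is an ancestor of its scaffold parent MIDx
        assert report.status["Mx"] == "CONFIRMED"
        assert report.status["MIDx"] == "UNPLACED"

    def test_absent_marker_unplaced(self):
        tree = self.build_named([("L21x", {"a", "b"})], list("abc"))
        scaffold = self.scaffold(
            [("ANCH", None), ("L21x", "ANCH"), ("GHOST", "L21x")]
        )
        assert reconcile_scaffold(tree, scaffold).status["GHOST"] == "UNPLACED"

    def test_scaffold_validation(self, tmp_path):
        from yphylo.core import FormatError

        p = tmp_path / "scaffold.tsv"
        p.write_text("marker_name\tparent_name\nA\t\nB\tA\nC\tZ\n")
        with pytest.raises(FormatError):
            read_scaffold(p)
        p.write_text("marker_name\tparent_name\nA\t\nB\t\n")
        with pytest.raises(FormatError):
            read_scaffold(p)

    def test_scaffold_tsv_round_trip(self, tmp_path):
        p = tmp_path / "scaffold.tsv"
        p.write_text("marker_name\tparent_name\nANCH\t\nL21x\tANCH\nDF13x\tL21x\n")
        scaffold = read_scaffold(p)
        assert scaffold.root == "ANCH"
        assert scaffold.ancestors("DF13x") == ["L21x", "ANCH"]


class TestNewick:
    def test_single_block_shape(self, tmp_path):
        matrix = make_matrix(["s1", "s2"], [(100, "blockA")], [[D], [D]])
        blocks = equivalence_blocks(matrix, matrix.variants, matrix.samples)
        tree = build_tree(blocks, matrix.samples)
        path = tmp_path / "t.nwk"
        export_newick(tree, path)
        assert path.read_text().strip() == "((s1,s2)blockA)ROOT;"

    def test_round_trip_reproduces_topology_and_labels(self, tmp_path):
        config = noiseless_config(seed=3)
        matrix, _ = simulate_dataset(config)
        screen = screen_samples(matrix, config.anchor_name)
        report = run_filters(matrix, screen)
        retained = [v for v in matrix.variants if v.key in report.retained_keys]
        blocks = equivalence_blocks(matrix, retained, sorted(screen.cases))
        tree = build_tree(blocks, sorted(screen.cases))
        path = tmp_path / "t.nwk"
        export_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        internal_labels = {
            n.label for n in parsed if not n.is_leaf() and n.label != "ROOT"
        }
        assert internal_labels == {b.label for b in blocks}
        leaf_labels = {n.taxon.label for n in parsed.leaf_node_iter()}
        assert leaf_labels == set(screen.cases)
        # clade structure is preserved
        def parsed_clades():
            out = set()
            for n in parsed.preorder_node_iter():
                if n.is_leaf() or n.label == "ROOT":
                    continue
                out.add(frozenset(l.taxon.label for l in n.leaf_iter()))
            return out

        assert parsed_clades() == clade_sample_sets(tree)

    def test_internal_node_count_equals_block_count(self, tmp_path):
        config = noiseless_config(seed=6)
        matrix, _ = simulate_dataset(config)
        screen = screen_samples(matrix, config.anchor_name)
        report = run_filters(matrix, screen)
        retained = [v for v in matrix.variants if v.key in report.retained_keys]
        blocks = equivalence_blocks(matrix, retained, sorted(screen.cases))
        tree = build_tree(blocks, sorted(screen.cases))
        path = tmp_path / "t.nwk"
        export_newick(tree, path)
        parsed = dendropy.Tree.get(path=str(path), schema="newick")
        internal = [n for n in parsed if not n.is_leaf() and n.label != "ROOT"]
        assert len(internal) == len(blocks)
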