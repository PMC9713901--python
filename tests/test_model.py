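"""Hierarchy model: loading, statistics, node selection, sequence rollup."""

import numpy as np
import pytest

import funcmap as fm
from funcmap.errors import LoadError, SelectionError, StructureError
from funcmap.model import sequences_under
from funcmap.simulate import ClassificationDesign, SyntheticDesign, generate_bundle

from conftest import build_classification
from oracles import enumerate_root_paths, sequences_under_bruteforce


def _write_bundle_files(tmp_path, paths, leaf_map, fasta, taxa=None):
    h = tmp_path / "h.tsv"
    h.write_text("".join("\t".join(p) + "\n" for p in paths))
    lm = tmp_path / "lm.tsv"
    lm.write_text("".join(f"{a}\t{b}\n" for a, b in leaf_map))
    fa = tmp_path / "seqs.fasta"
    fa.write_text("".join(f">{sid}\n{res}\n" for sid, res in fasta.items()))
    tx = None
    if taxa:
        tx = tmp_path / "taxa.tsv"
        tx.write_text("".join(f"{a}\t{b}\n" for a, b in taxa))
    return h, fa, lm, tx


class TestLoad:
    def test_toy_bundle_counts(self, tmp_path):
        h, fa, lm, _ = _write_bundle_files(
            tmp_path,
            [("root", "A", "x"), ("root", "A", "y"), ("root", "B", "z")],
            [("x", "s1"), ("y", "s2"), ("z", "s3")],
            {"s1": "MKV", "s2": "MKL", "s3": "MKI"},
        )
        c = fm.load_classification(h, fa, lm)
        assert len(c.nodes) == 6
        st = fm.hierarchy_stats(c)
        assert (st.leaves, st.internal_nodes) == (3, 3)
        # no taxa file -> Unclassified
        assert all(r.superkingdom == "Unclassified" for r in c.records.values())

    def test_duplicated_leaf_is_structure_error(self, tmp_path):
        h, fa, lm, _ = _write_bundle_files(
            tmp_path,
            [("root", "A", "x"), ("root", "B", "x")],
            [("x", "s1")],
            {"s1": "MKV"},
        )
        with pytest.raises(StructureError):
            fm.load_classification(h, fa, lm)

    def test_duplicated_internal_label_is_flattened(self, tmp_path):
        # DAG-derived duplication: same internal term under two parents
        h, fa, lm, _ = _write_bundle_files(
            tmp_path,
            [("root", "A", "D", "x"), ("root", "B", "D", "y")],
            [("x", "s1"), ("y", "s2")],
            {"s1": "MKV", "s2": "MKL"},
        )
        c = fm.load_classification(h, fa, lm)
        dups = [n for n in c.nodes.values() if n.label == "D"]
        assert len(dups) == 2
        assert {n.node_id for n in dups} == {"D", "D#2"}

    def test_node_both_leaf_and_internal_is_error(self, tmp_path):
        h, fa, lm, _ = _write_bundle_files(
            tmp_path,
            [("root", "A"), ("root", "A", "x")],
            [("x", "s1")],
            {"s1": "MKV"},
        )
        with pytest.raises(StructureError):
            fm.load_classification(h, fa, lm)

    def test_unknown_identifiers_named_in_error(self, tmp_path):
        h, fa, lm, _ = _write_bundle_files(
            tmp_path,
            [("root", "x")],
            [("x", "ghost")],
            {"s1": "MKV"},
        )
        with pytest.raises(LoadError, match="ghost"):
            fm.load_classification(h, fa, lm)

    def test_round_trip_is_identity(self, tmp_path):
        design = SyntheticDesign(
            seed=11,
            classifications=(ClassificationDesign("rt", shape=(3, 2), n_families=6),),
            sharing_probability=0.3,
        )
        bundles, _ = generate_bundle(design)
        c = bundles["rt"]
        paths = fm.write_classification(c, tmp_path)
        c2 = fm.load_classification(
            paths["hierarchy"], paths["fasta"], paths["leaf_map"], paths["taxa"], name="rt"
        )
        assert set(c.nodes) == set(c2.nodes)
        for nid in c.nodes:
            a, b = c.nodes[nid], c2.nodes[nid]
            assert (a.label, a.parent, sorted(a.children)) == (b.label, b.parent, sorted(b.children))
        assert c.leaf_sequences == c2.leaf_sequences
        assert c.records == c2.records


class TestStats:
    def test_single_chain(self):
        c = build_classification("chain", [("root", "a", "leaf")], {"leaf": {"s"}}, {"s": "MKV"})
        st = fm.hierarchy_stats(c)
        assert (st.median_depth, st.internal_nodes, st.leaves, st.sequences) == (3, 2, 1, 1)

    def test_even_median_rounds_half_up(self):
        c = build_classification(
            "m", [("root", "x"), ("root", "a", "y")], {"x": {"s"}, "y": {"s"}}, {"s": "MKV"}
        )
        # leaf depths 2 and 3 -> mean 2.5 -> rounds to 3
        assert fm.hierarchy_stats(c).median_depth == 3

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce_path_walker(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(int(rng.integers(1, 4)) for _ in range(int(rng.integers(1, 4))))
        design = SyntheticDesign(
            seed=seed,
            classifications=(ClassificationDesign("r", shape=shape, n_families=4),),
        )
        bundles, _ = generate_bundle(design)
        c = bundles["r"]
        paths = enumerate_root_paths(c.nodes)
        depths = sorted(len(p) for p in paths)
        n = len(depths)
        med = depths[n // 2] if n % 2 else -((-(depths[n // 2 - 1] + depths[n // 2])) // 2)
        st = fm.hierarchy_stats(c)
        assert st.median_depth == med
        assert st.leaves == len(paths)
        assert st.leaves + st.internal_nodes == len(c.nodes)

    def test_distinct_sequence_count_with_multi_leaf_membership(self):
        c = build_classification(
            "m", [("root", "x"), ("root", "y")], {"x": {"s"}, "y": {"s"}}, {"s": "MKV"}
        )
        assert fm.hierarchy_stats(c).sequences == 1

    def test_invariant_under_child_order_permutation(self, toy_tree):
        st = fm.hierarchy_stats(toy_tree)
        toy_tree.nodes["root"].children.reverse()
        assert fm.hierarchy_stats(toy_tree) == st


class TestSelection:
    def test_depth_level_one_is_root_children(self, toy_tree):
        sel = fm.select_nodes(toy_tree, 1)
        assert set(sel.selected) == {"A", "B"}

    def test_explicit_ancestor_violation(self, toy_tree):
        with pytest.raises(SelectionError):
            fm.select_nodes(toy_tree, ["root", "A"])

    def test_explicit_unknown_node(self, toy_tree):
        with pytest.raises(SelectionError):
            fm.select_nodes(toy_tree, ["nope"])

    def test_depth_level_hits_planted_tier(self):
        design = SyntheticDesign(
            seed=3,
            classifications=(
                ClassificationDesign("egg", shape=(4, 2, 2), selection_level=2, n_families=8),
            ),
        )
        bundles, truth = generate_bundle(design)
        sel = fm.select_nodes(bundles["egg"], 2)
        assert list(sel.selected) == sorted(truth.selection_nodes["egg"])


class TestSequencesUnder:
    def test_leaf_and_root(self, toy_tree):
        assert sequences_under(toy_tree, "x") == {"s1"}
        assert sequences_under(toy_tree, "root") == {"s1", "s2", "s3"}
        assert len(sequences_under(toy_tree, "root")) == fm.hierarchy_stats(toy_tree).sequences

    def test_unknown_node(self, toy_tree):
        with pytest.raises(LoadError):
            sequences_under(toy_tree, "nope")

    def test_child_subset_of_parent(self, toy_tree):
        for nid, node in toy_tree.nodes.items():
            for ch in node.children:
                assert sequences_under(toy_tree, ch) <= sequences_under(toy_tree, nid)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_bruteforce_union(self, seed):
        design = SyntheticDesign(
            seed=seed,
            classifications=(ClassificationDesign("r", shape=(3, 2), n_families=6),),
            sharing_probability=0.5,
        )
        bundles, _ = generate_bundle(design)
        c = bundles["r"]
        for nid in c.nodes:
            assert sequences_under(c, nid) == sequences_under_bruteforce(c, nid)
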