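"""Cross-mapping: coverage asymmetry, concordance recovery, self-overlap."""

import math

import numpy as np
import pytest

import funcmap as fm
from funcmap.crossmap import best_match_table
from funcmap.errors import InputError
from funcmap.model import ProteinRecord
from funcmap.simulate import (
    ClassificationDesign,
    ShareSpec,
    SyntheticDesign,
    generate_bundle,
    random_protein,
)

from conftest import build_classification


def subset_pair(rng, n_total=8, n_sub=4, length=90):
    """b holds n_total sequences; a holds a strict subset of them."""
    seqs = {f"s{i}": random_protein(length, rng) for i in range(n_total)}
    b = build_classification(
        "bigdb", [("bigdb", "n", f"l{i}") for i in range(n_total)],
        {f"l{i}": {f"s{i}"} for i in range(n_total)}, seqs,
    )
    sub = {f"s{i}": seqs[f"s{i}"] for i in range(n_sub)}
    a = build_classification(
        "subdb", [("subdb", "n", f"l{i}") for i in range(n_sub)],
        {f"l{i}": {f"s{i}"} for i in range(n_sub)}, sub,
    )
    return a, b


class TestCoverage:
    def test_subset_maps_fully_superset_does_not(self, rng):
        a, b = subset_pair(rng)
        assert fm.database_coverage(a, b).percent_covered == 100.0
        assert fm.database_coverage(b, a).percent_covered < 100.0

    def test_empty_source_is_error(self, rng):
        a, b = subset_pair(rng)
        a.records = {}
        with pytest.raises(InputError):
            fm.database_coverage(a, b)

    def test_planted_share_fraction_recovered(self):
        a = ClassificationDesign("A", shape=(1, 5), n_families=10, copies_per_family=2)
        b = ClassificationDesign("B", shape=(1, 5), n_families=4, copies_per_family=2)
        design = SyntheticDesign(
            seed=9, classifications=(a, b),
            shares=(ShareSpec("A", "B", 0, (0,), 0.6),),
        )
        bundles, truth = generate_bundle(design)
        cov = fm.database_coverage(bundles["A"], bundles["B"])
        assert cov.percent_covered == pytest.approx(
            100 * truth.expected_coverage["A->B"], abs=1e-9
        )
        assert cov.percent_covered == pytest.approx(60.0)


def planted_2x2(seed=7):
    """Two row nodes, each: 60% C1-only, 10% C1∧C2, 20% C2-only, 10% exclusive."""
    a = ClassificationDesign("A", shape=(2, 3), selection_level=1, n_families=40,
                             copies_per_family=3)
    b = ClassificationDesign("B", shape=(2, 3), selection_level=1, n_families=10,
                             copies_per_family=2)
    shares = []
    for i in range(2):
        shares.append(ShareSpec("A", "B", i, (0,), 0.60))
        shares.append(ShareSpec("A", "B", i, (0, 1), 0.10))
        shares.append(ShareSpec("A", "B", i, (1,), 0.20))
    return SyntheticDesign(seed=seed, classifications=(a, b), shares=tuple(shares))


class TestConcordance:
    def test_self_concordance_has_unit_diagonal(self, rng):
        _, b = subset_pair(rng)
        sel = fm.select_nodes(b, 1)
        m = fm.concordance_matrix(b, b, sel, sel)
        for n in sel.selected:
            assert m.entries[(n, n)] == 1.0
            assert m.unassigned[n] == 0.0

    def test_unrelated_target_all_unassigned(self, rng):
        a, _ = subset_pair(rng)
        other = {f"z{i}": random_protein(90, rng) for i in range(4)}
        b = build_classification(
            "other", [("other", "n", f"l{i}") for i in range(4)],
            {f"l{i}": {f"z{i}"} for i in range(4)}, other,
        )
        m = fm.concordance_matrix(a, b, fm.select_nodes(a, 1), fm.select_nodes(b, 1))
        assert all(v == 1.0 for v in m.unassigned.values())

    def test_planted_fractions_recovered(self):
        bundles, truth = generate_bundle(planted_2x2())
        A, B = bundles["A"], bundles["B"]
        m = fm.concordance_matrix(A, B, fm.select_nodes(A, 1), fm.select_nodes(B, 1))
        for r, want in truth.expected_concordance["A->B"].items():
            for c, frac in want["entries"].items():
                assert m.entries[(r, c)] == pytest.approx(frac, abs=0.05)
            assert m.unassigned[r] == pytest.approx(want["unassigned"], abs=0.05)

    def test_accounting_identity_per_row(self):
        bundles, _ = generate_bundle(planted_2x2())
        A, B = bundles["A"], bundles["B"]
        m = fm.concordance_matrix(A, B, fm.select_nodes(A, 1), fm.select_nodes(B, 1))
        ctx_hits = {}
        for r in m.row_nodes.selected:
            # hit fraction (landed anywhere) + unassigned = 1
            assert m.unassigned[r] + m.hit_outside[r] <= 1.0
            covered = 1.0 - m.unassigned[r]
            assert covered >= max(m.entries[(r, c)] for c in m.col_nodes.selected)

    def test_zero_size_row_flagged_not_zero(self, rng):
        a, b = subset_pair(rng)
        # add an empty leaf-less internal node via an empty leaf set
        a.nodes["n"].children.append("empty")
        from funcmap.model import ClassNode

        a.nodes["empty"] = ClassNode("empty", "empty", "n")
        sel = fm.NodeSelection("subdb", ("empty",), "explicit")
        m = fm.concordance_matrix(a, b, sel, fm.select_nodes(b, 1))
        assert m.row_sizes["empty"] == 0
        assert math.isnan(m.unassigned["empty"])

    def test_growing_target_never_increases_unassigned(self, rng):
        bundles, _ = generate_bundle(planted_2x2())
        A, B = bundles["A"], bundles["B"]
        rows = fm.select_nodes(A, 1)
        m1 = fm.concordance_matrix(A, B, rows, fm.select_nodes(B, 1))
        # graft every sequence of A into a new leaf of B
        from funcmap.model import ClassNode

        B.nodes["B.0"].children.append("graft")
        B.nodes["graft"] = ClassNode("graft", "graft", "B.0")
        for sid, rec in A.records.items():
            B.records[f"g_{sid}"] = ProteinRecord(f"g_{sid}", rec.residues, rec.superkingdom, "B")
        B.leaf_sequences["graft"] = {f"g_{sid}" for sid in A.records}
        B._seq_leaves = None
        m2 = fm.concordance_matrix(A, B, rows, fm.select_nodes(B, 1))
        for r in rows.selected:
            assert m2.unassigned[r] <= m1.unassigned[r]


class TestBestMatch:
    def _toy_matrix(self):
        rows = fm.NodeSelection("A", ("r1", "r2", "r3"), "explicit")
        cols = fm.NodeSelection("B", ("c1", "c2"), "explicit")
        entries = {
            ("r1", "c1"): 0.33, ("r1", "c2"): 0.10,
            ("r2", "c1"): 0.05, ("r2", "c2"): 0.12,
            ("r3", "c1"): 0.50, ("r3", "c2"): 0.50,
        }
        m = fm.ConcordanceMatrix(
            rows, cols, entries,
            {r: 0.0 for r in rows.selected}, {r: 0.0 for r in rows.selected},
            {r: 10 for r in rows.selected},
        )
        a = build_classification("A", [("A", r) for r in rows.selected],
                                 {r: {"s"} for r in rows.selected}, {"s": "MKV"})
        b = build_classification("B", [("B", c) for c in cols.selected],
                                 {c: {"t"} for c in cols.selected}, {"t": "MKV"})
        return m, a, b

    def test_argmax_filter_and_tiebreak(self):
        m, a, b = self._toy_matrix()
        rows = best_match_table(m, a, b, min_percent=15)
        got = {r.source_path: (r.target_path, r.percent) for r in rows}
        # r2's max (12%) is below the filter; r3 ties -> lexicographic target
        assert got == {"A → r1": ("B → c1", 33), "A → r3": ("B → c1", 50)}

    def test_all_below_threshold_empty(self):
        m, a, b = self._toy_matrix()
        assert best_match_table(m, a, b, min_percent=60) == []


class TestSelfOverlap:
    def test_partitioned_classification_is_strict(self, rng):
        _, b = subset_pair(rng)
        sel = fm.select_nodes(b, 2)
        m = fm.self_overlap(b, sel)
        assert all(
            m.overlap[(i, j)] == (1.0 if i == j else 0.0)
            for i in sel.selected for j in sel.selected
        )
        assert fm.strictness_check(b, sel) is True

    def test_contained_node_pattern(self):
        # node W's single sequence also lies under U -> overlap(W, U) = 1
        c = build_classification(
            "kegglike",
            [("root", "U", "u1"), ("root", "W", "w1")],
            {"u1": {"s1", "s2"}, "w1": {"s1"}},
            {"s1": "MKVLA", "s2": "MWIPT"},
        )
        sel = fm.select_nodes(c, 1)
        m = fm.self_overlap(c, sel)
        assert m.overlap[("W", "U")] == 1.0
        assert m.overlap[("U", "W")] == 0.5
        assert fm.strictness_check(c, sel) is False

    @pytest.mark.parametrize("seed", range(5))
    def test_no_sharing_designs_are_strict(self, seed):
        design = SyntheticDesign(
            seed=seed,
            classifications=(ClassificationDesign("s", shape=(3, 2), n_families=6),),
            sharing_probability=0.0,
        )
        bundles, _ = generate_bundle(design)
        c = bundles["s"]
        assert fm.strictness_check(c, fm.select_nodes(c, 1)) is True

    def test_matches_bruteforce_set_intersections(self):
        design = SyntheticDesign(
            seed=77,
            classifications=(ClassificationDesign("s", shape=(3, 2), n_families=9),),
            sharing_probability=0.6,
        )
        bundles, _ = generate_bundle(design)
        c = bundles["s"]
        sel = fm.select_nodes(c, 1)
        m = fm.self_overlap(c, sel)
        from funcmap.model import sequences_under

        for i in sel.selected:
            si = sequences_under(c, i)
            for j in sel.selected:
                assert m.overlap[(i, j)] == len(si & sequences_under(c, j)) / len(si)
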