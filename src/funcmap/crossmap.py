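"""Cross-mapping of classification systems by sequence content.

The core comparison: every sequence of one system is queried against the
reference sequences of another; a single best hit passing the
query-coverage gate links it to the leaves (hence nodes) of the target
system. Aggregated at chosen comparison-level nodes this yields

* database coverage — the percentage of one system's sequences with a
  qualifying hit anywhere in the other,
* concordance matrices — per (source node, target node), the proportion
  of sequences under the source node (with descendants) whose best hit
  falls under the target node, plus the unassigned fraction,
* best-match tables — per source node, the argmax target node, filtered
  at a minimum percentage,
* self-overlap — identifier intersections between nodes of the *same*
  system (no alignment), and the derived strict-hierarchy check.

Cross-mapping is generally asymmetric: node sizes differ between systems
and alignment coverage is measured on the query.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import pandas as pd

from .align import AlignmentContext
from .errors import InputError
from .model import Classification, NodeSelection, sequences_under


@dataclass(frozen=True)
class CoverageResult:
    from_db: str
    to_db: str
    n_queries: int
    n_with_hit: int

    @property
    def percent_covered(self) -> float:
        return 100.0 * self.n_with_hit / self.n_queries


@dataclass
class ConcordanceMatrix:
    """Node-by-node proportion table between two classifications.

    ``entries[(r, c)]`` is the fraction of distinct sequences under row
    node ``r`` whose best hit lands under column node ``c``. One best hit
    can credit several overlapping column nodes, so row sums may exceed 1.
    ``unassigned[r]`` is the fraction with no qualifying hit at all;
    ``hit_outside[r]`` the fraction with a hit that falls under none of
    the selected column nodes. Rows with zero sequences carry NaN.
    """

    row_nodes: NodeSelection
    col_nodes: NodeSelection
    entries: dict[tuple[str, str], float]
    unassigned: dict[str, float]
    hit_outside: dict[str, float]
    row_sizes: dict[str, int]

    def to_frame(self) -> pd.DataFrame:
        rows = list(self.row_nodes.selected)
        cols = list(self.col_nodes.selected)
        data = {
            c: [self.entries[(r, c)] for r in rows] for c in cols
        }
        data["unassigned"] = [self.unassigned[r] for r in rows]
        data["hit_outside_selection"] = [self.hit_outside[r] for r in rows]
        return pd.DataFrame(data, index=rows)


@dataclass(frozen=True)
class BestMatchRow:
    source_path: str
    target_path: str
    percent: int


@dataclass
class SelfOverlapMatrix:
    nodes: NodeSelection
    overlap: dict[tuple[str, str], float]

    def to_frame(self) -> pd.DataFrame:
        sel = list(self.nodes.selected)
        return pd.DataFrame(
            {j: [self.overlap[(i, j)] for i in sel] for j in sel}, index=sel
        )


# ---------------------------------------------------------------------------


def database_coverage(
    a: Classification,
    b: Classification,
    ctx: AlignmentContext | None = None,
    min_query_cover: float = 0.9,
) -> CoverageResult:
    """Percentage of ``a``'s sequences with a qualifying best hit in ``b``."""
    if not a.records:
        raise InputError(f"{a.name}: no sequences to map")
    ctx = ctx or AlignmentContext(records=b.records, min_query_cover=min_query_cover)
    n_hit = sum(
        1 for sid in sorted(a.records) if ctx.best_hit(a.records[sid]) is not None
    )
    return CoverageResult(a.name, b.name, n_queries=len(a.records), n_with_hit=n_hit)


def concordance_matrix(
    a: Classification,
    b: Classification,
    rows: NodeSelection,
    cols: NodeSelection,
    ctx: AlignmentContext | None = None,
    min_query_cover: float = 0.9,
) -> ConcordanceMatrix:
    """Best-hit concordance between selected nodes of two classifications."""
    if rows.classification != a.name or cols.classification != b.name:
        raise InputError("node selections do not match the classifications")
    ctx = ctx or AlignmentContext(records=b.records, min_query_cover=min_query_cover)

    col_sets = {c: sequences_under(b, c) for c in cols.selected}
    subj_to_cols: dict[str, list[str]] = {}
    for c, seqs in col_sets.items():
        for sid in seqs:
            subj_to_cols.setdefault(sid, []).append(c)

    entries: dict[tuple[str, str], float] = {}
    unassigned: dict[str, float] = {}
    hit_outside: dict[str, float] = {}
    row_sizes: dict[str, int] = {}
    for r in rows.selected:
        seqs = sorted(sequences_under(a, r))
        row_sizes[r] = len(seqs)
        if not seqs:
            # zero-sequence rows are flagged undefined, not silently zero
            for c in cols.selected:
                entries[(r, c)] = math.nan
            unassigned[r] = math.nan
            hit_outside[r] = math.nan
            continue
        col_counts = {c: 0 for c in cols.selected}
        n_unassigned = 0
        n_outside = 0
        for sid in seqs:
            hit = ctx.best_hit(a.records[sid])
            if hit is None:
                n_unassigned += 1
                continue
            owners = subj_to_cols.get(hit.subject_id)
            if not owners:
                n_outside += 1
                continue
            for c in owners:
                col_counts[c] += 1
        n = len(seqs)
        for c in cols.selected:
            entries[(r, c)] = col_counts[c] / n
        unassigned[r] = n_unassigned / n
        hit_outside[r] = n_outside / n
    return ConcordanceMatrix(rows, cols, entries, unassigned, hit_outside, row_sizes)


def _round_half_up(x: float) -> int:
    return int(math.floor(x + 0.5))


def best_match_table(
    m: ConcordanceMatrix,
    a: Classification,
    b: Classification,
    min_percent: float = 15.0,
) -> list[BestMatchRow]:
    """Per source node, the argmax target node, filtered at ``min_percent``.

    Node paths are reported as " → "-joined labels; percentages as
    integers (rounded half up). Ties go to the lexicographically smallest
    target node path.
    """
    out: list[BestMatchRow] = []
    for r in m.row_nodes.selected:
        if m.row_sizes[r] == 0:
            continue
        ranked = sorted(
            ((m.entries[(r, c)], b.path_labels(c)) for c in m.col_nodes.selected),
            key=lambda t: (-t[0], t[1]),
        )
        if not ranked:
            continue
        frac, target = ranked[0]
        if frac * 100 >= min_percent:
            out.append(BestMatchRow(a.path_labels(r), target, _round_half_up(frac * 100)))
    return out


def self_overlap(c: Classification, sel: NodeSelection) -> SelfOverlapMatrix:
    """Pairwise identifier sharing among nodes of one classification.

    ``overlap[(i, j)]`` = |sequences under i ∩ sequences under j| /
    |sequences under i|; an asymmetric containment measure. Nodes with no
    sequences get NaN rows.
    """
    if sel.classification != c.name:
        raise InputError("selection does not belong to this classification")
    sets = {n: sequences_under(c, n) for n in sel.selected}
    overlap: dict[tuple[str, str], float] = {}
    for i in sel.selected:
        si = sets[i]
        for j in sel.selected:
            overlap[(i, j)] = len(si & sets[j]) / len(si) if si else math.nan
    return SelfOverlapMatrix(sel, overlap)


def strictness_check(c: Classification, sel: NodeSelection) -> bool:
    """True iff selected nodes share no sequences (a strict hierarchy)."""
    m = self_overlap(c, sel)
    return all(
        m.overlap[(i, j)] == 0
        for i in sel.selected
        for j in sel.selected
        if i != j and not math.isnan(m.overlap[(i, j)])
    )


# ---------------------------------------------------------------------------
# TSV export (full precision; percent rounding happens only here)


def write_concordance(
    m: ConcordanceMatrix,
    a: Classification,
    b: Classification,
    path: str | Path,
    header: str = "",
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        cols = [b.path_labels(c) for c in m.col_nodes.selected]
        fh.write("source\tsize\t" + "\t".join(cols) + "\tunassigned\thit_outside_selection\n")
        for r in m.row_nodes.selected:
            vals = [m.entries[(r, c)] for c in m.col_nodes.selected]
            vals += [m.unassigned[r], m.hit_outside[r]]
            cells = "\t".join("NA" if math.isnan(v) else f"{v:.6f}" for v in vals)
            fh.write(f"{a.path_labels(r)}\t{m.row_sizes[r]}\t{cells}\n")


def write_best_matches(
    rows: list[BestMatchRow], path: str | Path, header: str = ""
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        fh.write("source\ttarget\tpercent\n")
        for row in rows:
            fh.write(f"{row.source_path}\t{row.target_path}\t{row.percent}\n")


def write_self_overlap(
    m: SelfOverlapMatrix, c: Classification, path: str | Path, header: str = ""
) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        sel = list(m.nodes.selected)
        fh.write("node\t" + "\t".join(c.path_labels(j) for j in sel) + "\n")
        for i in sel:
            cells = "\t".join(
                "NA" if math.isnan(m.overlap[(i, j)]) else f"{m.overlap[(i, j)]:.6f}"
                for j in sel
            )
            fh.write(f"{c.path_labels(i)}\t{cells}\n")
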