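"""Data model and I/O for sequence-annotated classification hierarchies.

A classification is a rooted hierarchy of functional terms whose leaves
(the most specific terms: orthologous groups, protein families,
subsystems) carry sets of reference protein sequences. One sequence may
sit under several leaves, and — after flattening DAG-derived hierarchies —
the same term label may occur on several nodes.

The on-disk bundle dialect is deliberately minimal, because the native
distribution formats of real systems (eggNOG, KEGG, SEED, InterPro) vary:

* ``hierarchy``: UTF-8 text, one tab-separated root-to-leaf path per line,
  ``#`` starts a comment, first component is the root.
* ``leaf_map``: 2-column TSV ``leaf_node_id<TAB>seq_id``.
* ``taxa``: 2-column TSV ``seq_id<TAB>superkingdom`` (optional).
* ``sequences``: protein FASTA; identifier = first whitespace token.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO

from .errors import InputError, LoadError, SelectionError, StructureError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")

SUPERKINGDOMS = ("Archaea", "Bacteria", "Eukarya", "Virus", "Unclassified")

#: separator appended to duplicated node labels to keep node_ids unique
DUP_SUFFIX_SEP = "#"


@dataclass(frozen=True)
class ProteinRecord:
    """A reference amino-acid sequence with taxonomic provenance."""

    seq_id: str
    residues: str
    superkingdom: str = "Unclassified"
    source_db: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise InputError(f"empty residue string for {self.seq_id!r}")
        bad = set(self.residues) - ALLOWED_RESIDUES
        if bad:
            raise InputError(
                f"illegal residues {sorted(bad)} in {self.seq_id!r}"
            )
        if self.superkingdom not in SUPERKINGDOMS:
            raise InputError(
                f"unknown superkingdom {self.superkingdom!r} for {self.seq_id!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class ClassNode:
    node_id: str
    label: str
    parent: str | None
    children: list[str] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children


@dataclass
class Classification:
    """A rooted hierarchy whose leaves carry sets of protein sequence ids."""

    name: str
    nodes: dict[str, ClassNode]
    leaf_sequences: dict[str, set[str]]
    records: dict[str, ProteinRecord]

    def __post_init__(self) -> None:
        self._validate()
        self._seq_leaves: dict[str, set[str]] | None = None

    # -- structure ---------------------------------------------------------

    def _validate(self) -> None:
        roots = [n.node_id for n in self.nodes.values() if n.parent is None]
        if len(roots) != 1:
            raise StructureError(f"{self.name}: expected one root, found {roots}")
        for n in self.nodes.values():
            for ch in n.children:
                if self.nodes[ch].parent != n.node_id:
                    raise StructureError(
                        f"{self.name}: inconsistent parent link at {ch!r}"
                    )
        # cycle check: every node must reach the root
        for n in self.nodes.values():
            seen = set()
            cur: str | None = n.node_id
            while cur is not None:
                if cur in seen:
                    raise StructureError(f"{self.name}: cycle through {cur!r}")
                seen.add(cur)
                cur = self.nodes[cur].parent
        for leaf_id in self.leaf_sequences:
            if leaf_id not in self.nodes:
                raise LoadError(f"{self.name}: unknown leaf {leaf_id!r} in leaf map")
            if not self.nodes[leaf_id].is_leaf:
                raise StructureError(
                    f"{self.name}: leaf map entry {leaf_id!r} is not a leaf"
                )
        mapped = set()
        for leaf_id, seqs in self.leaf_sequences.items():
            for sid in seqs:
                if sid not in self.records:
                    raise LoadError(
                        f"{self.name}: leaf {leaf_id!r} references unknown sequence {sid!r}"
                    )
            mapped |= seqs
        orphans = set(self.records) - mapped
        if orphans:
            raise LoadError(
                f"{self.name}: records unreachable from any leaf: {sorted(orphans)[:5]}"
            )

    @property
    def root(self) -> ClassNode:
        return next(n for n in self.nodes.values() if n.parent is None)

    def leaves(self) -> list[str]:
        return [nid for nid, n in self.nodes.items() if n.is_leaf]

    def path_to_root(self, node_id: str) -> list[str]:
        """Node ids from root to ``node_id``, inclusive."""
        if node_id not in self.nodes:
            raise LoadError(f"{self.name}: unknown node {node_id!r}")
        path = []
        cur: str | None = node_id
        while cur is not None:
            path.append(cur)
            cur = self.nodes[cur].parent
        return path[::-1]

    def path_labels(self, node_id: str) -> str:
        return " → ".join(self.nodes[nid].label for nid in self.path_to_root(node_id))

    def descendants(self, node_id: str) -> list[str]:
        """All descendants of ``node_id`` (excluding itself), preorder."""
        out: list[str] = []
        stack = list(reversed(self.nodes[node_id].children))
        while stack:
            nid = stack.pop()
            out.append(nid)
            stack.extend(reversed(self.nodes[nid].children))
        return out

    def leaves_of_sequence(self, seq_id: str) -> set[str]:
        if self._seq_leaves is None:
            rev: dict[str, set[str]] = {}
            for leaf_id, seqs in self.leaf_sequences.items():
                for sid in seqs:
                    rev.setdefault(sid, set()).add(leaf_id)
            self._seq_leaves = rev
        return self._seq_leaves.get(seq_id, set())


@dataclass(frozen=True)
class HierarchyStats:
    """Summary statistics of one hierarchy (depth counts nodes, root = 1)."""

    median_depth: int
    internal_nodes: int
    leaves: int
    sequences: int


@dataclass(frozen=True)
class NodeSelection:
    """Validated set of comparison-level nodes of one classification."""

    classification: str
    selected: tuple[str, ...]
    policy: str


# ---------------------------------------------------------------------------
# loading / writing


def _parse_hierarchy(path: Path, name: str) -> dict[str, ClassNode]:
    """Parse root-to-leaf path lines into a flattened tree.

    A label reappearing under a *different* parent is DAG-derived
    duplication: the node is duplicated with a suffixed node_id and the
    label preserved. A label terminating two paths under different parents
    would leave the leaf map ambiguous and is a structure error.
    """
    nodes: dict[str, ClassNode] = {}
    by_parent: dict[tuple[str | None, str], str] = {}  # (parent_id, label) -> node_id
    label_count: dict[str, int] = {}
    path_ends: set[str] = set()  # node_ids that terminate some path (leaves)

    def base_label(component: str) -> str:
        return component.split(DUP_SUFFIX_SEP, 1)[0]

    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.lstrip().startswith("#"):
                continue
            components = line.split("\t")
            parent_id: str | None = None
            for depth, comp in enumerate(components):
                label = base_label(comp)
                key = (parent_id, label)
                if key in by_parent:
                    nid = by_parent[key]
                else:
                    if parent_id is None and by_parent:
                        raise StructureError(
                            f"{name}:{lineno}: second root {label!r}"
                        )
                    n = label_count.get(label, 0)
                    nid = label if n == 0 else f"{label}{DUP_SUFFIX_SEP}{n + 1}"
                    label_count[label] = n + 1
                    if n > 0 and depth == len(components) - 1:
                        raise StructureError(
                            f"{name}:{lineno}: leaf {label!r} listed under "
                            f"conflicting parents"
                        )
                    nodes[nid] = ClassNode(nid, label, parent_id)
                    by_parent[key] = nid
                    if parent_id is not None:
                        nodes[parent_id].children.append(nid)
                parent_id = nid
            assert parent_id is not None
            path_ends.add(parent_id)

    if not nodes:
        raise LoadError(f"{name}: hierarchy file {path} is empty")
    for nid in path_ends:
        if nodes[nid].children:
            raise StructureError(
                f"{name}: node {nid!r} is both a leaf and an internal node"
            )
    return nodes


def load_classification(
    hierarchy_path: str | Path,
    fasta: str | Path,
    leaf_map: str | Path,
    taxa: str | Path | None = None,
    name: str | None = None,
) -> Classification:
    """Load a classification bundle from its four text files.

    Sequences without a ``taxa`` entry get superkingdom ``Unclassified``.
    """
    hierarchy_path = Path(hierarchy_path)
    name = name or hierarchy_path.stem
    nodes = _parse_hierarchy(hierarchy_path, name)

    taxa_map: dict[str, str] = {}
    if taxa is not None:
        for sid, kingdom in _read_tsv2(taxa):
            taxa_map[sid] = kingdom

    records: dict[str, ProteinRecord] = {}
    for rec in SeqIO.parse(str(fasta), "fasta"):
        if rec.id in records:
            raise LoadError(f"{name}: duplicate sequence id {rec.id!r}")
        records[rec.id] = ProteinRecord(
            seq_id=rec.id,
            residues=str(rec.seq).upper(),
            superkingdom=taxa_map.get(rec.id, "Unclassified"),
            source_db=name,
        )

    leaf_sequences: dict[str, set[str]] = {}
    for leaf_id, sid in _read_tsv2(leaf_map):
        if leaf_id not in nodes:
            raise LoadError(f"{name}: leaf map references unknown leaf {leaf_id!r}")
        if sid not in records:
            raise LoadError(f"{name}: leaf map references unknown sequence {sid!r}")
        leaf_sequences.setdefault(leaf_id, set()).add(sid)

    return Classification(name, nodes, leaf_sequences, records)


def _read_tsv2(path: str | Path) -> Iterable[tuple[str, str]]:
    with open(path, encoding="utf-8") as fh:
        for lineno, raw in enumerate(fh, 1):
            line = raw.rstrip("\n")
            if not line or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise LoadError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            yield parts[0], parts[1]


def write_classification(c: Classification, out_dir: str | Path) -> dict[str, Path]:
    """Write a bundle; ``load_classification`` of the result reproduces ``c``.

    Path components are node_ids (suffixed ids round-trip to the same
    label), so writing and reloading is the identity on all fields.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "hierarchy": out / f"{c.name}.hierarchy.tsv",
        "fasta": out / f"{c.name}.fasta",
        "leaf_map": out / f"{c.name}.leaf_map.tsv",
        "taxa": out / f"{c.name}.taxa.tsv",
    }
    with open(paths["hierarchy"], "w", encoding="utf-8") as fh:
        for leaf_id in sorted(c.leaves()):
            fh.write("\t".join(c.path_to_root(leaf_id)) + "\n")
    with open(paths["fasta"], "w", encoding="utf-8") as fh:
        for sid in sorted(c.records):
            fh.write(f">{sid}\n")
            res = c.records[sid].residues
            for i in range(0, len(res), 60):
                fh.write(res[i : i + 60] + "\n")
    with open(paths["leaf_map"], "w", encoding="utf-8") as fh:
        for leaf_id in sorted(c.leaf_sequences):
            for sid in sorted(c.leaf_sequences[leaf_id]):
                fh.write(f"{leaf_id}\t{sid}\n")
    with open(paths["taxa"], "w", encoding="utf-8") as fh:
        for sid in sorted(c.records):
            fh.write(f"{sid}\t{c.records[sid].superkingdom}\n")
    return paths


# ---------------------------------------------------------------------------
# statistics and node selection


def _round_half_up(x_num: int, x_den: int) -> int:
    # round(num/den) half up, integer arithmetic to dodge float ties
    return (2 * x_num + x_den) // (2 * x_den)


def hierarchy_stats(c: Classification) -> HierarchyStats:
    """Depth, node and sequence counts.

    Depth of a leaf counts the nodes on the root→leaf path inclusive of
    both ends (root alone = depth 1). The median of an even number of
    leaves is the mean of the two central depths, rounded half up.
    Sequences counts distinct seq_ids (one sequence under several leaves
    counts once).
    """
    depths = sorted(len(c.path_to_root(leaf)) for leaf in c.leaves())
    n = len(depths)
    if n % 2 == 1:
        med = depths[n // 2]
    else:
        med = _round_half_up(depths[n // 2 - 1] + depths[n // 2], 2)
    leaves = n
    internal = len(c.nodes) - leaves
    return HierarchyStats(
        median_depth=med,
        internal_nodes=internal,
        leaves=leaves,
        sequences=len(c.records),
    )


def select_nodes(
    c: Classification,
    policy: int | Sequence[str],
) -> NodeSelection:
    """Pick comparison-level nodes.

    ``policy`` is either an integer k (all nodes exactly k levels below
    the root, i.e. whose root→node path has k+1 nodes) or an explicit
    list of node_ids. Real systems need both: eggNOG/KEGG-style systems
    use a fixed tier, SEED-style systems a hand-picked mixture of levels.
    """
    if isinstance(policy, int):
        if policy < 1:
            raise SelectionError("depth level must be >= 1")
        selected = sorted(
            nid for nid in c.nodes if len(c.path_to_root(nid)) == policy + 1
        )
        return NodeSelection(c.name, tuple(selected), f"depth-level {policy}")
    selected = list(policy)
    for nid in selected:
        if nid not in c.nodes:
            raise SelectionError(f"{c.name}: unknown node {nid!r}")
    ancestry = {nid: set(c.path_to_root(nid)[:-1]) for nid in selected}
    for a in selected:
        for b in selected:
            if a != b and a in ancestry[b]:
                raise SelectionError(
                    f"{c.name}: {a!r} is an ancestor of selected node {b!r}"
                )
    return NodeSelection(c.name, tuple(selected), "explicit")


def sequences_under(c: Classification, node_id: str) -> set[str]:
    """Distinct seq_ids under ``node_id`` and all its descendants."""
    if node_id not in c.nodes:
        raise LoadError(f"{c.name}: unknown node {node_id!r}")
    out: set[str] = set()
    for nid in [node_id, *c.descendants(node_id)]:
        if c.nodes[nid].is_leaf:
            out |= c.leaf_sequences.get(nid, set())
    return out
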