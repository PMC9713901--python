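"""Synthetic classification bundles with planted ground truth.

The generator emulates the *structure* of real functional classification
systems — multi-level hierarchies with sequence-bearing leaves, protein
families with controlled within-family identity (redundancy), controlled
cross-database sharing of families, optional DAG-derived node label
duplication, multi-leaf sequence membership, superkingdom labels, and
shotgun reads sampled from coding sequences with errors — at desk scale.

Every quantity a downstream analysis should recover (cluster counts,
concordance fractions, coverage, taxonomy counts, read provenance) is
recorded in a :class:`GroundTruth` manifest at generation time, so tests
never re-derive planted truth from the emitted files.

Design of the planted families: each family has an unmutated *founder*
(copy 0) and copies mutated from the founder at exactly the designed
identity, with substitutions only (no indels), so planted identities are
exact by construction. Because the founder is itself the longest-or-tied,
lexicographically first member, it becomes the greedy clustering
representative and every member sits at exactly the designed identity
from it. Families of different lineages are drawn independently and stay
far below any clustering threshold (empirical pairwise identity < 0.4).
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from Bio.Data import CodonTable

from .errors import DesignError, InputError
from .model import (
    AMINO_ACIDS,
    SUPERKINGDOMS,
    Classification,
    ClassNode,
    ProteinRecord,
    sequences_under,
    write_classification,
)
from .reads import Read, write_fastq

DEFAULT_TAXONOMY_MIX: dict[str, float] = {
    "Bacteria": 0.70,
    "Eukarya": 0.15,
    "Archaea": 0.05,
    "Virus": 0.05,
    "Unclassified": 0.05,
}


@dataclass(frozen=True)
class ClassificationDesign:
    """Shape and family content of one synthetic classification."""

    name: str
    shape: tuple[int, ...] = (3, 3, 2)  # branching factors root -> leaves
    selection_level: int = 1  # comparison tier (levels below root)
    n_families: int = 30
    copies_per_family: int = 3
    within_family_identity: float = 0.95
    node_taxonomy: tuple[Mapping[str, float], ...] | None = None
    dag_duplications: int = 0

    def __post_init__(self) -> None:
        if any(b < 1 for b in self.shape):
            raise DesignError("branching factors must be >= 1")
        if not 1 <= self.selection_level <= len(self.shape):
            raise DesignError("selection_level outside the hierarchy depth")


@dataclass(frozen=True)
class ShareSpec:
    """Plant cross-database sharing: a fraction of the families of one
    selection-level node of ``src`` gets homologous copies under the given
    selection-level node(s) of ``dst`` (one record attached under every
    listed node — multi-membership)."""

    src: str
    dst: str
    src_node: int  # index among src's selection-level nodes
    dst_nodes: tuple[int, ...]
    fraction: float
    copies_in_dst: int = 1


@dataclass(frozen=True)
class ReadDesign:
    n_reads: int = 500
    length: int = 150
    error_rate: float = 0.01


@dataclass(frozen=True)
class SyntheticDesign:
    seed: int = 0
    classifications: tuple[ClassificationDesign, ...] = ()
    shares: tuple[ShareSpec, ...] = ()
    family_length: tuple[int, int] = (80, 140)
    cross_copy_identity: float = 0.95
    taxonomy_mix: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TAXONOMY_MIX)
    )
    sharing_probability: float = 0.0  # second-leaf attachment within a db
    reads: ReadDesign | None = None


@dataclass
class FamilyTruth:
    family_id: str
    classification: str
    selection_node: str
    superkingdom: str
    founder: str  # residues of copy 0
    members: list[str]  # seq_ids in the home classification
    category: str  # "exclusive" | "shared"
    dst_members: dict[str, list[str]] = field(default_factory=dict)
    dst_nodes: dict[str, list[str]] = field(default_factory=dict)


@dataclass
class GroundTruth:
    """Planted truth for one generated bundle set."""

    seed: int
    families: dict[str, dict[str, FamilyTruth]]  # class -> family_id -> truth
    record_family: dict[str, dict[str, str]]  # class -> seq_id -> family_id
    selection_nodes: dict[str, list[str]]
    expected_clusters: dict[str, int]
    expected_concordance: dict[str, dict[str, dict[str, object]]]
    expected_coverage: dict[str, float]  # "src->dst" -> fraction
    taxonomy_counts: dict[str, dict[str, int]]
    read_provenance: dict[str, str] = field(default_factory=dict)

    def validate(self, bundles: Mapping[str, Classification]) -> None:
        """Check manifest ↔ bundle consistency; raises on any mismatch."""
        for cname, fams in self.families.items():
            c = bundles[cname]
            for fam in fams.values():
                for sid in fam.members:
                    if sid not in c.records:
                        raise DesignError(f"manifest member {sid!r} missing from {cname}")
                for dst, sids in fam.dst_members.items():
                    for sid in sids:
                        if sid not in bundles[dst].records:
                            raise DesignError(
                                f"manifest cross copy {sid!r} missing from {dst}"
                            )
        for cname, counts in self.taxonomy_counts.items():
            c = bundles[cname]
            real = {k: 0 for k in SUPERKINGDOMS}
            for rec in c.records.values():
                real[rec.superkingdom] += 1
            if real != counts:
                raise DesignError(f"taxonomy counts mismatch for {cname}")
        for cname, mapping in self.record_family.items():
            if set(mapping) != set(bundles[cname].records):
                raise DesignError(f"record/family map incomplete for {cname}")


# ---------------------------------------------------------------------------
# primitives

_AA = np.array(list(AMINO_ACIDS))


def _rng(rng_or_seed: np.random.Generator | int) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def random_protein(length: int, rng: np.random.Generator) -> str:
    return "".join(_AA[rng.integers(0, len(_AA), size=length)])


def mutate_to_identity(
    seq: str, target_identity: float, rng: np.random.Generator | int
) -> str:
    """Substitute exactly ``ceil((1 - target) * len)`` positions to different
    residues. No indels, so the identity of the mutant to its parent is
    exact under an ungapped alignment."""
    if not 0 < target_identity <= 1:
        raise InputError("target identity must be in (0, 1]")
    rng = _rng(rng)
    n_mut = math.ceil((1 - target_identity) * len(seq))
    if n_mut == 0:
        return seq
    positions = rng.choice(len(seq), size=n_mut, replace=False)
    out = list(seq)
    for pos in positions:
        alternatives = [a for a in AMINO_ACIDS if a != out[pos]]
        out[pos] = alternatives[rng.integers(0, len(alternatives))]
    return "".join(out)


def _sample_kingdom(mix: Mapping[str, float], rng: np.random.Generator) -> str:
    labels = [k for k in SUPERKINGDOMS if mix.get(k, 0) > 0]
    probs = np.array([mix[k] for k in labels], dtype=float)
    if not math.isclose(probs.sum(), 1.0, abs_tol=1e-9):
        raise DesignError("taxonomy mix must sum to 1")
    return labels[rng.choice(len(labels), p=probs / probs.sum())]


# ---------------------------------------------------------------------------
# hierarchy scaffolding


def _build_tree(cd: ClassificationDesign) -> tuple[dict[str, ClassNode], list[list[str]]]:
    """Balanced tree from branching factors; returns nodes and per-level ids."""
    nodes: dict[str, ClassNode] = {}
    root_id = cd.name
    nodes[root_id] = ClassNode(root_id, root_id, None)
    levels: list[list[str]] = [[root_id]]
    for lvl, branch in enumerate(cd.shape, start=1):
        ids: list[str] = []
        for parent in levels[-1]:
            for i in range(branch):
                nid = f"{parent}.{i}"
                nodes[nid] = ClassNode(nid, nid, parent)
                nodes[parent].children.append(nid)
                ids.append(nid)
        levels.append(ids)
    _apply_dag_duplication(cd, nodes, levels)
    return nodes, levels


def _apply_dag_duplication(
    cd: ClassificationDesign, nodes: dict[str, ClassNode], levels: list[list[str]]
) -> None:
    """Give an internal node the label of a cousin under a different parent,
    emulating DAG-derived term duplication. The node keeps a unique id in
    the loader's ``label#k`` convention, so bundles round-trip."""
    if cd.dag_duplications == 0:
        return
    dup_level = cd.selection_level + 1
    if dup_level >= len(cd.shape):
        raise DesignError("dag duplication needs an internal level below the selection tier")
    tier = levels[dup_level]
    branch = cd.shape[dup_level - 1]
    if len(tier) <= branch:
        raise DesignError("dag duplication needs nodes under at least two parents")
    done = 0
    for i in range(cd.dag_duplications):
        orig, twin = tier[2 * i], tier[2 * i + branch]
        if nodes[orig].parent == nodes[twin].parent:
            continue
        old = nodes.pop(twin)
        new_id = f"{nodes[orig].label}#2"
        parent = nodes[old.parent]
        parent.children[parent.children.index(twin)] = new_id
        nodes[new_id] = ClassNode(new_id, nodes[orig].label, old.parent, old.children)
        for ch in old.children:
            nodes[ch].parent = new_id
        tier[tier.index(twin)] = new_id
        done += 1
    if done < cd.dag_duplications:
        raise DesignError("could not place all requested dag duplications")


def _leaves_below(nodes: dict[str, ClassNode], nid: str) -> list[str]:
    out, stack = [], [nid]
    while stack:
        cur = stack.pop()
        if not nodes[cur].children:
            out.append(cur)
        else:
            stack.extend(reversed(nodes[cur].children))
    return out


# ---------------------------------------------------------------------------
# bundle generation


def generate_bundle(
    d: SyntheticDesign, out_dir: str | Path | None = None
) -> tuple[dict[str, Classification], GroundTruth]:
    """Generate all classification bundles of a design plus ground truth.

    With ``out_dir`` set, bundles are written in the standard dialect and
    the manifest as ``manifest.json``.
    """
    if not d.classifications:
        raise DesignError("design contains no classifications")
    rng = np.random.default_rng(d.seed)
    names = [cd.name for cd in d.classifications]
    if len(set(names)) != len(names):
        raise DesignError("duplicate classification names")
    by_name = {cd.name: cd for cd in d.classifications}
    for sh in d.shares:
        if sh.src not in by_name or sh.dst not in by_name:
            raise DesignError(f"share references unknown classification: {sh}")
        if not 0 <= sh.fraction <= 1:
            raise DesignError("share fraction outside [0, 1]")

    trees = {cd.name: _build_tree(cd) for cd in d.classifications}
    sel_nodes = {
        cd.name: list(trees[cd.name][1][cd.selection_level]) for cd in d.classifications
    }

    # -- own families per classification ----------------------------------
    families: dict[str, dict[str, FamilyTruth]] = {n: {} for n in names}
    fam_by_node: dict[str, dict[str, list[str]]] = {n: {} for n in names}
    leaf_sequences: dict[str, dict[str, set[str]]] = {n: {} for n in names}
    records: dict[str, dict[str, ProteinRecord]] = {n: {} for n in names}
    leaf_cursor: dict[tuple[str, str], int] = {}

    def _attach(cname: str, leaf: str, sid: str) -> None:
        leaf_sequences[cname].setdefault(leaf, set()).add(sid)

    def _next_leaf(cname: str, sel_node: str) -> str:
        nodes = trees[cname][0]
        leaves = _leaves_below(nodes, sel_node)
        cur = leaf_cursor.get((cname, sel_node), 0)
        leaf_cursor[(cname, sel_node)] = cur + 1
        return leaves[cur % len(leaves)]

    lo, hi = d.family_length
    for cd in d.classifications:
        sel = sel_nodes[cd.name]
        for fi in range(cd.n_families):
            node = sel[fi % len(sel)]
            fam_id = f"{cd.name}_fam{fi:03d}"
            length = int(rng.integers(lo, hi + 1))
            founder = random_protein(length, rng)
            mix = d.taxonomy_mix
            if cd.node_taxonomy is not None:
                mix = cd.node_taxonomy[sel.index(node)]
            kingdom = _sample_kingdom(mix, rng)
            leaf = _next_leaf(cd.name, node)
            members = []
            for ci in range(cd.copies_per_family):
                sid = f"{fam_id}_c{ci:02d}"
                res = founder if ci == 0 else mutate_to_identity(
                    founder, cd.within_family_identity, rng
                )
                records[cd.name][sid] = ProteinRecord(sid, res, kingdom, cd.name)
                _attach(cd.name, leaf, sid)
                if d.sharing_probability > 0 and rng.random() < d.sharing_probability:
                    all_leaves = _leaves_below(trees[cd.name][0], cd.name)
                    others = [l for l in all_leaves if l != leaf]
                    if others:
                        _attach(cd.name, others[rng.integers(0, len(others))], sid)
                members.append(sid)
            families[cd.name][fam_id] = FamilyTruth(
                fam_id, cd.name, node, kingdom, founder, members, "exclusive"
            )
            fam_by_node[cd.name].setdefault(node, []).append(fam_id)

    # -- cross-database sharing -------------------------------------------
    share_cursor: dict[tuple[str, str], int] = {}
    for sh in d.shares:
        src_sel = sel_nodes[sh.src]
        if sh.src_node >= len(src_sel):
            raise DesignError(f"src_node {sh.src_node} out of range for {sh.src}")
        node = src_sel[sh.src_node]
        fam_ids = fam_by_node[sh.src].get(node, [])
        n_take = round(sh.fraction * len(fam_ids))
        cur = share_cursor.get((sh.src, node), 0)
        if cur + n_take > len(fam_ids):
            raise DesignError(
                f"share fractions for node {node!r} of {sh.src} exceed 1"
            )
        taken = fam_ids[cur : cur + n_take]
        share_cursor[(sh.src, node)] = cur + n_take
        dst_sel = sel_nodes[sh.dst]
        dst_node_ids = [dst_sel[i] for i in sh.dst_nodes]
        for fam_id in taken:
            fam = families[sh.src][fam_id]
            fam.category = "shared"
            primary = mutate_to_identity(fam.founder, d.cross_copy_identity, rng)
            home_leaves = [_next_leaf(sh.dst, dn) for dn in dst_node_ids]
            sids = []
            for j in range(sh.copies_in_dst):
                sid = f"{sh.dst}_x_{fam_id}_{j:02d}"
                res = primary if j == 0 else mutate_to_identity(
                    primary, by_name[sh.dst].within_family_identity, rng
                )
                records[sh.dst][sid] = ProteinRecord(
                    sid, res, fam.superkingdom, sh.dst
                )
                for leaf in home_leaves:
                    _attach(sh.dst, leaf, sid)
                sids.append(sid)
            fam.dst_members.setdefault(sh.dst, []).extend(sids)
            fam.dst_nodes.setdefault(sh.dst, []).extend(dst_node_ids)

    # -- assemble classifications ------------------------------------------
    bundles: dict[str, Classification] = {}
    for cd in d.classifications:
        bundles[cd.name] = Classification(
            cd.name, trees[cd.name][0], leaf_sequences[cd.name], records[cd.name]
        )

    truth = _derive_truth(d, bundles, families, sel_nodes)
    truth.validate(bundles)

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c in bundles.values():
            write_classification(c, out)
        write_manifest(truth, out / "manifest.json")
    return bundles, truth


def _derive_truth(
    d: SyntheticDesign,
    bundles: Mapping[str, Classification],
    families: dict[str, dict[str, FamilyTruth]],
    sel_nodes: dict[str, list[str]],
) -> GroundTruth:
    names = list(bundles)
    record_family: dict[str, dict[str, str]] = {n: {} for n in names}
    for cname, fams in families.items():
        for fam in fams.values():
            for sid in fam.members:
                record_family[cname][sid] = fam.family_id
            for dst, sids in fam.dst_members.items():
                for sid in sids:
                    record_family[dst][sid] = fam.family_id

    # planted clusters: one per own family plus one per incoming shared family
    expected_clusters = {}
    for cname in names:
        incoming = sum(
            1
            for src, fams in families.items()
            if src != cname
            for fam in fams.values()
            if cname in fam.dst_members
        )
        expected_clusters[cname] = len(families[cname]) + incoming

    # planted coverage and concordance from realized family placement
    fam_presence: dict[str, dict[str, set[str]]] = {}  # fam -> dst -> node ids
    for fams in families.values():
        for fam in fams.values():
            pres = {fam.classification: {fam.selection_node}}
            for dst, nodes in fam.dst_nodes.items():
                pres.setdefault(dst, set()).update(nodes)
            fam_presence[fam.family_id] = pres

    expected_coverage: dict[str, float] = {}
    expected_concordance: dict[str, dict[str, dict[str, object]]] = {}
    for src in names:
        for dst in names:
            if src == dst:
                continue
            recs = record_family[src]
            n_cov = sum(1 for fam_id in recs.values() if dst in fam_presence[fam_id])
            expected_coverage[f"{src}->{dst}"] = n_cov / len(recs) if recs else 0.0
            per_row: dict[str, dict[str, object]] = {}
            c = bundles[src]
            for r in sel_nodes[src]:
                sids = sequences_under(c, r)
                if not sids:
                    continue
                col_counts: dict[str, int] = {}
                n_unassigned = 0
                for sid in sids:
                    pres = fam_presence[record_family[src][sid]]
                    if dst not in pres:
                        n_unassigned += 1
                        continue
                    for cn in pres[dst]:
                        col_counts[cn] = col_counts.get(cn, 0) + 1
                per_row[r] = {
                    "entries": {cn: cnt / len(sids) for cn, cnt in sorted(col_counts.items())},
                    "unassigned": n_unassigned / len(sids),
                }
            expected_concordance[f"{src}->{dst}"] = per_row

    taxonomy_counts = {}
    for cname, c in bundles.items():
        counts = {k: 0 for k in SUPERKINGDOMS}
        for rec in c.records.values():
            counts[rec.superkingdom] += 1
        taxonomy_counts[cname] = counts

    return GroundTruth(
        seed=d.seed,
        families=families,
        record_family=record_family,
        selection_nodes=sel_nodes,
        expected_clusters=expected_clusters,
        expected_concordance=expected_concordance,
        expected_coverage=expected_coverage,
        taxonomy_counts=taxonomy_counts,
    )


def write_manifest(truth: GroundTruth, path: str | Path) -> None:
    payload = asdict(truth)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1, sort_keys=True)
        fh.write("\n")


# ---------------------------------------------------------------------------
# read generation

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
_AA_TO_CODONS: dict[str, list[str]] = {}
for codon, aa in sorted(_STANDARD.forward_table.items()):
    _AA_TO_CODONS.setdefault(aa, []).append(codon)


def reverse_translate(residues: str, rng: np.random.Generator) -> str:
    """Uniformly chosen synonymous codons per residue."""
    parts = []
    for aa in residues:
        codons = _AA_TO_CODONS[aa]
        parts.append(codons[rng.integers(0, len(codons))])
    return "".join(parts)


_BASES = "ACGT"


def generate_reads(
    bundle: Classification,
    rd: ReadDesign,
    rng: np.random.Generator | int,
    source_ids: Sequence[str] | None = None,
    out_path: str | Path | None = None,
    id_prefix: str = "read",
) -> tuple[list[Read], dict[str, str]]:
    """Sample error-bearing shotgun reads from coding sequences.

    Each read: pick a source protein (uniformly over ``source_ids`` or
    all records), reverse-translate it with uniformly chosen synonymous
    codons, cut a fragment of the designed length at a uniform offset,
    flip to the reverse strand with probability 1/2, and substitute each
    base independently with the designed error rate. Provenance
    (read_id → source seq_id) is returned alongside. Qualities are a
    constant Q35.
    """
    rng = _rng(rng)
    pool = sorted(source_ids) if source_ids is not None else sorted(bundle.records)
    eligible = [sid for sid in pool if 3 * len(bundle.records[sid]) >= rd.length]
    if not eligible:
        raise DesignError("read length exceeds every coding sequence in the pool")
    reads: list[Read] = []
    provenance: dict[str, str] = {}
    for i in range(rd.n_reads):
        sid = eligible[rng.integers(0, len(eligible))]
        cds = reverse_translate(bundle.records[sid].residues, rng)
        start = int(rng.integers(0, len(cds) - rd.length + 1))
        frag = cds[start : start + rd.length]
        if rng.integers(0, 2):
            frag = frag.translate(str.maketrans("ACGT", "TGCA"))[::-1]
        if rd.error_rate > 0:
            chars = list(frag)
            hits = np.nonzero(rng.random(len(chars)) < rd.error_rate)[0]
            for pos in hits:
                alt = [b for b in _BASES if b != chars[pos]]
                chars[pos] = alt[rng.integers(0, 3)]
            frag = "".join(chars)
        rid = f"{id_prefix}_{i:05d}"
        reads.append(Read(rid, frag, tuple([35] * rd.length)))
        provenance[rid] = sid
    if out_path is not None:
        write_fastq(reads, out_path)
    return reads, provenance


# ---------------------------------------------------------------------------
# a ready-made design shaped like the four large real systems


def four_system_design(seed: int = 0, reads: ReadDesign | None = None) -> SyntheticDesign:
    """Four classifications with depth profile 4/5/3/5 (median root→leaf
    node counts matching the tier structure of eggNOG-, KEGG-,
    GO-slim- and SEED-like systems), cross-shared family pools, and a
    mixed taxonomy."""
    a = ClassificationDesign("eggnog_like", shape=(4, 2, 2), selection_level=2,
                             n_families=32, copies_per_family=3)
    b = ClassificationDesign("kegg_like", shape=(3, 2, 2, 2), selection_level=2,
                             n_families=30, copies_per_family=3)
    c = ClassificationDesign("goslim_like", shape=(6, 3), selection_level=1,
                             n_families=30, copies_per_family=2)
    e = ClassificationDesign("seed_like", shape=(3, 2, 2, 2), selection_level=1,
                             n_families=30, copies_per_family=4)
    # shares touch every selection node so pairwise coverage is substantial
    shares = []
    for i in range(8):  # eggnog_like has 4*2 selection nodes
        shares.append(ShareSpec("eggnog_like", "kegg_like", i, (i % 6,), 0.50))
        shares.append(ShareSpec("eggnog_like", "goslim_like", i, (i % 6,), 0.25))
    for i in range(6):  # kegg_like has 3*2 selection nodes
        shares.append(ShareSpec("kegg_like", "seed_like", i, (i % 3,), 0.40))
        shares.append(ShareSpec("kegg_like", "goslim_like", i, (i % 6,), 0.20))
    for i in range(3):  # seed_like has 3 selection nodes
        shares.append(ShareSpec("seed_like", "eggnog_like", i, (i % 8,), 0.30))
    return SyntheticDesign(
        seed=seed, classifications=(a, b, c, e), shares=shares, reads=reads
    )
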