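"""Independent oracles used by the test suite.

Everything here is written from first principles — a quadratic-time
Gotoh dynamic program for local alignment scores, a literal codon table
for translation, exhaustive path walkers for hierarchy statistics, and
a replay of the greedy clustering rule — so agreement with the package
is evidence, not tautology.
"""

from __future__ import annotations

from Bio.Align import substitution_matrices

# ---------------------------------------------------------------------------
# Smith–Waterman score by explicit Gotoh recursion.
# Gap of length L costs open + L * extend (the package's convention).

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def sw_score(a: str, b: str, gap_open: int = 11, gap_extend: int = 1) -> int:
    n, m = len(a), len(b)
    NEG = float("-inf")
    H = [[0.0] * (m + 1) for _ in range(n + 1)]
    E = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in a (horizontal)
    F = [[NEG] * (m + 1) for _ in range(n + 1)]  # gap in b (vertical)
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            E[i][j] = max(E[i][j - 1] - gap_extend, H[i][j - 1] - gap_open - gap_extend)
            F[i][j] = max(F[i - 1][j] - gap_extend, H[i - 1][j] - gap_open - gap_extend)
            diag = H[i - 1][j - 1] + _BLOSUM62[a[i - 1]][b[j - 1]]
            H[i][j] = max(0.0, diag, E[i][j], F[i][j])
            if H[i][j] > best:
                best = H[i][j]
    return int(best)


# ---------------------------------------------------------------------------
# Standard genetic code, written out literally.

CODON_TABLE = {
    "TTT": "F", "TTC": "F", "TTA": "L", "TTG": "L",
    "CTT": "L", "CTC": "L", "CTA": "L", "CTG": "L",
    "ATT": "I", "ATC": "I", "ATA": "I", "ATG": "M",
    "GTT": "V", "GTC": "V", "GTA": "V", "GTG": "V",
    "TCT": "S", "TCC": "S", "TCA": "S", "TCG": "S",
    "CCT": "P", "CCC": "P", "CCA": "P", "CCG": "P",
    "ACT": "T", "ACC": "T", "ACA": "T", "ACG": "T",
    "GCT": "A", "GCC": "A", "GCA": "A", "GCG": "A",
    "TAT": "Y", "TAC": "Y", "TAA": "*", "TAG": "*",
    "CAT": "H", "CAC": "H", "CAA": "Q", "CAG": "Q",
    "AAT": "N", "AAC": "N", "AAA": "K", "AAG": "K",
    "GAT": "D", "GAC": "D", "GAA": "E", "GAG": "E",
    "TGT": "C", "TGC": "C", "TGA": "*", "TGG": "W",
    "CGT": "R", "CGC": "R", "CGA": "R", "CGG": "R",
    "AGT": "S", "AGC": "S", "AGA": "R", "AGG": "R",
    "GGT": "G", "GGC": "G", "GGA": "G", "GGG": "G",
}

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def translate_frames_oracle(read: str) -> list[str]:
    read = read.upper()
    rc = "".join(_COMP[b] for b in reversed(read))
    out = []
    for template in (read, rc):
        for f in range(3):
            pep = []
            for i in range(f, len(template) - 2, 3):
                pep.append(CODON_TABLE.get(template[i : i + 3], "X"))
            out.append("".join(pep))
    return out


# ---------------------------------------------------------------------------
# exhaustive hierarchy walkers


def enumerate_root_paths(nodes) -> list[list[str]]:
    """All root-to-leaf node paths, by recursive descent over ClassNode dicts."""
    root = next(n for n in nodes.values() if n.parent is None)
    paths = []

    def walk(nid, acc):
        acc = acc + [nid]
        children = nodes[nid].children
        if not children:
            paths.append(acc)
        for ch in children:
            walk(ch, acc)

    walk(root.node_id, [])
    return paths


def sequences_under_bruteforce(c, node_id) -> set[str]:
    """Union of leaf sequence sets by walking every root path through the node."""
    out = set()
    for path in enumerate_root_paths(c.nodes):
        if node_id in path:
            out |= c.leaf_sequences.get(path[-1], set())
    return out


# ---------------------------------------------------------------------------
# greedy clustering replayed from scratch


def greedy_cluster_replay(
    records: dict,
    identity_threshold: float,
    length_diff_cutoff: float = 0.9,
    min_coverage: float = 0.9,
    gap_open: int = 11,
    gap_extend: int = 1,
):
    """Replays the greedy rule with its own exhaustive alignment calls.

    Uses Bio.Align.PairwiseAligner directly, with its own identity and
    coverage extraction, its own sorting and first-match scan; shares no
    code with funcmap.cluster.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = _BLOSUM62
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend

    order = sorted(records.values(), key=lambda r: (-len(r.residues), r.seq_id))
    reps: list = []
    clusters: dict[str, list[str]] = {}
    for rec in order:
        home = None
        for rep in reps:
            if len(rec.residues) / len(rep.residues) < length_diff_cutoff:
                continue
            alns = aligner.align(rec.residues, rep.residues)
            if alns.score <= 0:
                continue
            best = alns[0]
            counts = best.counts()
            qblocks = best.aligned[0]
            span = qblocks[-1][1] - qblocks[0][0]
            if span / len(rec.residues) < min_coverage:
                continue
            if counts.identities / len(rec.residues) < identity_threshold:
                continue
            home = rep
            break
        if home is None:
            reps.append(rec)
            clusters[rec.seq_id] = [rec.seq_id]
        else:
            clusters[home.seq_id].append(rec.seq_id)
    return clusters
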