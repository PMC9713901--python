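"""Desk-scale protein similarity search.

A stand-in for a production translated-search engine: Smith–Waterman
local alignment with affine gaps (via Bio.Align.PairwiseAligner), k-mer
seeded candidate filtering, best-hit retrieval under a query-coverage
gate, and six-frame translation for nucleotide reads.

Conventions (each module of this package states its own denominators):

* raw score — affine-gap local alignment score; a gap of length L costs
  ``gap_open + L * gap_extend`` (BLAST-style accounting).
* identity — identical aligned positions / alignment columns, where
  columns include internal gap columns of the optimal local path.
* query coverage — query residues spanned by the local alignment window
  / query length (BLAST qcov-style span on the query).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices
from Bio.Data import CodonTable

from .errors import InputError
from .model import ProteinRecord


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters (defaults follow BLASTP)."""

    matrix: str = "BLOSUM62"
    gap_open: int = 11
    gap_extend: int = 1
    min_score: int = 50

    def __post_init__(self) -> None:
        if self.gap_open < 0 or self.gap_extend < 0:
            raise InputError("gap penalties must be >= 0")
        if self.gap_extend > self.gap_open:
            raise InputError("gap_extend must not exceed gap_open")


@dataclass(frozen=True)
class AlignmentHit:
    """One pairwise protein match."""

    query_id: str
    subject_id: str
    raw_score: int
    identity: float
    query_coverage: float
    aln_columns: int
    n_identical: int = 0


@dataclass
class SequenceIndex:
    """Exact k-mer postings over a set of subject sequences."""

    k: int
    postings: dict[str, list[tuple[str, int]]]
    lengths: dict[str, int]


_ALIGNER_CACHE: dict[ScoringScheme, Align.PairwiseAligner] = {}


def _aligner(s: ScoringScheme) -> Align.PairwiseAligner:
    al = _ALIGNER_CACHE.get(s)
    if al is None:
        al = Align.PairwiseAligner()
        al.mode = "local"
        al.substitution_matrix = substitution_matrices.load(s.matrix)
        # PairwiseAligner charges open_gap_score for the first gap position;
        # shift by one extension to get open + L*extend semantics.
        al.open_gap_score = -(s.gap_open + s.gap_extend)
        al.extend_gap_score = -s.gap_extend
        _ALIGNER_CACHE[s] = al
    return al


def _align_strings(
    query_id: str,
    query: str,
    subject_id: str,
    subject: str,
    s: ScoringScheme,
    min_score: int | None,
) -> AlignmentHit | None:
    """Align plain strings; ``min_score=None`` disables the score gate."""
    if not query or not subject:
        raise InputError("cannot align an empty sequence")
    alns = _aligner(s).align(query, subject)
    score = int(alns.score)
    if min_score is not None and score < min_score:
        return None
    if score <= 0:
        return None
    best = alns[0]
    counts = best.counts()
    columns = counts.identities + counts.mismatches + counts.gaps
    qblocks = best.aligned[0]
    span = int(qblocks[-1][1] - qblocks[0][0])
    return AlignmentHit(
        query_id=query_id,
        subject_id=subject_id,
        raw_score=score,
        identity=counts.identities / columns,
        query_coverage=span / len(query),
        aln_columns=int(columns),
        n_identical=int(counts.identities),
    )


def align_pair(
    query: ProteinRecord,
    subject: ProteinRecord,
    s: ScoringScheme = ScoringScheme(),
) -> AlignmentHit | None:
    """Optimal local alignment of two protein records.

    Returns ``None`` when the optimal raw score is below ``s.min_score``.
    """
    return _align_strings(
        query.seq_id, query.residues, subject.seq_id, subject.residues, s, s.min_score
    )


def build_index(
    records: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    k: int = 5,
) -> SequenceIndex:
    """Exact k-mer postings over all records (k >= 3)."""
    if k < 3:
        raise InputError("k must be >= 3")
    recs = records.values() if isinstance(records, Mapping) else records
    postings: dict[str, list[tuple[str, int]]] = {}
    lengths: dict[str, int] = {}
    for rec in sorted(recs, key=lambda r: r.seq_id):
        res = rec.residues
        lengths[rec.seq_id] = len(res)
        for off in range(len(res) - k + 1):
            postings.setdefault(res[off : off + k], []).append((rec.seq_id, off))
    return SequenceIndex(k=k, postings=postings, lengths=lengths)


def _seed_candidates(query: str, idx: SequenceIndex) -> list[str]:
    hits: set[str] = set()
    k = idx.k
    for off in range(len(query) - k + 1):
        for sid, _ in idx.postings.get(query[off : off + k], ()):
            hits.add(sid)
    return sorted(hits)


def best_hit(
    query: ProteinRecord,
    idx: SequenceIndex,
    records: Mapping[str, ProteinRecord],
    s: ScoringScheme = ScoringScheme(),
    min_query_cover: float = 0.9,
) -> AlignmentHit | None:
    """Single best qualifying hit of ``query`` against the indexed subjects.

    Subjects sharing at least one seed k-mer with the query are aligned;
    hits with query coverage below ``min_query_cover`` are discarded; the
    highest raw score wins, ties broken by lexicographically smallest
    subject id.
    """
    return _best_hit_str(query.seq_id, query.residues, idx, records, s, min_query_cover)


def _best_hit_str(
    query_id: str,
    query: str,
    idx: SequenceIndex,
    records: Mapping[str, ProteinRecord],
    s: ScoringScheme,
    min_query_cover: float,
) -> AlignmentHit | None:
    if not 0 < min_query_cover <= 1:
        raise InputError("min_query_cover must be in (0, 1]")
    best: AlignmentHit | None = None
    for sid in _seed_candidates(query, idx):
        hit = _align_strings(query_id, query, sid, records[sid].residues, s, s.min_score)
        if hit is None or hit.query_coverage < min_query_cover:
            continue
        if best is None or hit.raw_score > best.raw_score:
            best = hit
    return best


@dataclass
class AlignmentContext:
    """A target database prepared for repeated best-hit queries.

    Caches one best hit per query id, so coverage, concordance and
    stratified analyses against the same target reuse alignments.
    """

    records: Mapping[str, ProteinRecord]
    scheme: ScoringScheme = ScoringScheme()
    k: int = 5
    min_query_cover: float = 0.9
    _index: SequenceIndex | None = field(default=None, repr=False)
    _cache: dict[str, AlignmentHit | None] = field(default_factory=dict, repr=False)

    @property
    def index(self) -> SequenceIndex:
        if self._index is None:
            self._index = build_index(self.records, self.k)
        return self._index

    def best_hit(self, query: ProteinRecord) -> AlignmentHit | None:
        if query.seq_id not in self._cache:
            self._cache[query.seq_id] = best_hit(
                query, self.index, self.records, self.scheme, self.min_query_cover
            )
        return self._cache[query.seq_id]

    def best_hit_peptide(self, query_id: str, peptide: str) -> AlignmentHit | None:
        """Best hit for a raw peptide string (e.g. a translated read frame)."""
        return _best_hit_str(
            query_id, peptide, self.index, self.records, self.scheme, self.min_query_cover
        )


# ---------------------------------------------------------------------------
# six-frame translation

_STANDARD = CodonTable.unambiguous_dna_by_name["Standard"]
_CODON_TO_AA: dict[str, str] = dict(_STANDARD.forward_table)
_CODON_TO_AA.update({codon: "*" for codon in _STANDARD.stop_codons})

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _translate_frame(seq: str) -> str:
    aas = []
    for i in range(0, len(seq) - 2, 3):
        codon = seq[i : i + 3]
        aas.append(_CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


def six_frame_translate(read: str) -> list[str]:
    """Translate a read in all six frames under the standard genetic code.

    Frames are ordered +1, +2, +3, -1, -2, -3. Stop codons are emitted as
    ``*``; codons containing ``N`` (or any non-ACGT base) emit ``X``.
    Reads shorter than 3 yield six empty peptides.
    """
    read = read.upper()
    bad = set(read) - set("ACGTN")
    if bad:
        raise InputError(f"illegal bases {sorted(bad)} in read")
    rc = reverse_complement(read)
    return [_translate_frame(read[f:]) for f in range(3)] + [
        _translate_frame(rc[f:]) for f in range(3)
    ]


# ---------------------------------------------------------------------------
# hit table I/O (minimal BLAST-tabular dialect)


def write_hits(hits: Iterable[AlignmentHit], path) -> None:
    """6-column tabular text: query, subject, identity, columns, score, qcov."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# query\tsubject\tidentity\taln_columns\traw_score\tquery_coverage\n")
        for h in hits:
            fh.write(
                f"{h.query_id}\t{h.subject_id}\t{h.identity:.4f}\t"
                f"{h.aln_columns}\t{h.raw_score}\t{h.query_coverage:.4f}\n"
            )


def read_hits(path) -> list[AlignmentHit]:
    """Read the 6-column dialect; also accepts standard 12-column outfmt-6
    (bitscore is then taken as the raw score, coverage is left at 1.0)."""
    out: list[AlignmentHit] = []
    with open(path, encoding="utf-8") as fh:
        for raw in fh:
            line = raw.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) == 6:
                out.append(
                    AlignmentHit(f[0], f[1], int(f[4]), float(f[2]), float(f[5]), int(f[3]))
                )
            elif len(f) == 12:
                ident = float(f[2])
                out.append(
                    AlignmentHit(
                        f[0],
                        f[1],
                        int(float(f[11])),
                        ident / 100 if ident > 1 else ident,
                        1.0,
                        int(f[3]),
                    )
                )
            else:
                raise InputError(f"unrecognised hit table row with {len(f)} columns")
    return out
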