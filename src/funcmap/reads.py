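"""Functional assignment of shotgun reads.

Reads are translated in all six frames and searched against a
classification's reference proteins; the single best hit over all frames
(passing the query-coverage gate on the translated peptide) assigns the
read to the leaf — or leaves — carrying the subject sequence. This is a
direct best-hit-to-leaf assignment: no lowest-common-ancestor or
top-percent binning machinery is layered on top, so assignment rates
reflect the databases themselves, not a binning heuristic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO

from .align import AlignmentContext, ScoringScheme, six_frame_translate
from .errors import InputError
from .model import Classification


@dataclass(frozen=True)
class Read:
    read_id: str
    bases: str
    qualities: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        bad = set(self.bases.upper()) - set("ACGTN")
        if bad:
            raise InputError(f"illegal bases {sorted(bad)} in read {self.read_id!r}")
        if self.qualities is not None and len(self.qualities) != len(self.bases):
            raise InputError(f"quality/base length mismatch in read {self.read_id!r}")

    @property
    def mean_quality(self) -> float | None:
        if not self.qualities:
            return None
        return sum(self.qualities) / len(self.qualities)


@dataclass
class ReadAssignments:
    """Partition of a read set into assigned (with leaves) and unassigned."""

    classification: str
    assigned: dict[str, tuple[str, ...]]
    unassigned: set[str]

    @property
    def n_reads(self) -> int:
        return len(self.assigned) + len(self.unassigned)

    @property
    def percent_assigned(self) -> float:
        return 100.0 * len(self.assigned) / self.n_reads if self.n_reads else 0.0


@dataclass(frozen=True)
class OverlapPartition:
    only_a: float
    both: float
    only_b: float


# ---------------------------------------------------------------------------
# I/O


def read_reads(path: str | Path) -> list[Read]:
    """Read FASTA or FASTQ (Sanger/Phred+33), sniffed from the first byte."""
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        first = fh.read(1)
    fmt = "fastq" if first == "@" else "fasta"
    out = []
    for rec in SeqIO.parse(str(path), fmt):
        quals = rec.letter_annotations.get("phred_quality")
        out.append(
            Read(rec.id, str(rec.seq).upper(), tuple(quals) if quals else None)
        )
    return out


def write_fastq(reads: Iterable[Read], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for r in reads:
            quals = r.qualities or tuple([30] * len(r.bases))
            qstr = "".join(chr(q + 33) for q in quals)
            fh.write(f"@{r.read_id}\n{r.bases}\n+\n{qstr}\n")


# ---------------------------------------------------------------------------
# pipeline steps


def quality_filter(reads: Sequence[Read], q_threshold: float = 20) -> list[Read]:
    """Keep reads whose mean base quality is >= ``q_threshold``.

    Reads without qualities pass unchanged (with a warning), so FASTA
    input flows through the same pipeline.
    """
    out = []
    warned = False
    for r in reads:
        mq = r.mean_quality
        if mq is None:
            if not warned:
                warnings.warn("reads without qualities pass the filter unchanged")
                warned = True
            out.append(r)
        elif mq >= q_threshold:
            out.append(r)
    return out


def assign_reads(
    reads: Sequence[Read],
    c: Classification,
    ctx: AlignmentContext | None = None,
    min_query_cover: float = 0.9,
    scheme: ScoringScheme = ScoringScheme(),
) -> ReadAssignments:
    """Best-hit functional assignment of reads against one classification.

    Each read is translated in six frames; every frame peptide is
    searched and the highest-scoring qualifying hit over all frames wins
    (ties: lowest frame index, then smallest subject id). The read is
    assigned to every leaf containing the subject.
    """
    ctx = ctx or AlignmentContext(
        records=c.records, scheme=scheme, min_query_cover=min_query_cover
    )
    assigned: dict[str, tuple[str, ...]] = {}
    unassigned: set[str] = set()
    for read in reads:
        best = None
        for fi, pep in enumerate(six_frame_translate(read.bases)):
            if len(pep) < ctx.index.k:
                continue
            hit = ctx.best_hit_peptide(f"{read.read_id}|f{fi}", pep)
            if hit is None:
                continue
            if best is None or hit.raw_score > best.raw_score:
                best = hit
        if best is None:
            unassigned.add(read.read_id)
        else:
            leaves = tuple(sorted(c.leaves_of_sequence(best.subject_id)))
            assigned[read.read_id] = leaves
    return ReadAssignments(c.name, assigned, unassigned)


def overlap_partition(ra: ReadAssignments, rb: ReadAssignments) -> OverlapPartition:
    """Fractions of reads assigned only in A, in both, or only in B.

    Fractions are over the union of assigned reads, so they sum to 1.
    """
    universe_a = set(ra.assigned) | ra.unassigned
    universe_b = set(rb.assigned) | rb.unassigned
    if universe_a != universe_b:
        raise InputError("read universes differ between the two assignments")
    sa, sb = set(ra.assigned), set(rb.assigned)
    union = sa | sb
    if not union:
        raise InputError("no read assigned in either classification")
    n = len(union)
    return OverlapPartition(
        only_a=len(sa - sb) / n, both=len(sa & sb) / n, only_b=len(sb - sa) / n
    )


def specific_vs_pooled(
    reads: Sequence[Read],
    c: Classification,
    pool: Sequence[Classification],
    min_query_cover: float = 0.9,
    scheme: ScoringScheme = ScoringScheme(),
) -> tuple[float, float]:
    """Assignment rate against ``c`` alone vs against the pooled databases.

    In the pooled run all records of all classifications compete; a read
    counts as assigned to ``c`` only when the overall best hit belongs to
    ``c``. Because best-hit competition can only divert reads, the
    specific rate is always >= the pooled rate.
    """
    pooled: dict = {}
    for cls in pool:
        for sid, rec in cls.records.items():
            if sid in pooled and pooled[sid].residues != rec.residues:
                raise InputError(f"sequence id collision across pool: {sid!r}")
            pooled[sid] = rec
    for sid, rec in c.records.items():
        if sid not in pooled:
            pooled[sid] = rec

    specific = assign_reads(reads, c, min_query_cover=min_query_cover, scheme=scheme)
    pooled_ctx = AlignmentContext(
        records=pooled, scheme=scheme, min_query_cover=min_query_cover
    )
    n_pooled_in_c = 0
    for read in reads:
        best = None
        for fi, pep in enumerate(six_frame_translate(read.bases)):
            if len(pep) < pooled_ctx.index.k:
                continue
            hit = pooled_ctx.best_hit_peptide(f"{read.read_id}|f{fi}", pep)
            if hit is None:
                continue
            if best is None or hit.raw_score > best.raw_score:
                best = hit
        if best is not None and best.subject_id in c.records:
            n_pooled_in_c += 1
    n = len(reads)
    if n == 0:
        raise InputError("empty read set")
    return specific.percent_assigned, 100.0 * n_pooled_in_c / n


# ---------------------------------------------------------------------------
# output


def write_assignments(
    ra: ReadAssignments, c: Classification, path: str | Path, header: str = ""
) -> None:
    """2-column TSV (read_id, node path); multi-leaf reads emit one row per leaf."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        fh.write("read_id\tnode_path\n")
        for rid in sorted(ra.assigned):
            for leaf in ra.assigned[rid]:
                fh.write(f"{rid}\t{c.path_labels(leaf)}\n")
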