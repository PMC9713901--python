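"""Greedy incremental identity clustering and redundancy ratios.

Mirrors the classic greedy clustering of protein databases: sequences are
sorted longest-first and each is compared against existing cluster
representatives; it joins the first representative it matches under the
identity / length-difference / coverage gates, otherwise it founds a new
cluster. The cluster-to-sequence ratio (clusters / sequences) summarises
redundancy: low values mean a highly redundant database.

Identity here is identical aligned positions divided by the length of the
*shorter* sequence (the CD-HIT convention), which differs from the
alignment module's per-column identity.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

from .align import ScoringScheme, _align_strings
from .errors import InputError
from .model import ProteinRecord


@dataclass(frozen=True)
class ClusteringParams:
    identity_threshold: float = 0.9
    length_diff_cutoff: float = 0.9
    min_coverage: float = 0.9

    def __post_init__(self) -> None:
        for name in ("identity_threshold", "length_diff_cutoff", "min_coverage"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise InputError(f"{name} must be in (0, 1], got {v}")


@dataclass
class ClusterSet:
    """Clusters keyed by representative; the representative is member [0]."""

    clusters: dict[str, list[str]]
    params: ClusteringParams

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)

    def membership(self) -> dict[str, str]:
        return {m: rep for rep, members in self.clusters.items() for m in members}


def greedy_cluster(
    records: Mapping[str, ProteinRecord] | Iterable[ProteinRecord],
    p: ClusteringParams = ClusteringParams(),
    s: ScoringScheme = ScoringScheme(),
) -> ClusterSet:
    """CD-HIT-style greedy clustering.

    Input order is canonicalised internally (length descending, seq_id
    ascending on ties), so the result is independent of record order. A
    sequence joins the *first* representative, in founding order, that
    passes all three gates:

    1. shorter/longer length ratio >= ``length_diff_cutoff``,
    2. the local alignment spans >= ``min_coverage`` of the member,
    3. identical positions / member length >= ``identity_threshold``.

    ``s.min_score`` is not applied here — the gates above are the only
    acceptance rules, as in CD-HIT.
    """
    recs = list(records.values() if isinstance(records, Mapping) else records)
    if not recs:
        raise InputError("cannot cluster an empty record set")
    recs.sort(key=lambda r: (-len(r.residues), r.seq_id))

    reps: list[ProteinRecord] = []
    clusters: dict[str, list[str]] = {}
    for rec in recs:
        home = None
        for rep in reps:
            if len(rec) / len(rep) < p.length_diff_cutoff:
                continue
            hit = _align_strings(
                rec.seq_id, rec.residues, rep.seq_id, rep.residues, s, min_score=None
            )
            if hit is None:
                continue
            if hit.query_coverage < p.min_coverage:
                continue
            if hit.n_identical / len(rec) < p.identity_threshold:
                continue
            home = rep
            break
        if home is None:
            reps.append(rec)
            clusters[rec.seq_id] = [rec.seq_id]
        else:
            clusters[home.seq_id].append(rec.seq_id)
    return ClusterSet(clusters=clusters, params=p)


def cluster_ratio(cs: ClusterSet, n_sequences: int) -> float:
    """Clusters / sequences; 1.0 means no redundancy at the threshold."""
    if n_sequences <= 0:
        raise InputError("n_sequences must be positive")
    if n_sequences < cs.n_clusters:
        raise InputError("n_sequences smaller than the number of clusters")
    return cs.n_clusters / n_sequences


# ---------------------------------------------------------------------------
# output


def write_clstr(cs: ClusterSet, path: str | Path) -> None:
    """CD-HIT ``.clstr``-style text output."""
    with open(path, "w", encoding="utf-8") as fh:
        for i, (rep, members) in enumerate(cs.clusters.items()):
            fh.write(f">Cluster {i}\n")
            for j, m in enumerate(members):
                mark = "*" if m == rep else ""
                fh.write(f"{j}\t{m} {mark}\n")


def write_membership(cs: ClusterSet, path: str | Path) -> None:
    """2-column TSV: member, representative."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# member\trepresentative\n")
        for m, rep in sorted(cs.membership().items()):
            fh.write(f"{m}\t{rep}\n")
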