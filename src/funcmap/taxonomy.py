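"""Superkingdom composition of databases and nodes.

Taxonomic resolution is deliberately coarse — five fixed superkingdom
bins (Archaea, Bacteria, Eukarya, Virus, Unclassified) — matching the
resolution at which functional reference databases are typically
profiled. No taxonomy traversal or LCA machinery is involved.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable

from .align import AlignmentContext
from .errors import InputError
from .model import (
    SUPERKINGDOMS,
    Classification,
    NodeSelection,
    ProteinRecord,
    sequences_under,
)

__all__ = [
    "SUPERKINGDOMS",
    "TaxProfile",
    "db_composition",
    "node_composition",
    "stratified_coverage",
]


@dataclass(frozen=True)
class TaxProfile:
    """Fraction of sequences per superkingdom within one scope."""

    scope: str
    proportions: dict[str, float]
    n_sequences: int

    @property
    def defined(self) -> bool:
        return self.n_sequences > 0


def _profile(scope: str, records: Iterable[ProteinRecord]) -> TaxProfile:
    counts = {k: 0 for k in SUPERKINGDOMS}
    n = 0
    for rec in records:
        counts[rec.superkingdom] += 1
        n += 1
    if n == 0:
        return TaxProfile(scope, {k: float("nan") for k in SUPERKINGDOMS}, 0)
    return TaxProfile(scope, {k: counts[k] / n for k in SUPERKINGDOMS}, n)


def db_composition(c: Classification) -> TaxProfile:
    """Superkingdom fractions over the distinct sequences of a database."""
    return _profile(c.name, c.records.values())


def node_composition(c: Classification, sel: NodeSelection) -> list[TaxProfile]:
    """One profile per selected node over the sequences under it.

    Empty nodes yield a profile with ``defined == False`` (NaN fractions).
    """
    if sel.classification != c.name:
        raise InputError("selection does not belong to this classification")
    return [
        _profile(n, (c.records[sid] for sid in sorted(sequences_under(c, n))))
        for n in sel.selected
    ]


def stratified_coverage(
    a: Classification,
    b: Classification,
    ctx: AlignmentContext | None = None,
    min_query_cover: float = 0.9,
) -> dict[str, float]:
    """Database coverage of ``a`` in ``b``, split by superkingdom of the query.

    Empty strata are omitted. The size-weighted average of the stratified
    percentages equals the overall coverage percentage exactly.
    """
    ctx = ctx or AlignmentContext(records=b.records, min_query_cover=min_query_cover)
    out: dict[str, float] = {}
    for kingdom in SUPERKINGDOMS:
        sids = sorted(s for s, r in a.records.items() if r.superkingdom == kingdom)
        if not sids:
            continue
        n_hit = sum(1 for sid in sids if ctx.best_hit(a.records[sid]) is not None)
        out[kingdom] = 100.0 * n_hit / len(sids)
    return out


def write_profiles(
    profiles: Iterable[TaxProfile], path: str | Path, header: str = ""
) -> None:
    """Long-form TSV: scope, superkingdom, fraction."""
    with open(path, "w", encoding="utf-8") as fh:
        if header:
            fh.write(header)
        fh.write("scope\tsuperkingdom\tfraction\n")
        for p in profiles:
            for k in SUPERKINGDOMS:
                v = p.proportions[k]
                cell = "NA" if not p.defined else f"{v:.6f}"
                fh.write(f"{p.scope}\t{k}\t{cell}\n")
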