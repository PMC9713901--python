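"""End-to-end orchestration: run every comparison on a set of bundles.

``run_all`` reproduces the full report set for any collection of
classification bundles: hierarchy statistics, redundancy summaries at
two identity thresholds, pairwise coverage, concordance matrices with
unassigned columns, best-match tables, self-overlap matrices with the
strict-hierarchy verdict, taxonomy profiles, kingdom-stratified
coverage, and — when reads are supplied — read-overlap partitions and
specific-versus-pooled assignment rates. All outputs are numeric TSV;
every file carries a header naming the tool version and a digest of the
configuration, and identical config + seed yields byte-identical files.
"""

from __future__ import annotations

import hashlib
import json
import logging
import sys
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from . import __version__
from .align import AlignmentContext, ScoringScheme
from .cluster import ClusteringParams, cluster_ratio, greedy_cluster, write_membership
from .crossmap import (
    best_match_table,
    concordance_matrix,
    database_coverage,
    self_overlap,
    strictness_check,
    write_best_matches,
    write_concordance,
    write_self_overlap,
)
from .errors import FuncmapError, InputError
from .model import (
    Classification,
    hierarchy_stats,
    load_classification,
    select_nodes,
)
from .reads import (
    assign_reads,
    overlap_partition,
    quality_filter,
    read_reads,
    specific_vs_pooled,
)
from .taxonomy import db_composition, node_composition, stratified_coverage, write_profiles

log = logging.getLogger("funcmap")


@dataclass
class BundleConfig:
    name: str
    hierarchy: str
    fasta: str
    leaf_map: str
    taxa: str | None = None
    selection: int | list[str] = 1  # depth level or explicit node list


@dataclass
class RunConfig:
    bundles: list[BundleConfig]
    out_dir: str = "funcmap_out"
    seed: int = 0
    identity_thresholds: tuple[float, ...] = (0.9, 0.7)
    min_query_cover: float = 0.9
    best_match_min_percent: float = 15.0
    quality_threshold: float = 20.0
    min_score: int = 50
    reads: str | None = None  # FASTA/FASTQ path

    def digest(self) -> str:
        # out_dir does not affect results and is excluded, so the same
        # analysis into two directories produces byte-identical reports
        payload = {k: v for k, v in asdict(self).items() if k != "out_dir"}
        canon = json.dumps(payload, sort_keys=True, default=str)
        return hashlib.sha256(canon.encode()).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        bundles = [BundleConfig(**b) for b in raw.pop("bundles")]
        cfg = cls(bundles=bundles, **raw)
        if isinstance(cfg.identity_thresholds, list):
            cfg.identity_thresholds = tuple(cfg.identity_thresholds)
        return cfg


def _header(config: RunConfig) -> str:
    return f"# funcmap {__version__} config={config.digest()} seed={config.seed}\n"


def _pct(x: float) -> str:
    return f"{x:.1f}"


def run_all(config: RunConfig) -> Path:
    """Run every stage; returns the output directory.

    Stages abort on the first failure with the failing stage named;
    each report file is written atomically (tmp file + rename).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log", mode="w")
    handler.setFormatter(logging.Formatter("%(levelname)s %(message)s"))
    log.addHandler(handler)
    log.setLevel(logging.INFO)
    hdr = _header(config)
    log.info("funcmap %s seed=%d config=%s", __version__, config.seed, config.digest())
    log.info(
        "thresholds: identity=%s min_query_cover=%s best_match=%s%% quality=%s min_score=%s",
        config.identity_thresholds,
        config.min_query_cover,
        config.best_match_min_percent,
        config.quality_threshold,
        config.min_score,
    )
    scheme = ScoringScheme(min_score=config.min_score)

    stage = "load"
    try:
        classifications: dict[str, Classification] = {}
        selections = {}
        for b in config.bundles:
            for p in (b.hierarchy, b.fasta, b.leaf_map):
                if not Path(p).exists():
                    raise InputError(f"missing bundle file: {p}")
            if b.taxa is not None and not Path(b.taxa).exists():
                raise InputError(f"missing bundle file: {b.taxa}")
            c = load_classification(b.hierarchy, b.fasta, b.leaf_map, b.taxa, name=b.name)
            classifications[b.name] = c
            selections[b.name] = select_nodes(c, b.selection)
        names = list(classifications)

        stage = "stats"
        _atomic_write(out / "hierarchy_stats.tsv", _stats_tsv(classifications, hdr))

        stage = "cluster"
        lines = [hdr, "database\tthreshold\tsequences\tclusters\tratio\n"]
        for name in names:
            c = classifications[name]
            for thr in config.identity_thresholds:
                cs = greedy_cluster(c.records, ClusteringParams(identity_threshold=thr), scheme)
                ratio = cluster_ratio(cs, len(c.records))
                lines.append(
                    f"{name}\t{thr}\t{len(c.records)}\t{cs.n_clusters}\t{ratio:.4f}\n"
                )
                write_membership(cs, out / f"clusters_{name}_t{int(thr * 100)}.tsv")
        _atomic_write(out / "redundancy_summary.tsv", "".join(lines))

        stage = "coverage"
        contexts = {
            name: AlignmentContext(
                records=classifications[name].records,
                scheme=scheme,
                min_query_cover=config.min_query_cover,
            )
            for name in names
        }
        lines = [hdr, "from_db\tto_db\tn_queries\tn_with_hit\tpercent_covered\n"]
        for a in names:
            for b in names:
                if a == b:
                    continue
                cov = database_coverage(
                    classifications[a], classifications[b], contexts[b]
                )
                lines.append(
                    f"{a}\t{b}\t{cov.n_queries}\t{cov.n_with_hit}\t{_pct(cov.percent_covered)}\n"
                )
        _atomic_write(out / "coverage.tsv", "".join(lines))

        stage = "concordance"
        for a in names:
            for b in names:
                if a == b:
                    continue
                m = concordance_matrix(
                    classifications[a],
                    classifications[b],
                    selections[a],
                    selections[b],
                    contexts[b],
                )
                write_concordance(
                    m, classifications[a], classifications[b],
                    out / f"concordance_{a}__{b}.tsv", hdr,
                )
                rows = best_match_table(
                    m, classifications[a], classifications[b],
                    config.best_match_min_percent,
                )
                write_best_matches(rows, out / f"best_match_{a}__{b}.tsv", hdr)

        stage = "selfmap"
        lines = [hdr, "database\tstrict_hierarchy\n"]
        for name in names:
            m = self_overlap(classifications[name], selections[name])
            write_self_overlap(
                m, classifications[name], out / f"self_overlap_{name}.tsv", hdr
            )
            strict = strictness_check(classifications[name], selections[name])
            lines.append(f"{name}\t{str(strict).lower()}\n")
        _atomic_write(out / "strictness.tsv", "".join(lines))

        stage = "taxonomy"
        profiles = [db_composition(classifications[n]) for n in names]
        for n in names:
            profiles.extend(node_composition(classifications[n], selections[n]))
        write_profiles(profiles, out / "taxonomy_profiles.tsv", hdr)
        lines = [hdr, "from_db\tto_db\tsuperkingdom\tpercent_covered\n"]
        for a in names:
            for b in names:
                if a == b:
                    continue
                strata = stratified_coverage(classifications[a], classifications[b], contexts[b])
                for kingdom, pct in strata.items():
                    lines.append(f"{a}\t{b}\t{kingdom}\t{_pct(pct)}\n")
        _atomic_write(out / "stratified_coverage.tsv", "".join(lines))

        if config.reads is not None:
            stage = "reads"
            reads = quality_filter(read_reads(config.reads), config.quality_threshold)
            log.info("reads: %d pass the quality filter", len(reads))
            assignments = {
                n: assign_reads(
                    reads, classifications[n], contexts[n], config.min_query_cover
                )
                for n in names
            }
            lines = [hdr, "classification\tn_reads\tn_assigned\tpercent\n"]
            for n in names:
                ra = assignments[n]
                lines.append(
                    f"{n}\t{ra.n_reads}\t{len(ra.assigned)}\t{_pct(ra.percent_assigned)}\n"
                )
            _atomic_write(out / "read_assignment.tsv", "".join(lines))

            lines = [hdr, "db_a\tdb_b\tonly_a\tboth\tonly_b\n"]
            for i, a in enumerate(names):
                for b in names[i + 1 :]:
                    part = overlap_partition(assignments[a], assignments[b])
                    lines.append(
                        f"{a}\t{b}\t{part.only_a:.4f}\t{part.both:.4f}\t{part.only_b:.4f}\n"
                    )
            _atomic_write(out / "read_overlap.tsv", "".join(lines))

            pool = list(classifications.values())
            lines = [hdr, "classification\tspecific_percent\tpooled_percent\n"]
            for n in names:
                spec, pooled = specific_vs_pooled(
                    reads, classifications[n], pool, config.min_query_cover, scheme
                )
                lines.append(f"{n}\t{_pct(spec)}\t{_pct(pooled)}\n")
            _atomic_write(out / "specific_vs_pooled.tsv", "".join(lines))
    except Exception as exc:
        log.error("stage %s failed: %s", stage, exc)
        raise FuncmapError(f"stage {stage!r} failed: {exc}") from exc
    finally:
        log.removeHandler(handler)
        handler.close()
    return out


def _stats_tsv(classifications: Mapping[str, Classification], hdr: str) -> str:
    lines = [hdr, "database\tmedian_depth\tinternal_nodes\tleaves\tsequences\n"]
    for name, c in classifications.items():
        st = hierarchy_stats(c)
        lines.append(
            f"{name}\t{st.median_depth}\t{st.internal_nodes}\t{st.leaves}\t{st.sequences}\n"
        )
    return "".join(lines)


def _atomic_write(path: Path, text: str) -> None:
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text, encoding="utf-8")
    tmp.replace(path)
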