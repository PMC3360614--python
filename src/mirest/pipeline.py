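"""Orchestration of the discovery, expression and target stages.

These are the library entry points the command-line interface wraps: each
takes parsed inputs plus a :class:`~mirest.config.PipelineConfig`, returns
plain result objects, and is deterministic given config and seed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd

from .config import PipelineConfig
from .energy import EnergyModel, default_model
from .expression import (
    ExpressionMatrix,
    ClusterResult,
    cluster_rows,
    count_classes,
    relative_expression,
)
from .fold import fold_single_hairpin
from .homology import HomologyHit, extract_windows, scan_est
from .io import ESTRecord, MatureMiRNA, UTRRecord
from .precursor import (
    AcceptedMature,
    MiRNACluster,
    PrecursorCandidate,
    detect_clusters,
    evaluate_candidate,
    select_best_precursor,
)
from .targets import DuplexResult, find_class1_sites, find_class2_targets

log = logging.getLogger("mirest")

__all__ = ["AcceptedPrecursor", "DiscoveryResult", "discover",
           "expression_profile", "predict_targets"]


@dataclass(frozen=True)
class AcceptedPrecursor:
    """A validated precursor: the product of the discovery pipeline."""

    name: str
    est_id: str
    ref_name: str
    strand: str
    win_start: int
    win_end: int
    mature_start: int
    mature_end: int
    mismatches: int
    dg: float
    sequence: str
    dot_bracket: str
    mature_seq: str


@dataclass
class DiscoveryResult:
    hits: list[HomologyHit] = field(default_factory=list)
    accepted: list[AcceptedPrecursor] = field(default_factory=list)
    clusters: list[MiRNACluster] = field(default_factory=list)
    counts: dict = field(default_factory=dict)


def discover(
    ests: list[ESTRecord],
    refs: list[MatureMiRNA],
    config: PipelineConfig | None = None,
    model: EnergyModel | None = None,
) -> DiscoveryResult:
    """Homology scan -> window extraction -> hairpin filter -> clusters.

    Stage counts (input ESTs, ESTs with homologous fragments, accepted
    precursors) are logged and returned in ``result.counts``.
    """
    config = config or PipelineConfig()
    model = model or default_model()
    thr = config.thresholds()
    result = DiscoveryResult()
    ests_with_hits = 0
    n_candidates = 0

    for est in ests:
        hits = scan_est(est, refs, config.max_mm)
        if hits:
            ests_with_hits += 1
        result.hits.extend(hits)
        for hit in hits:
            candidates = []
            for win in extract_windows(est, hit, config.window_len):
                st = fold_single_hairpin(win.sequence, model)
                candidates.append(
                    evaluate_candidate(PrecursorCandidate(win, st), thr, model)
                )
            n_candidates += len(candidates)
            best = select_best_precursor(candidates)
            if best is None:
                continue
            w, s = best.window, best.structure
            mo = w.mature_offset
            result.accepted.append(AcceptedPrecursor(
                name=f"{est.id}|{hit.ref_name}",
                est_id=est.id,
                ref_name=hit.ref_name,
                strand=hit.strand,
                win_start=w.win_start,
                win_end=w.win_end,
                mature_start=hit.start,
                mature_end=hit.end,
                mismatches=hit.mismatches,
                dg=s.mfe,
                sequence=w.sequence,
                dot_bracket=s.dot_bracket,
                mature_seq=w.sequence[mo:mo + w.mature_length],
            ))

    result.clusters = detect_clusters(
        [
            AcceptedMature(a.est_id, a.name, a.mature_start,
                           a.mature_end, a.strand)
            for a in result.accepted
        ],
        config.max_spacer,
    )
    result.counts = {
        "n_ests": len(ests),
        "n_ests_with_hits": ests_with_hits,
        "n_hits": len(result.hits),
        "n_candidates": n_candidates,
        "n_accepted": len(result.accepted),
        "n_clusters": len(result.clusters),
    }
    log.info(
        "discover [%s]: %d ESTs -> %d homologous -> %d validated precursors",
        config.config_hash, result.counts["n_ests"],
        result.counts["n_ests_with_hits"], result.counts["n_accepted"],
    )
    return result


@dataclass
class ExpressionRunResult:
    matrix: ExpressionMatrix
    class_counts: dict
    clustering: ClusterResult | None


def expression_profile(
    table: pd.DataFrame, config: PipelineConfig | None = None
) -> ExpressionRunResult:
    """Relative expression, fold classes and clustered row order."""
    config = config or PipelineConfig()
    matrix = relative_expression(
        table, config.expression_control, config.expression_reference
    )
    counts = {
        label: count_classes(matrix, label)
        for label in ("high", "moderate", "very_low", "intermediate",
                      "undefined")
    }
    clustering = None
    if matrix.clamped.shape[0] >= 2:
        clustering = cluster_rows(matrix)
    else:
        log.warning("fewer than two miRNA rows: clustering skipped")
    log.info("expression [%s]: classes %s", config.config_hash, counts)
    return ExpressionRunResult(matrix, counts, clustering)


@dataclass
class TargetRunResult:
    results: list[DuplexResult]
    per_mirna: dict


def predict_targets(
    mirnas: list[MatureMiRNA],
    utrs: list[UTRRecord],
    config: PipelineConfig | None = None,
    model: EnergyModel | None = None,
) -> TargetRunResult:
    """Class I and Class II sites for each miRNA over a 3'UTR set."""
    config = config or PipelineConfig()
    model = model or default_model()
    all_results: list[DuplexResult] = []
    per_mirna: dict[str, dict] = {}
    for m in mirnas:
        rows: list[DuplexResult] = []
        if m.length >= 8:
            for utr in utrs:
                rows.extend(find_class1_sites(
                    m, utr, model, config.duplex_dg_max
                ))
        if m.length >= 14:
            rows.extend(find_class2_targets(
                m, utrs, model, config.duplex_dg_max, config.class2_mode
            ))
        # per-gene counting: a gene is one target however many sites it has
        genes = {r.gene_id for r in rows}
        genes2 = {r.gene_id for r in rows if r.site_class == "II"}
        per_mirna[m.name] = {
            "n_targets": len(genes),
            "n_class2": len(genes2),
        }
        all_results.extend(rows)
    log.info("targets [%s]: %d site(s) across %d miRNA(s)",
             config.config_hash, len(all_results), len(mirnas))
    return TargetRunResult(all_results, per_mirna)


def clusters_to_gff3(clusters: list[MiRNACluster]) -> str:
    lines = ["##gff-version 3"]
    for c in clusters:
        lines.append("\t".join([
            c.est_id, "mirest", "miRNA_cluster", "1", "1", ".", "+", ".",
            f"ID={c.est_id}_cluster;members={','.join(c.member_names)};"
            f"spacers={','.join(str(s) for s in c.spacers)}",
        ]))
    return "\n".join(lines) + "\n"
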