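"""End-to-end assembly: SAM alignments in, transcript models out."""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from typing import Optional

from .alignments import detect_regions, estimate_fragment_stats, parse_alignments
from .core import FragmentStats, Transcript
from .exons import infer_region_exons
from .graph import build_graph, enumerate_maximal_paths
from .gtf import write_gtf
from .selection import (
    IntervalIndex,
    build_constraint_graph,
    derive_constraints,
    load_evidence_intron_pairs,
    prune_unsatisfiable,
    transcript_weight,
    weighted_greedy_set_cover,
)

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """All tunable assembly parameters; JSON round-trippable."""

    min_mapq: int = 0
    max_gap: int = 0
    min_region_len: int = 25
    min_junction_support: int = 1
    min_anchor: int = 8
    frag_len: Optional[float] = None
    frag_sd: Optional[float] = None
    lp_lower_bound: float = 1.0
    max_candidates: int = 16
    max_paths: int = 1000
    evidence_lambda: float = 1.0
    weighted: bool = True

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        return cls(**json.loads(text))


@dataclass
class AssemblyResult:
    transcripts: list[Transcript]
    stats: Optional[FragmentStats]
    diagnostics: dict = field(default_factory=dict)


def assemble(
    sam_path: str,
    annotation: Optional[str] = None,
    config: Optional[RunConfig] = None,
) -> AssemblyResult:
    """Run ingest -> exon inference -> splice graph -> set-cover selection.

    The weighted selection mode is used iff an annotation is given and
    ``config.weighted`` is true; otherwise selection is unweighted.
    """
    cfg = config or RunConfig()
    log.debug("resolved config: %s", cfg.to_json())
    store = parse_alignments(sam_path, min_mapq=cfg.min_mapq)
    regions = detect_regions(
        store, max_gap=cfg.max_gap, min_region_len=cfg.min_region_len
    )
    stats: Optional[FragmentStats] = None
    if cfg.frag_len is not None:
        stats = FragmentStats(f_l=cfg.frag_len, f_sigma=cfg.frag_sd or 0.0)
    elif store.pairs:
        stats = estimate_fragment_stats(store, regions)
    junctions = store.junction_list(
        min_support=cfg.min_junction_support, min_anchor=cfg.min_anchor
    )

    exons = []
    n_fallback = 0
    for region in regions:
        for res in infer_region_exons(
            region, store, junctions, stats,
            min_junction_support=cfg.min_junction_support,
            min_anchor=cfg.min_anchor,
            max_candidates=cfg.max_candidates,
            lp_lower_bound=cfg.lp_lower_bound,
        ):
            exons.extend(res.exons)
            n_fallback += res.fallback

    graph = build_graph(exons, junctions)
    candidates, truncated = enumerate_maximal_paths(graph, max_paths=cfg.max_paths)

    boundary_positions: dict[str, set[int]] = {}
    for j in junctions:
        boundary_positions.setdefault(j.contig, set()).update((j.donor, j.acceptor))
    index = IntervalIndex(regions, boundary_positions)
    constraints, dropped = derive_constraints(store, index)
    cgraph = build_constraint_graph(constraints, candidates, stats, index)
    pruned = prune_unsatisfiable(cgraph)

    weights = None
    if annotation is not None and cfg.weighted:
        evidence = load_evidence_intron_pairs(annotation)
        weights = [
            transcript_weight(t, evidence, cfg.evidence_lambda).value
            for t in pruned.transcripts
        ]
    selected_idx = weighted_greedy_set_cover(pruned, weights)
    selected = sorted(
        (pruned.transcripts[i] for i in selected_idx), key=lambda t: t.sort_key()
    )
    transcripts = _assign_ids(selected)
    diagnostics = {
        "n_reads": len(store.reads),
        "n_pairs": len(store.pairs),
        "n_skipped_records": store.n_skipped,
        "n_regions": len(regions),
        "n_exons": len(set(exons)),
        "n_candidate_transcripts": len(candidates),
        "n_constraints": len(constraints),
        "n_constraints_pruned": len(constraints) - len(pruned.constraints),
        "n_orphan_reads": dropped,
        "n_region_fallbacks": n_fallback,
        "paths_truncated": truncated,
        "mode": "weighted" if weights is not None else "unweighted",
    }
    log.info("assembled %d transcripts (%s)", len(transcripts), diagnostics["mode"])
    return AssemblyResult(transcripts=transcripts, stats=stats, diagnostics=diagnostics)


def _assign_ids(selected: list[Transcript]) -> list[Transcript]:
    """Cluster overlapping transcripts (same contig/strand) into genes and
    assign sequential identifiers."""
    out: list[Transcript] = []
    gene_no = 0
    cluster: list[Transcript] = []
    cluster_end = -1
    cluster_key: Optional[tuple] = None

    def flush():
        nonlocal gene_no
        if not cluster:
            return
        gene_no += 1
        gid = f"G{gene_no:06d}"
        for k, t in enumerate(sorted(cluster, key=lambda t: t.sort_key()), start=1):
            out.append(
                Transcript(
                    contig=t.contig, strand=t.strand, exons=t.exons,
                    transcript_id=f"{gid}.{k}", gene_id=gid,
                )
            )
        cluster.clear()

    for t in sorted(selected, key=lambda t: (t.contig, t.strand, t.start, t.end)):
        key = (t.contig, t.strand)
        if cluster and (key != cluster_key or t.start >= cluster_end):
            flush()
        cluster.append(t)
        cluster_key = key
        cluster_end = max(cluster_end, t.end) if len(cluster) > 1 else t.end
    flush()
    out.sort(key=lambda t: t.sort_key())
    return out


def assemble_to_gtf(
    sam_path: str,
    out_gtf: str,
    annotation: Optional[str] = None,
    config: Optional[RunConfig] = None,
) -> AssemblyResult:
    result = assemble(sam_path, annotation=annotation, config=config)
    write_gtf(out_gtf, result.transcripts)
    return result
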