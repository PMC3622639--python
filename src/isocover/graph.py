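"""Splice graph assembly and maximal-path enumeration.

Exons chosen per region become nodes; a filtered junction whose donor
equals one exon's end and whose acceptor equals another exon's start (with
agreeing strands) becomes a directed edge.  Candidate transcripts are the
maximal source-to-sink paths; isolated exons yield single-exon candidates.
"""

from __future__ import annotations

import logging
from typing import Iterable, Sequence

import networkx as nx

from .core import Exon, Junction, Transcript

log = logging.getLogger(__name__)


def _strands_agree(a: str, b: str) -> bool:
    return a == b or a == "." or b == "."


def build_graph(exons: Iterable[Exon], junctions: Sequence[Junction]) -> nx.DiGraph:
    """Connect exons via read-supported introns into a DAG.

    Edge (u, v) exists iff a junction has donor == u.end, acceptor ==
    v.start, same contig and compatible strand.  Junctions matching no exon
    boundary are logged as dangling.
    """
    g = nx.DiGraph()
    by_end: dict[tuple[str, int], list[Exon]] = {}
    by_start: dict[tuple[str, int], list[Exon]] = {}
    for e in sorted(set(exons), key=lambda e: e.sort_key()):
        g.add_node(e)
        by_end.setdefault((e.contig, e.end), []).append(e)
        by_start.setdefault((e.contig, e.start), []).append(e)
    for j in junctions:
        donors = by_end.get((j.contig, j.donor), [])
        acceptors = by_start.get((j.contig, j.acceptor), [])
        linked = False
        for u in donors:
            for v in acceptors:
                if (
                    _strands_agree(u.strand, v.strand)
                    and _strands_agree(u.strand, j.strand)
                    and _strands_agree(v.strand, j.strand)
                ):
                    g.add_edge(u, v, support=j.support, strand=j.strand)
                    linked = True
        if not linked:
            log.debug(
                "dangling junction %s:%d-%d (%s), support %d",
                j.contig, j.donor, j.acceptor, j.strand, j.support,
            )
    if not nx.is_directed_acyclic_graph(g):
        raise RuntimeError("splice graph contains a cycle; exon/junction coordinates inconsistent")
    return g


def enumerate_maximal_paths(
    g: nx.DiGraph, max_paths: int = 1000
) -> tuple[list[Transcript], bool]:
    """All source-to-sink paths, per weakly connected component.

    When a component holds more than ``max_paths`` maximal paths,
    enumeration explores highest-support edges first and stops at the cap
    (truncation flagged), so the retained paths are biased toward
    well-supported splice structures.
    """
    transcripts: list[Transcript] = []
    truncated = False
    components = sorted(
        nx.weakly_connected_components(g),
        key=lambda nodes: min(e.sort_key() for e in nodes),
    )
    for nodes in components:
        sub = g.subgraph(nodes)
        sources = sorted(
            (n for n in sub.nodes if sub.in_degree(n) == 0), key=lambda e: e.sort_key()
        )
        paths: list[tuple[Exon, ...]] = []
        overflow = False

        def dfs(node: Exon, prefix: list[Exon]) -> bool:
            nonlocal overflow
            prefix.append(node)
            succ = sorted(
                sub.successors(node),
                key=lambda v: (-sub.edges[node, v].get("support", 0), v.sort_key()),
            )
            if not succ:
                if len(paths) >= max_paths:
                    overflow = True
                    prefix.pop()
                    return False
                paths.append(tuple(prefix))
            else:
                for v in succ:
                    if not dfs(v, prefix):
                        prefix.pop()
                        return False
            prefix.pop()
            return True

        for s in sources:
            if not dfs(s, []):
                break
        if overflow:
            truncated = True
            log.warning("component truncated at %d maximal paths", max_paths)
        for chain in paths:
            strand = next((e.strand for e in chain if e.strand in "+-"), ".")
            if strand == ".":
                strand = next(
                    (
                        sub.edges[u, v].get("strand", ".")
                        for u, v in zip(chain[:-1], chain[1:])
                        if sub.edges[u, v].get("strand", ".") in "+-"
                    ),
                    ".",
                )
            transcripts.append(
                Transcript(
                    contig=chain[0].contig,
                    strand=strand,
                    exons=tuple((e.start, e.end) for e in chain),
                )
            )
    transcripts.sort(key=lambda t: t.sort_key())
    return transcripts, truncated
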