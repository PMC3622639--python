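"""Transcript selection by (weighted) greedy set cover.

Every read or read pair induces a contiguity constraint: the ordered
intervals it overlaps, the junctions it spans, and for pairs the
(left-start interval, right-end interval) fragment class.  Identical
constraints collapse with a multiplicity.  A candidate transcript
satisfies a constraint when it contains all its intervals, reproduces its
junctions exactly over the read's footprint, and (for pairs) admits a
fragment length inside the f_l +/- 2 f_sigma window.  Selection covers all
satisfiable constraints with greedily chosen transcripts; the weighted
mode divides each transcript's weight by the number of newly covered
constraints, where weights derive from annotation support of consecutive
intron pairs.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

from .core import FragmentStats, ReadPair, Region, Transcript
from .alignments import ReadStore
from .gtf import read_gtf

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class GlobalInterval:
    gid: int
    contig: str
    start: int
    end: int


class IntervalIndex:
    """Global tiling of all regions into boundary-delimited intervals."""

    def __init__(self, regions: Sequence[Region], boundary_positions: dict[str, set[int]]):
        self.intervals: list[GlobalInterval] = []
        self._by_contig: dict[str, tuple[list[int], list[GlobalInterval]]] = {}
        per_contig: dict[str, list[GlobalInterval]] = {}
        for region in sorted(regions, key=lambda r: (r.contig, r.start)):
            cuts = sorted(
                p
                for p in boundary_positions.get(region.contig, set())
                if region.start < p < region.end
            )
            edges = [region.start] + cuts + [region.end]
            for s, e in zip(edges[:-1], edges[1:]):
                gi = GlobalInterval(gid=len(self.intervals), contig=region.contig, start=s, end=e)
                self.intervals.append(gi)
                per_contig.setdefault(region.contig, []).append(gi)
        for contig, ivs in per_contig.items():
            self._by_contig[contig] = ([iv.start for iv in ivs], ivs)

    def locate(self, contig: str, pos: int) -> Optional[int]:
        entry = self._by_contig.get(contig)
        if entry is None:
            return None
        starts, ivs = entry
        k = bisect_right(starts, pos) - 1
        if 0 <= k < len(ivs) and ivs[k].start <= pos < ivs[k].end:
            return ivs[k].gid
        return None

    def span_gids(self, contig: str, start: int, end: int) -> Optional[tuple[int, ...]]:
        """Contiguous run of intervals overlapping [start, end); None if a
        base falls outside all intervals."""
        first = self.locate(contig, start)
        last = self.locate(contig, end - 1)
        if first is None or last is None:
            return None
        gids = tuple(range(first, last + 1))
        # verify tiling continuity across the span
        for a, b in zip(gids[:-1], gids[1:]):
            if self.intervals[a].end != self.intervals[b].start:
                return None
        return gids

    def covered_by_exons(self, contig: str, exons: Sequence[tuple[int, int]]) -> frozenset[int]:
        out = set()
        for s, e in exons:
            gids = self.span_gids(contig, s, e)
            if gids:
                out.update(
                    g
                    for g in gids
                    if self.intervals[g].start >= s and self.intervals[g].end <= e
                )
        return frozenset(out)


# chain item: ('I', gid) or ('J', donor, acceptor)
Chain = tuple[tuple, ...]


@dataclass(frozen=True)
class Constraint:
    contig: str
    chains: tuple[Chain, ...]
    pair_info: Optional[tuple[int, int]] = None
    multiplicity: int = 1

    @property
    def interval_ids(self) -> frozenset[int]:
        return frozenset(it[1] for ch in self.chains for it in ch if it[0] == "I")

    @property
    def junction_chain(self) -> tuple[tuple[int, int], ...]:
        return tuple((it[1], it[2]) for ch in self.chains for it in ch if it[0] == "J")


def _read_chain(read, index: IntervalIndex) -> Optional[Chain]:
    items: list[tuple] = []
    for k, (bs, be) in enumerate(read.blocks):
        gids = index.span_gids(read.contig, bs, be)
        if gids is None:
            return None
        if k > 0:
            d, a = read.junctions[k - 1]
            items.append(("J", d, a))
        items.extend(("I", g) for g in gids)
    return tuple(items)


def derive_constraints(
    store: ReadStore, index: IntervalIndex
) -> tuple[list[Constraint], int]:
    """Deduplicated constraints from all reads and read pairs.

    Paired reads contribute one constraint per pair (both mates' chains
    plus the fragment class); unpaired reads one each.  Reads touching
    bases outside every interval are dropped with a counter.
    """
    counts: dict[tuple, int] = {}
    dropped = 0
    paired = store.paired_read_ids
    for i, read in enumerate(store.reads):
        if i in paired:
            continue
        chain = _read_chain(read, index)
        if chain is None:
            dropped += 1
            continue
        counts[(read.contig, (chain,), None)] = counts.get((read.contig, (chain,), None), 0) + 1
    for pair in store.pairs:
        lc = _read_chain(pair.left, index)
        rc = _read_chain(pair.right, index)
        if lc is None or rc is None:
            dropped += 1
            continue
        gi = index.locate(pair.left.contig, pair.left.start)
        gj = index.locate(pair.right.contig, pair.right.end - 1)
        pair_info = (gi, gj) if gi is not None and gj is not None else None
        key = (pair.left.contig, (lc, rc), pair_info)
        counts[key] = counts.get(key, 0) + 1
    out = [
        Constraint(contig=contig, chains=chains, pair_info=pi, multiplicity=m)
        for (contig, chains, pi), m in sorted(counts.items())
    ]
    return out, dropped


@dataclass
class TranscriptFacts:
    """Precomputed lookups for constraint satisfaction."""

    transcript: Transcript
    interval_ids: frozenset[int]
    introns: frozenset[tuple[int, int]]
    donor_positions: frozenset[int]


def transcript_facts(t: Transcript, index: IntervalIndex) -> TranscriptFacts:
    introns = frozenset(t.introns)
    return TranscriptFacts(
        transcript=t,
        interval_ids=index.covered_by_exons(t.contig, t.exons),
        introns=introns,
        donor_positions=frozenset(d for d, _ in introns),
    )


def satisfies(
    facts: TranscriptFacts,
    c: Constraint,
    stats: Optional[FragmentStats],
    index: IntervalIndex,
) -> bool:
    """Whether a transcript explains a read/pair constraint."""
    t = facts.transcript
    if t.contig != c.contig:
        return False
    if not c.interval_ids <= facts.interval_ids:
        return False
    for chain in c.chains:
        prev_gid: Optional[int] = None
        pending_junction: Optional[tuple[int, int]] = None
        for item in chain:
            if item[0] == "J":
                pending_junction = (item[1], item[2])
                continue
            gid = item[1]
            if prev_gid is not None:
                if pending_junction is not None:
                    if pending_junction not in facts.introns:
                        return False
                else:
                    # contiguously covered adjacent intervals: the shared
                    # boundary must not be a donor of this transcript
                    boundary = index.intervals[prev_gid].end
                    if boundary in facts.donor_positions:
                        return False
            prev_gid = gid
            pending_junction = None
    if c.pair_info is not None and stats is not None:
        gi, gj = c.pair_info
        iv_i, iv_j = index.intervals[gi], index.intervals[gj]
        if iv_j.start + 1 > iv_i.end - 1:
            d_min = t.spliced_distance(iv_i.end - 1, iv_j.start + 1)
        else:
            d_min = 0
        d_max = t.spliced_distance(iv_i.start, iv_j.end)
        lo, hi = stats.window
        if d_max < lo or d_min > hi:
            return False
    return True


@dataclass
class ConstraintGraph:
    constraints: list[Constraint]
    transcripts: list[Transcript]
    # sat[t] = set of constraint indices transcript t satisfies
    sat: list[set[int]] = field(default_factory=list)

    @property
    def n_edges(self) -> int:
        return sum(len(s) for s in self.sat)


def build_constraint_graph(
    constraints: Sequence[Constraint],
    transcripts: Sequence[Transcript],
    stats: Optional[FragmentStats],
    index: IntervalIndex,
) -> ConstraintGraph:
    facts = [transcript_facts(t, index) for t in transcripts]
    sat = []
    for f in facts:
        sat.append(
            {ci for ci, c in enumerate(constraints) if satisfies(f, c, stats, index)}
        )
    return ConstraintGraph(
        constraints=list(constraints), transcripts=list(transcripts), sat=sat
    )


def prune_unsatisfiable(graph: ConstraintGraph) -> ConstraintGraph:
    """Drop constraints no candidate transcript satisfies (likely artifacts)."""
    satisfiable = set()
    for s in graph.sat:
        satisfiable |= s
    keep = sorted(satisfiable)
    if len(keep) < len(graph.constraints):
        log.info(
            "pruned %d unsatisfiable constraints of %d",
            len(graph.constraints) - len(keep), len(graph.constraints),
        )
    remap = {old: new for new, old in enumerate(keep)}
    return ConstraintGraph(
        constraints=[graph.constraints[i] for i in keep],
        transcripts=graph.transcripts,
        sat=[{remap[i] for i in s} for s in graph.sat],
    )


def weighted_greedy_set_cover(
    graph: ConstraintGraph, weights: Optional[Sequence[float]] = None
) -> list[int]:
    """Greedy cover: repeatedly add the transcript minimising
    weight / newly-covered-constraints.

    With all weights equal this reduces exactly to the unweighted rule
    (most new constraints first).  Ties prefer smaller weight, then longer
    intron chain, then lexicographically smaller coordinates.  Returns
    selected transcript indices in selection order.
    """
    n_t = len(graph.transcripts)
    w = [1.0] * n_t if weights is None else [float(x) for x in weights]
    uncovered: set[int] = set()
    for s in graph.sat:
        uncovered |= s
    selected: list[int] = []
    chosen: set[int] = set()
    while uncovered:
        best_key = None
        best_t = None
        for ti in range(n_t):
            if ti in chosen:
                continue
            new = len(graph.sat[ti] & uncovered)
            if new == 0:
                continue
            key = (
                w[ti] / new,
                w[ti],
                -(graph.transcripts[ti].n_exons - 1),
                graph.transcripts[ti].sort_key(),
            )
            if best_key is None or key < best_key:
                best_key = key
                best_t = ti
        if best_t is None:
            break  # cannot happen on a pruned graph
        selected.append(best_t)
        chosen.add(best_t)
        uncovered -= graph.sat[best_t]
    return selected


def greedy_set_cover(graph: ConstraintGraph) -> list[int]:
    """Unweighted greedy cover (largest number of new constraints first)."""
    return weighted_greedy_set_cover(graph, None)


# ---------------------------------------------------------------------------
# Annotation-derived weights


def load_evidence_intron_pairs(
    annotation_path: str,
) -> set[tuple[str, str, tuple[int, int], tuple[int, int]]]:
    """Consecutive intron pairs of every annotated multi-intron transcript."""
    pairs = set()
    for t in read_gtf(annotation_path):
        introns = t.introns
        for k in range(len(introns) - 1):
            pairs.add((t.contig, t.strand, introns[k], introns[k + 1]))
    return pairs


@dataclass(frozen=True)
class TranscriptWeight:
    value: float
    evidence_fraction: float


def transcript_weight(
    t: Transcript,
    evidence: set[tuple[str, str, tuple[int, int], tuple[int, int]]],
    lam: float = 1.0,
) -> TranscriptWeight:
    """1 + lambda * (fraction of consecutive intron pairs not in evidence).

    Transcripts with fewer than two introns have no intron pairs; the
    measure is undefined for them and they get evidence fraction 1 (weight
    1) so short genes are not penalised.
    """
    introns = t.introns
    pairs = [
        (t.contig, t.strand, introns[k], introns[k + 1])
        for k in range(len(introns) - 1)
    ]
    if not pairs:
        frac = 1.0
    else:
        hits = sum(1 for p in pairs if p in evidence)
        # strand-agnostic fallback for unstranded predictions
        if hits == 0 and t.strand == ".":
            hits = sum(
                1
                for p in pairs
                if any((p[0], s, p[2], p[3]) in evidence for s in "+-")
            )
        frac = hits / len(pairs)
    return TranscriptWeight(value=1.0 + lam * (1.0 - frac), evidence_fraction=frac)
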