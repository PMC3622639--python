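"""Exon inference per covered region.

Each covered region is split at splice sites into intervals.  Candidate
exons pair a left boundary (region start or an acceptor site) with a right
boundary (a donor site or the region end).  Every feasible subset of
candidates is scored with a linear program whose variables are per-subexon
coverages c_{i,j}: slack is paid where interval coverages fail additivity
(the coverages of the subexons stacked in an interval should sum to the
interval's mean coverage) or continuity (adjacent subexons of one exon
should have equal coverage), under a hard conservation equality on total
coverage.  Paired-end data adds, per (left-start interval, right-end
interval) pair class, the fraction of pairs whose feasible fragment-length
range misses the f_l +/- 2 f_sigma window.  The minimum-score subset wins;
ties prefer fewer exons, then lexicographically smaller coordinates.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.optimize import linprog

from .core import Exon, FragmentStats, Junction, Region
from .alignments import ReadStore

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Interval:
    """One piece of a region between consecutive splice-site boundaries."""

    index: int
    start: int
    end: int
    mean_coverage: float

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class CandidateExon:
    start: int
    end: int
    first_j: int
    last_j: int
    left_kind: str  # 'region_edge' | 'acceptor'
    right_kind: str  # 'region_edge' | 'donor'

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end


@dataclass
class LPSolution:
    status: str  # 'optimal' | 'infeasible'
    objective: float = float("inf")
    c: dict[tuple[int, int], float] = field(default_factory=dict)
    eps: list[float] = field(default_factory=list)
    lower_bound_used: float = 1.0


@dataclass
class CombinationScore:
    lp_objective: float
    pair_penalty: float
    n_exons: int

    @property
    def total(self) -> float:
        return self.lp_objective + self.pair_penalty


@dataclass
class RegionResult:
    """Chosen exon set for one region, plus its intervals for later reuse."""

    region: Region
    strand: str
    intervals: list[Interval]
    exons: list[Exon]
    score: Optional[CombinationScore]
    fallback: bool = False


def partition_intervals(
    region: Region,
    boundaries: Sequence[int],
    store: ReadStore,
) -> list[Interval]:
    """Split a region at boundary positions; attach per-interval coverage.

    Mean coverage of interval j is the number of aligned read-block bases
    falling in the interval divided by its length.
    """
    cuts = [region.start] + sorted(set(boundaries)) + [region.end]
    base = np.zeros(region.length + 1, dtype=np.int64)
    for rid in region.read_ids:
        for bs, be in store.reads[rid].blocks:
            lo, hi = max(bs, region.start), min(be, region.end)
            if lo < hi:
                base[lo - region.start] += 1
                base[hi - region.start] -= 1
    cov = np.cumsum(base)[:-1]
    out = []
    for j, (s, e) in enumerate(zip(cuts[:-1], cuts[1:])):
        mean = float(cov[s - region.start : e - region.start].sum()) / (e - s)
        out.append(Interval(index=j, start=s, end=e, mean_coverage=mean))
    return out


def enumerate_candidate_exons(
    region: Region,
    intervals: Sequence[Interval],
    boundaries: Sequence[tuple[int, str]],
) -> list[CandidateExon]:
    """All (left boundary, right boundary) pairings with left < right.

    Left boundaries are the region start and every acceptor site; right
    boundaries are every donor site and the region end.
    """
    starts = {iv.start: iv.index for iv in intervals}
    ends = {iv.end: iv.index for iv in intervals}
    lefts = [(region.start, "region_edge")] + [
        (p, "acceptor") for p, lab in boundaries if lab == "acceptor"
    ]
    rights = [(p, "donor") for p, lab in boundaries if lab == "donor"] + [
        (region.end, "region_edge")
    ]
    out = []
    for (ls, lk), (rs, rk) in itertools.product(lefts, rights):
        if ls < rs:
            out.append(
                CandidateExon(
                    start=ls, end=rs, first_j=starts[ls], last_j=ends[rs],
                    left_kind=lk, right_kind=rk,
                )
            )
    out.sort(key=lambda c: (c.start, c.end))
    return out


# ---------------------------------------------------------------------------
# Feasibility evidence, precomputed once per region


@dataclass
class RegionEvidence:
    """Read-derived facts a candidate-exon subset must explain.

    ``requirements`` are deduplicated read blocks with optional pinned
    boundaries (a block preceded by a junction must start exactly at its
    acceptor; one followed by a junction must end exactly at its donor).
    ``pair_points`` are deduplicated inner-endpoint pairs of read pairs.
    ``pair_classes`` count pairs by (left-start interval, right-end
    interval).  ``n_pairs`` is the total pair count N of the region.
    """

    requirements: list[tuple[int, int, Optional[int], Optional[int]]]
    pair_points: list[tuple[int, int]]
    pair_classes: dict[tuple[int, int], int]
    n_pairs: int
    n_dropped: int = 0


def collect_region_evidence(
    region: Region,
    store: ReadStore,
    intervals: Sequence[Interval],
    boundary_positions: set[int],
) -> RegionEvidence:
    valid_pins = boundary_positions | {region.start, region.end}
    reqs: set[tuple[int, int, Optional[int], Optional[int]]] = set()
    dropped = 0
    region_read_ids = set(region.read_ids)
    for rid in region.read_ids:
        read = store.reads[rid]
        nb = len(read.blocks)
        for k, (bs, be) in enumerate(read.blocks):
            if be <= region.start or bs >= region.end:
                continue
            pin_l = bs if k > 0 else None
            pin_r = be if k < nb - 1 else None
            if (pin_l is not None and pin_l not in valid_pins) or (
                pin_r is not None and pin_r not in valid_pins
            ):
                dropped += 1  # junction filtered out; don't poison the region
                continue
            reqs.add((bs, be, pin_l, pin_r))
    pair_points: set[tuple[int, int]] = set()
    pair_classes: dict[tuple[int, int], int] = {}
    n_pairs = 0
    iv_starts = [iv.start for iv in intervals]

    def interval_of(pos: int) -> Optional[int]:
        from bisect import bisect_right

        k = bisect_right(iv_starts, pos) - 1
        if 0 <= k < len(intervals) and intervals[k].start <= pos < intervals[k].end:
            return k
        return None

    read_index = {id(store.reads[i]): i for i in region.read_ids}
    for pair in store.pairs:
        li = read_index.get(id(pair.left))
        ri = read_index.get(id(pair.right))
        if li is None or ri is None:
            continue  # cross-region pair; handled by global selection
        if li not in region_read_ids or ri not in region_read_ids:
            continue
        n_pairs += 1
        x = pair.left.end - 1
        y = pair.right.start
        if region.start <= x < region.end and region.start <= y < region.end:
            pair_points.add((x, y))
        ci = interval_of(pair.left.start)
        cj = interval_of(pair.right.end - 1)
        if ci is not None and cj is not None:
            pair_classes[(ci, cj)] = pair_classes.get((ci, cj), 0) + 1
    return RegionEvidence(
        requirements=sorted(reqs, key=lambda t: (t[0], t[1], t[2] or -1, t[3] or -1)),
        pair_points=sorted(pair_points),
        pair_classes=pair_classes,
        n_pairs=n_pairs,
        n_dropped=dropped,
    )


def _requirement_mask(
    candidates: Sequence[CandidateExon],
    req: tuple[int, int, Optional[int], Optional[int]],
) -> int:
    bs, be, pin_l, pin_r = req
    mask = 0
    for i, cand in enumerate(candidates):
        if cand.start <= bs and be <= cand.end:
            if pin_l is not None and cand.start != pin_l:
                continue
            if pin_r is not None and cand.end != pin_r:
                continue
            mask |= 1 << i
    return mask


def _pair_point_masks(
    candidates: Sequence[CandidateExon], x: int, y: int
) -> list[int]:
    """Bitmasks of candidate pairs (E1, E2) connecting inner points x, y."""
    out = []
    for i, a in enumerate(candidates):
        if not a.contains_point(x):
            continue
        for j, b in enumerate(candidates):
            if not b.contains_point(y):
                continue
            if i == j or a.end <= b.start:
                out.append((1 << i) | (1 << j))
    return out


def is_feasible_combination(
    member_idx: Sequence[int],
    candidates: Sequence[CandidateExon],
    boundaries: Sequence[tuple[int, str]],
    evidence: RegionEvidence,
) -> tuple[bool, str]:
    """Direct (non-bitmask) check of feasibility conditions.

    1) every splice site lies on a member-exon boundary; 2) every read is
    compatible with the member exons; 3) each pair's inner endpoints sit in
    one member exon or in two chainable non-overlapping member exons.
    """
    members = [candidates[i] for i in member_idx]
    for pos, lab in boundaries:
        if lab == "donor" and not any(m.end == pos for m in members):
            return False, "uncovered_splice_site"
        if lab == "acceptor" and not any(m.start == pos for m in members):
            return False, "uncovered_splice_site"
    for bs, be, pin_l, pin_r in evidence.requirements:
        ok = any(
            m.start <= bs
            and be <= m.end
            and (pin_l is None or m.start == pin_l)
            and (pin_r is None or m.end == pin_r)
            for m in members
        )
        if not ok:
            return False, "incompatible_read"
    for x, y in evidence.pair_points:
        ok = any(
            a.contains_point(x)
            and b.contains_point(y)
            and (a is b or a.end <= b.start)
            for a in members
            for b in members
        )
        if not ok:
            return False, "disconnected_pair"
    return True, "ok"


# ---------------------------------------------------------------------------
# Linear program


def build_and_solve_lp(
    member_exons: Sequence[CandidateExon],
    intervals: Sequence[Interval],
    lower_bound: float = 1.0,
) -> LPSolution:
    """Solve the slack-minimisation LP for one exon combination.

    Variables: one coverage c_{i,j} per subexon, one slack per additivity
    constraint (per interval) and one per continuity constraint (per
    adjacent same-exon interval pair); conservation is a hard equality; all
    c_{i,j} >= ``lower_bound``.  If the system is infeasible with the
    default lower bound of 1 it is retried once with 0 (low-coverage
    regions); if still infeasible the combination is discarded.
    """
    c_vars: list[tuple[int, int]] = []
    for i, ex in enumerate(member_exons):
        for j in range(ex.first_j, ex.last_j + 1):
            c_vars.append((i, j))
    n_c = len(c_vars)
    cont_pairs = [
        (i, j)
        for i, ex in enumerate(member_exons)
        for j in range(ex.first_j, ex.last_j)
    ]
    n_eps = len(intervals) + len(cont_pairs)
    n = n_c + n_eps
    col = {v: k for k, v in enumerate(c_vars)}

    rows_ub, rhs_ub = [], []
    for j, iv in enumerate(intervals):
        pos = np.zeros(n)
        for i, _ in enumerate(member_exons):
            if (i, j) in col:
                pos[col[(i, j)]] = 1.0
        pos[n_c + j] = -1.0
        rows_ub.append(pos.copy())
        rhs_ub.append(iv.mean_coverage)
        neg = -pos
        neg[n_c + j] = -1.0
        rows_ub.append(neg)
        rhs_ub.append(-iv.mean_coverage)
    for k, (i, j) in enumerate(cont_pairs):
        row = np.zeros(n)
        row[col[(i, j)]] = 1.0
        row[col[(i, j + 1)]] = -1.0
        row[n_c + len(intervals) + k] = -1.0
        rows_ub.append(row.copy())
        rhs_ub.append(0.0)
        row2 = -row
        row2[n_c + len(intervals) + k] = -1.0
        rows_ub.append(row2)
        rhs_ub.append(0.0)

    a_eq = np.zeros((1, n))
    for (i, j), k in col.items():
        a_eq[0, k] = intervals[j].length
    b_eq = [sum(iv.mean_coverage * iv.length for iv in intervals)]

    obj = np.concatenate([np.zeros(n_c), np.ones(n_eps)])

    for lb in ([lower_bound, 0.0] if lower_bound > 0 else [lower_bound]):
        bounds = [(lb, None)] * n_c + [(0, None)] * n_eps
        res = linprog(
            obj,
            A_ub=np.array(rows_ub),
            b_ub=np.array(rhs_ub),
            A_eq=a_eq,
            b_eq=b_eq,
            bounds=bounds,
            method="highs",
        )
        if res.status == 0:
            return LPSolution(
                status="optimal",
                objective=float(res.fun),
                c={v: float(res.x[col[v]]) for v in c_vars},
                eps=[float(v) for v in res.x[n_c:]],
                lower_bound_used=lb,
            )
    return LPSolution(status="infeasible")


# ---------------------------------------------------------------------------
# Pair feasibility penalty


def chain_distance_range(
    member_exons: Sequence[CandidateExon], p: int, q: int
) -> Optional[tuple[int, int]]:
    """Min/max exonic bases of [p, q) over chains of non-overlapping exons.

    A chain starts at an exon containing p and ends at one containing q-1;
    consecutive chain exons must not overlap.  Returns None when no chain
    connects the two points.
    """
    if q <= p:
        return (0, 0) if any(e.contains_point(p) for e in member_exons) else None
    exons = sorted(member_exons, key=lambda e: (e.start, e.end))
    w = [max(0, min(e.end, q) - max(e.start, p)) for e in exons]
    starts = [e.contains_point(p) for e in exons]
    ends = [e.contains_point(q - 1) for e in exons]
    dmin: list[Optional[int]] = [None] * len(exons)
    dmax: list[Optional[int]] = [None] * len(exons)
    for k, e in enumerate(exons):
        if starts[k]:
            dmin[k] = w[k]
            dmax[k] = w[k]
        for m in range(k):
            if exons[m].end <= e.start and dmin[m] is not None:
                cand_min = dmin[m] + w[k]
                cand_max = dmax[m] + w[k]
                dmin[k] = cand_min if dmin[k] is None else min(dmin[k], cand_min)
                dmax[k] = cand_max if dmax[k] is None else max(dmax[k], cand_max)
    lo = [dmin[k] for k in range(len(exons)) if ends[k] and dmin[k] is not None]
    hi = [dmax[k] for k in range(len(exons)) if ends[k] and dmax[k] is not None]
    if not lo:
        return None
    return (min(lo), max(hi))


def pair_feasibility_penalty(
    member_exons: Sequence[CandidateExon],
    pair_classes: dict[tuple[int, int], int],
    n_pairs: int,
    stats: Optional[FragmentStats],
    intervals: Sequence[Interval],
) -> float:
    """Fraction of read pairs whose fragment length cannot fit the window.

    For a pair class (left reads start in interval i, right reads end in
    interval j), the achievable fragment range over all member-exon chains
    is compared with f_l +/- 2 f_sigma; unsatisfiable classes contribute
    n_{i,j} / N.
    """
    if stats is None or not pair_classes or n_pairs == 0:
        return 0.0
    win_lo, win_hi = stats.window
    penalty = 0.0
    for (ci, cj), count in sorted(pair_classes.items()):
        iv_i, iv_j = intervals[ci], intervals[cj]
        rng_max = chain_distance_range(member_exons, iv_i.start, iv_j.end)
        rng_min = chain_distance_range(member_exons, iv_i.end - 1, iv_j.start + 1)
        if rng_max is None and rng_min is None:
            penalty += count / n_pairs
            continue
        d_lo = rng_min[0] if rng_min is not None else rng_max[0]
        d_hi = rng_max[1] if rng_max is not None else rng_min[1]
        if d_hi < win_lo or d_lo > win_hi:
            penalty += count / n_pairs
    return penalty


# ---------------------------------------------------------------------------
# Combination enumeration and selection


def _evidence_candidates(
    candidates: Sequence[CandidateExon],
    boundaries: Sequence[tuple[int, str]],
    evidence: RegionEvidence,
    region: Region,
) -> list[int]:
    """Restricted candidate list for regions above the enumeration cap.

    Keeps exons directly pinned by spliced-read blocks, tightest containing
    exons for terminal read blocks, minimal completions so every splice
    site stays coverable, and the whole-region exon.
    """
    keep: set[int] = set()
    by_coords = {(c.start, c.end): i for i, c in enumerate(candidates)}
    lefts = sorted({c.start for c in candidates})
    rights = sorted({c.end for c in candidates})
    from bisect import bisect_left, bisect_right

    def tightest(bs: int, be: int, pin_l: Optional[int], pin_r: Optional[int]):
        ls = pin_l if pin_l is not None else lefts[max(0, bisect_right(lefts, bs) - 1)]
        k = bisect_left(rights, be)
        rs = pin_r if pin_r is not None else (rights[k] if k < len(rights) else None)
        if rs is not None and (ls, rs) in by_coords:
            keep.add(by_coords[(ls, rs)])

    for bs, be, pin_l, pin_r in evidence.requirements:
        tightest(bs, be, pin_l, pin_r)
    for pos, lab in boundaries:
        if lab == "donor" and not any(candidates[i].end == pos for i in keep):
            ls = lefts[max(0, bisect_right(lefts, pos - 1) - 1)]
            if (ls, pos) in by_coords:
                keep.add(by_coords[(ls, pos)])
        if lab == "acceptor" and not any(candidates[i].start == pos for i in keep):
            k = bisect_left(rights, pos + 1)
            if k < len(rights) and (pos, rights[k]) in by_coords:
                keep.add(by_coords[(pos, rights[k])])
    if (region.start, region.end) in by_coords:
        keep.add(by_coords[(region.start, region.end)])
    return sorted(keep)


def select_exon_set(
    region: Region,
    intervals: Sequence[Interval],
    candidates: Sequence[CandidateExon],
    boundaries: Sequence[tuple[int, str]],
    evidence: RegionEvidence,
    stats: Optional[FragmentStats],
    max_candidates: int = 16,
    lp_lower_bound: float = 1.0,
) -> tuple[list[CandidateExon], Optional[CombinationScore], bool]:
    """Choose the best-scoring feasible exon combination for a region.

    Returns (exons, score, fallback); fallback means no combination was
    feasible and the whole region is emitted as a single exon.
    """
    idx_pool = list(range(len(candidates)))
    if len(candidates) > max_candidates:
        idx_pool = _evidence_candidates(candidates, boundaries, evidence, region)
        log.debug(
            "region %s:%d-%d: %d candidates above cap %d; restricted to %d evidenced",
            region.contig, region.start, region.end,
            len(candidates), max_candidates, len(idx_pool),
        )
        if len(idx_pool) > max_candidates:
            idx_pool = idx_pool[:max_candidates]
    pool = [candidates[i] for i in idx_pool]
    n = len(pool)

    # bitmask precomputation for fast feasibility screening
    boundary_masks = []
    for pos, lab in boundaries:
        if lab == "donor":
            boundary_masks.append(sum(1 << i for i, c in enumerate(pool) if c.end == pos))
        else:
            boundary_masks.append(sum(1 << i for i, c in enumerate(pool) if c.start == pos))
    req_masks = sorted({_requirement_mask(pool, r) for r in evidence.requirements})
    pair_masks = [_pair_point_masks(pool, x, y) for x, y in evidence.pair_points]
    unsatisfiable = (req_masks and req_masks[0] == 0) or any(
        not pm for pm in pair_masks
    )

    best: Optional[tuple[float, int, tuple, list[CandidateExon], CombinationScore]] = None
    for subset in [] if unsatisfiable else range(1, 1 << n):
        if any(not (subset & m) for m in boundary_masks):
            continue
        if any(not (subset & m) for m in req_masks):
            continue
        if any(
            all((subset & m) != m for m in pms) for pms in pair_masks
        ):
            continue
        members = [pool[i] for i in range(n) if subset & (1 << i)]
        sol = build_and_solve_lp(members, intervals, lower_bound=lp_lower_bound)
        if sol.status != "optimal":
            continue
        penalty = pair_feasibility_penalty(
            members, evidence.pair_classes, evidence.n_pairs, stats, intervals
        )
        score = CombinationScore(
            lp_objective=sol.objective, pair_penalty=penalty, n_exons=len(members)
        )
        coords = tuple((m.start, m.end) for m in members)
        key = (round(score.total, 9), len(members), coords)
        if best is None or key < (round(best[4].total, 9), best[1], best[2]):
            best = (score.total, len(members), coords, members, score)
    if best is None:
        log.warning(
            "region %s:%d-%d: no feasible exon combination; emitting whole region",
            region.contig, region.start, region.end,
        )
        whole = CandidateExon(
            start=region.start, end=region.end,
            first_j=0, last_j=len(intervals) - 1,
            left_kind="region_edge", right_kind="region_edge",
        )
        return [whole], None, True
    return best[3], best[4], False


def infer_region_exons(
    region: Region,
    store: ReadStore,
    junctions: Sequence[Junction],
    stats: Optional[FragmentStats],
    min_junction_support: int = 1,
    min_anchor: int = 8,
    max_candidates: int = 16,
    lp_lower_bound: float = 1.0,
) -> list[RegionResult]:
    """Full exon inference for one region.

    Regions touched by junctions of both strands are processed once per
    strand and the results merged; unstranded regions get strand '.'.
    """
    from .alignments import extract_splice_sites

    strands = sorted(
        {
            j.strand
            for j in junctions
            if j.contig == region.contig
            and j.strand in "+-"
            and (region.start < j.donor < region.end or region.start < j.acceptor < region.end)
        }
    )
    passes: list[Optional[str]] = list(strands) if len(strands) > 1 else [None]
    results = []
    for strand in passes:
        boundaries = extract_splice_sites(
            junctions, region, min_support=min_junction_support,
            min_anchor=min_anchor, strand=strand,
        )
        intervals = partition_intervals(region, [p for p, _ in boundaries], store)
        candidates = enumerate_candidate_exons(region, intervals, boundaries)
        evidence = collect_region_evidence(
            region, store, intervals, {p for p, _ in boundaries}
        )
        exon_cands, score, fallback = select_exon_set(
            region, intervals, candidates, boundaries, evidence, stats,
            max_candidates=max_candidates, lp_lower_bound=lp_lower_bound,
        )
        if strand is not None:
            out_strand = strand
        elif len(strands) == 1:
            out_strand = strands[0]
        else:
            out_strand = "."
        exons = [
            Exon(contig=region.contig, start=c.start, end=c.end, strand=out_strand)
            for c in exon_cands
        ]
        results.append(
            RegionResult(
                region=region, strand=out_strand, intervals=list(intervals),
                exons=exons, score=score, fallback=fallback,
            )
        )
    return results
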