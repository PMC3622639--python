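"""SAM ingestion: reads, junctions, pairs, covered regions, fragment stats.

Only primary alignments are used (secondary and supplementary records are
skipped), so per-base coverage counts each sequenced base once.  Junction
strand is taken from the aligner's XS tag when present.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pysam

from .core import AlignedRead, FragmentStats, Junction, ReadPair, Region

log = logging.getLogger(__name__)

# CIGAR operation codes that consume the reference without splicing
_REF_BLOCK_OPS = {0, 2, 7, 8}  # M, D, =, X
_SPLICE_OP = 3  # N


@dataclass
class ReadStore:
    """All accepted alignments plus derived junction and pair tables."""

    reads: list[AlignedRead] = field(default_factory=list)
    pairs: list[ReadPair] = field(default_factory=list)
    junctions: dict[tuple[str, int, int, str], Junction] = field(default_factory=dict)
    contig_lengths: dict[str, int] = field(default_factory=dict)
    n_skipped: int = 0
    paired_read_ids: set[int] = field(default_factory=set)

    def reads_on(self, contig: str) -> list[int]:
        return [i for i, r in enumerate(self.reads) if r.contig == contig]

    @property
    def contigs(self) -> list[str]:
        seen = {r.contig for r in self.reads}
        return sorted(seen)

    def junction_list(self, min_support: int = 1, min_anchor: int = 0) -> list[Junction]:
        """Junctions passing support/anchor filters, sorted genomically."""
        out = [
            j
            for j in self.junctions.values()
            if j.support >= min_support and j.max_anchor >= min_anchor
        ]
        out.sort(key=lambda j: (j.contig, j.donor, j.acceptor, j.strand))
        return out


def _blocks_from_cigar(pos: int, cigartuples) -> list[tuple[int, int]]:
    """Reference blocks separated only at N (splice) operations."""
    blocks: list[tuple[int, int]] = []
    cur_start = pos
    cur = pos
    for op, length in cigartuples:
        if op in _REF_BLOCK_OPS:
            cur += length
        elif op == _SPLICE_OP:
            if cur > cur_start:
                blocks.append((cur_start, cur))
            cur_start = cur + length
            cur = cur_start
    if cur > cur_start:
        blocks.append((cur_start, cur))
    return blocks


def parse_alignments(path: str, min_mapq: int = 0) -> ReadStore:
    """Parse a SAM file into a :class:`ReadStore`.

    Mapped primary alignments with MAPQ >= ``min_mapq`` are kept; junctions
    implied by N CIGAR operations are aggregated with read support and
    maximum flanking-anchor length; mates are linked by query name when both
    map to the same contig.
    """
    store = ReadStore()
    pending: dict[str, int] = {}  # query name -> index of first-seen mate
    with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
        if not sam.header.references:
            raise ValueError(f"{path}: SAM header lacks @SQ reference lines")
        for name, length in zip(sam.header.references, sam.header.lengths):
            store.contig_lengths[name] = length
        for seg in sam:
            if seg.is_unmapped or seg.is_secondary or seg.is_supplementary:
                store.n_skipped += 1
                continue
            if seg.mapping_quality < min_mapq:
                store.n_skipped += 1
                continue
            try:
                blocks = _blocks_from_cigar(seg.reference_start, seg.cigartuples or [])
                if not blocks:
                    raise ValueError("alignment consumes no reference bases")
            except Exception as exc:  # malformed record: skip, keep going
                log.warning("skipping malformed record %s: %s", seg.query_name, exc)
                store.n_skipped += 1
                continue
            strand = "."
            if seg.has_tag("XS"):
                strand = str(seg.get_tag("XS"))
            read = AlignedRead(
                read_id=seg.query_name or "",
                contig=seg.reference_name,
                strand=strand,
                blocks=tuple(blocks),
                mate_key=seg.query_name if seg.is_paired else None,
                is_first_mate=(not seg.is_paired) or seg.is_read1,
            )
            idx = len(store.reads)
            store.reads.append(read)
            _record_junctions(store, read)
            if seg.is_paired and seg.query_name:
                other = pending.pop(seg.query_name, None)
                if other is None:
                    pending[seg.query_name] = idx
                else:
                    mate = store.reads[other]
                    if mate.contig == read.contig:
                        left, right = (mate, read) if mate.start <= read.start else (read, mate)
                        store.pairs.append(ReadPair(left=left, right=right))
                        store.paired_read_ids.update((other, idx))
    return store


def _record_junctions(store: ReadStore, read: AlignedRead) -> None:
    blocks = read.blocks
    for k, (donor, acceptor) in enumerate(read.junctions):
        anchor = min(blocks[k][1] - blocks[k][0], blocks[k + 1][1] - blocks[k + 1][0])
        key = (read.contig, donor, acceptor, read.strand)
        j = store.junctions.get(key)
        if j is None:
            store.junctions[key] = Junction(
                contig=read.contig,
                donor=donor,
                acceptor=acceptor,
                strand=read.strand,
                support=1,
                max_anchor=anchor,
            )
        else:
            j.support += 1
            j.max_anchor = max(j.max_anchor, anchor)


def coverage_array(
    store: ReadStore, contig: str, start: int, end: int
) -> np.ndarray:
    """Per-base read coverage over [start, end) from block alignments."""
    cov = np.zeros(end - start + 1, dtype=np.int64)
    for read in store.reads:
        if read.contig != contig:
            continue
        for bs, be in read.blocks:
            lo, hi = max(bs, start), min(be, end)
            if lo < hi:
                cov[lo - start] += 1
                cov[hi - start] -= 1
    return np.cumsum(cov)[:-1]


def detect_regions(
    store: ReadStore,
    max_gap: int = 0,
    min_region_len: int = 25,
) -> list[Region]:
    """Maximal covered stretches per contig.

    Bases with coverage >= 1 form runs; zero-coverage gaps of at most
    ``max_gap`` bases are bridged; runs shorter than ``min_region_len`` are
    dropped as noise islands.  Reads are attached to every region their
    blocks overlap.
    """
    regions: list[Region] = []
    by_contig: dict[str, list[int]] = {}
    for i, r in enumerate(store.reads):
        by_contig.setdefault(r.contig, []).append(i)
    for contig in sorted(by_contig):
        idxs = by_contig[contig]
        lo = min(store.reads[i].start for i in idxs)
        hi = max(store.reads[i].end for i in idxs)
        cov = np.zeros(hi - lo + 1, dtype=np.int64)
        for i in idxs:
            for bs, be in store.reads[i].blocks:
                cov[bs - lo] += 1
                cov[be - lo] -= 1
        covered = np.cumsum(cov)[:-1] > 0
        runs = _covered_runs(covered, max_gap)
        spans = [(lo + s, lo + e) for s, e in runs if e - s >= min_region_len]
        # attach reads by first-overlapped region
        starts = [s for s, _ in spans]
        contig_regions = [Region(contig=contig, start=s, end=e) for s, e in spans]
        for i in idxs:
            read = store.reads[i]
            hit = set()
            for bs, be in read.blocks:
                k = bisect_right(starts, bs) - 1
                if 0 <= k < len(spans) and bs < spans[k][1] and be > spans[k][0]:
                    hit.add(k)
            for k in sorted(hit):
                contig_regions[k].read_ids.append(i)
        regions.extend(contig_regions)
    return regions


def _covered_runs(covered: np.ndarray, max_gap: int) -> list[tuple[int, int]]:
    if covered.size == 0 or not covered.any():
        return []
    edges = np.flatnonzero(np.diff(np.concatenate(([0], covered.view(np.int8), [0]))))
    runs = list(zip(edges[::2].tolist(), edges[1::2].tolist()))
    merged = [runs[0]]
    for s, e in runs[1:]:
        if s - merged[-1][1] <= max_gap:
            merged[-1] = (merged[-1][0], e)
        else:
            merged.append((s, e))
    return merged


def extract_splice_sites(
    junctions: Sequence[Junction],
    region: Region,
    min_support: int = 1,
    min_anchor: int = 8,
    strand: Optional[str] = None,
) -> list[tuple[int, str]]:
    """Splice-site boundaries strictly inside a region.

    A junction's donor contributes a boundary where an exon must end; its
    acceptor a boundary where an exon must start.  A junction spanning two
    regions contributes one boundary to each.  Returns sorted
    ``(position, label)`` with label 'donor' or 'acceptor'; a position
    carrying both roles appears twice.
    """
    sites: set[tuple[int, str]] = set()
    for j in junctions:
        if j.contig != region.contig:
            continue
        if j.support < min_support or j.max_anchor < min_anchor:
            continue
        if strand is not None and j.strand not in (".", strand):
            continue
        if region.start < j.donor < region.end:
            sites.add((j.donor, "donor"))
        if region.start < j.acceptor < region.end:
            sites.add((j.acceptor, "acceptor"))
    return sorted(sites)


def estimate_fragment_stats(
    store: ReadStore,
    regions: Optional[Sequence[Region]] = None,
    override: Optional[tuple[float, float]] = None,
    trim: float = 0.05,
) -> FragmentStats:
    """Fragment length mean/sd from unspliced, co-located read pairs.

    A pair is eligible when both mates are single-block and fall inside one
    covered region; its fragment length is (right end - left start).  A
    two-sided ``trim`` fraction is removed before the mean and sd are taken,
    for robustness against chimeric pairs.  ``override`` short-circuits the
    estimate.
    """
    if override is not None:
        return FragmentStats(f_l=float(override[0]), f_sigma=float(override[1]), n_used=0)
    region_index: Optional[dict[str, list[tuple[int, int]]]] = None
    if regions is not None:
        region_index = {}
        for r in regions:
            region_index.setdefault(r.contig, []).append((r.start, r.end))
        for spans in region_index.values():
            spans.sort()
    lengths = []
    for pair in store.pairs:
        if pair.left.is_spliced or pair.right.is_spliced:
            continue
        s, e = pair.fragment_span
        if region_index is not None:
            spans = region_index.get(pair.left.contig, [])
            k = bisect_right([a for a, _ in spans], s) - 1
            if k < 0 or not (spans[k][0] <= s and e <= spans[k][1]):
                continue
        lengths.append(e - s)
    if not lengths:
        raise ValueError(
            "no eligible read pairs to estimate fragment length; "
            "pass explicit fragment mean/sd (e.g. --frag-len/--frag-sd)"
        )
    arr = np.sort(np.asarray(lengths, dtype=float))
    k = int(len(arr) * trim)
    trimmed = arr[k : len(arr) - k] if len(arr) > 2 * k else arr
    sd = float(np.std(trimmed, ddof=1)) if len(trimmed) > 1 else 0.0
    if 0 < trim < 0.5 and len(arr) > 2 * k > 0:
        # trimming shrinks the sd of a clean Gaussian; rescale by the sd of
        # a standard normal truncated at the same quantiles so the estimate
        # stays unbiased on well-behaved libraries yet robust to chimeras
        from scipy.stats import norm

        q = norm.ppf(1.0 - trim)
        factor = np.sqrt(1.0 - 2.0 * q * norm.pdf(q) / (1.0 - 2.0 * trim))
        sd /= factor
    return FragmentStats(
        f_l=float(np.mean(trimmed)),
        f_sigma=sd,
        n_used=int(len(trimmed)),
    )
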