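"""Shared genomic data types.

All coordinates are 0-based, half-open ``[start, end)`` internally.  An
intron is stored as ``[donor, acceptor)`` = [first intronic base, one past
the last intronic base), so a junction's donor equals the end of the
upstream exon and its acceptor equals the start of the downstream exon.
GTF input/output converts to/from 1-based inclusive coordinates at the
boundary of the package.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence


@dataclass
class AlignedRead:
    """A single mapped read, possibly spliced.

    ``blocks`` are the reference-consuming stretches of the alignment
    (M/=/X/D runs); gaps between consecutive blocks (CIGAR N runs) are the
    read's junctions.
    """

    read_id: str
    contig: str
    strand: str  # '+', '-', or '.' when unknown
    blocks: tuple[tuple[int, int], ...]
    mate_key: Optional[str] = None
    is_first_mate: bool = True

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    @property
    def junctions(self) -> tuple[tuple[int, int], ...]:
        """Gaps between consecutive blocks as (donor, acceptor) pairs."""
        return tuple(
            (self.blocks[k][1], self.blocks[k + 1][0])
            for k in range(len(self.blocks) - 1)
        )

    @property
    def is_spliced(self) -> bool:
        return len(self.blocks) > 1


@dataclass
class ReadPair:
    """Two mates of a fragment, ordered so ``left`` starts first."""

    left: AlignedRead
    right: AlignedRead

    @property
    def inner_span(self) -> tuple[int, int]:
        return (self.left.end, self.right.start)

    @property
    def fragment_span(self) -> tuple[int, int]:
        return (self.left.start, self.right.end)


@dataclass
class Junction:
    """An intron observed in spliced alignments, with read support."""

    contig: str
    donor: int
    acceptor: int
    strand: str = "."
    support: int = 0
    max_anchor: int = 0

    def __post_init__(self) -> None:
        if self.donor >= self.acceptor:
            raise ValueError(f"junction donor {self.donor} >= acceptor {self.acceptor}")


@dataclass
class Region:
    """A maximal read-covered genomic stretch; the unit of exon inference."""

    contig: str
    start: int
    end: int
    strand_hint: str = "both"
    read_ids: list[int] = field(default_factory=list)

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class FragmentStats:
    """Fragment (insert) length distribution summary."""

    f_l: float
    f_sigma: float
    n_used: int = 0

    def __post_init__(self) -> None:
        if self.f_l <= 0:
            raise ValueError("mean fragment length must be positive")
        if self.f_sigma < 0:
            raise ValueError("fragment sd must be non-negative")

    @property
    def window(self) -> tuple[float, float]:
        """Admissible fragment lengths: mean +/- 2 sd."""
        return (self.f_l - 2.0 * self.f_sigma, self.f_l + 2.0 * self.f_sigma)


@dataclass(frozen=True)
class Exon:
    """A genomic exon (node of the splice graph)."""

    contig: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"empty exon [{self.start},{self.end})")

    @property
    def length(self) -> int:
        return self.end - self.start

    def contains_point(self, pos: int) -> bool:
        return self.start <= pos < self.end

    def contains_span(self, start: int, end: int) -> bool:
        return self.start <= start and end <= self.end

    def sort_key(self) -> tuple:
        return (self.contig, self.start, self.end, self.strand)


@dataclass(frozen=True)
class Transcript:
    """An ordered chain of exons on one contig and strand."""

    contig: str
    strand: str
    exons: tuple[tuple[int, int], ...]
    transcript_id: str = ""
    gene_id: str = ""

    def __post_init__(self) -> None:
        prev_end = None
        for s, e in self.exons:
            if s >= e:
                raise ValueError(f"empty exon [{s},{e}) in transcript")
            if prev_end is not None and s < prev_end:
                raise ValueError("transcript exons overlap or are unsorted")
            prev_end = e

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> tuple[tuple[int, int], ...]:
        return tuple(
            (self.exons[k][1], self.exons[k + 1][0])
            for k in range(len(self.exons) - 1)
        )

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        return sum(e - s for s, e in self.exons)

    def genome_overlap(self, start: int, end: int) -> int:
        """Total exonic bases of this transcript inside [start, end)."""
        total = 0
        for s, e in self.exons:
            total += max(0, min(e, end) - max(s, start))
        return total

    def spliced_distance(self, x: int, y: int) -> int:
        """Exonic bases between genomic positions x and y (x <= y)."""
        return self.genome_overlap(x, y)

    def sort_key(self) -> tuple:
        return (self.contig, self.start, self.end, self.strand, self.exons)


def merge_spans(spans: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    """Union of half-open spans as a sorted, disjoint list."""
    out: list[tuple[int, int]] = []
    for s, e in sorted(spans):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def iter_adjacent(seq: Sequence) -> Iterator[tuple]:
    for k in range(len(seq) - 1):
        yield seq[k], seq[k + 1]
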