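"""Synthetic multi-isoform gene models and spliced read alignments.

The generator emulates the study conditions the assembler is designed
for: multi-isoform genes on a toy contig whose isoforms differ by
skipped exons, alternative donors/acceptors or alternative terminal
exons; roughly uniform fragment sampling along each isoform; Gaussian
fragment lengths (truncated to [read length, transcript length] by
rejection); spliced alignments with gapped (N) CIGAR strings and no
sequencing errors.  Given a seed, output is byte-identical across runs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pysam

from .core import Transcript
from .gtf import write_gtf

EVENTS = ("skipped_exon", "alt_donor", "alt_acceptor", "alt_terminal")
_INTERNAL_EVENTS = ("skipped_exon", "alt_donor", "alt_acceptor")


@dataclass
class GeneModel:
    gene_id: str
    contig: str
    strand: str
    isoforms: list[tuple[tuple[int, int], ...]]  # exon chains
    weights: list[float]

    def transcripts(self) -> list[Transcript]:
        return [
            Transcript(
                contig=self.contig,
                strand=self.strand,
                exons=iso,
                transcript_id=f"{self.gene_id}.t{k + 1}",
                gene_id=self.gene_id,
            )
            for k, iso in enumerate(self.isoforms)
        ]


def _internal_variant(
    rng: np.random.Generator,
    base: tuple[tuple[int, int], ...],
    event: str,
    k: int,
) -> Optional[tuple[tuple[int, int], ...]]:
    """Apply a splice event at focal internal exon k of the base isoform."""
    exons = list(base)
    if event == "skipped_exon":
        return tuple(exons[:k] + exons[k + 1 :])
    s, e = exons[k]
    delta = int(rng.integers(20, 51))
    if event == "alt_donor":
        if e - delta - s < 50:
            return None
        exons[k] = (s, e - delta)
        return tuple(exons)
    if event == "alt_acceptor":
        if e - (s + delta) < 50:
            return None
        exons[k] = (s + delta, e)
        return tuple(exons)
    return None


def _terminal_variants(
    rng: np.random.Generator,
    base: tuple[tuple[int, int], ...],
    end: str,
    n_wanted: int,
) -> list[tuple[tuple[int, int], ...]]:
    """Replace the first or last exon with novel exons in the flanking
    intron, placed left-to-right without overlap."""
    if end == "last":
        intron_s, intron_e = base[-2][1], base[-1][0]
    else:
        intron_s, intron_e = base[0][1], base[1][0]
    out = []
    pos = intron_s + 60
    for _ in range(n_wanted):
        alt_len = int(rng.integers(80, 121))
        if pos + alt_len + 60 > intron_e:
            break
        alt = (pos, pos + alt_len)
        if end == "last":
            out.append(tuple(list(base[:-1]) + [alt]))
        else:
            out.append(tuple([alt] + list(base[1:])))
        pos += alt_len + 60
    return out


def make_gene_models(
    seed: int,
    n_genes: int = 20,
    exon_len: tuple[int, int] = (100, 300),
    intron_len: tuple[int, int] = (200, 800),
    n_exons: tuple[int, int] = (4, 8),
    isoforms_per_gene: tuple[int, int] = (1, 3),
    gene_spacing: int = 2000,
    contig: str = "chrS",
    events: tuple[str, ...] = EVENTS,
) -> list[GeneModel]:
    """Deterministic toy gene models.

    Each gene's isoform diversity is concentrated at a single focal
    alternative site — either one internal exon (skipping, alternative
    donor/acceptor) or one terminus (alternative first/last exons) — as is
    typical of alternatively spliced genes.  Variants at one site are
    mutually exclusive in the splice graph, so every isoform carries reads
    private to it and the set is identifiable at realistic fragment
    lengths.  Isoforms within a gene always differ by at least one intron.
    """
    for lo, hi, name in (
        (*exon_len, "exon_len"), (*intron_len, "intron_len"),
        (*n_exons, "n_exons"), (*isoforms_per_gene, "isoforms_per_gene"),
    ):
        if lo <= 0 or hi < lo:
            raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
    unknown = set(events) - set(EVENTS)
    if unknown or not events:
        raise ValueError(f"unknown or empty event set: {sorted(unknown)}")
    rng = np.random.default_rng(seed)
    models = []
    cursor = gene_spacing
    for gi in range(n_genes):
        ne = int(rng.integers(n_exons[0], n_exons[1] + 1))
        exons = []
        pos = cursor
        for k in range(ne):
            length = int(rng.integers(exon_len[0], exon_len[1] + 1))
            exons.append((pos, pos + length))
            pos += length
            if k < ne - 1:
                pos += int(rng.integers(intron_len[0], intron_len[1] + 1))
        base = tuple(exons)
        strand = "+" if rng.random() < 0.5 else "-"
        target = int(rng.integers(isoforms_per_gene[0], isoforms_per_gene[1] + 1))
        isoforms = [base]
        n_extra = target - 1
        if n_extra > 0:
            internal_pool = [e for e in _INTERNAL_EVENTS if e in events]
            sites = []
            if internal_pool and ne >= 3:
                sites.extend(["internal"] * 3)
            if "alt_terminal" in events:
                sites.extend(["last", "first"])
            site = sites[int(rng.integers(0, len(sites)))] if sites else None
            if site == "internal":
                # focal exon k; a donor and an acceptor variant are placed on
                # adjacent exons, never the same one, so that no chimeric
                # exon (alt start x alt end) is consistent with the reads
                k = int(rng.integers(1, max(2, ne - 1)))
                if n_extra == 1:
                    plan = [(internal_pool[int(rng.integers(0, len(internal_pool)))], k)]
                else:
                    combos = [
                        c
                        for c in (
                            (("skipped_exon", k), ("alt_donor", k)),
                            (("skipped_exon", k), ("alt_acceptor", k)),
                            (("alt_donor", k), ("alt_acceptor", min(k + 1, ne - 1))),
                        )
                        if all(ev in internal_pool for ev, _ in c)
                    ]
                    if combos:
                        plan = list(combos[int(rng.integers(0, len(combos)))])
                    else:
                        plan = [(internal_pool[0], k)]
                chains = {base}
                for ev, at in plan:
                    alt = _internal_variant(rng, base, ev, at)
                    if alt is not None and alt not in chains:
                        chains.add(alt)
                        isoforms.append(alt)
            elif site in ("last", "first"):
                isoforms.extend(_terminal_variants(rng, base, site, n_extra))
        w = 1.0 / len(isoforms)
        models.append(
            GeneModel(
                gene_id=f"g{gi + 1:03d}",
                contig=contig,
                strand=strand,
                isoforms=isoforms,
                weights=[w] * len(isoforms),
            )
        )
        cursor = pos + gene_spacing
    return models


def _project(exons: Sequence[tuple[int, int]], t_start: int, t_end: int) -> list[tuple[int, int]]:
    """Map a transcript-coordinate span to genomic blocks."""
    blocks = []
    offset = 0
    for s, e in exons:
        length = e - s
        lo = max(t_start, offset)
        hi = min(t_end, offset + length)
        if lo < hi:
            blocks.append((s + lo - offset, s + hi - offset))
        offset += length
    return blocks


def _cigar(blocks: Sequence[tuple[int, int]]) -> str:
    parts = []
    for k, (s, e) in enumerate(blocks):
        if k > 0:
            parts.append(f"{s - blocks[k - 1][1]}N")
        parts.append(f"{e - s}M")
    return "".join(parts)


def _truncated_normal(rng: np.random.Generator, mean: float, sd: float, lo: int, hi: int) -> int:
    if hi <= lo:
        return lo
    for _ in range(100):
        x = int(round(rng.normal(mean, sd)))
        if lo <= x <= hi:
            return x
    return int(min(max(round(mean), lo), hi))


def simulate_alignments(
    models: Sequence[GeneModel],
    out_sam: str,
    out_gtf: Optional[str] = None,
    depth: float = 50.0,
    read_len: int = 75,
    paired: bool = True,
    frag_mean: float = 250.0,
    frag_sd: float = 25.0,
    seed: int = 0,
) -> list[Transcript]:
    """Write simulated alignments (SAM) and the truth annotation (GTF).

    Fragment counts per isoform are depth * weight * spliced_length /
    (read bases per fragment), giving a summed per-base exon coverage of
    about ``depth`` for each gene.  Returns the truth transcripts.
    """
    if depth <= 0:
        raise ValueError("depth must be positive")
    truth: list[Transcript] = []
    for m in models:
        truth.extend(m.transcripts())
    min_len = min(t.spliced_length for t in truth) if truth else read_len
    if read_len > min_len:
        raise ValueError(f"read length {read_len} exceeds shortest transcript {min_len}")
    contigs = sorted({m.contig for m in models})
    contig_len = {
        c: max(m.isoforms[0][-1][1] for m in models if m.contig == c) + 2000
        for c in contigs
    }
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": contig_len[c]} for c in contigs],
    }
    bases_per_frag = 2 * read_len if paired else read_len
    records = []
    for gi, m in enumerate(models):
        rng = np.random.default_rng((seed, gi))
        for k, iso in enumerate(m.isoforms):
            t = Transcript(contig=m.contig, strand=m.strand, exons=iso)
            L = t.spliced_length
            n_frag = int(round(depth * m.weights[k] * L / bases_per_frag))
            for fi in range(n_frag):
                name = f"{m.gene_id}.t{k + 1}.f{fi + 1}"
                if paired:
                    flen = _truncated_normal(rng, frag_mean, frag_sd, read_len, L)
                    start = int(rng.integers(0, L - flen + 1))
                    b1 = _project(iso, start, start + read_len)
                    b2 = _project(iso, start + flen - read_len, start + flen)
                    records.append((name, m.contig, m.strand, b1, b2))
                else:
                    start = int(rng.integers(0, L - read_len + 1))
                    b1 = _project(iso, start, start + read_len)
                    records.append((name, m.contig, m.strand, b1, None))

    with pysam.AlignmentFile(out_sam, "wh", header=header) as sam:
        tid = {c: i for i, c in enumerate(contigs)}
        segs = []
        for name, contig, strand, b1, b2 in records:
            segs.extend(_make_segments(sam.header, tid[contig], name, strand, b1, b2, read_len))
        segs.sort(key=lambda s: (s.reference_id, s.reference_start, s.query_name, s.flag))
        for s in segs:
            sam.write(s)
    if out_gtf is not None:
        write_gtf(out_gtf, truth, source="truth")
    return truth


def _make_segments(header, tid: int, name: str, strand: str, b1, b2, read_len: int):
    def seg(blocks, flag, mate_blocks):
        a = pysam.AlignedSegment(header)
        a.query_name = name
        a.flag = flag
        a.reference_id = tid
        a.reference_start = blocks[0][0]
        a.mapping_quality = 60
        a.cigarstring = _cigar(blocks)
        if mate_blocks is not None:
            a.next_reference_id = tid
            a.next_reference_start = mate_blocks[0][0]
            span = max(blocks[-1][1], mate_blocks[-1][1]) - min(
                blocks[0][0], mate_blocks[0][0]
            )
            a.template_length = span if blocks[0][0] <= mate_blocks[0][0] else -span
        else:
            a.next_reference_id = -1
            a.next_reference_start = -1
        if len(blocks) > 1 and strand in "+-":
            a.set_tag("XS", strand)
        return a

    if b2 is None:
        return [seg(b1, 0, None)]
    return [seg(b1, 99, b2), seg(b2, 147, b1)]
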