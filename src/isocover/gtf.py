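"""GTF reading and writing.

External files are GTF with 1-based inclusive coordinates; everything
in-memory is 0-based half-open.  Reading goes through gffutils; writing
emits transcript + exon feature lines with gene_id/transcript_id
attributes.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import gffutils

from .core import Transcript


def read_gtf(path: str) -> list[Transcript]:
    """Load transcripts (grouped exon features) from a GTF file."""
    db = gffutils.create_db(
        path,
        dbfn=":memory:",
        force=True,
        keep_order=True,
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, list] = {}
    meta: dict[str, tuple[str, str, str]] = {}
    for feat in db.features_of_type("exon"):
        tid = feat.attributes.get("transcript_id", [""])[0]
        gid = feat.attributes.get("gene_id", [""])[0]
        if not tid:
            continue
        grouped.setdefault(tid, []).append((feat.start - 1, feat.end))
        meta[tid] = (feat.seqid, feat.strand or ".", gid)
    out = []
    for tid in sorted(grouped):
        contig, strand, gid = meta[tid]
        exons = tuple(sorted(grouped[tid]))
        out.append(
            Transcript(
                contig=contig, strand=strand, exons=exons,
                transcript_id=tid, gene_id=gid,
            )
        )
    out.sort(key=lambda t: t.sort_key())
    return out


def format_gtf(transcripts: Sequence[Transcript], source: str = "isocover") -> str:
    """Render transcripts as GTF text (transcript + exon lines)."""
    lines = []
    for t in transcripts:
        attrs = f'gene_id "{t.gene_id}"; transcript_id "{t.transcript_id}";'
        lines.append(
            "\t".join(
                [
                    t.contig, source, "transcript",
                    str(t.start + 1), str(t.end), ".", t.strand, ".", attrs,
                ]
            )
        )
        for k, (s, e) in enumerate(t.exons, start=1):
            lines.append(
                "\t".join(
                    [
                        t.contig, source, "exon",
                        str(s + 1), str(e), ".", t.strand, ".",
                        attrs + f' exon_number "{k}";',
                    ]
                )
            )
    return "\n".join(lines) + ("\n" if lines else "")


def write_gtf(path: str, transcripts: Iterable[Transcript], source: str = "isocover") -> None:
    with open(path, "w") as fh:
        fh.write(format_gtf(list(transcripts), source=source))
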