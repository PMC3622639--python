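from __future__ import annotations

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # for oracles.py

from isocover import assemble_to_gtf, make_gene_models, simulate_alignments
from isocover.pipeline import RunConfig


def sam_text(contigs: dict[str, int], records: list[str]) -> str:
    """Assemble a SAM document from header contigs and record lines."""
    lines = ["@HD\tVN:1.6\tSO:coordinate"]
    lines += [f"@SQ\tSN:{name}\tLN:{length}" for name, length in contigs.items()]
    lines += records
    return "\n".join(lines) + "\n"


def unspliced(name: str, contig: str, pos0: int, length: int, flag: int = 0) -> str:
    """A single-block SAM record at 0-based pos0 (SAM POS is 1-based)."""
    return (
        f"{name}\t{flag}\t{contig}\t{pos0 + 1}\t60\t{length}M\t*\t0\t0\t*\t*"
    )


def spliced(name: str, contig: str, pos0: int, cigar: str, flag: int = 0, xs: str | None = None) -> str:
    tag = f"\tXS:A:{xs}" if xs else ""
    return f"{name}\t{flag}\t{contig}\t{pos0 + 1}\t60\t{cigar}\t*\t0\t0\t*\t*{tag}"


@pytest.fixture(scope="session")
def study_run(tmp_path_factory) -> dict:
    """One full study-condition run: 20 genes, paired 75 nt reads, depth 50,
    fragments 250 +/- 25, no errors; assembled with known fragment stats."""
    d = tmp_path_factory.mktemp("study")
    sam, truth_gtf, pred_gtf = d / "sim.sam", d / "truth.gtf", d / "pred.gtf"
    models = make_gene_models(seed=1, n_genes=20, isoforms_per_gene=(1, 3))
    truth = simulate_alignments(
        models, out_sam=str(sam), out_gtf=str(truth_gtf),
        depth=50.0, read_len=75, paired=True, frag_mean=250.0, frag_sd=25.0, seed=1,
    )
    cfg = RunConfig(frag_len=250.0, frag_sd=25.0)
    result = assemble_to_gtf(str(sam), str(pred_gtf), config=cfg)
    return {
        "sam": str(sam),
        "truth_gtf": str(truth_gtf),
        "pred_gtf": str(pred_gtf),
        "truth": truth,
        "result": result,
        "config": cfg,
    }
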