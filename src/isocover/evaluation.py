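"""Assembly accuracy metrics.

Transcript matching is by intron chain: a prediction matches a reference
when all of its introns appear consecutively in the reference (strict
mode), each boundary within a margin V; compatible mode accepts
containment in either direction, for comparisons where the reference
itself may be partial.  Effective coverage grades partial matches by the
fraction of the assessed transcript's exons inside the longest matched
stretch.  Recall = K/M matched references, precision = K'/N matched
predictions, F = 2RP/(R+P).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal
from typing import Optional, Sequence

import pandas as pd

from .core import Transcript
from .gtf import read_gtf


@dataclass(frozen=True)
class MatchSpec:
    margin: int = 0  # V
    multi_exon_only: bool = False
    coverage_cutoff: float = 0.0
    mode: str = "strict"  # 'strict' | 'compatible'

    def __post_init__(self) -> None:
        if self.margin < 0:
            raise ValueError("margin V must be >= 0")
        if not 0.0 <= self.coverage_cutoff <= 1.0:
            raise ValueError("coverage cutoff must be in [0, 1]")
        if self.mode not in ("strict", "compatible"):
            raise ValueError(f"unknown match mode {self.mode!r}")


@dataclass
class AccuracyReport:
    m_ref: int
    n_pred: int
    k_ref_matched: int
    k_pred_matched: int
    recall: float
    precision: float
    f_value: float
    curve: pd.DataFrame = field(default_factory=pd.DataFrame)

    def summary(self) -> str:
        return (
            f"references matched K/M = {self.k_ref_matched}/{self.m_ref}, "
            f"predictions matched K'/N = {self.k_pred_matched}/{self.n_pred}, "
            f"recall {round3(self.recall)}, precision {round3(self.precision)}, "
            f"F {round3(self.f_value)}"
        )


def round3(x: float) -> float:
    """Three decimals, round-half-up (table convention)."""
    return float(Decimal(repr(x)).quantize(Decimal("0.001"), rounding=ROUND_HALF_UP))


def recall_value(k: int, m: int) -> float:
    return k / m if m else 0.0


def precision_value(k_prime: int, n: int) -> float:
    return k_prime / n if n else 0.0


def f_value(recall: float, precision: float) -> float:
    if recall + precision <= 0:
        return 0.0
    return 2.0 * recall * precision / (recall + precision)


def _close(a: int, b: int, v: int) -> bool:
    return abs(a - b) <= v


def exon_match(
    pred: tuple[int, int],
    ref: tuple[int, int],
    kind: str,
    v: int = 0,
) -> bool:
    """Exon-level match criteria.

    internal: both boundaries agree within +/-V; terminal: the splice-site
    boundary agrees within +/-V and the exon is included in the reference
    exon (V slack at the free end); unbounded: inclusion in the reference
    exon with V slack.
    """
    ps, pe = pred
    rs, re = ref
    if kind == "internal":
        return _close(ps, rs, v) and _close(pe, re, v)
    if kind == "terminal_left":  # splice site on the right edge
        return _close(pe, re, v) and ps >= rs - v
    if kind == "terminal_right":  # splice site on the left edge
        return _close(ps, rs, v) and pe <= re + v
    if kind == "unbounded":
        return ps >= rs - v and pe <= re + v
    raise ValueError(f"unknown exon kind {kind!r}")


def _chain_match_at(
    pred_introns: Sequence[tuple[int, int]],
    ref_introns: Sequence[tuple[int, int]],
    offset: int,
    v: int,
) -> bool:
    return all(
        _close(pd_, rd, v) and _close(pa, ra, v)
        for (pd_, pa), (rd, ra) in zip(
            pred_introns, ref_introns[offset : offset + len(pred_introns)]
        )
    )


def _subchain_offsets(
    small: Sequence[tuple[int, int]],
    big: Sequence[tuple[int, int]],
    v: int,
) -> list[int]:
    if len(small) > len(big):
        return []
    return [
        off
        for off in range(len(big) - len(small) + 1)
        if _chain_match_at(small, big, off, v)
    ]


def transcript_match(
    pred: Transcript,
    ref: Transcript,
    v: int = 0,
    mode: str = "strict",
) -> bool:
    """Intron-chain transcript matching.

    strict: the prediction's introns are a consecutive subchain of the
    reference's; compatible: additionally accepts the reference's chain
    being a consecutive subchain of the prediction's.  Single-exon
    transcripts match single-exon counterparts by containment with V slack.
    """
    if pred.contig != ref.contig:
        return False
    if pred.strand in "+-" and ref.strand in "+-" and pred.strand != ref.strand:
        return False
    pi, ri = pred.introns, ref.introns
    if not pi or not ri:
        if pi or ri:
            return False
        return exon_match(pred.exons[0], ref.exons[0], "unbounded", v)
    if _subchain_offsets(pi, ri, v):
        return True
    if mode == "compatible" and _subchain_offsets(ri, pi, v):
        return True
    return False


def effective_coverage(
    assessed: Transcript,
    other: Transcript,
    v: int = 0,
    mode: str = "strict",
) -> float:
    """Fraction of the assessed transcript's exons in the longest match."""
    ai, oi = assessed.introns, other.introns
    if not ai and not oi:
        return (
            1.0
            if exon_match(assessed.exons[0], other.exons[0], "unbounded", v)
            or exon_match(other.exons[0], assessed.exons[0], "unbounded", v)
            else 0.0
        )
    if not ai or not oi:
        return 0.0
    # the matched stretch is the shorter chain placed inside the longer one
    k = 0
    if len(oi) <= len(ai) and _subchain_offsets(oi, ai, v):
        k = len(oi)
    elif len(ai) <= len(oi) and _subchain_offsets(ai, oi, v):
        k = len(ai)
    return (k + 1) / assessed.n_exons if k else 0.0


def _match_pairs(
    preds: Sequence[Transcript],
    refs: Sequence[Transcript],
    spec: MatchSpec,
) -> list[tuple[int, int, float, float]]:
    """(pred_idx, ref_idx, cov_pred, cov_ref) for every matching pair."""
    by_contig: dict[str, list[int]] = {}
    for ri, r in enumerate(refs):
        by_contig.setdefault(r.contig, []).append(ri)
    out = []
    for pi, p in enumerate(preds):
        for ri in by_contig.get(p.contig, []):
            r = refs[ri]
            if r.end <= p.start or p.end <= r.start:
                continue
            if transcript_match(p, r, spec.margin, spec.mode):
                cov_r = effective_coverage(r, p, spec.margin, spec.mode)
                cov_p = effective_coverage(p, r, spec.margin, spec.mode)
                out.append((pi, ri, cov_p, cov_r))
    return out


def _classified_exons(transcripts: Sequence[Transcript]) -> dict[tuple[str, str, int, int], str]:
    """Unique exon spans with their match kind.

    Internal exons are spliced on both sides, terminal exons on one side,
    and exons of single-exon transcripts are unbounded.  When a span occurs
    in several roles the most constrained one is kept.
    """
    rank = {"internal": 3, "terminal_left": 2, "terminal_right": 2, "unbounded": 1}
    out: dict[tuple[str, str, int, int], str] = {}
    for t in transcripts:
        for k, (s, e) in enumerate(t.exons):
            if t.n_exons == 1:
                kind = "unbounded"
            elif k == 0:
                kind = "terminal_left"
            elif k == t.n_exons - 1:
                kind = "terminal_right"
            else:
                kind = "internal"
            key = (t.contig, t.strand, s, e)
            if key not in out or rank[kind] > rank[out[key]]:
                out[key] = kind
    return out


def exon_level_report(
    preds: Sequence[Transcript] | str,
    refs: Sequence[Transcript] | str,
    v: int = 0,
) -> dict[str, float | int]:
    """Exon-level recall/precision over unique exon spans.

    A predicted exon matches per its kind: internal exons at both
    boundaries, terminal exons at the splice-site boundary with inclusion
    in the reference exon, unbounded exons by inclusion.
    """
    if isinstance(preds, str):
        preds = read_gtf(preds)
    if isinstance(refs, str):
        refs = read_gtf(refs)
    pred_exons = _classified_exons(preds)
    ref_exons = _classified_exons(refs)
    ref_by_contig: dict[str, list[tuple[str, int, int]]] = {}
    for (contig, strand, s, e), kind in ref_exons.items():
        ref_by_contig.setdefault(contig, []).append((strand, s, e))
    matched_pred = 0
    hit_refs: set[tuple[str, str, int, int]] = set()
    for (contig, strand, s, e), kind in pred_exons.items():
        for rstrand, rs, re in ref_by_contig.get(contig, []):
            if strand in "+-" and rstrand in "+-" and strand != rstrand:
                continue
            if re <= s - v or rs >= e + v:
                continue
            if exon_match((s, e), (rs, re), kind, v):
                matched_pred += 1
                hit_refs.add((contig, rstrand, rs, re))
                break
    # reference side: a reference exon is found if any predicted exon of a
    # compatible kind matches it
    matched_ref = 0
    pred_by_contig: dict[str, list[tuple[str, int, int, str]]] = {}
    for (contig, strand, s, e), kind in pred_exons.items():
        pred_by_contig.setdefault(contig, []).append((strand, s, e, kind))
    for (contig, rstrand, rs, re), _ in ref_exons.items():
        for strand, s, e, kind in pred_by_contig.get(contig, []):
            if strand in "+-" and rstrand in "+-" and strand != rstrand:
                continue
            if exon_match((s, e), (rs, re), kind, v):
                matched_ref += 1
                break
    n_pred, n_ref = len(pred_exons), len(ref_exons)
    return {
        "total_pred": n_pred,
        "total_ref": n_ref,
        "matched_pred": matched_pred,
        "matched_ref": matched_ref,
        "recall": matched_ref / n_ref if n_ref else 0.0,
        "precision": matched_pred / n_pred if n_pred else 0.0,
    }


def accuracy_report(
    preds: Sequence[Transcript] | str,
    refs: Sequence[Transcript] | str,
    spec: MatchSpec = MatchSpec(),
) -> AccuracyReport:
    """Recall/precision/F of a predicted transcript set against a reference.

    Accepts transcript lists or GTF paths.  A reference counts as matched
    when some prediction matches it with effective coverage >= the cutoff,
    and symmetrically for predictions.  The report carries a decile-cutoff
    recall/precision curve.
    """
    if isinstance(preds, str):
        preds = read_gtf(preds)
    if isinstance(refs, str):
        refs = read_gtf(refs)
    if spec.multi_exon_only:
        preds = [t for t in preds if t.n_exons > 1]
        refs = [t for t in refs if t.n_exons > 1]
    pairs = _match_pairs(preds, refs, spec)

    def counts(cutoff: float) -> tuple[int, int]:
        k_ref = len({ri for _, ri, _, cr in pairs if cr >= cutoff})
        k_pred = len({pi for pi, _, cp, _ in pairs if cp >= cutoff})
        return k_ref, k_pred

    k_ref, k_pred = counts(spec.coverage_cutoff)
    m, n = len(refs), len(preds)
    rec = recall_value(k_ref, m)
    prec = precision_value(k_pred, n)
    rows = []
    for cutoff in [round(0.1 * i, 1) for i in range(1, 11)]:
        kr, kp = counts(cutoff)
        r_c, p_c = recall_value(kr, m), precision_value(kp, n)
        rows.append(
            {
                "cutoff": cutoff, "matched_ref": kr, "matched_pred": kp,
                "recall": r_c, "precision": p_c, "f_value": f_value(r_c, p_c),
            }
        )
    return AccuracyReport(
        m_ref=m,
        n_pred=n,
        k_ref_matched=k_ref,
        k_pred_matched=k_pred,
        recall=rec,
        precision=prec,
        f_value=f_value(rec, prec),
        curve=pd.DataFrame(rows),
    )
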