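"""Benchmark detected CNV calls against a truth set.

Matching is greedy bipartite on reciprocal overlap: candidate (truth, call)
pairs share a chromosome (and event type when type_strict), overlap by at
least the threshold fraction of both lengths, and are consumed best-overlap
first so no interval is double-counted. TPR = matched truth / all truth;
FDR = unmatched calls / all calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from ._intervals import overlap_bp, reciprocal_overlap
from .model import CnvCall, SyntheticTruth
from .variant_io import read_cnv_calls


@dataclass
class MatchReport:
    tp: int
    fp: int
    fn: int
    reciprocal: float
    by_type: dict[str, dict[str, int]] = field(default_factory=dict)

    @property
    def tpr(self) -> float:
        total = self.tp + self.fn
        return self.tp / total if total else float("nan")

    @property
    def fdr(self) -> float:
        total = self.tp + self.fp
        return self.fp / total if total else float("nan")


def truth_to_calls(truth: SyntheticTruth) -> list[CnvCall]:
    """Planted loci as one CnvCall each (locus-level truth for matching)."""
    return [
        CnvCall(f"locus{i}", chrom, s, e, t)
        for i, (chrom, s, e, t, _f1, _f2) in enumerate(truth.planted_loci)
    ]


def cnvrs_to_calls(cnvrs) -> list[CnvCall]:
    """CNVRs as locus-level calls for truth matching (one per event class)."""
    out = []
    for r in cnvrs:
        types = {"loss": ["DEL"], "gain": ["DUP"], "both": ["DEL", "DUP"]}[r.event_type]
        for t in types:
            out.append(CnvCall(r.id, r.chrom, r.start, r.end, t))
    return out


def match_calls(
    truth: list[CnvCall],
    calls: list[CnvCall],
    reciprocal: float = 0.5,
    type_strict: bool = True,
) -> MatchReport:
    """Greedy one-to-one matching of calls to truth intervals.

    Candidate pairs are ordered by descending reciprocal-overlap fraction,
    with ties broken by (truth, call) sort order, and consumed so that every
    truth entry and every call is matched at most once.
    """
    if not 0 < reciprocal <= 1:
        raise ValueError("reciprocal must lie in (0, 1]")
    truth_sorted = sorted(truth)
    calls_sorted = sorted(calls)
    candidates = []
    for i, t in enumerate(truth_sorted):
        for j, c in enumerate(calls_sorted):
            if t.chrom != c.chrom:
                continue
            if type_strict and t.svtype != c.svtype:
                continue
            if overlap_bp((t.start, t.end), (c.start, c.end)) == 0:
                continue
            ro = reciprocal_overlap((t.start, t.end), (c.start, c.end))
            if ro >= reciprocal:
                candidates.append((-ro, i, j))
    candidates.sort()
    used_t: set[int] = set()
    used_c: set[int] = set()
    matched: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_t or j in used_c:
            continue
        used_t.add(i)
        used_c.add(j)
        matched.append((i, j))

    by_type: dict[str, dict[str, int]] = {}
    for t in ("DEL", "DUP"):
        t_idx = {i for i, x in enumerate(truth_sorted) if x.svtype == t}
        c_idx = {j for j, x in enumerate(calls_sorted) if x.svtype == t}
        tp_t = sum(1 for i, _ in matched if i in t_idx)
        matched_c = sum(1 for _, j in matched if j in c_idx)
        by_type[t] = {"tp": tp_t, "fn": len(t_idx) - tp_t, "fp": len(c_idx) - matched_c}
    return MatchReport(
        tp=len(matched),
        fp=len(calls_sorted) - len(matched),
        fn=len(truth_sorted) - len(matched),
        reciprocal=reciprocal,
        by_type=by_type,
    )


def evaluate_against_truth_files(
    truth_tsv: str,
    calls_tsv: str,
    thresholds: list[float] = (0.5,),
    type_strict: bool = True,
) -> pd.DataFrame:
    """Run match_calls across thresholds from call-table files."""
    truth = read_cnv_calls(truth_tsv)
    calls = read_cnv_calls(calls_tsv)
    rows = []
    for thr in thresholds:
        rep = match_calls(truth, calls, reciprocal=thr, type_strict=type_strict)
        rows.append(
            {
                "reciprocal": thr,
                "tp": rep.tp,
                "fp": rep.fp,
                "fn": rep.fn,
                "tpr": rep.tpr,
                "fdr": rep.fdr,
            }
        )
    return pd.DataFrame(rows)
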