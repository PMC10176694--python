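"""CNVR definition: merge per-accession CNV calls into CNV regions.

Calls from different accessions are clustered when they overlap the growing
region reciprocally by at least 90% of both lengths; the region extent is the
union of its members. Regions carried by fewer than ten accessions are
dropped, the rest are classified loss / gain / both from their member event
types and recoded to allele dosages for downstream LD and PCA.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._intervals import reciprocal_overlap, total_length
from .model import CnvCall, CnvrRecord


@dataclass
class FilterReport:
    kept: int
    removed: int
    removed_by_type: dict[str, int]


def filter_calls(
    calls: list[CnvCall], min_len: int = 50
) -> tuple[list[CnvCall], FilterReport]:
    """Retain calls of length >= min_len (the 50 bp CNV size definition)."""
    kept = [c for c in calls if c.length >= min_len]
    removed = [c for c in calls if c.length < min_len]
    by_type: dict[str, int] = {}
    for c in removed:
        by_type[c.svtype] = by_type.get(c.svtype, 0) + 1
    return kept, FilterReport(kept=len(kept), removed=len(removed), removed_by_type=by_type)


def _carrier_event(events: set[str]) -> str:
    if events == {"DEL"}:
        return "loss"
    if events == {"DUP"}:
        return "gain"
    return "both"


def _event_type(carriers: dict[str, str]) -> str:
    evs = set(carriers.values())
    if evs == {"loss"}:
        return "loss"
    if evs == {"gain"}:
        return "gain"
    return "both"


def merge_to_cnvrs(
    calls: list[CnvCall],
    reciprocal: float = 0.90,
    min_carriers: int = 10,
    samples: list[str] | None = None,
) -> list[CnvrRecord]:
    """Greedy single-pass merge of sorted calls into CNVRs.

    Calls are visited in (chrom, start, end, accession) order. A call joins
    the open cluster iff its overlap with the cluster's current union extent
    is at least ``reciprocal`` of both the call length and the extent length;
    on joining, the extent extends to the union. Otherwise the cluster is
    closed and a new one opens. Clusters with fewer than ``min_carriers``
    distinct accessions are dropped. An accession appearing twice in one
    cluster counts once; it is recorded as loss and/or gain from its member
    types. When ``samples`` is given, each CNVR's MAF is filled in under the
    0/1 (loss) / 1/1 (gain) recoding.
    """
    if not 0 < reciprocal <= 1:
        raise ValueError("reciprocal must lie in (0, 1]")
    ordered = sorted(calls, key=lambda c: (c.chrom, c.start, c.end, c.accession))
    clusters: list[dict] = []
    cur: dict | None = None
    for c in ordered:
        if cur is not None and c.chrom == cur["chrom"]:
            extent = (cur["start"], cur["end"])
            if reciprocal_overlap((c.start, c.end), extent) >= reciprocal:
                cur["start"] = min(cur["start"], c.start)
                cur["end"] = max(cur["end"], c.end)
                cur["members"].append(c)
                continue
        cur = {"chrom": c.chrom, "start": c.start, "end": c.end, "members": [c]}
        clusters.append(cur)

    cnvrs: list[CnvrRecord] = []
    idx = 0
    for cl in clusters:
        by_acc: dict[str, set[str]] = {}
        for m in cl["members"]:
            by_acc.setdefault(m.accession, set()).add(m.svtype)
        if len(by_acc) < min_carriers:
            continue
        carriers = {a: _carrier_event(evs) for a, evs in sorted(by_acc.items())}
        rec = CnvrRecord(
            id=f"cnvr{idx:05d}",
            chrom=cl["chrom"],
            start=cl["start"],
            end=cl["end"],
            event_type=_event_type(carriers),
            carriers=carriers,
        )
        if samples is not None:
            rec.maf = compute_cnvr_maf(rec, samples)
        cnvrs.append(rec)
        idx += 1
    return cnvrs


def compute_cnvr_maf(cnvr: CnvrRecord, all_samples: list[str]) -> float:
    """MAF of a CNVR under the loss=0/1, gain=1/1, neutral=0/0 recoding.

    A loss carrier contributes one alt allele, a gain carrier two, out of
    2 x n_samples alleles in total.
    """
    stray = set(cnvr.carriers) - set(all_samples)
    if stray:
        raise ValueError(f"carriers not in sample list: {sorted(stray)[:5]}")
    alt = len(cnvr.loss_carriers()) + 2 * len(cnvr.gain_carriers())
    f = alt / (2 * len(all_samples))
    return min(f, 1 - f)


def filter_cnvrs_by_maf(
    cnvrs: list[CnvrRecord], floor: float = 0.05
) -> tuple[list[CnvrRecord], FilterReport]:
    """Retain CNVRs with MAF >= floor (matching the SNP filtering criterion)."""
    kept = [r for r in cnvrs if r.maf >= floor]
    removed = [r for r in cnvrs if not (r.maf >= floor)]
    by_type: dict[str, int] = {}
    for r in removed:
        by_type[r.event_type] = by_type.get(r.event_type, 0) + 1
    return kept, FilterReport(kept=len(kept), removed=len(removed), removed_by_type=by_type)


def cnvr_dosages(cnvrs: list[CnvrRecord], samples: list[str]) -> np.ndarray:
    """CNVR x sample dosage matrix from the recoding (loss 1, gain 2, neutral 0)."""
    d = np.zeros((len(cnvrs), len(samples)), dtype=np.int16)
    col = {s: j for j, s in enumerate(samples)}
    for i, r in enumerate(cnvrs):
        for a in r.loss_carriers():
            d[i, col[a]] = 1
        for a in r.gain_carriers():
            d[i, col[a]] = 2
    return d


def summarize_cnvrs(
    cnvrs: list[CnvrRecord], genome_length: int | None = None
) -> pd.Series:
    """Counts per event type, union bp, genome fraction and length stats."""
    lengths = np.array([r.length for r in cnvrs], dtype=float)
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in cnvrs:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    union_bp = sum(total_length(ivs) for ivs in by_chrom.values())
    out = {
        "n_cnvrs": len(cnvrs),
        "n_loss": sum(r.event_type == "loss" for r in cnvrs),
        "n_gain": sum(r.event_type == "gain" for r in cnvrs),
        "n_both": sum(r.event_type == "both" for r in cnvrs),
        "union_bp": union_bp,
        "length_min": float(lengths.min()) if len(lengths) else float("nan"),
        "length_mean": float(lengths.mean()) if len(lengths) else float("nan"),
        "length_max": float(lengths.max()) if len(lengths) else float("nan"),
    }
    if genome_length is not None:
        out["genome_fraction"] = union_bp / genome_length
    return pd.Series(out)
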