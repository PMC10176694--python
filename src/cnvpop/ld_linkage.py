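"""CNVR-SNP linkage disequilibrium classification by a rank statistic.

For each CNVR the nearest 300 SNPs upstream and 300 downstream (MAF > 5%)
are selected. All SNP-SNP pairwise r-squared values and all CNVR-SNP
r-squared values are pooled and ranked by decreasing r-squared; the median
rank of the SNP-SNP values is the reference, and N counts how many CNVR-SNP
pairs rank above (strictly better than) that median. With the full 600 SNPs
the classification is Low for N <= 200, Mid for 200 < N <= 400 and High for
400 < N <= 600; with fewer eligible SNPs near chromosome ends the thresholds
scale to thirds of the achieved pair count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .model import MISSING, CnvrRecord, GenotypeMatrix

CATEGORY_ORDER = {"Low": 0, "Mid": 1, "High": 2}


def r2(dosage_a: np.ndarray, dosage_b: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors, pairwise-complete.

    Returns NaN when fewer than two complete pairs remain or either vector is
    constant on the complete pairs (r-squared undefined).
    """
    a = np.asarray(dosage_a, dtype=float)
    b = np.asarray(dosage_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    ok = (a != MISSING) & (b != MISSING)
    a, b = a[ok], b[ok]
    if a.size < 2 or np.ptp(a) == 0 or np.ptp(b) == 0:
        return float("nan")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _pairwise_r2_matrix(d: np.ndarray) -> np.ndarray:
    """r2 for all row pairs of a dosage matrix (missing handled pairwise)."""
    x = np.asarray(d, dtype=float)
    if np.any(x == MISSING):
        xm = np.ma.masked_equal(x, MISSING)
        c = np.ma.corrcoef(xm)
        c = np.asarray(c.filled(np.nan))
    else:
        sd = x.std(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            c = np.corrcoef(x)
        c[sd == 0, :] = np.nan
        c[:, sd == 0] = np.nan
    return c * c


@dataclass
class LdResult:
    cnvr_id: str
    n_snps_used: int
    N: int
    N_by_value: int  # CNVR-SNP r2 values strictly above the median SNP-SNP r2
    category: str  # Low | Mid | High | Unclassifiable
    median_snp_snp_r2: float

    @property
    def classified(self) -> bool:
        return self.category in CATEGORY_ORDER


def rank_statistic(
    snp_snp: np.ndarray, cnvr_snp: np.ndarray
) -> tuple[int, int, float, float]:
    """Pooled decreasing-r2 ranking of SNP-SNP and CNVR-SNP values.

    Returns (N, N_by_value, median_snp_snp_rank, median_snp_snp_r2): N counts
    CNVR-SNP values whose average rank is strictly smaller (better) than the
    median SNP-SNP rank; N_by_value counts CNVR-SNP r2 strictly above the
    median SNP-SNP r2 (the two coincide when there are no ties).
    """
    snp_snp = np.asarray(snp_snp, dtype=float)
    cnvr_snp = np.asarray(cnvr_snp, dtype=float)
    pooled = np.concatenate([snp_snp, cnvr_snp])
    ranks = rankdata(-pooled, method="average")
    median_rank = float(np.median(ranks[: snp_snp.size]))
    N = int(np.sum(ranks[snp_snp.size :] < median_rank))
    median_r2 = float(np.median(snp_snp))
    N_by_value = int(np.sum(cnvr_snp > median_r2))
    return N, N_by_value, median_rank, median_r2


def classify_n(N: int, n_snps_used: int) -> str:
    """Low/Mid/High from N with thirds-of-n thresholds (200/400 at n=600)."""
    if N <= n_snps_used / 3:
        return "Low"
    if N <= 2 * n_snps_used / 3:
        return "Mid"
    return "High"


def select_flanking_snps(
    snps: GenotypeMatrix,
    chrom: str,
    start: int,
    end: int,
    k_per_side: int = 300,
    maf_floor: float = 0.05,
) -> np.ndarray:
    """Row indices of the nearest k SNPs strictly upstream and downstream.

    SNPs must lie on the CNVR's chromosome with MAF above the floor; SNPs
    inside the CNVR interval are not used (they sit in the variable sequence
    itself). Returned sorted by position.
    """
    on_chrom = (snps.markers["chrom"] == chrom).to_numpy()
    eligible = on_chrom & (snps.maf > maf_floor)
    idx = np.flatnonzero(eligible)
    pos = snps.markers["pos"].to_numpy()[idx]
    up = idx[pos < start][-k_per_side:]
    down = idx[pos >= end][:k_per_side]
    return np.concatenate([up, down])


def classify_cnvr_ld(
    cnvr_dosage: np.ndarray,
    snps: GenotypeMatrix,
    cnvr_id: str,
    chrom: str,
    start: int,
    end: int,
    k_per_side: int = 300,
    maf_floor: float = 0.05,
    max_snp_pairs: int | None = None,
    seed: int = 0,
) -> LdResult:
    """Rank-classify one CNVR's LD with its flanking SNPs.

    ``cnvr_dosage`` is the recoded genotype vector (neutral 0, loss 1,
    gain 2) over the same samples as ``snps``. ``max_snp_pairs`` optionally
    subsamples the SNP-SNP pairs (seeded) for speed; the full set is used by
    default. Ties in the pooled ranking get average ranks and "above the
    median" means a strictly smaller average rank.
    """
    sel = select_flanking_snps(snps, chrom, start, end, k_per_side, maf_floor)
    if sel.size == 0:
        return LdResult(cnvr_id, 0, 0, 0, "Unclassifiable", float("nan"))

    d = snps.dosage[sel]
    stacked = np.vstack([np.asarray(cnvr_dosage, dtype=np.int16)[None, :], d])
    r2m = _pairwise_r2_matrix(stacked)
    cnvr_snp = r2m[0, 1:]

    iu, ju = np.triu_indices(len(sel), k=1)
    snp_snp = r2m[1:, 1:][iu, ju]
    if max_snp_pairs is not None and snp_snp.size > max_snp_pairs:
        rng = np.random.default_rng(seed)
        snp_snp = snp_snp[rng.choice(snp_snp.size, size=max_snp_pairs, replace=False)]

    cnvr_snp = cnvr_snp[~np.isnan(cnvr_snp)]
    snp_snp = snp_snp[~np.isnan(snp_snp)]
    n_used = int(cnvr_snp.size)
    if n_used == 0 or snp_snp.size == 0:
        return LdResult(cnvr_id, n_used, 0, 0, "Unclassifiable", float("nan"))

    N, N_by_value, _median_rank, median_r2 = rank_statistic(snp_snp, cnvr_snp)
    return LdResult(cnvr_id, n_used, N, N_by_value, classify_n(N, n_used), median_r2)


def classify_all(
    cnvrs: list[CnvrRecord],
    cnvr_dosage: np.ndarray,
    snps: GenotypeMatrix,
    k_per_side: int = 300,
    maf_floor: float = 0.05,
    max_snp_pairs: int | None = None,
    seed: int = 0,
) -> list[LdResult]:
    """classify_cnvr_ld over a CNVR list; dosage rows align with cnvrs."""
    return [
        classify_cnvr_ld(
            cnvr_dosage[i], snps, r.id, r.chrom, r.start, r.end,
            k_per_side=k_per_side, maf_floor=maf_floor,
            max_snp_pairs=max_snp_pairs, seed=seed,
        )
        for i, r in enumerate(cnvrs)
    ]


def ld_summary(results: list[LdResult], cnvrs: list[CnvrRecord]) -> pd.DataFrame:
    """Category proportions overall and per CNVR event type, with MAF stats."""
    by_id = {r.id: r for r in cnvrs}
    rows = []
    for res in results:
        if not res.classified:
            continue
        rec = by_id.get(res.cnvr_id)
        rows.append(
            {
                "cnvr_id": res.cnvr_id,
                "category": res.category,
                "event_type": rec.event_type if rec else "unknown",
                "maf": rec.maf if rec else float("nan"),
            }
        )
    df = pd.DataFrame(rows, columns=["cnvr_id", "category", "event_type", "maf"])
    if df.empty:
        return pd.DataFrame(
            columns=["group", "category", "proportion", "n", "maf_median"]
        )
    out = []
    for group, sub in [("all", df)] + [
        (f"type:{t}", df[df["event_type"] == t]) for t in sorted(df["event_type"].unique())
    ]:
        for cat in ("Low", "Mid", "High"):
            hit = sub[sub["category"] == cat]
            out.append(
                {
                    "group": group,
                    "category": cat,
                    "proportion": len(hit) / len(sub) if len(sub) else float("nan"),
                    "n": len(hit),
                    "maf_median": float(hit["maf"].median()) if len(hit) else float("nan"),
                }
            )
    return pd.DataFrame(out)
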