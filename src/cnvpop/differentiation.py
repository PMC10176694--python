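"""Copy-number population differentiation between cultivars and wild relatives.

Vst compares total copy-number variance with the size-weighted within-group
variances:

    Vst = (V_total - (V_cult * N_cult + V_wild * N_wild) / N_total) / V_total

where variances are population variances (denominator = group size). Under
that convention the law of total variance makes Vst exactly the between-
group share of the total variance: 0 for identical group distributions, 1
for complete differentiation, and never outside [0, 1] (no clamping is
applied; with sample variances small negative values could arise). Genes in
the top 1% of the Vst distribution are called CN-differentiated.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import mannwhitneyu

from .model import CnMatrix


@dataclass
class VstRecord:
    gene_id: str
    v_total: float
    v_cultivars: float
    v_wild: float
    n_cultivars: int
    n_wild: int
    n_total: int
    vst: float  # NaN when v_total == 0 (undefined)

    @property
    def defined(self) -> bool:
        return not np.isnan(self.vst)


def vst(cn_cultivars: np.ndarray, cn_wild: np.ndarray, gene_id: str = "") -> VstRecord:
    """Vst between two copy-number vectors.

    Uses population variances (ddof=0), which is the only convention under
    which the size-weighted group term is internally consistent. Undefined
    (NaN) when the pooled variance is zero.
    """
    c = np.asarray(cn_cultivars, dtype=float)
    w = np.asarray(cn_wild, dtype=float)
    if c.size == 0 or w.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.all(np.isfinite(c)) and np.all(np.isfinite(w))):
        raise ValueError("non-finite copy-number values")
    pooled = np.concatenate([c, w])
    v_total = float(np.var(pooled))
    v_c = float(np.var(c))
    v_w = float(np.var(w))
    n_c, n_w = c.size, w.size
    n_total = n_c + n_w
    if v_total == 0:
        value = float("nan")
    else:
        value = (v_total - (v_c * n_c + v_w * n_w) / n_total) / v_total
    return VstRecord(gene_id, v_total, v_c, v_w, n_c, n_w, n_total, value)


def vst_scan(cn: CnMatrix, wild_subset: list[str] | None = None) -> list[VstRecord]:
    """Per-gene Vst between cultivars and (optionally a subset of) wild accessions.

    ``wild_subset`` restricts the wild group to the named accessions, mirroring
    the restriction to particular progenitor species; cultivars are always all
    accessions labeled "cultivar".
    """
    cult = cn.group_columns("cultivar")
    wild = cn.group_columns("wild", subset=wild_subset)
    if cult.size == 0 or wild.size == 0:
        raise ValueError("both populations must be represented")
    return [
        vst(cn.cn[i, cult], cn.cn[i, wild], gene_id=g)
        for i, g in enumerate(cn.genes)
    ]


def top_percentile_genes(records: list[VstRecord], pct: float = 0.01) -> set[str]:
    """Genes at or above the (1 - pct) empirical quantile of defined Vst values.

    Linear-interpolation quantile; ties at the cutoff are included, so the
    returned set can exceed pct * n genes.
    """
    defined = [r for r in records if r.defined]
    if not defined:
        raise ValueError("no defined Vst values")
    values = np.array([r.vst for r in defined])
    cutoff = float(np.quantile(values, 1 - pct))
    return {r.gene_id for r in defined if r.vst >= cutoff}


def group_cn_test(
    cn_cultivars: np.ndarray, cn_wild: np.ndarray
) -> tuple[float, float, float, bool]:
    """Two-sided Wilcoxon rank-sum test (normal approximation with continuity
    correction, matching R's wilcox.test default) on per-group CN.

    Returns (mean_cultivars, mean_wild, p_value, degenerate). When every value
    in both groups is identical the test is undefined; p = 1 is reported with
    the degenerate flag set.
    """
    c = np.asarray(cn_cultivars, dtype=float)
    w = np.asarray(cn_wild, dtype=float)
    if c.size == 0 or w.size == 0:
        raise ValueError("both groups must be non-empty")
    if np.ptp(np.concatenate([c, w])) == 0:
        return float(c.mean()), float(w.mean()), 1.0, True
    res = mannwhitneyu(c, w, alternative="two-sided", use_continuity=True, method="asymptotic")
    return float(c.mean()), float(w.mean()), float(res.pvalue), False
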