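"""PCA of dosage-recoded genotype matrices for population-structure plots.

Works identically on SNP dosages and on recoded CNVR genotypes (loss 0/1,
gain 1/1). Markers are centered (optionally scaled by the binomial
allele-frequency standard deviation, smartpca-style); scores come from the
SVD of the centered sample x marker matrix with a deterministic sign
convention so runs are reproducible.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .model import MISSING, GenotypeMatrix


@dataclass
class PcaResult:
    scores: np.ndarray  # samples x k
    explained_variance_pct: np.ndarray  # length k
    samples: list[str]
    k: int
    n_markers_used: int
    n_monomorphic_dropped: int


def genotype_pca(
    g: GenotypeMatrix, k: int = 2, scale: bool = False
) -> PcaResult:
    """Centered-dosage PCA.

    Monomorphic markers are dropped (with a count); missing dosages are
    replaced by the marker mean (so they do not contribute to covariance).
    With ``scale`` each marker is divided by sqrt(p(1-p)), p the alt-allele
    frequency. Sign convention: for every component the loading with the
    largest magnitude is made positive.
    """
    if g.n_samples < 2:
        raise ValueError("need at least 2 samples")
    d = g.dosage.astype(float)
    d[g.dosage == MISSING] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(d, axis=1)
    poly = ~np.isnan(mean) & (np.nanmax(d, axis=1) != np.nanmin(d, axis=1))
    n_dropped = int((~poly).sum())
    d = d[poly]
    mean = mean[poly]
    if d.shape[0] == 0:
        warnings.warn("no polymorphic markers; returning zero scores", stacklevel=2)
        return PcaResult(
            scores=np.zeros((g.n_samples, k)),
            explained_variance_pct=np.zeros(k),
            samples=list(g.samples),
            k=k,
            n_markers_used=0,
            n_monomorphic_dropped=n_dropped,
        )
    x = d - mean[:, None]
    x[np.isnan(x)] = 0.0
    if scale:
        p = mean / 2.0
        sd = np.sqrt(np.clip(p * (1 - p), 1e-12, None))
        x = x / sd[:, None]

    # samples x markers
    xt = x.T
    u, s, vt = np.linalg.svd(xt, full_matrices=False)
    rank = int(np.sum(s > s[0] * 1e-12)) if s.size else 0
    if k > rank:
        warnings.warn(f"k={k} exceeds matrix rank {rank}; truncating", stacklevel=2)
        k = max(rank, 1)
    # deterministic sign: largest-magnitude loading (row of vt) positive
    for i in range(min(k, len(s))):
        load = vt[i]
        j = int(np.argmax(np.abs(load)))
        if load[j] < 0:
            vt[i] = -load
            u[:, i] = -u[:, i]
    var = s**2
    total = var.sum()
    explained = 100.0 * var[:k] / total if total > 0 else np.zeros(k)
    scores = u[:, :k] * s[:k]
    return PcaResult(
        scores=scores,
        explained_variance_pct=explained,
        samples=list(g.samples),
        k=k,
        n_markers_used=int(poly.sum()),
        n_monomorphic_dropped=n_dropped,
    )
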