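"""Gene-CNVR overlap annotation, feature base-pair impact, windowed densities
and term enrichment.

Feature-class accounting assigns every genomic base to exactly one class with
precedence CDS > exon > intron > flank > intergenic, so that deletion and
duplication base totals are conserved across classes; ``gene_body`` is
additionally reported as the (non-disjoint) union of exonic and intronic
bases. Flanks default to 2 kb on each side of a gene, strand-aware.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom, pearsonr
from statsmodels.stats.multitest import multipletests

from . import _intervals as iv
from .model import CnvCall, CnvrRecord, GeneFeature, GenomeModel

DISJOINT_CLASSES = ("CDS", "exon", "intron", "flank_upstream", "flank_downstream", "intergenic")


def cn_variable_genes(
    genes: list[GeneFeature],
    cnvrs: list[CnvrRecord],
    min_frac: float = 0.5,
) -> dict[str, float]:
    """Genes whose span is covered by the CNVR union by more than min_frac.

    The covered fraction uses the union of all CNVR intervals over the gene
    span; the threshold is strict (fraction > min_frac).
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for r in cnvrs:
        by_chrom.setdefault(r.chrom, []).append((r.start, r.end))
    merged = {c: iv.merge(ivs) for c, ivs in by_chrom.items()}
    out: dict[str, float] = {}
    for g in genes:
        cov = iv.total_length(iv.intersect(merged.get(g.chrom, []), [(g.start, g.end)]))
        frac = cov / g.span
        if frac > min_frac:
            out[g.id] = frac
    return out


@dataclass
class FeatureImpact:
    feature_class: str
    total_bp: int
    del_bp: int
    dup_bp: int

    @property
    def del_pct(self) -> float:
        return 100.0 * self.del_bp / self.total_bp if self.total_bp else 0.0

    @property
    def dup_pct(self) -> float:
        return 100.0 * self.dup_bp / self.total_bp if self.total_bp else 0.0


def feature_classes(
    genome: GenomeModel, flank_bp: int = 2000
) -> dict[str, dict[str, list[tuple[int, int]]]]:
    """Disjoint feature-class intervals per chromosome.

    Precedence CDS > exon > intron > flank > intergenic; the exon class holds
    non-coding exonic bases (UTRs) only. Flanks are clipped to chromosome
    bounds and lose any base already claimed by a gene body.
    """
    sizes = dict(genome.chromosomes)
    classes: dict[str, dict[str, list[tuple[int, int]]]] = {}
    raw: dict[str, dict[str, list[tuple[int, int]]]] = {
        c: {"cds": [], "exon": [], "gene": [], "up": [], "down": []} for c in sizes
    }
    for g in genome.genes:
        r = raw[g.chrom]
        r["gene"].append((g.start, g.end))
        r["cds"].extend(g.cds)
        r["exon"].extend(g.exons)
        L = sizes[g.chrom]
        before = (max(0, g.start - flank_bp), g.start)
        after = (g.end, min(L, g.end + flank_bp))
        if g.strand == "-":
            before, after = after, before
        if before[1] > before[0]:
            r["up"].append(before)
        if after[1] > after[0]:
            r["down"].append(after)
    for chrom, L in sizes.items():
        r = raw[chrom]
        cds = iv.merge(r["cds"])
        exon_all = iv.merge(r["exon"] + r["cds"])
        gene = iv.merge(r["gene"])
        exon_nc = iv.subtract(exon_all, cds)
        intron = iv.subtract(gene, exon_all)
        up = iv.subtract(r["up"], gene)
        down = iv.subtract(iv.merge(r["down"]), iv.merge(r["up"] + r["gene"]))
        flanks_and_gene = iv.merge(r["up"] + r["down"] + r["gene"])
        intergenic = iv.subtract([(0, L)], flanks_and_gene)
        classes[chrom] = {
            "CDS": cds,
            "exon": exon_nc,
            "intron": intron,
            "flank_upstream": up,
            "flank_downstream": down,
            "intergenic": intergenic,
        }
    return classes


def feature_impact(
    genome: GenomeModel, calls: list[CnvCall], flank_bp: int = 2000
) -> list[FeatureImpact]:
    """Percentage of each feature class covered by non-overlapping CNV bases.

    Calls are unioned per svtype first, so overlapping calls from different
    accessions count once. ``gene_body`` is reported alongside the six
    disjoint classes as CDS + exon + intron.
    """
    unions: dict[str, dict[str, list[tuple[int, int]]]] = {"DEL": {}, "DUP": {}}
    for c in calls:
        unions[c.svtype].setdefault(c.chrom, []).append((c.start, c.end))
    for t in unions:
        unions[t] = {c: iv.merge(ivs) for c, ivs in unions[t].items()}

    classes = feature_classes(genome, flank_bp=flank_bp)
    totals = {k: 0 for k in DISJOINT_CLASSES + ("gene_body",)}
    hit = {t: dict(totals) for t in ("DEL", "DUP")}
    for chrom, cls in classes.items():
        gene_body = iv.merge(cls["CDS"] + cls["exon"] + cls["intron"])
        for name, intervals in list(cls.items()) + [("gene_body", gene_body)]:
            totals[name] += iv.total_length(intervals)
            for t in ("DEL", "DUP"):
                hit[t][name] += iv.total_length(
                    iv.intersect(intervals, unions[t].get(chrom, []))
                )
    return [
        FeatureImpact(name, totals[name], hit["DEL"][name], hit["DUP"][name])
        for name in DISJOINT_CLASSES + ("gene_body",)
    ]


def window_density(
    positions: list[tuple[str, int]],
    genome: GenomeModel,
    window_bp: int = 1_000_000,
    step_bp: int | None = None,
) -> pd.DataFrame:
    """Per-window counts of features, assigned by start coordinate.

    step_bp defaults to window_bp (non-overlapping windows); a smaller step
    gives sliding windows. Only windows fully inside the chromosome are kept.
    """
    if step_bp is None:
        step_bp = window_bp
    rows = []
    grouped: dict[str, list[int]] = {}
    for chrom, pos in positions:
        grouped.setdefault(chrom, []).append(pos)
    for chrom, length in genome.chromosomes:
        pos = np.sort(np.array(grouped.get(chrom, []), dtype=int))
        start = 0
        while start + window_bp <= length:
            n = int(np.searchsorted(pos, start + window_bp) - np.searchsorted(pos, start))
            rows.append({"chrom": chrom, "start": start, "end": start + window_bp, "count": n})
            start += step_bp
    return pd.DataFrame(rows, columns=["chrom", "start", "end", "count"])


def density_correlation(track_a: np.ndarray, track_b: np.ndarray) -> tuple[float, float]:
    """Pearson correlation between two aligned window-count tracks."""
    a = np.asarray(track_a, dtype=float)
    b = np.asarray(track_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("tracks must be aligned and equal length")
    r, p = pearsonr(a, b)
    return float(r), float(p)


def term_enrichment(
    study_genes: set[str],
    universe: set[str],
    term_map: dict[str, set[str]],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """One-sided Fisher (hypergeometric tail) enrichment with BH correction.

    For each term with k study hits out of K universe term genes, the p-value
    is P[X >= k] for X hypergeometric(M=|universe|, K, n=|study|). Terms with
    no universe genes are skipped. ``significant`` marks BH-adjusted p < alpha.
    """
    if not study_genes <= universe:
        raise ValueError("study set must be a subset of the universe")
    M = len(universe)
    n = len(study_genes)
    rows = []
    skipped = []
    for term, genes in sorted(term_map.items()):
        term_in_universe = genes & universe
        K = len(term_in_universe)
        if K == 0:
            skipped.append(term)
            continue
        k = len(term_in_universe & study_genes)
        p = float(hypergeom.sf(k - 1, M, K, n))
        rows.append({"term": term, "k_study": k, "K_universe": K, "p_value": p})
    df = pd.DataFrame(rows, columns=["term", "k_study", "K_universe", "p_value"])
    if not df.empty:
        rej, padj, _, _ = multipletests(df["p_value"], alpha=alpha, method="fdr_bh")
        df["p_adjusted"] = padj
        df["significant"] = rej
    else:
        df["p_adjusted"] = []
        df["significant"] = []
    df.attrs["skipped_terms"] = skipped
    return df


def te_overlap_fraction(
    cnvrs: list[CnvrRecord], tes: list[tuple[str, int, int]]
) -> float:
    """Fraction of CNVRs overlapping at least one TE base."""
    if not cnvrs:
        return float("nan")
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for chrom, s, e in tes:
        by_chrom.setdefault(chrom, []).append((s, e))
    merged = {c: iv.merge(ivs) for c, ivs in by_chrom.items()}
    n_hit = sum(
        bool(iv.intersect(merged.get(r.chrom, []), [(r.start, r.end)])) for r in cnvrs
    )
    return n_hit / len(cnvrs)
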