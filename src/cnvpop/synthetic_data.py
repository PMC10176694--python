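"""Synthetic two-population CNV study generator with known ground truth.

Emulates the statistical structure of a cultivar / wild-relative resequencing
panel: a multi-chromosome genome with gene and TE annotation, planted CNV
loci with per-population carrier frequencies and breakpoint jitter, founder-
mosaic SNP haplotypes with block-wise LD, and a gene x accession copy-number
matrix centered at 2 with planted shifts for carriers.

Every operation takes one explicit integer seed and is bit-reproducible; no
global RNG state is used. Breakpoint jitter is truncated so each carrier call
keeps at least 90% reciprocal overlap with its planted locus, which makes the
planted truth consistent with the downstream merge criterion.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from ._intervals import overlap_bp, reciprocal_overlap
from .model import CnMatrix, CnvCall, GeneFeature, GenomeModel, GenotypeMatrix, SyntheticTruth

import pandas as pd


class PackingError(ValueError):
    """Requested features cannot fit in the genome without overlap."""


def _place_nonoverlapping(
    lengths: list[int], chrom_len: int, rng: np.random.Generator
) -> list[int]:
    """Start coordinates for non-overlapping spans, uniform over placements."""
    total = sum(lengths)
    free = chrom_len - total
    if free < 0:
        raise PackingError(
            f"{total} bp of spans cannot fit in a {chrom_len} bp chromosome"
        )
    gaps = np.sort(rng.uniform(0, free, size=len(lengths)))
    starts = []
    cum = 0
    for g, ln in zip(gaps, lengths):
        starts.append(int(g) + cum)
        cum += ln
    return starts


def _split_exons(
    start: int, end: int, n_exons: int, rng: np.random.Generator, min_seg: int = 30
) -> list[tuple[int, int]]:
    """Partition a gene span into alternating exon/intron segments."""
    span = end - start
    while n_exons > 1 and span < (2 * n_exons - 1) * min_seg:
        n_exons -= 1
    n_seg = 2 * n_exons - 1
    extra = span - n_seg * min_seg
    alloc = rng.multinomial(extra, np.full(n_seg, 1.0 / n_seg)) if extra > 0 else np.zeros(n_seg, dtype=int)
    seg_lens = alloc + min_seg
    exons = []
    pos = start
    for i, ln in enumerate(seg_lens):
        if i % 2 == 0:
            exons.append((pos, pos + int(ln)))
        pos += int(ln)
    # absorb rounding: stretch last exon to the gene end
    if exons[-1][1] != end and len(seg_lens) % 2 == 1:
        exons[-1] = (exons[-1][0], end)
    return exons


def _cds_from_exons(exons: list[tuple[int, int]]) -> tuple[tuple[int, int], ...]:
    """Exons trimmed by short terminal UTRs (coding portion of the model gene)."""
    cds = [list(x) for x in exons]
    first_len = cds[0][1] - cds[0][0]
    last_len = cds[-1][1] - cds[-1][0]
    utr5 = min(100, max(0, first_len - 10))
    cds[0][0] += utr5
    utr3 = min(100, max(0, (cds[-1][1] - cds[-1][0]) - 10))
    cds[-1][1] -= utr3
    return tuple((s, e) for s, e in cds if e > s)


def simulate_genome(
    n_chrom: int,
    chrom_length: int,
    n_genes: int,
    te_density: float,
    seed: int,
    mean_gene_length: int = 5000,
) -> GenomeModel:
    """Random genome: non-overlapping genes with 1-5 exons, plus a TE track.

    Gene spans are uniform on [0.4, 1.6] x mean_gene_length; genes are
    assigned to chromosomes by remaining capacity and placed uniformly at
    random without overlap. TEs (100 bp - 5 kb) are placed independently of
    genes until their summed length reaches te_density x genome length, so
    realized coverage is approximately the requested density.
    """
    if n_chrom < 1 or chrom_length < 1:
        raise ValueError("need at least one chromosome of positive length")
    if n_genes < 0 or not 0 <= te_density < 1:
        raise ValueError("invalid n_genes or te_density")
    if n_genes > 0 and chrom_length < 10 * mean_gene_length:
        raise PackingError("chromosome length must be >= 10 x mean gene length")
    rng = np.random.default_rng(seed)
    chroms = [(f"chr{i + 1}", chrom_length) for i in range(n_chrom)]

    spans = rng.integers(
        int(0.4 * mean_gene_length), int(1.6 * mean_gene_length) + 1, size=n_genes
    )
    if spans.sum() > n_chrom * chrom_length:
        raise PackingError(
            f"{int(spans.sum())} bp of gene span cannot fit {n_chrom} x {chrom_length} bp"
        )
    # balance by remaining capacity so no chromosome overflows spuriously
    capacity = np.full(n_chrom, chrom_length, dtype=np.int64)
    assignment: list[list[int]] = [[] for _ in range(n_chrom)]
    for gi in rng.permutation(n_genes):
        ci = int(np.argmax(capacity))
        if capacity[ci] < spans[gi]:
            raise PackingError("infeasible gene packing")
        assignment[ci].append(int(gi))
        capacity[ci] -= spans[gi]

    genes: list[GeneFeature] = []
    placed: list[tuple[str, int, int, int]] = []
    for ci, (cname, clen) in enumerate(chroms):
        gidx = assignment[ci]
        lens = [int(spans[g]) for g in gidx]
        starts = _place_nonoverlapping(lens, clen, rng) if gidx else []
        for g, s in zip(gidx, starts):
            placed.append((cname, s, s + int(spans[g]), g))
    placed.sort()
    for i, (cname, s, e, _g) in enumerate(placed, 1):
        n_ex = int(rng.integers(1, 6))
        exons = _split_exons(s, e, n_ex, rng)
        genes.append(
            GeneFeature(
                id=f"gene{i:05d}",
                chrom=cname,
                start=s,
                end=e,
                strand="+" if rng.random() < 0.5 else "-",
                exons=tuple(exons),
                cds=_cds_from_exons(exons),
            )
        )

    tes: list[tuple[str, int, int]] = []
    for cname, clen in chroms:
        target = te_density * clen
        covered = 0
        while covered < target:
            ln = int(rng.integers(100, 5001))
            ln = min(ln, clen)
            s = int(rng.integers(0, clen - ln + 1))
            tes.append((cname, s, s + ln))
            covered += ln
    return GenomeModel(chromosomes=chroms, genes=genes, tes=tes)


def _draw_locus_lengths(
    n: int, min_len: int, max_len: int, rng: np.random.Generator
) -> np.ndarray:
    """Log-uniform lengths in [min_len, max_len]."""
    u = rng.uniform(math.log(min_len), math.log(max_len), size=n)
    return np.clip(np.exp(u).astype(int), min_len, max_len)


def sample_ids(n_pop1: int, n_pop2: int) -> tuple[list[str], dict[str, str]]:
    """Cultivar/wild accession ids and their population labels."""
    pop1 = [f"C{i + 1:03d}" for i in range(n_pop1)]
    pop2 = [f"W{i + 1:03d}" for i in range(n_pop2)]
    labels = {a: "cultivar" for a in pop1} | {a: "wild" for a in pop2}
    return pop1 + pop2, labels


def simulate_population_cnvs(
    genome: GenomeModel,
    n_pop1: int,
    n_pop2: int,
    n_loci: int,
    freq_spec=( (0.05, 0.95), (0.05, 0.95) ),
    jitter_sd: float = 0.0,
    min_len: int = 100,
    max_len: int = 50_000,
    seed: int = 0,
    del_dup_ratio: float = 10.0,
    diff_threshold: float = 0.5,
    on_genes: list[str] | None = None,
) -> tuple[list[CnvCall], SyntheticTruth]:
    """Plant CNV loci in two populations and emit per-accession calls.

    ``freq_spec`` is either a pair of (lo, hi) per-population frequency
    ranges, from which each locus draws its frequencies uniformly, or an
    explicit list of (freq_pop1, freq_pop2) per locus. Carriers are
    independent Bernoulli draws at the locus frequency. Each carrier's call
    is the locus interval with Gaussian breakpoint jitter, truncated so the
    call stays >= min_len long and keeps >= 90% reciprocal overlap with the
    locus. Loci are deletions with probability del_dup_ratio/(1+del_dup_ratio)
    and are placed non-overlapping with a jitter-sized buffer so distinct
    loci never merge into one CNVR.

    Genes overlapping a locus whose two population frequencies differ by at
    least ``diff_threshold`` are recorded as differentiated in the truth.
    With ``on_genes``, loci are planted exactly on the named genes' spans
    (one locus per gene, in order) instead of at random positions, which
    guarantees gene-level copy-number shifts for carriers.
    """
    if min_len < 50:
        raise ValueError("min_len must be >= 50 (CNV size definition)")
    if max_len < min_len:
        raise ValueError("max_len < min_len")
    if jitter_sd < 0:
        raise ValueError("jitter_sd must be >= 0")
    rng = np.random.default_rng(seed)
    samples, labels = sample_ids(n_pop1, n_pop2)
    pop1 = samples[:n_pop1]
    pop2 = samples[n_pop1:]

    if n_loci == 0:
        truth = SyntheticTruth([], labels, {}, [], seed)
        return [], truth

    # a *list* is an explicit per-locus (f1, f2) table; a *tuple* holds the
    # two per-population uniform ranges
    if isinstance(freq_spec, (list, np.ndarray)):
        pairs = [(float(f1), float(f2)) for f1, f2 in freq_spec]
        if len(pairs) != n_loci:
            raise ValueError("explicit freq list must have one pair per locus")
    else:
        (lo1, hi1), (lo2, hi2) = freq_spec
        pairs = [
            (float(rng.uniform(lo1, hi1)), float(rng.uniform(lo2, hi2)))
            for _ in range(n_loci)
        ]
    for f1, f2 in pairs:
        if not (0 <= f1 <= 1 and 0 <= f2 <= 1):
            raise ValueError("carrier frequency outside [0, 1]")

    types = np.where(
        rng.random(n_loci) < del_dup_ratio / (1 + del_dup_ratio), "DEL", "DUP"
    )
    pad = int(4 * jitter_sd) + 100
    loci: list[tuple[str, int, int, str, float, float]]
    if on_genes is not None:
        if len(on_genes) != n_loci:
            raise ValueError("on_genes must name one gene per locus")
        by_id = {g.id: g for g in genome.genes}
        loci = [
            (by_id[gid].chrom, by_id[gid].start, by_id[gid].end, str(types[li]), *pairs[li])
            for li, gid in enumerate(on_genes)
        ]
    else:
        lengths = _draw_locus_lengths(n_loci, min_len, max_len, rng)
        # spread loci over chromosomes by remaining capacity, then place padded
        capacity = np.array([l for _, l in genome.chromosomes], dtype=np.int64)
        assignment: list[list[int]] = [[] for _ in genome.chromosomes]
        for li in range(n_loci):
            ci = int(np.argmax(capacity))
            need = int(lengths[li]) + 2 * pad
            if capacity[ci] < need:
                raise PackingError("too many/long CNV loci for this genome")
            assignment[ci].append(li)
            capacity[ci] -= need
        loci = [None] * n_loci  # type: ignore
        for ci, (cname, clen) in enumerate(genome.chromosomes):
            idx = assignment[ci]
            padded = [int(lengths[li]) + 2 * pad for li in idx]
            starts = _place_nonoverlapping(padded, clen, rng) if idx else []
            for li, s in zip(idx, starts):
                start = s + pad
                loci[li] = (cname, start, start + int(lengths[li]), str(types[li]), *pairs[li])

    calls: list[CnvCall] = []
    carriers: dict[int, list[str]] = {}
    for li, (chrom, start, end, svtype, f1, f2) in enumerate(loci):
        chosen = [a for a in pop1 if rng.random() < f1]
        chosen += [a for a in pop2 if rng.random() < f2]
        carriers[li] = chosen
        clen = genome.chrom_length(chrom)
        for acc in chosen:
            s, e = start, end
            if jitter_sd > 0:
                for _ in range(100):
                    js = start + int(round(rng.normal(0, jitter_sd)))
                    je = end + int(round(rng.normal(0, jitter_sd)))
                    if (
                        js >= 0
                        and je <= clen
                        and je - js >= min_len
                        and reciprocal_overlap((js, je), (start, end)) >= 0.9
                    ):
                        s, e = js, je
                        break
            calls.append(CnvCall(acc, chrom, s, e, svtype))

    diff_genes = []
    for g in genome.genes:
        for chrom, s, e, _t, f1, f2 in loci:
            if g.chrom == chrom and overlap_bp((g.start, g.end), (s, e)) > 0 and abs(f1 - f2) >= diff_threshold:
                diff_genes.append(g.id)
                break
    truth = SyntheticTruth(loci, labels, carriers, diff_genes, seed)
    return calls, truth


@dataclass
class HaplotypeMosaic:
    """Founder-mosaic diploid haplotypes: the shared LD backbone.

    Each of the 2 x n_samples haplotypes is, per chromosome, a piecewise-
    constant founder assignment with recombination breakpoints at exponential
    spacing (mean block_length). SNP alleles and haplotype-linked CNV alleles
    both read founder identity off this object, so they share realistic
    block-wise LD.

    segments[chrom][h] = (segment end positions ascending, founder ids).
    """

    genome: GenomeModel
    n_samples: int
    n_founders: int
    block_length: float
    seed: int
    segments: dict[str, list[tuple[np.ndarray, np.ndarray]]]

    @property
    def n_hap(self) -> int:
        return 2 * self.n_samples

    def founders_at(self, chrom: str, positions: np.ndarray) -> np.ndarray:
        """Founder id per (haplotype, position): shape (n_hap, len(positions))."""
        positions = np.asarray(positions)
        out = np.empty((self.n_hap, positions.size), dtype=np.int32)
        for h, (ends, fids) in enumerate(self.segments[chrom]):
            out[h] = fids[np.searchsorted(ends, positions, side="right")]
        return out


def simulate_haplotype_mosaic(
    genome: GenomeModel,
    n_samples: int,
    n_founders: int = 8,
    block_length: float = 50_000,
    seed: int = 0,
) -> HaplotypeMosaic:
    """Draw the recombination mosaic underlying SNPs and linked CNVs."""
    if n_founders < 2:
        raise ValueError("need at least 2 founders")
    rng = np.random.default_rng(seed)
    segments: dict[str, list[tuple[np.ndarray, np.ndarray]]] = {}
    for cname, clen in genome.chromosomes:
        per_hap = []
        for _h in range(2 * n_samples):
            ends: list[float] = []
            pos = 0.0
            while pos < clen:
                pos += rng.exponential(block_length)
                ends.append(pos)
            ends_arr = np.array(ends)
            fids = rng.integers(0, n_founders, size=len(ends), dtype=np.int32)
            per_hap.append((ends_arr, fids))
        segments[cname] = per_hap
    return HaplotypeMosaic(genome, n_samples, n_founders, block_length, seed, segments)


def snp_genotypes_from_mosaic(
    mosaic: HaplotypeMosaic,
    n_snps: int,
    maf_floor: float = 0.05,
    seed: int = 0,
    sample_names: list[str] | None = None,
    max_attempts: int = 5,
) -> GenotypeMatrix:
    """SNP dosages from the mosaic: founder alleles Bernoulli(1/2) per site.

    Candidate sites are drawn uniformly per chromosome (proportional to
    length); sites below the MAF floor are discarded and the pool is enlarged
    until n_snps survive (then evenly thinned to preserve genome-wide spread)
    or max_attempts pool doublings fail, which raises.
    """
    genome = mosaic.genome
    n_samples = mosaic.n_samples
    if sample_names is not None and len(sample_names) != n_samples:
        raise ValueError("sample_names length mismatch")
    rng = np.random.default_rng(seed)
    pool = int(n_snps * 1.5) + 10
    for _attempt in range(max_attempts):
        sub = np.random.default_rng(rng.integers(2**31))
        markers, dosage = _draw_candidate_snps(mosaic, pool, sub)
        maf = _maf(dosage)
        keep = np.flatnonzero(maf >= maf_floor)
        if keep.size >= n_snps:
            # even thinning; strictly increasing because keep.size >= n_snps
            sel = keep[np.floor(np.arange(n_snps) * keep.size / n_snps).astype(int)]
            markers = markers.iloc[sel].reset_index(drop=True)
            dosage = dosage[sel]
            names = sample_names or [f"S{i + 1:04d}" for i in range(n_samples)]
            return GenotypeMatrix(markers, names, dosage)
        pool *= 2
    raise RuntimeError(
        f"could not obtain {n_snps} SNPs with MAF >= {maf_floor} after {max_attempts} attempts"
    )


def simulate_snp_genotypes(
    genome: GenomeModel,
    n_samples: int,
    n_snps: int,
    n_founders: int = 8,
    block_length: float = 50_000,
    maf_floor: float = 0.05,
    seed: int = 0,
    sample_names: list[str] | None = None,
    max_attempts: int = 5,
) -> GenotypeMatrix:
    """LD-structured SNP genotypes (mosaic drawn and discarded in one step)."""
    mosaic = simulate_haplotype_mosaic(genome, n_samples, n_founders, block_length, seed)
    return snp_genotypes_from_mosaic(
        mosaic, n_snps, maf_floor=maf_floor, seed=seed + 1,
        sample_names=sample_names, max_attempts=max_attempts,
    )


def linked_cnv_carriers(
    mosaic: HaplotypeMosaic,
    loci: list[tuple[str, int, int]],
    seed: int = 0,
) -> np.ndarray:
    """Carrier indicators for CNV alleles planted on founder haplotypes.

    Each locus is (chrom, pos, n_carrier_founders): the CNV allele resides on
    a seeded random subset of that many founders, so a sample is a carrier
    iff either of its haplotypes descends from a carrier founder at pos.
    Common alleles (more founders) are better tagged by flanking SNPs, which
    reproduces the positive MAF/LD relationship of real panels.
    """
    rng = np.random.default_rng(seed)
    out = np.zeros((len(loci), mosaic.n_samples), dtype=bool)
    for i, (chrom, pos, k) in enumerate(loci):
        if not 1 <= k <= mosaic.n_founders:
            raise ValueError("n_carrier_founders out of range")
        carrier_founders = rng.choice(mosaic.n_founders, size=k, replace=False)
        fids = mosaic.founders_at(chrom, np.array([pos]))[:, 0]
        hap_carrier = np.isin(fids, carrier_founders)
        out[i] = hap_carrier[0::2] | hap_carrier[1::2]
    return out


def _maf(dosage: np.ndarray) -> np.ndarray:
    f = dosage.sum(axis=1) / (2 * dosage.shape[1])
    return np.minimum(f, 1 - f)


def _draw_candidate_snps(mosaic: HaplotypeMosaic, pool: int, rng: np.random.Generator):
    genome = mosaic.genome
    per_chrom = _allocate_proportional(genome, pool)
    frames = []
    dosages = []
    for (cname, clen), m in zip(genome.chromosomes, per_chrom):
        if m == 0:
            continue
        cand = np.unique(rng.integers(0, clen, size=2 * m + 10))
        if cand.size > m:  # thin evenly so sites cover the whole chromosome
            cand = cand[np.floor(np.arange(m) * cand.size / m).astype(int)]
        pos = cand
        m = len(pos)
        founders = rng.integers(0, 2, size=(mosaic.n_founders, m), dtype=np.int8)
        fids = mosaic.founders_at(cname, pos)  # n_hap x m
        hap = founders[fids, np.arange(m)[None, :]]
        dose = (hap[0::2] + hap[1::2]).T.astype(np.int16)  # markers x samples
        frames.append(
            pd.DataFrame(
                {
                    "id": [f"{cname}_snp{p}" for p in pos],
                    "chrom": cname,
                    "pos": pos,
                    "ref": "A",
                    "alt": "T",
                }
            )
        )
        dosages.append(dose)
    markers = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["id", "chrom", "pos", "ref", "alt"]
    )
    dosage = (
        np.vstack(dosages) if dosages else np.zeros((0, mosaic.n_samples), dtype=np.int16)
    )
    return markers, dosage


def _allocate_proportional(genome: GenomeModel, n: int) -> list[int]:
    lens = np.array([l for _, l in genome.chromosomes], dtype=float)
    raw = lens / lens.sum() * n
    alloc = np.floor(raw).astype(int)
    rem = n - alloc.sum()
    order = np.argsort(-(raw - alloc))
    for i in range(rem):
        alloc[order[i % len(alloc)]] += 1
    return list(alloc)


def simulate_cn_matrix(
    genome: GenomeModel,
    truth: SyntheticTruth,
    noise_sd: float = 0.2,
    seed: int = 0,
) -> CnMatrix:
    """Gene x accession copy numbers: baseline 2, planted shifts, noise.

    Carriers of a deletion locus lose one copy (and of a duplication gain
    one) at every gene the locus overlaps; Gaussian noise with the given SD
    is added and values are clipped at 0.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    rng = np.random.default_rng(seed)
    accessions = list(truth.population_labels)
    col = {a: j for j, a in enumerate(accessions)}
    genes = [g.id for g in genome.genes]
    cn = np.full((len(genes), len(accessions)), 2.0)
    for li, (chrom, s, e, svtype, _f1, _f2) in enumerate(truth.planted_loci):
        delta = -1.0 if svtype == "DEL" else 1.0
        rows = [
            i
            for i, g in enumerate(genome.genes)
            if g.chrom == chrom and overlap_bp((g.start, g.end), (s, e)) > 0
        ]
        for a in truth.carriers.get(li, []):
            for i in rows:
                cn[i, col[a]] += delta
    if noise_sd > 0:
        cn += rng.normal(0, noise_sd, size=cn.shape)
    cn = np.clip(cn, 0, None)
    return CnMatrix(genes, accessions, cn, truth.population_labels)
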