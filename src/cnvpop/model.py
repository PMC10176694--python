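"""Core data containers shared across the pipeline.

All genomic coordinates are 0-based half-open internally. Conversion to and
from 1-based inclusive conventions (GFF3, VCF) happens only at the I/O
boundary (:mod:`cnvpop.variant_io`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel for a missing genotype dosage.
MISSING = -1

SVTYPES = ("DEL", "DUP")
EVENT_TYPES = ("loss", "gain", "both")


@dataclass(frozen=True, order=True)
class CnvCall:
    """One deletion or duplication detected in one accession."""

    accession: str
    chrom: str
    start: int  # 0-based
    end: int  # half-open
    svtype: str  # DEL or DUP

    def __post_init__(self) -> None:
        if self.svtype not in SVTYPES:
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.start < 0 or self.end <= self.start:
            raise ValueError(
                f"invalid interval [{self.start}, {self.end}) on {self.chrom}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneFeature:
    """A gene with its exon and CDS child intervals (all 0-based half-open)."""

    id: str
    chrom: str
    start: int
    end: int
    strand: str = "+"
    exons: tuple[tuple[int, int], ...] = ()
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"gene {self.id}: empty span")
        for s, e in self.exons:
            if not (self.start <= s < e <= self.end):
                raise ValueError(f"gene {self.id}: exon [{s},{e}) outside span")

    @property
    def span(self) -> int:
        return self.end - self.start


@dataclass
class GenomeModel:
    """Chromosome sizes plus gene and TE annotation.

    Stands in for a reference assembly and its GFF3/BED annotation; no
    nucleotide sequence is carried because nothing downstream of CNV calling
    needs it.
    """

    chromosomes: list[tuple[str, int]]
    genes: list[GeneFeature] = field(default_factory=list)
    tes: list[tuple[str, int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        sizes = dict(self.chromosomes)
        if len(sizes) != len(self.chromosomes):
            raise ValueError("duplicate chromosome names")
        ids = [g.id for g in self.genes]
        if len(set(ids)) != len(ids):
            raise ValueError("gene ids are not unique")
        for g in self.genes:
            if g.chrom not in sizes or g.end > sizes[g.chrom] or g.start < 0:
                raise ValueError(f"gene {g.id} outside chromosome bounds")
        for chrom, s, e in self.tes:
            if chrom not in sizes or s < 0 or e > sizes[chrom] or e <= s:
                raise ValueError(f"TE [{s},{e}) outside {chrom}")

    @property
    def total_length(self) -> int:
        return sum(l for _, l in self.chromosomes)

    def chrom_length(self, name: str) -> int:
        return dict(self.chromosomes)[name]


@dataclass
class SyntheticTruth:
    """Ground truth emitted by the synthetic-data generator.

    planted_loci rows are (chrom, start, end, svtype, freq_pop1, freq_pop2);
    carriers maps a locus index to the accessions drawn as carriers.
    """

    planted_loci: list[tuple[str, int, int, str, float, float]]
    population_labels: dict[str, str]  # accession -> "cultivar" | "wild"
    carriers: dict[int, list[str]]
    differentiated_genes: list[str]
    seed: int

    def __post_init__(self) -> None:
        for chrom, s, e, t, f1, f2 in self.planted_loci:
            if t not in SVTYPES:
                raise ValueError(f"unknown svtype {t!r}")
            if not (0 <= f1 <= 1 and 0 <= f2 <= 1):
                raise ValueError("carrier frequencies must lie in [0, 1]")
            if e <= s:
                raise ValueError("empty planted locus")


class GenotypeMatrix:
    """Marker x sample allele-dosage matrix.

    Houses both SNP genotypes and recoded CNVR genotypes. Dosages are integer
    alt-allele counts in {0, 1, 2} with :data:`MISSING` for no-calls.
    """

    def __init__(self, markers: pd.DataFrame, samples: list[str], dosage: np.ndarray):
        markers = markers.reset_index(drop=True)
        required = {"id", "chrom", "pos"}
        if not required.issubset(markers.columns):
            raise ValueError(f"markers frame needs columns {sorted(required)}")
        dosage = np.asarray(dosage, dtype=np.int16)
        if dosage.shape != (len(markers), len(samples)):
            raise ValueError(
                f"dosage shape {dosage.shape} != ({len(markers)}, {len(samples)})"
            )
        for _, sub in markers.groupby("chrom", sort=False):
            pos = sub["pos"].to_numpy()
            if np.any(np.diff(pos) <= 0):
                raise ValueError("marker positions must be strictly increasing per chromosome")
        if len(set(samples)) != len(samples):
            raise ValueError("duplicate sample ids")
        self.markers = markers
        self.samples = list(samples)
        self.dosage = dosage

    @property
    def n_markers(self) -> int:
        return len(self.markers)

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def maf(self) -> np.ndarray:
        """Per-marker minor-allele frequency from non-missing dosages."""
        d = self.dosage
        ok = d != MISSING
        alt = np.where(ok, d, 0).sum(axis=1)
        n = 2 * ok.sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            f = np.where(n > 0, alt / np.maximum(n, 1), np.nan)
        return np.minimum(f, 1 - f)

    def subset_markers(self, mask: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(self.markers.loc[np.asarray(mask)], self.samples, self.dosage[np.asarray(mask)])


@dataclass
class CnvrRecord:
    """A CNV region: the union extent of reciprocally-overlapping calls.

    carriers maps accession -> per-accession event ("loss", "gain" or "both"
    when that accession contributed both a deletion and a duplication).
    """

    id: str
    chrom: str
    start: int
    end: int
    event_type: str
    carriers: dict[str, str]
    maf: float = float("nan")

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.end <= self.start:
            raise ValueError("empty CNVR extent")

    @property
    def n_carriers(self) -> int:
        return len(self.carriers)

    @property
    def length(self) -> int:
        return self.end - self.start

    def loss_carriers(self) -> list[str]:
        return [a for a, ev in self.carriers.items() if ev == "loss"]

    def gain_carriers(self) -> list[str]:
        """Accessions emitted as 1/1: pure gain plus mixed loss+gain carriers."""
        return [a for a, ev in self.carriers.items() if ev in ("gain", "both")]


class CnMatrix:
    """Gene x accession real-valued copy-number estimates with population labels."""

    def __init__(
        self,
        genes: list[str],
        accessions: list[str],
        cn: np.ndarray,
        population_labels: dict[str, str],
    ):
        cn = np.asarray(cn, dtype=float)
        if cn.shape != (len(genes), len(accessions)):
            raise ValueError("cn shape mismatch")
        if np.any(cn < 0):
            raise ValueError("negative copy number")
        missing = [a for a in accessions if a not in population_labels]
        if missing:
            raise ValueError(f"unlabeled accessions: {missing[:5]}")
        self.genes = list(genes)
        self.accessions = list(accessions)
        self.cn = cn
        self.population_labels = dict(population_labels)

    def group_columns(self, label: str, subset: list[str] | None = None) -> np.ndarray:
        """Column indices of accessions with the given population label."""
        keep = set(subset) if subset is not None else None
        return np.array(
            [
                i
                for i, a in enumerate(self.accessions)
                if self.population_labels[a] == label and (keep is None or a in keep)
            ],
            dtype=int,
        )
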