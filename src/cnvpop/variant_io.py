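"""Readers and writers for the formats the pipeline touches.

Coordinate conventions are handled strictly: everything in memory is 0-based
half-open; GFF3 and VCF on disk are 1-based inclusive; BED is 0-based
half-open. Call tables (TSV) declare their dialect on a ``#coords=`` comment
line (``0half`` or ``1incl``).
"""

from __future__ import annotations

import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .model import (
    MISSING,
    SVTYPES,
    CnMatrix,
    CnvCall,
    CnvrRecord,
    GeneFeature,
    GenomeModel,
    GenotypeMatrix,
    SyntheticTruth,
)

CALL_COLUMNS = ["accession", "chrom", "start", "end", "svtype"]


class FormatError(ValueError):
    """Malformed input file."""


# ---------------------------------------------------------------------------
# CNV call tables

def read_cnv_calls(path: str | Path, coords: str | None = None) -> list[CnvCall]:
    """Read a per-accession CNV call table.

    The table is TSV with header accession/chrom/start/end/svtype. The
    coordinate dialect is declared on a leading ``#coords=0half`` or
    ``#coords=1incl`` comment line; a ``coords`` argument overrides it.
    1-based inclusive rows are converted to 0-based half-open. Rows whose
    interval is empty after conversion are skipped with a warning naming
    their line numbers.
    """
    path = Path(path)
    dialect = coords
    lines = path.read_text().splitlines()
    body_start = 0
    for ln in lines:
        if ln.startswith("#coords="):
            file_dialect = ln.split("=", 1)[1].strip()
            if dialect is None:
                dialect = file_dialect
            body_start += 1
        elif ln.startswith("#"):
            body_start += 1
        else:
            break
    if dialect is None:
        dialect = "0half"
    if dialect not in ("0half", "1incl"):
        raise FormatError(f"unknown coordinate dialect {dialect!r}")
    if body_start >= len(lines):
        raise FormatError(f"{path}: missing header line")
    header = lines[body_start].rstrip("\n").split("\t")
    if header != CALL_COLUMNS:
        raise FormatError(f"{path}: expected header {CALL_COLUMNS}, got {header}")

    calls: list[CnvCall] = []
    rejected: list[int] = []
    for lineno, ln in enumerate(lines[body_start + 1 :], start=body_start + 2):
        if not ln.strip():
            continue
        parts = ln.split("\t")
        if len(parts) != 5:
            raise FormatError(f"{path}: line {lineno}: expected 5 fields")
        acc, chrom, s, e, svtype = parts
        try:
            start, end = int(s), int(e)
        except ValueError as exc:
            raise FormatError(f"{path}: line {lineno}: malformed coordinates") from exc
        if dialect == "1incl":
            start -= 1
        if svtype not in SVTYPES:
            raise FormatError(f"{path}: line {lineno}: unknown svtype {svtype!r}")
        if end <= start or start < 0:
            rejected.append(lineno)
            continue
        calls.append(CnvCall(acc, chrom, start, end, svtype))
    if rejected:
        warnings.warn(
            f"{path}: rejected {len(rejected)} rows with empty intervals "
            f"(lines {rejected})",
            stacklevel=2,
        )
    return calls


def write_cnv_calls(calls: list[CnvCall], path: str | Path, coords: str = "0half") -> None:
    """Write a call table in the declared coordinate dialect."""
    if coords not in ("0half", "1incl"):
        raise ValueError(f"unknown coordinate dialect {coords!r}")
    off = 1 if coords == "1incl" else 0
    with open(path, "w") as fh:
        fh.write(f"#coords={coords}\n")
        fh.write("\t".join(CALL_COLUMNS) + "\n")
        for c in calls:
            fh.write(f"{c.accession}\t{c.chrom}\t{c.start + off}\t{c.end}\t{c.svtype}\n")


# ---------------------------------------------------------------------------
# CNVR VCF (recoded genotypes)

_VCF_HEADER = """\
##fileformat=VCFv4.2
##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">
##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">
##INFO=<ID=CNVCLASS,Number=1,Type=String,Description="CNVR event class: loss, gain or both">
##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">
"""


def write_cnvr_vcf(
    cnvrs: list[CnvrRecord],
    samples: list[str],
    path: str | Path,
    contigs: list[tuple[str, int]] | None = None,
) -> None:
    """Write CNVRs as one VCF 4.2 record each, with dosage-recoded genotypes.

    A loss carrier is emitted 0/1, a gain carrier 1/1 and a non-carrier 0/0;
    an accession carrying both events in one CNVR is emitted 1/1. In a
    "both"-class record loss and gain carriers coexist with their respective
    genotypes.
    """
    if len(set(samples)) != len(samples):
        raise ValueError("duplicate sample ids")
    sample_set = set(samples)
    for r in cnvrs:
        stray = set(r.carriers) - sample_set
        if stray:
            raise ValueError(f"CNVR {r.id}: carriers not in sample list: {sorted(stray)[:5]}")
    with open(path, "w") as fh:
        fh.write(_VCF_HEADER)
        for name, length in contigs or []:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples) + "\n")
        for r in sorted(cnvrs, key=lambda x: (x.chrom, x.start, x.end)):
            loss = set(r.loss_carriers())
            gain = set(r.gain_carriers())
            gts = []
            for s in samples:
                if s in gain:
                    gts.append("1/1")
                elif s in loss:
                    gts.append("0/1")
                else:
                    gts.append("0/0")
            info = f"SVTYPE=CNV;END={r.end};CNVCLASS={r.event_type}"
            fh.write(
                f"{r.chrom}\t{r.start + 1}\t{r.id}\tN\t<CNV>\t.\tPASS\t{info}\tGT\t"
                + "\t".join(gts)
                + "\n"
            )


def read_cnvr_vcf(path: str | Path) -> tuple[list[CnvrRecord], list[str]]:
    """Read a recoded CNVR VCF back into records.

    Genotype 0/1 maps to a loss carrier and 1/1 to a gain carrier; an
    accession that carried both events was emitted 1/1 and reads back as gain.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    cnvrs = []
    for v in vcf:
        carriers: dict[str, str] = {}
        for s, gt in zip(samples, v.genotypes):
            a, b = gt[0], gt[1]
            if a < 0 or b < 0:
                continue
            dose = a + b
            if dose == 1:
                carriers[s] = "loss"
            elif dose == 2:
                carriers[s] = "gain"
        rec = CnvrRecord(
            id=v.ID or f"cnvr_{v.CHROM}_{v.start}",
            chrom=v.CHROM,
            start=v.start,  # cyvcf2 start is 0-based
            end=int(v.INFO.get("END")),
            event_type=v.INFO.get("CNVCLASS"),
            carriers=carriers,
        )
        cnvrs.append(rec)
    vcf.close()
    return cnvrs, samples


# ---------------------------------------------------------------------------
# SNP VCF

def write_snp_vcf(g: GenotypeMatrix, path: str | Path, contigs: list[tuple[str, int]] | None = None) -> None:
    """Write a biallelic SNP genotype matrix as VCF 4.2 (unphased GTs)."""
    gt_of = {0: "0/0", 1: "0/1", 2: "1/1", MISSING: "./."}
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for name, length in contigs or []:
            fh.write(f"##contig=<ID={name},length={length}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(g.samples) + "\n")
        ref = g.markers["ref"] if "ref" in g.markers else pd.Series(["A"] * g.n_markers)
        alt = g.markers["alt"] if "alt" in g.markers else pd.Series(["T"] * g.n_markers)
        for i, row in enumerate(g.markers.itertuples(index=False)):
            gts = "\t".join(gt_of[int(d)] for d in g.dosage[i])
            fh.write(
                f"{row.chrom}\t{row.pos + 1}\t{row.id}\t{ref.iloc[i]}\t{alt.iloc[i]}\t.\tPASS\t.\tGT\t{gts}\n"
            )


def read_snp_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a sorted biallelic SNP VCF into a dosage matrix.

    Dosage is the alt-allele count; any missing allele makes the genotype
    missing. Multi-allelic records are rejected with a count. An unsorted
    file (positions not strictly increasing within a chromosome block)
    raises, since downstream nearest-SNP queries require sorted input.
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path), gts012=True)
    samples = list(vcf.samples)
    rows = []
    dosages = []
    n_multi = 0
    last: dict[str, int] = {}
    seen_order: list[str] = []
    for v in vcf:
        if len(v.ALT) != 1:
            n_multi += 1
            continue
        if v.CHROM not in last:
            seen_order.append(v.CHROM)
        elif seen_order[-1] != v.CHROM:
            raise FormatError(f"{path}: unsorted VCF: chromosome {v.CHROM} appears in two blocks")
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise FormatError(f"{path}: unsorted VCF at {v.CHROM}:{v.POS}")
        last[v.CHROM] = v.POS
        d = v.gt_types.astype(np.int16)
        d[d == 3] = MISSING
        rows.append((v.ID or f"{v.CHROM}_{v.POS}", v.CHROM, v.start, v.REF, v.ALT[0]))
        dosages.append(d)
    vcf.close()
    if n_multi:
        warnings.warn(f"{path}: rejected {n_multi} multi-allelic records", stacklevel=2)
    markers = pd.DataFrame(rows, columns=["id", "chrom", "pos", "ref", "alt"])
    dosage = np.vstack(dosages) if dosages else np.zeros((0, len(samples)), dtype=np.int16)
    return GenotypeMatrix(markers, samples, dosage)


# ---------------------------------------------------------------------------
# GFF3 / BED / chromosome sizes

def write_gff(genome: GenomeModel, path: str | Path) -> None:
    """Write gene annotation as GFF3 with gene/mRNA/exon/CDS hierarchy."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for name, length in genome.chromosomes:
            fh.write(f"##sequence-region {name} 1 {length}\n")
        for g in genome.genes:
            fh.write(
                f"{g.chrom}\tcnvpop\tgene\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={g.id}\n"
            )
            mrna = f"{g.id}.t1"
            fh.write(
                f"{g.chrom}\tcnvpop\tmRNA\t{g.start + 1}\t{g.end}\t.\t{g.strand}\t.\tID={mrna};Parent={g.id}\n"
            )
            for i, (s, e) in enumerate(g.exons, 1):
                fh.write(
                    f"{g.chrom}\tcnvpop\texon\t{s + 1}\t{e}\t.\t{g.strand}\t.\tID={mrna}.exon{i};Parent={mrna}\n"
                )
            for i, (s, e) in enumerate(g.cds, 1):
                fh.write(
                    f"{g.chrom}\tcnvpop\tCDS\t{s + 1}\t{e}\t.\t{g.strand}\t0\tID={mrna}.cds{i};Parent={mrna}\n"
                )


def read_gff_genes(path: str | Path) -> list[GeneFeature]:
    """Parse GFF3 genes with exon/CDS children (1-inclusive -> 0-half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique", keep_order=True
    )
    genes = []
    for g in db.features_of_type("gene"):
        exons = tuple(
            sorted((f.start - 1, f.end) for f in db.children(g, featuretype="exon"))
        )
        cds = tuple(
            sorted((f.start - 1, f.end) for f in db.children(g, featuretype="CDS"))
        )
        genes.append(
            GeneFeature(
                id=g.id, chrom=g.seqid, start=g.start - 1, end=g.end,
                strand=g.strand or "+", exons=exons, cds=cds,
            )
        )
    return genes


def write_bed(intervals: list[tuple[str, int, int]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, s, e in intervals:
            fh.write(f"{chrom}\t{s}\t{e}\n")


def read_bed(path: str | Path) -> list[tuple[str, int, int]]:
    """Read a 3+ column BED (already 0-based half-open)."""
    out = []
    for lineno, ln in enumerate(Path(path).read_text().splitlines(), 1):
        if not ln.strip() or ln.startswith(("#", "track", "browser")):
            continue
        parts = ln.split("\t")
        if len(parts) < 3:
            raise FormatError(f"{path}: line {lineno}: fewer than 3 BED columns")
        out.append((parts[0], int(parts[1]), int(parts[2])))
    return out


def write_chrom_sizes(genome: GenomeModel, path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, length in genome.chromosomes:
            fh.write(f"{name}\t{length}\n")


def read_chrom_sizes(path: str | Path) -> list[tuple[str, int]]:
    out = []
    for ln in Path(path).read_text().splitlines():
        if not ln.strip():
            continue
        name, length = ln.split("\t")
        out.append((name, int(length)))
    return out


# ---------------------------------------------------------------------------
# Truth tables (synthetic ground truth, file-based evaluation)

def write_truth(truth: SyntheticTruth, prefix: str | Path) -> None:
    """Write truth as three TSVs: <prefix>.loci.tsv, .carriers.tsv, .labels.tsv."""
    prefix = str(prefix)
    loci = pd.DataFrame(
        truth.planted_loci,
        columns=["chrom", "start", "end", "svtype", "freq_pop1", "freq_pop2"],
    )
    loci.insert(0, "locus", range(len(loci)))
    loci.to_csv(prefix + ".loci.tsv", sep="\t", index=False)
    rows = [(i, a) for i, accs in sorted(truth.carriers.items()) for a in accs]
    pd.DataFrame(rows, columns=["locus", "accession"]).to_csv(
        prefix + ".carriers.tsv", sep="\t", index=False
    )
    labels = pd.DataFrame(
        sorted(truth.population_labels.items()), columns=["accession", "population"]
    )
    labels.to_csv(prefix + ".labels.tsv", sep="\t", index=False)
    with open(prefix + ".meta.tsv", "w") as fh:
        fh.write("seed\t%d\n" % truth.seed)
        fh.write("differentiated_genes\t%s\n" % ",".join(truth.differentiated_genes))


def read_truth(prefix: str | Path) -> SyntheticTruth:
    prefix = str(prefix)
    loci = pd.read_csv(prefix + ".loci.tsv", sep="\t", float_precision="round_trip")
    carriers_df = pd.read_csv(prefix + ".carriers.tsv", sep="\t")
    labels = pd.read_csv(prefix + ".labels.tsv", sep="\t")
    meta = dict(
        ln.split("\t", 1) for ln in Path(prefix + ".meta.tsv").read_text().splitlines()
    )
    carriers: dict[int, list[str]] = {int(i): [] for i in loci["locus"]}
    for row in carriers_df.itertuples(index=False):
        carriers[int(row.locus)].append(str(row.accession))
    diff = [g for g in meta.get("differentiated_genes", "").split(",") if g]
    return SyntheticTruth(
        planted_loci=[
            (r.chrom, int(r.start), int(r.end), r.svtype, float(r.freq_pop1), float(r.freq_pop2))
            for r in loci.itertuples(index=False)
        ],
        population_labels=dict(zip(labels["accession"].astype(str), labels["population"])),
        carriers=carriers,
        differentiated_genes=diff,
        seed=int(meta["seed"]),
    )


# ---------------------------------------------------------------------------
# CN matrix / CNVR tables

def write_cn_matrix(cn: CnMatrix, path: str | Path, labels_path: str | Path | None = None) -> None:
    df = pd.DataFrame(cn.cn, index=cn.genes, columns=cn.accessions)
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.6g")
    if labels_path is not None:
        pd.DataFrame(
            sorted(cn.population_labels.items()), columns=["accession", "population"]
        ).to_csv(labels_path, sep="\t", index=False)


def read_cn_matrix(path: str | Path, labels_path: str | Path) -> CnMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    labels = pd.read_csv(labels_path, sep="\t")
    return CnMatrix(
        genes=list(df.index.astype(str)),
        accessions=list(df.columns.astype(str)),
        cn=df.to_numpy(),
        population_labels=dict(zip(labels["accession"].astype(str), labels["population"])),
    )


def write_cnvr_table(cnvrs: list[CnvrRecord], path: str | Path) -> None:
    rows = [
        (r.id, r.chrom, r.start, r.end, r.event_type, r.n_carriers, r.maf)
        for r in cnvrs
    ]
    pd.DataFrame(
        rows, columns=["id", "chrom", "start", "end", "type", "n_carriers", "maf"]
    ).to_csv(path, sep="\t", index=False)
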