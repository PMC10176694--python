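# Methods

`cnvpop` implements a population-scale copy-number-variation (CNV) analysis
for a two-population design — "cultivars" versus "wild relatives" in the
terminology used throughout — together with a synthetic-data generator that
reproduces the statistical structure the analysis assumes. This note records
the models, conventions, parameter choices and known limitations.

## Coordinates and formats

All in-memory coordinates are 0-based half-open. GFF3 and VCF are written and
read as 1-based inclusive; BED as 0-based half-open. CNV call tables (TSV)
declare their dialect on a `#coords=0half` or `#coords=1incl` comment line.
Chromosome names match by exact string equality — no `chr` aliasing.

## CNVR definition (`cnvr_core`)

A CNV is a deletion (DEL) or duplication (DUP) at least 50 bp long;
`filter_calls` applies the length floor inclusively (length ≥ 50; the choice
of inclusive boundary is a pinned configuration knob — the 1 bp difference is
immaterial but must be fixed).

`merge_to_cnvrs` merges calls across accessions into CNV regions (CNVRs)
under a 90% *reciprocal* overlap rule: calls are visited in
(chrom, start, end, accession) order; a call joins the open cluster iff its
intersection with the cluster's current union extent is at least 90% of both
the call length and the extent length, and the extent then grows to the
union. Reciprocal-overlap merging is ambiguous between clique and chain
semantics; this greedy extent-chaining reading is deterministic (the sort
order is the tie-break) and is validated against an independent restatement
of the same rule on random instances. CNVRs carried by fewer than ten
distinct accessions are dropped. An accession contributing both a DEL and a
DUP to one cluster counts once, with both event flags.

Event classes: *loss* if every carrier event is a deletion, *gain* if every
one is a duplication, *both* otherwise.

**Genotype recoding.** Each CNVR becomes one VCF record: loss carriers are
genotyped `0/1`, gain carriers `1/1`, non-carriers `0/0` (loss is recoded as
heterozygous regardless of true zygosity — the recoding is a bookkeeping
device, not a zygosity call). A carrier with both events is emitted `1/1`
(gain wins) — arbitrary but pinned. CNVR MAF follows directly: a loss
carrier contributes one alternate allele, a gain carrier two, out of
2 × n_samples alleles; CNVRs with MAF < 0.05 are filtered to match the SNP
criterion. The same recoding gives the CNVR "dosage" vector
(neutral 0, loss 1, gain 2) used for LD and PCA.

## CNVR–SNP linkage disequilibrium (`ld_linkage`)

For each CNVR the nearest 300 SNPs strictly upstream (pos < start) and 300
strictly downstream (pos ≥ end) with MAF > 5% are selected; SNPs inside the
CNVR interval are excluded, since they sit in the copy-variable sequence
itself. r² is the squared Pearson correlation of dosage vectors, computed
pairwise-complete over non-missing genotypes (PLINK's default behaviour) and
undefined when either vector is constant.

All SNP–SNP pairs among the selected set (up to C(600,2)) and all CNVR–SNP
pairs are pooled and ranked by decreasing r² with average ranks for ties.
N counts the CNVR–SNP pairs whose rank is strictly better (smaller) than the
median SNP–SNP rank. Classification: Low for N ≤ n/3, Mid for
n/3 < N ≤ 2n/3, High otherwise, where n is the achieved CNVR–SNP pair count —
identical to the 0–200 / 200–400 / 400–600 boundaries when the full 600 SNPs
exist, and scaled proportionally near chromosome ends rather than dropping
the CNVR. Whether the median is taken over ranks or over r² values is
ambiguous in principle; both counts are recorded (`N` and `N_by_value`) and
coincide whenever there are no ties. `max_snp_pairs` optionally subsamples
SNP–SNP pairs with a pinned seed for very large panels; the default uses all
pairs.

A practical caveat verified during development: the rank statistic is only
discriminative when the selected SNP window is narrow relative to the local
LD scale. If the 600-SNP window spans many independent LD blocks, the median
SNP–SNP r² collapses to the chance level (≈ 1/n_samples) and even an
unlinked CNVR ranks mid-pack. Test and acceptance panels therefore use SNP
densities where the window covers only a few blocks, as in a real
resequencing panel.

## Copy-number differentiation (`differentiation`)

Per gene, with one copy-number (CN) value per accession,

    Vst = (V_total − (V_cult·N_cult + V_wild·N_wild) / N_total) / V_total

where V are *population* variances (denominator = group size) and N are
group sizes. The N-denominator convention is the only one under which the
size-weighted within-group term is internally consistent; with it, the law
of total variance makes Vst exactly the between-group share of total
variance, hence confined to [0, 1] (0 = identical distributions, 1 =
complete differentiation). No clamping is applied anywhere — had sample
variances been used, slightly negative values could appear and would be
preserved. Vst is undefined (NaN, flagged) when the pooled variance is zero;
undefined genes are excluded from ranking but reported.

CN-differentiated genes are those at or above the empirical 0.99 quantile
(linear interpolation) of defined Vst values, ties at the cutoff included.
The wild group can be restricted to a named accession subset
(`wild_subset`), mirroring a restriction to particular progenitor species.
`group_cn_test` is the two-sided Wilcoxon rank-sum test in its normal
approximation with continuity correction (matching R's `wilcox.test`
default); identical-value inputs report p = 1 with a degeneracy flag.

## Annotation and feature impact (`annotation_impact`)

*CN-variable genes*: a gene qualifies when the union of CNVR intervals
covers **strictly more than** 50% of its span (plural CNVRs are unioned
before the fraction is taken).

*Feature impact*: calls are unioned per type first ("non-overlapping CNVs"),
then intersected with feature classes. Every base belongs to exactly one
class under the precedence CDS > exon > intron > flank upstream > flank
downstream > intergenic, so DEL/DUP base totals are conserved across
classes (verified exactly against per-base scanning). `gene_body`
(CDS + exon + intron) is reported as an additional, non-disjoint class.
Flank length defaults to 2 kb per side, strand-aware; the exact flank
definition behind published feature-impact figures is rarely stated, so this
is an explicit artifact choice, configurable.

*Windowed densities* count features by start coordinate in 1 Mb windows
(non-overlapping by default; a smaller step gives sliding windows; only
windows fully inside a chromosome are emitted). *Density correlation* is a
plain Pearson r with two-sided p on aligned tracks.

*Term enrichment* is a one-sided Fisher exact test (hypergeometric upper
tail) per term with Benjamini–Hochberg correction at α = 0.05. This is a
deliberate simplification of DAG-aware GO methods (topGO's `elim`): terms
are treated as flat gene sets supplied as a two-column mapping.

## Benchmarking (`sim_eval`)

`match_calls` scores calls against truth by greedy bipartite matching:
candidate pairs share a chromosome (and type, unless `type_strict=False`)
and overlap reciprocally at ≥ 50% (configurable); pairs are consumed
best-overlap-first with deterministic tie-breaks, each interval used at most
once. TPR = matched truth / all truth, FDR = unmatched calls / all calls,
with per-type breakdowns. Greedy best-first was chosen over optimal
assignment for determinism and interpretability; it is a maximal matching,
so it recovers at least half the optimum in the worst case and is provably
optimal whenever each call can overlap at most one truth interval (the
typical benchmarking geometry of well-separated loci) — both properties are
tested against a maximum-cardinality matching oracle. On dense, deeply
overlapping call sets greedy can fall below the optimum; counts are still
conserved (tp+fn = |truth|, tp+fp = |calls|).

## Population structure (`popstructure`)

Centered-dosage PCA via SVD of the sample × marker matrix. Monomorphic
markers are dropped (counted), missing dosages are mean-imputed per marker
(contributing zero to covariance), and an optional flag scales markers by
the binomial allele-frequency SD (eigenstrat-style normalisation) — the
qualitative claim of interest (two-population separation) is robust to the
normalisation. Eigenvector signs are fixed deterministically (the
largest-magnitude loading of each component is made positive) so scores are
bit-reproducible. `k` above the matrix rank is truncated with a warning;
an all-monomorphic matrix yields zero scores with a warning.

## Synthetic data (`synthetic_data`)

The generator emulates the structure the analysis assumes, with one explicit
integer seed per operation and no global RNG state (same seed ⇒ bit-identical
output).

- **Genome**: uniform random non-overlapping gene placement (spans uniform
  on [0.4, 1.6] × mean gene length, default mean 5 kb; 1–5 exons each,
  CDS = exons minus short terminal UTRs); infeasible packing raises. TEs
  (100 bp – 5 kb) are placed independently of genes until their summed
  length reaches the requested density, so realized coverage approximates
  the target.
- **CNV loci**: deletions with probability 10/11 by default (the strong
  deletion excess of real panels; configurable DEL:DUP ratio), lengths
  log-uniform on 100 bp – 50 kb (a modeling choice — real CNV length
  distributions are only known in coarse bins), placed non-overlapping with
  a jitter-sized buffer so distinct loci can never merge. Per-population
  carrier frequencies are drawn from configurable ranges or given
  explicitly per locus; carriers are independent Bernoulli draws. Each
  carrier call jitters both breakpoints by truncated Gaussians that
  preserve length ≥ min_len and ≥ 90% reciprocal overlap with the locus, so
  the planted truth stays consistent with the merge criterion. `on_genes`
  plants loci exactly on named gene spans, guaranteeing gene-level CN
  shifts. Genes overlapping a locus whose population frequencies differ by
  ≥ 0.5 are recorded as differentiated truth.
- **SNP haplotypes**: a founder-mosaic model (not a coalescent — the LD
  module only needs tunable block-wise r², not realistic genealogies).
  Each of the 2n haplotypes is a piecewise-constant mosaic of `n_founders`
  founder haplotypes with exponential(block_length) recombination spacing;
  founder alleles are Bernoulli(½) per site; sites failing the MAF floor
  are redrawn from an enlarged pool (bounded attempts, then an error).
  `linked_cnv_carriers` plants CNV alleles on founder subsets of the same
  mosaic, so CNVR–SNP LD arises through shared descent: alleles on more
  founders are commoner and better tagged, reproducing the positive
  MAF–LD relationship of real panels.
- **CN matrix**: baseline 2.0 per gene and accession; carriers of a
  deletion (duplication) locus shift every overlapped gene by −1 (+1);
  Gaussian noise (default SD 0.2 CN units) is added and values clipped
  at 0.

What the generator does *not* emulate: read-level signal (no FASTQ/depth
modelling — caller performance versus sequencing depth is out of scope),
TE-coupled CNV placement (TE tracks are independent of CNV loci, so
TE–CNVR density correlations are near zero by construction, unlike the
strong enrichment reported in real genomes), population structure in the
SNP mosaic (both populations share one founder pool; PCA separation comes
from the planted CNVR frequency differences), and locus-length/frequency
correlations. Passing tests therefore demonstrate correctness of the
statistics and the merge/match/recode machinery under the stated model, not
calling accuracy on real reads.

## Problem sizes and numerical choices

The test suite and the acceptance script run desk-scale studies: genomes of
2 × 5 Mb with 500 genes, panels of ~100 accessions (a 5:1 cultivar:wild
ratio, 96/19, in the acceptance study), 60 planted loci with 20 bp
breakpoint jitter, 3000-SNP LD panels, and 20-seed repetitions for the
differentiation-recovery rate. Vst fixtures are checked to 1e-12; interval
arithmetic is checked exactly (integer base counts); PCA orthogonality to
1e-8. With 20 bp jitter and the strict 90% reciprocal rule, short loci
occasionally split into two CNVRs, which depresses the merge TPR/FDR a few
points below perfect — an inherent property of reciprocal-overlap merging,
not a defect of the implementation.
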