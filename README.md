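# cnvpop

Population-scale copy-number-variation (CNV) analysis for two-population
resequencing panels — the kind of design that compares crop cultivars with
their wild relatives.

Structural-variant callers emit per-accession deletion/duplication calls;
the population-level questions start after that. `cnvpop` covers the
downstream analysis:

- **CNVR definition** — merge per-accession CNV calls (≥ 50 bp) into CNV
  regions under a 90% reciprocal-overlap rule, classify them loss / gain /
  both, drop regions carried by fewer than ten accessions, and recode each
  CNVR to VCF genotypes (loss → `0/1`, neutral → `0/0`, gain → `1/1`) with
  a MAF ≥ 0.05 filter.
- **CNVR–SNP linkage disequilibrium** — for each CNVR, pool r² of the
  nearest 300 SNPs per side (SNP–SNP and CNVR–SNP pairs), rank by
  decreasing r², and count how often the CNVR ranks above the SNP–SNP
  median rank (N). Low-LD: N ≤ 200, Mid: 200 < N ≤ 400, High: 400 < N ≤ 600
  at the full 600 SNPs (thresholds scale to thirds elsewhere).
- **Copy-number differentiation** — per-gene
  V<sub>st</sub> = (V<sub>total</sub> − (V₁N₁ + V₂N₂)/N<sub>total</sub>) / V<sub>total</sub>
  between the two populations (population variances), with the top 1% of
  genes called CN-differentiated, plus Wilcoxon rank-sum group comparisons.
- **Annotation impact** — CN-variable genes (gene span covered > 50% by
  CNVRs), per-feature-class deletion/duplication base-pair percentages
  (CDS / exon / intron / flanks / intergenic), windowed feature densities
  with Pearson track correlations, TE overlap, and Fisher + Benjamini–
  Hochberg term enrichment.
- **Population structure** — deterministic centered-dosage PCA of SNP or
  recoded-CNVR genotypes.
- **Benchmarking** — TP/FP/FN, TPR and FDR of a call set against a truth
  set by reciprocal-overlap matching.
- **Synthetic data** — a generator for genomes, two-population CNV call
  sets with planted loci and breakpoint jitter, founder-mosaic SNP
  haplotypes with block-wise LD (and haplotype-linked CNV alleles), and
  gene × accession copy-number matrices with known ground truth.

See `docs/methods.md` for the full model description and conventions.

## Worked example

```python
from cnvpop import synthetic_data as sd, cnvr_core, differentiation as dif, sim_eval

genome = sd.simulate_genome(2, 5_000_000, 300, 0.3, seed=1)
calls, truth = sd.simulate_population_cnvs(
    genome, n_pop1=60, n_pop2=30, n_loci=25,
    freq_spec=((0.2, 0.9), (0.2, 0.9)), jitter_sd=20.0, seed=2,
)
samples = list(truth.population_labels)
kept, report = cnvr_core.filter_calls(calls, min_len=50)
cnvrs = cnvr_core.merge_to_cnvrs(kept, reciprocal=0.9, min_carriers=10, samples=samples)
print(f"{len(calls)} calls -> {len(cnvrs)} CNVRs")

score = sim_eval.match_calls(sim_eval.truth_to_calls(truth),
                             sim_eval.cnvrs_to_calls(cnvrs), reciprocal=0.5)
print(f"TPR {score.tpr:.2f}, FDR {score.fdr:.2f}")

cnm = sd.simulate_cn_matrix(genome, truth, noise_sd=0.2, seed=3)
top = dif.top_percentile_genes(dif.vst_scan(cnm), pct=0.01)
print(f"{len(top)} CN-differentiated genes (top 1% Vst): {sorted(top)}")
```

prints

```
1256 calls -> 33 CNVRs
TPR 0.88, FDR 0.33
3 CN-differentiated genes (top 1% Vst): ['gene00093', 'gene00160', 'gene00161']
```

1,256 per-accession calls over 25 planted loci collapse to 33 CNVRs (33
rather than 25 because 20 bp breakpoint jitter occasionally splits a short
locus under the strict 90% reciprocal rule, and loci with fewer than ten
carriers are dropped — hence TPR below 1 and a nonzero FDR against the
planted truth). The three CN-differentiated genes are the genes overlapped
by the most frequency-differentiated planted loci.

The same steps are available from the shell:

```bash
cnvpop simulate --seed 1 --out-prefix study
cnvpop merge --calls study.calls.tsv --out-table cnvrs.tsv --out-vcf cnvrs.vcf
cnvpop ld --snps study.snps.vcf --cnvr-vcf cnvrs.vcf --out ld.tsv
cnvpop vst --cn study.cn.tsv --labels study.labels.tsv --out vst.tsv
cnvpop evaluate --truth study.calls.tsv --calls study.calls.tsv --out eval.tsv
cnvpop pca --vcf cnvrs.vcf --k 3 --out pca.tsv
```

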