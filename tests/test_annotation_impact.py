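"""Interval arithmetic vs per-base scanning, densities, enrichment oracles."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cnvpop import _intervals as iv
from cnvpop import annotation_impact as ai
from cnvpop.model import CnvCall, CnvrRecord, GeneFeature, GenomeModel


def interval_strategy():
    return st.lists(
        st.tuples(st.integers(0, 200), st.integers(1, 40)).map(lambda t: (t[0], t[0] + t[1])),
        max_size=12,
    )


class TestIntervalOps:
    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(a=interval_strategy(), b=interval_strategy())
    def test_ops_match_per_base_sets(self, a, b):
        sa = set().union(*[set(range(s, e)) for s, e in a]) if a else set()
        sb = set().union(*[set(range(s, e)) for s, e in b]) if b else set()
        assert iv.total_length(iv.merge(a)) == len(sa)
        assert iv.total_length(iv.intersect(iv.merge(a), iv.merge(b))) == len(sa & sb)
        assert iv.total_length(iv.subtract(a, b)) == len(sa - sb)

    def test_reciprocal_overlap(self):
        assert iv.reciprocal_overlap((0, 1000), (500, 1500)) == pytest.approx(0.5)
        assert iv.reciprocal_overlap((0, 10), (20, 30)) == 0.0


def _cnvr(chrom, s, e, i=0):
    return CnvrRecord(f"c{i}", chrom, s, e, "loss", {"S0": "loss"})


class TestCnVariableGenes:
    def test_just_over_half(self):
        gene = GeneFeature("g1", "chr1", 0, 1000)
        assert ai.cn_variable_genes([gene], [_cnvr("chr1", 0, 501)]) == {
            "g1": pytest.approx(0.501)
        }
        # exactly half is excluded (strict threshold)
        assert ai.cn_variable_genes([gene], [_cnvr("chr1", 0, 500)]) == {}

    def test_union_of_two_cnvrs(self):
        gene = GeneFeature("g1", "chr1", 0, 1000)
        cnvrs = [_cnvr("chr1", 0, 300, 0), _cnvr("chr1", 200, 550, 1)]
        assert ai.cn_variable_genes([gene], cnvrs) == {"g1": pytest.approx(0.55)}

    def test_fully_contained_gene(self):
        gene = GeneFeature("g1", "chr1", 100, 200)
        assert ai.cn_variable_genes([gene], [_cnvr("chr1", 0, 1000)]) == {"g1": 1.0}

    def test_monotone_in_threshold(self, small_genome, population_study):
        from cnvpop.cnvr_core import merge_to_cnvrs

        calls, _ = population_study
        cnvrs = merge_to_cnvrs(calls)
        loose = set(ai.cn_variable_genes(small_genome.genes, cnvrs, min_frac=0.3))
        strict = set(ai.cn_variable_genes(small_genome.genes, cnvrs, min_frac=0.7))
        assert strict <= loose


def per_base_impact(genome, calls, flank_bp):
    """Brute-force per-base class assignment and CNV coverage counting."""
    impacts = {}
    for chrom, length in genome.chromosomes:
        cds = np.zeros(length, bool)
        exon = np.zeros(length, bool)
        gene = np.zeros(length, bool)
        up = np.zeros(length, bool)
        down = np.zeros(length, bool)
        for g in genome.genes:
            if g.chrom != chrom:
                continue
            gene[g.start:g.end] = True
            for s, e in g.exons:
                exon[s:e] = True
            for s, e in g.cds:
                cds[s:e] = True
            lo, hi = (g.start - flank_bp, g.start) if g.strand == "+" else (g.end, g.end + flank_bp)
            up[max(0, lo):max(0, min(length, hi))] = True
            lo, hi = (g.end, g.end + flank_bp) if g.strand == "+" else (g.start - flank_bp, g.start)
            down[max(0, lo):max(0, min(length, hi))] = True
        masks = {  # precedence CDS > exon > intron > flank up > flank down
            "CDS": cds,
            "exon": exon & ~cds,
            "intron": gene & ~exon & ~cds,
            "flank_upstream": up & ~gene,
            "flank_downstream": down & ~up & ~gene,
        }
        masks["intergenic"] = ~np.any(list(masks.values()), axis=0)
        cov = {"DEL": np.zeros(length, bool), "DUP": np.zeros(length, bool)}
        for c in calls:
            if c.chrom == chrom:
                cov[c.svtype][c.start:c.end] = True
        for name in ai.DISJOINT_CLASSES:
            mask = masks[name]
            d = impacts.setdefault(name, [0, 0, 0])
            d[0] += int(mask.sum())
            d[1] += int((mask & cov["DEL"]).sum())
            d[2] += int((mask & cov["DUP"]).sum())
    return impacts


class TestFeatureImpact:
    def test_no_calls_all_zero(self, small_genome):
        for fi in ai.feature_impact(small_genome, []):
            assert fi.del_pct == 0.0 and fi.dup_pct == 0.0

    def test_whole_chromosome_deletion(self):
        gene = GeneFeature("g1", "chr1", 4000, 6000, exons=((4000, 6000),))
        genome = GenomeModel([("chr1", 10_000)], [gene])
        call = CnvCall("S1", "chr1", 0, 10_000, "DEL")
        for fi in ai.feature_impact(genome, [call]):
            if fi.total_bp:
                assert fi.del_pct == pytest.approx(100.0)
            assert fi.dup_pct == 0.0

    def test_hand_built_exon_half_covered(self):
        # 10 kb genome, one 2 kb gene with 1 kb exon starting at the gene start
        gene = GeneFeature("g1", "chr1", 1000, 3000, exons=((1000, 2000),))
        genome = GenomeModel([("chr1", 10_000)], [gene])
        call = CnvCall("S1", "chr1", 500, 1500, "DEL")
        by_class = {f.feature_class: f for f in ai.feature_impact(genome, [call])}
        assert by_class["exon"].del_pct == pytest.approx(50.0)
        assert by_class["gene_body"].del_bp == 500

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_per_base_scanning(self, seed):
        from cnvpop import synthetic_data as sd

        genome = sd.simulate_genome(
            1, 100_000, 8, 0.0, seed=seed, mean_gene_length=3000
        )
        rng = np.random.default_rng(seed + 100)
        calls = []
        for i in range(25):
            s = int(rng.integers(0, 95_000))
            e = s + int(rng.integers(100, 5000))
            calls.append(CnvCall(f"S{i}", "chr1", s, min(e, 100_000), "DEL" if rng.random() < 0.7 else "DUP"))
        got = {f.feature_class: f for f in ai.feature_impact(genome, calls, flank_bp=1500)}
        want = per_base_impact(genome, calls, flank_bp=1500)
        for name, (total, dele, dup) in want.items():
            assert got[name].total_bp == total, name
            assert got[name].del_bp == dele, name
            assert got[name].dup_bp == dup, name

    def test_base_conservation(self, small_genome, population_study):
        calls, _ = population_study
        fis = {f.feature_class: f for f in ai.feature_impact(small_genome, calls)}
        # disjoint classes partition the genome
        assert sum(fis[c].total_bp for c in ai.DISJOINT_CLASSES) == small_genome.total_length
        # and conserve the DEL union length
        del_union = sum(
            iv.total_length([(c.start, c.end) for c in calls if c.svtype == "DEL" and c.chrom == chrom])
            for chrom, _ in small_genome.chromosomes
        )
        assert sum(fis[c].del_bp for c in ai.DISJOINT_CLASSES) == del_union


class TestWindowDensity:
    def test_single_feature_in_second_window(self):
        genome = GenomeModel([("chr1", 3_000_000)])
        df = ai.window_density([("chr1", 1_500_000)], genome)
        assert df["count"].tolist() == [0, 1, 0]

    def test_empty(self):
        genome = GenomeModel([("chr1", 2_000_000)])
        df = ai.window_density([], genome)
        assert (df["count"] == 0).all()

    def test_sliding_window_count(self):
        genome = GenomeModel([("chr1", 3_000_000)])
        df = ai.window_density([], genome, window_bp=1_000_000, step_bp=500_000)
        assert len(df) == 5

    def test_start_coordinate_assignment(self):
        genome = GenomeModel([("chr1", 2_000_000)])
        # interval starting at 999_999 belongs to window 1 even if it extends on
        df = ai.window_density([("chr1", 999_999)], genome)
        assert df["count"].tolist() == [1, 0]


class TestDensityCorrelation:
    def test_identical_tracks(self):
        a = np.array([1.0, 2, 3, 4])
        r, p = ai.density_correlation(a, a)
        assert r == pytest.approx(1.0)

    def test_anticorrelated(self):
        a = np.array([1.0, 2, 3, 4])
        r, _ = ai.density_correlation(a, -a)
        assert r == pytest.approx(-1.0)

    def test_matches_hand_covariance(self):
        a = np.array([1.0, 3, 2, 5])
        b = np.array([2.0, 1, 4, 3])
        expected = np.mean((a - a.mean()) * (b - b.mean())) / (a.std() * b.std())
        r, _ = ai.density_correlation(a, b)
        assert r == pytest.approx(expected, abs=1e-12)


def hypergeom_tail_oracle(k, M, K, n):
    """P[X >= k] by explicit enumeration of the hypergeometric pmf."""
    total = 0.0
    for x in range(k, min(K, n) + 1):
        total += math.comb(K, x) * math.comb(M - K, n - x) / math.comb(M, n)
    return total


class TestTermEnrichment:
    def test_perfect_enrichment_matches_oracle(self):
        universe = {f"g{i}" for i in range(100)}
        study = {f"g{i}" for i in range(10)}
        term_map = {"T1": set(study)}
        df = ai.term_enrichment(study, universe, term_map)
        expected = hypergeom_tail_oracle(10, 100, 10, 10)
        assert df.loc[0, "p_value"] == pytest.approx(expected, rel=1e-9)
        assert expected == pytest.approx(1 / math.comb(100, 10), rel=1e-9)

    def test_disjoint_term_p_near_one(self):
        universe = {f"g{i}" for i in range(30)}
        study = {f"g{i}" for i in range(5)}
        term_map = {"T1": {f"g{i}" for i in range(10, 14)}}
        df = ai.term_enrichment(study, universe, term_map)
        assert df.loc[0, "p_value"] == pytest.approx(
            hypergeom_tail_oracle(0, 30, 4, 5), rel=1e-9
        )
        assert df.loc[0, "p_value"] == pytest.approx(1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_random_small_universes_match_oracle(self, seed):
        rng = np.random.default_rng(seed)
        M = int(rng.integers(8, 26))
        universe = {f"g{i}" for i in range(M)}
        study = set(rng.choice(sorted(universe), size=int(rng.integers(1, M // 2 + 1)), replace=False))
        term_map = {
            f"T{j}": set(rng.choice(sorted(universe), size=int(rng.integers(1, M)), replace=False))
            for j in range(4)
        }
        df = ai.term_enrichment(study, universe, term_map).set_index("term")
        for term, genes in term_map.items():
            k = len(genes & study)
            expected = hypergeom_tail_oracle(k, M, len(genes), len(study))
            assert df.loc[term, "p_value"] == pytest.approx(expected, rel=1e-9)

    def test_bh_step_up_hand_arithmetic(self):
        universe = {f"g{i}" for i in range(100)}
        study = {f"g{i}" for i in range(10)}
        # four nested terms producing increasing p-values
        term_map = {
            "T1": {f"g{i}" for i in range(10)},
            "T2": {f"g{i}" for i in range(5)} | {f"g{i}" for i in range(50, 60)},
            "T3": {f"g{i}" for i in range(3)} | {f"g{i}" for i in range(50, 80)},
            "T4": {f"g{i}" for i in range(90, 95)},
        }
        df = ai.term_enrichment(study, universe, term_map)
        p = df["p_value"].to_numpy()
        order = np.argsort(p)
        m = len(p)
        # BH step-up by hand
        adj = np.empty(m)
        prev = 1.0
        for rank_idx in range(m - 1, -1, -1):
            i = order[rank_idx]
            prev = min(prev, p[i] * m / (rank_idx + 1))
            adj[i] = prev
        assert np.allclose(df["p_adjusted"].to_numpy(), adj)

    def test_study_must_be_subset(self):
        with pytest.raises(ValueError):
            ai.term_enrichment({"x"}, {"y"}, {})

    def test_empty_term_skipped(self):
        universe = {"a", "b"}
        df = ai.term_enrichment({"a"}, universe, {"T": {"z"}})
        assert df.empty and df.attrs["skipped_terms"] == ["T"]


class TestTeOverlap:
    def test_no_tes(self):
        assert ai.te_overlap_fraction([_cnvr("chr1", 0, 100)], []) == 0.0

    def test_all_inside(self):
        cnvrs = [_cnvr("chr1", 10, 20, 0), _cnvr("chr1", 30, 40, 1)]
        assert ai.te_overlap_fraction(cnvrs, [("chr1", 0, 100)]) == 1.0

    def test_three_of_four(self):
        cnvrs = [
            _cnvr("chr1", 0, 100, 0),
            _cnvr("chr1", 200, 300, 1),
            _cnvr("chr1", 400, 500, 2),
            _cnvr("chr2", 0, 100, 3),
        ]
        tes = [("chr1", 50, 250), ("chr1", 450, 460)]
        assert ai.te_overlap_fraction(cnvrs, tes) == pytest.approx(0.75)
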