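import numpy as np
import pytest
from scipy import stats

from tsdmeth.annotation import (
    CGIAnnotation,
    DensityTile,
    GeneModel,
    annotate_cgi_classes,
    annotate_loci,
    enrichment_test,
    find_cgis,
    gene_context,
    mean_meth_bin,
    nearest_gene,
    read_gene_table,
    tile_cpg_density,
    write_gene_table,
)
from tsdmeth.io import CpGLocus


# ---------------------------------------------------------------------------
# exhaustive per-position island oracle (naive loops, no vectorization)


def oracle_cgis(seq, window=100, minlen=200, min_oe=0.6, min_gc=50.0):
    seq = seq.upper()
    L = len(seq)
    flagged = [False] * L
    for start in range(0, L - window + 1):
        w = seq[start : start + window]
        n_c = w.count("C")
        n_g = w.count("G")
        n_cg = sum(1 for i in range(window - 1) if w[i : i + 2] == "CG")
        gc = 100.0 * (n_c + n_g) / window
        oe = (n_cg * window) / (n_c * n_g) if n_c * n_g > 0 else 0.0
        if gc >= min_gc and oe >= min_oe:
            for i in range(start, start + window):
                flagged[i] = True
    islands, i = [], 0
    while i < L:
        if flagged[i]:
            j = i
            while j < L and flagged[j]:
                j += 1
            if j - i >= minlen:
                islands.append((i, j))
            i = j
        else:
            i += 1
    return islands


class TestFindCGIs:
    def test_poly_a_has_no_islands(self):
        assert find_cgis("A" * 300) == []

    def test_short_sequence_is_empty(self):
        assert find_cgis("CG" * 20) == []

    def test_cg_tract_yields_one_island_covering_tract(self):
        seq = "A" * 200 + "CG" * 120 + "A" * 200
        islands = find_cgis(seq)
        assert len(islands) == 1
        (s, e) = islands[0]
        assert e - s >= 200
        assert s <= 200 and e >= 200 + 240
        assert islands == oracle_cgis(seq)

    def test_oe_formula_on_pure_cg(self):
        # 240 bp of CG repeats in a 100-bp window: 50 C, 50 G, 99 CG starts
        # in-window would be 49 fully inside -> oe = 49*100/2500 = 1.96 >= 0.6
        seq = "CG" * 120
        islands = find_cgis(seq, minlen=100)
        assert islands and islands[0] == (0, 240)

    def test_matches_oracle_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for gc in (0.4, 0.55, 0.7):
            seq = "".join(
                rng.choice(list("ACGT"), p=[(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2], size=1500)
            )
            assert find_cgis(seq) == oracle_cgis(seq)

    def test_n_bases_break_cg_dinucleotides(self):
        seq = ("CG" * 50 + "N" * 0) * 1
        with_n = "C" + "N" + seq + "A" * 100
        assert find_cgis(with_n, minlen=90) == oracle_cgis(with_n, minlen=90)


class TestCGIClasses:
    @pytest.fixture()
    def annotation(self):
        seq = "A" * 5000 + "CG" * 150 + "A" * 10000
        return annotate_cgi_classes({"s1": seq})

    def test_classes_partition_scaffold(self, annotation):
        total = 0
        for name in ("islands", "shores", "shelves", "open_sea"):
            for s, e in getattr(annotation, name)["s1"]:
                total += e - s
        assert total == annotation.scaffold_lengths["s1"]

    def test_context_precedence_by_distance(self, annotation):
        (isl_s, isl_e) = annotation.islands["s1"][0]
        assert annotation.context(CpGLocus("s1", (isl_s + isl_e) // 2)) == "island"
        assert annotation.context(CpGLocus("s1", isl_e + 1500)) == "shore"
        assert annotation.context(CpGLocus("s1", isl_e + 3500)) == "shelf"
        assert annotation.context(CpGLocus("s1", isl_e + 4500)) == "open_sea"

    def test_partition_holds_on_random_genomes(self):
        rng = np.random.default_rng(5)
        seq = "".join(rng.choice(list("ACGT"), p=[0.2, 0.3, 0.3, 0.2], size=8000))
        ann = annotate_cgi_classes({"r": seq})
        covered = np.zeros(8000, dtype=int)
        for name in ("islands", "shores", "shelves", "open_sea"):
            for s, e in getattr(ann, name)["r"]:
                covered[s:e] += 1
        assert (covered == 1).all()


class TestGeneContext:
    @pytest.fixture()
    def genes(self):
        # gene A: [1000, 4000) on +, exons [1000,1500) [2000,2500) [3500,4000)
        # gene B: [3200, 9000) on +, intron everywhere in [3200, 4200)
        a = GeneModel("A", "s1", "+", 1000, 4000, [(1000, 1500), (2000, 2500), (3500, 4000)])
        b = GeneModel("B", "s1", "+", 3200, 9000, [(8000, 9000)])
        return [a, b]

    def test_promoter_takes_precedence_over_intron(self, genes):
        # 500 lies in A's promoter [0, 1200) and nothing else
        assert gene_context(CpGLocus("s1", 500), genes) == "promoter"
        # 3600 is exon of A and intron of B -> exon
        assert gene_context(CpGLocus("s1", 3600), genes) == "exon"

    def test_intron_between_exons(self, genes):
        assert gene_context(CpGLocus("s1", 1700), genes) == "intron"

    def test_exon_halfopen_end_is_intron(self, genes):
        assert gene_context(CpGLocus("s1", 1500), genes) == "intron"

    def test_gene_free_scaffold_is_intergenic(self, genes):
        assert gene_context(CpGLocus("s2", 500), genes) == "intergenic"

    def test_minus_strand_promoter_is_downstream_of_tx_end(self):
        g = GeneModel("C", "s1", "-", 1000, 4000, [(1000, 4000)])
        assert gene_context(CpGLocus("s1", 4500), [g]) == "promoter"
        assert gene_context(CpGLocus("s1", 500), [g]) == "intergenic"

    def test_gene_table_round_trip(self, genes, tmp_path):
        f = tmp_path / "genes.tsv"
        write_gene_table(genes, f)
        back = read_gene_table(f)
        assert [(g.gene_id, g.tx_start, g.exons) for g in back] == [
            (g.gene_id, g.tx_start, g.exons) for g in genes
        ]


class TestNearestGene:
    def test_inside_gene_distance_zero(self):
        g = GeneModel("A", "s1", "+", 1000, 2000, [(1000, 2000)])
        assert nearest_gene(CpGLocus("s1", 1500), [g]) == ("A", 0)

    def test_halfopen_downstream_distance(self):
        g = GeneModel("A", "s1", "+", 1000, 2000, [(1000, 2000)])
        assert nearest_gene(CpGLocus("s1", 2500), [g]) == ("A", 500)

    def test_equidistant_tie_breaks_to_lower_start(self):
        a = GeneModel("zzz", "s1", "+", 0, 1000, [(0, 1000)])
        b = GeneModel("aaa", "s1", "+", 2000, 3000, [(2000, 3000)])
        # locus 1500: 500 downstream of a (1500-1000), 500 upstream of b
        assert nearest_gene(CpGLocus("s1", 1500), [a, b]) == ("zzz", 500)

    def test_empty_scaffold_returns_none(self):
        g = GeneModel("A", "s1", "+", 0, 100, [(0, 100)])
        assert nearest_gene(CpGLocus("s2", 50), [g]) is None


class TestDensityTiles:
    def test_poly_a_tile_is_empty(self):
        tiles = tile_cpg_density({"s": "A" * 1000})
        assert tiles == [DensityTile("s", 0, 1000, 0)]
        assert tiles[0].density_bin == 0

    def test_pure_cg_tile_count_and_bin(self):
        (tile,) = tile_cpg_density({"s": "CG" * 500})
        assert tile.cpg_count == 500 and tile.density_bin == 25

    def test_tile_counts_sum_to_genome_cg_total(self):
        rng = np.random.default_rng(2)
        seq = "".join(rng.choice(list("ACGT"), size=5432))
        tiles = tile_cpg_density({"s": seq})
        total = sum(1 for i in range(len(seq) - 1) if seq[i : i + 2] == "CG")
        assert sum(t.cpg_count for t in tiles) == total
        assert tiles[-1].end == 5432


class TestMeanMethBin:
    def test_binning_rules(self):
        X = np.array([[90.0, 90.0], [20.0, 20.0], [0.0, 0.0], [np.nan, np.nan], [20.1, 20.1]])
        bins = mean_meth_bin(X)
        assert list(bins) == ["80-100", "0-20", "0-20", None, "20-40"]

    def test_mean_over_nonmissing_only(self):
        bins = mean_meth_bin(np.array([[np.nan, 90.0]]))
        assert bins[0] == "80-100"


# ---------------------------------------------------------------------------
# hypergeometric enumeration oracle for the two-sided Fisher test


def oracle_fisher(a, b, c, d):
    from math import comb

    n, r1, c1 = a + b + c + d, a + b, a + c
    def prob(x):
        return comb(r1, x) * comb(n - r1, c1 - x) / comb(n, c1)

    p_obs = prob(a)
    lo, hi = max(0, c1 - (n - r1)), min(r1, c1)
    return sum(prob(x) for x in range(lo, hi + 1) if prob(x) <= p_obs * (1 + 1e-9))


class TestEnrichment:
    def test_balanced_table_is_null(self):
        df = enrichment_test({"in": 5, "out": 5}, {"in": 5, "out": 5})
        row = df.set_index("category").loc["in"]
        assert row["odds_ratio"] == pytest.approx(1.0)
        assert row["p"] == pytest.approx(1.0)

    def test_matches_hypergeometric_enumeration(self):
        df = enrichment_test({"in": 8, "out": 2}, {"in": 2, "out": 8})
        row = df.set_index("category").loc["in"]
        assert row["p"] == pytest.approx(oracle_fisher(8, 2, 2, 8), rel=1e-9)
        assert row["p"] == pytest.approx(0.02301413756522116, rel=1e-9)

    def test_swapping_rows_inverts_odds_ratio(self):
        d1 = enrichment_test({"in": 8, "out": 2}, {"in": 2, "out": 8}).set_index("category")
        d2 = enrichment_test({"in": 2, "out": 8}, {"in": 8, "out": 2}).set_index("category")
        assert d1.loc["in", "odds_ratio"] == pytest.approx(1 / d2.loc["in", "odds_ratio"])
        assert d1.loc["in", "p"] == pytest.approx(d2.loc["in", "p"])

    def test_zero_margin_is_degenerate(self):
        df = enrichment_test({"in": 0, "out": 0}, {"in": 5, "out": 5})
        assert (df["p"] == 1.0).all()

    def test_planted_island_enrichment_detected(self):
        rng = np.random.default_rng(6)
        # background: 10% island; DMCs drawn preferentially from islands
        bg = {"island": 100, "open_sea": 900}
        dmc = {"island": int(rng.binomial(50, 0.5)), "open_sea": 0}
        dmc["open_sea"] = 50 - dmc["island"]
        df = enrichment_test(dmc, bg).set_index("category")
        assert df.loc["island", "odds_ratio"] > 1
        assert df.loc["island", "q"] < 0.05


class TestAnnotateLoci:
    def test_all_layers_tabulated(self):
        seq = "A" * 3000 + "CG" * 150 + "A" * 3000
        cgi = annotate_cgi_classes({"s1": seq})
        genes = [GeneModel("A", "s1", "+", 1000, 2000, [(1000, 2000)])]
        tiles = tile_cpg_density({"s1": seq})
        loci = [CpGLocus("s1", 1500), CpGLocus("s1", 3100)]
        df = annotate_loci(loci, genes=genes, cgi=cgi, tiles=tiles)
        assert list(df["gene_context"]) == ["exon", "intergenic"]
        assert df.loc[1, "cgi_context"] == "island"
        assert df.loc[0, "nearest_gene_distance"] == 0
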