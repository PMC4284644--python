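from math import comb

import numpy as np
import pandas as pd
import pytest

from twindmr.enrichment import (annotate_dmrs_to_genes, gene_level_pvalues,
                                gene_set_fisher, gwas_windows, promoter_intervals,
                                rank_resampling_test, region_overlap_fisher,
                                tss_proximity_test)
from twindmr.errors import ConfigurationError, DataError
from twindmr.quantify import bin_ids


def hypergeom_tail_oracle(x, N, K, n):
    """P(X >= x) by exact integer summation of the hypergeometric pmf."""
    denom = comb(N, n)
    return sum(comb(K, k) * comb(N - K, n - k) for k in range(x, min(K, n) + 1)) / denom


def make_genes(rows):
    df = pd.DataFrame(rows, columns=["gene_id", "chrom", "strand", "start", "end"])
    df["tss"] = np.where(df["strand"] == "+", df["start"], df["end"] - 1)
    return df[["gene_id", "chrom", "strand", "tss", "start", "end"]]


def make_dmrs(rows):
    df = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    df["bin"] = bin_ids(df)
    return df


class TestAnnotation:
    def test_upstream_promoter_is_strand_aware(self):
        genes = make_genes([("g1", "chr1", "+", 100_000, 150_000)])
        # 15 kb upstream of a + strand TSS -> extended promoter
        dmr_up = make_dmrs([("chr1", 84_800, 85_300)])
        out = annotate_dmrs_to_genes(dmr_up, genes)
        assert list(out["cls"]) == ["promoter"]
        # same distance downstream of the gene end -> intergenic
        dmr_down = make_dmrs([("chr1", 164_800, 165_300)])
        out = annotate_dmrs_to_genes(dmr_down, genes)
        assert list(out["cls"]) == ["intergenic"]

    def test_minus_strand_downstream_is_intergenic(self):
        genes = make_genes([("g1", "chr1", "-", 100_000, 150_000)])
        # "downstream" of a - strand gene is the low-coordinate side
        out = annotate_dmrs_to_genes(make_dmrs([("chr1", 84_800, 85_300)]), genes)
        assert list(out["cls"]) == ["intergenic"]
        # upstream (high-coordinate side) within 20 kb is promoter
        out = annotate_dmrs_to_genes(make_dmrs([("chr1", 164_800, 165_300)]), genes)
        assert list(out["cls"]) == ["promoter"]

    def test_gene_body_takes_precedence(self):
        genes = make_genes([("g1", "chr1", "+", 100_000, 150_000)])
        out = annotate_dmrs_to_genes(make_dmrs([("chr1", 99_900, 100_400)]), genes)
        assert list(out["cls"]) == ["gene_body"]

    def test_matches_bruteforce_interval_check(self, rng):
        genes = make_genes([
            (f"g{i}", "chr1", "+" if rng.random() < 0.5 else "-",
             int(s), int(s) + int(rng.integers(2_000, 40_000)))
            for i, s in enumerate(rng.integers(50_000, 900_000, 40))])
        dmrs = make_dmrs([("chr1", int(s), int(s) + 500)
                          for s in rng.integers(0, 999_000, 60)])
        out = annotate_dmrs_to_genes(dmrs, genes)
        prom = promoter_intervals(genes)
        for _, d in dmrs.iterrows():
            expected = {}
            for i, g in genes.iterrows():
                p = prom.iloc[i]
                if d["start"] < p["end"] and p["start"] < d["end"]:
                    expected[g["gene_id"]] = "promoter"
                if d["start"] < g["end"] and g["start"] < d["end"]:
                    expected[g["gene_id"]] = "gene_body"
            got = out.loc[(out["bin"] == d["bin"]) & (out["gene_id"] != "")]
            assert dict(zip(got["gene_id"], got["cls"])) == expected

    def test_bad_strand_rejected(self):
        genes = make_genes([("g1", "chr1", "+", 0, 100)])
        genes.loc[0, "strand"] = "*"
        with pytest.raises(DataError):
            annotate_dmrs_to_genes(make_dmrs([("chr1", 0, 500)]), genes)

    def test_promoter_clipped_to_chromosome(self):
        genes = make_genes([("g1", "chr1", "+", 5_000, 9_000)])
        prom = promoter_intervals(genes, {"chr1": 10_000})
        assert prom.iloc[0]["start"] == 0


class TestTssProximity:
    def test_extremal_input_attains_minimum_p(self):
        genes = make_genes([(f"g{i}", "chr1", "+", p, p + 1000)
                            for i, p in enumerate(range(100_000, 110_000, 2_000))])
        dmrs = make_dmrs([("chr1", t - 250, t + 250) for t in genes["tss"]])
        res = tss_proximity_test(dmrs, genes, {"chr1": 10_000_000}, n_perm=20, seed=1)
        assert res.observed == 1.0
        assert res.p == pytest.approx(1 / 21)

    def test_needs_permutations_and_input(self):
        genes = make_genes([("g1", "chr1", "+", 0, 100)])
        dmrs = make_dmrs([("chr1", 0, 500)])
        with pytest.raises(ConfigurationError):
            tss_proximity_test(dmrs, genes, {"chr1": 1000}, n_perm=0)
        with pytest.raises(DataError):
            tss_proximity_test(dmrs.iloc[:0], genes, {"chr1": 1000})

    def test_seeded_reproducibility(self, rng):
        genes = make_genes([(f"g{i}", "chr1", "+", int(s), int(s) + 500)
                            for i, s in enumerate(rng.integers(0, 900_000, 30))])
        dmrs = make_dmrs([("chr1", int(s), int(s) + 500)
                          for s in rng.integers(0, 999_000, 40)])
        r1 = tss_proximity_test(dmrs, genes, {"chr1": 1_000_000}, seed=9)
        r2 = tss_proximity_test(dmrs, genes, {"chr1": 1_000_000}, seed=9)
        assert r1 == r2


class TestFisher:
    def test_region_overlap_matches_summation_oracle(self):
        universe = make_dmrs([("chr1", i * 1000, i * 1000 + 500) for i in range(1000)])
        dmrs = universe.head(100)
        windows = pd.DataFrame({"chrom": "chr1", "start": [0], "end": [20 * 1000]})
        # windows overlap the first 20 universe bins, all of which are DMRs
        res = region_overlap_fisher(dmrs, windows, universe)
        assert res.observed == 20
        assert res.p == pytest.approx(hypergeom_tail_oracle(20, 1000, 100, 20), abs=1e-12)

    def test_random_tables_match_oracle(self, rng):
        for _ in range(200):
            N = int(rng.integers(20, 2000))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            x = int(rng.integers(max(0, K + n - N), min(K, n) + 1))
            got = gene_set_fisher([f"g{i}" for i in range(x)]
                                  + [f"h{i}" for i in range(K - x)],
                                  [f"g{i}" for i in range(x)]
                                  + [f"t{i}" for i in range(n - x)],
                                  [f"g{i}" for i in range(x)]
                                  + [f"h{i}" for i in range(K - x)]
                                  + [f"t{i}" for i in range(n - x)]
                                  + [f"u{i}" for i in range(N - K - (n - x))])
            if got.untestable:
                continue
            assert got.p == pytest.approx(hypergeom_tail_oracle(x, N, K, n), abs=1e-10)

    def test_fold_worked_example(self):
        universe = [f"g{i}" for i in range(1000)]
        dmr = universe[:100]
        target = universe[:5] + universe[500:505]
        res = gene_set_fisher(dmr, target, universe)
        assert res.observed == 5
        assert res.fold == pytest.approx(5.0)
        assert res.p == pytest.approx(hypergeom_tail_oracle(5, 1000, 100, 10), abs=1e-12)

    def test_zero_overlap(self):
        universe = [f"g{i}" for i in range(50)]
        res = gene_set_fisher(universe[:10], universe[40:45], universe)
        assert res.fold == 0.0
        assert res.p == pytest.approx(1.0, abs=1e-9)

    def test_degenerate_margin_untestable(self):
        universe = [f"g{i}" for i in range(50)]
        res = gene_set_fisher(universe[:10], universe, universe)
        assert res.untestable

    def test_target_outside_universe(self):
        with pytest.raises(DataError, match="zzz"):
            gene_set_fisher(["a"], ["zzz"], ["a", "b"])
        res = gene_set_fisher(["a"], ["zzz", "b"], ["a", "b"], allow_drop=True)
        assert res.observed == 0

    def test_dmr_bins_must_be_subset(self):
        universe = make_dmrs([("chr1", 0, 500)])
        outside = make_dmrs([("chr2", 0, 500)])
        with pytest.raises(DataError):
            region_overlap_fisher(outside, pd.DataFrame(columns=["chrom", "start", "end"]),
                                  universe)


class TestRankResampling:
    def test_extremal_target_attains_minimum(self, rng):
        p = pd.Series(rng.random(200), index=[f"g{i}" for i in range(200)])
        target = p.nsmallest(10).index.tolist()
        res = rank_resampling_test(p, target, n_draws=999, seed=3)
        assert res.p == pytest.approx(1 / 1000)

    def test_target_larger_than_universe(self):
        p = pd.Series([0.5, 0.6], index=["a", "b"])
        with pytest.raises(DataError):
            rank_resampling_test(p, ["a", "b", "c"])

    def test_order_invariance(self, rng):
        p = pd.Series(rng.random(50), index=[f"g{i}" for i in range(50)])
        target = ["g3", "g7", "g11"]
        r1 = rank_resampling_test(p, target, n_draws=200, seed=5)
        r2 = rank_resampling_test(p.sample(frac=1, random_state=1), target[::-1],
                                  n_draws=200, seed=5)
        assert r1.observed == r2.observed

    def test_uncovered_target_rejected(self):
        p = pd.Series([0.5], index=["a"])
        with pytest.raises(DataError, match="coverage"):
            rank_resampling_test(p, ["b"])


class TestGeneLevelP:
    def test_minimum_across_assigned_dmrs(self):
        annot = pd.DataFrame({"gene_id": ["g1", "g1", "g2", ""],
                              "bin": ["b1", "b2", "b2", "b3"]})
        records = pd.DataFrame({"bin": ["b1", "b2", "b3"], "p": [0.2, 0.01, 0.5]})
        gp = gene_level_pvalues(annot, records)
        assert gp["g1"] == 0.01 and gp["g2"] == 0.01
        assert "b3" not in gp.index


class TestGwasWindows:
    def test_flank_and_clipping(self):
        gwas = pd.DataFrame({"locus_id": ["L1", "L2"], "chrom": ["chr1", "chr1"],
                             "pos": [10_000, 990_000]})
        w = gwas_windows(gwas, {"chr1": 1_000_000})
        assert (w.loc[0, "start"], w.loc[0, "end"]) == (0, 60_000)
        assert (w.loc[1, "start"], w.loc[1, "end"]) == (940_000, 1_000_000)
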