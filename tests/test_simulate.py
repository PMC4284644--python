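import numpy as np
import pandas as pd
import pytest

from twindmr.errors import ConfigurationError
from twindmr.simulate import (PlantedTruth, SimulationConfig, simulate_annotations,
                              simulate_fragments, simulate_genotypes,
                              simulate_mediation_triple, simulate_metabolites,
                              simulate_twin_methylome)

from conftest import small_sim_config


class TestConfigValidation:
    @pytest.mark.parametrize("field,value", [
        ("n_bins", -1), ("n_planted_dmrs", -3), ("n_snps", -2),
    ])
    def test_negative_counts_name_the_field(self, field, value):
        with pytest.raises(ConfigurationError, match=field):
            SimulationConfig(**{field: value})

    def test_planted_exceeding_bins(self):
        with pytest.raises(ConfigurationError, match="n_planted_dmrs"):
            SimulationConfig(n_bins=10, n_planted_dmrs=11)

    @pytest.mark.parametrize("bad", [(0.0, 0.3), (0.1, 0.6), (-0.1, 0.2)])
    def test_maf_bounds(self, bad):
        with pytest.raises(ConfigurationError, match="maf_range"):
            SimulationConfig(maf_range=bad)

    def test_unknown_scenario(self):
        with pytest.raises(ConfigurationError, match="mediation_scenario"):
            SimulationConfig(mediation_scenario="sideways")


class TestSeeding:
    def test_same_seed_is_bit_identical(self):
        a = simulate_twin_methylome(small_sim_config(seed=5))
        b = simulate_twin_methylome(small_sim_config(seed=5))
        assert np.array_equal(a[0].values, b[0].values)
        assert a[1].equals(b[1])
        assert a[2].dmr_bin_indices == b[2].dmr_bin_indices

    def test_different_seeds_differ(self):
        a = simulate_twin_methylome(small_sim_config(seed=5))
        b = simulate_twin_methylome(small_sim_config(seed=6))
        assert not np.array_equal(a[0].values, b[0].values)

    def test_component_streams_are_stable(self):
        # the methylome draw does not depend on downstream components
        cfg1 = small_sim_config(seed=5, n_metabolites=10)
        cfg2 = small_sim_config(seed=5, n_metabolites=99)
        assert np.array_equal(simulate_twin_methylome(cfg1)[0].values,
                              simulate_twin_methylome(cfg2)[0].values)


class TestTwinMethylome:
    def test_design_counts(self, twin_sim):
        _, methylome, samples, _ = twin_sim
        assert (samples["pair_type"] == "discordant").sum() == 34
        assert (samples["pair_type"] == "concordant_case").sum() == 6
        assert (samples["pair_type"] == "concordant_control").sum() == 14
        assert methylome.values.shape == (60, 54)

    def test_cotwins_share_age_sex_family(self, twin_sim):
        _, _, samples, _ = twin_sim
        twins = samples[samples["pair_type"] != "unrelated"]
        for _, grp in twins.groupby("family_id"):
            assert grp["age"].nunique() == 1
            assert grp["sex"].nunique() == 1

    def test_icc_matches_variance_ratio(self):
        """Within-pair correlation at null bins ~ sigma_f^2/(sigma_f^2+sigma_e^2)."""
        cfg = small_sim_config(n_bins=600, n_planted_dmrs=0, dmr_effect=0.0,
                               sigma_family_sq=3.0, sigma_resid_sq=1.0,
                               covariate_effects={})
        methylome, samples, _ = simulate_twin_methylome(cfg)
        a = methylome.values[:, ::2]
        b = methylome.values[:, 1::2]
        ac = a - a.mean(axis=1, keepdims=True)
        bc = b - b.mean(axis=1, keepdims=True)
        r = (ac * bc).sum(1) / np.sqrt((ac**2).sum(1) * (bc**2).sum(1))
        assert r.mean() == pytest.approx(0.75, abs=0.05)

    def test_null_config_iid(self):
        cfg = small_sim_config(n_bins=300, n_planted_dmrs=0, dmr_effect=0.0,
                               sigma_family_sq=0.0, sigma_resid_sq=1.0,
                               covariate_effects={})
        methylome, *_ = simulate_twin_methylome(cfg)
        centered = methylome.values - methylome.values.mean(axis=1, keepdims=True)
        a, b = centered[:, ::2], centered[:, 1::2]
        r = (a * b).sum(1) / np.sqrt((a**2).sum(1) * (b**2).sum(1))
        assert abs(r.mean()) < 3 / np.sqrt(300 * 25)
        assert methylome.values.std(axis=1).mean() == pytest.approx(1.0, abs=0.05)

    def test_planted_truth_indices_valid(self, twin_sim):
        _, methylome, _, truth = twin_sim
        truth.validate(methylome.n_bins)
        assert len(truth.dmr_bin_indices) == 6


class TestGenotypes:
    def test_mz_twins_share_dosage(self, twin_sim):
        cfg, methylome, samples, truth = twin_sim
        geno, _ = simulate_genotypes(cfg, methylome, samples, truth)
        twins = samples[samples["pair_type"] != "unrelated"]
        for _, grp in twins.groupby("family_id"):
            i, j = [geno.samples.index(s) for s in grp["sample_id"]]
            assert np.array_equal(geno.dosage[:, i], geno.dosage[:, j])

    def test_cis_effect_planted_on_assigned_bins(self):
        cfg = small_sim_config(seed=2, cis_effect=2.0)
        methylome, samples, truth = simulate_twin_methylome(cfg)
        before = methylome.values.copy()
        geno, truth = simulate_genotypes(cfg, methylome, samples, truth)
        assert truth.mqtl_assignments
        for snp_i, bin_i, eff in truth.mqtl_assignments:
            assert eff == 2.0
            expected = before[bin_i] + 2.0 * geno.dosage[snp_i]
            assert np.allclose(methylome.values[bin_i], expected)

    def test_zero_cis_effect_leaves_methylome(self):
        cfg = small_sim_config(seed=2, cis_effect=0.0)
        methylome, samples, truth = simulate_twin_methylome(cfg)
        before = methylome.values.copy()
        simulate_genotypes(cfg, methylome, samples, truth)
        assert np.allclose(methylome.values, before)

    def test_assigned_snps_are_cis_to_their_bins(self, twin_sim):
        cfg, methylome, samples, truth = twin_sim
        geno, truth = simulate_genotypes(cfg, methylome, samples, truth)
        for snp_i, bin_i, _ in truth.mqtl_assignments:
            b = methylome.bins.iloc[bin_i]
            s = geno.snps.iloc[snp_i]
            assert s["chrom"] == b["chrom"]
            assert b["start"] - 50_000 <= s["pos"] < b["end"] + 50_000


class TestAnnotations:
    def test_genes_within_chromosome_bounds(self, twin_sim):
        cfg, methylome, _, truth = twin_sim
        genes, gwas, imprinted = simulate_annotations(cfg, methylome, truth, 0.5)
        sizes = cfg.chrom_sizes
        assert (genes["start"] >= 0).all()
        assert all(e <= sizes[c] for c, e in zip(genes["chrom"], genes["end"]))
        assert len(gwas) == 65 and len(imprinted) == 50

    def test_full_enrichment_places_loci_on_planted_bins(self, twin_sim):
        cfg, methylome, _, truth = twin_sim
        _, gwas, _ = simulate_annotations(cfg, methylome, truth, 1.0)
        planted = methylome.bins.iloc[truth.dmr_bin_indices]
        for _, locus in gwas.iterrows():
            hit = ((planted["chrom"] == locus["chrom"])
                   & (planted["start"] <= locus["pos"])
                   & (locus["pos"] < planted["end"])).any()
            assert hit

    def test_zero_genes_gives_empty_tables(self, twin_sim):
        cfg, methylome, _, truth = twin_sim
        genes, gwas, imprinted = simulate_annotations(cfg, methylome, truth, 0.0,
                                                      n_genes=0, n_gwas_loci=0,
                                                      n_imprinted=0)
        assert genes.empty and gwas.empty and imprinted == []


class TestFragments:
    def test_zero_rates_give_empty_bed(self, twin_sim):
        cfg, methylome, *_ = twin_sim
        frags, sizes = simulate_fragments(cfg, methylome.bins, np.zeros(60), ["s1"])
        assert frags["s1"].empty

    def test_poisson_mean_recovered(self, twin_sim):
        cfg, methylome, *_ = twin_sim
        bins = methylome.bins.head(1)
        frags, _ = simulate_fragments(cfg, bins, np.array([100.0]),
                                      [f"s{i}" for i in range(10)])
        counts = [len(frags[s]) for s in frags]
        assert abs(np.mean(counts) - 100) < 3 * np.sqrt(100 / 10)

    def test_fragments_clipped_to_chromosome(self):
        cfg = small_sim_config(toy_genome=(("chr1", 1000),), n_bins=3,
                               n_planted_dmrs=1)
        bins = pd.DataFrame({"chrom": ["chr1"], "start": [900], "end": [1000]})
        frags, _ = simulate_fragments(cfg, bins, np.array([50.0]), ["s"],
                                      fragment_length=300)
        assert (frags["s"]["end"] <= 1000).all()

    def test_negative_rate_rejected(self, twin_sim):
        cfg, methylome, *_ = twin_sim
        with pytest.raises(ConfigurationError):
            simulate_fragments(cfg, methylome.bins, -np.ones(60), ["s"])


class TestMetabolites:
    def test_coupling_without_planted_dmrs_rejected(self):
        cfg = small_sim_config(n_planted_dmrs=0, metabolite_coupling=0.5)
        methylome, samples, truth = simulate_twin_methylome(cfg)
        with pytest.raises(ConfigurationError):
            simulate_metabolites(cfg, methylome, samples, truth)

    def test_zero_metabolites_empty(self):
        cfg = small_sim_config(n_metabolites=0)
        methylome, samples, truth = simulate_twin_methylome(cfg)
        mat, days = simulate_metabolites(cfg, methylome, samples, truth)
        assert mat.empty and len(days) == 54

    def test_coupled_indices_recorded(self, twin_sim):
        cfg, methylome, samples, truth = twin_sim
        mat, days = simulate_metabolites(cfg, methylome, samples, truth, n_coupled=5)
        assert len(truth.coupled_metabolite_indices) == 5
        assert truth.anchor_bin_index in truth.dmr_bin_indices
        assert mat.shape == (20, 54)


class TestMediationTriples:
    @pytest.mark.parametrize("scenario", ["causal", "reactive", "independent", "null"])
    def test_trait_is_balanced_binary(self, scenario, rng):
        d = simulate_mediation_triple(scenario, 100, rng)
        assert set(np.unique(d["T"])) == {0.0, 1.0}
        assert d["T"].sum() == 50

    def test_causal_chain_wiring(self, rng):
        d = simulate_mediation_triple("causal", 4000, rng)
        assert np.corrcoef(d["L"], d["M"])[0, 1] > 0.3
        assert np.corrcoef(d["M"], d["T"])[0, 1] > 0.3

    def test_null_has_no_edges(self, rng):
        d = simulate_mediation_triple("null", 4000, rng)
        assert abs(np.corrcoef(d["L"], d["M"])[0, 1]) < 0.06
        assert abs(np.corrcoef(d["L"], d["T"])[0, 1]) < 0.06


class TestTruthIO:
    def test_roundtrip(self, tmp_path):
        t = PlantedTruth(dmr_bin_indices=[3, 9], dmr_effect=0.8,
                         mqtl_assignments=[(0, 3, 0.5), (1, 9, 0.5)],
                         mediation_scenario="causal",
                         coupled_metabolite_indices=[1, 4], anchor_bin_index=3, seed=11)
        t.save(tmp_path / "truth.txt")
        back = PlantedTruth.load(tmp_path / "truth.txt")
        assert back == t
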