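"""Simulator contracts: determinism, meiosis statistics, noise model, phenotypes."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import binmapqtl as bq


class TestFounderVariants:
    def test_deterministic_under_seed(self, small_genome):
        a = bq.simulate_founder_variants(small_genome, seed=3)
        b = bq.simulate_founder_variants(small_genome, seed=3)
        pd.testing.assert_frame_equal(a.parent1, b.parent1)
        pd.testing.assert_frame_equal(a.parent2, b.parent2)
        c = bq.simulate_founder_variants(small_genome, seed=4)
        assert not a.parent1.equals(c.parent1)

    def test_zero_common_fraction_makes_all_snps_specific(self, small_genome):
        founders = bq.simulate_founder_variants(small_genome, seed=1, common_fraction=0.0)
        specific = bq.identify_specific_snps(founders.parent1, founders.parent2)
        assert len(specific) == sum(small_genome.snps_per_chromosome)

    def test_common_fraction_controls_shared_sites(self, small_genome):
        founders = bq.simulate_founder_variants(small_genome, seed=1, common_fraction=0.3)
        shared = founders.parent1.merge(founders.parent2, on=["chrom", "pos", "ref", "alt"])
        n = sum(small_genome.snps_per_chromosome)
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n, 0.3)
        assert lo <= len(shared) <= hi

    def test_invalid_parameters_raise(self, small_genome):
        with pytest.raises(ValueError):
            bq.simulate_founder_variants(small_genome, seed=1, common_fraction=1.5)
        with pytest.raises(ValueError):
            bq.GenomeSpec(1, [1000], [1.0], [0])


class TestRILGenotypes:
    def test_deterministic_under_seed(self, small_genome):
        a = bq.simulate_ril_genotypes(small_genome, 5, 7, seed=9)
        b = bq.simulate_ril_genotypes(small_genome, 5, 7, seed=9)
        for chrom in a.haplotypes:
            assert np.array_equal(a.haplotypes[chrom], b.haplotypes[chrom])
        pd.testing.assert_frame_equal(a.crossover_log, b.crossover_log)

    def test_crossover_count_fits_poisson(self):
        """Crossovers per transmitted gamete ~ Poisson(genetic length)."""
        genome = bq.GenomeSpec(1, [10_000_000], [1.0], [50])
        truth = bq.simulate_ril_genotypes(genome, n_lines=5000, n_selfing_generations=1, seed=2)
        counts = truth.crossover_log.groupby(["line", "gamete"]).size()
        # include gametes with zero crossovers (absent from the log)
        per_gamete = counts.reindex(
            pd.MultiIndex.from_product([truth.lines, [0, 1]]), fill_value=0
        ).to_numpy()
        assert len(per_gamete) == 10_000
        assert per_gamete.mean() == pytest.approx(1.0, abs=0.05)
        kmax = 6
        observed = np.bincount(np.minimum(per_gamete, kmax), minlength=kmax + 1)
        expected = stats.poisson.pmf(np.arange(kmax), 1.0)
        expected = np.append(expected, 1 - expected.sum()) * len(per_gamete)
        chi2 = ((observed - expected) ** 2 / expected).sum()
        assert stats.chi2.sf(chi2, df=kmax) > 0.01

    def test_residual_heterozygosity_halves_per_generation(self):
        genome = bq.GenomeSpec(2, [20_000_000, 20_000_000], [1.0, 1.0], [400, 400])
        truth = bq.simulate_ril_genotypes(genome, n_lines=400, n_selfing_generations=7, seed=5)
        het = np.mean([(g == 0.5).mean() for g in truth.genotypes.values()])
        assert het == pytest.approx(0.5**7, abs=0.003)

    def test_zero_genetic_length_gives_whole_chromosome_blocks(self):
        genome = bq.GenomeSpec(1, [10_000_000], [0.0], [100])
        truth = bq.simulate_ril_genotypes(genome, n_lines=30, n_selfing_generations=7, seed=1)
        for hap in truth.haplotypes.values():
            for li in range(hap.shape[0]):
                assert len(np.unique(hap[li, :, 0])) == 1
                assert len(np.unique(hap[li, :, 1])) == 1

    def test_mosaic_transitions_only_at_logged_crossovers(self, small_genome):
        """Every parental-origin switch must coincide with a recorded crossover."""
        truth = bq.simulate_ril_genotypes(small_genome, 10, 4, seed=7)
        for chrom in truth.positions:
            pos = truth.positions[chrom]
            for li, line in enumerate(truth.lines):
                cuts = truth.crossover_log.query("line == @line and chrom == @chrom")["pos_bp"]
                for h in range(2):
                    hap = truth.haplotypes[chrom][li, :, h]
                    switches = np.flatnonzero(hap[1:] != hap[:-1])
                    for s in switches:
                        assert ((cuts > pos[s]) & (cuts <= pos[s + 1])).any()

    def test_haldane_waddington_two_locus_recombinants(self):
        """Observed RIL recombinant fraction converges to R = 2r/(1+2r)."""
        genome = bq.GenomeSpec(1, [10_000_000], [0.4], [200])
        truth = bq.simulate_ril_genotypes(genome, n_lines=2500, n_selfing_generations=25, seed=13)
        g = truth.genotypes["Chr1"]
        pos = truth.positions["Chr1"]
        i, j = 20, 140  # two loci a known genetic distance apart
        d_m = 0.4 * (pos[j] - pos[i]) / 10_000_000
        r = 0.5 * (1 - np.exp(-2 * d_m))  # Haldane single-meiosis fraction
        hom = (g[:, i] != 0.5) & (g[:, j] != 0.5)
        R_obs = np.mean(g[hom, i] != g[hom, j])
        R_exp = 2 * r / (1 + 2 * r)
        se = np.sqrt(R_exp * (1 - R_exp) / hom.sum())
        assert abs(R_obs - R_exp) < 4 * se

    def test_transmission_bias_skews_allele_frequency(self):
        genome = bq.GenomeSpec(1, [10_000_000], [0.5], [100])
        biased = bq.simulate_ril_genotypes(
            genome, 150, 7, seed=3, transmission_bias=("Chr1", 5_000_000, 0.7)
        )
        idx = np.argmin(np.abs(biased.positions["Chr1"] - 5_000_000))
        freq = biased.genotypes["Chr1"][:, idx].mean()
        assert freq > 0.6  # Longgu7 allele over-transmitted


class TestObservedCalls:
    def test_zero_noise_is_identity(self, small_study):
        calls = small_study["calls"]
        truth, spec = small_study["truth"], small_study["specific"]
        geno = truth.genotype_frame().loc[calls.index]
        l_allele = spec.set_index(["chrom", "pos"]).loc[calls.index, "allele_longgu7"]
        hom_l = geno.to_numpy() == 1.0
        assert (calls.to_numpy()[hom_l] == np.broadcast_to(
            l_allele.to_numpy()[:, None], calls.shape)[hom_l]).all()
        assert (calls.to_numpy() == ".").sum() == 0

    def test_error_rate_one_flips_every_homozygous_call(self, small_study):
        truth, spec = small_study["truth"], small_study["specific"]
        flipped = bq.simulate_observed_calls(truth, spec, error_rate=1.0, missing_rate=0.0, seed=1)
        clean = small_study["calls"]
        hom = (clean.to_numpy() != "H")
        assert (flipped.to_numpy()[hom] != clean.to_numpy()[hom]).all()

    def test_missing_rate_matches_binomial(self, small_study):
        truth, spec = small_study["truth"], small_study["specific"]
        calls = bq.simulate_observed_calls(truth, spec, error_rate=0.0, missing_rate=0.2, seed=4)
        n_cells = calls.size
        n_missing = (calls.to_numpy() == ".").sum()
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n_cells, 0.2)
        assert lo <= n_missing <= hi

    def test_rates_validated(self, small_study):
        with pytest.raises(ValueError):
            bq.simulate_observed_calls(
                small_study["truth"], small_study["specific"], error_rate=1.5, missing_rate=0.0, seed=1
            )


class TestPhenotypes:
    def test_noiseless_single_qtl_takes_three_values_per_environment(self):
        genome = bq.GenomeSpec(1, [10_000_000], [1.0], [100])
        truth = bq.simulate_ril_genotypes(genome, 200, 1, seed=2)  # F2: many hets
        model = bq.TraitModel(
            name="T", qtls=[bq.PlantedQTL("Chr1", 5_000_000, pve=0.5)],
            phen_var=1.0, env_effects=[0.0, 3.0],
        )
        # zero noise: phenotypic variance equals the QTL variance exactly
        j = np.argmin(np.abs(truth.positions["Chr1"] - 5_000_000))
        model.qtls[0].effect = 1.0
        model.phen_var = float((2 * truth.genotypes["Chr1"][:, j] - 1).var())
        traits, _ = bq.simulate_phenotypes(truth, [model], ["E1", "E2"], seed=1)
        for _, grp in traits.groupby("environment"):
            assert grp["value"].nunique() == 3

    def test_realized_pve_matches_target(self):
        genome = bq.GenomeSpec(1, [10_000_000], [1.0], [200])
        pves = []
        for rep in range(30):
            truth = bq.simulate_ril_genotypes(genome, 164, 7, seed=100 + rep)
            model = bq.TraitModel(name="T", qtls=[bq.PlantedQTL("Chr1", 5_000_000, pve=0.10)])
            traits, realized = bq.simulate_phenotypes(truth, [model], ["E1"], seed=rep)
            # empirical R^2 of trait on the causal genotype
            j = np.argmin(np.abs(truth.positions["Chr1"] - 5_000_000))
            x = 2 * truth.genotypes["Chr1"][:, j] - 1
            y = traits["value"].to_numpy()
            pves.append(np.corrcoef(x, y)[0, 1] ** 2)
        assert np.mean(pves) == pytest.approx(0.10, abs=0.02)

    def test_unreachable_pve_raises(self):
        with pytest.raises(ValueError):
            bq.TraitModel(
                name="T",
                qtls=[bq.PlantedQTL("Chr1", 1, pve=0.6), bq.PlantedQTL("Chr1", 2, pve=0.5)],
            )

    def test_null_trait_is_pure_noise(self, small_study):
        bins = small_study["bin_map"]
        lm = bq.build_linkage_map(bins)
        rng = np.random.default_rng(0)
        traits = pd.DataFrame(
            {"line": bins.lines, "environment": "E1", "trait": "NULL",
             "value": rng.normal(size=len(bins.lines))}
        )
        prof = bq.genome_scan(bins, lm, traits)
        assert prof["LOD"].max() < 4.0  # no spurious strong signal in one replicate
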