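"""Marker regression, QTL calling, merging, nomenclature and clusters."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import binmapqtl as bq
from binmapqtl.binmap import GENO_L, GENO_MISSING, GENO_Y
from binmapqtl.qtl import QTLRecord

from conftest import binmap_from_genotypes

L, Y, M = int(GENO_L), int(GENO_Y), int(GENO_MISSING)


class TestSinglePositionFit:
    def test_worked_micro_example(self):
        """Hand least squares: RSS0 = 5, RSS1 = 1 on the 4-line toy."""
        lod, a, pve = bq.single_position_fit(np.array([1, 1, 0, 0]), np.array([10.0, 9, 8, 7]))
        assert lod == pytest.approx(1.39794, abs=1e-5)
        assert a == pytest.approx(1.0, abs=1e-12)
        assert pve == pytest.approx(80.0, abs=1e-9)

    def test_equal_group_means_give_zero_everything(self):
        lod, a, pve = bq.single_position_fit(np.array([1, 1, 0, 0]), np.array([5.0, 7, 5, 7]))
        assert lod == pytest.approx(0.0, abs=1e-12)
        assert a == 0.0
        assert pve == pytest.approx(0.0, abs=1e-9)

    def test_sign_convention_longgu7_increases(self):
        _, a, _ = bq.single_position_fit(np.array([1, 1, 0, 0]), np.array([9.0, 11, 2, 4]))
        assert a > 0
        _, a, _ = bq.single_position_fit(np.array([0, 0, 1, 1]), np.array([9.0, 11, 2, 4]))
        assert a < 0

    def test_missing_class_returns_nan(self):
        lod, a, pve = bq.single_position_fit(np.array([1, 1, -1]), np.array([1.0, 2, 3]))
        assert np.isnan(lod) and np.isnan(a) and np.isnan(pve)

    def test_zero_trait_variance_warns_and_gives_zero_lod(self):
        with pytest.warns(UserWarning, match="zero variance"):
            lod, _, _ = bq.single_position_fit(np.array([1, 1, 0, 0]), np.array([3.0, 3, 3, 3]))
        assert lod == 0.0

    def test_lod_equals_gaussian_likelihood_ratio(self):
        """Oracle: LOD from explicit normal log-likelihoods with MLE variance."""
        rng = np.random.default_rng(7)
        for _ in range(25):
            n = rng.integers(6, 40)
            g = rng.integers(0, 2, size=n)
            if g.sum() in (0, n):
                continue
            y = rng.normal(size=n) + 0.8 * g
            lod, _, _ = bq.single_position_fit(g, y)
            # null model: single normal, MLE
            ll0 = stats.norm.logpdf(y, y.mean(), y.std()).sum()
            # alt model: per-class means, pooled MLE sigma
            resid = y.copy()
            resid[g == 1] -= y[g == 1].mean()
            resid[g == 0] -= y[g == 0].mean()
            sigma1 = np.sqrt(np.mean(resid**2))
            ll1 = stats.norm.logpdf(resid, 0, sigma1).sum()
            assert lod == pytest.approx((ll1 - ll0) / np.log(10), abs=1e-9)


def make_profile(trait, env, lods, chrom="Chr1", cm_step=5.0):
    n = len(lods)
    return pd.DataFrame(
        {
            "trait": trait,
            "environment": env,
            "chrom": chrom,
            "bin_id": [f"Bin{i + 1:04d}" for i in range(n)],
            "cM": np.arange(n) * cm_step,
            "LOD": lods,
            "additive": -1.0,
            "PVE": 8.0,
            "n_lines": 164,
        }
    )


class TestCallQTLs:
    def test_below_threshold_yields_no_qtl(self):
        prof = make_profile("SWP", "E1", [0.5, 1.9, 1.2])
        assert bq.call_qtls(prof) == []

    def test_overlapping_environments_merge_into_one_qtl(self):
        lods = [0.1, 1.0, 3.0, 1.0, 0.1, 0.1, 0.1]
        prof = pd.concat([make_profile("SWP", "E1", lods), make_profile("SWP", "E2", lods)])
        recs = bq.call_qtls(prof)
        assert len(recs) == 1
        assert recs[0].environments == ["E1", "E2"]
        assert len(recs[0].env_table) == 2

    def test_disjoint_peaks_stay_separate(self):
        lods = [0.1] * 13
        lods[2], lods[8] = 3.0, 3.5  # 30 cM apart, tight 1-LOD intervals
        recs = bq.call_qtls(make_profile("SWP", "E1", lods))
        assert len(recs) == 2

    def test_merging_is_environment_order_independent(self):
        lods_a = [0.1, 1.0, 3.0, 1.5, 0.1, 0.1, 0.1]
        lods_b = [0.1, 0.1, 1.5, 2.8, 1.0, 0.1, 0.1]
        p1 = pd.concat([make_profile("SWP", "E1", lods_a), make_profile("SWP", "E2", lods_b)])
        p2 = pd.concat([make_profile("SWP", "E2", lods_b), make_profile("SWP", "E1", lods_a)])
        r1, r2 = bq.call_qtls(p1), bq.call_qtls(p2)
        key = lambda r: (r.trait, r.chrom, r.peak_bin, tuple(r.environments))
        assert sorted(map(key, r1)) == sorted(map(key, r2))

    def test_stable_flag_requires_three_environments(self):
        lods = [0.1, 1.0, 3.0, 1.0, 0.1]
        two = pd.concat([make_profile("SWP", e, lods) for e in ("E1", "E2")])
        three = pd.concat([make_profile("SWP", e, lods) for e in ("E1", "E2", "E3")])
        assert not bq.call_qtls(two)[0].stable
        assert bq.call_qtls(three)[0].stable

    def test_support_interval_contains_peak(self):
        lods = [0.1, 1.5, 3.2, 2.5, 0.4]
        rec = bq.call_qtls(make_profile("SWP", "E1", lods))[0]
        assert rec.ci_lo_cM <= rec.peak_cM <= rec.ci_hi_cM
        # contiguous positions with LOD >= peak - 1 (3.2 - 1 = 2.2): only 2.5 qualifies
        assert rec.ci_lo_cM == 10.0 and rec.ci_hi_cM == 15.0


def record(trait, chrom, cm, name=""):
    return QTLRecord(
        trait=trait, chrom=chrom, environments=["E1"], peak_bin="BinX", peak_cM=cm,
        lod=3.0, additive=-1.0, pve=8.0, ci_lo_cM=cm - 2, ci_hi_cM=cm + 2,
        stable=False, name=name,
    )


class TestNaming:
    def test_serials_follow_map_order_within_trait_and_chromosome(self):
        recs = [record("SWP", "Chr7", c) for c in (119.5, 14.3, 51.6, 100.5)]
        named = bq.name_qtls(recs)
        assert [r.name for r in named] == ["qSWP7.1", "qSWP7.2", "qSWP7.3", "qSWP7.4"]
        assert named[-1].peak_cM == 119.5  # fourth SWP QTL on Chr7

    def test_single_qtl_serial_starts_at_one(self):
        assert bq.name_qtls([record("GWP", "Chr3", 10.0)])[0].name == "qGWP3.1"

    def test_tgw_serials_ordered_by_cm(self):
        recs = [record("TGW", "Chr8", 107.93), record("TGW", "Chr8", 46.39)]
        named = bq.name_qtls(recs)
        assert [(r.name, r.peak_cM) for r in named] == [("qTGW8.1", 46.39), ("qTGW8.2", 107.93)]


class TestClusters:
    def test_same_trait_only_is_not_a_cluster(self):
        recs = bq.name_qtls([record("SWP", "Chr1", 10.0), record("SWP", "Chr1", 15.0)])
        assert len(bq.find_clusters(recs)) == 0

    def test_three_traits_within_window_form_one_cluster(self):
        recs = bq.name_qtls(
            [record("SWP", "Chr9", 10.0), record("PWP", "Chr9", 18.0), record("GWP", "Chr9", 22.0)]
        )
        out = bq.find_clusters(recs)
        assert len(out) == 1
        assert out.loc[0, "n_qtls"] == 3
        assert out.loc[0, "traits"] == "GWP,PWP,SWP"

    def test_empty_records_give_empty_table(self):
        assert len(bq.find_clusters([])) == 0

    def test_far_apart_qtls_do_not_cluster(self):
        recs = bq.name_qtls([record("SWP", "Chr2", 5.0), record("PWP", "Chr2", 40.0)])
        assert len(bq.find_clusters(recs)) == 0


@pytest.fixture(scope="module")
def planted():
    genome = bq.GenomeSpec(2, [20_000_000, 20_000_000], [0.9, 0.9], [600, 600])
    founders = bq.simulate_founder_variants(genome, seed=31, common_fraction=0.0)
    spec = bq.identify_specific_snps(founders.parent1, founders.parent2)
    truth = bq.simulate_ril_genotypes(genome, 164, 7, seed=31)
    calls = bq.simulate_observed_calls(truth, spec, 0.0, 0.0, seed=31)
    bins = bq.merge_bins(bq.call_windows(bq.encode_ril_calls(calls, spec).matrix))
    lm = bq.build_linkage_map(bins)
    model = bq.TraitModel(
        name="SWP", qtls=[bq.PlantedQTL("Chr1", 10_000_000, pve=0.15, sign=-1)],
        env_effects=[0.0, 2.0],
    )
    traits, _ = bq.simulate_phenotypes(truth, [model], ["E1", "E2"], seed=31)
    return truth, bins, lm, traits


class TestGenomeScan:
    def test_profile_covers_every_bin_per_trait_environment(self, planted):
        _, bins, lm, traits = planted
        prof = bq.genome_scan(bins, lm, traits)
        assert len(prof) == 2 * len(bins.bins)

    def test_planted_qtl_found_with_negative_effect(self, planted):
        truth, bins, lm, traits = planted
        prof = bq.genome_scan(bins, lm, traits)
        recs = bq.name_qtls(bq.call_qtls(prof))
        assert any(r.chrom == "Chr1" for r in recs)
        best = max((r for r in recs if r.chrom == "Chr1"), key=lambda r: r.lod)
        assert best.additive < 0  # Yugu1 allele increases the trait
        # peak near the planted position (10 Mb on a 20 Mb chromosome)
        peak_bin = bins.bins.set_index("bin_id").loc[best.peak_bin]
        assert abs((peak_bin["start_bp"] + peak_bin["end_bp"]) / 2 - 10_000_000) < 3_000_000

    def test_cofactor_mode_still_finds_the_qtl(self, planted):
        _, bins, lm, traits = planted
        cfg = bq.PipelineConfig(cofactor_mode=True)
        prof = bq.genome_scan(bins, lm, traits, cfg)
        recs = bq.call_qtls(prof, cfg)
        assert any(r.chrom == "Chr1" for r in recs)

    def test_disjoint_line_sets_raise(self, planted):
        _, bins, lm, traits = planted
        bad = traits.assign(line=traits["line"] + "_other")
        with pytest.raises(ValueError, match="no lines shared"):
            bq.genome_scan(bins, lm, bad)

    def test_constant_trait_warns(self, planted):
        _, bins, lm, traits = planted
        flat = traits.assign(value=1.0)
        with pytest.warns(UserWarning, match="constant"):
            prof = bq.genome_scan(bins, lm, flat)
        assert (prof["LOD"].dropna() == 0).all()
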