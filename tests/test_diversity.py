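"""Diversity statistics: census, AMOVA, distances, LD, decay fits, LPS."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

import landracegp as lg
from landracegp.diversity import hill_weir_expected_r2

from conftest import make_fixed_p_pool


class TestAlleleFrequencies:
    def test_basic_and_monomorphic(self, landrace):
        pool, capture = landrace
        dh = lg.derive_dh(pool, 100, rng=1)
        f = lg.allele_frequencies(dh)
        assert np.all((f >= 0) & (f <= 1))
        assert np.all(f[capture.private_loci] == 0.0)
        mono = np.full((5, 3), 2)
        np.testing.assert_array_equal(lg.allele_frequencies(mono), [1, 1, 1])

    def test_gc_s1_frequency_at_private_loci(self, landrace):
        pool, capture = landrace
        _, s1 = lg.derive_gc(pool, capture, 800, rng=2)
        f = lg.allele_frequencies(s1)[capture.private_loci]
        assert f.mean() == pytest.approx(0.5, abs=0.02)


class TestPolymorphismCensus:
    def test_identical_populations_all_in_triple_region(self, landrace):
        pool, _ = landrace
        plants = lg.sample_plants(pool, 40, seed=3)  # exactly 80 gametes: full draw
        census = lg.polymorphism_census(
            {"LS": plants, "DH": plants, "GC": plants}, n_gametes=80, n_reps=5, seed=4
        )
        triple = census[census["region"] == "DH&GC&LS"]["mean_count"].iloc[0]
        singles = census[census["n_populations"] == 1]
        assert np.all(singles[singles["region"] != "GC_private_capture_line"]["mean_count"] == 0)
        assert triple > 0

    def test_regions_partition_polymorphic_set(self, landrace):
        pool, capture = landrace
        ls = lg.sample_plants(pool, 48, seed=5)
        dh = lg.derive_dh(pool, 100, rng=6)
        _, gc = lg.derive_gc(pool, capture, 100, rng=7)
        census = lg.polymorphism_census(
            {"LS": ls, "DH": dh, "GC": gc}, n_gametes=80, n_reps=3, seed=8
        )
        venn = census[census["region"] != "GC_private_capture_line"]
        # per-replicate counts sum to the polymorphic total; means preserve this
        total = venn["mean_count"].sum()
        assert 0 < total <= pool.n_markers
        # capture-line-attributable GC-private polymorphisms track the private loci
        priv = census[census["region"] == "GC_private_capture_line"]["mean_count"].iloc[0]
        only_gc = census[census["region"] == "GC"]["mean_count"].iloc[0]
        assert priv >= 0.5 * len(capture.private_loci)
        assert priv <= only_gc

    def test_insufficient_gametes_rejected(self, landrace):
        pool, _ = landrace
        tiny = lg.sample_plants(pool, 10, seed=9)
        with pytest.raises(ValueError):
            lg.polymorphism_census({"LS": tiny}, n_gametes=80, n_reps=2, seed=10)


class TestMolecularVariance:
    def test_dh_has_no_within_individual_component(self, landrace):
        pool, _ = landrace
        dh = lg.derive_dh(pool, 150, rng=11)
        res = lg.molecular_variance(dh)
        assert res.var_within == 0.0
        assert res.ss_within == 0.0

    def test_hwe_within_between_ratio(self):
        """Under HWE the within-individual gamete variance is p(1-p) and the
        between-individual component vanishes (enumeration expectation)."""
        pool = make_fixed_p_pool(0.3, 400, 4000, seed=12)
        plants = lg.sample_plants(pool, 2000, seed=13)
        res = lg.molecular_variance(plants)
        p_hat = lg.allele_frequencies(plants)
        expected_within = np.sum(p_hat * (1 - p_hat))
        assert res.var_within == pytest.approx(expected_within, rel=0.05)
        assert abs(res.var_between) < 0.05 * expected_within

    def test_gc_total_at_private_loci_is_half(self, landrace):
        pool, capture = landrace
        _, s1 = lg.derive_gc(pool, capture, 1500, rng=14)
        res = lg.molecular_variance(s1)
        assert res.per_locus[capture.private_loci].mean() == pytest.approx(0.5, abs=0.01)

    def test_ls_and_dh_molecular_variance_agree(self):
        """2f(1-f) among LS equals that among DH at matched ancestral p."""
        for p in (0.1, 0.3, 0.5, 0.7):
            pool = make_fixed_p_pool(p, 300, 20_000, seed=int(100 * p))
            ls = lg.sample_plants(pool, 2000, seed=15)
            dh = lg.derive_dh(pool, 2000, rng=16)
            v_ls = lg.molecular_variance(ls).per_locus.mean()
            v_dh = lg.molecular_variance(dh).per_locus.mean()
            assert v_ls == pytest.approx(v_dh, rel=0.03)
            assert v_ls == pytest.approx(2 * p * (1 - p), rel=0.03)

    def test_ss_partition_adds_up(self, landrace):
        pool, _ = landrace
        plants = lg.sample_plants(pool, 80, seed=17)
        res = lg.molecular_variance(plants)
        X = plants.gametes().astype(float)
        ss_total = float(((X - X.mean(axis=0)) ** 2).sum())
        assert res.ss_between + res.ss_within == pytest.approx(ss_total, rel=1e-10)


class TestGeneticDistance:
    def test_allele_sharing_scores(self):
        assert lg.genetic_distance([0], [0]) == 0.0
        assert lg.genetic_distance([0], [1]) == 0.25 / 0.5  # |0-1|/2 = 0.5
        assert lg.genetic_distance([0], [2]) == 1.0
        assert lg.genetic_distance([1], [1]) == 0.0
        assert lg.genetic_distance([0, 2, 1, 1], [0, 0, 1, 2]) == pytest.approx(
            (0 + 2 + 0 + 1) / 2 / 4
        )

    @settings(deadline=None, derandomize=True)
    @given(
        hnp.arrays(np.int64, st.integers(1, 30), elements=st.integers(0, 2)),
        st.data(),
    )
    def test_metric_like_properties(self, g1, data):
        g2 = data.draw(hnp.arrays(np.int64, g1.shape, elements=st.integers(0, 2)))
        d12 = lg.genetic_distance(g1, g2)
        assert d12 == lg.genetic_distance(g2, g1)
        assert 0.0 <= d12 <= 1.0
        assert lg.genetic_distance(g1, g1) == 0.0

    def test_gc_to_capture_distance_on_private_loci(self, landrace):
        """Mean GC-S1 distance to the capture line on diagnostic loci is 0.5,
        the F2-generation expectation for a biparental cross."""
        pool, capture = landrace
        _, s1 = lg.derive_gc(pool, capture, 500, rng=18)
        cap_dose = 2 * np.ones(len(capture.private_loci))
        gd = [
            lg.genetic_distance(s1.dosage()[i, capture.private_loci], cap_dose)
            for i in range(s1.n)
        ]
        assert np.mean(gd) == pytest.approx(0.5, abs=0.02)

    def test_matrix_against_pairwise(self, landrace):
        pool, _ = landrace
        plants = lg.sample_plants(pool, 12, seed=19)
        M = lg.genetic_distance_matrix(plants)
        dose = plants.dosage()
        for i in range(4):
            for j in range(4):
                assert M[i, j] == pytest.approx(lg.genetic_distance(dose[i], dose[j]))
        with pytest.raises(ValueError):
            lg.genetic_distance_matrix(plants, marker_subset=np.array([], dtype=int))


class TestLDPairs:
    def test_duplicated_marker_r2_one(self):
        gmap = lg.GeneticMap(
            chrom=np.array([1, 1]), pos_bp=np.array([100, 200]),
            pos_cm=np.array([0.0, 0.1]), marker=np.array(["a", "b"], dtype=object),
        )
        rng = np.random.default_rng(20)
        col = (rng.random(50) < 0.4).astype(float)
        gam = np.column_stack([col, col])
        ld = lg.ld_pairs(gam, gmap)
        assert len(ld) == 1
        assert ld["r2"].iloc[0] == pytest.approx(1.0)

    def test_independent_loci_mean_r2_near_sampling_floor(self):
        pool = make_fixed_p_pool(0.5, 200, 2000, seed=21)
        ld = lg.ld_pairs(pool.gametes, pool.gmap, n_gametes=94, seed=22)
        assert ld["r2"].mean() == pytest.approx(1 / 94, rel=0.3)

    def test_distance_cutoff_and_monomorphic_skip(self, gmap_small):
        rng = np.random.default_rng(23)
        gam = (rng.random((60, gmap_small.n_markers)) < 0.5).astype(float)
        gam[:, 0] = 0.0  # monomorphic
        ld = lg.ld_pairs(gam, gmap_small, max_dist_bp=2_000_000)
        assert np.all(ld["dist_bp"] <= 2_000_000)
        assert "chr1_m1" not in set(ld["marker_i"]) | set(ld["marker_j"])


class TestDecayFit:
    def test_parameter_recovery_on_exact_curve(self):
        """Data generated exactly on the expected-r2 curve recover rho."""
        rho = 2e-6
        d = np.linspace(1e3, 2e6, 300)
        y = hill_weir_expected_r2(d, rho, 94)
        fit = lg.fit_ld_decay(__import__("pandas").DataFrame({"dist_bp": d, "r2": y}), 94)
        assert fit.rho == pytest.approx(rho, rel=1e-4)
        # delta solves the curve at 0.2 and is monotone decreasing in rho
        assert hill_weir_expected_r2(np.array([fit.delta_kb * 1e3]), fit.rho, 94)[0] == pytest.approx(0.2, abs=1e-9)

    def test_delta_monotone_in_decay_coefficient(self):
        import pandas as pd

        deltas = []
        for rho in (1e-6, 4e-6):
            d = np.linspace(1e3, 2e6, 200)
            y = hill_weir_expected_r2(d, rho, 94)
            deltas.append(lg.fit_ld_decay(pd.DataFrame({"dist_bp": d, "r2": y}), 94).delta_kb)
        assert deltas[1] < deltas[0]

    def test_stronger_ld_gives_larger_delta(self):
        """A smaller, less-recombined pool shows slower r2 decay (larger delta)."""
        gmap = lg.make_genetic_map(1, 120, 100.0, 20e6, seed=24)
        strong = lg.simulate_ancestral_pool(gmap, 120, burnin_generations=30, seed=25)
        weak = lg.simulate_ancestral_pool(gmap, 600, burnin_generations=8, seed=26)
        fits = []
        for pool in (strong, weak):
            ld = lg.ld_pairs(pool.gametes, gmap, max_dist_bp=20_000_000, n_gametes=94, seed=27)
            fits.append(lg.fit_ld_decay(ld, 94))
        assert fits[0].rho < fits[1].rho

    def test_too_few_records_rejected(self):
        import pandas as pd

        with pytest.raises(ValueError):
            lg.fit_ld_decay(pd.DataFrame({"dist_bp": [1, 2], "r2": [0.5, 0.4]}), 94)


class TestCrossChromosomeLD:
    def test_pair_enumeration_and_floor(self, pool_hwe, gmap_small):
        mean_r2, table = lg.cross_chromosome_ld(pool_hwe.gametes[:94], gmap_small, seed=28)
        assert len(table) == 1  # 2 chromosomes -> 1 pair
        assert mean_r2 == pytest.approx(1 / 94, rel=0.4)

    def test_ten_chromosomes_enumerate_45_pairs(self):
        gmap = lg.make_genetic_map(10, 20, 50.0, 50e6, seed=29)
        pool = lg.simulate_ancestral_pool(gmap, 100, burnin_generations=0, seed=30)
        _, table = lg.cross_chromosome_ld(pool.gametes, gmap, n_pairs_per_chrom_pair=200, seed=31)
        assert len(table) == 45

    def test_duplicated_chromosome_contents_show_ld(self, gmap_small):
        rng = np.random.default_rng(32)
        half = gmap_small.n_markers // 2
        base = (rng.random(80) < 0.5).astype(float)
        # strongly correlated markers within the chromosome, duplicated across
        flips = rng.random((80, half)) < 0.05
        block = np.abs(base[:, None] - flips)
        gam = np.hstack([block, block])  # chromosome 2 duplicates chromosome 1
        mean_r2, _ = lg.cross_chromosome_ld(gam, gmap_small, seed=33)
        within = lg.ld_pairs(gam[:, :half], lg.make_genetic_map(1, half, 100.0, 100e6, seed=1))
        assert mean_r2 > 0.5
        assert mean_r2 == pytest.approx(within["r2"].mean(), rel=0.1)

    def test_single_chromosome_rejected(self):
        gmap = lg.make_genetic_map(1, 10, 50.0, 1e6, seed=34)
        with pytest.raises(ValueError):
            lg.cross_chromosome_ld(np.zeros((10, 10)), gmap)


class TestLinkagePhaseSimilarity:
    def test_self_comparison_is_one(self, landrace):
        pool, _ = landrace
        lps = lg.linkage_phase_similarity(pool.gametes, pool.gametes, pool.gmap,
                                          bin_kb=100, max_dist_kb=5000)
        filled = lps.dropna(subset=["lps"])
        assert len(filled) > 0
        assert np.all(filled["lps"] == 1.0)

    def test_independent_populations_near_half(self):
        a = make_fixed_p_pool(0.5, 400, 200, seed=35)
        b = make_fixed_p_pool(0.5, 400, 200, seed=36)
        lps = lg.linkage_phase_similarity(a.gametes, b.gametes, a.gmap,
                                          bin_kb=1000, max_dist_kb=100_000)
        filled = lps.dropna(subset=["lps"])
        weighted = np.average(filled["lps"], weights=filled["n_pairs"])
        assert weighted == pytest.approx(0.5, abs=0.05)

    def test_dh_preserve_phase_better_than_gc(self, landrace):
        """DH keep the ancestral linkage phases; the capture cross dilutes them."""
        pool, capture = landrace
        dh = lg.derive_dh(pool, 100, rng=37)
        _, gc = lg.derive_gc(pool, capture, 100, rng=38)
        kw = dict(bin_kb=2000, max_dist_kb=20_000)
        lps_dh = lg.linkage_phase_similarity(pool.gametes, dh.gametes(), pool.gmap, **kw)
        lps_gc = lg.linkage_phase_similarity(pool.gametes, gc.gametes(), pool.gmap, **kw)
        w_dh = np.average(lps_dh.dropna()["lps"], weights=lps_dh.dropna()["n_pairs"])
        w_gc = np.average(lps_gc.dropna()["lps"], weights=lps_gc.dropna()["n_pairs"])
        assert w_dh > w_gc

    def test_orientation_invariant_to_individual_permutation(self, landrace):
        pool, _ = landrace
        rng = np.random.default_rng(39)
        perm = rng.permutation(pool.n_gametes)
        lps = lg.linkage_phase_similarity(pool.gametes, pool.gametes[perm], pool.gmap,
                                          bin_kb=100, max_dist_kb=5000)
        filled = lps.dropna(subset=["lps"])
        assert np.all(filled["lps"] == 1.0)

    def test_corr_mode_and_bad_mode(self, landrace):
        pool, _ = landrace
        lps = lg.linkage_phase_similarity(pool.gametes, pool.gametes, pool.gmap,
                                          bin_kb=1000, max_dist_kb=10_000, mode="corr")
        filled = lps.dropna(subset=["lps"])
        assert np.all(filled["lps"] > 0.999)
        with pytest.raises(ValueError):
            lg.linkage_phase_similarity(pool.gametes, pool.gametes, pool.gmap, mode="nope")
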