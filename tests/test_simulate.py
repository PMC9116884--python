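"""Unit and property tests for the synthetic-data generators."""

import numpy as np
import pytest

from adaptscan import cnv, popgen, simulate


def small_cross(n=2_000, seed=0, noise_sd=simulate.DEFAULT_NOISE_SD, means=None):
    marker_map = [("1", 100_000), ("1", 5_000_000), ("2", 5_000_000), ("2", 9_000_000)]
    return simulate.CrossConfig(
        n_individuals=n,
        locus_a=("1", 5_000_000),
        locus_b=("2", 5_000_000),
        marker_map=marker_map,
        phenotype_means=means,
        noise_sd=noise_sd,
        seed=seed,
    )


class TestF2Cross:
    def test_affected_fraction_near_one_sixteenth(self):
        cohort = simulate.simulate_f2_cross(small_cross(n=100_000, seed=11))
        p = 1 / 16
        sd = np.sqrt(p * (1 - p) / 100_000)
        assert abs(cohort.affected.mean() - p) < 3 * sd

    def test_single_marker_genotype_distribution_is_mendelian(self):
        cohort = simulate.simulate_f2_cross(small_cross(n=100_000, seed=3))
        counts = np.bincount(cohort.genotypes[:, 0], minlength=3) / 100_000
        for obs, exp in zip(counts, (0.25, 0.5, 0.25)):
            assert abs(obs - exp) < 3 * np.sqrt(exp * (1 - exp) / 100_000)

    def test_zero_noise_equal_means_gives_constant_phenotype(self):
        means = {(a, b): 0.7 for a in (0, 1, 2) for b in (0, 1, 2)}
        cohort = simulate.simulate_f2_cross(small_cross(n=500, noise_sd=0.0, means=means))
        assert np.all(cohort.phenotype == 0.7)

    def test_affected_flag_consistent_with_causal_genotypes(self):
        cohort = simulate.simulate_f2_cross(small_cross(n=5_000, seed=5))
        expect = (cohort.genotypes[:, cohort.locus_a_index] == 0) & (
            cohort.genotypes[:, cohort.locus_b_index] == 2
        )
        assert np.array_equal(cohort.affected, expect)

    def test_missing_causal_locus_raises_naming_it(self):
        cfg = small_cross()
        cfg.locus_a = ("1", 123)
        with pytest.raises(ValueError, match="locus_a"):
            simulate.simulate_f2_cross(cfg)

    def test_linked_markers_correlate_by_map_distance(self):
        # F2 dosage correlation between linked markers is 1 - 2r (Haldane r)
        mm = [("1", 1_000_000), ("1", 1_250_000), ("1", 9_000_000), ("2", 1_000_000)]
        cfg = simulate.CrossConfig(
            5_000, ("1", 1_000_000), ("2", 1_000_000), mm, seed=9
        )
        cohort = simulate.simulate_f2_cross(cfg)
        g = cohort.genotypes.astype(float)

        def expected_corr(d_bp):
            d_cm = d_bp / 1e6 * cfg.cm_per_mb
            r = 0.5 * (1 - np.exp(-2 * d_cm / 100))
            return 1 - 2 * r

        r_close = np.corrcoef(g[:, 0], g[:, 1])[0, 1]
        r_far = np.corrcoef(g[:, 0], g[:, 2])[0, 1]
        r_trans = np.corrcoef(g[:, 0], g[:, 3])[0, 1]
        assert r_close == pytest.approx(expected_corr(250_000), abs=0.03)
        assert r_far == pytest.approx(expected_corr(8_000_000), abs=0.05)
        assert abs(r_trans) < 0.05  # unlinked across chromosomes

    def test_bit_reproducible_given_seed(self):
        a = simulate.simulate_f2_cross(small_cross(seed=42))
        b = simulate.simulate_f2_cross(small_cross(seed=42))
        assert np.array_equal(a.genotypes, b.genotypes)
        assert np.array_equal(a.phenotype, b.phenotype)


class TestExtremePool:
    @pytest.mark.parametrize(
        "phenotype, k, expected",
        [
            ([5, 1, 3], 1, [1]),
            ([5, 1, 3], 3, [0, 1, 2]),
            ([2, 1, 1, 5], 1, [1]),  # duplicate minimum: earliest index
        ],
    )
    def test_selects_k_smallest_with_stable_ties(self, phenotype, k, expected):
        assert simulate.select_extreme_pool(np.array(phenotype), k).tolist() == expected

    def test_rejects_nonpositive_k(self):
        with pytest.raises(ValueError):
            simulate.select_extreme_pool(np.array([1.0, 2.0]), 0)


class TestPoolReads:
    def test_monomorphic_pool_yields_only_parent_a_reads(self):
        cohort = simulate.simulate_f2_cross(small_cross(n=200, seed=1))
        cohort.genotypes[:] = 2
        counts = simulate.simulate_pool_reads(cohort, np.arange(200), 30.0, 0.0, seed=2)
        assert np.all(counts.count_b == 0)

    def test_mean_frequency_matches_pool_dosage(self):
        # pooled frequency 0.25 across many markers
        n_markers = 10_000
        cohort = simulate.F2Cohort(
            genotypes=np.tile(np.array([[2], [0], [0], [0]], dtype=np.int8), (1, n_markers)),
            phenotype=np.zeros(4),
            affected=np.zeros(4, bool),
            chroms=np.repeat("1", n_markers),
            positions=np.arange(1, n_markers + 1),
            locus_a_index=0,
            locus_b_index=0,
        )
        counts = simulate.simulate_pool_reads(cohort, np.arange(4), 30.0, 0.0, seed=5)
        freq = counts.count_a.sum() / (counts.count_a + counts.count_b).sum()
        se = np.sqrt(0.25 * 0.75 / (30.0 * n_markers))
        assert abs(freq - 0.25) < 3 * se

    def test_empty_pool_rejected(self):
        cohort = simulate.simulate_f2_cross(small_cross(n=10))
        with pytest.raises(ValueError):
            simulate.simulate_pool_reads(cohort, np.array([], dtype=int), 30.0)


class TestCoverage:
    def test_flat_region_matches_base_depth(self):
        spec = simulate.CoverageSimSpec(1_000_000, 30.0, seed=0)
        profile = simulate.simulate_coverage(spec)
        assert abs(profile.depth.mean() - 30.0) / 30.0 < 0.01

    @pytest.mark.parametrize("zygosity, ratio", [("homozygous", 3.0), ("heterozygous", 2.0)])
    def test_three_copy_duplication_depth_ratio(self, zygosity, ratio):
        spec = simulate.CoverageSimSpec(
            600_000, 30.0, cn_track=[(200_001, 400_001, 3)], zygosity=zygosity, seed=1
        )
        profile = simulate.simulate_coverage(spec)
        inside = profile.depth[200_000:400_000].mean()
        outside = np.concatenate([profile.depth[:200_000], profile.depth[400_000:]]).mean()
        assert abs(inside / outside - ratio) / ratio < 0.01

    def test_reproducible(self):
        spec = simulate.CoverageSimSpec(10_000, 20.0, seed=9)
        a = simulate.simulate_coverage(spec)
        b = simulate.simulate_coverage(spec)
        assert np.array_equal(a.depth, b.depth)


class TestJunctions:
    def test_blunt_derived_length_adds_interval_length(self, random_dna):
        ref = random_dna(500, seed=1)
        res = simulate.make_duplication_junction(
            simulate.JunctionSpec(ref, (150, 350), simulate.Blunt()), seed=0
        )
        assert len(res.derived) == len(res.reference) + 200
        assert res.annotation.mechanism == "blunt"

    def test_microhomology_round_trips_through_classifier(self, random_dna):
        ref = random_dna(500, seed=2)
        res = simulate.make_duplication_junction(
            simulate.JunctionSpec(ref, (150, 350), simulate.Microhomology("CT")), seed=1
        )
        call = cnv.classify_junction(res.reference, 350, 150, res.derived[325:375])
        assert call.mechanism == "microhomology"
        assert call.signature == "CT"
        assert call.length == 2

    def test_templated_insert_annotated_with_true_length(self, random_dna):
        ref = random_dna(500, seed=3)
        res = simulate.make_duplication_junction(
            simulate.JunctionSpec(ref, (150, 350), simulate.Templated("AAGACATAA")), seed=2
        )
        assert res.annotation.mechanism == "templated"
        assert res.annotation.length == 9
        # the derived sequence carries the insert at the junction
        assert res.derived[350:359] == "AAGACATAA"

    def test_interval_in_tandem_in_derived(self, random_dna):
        ref = random_dna(400, seed=4)
        res = simulate.make_duplication_junction(
            simulate.JunctionSpec(ref, (100, 300), simulate.Blunt()), seed=3
        )
        assert res.derived[100:300] == res.derived[300:500] == res.reference[100:300]


class TestWrightFisher:
    def test_neutral_deterministic_frequency_constant(self):
        traj = simulate.simulate_wright_fisher(
            simulate.WFParams(N=100, s=0.0, h=0.5, p0=0.3, generations=50)
        )
        assert np.all(traj.freq == 0.3)

    def test_one_step_matches_hand_evaluated_recursion(self):
        # p' = (0.25*1.1 + 0.25*1.05) / (0.25*1.1 + 0.5*1.05 + 0.25)
        traj = simulate.simulate_wright_fisher(
            simulate.WFParams(N=100, s=0.1, h=0.5, p0=0.5, generations=1)
        )
        assert traj.freq[-1] == pytest.approx(0.5375 / 1.05, abs=1e-12)

    def test_neutral_stochastic_mean_is_martingale(self):
        finals = [
            simulate.simulate_wright_fisher(
                simulate.WFParams(N=200, s=0.0, h=0.5, p0=0.4, generations=20,
                                  mode="stochastic", seed=s)
            ).freq[-1]
            for s in range(400)
        ]
        se = np.std(finals) / np.sqrt(len(finals))
        assert abs(np.mean(finals) - 0.4) < 3.5 * se

    @pytest.mark.parametrize("h", [0.0, 0.5, 1.0])
    def test_deterministic_trajectory_monotone_in_s(self, h):
        s_grid = [0.0, 0.02, 0.05, 0.1, 0.3]
        trajs = [popgen.wright_fisher_deterministic(0.05, s, h, 100) for s in s_grid]
        for lo, hi in zip(trajs[:-1], trajs[1:]):
            assert np.all(hi >= lo - 1e-15)


class TestSplitSample:
    def test_output_dimensions(self):
        cfg = simulate.SplitSimConfig(
            N_anc=100, N_1=100, N_2=100, T_split=10, n_1=6, n_2=4, n_sites=50, seed=0
        )
        g1, g2 = simulate.simulate_split_sample(cfg)
        assert g1.shape == (50, 6)
        assert g2.shape == (50, 4)

    def test_no_split_time_gives_matching_frequencies(self):
        cfg = simulate.SplitSimConfig(
            N_anc=500, N_1=500, N_2=500, T_split=0, n_1=200, n_2=200, n_sites=400, seed=1
        )
        g1, g2 = simulate.simulate_split_sample(cfg)
        diff = np.abs(g1.mean(axis=1) - g2.mean(axis=1))
        # both samples draw from the identical per-site frequency
        assert diff.mean() < 0.06

    def test_long_isolation_fixes_most_sites(self):
        cfg = simulate.SplitSimConfig(
            N_anc=20, N_1=20, N_2=20, T_split=2_000, n_1=10, n_2=10, n_sites=300, seed=2
        )
        g1, g2 = simulate.simulate_split_sample(cfg)
        fixed1 = np.isin(g1.sum(axis=1), [0, 10]).mean()
        fixed2 = np.isin(g2.sum(axis=1), [0, 10]).mean()
        assert fixed1 > 0.9 and fixed2 > 0.9

    def test_reproducible(self):
        cfg = simulate.SplitSimConfig(
            N_anc=50, N_1=50, N_2=50, T_split=5, n_1=5, n_2=5, n_sites=30, seed=3
        )
        a1, a2 = simulate.simulate_split_sample(cfg)
        b1, b2 = simulate.simulate_split_sample(cfg)
        assert np.array_equal(a1, b1) and np.array_equal(a2, b2)
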