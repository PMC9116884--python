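"""Spectra, sweep model, CLR scan, selection fitting, rate/map utilities."""

import math

import numpy as np
import pandas as pd
import pytest

from adaptscan import popgen, simulate
from adaptscan.popgen import (
    BackgroundSpectrum,
    clr_scan,
    corrected_mutation_rate,
    estimate_s,
    estimate_s_epochs,
    folded_jsfs,
    scale_genetic_map,
    sweep_spectrum,
    watterson_theta,
)


class TestWattersonTheta:
    def test_no_segregating_sites(self):
        assert watterson_theta(0, 10, 1_000) == 0.0

    def test_pairwise_sample_harmonic_is_one(self):
        assert watterson_theta(5, 2, 1_000) == pytest.approx(0.005)

    def test_five_sample_harmonic_sum(self):
        # a1 = 1 + 1/2 + 1/3 + 1/4 = 25/12
        expected = 10 / ((25 / 12) * 10_000)
        assert watterson_theta(10, 5, 10_000) == pytest.approx(expected)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            watterson_theta(5, 1, 100)


class TestRateAndMap:
    @pytest.mark.parametrize(
        "missing, total, expected",
        [(0, 100, 7e-9), (50, 100, 3.5e-9)],
    )
    def test_missing_data_correction(self, missing, total, expected):
        assert corrected_mutation_rate(missing, total) == pytest.approx(expected)

    def test_inverts_to_printed_regional_rate(self):
        # fraction chosen so that 7e-9 * (1 - f) = 1.55189e-9
        total = 100_000
        missing = round((1 - 1.55189 / 7) * total)
        assert corrected_mutation_rate(missing, total) == pytest.approx(1.55189e-9, rel=1e-4)

    def test_two_constants_are_distinct(self):
        assert popgen.BASE_MUTATION_RATE != popgen.DADI_MUTATION_RATE

    @pytest.mark.parametrize("rate, divisor", [(0.05, 20.0), (1.0, 1.0), (0.1, 10.0)])
    def test_outcrossing_divisor(self, rate, divisor):
        gmap = pd.DataFrame({"position": [1, 100, 200], "cM": [0.0, 5.0, 10.0]})
        scaled = scale_genetic_map(gmap, outcrossing_rate=rate)
        assert scaled["cM"].iloc[2] == pytest.approx(10.0 / divisor)
        assert scaled["position"].tolist() == [1, 100, 200]

    def test_non_monotone_map_rejected(self):
        gmap = pd.DataFrame({"position": [1, 100], "cM": [5.0, 1.0]})
        with pytest.raises(ValueError):
            scale_genetic_map(gmap)


class TestFoldedJsfs:
    def test_single_site_hand_tabulation(self):
        # minor counts (1, 0) in samples of 4 and 4 haploids
        g1 = np.array([[1, 0, 0, 0]])
        g2 = np.array([[0, 0, 0, 0]])
        spec = folded_jsfs(g1, g2, subsample_fraction=1.0, seed=0)
        assert spec.jsfs[1, 0] == 1
        assert spec.jsfs.sum() == 1

    def test_monomorphic_input_rejected(self):
        g = np.zeros((5, 4), dtype=int)
        with pytest.raises(ValueError):
            folded_jsfs(g, g, seed=0)

    def test_invariant_to_allele_relabeling(self, rng):
        g1 = rng.integers(0, 2, size=(200, 10))
        g2 = rng.integers(0, 2, size=(200, 10))
        a = folded_jsfs(g1, g2, seed=7)
        b = folded_jsfs(1 - g1, 1 - g2, seed=7)
        assert np.array_equal(a.jsfs, b.jsfs)

    def test_no_mass_above_folded_margin(self, rng):
        g1 = rng.integers(0, 2, size=(300, 8))
        g2 = rng.integers(0, 2, size=(300, 8))
        spec = folded_jsfs(g1, g2, seed=1)
        c1, c2 = np.meshgrid(
            np.arange(spec.jsfs.shape[0]), np.arange(spec.jsfs.shape[1]), indexing="ij"
        )
        assert spec.jsfs[(c1 + c2) * 2 > spec.n1 + spec.n2].sum() == 0

    def test_missing_calls_respected(self):
        g1 = np.array([[1, 0, -1, 0, 0, 0, 0, 0, 0, 0]])
        g2 = np.ones((1, 10), dtype=int)
        spec = folded_jsfs(g1, g2, subsample_fraction=0.9, seed=3)
        # 9 of 10 non-missing calls available -> site usable
        assert spec.jsfs.sum() == 1

    def test_off_diagonal_mass_grows_with_split_time(self):
        masses = []
        for t_split in (0, 60, 400):
            cfg = simulate.SplitSimConfig(
                N_anc=100, N_1=100, N_2=100, T_split=t_split,
                n_1=10, n_2=10, n_sites=800, seed=5,
            )
            g1, g2 = simulate.simulate_split_sample(cfg)
            spec = folded_jsfs(g1, g2, seed=5)
            c1, c2 = np.meshgrid(
                np.arange(spec.jsfs.shape[0]), np.arange(spec.jsfs.shape[1]), indexing="ij"
            )
            denom = spec.n1 + spec.n2
            dist = np.abs(c1 / spec.n1 - c2 / spec.n2)
            masses.append((spec.jsfs * dist).sum() / spec.jsfs.sum())
        assert masses[0] < masses[1] < masses[2]


def enumerate_sweep_spectrum(bg: BackgroundSpectrum, p_esc: float, n: int) -> np.ndarray:
    """Exhaustive enumeration oracle for the sweep-perturbed spectrum.

    Walks every escape pattern of the n lineages, every background draw
    (derived count among the bg sample), every subsampled configuration and
    every choice of the sweeping ancestor, accumulating exact probabilities
    with binomial coefficients only.
    """
    probs = np.zeros(n + 1)
    for e in range(n + 1):
        w_e = math.comb(n, e) * p_esc**e * (1 - p_esc) ** (n - e)
        m = e + 1 if e < n else n
        for j_full in range(1, bg.n):
            p_j = bg.probs[j_full]
            if p_j == 0:
                continue
            for j in range(0, m + 1):
                # hypergeometric: j derived among m drawn from bg.n with j_full derived
                num = math.comb(j_full, j) * math.comb(bg.n - j_full, m - j)
                den = math.comb(bg.n, m)
                if num == 0:
                    continue
                q = p_j * num / den
                if e < n:
                    if j >= 1:
                        probs[j - 1 + (n - e)] += w_e * q * (j / m)
                    probs[j] += w_e * q * ((m - j) / m)
                else:
                    probs[j] += w_e * q
    return probs


class TestSweepSpectrum:
    def test_full_escape_recovers_background(self):
        n = 8
        bg = BackgroundSpectrum.from_polymorphic(1.0 / np.arange(1, n))
        out = sweep_spectrum(bg, math.inf, 100.0, n)
        assert np.allclose(out, bg.probs)

    def test_no_escape_is_star_like(self):
        n = 8
        bg = BackgroundSpectrum.from_polymorphic(1.0 / np.arange(1, n))
        out = sweep_spectrum(bg, 0.0, 0.0, n)
        assert out[1:-1].sum() == pytest.approx(0.0, abs=1e-12)
        assert out[0] + out[-1] == pytest.approx(1.0)

    @pytest.mark.parametrize("n", [2, 3, 4, 5, 6])
    def test_matches_exhaustive_enumeration(self, n):
        bg = BackgroundSpectrum.from_polymorphic(1.0 / np.arange(1, n))
        for alpha, d in ((1e-5, 10_000), (1e-4, 3_000), (2e-6, 100_000)):
            out = sweep_spectrum(bg, alpha, d, n)
            p_esc = 1 - math.exp(-alpha * d)
            brute = enumerate_sweep_spectrum(bg, p_esc, n)
            assert out.sum() == pytest.approx(1.0, abs=1e-12)
            assert np.allclose(out, brute, atol=1e-12)

    def test_pairwise_sample_uniform_background(self):
        # n = 2, bg concentrated on j = 1: full enumeration over escape states
        bg = BackgroundSpectrum.from_polymorphic(np.array([1.0]))
        out = sweep_spectrum(bg, 1e-4, 5_000, 2)
        brute = enumerate_sweep_spectrum(bg, 1 - math.exp(-0.5), 2)
        assert out.sum() == pytest.approx(1.0)
        assert np.allclose(out, brute)

    @pytest.mark.parametrize("n", [4, 8, 12])
    def test_normalization_across_parameters(self, n):
        bg = BackgroundSpectrum.from_polymorphic(1.0 / np.arange(1, n))
        for alpha in (0.0, 1e-6, 1e-4, 1e-2):
            for d in (0.0, 1_000.0, 1e6):
                assert sweep_spectrum(bg, alpha, d, n).sum() == pytest.approx(1.0, abs=1e-9)


class TestClrScan:
    def _bg(self, n):
        return BackgroundSpectrum.from_polymorphic(1.0 / np.arange(1, n))

    def test_null_data_keeps_clr_near_zero(self, rng):
        n = 10
        bg = self._bg(n)
        pos = np.sort(rng.choice(np.arange(1, 1_000_000), 600, replace=False))
        b = rng.choice(np.arange(1, n), p=bg.probs[1:-1], size=600)
        track = clr_scan(pos, b, n, bg)
        assert (track.clr >= 0).all()
        assert track.clr.max() < 15.0

    def test_translation_equivariance(self, rng):
        n = 6
        bg = self._bg(n)
        pos = np.sort(rng.choice(np.arange(1, 500_000), 300, replace=False))
        b = rng.choice(np.arange(1, n), p=bg.probs[1:-1], size=300)
        base = clr_scan(pos, b, n, bg)
        shift = clr_scan(pos + 777_000, b, n, bg)
        assert np.array_equal(shift.grid, base.grid + 777_000)
        assert np.allclose(shift.clr, base.clr)

    def test_incomplete_background_rejected(self):
        n = 6
        probs = np.zeros(n + 1)
        probs[1] = 1.0
        bg = BackgroundSpectrum(probs, n)
        with pytest.raises(ValueError, match="background spectrum incomplete"):
            clr_scan(np.array([100, 200]), np.array([1, 3]), n, bg)

    def test_top_percentile_regions_contain_the_peak(self, rng):
        n = 10
        bg = self._bg(n)
        pos = np.sort(rng.choice(np.arange(1, 2_000_000), 1_000, replace=False))
        freq = simulate.conditioned_sweep_trajectory(2_000, 0.1, 0.5, seed=8)
        from adaptscan.demo import _sample_sweep_sites

        b = _sample_sweep_sites(bg, pos, 1_000_000, freq, n, 1e-8, rng)
        track = clr_scan(pos, b, n, bg)
        regions = popgen.clr_regions(track, percentile=99.0)
        assert len(regions) >= 1
        peak_pos = track.grid[np.argmax(track.clr)]
        hit = ((regions["start"] <= peak_pos) & (peak_pos < regions["end"])).any()
        assert hit


class TestEstimateS:
    def test_recovers_generating_coefficient(self):
        traj = popgen.wright_fisher_deterministic(0.01, 0.1, 0.5, 200)
        fit = estimate_s(0.01, float(traj[-1]), 200, h=0.5)
        assert fit.converged
        assert fit.s_hat == pytest.approx(0.1, abs=1e-4)

    def test_recessive_needs_stronger_selection_from_rarity(self):
        s_rec = estimate_s(1e-3, 0.99, 500, h=0.0).s_hat
        s_add = estimate_s(1e-3, 0.99, 500, h=0.5).s_hat
        assert s_rec > s_add

    def test_non_increasing_frequency_rejected(self):
        with pytest.raises(ValueError, match="no positive-selection solution"):
            estimate_s(0.5, 0.5, 100, h=0.5)
        with pytest.raises(ValueError):
            estimate_s(0.6, 0.5, 100, h=0.5)

    def test_epochwise_fit_splits_trajectory(self):
        first = popgen.wright_fisher_deterministic(0.01, 0.05, 0.5, 100)
        second = popgen.wright_fisher_deterministic(float(first[-1]), 0.2, 0.5, 100)
        fits = estimate_s_epochs(
            [(0, 0.01), (100, float(first[-1])), (200, float(second[-1]))], h=0.5
        )
        assert fits[0].s_hat == pytest.approx(0.05, abs=1e-4)
        assert fits[1].s_hat == pytest.approx(0.2, abs=1e-4)


class TestSfsFromCounts:
    def test_folded_and_polarized_shapes(self):
        derived = np.array([1, 1, 3, 5, 5, 5])
        pol = popgen.sfs_from_counts(derived, 6, polarized=True)
        fold = popgen.sfs_from_counts(derived, 6, polarized=False)
        assert pol.sfs.tolist() == [0, 2, 0, 1, 0, 3, 0]
        assert fold.sfs.tolist() == [0, 5, 0, 1]
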