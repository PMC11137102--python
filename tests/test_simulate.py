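"""Synthetic cohort generator: archetypes, sampling models, ground truth."""

import numpy as np
import pandas as pd
import pytest

from cfcin import stats
from cfcin.simulate import (BimodalOffsets, CenterOffsets, CohortConfig,
                            expected_bin_ratio, generate_bin_grid,
                            generate_cluster_archetypes,
                            generate_nucleosome_track, simulate_binned_reads,
                            simulate_cohort, simulate_fragment_starts,
                            simulate_methylation, simulate_survival,
                            generate_methylation_regions)
from cfcin.nucleosome import NucleosomeTrack, distance_profile


def grid_and_arch(config):
    rng = np.random.default_rng(config.seed)
    grid = generate_bin_grid(config, rng)
    return grid, generate_cluster_archetypes(config, grid, rng)


class TestConfig:
    def test_cluster_probs_must_sum_to_one(self):
        with pytest.raises(ValueError):
            CohortConfig(cluster_probs=(0.2, 0.2, 0.2)).validate()

    def test_tf_range_in_unit_interval(self):
        with pytest.raises(ValueError):
            CohortConfig(tissue_tf_range=(0.2, 1.4)).validate()

    def test_too_few_bins_for_peaks(self):
        with pytest.raises(ValueError):
            CohortConfig(n_bins=80).validate()


class TestArchetypes:
    def test_default_peak_counts(self):
        config = CohortConfig().validate()
        _, arch = grid_and_arch(config)
        assert arch.peaks.n == 102
        assert arch.peaks.n_amp == 43
        assert arch.peaks.n_del == 59
        assert arch.centroids.centroids.shape == (3, 102)

    def test_empty_peak_set(self):
        config = CohortConfig(n_amp_peaks=0, n_del_peaks=0)
        _, arch = grid_and_arch(config)
        assert arch.peaks.n == 0
        assert arch.centroids.centroids.shape == (3, 0)

    def test_deterministic_under_seed(self, small_config):
        _, a1 = grid_and_arch(small_config)
        _, a2 = grid_and_arch(small_config)
        assert np.array_equal(a1.peaks.start, a2.peaks.start)
        assert np.array_equal(a1.centroids.centroids, a2.centroids.centroids)
        for k in (1, 2, 3):
            assert np.array_equal(a1.templates[k], a2.templates[k])

    def test_cluster1_near_diploid_others_heavy(self):
        config = CohortConfig().validate()
        _, arch = grid_and_arch(config)
        burden = {k: np.mean(arch.templates[k] != 2) for k in (1, 2, 3)}
        assert burden[1] < 0.05
        assert burden[2] > 0.1 and burden[3] > 0.1

    def test_high_cin_templates_contain_alias_breaking_states(self):
        config = CohortConfig().validate()
        _, arch = grid_and_arch(config)
        for k in (2, 3):
            assert np.any(arch.templates[k] == 4)
            assert np.any(arch.templates[k] == 0)

    def test_templates_distinguishable(self):
        config = CohortConfig().validate()
        _, arch = grid_and_arch(config)
        c2, c3 = arch.centroids.centroids[1], arch.centroids.centroids[2]
        r = np.corrcoef(c2, c3)[0, 1]
        assert 0.0 < r < 0.95  # overlapping but not identical patterns


class TestBinnedReads:
    def test_no_tumor_signal_uniform_up_to_gc(self):
        rng = np.random.default_rng(8)
        gc = np.linspace(0.8, 1.2, 200)
        counts = simulate_binned_reads(np.full(200, 2), 0.0, 2_000_000, rng,
                                       gc_factor=gc)
        expected = 2_000_000 * gc / gc.sum()
        nb_sd = np.sqrt(expected + expected ** 2 / 2000.0)
        assert np.all(np.abs(counts - expected) < 5.5 * nb_sd)

    def test_pure_tumor_cn4_doubles_mean(self, rng):
        template = np.full(200, 2)
        template[50:100] = 4
        counts = simulate_binned_reads(template, 1.0, 4_000_000, rng)
        ratio = counts[50:100].mean() / counts[150:].mean()
        assert ratio == pytest.approx(2.0, rel=0.02)

    def test_mixture_mean_matches_closed_form(self, rng):
        # tf=0.3, CN=3 -> ratio (2*0.7 + 0.3*3)/2 = 1.15
        assert expected_bin_ratio(3, 0.3) == pytest.approx(1.15)
        template = np.full(100, 2)
        template[:50] = 3
        reps = np.stack([
            simulate_binned_reads(template, 0.3, 100_000, rng,
                                  dispersion=np.inf) for _ in range(50)])
        ratio = reps[:, :50].mean() / reps[:, 50:].mean()
        # 3 standard errors of the Monte-Carlo ratio
        se = 1.15 * np.sqrt(2.0 / reps[:, 50:].sum())
        assert abs(ratio - 1.15) < 3 * se

    def test_negative_copy_number_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_binned_reads(np.array([2, -1]), 0.1, 1000, rng)

    def test_total_counts_near_target(self, rng):
        counts = simulate_binned_reads(np.full(500, 2), 0.2, 1_000_000, rng)
        assert counts.sum() == pytest.approx(1_000_000, rel=0.01)


class TestFragments:
    def track(self):
        return NucleosomeTrack({"chrN": 1000 + np.arange(3000) * 200})

    def test_pure_healthy_converges_to_healthy_profile(self, rng):
        t = self.track()
        h, m = BimodalOffsets(), CenterOffsets()
        prof = distance_profile(
            simulate_fragment_starts(0.0, 300_000, t, h, m, rng), t)
        ref = distance_profile(
            simulate_fragment_starts(0.0, 300_000, t, h, m, rng), t)
        assert np.max(np.abs(prof.fractions - ref.fractions)) < 0.01
        centers = (prof.edges[:-1] + prof.edges[1:]) / 2
        dip = np.argmin(np.abs(centers))
        assert prof.fractions[np.argmin(np.abs(centers + 73))] \
            > prof.fractions[dip]

    def test_half_mixture_is_average_of_pure_profiles(self, rng):
        t = self.track()
        h, m = BimodalOffsets(), CenterOffsets()
        n = 1_000_000
        p0 = distance_profile(
            simulate_fragment_starts(0.0, n, t, h, m, rng), t)
        p1 = distance_profile(
            simulate_fragment_starts(1.0, n, t, h, m, rng), t)
        p5 = distance_profile(
            simulate_fragment_starts(0.5, n, t, h, m, rng), t)
        expected = 0.5 * (p0.fractions + p1.fractions)
        # binomial sampling error per bin at n draws
        tol = 4 * np.sqrt(np.maximum(expected, 1e-6) / n) + 1e-4
        assert np.all(np.abs(p5.fractions - expected) < tol)

    def test_invalid_weight_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_fragment_starts(1.2, 100, self.track(),
                                     BimodalOffsets(), CenterOffsets(), rng)


class TestMethylationGenerator:
    def test_design_constraint_on_healthy_means(self):
        rng = np.random.default_rng(0)
        reg = generate_methylation_regions(CohortConfig(), rng)
        assert np.all(reg.healthy_mean < 0.03)

    def test_mixture_closed_form(self):
        rng = np.random.default_rng(0)
        reg = generate_methylation_regions(
            CohortConfig(n_meth_regions=1, healthy_beta_range=(0.02, 0.02001),
                         tumor_beta_high=(0.7, 0.70001)), rng)
        m = simulate_methylation(0.4, 0.4, False, reg, cluster=2, rng=rng,
                                 noise_sd=0.0)
        assert m["beta_pre"][0] == pytest.approx(0.6 * 0.02 + 0.4 * 0.7,
                                                 abs=1e-5)

    def test_pure_tumor_noiseless_returns_tumor_beta(self):
        rng = np.random.default_rng(1)
        reg = generate_methylation_regions(CohortConfig(), rng)
        m = simulate_methylation(1.0, 1.0, False, reg, cluster=3, rng=rng,
                                 noise_sd=0.0)
        assert np.allclose(m["beta_pre"], reg.tumor_mean_high)

    def test_tf_zero_indistinguishable_from_healthy(self):
        rng = np.random.default_rng(2)
        reg = generate_methylation_regions(CohortConfig(), rng)
        m = simulate_methylation(0.0, 0.0, False, reg, cluster=2, rng=rng,
                                 noise_sd=0.0)
        assert np.allclose(m["beta_pre"], reg.healthy_mean)

    def test_responder_post_shifted_down(self):
        rng = np.random.default_rng(3)
        reg = generate_methylation_regions(CohortConfig(), rng)
        m = simulate_methylation(0.5, 0.5, True, reg, cluster=2, rng=rng,
                                 treatment_effect=0.15, noise_sd=0.0)
        assert np.allclose(m["tumor_beta_pre"] - m["tumor_beta_post"], 0.15,
                           atol=0.15 + 1e-9)  # clip at 0 allows smaller
        assert np.all(m["beta_post"] <= m["beta_pre"] + 1e-12)


class TestSurvivalGenerator:
    def test_null_hazard_ratios_recovered(self, rng):
        clusters = np.where(rng.random(2000) < 0.5, 1, 2)
        df = simulate_survival(clusters, None, 1 / 300, 1.0, 1.0, 0.0, rng)
        fit = stats.cox_ph(np.isin(clusters, (2, 3)).astype(float)[:, None],
                           df.time, df.event)
        assert 0.85 <= fit.hr[0] <= 1.18

    def test_strong_effect_recovered(self, rng):
        clusters = np.where(rng.random(2000) < 0.5, 1, 2)
        df = simulate_survival(clusters, None, 1 / 300, 0.2, 1.0, 0.0, rng)
        fit = stats.cox_ph(np.isin(clusters, (2, 3)).astype(float)[:, None],
                           df.time, df.event)
        assert 0.15 <= fit.hr[0] <= 0.27

    def test_full_censoring_flags_km_median_undefined(self, rng):
        clusters = np.ones(50, dtype=int)
        df = simulate_survival(clusters, None, 1 / 300, 1.0, 1.0, 1.0, rng)
        assert (df.event == 0).all()
        with pytest.raises(ValueError):
            stats.kaplan_meier(df.time, df.event)

    def test_methylation_delta_lowers_hazard(self, rng):
        clusters = np.ones(4000, dtype=int)
        deltas = np.r_[np.full(2000, -0.2), np.zeros(2000)]
        df = simulate_survival(clusters, deltas, 1 / 300, 1.0, 0.5, 0.0, rng)
        fit = stats.cox_ph((deltas < np.median(deltas)).astype(float)[:, None],
                           df.time, df.event)
        assert 0.42 <= fit.hr[0] <= 0.60


class TestFullCohort:
    def test_cluster1_prevalence_within_binomial_noise(self):
        config = CohortConfig(n_patients=1000, n_bins=1500,
                              reads_per_sample=200_000, n_fragments=100,
                              n_healthy=3, seed=9)
        cohort = simulate_cohort(config)
        freq = float((cohort.truth.cluster == 1).mean())
        sd = np.sqrt(0.1 * 0.9 / 1000)
        assert abs(freq - 0.1) <= 3 * sd

    def test_plasma_tf_scales_exactly_with_ratio(self, small_cohort):
        t = small_cohort.truth
        ratio = small_cohort.config.plasma_to_tissue_tf_ratio
        assert np.allclose(t.plasma_tf, t.tissue_tf * ratio)

    def test_bitwise_reproducible_under_seed(self, small_config,
                                             small_cohort):
        again = simulate_cohort(small_config)
        assert np.array_equal(again.tissue_counts,
                              small_cohort.tissue_counts)
        assert np.array_equal(again.plasma_counts, small_cohort.plasma_counts)
        pd.testing.assert_frame_equal(again.truth, small_cohort.truth)
        pd.testing.assert_frame_equal(again.meth_beta_pre,
                                      small_cohort.meth_beta_pre)
        for f1, f2 in zip(again.plasma_fragments,
                          small_cohort.plasma_fragments):
            for c in f1:
                assert np.array_equal(f1[c], f2[c])

    def test_survival_times_positive_and_events_binary(self, small_cohort):
        t = small_cohort.truth
        assert (t.os_time > 0).all() and (t.pfs_time > 0).all()
        assert set(t.os_event) <= {0, 1}
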