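"""Generator determinism, design constants, and the closed-form
correlation oracle."""

import numpy as np
import pytest
from scipy import stats

from dyadsync import (GeneratorConfig, cronbach_alpha, dyad_isc,
                      expected_dyad_correlation, gaze_similarity_table,
                      generate_eeg_dataset, generate_fmri_dataset,
                      generate_gaze_dataset, generate_profiles,
                      dyad_similarity_table, nm_synchrony)
from dyadsync.config import ConfigurationError


def _oracle_config(**kw):
    base = dict(n_subjects=2, n_regions=1, n_subcortical=0,
                n_voxels_per_region=3, n_runs=1, seed=5)
    base.update(kw)
    return GeneratorConfig(**base)


class TestConfig:
    def test_invalid_likert_bounds_rejected(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(scale_min=5, scale_max=5)

    def test_images_must_tile_categories(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_images=10, n_categories=3)

    def test_counts_must_be_positive(self):
        with pytest.raises(ConfigurationError):
            GeneratorConfig(n_subjects=0)

    def test_default_design_constants(self):
        cfg = GeneratorConfig()
        assert cfg.n_regions == 200 + 14
        assert cfg.n_images == 104 and cfg.n_categories == 26
        assert cfg.n_channels == 32
        assert cfg.epoch_length / cfg.sampling_rate == 3.0  # 3-second epochs


class TestProfiles:
    def test_determinism(self):
        cfg = GeneratorConfig(n_subjects=8, seed=42)
        a = generate_profiles(cfg)
        b = generate_profiles(cfg)
        assert np.array_equal(a.latent_traits, b.latent_traits)
        assert a.item_responses.equals(b.item_responses)
        assert a.demographics.equals(b.demographics)

    def test_seed_changes_output(self):
        a = generate_profiles(GeneratorConfig(n_subjects=8, seed=1))
        b = generate_profiles(GeneratorConfig(n_subjects=8, seed=2))
        assert not np.array_equal(a.latent_traits, b.latent_traits)

    def test_bfi2_item_count(self):
        cfg = GeneratorConfig(n_subjects=225, n_traits=5,
                              n_facets_per_trait=3, n_items_per_facet=4,
                              seed=0)
        p = generate_profiles(cfg)
        assert p.item_responses.shape == (225, 60)

    def test_noise_free_items_identical_within_facet(self):
        cfg = GeneratorConfig(n_subjects=10, n_items_per_facet=4,
                              item_noise_sd=0.0, seed=9)
        p = generate_profiles(cfg)
        for facet, grp in p.keying.groupby("facet"):
            cols = []
            for _, row in grp.iterrows():
                col = p.item_responses[row["item"]].astype(float)
                if row["reverse"]:
                    col = row["scale_min"] + row["scale_max"] - col
                cols.append(col.to_numpy())
            arr = np.column_stack(cols)
            assert np.all(arr == arr[:, :1])
            assert cronbach_alpha(arr + 1e-9 * np.arange(len(arr))[:, None]
                                  ) == pytest.approx(1.0, abs=1e-6)

    def test_responses_within_scale(self, tiny_profiles):
        lo = tiny_profiles.keying["scale_min"].iloc[0]
        hi = tiny_profiles.keying["scale_max"].iloc[0]
        vals = tiny_profiles.item_responses.to_numpy()
        assert vals.min() >= lo and vals.max() <= hi


class TestOracle:
    def test_identical_traits_no_noise_is_one(self):
        cfg = _oracle_config(shared_signal_weight=1.0, trait_coupling=0.5,
                             noise_sd=0.0)
        p = np.array([1.0, -0.5, 0.2, 0.0, 1.3])
        assert expected_dyad_correlation(p, p, cfg) == pytest.approx(1.0)

    def test_gamma_zero_is_trait_independent(self):
        cfg = _oracle_config(shared_signal_weight=2.0, trait_coupling=0.0,
                             noise_sd=1.0)
        expected = 4.0 / 5.0  # a^2 / (a^2 + sigma^2)
        for p_i, p_j in [(np.zeros(5), np.ones(5)),
                         (np.ones(5), -np.ones(5))]:
            assert expected_dyad_correlation(p_i, p_j, cfg) == pytest.approx(expected)

    def test_orthogonal_unit_traits(self):
        cfg = _oracle_config(shared_signal_weight=1.0, trait_coupling=1.0,
                             noise_sd=1.0)
        rho = expected_dyad_correlation(np.array([1.0, 0.0]),
                                        np.array([0.0, 1.0]), cfg)
        assert rho == pytest.approx(1.0 / 3.0)

    def test_all_zero_parameters_raise(self):
        cfg = _oracle_config(shared_signal_weight=0.0, trait_coupling=0.0,
                             noise_sd=0.0)
        with pytest.raises(ValueError):
            expected_dyad_correlation(np.ones(2), np.ones(2), cfg)


class TestFmriGenerator:
    def test_determinism(self, tiny_config):
        p = generate_profiles(tiny_config)
        a = generate_fmri_dataset(p, tiny_config)
        b = generate_fmri_dataset(p, tiny_config)
        assert np.array_equal(a.magnitude, b.magnitude)
        assert np.array_equal(a.patterns, b.patterns)

    def test_too_few_voxels_rejected(self, tiny_profiles, tiny_config):
        with pytest.raises(ConfigurationError, match="voxels"):
            generate_fmri_dataset(tiny_profiles,
                                  tiny_config.replace(n_voxels_per_region=2))

    def test_shared_signal_limit_gives_unit_synchrony(self):
        cfg = _oracle_config(n_timepoints_per_run=500,
                             shared_signal_weight=1.0, trait_coupling=0.0,
                             noise_sd=1e-9)
        p = generate_profiles(cfg)
        ds = generate_fmri_dataset(p, cfg)
        r = nm_synchrony(ds.magnitude[0, 0], ds.magnitude[1, 0])
        assert r == pytest.approx(1.0, abs=1e-6)

    def test_pure_noise_gives_zero_synchrony(self):
        cfg = _oracle_config(n_timepoints_per_run=20000,
                             shared_signal_weight=0.0, trait_coupling=0.0,
                             noise_sd=1.0, signal_smooth_sigma=2.0)
        p = generate_profiles(cfg)
        ds = generate_fmri_dataset(p, cfg)
        r = nm_synchrony(ds.magnitude[0, 0], ds.magnitude[1, 0])
        assert abs(r) < 0.03

    def test_empirical_correlation_matches_oracle(self):
        # long-series simulation against the closed form
        cfg = _oracle_config(n_timepoints_per_run=20000,
                             shared_signal_weight=1.0, trait_coupling=0.5,
                             noise_sd=1.0, signal_smooth_sigma=2.0)
        p = generate_profiles(cfg)
        ds = generate_fmri_dataset(p, cfg)
        want = expected_dyad_correlation(p.latent_traits[0],
                                         p.latent_traits[1], cfg)
        got = nm_synchrony(ds.magnitude[0, 0], ds.magnitude[1, 0])
        assert got == pytest.approx(want, abs=0.04)

    def test_network_labels_cover_regions(self, tiny_fmri):
        nets = tiny_fmri.region_meta["network"]
        assert (nets == "subcortical").sum() == 1
        assert nets.notna().all()

    def test_excluded_runs_are_nan(self):
        cfg = GeneratorConfig(n_subjects=4, n_regions=3, n_subcortical=1,
                              n_runs=4, n_timepoints_per_run=20,
                              run_exclusion_prob=0.5, seed=8)
        ds = generate_fmri_dataset(generate_profiles(cfg), cfg)
        assert not ds.exclusion_mask.all()
        for i in range(4):
            for j, sl in enumerate(ds.run_slices()):
                block = ds.magnitude[i, :, sl]
                if ds.exclusion_mask[i, j]:
                    assert np.isfinite(block).all()
                else:
                    assert np.isnan(block).all()


class TestEegGenerator:
    def test_determinism(self, tiny_config, tiny_profiles):
        a = generate_eeg_dataset(tiny_profiles, tiny_config)
        b = generate_eeg_dataset(tiny_profiles, tiny_config)
        assert np.array_equal(a.epochs, b.epochs)

    def test_noise_free_epochs_identical_across_subjects(self):
        cfg = GeneratorConfig(n_subjects=3, n_regions=2, n_subcortical=0,
                              n_images=4, n_categories=2, n_channels=6,
                              n_sources=3, epoch_length=100,
                              trait_coupling=0.0, noise_sd=0.0, seed=4)
        ds = generate_eeg_dataset(generate_profiles(cfg), cfg)
        assert np.allclose(ds.epochs[0], ds.epochs[1])
        assert dyad_isc(ds.epochs[0], ds.epochs[1],
                        n_components=3) == pytest.approx(1.0, abs=1e-9)

    def test_pure_noise_gives_near_zero_isc(self):
        # in-sample CorrCA optimism on pure noise decays as sqrt(c/T);
        # 4000-sample epochs keep the bias comfortably inside the bound
        cfg = GeneratorConfig(n_subjects=2, n_regions=2, n_subcortical=0,
                              n_images=20, n_categories=4, n_channels=8,
                              n_sources=4, epoch_length=4000,
                              shared_signal_weight=0.0, trait_coupling=0.0,
                              noise_sd=1.0, seed=6)
        ds = generate_eeg_dataset(generate_profiles(cfg), cfg)
        isc = dyad_isc(ds.epochs[0], ds.epochs[1], n_components=3)
        assert abs(isc) < 0.05

    def test_channel_correlation_matches_oracle(self):
        # unit-norm mixing rows make each channel follow the closed form
        cfg = GeneratorConfig(n_subjects=2, n_regions=2, n_subcortical=0,
                              n_images=8, n_categories=2, n_channels=4,
                              n_sources=3, epoch_length=4000,
                              shared_signal_weight=1.0, trait_coupling=0.5,
                              noise_sd=1.0, signal_smooth_sigma=2.0, seed=13)
        p = generate_profiles(cfg)
        ds = generate_eeg_dataset(p, cfg)
        want = expected_dyad_correlation(p.latent_traits[0],
                                         p.latent_traits[1], cfg)
        x = ds.epochs[0].reshape(cfg.n_channels, -1)
        y = ds.epochs[1].reshape(cfg.n_channels, -1)
        got = np.mean([stats.pearsonr(x[c], y[c])[0]
                       for c in range(cfg.n_channels)])
        assert got == pytest.approx(want, abs=0.04)


class TestGazeGenerator:
    def test_determinism(self, tiny_config, tiny_profiles):
        a = generate_gaze_dataset(tiny_profiles, tiny_config)
        b = generate_gaze_dataset(tiny_profiles, tiny_config)
        for sid in a.subject_ids:
            for iid in a.image_ids:
                assert np.array_equal(a.fixations[sid][iid],
                                      b.fixations[sid][iid])

    def test_single_attractor_zero_dispersion_gives_zero_emd(self):
        cfg = GeneratorConfig(n_subjects=4, n_regions=2, n_subcortical=0,
                              n_images=2, n_categories=1,
                              attractors_per_image=1,
                              attractor_dispersion=0.0, seed=2)
        ds = generate_gaze_dataset(generate_profiles(cfg), cfg)
        tab = gaze_similarity_table(ds, grid_dims=(16, 16))
        assert np.allclose(tab["gaze_similarity"], 0.0)

    def test_fixations_in_bounds_with_positive_durations(self, tiny_gaze):
        w, h = tiny_gaze.screen_dims
        for per_image in tiny_gaze.fixations.values():
            for arr in per_image.values():
                assert (arr[:, 0] >= 0).all() and (arr[:, 0] < w).all()
                assert (arr[:, 1] >= 0).all() and (arr[:, 1] < h).all()
                assert (arr[:, 2] > 0).all()

    def test_uncoupled_gaze_regression_beta_covers_zero(self):
        # with gaze_coupling = 0 fixation distributions are exchangeable,
        # so the similarity-on-similarity slope should be null on average
        betas = []
        for rep in range(20):
            cfg = GeneratorConfig(n_subjects=10, n_regions=2, n_subcortical=0,
                                  n_images=6, n_categories=2,
                                  gaze_coupling=0.0, seed=300 + rep)
            p = generate_profiles(cfg)
            gz = gaze_similarity_table(generate_gaze_dataset(p, cfg),
                                       grid_dims=(16, 16))
            sim = dyad_similarity_table(p)
            merged = sim.merge(gz, on=["subject_a", "subject_b"])
            r = np.corrcoef(merged["personality_similarity"],
                            merged["gaze_similarity"])[0, 1]
            betas.append(r)
        lo = np.mean(betas) - 1.96 * np.std(betas, ddof=1) / np.sqrt(len(betas))
        hi = np.mean(betas) + 1.96 * np.std(betas, ddof=1) / np.sqrt(len(betas))
        assert lo < 0.0 < hi

    def test_coupled_gaze_orders_dyads_by_trait_distance(self):
        cfg = GeneratorConfig(n_subjects=4, n_regions=2, n_subcortical=0,
                              n_images=12, n_categories=3, gaze_coupling=1.0,
                              attractor_dispersion=0.01, seed=17)
        p = generate_profiles(cfg)
        # twin pair (identical traits) vs an antipodal pair
        t = np.array([1.2, -0.8, 0.5, 1.5, -1.0])
        p.latent_traits = np.vstack([t, t, 3 * t, -3 * t])
        ds = generate_gaze_dataset(p, cfg)
        tab = gaze_similarity_table(ds, grid_dims=(16, 16)).set_index(
            ["subject_a", "subject_b"])
        s = p.subject_ids
        twin = tab.loc[(s[0], s[1]), "gaze_similarity"]
        far = tab.loc[(s[2], s[3]), "gaze_similarity"]
        assert twin > far
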