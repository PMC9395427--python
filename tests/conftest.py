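import numpy as np
import pytest

from dyadsync import (GeneratorConfig, generate_eeg_dataset,
                      generate_fmri_dataset, generate_gaze_dataset,
                      generate_profiles)


@pytest.fixture(scope="session")
def tiny_config():
    """A fast, fully exercised study design: 6 subjects, 5 regions over
    4 runs, 4 images on 6 EEG channels, 3-facet surveys."""
    return GeneratorConfig(
        n_subjects=6, n_traits=5, n_facets_per_trait=3, n_items_per_facet=2,
        n_regions=5, n_subcortical=1, n_voxels_per_region=4, n_runs=4,
        n_timepoints_per_run=60, n_images=4, n_categories=2, n_channels=6,
        n_sources=3, epoch_length=120, attractors_per_image=3,
        fixations_per_image=6, seed=11)


@pytest.fixture(scope="session")
def tiny_profiles(tiny_config):
    return generate_profiles(tiny_config)


@pytest.fixture(scope="session")
def tiny_fmri(tiny_config, tiny_profiles):
    return generate_fmri_dataset(tiny_profiles, tiny_config)


@pytest.fixture(scope="session")
def tiny_eeg(tiny_config, tiny_profiles):
    return generate_eeg_dataset(tiny_profiles, tiny_config)


@pytest.fixture(scope="session")
def tiny_gaze(tiny_config, tiny_profiles):
    return generate_gaze_dataset(tiny_profiles, tiny_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240917)
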