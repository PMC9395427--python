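"""Generator configuration.

A single :class:`GeneratorConfig` parameterizes every synthetic dataset
(surveys, region-level BOLD-like data, multichannel EEG-like epochs, gaze
fixations).  Defaults encode the study designs the package emulates: a
66-subject fMRI sample with 200 cortical parcels + 14 subcortical regions
over 4 runs, and a 225-subject EEG sample with 32 channels sampled at
500 Hz viewing 104 images in 26 categories for 3 s each.

The coupling parameters share one generative model across modalities::

    x_i(t) = a * s(t) + gamma * sum_k p_ik * g_k(t) + eps_i(t)

where ``s`` and ``g_k`` are unit-variance smooth signals shared across
subjects, ``p_i`` is subject *i*'s latent trait vector, and
``eps ~ N(0, sigma^2)`` is subject-specific noise.  ``gamma = 0`` makes
cross-subject synchrony independent of personality.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: Names for the cortical network labels attached to regions.
CORTICAL_NETWORKS = (
    "visual",
    "somatomotor",
    "dorsal_attention",
    "ventral_attention",
    "limbic",
    "frontoparietal",
    "default_mode",
)

#: Canonical Big Five trait names, in fixed order.
TRAIT_NAMES = (
    "openness",
    "conscientiousness",
    "extraversion",
    "agreeableness",
    "neuroticism",
)

# Seed-substream offsets: each dataset draws from an independent child
# stream of the master seed so regenerating one modality never perturbs
# another.
_SUBSTREAMS = {
    "profiles": 0,
    "fmri": 1,
    "eeg": 2,
    "eeg_forward": 3,
    "gaze": 4,
}


class ConfigurationError(ValueError):
    """Raised when a GeneratorConfig violates its invariants."""


@dataclass(frozen=True)
class GeneratorConfig:
    # --- sample & survey design ---
    n_subjects: int = 66
    n_traits: int = 5
    n_facets_per_trait: int = 1   # 1: TIPI-like; 3: BFI-2-like
    n_items_per_facet: int = 2
    item_noise_sd: float = 1.0
    facet_scatter_sd: float = 0.5
    scale_min: int = 1
    scale_max: int = 7

    # --- fMRI-like design ---
    n_regions: int = 214
    n_subcortical: int = 14
    n_voxels_per_region: int = 12
    n_runs: int = 4
    n_timepoints_per_run: int = 450
    run_exclusion_prob: float = 0.0

    # --- EEG-like design ---
    n_images: int = 104
    n_categories: int = 26
    n_channels: int = 32
    n_sources: int = 5
    epoch_length: int = 1500
    sampling_rate: float = 500.0

    # --- gaze design ---
    attractors_per_image: int = 5
    fixations_per_image: int = 8
    attractor_dispersion: float = 0.04  # sd of fixation scatter, unit-square units
    mean_fixation_ms: float = 250.0
    screen_dims: tuple[int, int] = (1920, 1080)

    # --- coupling model ---
    shared_signal_weight: float = 0.3   # a
    trait_coupling: float = 0.15        # gamma
    noise_sd: float = 1.0               # sigma
    gaze_coupling: float = 0.3
    signal_smooth_sigma: float = 3.0    # samples; low-pass width of s and g

    seed: int = 0

    def __post_init__(self) -> None:
        counts = {
            "n_subjects": self.n_subjects,
            "n_traits": self.n_traits,
            "n_facets_per_trait": self.n_facets_per_trait,
            "n_items_per_facet": self.n_items_per_facet,
            "n_regions": self.n_regions,
            "n_voxels_per_region": self.n_voxels_per_region,
            "n_runs": self.n_runs,
            "n_timepoints_per_run": self.n_timepoints_per_run,
            "n_images": self.n_images,
            "n_categories": self.n_categories,
            "n_channels": self.n_channels,
            "n_sources": self.n_sources,
            "epoch_length": self.epoch_length,
            "attractors_per_image": self.attractors_per_image,
            "fixations_per_image": self.fixations_per_image,
        }
        for name, value in counts.items():
            if value < 1:
                raise ConfigurationError(f"{name} must be >= 1, got {value}")
        if self.scale_max <= self.scale_min:
            raise ConfigurationError(
                f"invalid Likert bounds [{self.scale_min}, {self.scale_max}]"
            )
        if self.n_images % self.n_categories != 0:
            raise ConfigurationError(
                f"n_images ({self.n_images}) must be a multiple of "
                f"n_categories ({self.n_categories})"
            )
        if not 0 <= self.n_subcortical < self.n_regions:
            raise ConfigurationError(
                "n_subcortical must satisfy 0 <= n_subcortical < n_regions"
            )
        for name in ("item_noise_sd", "facet_scatter_sd", "shared_signal_weight",
                     "trait_coupling", "gaze_coupling", "attractor_dispersion",
                     "run_exclusion_prob"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be nonnegative")
        if any(d < 1 for d in self.screen_dims):
            raise ConfigurationError("screen_dims must be positive")

    # ------------------------------------------------------------------
    @property
    def images_per_category(self) -> int:
        return self.n_images // self.n_categories

    @property
    def n_items(self) -> int:
        return self.n_traits * self.n_facets_per_trait * self.n_items_per_facet

    def rng(self, stream: str) -> np.random.Generator:
        """Independent generator for a named substream of the master seed."""
        if stream not in _SUBSTREAMS:
            raise KeyError(f"unknown substream {stream!r}")
        ss = np.random.SeedSequence(entropy=self.seed,
                                    spawn_key=(_SUBSTREAMS[stream],))
        return np.random.default_rng(ss)

    # ------------------------------------------------------------------
    def replace(self, **changes) -> "GeneratorConfig":
        return dataclasses.replace(self, **changes)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["screen_dims"] = list(self.screen_dims)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GeneratorConfig":
        d = dict(d)
        if "screen_dims" in d:
            d["screen_dims"] = tuple(d["screen_dims"])
        return cls(**d)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "GeneratorConfig":
        """Load a config from JSON or YAML."""
        path = Path(path)
        text = path.read_text()
        if path.suffix in {".yaml", ".yml"}:
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        return cls.from_dict(data)
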