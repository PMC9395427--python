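"""In-memory containers for synthetic multi-subject datasets.

All containers are plain dataclasses around numpy arrays and pandas
frames; they validate their structural invariants at construction and
are the interchange currency between the generator, the synchrony
modules, and the inference layer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd


class GenerationError(RuntimeError):
    """Raised when a synthetic dataset cannot satisfy its invariants."""


@dataclass
class ProfileSet:
    """Per-subject survey responses, latent traits and demographics.

    Attributes
    ----------
    subject_ids : list of str
        Stable labels, lexicographically ordered.
    latent_traits : (n_subjects, n_traits) ndarray
        The generative trait vectors ``p_i`` (standard-normal scale).
    item_responses : DataFrame, subjects x items
        Likert responses as recorded (reverse-keyed items stored in
        their administered direction).
    keying : DataFrame
        One row per item: ``item, trait, facet, reverse, scale_min,
        scale_max``.
    demographics : DataFrame indexed by subject
        ``gender, age, ethnicity (frozenset), handedness, nationality,
        political_ideology``.
    """

    subject_ids: list[str]
    latent_traits: np.ndarray
    item_responses: pd.DataFrame
    keying: pd.DataFrame
    demographics: pd.DataFrame

    def __post_init__(self) -> None:
        n = len(self.subject_ids)
        if self.latent_traits.shape[0] != n:
            raise GenerationError("latent_traits row count != n_subjects")
        if list(self.item_responses.index) != list(self.subject_ids):
            raise GenerationError("item_responses index mismatch")
        keyed = set(self.keying["item"])
        if set(self.item_responses.columns) != keyed:
            raise GenerationError("every item must be keyed exactly once")
        if self.keying["item"].duplicated().any():
            raise GenerationError("duplicate item in keying")
        lo = self.keying.set_index("item")["scale_min"]
        hi = self.keying.set_index("item")["scale_max"]
        vals = self.item_responses
        for item in vals.columns:
            col = vals[item]
            if (col < lo[item]).any() or (col > hi[item]).any():
                raise GenerationError(f"responses out of scale bounds for {item}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)


@dataclass
class FmriDataset:
    """Region-parcellated magnitude series and voxel patterns per subject.

    ``magnitude`` is (subject, region, time) over the full concatenated
    time axis; ``patterns`` is (subject, region, voxel, time).  Runs
    partition the time axis via ``run_boundaries`` (start indices, one
    per run).  Excluded runs (``exclusion_mask`` False) hold NaN and are
    dropped at analysis time.
    """

    subject_ids: list[str]
    magnitude: np.ndarray
    patterns: np.ndarray
    run_boundaries: np.ndarray  # start index of each run
    region_meta: pd.DataFrame   # region_id, hemisphere, network
    exclusion_mask: np.ndarray  # (subject, run) bool; True = retained

    def __post_init__(self) -> None:
        n, r, t = self.magnitude.shape
        if len(self.subject_ids) != n:
            raise GenerationError("subject count mismatch")
        if self.patterns.shape[:2] != (n, r) or self.patterns.shape[3] != t:
            raise GenerationError("patterns shape inconsistent with magnitude")
        if len(self.region_meta) != r:
            raise GenerationError("region_meta length mismatch")
        if self.region_meta["network"].isna().any():
            raise GenerationError("every region needs a network label")
        rb = np.asarray(self.run_boundaries)
        if rb[0] != 0 or np.any(np.diff(rb) <= 0) or rb[-1] >= t:
            raise GenerationError("run boundaries must partition the time axis")
        if self.exclusion_mask.shape != (n, len(rb)):
            raise GenerationError("exclusion_mask shape mismatch")

    @property
    def n_runs(self) -> int:
        return len(self.run_boundaries)

    def run_slices(self) -> list[slice]:
        starts = list(self.run_boundaries)
        stops = starts[1:] + [self.magnitude.shape[2]]
        return [slice(a, b) for a, b in zip(starts, stops)]


@dataclass
class EegDataset:
    """Channel x time epochs per subject and image."""

    subject_ids: list[str]
    epochs: np.ndarray          # (subject, image, channel, time)
    sampling_rate: float
    image_meta: pd.DataFrame    # image_id, category

    def __post_init__(self) -> None:
        if self.epochs.ndim != 4:
            raise GenerationError("epochs must be 4-D")
        if self.epochs.shape[0] != len(self.subject_ids):
            raise GenerationError("subject count mismatch")
        if self.epochs.shape[1] != len(self.image_meta):
            raise GenerationError("image_meta length mismatch")
        if self.image_meta["image_id"].duplicated().any():
            raise GenerationError("image ids must be unique")


@dataclass
class GazeDataset:
    """Ordered fixation sequences (x, y, duration_ms) per subject and image.

    ``fixations[subject_id][image_id]`` is an (n_fix, 3) float array with
    pixel coordinates (origin top-left) and positive durations.
    """

    subject_ids: list[str]
    image_ids: list[str]
    fixations: dict[str, dict[str, np.ndarray]]
    screen_dims: tuple[int, int]

    def __post_init__(self) -> None:
        w, h = self.screen_dims
        for sid, per_image in self.fixations.items():
            for iid, arr in per_image.items():
                arr = np.asarray(arr, dtype=float)
                if arr.ndim != 2 or arr.shape[1] != 3:
                    raise GenerationError(f"bad fixation array for {sid}/{iid}")
                x, y, dur = arr.T
                if (x < 0).any() or (x >= w).any() or (y < 0).any() or (y >= h).any():
                    raise GenerationError(f"fixation out of bounds for {sid}/{iid}")
                if (dur <= 0).any():
                    raise GenerationError(f"non-positive duration for {sid}/{iid}")


def dyad_pairs(labels: list[str]) -> list[tuple[str, str]]:
    """All unordered subject pairs, (a, b) with a < b by label order.

    n subjects yield exactly n(n-1)/2 pairs.
    """
    labels = sorted(labels)
    return [(a, b) for i, a in enumerate(labels) for b in labels[i + 1:]]
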