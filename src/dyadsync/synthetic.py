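"""Synthetic multi-subject data with tunable personality-synchrony coupling.

The shared generative model across modalities is, for subject *i* in
region (or source) *r*::

    x_ir(t) = a * s_r(t) + gamma * sum_k p_ik * g_rk(t) + eps_ir(t)

with ``s_r`` and ``g_rk`` unit-variance smooth signals shared across
subjects, ``p_i`` the subject's latent Big Five vector (i.i.d. standard
normal per trait) and ``eps ~ N(0, sigma^2)`` i.i.d. noise.  Under this
model the population Pearson correlation between two subjects' series
has the closed form computed by :func:`expected_dyad_correlation` —
the oracle every synchrony estimator is checked against.

Smoothness: ``s`` and ``g`` are low-pass filtered white noise
(Gaussian kernel, width ``signal_smooth_sigma`` samples) standardized to
unit sample variance; ISC-style methods assume a temporally structured
shared signal, and filtering supplies that structure without changing
the cross-subject covariance algebra.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .config import CORTICAL_NETWORKS, TRAIT_NAMES, ConfigurationError, GeneratorConfig
from .datasets import EegDataset, FmriDataset, GazeDataset, GenerationError, ProfileSet

__all__ = [
    "generate_profiles",
    "generate_fmri_dataset",
    "generate_eeg_dataset",
    "generate_gaze_dataset",
    "expected_dyad_correlation",
]

# Demographic composition, loosely matching undergraduate samples of the
# kind the analysis is designed for.  Proportions are descriptive
# plumbing, not contract.
_GENDERS = (["female", "male"], [0.61, 0.39])
_ETHNICITIES = (
    ["Asian", "Hispanic/Latinx", "Caucasian/White", "Mixed", "Black/African"],
    [0.32, 0.29, 0.23, 0.14, 0.02],
)
_HANDEDNESS = (["right", "left"], [0.9, 0.1])
_NATIONALITIES = (["USA", "China", "India", "Other"], [0.65, 0.15, 0.1, 0.1])


def _smooth_unit_signals(rng: np.random.Generator, shape: tuple[int, ...],
                         sigma: float) -> np.ndarray:
    """Low-pass filtered white noise standardized to unit variance along
    the last axis."""
    x = rng.standard_normal(shape)
    if sigma > 0:
        x = gaussian_filter1d(x, sigma=sigma, axis=-1)
    x = x - x.mean(axis=-1, keepdims=True)
    sd = x.std(axis=-1, keepdims=True)
    sd[sd == 0] = 1.0
    return x / sd


# ----------------------------------------------------------------------
# Profiles
# ----------------------------------------------------------------------

def generate_profiles(config: GeneratorConfig) -> ProfileSet:
    """Draw latent traits, item responses and demographics.

    Latent traits are i.i.d. standard normal.  Each facet's latent value
    is the trait latent plus a facet-specific offset
    ``N(0, facet_scatter_sd^2)``; items add ``N(0, item_noise_sd^2)``
    noise after an affine map onto the Likert range (midpoint + z *
    range/4, so +/-2 latent SD spans the scale), then are clipped and
    rounded.  Reverse-keyed items (every second item of a facet) are
    stored reflected, i.e. in their administered direction.
    """
    if config.scale_max <= config.scale_min:
        raise ConfigurationError("invalid scale bounds")
    rng = config.rng("profiles")
    n, k = config.n_subjects, config.n_traits
    width = max(3, len(str(n)))
    subject_ids = [f"S{i + 1:0{width}d}" for i in range(n)]

    latent = rng.standard_normal((n, k))

    lo, hi = config.scale_min, config.scale_max
    mid = (lo + hi) / 2.0
    unit = (hi - lo) / 4.0

    trait_names = list(TRAIT_NAMES[:k]) + [
        f"trait{j + 1}" for j in range(max(0, k - len(TRAIT_NAMES)))
    ]

    rows = []
    responses: dict[str, np.ndarray] = {}
    for t_idx, trait in enumerate(trait_names):
        for f_idx in range(config.n_facets_per_trait):
            facet = f"{trait}_f{f_idx + 1}"
            facet_latent = latent[:, t_idx] + config.facet_scatter_sd * rng.standard_normal(n)
            for i_idx in range(config.n_items_per_facet):
                item = f"{facet}_q{i_idx + 1}"
                reverse = i_idx % 2 == 1
                raw = mid + unit * facet_latent + rng.normal(
                    0.0, config.item_noise_sd, size=n)
                resp = np.clip(np.rint(raw), lo, hi)
                if reverse:
                    resp = lo + hi - resp
                responses[item] = resp.astype(int)
                rows.append({"item": item, "trait": trait, "facet": facet,
                             "reverse": reverse, "scale_min": lo, "scale_max": hi})

    item_responses = pd.DataFrame(responses, index=subject_ids)
    keying = pd.DataFrame(rows)

    demo = pd.DataFrame(index=subject_ids)
    demo["gender"] = rng.choice(_GENDERS[0], size=n, p=_GENDERS[1])
    demo["age"] = np.clip(np.rint(rng.normal(20.5, 2.5, size=n)), 18, 40).astype(int)
    eths = []
    pool, probs = _ETHNICITIES
    for _ in range(n):
        first = rng.choice(pool, p=probs)
        labels = {str(first)}
        if rng.random() < 0.12:  # some subjects identify with two groups
            labels.add(str(rng.choice(pool)))
        eths.append(frozenset(labels))
    demo["ethnicity"] = eths
    demo["handedness"] = rng.choice(_HANDEDNESS[0], size=n, p=_HANDEDNESS[1])
    demo["nationality"] = rng.choice(_NATIONALITIES[0], size=n, p=_NATIONALITIES[1])
    demo["political_ideology"] = rng.binomial(6, 0.5, size=n) + 1  # 1..7

    return ProfileSet(subject_ids=subject_ids, latent_traits=latent,
                      item_responses=item_responses, keying=keying,
                      demographics=demo)


# ----------------------------------------------------------------------
# fMRI-like data
# ----------------------------------------------------------------------

def generate_fmri_dataset(profiles: ProfileSet,
                          config: GeneratorConfig) -> FmriDataset:
    """Region magnitude series and voxel x time pattern arrays.

    Magnitudes follow the shared coupling model with region-specific
    signals; patterns follow the same model independently per voxel with
    voxel-specific signals.  Excluded runs (Bernoulli
    ``run_exclusion_prob`` per subject-run) are filled with NaN.
    """
    if config.n_voxels_per_region < 3:
        raise ConfigurationError(
            "n_voxels_per_region must be >= 3 (spatial correlation is "
            "undefined below 3 voxels)")
    if profiles.n_subjects != config.n_subjects:
        raise GenerationError("profiles inconsistent with config")
    rng = config.rng("fmri")
    n, r = config.n_subjects, config.n_regions
    t_run, n_runs = config.n_timepoints_per_run, config.n_runs
    t_total = t_run * n_runs
    k = config.n_traits
    a, gamma, sigma = (config.shared_signal_weight, config.trait_coupling,
                       config.noise_sd)
    p = profiles.latent_traits  # (n, k)

    # region magnitude signals: s_r and g_rk, (r, 1+k, T)
    sig = _smooth_unit_signals(rng, (r, 1 + k, t_total), config.signal_smooth_sigma)
    shared = a * sig[:, 0, :]                       # (r, T)
    coupled = np.einsum("ik,rkt->irt", p, sig[:, 1:, :])  # (n, r, T)
    magnitude = shared[None] + gamma * coupled
    magnitude = magnitude + rng.normal(0.0, sigma, size=(n, r, t_total))

    v = config.n_voxels_per_region
    vsig = _smooth_unit_signals(rng, (r, v, 1 + k, t_total),
                                config.signal_smooth_sigma)
    vshared = a * vsig[:, :, 0, :]                          # (r, v, T)
    vcoupled = np.einsum("ik,rvkt->irvt", p, vsig[:, :, 1:, :])
    patterns = vshared[None] + gamma * vcoupled
    patterns = patterns + rng.normal(0.0, sigma, size=(n, r, v, t_total))

    # run structure and exclusions; never exclude every run of a subject
    boundaries = np.arange(n_runs) * t_run
    mask = rng.random((n, n_runs)) >= config.run_exclusion_prob
    for i in range(n):
        if not mask[i].any():
            mask[i, int(rng.integers(n_runs))] = True
    for i in range(n):
        for j in range(n_runs):
            if not mask[i, j]:
                sl = slice(j * t_run, (j + 1) * t_run)
                magnitude[i, :, sl] = np.nan
                patterns[i, :, :, sl] = np.nan

    n_cort = r - config.n_subcortical
    networks = [CORTICAL_NETWORKS[i % len(CORTICAL_NETWORKS)]
                for i in range(n_cort)] + ["subcortical"] * config.n_subcortical
    region_meta = pd.DataFrame({
        "region_id": [f"R{i + 1:03d}" for i in range(r)],
        "hemisphere": ["L" if i % 2 == 0 else "R" for i in range(r)],
        "network": networks,
    })

    return FmriDataset(subject_ids=list(profiles.subject_ids),
                       magnitude=magnitude, patterns=patterns,
                       run_boundaries=boundaries, region_meta=region_meta,
                       exclusion_mask=mask)


# ----------------------------------------------------------------------
# EEG-like data
# ----------------------------------------------------------------------

def generate_eeg_dataset(profiles: ProfileSet,
                         config: GeneratorConfig) -> EegDataset:
    """Channel x time epochs per subject and image.

    Per image, source time courses follow the shared coupling model
    (without source noise); sources are mixed to channels by a fixed
    forward matrix with unit-norm rows, and i.i.d. sensor noise
    ``N(0, sigma^2)`` is added per subject.  Unit-norm mixing rows make
    each channel's cross-subject correlation follow the same closed form
    as the fMRI magnitudes.
    """
    if profiles.n_subjects != config.n_subjects:
        raise GenerationError("profiles inconsistent with config")
    n, m = config.n_subjects, config.n_images
    c, d, t = config.n_channels, config.n_sources, config.epoch_length
    k = config.n_traits
    a, gamma, sigma = (config.shared_signal_weight, config.trait_coupling,
                       config.noise_sd)

    fwd_rng = config.rng("eeg_forward")
    forward = fwd_rng.standard_normal((c, d))
    forward /= np.linalg.norm(forward, axis=1, keepdims=True)
    if np.linalg.matrix_rank(forward) < min(c, d):
        raise GenerationError("singular forward matrix")

    rng = config.rng("eeg")
    p = profiles.latent_traits
    epochs = np.empty((n, m, c, t))
    for img in range(m):
        sig = _smooth_unit_signals(rng, (d, 1 + k, t), config.signal_smooth_sigma)
        shared = a * sig[:, 0, :]                         # (d, t)
        coupled = np.einsum("ik,dkt->idt", p, sig[:, 1:, :])
        sources = shared[None] + gamma * coupled          # (n, d, t)
        clean = np.einsum("cd,idt->ict", forward, sources)
        if sigma > 0:
            clean = clean + rng.normal(0.0, sigma, size=(n, c, t))
        epochs[:, img] = clean

    cats = [f"category{j + 1:02d}" for j in range(config.n_categories)
            for _ in range(config.images_per_category)]
    image_meta = pd.DataFrame({
        "image_id": [f"img{j + 1:03d}" for j in range(m)],
        "category": cats,
    })
    return EegDataset(subject_ids=list(profiles.subject_ids), epochs=epochs,
                      sampling_rate=config.sampling_rate, image_meta=image_meta)


# ----------------------------------------------------------------------
# Gaze
# ----------------------------------------------------------------------

def generate_gaze_dataset(profiles: ProfileSet,
                          config: GeneratorConfig) -> GazeDataset:
    """Fixation sequences from a per-image attractor mixture.

    Each image carries ``attractors_per_image`` locations, a shared
    mixture prior (Dirichlet) and per-attractor trait loadings.  A
    subject's attractor weights interpolate between the shared prior and
    a softmax trait-determined prior with coefficient ``gaze_coupling``:
    at 0 all subjects' fixation distributions are exchangeable; at 1 two
    subjects with identical latent traits fixate identically-distributed
    locations, so their expected earth-mover distance is minimal.
    """
    if config.attractors_per_image < 1:
        raise ConfigurationError("attractors_per_image must be >= 1")
    if profiles.n_subjects != config.n_subjects:
        raise GenerationError("profiles inconsistent with config")
    rng = config.rng("gaze")
    w_px, h_px = config.screen_dims
    n, m, K = config.n_subjects, config.n_images, config.attractors_per_image
    k = config.n_traits
    coupling = config.gaze_coupling
    p = profiles.latent_traits

    image_ids = [f"img{j + 1:03d}" for j in range(m)]
    fixations: dict[str, dict[str, np.ndarray]] = {
        sid: {} for sid in profiles.subject_ids}

    for iid in image_ids:
        centers = rng.uniform([0.1, 0.1], [0.9, 0.9], size=(K, 2))  # unit square
        shared_prior = rng.dirichlet(np.full(K, 2.0))
        loadings = rng.standard_normal((K, k)) / np.sqrt(k)
        logits = p @ loadings.T                      # (n, K)
        trait_prior = np.exp(logits - logits.max(axis=1, keepdims=True))
        trait_prior /= trait_prior.sum(axis=1, keepdims=True)
        weights = (1 - coupling) * shared_prior[None] + coupling * trait_prior

        for i, sid in enumerate(profiles.subject_ids):
            idx = rng.choice(K, size=config.fixations_per_image, p=weights[i])
            pos = centers[idx] + config.attractor_dispersion * rng.standard_normal(
                (config.fixations_per_image, 2))
            pos = np.clip(pos, 0.0, 1.0 - 1e-9)
            dur = rng.gamma(4.0, config.mean_fixation_ms / 4.0,
                            size=config.fixations_per_image)
            dur = np.maximum(dur, 1.0)  # strictly positive dwell times
            arr = np.column_stack([pos[:, 0] * w_px, pos[:, 1] * h_px, dur])
            fixations[sid][iid] = arr

    return GazeDataset(subject_ids=list(profiles.subject_ids),
                       image_ids=image_ids, fixations=fixations,
                       screen_dims=config.screen_dims)


# ----------------------------------------------------------------------
# Oracle
# ----------------------------------------------------------------------

def expected_dyad_correlation(p_i: np.ndarray, p_j: np.ndarray,
                              config: GeneratorConfig) -> float:
    """Closed-form population correlation between two subjects' series.

    rho_ij = (a^2 + gamma^2 p_i.p_j) /
             sqrt((a^2 + gamma^2 |p_i|^2 + sigma^2)
                  (a^2 + gamma^2 |p_j|^2 + sigma^2))
    """
    p_i = np.asarray(p_i, dtype=float)
    p_j = np.asarray(p_j, dtype=float)
    if p_i.shape != p_j.shape:
        raise ValueError("trait vectors must have equal length")
    a, gamma, sigma = (config.shared_signal_weight, config.trait_coupling,
                       config.noise_sd)
    if a == 0 and gamma == 0 and sigma == 0:
        raise ValueError("a, gamma and sigma cannot all be zero")
    var_i = a**2 + gamma**2 * float(p_i @ p_i) + sigma**2
    var_j = a**2 + gamma**2 * float(p_j @ p_j) + sigma**2
    if var_i == 0 or var_j == 0:
        raise ValueError("degenerate dyad: zero variance series")
    rho = (a**2 + gamma**2 * float(p_i @ p_j)) / np.sqrt(var_i * var_j)
    return float(np.clip(rho, -1.0, 1.0))
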