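"""Calibration experiments for the full generate-analyze loop.

These helpers run the whole pipeline-in-memory many times to measure
operating characteristics: type-I error of the dyadic permutation test
under the uncoupled generator, recovery of the personality-synchrony
slope as the coupling grows, detection power, and agreement between
generated series and the closed-form correlation oracle.
"""

from __future__ import annotations

import numpy as np

from .config import GeneratorConfig
from .fmri import dyadic_synchrony_table
from .inference import build_dyad_table, subject_permutation_test
from .synthetic import (expected_dyad_correlation, generate_fmri_dataset,
                        generate_profiles)

__all__ = [
    "personality_synchrony_test",
    "type_i_error_pvalues",
    "beta_gamma_sweep",
    "detection_power",
    "oracle_agreement_error",
]

#: Fast study design reused by all calibration loops: it keeps the full
#: structure (survey scoring -> similarity -> NM synchrony -> Mantel
#: permutation) at a size where hundreds of replicates are cheap.
CALIBRATION_DESIGN = dict(
    n_subjects=16, n_traits=5, n_facets_per_trait=1, n_items_per_facet=2,
    n_regions=3, n_subcortical=1, n_voxels_per_region=3, n_runs=2,
    n_timepoints_per_run=80, n_images=2, n_categories=1, n_channels=4,
    n_sources=2, epoch_length=50)


def personality_synchrony_test(config: GeneratorConfig,
                               n_permutations: int = 199,
                               perm_seed: int | None = None):
    """One full replicate: generate, compute region-mean NM synchrony,
    and permutation-test the personality-similarity slope."""
    profiles = generate_profiles(config)
    fmri = generate_fmri_dataset(profiles, config)
    sync = dyadic_synchrony_table(fmri, measures=("NM",))
    table = build_dyad_table(profiles, synchrony_table=sync)
    return subject_permutation_test(
        table, "NM_mean", "personality_similarity",
        n_permutations=n_permutations,
        seed=config.seed if perm_seed is None else perm_seed)


def _design(seed: int, **overrides) -> GeneratorConfig:
    params = dict(CALIBRATION_DESIGN)
    params.update(overrides)
    return GeneratorConfig(seed=seed, **params)


def type_i_error_pvalues(n_replicates: int = 200, n_permutations: int = 199,
                         seed: int = 0, **overrides) -> np.ndarray:
    """Permutation p-values over replicate datasets with zero coupling.

    With ``trait_coupling = 0`` synchrony is personality-independent, so
    the returned p-values should be Uniform(0, 1).
    """
    rng = np.random.default_rng(seed)
    ps = np.empty(n_replicates)
    for r in range(n_replicates):
        cfg = _design(seed=int(rng.integers(2**31 - 1)), trait_coupling=0.0,
                      **overrides)
        ps[r] = personality_synchrony_test(cfg, n_permutations).p_permutation
    return ps


def beta_gamma_sweep(gammas=(0.0, 0.25, 0.5, 1.0), n_replicates: int = 10,
                     seed: int = 0, **overrides) -> dict[float, float]:
    """Mean standardized personality-similarity slope at each coupling."""
    out = {}
    rng = np.random.default_rng(seed)
    for gamma in gammas:
        betas = []
        for _ in range(n_replicates):
            cfg = _design(seed=int(rng.integers(2**31 - 1)),
                          trait_coupling=gamma, **overrides)
            betas.append(personality_synchrony_test(cfg, n_permutations=0,
                                                    perm_seed=0).beta_obs)
        out[float(gamma)] = float(np.mean(betas))
    return out


def detection_power(gamma: float = 1.0, n_subjects: int = 40,
                    n_replicates: int = 50, n_permutations: int = 199,
                    alpha: float = 0.05, seed: int = 0) -> float:
    """Fraction of replicates in which the personality slope is detected."""
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_replicates):
        cfg = _design(seed=int(rng.integers(2**31 - 1)),
                      n_subjects=n_subjects, trait_coupling=gamma)
        res = personality_synchrony_test(cfg, n_permutations)
        hits += res.p_permutation < alpha
    return hits / n_replicates


def oracle_agreement_error(n_timepoints: int = 50000, seed: int = 0) -> float:
    """Max |empirical - closed form| dyadic correlation on a long series."""
    cfg = GeneratorConfig(n_subjects=4, n_traits=5, n_facets_per_trait=1,
                          n_items_per_facet=2, n_regions=1, n_subcortical=0,
                          n_voxels_per_region=3, n_runs=1,
                          n_timepoints_per_run=n_timepoints,
                          shared_signal_weight=1.0, trait_coupling=0.5,
                          noise_sd=1.0, signal_smooth_sigma=2.0, seed=seed)
    profiles = generate_profiles(cfg)
    ds = generate_fmri_dataset(profiles, cfg)
    errs = []
    for i in range(cfg.n_subjects):
        for j in range(i + 1, cfg.n_subjects):
            want = expected_dyad_correlation(profiles.latent_traits[i],
                                             profiles.latent_traits[j], cfg)
            got = np.corrcoef(ds.magnitude[i, 0], ds.magnitude[j, 0])[0, 1]
            errs.append(abs(got - want))
    return float(max(errs))
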