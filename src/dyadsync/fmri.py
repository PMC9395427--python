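"""Dyadic neural synchrony for region-parcellated fMRI-like data.

Two measures per dyad and region:

* **NM-synchrony** — Pearson correlation of the two subjects'
  spatially-averaged magnitude time series.
* **NP-synchrony** — at each timepoint, the Pearson correlation across
  voxels between the two subjects' spatial patterns; the timepoint-wise
  correlations are Fisher-z transformed, averaged, and transformed back.

Runs are concatenated in order; runs excluded for either member of a
dyad are dropped for both (pairwise run intersection), so both series
always cover the same stimuli.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy.stats import pearsonr

from .datasets import FmriDataset, dyad_pairs

__all__ = [
    "concatenate_runs",
    "nm_synchrony",
    "np_synchrony",
    "dyadic_synchrony_table",
    "synchrony_split_half",
]

_Z_CLIP = 1.0 - 1e-7


class SynchronyError(RuntimeError):
    """Raised when a dyad-region synchrony value cannot be computed."""


def _retained_runs(dataset: FmriDataset, subject: str) -> list[int]:
    i = dataset.subject_ids.index(subject)
    return [j for j in range(dataset.n_runs) if dataset.exclusion_mask[i, j]]


def concatenate_runs(dataset: FmriDataset, subject: str,
                     runs: list[int] | None = None
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Concatenate a subject's retained runs in order.

    Returns ``(magnitude, patterns)`` with shapes (region, time) and
    (region, voxel, time).  ``runs`` restricts to a subset of run
    indices (still filtered by the subject's exclusion mask).
    """
    if subject not in dataset.subject_ids:
        raise KeyError(f"unknown subject {subject!r}")
    i = dataset.subject_ids.index(subject)
    retained = _retained_runs(dataset, subject)
    if runs is not None:
        retained = [j for j in retained if j in set(runs)]
    if not retained:
        raise SynchronyError(f"all runs excluded for subject {subject!r}")
    slices = dataset.run_slices()
    mag = np.concatenate([dataset.magnitude[i, :, slices[j]] for j in retained],
                         axis=-1)
    pat = np.concatenate([dataset.patterns[i, :, :, slices[j]] for j in retained],
                         axis=-1)
    return mag, pat


def nm_synchrony(ts_i: np.ndarray, ts_j: np.ndarray) -> float:
    """Pearson correlation of two magnitude time series."""
    x = np.asarray(ts_i, dtype=float)
    y = np.asarray(ts_j, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("series must be 1-D and of equal length")
    if x.size < 3:
        raise ValueError("need at least 3 timepoints")
    if np.std(x) == 0 or np.std(y) == 0:
        raise SynchronyError("zero-variance series")
    r, _ = pearsonr(x, y)
    return float(r)


def np_synchrony(pat_i: np.ndarray, pat_j: np.ndarray,
                 variant: str = "timepoint") -> float:
    """Fisher-z-averaged pattern synchrony.

    ``variant="timepoint"`` (default): at each timepoint, the Pearson
    correlation across voxels between the two spatial patterns;
    ``variant="voxelwise"``: per voxel, the temporal correlation between
    the two subjects, averaged over voxels.  Both average on the
    Fisher-z scale and transform back.  Zero-variance slices are dropped
    with a warning; if all are dropped a :class:`SynchronyError` is
    raised.  r = +/-1 is clipped to +/-(1 - 1e-7) before the
    z-transform.
    """
    x = np.asarray(pat_i, dtype=float)
    y = np.asarray(pat_j, dtype=float)
    if x.shape != y.shape or x.ndim != 2:
        raise ValueError("patterns must be (voxel, time) arrays of equal shape")
    v, t = x.shape
    if v < 3:
        raise ValueError("need at least 3 voxels")
    if t < 2:
        raise ValueError("need at least 2 timepoints")
    if variant == "voxelwise":
        x, y = x.T, y.T  # correlate along time, one r per voxel
    elif variant != "timepoint":
        raise ValueError(f"unknown variant {variant!r}")
    xc = x - x.mean(axis=0)
    yc = y - y.mean(axis=0)
    sx = np.sqrt((xc ** 2).sum(axis=0))
    sy = np.sqrt((yc ** 2).sum(axis=0))
    valid = (sx > 0) & (sy > 0)
    if not valid.all():
        warnings.warn("dropping slices with zero variance",
                      RuntimeWarning, stacklevel=2)
    if not valid.any():
        raise SynchronyError("all slices have zero variance")
    r_t = (xc[:, valid] * yc[:, valid]).sum(axis=0) / (sx[valid] * sy[valid])
    z = np.arctanh(np.clip(r_t, -_Z_CLIP, _Z_CLIP))
    return float(np.tanh(z.mean()))


def dyadic_synchrony_table(dataset: FmriDataset,
                           measures: tuple[str, ...] = ("NM", "NP"),
                           runs: list[int] | None = None) -> pd.DataFrame:
    """Long-format table of synchrony values: one row per
    (dyad, region, measure).

    Per-pair failures (e.g. zero variance) are recorded as NaN with
    ``ok=False`` rather than raised, so one bad cell never aborts a
    whole dataset.
    """
    if len(dataset.subject_ids) < 2:
        raise ValueError("need at least 2 subjects")
    region_ids = list(dataset.region_meta["region_id"])
    pairs = dyad_pairs(dataset.subject_ids)
    cache: dict[tuple[str, tuple[int, ...]], tuple[np.ndarray, np.ndarray]] = {}

    def fetch(subject: str, shared: tuple[int, ...]):
        key = (subject, shared)
        if key not in cache:
            cache[key] = concatenate_runs(dataset, subject, runs=list(shared))
        return cache[key]

    rows = []
    for a, b in pairs:
        shared = tuple(sorted(set(_retained_runs(dataset, a))
                              & set(_retained_runs(dataset, b))
                              & (set(runs) if runs is not None
                                 else set(range(dataset.n_runs)))))
        if not shared:
            for rid in region_ids:
                for meas in measures:
                    rows.append((a, b, rid, meas, np.nan, False))
            continue
        mag_a, pat_a = fetch(a, shared)
        mag_b, pat_b = fetch(b, shared)
        for r_idx, rid in enumerate(region_ids):
            for meas in measures:
                try:
                    if meas == "NM":
                        val = nm_synchrony(mag_a[r_idx], mag_b[r_idx])
                    elif meas == "NP":
                        val = np_synchrony(pat_a[r_idx], pat_b[r_idx])
                    else:
                        raise ValueError(f"unknown measure {meas!r}")
                    ok = True
                except SynchronyError:
                    val, ok = np.nan, False
                rows.append((a, b, rid, meas, val, ok))
    return pd.DataFrame(rows, columns=["subject_a", "subject_b", "region",
                                       "measure", "value", "ok"])


def synchrony_split_half(dataset: FmriDataset,
                         partition: tuple[tuple[int, ...], tuple[int, ...]] | None = None,
                         measure: str = "NM",
                         per_region: bool = False) -> float:
    """Split-half reliability of dyadic synchrony across run halves.

    Default partition pairs runs {1, 3} against runs {2, 4} (0-based
    {0, 2} vs {1, 3}).  Synchrony is computed per half and averaged
    across regions per dyad before correlating (set ``per_region=True``
    to correlate the full dyad x region vectors instead).
    """
    if partition is None:
        if dataset.n_runs < 4:
            raise ValueError(
                "default split-half partition needs >= 4 runs; pass an "
                "explicit partition for fewer")
        partition = ((0, 2), (1, 3))
    halves = []
    for half_runs in partition:
        if len(half_runs) < 1:
            raise ValueError("each half needs at least one run")
        tab = dyadic_synchrony_table(dataset, measures=(measure,),
                                     runs=list(half_runs))
        if per_region:
            vec = tab.sort_values(["subject_a", "subject_b", "region"])["value"]
        else:
            vec = (tab.groupby(["subject_a", "subject_b"], sort=True)["value"]
                   .mean())
        halves.append(vec.to_numpy())
    x, y = halves
    keep = np.isfinite(x) & np.isfinite(y)
    if keep.sum() < 3:
        raise ValueError("too few finite dyads for reliability")
    r, _ = pearsonr(x[keep], y[keep])
    return float(r)
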