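"""Dyadic correlated-components ISC for multichannel epoched data.

For a pair of subjects viewing the same stimulus, correlated components
analysis (CorrCA) finds channel-space projections ``w`` maximizing the
correlation between the two projected time courses.  With within-subject
covariances R11, R22 and cross-covariances R12, R21, the weights are the
eigenvectors of ``(R11 + R22)^-1 (R12 + R21)``; ranked eigenvalues
reflect the strength of correlation per component.  Like PCA, but the
objective is between-subject correlation rather than variance.

Dyad-level ISC averages the top components' projected-time-course
correlations per image, then averages across images.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
from scipy.stats import pearsonr

from .datasets import EegDataset, dyad_pairs

__all__ = ["CorrcaResult", "corrca_fit", "dyad_isc", "dyad_isc_table",
           "isc_split_half"]


@dataclass
class CorrcaResult:
    """Eigenpairs and per-component projected-time-course correlations."""

    eigenvalues: np.ndarray     # descending
    weights: np.ndarray         # (n_components, n_channels)
    component_isc: np.ndarray   # Pearson r of projections, per component

    def __post_init__(self) -> None:
        if np.any(np.diff(self.eigenvalues) > 1e-12):
            raise ValueError("eigenvalues must be sorted descending")
        if not np.all(np.isfinite(self.component_isc)):
            raise ValueError("component_isc must be finite")


def corrca_fit(X1: np.ndarray, X2: np.ndarray,
               shrinkage: float = 0.05) -> CorrcaResult:
    """Fit two-subject CorrCA on (channel, time) arrays.

    The pooled within covariance is regularized as
    ``(1 - shrinkage) * Rw + shrinkage * mean(diag(Rw)) * I``.  Complex
    eigenpairs of the non-symmetric product are reduced to their real
    parts and re-sorted.
    """
    X1 = np.asarray(X1, dtype=float)
    X2 = np.asarray(X2, dtype=float)
    if X1.shape != X2.shape or X1.ndim != 2:
        raise ValueError("X1 and X2 must be (channel, time) of equal shape")
    if not 0 <= shrinkage <= 1:
        raise ValueError("shrinkage must be in [0, 1]")
    c, t = X1.shape
    if t < c:
        warnings.warn("fewer samples than channels; covariance is rank "
                      "deficient — consider shrinkage", RuntimeWarning,
                      stacklevel=2)
    X1c = X1 - X1.mean(axis=1, keepdims=True)
    X2c = X2 - X2.mean(axis=1, keepdims=True)
    R11 = X1c @ X1c.T / (t - 1)
    R22 = X2c @ X2c.T / (t - 1)
    R12 = X1c @ X2c.T / (t - 1)
    Rw = R11 + R22
    Rb = R12 + R12.T
    if shrinkage > 0:
        Rw = (1 - shrinkage) * Rw + shrinkage * np.mean(np.diag(Rw)) * np.eye(c)
    try:
        M = np.linalg.solve(Rw, Rb)
    except np.linalg.LinAlgError as exc:
        raise np.linalg.LinAlgError(
            "pooled within-subject covariance is singular; use a nonzero "
            "shrinkage") from exc
    if not np.all(np.isfinite(M)):
        raise np.linalg.LinAlgError(
            "pooled within-subject covariance is singular; use a nonzero "
            "shrinkage")
    vals, vecs = scipy.linalg.eig(M)
    vals = np.real(vals)
    vecs = np.real(vecs)
    order = np.argsort(vals)[::-1]
    vals = vals[order]
    weights = vecs[:, order].T  # one component per row
    norms = np.linalg.norm(weights, axis=1)
    norms[norms == 0] = 1.0
    weights = weights / norms[:, None]

    isc = np.empty(c)
    for k in range(c):
        y1 = weights[k] @ X1c
        y2 = weights[k] @ X2c
        if np.std(y1) == 0 or np.std(y2) == 0:
            isc[k] = 0.0
        else:
            isc[k] = pearsonr(y1, y2)[0]
    return CorrcaResult(eigenvalues=vals, weights=weights, component_isc=isc)


def dyad_isc(epochs_i: np.ndarray, epochs_j: np.ndarray,
             n_components: int = 3, shrinkage: float = 0.05) -> float:
    """Dyad ISC: per image, mean of the top components' projected
    correlations; averaged over images.

    ``epochs_*`` are (image, channel, time) arrays over the same image
    set for both subjects.
    """
    E1 = np.asarray(epochs_i, dtype=float)
    E2 = np.asarray(epochs_j, dtype=float)
    if E1.shape != E2.shape or E1.ndim != 3:
        raise ValueError("epoch arrays must be (image, channel, time) of "
                         "equal shape")
    n_images, c, _ = E1.shape
    if n_components > c:
        raise ValueError(f"n_components ({n_components}) exceeds channel "
                         f"count ({c})")
    per_image = np.empty(n_images)
    for m in range(n_images):
        res = corrca_fit(E1[m], E2[m], shrinkage=shrinkage)
        per_image[m] = res.component_isc[:n_components].mean()
    return float(per_image.mean())


def dyad_isc_table(dataset: EegDataset, n_components: int = 3,
                   shrinkage: float = 0.05,
                   images: list[int] | None = None) -> pd.DataFrame:
    """Dyad ISC for every unordered pair of subjects in a dataset."""
    idx = {s: i for i, s in enumerate(dataset.subject_ids)}
    sel = slice(None) if images is None else images
    rows = []
    for a, b in dyad_pairs(dataset.subject_ids):
        val = dyad_isc(dataset.epochs[idx[a], sel],
                       dataset.epochs[idx[b], sel],
                       n_components=n_components, shrinkage=shrinkage)
        rows.append((a, b, val))
    return pd.DataFrame(rows, columns=["subject_a", "subject_b", "eeg_isc"])


def isc_split_half(dataset: EegDataset, n_components: int = 3,
                   shrinkage: float = 0.05,
                   partition: tuple[list[int], list[int]] | None = None) -> float:
    """Split-half reliability of dyad ISC across odd vs even images."""
    n_images = dataset.epochs.shape[1]
    if partition is None:
        partition = (list(range(0, n_images, 2)), list(range(1, n_images, 2)))
    halves = []
    for imgs in partition:
        if len(imgs) < 2:
            raise ValueError("each half needs at least 2 images")
        tab = dyad_isc_table(dataset, n_components=n_components,
                             shrinkage=shrinkage, images=imgs)
        vec = tab["eeg_isc"].to_numpy()
        if np.std(vec) == 0:
            raise ValueError("constant dyad ISC vector in one half")
        halves.append(vec)
    r, _ = pearsonr(halves[0], halves[1])
    return float(r)
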