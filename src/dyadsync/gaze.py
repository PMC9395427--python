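"""Dwell-time-weighted fixation distributions and earth-mover distance.

A subject's fixations on an image are binned on an H x W grid over the
unit square (pixel coordinates normalized by screen size), each fixation
contributing mass proportional to its duration; the result is a discrete
probability distribution.  Dyadic gaze similarity is the negated mean
exact earth-mover (optimal transport) distance across shared images,
with ground metric the Euclidean distance between cell centers in
unit-square coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linprog
from scipy.sparse import coo_matrix

from .datasets import GazeDataset, dyad_pairs

__all__ = ["FixationDistribution", "fixation_histogram", "emd",
           "dyad_gaze_similarity", "gaze_similarity_table"]


@dataclass
class FixationDistribution:
    """Normalized dwell-time mass on an H x W grid over the unit square."""

    mass: np.ndarray  # (H, W), rows = y (top to bottom), cols = x

    def __post_init__(self) -> None:
        m = np.asarray(self.mass, dtype=float)
        if m.ndim != 2 or m.shape[0] < 1 or m.shape[1] < 1:
            raise ValueError("mass must be a 2-D grid")
        if (m < 0).any():
            raise ValueError("masses must be nonnegative")
        if abs(m.sum() - 1.0) > 1e-9:
            raise ValueError("masses must sum to 1")
        self.mass = m

    @property
    def grid_dims(self) -> tuple[int, int]:
        return self.mass.shape

    def cell_centers(self) -> np.ndarray:
        """(H*W, 2) array of (x, y) cell centers in unit-square coords."""
        h, w = self.mass.shape
        ys = (np.arange(h) + 0.5) / h
        xs = (np.arange(w) + 0.5) / w
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])


def fixation_histogram(fixations: np.ndarray,
                       screen_dims: tuple[int, int],
                       grid_dims: tuple[int, int] = (32, 32)
                       ) -> FixationDistribution:
    """Bin fixations by dwell time onto a grid over the unit square.

    ``fixations`` is (n, 3): x, y in pixels (origin top-left), duration
    in ms.  Cells are half-open [lo, hi) with the last cell closed, so a
    fixation exactly on the right/bottom edge lands in the last
    column/row.
    """
    arr = np.asarray(fixations, dtype=float)
    if arr.size == 0:
        raise ValueError("empty fixation list")
    if arr.ndim != 2 or arr.shape[1] != 3:
        raise ValueError("fixations must be (n, 3): x, y, duration")
    w_px, h_px = screen_dims
    x, y, dur = arr.T
    if (dur <= 0).any():
        raise ValueError("durations must be positive")
    if (x < 0).any() or (x > w_px).any() or (y < 0).any() or (y > h_px).any():
        raise ValueError("fixation coordinates out of bounds")
    h, w = grid_dims
    hist, _, _ = np.histogram2d(y / h_px, x / w_px, bins=[h, w],
                                range=[[0, 1], [0, 1]], weights=dur)
    return FixationDistribution(mass=hist / hist.sum())


def emd(P: FixationDistribution, Q: FixationDistribution) -> float:
    """Exact earth-mover distance between two grid distributions.

    Solves the transportation linear program restricted to nonzero
    cells, with Euclidean ground metric between cell centers in
    unit-square coordinates.  Bounded above by the grid diagonal
    (sqrt(2)).
    """
    if P.grid_dims != Q.grid_dims:
        raise ValueError(f"grid mismatch: {P.grid_dims} vs {Q.grid_dims}")
    p = P.mass.ravel()
    q = Q.mass.ravel()
    centers = P.cell_centers()
    src = np.flatnonzero(p)
    dst = np.flatnonzero(q)
    a, b = p[src], q[dst]
    cost = np.linalg.norm(centers[src][:, None, :] - centers[dst][None, :, :],
                          axis=-1)
    n, m = len(src), len(dst)
    if n == 1 or m == 1:
        # transport plan is forced: outer product of the marginals
        return float((np.outer(a, b) * cost).sum())
    # flow variables f_ij >= 0; row sums = a, column sums = b
    rows, cols, data = [], [], []
    for i in range(n):
        rows.extend([i] * m)
        cols.extend(range(i * m, (i + 1) * m))
        data.extend([1.0] * m)
    for j in range(m):
        rows.extend([n + j] * n)
        cols.extend(range(j, n * m, m))
        data.extend([1.0] * n)
    A_eq = coo_matrix((data, (rows, cols)), shape=(n + m, n * m))
    res = linprog(cost.ravel(), A_eq=A_eq,
                  b_eq=np.concatenate([a, b]), bounds=(0, None),
                  method="highs")
    if not res.success:  # pragma: no cover - defensive
        raise RuntimeError(f"transport LP failed: {res.message}")
    return float(res.fun)


def dyad_gaze_similarity(subject_i: str, subject_j: str,
                         dataset: GazeDataset,
                         grid_dims: tuple[int, int] = (32, 32)) -> float:
    """Negated mean EMD across the images both subjects viewed."""
    fx_i = dataset.fixations.get(subject_i, {})
    fx_j = dataset.fixations.get(subject_j, {})
    shared = [iid for iid in dataset.image_ids if iid in fx_i and iid in fx_j]
    if not shared:
        raise ValueError(f"no shared images for {subject_i}/{subject_j}")
    dists = []
    for iid in shared:
        P = fixation_histogram(fx_i[iid], dataset.screen_dims, grid_dims)
        Q = fixation_histogram(fx_j[iid], dataset.screen_dims, grid_dims)
        dists.append(emd(P, Q))
    return float(0.0 - np.mean(dists))


def gaze_similarity_table(dataset: GazeDataset,
                          grid_dims: tuple[int, int] = (32, 32)) -> pd.DataFrame:
    """Dyadic gaze similarity (negated mean EMD) for all pairs.

    Histograms are computed once per subject-image and reused across
    dyads.
    """
    hists: dict[str, dict[str, FixationDistribution]] = {}
    for sid in dataset.subject_ids:
        hists[sid] = {
            iid: fixation_histogram(arr, dataset.screen_dims, grid_dims)
            for iid, arr in dataset.fixations.get(sid, {}).items()
        }
    rows = []
    for a, b in dyad_pairs(dataset.subject_ids):
        shared = [iid for iid in dataset.image_ids
                  if iid in hists[a] and iid in hists[b]]
        if not shared:
            rows.append((a, b, np.nan))
            continue
        val = -float(np.mean([emd(hists[a][iid], hists[b][iid])
                              for iid in shared]))
        rows.append((a, b, val))
    return pd.DataFrame(rows, columns=["subject_a", "subject_b",
                                       "gaze_similarity"])
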