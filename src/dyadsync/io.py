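"""Serialization: HDF5 for arrays, CSV for tabular data.

Layout of the HDF5 container (one file per run directory):

* ``fmri/magnitude``, ``fmri/patterns``, ``fmri/run_boundaries``,
  ``fmri/exclusion_mask``
* ``eeg/epochs`` (+ ``sampling_rate`` attribute)

Profiles (item responses, keying, demographics), region/image metadata,
gaze fixations and every result table travel as plain CSV so a run
directory is fully inspectable with standard tools.
"""

from __future__ import annotations

from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .datasets import EegDataset, FmriDataset, GazeDataset, ProfileSet

__all__ = [
    "save_profiles", "load_profiles",
    "save_arrays", "load_fmri", "load_eeg",
    "save_gaze", "load_gaze",
]

_ETH_SEP = ";"


def save_profiles(profiles: ProfileSet, out_dir: str | Path) -> list[Path]:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    p = out / "item_responses.csv"
    profiles.item_responses.rename_axis("subject").to_csv(p)
    paths.append(p)
    p = out / "keying.csv"
    profiles.keying.to_csv(p, index=False)
    paths.append(p)
    demo = profiles.demographics.copy()
    demo["ethnicity"] = demo["ethnicity"].map(
        lambda s: _ETH_SEP.join(sorted(s)))
    p = out / "demographics.csv"
    demo.rename_axis("subject").to_csv(p)
    paths.append(p)
    p = out / "latent_traits.csv"
    pd.DataFrame(profiles.latent_traits,
                 index=profiles.subject_ids).rename_axis("subject").to_csv(p)
    paths.append(p)
    return paths


def load_profiles(out_dir: str | Path) -> ProfileSet:
    out = Path(out_dir)
    items = pd.read_csv(out / "item_responses.csv", index_col="subject")
    keying = pd.read_csv(out / "keying.csv")
    demo = pd.read_csv(out / "demographics.csv", index_col="subject")
    demo["ethnicity"] = demo["ethnicity"].map(
        lambda s: frozenset(str(s).split(_ETH_SEP)))
    latent = pd.read_csv(out / "latent_traits.csv", index_col="subject")
    return ProfileSet(subject_ids=list(items.index),
                      latent_traits=latent.to_numpy(),
                      item_responses=items, keying=keying, demographics=demo)


def save_arrays(path: str | Path, fmri: FmriDataset | None = None,
                eeg: EegDataset | None = None) -> None:
    with h5py.File(path, "w") as f:
        if fmri is not None:
            g = f.create_group("fmri")
            g.create_dataset("magnitude", data=fmri.magnitude)
            g.create_dataset("patterns", data=fmri.patterns)
            g.create_dataset("run_boundaries", data=fmri.run_boundaries)
            g.create_dataset("exclusion_mask", data=fmri.exclusion_mask)
            g.attrs["subject_ids"] = list(fmri.subject_ids)
        if eeg is not None:
            g = f.create_group("eeg")
            g.create_dataset("epochs", data=eeg.epochs)
            g.attrs["sampling_rate"] = eeg.sampling_rate
            g.attrs["subject_ids"] = list(eeg.subject_ids)


def load_fmri(path: str | Path, region_meta: pd.DataFrame) -> FmriDataset:
    with h5py.File(path, "r") as f:
        g = f["fmri"]
        return FmriDataset(
            subject_ids=[s for s in g.attrs["subject_ids"]],
            magnitude=g["magnitude"][()],
            patterns=g["patterns"][()],
            run_boundaries=g["run_boundaries"][()],
            region_meta=region_meta,
            exclusion_mask=g["exclusion_mask"][()].astype(bool))


def load_eeg(path: str | Path, image_meta: pd.DataFrame) -> EegDataset:
    with h5py.File(path, "r") as f:
        g = f["eeg"]
        return EegDataset(
            subject_ids=[s for s in g.attrs["subject_ids"]],
            epochs=g["epochs"][()],
            sampling_rate=float(g.attrs["sampling_rate"]),
            image_meta=image_meta)


def save_gaze(gaze: GazeDataset, path: str | Path) -> None:
    rows = []
    for sid, per_image in gaze.fixations.items():
        for iid, arr in per_image.items():
            for order, (x, y, dur) in enumerate(np.asarray(arr)):
                rows.append((sid, iid, order, x, y, dur))
    df = pd.DataFrame(rows, columns=["subject", "image", "order", "x", "y",
                                     "duration_ms"])
    df.attrs["screen_dims"] = gaze.screen_dims
    df.to_csv(path, index=False)


def load_gaze(path: str | Path, screen_dims: tuple[int, int],
              image_ids: list[str] | None = None) -> GazeDataset:
    df = pd.read_csv(path)
    fixations: dict[str, dict[str, np.ndarray]] = {}
    for (sid, iid), grp in df.groupby(["subject", "image"], sort=True):
        grp = grp.sort_values("order")
        fixations.setdefault(str(sid), {})[str(iid)] = grp[
            ["x", "y", "duration_ms"]].to_numpy(dtype=float)
    subjects = sorted(fixations)
    if image_ids is None:
        image_ids = sorted(df["image"].unique())
    return GazeDataset(subject_ids=subjects, image_ids=list(image_ids),
                       fixations=fixations, screen_dims=screen_dims)
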