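"""Config-driven end-to-end runs.

Stages mirror the analysis workflow: ``generate`` (synthetic datasets)
-> ``similarity`` (dyadic predictors) -> ``synchrony`` (NM/NP, EEG ISC,
gaze EMD) -> ``infer`` (per-region OLS with permutation + FDR, network
t-tests, reliability, per-subject effects, mediation).  Every stage
writes plain CSV/JSON (arrays to HDF5) into one run directory and is
recorded in a manifest, so a rerun with the same config and seed
reproduces all outputs bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import GeneratorConfig
from .datasets import dyad_pairs
from .eeg import dyad_isc_table, isc_split_half
from .fmri import dyadic_synchrony_table, synchrony_split_half
from .gaze import gaze_similarity_table
from .inference import (build_dyad_table, fdr_bh, mediation_analysis,
                        network_coefficient_test, per_subject_effects,
                        subject_permutation_test)
from .io import (load_eeg, load_fmri, load_gaze, load_profiles, save_arrays,
                 save_gaze, save_profiles)
from .personality import (SimilarityMetricSpec, dyad_similarity_table,
                          split_half_reliability)
from .synthetic import (generate_eeg_dataset, generate_fmri_dataset,
                        generate_gaze_dataset, generate_profiles)

__all__ = ["RunManifest", "run_pipeline", "summarize_run", "PipelineError"]


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"stage {stage!r} failed: {message}")
        self.stage = stage


@dataclass
class RunManifest:
    out_dir: str
    config_hash: str
    master_seed: int
    version: str
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, outputs: list[Path], wall_time: float) -> None:
        self.stages[stage] = {
            "outputs": [str(p) for p in outputs],
            "wall_time_s": round(wall_time, 3),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.__dict__, indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunManifest":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _config_hash(config: GeneratorConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def run_pipeline(config: GeneratorConfig | str | Path, out_dir: str | Path,
                 n_permutations: int = 1000,
                 metric: str = "euclidean",
                 fdr_q: float = 0.05,
                 n_isc_components: int = 3,
                 stages: tuple[str, ...] = ("generate", "similarity",
                                            "synchrony", "infer")) -> RunManifest:
    """Execute the pipeline stages in order, writing all artifacts.

    ``stages`` may be truncated to stop early; later stages reload
    earlier artifacts from ``out_dir``, so user-supplied files in the
    same layout are picked up instead of regenerated.
    """
    if not isinstance(config, GeneratorConfig):
        config = GeneratorConfig.from_file(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_json(out / "config.json")
    spec = SimilarityMetricSpec(name=metric)
    manifest = RunManifest(out_dir=str(out), config_hash=_config_hash(config),
                           master_seed=config.seed, version=__version__)

    for stage in stages:
        t0 = time.perf_counter()
        try:
            if stage == "generate":
                outputs = _stage_generate(config, out)
            elif stage == "similarity":
                outputs = _stage_similarity(config, out, spec)
            elif stage == "synchrony":
                outputs = _stage_synchrony(config, out, n_isc_components)
            elif stage == "infer":
                outputs = _stage_infer(config, out, spec, n_permutations,
                                       fdr_q)
            else:
                raise ValueError(f"unknown stage {stage!r}")
        except Exception as exc:
            if isinstance(exc, PipelineError):
                raise
            raise PipelineError(stage, str(exc)) from exc
        manifest.record(stage, outputs, time.perf_counter() - t0)
    manifest.save(out / "manifest.json")
    return manifest


# ----------------------------------------------------------------------

def _stage_generate(config: GeneratorConfig, out: Path) -> list[Path]:
    profiles = generate_profiles(config)
    fmri = generate_fmri_dataset(profiles, config)
    eeg = generate_eeg_dataset(profiles, config)
    gaze = generate_gaze_dataset(profiles, config)
    paths = save_profiles(profiles, out)
    h5 = out / "arrays.h5"
    save_arrays(h5, fmri=fmri, eeg=eeg)
    paths.append(h5)
    p = out / "region_meta.csv"
    fmri.region_meta.to_csv(p, index=False)
    paths.append(p)
    p = out / "image_meta.csv"
    eeg.image_meta.to_csv(p, index=False)
    paths.append(p)
    p = out / "gaze_fixations.csv"
    save_gaze(gaze, p)
    paths.append(p)
    return paths


def _stage_similarity(config: GeneratorConfig, out: Path,
                      spec: SimilarityMetricSpec) -> list[Path]:
    profiles = load_profiles(out)
    per_facet = config.n_facets_per_trait > 1
    level = "facet" if per_facet else "trait"
    table = dyad_similarity_table(profiles, spec=spec, level=level,
                                  per_facet=per_facet)
    p = out / "dyad_similarity.csv"
    table.to_csv(p, index=False)
    return [p]


def _stage_synchrony(config: GeneratorConfig, out: Path,
                     n_isc_components: int = 3) -> list[Path]:
    profiles = load_profiles(out)
    region_meta = pd.read_csv(out / "region_meta.csv")
    image_meta = pd.read_csv(out / "image_meta.csv")
    fmri = load_fmri(out / "arrays.h5", region_meta)
    eeg = load_eeg(out / "arrays.h5", image_meta)
    gaze = load_gaze(out / "gaze_fixations.csv", config.screen_dims)
    paths = []
    sync = dyadic_synchrony_table(fmri)
    p = out / "synchrony.csv"
    sync.to_csv(p, index=False)
    paths.append(p)
    isc = dyad_isc_table(eeg, n_components=n_isc_components)
    p = out / "eeg_isc.csv"
    isc.to_csv(p, index=False)
    paths.append(p)
    gz = gaze_similarity_table(gaze)
    p = out / "gaze_similarity.csv"
    gz.to_csv(p, index=False)
    paths.append(p)

    rel = {}
    if fmri.n_runs >= 4:
        rel["nm_split_half"] = synchrony_split_half(fmri, measure="NM")
        rel["np_split_half"] = synchrony_split_half(fmri, measure="NP")
    if eeg.epochs.shape[1] >= 4:
        rel["isc_split_half"] = isc_split_half(eeg,
                                               n_components=n_isc_components)
    rel["personality_split_half"] = split_half_reliability(
        profiles.item_responses, profiles.keying)
    p = out / "reliability.json"
    p.write_text(json.dumps(rel, indent=2) + "\n")
    paths.append(p)
    return paths


_CONTROLS = ["gender_similarity", "age_similarity", "ethnicity_similarity",
             "handedness_similarity", "nationality_similarity",
             "politics_similarity"]


def _stage_infer(config: GeneratorConfig, out: Path,
                 spec: SimilarityMetricSpec, n_permutations: int,
                 fdr_q: float) -> list[Path]:
    profiles = load_profiles(out)
    region_meta = pd.read_csv(out / "region_meta.csv")
    sync = pd.read_csv(out / "synchrony.csv")
    isc = pd.read_csv(out / "eeg_isc.csv")
    gz = pd.read_csv(out / "gaze_similarity.csv")
    per_facet = config.n_facets_per_trait > 1
    level = "facet" if per_facet else "trait"
    table = build_dyad_table(profiles, synchrony_table=sync, isc_table=isc,
                             gaze_table=gz, metric_spec=spec, level=level,
                             per_facet=per_facet)
    p_table = out / "dyad_table.csv"
    table.to_csv(p_table, index=False)
    paths = [p_table]

    # per-region OLS + permutation + FDR, per measure
    region_rows = []
    for meas in sync["measure"].unique():
        for rid in region_meta["region_id"]:
            col = f"{meas}__{rid}"
            if col not in table.columns:
                continue
            res = subject_permutation_test(
                table, col, "personality_similarity",
                n_permutations=n_permutations, seed=config.seed)
            region_rows.append({
                "measure": meas, "region": rid,
                "network": region_meta.set_index("region_id").loc[rid, "network"],
                "beta": res.beta_obs, "se": res.se, "p": res.p_parametric,
                "p_permutation": res.p_permutation})
    regions = pd.DataFrame(region_rows)
    for meas, grp in regions.groupby("measure"):
        reject, p_adj = fdr_bh(grp["p_permutation"].to_numpy(), q=fdr_q)
        regions.loc[grp.index, "fdr_significant"] = reject
        regions.loc[grp.index, "p_fdr"] = p_adj
    p = out / "region_effects.csv"
    regions.to_csv(p, index=False)
    paths.append(p)

    # per-network one-sample t-tests on regional coefficients
    net_frames = []
    for meas, grp in regions.groupby("measure"):
        nt = network_coefficient_test(
            grp.set_index("region")["beta"],
            grp.set_index("region")["network"])
        nt.insert(0, "measure", meas)
        net_frames.append(nt)
    p = out / "network_tests.csv"
    pd.concat(net_frames, ignore_index=True).to_csv(p, index=False)
    paths.append(p)

    # whole-sample EEG ISC effect (with and without controls)
    results = {}
    controls = [c for c in _CONTROLS if table[c].std() > 0]
    for label, covs in (("eeg_m1", []), ("eeg_m2", controls)):
        res = subject_permutation_test(table, "eeg_isc",
                                       "personality_similarity",
                                       covariates=covs,
                                       n_permutations=n_permutations,
                                       seed=config.seed)
        results[label] = {"beta": res.beta_obs, "se": res.se,
                          "p": res.p_parametric,
                          "p_permutation": res.p_permutation,
                          "covariates": covs}

    # facet-level effects on EEG ISC
    facet_rows = []
    for col in [c for c in table.columns if c.startswith("sim_")]:
        res = subject_permutation_test(table, "eeg_isc", col,
                                       n_permutations=n_permutations,
                                       seed=config.seed)
        facet_rows.append({"facet": col.removeprefix("sim_"),
                           "beta": res.beta_obs, "se": res.se,
                           "p": res.p_parametric,
                           "p_permutation": res.p_permutation})
    if facet_rows:
        p = out / "facet_effects.csv"
        pd.DataFrame(facet_rows).sort_values(
            "beta", ascending=False).to_csv(p, index=False)
        paths.append(p)

    # mediation: personality -> gaze -> neural synchrony
    med = mediation_analysis(table, "personality_similarity",
                             "gaze_similarity", "eeg_isc",
                             n_permutations=n_permutations, seed=config.seed)
    results["mediation"] = {
        "path_a": med.path_a, "path_b": med.path_b, "total_c": med.total_c,
        "direct_c_prime": med.direct_c_prime, "indirect": med.indirect}

    # per-subject effect distribution on the EEG outcome
    betas, frac = per_subject_effects(table, "eeg_isc",
                                      "personality_similarity")
    results["per_subject"] = {"n_subjects": int(len(betas)),
                              "n_obs_per_subject": len(profiles.subject_ids) - 1,
                              "fraction_positive": frac}
    p = out / "inference.json"
    p.write_text(json.dumps(results, indent=2) + "\n")
    paths.append(p)
    return paths


# ----------------------------------------------------------------------

def summarize_run(manifest: RunManifest | str | Path) -> str:
    """Human-readable report over a completed run directory."""
    if not isinstance(manifest, RunManifest):
        manifest = RunManifest.load(manifest)
    out = Path(manifest.out_dir)
    lines = [f"dyadsync run {manifest.config_hash} (seed {manifest.master_seed})",
             ""]
    regions_path = out / "region_effects.csv"
    if not regions_path.exists():
        raise FileNotFoundError(f"missing artifact: {regions_path}")
    regions = pd.read_csv(regions_path)
    if regions.empty:
        raise ValueError("empty region set in region_effects.csv")
    lines.append("Per-region personality-similarity effects "
                 "(sorted by |beta|):")
    for meas, grp in regions.groupby("measure"):
        lines.append(f"  {meas}:")
        grp = grp.reindex(grp["beta"].abs().sort_values(ascending=False).index)
        for _, row in grp.head(10).iterrows():
            star = " *FDR" if row.get("fdr_significant") else ""
            lines.append(
                f"    {row['region']} ({row['network']}): beta="
                f"{row['beta']:+.3f}  p_perm={row['p_permutation']:.3f}{star}")
    net_path = out / "network_tests.csv"
    if net_path.exists():
        lines.append("")
        lines.append("Per-network one-sample t-tests on coefficients:")
        for _, row in pd.read_csv(net_path).iterrows():
            lines.append(f"    {row['measure']} {row['network']}: "
                         f"mean beta={row['mean_beta']:+.3f} "
                         f"t={row['t']:.2f} p={row['p']:.4f}")
    rel_path = out / "reliability.json"
    if rel_path.exists():
        rel = json.loads(rel_path.read_text())
        lines.append("")
        lines.append("Split-half reliabilities: " + ", ".join(
            f"{k}={v:.3f}" for k, v in rel.items()))
    inf_path = out / "inference.json"
    if inf_path.exists():
        res = json.loads(inf_path.read_text())
        if "eeg_m1" in res:
            m1 = res["eeg_m1"]
            lines.append("")
            lines.append(f"EEG ISC ~ personality similarity: beta="
                         f"{m1['beta']:+.3f} (SE {m1['se']:.3f}), "
                         f"p_perm={m1['p_permutation']:.3f}")
        if "mediation" in res:
            ind = res["mediation"]["indirect"]
            lines.append(f"Mediation via gaze: indirect beta="
                         f"{ind['beta']:+.4f}, "
                         f"p_perm={ind['p_permutation']:.3f}")
        if "per_subject" in res:
            ps = res["per_subject"]
            lines.append(f"Per-subject effects: {ps['fraction_positive']:.0%} "
                         f"positive ({ps['n_obs_per_subject']} obs/person)")
    facet_path = out / "facet_effects.csv"
    if facet_path.exists():
        lines.append("")
        lines.append("Facet effects on EEG ISC (sorted by beta):")
        for _, row in pd.read_csv(facet_path).iterrows():
            lines.append(f"    {row['facet']}: beta={row['beta']:+.3f} "
                         f"p_perm={row['p_permutation']:.3f}")
    return "\n".join(lines) + "\n"
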