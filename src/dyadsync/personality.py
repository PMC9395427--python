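"""Trait scoring and dyadic personality / socio-demographic similarity.

Scoring follows standard Big Five questionnaire practice: reverse-keyed
items are reflected as ``scale_min + scale_max - response``, a facet
score is the mean of its keyed items, and a trait score is the mean of
its facets.  Dyadic similarity is a distance between two subjects'
score vectors, subtracted from zero so that higher values mean a closer
match — the convention used for every predictor in the dyad table.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import chebyshev, cityblock, euclidean
from scipy.stats import pearsonr

from .datasets import ProfileSet, dyad_pairs

__all__ = [
    "SimilarityMetricSpec",
    "score_traits",
    "cronbach_alpha",
    "personality_similarity",
    "demographic_similarity",
    "dyad_similarity_table",
    "split_half_reliability",
]

_METRICS = ("euclidean", "manhattan", "canberra", "supremum")

#: Demographic similarity codings: binary same/different for gender,
#: handedness and nationality; set overlap for ethnicity; negated
#: absolute difference for age and 7-point political ideology.
DEMOGRAPHIC_FIELDS = ("gender", "age", "ethnicity", "handedness",
                      "nationality", "political_ideology")


@dataclass(frozen=True)
class SimilarityMetricSpec:
    """Which distance to use and whether to negate it into a similarity."""

    name: str = "euclidean"
    invert: bool = True

    def __post_init__(self) -> None:
        if self.name not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}, got {self.name!r}")


# ----------------------------------------------------------------------
# Scoring
# ----------------------------------------------------------------------

def score_traits(item_responses: pd.DataFrame,
                 keying: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score facet and trait means from item responses.

    Returns ``(traits, facets)`` DataFrames indexed like
    ``item_responses``.  Missing responses raise (no imputation).
    """
    if item_responses.isna().any().any():
        raise ValueError("missing responses are not allowed (no imputation)")
    keyed = set(keying["item"])
    unkeyed = set(item_responses.columns) - keyed
    if unkeyed:
        raise ValueError(f"unkeyed items: {sorted(unkeyed)}")

    reflected = item_responses.astype(float).copy()
    for _, row in keying.iterrows():
        if row["reverse"]:
            reflected[row["item"]] = (
                row["scale_min"] + row["scale_max"] - reflected[row["item"]]
            )

    facet_of = keying.set_index("item")["facet"]
    trait_of_facet = keying.drop_duplicates("facet").set_index("facet")["trait"]

    facets = reflected.T.groupby(facet_of).mean().T
    traits = facets.T.groupby(trait_of_facet).mean().T
    # keep key order stable (first appearance in the keying table)
    facets = facets[list(dict.fromkeys(keying["facet"]))]
    traits = traits[list(dict.fromkeys(keying["trait"]))]
    return traits, facets


def cronbach_alpha(items: np.ndarray | pd.DataFrame) -> float:
    """Internal consistency: alpha = k/(k-1) * (1 - sum(var_i)/var(total))."""
    x = np.asarray(items, dtype=float)
    if x.ndim != 2 or x.shape[1] < 2 or x.shape[0] < 2:
        raise ValueError("need >= 2 subjects and >= 2 items")
    k = x.shape[1]
    item_var = x.var(axis=0, ddof=1)
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("zero total variance")
    return float(k / (k - 1) * (1.0 - item_var.sum() / total_var))


# ----------------------------------------------------------------------
# Dyadic similarity
# ----------------------------------------------------------------------

def _canberra(x: np.ndarray, y: np.ndarray) -> float:
    denom = np.abs(x + y)
    if np.any(denom == 0):
        raise ValueError("canberra undefined: coordinate pair with x_i + y_i = 0")
    return float(np.sum(np.abs(x - y) / denom))


def personality_similarity(p_i, p_j, spec: SimilarityMetricSpec) -> float:
    """Distance between two score vectors, negated if ``spec.invert``.

    Euclidean, Manhattan and Supremum delegate to scipy; Canberra is
    computed with the |x+y| denominator.
    """
    x = np.asarray(p_i, dtype=float)
    y = np.asarray(p_j, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("score vectors must be 1-D and of equal length")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("score vectors must be finite")
    if spec.name == "euclidean":
        d = euclidean(x, y)
    elif spec.name == "manhattan":
        d = cityblock(x, y)
    elif spec.name == "supremum":
        d = chebyshev(x, y)
    else:
        d = _canberra(x, y)
    return float(0.0 - d) if spec.invert else float(d)


def demographic_similarity(profile_i: pd.Series | dict,
                           profile_j: pd.Series | dict) -> dict[str, float]:
    """Socio-demographic similarity codings for one dyad."""
    out: dict[str, float] = {}
    for f in DEMOGRAPHIC_FIELDS:
        for prof in (profile_i, profile_j):
            if f not in prof:
                raise ValueError(f"missing demographic field {f!r}")
    out["gender_similarity"] = float(profile_i["gender"] == profile_j["gender"])
    out["age_similarity"] = -abs(float(profile_i["age"]) - float(profile_j["age"]))
    eth_i, eth_j = set(profile_i["ethnicity"]), set(profile_j["ethnicity"])
    out["ethnicity_similarity"] = float(len(eth_i & eth_j) > 0)
    out["handedness_similarity"] = float(
        profile_i["handedness"] == profile_j["handedness"])
    out["nationality_similarity"] = float(
        profile_i["nationality"] == profile_j["nationality"])
    out["politics_similarity"] = -abs(
        float(profile_i["political_ideology"]) - float(profile_j["political_ideology"]))
    return out


def dyad_similarity_table(profiles: ProfileSet,
                          spec: SimilarityMetricSpec = SimilarityMetricSpec(),
                          level: str = "trait",
                          per_facet: bool = False) -> pd.DataFrame:
    """One row per unordered dyad with all similarity predictors.

    ``level`` selects the score vector behind ``personality_similarity``:
    the five trait means (``"trait"``) or all facet means (``"facet"``,
    e.g. 15 facets for a three-facet-per-trait design).  With
    ``per_facet=True``, a negated absolute difference per single facet is
    added as ``sim_<facet>`` columns.
    """
    if level not in {"trait", "facet"}:
        raise ValueError("level must be 'trait' or 'facet'")
    traits, facets = score_traits(profiles.item_responses, profiles.keying)
    scores = traits if level == "trait" else facets
    pairs = dyad_pairs(profiles.subject_ids)
    demo = profiles.demographics
    rows = []
    for a, b in pairs:
        row: dict = {"subject_a": a, "subject_b": b}
        row["personality_similarity"] = personality_similarity(
            scores.loc[a].to_numpy(), scores.loc[b].to_numpy(), spec)
        row.update(demographic_similarity(demo.loc[a], demo.loc[b]))
        if per_facet:
            for facet in facets.columns:
                row[f"sim_{facet}"] = -abs(facets.loc[a, facet] - facets.loc[b, facet])
        rows.append(row)
    return pd.DataFrame(rows)


# ----------------------------------------------------------------------
# Reliability
# ----------------------------------------------------------------------

def split_half_items(keying: pd.DataFrame) -> tuple[list[str], list[str]]:
    """Deterministic odd/even item split within each facet (balanced)."""
    half_a: list[str] = []
    half_b: list[str] = []
    for _, grp in keying.groupby("facet", sort=False):
        items = list(grp["item"])
        half_a.extend(items[0::2])
        half_b.extend(items[1::2])
    return half_a, half_b


def split_half_reliability(item_responses: pd.DataFrame,
                           keying: pd.DataFrame,
                           spec: SimilarityMetricSpec = SimilarityMetricSpec(),
                           level: str = "trait") -> float:
    """Split-half reliability of dyadic personality similarity.

    Scores each half of the survey separately, computes the dyadic
    similarity vector per half across all dyads, and returns the Pearson
    correlation between the two vectors.
    """
    if item_responses.shape[1] < 4:
        raise ValueError("need >= 4 items to split")
    if item_responses.shape[0] < 3:
        raise ValueError("need >= 3 subjects")
    half_a, half_b = split_half_items(keying)
    if not half_a or not half_b:
        raise ValueError("split produced an empty half")
    sims = []
    for half in (half_a, half_b):
        key_h = keying[keying["item"].isin(half)]
        traits, facets = score_traits(item_responses[half], key_h)
        scores = traits if level == "trait" else facets
        pairs = dyad_pairs(list(item_responses.index))
        vec = np.array([
            personality_similarity(scores.loc[a].to_numpy(),
                                   scores.loc[b].to_numpy(), spec)
            for a, b in pairs
        ])
        if np.std(vec) == 0:
            raise ValueError("constant similarity vector in one half")
        sims.append(vec)
    r, _ = pearsonr(sims[0], sims[1])
    return float(r)
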