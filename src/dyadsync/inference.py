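"""Statistical machinery on the dyad table.

The unit of analysis is the unordered subject pair.  Because the
n(n-1)/2 dyadic observations are not independent (every subject appears
in n-1 of them), parametric OLS p-values are anti-conservative; the
package therefore pairs every standardized OLS fit with a Mantel-style
permutation test that shuffles subject identities underlying the tested
dyadic predictor.  Permuting subject identities is applied directly to
the predictor's n x n dyadic matrix — permuting the rows and columns of
that matrix is exactly equivalent to re-deriving all dyad values after
shuffling the subject-level attribute, for any measure that is a
function of the two subjects' own data.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datasets import ProfileSet, dyad_pairs
from .personality import SimilarityMetricSpec, dyad_similarity_table

__all__ = [
    "PermutationResult",
    "MediationResult",
    "build_dyad_table",
    "standardized_ols",
    "subject_permutation_test",
    "fdr_bh",
    "network_coefficient_test",
    "per_subject_effects",
    "mediation_analysis",
    "compare_effect_sizes",
    "coefficient_contrast",
]


@dataclass
class PermutationResult:
    beta_obs: float
    se: float
    p_parametric: float
    p_permutation: float
    n_permutations: int
    seed: int | None
    null_quantiles: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.p_permutation <= 1:
            raise ValueError("p_permutation must be in (0, 1]")
        floor = 1.0 / (self.n_permutations + 1)
        if self.p_permutation < floor - 1e-12:
            raise ValueError("p_permutation below attainable floor")


@dataclass
class MediationResult:
    path_a: dict        # X -> M: beta, se, p, p_permutation
    path_b: dict        # M -> Y | X
    total_c: dict       # X -> Y
    direct_c_prime: dict  # X -> Y | M
    indirect: dict      # a*b: beta, p_permutation

    def __post_init__(self) -> None:
        gap = abs(self.total_c["beta"]
                  - (self.direct_c_prime["beta"] + self.indirect["beta"]))
        if gap > 1e-8:
            raise ValueError("total != direct + indirect beyond tolerance")


# ----------------------------------------------------------------------
# Table assembly
# ----------------------------------------------------------------------

def build_dyad_table(profiles: ProfileSet,
                     synchrony_table: pd.DataFrame | None = None,
                     isc_table: pd.DataFrame | None = None,
                     gaze_table: pd.DataFrame | None = None,
                     metric_spec: SimilarityMetricSpec = SimilarityMetricSpec(),
                     level: str = "trait",
                     per_facet: bool = False) -> pd.DataFrame:
    """Assemble one row per unordered dyad with predictors and outcomes.

    Predictors come from the profiles (personality + demographic
    similarity); outcomes are merged from the synchrony / ISC / gaze
    tables.  Region-level synchrony is pivoted to ``<measure>__<region>``
    columns plus region-mean ``<measure>_mean`` summaries.  Missing
    outcomes stay NaN (flagged, not dropped).
    """
    table = dyad_similarity_table(profiles, spec=metric_spec, level=level,
                                  per_facet=per_facet)
    known = set(profiles.subject_ids)
    key = ["subject_a", "subject_b"]

    def check_labels(df: pd.DataFrame, what: str) -> None:
        labels = set(df["subject_a"]) | set(df["subject_b"])
        if not labels <= known:
            raise ValueError(f"{what} contains unknown subjects: "
                             f"{sorted(labels - known)[:5]}")

    if synchrony_table is not None:
        check_labels(synchrony_table, "synchrony_table")
        wide = synchrony_table.pivot_table(
            index=key, columns=["measure", "region"], values="value")
        wide.columns = [f"{m}__{r}" for m, r in wide.columns]
        for meas in synchrony_table["measure"].unique():
            cols = [c for c in wide.columns if c.startswith(f"{meas}__")]
            wide[f"{meas}_mean"] = wide[cols].mean(axis=1)
        table = table.merge(wide.reset_index(), on=key, how="left")
    if isc_table is not None:
        check_labels(isc_table, "isc_table")
        table = table.merge(isc_table, on=key, how="left")
    if gaze_table is not None:
        check_labels(gaze_table, "gaze_table")
        table = table.merge(gaze_table, on=key, how="left")

    expected = len(known) * (len(known) - 1) // 2
    if len(table) != expected:
        raise ValueError(f"expected {expected} dyads, got {len(table)}")
    return table


# ----------------------------------------------------------------------
# Standardized OLS
# ----------------------------------------------------------------------

def _zscore(x: np.ndarray) -> np.ndarray:
    sd = x.std(ddof=1)
    if sd == 0 or not np.isfinite(sd):
        raise ValueError("zero or non-finite variance column")
    return (x - x.mean()) / sd


def standardized_ols(table: pd.DataFrame, outcome: str,
                     predictors: list[str] | str,
                     covariates: list[str] | tuple = ()) -> pd.DataFrame:
    """OLS on z-scored outcome and regressors.

    Returns a DataFrame indexed by regressor with columns ``beta, se,
    t, p`` (parametric, df = n - k - 1).  With a single standardized
    predictor and no covariates, beta equals the Pearson correlation.
    Rank-deficient designs raise, naming the collinear columns.
    """
    if isinstance(predictors, str):
        predictors = [predictors]
    cols = list(predictors) + list(covariates)
    sub = table[[outcome] + cols].dropna()
    n = len(sub)
    if n < len(cols) + 2:
        raise ValueError(f"need >= {len(cols) + 2} complete rows, got {n}")
    y = _zscore(sub[outcome].to_numpy(dtype=float))
    X = np.column_stack([np.ones(n)] +
                        [_zscore(sub[c].to_numpy(dtype=float)) for c in cols])
    if np.linalg.matrix_rank(X) < X.shape[1]:
        # identify offending columns via incremental rank
        bad = []
        rank = 1
        for j, c in enumerate(cols, start=1):
            r = np.linalg.matrix_rank(X[:, :j + 1])
            if r == rank:
                bad.append(c)
            rank = r
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df_resid = n - X.shape[1]
    sigma2 = resid @ resid / df_resid
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    with np.errstate(divide="ignore"):  # exact fits have se = 0, t = inf
        t = np.where(se > 0, beta / np.where(se > 0, se, 1.0),
                     np.sign(beta) * np.inf)
    p = 2 * stats.t.sf(np.abs(t), df_resid)
    out = pd.DataFrame({"beta": beta[1:], "se": se[1:], "t": t[1:], "p": p[1:]},
                       index=cols)
    out.attrs["n"] = n
    out.attrs["cov"] = cov[1:, 1:]
    out.attrs["df_resid"] = df_resid
    return out


# ----------------------------------------------------------------------
# Permutation machinery
# ----------------------------------------------------------------------

def _dyad_matrix(table: pd.DataFrame, col: str,
                 subjects: list[str]) -> np.ndarray:
    """Symmetric n x n matrix of a dyadic column (NaN diagonal)."""
    idx = {s: i for i, s in enumerate(subjects)}
    M = np.full((len(subjects), len(subjects)), np.nan)
    for a, b, v in zip(table["subject_a"], table["subject_b"], table[col]):
        M[idx[a], idx[b]] = v
        M[idx[b], idx[a]] = v
    return M


def _matrix_to_vector(M: np.ndarray, pair_idx: np.ndarray) -> np.ndarray:
    return M[pair_idx[:, 0], pair_idx[:, 1]]


def _perm_stats(y: np.ndarray, pred_matrix: np.ndarray,
                pair_idx: np.ndarray, Z: np.ndarray | None,
                permutations: list[np.ndarray]
                ) -> tuple[np.ndarray, np.ndarray]:
    """(beta, t) of the permuted predictor for each permutation.

    ``y`` is the z-scored outcome; ``Z`` the fixed covariate block
    (z-scored, with intercept) or None.  The t-statistic is the
    permutation statistic of record: unlike the raw coefficient it is
    approximately pivotal, so its null is not distorted when the
    observed predictor is collinear with covariates while its shuffled
    copies are not.
    """
    n = len(y)
    betas = np.empty(len(permutations))
    ts = np.empty(len(permutations))
    for i, perm in enumerate(permutations):
        Mp = pred_matrix[np.ix_(perm, perm)]
        x = _zscore(_matrix_to_vector(Mp, pair_idx))
        if Z is None:
            b = float(x @ y) / (n - 1)
            betas[i] = b
            # single-regressor t; guards the |b| -> 1 edge
            denom = max(1.0 - b * b, 1e-12)
            ts[i] = b * np.sqrt((n - 2) / denom)
        else:
            X = np.column_stack([Z, x])
            coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
            resid = y - X @ coef
            df = n - X.shape[1]
            sigma2 = max(float(resid @ resid) / df, 1e-300)
            xtx_inv_last = np.linalg.inv(X.T @ X)[-1, -1]
            betas[i] = coef[-1]
            ts[i] = coef[-1] / np.sqrt(sigma2 * xtx_inv_last)
    return betas, ts


def subject_permutation_test(table: pd.DataFrame, outcome: str,
                             predictor: str,
                             covariates: list[str] | tuple = (),
                             n_permutations: int = 1000,
                             seed: int | None = 0,
                             permutations: list[np.ndarray] | None = None
                             ) -> PermutationResult:
    """Mantel-style permutation test of one dyadic predictor.

    Each permutation shuffles the subject identities underlying the
    predictor (rows/columns of its dyadic matrix), rebuilds the dyadic
    predictor values, and re-fits the standardized OLS; covariates stay
    fixed so the partial effect is tested.  The permutation statistic is
    the predictor's t-value (equivalent to the coefficient when there
    are no covariates, and robust to predictor-covariate collinearity
    otherwise).  Two-sided p with the +1 correction:
    ``p = (1 + #{|t*| >= |t_obs|}) / (n_permutations + 1)``.
    """
    cols = [outcome, predictor] + list(covariates)
    sub = table[["subject_a", "subject_b"] + cols].dropna().reset_index(drop=True)
    fit = standardized_ols(sub, outcome, [predictor], covariates)
    beta_obs = float(fit.loc[predictor, "beta"])

    subjects = sorted(set(sub["subject_a"]) | set(sub["subject_b"]))
    expected = len(subjects) * (len(subjects) - 1) // 2
    if len(sub) != expected:
        raise ValueError(
            "predictor is not reconstructible from subject identities: the "
            "complete-case dyad set does not cover all pairs of its subjects")
    idx = {s: i for i, s in enumerate(subjects)}
    pair_idx = np.array([[idx[a], idx[b]]
                         for a, b in zip(sub["subject_a"], sub["subject_b"])])
    M = _dyad_matrix(sub, predictor, subjects)

    y = _zscore(sub[outcome].to_numpy(dtype=float))
    Z = None
    if covariates:
        Z = np.column_stack(
            [np.ones(len(sub))] +
            [_zscore(sub[c].to_numpy(dtype=float)) for c in covariates])
    if permutations is None:
        rng = np.random.default_rng(seed)
        permutations = [rng.permutation(len(subjects))
                        for _ in range(n_permutations)]
    betas, ts = _perm_stats(y, M, pair_idx, Z, permutations)
    t_obs = float(fit.loc[predictor, "t"])
    n_perm = len(betas)
    exceed = np.abs(ts) >= abs(t_obs) - 1e-9
    p_perm = (1 + int(np.sum(exceed))) / (n_perm + 1)
    qs = np.percentile(betas, [2.5, 50, 97.5]) if n_perm else [np.nan] * 3
    return PermutationResult(
        beta_obs=beta_obs, se=float(fit.loc[predictor, "se"]),
        p_parametric=float(fit.loc[predictor, "p"]),
        p_permutation=float(p_perm), n_permutations=n_perm, seed=seed,
        null_quantiles={"q2.5": float(qs[0]), "q50": float(qs[1]),
                        "q97.5": float(qs[2])})


# ----------------------------------------------------------------------
# Multiple testing and summaries
# ----------------------------------------------------------------------

def fdr_bh(p_values, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up: (reject flags, adjusted p)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.array([], dtype=bool), np.array([])
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    reject, p_adj, _, _ = multipletests(p, alpha=q, method="fdr_bh")
    return reject, p_adj


def network_coefficient_test(region_betas: pd.Series,
                             network_labels: pd.Series) -> pd.DataFrame:
    """One-sample t-test of each network's regional betas against zero.

    Descriptive: regional coefficients share dyads and are therefore not
    independent; the result carries a ``dependent_regions`` flag.
    """
    aligned = pd.DataFrame({"beta": region_betas,
                            "network": network_labels}).dropna()
    rows = []
    for net, grp in aligned.groupby("network", sort=True):
        b = grp["beta"].to_numpy()
        if len(b) < 2:
            continue
        if np.std(b, ddof=1) == 0:
            raise ValueError(f"zero-variance beta vector in network {net!r}")
        t, p = stats.ttest_1samp(b, 0.0)
        rows.append({"network": net, "n_regions": len(b),
                     "mean_beta": float(b.mean()), "t": float(t),
                     "p": float(p), "dependent_regions": True})
    return pd.DataFrame(rows)


def per_subject_effects(table: pd.DataFrame, outcome: str, predictor: str,
                        covariates: list[str] | tuple = ()
                        ) -> tuple[pd.Series, float]:
    """Per-subject standardized betas and the fraction positive.

    For each subject, the regression is re-run on only the dyads that
    include that subject (n - 1 observations for a complete design).
    Subjects with too few complete dyads are excluded with a warning.
    """
    import warnings

    subjects = sorted(set(table["subject_a"]) | set(table["subject_b"]))
    need = len(covariates) + 3
    betas = {}
    for s in subjects:
        rows = table[(table["subject_a"] == s) | (table["subject_b"] == s)]
        try:
            fit = standardized_ols(rows, outcome, [predictor], covariates)
        except ValueError:
            warnings.warn(f"subject {s!r} excluded: fewer than {need} usable "
                          "dyads", RuntimeWarning, stacklevel=2)
            continue
        betas[s] = float(fit.loc[predictor, "beta"])
    ser = pd.Series(betas, name="beta")
    frac = float((ser > 0).mean()) if len(ser) else np.nan
    return ser, frac


# ----------------------------------------------------------------------
# Mediation
# ----------------------------------------------------------------------

def mediation_analysis(table: pd.DataFrame, x: str, mediator: str,
                       outcome: str, n_permutations: int = 1000,
                       seed: int | None = 0) -> MediationResult:
    """Linear mediation with Mantel permutation p-values per path.

    a: M ~ X;  b: Y ~ M + X (coefficient of M);  c: Y ~ X;
    c': Y ~ X + M (coefficient of X);  indirect = a * b.
    The indirect effect's permutation p is the joint-significance rule
    ``max(p_a, p_b)``: the indirect effect is credited only when both
    constituent paths survive their own subject-shuffling nulls.  (A
    joint-shuffle product null is anti-conservative when one path is
    strong and the other null, because shuffling both deflates the null
    product far below the sampling spread of a * b_hat.)  The product
    null quantiles are still reported for inspection.
    """
    sub = table[["subject_a", "subject_b", x, mediator, outcome]].dropna()
    sub = sub.reset_index(drop=True)
    fit_a = standardized_ols(sub, mediator, [x])
    fit_b = standardized_ols(sub, outcome, [mediator], [x])
    fit_c = standardized_ols(sub, outcome, [x])
    fit_cp = standardized_ols(sub, outcome, [x], [mediator])
    a = float(fit_a.loc[x, "beta"])
    b = float(fit_b.loc[mediator, "beta"])
    c = float(fit_c.loc[x, "beta"])
    c_prime = float(fit_cp.loc[x, "beta"])

    res_a = subject_permutation_test(sub, mediator, x,
                                     n_permutations=n_permutations, seed=seed)
    res_b = subject_permutation_test(sub, outcome, mediator, covariates=[x],
                                     n_permutations=n_permutations,
                                     seed=None if seed is None else seed + 1)

    # joint-shuffle product null for the indirect effect
    subjects = sorted(set(sub["subject_a"]) | set(sub["subject_b"]))
    idx = {s: i for i, s in enumerate(subjects)}
    pair_idx = np.array([[idx[p], idx[q]]
                         for p, q in zip(sub["subject_a"], sub["subject_b"])])
    Mx = _dyad_matrix(sub, x, subjects)
    Mm = _dyad_matrix(sub, mediator, subjects)
    y_z = _zscore(sub[outcome].to_numpy(dtype=float))
    m_z = _zscore(sub[mediator].to_numpy(dtype=float))
    rng = np.random.default_rng(None if seed is None else seed + 2)
    prod_null = np.empty(n_permutations)
    n_subj = len(subjects)
    for i in range(n_permutations):
        perm_x = rng.permutation(n_subj)
        perm_m = rng.permutation(n_subj)
        x_star = _zscore(_matrix_to_vector(Mx[np.ix_(perm_x, perm_x)], pair_idx))
        m_star = _zscore(_matrix_to_vector(Mm[np.ix_(perm_m, perm_m)], pair_idx))
        a_star = float(x_star @ m_star) / (len(m_star) - 1)
        X = np.column_stack([np.ones(len(y_z)), x_star, m_star])
        coef, _, _, _ = np.linalg.lstsq(X, y_z, rcond=None)
        prod_null[i] = a_star * coef[2]
    indirect = a * b
    p_ind = max(res_a.p_permutation, res_b.p_permutation)
    q_null = np.percentile(prod_null, [2.5, 97.5])

    def path(fit, name, p_perm=None):
        d = {"beta": float(fit.loc[name, "beta"]),
             "se": float(fit.loc[name, "se"]),
             "p": float(fit.loc[name, "p"])}
        if p_perm is not None:
            d["p_permutation"] = p_perm
        return d

    return MediationResult(
        path_a=path(fit_a, x, res_a.p_permutation),
        path_b=path(fit_b, mediator, res_b.p_permutation),
        total_c=path(fit_c, x),
        direct_c_prime=path(fit_cp, x),
        indirect={"beta": indirect, "p_permutation": float(p_ind),
                  "product_null_q2.5": float(q_null[0]),
                  "product_null_q97.5": float(q_null[1])})


# ----------------------------------------------------------------------
# Effect-size comparison
# ----------------------------------------------------------------------

def compare_effect_sizes(coefs_a, coefs_b) -> tuple[float, int, float]:
    """Pooled two-sample t-test comparing two predictors' coefficient
    vectors across k focal effects; df = 2k - 2."""
    a = np.asarray(coefs_a, dtype=float)
    b = np.asarray(coefs_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("coefficient vectors must be 1-D of equal length")
    if len(a) < 2:
        raise ValueError("need >= 2 focal effects")
    t, p = stats.ttest_ind(a, b, equal_var=True)
    df = 2 * len(a) - 2
    return float(t), df, float(p)


def coefficient_contrast(table: pd.DataFrame, outcome: str,
                         predictor_a: str, predictor_b: str,
                         covariates: list[str] | tuple = ()
                         ) -> dict[str, float]:
    """Wald test on the difference of two standardized coefficients from
    one joint model."""
    fit = standardized_ols(table, outcome, [predictor_a, predictor_b],
                           covariates)
    cov = fit.attrs["cov"]
    i, j = 0, 1
    diff = float(fit.iloc[i]["beta"] - fit.iloc[j]["beta"])
    var = cov[i, i] + cov[j, j] - 2 * cov[i, j]
    se = float(np.sqrt(var))
    t = diff / se
    p = float(2 * stats.t.sf(abs(t), fit.attrs["df_resid"]))
    return {"difference": diff, "se": se, "t": float(t), "p": p,
            "df": fit.attrs["df_resid"]}
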