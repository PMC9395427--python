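"""Dyad-table assembly, standardized OLS, permutation tests, FDR,
network tests, per-subject effects, mediation, effect-size comparison."""

import numpy as np
import pandas as pd
import pytest
import statsmodels.api as sm
from scipy import stats

from dyadsync import (GeneratorConfig, build_dyad_table, compare_effect_sizes,
                      dyad_pairs, fdr_bh, generate_profiles,
                      mediation_analysis, network_coefficient_test,
                      per_subject_effects, standardized_ols,
                      subject_permutation_test)
from dyadsync.inference import coefficient_contrast


def _attribute_table(n=12, seed=0, noise=1.0, coupling=1.0):
    """Dyad table derived from subject-level attributes: predictor is the
    negated attribute distance, outcome couples to it plus dyad noise."""
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:03d}" for i in range(n)]
    u = rng.normal(size=n)
    rows = []
    for i, a in enumerate(subjects):
        for j in range(i + 1, n):
            x = -abs(u[i] - u[j])
            y = coupling * x + noise * rng.normal()
            rows.append({"subject_a": a, "subject_b": subjects[j],
                         "x": x, "y": y})
    return pd.DataFrame(rows)


class TestBuildDyadTable:
    @pytest.mark.parametrize("n,rows", [(3, 3), (66, 2145), (225, 25200)])
    def test_dyad_counts(self, n, rows):
        cfg = GeneratorConfig(n_subjects=n, seed=1)
        table = build_dyad_table(generate_profiles(cfg))
        assert len(table) == rows

    def test_outcomes_merged_and_missing_flagged(self, tiny_profiles,
                                                 tiny_fmri):
        from dyadsync import dyadic_synchrony_table
        sync = dyadic_synchrony_table(tiny_fmri)
        table = build_dyad_table(tiny_profiles, synchrony_table=sync)
        assert "NM_mean" in table.columns and "NP_mean" in table.columns
        assert "NM__R001" in table.columns
        assert table["NM_mean"].notna().all()

    def test_unknown_subject_rejected(self, tiny_profiles):
        bad = pd.DataFrame({"subject_a": ["ZZZ"], "subject_b": ["S001"],
                            "eeg_isc": [0.1]})
        with pytest.raises(ValueError, match="unknown subjects"):
            build_dyad_table(tiny_profiles, isc_table=bad)


class TestStandardizedOls:
    def test_single_predictor_beta_is_pearson_r(self):
        tab = _attribute_table(n=10, seed=3)
        fit = standardized_ols(tab, "y", ["x"])
        r = stats.pearsonr(tab["x"], tab["y"])[0]
        assert fit.loc["x", "beta"] == pytest.approx(r, abs=1e-12)

    def test_outcome_equals_predictor(self):
        tab = _attribute_table(n=8, seed=4)
        tab["y"] = tab["x"]
        fit = standardized_ols(tab, "y", ["x"])
        assert fit.loc["x", "beta"] == pytest.approx(1.0)
        assert fit.loc["x", "se"] == pytest.approx(0.0, abs=1e-10)

    def test_matches_normal_equations_and_statsmodels(self):
        rng = np.random.default_rng(9)
        tab = pd.DataFrame({"y": rng.normal(size=6),
                            "p1": rng.normal(size=6),
                            "p2": rng.normal(size=6)})
        fit = standardized_ols(tab, "y", ["p1", "p2"])
        z = (tab - tab.mean()) / tab.std(ddof=1)
        X = sm.add_constant(z[["p1", "p2"]].to_numpy())
        ref = sm.OLS(z["y"].to_numpy(), X).fit()
        assert fit["beta"].to_numpy() == pytest.approx(ref.params[1:], abs=1e-10)
        assert fit["se"].to_numpy() == pytest.approx(ref.bse[1:], abs=1e-10)
        assert fit["p"].to_numpy() == pytest.approx(ref.pvalues[1:], abs=1e-10)
        # independent brute-force normal equations
        bf = np.linalg.solve(X.T @ X, X.T @ z["y"].to_numpy())
        assert fit["beta"].to_numpy() == pytest.approx(bf[1:], abs=1e-10)

    def test_collinear_design_names_columns(self):
        tab = _attribute_table(n=8, seed=5)
        tab["x2"] = 2.0 * tab["x"]
        with pytest.raises(ValueError, match="x2"):
            standardized_ols(tab, "y", ["x", "x2"])


class TestSubjectPermutation:
    def test_identity_permutation_gives_p_one(self):
        tab = _attribute_table(n=10, seed=6)
        n_subj = 10
        res = subject_permutation_test(tab, "y", "x",
                                       permutations=[np.arange(n_subj)])
        assert res.p_permutation == 1.0

    def test_mechanical_outcome_attains_minimum_p(self):
        tab = _attribute_table(n=20, seed=7)
        tab["y"] = tab["x"]
        res = subject_permutation_test(tab, "y", "x", n_permutations=999,
                                       seed=0)
        assert res.p_permutation == pytest.approx(1 / 1000)
        assert res.beta_obs == pytest.approx(1.0)

    def test_permuted_beta_distribution_centered_at_zero(self):
        tab = _attribute_table(n=14, seed=8, coupling=0.0)
        res = subject_permutation_test(tab, "y", "x", n_permutations=500,
                                       seed=1)
        assert res.null_quantiles["q2.5"] < 0 < res.null_quantiles["q97.5"]
        assert res.p_permutation > 0.05

    def test_covariates_held_fixed(self):
        tab = _attribute_table(n=12, seed=9)
        rng = np.random.default_rng(2)
        tab["z"] = rng.normal(size=len(tab))
        res = subject_permutation_test(tab, "y", "x", covariates=["z"],
                                       n_permutations=99, seed=3)
        fit = standardized_ols(tab, "y", ["x"], ["z"])
        assert res.beta_obs == pytest.approx(fit.loc["x", "beta"])

    def test_exchangeability_under_relabeling(self):
        tab = _attribute_table(n=10, seed=10)
        relabel = {f"S{i + 1:03d}": f"T{(i * 7) % 10 + 1:03d}" for i in range(10)}
        tab2 = tab.assign(subject_a=tab["subject_a"].map(relabel),
                          subject_b=tab["subject_b"].map(relabel))
        swap = tab2["subject_a"] > tab2["subject_b"]
        tab2.loc[swap, ["subject_a", "subject_b"]] = \
            tab2.loc[swap, ["subject_b", "subject_a"]].to_numpy()
        a = subject_permutation_test(tab, "y", "x", n_permutations=200, seed=5)
        b = subject_permutation_test(tab2, "y", "x", n_permutations=200, seed=5)
        assert a.beta_obs == pytest.approx(b.beta_obs, abs=1e-12)
        assert a.p_parametric == pytest.approx(b.p_parametric, abs=1e-12)


class TestFdrBh:
    def test_stepup_hand_case(self):
        # thresholds i*q/m = .0125, .025, .0375, .05 -> all rejected
        reject, _ = fdr_bh([0.01, 0.02, 0.03, 0.04], q=0.05)
        assert reject.all()

    def test_all_ones_rejects_none(self):
        reject, _ = fdr_bh([1.0, 1.0, 1.0], q=0.05)
        assert not reject.any()

    def test_single_p_compares_to_q(self):
        assert fdr_bh([0.04], q=0.05)[0].all()
        assert not fdr_bh([0.06], q=0.05)[0].any()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_bh([0.5, 1.2])

    def test_matches_bruteforce_stepup(self, rng):
        # brute-force step-up: largest i with p_(i) <= i*q/m
        def brute(p, q):
            p = np.asarray(p)
            order = np.argsort(p)
            m = len(p)
            k = 0
            for rank, idx in enumerate(order, start=1):
                if p[idx] <= rank * q / m:
                    k = rank
            reject = np.zeros(m, dtype=bool)
            reject[order[:k]] = True
            return reject

        grid = np.round(np.arange(0, 1.0001, 0.01), 2)
        for m in range(1, 7):
            for _ in range(200):
                p = rng.choice(grid, size=m)
                got, _ = fdr_bh(p, q=0.05)
                assert np.array_equal(got, brute(p, 0.05))


class TestNetworkTest:
    def test_hand_computed_t(self):
        betas = pd.Series([0.1, 0.2, 0.15, 0.25],
                          index=["R1", "R2", "R3", "R4"])
        nets = pd.Series(["dmn"] * 4, index=betas.index)
        res = network_coefficient_test(betas, nets)
        b = betas.to_numpy()
        want_t = b.mean() / (b.std(ddof=1) / 2.0)
        assert res.loc[0, "t"] == pytest.approx(want_t)
        assert res.loc[0, "n_regions"] == 4

    def test_zero_variance_raises(self):
        betas = pd.Series([0.0, 0.0, 0.0], index=list("abc"))
        nets = pd.Series(["dmn"] * 3, index=betas.index)
        with pytest.raises(ValueError, match="zero-variance"):
            network_coefficient_test(betas, nets)

    def test_null_betas_give_uniform_p(self, rng):
        ps = []
        for _ in range(300):
            betas = pd.Series(rng.normal(size=8))
            nets = pd.Series(["n1"] * 8, index=betas.index)
            ps.append(network_coefficient_test(betas, nets).loc[0, "p"])
        assert stats.kstest(ps, "uniform").pvalue > 0.01


class TestPerSubjectEffects:
    def test_observation_count_per_subject(self):
        tab = _attribute_table(n=12, seed=11)
        betas, frac = per_subject_effects(tab, "y", "x")
        assert len(betas) == 12
        # each per-subject regression uses n - 1 = 11 dyads
        one = tab[(tab["subject_a"] == "S001") | (tab["subject_b"] == "S001")]
        assert len(one) == 11

    def test_mechanical_outcome_gives_all_positive(self):
        tab = _attribute_table(n=8, seed=12)
        tab["y"] = tab["x"]
        betas, frac = per_subject_effects(tab, "y", "x")
        assert np.allclose(betas, 1.0)
        assert frac == 1.0

    def test_coupled_generator_majority_positive(self):
        fracs = []
        for rep in range(5):
            tab = _attribute_table(n=14, seed=100 + rep, coupling=1.0,
                                   noise=1.0)
            fracs.append(per_subject_effects(tab, "y", "x")[1])
        assert np.mean(fracs) > 0.5


class TestMediation:
    def test_effect_decomposition_identity(self):
        tab = _attribute_table(n=10, seed=13)
        rng = np.random.default_rng(4)
        tab["m"] = 0.5 * tab["x"] + rng.normal(size=len(tab))
        res = mediation_analysis(tab, "x", "m", "y", n_permutations=49, seed=1)
        total = res.total_c["beta"]
        assert total == pytest.approx(
            res.direct_c_prime["beta"] + res.indirect["beta"], abs=1e-8)

    def test_null_mediator_gives_nonsignificant_indirect(self):
        rejections = 0
        for rep in range(20):
            tab = _attribute_table(n=12, seed=200 + rep)
            rng = np.random.default_rng(rep)
            # M depends on X but Y does not depend on M given X
            tab["m"] = 0.7 * tab["x"] + rng.normal(size=len(tab))
            res = mediation_analysis(tab, "x", "m", "y", n_permutations=99,
                                     seed=rep)
            rejections += res.indirect["p_permutation"] <= 0.05
        assert rejections <= 3

    def test_collinear_mediator_rejected(self):
        tab = _attribute_table(n=8, seed=14)
        tab["m"] = tab["x"]
        with pytest.raises(ValueError):
            mediation_analysis(tab, "x", "m", "y", n_permutations=19, seed=0)


class TestEffectSizeComparison:
    def test_identical_vectors_give_zero_t(self):
        v = [0.1, 0.2, 0.3]
        t, df, p = compare_effect_sizes(v, v)
        assert t == pytest.approx(0.0)
        assert p == pytest.approx(1.0)

    def test_six_focal_effects_give_df_ten(self):
        t, df, p = compare_effect_sizes([0.2] * 6, [0.1] * 5 + [0.2])
        assert df == 10
        assert t == pytest.approx(5.0)  # hand-computed pooled-variance t

    def test_matches_scipy(self, rng):
        a = rng.normal(size=6)
        b = rng.normal(size=6)
        t, df, p = compare_effect_sizes(a, b)
        ref_t, ref_p = stats.ttest_ind(a, b, equal_var=True)
        assert (t, p) == pytest.approx((ref_t, ref_p))

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError):
            compare_effect_sizes([0.1, 0.2], [0.1, 0.2, 0.3])


class TestCoefficientContrast:
    def test_symmetric_predictors_give_null_contrast(self):
        rng = np.random.default_rng(15)
        n = 14
        subjects = [f"S{i + 1:03d}" for i in range(n)]
        u, v = rng.normal(size=n), rng.normal(size=n)
        rows = []
        for i in range(n):
            for j in range(i + 1, n):
                x1 = -abs(u[i] - u[j])
                x2 = -abs(v[i] - v[j])
                rows.append({"subject_a": subjects[i],
                             "subject_b": subjects[j], "x": x1, "x2": x2,
                             "y": x1 + x2 + 0.5 * rng.normal()})
        tab = pd.DataFrame(rows)
        res = coefficient_contrast(tab, "y", "x", "x2")
        assert res["p"] > 0.05
        assert abs(res["difference"]) < 3 * res["se"]

    def test_dominant_predictor_detected(self):
        tab = _attribute_table(n=16, seed=16, noise=0.3)
        rng = np.random.default_rng(5)
        tab["w"] = rng.normal(size=len(tab))  # unrelated predictor
        res = coefficient_contrast(tab, "y", "x", "w")
        assert res["p"] < 0.01
        assert res["difference"] > 0
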