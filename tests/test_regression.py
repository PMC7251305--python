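"""Transition-law regression: design assembly, standardized OLS, mode ranking."""

import numpy as np
import pytest

from tcmnet.markov import TransitionMatrix, mtm, state_frequencies
from tcmnet.regression import (
    RegressionError,
    RegressionResult,
    adjusted_r2,
    build_design,
    centroid_distances,
    cohort_summary,
    compare_modes,
    fit_model,
)
from tcmnet.simulate import GeneratorConfig, build_generator_matrix, simulate_states
from tcmnet.states import ClusterModel


def make_design(seed=0, k=4, n=2000):
    rng = np.random.default_rng(seed)
    centroids = rng.normal(size=(k, 3))
    labels = rng.integers(1, k + 1, size=n)
    T = mtm(labels, k=k)
    return build_design(T, centroid_distances(centroids), state_frequencies(labels, k))


class TestCentroidDistances:
    def test_zero_diagonal_and_symmetry(self):
        rng = np.random.default_rng(1)
        d = centroid_distances(rng.normal(size=(5, 3)))
        assert np.allclose(np.diag(d), 0.0)
        assert np.allclose(d, d.T)

    def test_three_four_five_triangle(self):
        d = centroid_distances(np.array([[0.0, 0, 0], [3.0, 4.0, 0]]))
        assert d[0, 1] == pytest.approx(5.0)

    def test_matches_brute_force(self):
        rng = np.random.default_rng(2)
        c = rng.normal(size=(6, 3))
        d = centroid_distances(c)
        for i in range(6):
            for j in range(6):
                assert d[i, j] == pytest.approx(np.sqrt(((c[i] - c[j]) ** 2).sum()))

    def test_accepts_cluster_model(self):
        model = ClusterModel(
            role="patient", k=2, feature_means=np.zeros(3), feature_sds=np.ones(3),
            centroids=np.array([[0.0, 0, 0], [3.0, 4.0, 0]]),
            occupancy=np.array([1, 1]), variance_explained=0.5,
        )
        assert centroid_distances(model)[0, 1] == pytest.approx(5.0)


class TestBuildDesign:
    def test_six_active_states_give_36_rows(self, example_patient_mtm):
        k = example_patient_mtm.k
        rng = np.random.default_rng(3)
        freqs = np.zeros(k)
        freqs[[0, 1, 2, 3, 6, 7]] = [0.3, 0.2, 0.2, 0.15, 0.1, 0.05]
        design = build_design(
            example_patient_mtm, centroid_distances(rng.normal(size=(k, 3))), freqs
        )
        assert design.n_cells == 36

    def test_composite_regressor_is_frequency_product(self):
        labels = np.tile([1, 2, 3], 200)
        T = mtm(labels, k=3)
        freqs = np.array([0.5, 0.3, 0.2])
        design = build_design(T, centroid_distances(np.eye(3)), freqs)
        cell = design.frame.query("i == 1 and j == 3")
        assert cell["x_comp"].iloc[0] == pytest.approx(0.10)

    def test_response_reassembles_probabilities(self, example_patient_mtm):
        rng = np.random.default_rng(4)
        freqs = np.full(8, 1 / 8)
        design = build_design(
            example_patient_mtm, centroid_distances(rng.normal(size=(8, 3))), freqs
        )
        p = example_patient_mtm.probs
        for _, row in design.frame.iterrows():
            assert row["y"] == pytest.approx(p[int(row["i"]) - 1, int(row["j"]) - 1])

    def test_diagonal_can_be_excluded(self, example_patient_mtm):
        rng = np.random.default_rng(5)
        design = build_design(
            example_patient_mtm,
            centroid_distances(rng.normal(size=(8, 3))),
            np.full(8, 1 / 8),
            include_diagonal=False,
        )
        assert design.n_cells == 30
        assert (design.frame["i"] != design.frame["j"]).all()


class TestFitModel:
    def test_exact_affine_fit_recovers_unit_beta(self):
        design = make_design(seed=6)
        design.frame["y"] = 3.0 * design.frame["x_comp"] + 0.2
        res = fit_model(design, "full")
        assert res.beta_comp == pytest.approx(1.0, abs=1e-8)
        assert res.beta_dist == pytest.approx(0.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0)

    def test_single_regressor_beta_equals_pearson_r(self):
        design = make_design(seed=7)
        res = fit_model(design, "distance")
        y = design.frame["y"]
        r = np.corrcoef(y, design.frame["x_dist"])[0, 1]
        assert res.beta_dist == pytest.approx(r)
        assert res.r2 == pytest.approx(r**2)

    def test_matches_normal_equations_oracle(self):
        """Standardized betas and R^2 agree with a closed-form least-squares
        solve on designs up to 5 states."""
        for seed, k in [(8, 3), (9, 4), (10, 5)]:
            design = make_design(seed=seed, k=k)
            res = fit_model(design, "full")
            y = design.frame["y"].to_numpy()
            X = design.frame[["x_dist", "x_comp"]].to_numpy()
            yz = (y - y.mean()) / y.std()
            Xz = (X - X.mean(axis=0)) / X.std(axis=0)
            beta = np.linalg.solve(Xz.T @ Xz, Xz.T @ yz)
            pred = Xz @ beta
            r2 = 1 - ((yz - pred) ** 2).sum() / ((yz - yz.mean()) ** 2).sum()
            assert res.beta_dist == pytest.approx(beta[0])
            assert res.beta_comp == pytest.approx(beta[1])
            assert res.r2 == pytest.approx(r2)

    def test_adjusted_r2_formula_exact_on_stored_fields(self):
        res = fit_model(make_design(seed=11), "full")
        assert res.adj_r2 == pytest.approx(
            1 - (1 - res.r2) * (res.n_cells - 1) / (res.n_cells - res.k_predictors - 1)
        )
        assert res.adj_r2 <= res.r2
        assert res.r == pytest.approx(np.sqrt(res.r2))

    def test_worked_example_beta_ratio(self):
        res = RegressionResult(
            mode="full", beta_dist=-0.295, beta_comp=0.709,
            r=0.864, r2=0.746, adj_r2=0.717, p_model=1e-5, n_cells=36, k_predictors=2,
        )
        assert res.beta_ratio == pytest.approx(2.403, abs=5e-4)

    def test_f_test_agrees_with_permutation_pvalue(self):
        """Overall-F p-value matches a label-permutation null within
        Monte-Carlo error on a small design."""
        design = make_design(seed=12, k=5, n=2000)
        res = fit_model(design, "full")
        y = design.frame["y"].to_numpy()
        X = design.frame[["x_dist", "x_comp"]].to_numpy()
        Xz = (X - X.mean(axis=0)) / X.std(axis=0)
        Q, _ = np.linalg.qr(np.column_stack([np.ones(len(y)), Xz]))
        rng = np.random.default_rng(0)
        n_perm = 10_000
        perms = np.stack([rng.permutation(y) for _ in range(n_perm)])
        perms = (perms - perms.mean(axis=1, keepdims=True))
        fitted = perms @ Q @ Q.T  # projection onto the design span
        r2s = (fitted * perms).sum(axis=1) / (perms**2).sum(axis=1)
        yz = y - y.mean()
        r2_obs = ((yz @ Q @ Q.T) * yz).sum() / (yz**2).sum()
        p_perm = (r2s >= r2_obs - 1e-12).mean()
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_perm)
        assert abs(res.p_model - p_perm) < max(5 * se, 0.02)

    def test_zero_variance_response_rejected(self):
        design = make_design(seed=13)
        design.frame["y"] = 0.25
        with pytest.raises(RegressionError, match="variance"):
            fit_model(design, "full")

    def test_collinear_regressors_rejected(self):
        design = make_design(seed=14)
        design.frame["x_comp"] = 2.0 * design.frame["x_dist"] + 1.0
        with pytest.raises(RegressionError, match="collinear"):
            fit_model(design, "full")


class TestCompareModes:
    def test_frequency_generated_data_ranks_composite_first(self):
        cfg = GeneratorConfig(w_dist=0.0)
        T = build_generator_matrix(cfg)
        labels = simulate_states(T, 5000, seed=15)
        Tm = mtm(labels, k=8)
        results = compare_modes(
            Tm, centroid_distances(cfg.centroids), state_frequencies(labels, 8)
        )
        assert results[0].mode in ("composite", "full", "freq_j")
        ranks = {r.mode: i for i, r in enumerate(results)}
        assert ranks["distance"] == 3

    def test_pure_noise_response_has_negligible_r2(self):
        design = make_design(seed=16, k=5, n=3000)
        rng = np.random.default_rng(17)
        design.frame["y"] = rng.normal(size=len(design.frame))
        for mode in ("distance", "freq_j", "composite", "full"):
            assert fit_model(design, mode).r2 < 0.3


class TestCohortSummary:
    def test_single_subject_summary_equals_subject(self):
        res = fit_model(make_design(seed=18), "full", role="patient")
        summary = cohort_summary({"patient": [res], "therapist": [res]})
        assert summary.by_role["patient"]["beta_dist"] == pytest.approx(res.beta_dist)
        assert summary.distance_dependence_ratio == pytest.approx(1.0)

    def test_means_match_direct_arithmetic(self):
        results = [fit_model(make_design(seed=s), "full", role="patient") for s in (19, 20, 21)]
        summary = cohort_summary({"patient": results, "therapist": results})
        assert summary.by_role["patient"]["r2"] == pytest.approx(
            np.mean([r.r2 for r in results])
        )

    def test_empty_role_rejected(self):
        with pytest.raises(RegressionError, match="no results"):
            cohort_summary({"patient": []})
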