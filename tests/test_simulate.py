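"""Generator kernel, chain sampling, emission and dyad coupling."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from tcmnet.compare import mtm_correlation
from tcmnet.markov import mtm, state_frequencies, stationary_distribution
from tcmnet.simulate import (
    GeneratorConfig,
    SimulationError,
    build_generator_matrix,
    cube_centroids,
    emit_blocks,
    simulate_cohort,
    simulate_dyad,
    simulate_states,
)
from tcmnet.states import fit_states, standardize


class TestGeneratorMatrix:
    def test_pure_frequency_uniform_targets_gives_uniform_kernel(self):
        cfg = GeneratorConfig(k=4, w_dist=0.0, target_freqs=np.full(4, 0.25),
                              centroids=cube_centroids(4))
        T = build_generator_matrix(cfg)
        assert np.allclose(T, 0.25)

    def test_tiny_length_scale_concentrates_on_self_transitions(self):
        cfg = GeneratorConfig(k=4, w_freq=0.0, w_dist=1.0, length_scale=1e-3,
                              target_freqs=np.full(4, 0.25), centroids=cube_centroids(4))
        T = build_generator_matrix(cfg)
        assert np.allclose(np.diag(T), 1.0, atol=1e-12)

    def test_pure_frequency_rows_equal_target_vector(self):
        f = np.array([0.5, 0.3, 0.2])
        cfg = GeneratorConfig(k=3, w_dist=0.0, target_freqs=f, centroids=cube_centroids(3))
        T = build_generator_matrix(cfg)
        # row i proportional to (f_i f_1, f_i f_2, f_i f_3): identical rows = f
        assert np.allclose(T, np.tile(f, (3, 1)))

    @pytest.mark.parametrize("w_dist,w_freq", [(0.0, 1.0), (1.0, 0.0), (0.5, 0.5)])
    def test_rows_exactly_stochastic(self, w_dist, w_freq):
        cfg = GeneratorConfig(w_dist=w_dist, w_freq=w_freq)
        T = build_generator_matrix(cfg)
        assert np.abs(T.sum(axis=1) - 1.0).max() < 1e-12

    def test_invalid_configs_rejected(self):
        with pytest.raises(SimulationError):
            GeneratorConfig(w_dist=0.0, w_freq=0.0)
        with pytest.raises(SimulationError):
            GeneratorConfig(target_freqs=np.full(8, 0.2))
        with pytest.raises(SimulationError):
            GeneratorConfig(centroids=np.zeros((8, 3)))


class TestSimulateStates:
    def test_absorbing_chain_stays_put(self):
        seq = simulate_states(np.eye(4), 50, seed=0, init_dist=[0, 0, 1, 0])
        assert np.all(seq == 3)

    def test_periodic_chain_alternates(self):
        seq = simulate_states(np.array([[0.0, 1.0], [1.0, 0.0]]), 40, seed=0)
        assert np.all(seq[:-1] != seq[1:])

    def test_empirical_frequencies_match_stationary(self):
        T = np.array([[0.5, 0.4, 0.1], [0.2, 0.5, 0.3], [0.1, 0.2, 0.7]])
        pi = stationary_distribution(T)
        n = 100_000
        f = state_frequencies(simulate_states(T, n, seed=2), k=3)
        se = np.sqrt(pi * (1 - pi) / n)
        assert np.all(np.abs(f - pi) < 3 * se + 0.004)

    def test_reproducible_per_seed(self):
        T = build_generator_matrix(GeneratorConfig())
        assert np.array_equal(
            simulate_states(T, 500, seed=5), simulate_states(T, 500, seed=5)
        )


class TestEmission:
    def test_noiseless_emission_sits_on_centroids(self):
        cfg = GeneratorConfig(emission_sd=0.0, n_blocks=10)
        states = np.array([1, 2, 3, 4, 5, 6, 7, 8, 1, 2])
        series, info = emit_blocks(states, states, cfg, seed=0)
        back = cfg.feature_means + cfg.feature_sds * cfg.centroids[states - 1]
        assert np.allclose(series.features("patient"), back)
        assert info["clip_rate"] == 0.0

    def test_noiseless_clustering_recovers_labels(self):
        cfg = GeneratorConfig(emission_sd=0.0, n_blocks=400)
        T = build_generator_matrix(cfg)
        states = simulate_states(T, 400, seed=1)
        series, _ = emit_blocks(states, states, cfg, seed=1)
        Z, const = standardize(series.features("patient"))
        _, labels = fit_states(Z, k=8, n_restarts=10, seed=0, constants=const)
        assert adjusted_rand_score(states, labels) == 1.0

    def test_moderate_noise_label_recovery_rate(self):
        """At emission_sd 0.2 and cube-corner centroids, >= 95% of blocks are
        assigned to their generating state (up to permutation)."""
        cfg = GeneratorConfig(emission_sd=0.2, n_blocks=3000)
        T = build_generator_matrix(cfg)
        states = simulate_states(T, 3000, seed=4)
        series, _ = emit_blocks(states, states, cfg, seed=4)
        Z, const = standardize(series.features("patient"))
        model, labels = fit_states(Z, k=8, n_restarts=20, seed=0, constants=const)
        # map each fitted cluster to its majority generating state
        agree = 0
        for s in range(1, 9):
            mask = labels == s
            if mask.any():
                agree += np.bincount(states[mask]).max()
        assert agree / len(states) >= 0.95

    def test_negative_sd_rejected(self):
        with pytest.raises(SimulationError):
            GeneratorConfig(emission_sd=-0.1)

    def test_excessive_clipping_warns(self):
        cfg = GeneratorConfig(
            emission_sd=0.2, n_blocks=50,
            feature_means=np.array([0.01, 0.01, 0.01]),
            feature_sds=np.array([0.05, 0.05, 0.05]),
        )
        states = np.ones(50, dtype=int)
        with pytest.warns(UserWarning, match="clipped"):
            emit_blocks(states, states, cfg, seed=0)


class TestDyadCoupling:
    def test_full_coupling_identity_map_copies_patient(self):
        cfg = GeneratorConfig(n_blocks=300)
        sim = simulate_dyad(cfg, coupling=1.0, seed=0)
        assert np.array_equal(sim.pat_seq.labels, sim.ther_seq.labels)

    def test_zero_coupling_roles_independent(self):
        """Chi-square on the joint patient/therapist state table stays
        non-significant at alpha = 0.01 across seeds."""
        pvals = []
        for seed in range(5):
            cfg = GeneratorConfig(n_blocks=2000, w_dist=0.0)
            sim = simulate_dyad(cfg, coupling=0.0, seed=seed)
            table = np.zeros((8, 8))
            np.add.at(table, (sim.pat_seq.labels - 1, sim.ther_seq.labels - 1), 1)
            table = table[table.sum(axis=1) > 0][:, table.sum(axis=0) > 0]
            pvals.append(stats.chi2_contingency(table).pvalue)
        assert np.median(pvals) > 0.01

    def test_role_similarity_increases_with_coupling(self):
        """Stronger coupling makes the two roles' transition matrices more
        alike (monotone over kappa in {0, 0.5, 1} at a fixed seed set)."""
        freqs_t = np.array([0.05, 0.05, 0.1, 0.1, 0.15, 0.15, 0.2, 0.2])
        corr_at = []
        for kappa in (0.0, 0.5, 1.0):
            vals = []
            for seed in range(3):
                cfg_p = GeneratorConfig(n_blocks=3000, w_dist=0.0)
                cfg_t = GeneratorConfig(n_blocks=3000, w_dist=0.0, target_freqs=freqs_t)
                sim = simulate_dyad(cfg_p, cfg_t, coupling=kappa, seed=seed)
                vals.append(
                    mtm_correlation(mtm(sim.pat_seq, 8), mtm(sim.ther_seq, 8))
                )
            corr_at.append(np.mean(vals))
        assert corr_at[0] < corr_at[1] < corr_at[2]

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(SimulationError, match="n_blocks"):
            simulate_dyad(GeneratorConfig(n_blocks=100), GeneratorConfig(n_blocks=200))

    def test_target_vs_realized_stationary_reported_separately(self):
        cfg = GeneratorConfig(n_blocks=500)
        sim = simulate_dyad(cfg, seed=0)
        # they differ in general: the kernel mixes frequency and distance terms
        assert sim.stationary_pat.shape == (8,)
        assert not np.allclose(sim.stationary_pat, cfg.target_freqs, atol=1e-6)


class TestCohort:
    def test_cohort_structure_and_reproducibility(self):
        d1 = simulate_cohort(n_good=2, n_poor=2, n_blocks=300, seed=3)
        d2 = simulate_cohort(n_good=2, n_poor=2, n_blocks=300, seed=3)
        assert [d.outcome for d in d1] == ["good", "good", "poor", "poor"]
        for a, b in zip(d1, d2):
            assert np.array_equal(a.sim.pat_seq.labels, b.sim.pat_seq.labels)
            assert np.array_equal(a.sim.ther_seq.labels, b.sim.ther_seq.labels)
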