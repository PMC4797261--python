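"""Learning tests: initialization, tied EM updates, convergence, recovery."""

import itertools

import numpy as np
import pytest
from scipy.optimize import linear_sum_assignment
from scipy.stats import multivariate_normal

from dshmm import (
    CoreModel,
    DataError,
    FitConfig,
    ObservationSet,
    StrandStateEmission,
    assemble_paired_model,
    em_step,
    fit,
    kmeans_initialize,
    random_model,
    sample_from_model,
)
from dshmm.learning import relabel_transcribed


def match_states(fitted: CoreModel, truth: CoreModel) -> np.ndarray:
    """perm[j] = fitted state index matched to truth state j (by mean distance)."""
    fm, tm = fitted.means_matrix(), truth.means_matrix()
    d = np.linalg.norm(fm[:, None, :] - tm[None, :, :], axis=2)
    rows, cols = linear_sum_assignment(d)
    perm = np.empty(truth.n_states, dtype=int)
    perm[cols] = rows
    return perm


class TestInitialization:
    def test_planted_clusters_recovered(self, tracks, rng):
        # two well-separated planted clusters: one transcribed, one intergenic
        active = rng.normal([0.8, 1.0, 0.0], 0.05, size=(300, 3))
        inactive = rng.normal([0.1, 0.0, 0.0], 0.05, size=(300, 3))
        obs = ObservationSet(np.vstack([active, inactive]), tracks)
        cfg = FitConfig(n_transcribed=1, n_intergenic=1, activity_threshold=0.5)
        model = kmeans_initialize(obs, cfg)
        means = model.means_matrix()
        tr = model.transcribed
        t_mean = means[tr][0]
        i_mean = means[~tr][0]
        np.testing.assert_allclose(t_mean, [0.8, 1.0], atol=0.03)
        np.testing.assert_allclose(i_mean, [0.1, 0.0], atol=0.03)

    def test_uniform_transitions_give_uniform_stationary(self, tracks, rng):
        obs = ObservationSet(rng.random((100, 3)), tracks)
        cfg = FitConfig(n_transcribed=2, n_intergenic=1, activity_threshold=0.5)
        model = kmeans_initialize(obs, cfg)
        np.testing.assert_allclose(model.A, 1 / 3)
        np.testing.assert_allclose(model.pi, [1 / 3, 1 / 3, 1 / 3], atol=1e-12)

    def test_degenerate_split_raises(self, tracks, rng):
        obs = ObservationSet(rng.random((50, 3)) * 0.1, tracks)
        cfg = FitConfig(n_transcribed=1, n_intergenic=1, activity_threshold=5.0)
        with pytest.raises(DataError, match="activity_threshold"):
            kmeans_initialize(obs, cfg)

    def test_requires_expression_pair(self, nuc_tracks, rng):
        obs = ObservationSet(rng.random((50, 2)), nuc_tracks[:2])
        with pytest.raises(DataError, match="expression"):
            kmeans_initialize(obs, FitConfig(n_transcribed=1, n_intergenic=1))


class TestEmStep:
    def test_single_state_reduces_to_plain_averages(self, tracks, rng):
        values = rng.random((40, 3))
        obs = ObservationSet(values, tracks)
        em = StrandStateEmission(np.array([0.5, 0.5]), np.eye(2) * 0.1, True)
        model = CoreModel(("only",), np.array([[1.0]]), (em,))
        new, _ = em_step(model, obs)
        np.testing.assert_array_equal(new.A, [[1.0]])
        # occupancy mean -> plain column average; expression mean -> pooled
        # average of the e+ and e- columns
        assert new.emissions[0].mean[0] == pytest.approx(values[:, 0].mean())
        assert new.emissions[0].mean[1] == pytest.approx(values[:, 1:].mean())

    def test_tied_updates_match_enumeration_oracle(self, tracks):
        # T = 3, two states: expected counts computed from an explicit sum
        # over all 4^3 pair paths, then pushed through the tied-update
        # arithmetic by hand
        model = random_model(2, tracks, seed=21)
        pm = assemble_paired_model(model, tracks)
        obs, _ = sample_from_model(model, tracks, 3, seed=77)
        T, n, S = 3, 2, 4

        logpsi = np.array([
            [multivariate_normal.logpdf(obs.values[t], pm.pair_means[s],
                                        pm.pair_covs[s])
             for s in range(S)] for t in range(T)
        ])
        path_p = {}
        for path in itertools.product(range(S), repeat=T):
            lp = np.log(pm.tau[path[0]]) + logpsi[0, path[0]]
            for t in range(1, T):
                lp += np.log(pm.Bmat[path[t - 1], path[t]]) + logpsi[t, path[t]]
            path_p[path] = np.exp(lp)
        total = sum(path_p.values())

        xi = np.zeros((S, S))
        gamma = np.zeros((T, S))
        for path, p in path_p.items():
            for t in range(T - 1):
                xi[path[t], path[t + 1]] += p / total
            for t in range(T):
                gamma[t, path[t]] += p / total

        counts = np.zeros((n, n))
        for r in range(S):
            for s in range(S):
                rf, rr = divmod(r, n)
                sf, sr = divmod(s, n)
                counts[rf, sf] += xi[r, s]  # forward chain
                counts[sr, rr] += xi[r, s]  # reverse chain (reads right-to-left)
        A_hand = counts / counts.sum(axis=1, keepdims=True)

        acc = np.zeros((n, 2))
        wgt = np.zeros((n, 2))
        base_index = [0, 1, 1]
        for s in range(S):
            sf, sr = divmod(s, n)
            for p in range(3):
                det = sf if pm.dominance[s, p] else sr
                acc[det, base_index[p]] += gamma[:, s] @ obs.values[:, p]
                wgt[det, base_index[p]] += gamma[:, s].sum()
        mu_hand = np.where(wgt > 0, acc / np.maximum(wgt, 1e-300),
                           model.means_matrix())

        new, ll = em_step(model, obs)
        assert ll == pytest.approx(np.log(total), abs=1e-10)
        np.testing.assert_allclose(new.A, A_hand, atol=1e-10)
        np.testing.assert_allclose(new.means_matrix(), mu_hand, atol=1e-10)

    def test_stationary_point_stays_put(self, demo_model):
        model, tracks = demo_model
        obs, _ = sample_from_model(model, tracks, 400, seed=5)
        cur = model
        for _ in range(200):
            new, _ = em_step(cur, obs)
            delta = max(
                np.abs(new.A - cur.A).max(),
                max(np.abs(a.mean - b.mean).max()
                    for a, b in zip(new.emissions, cur.emissions)),
            )
            cur = new
            if delta < 1e-9:
                break
        final, _ = em_step(cur, obs)
        assert np.abs(final.A - cur.A).max() < 1e-6
        assert max(np.abs(a.mean - b.mean).max()
                   for a, b in zip(final.emissions, cur.emissions)) < 1e-6

    def test_label_permutation_equivariance(self, tracks):
        model = random_model(3, tracks, seed=4)
        obs, _ = sample_from_model(model, tracks, 50, seed=8)
        perm = np.array([2, 0, 1])
        permuted = CoreModel(
            tuple(model.states[p] for p in perm),
            model.A[np.ix_(perm, perm)],
            tuple(model.emissions[p] for p in perm),
        )
        new, ll = em_step(model, obs)
        new_p, ll_p = em_step(permuted, obs)
        assert ll == pytest.approx(ll_p, abs=1e-8)
        np.testing.assert_allclose(new.A[np.ix_(perm, perm)], new_p.A, atol=1e-8)
        for i, p in enumerate(perm):
            np.testing.assert_allclose(
                new.emissions[p].mean, new_p.emissions[i].mean, atol=1e-8
            )


class TestFit:
    def test_infinite_tolerance_runs_exactly_one_iteration(self, demo_model):
        model, tracks = demo_model
        obs, _ = sample_from_model(model, tracks, 200, seed=1)
        cfg = FitConfig(n_transcribed=2, n_intergenic=1,
                        activity_threshold=0.45, tol=np.inf, max_iter=50)
        fitted, trace = fit(obs, cfg)
        manual, _ = em_step(kmeans_initialize(obs, cfg), obs)
        assert len(trace.log_likelihood) == 2
        assert trace.converged
        np.testing.assert_array_equal(fitted.A, manual.A)

    def test_loglik_nondecreasing_with_damping_logged(self, demo_model):
        model, tracks = demo_model
        obs, _ = sample_from_model(model, tracks, 1500, seed=2)
        cfg = FitConfig(n_transcribed=2, n_intergenic=1,
                        activity_threshold=0.45, tol=1e-8, max_iter=60)
        _, trace = fit(obs, cfg)
        lls = np.array(trace.log_likelihood)
        assert np.all(np.diff(lls) >= -1e-9 * np.maximum(1.0, np.abs(lls[:-1])))

    def test_same_seed_bitwise_identical(self, demo_model):
        model, tracks = demo_model
        obs, _ = sample_from_model(model, tracks, 500, seed=3)
        cfg = FitConfig(n_transcribed=2, n_intergenic=1,
                        activity_threshold=0.45, seed=11, max_iter=15)
        m1, t1 = fit(obs, cfg)
        m2, t2 = fit(obs, cfg)
        assert t1.log_likelihood == t2.log_likelihood
        assert np.array_equal(m1.A, m2.A)
        for a, b in zip(m1.emissions, m2.emissions):
            assert np.array_equal(a.mean, b.mean)

    def test_parameter_recovery_from_sampled_data(self, demo_model):
        truth, tracks = demo_model
        obs, _ = sample_from_model(truth, tracks, 3000, seed=7)
        cfg = FitConfig(n_transcribed=2, n_intergenic=1,
                        activity_threshold=0.45, tol=1e-7, max_iter=100)
        fitted, _ = fit(obs, cfg)
        perm = match_states(fitted, truth)
        assert np.abs(
            fitted.means_matrix()[perm] - truth.means_matrix()
        ).max() < 0.05
        assert np.abs(fitted.A[np.ix_(perm, perm)] - truth.A).max() < 0.05


class TestConfig:
    def test_yaml_round_trip(self, tmp_path):
        cfg = FitConfig(n_transcribed=3, n_intergenic=2, tol=1e-5, seed=9)
        path = tmp_path / "cfg.yaml"
        cfg.to_yaml(path)
        assert FitConfig.from_yaml(path) == cfg

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_transcribed: 2\nn_intergenic: 1\nbogus: 3\n")
        with pytest.raises(DataError, match="bogus"):
            FitConfig.from_yaml(path)

    def test_invalid_values_rejected(self):
        with pytest.raises(DataError):
            FitConfig(n_transcribed=0, n_intergenic=1)
        with pytest.raises(DataError):
            FitConfig(tol=0.0)


def test_relabel_transcribed_uses_expression_threshold(demo_model):
    model, tracks = demo_model
    obs, _ = sample_from_model(model, tracks, 10, seed=0)
    relabeled = relabel_transcribed(model, obs, threshold=0.2)
    assert relabeled.transcribed.tolist() == [False, True, True]
    strict = relabel_transcribed(model, obs, threshold=0.8)
    assert strict.transcribed.tolist() == [False, True, False]
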