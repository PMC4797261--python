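"""Structural tests of the core model and the paired-state construction."""

import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from dshmm import (
    CoreModel,
    DataError,
    ModelValidationError,
    StrandStateEmission,
    TrackMeta,
    assemble_paired_model,
    build_pair_emission,
    build_pair_transition,
    compute_dominance_sets,
    derive_stationary,
    n_free_parameters,
    random_model,
    standard_hmm_n_parameters,
    track_layout,
)
from dshmm.model import model_from_dict, model_to_dict


class TestStationary:
    def test_symmetric_matrix_gives_uniform(self):
        pi = derive_stationary([[0.9, 0.1], [0.1, 0.9]])
        np.testing.assert_allclose(pi, [0.5, 0.5], atol=1e-12)

    def test_linear_solve_value(self):
        # pi A = pi solved by hand: pi = (1/3, 2/3)
        pi = derive_stationary([[0.5, 0.5], [0.25, 0.75]])
        np.testing.assert_allclose(pi, [1 / 3, 2 / 3], atol=1e-12)

    def test_identity_is_not_ergodic(self):
        with pytest.raises(ModelValidationError, match="ergodic"):
            derive_stationary(np.eye(2))

    def test_periodic_chain_rejected(self):
        with pytest.raises(ModelValidationError, match="periodic"):
            derive_stationary([[0.0, 1.0], [1.0, 0.0]])

    def test_non_stochastic_names_row(self):
        with pytest.raises(ModelValidationError, match=r"rows \[1\]"):
            derive_stationary([[0.5, 0.5], [0.5, 0.6]])

    @given(st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_random_ergodic_is_stationary(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 6))
        A = rng.dirichlet(np.ones(n), size=n)
        pi = derive_stationary(A)
        np.testing.assert_allclose(pi @ A, pi, atol=1e-10)
        assert abs(pi.sum() - 1) < 1e-12 and pi.min() > 0


class TestTrackMeta:
    def test_partner_required_for_strand_specific(self):
        with pytest.raises(DataError, match="partner"):
            TrackMeta("e", "forward_specific")

    def test_transcribed_dominates_only_on_undirected(self):
        with pytest.raises(DataError, match="undirected"):
            TrackMeta("e", "forward_specific", partner="x",
                      dominance_rule="transcribed_dominates")

    def test_partner_bijection_enforced(self):
        bad = (
            TrackMeta("a", "forward_specific", partner="b"),
            TrackMeta("b", "reverse_specific", partner="a"),
            TrackMeta("c", "forward_specific", partner="b"),
        )
        with pytest.raises(DataError):
            track_layout(bad)

    def test_shared_base_coordinate(self, tracks):
        lay = track_layout(tracks)
        assert lay.n_base == 2  # occupancy + one shared expression coordinate
        assert lay.base_index[1] == lay.base_index[2]


class TestDominance:
    def test_tie_resolved_toward_forward(self, tracks):
        # equal undirected means -> track assigned to the forward member
        mask = compute_dominance_sets([0.4, 0.0], [0.4, 0.0], tracks, True, True)
        assert mask[0]

    def test_mean_dominance_partition(self, tracks):
        mask = compute_dominance_sets([0.8, 0.9], [0.1, 0.0], tracks, True, False)
        # occupancy and e+ forward-dominated, e- reverse-dominated
        assert mask.tolist() == [True, True, False]

    def test_transcribed_overrides_higher_intergenic_nucleosome(self, nuc_tracks):
        # transcribed s+ has LOWER nucleosome mean yet determines the track,
        # so nucleosome depletion in transcribed regions is not masked
        mean_fwd = [0.5, 0.2, 1.0]  # tfiib, nucleosome, expression
        mean_rev = [0.1, 0.7, 0.0]
        mask = compute_dominance_sets(mean_fwd, mean_rev, nuc_tracks, True, False)
        assert mask[1]  # nucleosome forward despite 0.2 < 0.7
        mask = compute_dominance_sets(mean_rev, mean_fwd, nuc_tracks, False, True)
        assert not mask[1]

    def test_override_falls_back_to_mean_when_labels_agree(self, nuc_tracks):
        mean_fwd = [0.5, 0.2, 1.0]
        mean_rev = [0.1, 0.7, 0.8]
        mask = compute_dominance_sets(mean_fwd, mean_rev, nuc_tracks, True, True)
        assert not mask[1]  # plain mean dominance: 0.2 < 0.7

    def test_strand_specific_tracks_forced(self, tracks):
        for seed in range(5):
            m = random_model(3, tracks, seed)
            for i in range(3):
                for j in range(3):
                    mask = compute_dominance_sets(
                        m.emissions[i].mean, m.emissions[j].mean, tracks,
                        m.emissions[i].transcribed, m.emissions[j].transcribed,
                    )
                    assert mask[1] and not mask[2]


class TestPairEmission:
    def test_identical_pair_duplicates_expression(self, tracks):
        lay = track_layout(tracks)
        m = random_model(2, tracks, seed=7)
        e = m.emissions[0]
        mask = compute_dominance_sets(e.mean, e.mean, lay, e.transcribed, e.transcribed)
        nu, _ = build_pair_emission(e, e, mask, lay, jitter=0.0)
        assert nu[0] == e.mean[0]
        assert nu[1] == nu[2] == e.mean[1]

    def test_pair_mean_by_hand(self, tracks):
        lay = track_layout(tracks)
        cov = np.eye(2) * 0.01
        ef = StrandStateEmission([0.8, 0.9], cov, True)
        er = StrandStateEmission([0.1, 0.0], cov, False)
        mask = compute_dominance_sets(ef.mean, er.mean, lay, True, False)
        nu, _ = build_pair_emission(ef, er, mask, lay, jitter=0.0)
        np.testing.assert_array_equal(nu, [0.8, 0.9, 0.0])

    def test_cross_block_covariance_exactly_zero(self, tracks):
        lay = track_layout(tracks)
        m = random_model(2, tracks, seed=3)
        ef, er = m.emissions
        mask = compute_dominance_sets(ef.mean, er.mean, lay, ef.transcribed,
                                      er.transcribed)
        _, gamma = build_pair_emission(ef, er, mask, lay)
        fwd = np.where(mask)[0]
        rev = np.where(~mask)[0]
        assert np.all(gamma[np.ix_(fwd, rev)] == 0.0)
        assert np.all(gamma[np.ix_(rev, fwd)] == 0.0)

    def test_jitter_makes_positive_definite(self, tracks):
        lay = track_layout(tracks)
        degenerate = StrandStateEmission(np.zeros(2), np.zeros((2, 2)), False)
        with pytest.raises(ModelValidationError, match="positive definite"):
            build_pair_emission(degenerate, degenerate,
                                np.array([True, True, False]), lay, jitter=0.0)
        _, gamma = build_pair_emission(degenerate, degenerate,
                                       np.array([True, True, False]), lay,
                                       jitter=1e-8)
        np.linalg.cholesky(gamma)


class TestPairTransition:
    def test_single_state(self):
        bmat, tau = build_pair_transition(np.array([[1.0]]), np.array([1.0]))
        np.testing.assert_array_equal(bmat, [[1.0]])
        np.testing.assert_array_equal(tau, [1.0])

    def test_hand_computed_entries(self):
        A = np.array([[0.9, 0.1], [0.1, 0.9]])
        bmat, tau = build_pair_transition(A, np.array([0.5, 0.5]))
        # pair indices: (0,0)=0, (0,1)=1, (1,0)=2, (1,1)=3
        assert bmat[0, 1] == pytest.approx(0.09, abs=1e-15)
        assert bmat[1, 2] == pytest.approx(0.01, abs=1e-15)
        np.testing.assert_allclose(tau, [0.25, 0.25, 0.25, 0.25])

    def test_zero_pi_entry_rejected(self):
        with pytest.raises(ModelValidationError, match="zero entry"):
            build_pair_transition(np.array([[1.0]]), np.array([0.0]))

    @pytest.mark.parametrize("n_states", [2, 3, 4, 5])
    def test_rows_stochastic_and_tau_stationary(self, n_states, tracks):
        for seed in range(5):
            m = random_model(n_states, tracks, seed)
            bmat, tau = build_pair_transition(m.A, m.pi)
            np.testing.assert_allclose(bmat.sum(axis=1), 1.0, atol=1e-10)
            np.testing.assert_allclose(tau @ bmat, tau, atol=1e-10)
            assert abs(tau.sum() - 1) < 1e-12


class TestAssembledModel:
    def test_twenty_states_give_400_pairs(self, tracks):
        m = random_model(20, tracks, seed=0)
        pm = assemble_paired_model(m, tracks)
        assert pm.n_pairs == 400

    def test_parameter_count_matches_standard_hmm(self, tracks):
        m = random_model(2, tracks, seed=1)
        lay = track_layout(tracks)
        assert n_free_parameters(m) == standard_hmm_n_parameters(2, lay.n_base)
        # explicit count for 2 states on |B u E| = 2: 2 free A entries,
        # 2 means of length 2, 2 symmetric 2x2 covariances
        assert n_free_parameters(m) == 2 + 4 + 6

    def test_dominance_is_partition_with_strands_forced(self, nuc_tracks):
        for seed in range(5):
            m = random_model(3, nuc_tracks, seed)
            pm = assemble_paired_model(m, nuc_tracks)
            lay = pm.layout
            for s in range(pm.n_pairs):
                mask = pm.dominance[s]
                # a boolean mask is a partition by construction; check strands
                for p in lay.forward_cols:
                    assert mask[p]
                for p in lay.reverse_cols:
                    assert not mask[p]

    def test_pair_symmetry_mirrors_emissions(self, tracks):
        # swapping (s+, s-) swaps the roles of e+ and e-; the covariance
        # mirror is exact for distinct pairs, and for self-pairs whenever the
        # undirected/expression cross-covariance vanishes (a tied track in a
        # self-pair carries that cross term on the forward copy only)
        m = random_model(3, tracks, seed=9)
        pm = assemble_paired_model(m, tracks)
        m0 = random_model(3, tracks, seed=9, correlated=False)
        pm0 = assemble_paired_model(m0, tracks)
        swap = np.array([0, 2, 1])  # occupancy, e+ <-> e-
        for i in range(3):
            for j in range(3):
                a, b = pm.pair_index(i, j), pm.pair_index(j, i)
                np.testing.assert_allclose(
                    pm.pair_means[a], pm.pair_means[b][swap], atol=1e-14
                )
                np.testing.assert_allclose(
                    pm0.pair_covs[a], pm0.pair_covs[b][np.ix_(swap, swap)],
                    atol=1e-14,
                )
                if i != j:
                    np.testing.assert_allclose(
                        pm.pair_covs[a], pm.pair_covs[b][np.ix_(swap, swap)],
                        atol=1e-14,
                    )

    def test_serialization_round_trip_bitwise(self, nuc_tracks):
        m = random_model(3, nuc_tracks, seed=5)
        doc = json.loads(json.dumps(model_to_dict(m, nuc_tracks)))
        m2, tracks2 = model_from_dict(doc)
        assert tracks2 == nuc_tracks
        pm, pm2 = (assemble_paired_model(x, nuc_tracks) for x in (m, m2))
        assert np.array_equal(pm.Bmat, pm2.Bmat)
        assert np.array_equal(pm.pair_means, pm2.pair_means)
        assert np.array_equal(pm.pair_covs, pm2.pair_covs)

    def test_emission_dimension_mismatch_rejected(self, nuc_tracks):
        m = random_model(2, nuc_tracks, seed=0)
        with pytest.raises(ModelValidationError, match="dimension"):
            assemble_paired_model(m, nuc_tracks[:2])


def test_core_model_rejects_wrong_pi(tracks):
    m = random_model(2, tracks, seed=0)
    with pytest.raises(ModelValidationError, match="stationary"):
        CoreModel(m.states, m.A, m.emissions, pi=np.array([0.9, 0.1]))
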