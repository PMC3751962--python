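import itertools
import json
import math
import warnings

import numpy as np
import pandas as pd
import pytest

from trackmodes import dists, markov_models as mm
from trackmodes.dists import make_distribution
from trackmodes.markov_models import (HMMModel, HSMMModel, Segment,
                                      SegmentSequence, StateSequence,
                                      decode_hmm_viterbi, decode_hsmm_viterbi,
                                      emission_loglik_matrix,
                                      hmm_from_hsmm_geometric,
                                      hmm_joint_loglik, hsmm_joint_loglik,
                                      segment_transition_frequencies,
                                      segments_from_states,
                                      states_from_segments,
                                      step_transition_frequencies)

from conftest import (brute_force_hmm_path, brute_force_hsmm_path,
                      make_gaussian_hmm, make_gaussian_hsmm, random_features)


# ---------------------------------------------------------------------------
# segments <-> states
# ---------------------------------------------------------------------------

class TestSegments:
    def test_run_length_example(self):
        seq = StateSequence(states=list("CCFFFC"), dt=np.ones(6))
        segs = segments_from_states(seq)
        assert [(s.mode, s.n_steps, s.duration) for s in segs] == \
            [("C", 2, 2.0), ("F", 3, 3.0), ("C", 1, 1.0)]

    def test_single_state_single_segment(self):
        seq = StateSequence(states=["F"] * 5, dt=np.full(5, 0.5))
        segs = segments_from_states(seq)
        assert len(segs) == 1 and segs[0].duration == pytest.approx(2.5)

    def test_round_trip_on_random_sequences(self):
        rng = np.random.default_rng(0)
        for _ in range(1000):
            T = int(rng.integers(1, 12))
            states = [str(s) for s in rng.integers(0, 3, size=T)]
            seq = StateSequence(states=states, dt=np.ones(T))
            assert states_from_segments(segments_from_states(seq)).states == states


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

class TestTraining:
    def test_step_transition_counting_example(self):
        A = step_transition_frequencies([list("CCFF")], ["C", "F"])
        assert A[0, 0] == pytest.approx(0.5)
        assert A[0, 1] == pytest.approx(0.5)
        assert A[1, 1] == pytest.approx(1.0)

    def test_segment_transition_counting_example(self):
        A = segment_transition_frequencies([["C", "F", "C", "F"]], ["C", "F"])
        assert A[0, 1] == pytest.approx(1.0) and A[1, 0] == pytest.approx(1.0)
        assert A[0, 0] == 0.0 and A[1, 1] == 0.0

    def test_mode_without_transitions_gets_uniform_row(self):
        with pytest.warns(UserWarning, match="no outgoing"):
            A = step_transition_frequencies([list("CCF")], ["C", "F"])
        assert np.allclose(A[1], 0.5)

    def test_transition_estimator_consistency(self):
        """Relative frequencies recover a known chain at 1e5 steps."""
        rng = np.random.default_rng(1)
        A = np.array([[0.9, 0.1], [0.3, 0.7]])
        states = [0]
        for _ in range(100_000):
            states.append(rng.choice(2, p=A[states[-1]]))
        labels = ["C" if s == 0 else "F" for s in states]
        A_hat = step_transition_frequencies([labels], ["C", "F"])
        counts = np.array([labels[:-1].count("C"), labels[:-1].count("F")])
        for i in range(2):
            se = math.sqrt(A[i, 0] * (1 - A[i, 0]) / counts[i])
            assert abs(A_hat[i, 0] - A[i, 0]) <= 3 * se

    def test_hmm_initial_probabilities_point_to_cruising(self, trained_hourly_models):
        hmm, hsmm = trained_hourly_models
        i = hmm.modes.index("cruising")
        assert hmm.pi[i] == 1.0 and hmm.pi.sum() == 1.0
        assert hsmm.pi[i] == 1.0

    def test_hsmm_selects_lognormal_fishing_durations(self, trained_hourly_models):
        _, hsmm = trained_hourly_models
        assert hsmm.durations["fishing"].family == "lognormal"

    def test_duration_parameters_recovered_from_segments(self):
        gen = make_distribution("lognormal", s=0.5, loc=0.0, scale=1.8)
        rng = np.random.default_rng(2)
        durs = gen.rvs(1000, rng)
        # five-segment trips, final segment censored and excluded
        seqs = []
        for i in range(0, 1000, 5):
            segs = [Segment("fishing", 0, 1, d) for d in durs[i:i + 5]]
            seqs.append(SegmentSequence(segs))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fits = mm.fit_durations(seqs, ["fishing"],
                                    duration_candidates=("lognormal",),
                                    rng=rng)
        kept = np.concatenate([durs[i:i + 4] for i in range(0, 1000, 5)])
        se = kept.std() / math.sqrt(kept.size)
        assert fits["fishing"].family == "lognormal"
        assert abs(fits["fishing"].mean() - kept.mean()) < 3 * se

    def test_sparse_mode_falls_back_to_moment_fit(self):
        seqs = [SegmentSequence([Segment("A", 0, 2, 2.0),
                                 Segment("B", 2, 1, 1.0),
                                 Segment("A", 3, 2, 2.0)])]
        with pytest.warns(UserWarning, match="falling back"):
            fits = mm.fit_durations(seqs, ["A", "B"])
        assert fits["B"].family == "lognormal"


# ---------------------------------------------------------------------------
# joint log-likelihoods
# ---------------------------------------------------------------------------

class TestJointLoglik:
    def deterministic_model(self):
        emissions = {"A": {"v": make_distribution("point_mass", value=1.0)},
                     "B": {"v": make_distribution("point_mass", value=2.0)}}
        return HMMModel(modes=["A", "B"], pi=np.array([1.0, 0.0]),
                        A=np.array([[0.0, 1.0], [1.0, 0.0]]),
                        emissions=emissions, variables=["v"])

    def test_deterministic_chain_with_point_mass_emissions_scores_zero(self):
        model = self.deterministic_model()
        feats = pd.DataFrame({"v": [1.0, 2.0, 1.0, 2.0], "dt": np.ones(4)})
        assert hmm_joint_loglik(model, feats, list("ABAB")) == pytest.approx(0.0)

    def test_matches_linear_space_product_at_T5(self):
        rng = np.random.default_rng(3)
        model = make_gaussian_hmm(rng)
        feats = random_features(rng, 5)
        states = [model.modes[i] for i in rng.integers(0, 2, size=5)]
        E = np.exp(emission_loglik_matrix(model, feats))
        idx = [model.modes.index(s) for s in states]
        prob = model.pi[idx[0]] * E[0, idx[0]]
        for t in range(1, 5):
            prob *= model.A[idx[t - 1], idx[t]] * E[t, idx[t]]
        assert hmm_joint_loglik(model, feats, states) == \
            pytest.approx(math.log(prob), rel=1e-9)

    def test_transposing_states_changes_the_value(self):
        rng = np.random.default_rng(4)
        model = make_gaussian_hmm(rng)
        feats = random_features(rng, 6)
        states = ["m0", "m0", "m1", "m0", "m1", "m1"]
        swapped = states.copy()
        swapped[1], swapped[2] = swapped[2], swapped[1]
        assert hmm_joint_loglik(model, feats, states) != \
            hmm_joint_loglik(model, feats, swapped)

    def test_hsmm_single_segment_uses_survival_only(self):
        rng = np.random.default_rng(5)
        model = make_gaussian_hsmm(rng, d_max_steps=10)
        feats = random_features(rng, 4)
        segs = SegmentSequence([Segment("m0", 0, 4, 4.0)])
        E = emission_loglik_matrix(model, feats)
        expected = (math.log(model.pi[0]) + E[:, 0].sum()
                    + float(model.durations["m0"].log_sf(4.0)))
        assert hsmm_joint_loglik(model, feats, segs) == pytest.approx(expected)

    def test_hsmm_two_segment_hand_computation(self):
        durations = {"A": make_distribution("point_mass", value=2.0),
                     "B": make_distribution("lognormal", s=0.5, loc=0.0, scale=2.0)}
        emissions = {"A": {"v": make_distribution("point_mass", value=1.0)},
                     "B": {"v": make_distribution("point_mass", value=5.0)}}
        model = HSMMModel(modes=["A", "B"], pi=np.array([1.0, 0.0]),
                          A_distinct=np.array([[0.0, 1.0], [1.0, 0.0]]),
                          durations=durations, emissions=emissions,
                          variables=["v"], d_max_steps=10)
        feats = pd.DataFrame({"v": [1.0, 1.0, 5.0], "dt": np.ones(3)})
        segs = SegmentSequence([Segment("A", 0, 2, 2.0), Segment("B", 2, 1, 1.0)])
        # log pi + log d_A(2) + log a_AB + log S_B(1); emissions all log 1
        expected = 0.0 + 0.0 + 0.0 + float(durations["B"].log_sf(1.0))
        assert hsmm_joint_loglik(model, feats, segs) == pytest.approx(expected)

    def test_longer_censored_segment_weakly_decreases_survival_term(self):
        d = make_distribution("lognormal", s=0.5, loc=0.0, scale=2.0)
        assert d.log_sf(3.0) <= d.log_sf(2.0) <= d.log_sf(1.0)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

class TestHMMDecoding:
    def test_disjoint_supports_recover_generating_states(self):
        emissions = {"A": {"v": make_distribution("uniform", loc=0.0, scale=1.0)},
                     "B": {"v": make_distribution("uniform", loc=5.0, scale=1.0)}}
        model = HMMModel(modes=["A", "B"], pi=np.array([0.5, 0.5]),
                         A=np.full((2, 2), 0.5), emissions=emissions,
                         variables=["v"])
        feats = pd.DataFrame({"v": [0.2, 0.8, 5.5, 5.1, 0.3], "dt": np.ones(5)})
        assert decode_hmm_viterbi(model, feats).states == list("AABBA")

    def test_single_state_model_decodes_constant(self):
        emissions = {"A": {"v": make_distribution("gumbel", loc=0.0, scale=1.0)}}
        model = HMMModel(modes=["A"], pi=np.array([1.0]), A=np.array([[1.0]]),
                         emissions=emissions, variables=["A" and "v"])
        feats = random_features(np.random.default_rng(0), 7)
        assert decode_hmm_viterbi(model, feats).states == ["A"] * 7

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            M = int(rng.integers(2, 4))
            T = int(rng.integers(2, 7))
            model = make_gaussian_hmm(rng, n_modes=M)
            feats = random_features(rng, T)
            expected, best = brute_force_hmm_path(model, feats)
            got = decode_hmm_viterbi(model, feats)
            assert got.states == expected
            assert hmm_joint_loglik(model, feats, got.states) == \
                pytest.approx(best, rel=1e-9)


class TestHSMMDecoding:
    def test_point_mass_durations_force_three_blocks(self):
        durations = {m: make_distribution("point_mass", value=3.0)
                     for m in ("A", "B")}
        emissions = {m: {"v": make_distribution("gumbel", loc=0.0, scale=1.0)}
                     for m in ("A", "B")}
        model = HSMMModel(modes=["A", "B"], pi=np.array([1.0, 0.0]),
                          A_distinct=np.array([[0.0, 1.0], [1.0, 0.0]]),
                          durations=durations, emissions=emissions,
                          variables=["v"], d_max_steps=9)
        feats = random_features(np.random.default_rng(1), 9)
        segs = segments_from_states(decode_hsmm_viterbi(model, feats))
        assert [(s.mode, s.n_steps) for s in segs] == \
            [("A", 3), ("B", 3), ("A", 3)]

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            M = int(rng.integers(2, 4))
            T = int(rng.integers(2, 7))
            model = make_gaussian_hsmm(rng, n_modes=M, d_max_steps=T)
            feats = random_features(rng, T)
            expected, best = brute_force_hsmm_path(model, feats)
            got = decode_hsmm_viterbi(model, feats)
            assert got.states == expected

    def test_decoded_path_dominates_truth_and_random_paths(
            self, trained_hourly_models, fishery_trips):
        _, hsmm = trained_hourly_models
        rng = np.random.default_rng(8)
        for trip in fishery_trips[20:24]:
            feats = trip.features
            decoded = decode_hsmm_viterbi(hsmm, feats)
            ll_dec = hsmm_joint_loglik(hsmm, feats,
                                       segments_from_states(decoded))
            ll_true = hsmm_joint_loglik(
                hsmm, feats, segments_from_states(trip.true_states))
            assert ll_dec >= ll_true - 1e-9
            for _ in range(25):
                states = [hsmm.modes[i] for i in
                          rng.integers(0, 3, size=len(feats))]
                seq = StateSequence(states=states,
                                    dt=feats["dt"].to_numpy(dtype=float))
                ll_rand = hsmm_joint_loglik(hsmm, feats,
                                            segments_from_states(seq))
                assert ll_dec >= ll_rand - 1e-9

    def test_d_max_validation(self):
        rng = np.random.default_rng(9)
        model = make_gaussian_hsmm(rng)
        with pytest.raises(ValueError, match="d_max_steps"):
            HSMMModel(modes=model.modes, pi=model.pi,
                      A_distinct=model.A_distinct, durations=model.durations,
                      emissions=model.emissions, variables=model.variables,
                      d_max_steps=0)


class TestGeometricEquivalence:
    def test_geometric_duration_hsmm_equals_self_transition_hmm(self):
        """Discrete-geometric durations with parameter p decode identically
        to the HMM with self-transition 1 - p (classical equivalence)."""
        rng = np.random.default_rng(10)
        for _ in range(5):
            hsmm = make_gaussian_hsmm(rng, n_modes=2, d_max_steps=30)
            hsmm.durations = {
                m: make_distribution("geometric_steps",
                                     p=float(rng.uniform(0.2, 0.7)),
                                     step_hours=1.0)
                for m in hsmm.modes
            }
            hmm = hmm_from_hsmm_geometric(hsmm, step_hours=1.0)
            feats = random_features(rng, 30)
            assert decode_hsmm_viterbi(hsmm, feats).states == \
                decode_hmm_viterbi(hmm, feats).states


class TestSerialisation:
    def test_hmm_json_round_trip(self, trained_hourly_models):
        hmm, _ = trained_hourly_models
        back = HMMModel.from_dict(json.loads(json.dumps(hmm.to_dict())))
        assert back.modes == hmm.modes
        assert np.allclose(back.A, hmm.A)
        feats = pd.DataFrame({v: [1.0] for v in hmm.variables} | {"dt": [1.0]})
        assert np.allclose(emission_loglik_matrix(back, feats),
                           emission_loglik_matrix(hmm, feats))

    def test_hsmm_json_round_trip(self, trained_hourly_models):
        _, hsmm = trained_hourly_models
        back = HSMMModel.from_dict(json.loads(json.dumps(hsmm.to_dict())))
        assert np.allclose(back.A_distinct, hsmm.A_distinct)
        assert back.durations["fishing"].params == hsmm.durations["fishing"].params
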