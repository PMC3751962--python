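import json
import math

import numpy as np
import pandas as pd
import pytest

from trackmodes import synthetic_data as sd
from trackmodes.dists import make_distribution
from trackmodes.features import compute_step_features
from trackmodes.markov_models import (StateSequence, segments_from_states,
                                      states_from_segments)
from trackmodes.synthetic_data import (IrregularitySpec, ScenarioConfig,
                                       SimulatedTrip, apply_dt_irregularity,
                                       make_fishery_scenario,
                                       make_highres_scenario,
                                       simulate_observations,
                                       simulate_state_sequence, simulate_trip,
                                       simulate_trips, subsample_sequence)


def two_mode_cycle_cfg(duration_hours=3.0, trip_length=9.0, step=1.0):
    """Degenerate scenario: point-mass durations, deterministic A-B cycle."""
    return ScenarioConfig(
        modes=["A", "B"],
        initial_probs=np.array([1.0, 0.0]),
        transition_probs=np.array([[0.0, 1.0], [1.0, 0.0]]),
        duration_dists={m: make_distribution("point_mass", value=duration_hours)
                        for m in ("A", "B")},
        emission_dists={"A": {"v": make_distribution("point_mass", value=10.0)},
                        "B": {"v": make_distribution("point_mass", value=2.0)}},
        base_step_hours=step, trip_length_hours=trip_length,
    )


class TestScenario:
    def test_fishery_scenario_matches_study_facts(self, fishery_cfg):
        assert fishery_cfg.duration_dists["fishing"].family == "lognormal"
        assert fishery_cfg.duration_dists["searching"].family == "gev"
        assert fishery_cfg.duration_dists["cruising"].family == "gev"
        assert np.all(np.diag(fishery_cfg.transition_probs) == 0.0)
        assert 1.5 <= fishery_cfg.duration_dists["fishing"].mean() <= 2.5
        # trips start in cruising
        i = fishery_cfg.modes.index("cruising")
        assert fishery_cfg.initial_probs[i] == 1.0
        # cruising fast, fishing slow
        assert (fishery_cfg.emission_dists["cruising"]["v"].mean()
                > fishery_cfg.emission_dists["fishing"]["v"].mean())

    def test_invalid_transition_diagonal_rejected(self):
        with pytest.raises(ValueError, match="zero diagonal"):
            ScenarioConfig(
                modes=["A", "B"],
                initial_probs=np.array([1.0, 0.0]),
                transition_probs=np.array([[0.5, 0.5], [1.0, 0.0]]),
                duration_dists={m: make_distribution("point_mass", value=1.0)
                                for m in ("A", "B")},
                emission_dists={m: {} for m in ("A", "B")},
                base_step_hours=1.0, trip_length_hours=5.0)

    def test_json_round_trip(self, tmp_path, fishery_cfg):
        path = tmp_path / "cfg.json"
        fishery_cfg.to_json(path)
        back = ScenarioConfig.from_json(path)
        assert back.modes == fishery_cfg.modes
        assert np.allclose(back.transition_probs, fishery_cfg.transition_probs)
        assert back.duration_dists["fishing"].params == \
            fishery_cfg.duration_dists["fishing"].params
        assert back.dt_irregularity.probability == \
            fishery_cfg.dt_irregularity.probability


class TestStateSequence:
    def test_point_mass_cycle_produces_exact_blocks(self):
        rng = np.random.default_rng(0)
        seq, segs = simulate_state_sequence(two_mode_cycle_cfg(), rng)
        assert seq.states == ["A"] * 3 + ["B"] * 3 + ["A"] * 3
        assert [s.mode for s in segs] == ["A", "B", "A"]

    def test_final_segment_is_right_censored(self):
        rng = np.random.default_rng(0)
        seq, segs = simulate_state_sequence(
            two_mode_cycle_cfg(duration_hours=3.0, trip_length=7.0), rng)
        assert seq.states == ["A"] * 3 + ["B"] * 3 + ["A"]
        assert segs[-1].duration <= 3.0

    def test_segments_match_states_round_trip(self, fishery_cfg):
        rng = np.random.default_rng(5)
        for _ in range(20):
            seq, segs = simulate_state_sequence(fishery_cfg, rng)
            assert states_from_segments(segs).states == seq.states

    def test_empirical_fishing_duration_mean(self, fishery_cfg):
        """Monte-Carlo mean of drawn fishing durations vs the analytic mean.

        Long simulation windows are used so that excluding the censored
        final segment (renewal inspection bias) is negligible.
        """
        import copy
        cfg = copy.deepcopy(fishery_cfg)
        cfg.trip_length_hours = 2000.0
        rng = np.random.default_rng(6)
        durs = []
        while len(durs) < 10_000:
            cont = sd._draw_segments(cfg, rng)
            durs.extend(e - s for m, s, e in cont[:-1] if m == "fishing")
        durs = np.array(durs[:10_000])
        target = cfg.duration_dists["fishing"].mean()
        se = durs.std() / math.sqrt(durs.size)
        assert abs(durs.mean() - target) < 3 * se

    def test_transition_frequencies_recover_the_matrix(self, fishery_cfg):
        rng = np.random.default_rng(7)
        counts = np.zeros((3, 3))
        idx = {m: i for i, m in enumerate(fishery_cfg.modes)}
        n_tr = 0
        while n_tr < 10_000:
            cont = sd._draw_segments(fishery_cfg, rng)
            labels = [m for m, _, _ in cont]
            for a, b in zip(labels[:-1], labels[1:]):
                counts[idx[a], idx[b]] += 1
            n_tr += len(labels) - 1
        A_hat = counts / counts.sum(axis=1, keepdims=True)
        for i in range(3):
            n_row = counts[i].sum()
            for j in range(3):
                p = fishery_cfg.transition_probs[i, j]
                se = math.sqrt(max(p * (1 - p), 1e-12) / n_row)
                assert abs(A_hat[i, j] - p) <= 3 * se + 1e-9


class TestObservations:
    def test_point_mass_emissions_are_exact(self):
        cfg = two_mode_cycle_cfg()
        seq = StateSequence(states=["A"] * 4, dt=np.ones(4))
        obs = simulate_observations(seq, cfg, np.random.default_rng(0))
        assert np.all(obs["v"] == 10.0)

    def test_circular_variables_wrapped(self, fishery_cfg):
        rng = np.random.default_rng(8)
        seq, _ = simulate_state_sequence(fishery_cfg, rng)
        obs = simulate_observations(seq, fishery_cfg, rng)
        for var in ("phi", "dphi_prev", "dphi_next"):
            assert np.all(obs[var] > -math.pi) and np.all(obs[var] <= math.pi)

    def test_fishing_speed_mean_recovers_configured_mean(self, fishery_cfg):
        rng = np.random.default_rng(9)
        seq = StateSequence(states=["fishing"] * 10_000, dt=np.ones(10_000))
        obs = simulate_observations(seq, fishery_cfg, rng)
        v = obs["v"].to_numpy()
        target = fishery_cfg.emission_dists["fishing"]["v"].mean()
        assert abs(v.mean() - target) < 3 * v.std() / math.sqrt(v.size)

    def test_block_draws_are_constant_within_blocks(self, highres_cfg):
        rng = np.random.default_rng(10)
        seq, segs, cont = simulate_state_sequence(highres_cfg, rng,
                                                  return_continuous=True)
        obs = simulate_observations(seq, highres_cfg, rng, cont_segments=cont)
        v = obs["v"].to_numpy()
        # the decorrelation horizon spans 12 one-minute steps: consecutive
        # equal values must be common, and changes must exist
        repeats = np.mean(v[1:] == v[:-1])
        assert repeats > 0.8
        assert np.unique(v).size > len(segs)


class TestTripsAndSubsampling:
    def test_seed_determinism(self, fishery_cfg):
        a = simulate_trips(fishery_cfg, 3, seed=42)
        b = simulate_trips(fishery_cfg, 3, seed=42)
        for ta, tb in zip(a, b):
            pd.testing.assert_frame_equal(ta.features, tb.features)

    def test_true_segments_expand_to_true_states(self, fishery_trips):
        for trip in fishery_trips[:10]:
            assert states_from_segments(trip.true_segments).states == \
                trip.true_states.states

    def test_subsample_identity_and_indexing(self, highres_cfg):
        trip = simulate_trips(highres_cfg, 1, seed=11)[0]
        assert subsample_sequence(trip, 1) is trip
        sub = subsample_sequence(trip, 2)
        assert sub.true_states.states == trip.true_states.states[::2]
        assert np.allclose(sub.features["dt"], 2.0 / 60.0)

    def test_subsample_small_example(self):
        feats = pd.DataFrame({"v": np.arange(6.0), "dt": np.ones(6),
                              "mode": ["A", "A", "A", "A", "B", "B"]})
        seq = StateSequence(states=feats["mode"].tolist(), dt=feats["dt"].to_numpy())
        trip = SimulatedTrip(trip_id="x", features=feats, true_states=seq,
                             true_segments=segments_from_states(seq))
        sub = subsample_sequence(trip, 2)
        assert sub.true_states.states == ["A", "A", "B"]
        assert np.allclose(sub.features["dt"], 2.0)

    def test_subsample_sixty_gives_minutes(self):
        n = 360
        feats = pd.DataFrame({"v": np.ones(n), "dt": np.full(n, 1.0 / 3600.0),
                              "mode": ["A"] * n})
        seq = StateSequence(states=["A"] * n, dt=feats["dt"].to_numpy())
        trip = SimulatedTrip(trip_id="x", features=feats, true_states=seq,
                             true_segments=segments_from_states(seq))
        sub = subsample_sequence(trip, 60)
        assert np.allclose(sub.features["dt"], 1.0 / 60.0)  # one minute

    def test_subsample_factor_too_large_errors(self, highres_cfg):
        trip = simulate_trips(highres_cfg, 1, seed=12)[0]
        with pytest.raises(ValueError, match="larger than"):
            subsample_sequence(trip, len(trip.features) + 1)


class TestIrregularity:
    def make_track(self, n=200):
        from trackmodes.features import Track
        ts = pd.Timestamp("2008-06-01") + pd.to_timedelta(range(n), unit="h")
        return Track(trip_id="t", records=pd.DataFrame(
            {"timestamp": ts, "lon": np.linspace(0, 1, n),
             "lat": np.zeros(n), "mode": [None] * n}))

    def test_zero_probability_is_identity(self):
        tr = self.make_track()
        spec = IrregularitySpec(probability=0.0,
                                dist=make_distribution("point_mass", value=0.5))
        out = apply_dt_irregularity(tr, spec, np.random.default_rng(0))
        assert (out.records["timestamp"] == tr.records["timestamp"]).all()

    def test_certain_point_mass_replaces_all_intervals(self):
        tr = self.make_track(n=20)
        spec = IrregularitySpec(probability=1.0,
                                dist=make_distribution("point_mass", value=0.5))
        out = apply_dt_irregularity(tr, spec, np.random.default_rng(0))
        dt = np.diff(out.records["timestamp"].to_numpy()).astype(
            "timedelta64[ns]").astype(float) / 3.6e12
        assert np.allclose(dt, 0.5)

    def test_irregular_fraction_matches_probability(self):
        tr = self.make_track(n=10_001)
        spec = IrregularitySpec(probability=0.05,
                                dist=make_distribution("point_mass", value=0.5))
        out = apply_dt_irregularity(tr, spec, np.random.default_rng(1))
        dt = np.diff(out.records["timestamp"].to_numpy()).astype(
            "timedelta64[ns]").astype(float) / 3.6e12
        frac = np.mean(~np.isclose(dt, 1.0))
        se = math.sqrt(0.05 * 0.95 / 10_000)
        assert abs(frac - 0.05) < 3 * se


class TestPositionLevel:
    def test_dead_reckoned_track_reproduces_features(self, fishery_cfg):
        """End-to-end: emitted v/phi -> lon/lat -> feature extraction."""
        trip = simulate_trip(fishery_cfg, np.random.default_rng(21),
                             trip_id="t0", with_track=True)
        f = compute_step_features(trip.track)
        v_in = trip.features["v"].to_numpy()
        assert np.allclose(f["v"].to_numpy(), v_in, rtol=0.02)
        dphi = np.abs(f["phi"].to_numpy() - trip.features["phi"].to_numpy())
        assert np.all(np.minimum(dphi, 2 * math.pi - dphi) < 0.05)
        assert np.allclose(f["dt"].to_numpy(), trip.features["dt"].to_numpy(),
                           rtol=1e-6)
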