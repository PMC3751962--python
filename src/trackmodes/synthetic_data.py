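"""Semi-Markov trajectory simulator emulating the groundtruthed fishery
dataset (and its high-resolution variant) so every downstream stage is
testable without the confidential observer data.

The latent process is an explicit-duration semi-Markov chain over three
behavioural modes (cruising, searching, fishing): trips start in cruising,
each visited mode draws a continuous duration in hours from its duration
distribution, transitions happen only between distinct modes, and the
final segment is right-censored at the trip end.  The observed process
draws each step's variables from the current mode's state-conditional
distributions (mutual independence given the mode, mirroring the models'
emission assumption), with circular variables wrapped to (-pi, pi].

Simulation is feature-level by default (the models consume features, not
positions); a secondary position-level path dead-reckons speed and heading
into lon/lat so the feature-extraction stage can be tested end to end.

For sub-hourly steps, real movement variables are smooth in time rather
than independent draws: the generator therefore supports a decorrelation
horizon (``emission_block_hours``), drawing one value per within-segment
block of that length.  At the fishery's native ~1-hour steps the horizon
is shorter than a step and emissions are independent per step.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .dists import CIRCULAR, FittedDistribution, Rescale, make_distribution
from .features import CIRCULAR_VARIABLES, Track
from .markov_models import SegmentSequence, StateSequence, segments_from_states
from .utils import wrap_to_pi

MODES = ("cruising", "searching", "fishing")

_MAX_DURATION_RETRIES = 100


@dataclass(frozen=True)
class IrregularitySpec:
    """Occasional replacement of the nominal step interval."""

    probability: float
    dist: FittedDistribution  # distribution of the irregular interval, hours

    def to_dict(self) -> dict:
        return {"probability": self.probability, "dist": self.dist.to_dict()}

    @staticmethod
    def from_dict(d: dict) -> "IrregularitySpec":
        return IrregularitySpec(probability=float(d["probability"]),
                                dist=FittedDistribution.from_dict(d["dist"]))


@dataclass
class ScenarioConfig:
    """Full specification of a simulated fishery: initial probabilities,
    distinct-state transitions, per-mode duration distributions and
    per-(mode, variable) emission distributions."""

    modes: list[str]
    initial_probs: np.ndarray
    transition_probs: np.ndarray  # square over modes, zero diagonal
    duration_dists: dict[str, FittedDistribution]
    emission_dists: dict[str, dict[str, FittedDistribution]]
    base_step_hours: float
    trip_length_hours: float
    dt_irregularity: IrregularitySpec | None = None
    emission_block_hours: float | None = None
    seed: int = 0

    def __post_init__(self):
        self.initial_probs = np.asarray(self.initial_probs, dtype=float)
        self.transition_probs = np.asarray(self.transition_probs, dtype=float)
        m = len(self.modes)
        if self.initial_probs.shape != (m,) or abs(self.initial_probs.sum() - 1.0) > 1e-9:
            raise ValueError("initial_probs must be a probability vector over modes")
        if self.transition_probs.shape != (m, m):
            raise ValueError("transition_probs must be square over modes")
        if np.any(np.diag(self.transition_probs) != 0.0):
            raise ValueError("transition_probs must have an exactly zero diagonal")
        if np.any(np.abs(self.transition_probs.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("transition rows must sum to 1")
        if self.base_step_hours <= 0 or self.trip_length_hours <= 0:
            raise ValueError("base_step_hours and trip_length_hours must be positive")
        for mode in self.modes:
            if mode not in self.duration_dists:
                raise ValueError(f"missing duration distribution for {mode!r}")
            if mode not in self.emission_dists:
                raise ValueError(f"missing emission distributions for {mode!r}")

    @property
    def variables(self) -> list[str]:
        return list(next(iter(self.emission_dists.values())).keys())

    # -- serialisation ---------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "modes": list(self.modes),
            "initial_probs": self.initial_probs.tolist(),
            "transition_probs": self.transition_probs.tolist(),
            "duration_dists": {m: d.to_dict() for m, d in self.duration_dists.items()},
            "emission_dists": {m: {v: d.to_dict() for v, d in e.items()}
                               for m, e in self.emission_dists.items()},
            "base_step_hours": self.base_step_hours,
            "trip_length_hours": self.trip_length_hours,
            "dt_irregularity": (self.dt_irregularity.to_dict()
                                if self.dt_irregularity else None),
            "emission_block_hours": self.emission_block_hours,
            "seed": self.seed,
        }

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @staticmethod
    def from_dict(d: dict) -> "ScenarioConfig":
        return ScenarioConfig(
            modes=list(d["modes"]),
            initial_probs=np.array(d["initial_probs"]),
            transition_probs=np.array(d["transition_probs"]),
            duration_dists={m: FittedDistribution.from_dict(dd)
                            for m, dd in d["duration_dists"].items()},
            emission_dists={m: {v: FittedDistribution.from_dict(dd)
                                for v, dd in e.items()}
                            for m, e in d["emission_dists"].items()},
            base_step_hours=float(d["base_step_hours"]),
            trip_length_hours=float(d["trip_length_hours"]),
            dt_irregularity=(IrregularitySpec.from_dict(d["dt_irregularity"])
                             if d.get("dt_irregularity") else None),
            emission_block_hours=d.get("emission_block_hours"),
            seed=int(d.get("seed", 0)),
        )

    @staticmethod
    def from_json(path) -> "ScenarioConfig":
        return ScenarioConfig.from_dict(json.loads(Path(path).read_text()))


@dataclass
class SimulatedTrip:
    """One simulated trip: per-step features with ground truth, and
    optionally the dead-reckoned position track."""

    trip_id: str
    features: pd.DataFrame
    true_states: StateSequence
    true_segments: SegmentSequence
    track: Track | None = None


# ---------------------------------------------------------------------------
# default scenarios
# ---------------------------------------------------------------------------

def make_fishery_scenario(seed: int = 0) -> ScenarioConfig:
    """The default three-mode anchovy-fishery scenario at ~1-hour steps.

    Reconstructed from the study facts: trips start in cruising; fishing
    lasts ~2 h on average (lognormal durations); searching segments can be
    as short as 30 min (GEV durations); cruising durations GEV; emissions
    follow the per-variable families of the fishery analysis, with
    cruising fast and fishing slow, and searching overlapping both (the
    mode the observers found hardest to separate).
    """
    modes = list(MODES)
    initial = np.array([1.0, 0.0, 0.0])  # all trips start in cruising
    #                 C    S    F
    A = np.array([[0.0, 0.7, 0.3],
                  [0.3, 0.0, 0.7],
                  [0.4, 0.6, 0.0]])
    durations = {
        # GEV mean ~3.2 h for cruising, ~0.9 h (down to 0.5 h) for searching
        "cruising": make_distribution("gev", c=-0.1, loc=2.5, scale=1.0),
        "searching": make_distribution("gev", c=-0.15, loc=0.7, scale=0.3),
        # lognormal with mean exp(mu + s^2/2) = 2.0 h
        "fishing": make_distribution("lognormal", s=0.7, loc=0.0,
                                     scale=2.0 * math.exp(-0.245)),
    }
    emissions = {
        "searching": {
            "v": make_distribution("genpareto", c=0.15, loc=1.2, scale=2.8),
            "phi": make_distribution("uniform", loc=-math.pi, scale=2.0 * math.pi),
            "dv_prev": make_distribution("kumaraswamy", a=2.0, b=2.0,
                                         rescale=Rescale(loc=-4.0, scale=8.0)),
            "dv_next": make_distribution("beta", a=2.0, b=2.0, loc=0.0, scale=1.0,
                                         rescale=Rescale(loc=-4.0, scale=8.0)),
            "dphi_prev": make_distribution("laplace", loc=0.0, scale=0.9),
            "dphi_next": make_distribution("laplace", loc=0.0, scale=0.9),
        },
        "fishing": {
            "v": make_distribution("gev", c=-0.1, loc=1.8, scale=0.9),
            "phi": make_distribution("wrapped_cauchy", mu=0.5, rho=0.2),
            "dv_prev": make_distribution("uniform", loc=-2.2, scale=4.4),
            "dv_next": make_distribution("uniform", loc=-2.2, scale=4.4),
            "dphi_prev": make_distribution("gaussian_mixture", w1=0.5, mu1=-1.2,
                                           s1=0.7, mu2=1.2, s2=0.7),
            "dphi_next": make_distribution("gumbel", loc=-0.4, scale=0.9),
        },
        "cruising": {
            "v": make_distribution("gaussian_mixture", w1=0.4, mu1=4.5, s1=2.0,
                                   mu2=10.5, s2=2.8),
            "phi": make_distribution("laplace_gaussian_mixture", w_l=0.6,
                                     loc_l=-0.8, b_l=0.5, mu_g=-0.8, s_g=1.4),
            "dv_prev": make_distribution("loglogistic", c=2.5, loc=0.0, scale=1.0,
                                         rescale=Rescale(loc=-2.5, scale=2.5)),
            "dv_next": make_distribution("loglogistic", c=2.5, loc=0.0, scale=1.0,
                                         rescale=Rescale(loc=-2.5, scale=2.5)),
            "dphi_prev": make_distribution("student_t", df=4.0, loc=0.0, scale=0.45),
            "dphi_next": make_distribution("student_t", df=4.0, loc=0.0, scale=0.45),
        },
    }
    irregular = IrregularitySpec(
        probability=0.05,
        dist=make_distribution("lognormal", s=1.1, loc=0.0, scale=0.9),
    )
    return ScenarioConfig(
        modes=modes, initial_probs=initial, transition_probs=A,
        duration_dists=durations, emission_dists=emissions,
        base_step_hours=1.0, trip_length_hours=24.0,
        dt_irregularity=irregular, emission_block_hours=None, seed=seed,
    )


def make_highres_scenario(seed: int = 0) -> ScenarioConfig:
    """High-resolution variant for the sampling-rate experiment.

    Same three-mode latent structure as the fishery scenario, with the
    duration distributions concentrated around their characteristic times
    (fishing ~2 h, searching ~1 h, cruising ~3 h) — the regime in which
    explicit duration modelling carries real information.  The observed
    process is reduced to speed, whose values decorrelate over a
    ~12-minute movement-smoothness horizon (one draw per within-segment
    block), so sub-hourly steps see temporally correlated observations the
    way position-derived features do.  Each mode's speed distribution
    leaks into a neighbouring mode's range (cruising has a slow
    manoeuvring component, fishing a fast tail, searching overlaps
    fishing), which makes single blocks ambiguous while segments remain
    identifiable from their aggregate evidence and duration.  Steps are
    regular; the sampling-rate comparison needs clean subsampling.
    """
    base = make_fishery_scenario(seed)
    durations = {
        "cruising": make_distribution("gev", c=-0.05, loc=2.9, scale=0.5),
        "searching": make_distribution("gev", c=-0.1, loc=1.0, scale=0.2),
        "fishing": make_distribution("lognormal", s=0.2, loc=0.0,
                                     scale=2.0 * math.exp(-0.02)),
    }
    emissions = {
        "cruising": {"v": make_distribution("gaussian_mixture", w1=0.3, mu1=2.4,
                                            s1=0.8, mu2=11.0, s2=2.2)},
        "fishing": {"v": make_distribution("gev", c=-0.25, loc=1.6, scale=0.6)},
        "searching": {"v": make_distribution("genpareto", c=0.15, loc=2.2,
                                             scale=0.9)},
    }
    return ScenarioConfig(
        modes=base.modes, initial_probs=base.initial_probs,
        transition_probs=base.transition_probs,
        duration_dists=durations, emission_dists=emissions,
        base_step_hours=1.0 / 60.0, trip_length_hours=16.0,
        dt_irregularity=None, emission_block_hours=0.2, seed=seed,
    )


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

def _draw_segments(cfg: ScenarioConfig, rng: np.random.Generator
                   ) -> list[tuple[str, float, float]]:
    """Draw (mode, t_start, t_end) continuous segments covering the trip;
    the last segment is truncated (right-censored) at trip_length."""
    t = 0.0
    out = []
    mode_idx = int(rng.choice(len(cfg.modes), p=cfg.initial_probs))
    while t < cfg.trip_length_hours:
        mode = cfg.modes[mode_idx]
        d = np.nan
        for _ in range(_MAX_DURATION_RETRIES):
            d = float(cfg.duration_dists[mode].rvs(1, rng)[0])
            if np.isfinite(d) and d > 0:
                break
        else:
            raise RuntimeError(f"could not draw a positive finite duration for {mode!r}")
        end = min(t + d, cfg.trip_length_hours)
        out.append((mode, t, end))
        t = t + d
        mode_idx = int(rng.choice(len(cfg.modes), p=cfg.transition_probs[mode_idx]))
    return out


def _sample_states(cfg: ScenarioConfig, cont_segments) -> list[str]:
    n_steps = int(math.floor(cfg.trip_length_hours / cfg.base_step_hours + 1e-9))
    times = np.arange(n_steps) * cfg.base_step_hours
    states = []
    k = 0
    for t in times:
        while cont_segments[k][2] <= t and k < len(cont_segments) - 1:
            k += 1
        states.append(cont_segments[k][0])
    return states


def simulate_state_sequence(cfg: ScenarioConfig, rng: np.random.Generator,
                            return_continuous: bool = False):
    """Draw one trip's latent semi-Markov sequence sampled at the base step.

    Returns (true_states, true_segments); the segments are the run-length
    encoding of the *sampled* states, so sub-step excursions shorter than
    the sampling interval do not appear (exactly as in real sampled data).
    """
    cont = _draw_segments(cfg, rng)
    states = _sample_states(cfg, cont)
    seq = StateSequence(states=states,
                        dt=np.full(len(states), cfg.base_step_hours))
    segs = segments_from_states(seq)
    if return_continuous:
        return seq, segs, cont
    return seq, segs


def simulate_observations(true_states: StateSequence, cfg: ScenarioConfig,
                          rng: np.random.Generator,
                          cont_segments=None) -> pd.DataFrame:
    """Draw per-step observed variables given the state sequence.

    Variables are mutually independent given the mode.  When a
    decorrelation horizon is configured and is longer than the step, one
    value is drawn per within-segment block of that length and shared by
    the steps falling in the block.  Circular variables are wrapped to
    (-pi, pi]; a draw outside a variable's declared support is an error.
    """
    n = len(true_states)
    step = cfg.base_step_hours
    times = np.arange(n) * step

    # segment id per step
    seg_id = np.zeros(n, dtype=int)
    seg_start_time = np.zeros(n, dtype=float)
    if cont_segments is not None:
        k = 0
        for t_i in range(n):
            while cont_segments[k][2] <= times[t_i] and k < len(cont_segments) - 1:
                k += 1
            seg_id[t_i] = k
            seg_start_time[t_i] = cont_segments[k][1]
    else:
        sid = 0
        start = 0.0
        for t_i in range(n):
            if t_i > 0 and true_states.states[t_i] != true_states.states[t_i - 1]:
                sid += 1
                start = times[t_i]
            seg_id[t_i] = sid
            seg_start_time[t_i] = start

    block = cfg.emission_block_hours
    if block is None or block <= step:
        draw_key = np.arange(n)  # independent draw per step
    else:
        block_idx = np.floor((times - seg_start_time) / block + 1e-12).astype(int)
        _, draw_key = np.unique(np.stack([seg_id, block_idx]), axis=1,
                                return_inverse=True)

    n_draws = int(draw_key.max()) + 1
    mode_of_draw = np.empty(n_draws, dtype=object)
    mode_of_draw[draw_key] = np.array(true_states.states, dtype=object)

    data = {}
    for var in cfg.variables:
        col = np.empty(n_draws)
        for mode in cfg.modes:
            mask = mode_of_draw == mode
            cnt = int(mask.sum())
            if cnt == 0:
                continue
            dist = cfg.emission_dists[mode][var]
            vals = dist.rvs(cnt, rng)
            if var in CIRCULAR_VARIABLES:
                vals = wrap_to_pi(vals)
            sup = dist.raw_support()
            if sup != CIRCULAR:
                lo, hi = sup
                if np.any(vals < lo - 1e-9) or np.any(vals > hi + 1e-9):
                    raise ValueError(f"draw outside declared support for "
                                     f"({mode!r}, {var!r})")
            col[mask] = vals
        data[var] = col[draw_key]

    df = pd.DataFrame(data)
    df["dt"] = np.full(n, step)
    df["mode"] = list(true_states.states)
    return df


def _dead_reckon_track(features: pd.DataFrame, trip_id: str,
                       lon0: float = -78.0, lat0: float = -12.0,
                       t0: str = "2008-06-01T06:00:00") -> Track:
    """Integrate per-step speed and heading into lon/lat positions.

    Planar small-step approximation around the start point; adequate for
    trip-scale distances (hundreds of km)."""
    km_per_deg = 111.1949
    v = features["v"].to_numpy(dtype=float)
    phi = features["phi"].to_numpy(dtype=float)
    dt = features["dt"].to_numpy(dtype=float)
    dist = v * dt
    lat = np.empty(len(features) + 1)
    lon = np.empty(len(features) + 1)
    lat[0], lon[0] = lat0, lon0
    for i in range(len(features)):
        lat[i + 1] = lat[i] + dist[i] * np.cos(phi[i]) / km_per_deg
        lon[i + 1] = lon[i] + dist[i] * np.sin(phi[i]) / (
            km_per_deg * np.cos(np.radians(lat[i])))
    ts = pd.Timestamp(t0) + pd.to_timedelta(
        np.concatenate([[0.0], np.cumsum(dt)]), unit="h")
    modes = list(features["mode"]) + [features["mode"].iloc[-1]]
    return Track(trip_id=trip_id, records=pd.DataFrame(
        {"timestamp": ts, "lon": lon, "lat": lat, "mode": modes}))


def simulate_trip(cfg: ScenarioConfig, rng: np.random.Generator,
                  trip_id: str = "trip000", with_track: bool = False
                  ) -> SimulatedTrip:
    """Simulate one trip: latent sequence, observations, ground truth."""
    seq, _, cont = simulate_state_sequence(cfg, rng, return_continuous=True)
    feats = simulate_observations(seq, cfg, rng, cont_segments=cont)

    if cfg.dt_irregularity is not None and cfg.dt_irregularity.probability > 0:
        spec = cfg.dt_irregularity
        hit = rng.uniform(size=len(feats)) < spec.probability
        if hit.any():
            new_dt = feats["dt"].to_numpy(dtype=float)
            new_dt[hit] = spec.dist.rvs(int(hit.sum()), rng)
            feats["dt"] = new_dt
            seq = StateSequence(states=seq.states, dt=new_dt)

    feats.insert(0, "trip_id", trip_id)
    segs = segments_from_states(seq)
    track = None
    if with_track:
        if not {"v", "phi"} <= set(cfg.variables):
            raise ValueError("position-level simulation needs 'v' and 'phi' emissions")
        track = _dead_reckon_track(feats, trip_id)
    return SimulatedTrip(trip_id=trip_id, features=feats, true_states=seq,
                         true_segments=segs, track=track)


def simulate_trips(cfg: ScenarioConfig, n_trips: int, seed: int | None = None,
                   with_track: bool = False) -> list[SimulatedTrip]:
    """Simulate independent trips with per-trip child seeds (deterministic
    for a given (cfg, seed))."""
    root = np.random.SeedSequence(cfg.seed if seed is None else seed)
    out = []
    for i, child in enumerate(root.spawn(n_trips)):
        rng = np.random.default_rng(child)
        out.append(simulate_trip(cfg, rng, trip_id=f"trip{i:03d}",
                                 with_track=with_track))
    return out


# ---------------------------------------------------------------------------
# subsampling and irregularity
# ---------------------------------------------------------------------------

def subsample_sequence(trip: SimulatedTrip, factor: int) -> SimulatedTrip:
    """Keep every factor-th record (the instantaneous state and observation
    at the retained instant); per-step durations scale by the factor and
    ground-truth segments are recomputed from the retained states."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return trip
    n = len(trip.features)
    if factor > n:
        raise ValueError(f"factor {factor} larger than sequence length {n}")
    feats = trip.features.iloc[::factor].reset_index(drop=True).copy()
    feats["dt"] = feats["dt"] * factor
    seq = StateSequence(states=feats["mode"].tolist(),
                        dt=feats["dt"].to_numpy(dtype=float))
    return SimulatedTrip(trip_id=trip.trip_id, features=feats, true_states=seq,
                         true_segments=segments_from_states(seq), track=None)


def apply_dt_irregularity(track: Track, spec: IrregularitySpec,
                          rng: np.random.Generator) -> Track:
    """Replace a random small fraction of inter-record intervals with draws
    from the irregularity distribution; timestamps stay strictly increasing."""
    df = track.records.copy()
    ts = df["timestamp"].to_numpy()
    dt_h = np.diff(ts).astype("timedelta64[ns]").astype(float) / 3.6e12
    hit = rng.uniform(size=dt_h.size) < spec.probability
    if hit.any():
        draws = spec.dist.rvs(int(hit.sum()), rng)
        if np.any(draws <= 0):
            raise ValueError("irregular intervals must be positive")
        dt_h[hit] = draws
    new_ts = pd.Timestamp(ts[0]) + pd.to_timedelta(
        np.concatenate([[0.0], np.cumsum(dt_h)]), unit="h")
    df["timestamp"] = new_ts
    return Track(trip_id=track.trip_id, records=df)


# ---------------------------------------------------------------------------
# dataset output
# ---------------------------------------------------------------------------

def trips_to_features_frame(trips: list[SimulatedTrip]) -> pd.DataFrame:
    return pd.concat([t.features for t in trips], ignore_index=True)


def write_trips(trips: list[SimulatedTrip], out_dir) -> None:
    """Write a simulated dataset: a features CSV, plus a track CSV when
    position-level tracks were simulated."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    trips_to_features_frame(trips).to_csv(out_dir / "features.csv", index=False)
    tracked = [t.track for t in trips if t.track is not None]
    if tracked:
        from .features import write_tracks
        write_tracks(tracked, out_dir / "tracks.csv")
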