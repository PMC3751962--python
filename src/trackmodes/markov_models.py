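"""Supervised hidden Markov and hidden semi-Markov models for
behavioural-mode inference, with exact joint log-likelihoods and global
(Viterbi) decoding.

The HMM models the state process at the step scale: a first-order Markov
chain whose self-transitions imply geometric segment durations.  The HSMM
models it at the segment scale: transitions only between distinct states,
an explicit continuous duration distribution per state, and a survival
term for the right-censored final segment of a trip.  Both share the
state-conditional emission machinery: observed variables are assumed
mutually independent given the state, each following a univariate fitted
distribution; a missing variable contributes a factor of one.

Training is supervised throughout: transition probabilities are relative
frequencies of observed transitions, initial probabilities put mass one on
the trip-starting mode (cruising in the fishery), and emission/duration
distributions are selected among candidate families by maximum likelihood
with optional Cramér-von Mises screening and AIC selection.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import dists
from .dists import FittedDistribution

logger = logging.getLogger(__name__)

NEG_INF = -np.inf

#: floor (nats) on any single variable's per-step emission log-density
LOG_DENSITY_FLOOR = -40.0

#: candidate emission families per observed variable (the families used for
#: the corresponding variables in the fishery analysis); families whose
#: support cannot hold the data are skipped during selection.
DEFAULT_EMISSION_CANDIDATES: dict[str, tuple[str, ...]] = {
    "v": ("genpareto", "gev", "gaussian_mixture"),
    "phi": ("uniform", "wrapped_cauchy", "laplace_gaussian_mixture"),
    "dv_prev": ("kumaraswamy", "beta", "uniform", "loglogistic"),
    "dv_next": ("kumaraswamy", "beta", "uniform", "loglogistic"),
    "dphi_prev": ("laplace", "gaussian_mixture", "student_t", "gumbel"),
    "dphi_next": ("laplace", "gaussian_mixture", "student_t", "gumbel"),
}

#: the seven continuous duration candidates examined per behavioural mode
DEFAULT_DURATION_CANDIDATES: tuple[str, ...] = (
    "lognormal", "gev", "gamma", "weibull", "loglogistic", "exponential",
    "genpareto_zero",
)


# ---------------------------------------------------------------------------
# sequences and segments
# ---------------------------------------------------------------------------

@dataclass
class StateSequence:
    """A mode label per step plus each step's duration in hours."""

    states: list[str]
    dt: np.ndarray

    def __post_init__(self):
        self.states = list(self.states)
        self.dt = np.asarray(self.dt, dtype=float)
        if len(self.states) != self.dt.size:
            raise ValueError("states and dt must have equal length")
        if self.dt.size and np.any(self.dt <= 0):
            raise ValueError("step durations must be positive")

    def __len__(self) -> int:
        return len(self.states)


@dataclass(frozen=True)
class Segment:
    mode: str
    start: int
    n_steps: int
    duration: float  # hours, sum of member step durations


@dataclass
class SegmentSequence:
    """Run-length encoding of a state sequence into maximal same-mode runs."""

    segments: list[Segment]

    def __len__(self) -> int:
        return len(self.segments)

    def __iter__(self):
        return iter(self.segments)

    def __getitem__(self, i):
        return self.segments[i]

    def modes(self) -> list[str]:
        return [s.mode for s in self.segments]

    def durations(self) -> np.ndarray:
        return np.array([s.duration for s in self.segments], dtype=float)


def segments_from_states(seq: StateSequence) -> SegmentSequence:
    """Run-length encode a state sequence; segment durations sum member dts."""
    if len(seq) == 0:
        raise ValueError("empty state sequence")
    states = seq.states
    out: list[Segment] = []
    start = 0
    for t in range(1, len(states) + 1):
        if t == len(states) or states[t] != states[start]:
            out.append(Segment(mode=states[start], start=start, n_steps=t - start,
                               duration=float(np.sum(seq.dt[start:t]))))
            start = t
    return SegmentSequence(out)


def states_from_segments(segs: SegmentSequence) -> StateSequence:
    """Expand segments back to a per-step sequence.

    Step durations are reconstructed as duration / n_steps within each
    segment (exact whenever steps are regular within segments).
    """
    if len(segs) == 0:
        raise ValueError("empty segment sequence")
    states: list[str] = []
    dt: list[float] = []
    for s in segs:
        states.extend([s.mode] * s.n_steps)
        dt.extend([s.duration / s.n_steps] * s.n_steps)
    return StateSequence(states=states, dt=np.array(dt))


# ---------------------------------------------------------------------------
# models
# ---------------------------------------------------------------------------

@dataclass
class HMMModel:
    modes: list[str]
    pi: np.ndarray
    A: np.ndarray  # step-scale transitions; diagonal allowed
    emissions: dict[str, dict[str, FittedDistribution]]  # mode -> variable -> dist
    variables: list[str]

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.A = np.asarray(self.A, dtype=float)
        m = len(self.modes)
        if self.pi.shape != (m,) or self.A.shape != (m, m):
            raise ValueError("pi/A shapes inconsistent with modes")
        if abs(self.pi.sum() - 1.0) > 1e-9:
            raise ValueError("pi must sum to 1")
        if np.any(np.abs(self.A.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("rows of A must sum to 1")
        for mode in self.modes:
            for var in self.variables:
                if var not in self.emissions.get(mode, {}):
                    raise ValueError(f"missing emission distribution for ({mode}, {var})")

    def to_dict(self) -> dict:
        return {
            "kind": "hmm",
            "modes": list(self.modes),
            "pi": self.pi.tolist(),
            "A": self.A.tolist(),
            "variables": list(self.variables),
            "emissions": {m: {v: d.to_dict() for v, d in e.items()}
                          for m, e in self.emissions.items()},
        }

    @staticmethod
    def from_dict(d: dict) -> "HMMModel":
        return HMMModel(
            modes=list(d["modes"]), pi=np.array(d["pi"]), A=np.array(d["A"]),
            variables=list(d["variables"]),
            emissions={m: {v: FittedDistribution.from_dict(dd) for v, dd in e.items()}
                       for m, e in d["emissions"].items()},
        )


@dataclass
class HSMMModel:
    modes: list[str]
    pi: np.ndarray
    A_distinct: np.ndarray  # transitions between distinct states; zero diagonal
    durations: dict[str, FittedDistribution]  # per-mode, over hours
    emissions: dict[str, dict[str, FittedDistribution]]
    variables: list[str]
    d_max_steps: int = 50

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.A_distinct = np.asarray(self.A_distinct, dtype=float)
        m = len(self.modes)
        if self.pi.shape != (m,) or self.A_distinct.shape != (m, m):
            raise ValueError("pi/A_distinct shapes inconsistent with modes")
        if np.any(np.diag(self.A_distinct) != 0.0):
            raise ValueError("A_distinct must have an exactly zero diagonal")
        if np.any(np.abs(self.A_distinct.sum(axis=1) - 1.0) > 1e-9):
            raise ValueError("rows of A_distinct must sum to 1")
        if self.d_max_steps < 1:
            raise ValueError("d_max_steps must be >= 1")
        for mode in self.modes:
            if mode not in self.durations:
                raise ValueError(f"missing duration distribution for {mode}")
            for var in self.variables:
                if var not in self.emissions.get(mode, {}):
                    raise ValueError(f"missing emission distribution for ({mode}, {var})")

    def to_dict(self) -> dict:
        return {
            "kind": "hsmm",
            "modes": list(self.modes),
            "pi": self.pi.tolist(),
            "A_distinct": self.A_distinct.tolist(),
            "variables": list(self.variables),
            "d_max_steps": int(self.d_max_steps),
            "durations": {m: d.to_dict() for m, d in self.durations.items()},
            "emissions": {m: {v: d.to_dict() for v, d in e.items()}
                          for m, e in self.emissions.items()},
        }

    @staticmethod
    def from_dict(d: dict) -> "HSMMModel":
        return HSMMModel(
            modes=list(d["modes"]), pi=np.array(d["pi"]),
            A_distinct=np.array(d["A_distinct"]),
            variables=list(d["variables"]), d_max_steps=int(d["d_max_steps"]),
            durations={m: FittedDistribution.from_dict(dd)
                       for m, dd in d["durations"].items()},
            emissions={m: {v: FittedDistribution.from_dict(dd) for v, dd in e.items()}
                       for m, e in d["emissions"].items()},
        )


# ---------------------------------------------------------------------------
# emission machinery
# ---------------------------------------------------------------------------

def emission_loglik_matrix(model, features: pd.DataFrame) -> np.ndarray:
    """(T, M) matrix of per-step emission log-likelihoods.

    Observed variables are treated as conditionally independent given the
    state; a missing (NaN) variable contributes log-factor 0.  Two
    numerical guards keep bounded-support families (uniform, rescaled
    Beta/Kumaraswamy, threshold GPD) usable across partitions: a value
    outside *every* mode's fitted support carries no discriminative
    information and contributes a unit factor, and each per-variable
    log-density is floored at LOG_DENSITY_FLOOR so an out-of-support
    value under one mode penalises that mode heavily instead of making
    every path infeasible.
    """
    T = len(features)
    M = len(model.modes)
    out = np.zeros((T, M))
    for var in model.variables:
        x = features[var].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if not ok.any():
            continue
        contrib = np.zeros((T, M))
        for j, mode in enumerate(model.modes):
            lp = np.asarray(model.emissions[mode][var].logpdf(x[ok]), dtype=float)
            contrib[ok, j] = lp
        dead = np.all(~np.isfinite(contrib), axis=1)
        contrib[dead] = 0.0
        out += np.maximum(contrib, LOG_DENSITY_FLOOR)
    return out


def _dt_from_features(features: pd.DataFrame) -> np.ndarray:
    if "dt" not in features.columns:
        raise ValueError("features must carry a 'dt' column (hours)")
    return features["dt"].to_numpy(dtype=float)


def _log(x: np.ndarray) -> np.ndarray:
    with np.errstate(divide="ignore"):
        return np.log(x)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def _mode_order(trips: list[pd.DataFrame], modes=None) -> list[str]:
    if modes is not None:
        return list(modes)
    seen: dict[str, None] = {}
    for trip in trips:
        for m in trip["mode"]:
            if isinstance(m, str) and m not in seen:
                seen[m] = None
    return sorted(seen)


def _initial_vector(modes: list[str], initial_mode: str | None,
                    trips: list[pd.DataFrame]) -> np.ndarray:
    if initial_mode is None:
        initial_mode = "cruising" if "cruising" in modes else trips[0]["mode"].iloc[0]
    if initial_mode not in modes:
        raise ValueError(f"initial mode {initial_mode!r} not among modes {modes}")
    pi = np.zeros(len(modes))
    pi[modes.index(initial_mode)] = 1.0
    return pi


def _candidates_for(var: str, dist_candidates) -> tuple[str, ...]:
    if dist_candidates is None:
        return DEFAULT_EMISSION_CANDIDATES.get(var, ("gaussian_mixture",))
    if isinstance(dist_candidates, dict):
        return tuple(dist_candidates.get(var) or
                     DEFAULT_EMISSION_CANDIDATES.get(var, ("gaussian_mixture",)))
    return tuple(dist_candidates)


def fit_emissions(trips: list[pd.DataFrame], modes: list[str], variables: list[str],
                  dist_candidates=None, alpha: float = 0.05, n_boot: int = 0,
                  rng: np.random.Generator | None = None,
                  ) -> dict[str, dict[str, FittedDistribution]]:
    """Per-(mode, variable) family selection on pooled labelled steps.

    Boundary steps with a missing value of a variable are excluded from
    that variable's fit.  ``n_boot=0`` (default) selects by AIC alone;
    ``n_boot>0`` adds the Cramér-von Mises screen.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    pooled = pd.concat(trips, ignore_index=True)
    emissions: dict[str, dict[str, FittedDistribution]] = {}
    for mode in modes:
        rows = pooled[pooled["mode"] == mode]
        emissions[mode] = {}
        for var in variables:
            data = rows[var].to_numpy(dtype=float)
            data = data[np.isfinite(data)]
            cands = _candidates_for(var, dist_candidates)
            emissions[mode][var] = dists.select_family(
                cands, data, alpha=alpha, n_boot=n_boot, rng=rng)
    return emissions


def _labelled_state_arrays(trips: list[pd.DataFrame], modes: list[str]) -> list[np.ndarray]:
    index = {m: i for i, m in enumerate(modes)}
    out = []
    for trip in trips:
        labels = trip["mode"].tolist()
        if any(not isinstance(m, str) for m in labels):
            raise ValueError("all steps must carry a mode label for supervised training")
        out.append(np.array([index[m] for m in labels], dtype=int))
    return out


def step_transition_frequencies(state_lists: list[list[str]], modes: list[str]
                                ) -> np.ndarray:
    """Relative frequencies of transitions between consecutive steps,
    counted within sequences (never across sequence boundaries).  A mode
    with no outgoing transitions gets a uniform row with a warning."""
    M = len(modes)
    index = {m: i for i, m in enumerate(modes)}
    counts = np.zeros((M, M))
    for states in state_lists:
        arr = np.array([index[m] for m in states], dtype=int)
        np.add.at(counts, (arr[:-1], arr[1:]), 1.0)
    A = np.empty_like(counts)
    for i in range(M):
        row = counts[i]
        if row.sum() == 0:
            warnings.warn(f"mode {modes[i]!r} has no outgoing transitions; "
                          "using a uniform row")
            A[i] = 1.0 / M
        else:
            A[i] = row / row.sum()
    return A


def segment_transition_frequencies(segment_mode_lists: list[list[str]],
                                   modes: list[str]) -> np.ndarray:
    """Relative frequencies of transitions between consecutive distinct
    segments; zero diagonal.  A mode with no outgoing transitions gets a
    uniform off-diagonal row with a warning."""
    M = len(modes)
    index = {m: i for i, m in enumerate(modes)}
    counts = np.zeros((M, M))
    for labels in segment_mode_lists:
        for a, b in zip(labels[:-1], labels[1:]):
            counts[index[a], index[b]] += 1.0
    A = np.zeros((M, M))
    for i in range(M):
        row = counts[i]
        if row.sum() == 0:
            warnings.warn(f"mode {modes[i]!r} has no outgoing distinct-state "
                          "transitions; using a uniform off-diagonal row")
            A[i] = 1.0 / (M - 1)
            A[i, i] = 0.0
        else:
            A[i] = row / row.sum()
    return A


def train_hmm(trips: list[pd.DataFrame], variables, dist_candidates=None,
              alpha: float = 0.05, n_boot: int = 0, modes=None,
              initial_mode: str | None = None,
              rng: np.random.Generator | None = None) -> HMMModel:
    """Supervised HMM fit on labelled trips.

    Transition probabilities are relative frequencies of consecutive step
    pairs within trips (never across trip boundaries); initial
    probabilities put mass one on the trip-starting mode; emissions are
    selected per (mode, variable) among the candidate families.
    """
    variables = list(variables)
    modes = _mode_order(trips, modes)
    _labelled_state_arrays(trips, modes)  # validates labels
    A = step_transition_frequencies([trip["mode"].tolist() for trip in trips], modes)
    pi = _initial_vector(modes, initial_mode, trips)
    emissions = fit_emissions(trips, modes, variables, dist_candidates,
                              alpha=alpha, n_boot=n_boot, rng=rng)
    return HMMModel(modes=modes, pi=pi, A=A, emissions=emissions, variables=variables)


def _lognormal_moment_fit(durations: np.ndarray) -> FittedDistribution:
    m = float(np.mean(durations))
    v = float(np.var(durations)) if durations.size > 1 else (0.5 * m) ** 2
    sigma2 = math.log1p(v / m ** 2) if m > 0 else 0.25
    s = max(math.sqrt(sigma2), 1e-3)
    scale = m * math.exp(-sigma2 / 2.0)
    return dists.make_distribution("lognormal", s=s, loc=0.0, scale=scale)


def fit_durations(trips_segments: list[SegmentSequence], modes: list[str],
                  duration_candidates=None, alpha: float = 0.05, n_boot: int = 0,
                  dequantize_step: float | None = None,
                  rng: np.random.Generator | None = None,
                  ) -> dict[str, FittedDistribution]:
    """Per-mode duration fits on segment durations in hours.

    Each trip's final segment is right-censored by the end of the trip and
    is excluded from fitting.  A mode with fewer than 3 usable segments
    falls back to a lognormal moment fit with a warning.

    Observed durations are whole multiples of the sampling step; fitting a
    continuous family directly to such quantized values can collapse onto
    degenerate density spikes at coarse steps.  When ``dequantize_step``
    is given, a uniform jitter of +/- half that step (kept positive) is
    added before fitting, the usual continuity correction for binned data.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    cands = tuple(duration_candidates) if duration_candidates is not None \
        else DEFAULT_DURATION_CANDIDATES
    pool: dict[str, list[float]] = {m: [] for m in modes}
    for segs in trips_segments:
        for seg in list(segs)[:-1]:  # drop the right-censored final segment
            pool[seg.mode].append(seg.duration)
    out: dict[str, FittedDistribution] = {}
    for mode in modes:
        durs = np.array(pool[mode], dtype=float)
        if dequantize_step is not None and durs.size:
            jitter = rng.uniform(-0.5 * dequantize_step, 0.5 * dequantize_step,
                                 size=durs.size)
            durs = np.maximum(durs + jitter, 0.25 * dequantize_step)
        if durs.size < 3:
            warnings.warn(f"mode {mode!r} has only {durs.size} uncensored segments; "
                          "falling back to a lognormal moment fit")
            out[mode] = _lognormal_moment_fit(durs if durs.size else np.array([1.0]))
            continue
        try:
            out[mode] = dists.select_family(cands, durs, alpha=alpha,
                                            n_boot=n_boot, rng=rng)
        except dists.FitError:
            warnings.warn(f"duration family selection failed for {mode!r}; "
                          "falling back to a lognormal moment fit")
            out[mode] = _lognormal_moment_fit(durs)
    return out


def train_hsmm(trips: list[pd.DataFrame], variables, dist_candidates=None,
               duration_candidates=None, alpha: float = 0.05, n_boot: int = 0,
               modes=None, initial_mode: str | None = None, d_max_steps: int = 50,
               rng: np.random.Generator | None = None) -> HSMMModel:
    """Supervised HSMM fit on labelled trips.

    Transitions between distinct states are relative frequencies of
    consecutive distinct-segment pairs; per-mode duration distributions
    are fitted on uncensored segment durations; emissions as for the HMM.
    """
    variables = list(variables)
    modes = _mode_order(trips, modes)

    trips_segments = []
    seg_count = {m: 0 for m in modes}
    for trip in trips:
        seq = StateSequence(states=trip["mode"].tolist(),
                            dt=trip["dt"].to_numpy(dtype=float))
        segs = segments_from_states(seq)
        trips_segments.append(segs)
        for m in segs.modes():
            seg_count[m] += 1
    for m, c in seg_count.items():
        if c < 2:
            warnings.warn(f"mode {m!r} has only {c} segments; estimates will be weak")

    A = segment_transition_frequencies([s.modes() for s in trips_segments], modes)
    pi = _initial_vector(modes, initial_mode, trips)
    step = float(np.median(np.concatenate(
        [trip["dt"].to_numpy(dtype=float) for trip in trips])))
    durations = fit_durations(trips_segments, modes, duration_candidates,
                              alpha=alpha, n_boot=n_boot,
                              dequantize_step=step, rng=rng)
    emissions = fit_emissions(trips, modes, variables, dist_candidates,
                              alpha=alpha, n_boot=n_boot, rng=rng)
    return HSMMModel(modes=modes, pi=pi, A_distinct=A, durations=durations,
                     emissions=emissions, variables=variables,
                     d_max_steps=d_max_steps)


# ---------------------------------------------------------------------------
# joint log-likelihoods
# ---------------------------------------------------------------------------

def hmm_joint_loglik(model: HMMModel, features: pd.DataFrame, states) -> float:
    """log p(states, observations) under the HMM."""
    states = list(states)
    if len(states) != len(features):
        raise ValueError("states and features must be aligned")
    idx = [model.modes.index(s) for s in states]
    E = emission_loglik_matrix(model, features)
    logpi = _log(model.pi)
    logA = _log(model.A)
    ll = logpi[idx[0]] + E[0, idx[0]]
    for t in range(1, len(idx)):
        ll += logA[idx[t - 1], idx[t]] + E[t, idx[t]]
    return float(ll)


def hsmm_joint_loglik(model: HSMMModel, features: pd.DataFrame,
                      segments: SegmentSequence) -> float:
    """log p(segments, observations) under the HSMM.

    Visited states contribute their duration density and the transition to
    the next distinct state; the last visited state contributes the
    survival P(duration >= observed) of its right-censored duration.
    """
    n_steps = sum(s.n_steps for s in segments)
    if n_steps != len(features):
        raise ValueError("segments inconsistent with features length")
    E = emission_loglik_matrix(model, features)
    logpi = _log(model.pi)
    logA = _log(model.A_distinct)
    segs = list(segments)
    ll = logpi[model.modes.index(segs[0].mode)]
    for r, seg in enumerate(segs):
        j = model.modes.index(seg.mode)
        ll += float(np.sum(E[seg.start:seg.start + seg.n_steps, j]))
        if r < len(segs) - 1:
            ll += float(model.durations[seg.mode].logpdf(seg.duration))
            ll += logA[j, model.modes.index(segs[r + 1].mode)]
        else:
            ll += float(model.durations[seg.mode].log_sf(seg.duration))
    return float(ll)


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def decode_hmm_viterbi(model: HMMModel, features: pd.DataFrame) -> StateSequence:
    """Most probable state sequence under the HMM (log-space Viterbi).

    Ties are broken toward the lower mode index.
    """
    E = emission_loglik_matrix(model, features)
    T, M = E.shape
    if T == 0:
        raise ValueError("empty feature sequence")
    bad = np.where(np.all(~np.isfinite(E), axis=1))[0]
    if bad.size:
        raise ValueError(f"all-zero emission likelihood at step {int(bad[0])}")
    logpi = _log(model.pi)
    logA = _log(model.A)
    delta = logpi + E[0]
    back = np.zeros((T, M), dtype=int)
    for t in range(1, T):
        cand = delta[:, None] + logA  # cand[i, j]
        back[t] = np.argmax(cand, axis=0)
        delta = cand[back[t], np.arange(M)] + E[t]
    path = np.empty(T, dtype=int)
    path[-1] = int(np.argmax(delta))
    for t in range(T - 1, 0, -1):
        path[t - 1] = back[t, path[t]]
    return StateSequence(states=[model.modes[i] for i in path],
                         dt=_dt_from_features(features))


def _duration_tables(model: HSMMModel, dt: np.ndarray):
    """Pre-tabulated duration log-density and log-survival for regular dt."""
    U = min(model.d_max_steps, dt.size)
    durs = dt[0] * np.arange(1, U + 1)
    logd = np.empty((len(model.modes), U))
    logs = np.empty((len(model.modes), U))
    for j, mode in enumerate(model.modes):
        d = model.durations[mode]
        logd[j] = np.asarray(d.logpdf(durs), dtype=float)
        logs[j] = np.asarray(d.log_sf(durs), dtype=float)
    return logd, logs


def decode_hsmm_viterbi(model: HSMMModel, features: pd.DataFrame) -> StateSequence:
    """Most probable segmentation under the HSMM, by dynamic programming
    over (step, mode, segment length <= d_max_steps) in log space.

    The final segment is scored with the survival of its duration
    (right-censoring at the end of the trip).  Ties are broken toward the
    lower mode index, then the shorter segment.  Complexity
    O(T * d_max * M^2).
    """
    if model.d_max_steps < 1:
        raise ValueError("d_max_steps must be >= 1")
    E = emission_loglik_matrix(model, features)
    T, M = E.shape
    if T == 0:
        raise ValueError("empty feature sequence")
    bad = np.where(np.all(~np.isfinite(E), axis=1))[0]
    if bad.size:
        raise ValueError(f"all-zero emission likelihood at step {int(bad[0])}")
    dt = _dt_from_features(features)
    cumdt = np.concatenate([[0.0], np.cumsum(dt)])
    cumE = np.vstack([np.zeros((1, M)), np.cumsum(E, axis=0)])  # cumE[e, j]

    regular = bool(np.allclose(dt, dt[0], rtol=1e-9, atol=1e-12))
    if regular:
        logd_tab, logs_tab = _duration_tables(model, dt)

    logpi = _log(model.pi)
    logA = _log(model.A_distinct)
    off_diag_mask = ~np.eye(M, dtype=bool)

    # trans_in[e, j]: best score of a segmentation of steps [0, e) followed
    # by an entry into mode j at step e (log pi_j when e == 0)
    trans_in = np.full((T, M), NEG_INF)
    trans_from = np.full((T, M), -1, dtype=int)
    trans_in[0] = logpi
    # best[e, j]: best score of steps [0, e) ending with a completed
    # (density-scored) segment of mode j at e
    best = np.full((T + 1, M), NEG_INF)
    best_u = np.zeros((T + 1, M), dtype=int)

    def seg_scores(e: int, j: int, u_max: int, final: bool) -> np.ndarray:
        """Scores of a mode-j segment of length u = 1..u_max ending at e."""
        u = np.arange(1, u_max + 1)
        starts = e - u
        emit = cumE[e, j] - cumE[starts, j]
        if regular:
            tab = logs_tab if final else logd_tab
            dur_term = tab[j, :u_max]
        else:
            durs = cumdt[e] - cumdt[starts]
            d = model.durations[model.modes[j]]
            dur_term = np.asarray(d.log_sf(durs) if final else d.logpdf(durs),
                                  dtype=float)
        return trans_in[starts, j] + dur_term + emit

    for e in range(1, T):
        u_max = min(model.d_max_steps, e)
        for j in range(M):
            sc = seg_scores(e, j, u_max, final=False)
            k = int(np.argmax(sc))  # first max: shorter segment wins ties
            best[e, j] = sc[k]
            best_u[e, j] = k + 1
        # entries into each mode at step e come from a distinct completed mode
        cand = best[e][:, None] + logA  # cand[i, j]
        cand[~off_diag_mask] = NEG_INF
        trans_from[e] = np.argmax(cand, axis=0)
        trans_in[e] = cand[trans_from[e], np.arange(M)]

    # final segment, scored with the survival of its censored duration
    final_score = np.full(M, NEG_INF)
    final_u = np.zeros(M, dtype=int)
    u_max = min(model.d_max_steps, T)
    for j in range(M):
        sc = seg_scores(T, j, u_max, final=True)
        k = int(np.argmax(sc))
        final_score[j] = sc[k]
        final_u[j] = k + 1
    j = int(np.argmax(final_score))
    if not np.isfinite(final_score[j]):
        raise ValueError("no feasible segmentation under d_max_steps; "
                         "increase d_max_steps")

    # backtrack
    segments: list[tuple[int, int]] = []  # (mode index, length), reversed
    e = T
    u = int(final_u[j])
    while True:
        segments.append((j, u))
        e -= u
        if e == 0:
            break
        j = int(trans_from[e, j])
        u = int(best_u[e, j])
    segments.reverse()

    if any(u == model.d_max_steps for _, u in segments) and model.d_max_steps < T:
        warnings.warn("a decoded segment hit d_max_steps; the unconstrained "
                      "optimum may be longer — consider raising d_max_steps")

    states: list[str] = []
    for jj, uu in segments:
        states.extend([model.modes[jj]] * uu)
    return StateSequence(states=states, dt=dt)


def hmm_from_hsmm_geometric(model: HSMMModel, step_hours: float) -> HMMModel:
    """The step-scale HMM equivalent to an HSMM with discrete-geometric
    durations: self-transition 1 - p_j, off-diagonal p_j * A_distinct[i, j]."""
    M = len(model.modes)
    A = np.zeros((M, M))
    for i, mode in enumerate(model.modes):
        d = model.durations[mode]
        if d.family != "geometric_steps":
            raise ValueError("geometric equivalence requires geometric_steps durations")
        p = d.params["p"]
        A[i] = p * model.A_distinct[i]
        A[i, i] = 1.0 - p
    return HMMModel(modes=list(model.modes), pi=model.pi.copy(), A=A,
                    emissions=model.emissions, variables=list(model.variables))
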