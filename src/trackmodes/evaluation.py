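"""Performance indicators, model-comparison protocol and the
sampling-rate experiment.

Two scales of analysis.  At the step scale, accuracy is the percentage of
steps whose inferred mode matches the true one, and the mean accuracy
(MA) averages the per-mode step accuracies without weighting by mode
frequency.  At the segment scale — the scale that characterises
behavioural modes — an inferred segment counts toward precision when it
overlaps (shares at least one step with) a true segment of the same mode,
a true segment counts toward recall when it is overlapped by at least one
inferred step of its mode, F1 is their harmonic mean, and the duration
statistic is the mean squared difference between the empirical CDFs of
true and inferred segment durations (0 = error-free).

Model comparison uses trip-level repeated random sub-sampling: trips are
split 50/50 into training and validation partitions, 20 repetitions by
default, the same partitions for every model, with a paired sign-flip
randomization test on per-repetition scores.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import discriminative, markov_models
from .markov_models import (SegmentSequence, StateSequence,
                            segments_from_states)
from .synthetic_data import ScenarioConfig, SimulatedTrip, simulate_trips, subsample_sequence

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# step-scale indicators
# ---------------------------------------------------------------------------

def step_accuracy(true_states, pred_states) -> float:
    """Percentage of steps whose inferred mode equals the true one."""
    t = list(true_states)
    p = list(pred_states)
    if len(t) != len(p):
        raise ValueError("sequences must have equal length")
    if not t:
        raise ValueError("empty sequences")
    return 100.0 * sum(a == b for a, b in zip(t, p)) / len(t)


def confusion_matrix(true_states, pred_states, modes) -> pd.DataFrame:
    """Mode-by-mode step counts (rows: true, columns: predicted)."""
    conf = pd.DataFrame(0, index=list(modes), columns=list(modes), dtype=int)
    for a, b in zip(true_states, pred_states):
        conf.loc[a, b] += 1
    return conf


def mean_accuracy(confusion: pd.DataFrame) -> float:
    """Unweighted mean of per-mode step accuracies (diagonal over row sum);
    modes with no true steps are excluded."""
    accs = []
    for mode in confusion.index:
        total = confusion.loc[mode].sum()
        if total > 0:
            accs.append(100.0 * confusion.loc[mode, mode] / total)
    if not accs:
        raise ValueError("confusion matrix has no true steps")
    return float(np.mean(accs))


# ---------------------------------------------------------------------------
# segment-scale indicators
# ---------------------------------------------------------------------------

def _step_sets(segs: SegmentSequence, mode: str) -> list[set[int]]:
    return [set(range(s.start, s.start + s.n_steps)) for s in segs if s.mode == mode]


def _overlap_counts(true_segs: SegmentSequence, pred_segs: SegmentSequence,
                    mode: str, rule: str = "any") -> tuple[int, int, int, int]:
    """(recall hits, true count, precision hits, predicted count) for one
    mode under the segment-overlap rule ('any': >= 1 shared step;
    'majority': more than half the segment's steps shared)."""
    true_sets = _step_sets(true_segs, mode)
    pred_sets = _step_sets(pred_segs, mode)

    if rule == "any":
        r_hits = sum(1 for t in true_sets if any(t & p for p in pred_sets))
        p_hits = sum(1 for p in pred_sets if any(p & t for t in true_sets))
    elif rule == "majority":
        r_hits = sum(1 for t in true_sets
                     if max((len(t & p) for p in pred_sets), default=0) > len(t) / 2.0)
        p_hits = sum(1 for p in pred_sets
                     if max((len(p & t) for t in true_sets), default=0) > len(p) / 2.0)
    else:
        raise ValueError(f"unknown overlap rule {rule!r}")
    return r_hits, len(true_sets), p_hits, len(pred_sets)


def segment_prf(true_segs: SegmentSequence, pred_segs: SegmentSequence, mode: str,
                rule: str = "any") -> tuple[float, float, float]:
    """Segment-level (recall %, precision %, F1 %) for one mode.

    An indicator with an empty denominator (no segments of the mode on
    that side) is undefined and returned as NaN; F1 is 0 when P + R = 0
    and NaN when either input is undefined.
    """
    r_hits, n_true, p_hits, n_pred = _overlap_counts(true_segs, pred_segs, mode, rule)
    recall = 100.0 * r_hits / n_true if n_true else float("nan")
    precision = 100.0 * p_hits / n_pred if n_pred else float("nan")
    if math.isnan(recall) or math.isnan(precision):
        f1 = float("nan")
    elif precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return recall, precision, f1


def duration_statistic(true_segs: SegmentSequence, pred_segs: SegmentSequence,
                       mode: str) -> float:
    """Mean squared difference between the ECDFs of true and inferred
    segment durations of one mode, evaluated on the union of observed
    durations; ranges over [0, 1] with 0 for an error-free inference."""
    td = np.array([s.duration for s in true_segs if s.mode == mode])
    pd_ = np.array([s.duration for s in pred_segs if s.mode == mode])
    if td.size == 0 or pd_.size == 0:
        return float("nan")
    grid = np.union1d(td, pd_)
    f = np.searchsorted(np.sort(td), grid, side="right") / td.size
    g = np.searchsorted(np.sort(pd_), grid, side="right") / pd_.size
    return float(np.mean((f - g) ** 2))


# ---------------------------------------------------------------------------
# reports
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    """Step accuracy, MA, per-mode segment indicators and the confusion
    matrix for one validation pass (pooled over its trips)."""

    accuracy: float
    mean_acc: float
    per_mode: dict[str, dict[str, float]]  # recall/precision/f1/duration_stat, in %
    confusion: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for mode, vals in self.per_mode.items():
            rows.append({"mode": mode, **vals})
        return pd.DataFrame(rows)


def compute_metrics(pairs: list[tuple[StateSequence, StateSequence]],
                    modes=None, rule: str = "any") -> MetricsReport:
    """Evaluate predicted against true sequences, pooled over trips.

    Step counts pool across trips; segments are computed within trips
    (never across trip boundaries) and their per-mode hit counts and
    duration multisets pool across trips.
    """
    if not pairs:
        raise ValueError("no sequence pairs to evaluate")
    if modes is None:
        seen: dict[str, None] = {}
        for t, _ in pairs:
            for m in t.states:
                seen.setdefault(m, None)
        modes = sorted(seen)

    all_true: list[str] = []
    all_pred: list[str] = []
    counts = {m: np.zeros(4) for m in modes}  # r_hits, n_true, p_hits, n_pred
    true_durs: dict[str, list[float]] = {m: [] for m in modes}
    pred_durs: dict[str, list[float]] = {m: [] for m in modes}
    for true_seq, pred_seq in pairs:
        if len(true_seq) != len(pred_seq):
            raise ValueError("true and predicted sequences must align per trip")
        all_true.extend(true_seq.states)
        all_pred.extend(pred_seq.states)
        t_segs = segments_from_states(true_seq)
        p_segs = segments_from_states(pred_seq)
        for m in modes:
            counts[m] += _overlap_counts(t_segs, p_segs, m, rule)
            true_durs[m].extend(s.duration for s in t_segs if s.mode == m)
            pred_durs[m].extend(s.duration for s in p_segs if s.mode == m)

    conf = confusion_matrix(all_true, all_pred, modes)
    per_mode = {}
    for m in modes:
        r_hits, n_true, p_hits, n_pred = counts[m]
        recall = 100.0 * r_hits / n_true if n_true else float("nan")
        precision = 100.0 * p_hits / n_pred if n_pred else float("nan")
        if math.isnan(recall) or math.isnan(precision):
            f1 = float("nan")
        elif precision + recall == 0:
            f1 = 0.0
        else:
            f1 = 2.0 * precision * recall / (precision + recall)
        td, pdur = np.array(true_durs[m]), np.array(pred_durs[m])
        if td.size and pdur.size:
            grid = np.union1d(td, pdur)
            fe = np.searchsorted(np.sort(td), grid, side="right") / td.size
            ge = np.searchsorted(np.sort(pdur), grid, side="right") / pdur.size
            dstat = float(np.mean((fe - ge) ** 2))
        else:
            dstat = float("nan")
        per_mode[m] = {"recall": recall, "precision": precision, "f1": f1,
                       "duration_stat": dstat}
    return MetricsReport(accuracy=step_accuracy(all_true, all_pred),
                         mean_acc=mean_accuracy(conf),
                         per_mode=per_mode, confusion=conf)


# ---------------------------------------------------------------------------
# model adapters (uniform fit/predict interface over trips of features)
# ---------------------------------------------------------------------------

class HMMAdapter:
    """Supervised HMM with Viterbi decoding."""

    def __init__(self, variables, name: str = "hmm", **train_kwargs):
        self.variables = list(variables)
        self.name = name
        self.train_kwargs = train_kwargs

    def fit(self, trips: list[pd.DataFrame]):
        model = markov_models.train_hmm(trips, self.variables, **self.train_kwargs)
        return _FittedMarkov(model, markov_models.decode_hmm_viterbi)


class HSMMAdapter:
    """Supervised duration-explicit HSMM with forward-backward Viterbi."""

    def __init__(self, variables, name: str = "hsmm", **train_kwargs):
        self.variables = list(variables)
        self.name = name
        self.train_kwargs = train_kwargs

    def fit(self, trips: list[pd.DataFrame]):
        model = markov_models.train_hsmm(trips, self.variables, **self.train_kwargs)
        return _FittedMarkov(model, markov_models.decode_hsmm_viterbi)


class _FittedMarkov:
    def __init__(self, model, decoder):
        self.model = model
        self.decoder = decoder

    def predict(self, features: pd.DataFrame) -> StateSequence:
        return self.decoder(self.model, features)


class ClassifierAdapter:
    """Step-independent discriminative classifier."""

    def __init__(self, spec: discriminative.ClassifierSpec, variables,
                 name: str | None = None):
        self.spec = spec
        self.variables = list(variables)
        self.name = name or spec.kind

    def fit(self, trips: list[pd.DataFrame]):
        X, y = discriminative.training_rows(trips, self.variables)
        clf = discriminative.train_classifier(self.spec, X, y,
                                              variables=self.variables)
        return _FittedClassifier(clf)


class _FittedClassifier:
    def __init__(self, clf):
        self.clf = clf

    def predict(self, features: pd.DataFrame) -> StateSequence:
        return discriminative.predict_states(self.clf, features)


def _true_sequence(features: pd.DataFrame) -> StateSequence:
    return StateSequence(states=features["mode"].tolist(),
                         dt=features["dt"].to_numpy(dtype=float))


def _evaluate_fitted(fitted, val_trips: list[pd.DataFrame], modes=None) -> MetricsReport:
    pairs = [(_true_sequence(tr), fitted.predict(tr)) for tr in val_trips]
    return compute_metrics(pairs, modes=modes)


# ---------------------------------------------------------------------------
# variable-subset selection
# ---------------------------------------------------------------------------

def select_variable_subset(adapter_factory, trips: list[pd.DataFrame], variables,
                           seed: int = 0) -> tuple[str, ...]:
    """Exhaustive search for the variable subset with the highest
    state-inference accuracy on a fixed internal trip-level split.

    ``adapter_factory(subset)`` must return a fit/predict adapter.  Ties
    prefer the smaller subset, then lexicographic order.
    """
    variables = list(variables)
    if len(variables) > 10:
        raise ValueError("exhaustive subset search is limited to 10 variables")
    if len(trips) < 2:
        raise ValueError("need at least two trips for an internal split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(trips))
    n_train = max(1, len(trips) // 2)
    train = [trips[i] for i in order[:n_train]]
    val = [trips[i] for i in order[n_train:]]

    results = []
    for k in range(1, len(variables) + 1):
        for subset in itertools.combinations(sorted(variables), k):
            fitted = adapter_factory(subset).fit(train)
            pairs = [(_true_sequence(tr), fitted.predict(tr)) for tr in val]
            acc = step_accuracy([s for t, _ in pairs for s in t.states],
                                [s for _, p in pairs for s in p.states])
            results.append((acc, k, subset))
    results.sort(key=lambda r: (-r[0], r[1], r[2]))
    return results[0][2]


# ---------------------------------------------------------------------------
# cross-validation and model comparison
# ---------------------------------------------------------------------------

@dataclass
class CVConfig:
    """Repeated random sub-sampling at the trip level (never step level)."""

    n_repetitions: int = 20
    train_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must lie strictly between 0 and 1")


def cv_partitions(n_trips: int, cfg: CVConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    """The seeded trip-level partitions; identical for every model."""
    rng = np.random.default_rng(cfg.seed)
    n_train = int(round(n_trips * cfg.train_fraction))
    n_train = min(max(n_train, 1), n_trips - 1)
    parts = []
    for _ in range(cfg.n_repetitions):
        order = rng.permutation(n_trips)
        parts.append((order[:n_train], order[n_train:]))
    return parts


def cross_validate(models: dict[str, object], trips: list[pd.DataFrame],
                   cfg: CVConfig, modes=None) -> dict[str, list[MetricsReport]]:
    """Repeated random sub-sampling evaluation of several models on the
    same trip-level partitions."""
    if len(trips) < 2:
        raise ValueError("need at least two trips")
    parts = cv_partitions(len(trips), cfg)
    out: dict[str, list[MetricsReport]] = {name: [] for name in models}
    for rep, (train_idx, val_idx) in enumerate(parts):
        train = [trips[i] for i in train_idx]
        val = [trips[i] for i in val_idx]
        for name, adapter in models.items():
            fitted = adapter.fit(train)
            out[name].append(_evaluate_fitted(fitted, val, modes=modes))
    return out


def summarize_reports(reports: dict[str, list[MetricsReport]]) -> pd.DataFrame:
    """Mean and SD of the indicators across repetitions, one row per
    (model, mode) plus an overall row per model.  Undefined (NaN) per-mode
    values are excluded from the averages rather than zero-filled."""
    rows = []
    for name, reps in reports.items():
        accs = [r.accuracy for r in reps]
        mas = [r.mean_acc for r in reps]
        rows.append({"model": name, "mode": "(all)",
                     "accuracy_mean": np.mean(accs), "accuracy_sd": np.std(accs),
                     "mean_accuracy_mean": np.mean(mas), "mean_accuracy_sd": np.std(mas)})
        modes = reps[0].per_mode.keys()
        for m in modes:
            row = {"model": name, "mode": m}
            for key in ("recall", "precision", "f1", "duration_stat"):
                vals = np.array([r.per_mode[m][key] for r in reps])
                vals = vals[~np.isnan(vals)]
                row[f"{key}_mean"] = float(np.mean(vals)) if vals.size else float("nan")
                row[f"{key}_sd"] = float(np.std(vals)) if vals.size else float("nan")
            rows.append(row)
    return pd.DataFrame(rows)


def paired_randomization_test(scores_a, scores_b, n_perm: int = 10_000,
                              rng: np.random.Generator | None = None) -> float:
    """Two-sided sign-flip randomization test on paired score differences.

    Exhaustive over all 2^n sign patterns when that is cheaper than
    n_perm; otherwise Monte-Carlo with the provided generator.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired score vectors must have equal length")
    d = a - b
    n = d.size
    obs = abs(d.mean())
    if 2 ** n <= n_perm:
        signs = np.array(list(itertools.product([1.0, -1.0], repeat=n)))
        stats = np.abs((signs * d).mean(axis=1))
        return float(np.mean(stats >= obs - 1e-12))
    rng = rng if rng is not None else np.random.default_rng(0)
    signs = rng.choice([1.0, -1.0], size=(n_perm, n))
    stats = np.abs((signs * d).mean(axis=1))
    return float((1.0 + np.sum(stats >= obs - 1e-12)) / (1.0 + n_perm))


# ---------------------------------------------------------------------------
# sampling-rate (resolution) experiment
# ---------------------------------------------------------------------------

def run_resolution_experiment(scenario: ScenarioConfig, factors,
                              n_trips: int = 50, n_repetitions: int = 3,
                              seed: int = 0, out_csv=None, plot_path=None
                              ) -> pd.DataFrame:
    """Train and decode HMM and HSMM on sub-sampled versions of
    high-resolution semi-Markov trips and report mean accuracy per rate.

    For each repetition, ``n_trips`` trips are simulated from the
    scenario; half train the models, the disjoint half is decoded.  At
    each subsampling factor both models are retrained at that rate (so
    each sees the data as it would arrive at that resolution), with
    emission and duration candidate families taken from the generating
    scenario.  Returns a tidy frame (step_minutes, model, repetition,
    mean_accuracy).
    """
    factors = sorted(int(f) for f in factors)
    if len(set(factors)) < 1:
        raise ValueError("need at least one subsampling factor")
    variables = scenario.variables
    emission_cands = {
        var: tuple(dict.fromkeys(scenario.emission_dists[m][var].family
                                 for m in scenario.modes))
        for var in variables
    }
    duration_cands = tuple(dict.fromkeys(d.family
                                         for d in scenario.duration_dists.values()))
    rows = []
    root = np.random.SeedSequence(seed)
    for rep, child in enumerate(root.spawn(n_repetitions)):
        rep_seed = int(child.generate_state(1)[0] % (2 ** 31))
        trips = simulate_trips(scenario, n_trips, seed=rep_seed)
        half = n_trips // 2
        for factor in factors:
            step_hours = scenario.base_step_hours * factor
            sub = [subsample_sequence(t, factor) for t in trips]
            train = [t.features for t in sub[:half]]
            val = [t.features for t in sub[half:]]
            d_max = int(math.ceil(scenario.trip_length_hours / step_hours))
            adapters = {
                "hmm": HMMAdapter(variables, dist_candidates=emission_cands),
                "hsmm": HSMMAdapter(variables, dist_candidates=emission_cands,
                                    duration_candidates=duration_cands,
                                    d_max_steps=d_max),
            }
            for name, adapter in adapters.items():
                fitted = adapter.fit(train)
                report = _evaluate_fitted(fitted, val, modes=list(scenario.modes))
                rows.append({"step_minutes": step_hours * 60.0, "model": name,
                             "repetition": rep, "mean_accuracy": report.mean_acc})
    table = pd.DataFrame(rows)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    if plot_path is not None:
        _plot_resolution(table, plot_path)
    return table


def _plot_resolution(table: pd.DataFrame, path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    for name, grp in table.groupby("model"):
        agg = grp.groupby("step_minutes")["mean_accuracy"].agg(["mean", "std"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["std"], marker="o",
                    capsize=3, label=name.upper())
    ax.set_xlabel("step size (minutes)")
    ax.set_ylabel("mean accuracy (%)")
    ax.set_xscale("log")
    ax.set_ylim(0, 102)
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
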