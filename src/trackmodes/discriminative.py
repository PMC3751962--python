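"""Step-wise discriminative baselines: random forest, Gaussian-kernel SVM
and a single-hidden-layer perceptron.

These classifiers predict each step's behavioural mode independently from
its observed vector — no temporal coupling — which is exactly the property
the segment-scale evaluation probes (they tend to over-segment, inferring
more and shorter segments than the truth).  Hyperparameters are tuned by
classification accuracy on a stratified held-out share of the training
partition, then the winning setting is refitted on the full training data.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import train_test_split
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .markov_models import StateSequence

_TUNE_FRACTION = 0.25  # stratified share of the training rows held out for tuning


def default_grid(kind: str, n_variables: int) -> dict[str, list]:
    """Default hyperparameter grids.

    ANN hidden-neuron options span one to ten; RF and SVM grids cover the
    usual ranges (trees and per-node variables for the forest, kernel
    scale gamma and regularisation C for the SVM).
    """
    if kind == "rf":
        m = sorted({1, int(math.ceil(math.sqrt(n_variables))), n_variables})
        return {"n_trees": [100, 500], "max_features": m}
    if kind == "svm":
        return {"gamma": [0.01, 0.1, 1.0, 10.0], "C": [1.0, 10.0, 100.0]}
    if kind == "ann":
        return {"hidden_neurons": list(range(1, 11))}
    raise ValueError(f"unknown classifier kind {kind!r}")


@dataclass
class ClassifierSpec:
    kind: str  # rf | svm | ann
    grid: dict[str, list] | None = None
    seed: int = 0

    def __post_init__(self):
        if self.kind not in ("rf", "svm", "ann"):
            raise ValueError(f"unknown classifier kind {self.kind!r}")
        if self.grid is not None:
            if not self.grid or any(len(v) == 0 for v in self.grid.values()):
                raise ValueError("grid must be non-empty")
            if self.kind == "ann":
                opts = set(self.grid.get("hidden_neurons", []))
                if not opts <= set(range(1, 11)):
                    raise ValueError("hidden-neuron options must lie in 1..10")


@dataclass
class TrainedClassifier:
    kind: str
    model: object  # fitted sklearn estimator/pipeline
    variables: list[str]
    hyperparams: dict
    tuning_accuracy: float
    feature_means: np.ndarray  # for mean-imputing missing lag/lead values

    def predict(self, X: np.ndarray) -> np.ndarray:
        X = np.asarray(X, dtype=float)
        if np.isnan(X).any():
            X = np.where(np.isnan(X), self.feature_means, X)
        return self.model.predict(X)


def _build_estimator(kind: str, params: dict, n_variables: int, seed: int):
    if kind == "rf":
        return RandomForestClassifier(
            n_estimators=params["n_trees"],
            max_features=min(params["max_features"], n_variables),
            random_state=seed,
        )
    if kind == "svm":
        return Pipeline([
            ("scale", StandardScaler()),
            ("svc", SVC(kernel="rbf", gamma=params["gamma"], C=params["C"],
                        random_state=seed)),
        ])
    return Pipeline([
        ("scale", StandardScaler()),
        ("mlp", MLPClassifier(hidden_layer_sizes=(params["hidden_neurons"],),
                              max_iter=500, random_state=seed)),
    ])


def _grid_points(grid: dict[str, list]):
    keys = list(grid)
    for combo in itertools.product(*(grid[k] for k in keys)):
        yield dict(zip(keys, combo))


def train_classifier(spec: ClassifierSpec, X, y, variables=None) -> TrainedClassifier:
    """Grid-tune and fit one discriminative classifier.

    Rows containing missing values (trip-boundary lag/lead variables) must
    already be removed from X.  Each grid point is fitted on the tuning
    split's complement and scored by accuracy on the held-out tuning rows;
    the winner is refitted on all rows.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.ndim != 2:
        raise ValueError("X must be 2-D (rows of observed vectors)")
    if np.isnan(X).any():
        raise ValueError("training rows with missing variables must be removed")
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain at least two classes")
    n_vars = X.shape[1]
    variables = list(variables) if variables is not None else [f"x{i}" for i in range(n_vars)]
    grid = spec.grid if spec.grid is not None else default_grid(spec.kind, n_vars)

    X_fit, X_tune, y_fit, y_tune = train_test_split(
        X, y, test_size=_TUNE_FRACTION, stratify=y, random_state=spec.seed)

    best = None
    for params in _grid_points(grid):
        est = _build_estimator(spec.kind, params, n_vars, spec.seed)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est.fit(X_fit, y_fit)
        acc = float(np.mean(est.predict(X_tune) == y_tune))
        if best is None or acc > best[0]:
            best = (acc, params)

    acc, params = best
    final = _build_estimator(spec.kind, params, n_vars, spec.seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        final.fit(X, y)
    return TrainedClassifier(kind=spec.kind, model=final, variables=variables,
                             hyperparams=params, tuning_accuracy=acc,
                             feature_means=np.nanmean(X, axis=0))


def training_rows(trips: list[pd.DataFrame], variables) -> tuple[np.ndarray, np.ndarray]:
    """Stack labelled steps into (X, y), dropping rows with any missing
    variable (trip-boundary lag/lead values)."""
    pooled = pd.concat(trips, ignore_index=True)
    X = pooled[list(variables)].to_numpy(dtype=float)
    y = pooled["mode"].to_numpy()
    keep = ~np.isnan(X).any(axis=1)
    return X[keep], y[keep]


def predict_states(clf: TrainedClassifier, features: pd.DataFrame) -> StateSequence:
    """Independent per-step prediction for one trip.

    Boundary rows with missing lag/lead values are predicted from the
    available variables with missing entries mean-imputed (training-set
    means).
    """
    X = features[clf.variables].to_numpy(dtype=float)
    pred = clf.predict(X)
    return StateSequence(states=list(pred),
                         dt=features["dt"].to_numpy(dtype=float))
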