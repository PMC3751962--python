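import warnings

import numpy as np
import pandas as pd
import pytest

from trackmodes import dists, markov_models as mm
from trackmodes.synthetic_data import (make_fishery_scenario,
                                       make_highres_scenario, simulate_trips)


@pytest.fixture(scope="session")
def fishery_cfg():
    return make_fishery_scenario(seed=1)


@pytest.fixture(scope="session")
def highres_cfg():
    return make_highres_scenario(seed=1)


@pytest.fixture(scope="session")
def fishery_trips(fishery_cfg):
    """Forty hourly trips shared across tests that only read them."""
    return simulate_trips(fishery_cfg, 40, seed=101)


@pytest.fixture(scope="session")
def fishery_features(fishery_trips):
    return [t.features for t in fishery_trips]


@pytest.fixture(scope="session")
def trained_hourly_models(fishery_features):
    """HMM and HSMM trained on the first 20 hourly trips (shared)."""
    train = fishery_features[:20]
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        hmm = mm.train_hmm(train, list(train[0].columns[1:7]))
        hsmm = mm.train_hsmm(train, list(train[0].columns[1:7]))
    return hmm, hsmm


def make_gaussian_hmm(rng, n_modes=2, spread=3.0):
    """Small random HMM with Gaussian speed emissions (test helper)."""
    modes = [f"m{i}" for i in range(n_modes)]
    pi = rng.dirichlet(np.ones(n_modes))
    A = rng.dirichlet(np.ones(n_modes), size=n_modes)
    emissions = {
        m: {"v": dists.make_distribution(
            "gaussian_mixture", w1=0.5,
            mu1=float(rng.normal(i * spread, 0.3)), s1=0.8,
            mu2=float(rng.normal(i * spread + 1.0, 0.3)), s2=0.8)}
        for i, m in enumerate(modes)
    }
    return mm.HMMModel(modes=modes, pi=pi, A=A, emissions=emissions,
                       variables=["v"])


def make_gaussian_hsmm(rng, n_modes=2, spread=3.0, d_max_steps=10):
    modes = [f"m{i}" for i in range(n_modes)]
    pi = rng.dirichlet(np.ones(n_modes))
    A = np.zeros((n_modes, n_modes))
    for i in range(n_modes):
        off = rng.dirichlet(np.ones(n_modes - 1))
        A[i, [j for j in range(n_modes) if j != i]] = off
    durations = {
        m: dists.make_distribution("lognormal",
                                   s=float(rng.uniform(0.3, 0.8)), loc=0.0,
                                   scale=float(rng.uniform(1.0, 3.0)))
        for m in modes
    }
    emissions = {
        m: {"v": dists.make_distribution(
            "gaussian_mixture", w1=0.5,
            mu1=float(rng.normal(i * spread, 0.3)), s1=0.8,
            mu2=float(rng.normal(i * spread + 1.0, 0.3)), s2=0.8)}
        for i, m in enumerate(modes)
    }
    return mm.HSMMModel(modes=modes, pi=pi, A_distinct=A, durations=durations,
                        emissions=emissions, variables=["v"],
                        d_max_steps=d_max_steps)


def random_features(rng, T):
    return pd.DataFrame({"v": rng.normal(1.5, 2.0, size=T),
                         "dt": np.ones(T)})


# ---------------------------------------------------------------------------
# exhaustive-enumeration oracles, independent of the DP decoders
# ---------------------------------------------------------------------------

def brute_force_hmm_path(model, features):
    """Argmax over all M^T state sequences of the joint log-likelihood,
    computed directly from the model definition."""
    import itertools

    E = mm.emission_loglik_matrix(model, features)
    T, M = E.shape
    logpi = np.log(model.pi)
    with np.errstate(divide="ignore"):
        logA = np.log(model.A)
    best, best_path = -np.inf, None
    for path in itertools.product(range(M), repeat=T):
        ll = logpi[path[0]] + E[0, path[0]]
        for t in range(1, T):
            ll += logA[path[t - 1], path[t]] + E[t, path[t]]
        if ll > best:
            best, best_path = ll, path
    return [model.modes[i] for i in best_path], best


def brute_force_hsmm_path(model, features):
    """Argmax over all labelled state sequences, scored segment-wise with
    duration densities and the survival of the final segment.  Requires
    unit step durations (duration tables are indexed by run length)."""
    import itertools

    E = mm.emission_loglik_matrix(model, features)
    T, M = E.shape
    dt = features["dt"].to_numpy(dtype=float)
    assert np.allclose(dt, dt[0])
    durs = dt[0] * np.arange(1, T + 1)
    logd = np.array([model.durations[m].logpdf(durs) for m in model.modes])
    logs = np.array([model.durations[m].log_sf(durs) for m in model.modes])
    logpi = np.log(model.pi)
    with np.errstate(divide="ignore"):
        logA = np.log(model.A_distinct)
    best, best_path = -np.inf, None
    for path in itertools.product(range(M), repeat=T):
        segs = []
        start = 0
        for t in range(1, T + 1):
            if t == T or path[t] != path[start]:
                segs.append((path[start], start, t - start))
                start = t
        if any(u > model.d_max_steps for _, _, u in segs):
            continue
        ll = logpi[segs[0][0]]
        for r, (j, s, u) in enumerate(segs):
            ll += E[s:s + u, j].sum()
            if r < len(segs) - 1:
                ll += logd[j, u - 1] + logA[j, segs[r + 1][0]]
            else:
                ll += logs[j, u - 1]
        if ll > best:
            best, best_path = ll, path
    return [model.modes[i] for i in best_path], best
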