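"""Univariate distribution families for state-conditional emissions and
state durations.

The families are those used for the fishery behavioural-mode analysis
(generalized Pareto, GEV, Gaussian mixture, uniform, wrapped Cauchy,
Laplace-Gaussian mixture, Kumaraswamy, Beta, loglogistic, Laplace,
Student's t, Gumbel, lognormal) plus the usual positive-support duration
candidates (gamma, Weibull, exponential) and two families used only in
model construction and testing (a point mass and a discrete geometric over
steps).

Everything is accessed through :class:`FittedDistribution`, which carries
the family name, the estimated parameters, an optional affine rescale map
(used where a bounded-support family such as Beta or Kumaraswamy is fitted
to data transformed to [0, 1]), and the fit log-likelihood.  Fitting is by
maximum likelihood (closed form where it exists, numerical otherwise);
goodness of fit is checked with the Cramér-von Mises statistic under a
parametric bootstrap, and model selection among non-rejected candidates is
by AIC.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy import optimize, special, stats

from .utils import wrap_to_pi

logger = logging.getLogger(__name__)

_LOG_TINY = -745.0  # log of the smallest positive double, used to floor log-probabilities

CIRCULAR = "circular"


@dataclass(frozen=True)
class Rescale:
    """Affine map raw -> native support: z = (x - loc) / scale."""

    loc: float
    scale: float

    def forward(self, x):
        return (np.asarray(x, dtype=float) - self.loc) / self.scale

    def backward(self, z):
        return self.loc + self.scale * np.asarray(z, dtype=float)


@dataclass(frozen=True)
class FittedDistribution:
    """A parameterised univariate distribution on an interval or the circle."""

    family: str
    params: dict
    support: tuple | str
    rescale: Rescale | None = None
    loglik: float = float("nan")
    n: int = 0

    # -- basic interface -------------------------------------------------
    @property
    def n_params(self) -> int:
        return _FAMILIES[self.family].n_params

    @property
    def aic(self) -> float:
        return 2.0 * self.n_params - 2.0 * self.loglik

    def _fwd(self, x):
        return self.rescale.forward(x) if self.rescale is not None else np.asarray(x, dtype=float)

    def logpdf(self, x):
        fam = _FAMILIES[self.family]
        z = self._fwd(x)
        out = fam.logpdf(self.params, z)
        if self.rescale is not None:
            out = out - math.log(self.rescale.scale)
        return out

    def pdf(self, x):
        return np.exp(self.logpdf(x))

    def cdf(self, x):
        fam = _FAMILIES[self.family]
        return fam.cdf(self.params, self._fwd(x))

    def sf(self, x):
        return 1.0 - self.cdf(x)

    def log_sf(self, x):
        """log P(X >= x); used as the survival score of a right-censored
        final segment.  Families with discrete support override the
        continuous 1 - cdf form so that P(X >= x) is inclusive."""
        fam = _FAMILIES[self.family]
        if fam.log_sf is not None:
            return fam.log_sf(self.params, self._fwd(x))
        with np.errstate(divide="ignore"):
            return np.maximum(np.log(np.clip(self.sf(x), 0.0, 1.0)), _LOG_TINY)

    def rvs(self, size, rng: np.random.Generator):
        fam = _FAMILIES[self.family]
        z = fam.rvs(self.params, size, rng)
        x = self.rescale.backward(z) if self.rescale is not None else z
        return np.asarray(x, dtype=float)

    def mean(self) -> float:
        fam = _FAMILIES[self.family]
        m = fam.mean(self.params)
        if self.rescale is not None:
            m = self.rescale.loc + self.rescale.scale * m
        return float(m)

    def raw_support(self) -> tuple | str:
        """Support on the raw data scale."""
        if self.support == CIRCULAR or self.rescale is None:
            return self.support
        lo, hi = self.support
        a = self.rescale.backward(lo) if np.isfinite(lo) else math.copysign(math.inf, lo)
        b = self.rescale.backward(hi) if np.isfinite(hi) else math.copysign(math.inf, hi)
        return (float(a), float(b))

    # -- (de)serialisation -----------------------------------------------
    def to_dict(self) -> dict:
        d = {
            "family": self.family,
            "params": {k: float(v) for k, v in self.params.items()},
            "support": list(self.support) if self.support != CIRCULAR else CIRCULAR,
            "loglik": float(self.loglik),
            "n": int(self.n),
        }
        if self.rescale is not None:
            d["rescale"] = {"loc": self.rescale.loc, "scale": self.rescale.scale}
        return d

    @staticmethod
    def from_dict(d: dict) -> "FittedDistribution":
        rescale = None
        if d.get("rescale") is not None:
            rescale = Rescale(loc=float(d["rescale"]["loc"]), scale=float(d["rescale"]["scale"]))
        support = d["support"]
        if support != CIRCULAR:
            support = tuple(float(v) for v in support)
        return FittedDistribution(
            family=d["family"],
            params={k: float(v) for k, v in d["params"].items()},
            support=support,
            rescale=rescale,
            loglik=float(d.get("loglik", float("nan"))),
            n=int(d.get("n", 0)),
        )


@dataclass(frozen=True)
class GofResult:
    """Cramér-von Mises goodness-of-fit outcome with a bootstrap p-value."""

    statistic: float
    p_value: float
    n_boot: int
    rejected: bool
    alpha: float


@dataclass
class _Family:
    name: str
    n_params: int
    support: Callable[[dict], tuple] | tuple | str
    fit: Callable
    logpdf: Callable
    cdf: Callable
    rvs: Callable
    mean: Callable
    needs_unit_rescale: bool = False
    log_sf: Callable | None = None

    def support_of(self, params) -> tuple | str:
        if callable(self.support):
            return self.support(params)
        return self.support


_FAMILIES: dict[str, _Family] = {}


def _register(fam: _Family):
    _FAMILIES[fam.name] = fam
    return fam


def available_families() -> list[str]:
    return sorted(_FAMILIES)


# ---------------------------------------------------------------------------
# scipy-backed families
# ---------------------------------------------------------------------------

def _scipy_logpdf(dist, order):
    def f(params, z):
        return dist.logpdf(z, *[params[k] for k in order])
    return f


def _scipy_cdf(dist, order):
    def f(params, z):
        return dist.cdf(z, *[params[k] for k in order])
    return f


def _scipy_rvs(dist, order):
    def f(params, size, rng):
        return dist.rvs(*[params[k] for k in order], size=size, random_state=rng)
    return f


def _scipy_mean(dist, order):
    def f(params):
        return dist.mean(*[params[k] for k in order])
    return f


def _loglik(logpdf, params, z) -> float:
    ll = logpdf(params, np.asarray(z, dtype=float))
    ll = np.asarray(ll, dtype=float)
    if not np.all(np.isfinite(ll)):
        raise FitError("non-finite log-density at data points")
    return float(np.sum(ll))


class FitError(RuntimeError):
    """Raised when maximum-likelihood fitting fails or is ill-posed."""


def _require_spread(z):
    if np.ptp(z) <= 0.0:
        raise FitError("degenerate (zero-variance) data for a family requiring spread")


def _fit_scipy(dist, order, **fixed):
    def fit(z, rng=None):
        _require_spread(z)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = dist.fit(z, **fixed)
        params = dict(zip(order, est))
        return params
    return fit


def _make_scipy_family(name, dist, order, support, fit=None, mean=None,
                       needs_unit_rescale=False):
    return _register(_Family(
        name=name,
        n_params=len(order),
        support=support,
        fit=fit or _fit_scipy(dist, order),
        logpdf=_scipy_logpdf(dist, order),
        cdf=_scipy_cdf(dist, order),
        rvs=_scipy_rvs(dist, order),
        mean=mean or _scipy_mean(dist, order),
        needs_unit_rescale=needs_unit_rescale,
    ))


# generalized Pareto: threshold (loc) pinned just below the sample minimum --
# free-location ML for the GPD is ill-posed (likelihood unbounded as the
# threshold approaches the minimum).
def _fit_genpareto(z, rng=None):
    _require_spread(z)
    loc = float(np.min(z)) - 1e-9 * max(1.0, float(np.ptp(z)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        c, loc_, scale = stats.genpareto.fit(z, floc=loc)
    return {"c": float(c), "loc": float(loc_), "scale": float(scale)}


_make_scipy_family(
    "genpareto", stats.genpareto, ("c", "loc", "scale"),
    support=lambda p: (p["loc"], math.inf) if p["c"] >= 0
    else (p["loc"], p["loc"] - p["scale"] / p["c"]),
    fit=_fit_genpareto,
)

_make_scipy_family(
    "gev", stats.genextreme, ("c", "loc", "scale"),
    # scipy's c is minus the usual shape xi; support is bounded on one side
    support=lambda p: ((p["loc"] - p["scale"] / -p["c"], math.inf) if p["c"] < 0
                       else (-math.inf, math.inf) if p["c"] == 0
                       else (-math.inf, p["loc"] + p["scale"] / p["c"])),
)


def _fit_uniform(z, rng=None):
    _require_spread(z)
    lo = float(np.min(z))
    hi = float(np.max(z))
    return {"loc": lo, "scale": hi - lo}


_make_scipy_family(
    "uniform", stats.uniform, ("loc", "scale"),
    support=lambda p: (p["loc"], p["loc"] + p["scale"]),
    fit=_fit_uniform,
)


def _fit_laplace(z, rng=None):
    _require_spread(z)
    loc = float(np.median(z))
    scale = float(np.mean(np.abs(z - loc)))
    return {"loc": loc, "scale": scale}


_make_scipy_family(
    "laplace", stats.laplace, ("loc", "scale"),
    support=(-math.inf, math.inf), fit=_fit_laplace,
)

_make_scipy_family(
    "gumbel", stats.gumbel_r, ("loc", "scale"),
    support=(-math.inf, math.inf),
)


def _fit_student_t(z, rng=None):
    _require_spread(z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        df, loc, scale = stats.t.fit(z)
        if not 1.0 <= df <= 100.0:
            df = float(np.clip(df, 1.0, 100.0))
            df, loc, scale = stats.t.fit(z, f0=df)
    return {"df": float(df), "loc": float(loc), "scale": float(scale)}


_make_scipy_family(
    "student_t", stats.t, ("df", "loc", "scale"),
    support=(-math.inf, math.inf), fit=_fit_student_t,
)


def _fit_lognormal(z, rng=None):
    z = np.asarray(z, dtype=float)
    if np.any(z <= 0):
        raise FitError("lognormal requires strictly positive data")
    _require_spread(z)
    logz = np.log(z)
    s = float(np.std(logz))  # ML uses the biased (1/n) variance
    if s <= 0:
        raise FitError("degenerate data for lognormal")
    return {"s": s, "loc": 0.0, "scale": float(np.exp(np.mean(logz)))}


_make_scipy_family(
    "lognormal", stats.lognorm, ("s", "loc", "scale"),
    support=(0.0, math.inf), fit=_fit_lognormal,
)
_FAMILIES["lognormal"].n_params = 2  # loc fixed at 0

_make_scipy_family(
    "loglogistic", stats.fisk, ("c", "loc", "scale"),
    support=(0.0, math.inf),
    fit=_fit_scipy(stats.fisk, ("c", "loc", "scale"), floc=0.0),
)
_FAMILIES["loglogistic"].n_params = 2

_make_scipy_family(
    "gamma", stats.gamma, ("a", "loc", "scale"),
    support=(0.0, math.inf),
    fit=_fit_scipy(stats.gamma, ("a", "loc", "scale"), floc=0.0),
)
_FAMILIES["gamma"].n_params = 2

_make_scipy_family(
    "weibull", stats.weibull_min, ("c", "loc", "scale"),
    support=(0.0, math.inf),
    fit=_fit_scipy(stats.weibull_min, ("c", "loc", "scale"), floc=0.0),
)
_FAMILIES["weibull"].n_params = 2


def _fit_expon(z, rng=None):
    z = np.asarray(z, dtype=float)
    if np.any(z < 0):
        raise FitError("exponential requires non-negative data")
    return {"loc": 0.0, "scale": float(np.mean(z))}


_make_scipy_family(
    "exponential", stats.expon, ("loc", "scale"),
    support=(0.0, math.inf), fit=_fit_expon,
)
_FAMILIES["exponential"].n_params = 1

# Generalized Pareto anchored at the origin: the right shape for duration
# data, whose support is all of (0, inf) — a data-dependent positive
# threshold would declare short segments impossible.
_make_scipy_family(
    "genpareto_zero", stats.genpareto, ("c", "loc", "scale"),
    support=lambda p: (0.0, math.inf) if p["c"] >= 0
    else (0.0, -p["scale"] / p["c"]),
    fit=_fit_scipy(stats.genpareto, ("c", "loc", "scale"), floc=0.0),
)
_FAMILIES["genpareto_zero"].n_params = 2


def _fit_beta(z, rng=None):
    z = np.asarray(z, dtype=float)
    _require_spread(z)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        a, b, loc, scale = stats.beta.fit(z, floc=0.0, fscale=1.0)
    return {"a": float(a), "b": float(b), "loc": 0.0, "scale": 1.0}


_make_scipy_family(
    "beta", stats.beta, ("a", "b", "loc", "scale"),
    support=(0.0, 1.0), fit=_fit_beta, needs_unit_rescale=True,
)
_FAMILIES["beta"].n_params = 2  # loc/scale are fixed, not estimated


# ---------------------------------------------------------------------------
# hand-rolled families
# ---------------------------------------------------------------------------

# Kumaraswamy on (0, 1): f(z) = a b z^(a-1) (1 - z^a)^(b-1)
def _kuma_logpdf(params, z):
    a, b = params["a"], params["b"]
    z = np.asarray(z, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        za = np.power(np.clip(z, 1e-300, 1.0), a)
        out = (math.log(a) + math.log(b) + (a - 1.0) * np.log(z)
               + (b - 1.0) * np.log1p(-np.clip(za, 0.0, 1.0 - 1e-16)))
    return np.where((z > 0) & (z < 1), out, -np.inf)


def _kuma_cdf(params, z):
    a, b = params["a"], params["b"]
    z = np.clip(np.asarray(z, dtype=float), 0.0, 1.0)
    return 1.0 - np.power(1.0 - np.power(z, a), b)


def _kuma_rvs(params, size, rng):
    a, b = params["a"], params["b"]
    u = rng.uniform(size=size)
    return np.power(1.0 - np.power(1.0 - u, 1.0 / b), 1.0 / a)


def _kuma_mean(params):
    a, b = params["a"], params["b"]
    return b * special.beta(1.0 + 1.0 / a, b)


def _fit_kumaraswamy(z, rng=None):
    z = np.asarray(z, dtype=float)
    _require_spread(z)
    z = np.clip(z, 1e-9, 1.0 - 1e-9)

    def nll(theta):
        params = {"a": math.exp(theta[0]), "b": math.exp(theta[1])}
        return -float(np.sum(_kuma_logpdf(params, z)))

    res = optimize.minimize(nll, x0=[0.0, 0.0], method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        raise FitError(f"Kumaraswamy ML did not converge: {res.message}")
    return {"a": math.exp(res.x[0]), "b": math.exp(res.x[1])}


_register(_Family(
    name="kumaraswamy", n_params=2, support=(0.0, 1.0),
    fit=_fit_kumaraswamy, logpdf=_kuma_logpdf, cdf=_kuma_cdf,
    rvs=_kuma_rvs, mean=_kuma_mean, needs_unit_rescale=True,
))


# Wrapped Cauchy on (-pi, pi]: f(x) = (1 - rho^2) / (2 pi (1 + rho^2 - 2 rho cos(x - mu)))
def _wc_logpdf(params, z):
    mu, rho = params["mu"], params["rho"]
    z = np.asarray(z, dtype=float)
    dens = (1.0 - rho ** 2) / (2.0 * np.pi * (1.0 + rho ** 2 - 2.0 * rho * np.cos(z - mu)))
    return np.log(dens)


def _wc_cdf(params, z):
    # CDF on (-pi, pi] with the cut at -pi, via the centred distribution on [0, 2pi)
    mu, rho = params["mu"], params["rho"]
    z = wrap_to_pi(np.asarray(z, dtype=float))
    y = np.mod(z - mu, 2.0 * np.pi)
    ym = np.mod(-np.pi - mu, 2.0 * np.pi)
    g = stats.wrapcauchy.cdf(y, rho)
    gm = stats.wrapcauchy.cdf(ym, rho)
    out = np.where(y >= ym, g - gm, 1.0 - (gm - g))
    out = np.where(z == np.pi, 1.0, out)  # upper endpoint closes the circle
    return np.clip(out, 0.0, 1.0)


def _wc_rvs(params, size, rng):
    mu, rho = params["mu"], params["rho"]
    w = stats.wrapcauchy.rvs(rho, size=size, random_state=rng)
    return wrap_to_pi(mu + w)


def _fit_wrapped_cauchy(z, rng=None):
    z = wrap_to_pi(np.asarray(z, dtype=float))
    _require_spread(z)
    c, s = float(np.mean(np.cos(z))), float(np.mean(np.sin(z)))
    mu0 = math.atan2(s, c)
    rbar = min(math.hypot(c, s), 0.999)  # for the wrapped Cauchy, E[Rbar] = rho

    def nll(theta):
        mu = theta[0]
        rho = 1.0 / (1.0 + math.exp(-theta[1]))  # logistic: rho in (0, 1)
        return -float(np.sum(_wc_logpdf({"mu": mu, "rho": rho}, z)))

    t0 = [mu0, math.log(max(rbar, 1e-3) / max(1.0 - rbar, 1e-3))]
    res = optimize.minimize(nll, x0=t0, method="Nelder-Mead",
                            options={"xatol": 1e-8, "fatol": 1e-10, "maxiter": 2000})
    if not res.success:
        raise FitError(f"wrapped Cauchy ML did not converge: {res.message}")
    return {"mu": wrap_to_pi(res.x[0]), "rho": 1.0 / (1.0 + math.exp(-res.x[1]))}


_register(_Family(
    name="wrapped_cauchy", n_params=2, support=CIRCULAR,
    fit=_fit_wrapped_cauchy, logpdf=_wc_logpdf, cdf=_wc_cdf,
    rvs=_wc_rvs, mean=lambda p: p["mu"],
))


# ---------------------------------------------------------------------------
# two-component mixtures
# ---------------------------------------------------------------------------

_EM_RESTARTS = 10
_EM_TOL = 1e-6
_EM_MAX_ITER = 500


def _norm_logpdf(x, mu, sd):
    return -0.5 * ((x - mu) / sd) ** 2 - math.log(sd) - 0.5 * math.log(2.0 * math.pi)


def _laplace_logpdf_np(x, loc, b):
    return -np.abs(x - loc) / b - math.log(2.0 * b)


def _gm_logpdf(params, z):
    z = np.asarray(z, dtype=float)
    l1 = math.log(params["w1"]) + _norm_logpdf(z, params["mu1"], params["s1"])
    l2 = math.log(1.0 - params["w1"]) + _norm_logpdf(z, params["mu2"], params["s2"])
    return np.logaddexp(l1, l2)


def _gm_cdf(params, z):
    z = np.asarray(z, dtype=float)
    return (params["w1"] * stats.norm.cdf(z, params["mu1"], params["s1"])
            + (1.0 - params["w1"]) * stats.norm.cdf(z, params["mu2"], params["s2"]))


def _gm_rvs(params, size, rng):
    n = int(np.prod(size)) if not np.isscalar(size) else int(size)
    comp = rng.uniform(size=n) < params["w1"]
    out = np.where(comp,
                   rng.normal(params["mu1"], params["s1"], size=n),
                   rng.normal(params["mu2"], params["s2"], size=n))
    return out.reshape(size) if not np.isscalar(size) else out


def _gm_mean(params):
    return params["w1"] * params["mu1"] + (1.0 - params["w1"]) * params["mu2"]


def _em_two_component(z, logpdf_comp1, mstep1, logpdf_comp2, mstep2, init, rng):
    """Generic 2-component EM with k-means-style initialisation and restarts."""
    z = np.asarray(z, dtype=float)
    n = z.size
    rng = rng if rng is not None else np.random.default_rng(0)
    best = None
    for restart in range(_EM_RESTARTS):
        p1, p2, w = init(z, rng, restart)
        ll_old = -np.inf
        for _ in range(_EM_MAX_ITER):
            l1 = math.log(max(w, 1e-12)) + logpdf_comp1(z, p1)
            l2 = math.log(max(1.0 - w, 1e-12)) + logpdf_comp2(z, p2)
            tot = np.logaddexp(l1, l2)
            ll = float(np.sum(tot))
            r1 = np.exp(l1 - tot)
            w = float(np.mean(r1))
            if w < 1e-6 or w > 1.0 - 1e-6:
                break
            p1 = mstep1(z, r1)
            p2 = mstep2(z, 1.0 - r1)
            if abs(ll - ll_old) < _EM_TOL * max(1.0, abs(ll)):
                break
            ll_old = ll
        if best is None or ll > best[0]:
            best = (ll, w, p1, p2)
    if best is None or not np.isfinite(best[0]):
        raise FitError("mixture EM failed to converge")
    return best


def _kmeans_two_split(z, rng, restart):
    z = np.sort(z)
    if restart == 0:
        cut = float(np.median(z))
    else:
        cut = float(rng.uniform(np.quantile(z, 0.2), np.quantile(z, 0.8)))
    lo = z[z <= cut]
    hi = z[z > cut]
    if lo.size < 2 or hi.size < 2:
        half = z.size // 2
        lo, hi = z[:half], z[half:]
    return lo, hi


def _fit_gaussian_mixture(z, rng=None):
    _require_spread(z)

    def init(z, rng, restart):
        lo, hi = _kmeans_two_split(z, rng, restart)
        p1 = (float(np.mean(lo)), max(float(np.std(lo)), 1e-3))
        p2 = (float(np.mean(hi)), max(float(np.std(hi)), 1e-3))
        return p1, p2, lo.size / z.size

    def logpdf_n(z, p):
        return _norm_logpdf(z, p[0], p[1])

    def mstep_n(z, r):
        sw = np.sum(r)
        mu = float(np.sum(r * z) / sw)
        sd = max(math.sqrt(float(np.sum(r * (z - mu) ** 2) / sw)), 1e-6)
        return (mu, sd)

    ll, w, p1, p2 = _em_two_component(z, logpdf_n, mstep_n, logpdf_n, mstep_n, init, rng)
    if p1[0] > p2[0]:  # canonical order: component 1 has the smaller mean
        p1, p2, w = p2, p1, 1.0 - w
    return {"w1": w, "mu1": p1[0], "s1": p1[1], "mu2": p2[0], "s2": p2[1]}


_register(_Family(
    name="gaussian_mixture", n_params=5, support=(-math.inf, math.inf),
    fit=_fit_gaussian_mixture, logpdf=_gm_logpdf, cdf=_gm_cdf,
    rvs=_gm_rvs, mean=_gm_mean,
))


def _lgm_logpdf(params, z):
    z = np.asarray(z, dtype=float)
    l1 = math.log(params["w_l"]) + _laplace_logpdf_np(z, params["loc_l"], params["b_l"])
    l2 = math.log(1.0 - params["w_l"]) + _norm_logpdf(z, params["mu_g"], params["s_g"])
    return np.logaddexp(l1, l2)


def _lgm_cdf(params, z):
    z = np.asarray(z, dtype=float)
    return (params["w_l"] * stats.laplace.cdf(z, params["loc_l"], params["b_l"])
            + (1.0 - params["w_l"]) * stats.norm.cdf(z, params["mu_g"], params["s_g"]))


def _lgm_rvs(params, size, rng):
    n = int(np.prod(size)) if not np.isscalar(size) else int(size)
    comp = rng.uniform(size=n) < params["w_l"]
    out = np.where(comp,
                   rng.laplace(params["loc_l"], params["b_l"], size=n),
                   rng.normal(params["mu_g"], params["s_g"], size=n))
    return out.reshape(size) if not np.isscalar(size) else out


def _fit_laplace_gaussian_mixture(z, rng=None):
    """Mixture of one Laplace and one Gaussian component, fitted by EM."""
    _require_spread(z)

    def init(z, rng, restart):
        lo, hi = _kmeans_two_split(z, rng, restart)
        p_l = (float(np.median(lo)), max(float(np.mean(np.abs(lo - np.median(lo)))), 1e-3))
        p_g = (float(np.mean(hi)), max(float(np.std(hi)), 1e-3))
        return p_l, p_g, lo.size / z.size

    def logpdf_l(z, p):
        return _laplace_logpdf_np(z, p[0], p[1])

    def mstep_l(z, r):
        # weighted median and weighted mean absolute deviation
        order = np.argsort(z)
        cw = np.cumsum(r[order])
        loc = float(z[order][np.searchsorted(cw, cw[-1] / 2.0)])
        b = max(float(np.sum(r * np.abs(z - loc)) / np.sum(r)), 1e-6)
        return (loc, b)

    def logpdf_g(z, p):
        return _norm_logpdf(z, p[0], p[1])

    def mstep_g(z, r):
        sw = np.sum(r)
        mu = float(np.sum(r * z) / sw)
        sd = max(math.sqrt(float(np.sum(r * (z - mu) ** 2) / sw)), 1e-6)
        return (mu, sd)

    ll, w, p_l, p_g = _em_two_component(z, logpdf_l, mstep_l, logpdf_g, mstep_g, init, rng)
    return {"w_l": w, "loc_l": p_l[0], "b_l": p_l[1], "mu_g": p_g[0], "s_g": p_g[1]}


def _lgm_mean(params):
    return params["w_l"] * params["loc_l"] + (1.0 - params["w_l"]) * params["mu_g"]


_register(_Family(
    name="laplace_gaussian_mixture", n_params=5, support=(-math.inf, math.inf),
    fit=_fit_laplace_gaussian_mixture, logpdf=_lgm_logpdf, cdf=_lgm_cdf,
    rvs=_lgm_rvs, mean=_lgm_mean,
))


# ---------------------------------------------------------------------------
# degenerate / discrete families (model construction and testing only)
# ---------------------------------------------------------------------------

def _pm_logpdf(params, z):
    z = np.asarray(z, dtype=float)
    tol = 1e-9 * max(1.0, abs(params["value"]))
    return np.where(np.abs(z - params["value"]) <= tol, 0.0, -np.inf)


def _pm_log_sf(params, z):
    z = np.asarray(z, dtype=float)
    tol = 1e-9 * max(1.0, abs(params["value"]))
    return np.where(z <= params["value"] + tol, 0.0, -np.inf)


_register(_Family(
    name="point_mass", n_params=1,
    support=lambda p: (p["value"], p["value"]),
    fit=lambda z, rng=None: {"value": float(np.mean(z))},
    logpdf=_pm_logpdf,
    cdf=lambda p, z: np.where(np.asarray(z, dtype=float) >= p["value"], 1.0, 0.0),
    rvs=lambda p, size, rng: np.full(size, p["value"], dtype=float),
    mean=lambda p: p["value"],
    log_sf=_pm_log_sf,
))


# Discrete geometric over steps of length step_hours: P(K = k) = p (1-p)^(k-1).
# Used for the classical HSMM/HMM equivalence (geometric durations with
# parameter p reproduce an HMM with self-transition 1 - p); its survival is
# the inclusive P(K >= k) = (1-p)^(k-1).
def _geo_k(params, z):
    return np.maximum(np.round(np.asarray(z, dtype=float) / params["step_hours"]), 1.0)


def _geo_logpdf(params, z):
    p = params["p"]
    k = _geo_k(params, z)
    return math.log(p) + (k - 1.0) * math.log1p(-p)


def _geo_log_sf(params, z):
    k = _geo_k(params, z)
    return (k - 1.0) * math.log1p(-params["p"])


_register(_Family(
    name="geometric_steps", n_params=1,
    support=(0.0, math.inf),
    fit=lambda z, rng=None: {
        "p": 1.0 / float(np.mean(np.maximum(np.round(np.asarray(z) / np.min(z)), 1.0))),
        "step_hours": float(np.min(z)),
    },
    logpdf=_geo_logpdf,
    cdf=lambda p, z: 1.0 - np.exp(_geo_k(p, z) * math.log1p(-p["p"])),
    rvs=lambda p, size, rng: rng.geometric(p["p"], size=size) * p["step_hours"],
    mean=lambda p: p["step_hours"] / p["p"],
    log_sf=_geo_log_sf,
))


# ---------------------------------------------------------------------------
# public operations
# ---------------------------------------------------------------------------

def make_distribution(family: str, rescale: Rescale | None = None,
                      **params) -> FittedDistribution:
    """Construct a distribution from explicit parameters (no data)."""
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {available_families()}")
    fam = _FAMILIES[family]
    params = {k: float(v) for k, v in params.items()}
    return FittedDistribution(family=family, params=params,
                              support=fam.support_of(params), rescale=rescale)


def fit_ml(family: str, data, rng: np.random.Generator | None = None) -> FittedDistribution:
    """Supervised maximum-likelihood fit of one family to a sample.

    Closed-form estimators are used where they exist; otherwise numerical
    optimisation (or EM for the two-component mixtures).  For the
    unit-interval families (Beta, Kumaraswamy) the data are first mapped
    affinely to [0, 1] and the map is stored with the fit so densities
    include the Jacobian.
    """
    if family not in _FAMILIES:
        raise ValueError(f"unknown family {family!r}; choose from {available_families()}")
    fam = _FAMILIES[family]
    x = np.asarray(data, dtype=float)
    x = x[np.isfinite(x)]
    if x.size < 10:
        raise FitError(f"need at least 10 observations to fit {family!r}, got {x.size}")

    rescale = None
    z = x
    if fam.needs_unit_rescale and (np.min(x) < 0.0 or np.max(x) > 1.0):
        lo, hi = float(np.min(x)), float(np.max(x))
        if hi <= lo:
            raise FitError("degenerate data cannot be rescaled to [0, 1]")
        # widen slightly so the extremes fall strictly inside (0, 1)
        pad = 1e-6 * (hi - lo)
        rescale = Rescale(loc=lo - pad, scale=(hi - lo) + 2.0 * pad)
        z = rescale.forward(x)

    if (not callable(fam.support)) and fam.support == CIRCULAR:
        z = wrap_to_pi(z)

    params = fam.fit(z, rng)
    ll = _loglik(fam.logpdf, params, z)
    if rescale is not None:
        ll -= x.size * math.log(rescale.scale)
    return FittedDistribution(family=family, params=params,
                              support=fam.support_of(params), rescale=rescale,
                              loglik=ll, n=int(x.size))


def cvm_statistic(data, dist: FittedDistribution) -> float:
    """Cramér-von Mises W^2 = 1/(12n) + sum_i (u_(i) - (2i-1)/(2n))^2."""
    x = np.sort(np.asarray(data, dtype=float))
    n = x.size
    u = np.clip(np.asarray(dist.cdf(x), dtype=float), 0.0, 1.0)
    i = np.arange(1, n + 1)
    return float(1.0 / (12.0 * n) + np.sum((u - (2.0 * i - 1.0) / (2.0 * n)) ** 2))


def cvm_gof(data, dist: FittedDistribution, n_boot: int = 200, alpha: float = 0.05,
            rng: np.random.Generator | None = None) -> GofResult:
    """Cramér-von Mises goodness of fit with a parametric-bootstrap p-value.

    Each bootstrap replicate redraws a sample of the original size from the
    fitted distribution, refits the same family, and recomputes W^2, so the
    p-value accounts for parameter estimation.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    x = np.asarray(data, dtype=float)
    x = x[np.isfinite(x)]
    if n_boot < 100:
        warnings.warn(f"n_boot={n_boot} < 100 gives a coarse p-value", stacklevel=2)
    w_obs = cvm_statistic(x, dist)
    exceed = 0
    done = 0
    for _ in range(n_boot):
        xb = dist.rvs(x.size, rng)
        try:
            db = fit_ml(dist.family, xb, rng=rng)
        except FitError:
            continue
        done += 1
        if cvm_statistic(xb, db) >= w_obs:
            exceed += 1
    p = (1.0 + exceed) / (1.0 + max(done, 1))
    return GofResult(statistic=w_obs, p_value=float(p), n_boot=done,
                     rejected=bool(p < alpha), alpha=alpha)


def select_family(candidates, data, alpha: float = 0.05, n_boot: int = 200,
                  rng: np.random.Generator | None = None) -> FittedDistribution:
    """Fit all candidate families, drop those rejected by the CvM test, and
    return the minimum-AIC fit among the survivors.

    With ``n_boot=0`` the goodness-of-fit screen is skipped and selection is
    by AIC alone.  If every candidate is rejected the overall minimum-AIC
    fit is returned with a logged warning.
    """
    if not candidates:
        raise ValueError("need at least one candidate family")
    rng = rng if rng is not None else np.random.default_rng(0)
    fits: list[FittedDistribution] = []
    kept: list[FittedDistribution] = []
    errors: list[str] = []
    for family in candidates:
        try:
            fit = fit_ml(family, data, rng=rng)
        except (FitError, ValueError) as exc:
            errors.append(f"{family}: {exc}")
            continue
        fits.append(fit)
        if n_boot > 0:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                gof = cvm_gof(data, fit, n_boot=n_boot, alpha=alpha, rng=rng)
            if not gof.rejected:
                kept.append(fit)
        else:
            kept.append(fit)
    if not fits:
        raise FitError("all candidate fits failed numerically: " + "; ".join(errors))
    pool = kept
    if not pool:
        logger.warning("all candidates rejected by the CvM test; "
                       "falling back to the overall minimum-AIC fit")
        pool = fits
    return min(pool, key=lambda f: f.aic)
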