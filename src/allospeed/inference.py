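"""Bayesian fitting of the travel-speed models.

The data model is a Gaussian likelihood on base-10 log speed:

    log10(v_i) ~ Normal( log10 f(M_i, theta), sigma )

with ``f`` one of the three process models (power-law, saturating,
hump-shaped), ``v0`` always fitted independently per locomotion mode, and the
heat-dissipation constant / ``c`` exponent pooled or grouped according to the
:class:`~allospeed.models.ModelSpec`.

Priors follow weakly informative families: half-normal on the exponents
``c`` and ``d``, gamma on the positive normalisation constants ``v0`` and
``k``, and half-Cauchy on ``sigma``.  All positive parameters are sampled on
the natural-log scale (with the Jacobian folded into the prior) because they
span orders of magnitude.

Sampling uses an affine-invariant ensemble MCMC (differential-evolution
moves).  The ensemble is initialised in a Laplace-scaled ball around a
multi-start posterior mode, run through an adaptation phase that is
discarded, and then thinned to the requested number of retained draws.
Walkers are treated as chains for rank-normalised split-R-hat and bulk
effective sample size; misses of the thresholds (r-hat <= 1.01,
ESS > 1000) are surfaced as :class:`ConvergenceWarning` and recorded on the
result, never silently ignored.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import arviz as az
import emcee
import numpy as np
import xarray as xr
from scipy import optimize, stats

from .data import SpeedRecord
from .exceptions import ConfigurationError, ConvergenceWarning
from .models import (
    LocomotionMode,
    ModelKind,
    ModelSpec,
    ParameterSet,
    Pooling,
    Realm,
    _ln_speed,
    log10_realised_speed,
)

__all__ = [
    "PriorConfig",
    "McmcConfig",
    "PosteriorResult",
    "fit",
    "pointwise_log_likelihood",
]

_LN10 = math.log(10.0)
_RHAT_THRESHOLD = 1.01
_ESS_THRESHOLD = 1000.0
#: internal ensemble moves per nominal sampling iteration (thinned away)
_OVERSAMPLE = 3


@dataclass(frozen=True)
class PriorConfig:
    """Hyperparameters of the prior families (all strictly positive).

    Defaults are diffuse enough to cover the plausible parameter space:
    gamma(1, 0.01) on ``v0`` spans ~0.01-300 m/s (flying rate constants are
    near 30, running near 0.3), gamma(1, 1) on the heat-dissipation
    constants, half-normal(1) on the exponents, half-Cauchy(2.5) on sigma.
    """

    c_scale: float = 1.0
    d_scale: float = 1.0
    v0_shape: float = 1.0
    v0_rate: float = 0.01
    k_shape: float = 1.0
    k_rate: float = 1.0
    sigma_scale: float = 2.5

    def __post_init__(self):
        for name, value in self.__dict__.items():
            if not value > 0:
                raise ConfigurationError(f"prior hyperparameter {name} must be > 0")

    def broadened(self, factor: float = 10.0) -> "PriorConfig":
        """Scaled-up priors for sensitivity checks (rates divided by factor)."""
        return PriorConfig(
            c_scale=self.c_scale * factor,
            d_scale=self.d_scale * factor,
            v0_shape=self.v0_shape,
            v0_rate=self.v0_rate / factor,
            k_shape=self.k_shape,
            k_rate=self.k_rate / factor,
            sigma_scale=self.sigma_scale * factor,
        )


@dataclass(frozen=True)
class McmcConfig:
    """Sampler protocol: 3 chains x (1500 adaptation + 3000 sampling) by
    default, retaining chains x sampling_iterations (= 9000) draws."""

    chains: int = 3
    warmup_iterations: int = 1500
    sampling_iterations: int = 3000
    seed: int = 0

    def __post_init__(self):
        for name in ("chains", "warmup_iterations", "sampling_iterations"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")

    @property
    def target_draws(self) -> int:
        return self.chains * self.sampling_iterations


# ---------------------------------------------------------------------------
# Parameter layout: maps a ModelSpec + dataset onto a flat log-scale vector.
# ---------------------------------------------------------------------------

class _ParamLayout:
    def __init__(self, spec: ModelSpec, records: Sequence[SpeedRecord]):
        self.spec = spec
        self.modes = [m for m in LocomotionMode if any(r.mode is m for r in records)]
        self.realms = [re for re in Realm if any(r.realm is re for r in records)]
        if not self.modes:
            raise ConfigurationError("dataset contains no records")
        for mode in self.modes:
            n = sum(r.mode is mode for r in records)
            if n < 2:
                raise ConfigurationError(
                    f"mode {mode.value!r} has {n} record(s); at least 2 are "
                    "required to fit its v0"
                )

        names: list[str] = []
        self.v0_col = {m: i for i, m in enumerate(self.modes)}
        names += [f"v0[{m.value}]" for m in self.modes]
        self.k_cols: dict[Realm, int] | None = None
        self.k_col: int | None = None
        if spec.uses_k:
            k_name = "k0" if spec.kind is ModelKind.CONSTANT_HD else "k_lambda"
            if spec.k_pooling is Pooling.BY_REALM:
                self.k_cols = {re: len(names) + i for i, re in enumerate(self.realms)}
                names += [f"{k_name}[{re.value}]" for re in self.realms]
            else:
                self.k_col = len(names)
                names.append(k_name)
        if spec.c_pooling is Pooling.BY_MODE:
            self.c_cols = {m: len(names) + i for i, m in enumerate(self.modes)}
            names += [f"c[{m.value}]" for m in self.modes]
            self.c_col = None
        else:
            self.c_col = len(names)
            self.c_cols = None
            names.append("c")
        self.d_col: int | None = None
        if spec.kind is ModelKind.ALLOMETRIC_HD:
            self.d_col = len(names)
            names.append("d")
        self.sigma_col = len(names)
        names.append("sigma")
        self.names = names
        self.ndim = len(names)

        # per-observation column indices
        mode_of = [r.mode for r in records]
        realm_of = [r.realm for r in records]
        self.obs_v0_col = np.array([self.v0_col[m] for m in mode_of])
        if self.c_cols is not None:
            self.obs_c_col = np.array([self.c_cols[m] for m in mode_of])
        else:
            self.obs_c_col = np.full(len(records), self.c_col)
        if spec.uses_k:
            if self.k_cols is not None:
                self.obs_k_col = np.array([self.k_cols[re] for re in realm_of])
            else:
                self.obs_k_col = np.full(len(records), self.k_col)
        else:
            self.obs_k_col = None

    # columns grouped by prior family
    @property
    def gamma_v0_cols(self):
        return np.array(sorted(self.v0_col.values()))

    @property
    def gamma_k_cols(self):
        if not self.spec.uses_k:
            return np.array([], dtype=int)
        if self.k_cols is not None:
            return np.array(sorted(self.k_cols.values()))
        return np.array([self.k_col])

    @property
    def halfnormal_c_cols(self):
        if self.c_cols is not None:
            return np.array(sorted(self.c_cols.values()))
        return np.array([self.c_col])


# ---------------------------------------------------------------------------
# Log posterior (vectorised over a batch of log-scale parameter vectors)
# ---------------------------------------------------------------------------

def _batch_mu_log10(theta: np.ndarray, layout: _ParamLayout, ln_mass: np.ndarray):
    """Expected log10 speed for each (parameter vector, observation) pair."""
    lv0 = theta[:, layout.obs_v0_col]  # (K, n)
    c = np.exp(theta[:, layout.obs_c_col])
    if layout.obs_k_col is not None:
        lk = theta[:, layout.obs_k_col]
    else:
        lk = 0.0
    d = np.exp(theta[:, layout.d_col])[:, None] if layout.d_col is not None else 0.0
    ln_v = _ln_speed(layout.spec.kind, ln_mass[None, :], lv0, lk, c, d)
    return ln_v / _LN10


def _log_prior(theta: np.ndarray, layout: _ParamLayout, priors: PriorConfig):
    """Unnormalised log prior density in the log-scale parameterisation
    (Jacobian terms included)."""
    lp = np.zeros(theta.shape[0])
    for cols, shape, rate in (
        (layout.gamma_v0_cols, priors.v0_shape, priors.v0_rate),
        (layout.gamma_k_cols, priors.k_shape, priors.k_rate),
    ):
        if cols.size:
            u = theta[:, cols]
            lp += np.sum(shape * u - rate * np.exp(u), axis=1)
    u = theta[:, layout.halfnormal_c_cols]
    lp += np.sum(u - np.exp(2 * u) / (2 * priors.c_scale**2), axis=1)
    if layout.d_col is not None:
        u = theta[:, layout.d_col]
        lp += u - np.exp(2 * u) / (2 * priors.d_scale**2)
    u = theta[:, layout.sigma_col]
    lp += u - np.log1p(np.exp(2 * u) / priors.sigma_scale**2)
    return lp


def _make_log_posterior(layout, priors, ln_mass, y):
    n = len(y)

    def log_post(theta):
        theta = np.atleast_2d(theta)
        with np.errstate(over="ignore"):
            lp = _log_prior(theta, layout, priors)
            mu = _batch_mu_log10(theta, layout, ln_mass)
            sigma = np.exp(theta[:, layout.sigma_col])
            resid = (y[None, :] - mu) / sigma[:, None]
            ll = (
                -0.5 * np.sum(resid**2, axis=1)
                - n * (np.log(sigma) + 0.5 * math.log(2 * math.pi))
            )
        out = lp + ll
        return np.where(np.isfinite(out), out, -np.inf)

    return log_post


# ---------------------------------------------------------------------------
# Result container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorResult:
    """Posterior draws (natural scale) with diagnostics and pointwise
    log-likelihoods.

    ``posterior[name]`` has shape (chain, draw); ``pointwise_loglik`` has
    shape (chain, draw, observation).
    """

    spec: ModelSpec
    param_names: list[str]
    posterior: Mapping[str, np.ndarray]
    rhat: Mapping[str, float]
    ess: Mapping[str, float]
    pointwise_loglik: np.ndarray
    warnings: list[str]
    mcmc: McmcConfig
    priors: PriorConfig
    n_obs: int
    map_estimate: Mapping[str, float] = field(default_factory=dict)

    @property
    def n_draws(self) -> int:
        first = self.posterior[self.param_names[0]]
        return first.shape[0] * first.shape[1]

    @property
    def converged(self) -> bool:
        return not self.warnings

    def flat(self, name: str) -> np.ndarray:
        return np.asarray(self.posterior[name]).reshape(-1)

    def means(self) -> dict[str, float]:
        return {n: float(self.flat(n).mean()) for n in self.param_names}

    def credible_interval(self, name: str, level: float = 0.9) -> tuple[float, float]:
        a = (1.0 - level) / 2.0
        lo, hi = np.quantile(self.flat(name), [a, 1.0 - a])
        return float(lo), float(hi)

    def flat_loglik(self) -> np.ndarray:
        """Pointwise log-likelihood as a (draws, observations) matrix."""
        return self.pointwise_loglik.reshape(-1, self.n_obs)

    def summary(self):
        import pandas as pd

        rows = []
        for name in self.param_names:
            x = self.flat(name)
            lo, hi = self.credible_interval(name)
            rows.append(
                {
                    "parameter": name,
                    "mean": x.mean(),
                    "sd": x.std(ddof=1),
                    "q5": lo,
                    "q95": hi,
                    "rhat": self.rhat[name],
                    "ess_bulk": self.ess[name],
                }
            )
        return pd.DataFrame(rows).set_index("parameter")

    def to_dataframe(self):
        """One row per retained draw, one column per parameter."""
        import pandas as pd

        nchain, ndraw = self.posterior[self.param_names[0]].shape
        frame = pd.DataFrame({n: self.flat(n) for n in self.param_names})
        frame.insert(0, "chain", np.repeat(np.arange(nchain), ndraw))
        frame.insert(1, "draw", np.tile(np.arange(ndraw), nchain))
        return frame

    def to_inference_data(self) -> az.InferenceData:
        posterior = {n: np.asarray(v) for n, v in self.posterior.items()}
        return az.from_dict(
            posterior=posterior,
            log_likelihood={"log10_speed": self.pointwise_loglik},
        )

    def parameter_set(self, how: str = "mean") -> ParameterSet:
        """Collapse the posterior to a single ParameterSet (posterior means
        or medians) for quick point predictions."""
        agg = np.mean if how == "mean" else np.median
        values = {n: float(agg(self.flat(n))) for n in self.param_names}
        return _values_to_parameter_set(self.spec, values)


def _values_to_parameter_set(spec: ModelSpec, values: Mapping[str, float]) -> ParameterSet:
    v0 = {}
    c_map, k_map = {}, {}
    c_scalar = values.get("c")
    d = values.get("d", 0.0)
    k_scalar = None
    for name, val in values.items():
        if name.startswith("v0["):
            v0[LocomotionMode(name[3:-1])] = val
        elif name.startswith("c["):
            c_map[LocomotionMode(name[2:-1])] = val
        elif name.startswith(("k0[", "k_lambda[")):
            k_map[Realm(name.split("[")[1][:-1])] = val
        elif name in ("k0", "k_lambda"):
            k_scalar = val
    kwargs = dict(
        v0=v0,
        c=c_map or c_scalar,
        d=d,
        sigma=values["sigma"],
    )
    k_value = k_map or k_scalar
    if spec.kind is ModelKind.CONSTANT_HD:
        kwargs["k0"] = k_value
    elif spec.kind is ModelKind.ALLOMETRIC_HD:
        kwargs["k_lambda"] = k_value
    return ParameterSet(**kwargs)


# ---------------------------------------------------------------------------
# Fitting
# ---------------------------------------------------------------------------

def _heuristic_start(layout: _ParamLayout, ln_mass, y, records):
    """Rough data-driven starting point: power-law intercepts per mode with a
    guessed exponent, saturation constant near the fastest observed speed."""
    theta = np.zeros(layout.ndim)
    c0 = 0.25
    for mode, col in layout.v0_col.items():
        sel = np.array([r.mode is mode for r in records])
        theta[col] = np.mean(y[sel] * _LN10 - c0 * ln_mass[sel])
    if layout.obs_k_col is not None:
        vmax = 10.0 ** y.max()
        for col in layout.gamma_k_cols:
            theta[col] = math.log(1.0 / (2.0 * vmax))
    theta[layout.halfnormal_c_cols] = math.log(c0)
    if layout.d_col is not None:
        theta[layout.d_col] = math.log(0.2)
    theta[layout.sigma_col] = math.log(0.3)
    return theta


def _prior_start(layout: _ParamLayout, priors: PriorConfig, rng):
    theta = np.empty(layout.ndim)
    for col in layout.gamma_v0_cols:
        theta[col] = np.log(rng.gamma(priors.v0_shape, 1.0 / priors.v0_rate))
    for col in layout.gamma_k_cols:
        theta[col] = np.log(rng.gamma(priors.k_shape, 1.0 / priors.k_rate))
    for col in layout.halfnormal_c_cols:
        theta[col] = np.log(abs(rng.normal(0.0, priors.c_scale)))
    if layout.d_col is not None:
        theta[layout.d_col] = np.log(abs(rng.normal(0.0, priors.d_scale)))
    theta[layout.sigma_col] = np.log(abs(priors.sigma_scale * rng.standard_cauchy()))
    return theta


def _find_map(log_post, layout, priors, ln_mass, y, records, rng, n_starts=6):
    starts = [_heuristic_start(layout, ln_mass, y, records)]
    while len(starts) < n_starts:
        cand = _prior_start(layout, priors, rng)
        if np.isfinite(log_post(cand)[0]):
            starts.append(cand)
    best_x, best_f = None, np.inf
    for x0 in starts:
        res = optimize.minimize(
            lambda th: -float(log_post(th[None, :])[0]),
            x0,
            method="Nelder-Mead",
            options={"maxiter": 4000, "fatol": 1e-9, "xatol": 1e-8},
        )
        if res.fun < best_f:
            best_x, best_f = res.x, res.fun
    if best_x is None or not np.isfinite(best_f):
        raise ConfigurationError(
            "could not find a finite posterior mode; last parameter values: "
            f"{dict(zip(layout.names, starts[-1]))}"
        )
    return best_x


def _laplace_scales(log_post, x_map, floor=1e-6, cap=2.0, h=1e-4):
    """Per-dimension curvature-based scales for ensemble initialisation."""
    f0 = float(log_post(x_map[None, :])[0])
    scales = np.empty(len(x_map))
    for j in range(len(x_map)):
        step = np.zeros_like(x_map)
        step[j] = h
        fp = float(log_post((x_map + step)[None, :])[0])
        fm = float(log_post((x_map - step)[None, :])[0])
        curv = -(fp + fm - 2 * f0) / h**2
        scales[j] = 1.0 / math.sqrt(curv) if curv > 0 else cap
    return np.clip(scales, floor, cap)


def fit(
    spec: ModelSpec,
    data: Sequence[SpeedRecord],
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
) -> PosteriorResult:
    """Fit ``spec`` to ``data`` by ensemble MCMC and return the posterior.

    Convergence problems (r-hat > 1.01 or bulk ESS <= 1000 for any
    parameter) emit a :class:`ConvergenceWarning` and are listed in
    ``result.warnings``.
    """
    priors = priors or PriorConfig()
    mcmc = mcmc or McmcConfig()
    records = list(data)
    layout = _ParamLayout(spec, records)
    ln_mass = np.log([r.mass for r in records])
    y = np.log10([r.speed for r in records])
    log_post = _make_log_posterior(layout, priors, ln_mass, y)

    rng = np.random.default_rng(mcmc.seed)
    x_map = _find_map(log_post, layout, priors, ln_mass, y, records, rng)
    scales = _laplace_scales(log_post, x_map)

    ndim = layout.ndim
    nwalkers = max(2 * ndim + 2, 18)
    nwalkers += nwalkers % 2
    p0 = x_map[None, :] + scales[None, :] * rng.normal(size=(nwalkers, ndim))
    bad = ~np.isfinite(log_post(p0))
    p0[bad] = x_map[None, :] + 0.01 * scales[None, :] * rng.normal(size=(int(bad.sum()), ndim))

    sampler = emcee.EnsembleSampler(
        nwalkers,
        ndim,
        log_post,
        vectorize=True,
        moves=[
            (emcee.moves.DEMove(), 0.6),
            (emcee.moves.DESnookerMove(), 0.2),
            (emcee.moves.StretchMove(), 0.2),
        ],
    )
    sampler.random_state = np.random.RandomState(
        rng.integers(0, 2**31 - 1)
    ).get_state()
    # The ensemble advances _OVERSAMPLE moves per nominal sampling iteration
    # and the walker histories are thinned back to ~chains *
    # sampling_iterations retained draws; the extra internal moves buy lower
    # autocorrelation per retained draw at modest cost.
    total_moves = _OVERSAMPLE * mcmc.sampling_iterations
    with np.errstate(all="ignore"):
        state = sampler.run_mcmc(p0, mcmc.warmup_iterations, progress=False)
        sampler.reset()
        sampler.run_mcmc(state, total_moves, progress=False)

    per_walker = max(1, mcmc.target_draws // nwalkers)
    per_walker = min(per_walker, total_moves)
    thin = max(1, total_moves // per_walker)
    idx = total_moves - 1 - thin * np.arange(per_walker)[::-1]
    chain = sampler.get_chain()[idx]  # (per_walker, nwalkers, ndim)
    theta = chain.transpose(1, 0, 2)  # (chain=walker, draw, ndim)
    natural = np.exp(theta)

    posterior = {
        name: natural[:, :, j].copy() for j, name in enumerate(layout.names)
    }
    ds = xr.Dataset(
        {name: (("chain", "draw"), arr) for name, arr in posterior.items()}
    )
    rhat_ds = az.rhat(ds)
    ess_ds = az.ess(ds, method="bulk")
    rhat = {n: float(rhat_ds[n].values) for n in layout.names}
    ess = {n: float(ess_ds[n].values) for n in layout.names}

    flat_theta = theta.reshape(-1, ndim)
    mu = _batch_mu_log10(flat_theta, layout, ln_mass)
    sigma = np.exp(flat_theta[:, layout.sigma_col])[:, None]
    pointwise = (
        -0.5 * ((y[None, :] - mu) / sigma) ** 2
        - np.log(sigma)
        - 0.5 * math.log(2 * math.pi)
    ).reshape(nwalkers, per_walker, len(records))

    problems = []
    for name in layout.names:
        if rhat[name] > _RHAT_THRESHOLD:
            problems.append(f"rhat[{name}] = {rhat[name]:.4f} > {_RHAT_THRESHOLD}")
        if ess[name] <= _ESS_THRESHOLD:
            problems.append(f"ess_bulk[{name}] = {ess[name]:.0f} <= {_ESS_THRESHOLD:.0f}")
    if problems:
        warnings.warn(
            "MCMC convergence diagnostics missed thresholds: " + "; ".join(problems),
            ConvergenceWarning,
            stacklevel=2,
        )

    return PosteriorResult(
        spec=spec,
        param_names=layout.names,
        posterior=posterior,
        rhat=rhat,
        ess=ess,
        pointwise_loglik=pointwise,
        warnings=problems,
        mcmc=mcmc,
        priors=priors,
        n_obs=len(records),
        map_estimate={n: float(np.exp(v)) for n, v in zip(layout.names, x_map)},
    )


def pointwise_log_likelihood(
    spec: ModelSpec, params: ParameterSet, data: Sequence[SpeedRecord]
) -> np.ndarray:
    """Gaussian log-density of each observation's log10 speed under ``params``.

    Entry ``i`` is ``Normal(log10 f(M_i, theta), sigma).logpdf(log10 v_i)``;
    the sum over entries is the total data log-likelihood.
    """
    records = list(data)
    mu = np.array(
        [
            log10_realised_speed(spec, r.mass, r.mode, params, realm=r.realm)
            for r in records
        ]
    )
    y = np.log10([r.speed for r in records])
    return stats.norm.logpdf(y, loc=mu, scale=params.sigma)
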