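"""Posterior prediction curves over body-mass grids.

Two kinds of 90% intervals are produced for every grid mass:

* **credible interval (CI)** — central quantiles of the expected curve
  ``f(M, theta)`` across posterior draws: uncertainty about the mean
  relationship;
* **prediction interval (PI)** — quantiles of a *new observation*, i.e. of
  the equal-weight Gaussian mixture ``log10 v ~ Normal(log10 f(M, theta_s),
  sigma_s)`` over draws ``s``.  The mixture quantile is solved
  deterministically by bisection in log10 space rather than by simulating
  noise, so the PI is reproducible given the draws.

Grid points outside the observed mass range of a mode are flagged so that
plots can draw them dashed (extrapolation).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.special import ndtr

from .data import SpeedRecord
from .exceptions import ConfigurationError
from .inference import PosteriorResult, _ParamLayout  # noqa: F401 (layout reused)
from .models import DEFAULT_REALM, LocomotionMode, ModelKind, ModelSpec, Realm, _ln_speed

__all__ = ["PredictionCurve", "predict_curve", "predict_point", "default_mass_grid", "plot_curves"]

_LN10 = math.log(10.0)

MODE_COLORS = {
    LocomotionMode.FLYING: "tab:green",
    LocomotionMode.RUNNING: "tab:red",
    LocomotionMode.SWIMMING: "tab:blue",
}


@dataclass
class PredictionCurve:
    """Posterior mean curve with 90% credible and prediction bands."""

    mode: LocomotionMode
    mass_grid: np.ndarray  # kg, strictly increasing
    mean: np.ndarray  # m/s
    ci90_low: np.ndarray
    ci90_high: np.ndarray
    pi90_low: np.ndarray
    pi90_high: np.ndarray
    in_observed_range: np.ndarray  # bool

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "mode": self.mode.value,
                "mass_kg": self.mass_grid,
                "mean_m_s": self.mean,
                "ci90_low": self.ci90_low,
                "ci90_high": self.ci90_high,
                "pi90_low": self.pi90_low,
                "pi90_high": self.pi90_high,
                "in_observed_range": self.in_observed_range,
            }
        )


def _draw_curve_log10(
    posterior: PosteriorResult, spec: ModelSpec, mode: LocomotionMode, realm, ln_mass
):
    """(draws, grid) matrix of log10 f(M, theta_s), plus per-draw sigma."""
    mode = LocomotionMode(mode)
    v0_name = f"v0[{mode.value}]"
    if v0_name not in posterior.param_names:
        raise ConfigurationError(
            f"posterior has no locomotion rate constant for mode {mode.value!r}"
        )
    lv0 = np.log(posterior.flat(v0_name))[:, None]
    c_name = f"c[{mode.value}]" if f"c[{mode.value}]" in posterior.param_names else "c"
    c = posterior.flat(c_name)[:, None]
    if spec.uses_k:
        base = "k0" if spec.kind is ModelKind.CONSTANT_HD else "k_lambda"
        if realm is None:
            realm = DEFAULT_REALM[mode]
        realm = Realm(realm)
        k_name = f"{base}[{realm.value}]" if f"{base}[{realm.value}]" in posterior.param_names else base
        if k_name not in posterior.param_names:
            raise ConfigurationError(f"posterior has no parameter {base!r}")
        lk = np.log(posterior.flat(k_name))[:, None]
    else:
        lk = 0.0
    d = posterior.flat("d")[:, None] if "d" in posterior.param_names else 0.0
    ln_v = _ln_speed(spec.kind, ln_mass[None, :], lv0, lk, c, d)
    sigma = posterior.flat("sigma")
    return ln_v / _LN10, sigma


def _mixture_quantile(mu: np.ndarray, sigma: np.ndarray, q: float, iters: int = 80):
    """Quantile of the equal-weight Gaussian mixture, columnwise.

    ``mu`` is (draws, grid); ``sigma`` is (draws,).  Solved by bisection on
    ``mean_s Phi((x - mu_s)/sigma_s) = q``; deterministic given the draws.
    """
    s = sigma[:, None]
    lo = (mu - 10.0 * s).min(axis=0)
    hi = (mu + 10.0 * s).max(axis=0)
    for _ in range(iters):
        mid = 0.5 * (lo + hi)
        cdf = ndtr((mid[None, :] - mu) / s).mean(axis=0)
        below = cdf < q
        lo = np.where(below, mid, lo)
        hi = np.where(below, hi, mid)
    return 0.5 * (lo + hi)


def default_mass_grid(
    data: Sequence[SpeedRecord],
    mode,
    n_points: int = 200,
    pad_decades: float = 1.0,
) -> np.ndarray:
    """Log-spaced grid spanning the observed mass range of ``mode``,
    extended ``pad_decades`` orders of magnitude on each side."""
    mode = LocomotionMode(mode)
    masses = [r.mass for r in data if r.mode is mode]
    if not masses:
        raise ConfigurationError(f"no records with mode {mode.value!r}")
    lo = math.log10(min(masses)) - pad_decades
    hi = math.log10(max(masses)) + pad_decades
    return np.logspace(lo, hi, n_points)


def predict_curve(
    posterior: PosteriorResult,
    spec: ModelSpec,
    mode,
    mass_grid=None,
    data_for_range: Sequence[SpeedRecord] | None = None,
    realm=None,
    level: float = 0.9,
) -> PredictionCurve:
    """Posterior mean curve and central ``level`` CI/PI bands for one mode.

    ``data_for_range`` supplies the observed mass range used to flag grid
    points as interpolation vs extrapolation (and, when ``mass_grid`` is
    omitted, to build the default grid).  Without it, every point is treated
    as in-range.
    """
    mode = LocomotionMode(mode)
    if mass_grid is None:
        if data_for_range is None:
            raise ConfigurationError("either mass_grid or data_for_range is required")
        mass_grid = default_mass_grid(data_for_range, mode)
    mass_grid = np.asarray(mass_grid, dtype=float)
    if mass_grid.ndim != 1 or np.any(~(mass_grid > 0)) or np.any(np.diff(mass_grid) <= 0):
        raise ConfigurationError("mass_grid must be strictly increasing and positive")

    mu, sigma = _draw_curve_log10(posterior, spec, mode, realm, np.log(mass_grid))
    a = (1.0 - level) / 2.0
    f = 10.0 ** mu
    mean = f.mean(axis=0)
    ci_lo, ci_hi = np.quantile(f, [a, 1.0 - a], axis=0)
    pi_lo = 10.0 ** _mixture_quantile(mu, sigma, a)
    pi_hi = 10.0 ** _mixture_quantile(mu, sigma, 1.0 - a)

    if data_for_range is not None:
        masses = [r.mass for r in data_for_range if r.mode is mode]
        in_range = (mass_grid >= min(masses)) & (mass_grid <= max(masses))
    else:
        in_range = np.ones_like(mass_grid, dtype=bool)

    return PredictionCurve(
        mode=mode,
        mass_grid=mass_grid,
        mean=mean,
        ci90_low=np.minimum(ci_lo, ci_hi),
        ci90_high=np.maximum(ci_lo, ci_hi),
        pi90_low=pi_lo,
        pi90_high=pi_hi,
        in_observed_range=in_range,
    )


def predict_point(
    posterior: PosteriorResult,
    spec: ModelSpec,
    mass: float,
    mode,
    realm=None,
    level: float = 0.9,
) -> dict:
    """Posterior predictive summary for a single (mass, mode) query.

    Returns the posterior mean of the expected speed together with the
    central ``level`` credible and prediction intervals (m/s).
    """
    curve = predict_curve(
        posterior, spec, mode, mass_grid=np.array([float(mass)]), realm=realm, level=level
    )
    return {
        "mean": float(curve.mean[0]),
        "ci_low": float(curve.ci90_low[0]),
        "ci_high": float(curve.ci90_high[0]),
        "pi_low": float(curve.pi90_low[0]),
        "pi_high": float(curve.pi90_high[0]),
    }


def predictive_cdf(
    posterior: PosteriorResult,
    spec: ModelSpec,
    records: Sequence[SpeedRecord],
    block: int = 256,
) -> np.ndarray:
    """Posterior predictive CDF value of each record's observed speed.

    Entry i is ``mean_s Phi((log10 v_i - log10 f(M_i, theta_s)) / sigma_s)``.
    An observation falls inside the central 90% prediction interval exactly
    when its CDF value lies in (0.05, 0.95), so empirical interval coverage
    is ``mean(0.05 < cdf < 0.95)`` without constructing the intervals.
    """
    records = list(records)
    sigma = posterior.flat("sigma")[:, None]
    out = np.empty(len(records))
    by_mode: dict[LocomotionMode, list[int]] = {}
    for i, r in enumerate(records):
        by_mode.setdefault(r.mode, []).append(i)
    for mode, idx in by_mode.items():
        idx = np.asarray(idx)
        ln_mass = np.log([records[i].mass for i in idx])
        y = np.log10([records[i].speed for i in idx])
        for start in range(0, idx.size, block):
            sl = slice(start, start + block)
            mu, _ = _draw_curve_log10(posterior, spec, mode, None, ln_mass[sl])
            out[idx[sl]] = ndtr((y[None, sl] - mu) / sigma).mean(axis=0)
    return out


def plot_curves(
    curves: Sequence[PredictionCurve],
    data: Sequence[SpeedRecord] | None = None,
    ax=None,
    show_pi: bool = False,
):
    """Log-log chart of prediction curves (one per mode) with 90% ribbons.

    Solid line segments cover the observed mass range; dashed segments mark
    extrapolation.  Returns the matplotlib axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(7, 5))
    for curve in curves:
        color = MODE_COLORS[curve.mode]
        lo = curve.pi90_low if show_pi else curve.ci90_low
        hi = curve.pi90_high if show_pi else curve.ci90_high
        ax.fill_between(curve.mass_grid, lo, hi, color=color, alpha=0.2, lw=0)
        inside = curve.in_observed_range
        for mask, style in ((inside, "-"), (~inside, "--")):
            y = np.where(mask, curve.mean, np.nan)
            ax.plot(curve.mass_grid, y, style, color=color, label=None)
        ax.plot([], [], "-", color=color, label=curve.mode.value)
    if data is not None:
        for mode in LocomotionMode:
            pts = [(r.mass, r.speed) for r in data if r.mode is mode]
            if pts:
                m, v = zip(*pts)
                ax.scatter(m, v, s=8, alpha=0.4, color=MODE_COLORS[mode])
    ax.set_xscale("log")
    ax.set_yscale("log")
    ax.set_xlabel("body mass (kg)")
    ax.set_ylabel("travel speed (m/s)")
    ax.legend(frameon=False)
    return ax
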