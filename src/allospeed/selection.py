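"""Out-of-sample model comparison via PSIS leave-one-out cross-validation.

For each fitted model the expected log pointwise predictive density (ELPD)
is estimated from the posterior pointwise log-likelihood matrix with
Pareto-smoothed importance sampling, and reported on the deviance scale as
LOOIC = -2 * ELPD.  Competing models fitted to the same observations are
ranked by LOOIC; a rival is distinguishable from the best model when its
ΔLOOIC exceeds twice the standard error of the (paired, pointwise)
difference.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import arviz as az
import numpy as np

from .exceptions import ConfigurationError, DegenerateDrawsError
from .inference import McmcConfig, PosteriorResult, PriorConfig
from .inference import fit as _fit
from .models import ModelSpec

__all__ = ["LooResult", "ComparisonRow", "ComparisonTable", "psis_loo", "compare", "exact_loo"]

PARETO_K_THRESHOLD = 0.7


@dataclass(frozen=True)
class LooResult:
    """PSIS-LOO estimate for one model."""

    elpd: float
    se: float
    pointwise_elpd: np.ndarray
    pareto_k: np.ndarray

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd

    @property
    def n_high_pareto_k(self) -> int:
        return int(np.sum(self.pareto_k > PARETO_K_THRESHOLD))


def _as_loglik_array(obj) -> np.ndarray:
    """Normalise input to a (chain, draw, obs) log-likelihood array."""
    if isinstance(obj, PosteriorResult):
        return np.asarray(obj.pointwise_loglik)
    arr = np.asarray(obj, dtype=float)
    if arr.ndim == 2:
        arr = arr[None, :, :]
    if arr.ndim != 3:
        raise ConfigurationError(
            "expected a (draws, observations) or (chain, draw, observations) array"
        )
    return arr


def psis_loo(pointwise_loglik) -> LooResult:
    """PSIS-LOO from a pointwise log-likelihood matrix or PosteriorResult.

    Requires at least 100 draws and finite log-likelihood values.
    Observations whose smoothed importance weights have Pareto k above 0.7
    are unreliable and can be recomputed exactly with :func:`exact_loo`.
    """
    arr = _as_loglik_array(pointwise_loglik)
    nchain, ndraw, nobs = arr.shape
    if nchain * ndraw < 100:
        raise ConfigurationError(
            f"PSIS-LOO needs >= 100 draws, got {nchain * ndraw}"
        )
    if not np.all(np.isfinite(arr)):
        raise ConfigurationError("pointwise log-likelihoods must be finite")
    if np.allclose(arr.std(axis=(0, 1)), 0.0):
        raise DegenerateDrawsError(
            "posterior draws are identical; importance weights are degenerate"
        )
    if isinstance(pointwise_loglik, PosteriorResult):
        idata = pointwise_loglik.to_inference_data()
        idata.log_likelihood["obs"] = idata.log_likelihood["log10_speed"]
        loo = az.loo(idata, var_name="obs", pointwise=True)
    else:
        idata = az.from_dict(log_likelihood={"obs": arr})
        loo = az.loo(idata, pointwise=True, reff=1.0)
    return LooResult(
        elpd=float(loo.elpd_loo),
        se=float(loo.se),
        pointwise_elpd=np.asarray(loo.loo_i.values, dtype=float),
        pareto_k=np.asarray(loo.pareto_k.values, dtype=float),
    )


@dataclass(frozen=True)
class ComparisonRow:
    name: str
    spec: ModelSpec
    elpd: float
    looic: float
    delta_looic: float
    se_delta: float
    verdict: str
    n_high_pareto_k: int


@dataclass(frozen=True)
class ComparisonTable:
    """Per-model LOOIC ranking with pairwise differences to the best model."""

    rows: tuple[ComparisonRow, ...]
    loos: Mapping[str, LooResult]

    @property
    def best(self) -> ComparisonRow:
        return self.rows[0]

    def __getitem__(self, name: str) -> ComparisonRow:
        for row in self.rows:
            if row.name == name:
                return row
        raise KeyError(name)

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "model": [r.name for r in self.rows],
                "description": [r.spec.label for r in self.rows],
                "LOOIC": [r.looic for r in self.rows],
                "dLOOIC": [r.delta_looic for r in self.rows],
                "SE_dLOOIC": [r.se_delta for r in self.rows],
                "verdict": [r.verdict for r in self.rows],
                "n_pareto_k_gt_0.7": [r.n_high_pareto_k for r in self.rows],
            }
        )

    def to_csv(self, path) -> None:
        self.to_dataframe().to_csv(path, index=False)


def compare(results: Mapping, data=None) -> ComparisonTable:
    """Rank fitted models by PSIS-LOO.

    ``results`` maps a model name (or ModelSpec) to its PosteriorResult; all
    models must have been fitted to the identical dataset (same records,
    same order).  The standard error of each ΔELPD comes from the pointwise
    ELPD differences, ``sqrt(n * var(elpd_i_best - elpd_i_rival))``, and is
    reported as ``se_delta`` on the same deviance (LOOIC) scale as
    ``delta_looic``.  The best model is "preferred" only if every rival's
    ΔLOOIC exceeds twice the corresponding SE.
    """
    named: dict[str, tuple[ModelSpec, PosteriorResult]] = {}
    for key, res in results.items():
        name = key.label if isinstance(key, ModelSpec) else str(key)
        named[name] = (res.spec, res)
    n_obs = {name: res.n_obs for name, (_, res) in named.items()}
    if len(set(n_obs.values())) > 1:
        raise ConfigurationError(
            f"models were fitted to different numbers of observations: {n_obs}"
        )
    loos = {name: psis_loo(res) for name, (_, res) in named.items()}
    order = sorted(loos, key=lambda name: loos[name].elpd, reverse=True)
    best_name = order[0]
    best_pointwise = loos[best_name].pointwise_elpd

    rows = []
    all_rivals_beaten = True
    for name in order:
        loo = loos[name]
        diff = best_pointwise - loo.pointwise_elpd
        n = diff.size
        if name == best_name:
            delta, se = 0.0, 0.0
        else:
            delta = loo.looic - loos[best_name].looic
            # SE of the pointwise ELPD difference, rescaled to the LOOIC
            # (deviance) scale on which delta is reported
            se = 2.0 * float(np.sqrt(n * np.var(diff, ddof=1))) if n > 1 else 0.0
            if not delta > 2.0 * se:
                all_rivals_beaten = False
        rows.append((name, loo, delta, se))

    table_rows = []
    for i, (name, loo, delta, se) in enumerate(rows):
        if i == 0:
            verdict = "preferred" if (len(rows) > 1 and all_rivals_beaten) else "indistinguishable"
            if len(rows) == 1:
                verdict = "preferred"
        else:
            verdict = "worse" if delta > 2.0 * se else "indistinguishable"
        spec, _ = named[name]
        table_rows.append(
            ComparisonRow(
                name=name,
                spec=spec,
                elpd=loo.elpd,
                looic=loo.looic,
                delta_looic=delta,
                se_delta=se,
                verdict=verdict,
                n_high_pareto_k=loo.n_high_pareto_k,
            )
        )
    return ComparisonTable(rows=tuple(table_rows), loos=loos)


def exact_loo(
    spec: ModelSpec,
    data: Sequence,
    priors: PriorConfig | None = None,
    mcmc: McmcConfig | None = None,
) -> np.ndarray:
    """Exact leave-one-out pointwise ELPD via n refits (brute force).

    For each observation i the model is refitted without it and
    ``elpd_i = log mean_s p(y_i | theta_s)`` is evaluated over the refit's
    draws.  Only practical for small n; serves as the gold standard against
    which PSIS-LOO is validated, and as the fallback for observations with
    high Pareto k.
    """
    from scipy.special import logsumexp

    from .inference import _ParamLayout

    records = list(data)
    n = len(records)
    out = np.empty(n)
    for i in range(n):
        held_out = records[i]
        rest = records[:i] + records[i + 1 :]
        res = _fit(spec, rest, priors=priors, mcmc=mcmc)
        # evaluate the held-out point under every retained draw
        layout = _ParamLayout(spec, rest)
        flat = np.column_stack(
            [np.log(res.flat(name)) for name in res.param_names]
        )
        y_i = np.log10(held_out.speed)
        mu = _mu_single(spec, layout, flat, held_out)
        sigma = np.exp(flat[:, layout.sigma_col])
        ll = (
            -0.5 * ((y_i - mu) / sigma) ** 2
            - np.log(sigma)
            - 0.5 * np.log(2 * np.pi)
        )
        out[i] = logsumexp(ll) - np.log(ll.size)
    return out


def _mu_single(spec, layout, flat_theta, record):
    """Expected log10 speed of one record under a batch of draws."""
    import math

    from .models import _ln_speed

    lv0 = flat_theta[:, layout.v0_col[record.mode]]
    if layout.c_cols is not None:
        c = np.exp(flat_theta[:, layout.c_cols[record.mode]])
    else:
        c = np.exp(flat_theta[:, layout.c_col])
    if layout.obs_k_col is not None:
        if layout.k_cols is not None:
            lk = flat_theta[:, layout.k_cols[record.realm]]
        else:
            lk = flat_theta[:, layout.k_col]
    else:
        lk = 0.0
    d = np.exp(flat_theta[:, layout.d_col]) if layout.d_col is not None else 0.0
    ln_v = _ln_speed(spec.kind, np.log(record.mass), lv0, lk, c, d)
    return ln_v / math.log(10.0)
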