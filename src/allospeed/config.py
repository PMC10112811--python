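"""YAML configuration for the command-line interface.

A config file may carry any of the sections ``model``, ``priors``, ``mcmc``,
``simulation``, and ``columns``; omitted sections fall back to package
defaults.  Example::

    model: {kind: allometric_hd, c_pooling: pooled, k_pooling: pooled}
    mcmc: {chains: 3, warmup_iterations: 1500, sampling_iterations: 3000}
    simulation:
      seed: 7
      true_params:
        v0: {flying: 30.54, running: 0.28, swimming: 0.39}
        k_lambda: 0.033
        c: 0.27
        d: 0.24
        sigma: 0.3
      n_per_mode: {flying: 233, running: 233, swimming: 233}
      mass_range_log10: {flying: [-10, 1.2], running: [-9, 4], swimming: [-6, 5.15]}
    columns: {species: species, mass: mass_kg, speed: speed_m_s, mode: mode}
"""

from __future__ import annotations

from dataclasses import replace

import yaml

from .data import ColumnMap
from .inference import McmcConfig, PriorConfig
from .models import ModelSpec, ParameterSet
from .simulate import SimulationConfig, default_empirical_emulation

__all__ = ["load_config", "Config"]


class Config:
    """Bundle of the typed configuration objects a CLI run needs."""

    def __init__(self, raw: dict | None = None):
        raw = raw or {}
        self.model = ModelSpec(**raw.get("model", {}))
        self.priors = PriorConfig(**raw.get("priors", {}))
        self.mcmc = McmcConfig(**raw.get("mcmc", {}))
        self.columns = ColumnMap(**raw.get("columns", {}))
        self.simulation = self._build_simulation(raw.get("simulation", {}))

    @staticmethod
    def _build_simulation(section: dict) -> SimulationConfig:
        base = default_empirical_emulation(
            seed=int(section.get("seed", 0)),
            sigma=float(section.get("sigma", 0.3)),
        )
        kwargs = {}
        if "true_model" in section:
            kwargs["true_spec"] = ModelSpec(**section["true_model"])
        if "true_params" in section:
            kwargs["true_params"] = ParameterSet(**section["true_params"])
        if "n_per_mode" in section:
            kwargs["n_per_mode"] = section["n_per_mode"]
        if "mass_range_log10" in section:
            kwargs["mass_range_log10"] = {
                m: tuple(v) for m, v in section["mass_range_log10"].items()
            }
        return replace(base, **kwargs) if kwargs else base


def load_config(path=None) -> Config:
    if path is None:
        return Config()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return Config(raw)
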