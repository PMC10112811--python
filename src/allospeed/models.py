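"""Allometric models of sustained (aerobic) travel speed.

Three competing process models describe how the travel speed ``v`` (m/s) that an
animal can sustain scales with its body mass ``M`` (kg):

* **metabolic** — a pure power law, ``v = v0 * M**c``.  All of the travel time
  budget goes into locomotion; speed is set by metabolic power supply and
  locomotion efficiency alone.
* **constant heat dissipation** (``constant_hd``) — a saturating curve,
  ``v = (1/k0) * M**c / (M**c + 1/(v0*k0))``.  A mass-independent share of the
  time budget is diverted to shedding metabolically produced heat, capping
  speed at ``1/k0`` for the largest animals.
* **allometric heat dissipation** (``allometric_hd``) — a hump-shaped curve,
  ``v = (1/k_lambda) * M**c / (M**(c+d) + 1/(v0*k_lambda))``.  Heat-dissipation
  time per unit distance itself grows with mass (exponent ``d``), so the very
  largest animals must slow down to avoid hyperthermia.

``v0`` is the mode-specific locomotion rate constant (m s^-1 kg^-c), fitted
separately for flying, running, and swimming animals; ``k0`` (s/m) and
``k_lambda`` (s m^-1 kg^-d) are heat-dissipation time constants; ``c`` and
``d`` are dimensionless scaling exponents.  Masses are always in kg and speeds
in m/s.

All curve evaluation happens in natural-log space so that extreme masses
(the supported range spans far more than the empirical 15 orders of
magnitude) neither overflow nor lose the saturating denominator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Mapping, Union

import numpy as np

from .exceptions import ConfigurationError

__all__ = [
    "LocomotionMode",
    "Realm",
    "ModelKind",
    "Pooling",
    "ModelSpec",
    "ParameterSet",
    "TheoryBounds",
    "realised_speed",
    "log10_realised_speed",
    "peak_mass",
    "exponent_bounds",
    "DEFAULT_REALM",
]


class LocomotionMode(str, Enum):
    """The three locomotion modes distinguished by the analysis."""

    FLYING = "flying"
    RUNNING = "running"
    SWIMMING = "swimming"


class Realm(str, Enum):
    """Medium the animal moves through; relevant only for per-realm k variants."""

    AQUATIC = "aquatic"
    TERRESTRIAL = "terrestrial"


#: Default realm assignment when a dataset does not state one.
DEFAULT_REALM: Mapping[LocomotionMode, Realm] = {
    LocomotionMode.FLYING: Realm.TERRESTRIAL,
    LocomotionMode.RUNNING: Realm.TERRESTRIAL,
    LocomotionMode.SWIMMING: Realm.AQUATIC,
}


class ModelKind(str, Enum):
    METABOLIC = "metabolic"
    CONSTANT_HD = "constant_hd"
    ALLOMETRIC_HD = "allometric_hd"


class Pooling(str, Enum):
    POOLED = "pooled"
    BY_MODE = "by_mode"
    BY_REALM = "by_realm"


def _coerce(enum_cls, value):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(str(value).strip().lower())
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        raise ConfigurationError(
            f"invalid {enum_cls.__name__} {value!r}; expected one of: {valid}"
        ) from None


@dataclass(frozen=True)
class ModelSpec:
    """Which process model to use, and how its parameters pool across groups.

    The default is the best-supported configuration: the allometric
    heat-dissipation model with a single shared ``c`` exponent and a single
    shared heat-dissipation constant (``v0`` is always fitted per mode).
    """

    kind: ModelKind = ModelKind.ALLOMETRIC_HD
    c_pooling: Pooling = Pooling.POOLED
    k_pooling: Pooling = Pooling.POOLED

    def __post_init__(self):
        object.__setattr__(self, "kind", _coerce(ModelKind, self.kind))
        object.__setattr__(self, "c_pooling", _coerce(Pooling, self.c_pooling))
        object.__setattr__(self, "k_pooling", _coerce(Pooling, self.k_pooling))
        if self.c_pooling not in (Pooling.POOLED, Pooling.BY_MODE):
            raise ConfigurationError("c_pooling must be 'pooled' or 'by_mode'")
        if self.k_pooling not in (Pooling.POOLED, Pooling.BY_REALM):
            raise ConfigurationError("k_pooling must be 'pooled' or 'by_realm'")

    @property
    def uses_k(self) -> bool:
        return self.kind is not ModelKind.METABOLIC

    @property
    def label(self) -> str:
        bits = [self.kind.value]
        if self.c_pooling is Pooling.BY_MODE:
            bits.append("c_by_mode")
        if self.uses_k and self.k_pooling is Pooling.BY_REALM:
            bits.append("k_by_realm")
        return "+".join(bits)


ScalarOrByMode = Union[float, Mapping[LocomotionMode, float]]
ScalarOrByRealm = Union[float, Mapping[Realm, float]]


def _lookup(value, key, name):
    if isinstance(value, Mapping):
        try:
            return float(value[key])
        except KeyError:
            raise ConfigurationError(f"{name} has no entry for {key!r}") from None
    if value is None:
        raise ConfigurationError(f"parameter {name!r} is required but absent")
    return float(value)


@dataclass
class ParameterSet:
    """One full parameter vector theta for any of the three models.

    ``v0`` maps locomotion mode to the rate constant.  ``k0``/``k_lambda`` may
    be a scalar (complete pooling) or a mapping keyed by :class:`Realm`.
    ``c`` may be a scalar or a mapping keyed by :class:`LocomotionMode`.
    ``sigma`` is the residual standard deviation of log10 speed.
    """

    v0: Mapping[LocomotionMode, float]
    c: ScalarOrByMode
    sigma: float = 0.3
    d: float = 0.0
    k0: ScalarOrByRealm | None = None
    k_lambda: ScalarOrByRealm | None = None

    def __post_init__(self):
        self.v0 = {
            _coerce(LocomotionMode, m): float(v) for m, v in dict(self.v0).items()
        }
        for m, v in self.v0.items():
            if not v > 0:
                raise ConfigurationError(f"v0[{m.value}] must be > 0, got {v}")
        for name in ("c", "k0", "k_lambda"):
            val = getattr(self, name)
            if isinstance(val, Mapping):
                key_cls = LocomotionMode if name == "c" else Realm
                setattr(
                    self,
                    name,
                    {_coerce(key_cls, k): float(v) for k, v in val.items()},
                )
        # sigma = 0 is allowed so the generator can run noise-free; the
        # Gaussian likelihood itself requires sigma > 0.
        for name, positive in (("c", True), ("sigma", False), ("d", False)):
            val = getattr(self, name)
            vals = val.values() if isinstance(val, Mapping) else [val]
            for v in vals:
                if positive and not v > 0:
                    raise ConfigurationError(f"{name} must be > 0, got {v}")
                if not positive and v < 0:
                    raise ConfigurationError(f"{name} must be >= 0, got {v}")
        for name in ("k0", "k_lambda"):
            val = getattr(self, name)
            if val is None:
                continue
            vals = val.values() if isinstance(val, Mapping) else [val]
            for v in vals:
                if not v > 0:
                    raise ConfigurationError(f"{name} must be > 0, got {v}")

    # -- keyed accessors -------------------------------------------------
    def v0_for(self, mode) -> float:
        return _lookup(self.v0, _coerce(LocomotionMode, mode), "v0")

    def c_for(self, mode) -> float:
        return _lookup(self.c, _coerce(LocomotionMode, mode), "c")

    def k_for(self, spec: ModelSpec, realm=None) -> float:
        if spec.kind is ModelKind.CONSTANT_HD:
            k, name = self.k0, "k0"
        elif spec.kind is ModelKind.ALLOMETRIC_HD:
            k, name = self.k_lambda, "k_lambda"
        else:
            raise ConfigurationError("metabolic model has no heat-dissipation constant")
        if isinstance(k, Mapping):
            if realm is None:
                raise ConfigurationError(f"{name} is keyed by realm; a realm is required")
            return _lookup(k, _coerce(Realm, realm), name)
        return _lookup(k, None, name)


# -- curve evaluation ----------------------------------------------------

def _ln_speed(kind: ModelKind, ln_mass, ln_v0, ln_k, c, d):
    """Natural-log travel speed; all arguments broadcast as numpy arrays.

    The heat-dissipation denominators are handled with ``logaddexp`` so that
    M**(c+d) never materialises on the natural scale.
    """
    if kind is ModelKind.METABOLIC:
        return ln_v0 + c * ln_mass
    exponent = c if kind is ModelKind.CONSTANT_HD else c + d
    # ln v = -ln k + c ln M - ln(M**e + 1/(v0 k))
    return -ln_k + c * ln_mass - np.logaddexp(exponent * ln_mass, -(ln_v0 + ln_k))


def log10_realised_speed(spec: ModelSpec, mass, mode, params: ParameterSet, realm=None):
    """log10 of :func:`realised_speed`; vectorised over ``mass``."""
    mode = _coerce(LocomotionMode, mode)
    mass_arr = np.asarray(mass, dtype=float)
    if np.any(~(mass_arr > 0)):
        raise ValueError("mass must be strictly positive (kg)")
    ln_m = np.log(mass_arr)
    ln_v0 = math.log(params.v0_for(mode))
    c = params.c_for(mode)
    d = params.d
    ln_k = 0.0
    if spec.uses_k:
        if realm is None:
            realm = DEFAULT_REALM[mode]
        k = params.k_for(spec, realm)
        ln_k = math.log(k)
    ln_v = _ln_speed(spec.kind, ln_m, ln_v0, ln_k, c, d)
    out = ln_v / math.log(10)
    return float(out) if np.isscalar(mass) or np.ndim(mass) == 0 else out


def realised_speed(spec: ModelSpec, mass, mode, params: ParameterSet, realm=None):
    """Sustained travel speed (m/s) predicted for ``mass`` (kg) and ``mode``.

    Accepts a scalar or array of masses.  For the per-realm heat-dissipation
    variants, ``realm`` defaults to the conventional assignment
    (swimming -> aquatic, flying/running -> terrestrial).
    """
    return 10.0 ** log10_realised_speed(spec, mass, mode, params, realm=realm)


def peak_mass(params: ParameterSet, mode, realm=None) -> float:
    """Body mass (kg) at which the hump-shaped curve attains its maximum speed.

    For the allometric heat-dissipation model the optimum is
    ``M* = (c*K/d)**(1/(c+d))`` with ``K = 1/(v0*k_lambda)``.  Raises
    :class:`ConfigurationError` when ``d == 0`` (the curve saturates and has
    no interior maximum) or when ``k_lambda`` is absent.
    """
    mode = _coerce(LocomotionMode, mode)
    spec = ModelSpec(kind=ModelKind.ALLOMETRIC_HD)
    if realm is None:
        realm = DEFAULT_REALM[mode]
    k = params.k_for(spec, realm)
    c = params.c_for(mode)
    d = params.d
    if d == 0:
        raise ConfigurationError(
            "d = 0: the speed curve saturates and has no interior maximum"
        )
    ln_K = -math.log(params.v0_for(mode) * k)
    return math.exp((math.log(c / d) + ln_K) / (c + d))


# -- theoretical exponent bounds -----------------------------------------

def exponent_bounds(a_range, b: float) -> tuple[float, float]:
    """Expected range for the speed exponent ``c = a + b``.

    Potential travel speed scales as ``M**(a+b)`` where ``a`` is the exponent
    of metabolic power input and ``b`` that of locomotion efficiency, so an
    interval of plausible ``a`` values translates additively into an interval
    for ``c``.
    """
    a_lo, a_hi = (float(a_range[0]), float(a_range[1]))
    if a_lo > a_hi:
        raise ValueError("a_range must be ordered (low, high)")
    return (a_lo + b, a_hi + b)


@dataclass(frozen=True)
class TheoryBounds:
    """Theoretical intervals for the scaling exponents of the speed models.

    ``a_range`` bounds the metabolic-power exponent, ``b`` is the
    locomotion-efficiency exponent, ``c_range = a_range + b`` bounds the rise
    of the speed curve, and ``d_range`` bounds the heat-dissipation-time
    exponent that controls its decline.
    """

    a_range: tuple[float, float]
    b: float
    d_range: tuple[float, float] | None = None
    c_range: tuple[float, float] = field(init=False)

    def __post_init__(self):
        object.__setattr__(self, "c_range", exponent_bounds(self.a_range, self.b))
        if self.d_range is not None and self.d_range[0] > self.d_range[1]:
            raise ValueError("d_range must be ordered (low, high)")
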