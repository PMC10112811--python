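"""Dataset records, CSV input/output, and species-level aggregation.

The canonical on-disk format is a UTF-8 CSV with a header row and columns
``species, mass_kg, speed_m_s, mode, realm`` ("." decimal separator).  Other
layouts — for instance a deposited dataset with its own column names and
units — are read through a :class:`ColumnMap`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, SchemaError, ValidationError
from .models import DEFAULT_REALM, LocomotionMode, Realm

__all__ = [
    "SpeedRecord",
    "ColumnMap",
    "read_dataset",
    "write_dataset",
    "records_to_frame",
    "frame_to_records",
    "aggregate_species",
]

#: Multiplicative factors to kg / (m/s) for the units a ColumnMap may declare.
MASS_FACTORS = {"kg": 1.0, "g": 1e-3, "mg": 1e-6, "t": 1e3, "tonne": 1e3}
SPEED_FACTORS = {"m/s": 1.0, "m_s": 1.0, "km/h": 1 / 3.6, "cm/s": 1e-2, "km/d": 1000 / 86400}


@dataclass(frozen=True)
class SpeedRecord:
    """One species-level travel-speed observation."""

    species: str
    mass: float  # kg
    speed: float  # m/s
    mode: LocomotionMode
    realm: Realm | None = None

    def __post_init__(self):
        object.__setattr__(self, "mode", LocomotionMode(self.mode))
        realm = self.realm
        if realm is None:
            realm = DEFAULT_REALM[self.mode]
        object.__setattr__(self, "realm", Realm(realm))
        if not self.mass > 0:
            raise ValueError(f"mass must be > 0 kg, got {self.mass}")
        if not self.speed > 0:
            raise ValueError(f"speed must be > 0 m/s, got {self.speed}")


@dataclass(frozen=True)
class ColumnMap:
    """Maps canonical field names onto the columns of a source CSV.

    ``realm`` may be ``None``, in which case realms default from the
    locomotion mode (swimming -> aquatic, otherwise terrestrial).
    """

    species: str = "species"
    mass: str = "mass_kg"
    speed: str = "speed_m_s"
    mode: str = "mode"
    realm: str | None = "realm"
    mass_unit: str = "kg"
    speed_unit: str = "m/s"

    def __post_init__(self):
        if self.mass_unit not in MASS_FACTORS:
            raise ConfigurationError(
                f"unknown mass unit {self.mass_unit!r}; known: {sorted(MASS_FACTORS)}"
            )
        if self.speed_unit not in SPEED_FACTORS:
            raise ConfigurationError(
                f"unknown speed unit {self.speed_unit!r}; known: {sorted(SPEED_FACTORS)}"
            )


def _parse_row(row_number, row, cmap: ColumnMap):
    """Return a SpeedRecord or raise ValueError with a row-local reason."""
    species = str(row[cmap.species]).strip()
    if not species or species.lower() == "nan":
        raise ValueError("missing species name")
    try:
        mass = float(row[cmap.mass]) * MASS_FACTORS[cmap.mass_unit]
        speed = float(row[cmap.speed]) * SPEED_FACTORS[cmap.speed_unit]
    except (TypeError, ValueError):
        raise ValueError(
            f"non-numeric mass/speed ({row[cmap.mass]!r}, {row[cmap.speed]!r})"
        ) from None
    if not np.isfinite(mass) or mass <= 0:
        raise ValueError(f"mass must be a positive finite number, got {mass!r}")
    if not np.isfinite(speed) or speed <= 0:
        raise ValueError(f"speed must be a positive finite number, got {speed!r}")
    raw_mode = str(row[cmap.mode]).strip().lower()
    try:
        mode = LocomotionMode(raw_mode)
    except ValueError:
        raise ValueError(f"unknown locomotion mode {raw_mode!r}") from None
    realm = None
    if cmap.realm is not None and cmap.realm in row.index:
        raw_realm = row[cmap.realm]
        if isinstance(raw_realm, str) and raw_realm.strip():
            try:
                realm = Realm(raw_realm.strip().lower())
            except ValueError:
                raise ValueError(f"unknown realm {raw_realm!r}") from None
    return SpeedRecord(species=species, mass=mass, speed=speed, mode=mode, realm=realm)


def read_dataset(
    path,
    column_map: ColumnMap | None = None,
    errors: str = "raise",
) -> list[SpeedRecord]:
    """Read a dataset CSV into validated :class:`SpeedRecord` objects.

    Every row either becomes a record or yields a row-numbered diagnostic
    (row numbers count data rows from 1, excluding the header).  With
    ``errors="raise"`` (default) any diagnostic aborts the read with a
    :class:`ValidationError`; with ``errors="skip"`` offending rows are
    dropped with a warning.
    """
    if errors not in ("raise", "skip"):
        raise ValueError("errors must be 'raise' or 'skip'")
    cmap = column_map or ColumnMap()
    frame = pd.read_csv(path, float_precision="round_trip")
    mandatory = {"species": cmap.species, "mass": cmap.mass,
                 "speed": cmap.speed, "mode": cmap.mode}
    missing = [col for col in mandatory.values() if col not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing mandatory column(s) {missing}; found {list(frame.columns)}"
        )
    records, diagnostics = [], []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        try:
            records.append(_parse_row(i, row, cmap))
        except ValueError as exc:
            diagnostics.append((i, str(exc)))
    if diagnostics:
        if errors == "raise":
            raise ValidationError(diagnostics)
        warnings.warn(
            f"skipped {len(diagnostics)} invalid row(s): "
            + "; ".join(f"row {r}: {m}" for r, m in diagnostics[:5]),
            stacklevel=2,
        )
    return records


def records_to_frame(records: Iterable[SpeedRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "species": [r.species for r in records],
            "mass_kg": [r.mass for r in records],
            "speed_m_s": [r.speed for r in records],
            "mode": [r.mode.value for r in records],
            "realm": [r.realm.value for r in records],
        }
    )


def frame_to_records(frame: pd.DataFrame) -> list[SpeedRecord]:
    return [
        SpeedRecord(
            species=row.species,
            mass=float(row.mass_kg),
            speed=float(row.speed_m_s),
            mode=LocomotionMode(row.mode),
            realm=Realm(row.realm) if isinstance(row.realm, str) else None,
        )
        for row in frame.itertuples(index=False)
    ]


def write_dataset(records: Iterable[SpeedRecord], path) -> None:
    """Write records to the canonical CSV schema."""
    records_to_frame(records).to_csv(path, index=False)


def aggregate_species(records: Sequence[SpeedRecord]) -> list[SpeedRecord]:
    """Collapse individual-level records to one record per species.

    Speed (and mass) become the unweighted geometric mean of the group's
    values.  All records of a species must share one locomotion mode;
    mixed-mode groups raise :class:`ConfigurationError`.  Output order follows
    the first appearance of each species.
    """
    groups: dict[str, list[SpeedRecord]] = {}
    for rec in records:
        groups.setdefault(rec.species, []).append(rec)
    out = []
    for species, group in groups.items():
        modes = {r.mode for r in group}
        if len(modes) > 1:
            raise ConfigurationError(
                f"species {species!r} has records with mixed modes: "
                f"{sorted(m.value for m in modes)}"
            )
        realms = {r.realm for r in group}
        out.append(
            replace(
                group[0],
                mass=float(np.exp(np.mean(np.log([r.mass for r in group])))),
                speed=float(np.exp(np.mean(np.log([r.speed for r in group])))),
                realm=group[0].realm if len(realms) == 1 else None,
            )
        )
    return out
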