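"""Shared data model and tabular I/O for leaf gas-exchange experiments.

The package analyses factorial growth experiments crossing atmospheric CO2
(450 / 720 ppm) with canopy vapour-pressure-deficit regime (ambient ~1.43 kPa
vs heatwave ~3.14 kPa) and four nitrogen-fertiliser levels.  Everything
downstream consumes the three record types defined here:

``GasExchangeRecord``
    one porometer or IRGA reading, per leaf surface or combined;
``Treatment``
    the factorial cell a plant belongs to;
``PlantLedger``
    per-plant seasonal water application and harvest mass.

Canonical units: A in umol m-2 s-1, gsw in mol m-2 s-1, E in mmol m-2 s-1,
CO2 mole fractions in umol mol-1, VPD (D) in kPa, temperatures in degC,
RH in percent, time in elapsed minutes.  Readers convert vendor columns to
these units through an explicit dialect mapping; they never guess.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

__all__ = [
    "AMBIENT_CANOPY_VPD_KPA",
    "HEATWAVE_CANOPY_VPD_KPA",
    "Treatment",
    "GasExchangeRecord",
    "PlantLedger",
    "ConfigurationError",
    "ParseError",
    "ValidationError",
    "read_gasx_table",
    "write_gasx_table",
    "records_to_frame",
    "load_dialect",
]

#: Nominal canopy VPD of the two growth regimes (kPa).
AMBIENT_CANOPY_VPD_KPA = 1.43
HEATWAVE_CANOPY_VPD_KPA = 3.14

_REGIME_VPD = {"ambient": AMBIENT_CANOPY_VPD_KPA, "heatwave": HEATWAVE_CANOPY_VPD_KPA}

N_LEVELS = ("N1", "N2", "N3", "N4")
SURFACES = ("abaxial", "adaxial", "combined")
WATERINGS = ("watered", "drought")


class ConfigurationError(ValueError):
    """A dialect/config file is missing something it must name."""


class ParseError(ValueError):
    """A cell could not be parsed; carries row/column context."""


class ValidationError(ValueError):
    """A record violates a physical invariant; carries offending rows."""

    def __init__(self, message: str, rows: Sequence[int] | None = None):
        self.rows = list(rows) if rows is not None else []
        if self.rows:
            message = f"{message} (rows: {self.rows})"
        super().__init__(message)


@dataclass(frozen=True)
class Treatment:
    """One cell of the CO2 x VPD-regime x N x watering factorial."""

    co2_ppm: float = 450.0
    vpd_regime: str = "ambient"
    n_level: str = "N1"
    watering: str = "watered"
    canopy_vpd_kpa: float | None = None

    def __post_init__(self):
        if self.co2_ppm <= 0:
            raise ValidationError(f"co2_ppm must be positive, got {self.co2_ppm}")
        if self.vpd_regime not in _REGIME_VPD:
            raise ValidationError(f"unknown vpd_regime {self.vpd_regime!r}")
        if self.n_level not in N_LEVELS:
            raise ValidationError(f"unknown n_level {self.n_level!r}")
        if self.watering not in WATERINGS:
            raise ValidationError(f"unknown watering {self.watering!r}")
        if self.canopy_vpd_kpa is None:
            object.__setattr__(self, "canopy_vpd_kpa", _REGIME_VPD[self.vpd_regime])
        elif self.canopy_vpd_kpa <= 0:
            raise ValidationError("canopy_vpd_kpa must be positive")


@dataclass
class GasExchangeRecord:
    """One leaf gas-exchange reading in canonical units.

    ``A`` and ``Ci`` may be absent (porometers do not measure them).
    Slightly negative single-surface gsw readings — a known porometer
    artefact on near-closed surfaces — are retained but ``flagged``;
    transforms that cannot accept them exclude flagged rows explicitly.
    """

    plant_id: str
    surface: str
    gsw: float
    E: float
    treatment: Treatment = field(default_factory=Treatment)
    A: float | None = None
    Ca: float | None = None
    Ci: float | None = None
    D: float | None = None
    T_leaf: float | None = None
    T_air: float | None = None
    RH: float | None = None
    time_min: float | None = None
    flagged: bool = False

    def __post_init__(self):
        if self.surface not in SURFACES:
            raise ValidationError(f"unknown surface {self.surface!r}")
        self.validate()
        if self.gsw < 0 and self.surface != "combined":
            self.flagged = True

    def validate(self) -> None:
        if self.surface == "combined" and self.E < 0:
            raise ValidationError(f"combined-surface E must be >= 0, got {self.E}")
        if self.D is not None and self.D < 0:
            raise ValidationError(f"D must be >= 0, got {self.D}")
        if self.RH is not None and not 0.0 <= self.RH <= 100.0:
            raise ValidationError(f"RH must lie in [0, 100], got {self.RH}")
        if (
            self.A is not None
            and self.A > 0
            and self.Ci is not None
            and self.Ca is not None
            and self.Ci >= self.Ca
        ):
            raise ValidationError(
                f"Ci ({self.Ci}) must be < Ca ({self.Ca}) when A > 0"
            )


@dataclass
class PlantLedger:
    """Seasonal per-plant water application and harvest masses."""

    plant_id: str
    water_applied_l: float
    ear_weight_g: float
    biomass_g: float = 0.0
    treatment: Treatment = field(default_factory=Treatment)

    def __post_init__(self):
        for name in ("water_applied_l", "ear_weight_g", "biomass_g"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")


# --------------------------------------------------------------------------
# Tabular I/O

_RECORD_FIELDS = [
    "plant_id", "surface", "A", "gsw", "E", "Ca", "Ci", "D",
    "T_leaf", "T_air", "RH", "time_min", "flagged",
]
_TREATMENT_FIELDS = ["co2_ppm", "vpd_regime", "canopy_vpd_kpa", "n_level", "watering"]
_MANDATORY = ("plant_id", "surface", "gsw", "E")

#: identity dialect: canonical column names, no unit conversion
DEFAULT_DIALECT: dict = {"columns": {}, "units": {}, "surface_map": {}}

_DEFAULT_SURFACE_MAP = {
    "abaxial": "abaxial", "ab": "abaxial", "lower": "abaxial",
    "adaxial": "adaxial", "ad": "adaxial", "upper": "adaxial",
    "combined": "combined", "both": "combined",
}


def load_dialect(path: str | Path) -> dict:
    """Load a YAML dialect file mapping vendor columns to canonical fields.

    Keys: ``columns`` (canonical -> vendor column name), ``units``
    (canonical field -> multiplicative factor applied on read, e.g. 1000
    for E exported in mol m-2 s-1), ``surface_map`` (vendor label ->
    canonical surface) and a free-text ``area_basis`` note that is carried
    through but never used for conversion.
    """
    with open(path) as fh:
        dialect = yaml.safe_load(fh) or {}
    if not isinstance(dialect, Mapping):
        raise ConfigurationError(f"dialect file {path} is not a mapping")
    return dict(dialect)


def _column_for(dialect: Mapping, canonical: str) -> str:
    return dialect.get("columns", {}).get(canonical, canonical)


def read_gasx_table(
    path: str | Path, dialect: Mapping | str | Path | None = None
) -> list[GasExchangeRecord]:
    """Read a gas-exchange CSV into validated records.

    Raises :class:`ConfigurationError` for a missing mandatory column,
    :class:`ParseError` for a non-numeric cell, and
    :class:`ValidationError` (listing row indices) for rows whose surface
    label cannot be mapped or whose values violate record invariants.
    """
    if dialect is None:
        dialect = DEFAULT_DIALECT
    elif isinstance(dialect, (str, Path)):
        dialect = load_dialect(dialect)

    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    for canonical in _MANDATORY:
        if _column_for(dialect, canonical) not in df.columns:
            raise ConfigurationError(
                f"mandatory column {canonical!r} "
                f"(file column {_column_for(dialect, canonical)!r}) is missing"
            )

    surface_map = dict(_DEFAULT_SURFACE_MAP)
    surface_map.update(dialect.get("surface_map", {}))
    units = dialect.get("units", {})

    records: list[GasExchangeRecord] = []
    bad_surface_rows: list[int] = []
    for i, row in df.iterrows():
        raw_surface = str(row[_column_for(dialect, "surface")]).strip().lower()
        if raw_surface not in surface_map:
            bad_surface_rows.append(int(i))
            continue
        kwargs: dict = {"surface": surface_map[raw_surface]}
        kwargs["plant_id"] = str(row[_column_for(dialect, "plant_id")])
        for fname in _RECORD_FIELDS:
            if fname in ("plant_id", "surface", "flagged"):
                continue
            col = _column_for(dialect, fname)
            if col not in df.columns:
                continue
            cell = row[col]
            if pd.isna(cell) or str(cell).strip() == "":
                continue
            try:
                value = float(cell)
            except (TypeError, ValueError) as exc:
                raise ParseError(
                    f"non-numeric value {cell!r} in column {col!r}, row {i}"
                ) from exc
            kwargs[fname] = value * float(units.get(fname, 1.0))
        tkw: dict = {}
        for fname in _TREATMENT_FIELDS:
            col = _column_for(dialect, fname)
            if col in df.columns and not pd.isna(row[col]):
                raw = row[col]
                tkw[fname] = (
                    float(raw) if fname in ("co2_ppm", "canopy_vpd_kpa") else str(raw)
                )
        if tkw:
            kwargs["treatment"] = Treatment(**tkw)
        try:
            records.append(GasExchangeRecord(**kwargs))
        except ValidationError as exc:
            raise ValidationError(str(exc), rows=[int(i)]) from exc

    if bad_surface_rows:
        raise ValidationError("unmappable surface labels", rows=bad_surface_rows)
    return records


def records_to_frame(records: Iterable[GasExchangeRecord]) -> pd.DataFrame:
    """Flatten records (and their treatments) into a canonical DataFrame."""
    rows = []
    for rec in records:
        d = {f: getattr(rec, f) for f in _RECORD_FIELDS}
        d.update({f: getattr(rec.treatment, f) for f in _TREATMENT_FIELDS})
        rows.append(d)
    return pd.DataFrame(rows, columns=_RECORD_FIELDS + _TREATMENT_FIELDS)


def write_gasx_table(records: Iterable[GasExchangeRecord], path: str | Path) -> None:
    """Write records to a canonical-unit CSV; round-trips through
    :func:`read_gasx_table` with the default dialect field-for-field."""
    records = list(records)
    df = records_to_frame(records)
    df.to_csv(path, index=False)


def frame_to_records(df: pd.DataFrame) -> list[GasExchangeRecord]:
    """Inverse of :func:`records_to_frame` for canonical frames."""
    out = []
    for _, row in df.iterrows():
        kwargs = {}
        for fname in _RECORD_FIELDS:
            if fname == "flagged":
                continue
            v = row.get(fname)
            if fname in ("plant_id", "surface"):
                kwargs[fname] = str(v)
            elif v is not None and not pd.isna(v):
                kwargs[fname] = float(v)
        tkw = {
            f: row[f]
            for f in _TREATMENT_FIELDS
            if f in row.index and not pd.isna(row[f])
        }
        if tkw:
            kwargs["treatment"] = Treatment(**tkw)
        out.append(GasExchangeRecord(**kwargs))
    return out


def ledgers_to_frame(ledgers: Iterable[PlantLedger]) -> pd.DataFrame:
    rows = []
    for led in ledgers:
        d = {
            "plant_id": led.plant_id,
            "water_applied_l": led.water_applied_l,
            "ear_weight_g": led.ear_weight_g,
            "biomass_g": led.biomass_g,
        }
        d.update({f: getattr(led.treatment, f) for f in _TREATMENT_FIELDS})
        rows.append(d)
    return pd.DataFrame(rows)
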