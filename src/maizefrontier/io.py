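"""Data model, CSV ingestion and unit/date normalisation.

All yields are carried internally in Mg ha^-1 on a 155 g kg^-1 grain-moisture
basis; all planting dates as 1-based day of the year (DOY).  Field records
come from yield-contest submissions or from literature compilations; only
latitude, planting date and yield are mandatory, every management covariate
may be missing.
"""

from __future__ import annotations

import datetime as _dt
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

#: target grain-moisture content, wet basis (155 g kg^-1)
MOISTURE_STANDARD = 0.155

#: mass of one maize bushel (56 lb) in kg
KG_PER_BUSHEL = 25.4012
#: hectares per acre
HA_PER_ACRE = 0.404686
#: Mg ha^-1 per bu ac^-1 for maize grain
BU_AC_TO_MG_HA = KG_PER_BUSHEL / HA_PER_ACRE / 1000.0

YIELD_UNITS = ("bu_ac", "t_ha", "mg_ha")
TILLAGE_CLASSES = ("CT", "NT", "RT")

#: canonical input CSV header
CSV_COLUMNS = (
    "year", "state", "county", "latitude", "planting_date",
    "yield_value", "yield_unit", "grain_moisture", "irrigated", "tillage",
    "row_spacing_cm", "seeding_rate", "n_kgha", "p_kgha", "k_kgha", "dataset",
)

MANDATORY_COLUMNS = ("latitude", "planting_date", "yield_value")

#: normalised (internal) column order
NORMALIZED_COLUMNS = (
    "year", "state", "county", "latitude", "planting_doy", "yield_mgha",
    "irrigated", "tillage", "row_spacing_cm", "seeding_rate",
    "n_kgha", "p_kgha", "k_kgha", "dataset",
)

LATITUDE_RANGE = (20.0, 55.0)


class SchemaError(ValueError):
    """A mandatory input column is missing or malformed."""


@dataclass(frozen=True)
class FieldRecord:
    """One field-year observation."""

    year: int | None
    state: str | None
    county: str | None
    latitude: float
    planting_doy: int
    yield_mgha: float
    irrigated: bool | None = None
    tillage: str | None = None
    row_spacing_cm: float | None = None
    seeding_rate: float | None = None
    n_kgha: float | None = None
    p_kgha: float | None = None
    k_kgha: float | None = None
    dataset: str | None = None


@dataclass
class LoadReport:
    """Row-level accounting of a CSV load."""

    n_read: int = 0
    n_loaded: int = 0
    n_dropped: int = 0
    reasons: Counter = field(default_factory=Counter)

    def to_dict(self) -> dict:
        return {
            "n_read": self.n_read,
            "n_loaded": self.n_loaded,
            "n_dropped": self.n_dropped,
            "reasons": dict(self.reasons),
        }


@dataclass
class Dataset:
    """An ordered collection of validated field records.

    ``df`` holds one row per record in the normalised column layout
    (:data:`NORMALIZED_COLUMNS`).  ``report`` is populated by
    :func:`load_dataset`.
    """

    df: pd.DataFrame
    provenance: str = ""
    report: LoadReport | None = None

    @property
    def n(self) -> int:
        return len(self.df)

    @property
    def records(self) -> Iterator[FieldRecord]:
        for row in self.df.itertuples(index=False):
            d = row._asdict()
            yield FieldRecord(**{
                k: (None if pd.isna(v) else v) for k, v in d.items()
                if k in FieldRecord.__dataclass_fields__
            })

    def to_csv(self, path: str | Path) -> None:
        """Write back in the input CSV schema (already-normalised units)."""
        out = pd.DataFrame({
            "year": self.df["year"],
            "state": self.df["state"],
            "county": self.df["county"],
            "latitude": self.df["latitude"],
            "planting_date": self.df["planting_doy"],
            "yield_value": self.df["yield_mgha"],
            "yield_unit": "mg_ha",
            "grain_moisture": MOISTURE_STANDARD,
            "irrigated": self.df["irrigated"],
            "tillage": self.df["tillage"],
            "row_spacing_cm": self.df["row_spacing_cm"],
            "seeding_rate": self.df["seeding_rate"],
            "n_kgha": self.df["n_kgha"],
            "p_kgha": self.df["p_kgha"],
            "k_kgha": self.df["k_kgha"],
            "dataset": self.df["dataset"],
        })
        out.to_csv(path, index=False)


def date_to_doy(date: _dt.date | str) -> int:
    """1-based ordinal day within the date's own calendar year."""
    if isinstance(date, str):
        try:
            date = _dt.date.fromisoformat(date)
        except ValueError as exc:
            raise ValueError(f"unparseable date {date!r}") from exc
    return date.timetuple().tm_yday


def unit_to_mgha(value: float, unit: str) -> float:
    """Convert a yield to Mg ha^-1.

    Supported units: ``bu_ac`` (maize bushel of 56 lb per acre), ``t_ha``
    (metric ton = Mg, identity) and ``mg_ha``.
    """
    if unit in ("mg_ha", "t_ha"):
        return float(value)
    if unit == "bu_ac":
        return float(value) * BU_AC_TO_MG_HA
    raise ValueError(f"unknown yield unit {unit!r}; supported: {YIELD_UNITS}")


def moisture_adjust(yield_wet: float, moisture_raw: float) -> float:
    """Rescale a yield to the 155 g kg^-1 moisture basis.

    Constant-dry-matter rule: ``y * (1 - m) / (1 - 0.155)``.
    """
    m = np.asarray(moisture_raw, dtype=float)
    if np.any(m < 0) or np.any(m >= 1):
        raise ValueError("grain moisture must be a fraction in [0, 1)")
    return yield_wet * (1.0 - m) / (1.0 - MOISTURE_STANDARD)


def _parse_doy(value, year) -> int | None:
    if pd.isna(value):
        return None
    s = str(value).strip()
    try:
        doy = int(float(s))
    except ValueError:
        try:
            doy = date_to_doy(s)
        except ValueError:
            return None
        return doy
    if float(s) != doy:
        return None
    return doy


_TRUTHY = {"1", "true", "t", "yes", "y", "irrigated"}
_FALSY = {"0", "false", "f", "no", "n", "non-irrigated", "nonirrigated", "dryland"}


def _parse_bool(value):
    if pd.isna(value):
        return pd.NA
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    s = str(value).strip().lower()
    if s in _TRUTHY:
        return True
    if s in _FALSY:
        return False
    return pd.NA


def _parse_moisture(value) -> float | None:
    """Grain moisture: fractions as-is, values > 1 read as g kg^-1."""
    if pd.isna(value) or str(value).strip() == "":
        return MOISTURE_STANDARD
    m = float(value)
    if m > 1.0:
        m = m / 1000.0
    return m


def load_dataset(path: str | Path, schema_options: Mapping | None = None) -> Dataset:
    """Load and validate a field-record CSV.

    Rows failing validation (non-positive yield, latitude outside
    [20, 55] degN, unparseable planting date, DOY outside [1, 366]) are
    dropped and tallied in ``Dataset.report``.

    Raises
    ------
    SchemaError
        if a mandatory column is absent.
    """
    opts = dict(schema_options or {})
    default_unit = opts.get("default_unit", "mg_ha")
    provenance = opts.get("provenance", str(path))

    raw = pd.read_csv(path, dtype={"state": str, "county": str, "dataset": str})
    for col in MANDATORY_COLUMNS:
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column {col!r}")
    for col in CSV_COLUMNS:
        if col not in raw.columns:
            raw[col] = pd.NA

    report = LoadReport(n_read=len(raw))
    rows = []
    for rec in raw.itertuples(index=False):
        reason = None
        year = None if pd.isna(rec.year) else int(rec.year)
        doy = _parse_doy(rec.planting_date, year)
        if doy is None:
            reason = "unparseable_planting_date"
        elif not (1 <= doy <= 366):
            reason = "doy_out_of_range"
        lat = None if pd.isna(rec.latitude) else float(rec.latitude)
        if reason is None and lat is None:
            reason = "missing_latitude"
        if reason is None and not (LATITUDE_RANGE[0] <= lat <= LATITUDE_RANGE[1]):
            reason = "latitude_out_of_range"
        if reason is None:
            unit = default_unit if pd.isna(rec.yield_unit) else str(rec.yield_unit)
            try:
                y = unit_to_mgha(float(rec.yield_value), unit)
                y = moisture_adjust(y, _parse_moisture(rec.grain_moisture))
            except (TypeError, ValueError):
                reason = "unparseable_yield"
            else:
                if not np.isfinite(y) or y <= 0:
                    reason = "nonpositive_yield"
        if reason is not None:
            report.n_dropped += 1
            report.reasons[reason] += 1
            continue
        till = rec.tillage
        if not pd.isna(till):
            till = str(till).strip().upper()
            if till not in TILLAGE_CLASSES:
                till = pd.NA
        rows.append({
            "year": year,
            "state": rec.state if not pd.isna(rec.state) else pd.NA,
            "county": rec.county if not pd.isna(rec.county) else pd.NA,
            "latitude": lat,
            "planting_doy": doy,
            "yield_mgha": y,
            "irrigated": _parse_bool(rec.irrigated),
            "tillage": till,
            "row_spacing_cm": float(rec.row_spacing_cm) if not pd.isna(rec.row_spacing_cm) else np.nan,
            "seeding_rate": float(rec.seeding_rate) if not pd.isna(rec.seeding_rate) else np.nan,
            "n_kgha": float(rec.n_kgha) if not pd.isna(rec.n_kgha) else np.nan,
            "p_kgha": float(rec.p_kgha) if not pd.isna(rec.p_kgha) else np.nan,
            "k_kgha": float(rec.k_kgha) if not pd.isna(rec.k_kgha) else np.nan,
            "dataset": rec.dataset if not pd.isna(rec.dataset) else pd.NA,
        })

    df = pd.DataFrame(rows, columns=list(NORMALIZED_COLUMNS))
    df["irrigated"] = df["irrigated"].astype("boolean")
    df["year"] = df["year"].astype("Int64")
    report.n_loaded = len(df)
    return Dataset(df=df, provenance=provenance, report=report)
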