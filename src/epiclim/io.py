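"""Case-table and gridded-field data model with CSV / NetCDF readers and writers.

The case table is the universal input: one row per disease onset with a
calendar date, WGS84 coordinates and optional clinical covariates.  Gridded
fields are daily (time, lat, lon) arrays read from CF-style NetCDF.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import xarray as xr

__all__ = [
    "SchemaError",
    "CaseValidationError",
    "GridFormatError",
    "StudyPeriod",
    "CaseRecord",
    "CaseTable",
    "DailyCounts",
    "GriddedSeries",
    "read_cases",
    "write_cases",
    "daily_counts",
    "read_gridded",
    "write_gridded",
]

#: Required columns of the case CSV schema.
REQUIRED_COLUMNS = ("case_id", "onset_date", "lat", "lon")
#: Optional clinical covariate columns.
OPTIONAL_COLUMNS = ("age", "sex", "esr", "anc", "crp", "ggt_elevated", "illness_day")

#: Known gridded variables and their units.
VARIABLE_UNITS = {
    "tmax": "degC",
    "tmin": "degC",
    "precip": "mm/day",
    "hgt700": "m",
    "uwnd": "m/s",
    "vwnd": "m/s",
}


class SchemaError(ValueError):
    """A file does not match the expected column/variable schema."""


class CaseValidationError(ValueError):
    """One or more case rows violate the data-model invariants."""


class GridFormatError(ValueError):
    """A gridded file has a malformed time axis or missing variable."""


@dataclass(frozen=True)
class StudyPeriod:
    """Inclusive range of calendar dates."""

    start: dt.date
    end: dt.date

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(f"start {self.start} after end {self.end}")

    @property
    def n_days(self) -> int:
        return (self.end - self.start).days + 1

    def contains(self, d: dt.date) -> bool:
        return self.start <= d <= self.end

    def day_index(self, d: dt.date) -> int:
        """0-based offset of ``d`` from the period start."""
        return (d - self.start).days

    def date_of(self, index: int) -> dt.date:
        return self.start + dt.timedelta(days=int(index))

    def dates(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, self.end, freq="D")


@dataclass(frozen=True)
class CaseRecord:
    """One disease onset: date, home location, and clinical covariates.

    ``onset_date`` is the first day of fever.  Missing covariates are None.
    """

    case_id: str
    onset_date: dt.date
    lat: float
    lon: float
    age: float | None = None
    sex: str = "unknown"  # one of {"M", "F", "unknown"}
    esr: float | None = None
    anc: float | None = None
    crp: float | None = None
    ggt_elevated: bool | None = None
    illness_day: int | None = None

    def __post_init__(self) -> None:
        if not -90.0 <= self.lat <= 90.0:
            raise CaseValidationError(f"case {self.case_id}: lat {self.lat} outside [-90, 90]")
        if not -180.0 <= self.lon <= 180.0:
            raise CaseValidationError(f"case {self.case_id}: lon {self.lon} outside [-180, 180]")
        if self.age is not None and self.age < 0:
            raise CaseValidationError(f"case {self.case_id}: negative age {self.age}")
        if self.sex not in ("M", "F", "unknown"):
            raise CaseValidationError(f"case {self.case_id}: bad sex {self.sex!r}")


@dataclass(frozen=True)
class CaseTable:
    """Date-sorted collection of :class:`CaseRecord` within a study period."""

    records: tuple[CaseRecord, ...]
    period: StudyPeriod

    def __post_init__(self) -> None:
        recs = tuple(sorted(self.records, key=lambda r: (r.onset_date, r.case_id)))
        object.__setattr__(self, "records", recs)
        seen: set[str] = set()
        bad_period: list[str] = []
        for r in recs:
            if r.case_id in seen:
                raise CaseValidationError(f"duplicate case_id {r.case_id!r}")
            seen.add(r.case_id)
            if not self.period.contains(r.onset_date):
                bad_period.append(r.case_id)
        if bad_period:
            raise CaseValidationError(
                f"onset outside study period for case_ids: {', '.join(bad_period)}"
            )

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[CaseRecord]:
        return iter(self.records)

    @property
    def onset_dates(self) -> list[dt.date]:
        return [r.onset_date for r in self.records]

    @property
    def day_indices(self) -> np.ndarray:
        """0-based day offset of each onset from the period start."""
        return np.array([self.period.day_index(r.onset_date) for r in self.records], dtype=int)

    @property
    def coords(self) -> np.ndarray:
        """(n, 2) array of (lat, lon)."""
        return np.array([(r.lat, r.lon) for r in self.records], dtype=float).reshape(-1, 2)

    def trait(self, name: str) -> np.ndarray:
        """Trait values as a float array with NaN for missing."""
        if not self.records:
            return np.empty(0)
        if name not in {f.name for f in dataclasses.fields(CaseRecord)}:
            raise SchemaError(f"unknown trait {name!r}")
        vals = []
        for r in self.records:
            v = getattr(r, name)
            if v is None:
                vals.append(np.nan)
            elif isinstance(v, bool):
                vals.append(float(v))
            else:
                vals.append(float(v))
        return np.asarray(vals, dtype=float)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for r in self.records:
            rows.append(
                {
                    "case_id": r.case_id,
                    "onset_date": r.onset_date.isoformat(),
                    "lat": r.lat,
                    "lon": r.lon,
                    "age": r.age,
                    "sex": r.sex if r.sex != "unknown" else "",
                    "esr": r.esr,
                    "anc": r.anc,
                    "crp": r.crp,
                    "ggt_elevated": (None if r.ggt_elevated is None else int(r.ggt_elevated)),
                    "illness_day": r.illness_day,
                }
            )
        cols = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
        return pd.DataFrame(rows, columns=cols)


@dataclass(frozen=True)
class DailyCounts:
    """Number of onsets per day over a study period."""

    period: StudyPeriod
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=int)
        if counts.shape != (self.period.n_days,):
            raise ValueError(
                f"counts length {counts.shape} != period length {self.period.n_days}"
            )
        if (counts < 0).any():
            raise ValueError("negative counts")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class GriddedSeries:
    """Daily gridded field: values shaped (time, lat, lon), NaN = missing."""

    variable: str
    units: str
    dates: pd.DatetimeIndex
    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        expected = (len(self.dates), len(self.lats), len(self.lons))
        if self.values.shape != expected:
            raise ValueError(f"values shape {self.values.shape} != {expected}")
        deltas = np.diff(self.dates.values).astype("timedelta64[D]").astype(int)
        if len(deltas) and not (deltas == 1).all():
            raise GridFormatError("time axis not daily-contiguous")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    def to_dataset(self) -> xr.Dataset:
        da = xr.DataArray(
            self.values,
            dims=("time", "lat", "lon"),
            coords={"time": self.dates, "lat": self.lats, "lon": self.lons},
            name=self.variable,
            attrs={"units": self.units},
        )
        return da.to_dataset()


def _parse_float(text: str, what: str, line: int) -> float:
    try:
        return float(text)
    except ValueError:
        raise CaseValidationError(f"line {line}: cannot parse {what} {text!r}") from None


def _row_to_record(row: pd.Series, line: int) -> CaseRecord:
    def opt(col: str) -> str | None:
        if col not in row or pd.isna(row[col]) or str(row[col]).strip() == "":
            return None
        return str(row[col]).strip()

    raw_date = str(row["onset_date"]).strip()
    try:
        onset = dt.date.fromisoformat(raw_date[:10]) if "T" in raw_date or " " in raw_date else dt.date.fromisoformat(raw_date)
    except ValueError:
        raise CaseValidationError(f"line {line}: unparseable onset_date {raw_date!r}") from None
    ggt = opt("ggt_elevated")
    sex = opt("sex") or "unknown"
    ill = opt("illness_day")
    return CaseRecord(
        case_id=str(row["case_id"]).strip(),
        onset_date=onset,
        lat=_parse_float(str(row["lat"]), "lat", line),
        lon=_parse_float(str(row["lon"]), "lon", line),
        age=None if opt("age") is None else _parse_float(opt("age"), "age", line),
        sex=sex,
        esr=None if opt("esr") is None else _parse_float(opt("esr"), "esr", line),
        anc=None if opt("anc") is None else _parse_float(opt("anc"), "anc", line),
        crp=None if opt("crp") is None else _parse_float(opt("crp"), "crp", line),
        ggt_elevated=None if ggt is None else bool(int(float(ggt))),
        illness_day=None if ill is None else int(float(ill)),
    )


def read_cases(path: str | Path, period: StudyPeriod) -> CaseTable:
    """Read and validate a case CSV into a :class:`CaseTable`.

    Rows with unparseable dates or coordinates raise a line-numbered
    :class:`CaseValidationError`; a missing required column raises
    :class:`SchemaError`; onsets outside ``period`` raise with offending ids.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns: {', '.join(missing)}")
    errors: list[str] = []
    records: list[CaseRecord] = []
    for i, (_, row) in enumerate(df.iterrows()):
        line = i + 2  # header is line 1
        try:
            records.append(_row_to_record(row, line))
        except CaseValidationError as exc:
            errors.append(str(exc))
    if errors:
        raise CaseValidationError("; ".join(errors))
    outside = [r.case_id for r in records if not period.contains(r.onset_date)]
    if outside:
        raise CaseValidationError(
            f"onset outside study period for case_ids: {', '.join(outside)}"
        )
    return CaseTable(records=tuple(records), period=period)


def write_cases(cases: CaseTable, path: str | Path) -> None:
    """Write a case table to CSV using the canonical schema."""
    cases.to_frame().to_csv(path, index=False)


def daily_counts(cases: CaseTable) -> DailyCounts:
    """Count onsets per day; the total always equals the number of cases."""
    counts = np.zeros(cases.period.n_days, dtype=int)
    if len(cases):
        np.add.at(counts, cases.day_indices, 1)
    return DailyCounts(period=cases.period, counts=counts)


_MAX_GAP_DAYS = 2


def read_gridded(path: str | Path, variable: str) -> GriddedSeries:
    """Read one variable from a CF-style NetCDF file.

    The time axis must be strictly increasing with no duplicates; gaps of at
    most two days are filled with NaN, longer gaps raise
    :class:`GridFormatError`.
    """
    ds = xr.open_dataset(path, engine="scipy")
    try:
        if variable not in ds.data_vars:
            avail = ", ".join(sorted(ds.data_vars))
            raise GridFormatError(f"{path}: variable {variable!r} not found; available: {avail}")
        da = ds[variable].load()
    finally:
        ds.close()
    times = pd.DatetimeIndex(da["time"].values).normalize()
    if times.has_duplicates:
        raise GridFormatError("time axis contains duplicate days")
    if not times.is_monotonic_increasing:
        raise GridFormatError("time axis not monotonically increasing")
    deltas = np.diff(times.values).astype("timedelta64[D]").astype(int)
    if len(deltas) and (deltas < 1).any():
        raise GridFormatError("time axis not daily (sub-daily spacing)")
    if len(deltas) and (deltas > _MAX_GAP_DAYS + 1).any():
        worst = int(deltas.max()) - 1
        raise GridFormatError(f"time axis gap of {worst} days exceeds {_MAX_GAP_DAYS}")
    full = pd.date_range(times[0], times[-1], freq="D")
    da = da.assign_coords(time=times).reindex(time=full)
    units = str(da.attrs.get("units", VARIABLE_UNITS.get(variable, "")))
    return GriddedSeries(
        variable=variable,
        units=units,
        dates=full,
        lats=np.asarray(da["lat"].values, dtype=float),
        lons=np.asarray(da["lon"].values, dtype=float),
        values=np.asarray(da.values, dtype=float),
    )


def write_gridded(series: GriddedSeries | Sequence[GriddedSeries], path: str | Path) -> None:
    """Write one or several gridded series (sharing axes) to NetCDF."""
    if isinstance(series, GriddedSeries):
        series = [series]
    ds = xr.merge([s.to_dataset() for s in series])
    ds.attrs["Conventions"] = "CF-1.6"
    ds.to_netcdf(path, engine="scipy")
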