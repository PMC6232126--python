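"""Day-of-year climatology, anomalies and event-lagged composite maps.

Climatology is a per-cell day-of-year mean over years, circularly smoothed
with a centred running mean (default 5 days for surface variables, 7 days
for 700 hPa fields).  Anomalies subtract the climatology by day-of-year
lookup; Feb 29 uses the mean of the Feb 28 and Mar 1 climatology.
Composites pool anomaly maps over event-relative lag bins around the date
of onset and mask cells where the one-sample t statistic exceeds the
two-sided critical value.
"""
from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .clusters import TemporalCluster
from .io import CaseTable, GriddedSeries

__all__ = [
    "Climatology",
    "AnomalySeries",
    "EventGroupSpec",
    "CompositeResult",
    "DEFAULT_LAG_BINS",
    "SEASON_MONTHS",
    "day_of_year_climatology",
    "anomalies",
    "resolve_event_groups",
    "composite_anomaly",
]

#: Season name -> set of calendar months.
SEASON_MONTHS = {
    "ALL": set(range(1, 13)),
    "DJFMA": {12, 1, 2, 3, 4},
    "MJJA": {5, 6, 7, 8},
}

#: Event-relative day-offset bins around the date of onset.
DEFAULT_LAG_BINS: tuple[tuple[int, ...], ...] = (
    (-5, -4),
    (-3, -2),
    (-1,),
    (0,),
    (1,),
    (2, 3),
    (4, 5),
)

GROUP_NAMES = ("no_case_days", "all_case_days", "noncluster_case_days", "cluster_case_days")


@dataclass(frozen=True)
class Climatology:
    """Smoothed per-cell day-of-year mean on a 365-day calendar."""

    variable: str
    units: str
    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray  # (365, nlat, nlon)
    smooth_window_days: int

    def __post_init__(self) -> None:
        if self.values.shape[0] != 365:
            raise ValueError("climatology must have 365 day-of-year rows")


@dataclass
class AnomalySeries:
    """Daily field minus its day-of-year climatology (same axes)."""

    variable: str
    units: str
    dates: pd.DatetimeIndex
    lats: np.ndarray
    lons: np.ndarray
    values: np.ndarray

    def map_on(self, day: dt.date) -> np.ndarray | None:
        """Anomaly map for a calendar day, or None if outside coverage."""
        ts = pd.Timestamp(day)
        if ts < self.dates[0] or ts > self.dates[-1]:
            return None
        return self.values[(ts - self.dates[0]).days]


@dataclass(frozen=True)
class EventGroupSpec:
    """A named set of event dates restricted to a season."""

    group: str
    season: str
    dates: tuple[dt.date, ...]

    def __post_init__(self) -> None:
        if self.group not in GROUP_NAMES:
            raise ValueError(f"unknown group {self.group!r}")
        if self.season not in SEASON_MONTHS:
            raise ValueError(f"unknown season {self.season!r}")

    @property
    def empty(self) -> bool:
        return len(self.dates) == 0


@dataclass(frozen=True)
class CompositeResult:
    """Per-lag-bin composite anomaly maps with t-statistic significance."""

    variable: str
    group: str
    season: str
    lag_bins: tuple[tuple[int, ...], ...]
    mean_maps: np.ndarray  # (n_bins, nlat, nlon)
    t_maps: np.ndarray
    masks: np.ndarray  # bool, |t| > two-sided critical value
    n_per_bin: np.ndarray
    n_dropped_per_bin: np.ndarray
    confidence: float


def _doy365(dates: pd.DatetimeIndex) -> tuple[np.ndarray, np.ndarray]:
    """Non-leap day-of-year index (0..364) and a Feb-29 flag per date."""
    doy = dates.dayofyear.values.copy()
    leap = dates.is_leap_year
    feb29 = leap & (dates.month == 2) & (dates.day == 29)
    after = leap & (doy > 59)  # dates after Feb 29 in leap years
    doy = np.where(after, doy - 1, doy)
    return doy - 1, np.asarray(feb29)


def _circular_running_mean(values: np.ndarray, window: int) -> np.ndarray:
    """Centred running mean along axis 0 with wraparound."""
    if window == 1:
        return values
    half = window // 2
    padded = np.concatenate([values[-half:], values, values[:half]], axis=0)
    csum = np.cumsum(padded, axis=0)
    csum = np.concatenate([np.zeros_like(csum[:1]), csum], axis=0)
    return (csum[window:] - csum[:-window]) / window


def day_of_year_climatology(
    field: GriddedSeries,
    smooth_window_days: int = 5,
    years: range | None = None,
) -> Climatology:
    """Per-cell smoothed day-of-year mean over at least two full years.

    Feb 29 values contribute to neither day-of-year slot; the Feb 29
    climatology is reconstructed at anomaly time from adjacent days.
    """
    if smooth_window_days < 1 or smooth_window_days % 2 == 0:
        raise ValueError("smooth_window_days must be odd and >= 1")
    dates = field.dates
    vals = field.values
    if years is not None:
        keep = np.isin(dates.year, np.asarray(list(years)))
        dates, vals = dates[keep], vals[keep]
    n_years = len(np.unique(dates.year))
    if len(dates) < 730 or n_years < 2:
        raise ValueError("climatology needs at least 2 full years of data")
    doy, feb29 = _doy365(dates)
    sums = np.zeros((365,) + vals.shape[1:])
    cnts = np.zeros((365,) + vals.shape[1:])
    ok = ~feb29
    good = ok[:, None, None] & np.isfinite(vals)
    np.add.at(sums, doy, np.where(good, vals, 0.0))
    np.add.at(cnts, doy, good.astype(float))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        clim = sums / cnts
    clim = _circular_running_mean(clim, smooth_window_days)
    return Climatology(
        variable=field.variable,
        units=field.units,
        lats=field.lats,
        lons=field.lons,
        values=clim,
        smooth_window_days=smooth_window_days,
    )


def anomalies(field: GriddedSeries, clim: Climatology) -> AnomalySeries:
    """Daily condition minus climatology, matched by day-of-year."""
    if field.variable != clim.variable:
        raise ValueError(f"variable mismatch: {field.variable} vs {clim.variable}")
    if field.values.shape[1:] != clim.values.shape[1:] or not (
        np.array_equal(field.lats, clim.lats) and np.array_equal(field.lons, clim.lons)
    ):
        raise ValueError("grid mismatch between field and climatology")
    doy, feb29 = _doy365(field.dates)
    ref = clim.values[doy]
    if feb29.any():
        feb28 = clim.values[58]  # doy index of Feb 28
        mar1 = clim.values[59]
        ref[feb29] = 0.5 * (feb28 + mar1)
    return AnomalySeries(
        variable=field.variable,
        units=field.units,
        dates=field.dates,
        lats=field.lats,
        lons=field.lons,
        values=field.values - ref,
    )


def resolve_event_groups(
    cases: CaseTable,
    clusters: list[TemporalCluster],
    season: str = "ALL",
    seed: int = 0,
) -> dict[str, EventGroupSpec]:
    """Resolve the four event-date groups for one season.

    Case-day groups are the distinct onset dates of the relevant cases;
    ``no_case_days`` is a seeded random sample (without replacement) of
    zero-onset days in the same season, matched in size to the all-case-day
    group.
    """
    months = SEASON_MONTHS[season]
    in_cluster_ids: set[str] = set()
    for cl in clusters:
        in_cluster_ids.update(cl.case_ids)

    def dates_of(records) -> tuple[dt.date, ...]:
        ds = sorted({r.onset_date for r in records if r.onset_date.month in months})
        return tuple(ds)

    all_days = dates_of(cases.records)
    cluster_days = dates_of([r for r in cases.records if r.case_id in in_cluster_ids])
    noncluster_days = dates_of([r for r in cases.records if r.case_id not in in_cluster_ids])

    onset_set = {r.onset_date for r in cases.records}
    candidates = [
        d.date()
        for d in cases.period.dates()
        if d.month in months and d.date() not in onset_set
    ]
    rng = np.random.default_rng(seed)
    k = min(len(all_days), len(candidates))
    no_case = tuple(sorted(
        candidates[i] for i in rng.choice(len(candidates), size=k, replace=False)
    )) if k else ()

    groups = {
        "no_case_days": EventGroupSpec("no_case_days", season, no_case),
        "all_case_days": EventGroupSpec("all_case_days", season, all_days),
        "noncluster_case_days": EventGroupSpec("noncluster_case_days", season, noncluster_days),
        "cluster_case_days": EventGroupSpec("cluster_case_days", season, cluster_days),
    }
    for name, spec in groups.items():
        if spec.empty:
            warnings.warn(f"event group {name!r} is empty for season {season}", stacklevel=2)
    return groups


def composite_anomaly(
    anoms: AnomalySeries,
    spec: EventGroupSpec,
    lag_bins: tuple[tuple[int, ...], ...] = DEFAULT_LAG_BINS,
    confidence: float = 0.95,
) -> CompositeResult:
    """Pooled mean anomaly, t statistic and significance mask per lag bin.

    Maps at date + offset are pooled over every event date and every offset
    in the bin (repeats kept).  Out-of-coverage days are dropped and
    counted.  t = mean / (sd / sqrt(n)); the mask is two-sided at the given
    confidence with n - 1 degrees of freedom (all-false when n < 2).
    """
    if not 0.5 < confidence < 1.0:
        raise ValueError("confidence must be in (0.5, 1)")
    shape = anoms.values.shape[1:]
    n_bins = len(lag_bins)
    mean_maps = np.full((n_bins,) + shape, np.nan)
    t_maps = np.full((n_bins,) + shape, np.nan)
    masks = np.zeros((n_bins,) + shape, dtype=bool)
    n_per_bin = np.zeros(n_bins, dtype=int)
    n_dropped = np.zeros(n_bins, dtype=int)
    for b, offsets in enumerate(lag_bins):
        maps = []
        for event in spec.dates:
            for off in offsets:
                m = anoms.map_on(event + dt.timedelta(days=int(off)))
                if m is None:
                    n_dropped[b] += 1
                else:
                    maps.append(m)
        n = len(maps)
        n_per_bin[b] = n
        if n == 0:
            continue
        stack = np.stack(maps)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            mean = np.nanmean(stack, axis=0)
            sd = np.nanstd(stack, axis=0, ddof=1) if n >= 2 else np.full(shape, np.nan)
        mean_maps[b] = mean
        if n >= 2:
            with np.errstate(divide="ignore", invalid="ignore"):
                t = mean / (sd / np.sqrt(n))
            t_maps[b] = t
            crit = stats.t.ppf(0.5 + confidence / 2.0, df=n - 1)
            masks[b] = np.abs(t) > crit
    return CompositeResult(
        variable=anoms.variable,
        group=spec.group,
        season=spec.season,
        lag_bins=tuple(tuple(b) for b in lag_bins),
        mean_maps=mean_maps,
        t_maps=t_maps,
        masks=masks,
        n_per_bin=n_per_bin,
        n_dropped_per_bin=n_dropped,
        confidence=confidence,
    )
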