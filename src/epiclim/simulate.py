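"""Synthetic case tables and gridded climate fields with known structure.

The case generator superimposes episodic bursts (clumped in time and space,
with burst-shared trait shifts) on a seasonal inhomogeneous background, so
downstream cluster, interaction, composite and trait analyses can be tested
against ground truth.  The climate generator emits seasonal-cycle + AR(1)
fields with an optional additive anomaly coupled to supplied event days.

All randomness flows from a single integer seed through one named
generator; identical configs give bit-identical output.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clusters import daily_probabilities
from .io import (
    VARIABLE_UNITS,
    CaseRecord,
    CaseTable,
    DailyCounts,
    GriddedSeries,
    StudyPeriod,
)

__all__ = [
    "MixtureComponent",
    "TraitModel",
    "GgtHotspot",
    "CaseSimConfig",
    "VariableSimParams",
    "ClimateSimConfig",
    "SimulatedCases",
    "simulate_cases",
    "simulate_climate",
    "seasonal_profile_from_counts",
]

_KM_PER_DEG_LAT = 111.19492664455873  # 2*pi*6371/360


@dataclass(frozen=True)
class MixtureComponent:
    """One Gaussian population centre of the background spatial mixture."""

    lat: float
    lon: float
    weight: float
    sd_km: float


@dataclass(frozen=True)
class TraitModel:
    """Baseline distribution of a clinical trait plus burst-shared shift.

    ``dist`` is "lognormal" (params mu, sigma on the log scale) or "gamma"
    (params shape, scale).  ``burst_shift_sd`` is the standard deviation of
    an additive shift on the log scale shared by all cases of one burst;
    zero disables trait autocorrelation.
    """

    dist: str
    params: tuple[float, ...]
    burst_shift_sd: float = 0.0
    missing_rate: float = 0.0

    def __post_init__(self) -> None:
        if self.dist not in ("lognormal", "gamma"):
            raise ValueError(f"unknown trait distribution {self.dist!r}")
        if self.burst_shift_sd < 0 or not 0 <= self.missing_rate <= 1:
            raise ValueError("invalid trait model parameters")

    def sample(self, n: int, shift: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        if self.dist == "lognormal":
            mu, sigma = self.params
            base = rng.lognormal(mu, sigma, size=n)
        else:
            shape, scale = self.params
            base = rng.gamma(shape, scale, size=n)
        vals = base * np.exp(shift)
        if self.missing_rate > 0:
            vals[rng.random(n) < self.missing_rate] = np.nan
        return vals


@dataclass(frozen=True)
class GgtHotspot:
    """Region where the binary trait is elevated with higher probability."""

    lat: float
    lon: float
    radius_km: float
    p_inside: float
    p_outside: float

    def __post_init__(self) -> None:
        if not (0 <= self.p_inside <= 1 and 0 <= self.p_outside <= 1):
            raise ValueError("probabilities must be in [0, 1]")
        if self.radius_km < 0:
            raise ValueError("radius_km must be >= 0")


def _default_centers() -> tuple[MixtureComponent, ...]:
    return (
        MixtureComponent(lat=32.9, lon=-117.1, weight=0.6, sd_km=15.0),
        MixtureComponent(lat=33.2, lon=-117.3, weight=0.25, sd_km=10.0),
        MixtureComponent(lat=32.7, lon=-116.8, weight=0.15, sd_km=20.0),
    )


def _default_profile() -> tuple[float, ...]:
    # winter-spring peak, secondary June bump, early-fall nadir
    return (1.5, 1.6, 1.5, 1.1, 0.9, 1.2, 0.9, 0.8, 0.6, 0.6, 0.9, 1.2)


def _default_traits() -> dict[str, TraitModel]:
    return {
        "age": TraitModel("lognormal", (1.0, 0.6)),
        "esr": TraitModel("gamma", (4.0, 15.0)),
        "anc": TraitModel("gamma", (5.0, 1600.0)),
    }


@dataclass(frozen=True)
class CaseSimConfig:
    """Parameters of the synthetic case generator."""

    period: StudyPeriod
    n_expected: float = 300.0
    monthly_rate_profile: tuple[float, ...] = field(default_factory=_default_profile)
    burst_rate: float = 0.0  # expected bursts per year
    burst_duration_days: float = 7.0
    burst_size_mean: float = 5.0
    burst_spatial_sd_km: float = 5.0
    background_centers: tuple[MixtureComponent, ...] = field(default_factory=_default_centers)
    trait_models: dict[str, TraitModel] = field(default_factory=_default_traits)
    ggt_hotspot: GgtHotspot | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        prof = np.asarray(self.monthly_rate_profile, dtype=float)
        if prof.shape != (12,) or (prof < 0).any() or not prof.any():
            raise ValueError("monthly_rate_profile must be 12 nonnegative weights, not all zero")
        for name, v in (
            ("n_expected", self.n_expected),
            ("burst_rate", self.burst_rate),
            ("burst_duration_days", self.burst_duration_days),
            ("burst_size_mean", self.burst_size_mean),
            ("burst_spatial_sd_km", self.burst_spatial_sd_km),
        ):
            if v < 0:
                raise ValueError(f"{name} must be >= 0")
        if not self.background_centers:
            raise ValueError("need at least one background centre")


@dataclass(frozen=True)
class SimulatedCases:
    """Synthetic case table with ground-truth burst membership."""

    cases: CaseTable
    burst_id: dict[str, int | None]  # case_id -> burst index (None = background)

    @property
    def burst_case_ids(self) -> set[str]:
        return {cid for cid, b in self.burst_id.items() if b is not None}


def _scatter_km(lat0: float, lon0: float, sd_km: float, n: int, rng: np.random.Generator):
    dlat = rng.normal(0.0, sd_km, size=n) / _KM_PER_DEG_LAT
    dlon = rng.normal(0.0, sd_km, size=n) / (
        _KM_PER_DEG_LAT * max(np.cos(np.radians(lat0)), 1e-6)
    )
    return lat0 + dlat, lon0 + dlon


def _mixture_points(
    centers: tuple[MixtureComponent, ...], n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    w = np.array([c.weight for c in centers], dtype=float)
    w = w / w.sum()
    comp = rng.choice(len(centers), size=n, p=w)
    lat = np.empty(n)
    lon = np.empty(n)
    for k, c in enumerate(centers):
        idx = np.flatnonzero(comp == k)
        if len(idx):
            la, lo = _scatter_km(c.lat, c.lon, c.sd_km, len(idx), rng)
            lat[idx], lon[idx] = la, lo
    return lat, lon


def simulate_cases(config: CaseSimConfig) -> SimulatedCases:
    """Draw a synthetic case table: seasonal background plus injected bursts.

    The background total is Poisson(n_expected) allocated multinomially over
    days with probability proportional to the monthly profile; bursts are a
    marked Poisson process in time adding spatially tight clumps of extra
    cases whose traits share a per-burst shift.
    """
    period = config.period
    if period.n_days < 1:
        raise ValueError("empty study period")
    rng = np.random.default_rng(config.seed)

    # --- background onsets
    n_bg = rng.poisson(config.n_expected)
    day_p = daily_probabilities(np.asarray(config.monthly_rate_profile), period)
    bg_days = np.repeat(np.arange(period.n_days), rng.multinomial(n_bg, day_p))
    bg_lat, bg_lon = _mixture_points(config.background_centers, n_bg, rng)

    # --- bursts
    years = period.n_days / 365.25
    n_bursts = rng.poisson(config.burst_rate * years) if config.burst_rate > 0 else 0
    burst_days: list[np.ndarray] = []
    burst_lat: list[np.ndarray] = []
    burst_lon: list[np.ndarray] = []
    burst_labels: list[np.ndarray] = []
    for b in range(n_bursts):
        dur = max(1, int(rng.poisson(config.burst_duration_days)))
        dur = min(dur, period.n_days)
        start = int(rng.integers(0, period.n_days - dur + 1))
        size = int(rng.poisson(config.burst_size_mean))
        if size == 0:
            continue
        c_lat, c_lon = _mixture_points(config.background_centers, 1, rng)
        days = start + rng.integers(0, dur, size=size)
        la, lo = _scatter_km(float(c_lat[0]), float(c_lon[0]), config.burst_spatial_sd_km, size, rng)
        burst_days.append(days)
        burst_lat.append(la)
        burst_lon.append(lo)
        burst_labels.append(np.full(size, b))

    all_days = np.concatenate([bg_days] + burst_days) if (len(bg_days) or burst_days) else np.empty(0, int)
    all_lat = np.concatenate([bg_lat] + burst_lat) if len(all_days) else np.empty(0)
    all_lon = np.concatenate([bg_lon] + burst_lon) if len(all_days) else np.empty(0)
    labels = (
        np.concatenate([np.full(len(bg_days), -1)] + burst_labels).astype(int)
        if len(all_days)
        else np.empty(0, int)
    )
    n = len(all_days)

    # --- traits: baseline * exp(per-burst shared shift)
    traits: dict[str, np.ndarray] = {}
    for name, model in config.trait_models.items():
        shifts = np.zeros(n)
        if model.burst_shift_sd > 0 and n_bursts > 0:
            per_burst = rng.normal(0.0, model.burst_shift_sd, size=n_bursts)
            in_burst = labels >= 0
            shifts[in_burst] = per_burst[labels[in_burst]]
        traits[name] = model.sample(n, shifts, rng)

    # --- binary GGT label from spatial hotspot
    ggt: np.ndarray | None = None
    if config.ggt_hotspot is not None:
        hs = config.ggt_hotspot
        from .knox import great_circle_km

        d = np.array([great_circle_km((hs.lat, hs.lon), (la, lo)) for la, lo in zip(all_lat, all_lon)])
        p = np.where(d <= hs.radius_km, hs.p_inside, hs.p_outside)
        ggt = rng.random(n) < p

    order = np.argsort(all_days, kind="stable")
    width = max(4, len(str(max(n, 1))))
    records = []
    burst_map: dict[str, int | None] = {}
    for rank, i in enumerate(order):
        cid = f"c{rank + 1:0{width}d}"
        records.append(
            CaseRecord(
                case_id=cid,
                onset_date=period.date_of(int(all_days[i])),
                lat=float(np.clip(all_lat[i], -90, 90)),
                lon=float(np.clip(all_lon[i], -180, 180)),
                age=_maybe(traits.get("age"), i),
                esr=_maybe(traits.get("esr"), i),
                anc=_maybe(traits.get("anc"), i),
                ggt_elevated=None if ggt is None else bool(ggt[i]),
            )
        )
        burst_map[cid] = None if labels[i] < 0 else int(labels[i])
    table = CaseTable(records=tuple(records), period=period)
    return SimulatedCases(cases=table, burst_id=burst_map)


def _maybe(arr: np.ndarray | None, i: int) -> float | None:
    if arr is None:
        return None
    v = float(arr[i])
    return None if np.isnan(v) else v


@dataclass(frozen=True)
class VariableSimParams:
    """Per-variable seasonal cycle, AR(1) weather noise, event coupling."""

    mean: float = 0.0
    seasonal_cycle_amplitude: float = 0.0
    seasonal_peak_doy: float = 196.0  # mid-July
    ar1_coefficient: float = 0.0
    noise_sd: float = 0.0
    coupling_amplitude: float = 0.0

    def __post_init__(self) -> None:
        if not abs(self.ar1_coefficient) < 1:
            raise ValueError("|ar1_coefficient| must be < 1")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


@dataclass(frozen=True)
class ClimateSimConfig:
    """Grid, time axis, and per-variable parameters for climate simulation."""

    period: StudyPeriod
    lat_start: float = 32.0
    lat_stop: float = 34.0
    lon_start: float = -118.0
    lon_stop: float = -116.0
    step_deg: float = 0.5
    variables: dict[str, VariableSimParams] = field(
        default_factory=lambda: {"tmax": VariableSimParams(mean=22.0, seasonal_cycle_amplitude=6.0, ar1_coefficient=0.6, noise_sd=2.0)}
    )
    event_window_days: int = 5
    seed: int = 0

    def lat_axis(self) -> np.ndarray:
        return np.arange(self.lat_start, self.lat_stop + 1e-9, self.step_deg)

    def lon_axis(self) -> np.ndarray:
        return np.arange(self.lon_start, self.lon_stop + 1e-9, self.step_deg)


def simulate_climate(
    config: ClimateSimConfig, event_days: list[dt.date] | None = None
) -> dict[str, GriddedSeries]:
    """Simulate daily gridded fields on the configured axes.

    value(t, x) = mean + seasonal cycle(doy) + AR(1) noise(t, x)
                  + coupling * 1[t within +/- event_window_days of an event].
    """
    event_days = list(event_days or [])
    dates = config.period.dates()
    nt = len(dates)
    lats = config.lat_axis()
    lons = config.lon_axis()
    for d in event_days:
        if not config.period.contains(d):
            raise ValueError(f"event day {d} outside simulated period")

    # indicator of proximity to an event day
    near_event = np.zeros(nt, dtype=bool)
    if event_days:
        idx = np.array([config.period.day_index(d) for d in event_days])
        for k in range(-config.event_window_days, config.event_window_days + 1):
            shifted = idx + k
            ok = (shifted >= 0) & (shifted < nt)
            near_event[shifted[ok]] = True

    doy = dates.dayofyear.values.astype(float)
    rng = np.random.default_rng(config.seed)
    out: dict[str, GriddedSeries] = {}
    for var in sorted(config.variables):
        p = config.variables[var]
        seasonal = p.mean + p.seasonal_cycle_amplitude * np.cos(
            2 * np.pi * (doy - p.seasonal_peak_doy) / 365.25
        )
        field3d = np.broadcast_to(seasonal[:, None, None], (nt, len(lats), len(lons))).copy()
        if p.noise_sd > 0:
            eps = rng.normal(0.0, p.noise_sd, size=(nt, len(lats), len(lons)))
            noise = np.empty_like(eps)
            stat_sd = p.noise_sd / np.sqrt(1 - p.ar1_coefficient**2)
            noise[0] = rng.normal(0.0, stat_sd, size=(len(lats), len(lons)))
            for t in range(1, nt):
                noise[t] = p.ar1_coefficient * noise[t - 1] + eps[t]
            field3d += noise
        if p.coupling_amplitude != 0 and near_event.any():
            field3d[near_event] += p.coupling_amplitude
        out[var] = GriddedSeries(
            variable=var,
            units=VARIABLE_UNITS.get(var, ""),
            dates=dates,
            lats=lats,
            lons=lons,
            values=field3d,
        )
    return out


def seasonal_profile_from_counts(counts: DailyCounts) -> tuple[np.ndarray, np.ndarray]:
    """Observed monthly incidence profile (mean cases/day per month).

    Returns (weights, sds): weight[m] = total cases in month m+1 across
    years / total days in month m+1 across years, and the standard deviation
    of the per-year daily rate across years.  Needs at least one full year.
    """
    if counts.period.n_days < 365:
        raise ValueError("period must cover at least one full year")
    dates = counts.period.dates()
    df = pd.DataFrame({"count": counts.counts, "month": dates.month, "year": dates.year})
    weights = np.zeros(12)
    sds = np.zeros(12)
    for m in range(1, 13):
        sub = df[df.month == m]
        if len(sub) == 0:
            continue
        weights[m - 1] = sub["count"].sum() / len(sub)
        yearly = sub.groupby("year")["count"].mean()
        sds[m - 1] = float(yearly.std(ddof=1)) if len(yearly) >= 2 else 0.0
    return weights, sds
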