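"""All-in-one pipeline: clusters -> knox -> composites -> traits.

Wires the analysis stages together from a single :class:`RunConfig`,
writes every artifact under an output directory, and records a manifest
(parameter echo, seeds, input digests, outputs per stage).  Reruns with
the same config and inputs are deterministic.
"""
from __future__ import annotations

import dataclasses
import datetime as dt
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import composites as comp
from . import clusters as tc
from . import knox as kx
from . import traits as tr
from .io import StudyPeriod, daily_counts, read_cases, read_gridded
from .simulate import seasonal_profile_from_counts

__all__ = ["RunConfig", "run_pipeline"]


@dataclass(frozen=True)
class RunConfig:
    cases_path: str
    output_dir: str
    period_start: str
    period_end: str
    field_paths: tuple[str, ...] = ()
    field_variables: tuple[str, ...] = ()
    window_days: int = 7
    min_cases: int = 4
    null_reps: int = 500
    knox_reps: int = 999
    tau_grid: tuple[float, ...] = tuple(float(t) for t in range(1, 31))
    delta_grid: tuple[float, ...] = (1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0)
    seasons: tuple[str, ...] = ("ALL",)
    confidence: float = 0.95
    smooth_window_days: dict | None = None
    trait_names: tuple[str, ...] = ("age", "esr", "anc")
    trait_window_days: int = 10
    spatial_label: str | None = "ggt_elevated"
    seed: int = 0

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("field_paths", "field_variables", "tau_grid", "delta_grid",
                    "seasons", "trait_names"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _smooth_for(variable: str, config: RunConfig) -> int:
    defaults = {"tmax": 5, "tmin": 5, "precip": 5, "hgt700": 7, "uwnd": 7, "vwnd": 7}
    if config.smooth_window_days and variable in config.smooth_window_days:
        return int(config.smooth_window_days[variable])
    return defaults.get(variable, 5)


def write_clusters_csv(clusters: list[tc.TemporalCluster], path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["start_day", "end_day", "size", "duration_days", "case_ids"])
        for c in clusters:
            w.writerow([c.start_day.isoformat(), c.end_day.isoformat(), c.size,
                        c.duration_days, ";".join(c.case_ids)])


def write_knox_csv(grid: kx.KnoxGrid, path: Path) -> None:
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["tau", "delta", "x", "n_close_time", "n_close_space", "n_pairs",
                    "expected", "excess", "p_value"])
        for c in grid.cells:
            w.writerow([c.tau, c.delta, c.n_close_both, c.n_close_time, c.n_close_space,
                        c.n_pairs, f"{c.expected:.6g}",
                        "" if c.excess is None else f"{c.excess:.6g}", c.p_value])


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    period = StudyPeriod(
        dt.date.fromisoformat(config.period_start), dt.date.fromisoformat(config.period_end)
    )
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "inputs": {config.cases_path: _sha256(config.cases_path)},
        "stages": {},
        "outputs": [],
    }
    for p in config.field_paths:
        manifest["inputs"][p] = _sha256(p)

    def record(stage: str, status: str, **info) -> None:
        manifest["stages"][stage] = {"status": status, **info}

    def emit(path: Path) -> str:
        manifest["outputs"].append(str(path))
        return str(path)

    cases = read_cases(config.cases_path, period)
    counts = daily_counts(cases)
    params = tc.ClusterParams(config.window_days, config.min_cases)

    # --- stage 1: temporal clusters + seasonal null
    try:
        flags = tc.flag_cluster_days(counts, params)
        clusters = tc.extract_clusters(counts, flags, cases, params)
        write_clusters_csv(clusters, out / "clusters.csv")
        emit(out / "clusters.csv")
        curve = tc.cluster_size_curve(clusters, s_max=max(10, max((c.size for c in clusters), default=1)))
        profile, _ = seasonal_profile_from_counts(counts)
        ens = tc.seasonal_null_ensemble(
            len(cases), profile, period, params, n_reps=config.null_reps, seed=config.seed
        )
        report = tc.cluster_excess_test(len(clusters), curve, ens)
        cluster_json = {
            "n_clusters": report.observed_count,
            "null_mean": report.null_mean,
            "null_sd": report.null_sd,
            "t_statistic": report.t_statistic,
            "p_t_two_sided": report.p_t_two_sided,
            "p_t_upper": report.p_t_upper,
            "p_empirical": report.p_empirical,
            "degenerate": report.degenerate,
        }
        (out / "cluster_test.json").write_text(json.dumps(cluster_json, indent=2))
        emit(out / "cluster_test.json")
        record("clusters", "complete", n_clusters=len(clusters))
    except Exception as exc:  # noqa: BLE001 - stage failures abort with context
        record("clusters", "failed", error=str(exc))
        raise RuntimeError(f"stage 'clusters' failed: {exc}") from exc

    # --- stage 2: knox
    try:
        thresholds = kx.KnoxThresholds(
            np.asarray(config.tau_grid), np.asarray(config.delta_grid)
        )
        grid = kx.knox_permutation_test(
            cases, thresholds, n_reps=config.knox_reps, seed=config.seed + 1
        )
        write_knox_csv(grid, out / "knox.csv")
        emit(out / "knox.csv")
        record("knox", "complete", n_cells=len(grid.cells))
    except Exception as exc:  # noqa: BLE001
        record("knox", "failed", error=str(exc))
        raise RuntimeError(f"stage 'knox' failed: {exc}") from exc

    # --- stage 3: composites (skipped when no fields supplied)
    if not config.field_paths:
        record("composites", "skipped", reason="no gridded fields supplied")
        warnings.warn("composites stage skipped: no gridded fields supplied", stacklevel=2)
    else:
        try:
            variables = config.field_variables or ()
            n_written = 0
            for path in config.field_paths:
                for var in variables:
                    field_series = read_gridded(path, var)
                    clim = comp.day_of_year_climatology(field_series, _smooth_for(var, config))
                    anoms = comp.anomalies(field_series, clim)
                    for season in config.seasons:
                        groups = comp.resolve_event_groups(
                            cases, clusters, season, seed=config.seed + 2
                        )
                        for gname, spec in groups.items():
                            if spec.empty:
                                continue
                            result = comp.composite_anomaly(
                                anoms, spec, confidence=config.confidence
                            )
                            fname = out / f"composite_{var}_{season}_{gname}.nc"
                            _write_composite(result, anoms, fname)
                            emit(fname)
                            n_written += 1
            record("composites", "complete", n_composites=n_written)
        except Exception as exc:  # noqa: BLE001
            record("composites", "failed", error=str(exc))
            raise RuntimeError(f"stage 'composites' failed: {exc}") from exc

    # --- stage 4: traits
    try:
        trait_out: dict = {}
        for name in config.trait_names:
            res = tr.conditional_median_analysis(cases, name, config.trait_window_days)
            trait_out[name] = {
                "n_points": len(res.points),
                "regression_points": None
                if res.regression_points is None
                else dataclasses.asdict(res.regression_points),
                "regression_bins": None
                if res.regression_bins is None
                else dataclasses.asdict(res.regression_bins),
            }
        if config.spatial_label:
            try:
                sl = tr.spatial_label_permutation_test(
                    cases, config.spatial_label, n_reps=999, seed=config.seed + 3
                )
                trait_out[config.spatial_label] = {
                    "statistic": sl.statistic_name,
                    "observed_km": sl.observed,
                    "p_value": sl.p_value,
                }
            except ValueError as exc:
                trait_out[config.spatial_label] = {"skipped": str(exc)}
        (out / "traits.json").write_text(json.dumps(trait_out, indent=2))
        emit(out / "traits.json")
        record("traits", "complete")
    except Exception as exc:  # noqa: BLE001
        record("traits", "failed", error=str(exc))
        raise RuntimeError(f"stage 'traits' failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return manifest


def _write_composite(result: comp.CompositeResult, anoms, path: Path) -> None:
    import xarray as xr

    bins = [",".join(str(o) for o in b) for b in result.lag_bins]
    ds = xr.Dataset(
        {
            "mean_anomaly": (("bin", "lat", "lon"), result.mean_maps),
            "t_statistic": (("bin", "lat", "lon"), result.t_maps),
            "significant": (("bin", "lat", "lon"), result.masks.astype(np.int8)),
        },
        coords={"bin": bins, "lat": anoms.lats, "lon": anoms.lons},
        attrs={
            "variable": result.variable,
            "group": result.group,
            "season": result.season,
            "confidence": result.confidence,
        },
    )
    ds.to_netcdf(path, engine="scipy")
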