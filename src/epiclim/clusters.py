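"""Two-stage temporal cluster construction with a seasonal Monte Carlo null.

A day is a *cluster day* if any full moving window of ``window_days``
consecutive days that contains it holds at least ``min_cases`` onsets.
Temporal clusters are maximal unbroken runs of cluster days together with
the cases whose onsets fall inside the run.  The null model redistributes
the same number of cases over the period with day probabilities
proportional to a 12-month seasonal profile.
"""
from __future__ import annotations

import datetime as dt
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CaseTable, DailyCounts, StudyPeriod

__all__ = [
    "ClusterParams",
    "TemporalCluster",
    "ClusterSizeCurve",
    "SeasonalNullEnsemble",
    "ClusterTestReport",
    "flag_cluster_days",
    "extract_clusters",
    "cluster_size_curve",
    "sample_seasonal_counts",
    "seasonal_null_ensemble",
    "cluster_excess_test",
    "daily_probabilities",
]


@dataclass(frozen=True)
class ClusterParams:
    """Moving-window size and minimum onset count defining a cluster day."""

    window_days: int = 7
    min_cases: int = 4

    def __post_init__(self) -> None:
        if self.window_days < 1:
            raise ValueError("window_days must be >= 1")
        if self.min_cases < 1:
            raise ValueError("min_cases must be >= 1")


@dataclass(frozen=True)
class TemporalCluster:
    """A maximal unbroken run of cluster days and its member cases."""

    start_day: dt.date
    end_day: dt.date
    case_ids: tuple[str, ...]
    size: int
    duration_days: int

    def __post_init__(self) -> None:
        if self.duration_days != (self.end_day - self.start_day).days + 1:
            raise ValueError("duration inconsistent with start/end")
        if self.size != len(self.case_ids):
            raise ValueError("size inconsistent with case_ids")


@dataclass(frozen=True)
class ClusterSizeCurve:
    """Number of clusters with more than S cases, per S."""

    s_values: np.ndarray
    n_exceeding: np.ndarray

    def __post_init__(self) -> None:
        s = np.asarray(self.s_values, dtype=int)
        n = np.asarray(self.n_exceeding, dtype=int)
        if s.shape != n.shape:
            raise ValueError("s_values and n_exceeding shape mismatch")
        if len(n) > 1 and (np.diff(n) > 0).any():
            raise ValueError("n_exceeding must be non-increasing in S")
        object.__setattr__(self, "s_values", s)
        object.__setattr__(self, "n_exceeding", n)


@dataclass(frozen=True)
class SeasonalNullEnsemble:
    """Cluster statistics from repeated seasonal-null case redistributions."""

    n_reps: int
    s_values: np.ndarray
    rep_curves: np.ndarray  # (n_reps, len(s_values))
    rep_counts: np.ndarray  # clusters per rep
    mean_curve: np.ndarray
    sd_curve: np.ndarray
    seed: int


@dataclass(frozen=True)
class ClusterTestReport:
    """Observed-vs-null comparison of the cluster count and size curve."""

    observed_count: int
    null_mean: float
    null_sd: float
    t_statistic: float | None
    p_t_two_sided: float | None
    p_t_upper: float | None
    p_empirical: float
    degenerate: bool
    s_values: np.ndarray
    p_empirical_per_s: np.ndarray


def flag_cluster_days(counts: DailyCounts, params: ClusterParams) -> np.ndarray:
    """Boolean per day: does any qualifying window contain the day?

    Windows are full ``window_days`` spans inside the period (no wraparound);
    if the period is shorter than the window, the whole period is the single
    window.
    """
    c = counts.counts
    n = len(c)
    w = min(params.window_days, n)
    # sum over each window starting at s: vectorized via cumulative sums
    csum = np.concatenate([[0], np.cumsum(c)])
    window_sums = csum[w:] - csum[:-w]  # length n - w + 1
    hot = window_sums >= params.min_cases
    flags = np.zeros(n, dtype=bool)
    # window starting at s covers days s .. s+w-1
    starts = np.flatnonzero(hot)
    for s in starts:
        flags[s : s + w] = True
    return flags


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as (start, end) inclusive index pairs."""
    if not flags.any():
        return []
    padded = np.concatenate([[False], flags, [False]])
    d = np.diff(padded.astype(int))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def extract_clusters(
    counts: DailyCounts,
    flags: np.ndarray,
    cases: CaseTable,
    params: ClusterParams,
) -> list[TemporalCluster]:
    """Maximal unbroken flagged runs with their member cases.

    Runs holding fewer than ``min_cases`` onsets are discarded (possible only
    in pathological inputs).  Each case belongs to at most one cluster.
    """
    flags = np.asarray(flags, dtype=bool)
    if flags.shape != counts.counts.shape:
        raise ValueError("flags length does not match counts length")
    period = counts.period
    day_idx = cases.day_indices
    clusters: list[TemporalCluster] = []
    for s, e in _runs(flags):
        member = (day_idx >= s) & (day_idx <= e)
        ids = tuple(cases.records[i].case_id for i in np.flatnonzero(member))
        if len(ids) < params.min_cases:
            continue
        clusters.append(
            TemporalCluster(
                start_day=period.date_of(s),
                end_day=period.date_of(e),
                case_ids=ids,
                size=len(ids),
                duration_days=e - s + 1,
            )
        )
    return clusters


def cluster_case_ids(clusters: list[TemporalCluster]) -> set[str]:
    """Union of member case ids over clusters."""
    out: set[str] = set()
    for cl in clusters:
        out.update(cl.case_ids)
    return out


def cluster_size_curve(clusters: list[TemporalCluster], s_max: int) -> ClusterSizeCurve:
    """n_exceeding[S] = number of clusters with size strictly greater than S."""
    if s_max < 1:
        raise ValueError("s_max must be >= 1")
    sizes = np.array([c.size for c in clusters], dtype=int)
    s_values = np.arange(1, s_max + 1)
    if len(sizes) == 0:
        n_exceeding = np.zeros_like(s_values)
    else:
        n_exceeding = (sizes[None, :] > s_values[:, None]).sum(axis=1)
    return ClusterSizeCurve(s_values=s_values, n_exceeding=n_exceeding)


def daily_probabilities(profile: np.ndarray, period: StudyPeriod) -> np.ndarray:
    """Per-day probability proportional to the day's month weight."""
    profile = np.asarray(profile, dtype=float)
    if profile.shape != (12,):
        raise ValueError("profile must have 12 monthly weights")
    if (profile < 0).any() or not profile.any():
        raise ValueError("profile must be nonnegative and not all zero")
    months = period.dates().month.values
    p = profile[months - 1]
    total = p.sum()
    if total <= 0:
        raise ValueError("profile assigns zero mass to the whole period")
    return p / total


def sample_seasonal_counts(
    n_cases: int,
    profile: np.ndarray,
    period: StudyPeriod,
    rng: np.random.Generator,
) -> DailyCounts:
    """Multinomial redistribution of ``n_cases`` onsets over the period."""
    p = daily_probabilities(profile, period)
    counts = rng.multinomial(n_cases, p)
    return DailyCounts(period=period, counts=counts)


def _clusters_from_counts(counts: DailyCounts, params: ClusterParams) -> np.ndarray:
    """Cluster sizes for a pure counts series (cases are anonymous)."""
    flags = flag_cluster_days(counts, params)
    sizes = []
    for s, e in _runs(flags):
        n = int(counts.counts[s : e + 1].sum())
        if n >= params.min_cases:
            sizes.append(n)
    return np.array(sizes, dtype=int)


def seasonal_null_ensemble(
    n_cases: int,
    profile: np.ndarray,
    period: StudyPeriod,
    params: ClusterParams,
    n_reps: int = 500,
    seed: int = 0,
    s_max: int | None = None,
) -> SeasonalNullEnsemble:
    """Distribution of cluster counts/size curves under the seasonal null.

    Each rep draws exactly ``n_cases`` onsets (multinomial over days with
    probability proportional to the monthly profile), runs the full cluster
    construction, and records the cluster count and exceedance curve.
    """
    if n_cases < 0:
        raise ValueError("n_cases must be >= 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if s_max is None:
        s_max = max(2 * params.min_cases, 10)
    s_values = np.arange(1, s_max + 1)
    rep_curves = np.zeros((n_reps, s_max), dtype=int)
    rep_counts = np.zeros(n_reps, dtype=int)
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    for i, ss in enumerate(streams):
        rng = np.random.default_rng(ss)
        counts = sample_seasonal_counts(n_cases, profile, period, rng)
        sizes = _clusters_from_counts(counts, params)
        rep_counts[i] = len(sizes)
        if len(sizes):
            rep_curves[i] = (sizes[None, :] > s_values[:, None]).sum(axis=1)
    return SeasonalNullEnsemble(
        n_reps=n_reps,
        s_values=s_values,
        rep_curves=rep_curves,
        rep_counts=rep_counts,
        mean_curve=rep_curves.mean(axis=0),
        sd_curve=rep_curves.std(axis=0, ddof=1) if n_reps >= 2 else np.zeros(s_max),
        seed=seed,
    )


def cluster_excess_test(
    observed_count: int,
    observed_curve: ClusterSizeCurve,
    ensemble: SeasonalNullEnsemble,
) -> ClusterTestReport:
    """Compare the observed cluster count to the null ensemble.

    Reports a t-statistic p-value (observed count against the simulated
    distribution; both one- and two-sided) and the empirical rank p-value
    ``(1 + #{reps >= observed}) / (n_reps + 1)``, overall and per S.
    """
    counts = ensemble.rep_counts
    mean = float(counts.mean())
    sd = float(counts.std(ddof=1)) if ensemble.n_reps >= 2 else 0.0
    degenerate = sd == 0.0
    if degenerate:
        t_stat = p_two = p_up = None
    else:
        t_stat = (observed_count - mean) / sd
        df = ensemble.n_reps - 1
        p_two = float(2 * stats.t.sf(abs(t_stat), df))
        p_up = float(stats.t.sf(t_stat, df))
    p_emp = float((1 + (counts >= observed_count).sum()) / (ensemble.n_reps + 1))
    # per-S empirical p on the common s grid
    s_obs = observed_curve.s_values
    obs_on_grid = np.zeros(len(ensemble.s_values), dtype=int)
    for j, s in enumerate(ensemble.s_values):
        k = np.searchsorted(s_obs, s)
        if k < len(s_obs) and s_obs[k] == s:
            obs_on_grid[j] = observed_curve.n_exceeding[k]
    p_per_s = (1 + (ensemble.rep_curves >= obs_on_grid[None, :]).sum(axis=0)) / (
        ensemble.n_reps + 1
    )
    return ClusterTestReport(
        observed_count=observed_count,
        null_mean=mean,
        null_sd=sd,
        t_statistic=None if t_stat is None else float(t_stat),
        p_t_two_sided=p_two,
        p_t_upper=p_up,
        p_empirical=p_emp,
        degenerate=degenerate,
        s_values=ensemble.s_values,
        p_empirical_per_s=p_per_s,
    )
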