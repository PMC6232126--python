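"""Temporal autocorrelation of clinical traits and spatial label testing.

For each reference case, the forward-window conditional median is the
median trait value among cases with onset in the ``window_days`` strictly
after the reference's onset (the reference day itself is excluded).
Regressing the window median on the reference value tests temporal
autocorrelation of the trait.  A binary trait's spatial clustering is
tested by permuting labels over cases and comparing the mean pairwise
distance among positives.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .io import CaseTable
from .knox import pairwise_great_circle_km

__all__ = [
    "ConditionalMedianSet",
    "SpatialLabelTest",
    "conditional_window_medians",
    "bin_medians",
    "trait_slope_regression",
    "conditional_median_analysis",
    "spatial_label_permutation_test",
]


@dataclass(frozen=True)
class RegressionResult:
    slope: float
    intercept: float
    r_squared: float
    p_slope: float


@dataclass(frozen=True)
class ConditionalMedianSet:
    """Reference-value / forward-window-median pairs with binned medians."""

    trait: str
    window_days: int
    points: list[tuple[float, float, int]]  # (x, y, n_in_window)
    bins: list[tuple[float, float, float]]  # (lo, hi, median y)
    regression_points: RegressionResult | None
    regression_bins: RegressionResult | None


@dataclass(frozen=True)
class SpatialLabelTest:
    """Permutation test of spatial clustering of a binary label."""

    trait: str
    statistic_name: str
    observed: float
    null_reps: np.ndarray
    p_value: float
    n_reps: int
    seed: int


def conditional_window_medians(
    cases: CaseTable, trait: str, window_days: int = 10,
    include_reference_day: bool = False,
) -> list[tuple[float, float, int]]:
    """(reference value, forward-window median, window size) per reference.

    The window is (onset, onset + window_days] — a case exactly
    ``window_days`` later is included, a same-day case is not (unless
    ``include_reference_day``).  References with empty windows (after
    dropping missing trait values) yield no point.
    """
    vals = cases.trait(trait)  # raises SchemaError for unknown traits
    days = cases.day_indices
    have = np.isfinite(vals)
    if have.sum() < 2:
        return []
    points: list[tuple[float, float, int]] = []
    lo_off = 0 if include_reference_day else 1
    for i in np.flatnonzero(have):
        lo = days[i] + lo_off
        hi = days[i] + window_days
        in_win = (days >= lo) & (days <= hi) & have
        in_win[i] = False
        if not in_win.any():
            continue
        y = float(np.median(vals[in_win]))
        points.append((float(vals[i]), y, int(in_win.sum())))
    return points


def bin_medians(
    points: list[tuple[float, float, int]], bin_edges: np.ndarray
) -> list[tuple[float, float, float]]:
    """Median of y per half-open x bin [e_k, e_{k+1}); empty bins omitted."""
    if len(points) < 1:
        raise ValueError("need at least one point")
    edges = np.asarray(bin_edges, dtype=float)
    if len(edges) < 2 or (np.diff(edges) <= 0).any():
        raise ValueError("bin edges must be sorted and strictly increasing")
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    out = []
    for lo, hi in zip(edges[:-1], edges[1:]):
        sel = (x >= lo) & (x < hi)
        if sel.any():
            out.append((float(lo), float(hi), float(np.median(y[sel]))))
    return out


def trait_slope_regression(x: np.ndarray, y: np.ndarray) -> RegressionResult:
    """OLS of y on x with a two-sided p for slope != 0."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3:
        raise ValueError("need at least 3 items for the slope regression")
    if np.ptp(x) == 0:
        raise ValueError("degenerate input: zero variance in x")
    res = stats.linregress(x, y)
    return RegressionResult(
        slope=float(res.slope),
        intercept=float(res.intercept),
        r_squared=float(res.rvalue**2),
        p_slope=float(res.pvalue),
    )


def _default_edges(x: np.ndarray, trait: str) -> np.ndarray:
    if trait == "age":
        lo, hi = np.floor(x.min()), np.ceil(x.max()) + 1
        return np.arange(lo, hi + 1e-9)
    qs = np.unique(np.quantile(x, np.linspace(0, 1, 11)))
    qs[-1] += 1e-9  # make the top value fall in the last half-open bin
    return qs


def conditional_median_analysis(
    cases: CaseTable,
    trait: str,
    window_days: int = 10,
    bin_edges: np.ndarray | None = None,
) -> ConditionalMedianSet:
    """Full forward-window analysis: points, binned medians, regressions.

    Regressions are reported both on the fine points and on the binned
    medians (bin midpoint as x); either is None when under-determined.
    """
    points = conditional_window_medians(cases, trait, window_days)
    bins: list[tuple[float, float, float]] = []
    reg_pts = reg_bins = None
    if points:
        x = np.array([p[0] for p in points])
        edges = _default_edges(x, trait) if bin_edges is None else np.asarray(bin_edges)
        bins = bin_medians(points, edges)
        y = np.array([p[1] for p in points])
        try:
            reg_pts = trait_slope_regression(x, y)
        except ValueError:
            reg_pts = None
        if len(bins) >= 3:
            bx = np.array([(lo + hi) / 2 for lo, hi, _ in bins])
            by = np.array([m for _, _, m in bins])
            try:
                reg_bins = trait_slope_regression(bx, by)
            except ValueError:
                reg_bins = None
    return ConditionalMedianSet(
        trait=trait,
        window_days=window_days,
        points=points,
        bins=bins,
        regression_points=reg_pts,
        regression_bins=reg_bins,
    )


def spatial_label_permutation_test(
    cases: CaseTable,
    label: str = "ggt_elevated",
    n_reps: int = 999,
    seed: int = 0,
) -> SpatialLabelTest:
    """Lower-tail permutation test of label-positive spatial clustering.

    Statistic: mean pairwise great-circle distance among label-positive
    cases; the null permutes labels over cases (counts preserved);
    p = (1 + #{rep <= observed}) / (n_reps + 1).
    """
    vals = cases.trait(label)
    have = np.isfinite(vals)
    pos = vals[have] > 0
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos < 2 or n_neg < 2:
        raise ValueError(
            f"need >= 2 positive and >= 2 negative labels (got {n_pos}, {n_neg})"
        )
    coords = cases.coords[have]
    dmat = pairwise_great_circle_km(coords)
    iu = np.triu_indices(len(coords), k=1)

    def mean_pos_distance(mask: np.ndarray) -> float:
        pairs = mask[:, None] & mask[None, :]
        return float(dmat[iu][pairs[iu]].mean())

    observed = mean_pos_distance(pos)
    rng = np.random.default_rng(seed)
    null = np.empty(n_reps)
    for r in range(n_reps):
        perm = rng.permutation(pos)
        assert perm.sum() == n_pos
        null[r] = mean_pos_distance(perm)
    p = float((1 + (null <= observed).sum()) / (n_reps + 1))
    return SpatialLabelTest(
        trait=label,
        statistic_name="mean_pairwise_distance_km",
        observed=observed,
        null_reps=null,
        p_value=p,
        n_reps=n_reps,
        seed=seed,
    )
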