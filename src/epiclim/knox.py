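"""Excess Knox space-time interaction statistic with a permutation null.

For thresholds (tau days, delta km) the statistic counts unordered case
pairs close in both time and space, X, and compares it with the
independence expectation E = N_T * N_S / M.  Significance comes from
shuffling case locations against the fixed onset dates, which leaves
N_T, N_S and M unchanged.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import CaseTable

__all__ = [
    "EARTH_RADIUS_KM",
    "KnoxThresholds",
    "KnoxCell",
    "KnoxGrid",
    "great_circle_km",
    "pairwise_great_circle_km",
    "close_pair_counts",
    "excess_knox",
    "knox_permutation_test",
]

EARTH_RADIUS_KM = 6371.0


@dataclass(frozen=True)
class KnoxThresholds:
    """Grids of temporal (days) and spatial (km) closeness thresholds."""

    time_days: np.ndarray
    space_km: np.ndarray

    def __post_init__(self) -> None:
        t = np.asarray(self.time_days, dtype=float)
        s = np.asarray(self.space_km, dtype=float)
        for name, g in (("time_days", t), ("space_km", s)):
            if g.ndim != 1 or len(g) == 0:
                raise ValueError(f"{name} must be a non-empty 1-D grid")
            if (g <= 0).any() or (np.diff(g) <= 0).any():
                raise ValueError(f"{name} must be positive and strictly increasing")
        object.__setattr__(self, "time_days", t)
        object.__setattr__(self, "space_km", s)

    @classmethod
    def default(cls) -> "KnoxThresholds":
        return cls(
            time_days=np.arange(1, 31, dtype=float),
            space_km=np.array([1.0, 2.0, 5.0, 10.0, 20.0, 50.0, 100.0]),
        )


@dataclass(frozen=True)
class KnoxCell:
    """Counts, excess statistic and permutation p for one (tau, delta)."""

    tau: float
    delta: float
    n_close_both: int
    n_close_time: int
    n_close_space: int
    n_pairs: int
    expected: float
    excess: float | None  # None when expected == 0 (undefined)
    p_value: float


@dataclass(frozen=True)
class KnoxGrid:
    """Complete grid of :class:`KnoxCell` plus the permutation settings."""

    thresholds: KnoxThresholds
    cells: list[KnoxCell]
    n_reps: int
    seed: int

    def cell(self, tau: float, delta: float) -> KnoxCell:
        for c in self.cells:
            if c.tau == tau and c.delta == delta:
                return c
        raise KeyError((tau, delta))

    def p_matrix(self) -> np.ndarray:
        """(n_tau, n_delta) matrix of permutation p-values."""
        nt, ns = len(self.thresholds.time_days), len(self.thresholds.space_km)
        out = np.empty((nt, ns))
        for c in self.cells:
            i = int(np.searchsorted(self.thresholds.time_days, c.tau))
            j = int(np.searchsorted(self.thresholds.space_km, c.delta))
            out[i, j] = c.p_value
        return out

    def excess_matrix(self) -> np.ndarray:
        nt, ns = len(self.thresholds.time_days), len(self.thresholds.space_km)
        out = np.full((nt, ns), np.nan)
        for c in self.cells:
            i = int(np.searchsorted(self.thresholds.time_days, c.tau))
            j = int(np.searchsorted(self.thresholds.space_km, c.delta))
            out[i, j] = np.nan if c.excess is None else c.excess
        return out


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine distance between (lat, lon) points on a 6371 km sphere."""
    lat1, lon1 = np.radians(a)
    lat2, lon2 = np.radians(b)
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2.0) ** 2
    return float(2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0))))


def pairwise_great_circle_km(coords: np.ndarray) -> np.ndarray:
    """Full (n, n) haversine distance matrix for (lat, lon) rows."""
    coords = np.asarray(coords, dtype=float)
    lat = np.radians(coords[:, 0])[:, None]
    lon = np.radians(coords[:, 1])[:, None]
    dlat = lat - lat.T
    dlon = lon - lon.T
    h = np.sin(dlat / 2.0) ** 2 + np.cos(lat) * np.cos(lat.T) * np.sin(dlon / 2.0) ** 2
    return 2.0 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(np.clip(h, 0.0, 1.0)))


def _pair_arrays(cases: CaseTable) -> tuple[np.ndarray, np.ndarray]:
    """Condensed |dt| (days) and distance (km) arrays over pairs i < j."""
    n = len(cases)
    if n < 2:
        raise ValueError("need at least 2 cases")
    days = cases.day_indices.astype(float)
    dist = pairwise_great_circle_km(cases.coords)
    iu = np.triu_indices(n, k=1)
    return np.abs(days[:, None] - days[None, :])[iu], dist[iu]


def close_pair_counts(
    cases: CaseTable, tau: float, delta: float
) -> tuple[int, int, int, int]:
    """(X, N_T, N_S, M): pairs close in both / time / space, and all pairs.

    Closeness is inclusive: |dt| <= tau and distance <= delta.
    """
    dt_pair, dist_pair = _pair_arrays(cases)
    tclose = dt_pair <= tau
    sclose = dist_pair <= delta
    return (
        int((tclose & sclose).sum()),
        int(tclose.sum()),
        int(sclose.sum()),
        len(dt_pair),
    )


def excess_knox(counts: tuple[int, int, int, int]) -> tuple[float, float | None]:
    """(expected, excess) where E = N_T*N_S/M and excess = (X - E)/E.

    Returns excess None (flagged undefined) when E == 0.
    """
    x, n_t, n_s, m = counts
    if m < 1:
        raise ValueError("need at least one pair")
    e = n_t * n_s / m
    if e == 0:
        return 0.0, None
    return e, (x - e) / e


def _grid_pair_counts(
    dt_pair: np.ndarray,
    dist_pair: np.ndarray,
    taus: np.ndarray,
    deltas: np.ndarray,
) -> np.ndarray:
    """X for every (tau, delta) cell via a cumulative 2-D histogram.

    Uses searchsorted bin assignment so closeness is exactly inclusive
    (``<=``) at both thresholds, matching :func:`close_pair_counts`.
    """
    ti = np.searchsorted(taus, dt_pair, side="left")
    si = np.searchsorted(deltas, dist_pair, side="left")
    nt, ns = len(taus) + 1, len(deltas) + 1
    hist = np.bincount(ti * ns + si, minlength=nt * ns).reshape(nt, ns)
    cum = hist.cumsum(axis=0).cumsum(axis=1)
    return cum[:-1, :-1]  # X[i, j] = #{dt <= taus[i], dist <= deltas[j]}


def knox_permutation_test(
    cases: CaseTable,
    thresholds: KnoxThresholds | None = None,
    n_reps: int = 999,
    seed: int = 0,
) -> KnoxGrid:
    """Excess Knox statistic over a threshold grid with location-shuffle p.

    Each rep permutes the multiset of case locations against the fixed onset
    dates (one shared permutation for all cells), recomputes X, and the
    upper-tail p is ``(1 + #{X_rep >= X_obs}) / (n_reps + 1)``.
    """
    if thresholds is None:
        thresholds = KnoxThresholds.default()
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    n = len(cases)
    if n < 2:
        raise ValueError("need at least 2 cases")
    days = cases.day_indices.astype(float)
    dist = pairwise_great_circle_km(cases.coords)
    iu = np.triu_indices(n, k=1)
    dt_pair = np.abs(days[:, None] - days[None, :])[iu]
    dist_pair = dist[iu]
    taus = thresholds.time_days
    deltas = thresholds.space_km

    x_obs = _grid_pair_counts(dt_pair, dist_pair, taus, deltas)
    # time-only and space-only counts are permutation invariant
    n_t = np.array([(dt_pair <= t).sum() for t in taus])
    n_s = np.array([(dist_pair <= d).sum() for d in deltas])
    m = len(dt_pair)

    rng = np.random.default_rng(seed)
    ge_count = np.zeros_like(x_obs)
    for _ in range(n_reps):
        perm = rng.permutation(n)
        dist_perm = dist[np.ix_(perm, perm)][iu]
        x_rep = _grid_pair_counts(dt_pair, dist_perm, taus, deltas)
        ge_count += x_rep >= x_obs
    p = (1 + ge_count) / (n_reps + 1)

    cells: list[KnoxCell] = []
    for i, tau in enumerate(taus):
        for j, delta in enumerate(deltas):
            e, excess = excess_knox((int(x_obs[i, j]), int(n_t[i]), int(n_s[j]), m))
            cells.append(
                KnoxCell(
                    tau=float(tau),
                    delta=float(delta),
                    n_close_both=int(x_obs[i, j]),
                    n_close_time=int(n_t[i]),
                    n_close_space=int(n_s[j]),
                    n_pairs=m,
                    expected=float(e),
                    excess=excess,
                    p_value=float(p[i, j]),
                )
            )
    return KnoxGrid(thresholds=thresholds, cells=cells, n_reps=n_reps, seed=seed)
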