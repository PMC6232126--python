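import datetime as dt
import warnings

import numpy as np
import pandas as pd
import pytest

from epiclim.clusters import ClusterParams, extract_clusters, flag_cluster_days
from epiclim.composites import (
    DEFAULT_LAG_BINS,
    EventGroupSpec,
    anomalies,
    composite_anomaly,
    day_of_year_climatology,
    resolve_event_groups,
)
from epiclim.io import GriddedSeries, StudyPeriod
from epiclim.simulate import ClimateSimConfig, VariableSimParams, simulate_climate

from conftest import make_cases


def constant_field(value, start="2010-01-01", n_days=730, nlat=3, nlon=3, variable="tmax"):
    dates = pd.date_range(start, periods=n_days)
    return GriddedSeries(
        variable=variable,
        units="degC",
        dates=dates,
        lats=np.arange(nlat, dtype=float),
        lons=np.arange(nlon, dtype=float),
        values=np.full((n_days, nlat, nlon), float(value)),
    )


class TestClimatology:
    def test_constant_field_constant_climatology(self):
        clim = day_of_year_climatology(constant_field(7.5), smooth_window_days=5)
        np.testing.assert_allclose(clim.values, 7.5)

    def test_repeated_years_zero_anomalies_unsmoothed(self):
        """Two identical non-leap years, window 1: anomalies exactly zero."""
        rng = np.random.default_rng(0)
        year = rng.integers(-5, 30, size=(365, 2, 2)).astype(float)
        f = constant_field(0.0, n_days=730, nlat=2, nlon=2)
        f.values = np.concatenate([year, year])
        clim = day_of_year_climatology(f, smooth_window_days=1)
        an = anomalies(f, clim)
        assert np.abs(an.values).max() < 1e-12

    def test_sinusoid_smoothing_attenuates_slightly(self):
        dates = pd.date_range("2010-01-01", periods=730)
        doy = dates.dayofyear.values
        vals = np.cos(2 * np.pi * doy / 365.0)[:, None, None] * np.ones((730, 1, 1))
        f = GriddedSeries("tmax", "degC", dates, [0.0], [0.0], vals)
        an = anomalies(f, day_of_year_climatology(f, smooth_window_days=5))
        # 5-day running mean of an annual sinusoid attenuates by <0.1%
        assert np.abs(an.values).max() < 1e-3

    def test_climatology_invariant_to_year_order(self):
        rng = np.random.default_rng(1)
        y1 = rng.normal(size=(365, 2, 2))
        y2 = rng.normal(size=(365, 2, 2))
        f12 = constant_field(0.0, n_days=730, nlat=2, nlon=2)
        f12.values = np.concatenate([y1, y2])
        f21 = constant_field(0.0, n_days=730, nlat=2, nlon=2)
        f21.values = np.concatenate([y2, y1])
        c12 = day_of_year_climatology(f12, 5)
        c21 = day_of_year_climatology(f21, 5)
        np.testing.assert_allclose(c12.values, c21.values, atol=1e-12)

    def test_white_noise_climatology_variance(self):
        """Var(climatology) ~ noise_var / (n_years * window)."""
        rng = np.random.default_rng(2)
        n_years, window, sigma = 8, 5, 2.0
        vals = rng.normal(0, sigma, size=(365 * n_years, 4, 4))
        f = constant_field(0.0, n_days=365 * n_years, nlat=4, nlon=4)
        f.values = vals
        clim = day_of_year_climatology(f, window)
        expected_var = sigma**2 / (n_years * window)
        got_var = clim.values.var()
        assert got_var == pytest.approx(expected_var, rel=0.15)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            day_of_year_climatology(constant_field(1.0, n_days=400), 5)

    def test_even_window_rejected(self):
        with pytest.raises(ValueError):
            day_of_year_climatology(constant_field(1.0), 4)

    def test_leap_day_uses_adjacent_climatology(self):
        # 2003-2006 covers leap year 2004
        f = constant_field(0.0, start="2003-01-01", n_days=4 * 365 + 1, nlat=1, nlon=1)
        dates = f.dates
        # deterministic day-of-year signal, Feb 29 gets the Feb28/Mar1 average
        base = {d: float((d.month * 40 + d.day) % 97) for d in
                pd.date_range("2003-01-01", "2003-12-31")}
        vals = []
        for d in dates:
            key = pd.Timestamp(2003, d.month, d.day) if not (d.month == 2 and d.day == 29) else None
            if key is None:
                vals.append(0.5 * (base[pd.Timestamp(2003, 2, 28)] + base[pd.Timestamp(2003, 3, 1)]))
            else:
                vals.append(base[key])
        f.values = np.array(vals)[:, None, None]
        an = anomalies(f, day_of_year_climatology(f, 1))
        assert np.abs(an.values).max() < 1e-12


class TestAnomalies:
    def test_field_equals_climatology_gives_zero(self):
        f = constant_field(3.0)
        clim = day_of_year_climatology(f, 5)
        np.testing.assert_allclose(anomalies(f, clim).values, 0.0, atol=1e-12)

    def test_plus_one_gives_ones(self):
        f = constant_field(3.0)
        clim = day_of_year_climatology(f, 5)
        f2 = constant_field(4.0)
        np.testing.assert_allclose(anomalies(f2, clim).values, 1.0, atol=1e-12)

    def test_grid_mismatch_rejected(self):
        f = constant_field(1.0)
        clim = day_of_year_climatology(constant_field(1.0, nlat=4), 5)
        with pytest.raises(ValueError):
            anomalies(f, clim)

    def test_variable_mismatch_rejected(self):
        f = constant_field(1.0)
        clim = day_of_year_climatology(constant_field(1.0, variable="tmin"), 5)
        with pytest.raises(ValueError):
            anomalies(f, clim)


class TestResolveEventGroups:
    def test_table1_toy_groups(self, table1_period, table1_cases, table1_counts):
        params = ClusterParams()
        clusters = extract_clusters(
            table1_counts, flag_cluster_days(table1_counts, params), table1_cases, params
        )
        groups = resolve_event_groups(table1_cases, clusters, "ALL", seed=0)
        cluster_dates = set(groups["cluster_case_days"].dates)
        assert cluster_dates == {
            dt.date(2010, 1, d) for d in (1, 2, 3, 15, 16, 17, 18)
        }
        assert groups["noncluster_case_days"].dates == (dt.date(2010, 1, 9),)
        assert len(groups["all_case_days"].dates) == 8  # distinct onset dates
        # size-matched, zero-onset, deterministic sample
        no_case = groups["no_case_days"].dates
        assert len(no_case) == 8
        onset = set(groups["all_case_days"].dates)
        assert not (set(no_case) & onset)
        again = resolve_event_groups(table1_cases, clusters, "ALL", seed=0)
        assert again["no_case_days"].dates == no_case

    def test_empty_season_warns(self, table1_period, table1_cases, table1_counts):
        params = ClusterParams()
        clusters = extract_clusters(
            table1_counts, flag_cluster_days(table1_counts, params), table1_cases, params
        )
        with pytest.warns(UserWarning, match="empty"):
            groups = resolve_event_groups(table1_cases, clusters, "MJJA", seed=0)
        assert groups["all_case_days"].empty

    def test_season_filters_months(self):
        period = StudyPeriod(dt.date(2010, 1, 1), dt.date(2010, 12, 31))
        days = [0, 100, 200, 300]  # Jan, Apr, Jul, Oct
        cases = make_cases(days, period)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            groups = resolve_event_groups(cases, [], "DJFMA", seed=1)
        months = {d.month for d in groups["all_case_days"].dates}
        assert months <= {12, 1, 2, 3, 4}
        for d in groups["no_case_days"].dates:
            assert d.month in {12, 1, 2, 3, 4}


class TestCompositeAnomaly:
    period = StudyPeriod(dt.date(2010, 1, 1), dt.date(2011, 12, 31))

    def _spec(self, dates):
        return EventGroupSpec("all_case_days", "ALL", tuple(dates))

    def test_zero_anomalies_zero_composite(self):
        f = constant_field(2.0)
        an = anomalies(f, day_of_year_climatology(f, 5))
        spec = self._spec([dt.date(2010, 5, 1), dt.date(2010, 7, 1)])
        res = composite_anomaly(an, spec)
        assert np.nanmax(np.abs(res.mean_maps)) < 1e-12
        assert not res.masks.any()

    def test_injected_anomaly_recovered_exactly(self):
        """+2 on event days with zero noise: DOO bin mean is exactly 2,
        bins not touching an event day are 0."""
        events = [dt.date(2010, 6, 15), dt.date(2011, 2, 1)]
        clean = constant_field(10.0)
        clim = day_of_year_climatology(clean, 1)  # uncontaminated baseline
        f = constant_field(10.0)
        for e in events:
            f.values[(pd.Timestamp(e) - f.dates[0]).days] += 2.0
        an = anomalies(f, clim)
        res = composite_anomaly(an, self._spec(events), lag_bins=((-3, -2), (0,), (2, 3)))
        np.testing.assert_allclose(res.mean_maps[1], 2.0, atol=0.02)
        np.testing.assert_allclose(res.mean_maps[0], 0.0, atol=0.02)
        np.testing.assert_allclose(res.mean_maps[2], 0.0, atol=0.02)

    def test_out_of_coverage_offsets_dropped_and_counted(self):
        f = constant_field(0.0)
        an = anomalies(f, day_of_year_climatology(f, 5))
        first = self.period.start
        res = composite_anomaly(an, self._spec([first]), lag_bins=((-5, -4), (0,)))
        assert res.n_dropped_per_bin[0] == 2
        assert res.n_per_bin[0] == 0
        assert res.n_per_bin[1] == 1

    def test_single_day_bin_mask_all_false(self):
        f = constant_field(0.0)
        f.values += np.random.default_rng(3).normal(size=f.values.shape)
        an = anomalies(f, day_of_year_climatology(f, 5))
        res = composite_anomaly(an, self._spec([dt.date(2010, 6, 1)]), lag_bins=((0,),))
        assert res.n_per_bin[0] == 1
        assert not res.masks.any()

    def test_linearity_over_disjoint_event_sets(self):
        rng = np.random.default_rng(5)
        f = constant_field(0.0)
        f.values += rng.normal(size=f.values.shape)
        an = anomalies(f, day_of_year_climatology(f, 5))
        d1 = [dt.date(2010, 4, 1), dt.date(2010, 9, 10)]
        d2 = [dt.date(2011, 3, 3)]
        bins = ((0,),)
        r1 = composite_anomaly(an, self._spec(d1), bins)
        r2 = composite_anomaly(an, self._spec(d2), bins)
        r12 = composite_anomaly(an, self._spec(d1 + d2), bins)
        n1, n2 = r1.n_per_bin[0], r2.n_per_bin[0]
        weighted = (n1 * r1.mean_maps[0] + n2 * r2.mean_maps[0]) / (n1 + n2)
        np.testing.assert_allclose(r12.mean_maps[0], weighted, atol=1e-12)

    def test_bad_confidence_rejected(self):
        f = constant_field(0.0)
        an = anomalies(f, day_of_year_climatology(f, 5))
        with pytest.raises(ValueError):
            composite_anomaly(an, self._spec([dt.date(2010, 6, 1)]), confidence=0.3)

    def test_coupled_synthetic_recovers_amplitude(self):
        """Coupling +2 degC recovered at the DOO bin within 3 composite se
        (acceptance criterion 4, composite part)."""
        period = StudyPeriod(dt.date(2008, 1, 1), dt.date(2013, 12, 31))
        rng = np.random.default_rng(11)
        events = sorted(
            period.date_of(int(i))
            for i in rng.choice(np.arange(30, period.n_days - 30), size=40, replace=False)
        )
        def cfg(coupling):
            return ClimateSimConfig(
                period=period,
                lat_start=32, lat_stop=33, lon_start=-118, lon_stop=-117, step_deg=0.5,
                variables={"tmax": VariableSimParams(
                    mean=20.0, seasonal_cycle_amplitude=6.0, ar1_coefficient=0.5,
                    noise_sd=1.5, coupling_amplitude=coupling,
                )},
                seed=12,
            )

        f = simulate_climate(cfg(2.0), list(events))["tmax"]
        # climatology from the uncoupled twin (same seed -> identical noise),
        # so the event signal does not contaminate its own baseline
        twin = simulate_climate(cfg(0.0))["tmax"]
        an = anomalies(f, day_of_year_climatology(twin, 5))
        res = composite_anomaly(an, self._spec(events), lag_bins=((0,),))
        n = res.n_per_bin[0]
        # composite standard error from the t map: se = mean / t
        cell_mean = res.mean_maps[0]
        cell_se = cell_mean / res.t_maps[0]
        assert (np.abs(cell_mean - 2.0) < 3 * np.abs(cell_se)).mean() > 0.95

    def test_null_mask_rate_calibrated(self):
        """Uncoupled noise: masked fraction ~ 5% at 95% confidence,
        averaged over seeds (acceptance criterion 3c)."""
        period = StudyPeriod(dt.date(2008, 1, 1), dt.date(2013, 12, 31))
        fractions = []
        for seed in range(25):
            rng = np.random.default_rng(seed)
            events = [
                period.date_of(int(i))
                for i in rng.choice(np.arange(10, period.n_days - 10), size=30, replace=False)
            ]
            cfg = ClimateSimConfig(
                period=period,
                lat_start=0, lat_stop=2, lon_start=0, lon_stop=2, step_deg=0.5,
                variables={"tmax": VariableSimParams(
                    mean=15.0, seasonal_cycle_amplitude=5.0, ar1_coefficient=0.3,
                    noise_sd=2.0, coupling_amplitude=0.0,
                )},
                seed=seed + 100,
            )
            f = simulate_climate(cfg)["tmax"]
            an = anomalies(f, day_of_year_climatology(f, 5))
            res = composite_anomaly(an, self._spec(events), lag_bins=((0,),), confidence=0.95)
            fractions.append(res.masks[0].mean())
        fractions = np.array(fractions)
        se = fractions.std(ddof=1) / np.sqrt(len(fractions))
        assert abs(fractions.mean() - 0.05) < max(3 * se, 0.02)
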