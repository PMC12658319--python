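"""Weather CSV import, validation, kNN imputation and trial-table I/O."""

import numpy as np
import pandas as pd
import pytest

import sorgsim as ss
from sorgsim.weather import (WEATHER_FIELDS, ImputationError, SchemaError,
                             impute_missing_knn, read_trial_table,
                             read_weather_csv, trial_series,
                             write_trial_table)


def _small_series(n_hours=72, seed=3):
    w = ss.generate_weather(2021, seed=seed)
    df = w.data.iloc[:n_hours].copy()
    return ss.WeatherSeries(df, latitude=w.latitude)


class TestReadWeatherCsv:
    def test_well_formed_file_round_trips(self, tmp_path):
        series = _small_series(24)
        path = tmp_path / "w.csv"
        series.to_csv(path)
        back = read_weather_csv(path)
        assert len(back) == 24
        assert back.n_missing == 0
        assert back.import_report.total_flagged == 0
        pd.testing.assert_frame_equal(back.data, series.data,
                                      check_freq=False)

    def test_blank_cell_flagged_missing(self, tmp_path):
        series = _small_series(24)
        path = tmp_path / "w.csv"
        series.to_csv(path)
        df = pd.read_csv(path).astype({"air_temp": object})
        df.loc[5, "air_temp"] = ""
        df.to_csv(path, index=False)
        back = read_weather_csv(path)
        assert np.isnan(back.data["air_temp"].iloc[5])
        assert back.n_missing == 1

    def test_out_of_range_humidity_rejected(self, tmp_path):
        series = _small_series(24)
        path = tmp_path / "w.csv"
        series.to_csv(path)
        df = pd.read_csv(path)
        df.loc[3, "rel_humidity"] = 250.0
        df.to_csv(path, index=False)
        back = read_weather_csv(path)
        assert np.isnan(back.data["rel_humidity"].iloc[3])
        assert back.import_report.out_of_range == {"rel_humidity": 1}

    def test_unparseable_cell_counted(self, tmp_path):
        series = _small_series(24)
        path = tmp_path / "w.csv"
        series.to_csv(path)
        df = pd.read_csv(path).astype({"wind_speed": object})
        df.loc[2, "wind_speed"] = "calm"
        df.to_csv(path, index=False)
        back = read_weather_csv(path)
        assert back.import_report.unparseable == {"wind_speed": 1}

    def test_missing_file_raises(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_weather_csv(tmp_path / "absent.csv")

    def test_missing_timestamp_column_raises(self, tmp_path):
        pd.DataFrame({"air_temp": [1.0]}).to_csv(tmp_path / "w.csv",
                                                 index=False)
        with pytest.raises(SchemaError, match="timestamp"):
            read_weather_csv(tmp_path / "w.csv")

    def test_non_monotone_timestamps_name_rows(self, tmp_path):
        series = _small_series(24)
        path = tmp_path / "w.csv"
        df = series.data.reset_index()
        df.loc[[4, 5], "timestamp"] = df.loc[[5, 4], "timestamp"].values
        df.to_csv(path, index=False)
        with pytest.raises(SchemaError, match="increasing"):
            read_weather_csv(path)

    def test_timestamp_gap_materialized_as_missing_rows(self, tmp_path):
        series = _small_series(48)
        df = series.data.drop(series.data.index[10:13])
        path = tmp_path / "w.csv"
        df.to_csv(path, index_label="timestamp")
        back = read_weather_csv(path)
        assert len(back) == 48
        assert back.data.iloc[10:13].isna().all().all()


class TestKnnImputation:
    def test_complete_series_returned_unchanged(self):
        series = _small_series(48)
        out = impute_missing_knn(series, k=3)
        pd.testing.assert_frame_equal(out.data, series.data)

    def test_exact_duplicate_neighbor_wins_at_k1(self):
        series = _small_series(72)
        df = series.data.copy()
        # row 34 duplicates row 10 exactly 24 h later, with air_temp hidden,
        # so its time encoding is (almost) identical and its field distance 0
        df.iloc[34] = df.iloc[10].values
        df.iloc[34, df.columns.get_loc("air_temp")] = np.nan
        target = 21.4
        df.iloc[10, df.columns.get_loc("air_temp")] = target
        out = impute_missing_knn(ss.WeatherSeries(df), k=1)
        assert out.data["air_temp"].iloc[34] == pytest.approx(target, abs=1e-9)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(42)
        w = ss.generate_weather(2021, seed=7)
        df = w.data.iloc[:500].copy()
        vals = df.to_numpy()
        mask = rng.random(vals.shape) < 0.03
        vals[mask] = np.nan
        series = ss.WeatherSeries(pd.DataFrame(vals, index=df.index,
                                               columns=df.columns))
        k = 3
        out = impute_missing_knn(series, k=k)

        # independent exhaustive-distance oracle
        data = series.data.to_numpy()
        mu = np.nanmean(data, axis=0)
        sd = np.nanstd(data, axis=0)
        sd[sd == 0] = 1.0
        z = (data - mu) / sd
        idx = series.data.index
        hour = idx.hour.to_numpy() / 24.0
        doy = idx.dayofyear.to_numpy() / 365.25
        tf = np.column_stack([np.sin(2 * np.pi * hour),
                              np.cos(2 * np.pi * hour),
                              np.sin(2 * np.pi * doy),
                              np.cos(2 * np.pi * doy)])
        complete = ~np.isnan(data).any(axis=1)
        for i in range(len(data)):
            miss = np.isnan(data[i])
            if not miss.any():
                continue
            obs = ~miss
            dists = []
            for j in np.flatnonzero(complete):
                d = np.sum((z[j, obs] - z[i, obs]) ** 2)
                d += np.sum((tf[j] - tf[i]) ** 2)
                dists.append((d, j))
            dists.sort()
            neighbors = [j for _, j in dists[:k]]
            for f in np.flatnonzero(miss):
                expected = data[neighbors, f].mean()
                assert out.data.iloc[i, f] == pytest.approx(expected,
                                                            rel=1e-9)

    def test_idempotent_and_non_destructive(self):
        rng = np.random.default_rng(1)
        series = _small_series(200, seed=9)
        vals = series.data.to_numpy()
        mask = rng.random(vals.shape) < 0.05
        vals[mask] = np.nan
        series = ss.WeatherSeries(pd.DataFrame(vals, index=series.data.index,
                                               columns=series.data.columns))
        once = impute_missing_knn(series, k=5)
        twice = impute_missing_knn(once, k=5)
        pd.testing.assert_frame_equal(once.data, twice.data)
        observed = ~series.data.isna()
        assert (once.data[observed] == series.data[observed]).all().all() or \
            np.allclose(once.data.to_numpy()[observed.to_numpy()],
                        series.data.to_numpy()[observed.to_numpy()])

    def test_imputed_values_within_observed_range(self):
        rng = np.random.default_rng(2)
        series = _small_series(300, seed=10)
        vals = series.data.to_numpy()
        mask = rng.random(vals.shape) < 0.05
        vals[mask] = np.nan
        series = ss.WeatherSeries(pd.DataFrame(vals, index=series.data.index,
                                               columns=series.data.columns))
        out = impute_missing_knn(series, k=4)
        for col in WEATHER_FIELDS:
            observed = series.data[col].dropna()
            filled = out.data[col][series.data[col].isna()]
            assert (filled >= observed.min() - 1e-12).all()
            assert (filled <= observed.max() + 1e-12).all()

    def test_field_missing_everywhere_raises(self):
        series = _small_series(48)
        df = series.data.copy()
        df["wind_speed"] = np.nan
        with pytest.raises(ImputationError, match="wind_speed"):
            impute_missing_knn(ss.WeatherSeries(df), k=2)


class TestTrialTable:
    def _observations(self, n_genotypes=5):
        obs = []
        for g in range(n_genotypes):
            for year in (2021, 2022):
                for block in (1, 2):
                    for day in (22, 36, 43):
                        obs.append(ss.TrialObservation(
                            genotype_id=f"G{g:03d}", year=year, block=block,
                            stand_count=14.0 + g, day_after_planting=day,
                            leaf_dry_biomass=1.0 * day + g,
                            stem_dry_biomass=2.0 * day + g,
                        ))
        return obs

    def test_round_trip_lossless(self, tmp_path):
        obs = self._observations(10)
        path = tmp_path / "trials.csv"
        write_trial_table(obs, path)
        back = read_trial_table(path)
        assert back == obs

    def test_negative_biomass_rejected(self, tmp_path):
        obs = self._observations(1)
        path = tmp_path / "trials.csv"
        write_trial_table(obs, path)
        df = pd.read_csv(path)
        df.loc[0, "stem_dry_biomass"] = -1.0
        df.to_csv(path, index=False)
        with pytest.raises(ValueError, match="negative biomass"):
            read_trial_table(path)

    def test_blocks_become_distinct_series(self):
        obs = self._observations(1)
        groups = trial_series(obs)
        keys = [k for k in groups if k[1] == 2021]
        assert len(keys) == 2  # two blocks for the one genotype
        assert all(len(groups[k]) == 3 for k in keys)


class TestManagementRecord:
    def test_invalid_dates_rejected(self):
        import datetime as dt
        with pytest.raises(ValueError):
            ss.ManagementRecord(dt.date(2021, 10, 1), dt.date(2021, 5, 1),
                                14.0)

    def test_non_positive_stand_rejected(self):
        import datetime as dt
        with pytest.raises(ValueError):
            ss.ManagementRecord(dt.date(2021, 5, 1), dt.date(2021, 10, 1),
                                0.0)
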