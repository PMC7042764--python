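"""Input validation, filters and dataset assembly."""

import numpy as np
import pandas as pd
import pytest

from birdipm import data_io
from birdipm.data_io import (
    CaptureData,
    CountDataset,
    SchemaError,
    ValidationError,
    assemble_dataset,
    compute_route_weights,
    filter_min_station_years,
    load_counts,
)


class TestCounts:
    def test_load_small_file(self, tiny_counts_frame, tmp_path):
        path = tmp_path / "counts.csv"
        tiny_counts_frame.to_csv(path, index=False)
        ds = load_counts(path)
        assert ds.n_units == 1
        assert len(ds.years) == 3
        assert ds.calendar_year_0 == 2000

    def test_novice_recomputed_from_first_appearance(self, tmp_path):
        df = pd.DataFrame(
            {
                "route_observer": ["r1_o2"] * 2,
                "stratum": ["s1"] * 2,
                "year": [2001, 2002],  # observer starts in year 2 of the study
                "count": [1, 2],
            }
        )
        path = tmp_path / "counts.csv"
        df.to_csv(path, index=False)
        ds = load_counts(path)
        flags = ds.records.set_index("year")["novice"]
        assert flags[2001] == 1 and flags[2002] == 0

    def test_duplicate_unit_year_rejected(self, tiny_counts_frame):
        bad = pd.concat([tiny_counts_frame, tiny_counts_frame.iloc[[0]]])
        with pytest.raises(ValidationError, match="duplicated"):
            CountDataset(bad)

    def test_negative_and_noninteger_counts_rejected(self, tiny_counts_frame):
        bad = tiny_counts_frame.assign(count=[3, -1, 5])
        with pytest.raises(ValidationError, match="negative or non-integer"):
            CountDataset(bad)

    def test_novice_flag_outside_first_year_rejected(self, tiny_counts_frame):
        bad = tiny_counts_frame.assign(novice=[1, 1, 0])
        with pytest.raises(ValidationError, match="novice"):
            CountDataset(bad)

    def test_missing_columns_is_schema_error(self, tmp_path):
        path = tmp_path / "counts.csv"
        pd.DataFrame({"stratum": ["s1"], "year": [2000]}).to_csv(path, index=False)
        with pytest.raises(SchemaError):
            load_counts(path)


class TestRouteWeights:
    def test_three_of_four_routes_positive(self):
        df = pd.DataFrame(
            {
                "route_observer": [f"r{i}_o1" for i in range(4)],
                "route": [f"r{i}" for i in range(4)],
                "stratum": ["s1"] * 4,
                "year": [2000] * 4,
                "count": [2, 1, 3, 0],
                "novice": [1] * 4,
            }
        )
        w = compute_route_weights(CountDataset(df))
        assert w["s1"] == pytest.approx(0.75)

    def test_all_routes_positive_gives_one(self, tiny_counts_frame):
        w = compute_route_weights(CountDataset(tiny_counts_frame))
        assert w["s1"] == pytest.approx(1.0)

    def test_matches_brute_force_enumeration(self, reduced_sim):
        counts = reduced_sim.counts
        w = compute_route_weights(counts)
        routes = {}
        for _, row in counts.records.iterrows():
            routes.setdefault(row["route"], 0)
            routes[row["route"]] += row["count"]
        expected = sum(1 for v in routes.values() if v > 0) / len(routes)
        assert w["st1"] == pytest.approx(expected)


def _capture_data(station_years):
    """Individuals spread over stations with given operation years."""
    years = np.arange(2000, 2006)
    individuals, det = [], []
    stations = []
    for k, (station, ny) in enumerate(station_years.items()):
        stations.append(
            {
                "station": station,
                "stratum": "s1",
                "first_year_operated": 2000,
                "last_year_operated": 2000 + ny - 1,
                "years_operated": ny,
            }
        )
        for j in range(3):
            individuals.append(
                {
                    "individual": f"{station}_i{j}",
                    "station": station,
                    "stratum": "s1",
                    "first_year": 2000,
                    "resident_observed": j % 2,
                }
            )
            h = np.zeros(len(years), dtype=int)
            h[0] = 1
            det.append(h)
    return CaptureData(pd.DataFrame(individuals), np.array(det), years,
                       pd.DataFrame(stations))


class TestStationFilter:
    def test_threshold_removes_short_lived_stations(self):
        cap = _capture_data({"a": 3, "b": 4, "c": 5})
        out = filter_min_station_years(cap, 4)
        assert set(out.stations["station"]) == {"b", "c"}
        assert out.n_individuals == 6

    def test_min_years_one_is_identity(self):
        cap = _capture_data({"a": 3, "b": 4})
        out = filter_min_station_years(cap, 1)
        assert out.n_individuals == cap.n_individuals

    def test_idempotent(self):
        cap = _capture_data({"a": 3, "b": 4, "c": 5})
        once = filter_min_station_years(cap, 4)
        twice = filter_min_station_years(once, 4)
        assert once.n_individuals == twice.n_individuals
        pd.testing.assert_frame_equal(once.individuals, twice.individuals)

    def test_retained_count_equals_independent_recount(self, rng):
        ny = {f"s{k}": int(rng.integers(1, 8)) for k in range(12)}
        cap = _capture_data(ny)
        out = filter_min_station_years(cap, 4)
        expected = 3 * sum(1 for v in ny.values() if v >= 4)
        assert out.n_individuals == expected

    def test_invalid_min_years(self):
        cap = _capture_data({"a": 4})
        with pytest.raises(ValueError):
            filter_min_station_years(cap, 0)


class TestCaptureValidation:
    def test_detection_required_in_marking_year(self):
        cap = _capture_data({"a": 4})
        det = cap.detections.copy()
        det[0, 0] = 0
        with pytest.raises(ValidationError, match="marking year"):
            CaptureData(cap.individuals, det, cap.years, cap.stations)

    def test_unknown_station_rejected(self):
        cap = _capture_data({"a": 4})
        bad = cap.individuals.assign(station="nowhere")
        with pytest.raises(ValidationError, match="unknown stations"):
            CaptureData(bad, cap.detections, cap.years, cap.stations)


class TestAssembly:
    def test_seventeen_year_span(self, reduced_sim, reduced_dataset):
        assert reduced_dataset.n_years == 17
        assert reduced_dataset.years[0] == 1992 and reduced_dataset.years[-1] == 2008

    def test_summary_matches_generator_truth(self, reduced_sim, reduced_dataset):
        row = reduced_dataset.summary.loc["st1"]
        assert row["n_routes"] == 40
        assert row["n_individuals"] == reduced_sim.captures.n_individuals
        det = reduced_sim.captures.detections
        first = np.argmax(det == 1, axis=1)
        recaps = sum(det[j, first[j] + 1:].sum() for j in range(len(det)))
        assert row["n_recaptures"] == recaps

    def test_stratum_mismatch_rejected(self, reduced_sim):
        cov = reduced_sim.covariates.frame.assign(stratum="other")
        from birdipm.covariates import CovariateSeries

        with pytest.raises(ValidationError, match="stratum mismatch"):
            assemble_dataset(reduced_sim.counts, reduced_sim.captures,
                             reduced_sim.ages, CovariateSeries(cov))

    def test_area_weights_must_sum_to_one(self, reduced_sim):
        meta = [data_io.StratumMeta("st1", area_weight=0.5, route_weight=0.9)]
        with pytest.raises(ValidationError, match="area weights"):
            assemble_dataset(reduced_sim.counts, reduced_sim.captures,
                             reduced_sim.ages, reduced_sim.covariates, meta)


class TestRoundTrip:
    def test_counts_round_trip(self, reduced_sim, tmp_path):
        path = tmp_path / "counts.csv"
        reduced_sim.counts.to_csv(path)
        back = load_counts(path)
        pd.testing.assert_frame_equal(
            back.records.sort_values(["route_observer", "year"]).reset_index(drop=True),
            reduced_sim.counts.records.sort_values(
                ["route_observer", "year"]
            ).reset_index(drop=True),
        )

    def test_captures_round_trip(self, reduced_sim, tmp_path):
        p1, p2 = tmp_path / "cap.csv", tmp_path / "sta.csv"
        reduced_sim.captures.to_csv(p1, p2)
        back = data_io.load_captures(p1, p2)
        assert np.array_equal(back.detections, reduced_sim.captures.detections)
        assert list(back.years) == list(reduced_sim.captures.years)

    def test_ages_round_trip(self, reduced_sim, tmp_path):
        path = tmp_path / "ages.csv"
        reduced_sim.ages.to_csv(path)
        back = data_io.load_ages(path)
        pd.testing.assert_frame_equal(
            back.rows, reduced_sim.ages.rows, check_exact=False, atol=1e-12
        )

    def test_config_driven_load(self, reduced_sim, tmp_path):
        reduced_sim.counts.to_csv(tmp_path / "counts.csv")
        reduced_sim.captures.to_csv(tmp_path / "cap.csv", tmp_path / "sta.csv")
        reduced_sim.ages.to_csv(tmp_path / "ages.csv")
        reduced_sim.covariates.to_csv(tmp_path / "cov.csv")
        cfg = """
paths:
  counts: counts.csv
  captures: cap.csv
  stations: sta.csv
  ages: ages.csv
  covariates: cov.csv
min_station_years: 4
strata:
  - {id: st1, area_weight: 1.0, route_weight: 0.95}
"""
        (tmp_path / "config.yaml").write_text(cfg)
        ds = data_io.load_dataset_from_config(tmp_path / "config.yaml")
        assert ds.n_strata == 1 and ds.n_years == 17
        assert ds.meta[0].route_weight == pytest.approx(0.95)
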