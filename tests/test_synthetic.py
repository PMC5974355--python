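"""Synthetic-data generators: calibration, censoring, determinism."""

import numpy as np
import pandas as pd
import pytest

from ternergy import (
    StageTruth,
    TruthParams,
    default_truth,
    generate_feeding_observations,
    generate_larid_allometry_table,
    generate_prey_photos,
    generate_trip_records,
)
from ternergy.observations import LengthMassCoefficients, length_to_mass
from ternergy.synthetic import read_table, write_table

EARLY, LATE = "early-provisioning", "late-provisioning"


def _durations_h(trips: pd.DataFrame) -> np.ndarray:
    return ((trips["arrival"] - trips["departure"]).dt.total_seconds() / 3600).to_numpy()


class TestTruthParams:
    def test_defaults_carry_study_stage_means(self, truth):
        assert truth.stage("incubation").trip_duration_h == 4.73
        assert truth.stage(EARLY).feeding_rate == 4.6
        assert truth.stage(LATE).trips_per_day == 4.57

    def test_yaml_round_trip(self, truth, tmp_path):
        p = tmp_path / "truth.yaml"
        truth.to_yaml(p)
        assert TruthParams.from_yaml(p) == truth

    def test_window_outside_twilight_rejected(self):
        with pytest.raises(ValueError, match="window"):
            TruthParams(stages={}, window_start="05:00")

    def test_unknown_stage_rejected(self, truth):
        with pytest.raises(ValueError, match="stage"):
            truth.stage("fledged")

    def test_nonpositive_means_rejected(self):
        with pytest.raises(ValueError):
            StageTruth(trip_duration_h=-1.0, trips_per_day=1.0)


class TestTripRecords:
    def test_mean_duration_and_rate_near_truth(self, truth):
        trips = generate_trip_records(truth, n_nests=200, n_days=5, stage="incubation")
        d = _durations_h(trips)
        assert np.all(d > 0)
        assert d.mean() == pytest.approx(4.73, rel=0.10)
        assert len(trips) / (200 * 5) == pytest.approx(1.52, rel=0.10)

    def test_large_sample_mean_within_two_percent(self, truth):
        trips = generate_trip_records(truth, n_nests=1500, n_days=7, stage="incubation")
        assert len(trips) > 10_000
        assert _durations_h(trips).mean() == pytest.approx(4.73, rel=0.02)
        assert len(trips) / (1500 * 7) == pytest.approx(1.52, rel=0.02)

    def test_full_window_means_no_censoring(self, truth):
        import dataclasses

        open_truth = dataclasses.replace(
            truth, window_start=truth.twilight_morning, window_end=truth.twilight_evening
        )
        trips = generate_trip_records(open_truth, 100, 5, "incubation")
        assert not trips["departure_censored"].any()
        assert not trips["arrival_censored"].any()

    def test_censored_timestamps_clipped_to_window_edge(self, truth):
        trips = generate_trip_records(truth, 300, 5, "incubation")
        assert trips["departure_censored"].any() and trips["arrival_censored"].any()
        dep_t = trips["departure"].dt.strftime("%H:%M")
        arr_t = trips["arrival"].dt.strftime("%H:%M")
        assert (dep_t[trips["departure_censored"]] == truth.window_start).all()
        assert (arr_t[trips["arrival_censored"]] == truth.window_end).all()
        # and uncensored timestamps lie inside the window ("HH:MM" display
        # truncates seconds, so the boundary minute itself can appear)
        assert (dep_t[~trips["departure_censored"]] >= truth.window_start).all()
        assert (arr_t[~trips["arrival_censored"]] <= truth.window_end).all()

    def test_seeded_determinism(self, truth):
        a = generate_trip_records(truth, 20, 3, EARLY)
        b = generate_trip_records(truth, 20, 3, EARLY)
        pd.testing.assert_frame_equal(a, b)

    @pytest.mark.parametrize("bad", [{"n_nests": 0}, {"n_days": -2}, {"stage": "moulting"}])
    def test_invalid_arguments_rejected(self, truth, bad):
        kwargs = {"n_nests": 5, "n_days": 2, "stage": "incubation", **bad}
        with pytest.raises(ValueError):
            generate_trip_records(truth, **kwargs)


class TestFeedingObservations:
    def test_mean_near_truth(self, truth):
        obs = generate_feeding_observations(truth, 240, EARLY)
        assert obs["deliveries"].mean() == pytest.approx(4.6, rel=0.10)
        assert (obs["deliveries"] >= 0).all()
        assert (obs["deliveries"] == obs["deliveries"].astype(int)).all()

    def test_large_sample_within_two_percent(self, truth):
        obs = generate_feeding_observations(truth, 10_000, EARLY)
        assert obs["deliveries"].mean() == pytest.approx(4.6, rel=0.02)

    def test_zero_rate_gives_all_zeros(self, truth):
        import dataclasses

        zero = dataclasses.replace(
            truth,
            stages={
                **truth.stages,
                EARLY: dataclasses.replace(truth.stages[EARLY], feeding_rate=0.0),
            },
        )
        obs = generate_feeding_observations(zero, 100, EARLY)
        assert (obs["deliveries"] == 0).all()

    def test_determinism_and_errors(self, truth):
        pd.testing.assert_frame_equal(
            generate_feeding_observations(truth, 50, LATE),
            generate_feeding_observations(truth, 50, LATE),
        )
        with pytest.raises(ValueError, match="feeding_rate"):
            generate_feeding_observations(truth, 50, "incubation")
        with pytest.raises(ValueError, match="n_units"):
            generate_feeding_observations(truth, 0, EARLY)


class TestPreyPhotos:
    def test_converted_mass_calibrated_to_stage_mean(self, truth):
        photos = generate_prey_photos(truth, 2000, EARLY)
        masses = length_to_mass(
            photos["standard_length_mm"].to_numpy(),
            LengthMassCoefficients(pooled=(truth.length_mass_a, truth.length_mass_b)),
        )
        assert masses.mean() == pytest.approx(4.4, rel=0.05)
        assert (photos["standard_length_mm"] > 0).all()

    def test_late_stage_mass_and_large_sample(self, truth):
        photos = generate_prey_photos(truth, 10_000, LATE)
        masses = length_to_mass(
            photos["standard_length_mm"].to_numpy(),
            LengthMassCoefficients(pooled=(truth.length_mass_a, truth.length_mass_b)),
        )
        assert masses.mean() == pytest.approx(5.2, rel=0.02)

    def test_zero_dispersion_collapses_to_mean(self, truth):
        import dataclasses

        st = truth.stages[EARLY]
        fixed = dataclasses.replace(
            truth,
            stages={**truth.stages, EARLY: dataclasses.replace(st, prey_length_cv=0.0)},
        )
        photos = generate_prey_photos(fixed, 50, EARLY)
        assert np.allclose(photos["standard_length_mm"], st.prey_length_mean_mm)

    def test_determinism(self, truth):
        pd.testing.assert_frame_equal(
            generate_prey_photos(truth, 30, LATE, year=2015),
            generate_prey_photos(truth, 30, LATE, year=2015),
        )


class TestAllometryTable:
    def test_noiseless_linear_form(self):
        table = generate_larid_allometry_table(
            539.5, 37.3, sigma=0.0, n_species=3, mass_range=(100, 1000), seed=0,
            masses=np.array([100.0, 370.0, 1000.0]),
        )
        assert np.allclose(table["tme_kj"], [4269.5, 14340.5, 37839.5])

    def test_zero_slope_constant(self):
        table = generate_larid_allometry_table(500.0, 0.0, 0.0, 5, (100, 1000), seed=0)
        assert np.allclose(table["tme_kj"], 500.0)

    def test_noiseless_table_refits_exactly(self):
        table = generate_larid_allometry_table(539.5, 37.3, 0.0, 10, (45, 1800), seed=1)
        slope, intercept = np.polyfit(table["asymptotic_mass_g"], table["tme_kj"], 1)
        assert slope == pytest.approx(37.3, abs=1e-9)
        assert intercept == pytest.approx(539.5, abs=1e-6)

    def test_calibrated_noise_preserves_ols_solution(self):
        table = generate_larid_allometry_table(
            539.5, 37.3, 2000.0, 10, (45, 1800), seed=3, calibrate=True
        )
        slope, intercept = np.polyfit(table["asymptotic_mass_g"], table["tme_kj"], 1)
        assert slope == pytest.approx(37.3, abs=1e-8)
        assert intercept == pytest.approx(539.5, abs=1e-5)
        resid = table["tme_kj"] - (539.5 + 37.3 * table["asymptotic_mass_g"])
        assert np.sqrt(np.mean(resid**2)) == pytest.approx(2000.0, rel=1e-9)

    def test_degenerate_mass_range_rejected(self):
        with pytest.raises(ValueError):
            generate_larid_allometry_table(539.5, 37.3, 0.0, 5, (370, 370), seed=0)
        with pytest.raises(ValueError):
            generate_larid_allometry_table(539.5, 37.3, 0.0, 2, (100, 1000), seed=0)


def test_tables_round_trip_as_delimited_text(truth, tmp_path):
    trips = generate_trip_records(truth, 10, 2, "incubation")
    p = tmp_path / "trips.tsv"
    write_table(trips, p)
    back = read_table(p)
    pd.testing.assert_frame_equal(trips, back)
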