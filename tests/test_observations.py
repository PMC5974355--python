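"""Ingestion: twilight substitution, trip assembly, length-mass conversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ternergy import (
    LengthMassCoefficients,
    TwilightTable,
    assemble_trip_durations,
    generate_trip_records,
    length_to_mass,
)

EARLY = "early-provisioning"


def _record(dep, arr, dep_cens=False, arr_cens=False, nest="n1", stage="incubation"):
    return {
        "nest_id": nest,
        "stage": stage,
        "date": dep[:10],
        "departure": pd.Timestamp(dep),
        "arrival": pd.Timestamp(arr),
        "departure_censored": dep_cens,
        "arrival_censored": arr_cens,
    }


class TestTwilightSubstitution:
    def test_departure_censored_record_extended_to_morning_twilight(self):
        # camera started 07:00; bird already gone; twilight 05:45, back 09:45
        rec = pd.DataFrame([_record("2014-03-01 07:00", "2014-03-01 09:45", dep_cens=True)])
        out = assemble_trip_durations(rec, TwilightTable(default=("05:45", "19:30")))
        assert out.durations["duration_h"].iloc[0] == pytest.approx(4.0)

    def test_uncensored_record_untouched(self):
        rec = pd.DataFrame([_record("2014-03-01 08:00", "2014-03-01 10:00")])
        out = assemble_trip_durations(rec)
        assert out.durations["duration_h"].iloc[0] == pytest.approx(2.0)

    def test_arrival_censored_record_extended_to_evening_twilight(self):
        rec = pd.DataFrame([_record("2014-03-01 15:00", "2014-03-01 19:00", arr_cens=True)])
        out = assemble_trip_durations(rec, TwilightTable(default=("05:45", "19:30")))
        assert out.durations["duration_h"].iloc[0] == pytest.approx(4.5)

    def test_substitution_never_shortens_a_trip(self, truth):
        trips = generate_trip_records(truth, 150, 5, "incubation")
        raw = ((trips["arrival"] - trips["departure"]).dt.total_seconds() / 3600).to_numpy()
        out = assemble_trip_durations(
            trips, TwilightTable(default=(truth.twilight_morning, truth.twilight_evening))
        )
        assert out.n_dropped == 0
        assert np.all(out.durations["duration_h"].to_numpy() >= raw - 1e-12)

    def test_assembled_mean_tracks_generator_truth(self, truth):
        trips = generate_trip_records(truth, 200, 5, "incubation")
        assert trips["departure_censored"].mean() > 0.03  # censoring exercised
        out = assemble_trip_durations(
            trips, TwilightTable(default=(truth.twilight_morning, truth.twilight_evening))
        )
        assert out.durations["duration_h"].mean() == pytest.approx(4.73, rel=0.10)

    def test_idempotent_under_reassembly(self, truth):
        trips = generate_trip_records(truth, 40, 3, EARLY)
        tw = TwilightTable(default=(truth.twilight_morning, truth.twilight_evening))
        a = assemble_trip_durations(trips, tw)
        b = assemble_trip_durations(trips, tw)
        pd.testing.assert_frame_equal(a.durations, b.durations)
        pd.testing.assert_frame_equal(a.trip_counts, b.trip_counts)

    def test_inverted_substitution_dropped_with_count(self, caplog):
        # arrival-censored record on a date whose evening twilight precedes
        # the recorded departure: substitution inverts it -> dropped
        rec = pd.DataFrame(
            [
                _record("2014-03-01 18:00", "2014-03-01 19:00", arr_cens=True),
                _record("2014-03-01 08:00", "2014-03-01 10:00"),
            ]
        )
        out = assemble_trip_durations(rec, TwilightTable(default=("05:45", "17:00")))
        assert out.n_dropped == 1
        assert len(out.durations) == 1

    def test_midnight_spanning_trip_rejected(self):
        rec = pd.DataFrame([_record("2014-03-01 18:00", "2014-03-02 06:00")])
        with pytest.raises(ValueError, match="midnight"):
            assemble_trip_durations(rec)

    def test_missing_columns_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            assemble_trip_durations(pd.DataFrame({"nest_id": []}))

    def test_unknown_stage_rejected(self):
        rec = pd.DataFrame([_record("2014-03-01 08:00", "2014-03-01 10:00", stage="odd")])
        with pytest.raises(ValueError, match="stage"):
            assemble_trip_durations(rec)


class TestTripCounts:
    def test_zero_trip_days_enter_denominator(self):
        # nest n1 observed on two dates but tripped on one: rate 1 trip / 2 d
        rec = pd.DataFrame(
            [
                _record("2014-03-01 08:00", "2014-03-01 10:00", nest="n1"),
                _record("2014-03-02 08:00", "2014-03-02 10:00", nest="n2"),
                _record("2014-03-01 09:00", "2014-03-01 11:00", nest="n2"),
            ]
        )
        out = assemble_trip_durations(rec)
        assert sorted(out.trips_per_day("incubation")) == [0.5, 1.0]

    def test_generated_rates_near_truth(self, truth):
        trips = generate_trip_records(truth, 300, 5, "incubation")
        out = assemble_trip_durations(
            trips, TwilightTable(default=(truth.twilight_morning, truth.twilight_evening))
        )
        assert out.trips_per_day("incubation").mean() == pytest.approx(1.52, rel=0.05)


class TestLengthToMass:
    def test_fixture_anchor_nine_cm_anchovy(self):
        assert length_to_mass(90.0, LengthMassCoefficients()) == pytest.approx(4.4)

    def test_zero_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            length_to_mass(0.0, LengthMassCoefficients())

    @given(length=st.floats(1.0, 300.0), factor=st.floats(1.01, 4.0))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_power_law_scaling_and_monotonicity(self, length, factor):
        c = LengthMassCoefficients()
        m1 = length_to_mass(length, c)
        m2 = length_to_mass(length * factor, c)
        assert m2 > m1
        assert m2 / m1 == pytest.approx(factor**3.2, rel=1e-9)

    def test_doubling_length_multiplies_mass(self):
        c = LengthMassCoefficients()
        assert length_to_mass(180.0, c) / length_to_mass(90.0, c) == pytest.approx(
            2**3.2, rel=1e-12
        )

    def test_year_specific_with_pooled_fallback(self):
        c = LengthMassCoefficients(pooled=(0.004, 3.0), by_year={2014: (0.005, 3.0)})
        assert length_to_mass(100.0, c, year=2014) == pytest.approx(0.005 * 10.0**3)
        assert length_to_mass(100.0, c, year=1999) == pytest.approx(0.004 * 10.0**3)

    def test_missing_year_without_fallback_rejected(self):
        c = LengthMassCoefficients(pooled=None, by_year={2014: (0.005, 3.0)})
        with pytest.raises(KeyError, match="1999"):
            length_to_mass(100.0, c, year=1999)
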