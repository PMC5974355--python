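"""Ingestion and cleaning of field observation tables.

Three delimited-text tables feed the pipeline: foraging-trip records
from nest cameras, chick feeding observations, and photo-sampled prey
records.  This module applies the twilight-censoring substitution (a
bird that had already left before filming began is assigned the morning
nautical-twilight departure; one that had not returned when filming
stopped is assigned the evening twilight arrival), derives per-stage
trip-duration samples and per-nest-day trip counts, and converts fish
standard lengths to wet masses through a power-law regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .synthetic import STAGES, _parse_clock

__all__ = [
    "TwilightTable",
    "LengthMassCoefficients",
    "AssembledTrips",
    "assemble_trip_durations",
    "length_to_mass",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TwilightTable:
    """Nautical-twilight clock times per date.

    ``times`` maps an ISO date string to ``(morning, evening)`` "HH:MM"
    pairs; ``default`` covers dates absent from the map (a single almanac
    pair is adequate for the few-week windows the colony is filmed over).
    """

    times: dict[str, tuple[str, str]] = field(default_factory=dict)
    default: tuple[str, str] | None = ("05:45", "19:30")

    def lookup(self, date: str) -> tuple[float, float]:
        pair = self.times.get(date, self.default)
        if pair is None:
            raise KeyError(f"no twilight times available for date {date}")
        morning, evening = _parse_clock(pair[0]), _parse_clock(pair[1])
        if not morning < evening:
            raise ValueError(f"twilight times inverted for date {date}")
        return morning, evening


@dataclass
class AssembledTrips:
    """Per-stage duration samples plus per-nest-day trip counts."""

    durations: pd.DataFrame  # columns: nest_id, stage, date, duration_h
    trip_counts: pd.DataFrame  # columns: nest_id, stage, date, n_trips
    n_dropped: int = 0

    def stage_durations(self, stage: str) -> np.ndarray:
        return self.durations.loc[self.durations["stage"] == stage, "duration_h"].to_numpy()

    def trips_per_day(self, stage: str, per_nest: bool = True) -> np.ndarray:
        """Trip rates for one stage.

        With ``per_nest=True`` (default) the rate is each nest's total
        trips divided by its number of fully covered days — a strictly
        positive quantity suitable for a gamma likelihood; otherwise raw
        per-nest-day counts are returned.
        """
        sub = self.trip_counts[self.trip_counts["stage"] == stage]
        if not per_nest:
            return sub["n_trips"].to_numpy(dtype=float)
        agg = sub.groupby("nest_id")["n_trips"].agg(["sum", "count"])
        return (agg["sum"] / agg["count"]).to_numpy(dtype=float)


_REQUIRED_TRIP_COLS = [
    "nest_id",
    "stage",
    "date",
    "departure",
    "arrival",
    "departure_censored",
    "arrival_censored",
]


def assemble_trip_durations(
    records: pd.DataFrame,
    twilight: TwilightTable | None = None,
    coverage: pd.DataFrame | None = None,
) -> AssembledTrips:
    """Apply the twilight substitution and derive durations and counts.

    For departure-censored records the departure timestamp is replaced by
    morning nautical twilight of that date; for arrival-censored records
    the arrival is replaced by evening twilight.  Durations are the
    arrival−departure difference in hours.  Records whose substituted
    departure is not strictly before their arrival, or that span
    midnight (the birds do not forage at night), are dropped with a
    logged warning and counted in ``n_dropped``.

    ``coverage`` optionally lists the fully camera-covered nest-days as
    a (nest_id, stage, date) table; covered days without any trip then
    count zero in the trips/day denominator.  Without it, every nest in
    a stage is assumed covered on every date that stage was filmed (true
    of the synthetic tables; supply the table for real data with uneven
    effort).  Partially covered days should be excluded from the table —
    only fully covered days enter the denominator.

    The operation is idempotent: re-assembling its own output table is a
    no-op because substitution only touches flagged timestamps.
    """
    missing = [c for c in _REQUIRED_TRIP_COLS if c not in records.columns]
    if missing:
        raise ValueError(f"trip records missing required columns: {missing}")
    unknown = set(records["stage"]) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage labels in trip records: {sorted(unknown)}")
    twilight = twilight or TwilightTable()

    df = records.copy()
    df["departure"] = pd.to_datetime(df["departure"])
    df["arrival"] = pd.to_datetime(df["arrival"])
    if (df["departure"].dt.date != df["arrival"].dt.date).any():
        n_span = int((df["departure"].dt.date != df["arrival"].dt.date).sum())
        raise ValueError(
            f"{n_span} trip record(s) span midnight; greater crested terns do not "
            "forage at night — check timestamps"
        )

    dates = df["date"].astype(str)
    tw = pd.DataFrame(
        [twilight.lookup(d) for d in dates], columns=["morning", "evening"], index=df.index
    )
    day_start = pd.to_datetime(dates)

    dep = df["departure"].copy()
    arr = df["arrival"].copy()
    dep_cens = df["departure_censored"].astype(bool)
    arr_cens = df["arrival_censored"].astype(bool)
    dep[dep_cens] = day_start[dep_cens] + pd.to_timedelta(tw.loc[dep_cens, "morning"], unit="h")
    arr[arr_cens] = day_start[arr_cens] + pd.to_timedelta(tw.loc[arr_cens, "evening"], unit="h")

    duration_h = (arr - dep).dt.total_seconds() / 3600.0
    valid = duration_h > 0
    n_dropped = int((~valid).sum())
    if n_dropped:
        logger.warning(
            "dropped %d trip record(s) with non-positive duration after twilight substitution",
            n_dropped,
        )

    durations = pd.DataFrame(
        {
            "nest_id": df.loc[valid, "nest_id"],
            "stage": df.loc[valid, "stage"],
            "date": dates[valid],
            "duration_h": duration_h[valid],
        }
    ).reset_index(drop=True)

    observed = (
        durations.groupby(["nest_id", "stage", "date"], as_index=False)
        .size()
        .rename(columns={"size": "n_trips"})
    )
    # a covered nest-day with no trips still counts in the trips/day
    # denominator: expand to the full nest x date grid per stage
    if coverage is None:
        grids = []
        for s, sub in observed.groupby("stage"):
            nests = sub["nest_id"].unique()
            dates = sub["date"].unique()
            grids.append(
                pd.MultiIndex.from_product(
                    [nests, [s], dates], names=["nest_id", "stage", "date"]
                ).to_frame(index=False)
            )
        coverage = pd.concat(grids, ignore_index=True)
    counts = coverage.merge(observed, on=["nest_id", "stage", "date"], how="left")
    counts["n_trips"] = counts["n_trips"].fillna(0).astype(int)
    return AssembledTrips(durations=durations, trip_counts=counts, n_dropped=n_dropped)


@dataclass(frozen=True)
class LengthMassCoefficients:
    """Power-law length–mass coefficients, optionally per calendar year.

    mass(g) = a · (length in cm) ** b.  ``by_year`` holds year-specific
    (a, b) pairs; ``pooled`` is the documented fallback applied when a
    year is missing.  With no pooled pair, a missing year is an error.
    """

    pooled: tuple[float, float] | None = (4.4 / 9.0**3.2, 3.2)
    by_year: dict[int, tuple[float, float]] = field(default_factory=dict)

    def coefficients_for(self, year: int | None) -> tuple[float, float]:
        if year is not None and int(year) in self.by_year:
            a, b = self.by_year[int(year)]
        elif self.pooled is not None:
            a, b = self.pooled
        else:
            raise KeyError(
                f"no length-mass coefficients for year {year} and no pooled fallback"
            )
        if a <= 0 or b <= 0:
            raise ValueError("length-mass coefficients must be positive")
        return a, b


def length_to_mass(
    length_mm: float | np.ndarray,
    coefficients: LengthMassCoefficients,
    year: int | None = None,
) -> float | np.ndarray:
    """Convert fish standard length (mm) to wet mass (g).

    Strictly increasing in length; rejects non-positive lengths.
    """
    a, b = coefficients.coefficients_for(year)
    length = np.asarray(length_mm, dtype=float)
    if np.any(length <= 0):
        raise ValueError("standard length must be strictly positive (mm)")
    mass = a * (length / 10.0) ** b
    return float(mass) if np.isscalar(length_mm) else mass
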