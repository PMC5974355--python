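"""Simulate the observation tables for a synthetic tern colony.

The generator emulates three non-invasive data streams from a breeding
colony of greater crested terns: nest-camera foraging-trip records
(with twilight censoring at the camera window edges), chick feeding
watches, and photo-sampled prey lengths.  Ground truth is known, so
every downstream estimate can be checked against it.
"""

import numpy as np

from ternergy import (
    LengthMassCoefficients,
    default_truth,
    generate_feeding_observations,
    generate_prey_photos,
    generate_trip_records,
    length_to_mass,
)

truth = default_truth(seed=1)

trips = generate_trip_records(truth, n_nests=100, n_days=5, stage="incubation")
durations = (trips["arrival"] - trips["departure"]).dt.total_seconds() / 3600
print(trips.head(3).to_string(index=False))
print(
    f"\n{len(trips)} incubation trips from 100 nests x 5 d: "
    f"mean duration {durations.mean():.2f} h (truth 4.73 h), "
    f"{trips['departure_censored'].mean():.1%} departure-censored"
)

feeding = generate_feeding_observations(truth, n_units=240, stage="early-provisioning")
print(
    f"feeding watches: {feeding['deliveries'].mean():.2f} deliveries per "
    "nest-day (truth 4.6) — the daily ration of whole anchovies a small chick receives"
)

photos = generate_prey_photos(truth, n_photos=500, stage="early-provisioning")
coeffs = LengthMassCoefficients(pooled=(truth.length_mass_a, truth.length_mass_b))
masses = length_to_mass(photos["standard_length_mm"].to_numpy(), coeffs)
print(
    f"prey photos: mean anchovy {photos['standard_length_mm'].mean():.0f} mm, "
    f"{masses.mean():.2f} g wet mass after length-mass conversion (truth 4.4 g)"
)
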