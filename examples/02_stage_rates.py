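"""Fit the stage-stratified gamma regression for trip durations.

Foraging-trip durations are positive and right-skewed, so stage means
are estimated with a gamma likelihood and log link (stage as a
categorical covariate), sampled by MCMC.  Censored trips are first
completed by substituting nautical twilight for the unseen departure or
arrival — a bird gone before the camera woke up left no later than
first light.
"""

import pandas as pd

from ternergy import (
    ChainConfig,
    TwilightTable,
    assemble_trip_durations,
    default_truth,
    fit_stage_gamma,
    generate_trip_records,
)

truth = default_truth(seed=2)
trips = pd.concat(
    [
        generate_trip_records(truth, 80, 5, "incubation"),
        generate_trip_records(truth, 80, 5, "early-provisioning"),
    ],
    ignore_index=True,
)
assembled = assemble_trip_durations(
    trips, TwilightTable(default=(truth.twilight_morning, truth.twilight_evening))
)

fit = fit_stage_gamma(
    assembled.durations["duration_h"].to_numpy(),
    assembled.durations["stage"].to_numpy(),
    ChainConfig.reduced(seed=2),
)
print(fit.summary().to_string(index=False))
print(
    "\nmu_<stage> rows are posterior mean trip durations (h); the truth values "
    "are 4.73 (incubation) and 1.83 (early provisioning). R-hat ~ 1 means the "
    "three chains agree."
)
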