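"""Adult time-energy budget: activity costs, DEE, DFI and scaling.

Daily energy expenditure follows the classic activity-budget form

    DEE = Σ_k D_k · M_k            (kJ·d⁻¹)

summing, over the activities k ∈ {colony, flying, diving}, the daily
duration D_k (min) times the whole-bird metabolic cost M_k (kJ·min⁻¹).
Time away from the colony is costed entirely at the flying rate (the
birds neither rest on the water nor dive for more than seconds), the
cost of resting at the colony is twice the basal metabolic rate, and
the flight cost is the midpoint of the minimum- and maximum-power
estimates from aerodynamic modelling (whose two printed power outputs
are inputs here, not recomputed).  DEE converts to daily food intake
through the prey's calorific value Cp and the assimilation efficiency
Ea:

    DFI = DEE / (Cp · Ea)          (g wet mass·d⁻¹)

All operations act element-wise on posterior/Monte-Carlo draw vectors,
so uncertainty propagates through the identities exactly.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .rates import StageTimeBudget

__all__ = [
    "EnergeticParams",
    "ActivityCosts",
    "flight_unit_cost",
    "activity_costs",
    "dee",
    "adult_dfi",
    "cpue",
    "population_dfi",
    "point_budget",
    "sensitivity_oat",
]

_WATT_PER_KG_TO_KJ_PER_KG_MIN = 60.0 / 1000.0  # 1 W·kg⁻¹ = 0.06 kJ·kg⁻¹·min⁻¹


@dataclass(frozen=True)
class EnergeticParams:
    """Energetic and life-history constants with uncertainty specification.

    Means/SDs follow the study's parameter table for the greater crested
    tern; an SD of zero marks an input held fixed during propagation.
    The assimilation efficiency carries an optional truncation interval
    (applied when ``assimilation_sd > 0``) because an unbounded normal
    with a large SD would produce non-positive or > 1 efficiencies.
    ``rounded_unit_costs=True`` switches to the table-rounded unit costs
    (0.8 / 2.0 kJ·kg⁻¹·min⁻¹) instead of the full-precision values
    derived from BMR and flight power.
    """

    body_mass_kg: float = 0.39
    body_mass_sd: float = 0.03
    bmr_w_per_kg: float = 6.73
    colony_cost_multiplier: float = 2.0  # resting at colony = 2 x BMR
    flight_power_min_w_per_kg: float = 31.8
    flight_power_max_w_per_kg: float = 39.5
    prey_energy_kj_per_g: float = 6.22
    prey_energy_sd: float = 0.65
    assimilation_efficiency: float = 0.77
    assimilation_sd: float = 0.0
    assimilation_bounds: tuple[float, float] = (0.05, 1.0)
    diving_min_per_day: float = 1.0
    diving_sd: float = 0.2
    incubation_days: int = 28
    early_provisioning_days: int = 4
    late_provisioning_days: int = 36
    fledging_days: int = 40
    asymptotic_chick_mass_g: float = 370.0
    allometry_intercept_kj: float = 539.5
    allometry_slope_kj_per_g: float = 37.3
    breeding_success: float = 0.59  # chicks fledged per pair
    breeding_pairs: int = 15_000
    rounded_unit_costs: bool = False

    def __post_init__(self) -> None:
        for name in (
            "body_mass_kg",
            "flight_power_min_w_per_kg",
            "flight_power_max_w_per_kg",
            "prey_energy_kj_per_g",
            "assimilation_efficiency",
            "fledging_days",
            "asymptotic_chick_mass_g",
            "breeding_success",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.bmr_w_per_kg < 0 or self.colony_cost_multiplier < 0:
            raise ValueError("BMR and colony-cost multiplier must be non-negative")
        if self.flight_power_min_w_per_kg > self.flight_power_max_w_per_kg:
            raise ValueError("flight power bounds inverted (min > max)")
        if not 0 < self.assimilation_efficiency <= 1:
            raise ValueError("assimilation efficiency must lie in (0, 1]")
        if self.breeding_pairs < 0:
            raise ValueError("breeding_pairs must be non-negative")

    def replace(self, **kwargs) -> "EnergeticParams":
        return dataclasses.replace(self, **kwargs)

    def to_yaml(self, path) -> None:
        d = dataclasses.asdict(self)
        d["assimilation_bounds"] = list(self.assimilation_bounds)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "EnergeticParams":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "assimilation_bounds" in d:
            d["assimilation_bounds"] = tuple(d["assimilation_bounds"])
        return cls(**d)


@dataclass
class ActivityCosts:
    """Whole-bird unit costs (kJ·min⁻¹) per activity; scalar or draws."""

    colony: float | np.ndarray
    flying: float | np.ndarray
    diving: float | np.ndarray

    def __post_init__(self) -> None:
        for name in ("colony", "flying", "diving"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} unit cost must be non-negative")
        if np.any(np.asarray(self.flying) < np.asarray(self.colony)):
            raise ValueError("flying must cost at least as much as resting at the colony")


def flight_unit_cost(
    p_min: float, p_max: float, mass: float | np.ndarray
) -> tuple[float, float | np.ndarray]:
    """Flight cost from min/max aerodynamic power estimates.

    Returns ``(mass-specific W·kg⁻¹, whole-bird kJ·min⁻¹)``: the
    mass-specific cost is the midpoint (p_min + p_max)/2; the whole-bird
    cost converts W·kg⁻¹ → kJ·kg⁻¹·min⁻¹ (× 60/1000) and multiplies by
    body mass.  ``mass`` may be a draw vector.
    """
    if not 0 < p_min <= p_max:
        raise ValueError("need 0 < p_min <= p_max (W·kg⁻¹)")
    mass = np.asarray(mass, dtype=float) if not np.isscalar(mass) else mass
    specific = (p_min + p_max) / 2.0
    whole_bird = specific * _WATT_PER_KG_TO_KJ_PER_KG_MIN * mass
    return specific, whole_bird


def activity_costs(
    params: EnergeticParams, mass: float | np.ndarray | None = None
) -> ActivityCosts:
    """Whole-bird unit costs per activity from the parameter set.

    Colony cost is ``colony_cost_multiplier × BMR`` converted to
    kJ·min⁻¹; flying comes from :func:`flight_unit_cost`; diving is
    costed at the flying rate (dives are brief and occur within flight).
    ``mass`` (scalar or draws) defaults to the central body mass.
    """
    m = params.body_mass_kg if mass is None else mass
    if params.rounded_unit_costs:
        colony_specific = 0.8  # kJ·kg⁻¹·min⁻¹, table-rounded
        flying_specific = 2.0
        colony = colony_specific * np.asarray(m, dtype=float)
        flying = flying_specific * np.asarray(m, dtype=float)
    else:
        colony = (
            params.colony_cost_multiplier
            * params.bmr_w_per_kg
            * _WATT_PER_KG_TO_KJ_PER_KG_MIN
            * np.asarray(m, dtype=float)
        )
        _, flying = flight_unit_cost(
            params.flight_power_min_w_per_kg, params.flight_power_max_w_per_kg, m
        )
    if np.ndim(colony) == 0:
        colony, flying = float(colony), float(flying)
    return ActivityCosts(colony=colony, flying=flying, diving=flying)


def dee(budget: StageTimeBudget, costs: ActivityCosts) -> np.ndarray:
    """Daily energy expenditure: Σ duration × unit cost, per draw (kJ·d⁻¹).

    Diving minutes are carved out of the flying block so each minute of
    the day is costed exactly once.
    """
    arrays = [np.asarray(a, dtype=float) for a in (costs.colony, costs.flying, costs.diving)]
    n = budget.flying_min.size
    for a in arrays:
        if a.ndim > 0 and a.size not in (1, n):
            raise ValueError(
                f"cost draws ({a.size}) not aligned with budget draws ({n})"
            )
    colony_c, flying_c, diving_c = arrays
    return (
        budget.colony_min * colony_c
        + (budget.flying_min - budget.diving_min) * flying_c
        + budget.diving_min * diving_c
    )


def adult_dfi(
    dee_draws: np.ndarray, cp_draws: np.ndarray, ea_draws: np.ndarray
) -> np.ndarray:
    """Daily food intake DFI = DEE / (Cp × Ea), per draw (g·d⁻¹)."""
    d = np.asarray(dee_draws, dtype=float)
    cp = np.asarray(cp_draws, dtype=float)
    ea = np.asarray(ea_draws, dtype=float)
    if np.any(cp <= 0) or np.any(ea <= 0):
        raise ValueError("Cp and Ea draws must be strictly positive")
    return d / (cp * ea)


def cpue(adult_dfi_draws: np.ndarray, minutes_at_sea: np.ndarray) -> np.ndarray:
    """Catch per unit effort: food caught per minute at sea (g·min⁻¹)."""
    m = np.asarray(minutes_at_sea, dtype=float)
    if np.any(m <= 0):
        raise ValueError("minutes at sea must be strictly positive")
    return np.asarray(adult_dfi_draws, dtype=float) / m


def population_dfi(pairs: int, per_capita_dfi_g: float | np.ndarray) -> float | np.ndarray:
    """Breeding-population daily food intake (kg·d⁻¹).

    Follows the published arithmetic: pairs × per-capita total DFI
    (fledging-period mean, g·d⁻¹) / 1000.
    """
    if pairs < 0:
        raise ValueError("pairs must be non-negative")
    out = pairs * np.asarray(per_capita_dfi_g, dtype=float) / 1000.0
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Deterministic point pipeline and one-at-a-time sensitivity
# ---------------------------------------------------------------------------

#: central-value stage time inputs (trip duration h, trips per day)
DEFAULT_STAGE_INPUTS: dict[str, tuple[float, float]] = {
    "incubation": (4.73, 1.52),
    "early-provisioning": (1.83, 4.08),
    "late-provisioning": (2.24, 4.57),
}


def point_budget(
    params: EnergeticParams,
    stage_inputs: dict[str, tuple[float, float]] | None = None,
) -> dict[str, float]:
    """All budget outputs at central parameter values (no uncertainty).

    Used by the sensitivity analysis and as a fast sanity check; the
    full pipeline replaces every scalar here with posterior draws.
    """
    from . import chick  # local import to avoid a cycle at module load

    stage_inputs = stage_inputs or DEFAULT_STAGE_INPUTS
    costs = activity_costs(params)
    cp_ea = params.prey_energy_kj_per_g * params.assimilation_efficiency

    out: dict[str, float] = {}
    for stage, (dur_h, trips) in stage_inputs.items():
        flying = 60.0 * dur_h * trips
        colony = 1440.0 - flying
        diving = min(params.diving_min_per_day, flying)
        d = colony * costs.colony + (flying - diving) * costs.flying + diving * costs.diving
        out[f"dee_{stage}"] = d
        out[f"adult_dfi_{stage}"] = d / cp_ea
        out[f"cpue_{stage}"] = (d / cp_ea) / flying

    tme = params.allometry_intercept_kj + (
        params.allometry_slope_kj_per_g * params.asymptotic_chick_mass_g
    )
    f_days = int(round(params.fledging_days))
    mei = tme / params.fledging_days
    chick_dfi_v = mei / cp_ea
    cmr = chick.daily_mortality(params.breeding_success, params.fledging_days)
    weight = chick.survival_weight(cmr, f_days)
    out["chick_mei"] = mei
    out["chick_dfi"] = chick_dfi_v
    out["survival_weight"] = weight
    out["chick_dfi_expected"] = chick_dfi_v * weight

    tdfi1 = out["adult_dfi_early-provisioning"] + chick_dfi_v * weight * 0.5
    tdfi2 = out["adult_dfi_late-provisioning"] + chick_dfi_v * weight * 0.5
    w_early = params.early_provisioning_days / (
        params.early_provisioning_days + params.late_provisioning_days
    )
    out["tdfi_early-provisioning"] = tdfi1
    out["tdfi_late-provisioning"] = tdfi2
    out["tdfi_fledging"] = tdfi1 * w_early + tdfi2 * (1.0 - w_early)
    out["population_dfi"] = population_dfi(params.breeding_pairs, out["tdfi_fledging"])
    return out


#: scalar inputs perturbed by the one-at-a-time sensitivity analysis
_SENSITIVITY_INPUTS = (
    "body_mass_kg",
    "bmr_w_per_kg",
    "colony_cost_multiplier",
    "flight_power_min_w_per_kg",
    "flight_power_max_w_per_kg",
    "prey_energy_kj_per_g",
    "assimilation_efficiency",
    "diving_min_per_day",
    "asymptotic_chick_mass_g",
    "allometry_intercept_kj",
    "allometry_slope_kj_per_g",
    "breeding_success",
    "fledging_days",
)


def sensitivity_oat(
    params: EnergeticParams,
    perturbation: float = 0.1,
    target: str = "tdfi_fledging",
    stage_inputs: dict[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """One-at-a-time sensitivity of a named budget output.

    Each scalar input is perturbed to (1 ± perturbation) × its central
    value with everything else fixed.  Reported per input: the relative
    output change (f₊ − f₋) / (2 f₀) and the elasticity
    Δlog(output) / Δlog(input) — exact for power-law dependencies (e.g.
    −1 for DFI with respect to Cp or Ea).  Rows are ranked by absolute
    elasticity.
    """
    if not 0 < perturbation < 1:
        raise ValueError("perturbation must be a fraction in (0, 1)")
    base = point_budget(params, stage_inputs)
    if target not in base:
        raise ValueError(
            f"unknown target {target!r}; known outputs: {sorted(base)}"
        )
    f0 = base[target]
    dlog_x = np.log1p(perturbation) - np.log1p(-perturbation)
    rows = []
    for name in _SENSITIVITY_INPUTS:
        x0 = getattr(params, name)
        try:
            f_plus = point_budget(params.replace(**{name: x0 * (1 + perturbation)}), stage_inputs)[target]
            f_minus = point_budget(params.replace(**{name: x0 * (1 - perturbation)}), stage_inputs)[target]
        except ValueError:
            continue  # perturbed value violates a parameter invariant
        rows.append(
            {
                "input": name,
                "rel_change": (f_plus - f_minus) / (2.0 * f0),
                "elasticity": (np.log(f_plus) - np.log(f_minus)) / dlog_x,
            }
        )
    table = pd.DataFrame(rows)
    table["abs_elasticity"] = table["elasticity"].abs()
    table = (
        table.sort_values("abs_elasticity", ascending=False)
        .drop(columns="abs_elasticity")
        .reset_index(drop=True)
    )
    return table
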