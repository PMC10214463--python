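"""Energy accounting for a foraging trip: tissue energy, field metabolic
rate, fever scenarios, blood-oxygen stores and fasting projections.

Tissue energy densities follow the standard composition chemistry for
phocids: lean tissue is 27% water-free matter at 17.99 MJ kg^-1 dry, lipid is
90% water-free at 39.33 MJ kg^-1. The at-sea field metabolic rate (FMR) for
post-breeding adult females is 90.1 kJ kg^-1 d^-1, blood volume is 20.2% of
body mass, and a fever raises metabolic rate by 10-12.5% per degree C, the
range reported for endotherms.

Internal arithmetic is full precision; the ``report_*`` values round the way
field studies print them (decimal half-up), via :func:`round_half_up`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

__all__ = [
    "EnergyConstants",
    "EnergyBudget",
    "round_half_up",
    "tissue_energy",
    "fmr_cost",
    "fever_fmr",
    "fever_cost",
    "blood_volume_L",
    "fasting_projection",
    "trip_energy_budget",
]


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal round-half-up (the convention of printed field tables).

    Python's built-in round is banker's rounding and binary floats carry
    representation error, so the value is first snapped to ``ndigits + 6``
    decimals before the half-up quantisation.
    """
    q = Decimal(1).scaleb(-ndigits)
    snapped = Decimal(str(round(x, ndigits + 6)))
    return float(snapped.quantize(q, rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class EnergyConstants:
    """Physiological constants of the energy budget (see module docstring)."""

    lean_dry_fraction: float = 0.27          # water-free fraction of lean tissue
    lean_energy_density: float = 17.99       # MJ per kg dry lean
    lipid_dry_fraction: float = 0.90
    lipid_energy_density: float = 39.33      # MJ per kg dry lipid
    fmr_baseline: float = 90.1               # kJ kg^-1 d^-1, at-sea post-breeding
    blood_fraction: float = 0.202            # blood mass as fraction of body mass
    fever_increase_per_degC: tuple = (0.10, 0.125)

    def __post_init__(self):
        for name in ("lean_dry_fraction", "lipid_dry_fraction", "blood_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.lean_energy_density <= 0 or self.lipid_energy_density <= 0 \
                or self.fmr_baseline <= 0:
            raise ValueError("energy densities and FMR must be positive")


@dataclass
class EnergyBudget:
    """Tissue losses and energy components for one trip."""

    lean_loss_kg: float
    lipid_loss_kg: float
    lean_MJ: float
    lipid_MJ: float
    total_MJ: float
    lean_share_pct: int
    scenario_MJ: dict = field(default_factory=dict)


def tissue_energy(lean_kg: float, lipid_kg: float,
                  c: EnergyConstants = EnergyConstants()):
    """Energy content of lean and lipid tissue masses.

    Returns (lean_MJ, lipid_MJ, total_MJ, lean_share_pct) with lean/lipid MJ
    rounded to 1 decimal, total to the nearest MJ and the lean share to the
    nearest percent, the precision these budgets are reported at.
    """
    if lean_kg < 0 or lipid_kg < 0:
        raise ValueError("tissue masses must be non-negative")
    lean = lean_kg * c.lean_dry_fraction * c.lean_energy_density
    lipid = lipid_kg * c.lipid_dry_fraction * c.lipid_energy_density
    total = lean + lipid
    share = 100.0 * lean / total if total > 0 else 0.0
    return (round_half_up(lean, 1), round_half_up(lipid, 1),
            round_half_up(total, 0), int(round_half_up(share, 0)))


def fmr_cost(mass_start_kg: float, mass_end_kg: float, days: float,
             fmr_kJ_per_kg_day: float = EnergyConstants.fmr_baseline) -> float:
    """Total metabolic cost (MJ) over a trip with linearly changing mass.

    Integrating fmr x m(t) with m(t) linear between the endpoints gives
    fmr x days x (m_start + m_end) / 2 exactly (trapezoid is exact for a
    linear integrand).
    """
    if days <= 0 or mass_start_kg <= 0 or mass_end_kg <= 0:
        raise ValueError("days and masses must be positive")
    return fmr_kJ_per_kg_day * days * 0.5 * (mass_start_kg + mass_end_kg) / 1000.0


def fever_fmr(baseline_kJ_per_kg_day: float, deltaT_degC: float,
              pct_per_degC: float) -> float:
    """Mass-specific FMR (kJ kg^-1 d^-1) elevated by a fever of ``deltaT``.

    baseline x (1 + pct_per_degC x deltaT), reported to 1 decimal.
    """
    if deltaT_degC < 0:
        raise ValueError("fever temperature rise must be non-negative")
    return round_half_up(baseline_kJ_per_kg_day * (1 + pct_per_degC * deltaT_degC), 1)


def fever_cost(mass_kg: float, days: float, fever_fmr_value: float,
               mass_end_kg: float | None = None) -> float:
    """Energy cost (MJ) of sustaining an elevated FMR over a fever window.

    By default the mass is held constant over the window (an acute illness is
    short against the trip's mass trajectory); pass ``mass_end_kg`` to use a
    linear mass decline instead.
    """
    if mass_kg <= 0 or days <= 0 or fever_fmr_value <= 0:
        raise ValueError("all inputs must be positive")
    if mass_end_kg is None:
        return mass_kg * fever_fmr_value * days / 1000.0
    return fmr_cost(mass_kg, mass_end_kg, days, fever_fmr_value)


def blood_volume_L(mass_kg: float,
                   fraction: float = EnergyConstants.blood_fraction) -> float:
    """Blood volume (L) as a fixed fraction of body mass (1 kg blood = 1 L)."""
    if mass_kg <= 0:
        raise ValueError("mass must be positive")
    return round_half_up(mass_kg * fraction, 1)


def fasting_projection(mass_kg: float, rate_kg_per_day: float, days: float):
    """Projected onshore fasting loss at a constant daily rate.

    Returns (loss_kg, final_mass_kg), loss reported to 1 decimal.
    Raises if the projection consumes the whole body mass.
    """
    if mass_kg <= 0 or rate_kg_per_day <= 0 or days < 0:
        raise ValueError("mass and rate must be positive, days non-negative")
    loss = rate_kg_per_day * days
    if loss >= mass_kg:
        raise ValueError("projection exceeds body mass")
    return round_half_up(loss, 1), mass_kg - loss


def trip_energy_budget(lean_loss_kg: float, lipid_loss_kg: float,
                       mass_start_kg: float, mass_end_kg: float,
                       trip_days: float,
                       fever_deltaT: float = 4.0, fever_days: float = 14.0,
                       c: EnergyConstants = EnergyConstants()) -> EnergyBudget:
    """Assemble the full illness energy budget for a trip.

    Combines the tissue-store deficit with two counterfactual scenarios: the
    cost of the whole trip with no foraging (FMR on the linear mass
    trajectory) and the cost of a fever window at departure mass, at the low
    and high ends of the per-degree metabolic increase.
    """
    lean_MJ, lipid_MJ, total_MJ, share = tissue_energy(lean_loss_kg, lipid_loss_kg, c)
    scenarios = {
        "no_foraging_trip_MJ": round_half_up(
            fmr_cost(mass_start_kg, mass_end_kg, trip_days, c.fmr_baseline), 0),
    }
    for pct in c.fever_increase_per_degC:
        rate = fever_fmr(c.fmr_baseline, fever_deltaT, pct)
        scenarios[f"fever_{pct:g}_per_degC_MJ"] = round_half_up(
            fever_cost(mass_start_kg, fever_days, rate), 0)
    return EnergyBudget(lean_loss_kg, lipid_loss_kg, lean_MJ, lipid_MJ,
                        total_MJ, share, scenarios)
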