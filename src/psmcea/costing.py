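"""Discounted strategy costs from the cohort trace.

Cost components follow first-line practice for the modelled regimen:

* drug acquisition — sugemalimab is a flat 1,200 mg dose, pemetrexed is
  dosed at 500 mg/m2 of body surface area, and carboplatin is dosed to a
  target AUC of 5 mg/ml-min through the Calvert formula
  ``dose = AUC x (CrCl + 25)``; doses are priced per mg with no vial
  rounding.  Combination therapy runs for the first four cycles, then
  maintenance drugs only, weighted by progression-free occupancy
  (treatment until progression by default; an alternative caps treated
  cycles at the trial's median duration);
* grade >=3 adverse-event management, priced per treatment cycle by
  default (a one-off application at cycle 1 is available);
* routine follow-up while progression-free;
* after progression, a share of patients receives subsequent anticancer
  therapy and the remainder best supportive care.

All components are discounted with the trace's per-cycle factors.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .distributions import ParametricDistribution
from .exceptions import ConfigurationError, DomainError
from .trace import OccupancyTrace

AE_COST_MODES = ("once", "per-treatment-cycle")
TREATMENT_DURATION_RULES = ("until-progression", "capped-at-median")
FOLLOWUP_STATES = ("pfd", "all-alive")


@dataclass(frozen=True)
class DosingInputs:
    """Patient covariates and per-drug dosing rules."""

    weight_kg: float = 65.0
    bsa_m2: float = 1.72
    crcl_ml_min: float = 70.0
    pemetrexed_mg_per_m2: float = 500.0
    carboplatin_auc: float = 5.0
    sugemalimab_flat_mg: float = 1200.0

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) <= 0:
                raise DomainError(f"dosing input {name} must be > 0")


@dataclass(frozen=True)
class UnitPrices:
    """Acquisition prices in USD per mg."""

    sugemalimab_per_mg: float = 3.08
    pemetrexed_per_mg: float = 1.672
    carboplatin_per_mg: float = 0.041

    def __post_init__(self):
        for name in self.__dataclass_fields__:
            if getattr(self, name) < 0:
                raise DomainError(f"price {name} must be >= 0")


@dataclass(frozen=True)
class AEEvent:
    """One grade >=3 adverse-event type for one arm."""

    cost_per_episode: float
    incidence: float
    disutility: float

    def __post_init__(self):
        if self.cost_per_episode < 0:
            raise DomainError("AE cost must be >= 0")
        if not 0 <= self.incidence <= 1:
            raise DomainError("AE incidence must be in [0, 1]")
        if self.disutility < 0:
            raise DomainError("AE disutility must be >= 0")


@dataclass(frozen=True)
class AEProfile:
    """Adverse-event costs/incidences/disutilities keyed by event name."""

    events: Mapping[str, AEEvent]

    def __post_init__(self):
        object.__setattr__(self, "events", dict(self.events))

    @property
    def expected_cost(self) -> float:
        """Sum of incidence x management cost over event types (USD)."""
        return sum(e.incidence * e.cost_per_episode for e in self.events.values())

    @property
    def expected_disutility(self) -> float:
        """Sum of incidence x disutility over event types (QALY units)."""
        return sum(e.incidence * e.disutility for e in self.events.values())


@dataclass(frozen=True)
class PostProgressionPolicy:
    """What progressed patients receive, and routine follow-up."""

    subsequent_therapy_share: float
    subsequent_cost_per_cycle: float = 854.05
    bsc_cost_per_cycle: float = 337.50
    followup_cost_per_cycle: float = 55.60

    def __post_init__(self):
        if not 0 <= self.subsequent_therapy_share <= 1:
            raise DomainError("subsequent_therapy_share must be in [0, 1]")
        for name in (
            "subsequent_cost_per_cycle",
            "bsc_cost_per_cycle",
            "followup_cost_per_cycle",
        ):
            if getattr(self, name) < 0:
                raise DomainError(f"{name} must be >= 0")

    @property
    def pd_cost_per_cycle(self) -> float:
        s = self.subsequent_therapy_share
        return (
            s * self.subsequent_cost_per_cycle + (1.0 - s) * self.bsc_cost_per_cycle
        )


@dataclass(frozen=True)
class StrategySpec:
    """One treatment arm: curves, drug schedule, AEs and progression policy."""

    name: str
    os_dist: ParametricDistribution
    pfs_dist: ParametricDistribution
    combo_drugs: Sequence[str]
    maintenance_drugs: Sequence[str]
    ae_profile: AEProfile
    post_progression: PostProgressionPolicy
    combo_cycles: int = 4
    treatment_cap_cycles: float | None = None

    def __post_init__(self):
        if self.combo_cycles < 0:
            raise DomainError("combo_cycles must be >= 0")
        object.__setattr__(self, "combo_drugs", tuple(self.combo_drugs))
        object.__setattr__(self, "maintenance_drugs", tuple(self.maintenance_drugs))


def bsa_dose(dose_per_m2: float, bsa: float) -> float:
    """Body-surface-area dose in mg."""
    if dose_per_m2 < 0 or bsa < 0:
        raise DomainError("dose_per_m2 and bsa must be >= 0")
    return dose_per_m2 * bsa


def calvert_dose(auc_target: float, crcl: float) -> float:
    """Carboplatin dose in mg: AUC x (CrCl + 25) (Calvert formula)."""
    if auc_target < 0 or crcl < 0:
        raise DomainError("auc_target and crcl must be >= 0")
    return auc_target * (crcl + 25.0)


def drug_dose_mg(drug: str, dosing: DosingInputs) -> float:
    """Per-administration dose of one regimen drug, in mg."""
    if drug == "sugemalimab":
        return dosing.sugemalimab_flat_mg
    if drug == "pemetrexed":
        return bsa_dose(dosing.pemetrexed_mg_per_m2, dosing.bsa_m2)
    if drug == "carboplatin":
        return calvert_dose(dosing.carboplatin_auc, dosing.crcl_ml_min)
    raise ConfigurationError(
        f"unknown drug {drug!r}; expected sugemalimab, pemetrexed or carboplatin"
    )


def _drug_price(drug: str, prices: UnitPrices) -> float:
    try:
        return getattr(prices, f"{drug}_per_mg")
    except AttributeError:
        raise ConfigurationError(f"no unit price for drug {drug!r}") from None


def cycle_drug_cost(
    strategy: StrategySpec,
    prices: UnitPrices,
    dosing: DosingInputs,
    cycle_index: int,
) -> float:
    """Acquisition cost (USD) of one treated cycle, 1-based index."""
    if cycle_index < 1:
        raise DomainError("cycle_index must be >= 1")
    drugs = (
        strategy.combo_drugs
        if cycle_index <= strategy.combo_cycles
        else strategy.maintenance_drugs
    )
    return sum(drug_dose_mg(d, dosing) * _drug_price(d, prices) for d in drugs)


def treatment_weights(
    strategy: StrategySpec,
    trace: OccupancyTrace,
    rule: str = "until-progression",
) -> np.ndarray:
    """Per-cycle fraction of the cohort on initial treatment.

    ``until-progression`` treats the whole progression-free occupancy;
    ``capped-at-median`` additionally zeroes cycles beyond the strategy's
    treated-cycles cap (the trial's median treatment duration).
    """
    if rule not in TREATMENT_DURATION_RULES:
        raise DomainError(f"rule must be one of {TREATMENT_DURATION_RULES}")
    weights = trace.pfd.copy()
    if rule == "capped-at-median":
        if strategy.treatment_cap_cycles is None:
            raise ConfigurationError(
                f"strategy {strategy.name!r} has no treatment_cap_cycles"
            )
        weights[trace.grid.cycle_numbers > strategy.treatment_cap_cycles] = 0.0
    return weights


def ae_cost_total(
    profile: AEProfile,
    mode: str,
    treated_weights: np.ndarray,
    discount: np.ndarray,
) -> float:
    """Discounted adverse-event management cost (USD).

    ``once`` applies the expected burden to the whole cohort at cycle 1;
    ``per-treatment-cycle`` applies it each on-treatment cycle (weighted
    by the treated fraction), as the per-cycle price list implies.
    """
    if mode not in AE_COST_MODES:
        raise DomainError(f"mode must be one of {AE_COST_MODES}")
    if mode == "once":
        return profile.expected_cost * float(discount[0])
    return profile.expected_cost * float(np.sum(treated_weights * discount))


def cost_breakdown(
    strategy: StrategySpec,
    trace: OccupancyTrace,
    prices: UnitPrices,
    dosing: DosingInputs,
    ae_cost_mode: str = "per-treatment-cycle",
    treatment_duration_rule: str = "until-progression",
    followup_state: str = "pfd",
) -> pd.DataFrame:
    """Per-cycle, per-component cost table (long format).

    Columns: cycle, state, component, undiscounted, discounted.
    """
    if followup_state not in FOLLOWUP_STATES:
        raise DomainError(f"followup_state must be one of {FOLLOWUP_STATES}")
    grid = trace.grid
    cycles = grid.cycle_numbers
    df = trace.discount_factor
    treated = treatment_weights(strategy, trace, treatment_duration_rule)
    drug_per_cycle = np.array(
        [cycle_drug_cost(strategy, prices, dosing, int(c)) for c in cycles]
    )
    followup_weight = trace.pfd if followup_state == "pfd" else trace.alive
    pp = strategy.post_progression

    rows = []

    def add(component, state, weights, unit_cost):
        und = weights * unit_cost
        rows.append(
            pd.DataFrame(
                {
                    "cycle": cycles,
                    "state": state,
                    "component": component,
                    "undiscounted": und,
                    "discounted": und * df,
                }
            )
        )

    add("drug", "pfd", treated, drug_per_cycle)
    add("followup", followup_state, followup_weight, pp.followup_cost_per_cycle)
    add(
        "subsequent_therapy",
        "pd",
        trace.pd * pp.subsequent_therapy_share,
        pp.subsequent_cost_per_cycle,
    )
    add(
        "bsc",
        "pd",
        trace.pd * (1.0 - pp.subsequent_therapy_share),
        pp.bsc_cost_per_cycle,
    )
    if ae_cost_mode == "once":
        ae_und = np.zeros_like(df)
        ae_und[0] = strategy.ae_profile.expected_cost
    else:
        if ae_cost_mode != "per-treatment-cycle":
            raise DomainError(f"ae_cost_mode must be one of {AE_COST_MODES}")
        ae_und = treated * strategy.ae_profile.expected_cost
    rows.append(
        pd.DataFrame(
            {
                "cycle": cycles,
                "state": "pfd",
                "component": "adverse_events",
                "undiscounted": ae_und,
                "discounted": ae_und * df,
            }
        )
    )
    return pd.concat(rows, ignore_index=True)


def total_cost(
    strategy: StrategySpec,
    trace: OccupancyTrace,
    prices: UnitPrices,
    dosing: DosingInputs,
    ae_cost_mode: str = "per-treatment-cycle",
    treatment_duration_rule: str = "until-progression",
    followup_state: str = "pfd",
) -> float:
    """Discounted total cost (USD) of one strategy over the horizon."""
    breakdown = cost_breakdown(
        strategy,
        trace,
        prices,
        dosing,
        ae_cost_mode=ae_cost_mode,
        treatment_duration_rule=treatment_duration_rule,
        followup_state=followup_state,
    )
    return float(breakdown["discounted"].sum())
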