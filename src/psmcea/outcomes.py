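"""Discounted health outcomes and incremental cost-effectiveness.

Life-years are the discounted time alive on the cycle grid; QALYs weight
progression-free and progressed time by their health-state utilities
(0.71 and 0.67 base case, death 0) and subtract the expected quality loss
from grade >=3 adverse events.  The printed base-case tables are only
consistent with that loss being the full ``sum(incidence x disutility)``
taken once per patient (a decrement persisting about a year), so that is
the default; a per-cycle-scaled variant is available.

Two strategies combine into an incremental result: the ICER
``delta_cost / delta_QALY`` on unrounded values, dominance labels when
the signs disagree, and a cost-effectiveness flag equivalent to a
nonnegative net monetary benefit at the willingness-to-pay threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .costing import AEProfile
from .exceptions import DomainError, GridMismatchError, UndefinedICERError
from .trace import OccupancyTrace

AE_DISUTILITY_MODES = ("once", "per-cycle-scaled")

DOMINANT = "dominant"
DOMINATED = "dominated"


@dataclass(frozen=True)
class UtilityInputs:
    """Health-state utilities and adverse-event disutilities."""

    u_pfd: float = 0.71
    u_pd: float = 0.67
    u_dead: float = 0.0

    def __post_init__(self):
        for name in ("u_pfd", "u_pd", "u_dead"):
            if not 0 <= getattr(self, name) <= 1:
                raise DomainError(f"{name} must be in [0, 1]")


@dataclass(frozen=True)
class EconResult:
    """Discounted totals for one strategy."""

    strategy: str
    total_cost: float
    life_years: float
    qalys: float
    n_cycles: Optional[int] = None

    def __post_init__(self):
        if self.total_cost < 0 or self.life_years < 0 or self.qalys < 0:
            raise DomainError("economic totals must be >= 0")
        if self.qalys > self.life_years + 1e-9:
            raise DomainError("QALYs cannot exceed life-years")


@dataclass(frozen=True)
class IncrementalResult:
    """Intervention-minus-comparator deltas with ICER and dominance."""

    intervention: str
    comparator: str
    delta_cost: float
    delta_qalys: float
    delta_life_years: float
    icer: Optional[float]
    dominance: Optional[str]
    wtp: float
    cost_effective: bool


def life_years(trace: OccupancyTrace) -> float:
    """Discounted life-years: sum of alive occupancy x discount x cycle length."""
    return float(
        np.sum(trace.alive * trace.discount_factor) * trace.grid.cycle_length_years
    )


def qalys(
    trace: OccupancyTrace,
    utilities: UtilityInputs,
    ae_profile: AEProfile,
    ae_disutility_mode: str = "once",
) -> float:
    """Discounted QALYs with the adverse-event decrement, floored at zero.

    ``once`` subtracts the expected disutility burden in full QALY units
    at model start; ``per-cycle-scaled`` scales it by one cycle's length
    in years (a decrement lasting a single cycle).
    """
    if ae_disutility_mode not in AE_DISUTILITY_MODES:
        raise DomainError(
            f"ae_disutility_mode must be one of {AE_DISUTILITY_MODES}"
        )
    base = float(
        np.sum(
            (trace.pfd * utilities.u_pfd + trace.pd * utilities.u_pd)
            * trace.discount_factor
        )
        * trace.grid.cycle_length_years
    )
    decrement = ae_profile.expected_disutility
    if ae_disutility_mode == "per-cycle-scaled":
        decrement *= trace.grid.cycle_length_years
    return max(base - decrement, 0.0)


def net_monetary_benefit(result: EconResult, wtp: float) -> float:
    """NMB = WTP x QALYs - cost for a single strategy."""
    return wtp * result.qalys - result.total_cost


def incremental(
    comparator: EconResult,
    intervention: EconResult,
    wtp: float,
    qaly_tol: float = 1e-12,
) -> IncrementalResult:
    """Pairwise incremental analysis (intervention minus comparator).

    Raises :class:`UndefinedICERError` when the QALY difference is
    numerically zero (below ``qaly_tol``).  Deltas and the ICER are
    computed on unrounded inputs.
    """
    if (
        comparator.n_cycles is not None
        and intervention.n_cycles is not None
        and comparator.n_cycles != intervention.n_cycles
    ):
        raise GridMismatchError("strategies were evaluated on different grids")
    dc = intervention.total_cost - comparator.total_cost
    dq = intervention.qalys - comparator.qalys
    dly = intervention.life_years - comparator.life_years

    dominance = None
    icer = None
    if abs(dq) < qaly_tol:
        raise UndefinedICERError(
            "QALY difference is numerically zero; the ICER is undefined"
        )
    elif dq > 0 and dc <= 0:
        dominance = DOMINANT
    elif dq < 0 and dc >= 0:
        dominance = DOMINATED
    else:
        icer = dc / dq

    if dominance == DOMINANT:
        cost_effective = True
    elif dominance == DOMINATED:
        cost_effective = False
    else:
        cost_effective = dq > 0 and icer is not None and icer <= wtp
    return IncrementalResult(
        intervention=intervention.strategy,
        comparator=comparator.strategy,
        delta_cost=dc,
        delta_qalys=dq,
        delta_life_years=dly,
        icer=icer,
        dominance=dominance,
        wtp=wtp,
        cost_effective=cost_effective,
    )
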