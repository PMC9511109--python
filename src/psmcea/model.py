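"""The cost-effectiveness model and its fitted results.

:class:`CostEffectivenessModel` wraps a validated configuration; calling
:meth:`~CostEffectivenessModel.fit` evaluates the partitioned-survival
cohort model for both strategies and returns a :class:`CEAResults` with
the discounted totals, the incremental analysis and the cohort traces.
Sensitivity analyses hang off the model:
:meth:`~CostEffectivenessModel.one_way_sensitivity` (tornado) and
:meth:`~CostEffectivenessModel.probabilistic_sensitivity` (Monte-Carlo
PSA with acceptability curves).

Example
-------
>>> from psmcea import CostEffectivenessModel
>>> results = CostEffectivenessModel.default().fit()
>>> print(results.summary())           # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional

import pandas as pd

from .config import ModelConfig, default_config, load_config
from .costing import total_cost
from .exceptions import UndefinedICERError
from .outcomes import EconResult, IncrementalResult, incremental, life_years, qalys
from .trace import OccupancyTrace, occupancy


@dataclass(frozen=True)
class CEAResults:
    """Base-case results for both strategies.

    Attributes
    ----------
    arms : mapping of strategy name to :class:`EconResult`
    incremental : :class:`IncrementalResult` or None
        Intervention vs comparator; None only when the ICER is undefined
        (identical arms), in which case ``undefined_icer`` is True.
    traces : mapping of strategy name to :class:`OccupancyTrace`
    """

    config: ModelConfig
    arms: Mapping[str, EconResult]
    traces: Mapping[str, OccupancyTrace]
    incremental: Optional[IncrementalResult]
    undefined_icer: bool = False

    def to_frame(self) -> pd.DataFrame:
        """Base-case report, one row per strategy plus the deltas."""
        inc = self.incremental
        rows = []
        for name in (self.config.comparator, self.config.intervention):
            r = self.arms[name]
            row = {
                "strategy": name,
                "total_cost": r.total_cost,
                "life_years": r.life_years,
                "qalys": r.qalys,
                "delta_cost": "",
                "delta_qaly": "",
                "icer": "",
            }
            if name == self.config.intervention:
                if inc is not None:
                    row["delta_cost"] = inc.delta_cost
                    row["delta_qaly"] = inc.delta_qalys
                    row["icer"] = (
                        inc.icer if inc.icer is not None else inc.dominance
                    )
                else:
                    row["icer"] = "undefined"
            rows.append(row)
        return pd.DataFrame(rows)

    def summary(self) -> str:
        """Human-readable base-case table."""
        lines = [
            "Partitioned-survival cost-effectiveness analysis",
            f"  horizon: {self.config.grid.horizon_years} years, "
            f"cycle: {self.config.grid.cycle_length_days} days, "
            f"discount: {self.config.discount_rate:.1%}, "
            f"WTP: {self.config.wtp:,.2f} USD/QALY",
            "",
            f"  {'strategy':<14}{'cost (USD)':>14}{'life-years':>12}{'QALYs':>10}",
        ]
        for name in (self.config.comparator, self.config.intervention):
            r = self.arms[name]
            lines.append(
                f"  {name:<14}{r.total_cost:>14,.2f}"
                f"{r.life_years:>12.3f}{r.qalys:>10.3f}"
            )
        inc = self.incremental
        lines.append("")
        if inc is None:
            lines.append("  ICER: undefined (identical QALYs, differing costs)")
        elif inc.dominance is not None:
            lines.append(
                f"  {inc.intervention} is {inc.dominance} "
                f"(dCost {inc.delta_cost:,.2f}, dQALY {inc.delta_qalys:.4f})"
            )
        else:
            verdict = "cost-effective" if inc.cost_effective else "not cost-effective"
            lines.append(
                f"  incremental cost {inc.delta_cost:,.2f} USD, "
                f"incremental QALYs {inc.delta_qalys:.4f}"
            )
            lines.append(
                f"  ICER {inc.icer:,.2f} USD/QALY -> {verdict} at WTP "
                f"{inc.wtp:,.2f}"
            )
        return "\n".join(lines)

    def plot_traces(self, ax=None):
        """Survival/state occupancy of both arms over the horizon."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name, tr in self.traces.items():
            years = tr.grid.eval_times(tr.eval_point) * tr.grid.cycle_length_years
            ax.plot(years, tr.alive, label=f"{name}: alive")
            ax.plot(years, tr.pfd, ls="--", label=f"{name}: progression-free")
        ax.set_xlabel("Years")
        ax.set_ylabel("Fraction of cohort")
        ax.legend()
        return ax


def evaluate_config(config: ModelConfig) -> CEAResults:
    """Evaluate the partitioned-survival model for one configuration."""
    grid = config.build_grid()
    toggles = config.toggles
    utilities = config.utilities.build()
    prices = config.prices.build()
    dosing = config.dosing.build()
    arms: dict[str, EconResult] = {}
    traces: dict[str, OccupancyTrace] = {}
    for name in (config.comparator, config.intervention):
        strat = config.build_strategy(name)
        tr = occupancy(
            strat.os_dist,
            strat.pfs_dist,
            grid,
            discount_rate=config.discount_rate,
            eval_point=toggles.eval_point,
            half_cycle_correction=toggles.half_cycle_correction,
        )
        traces[name] = tr
        arms[name] = EconResult(
            strategy=name,
            total_cost=total_cost(
                strat,
                tr,
                prices,
                dosing,
                ae_cost_mode=toggles.ae_cost_mode,
                treatment_duration_rule=toggles.treatment_duration_rule,
                followup_state=toggles.followup_state,
            ),
            life_years=life_years(tr),
            qalys=qalys(
                tr,
                utilities,
                strat.ae_profile,
                ae_disutility_mode=toggles.ae_disutility_mode,
            ),
            n_cycles=grid.n_cycles,
        )
    try:
        inc = incremental(
            arms[config.comparator], arms[config.intervention], config.wtp
        )
        undefined = False
    except UndefinedICERError:
        inc = None
        undefined = True
    return CEAResults(
        config=config, arms=arms, traces=traces, incremental=inc,
        undefined_icer=undefined,
    )


class CostEffectivenessModel:
    """Partitioned-survival cost-effectiveness model of two strategies.

    Parameters
    ----------
    config : ModelConfig
        Validated configuration; see :func:`psmcea.config.load_config`
        and the bundled default.
    """

    def __init__(self, config: ModelConfig):
        self.config = config

    @classmethod
    def from_yaml(cls, path) -> "CostEffectivenessModel":
        return cls(load_config(path))

    @classmethod
    def default(cls) -> "CostEffectivenessModel":
        """The bundled published-model configuration."""
        return cls(default_config())

    def fit(self) -> CEAResults:
        """Run the base case."""
        return evaluate_config(self.config)

    def one_way_sensitivity(self, ranges=None):
        """Tornado analysis; see :func:`psmcea.sensitivity.one_way_dsa`."""
        from .sensitivity import one_way_dsa

        return one_way_dsa(self.config, ranges)

    def probabilistic_sensitivity(
        self, n_draws: Optional[int] = None, seed: Optional[int] = None,
        progress_every: int = 0,
    ):
        """Monte-Carlo PSA; see :func:`psmcea.sensitivity.run_psa`."""
        from .sensitivity import run_psa

        return run_psa(
            self.config, n_draws=n_draws, seed=seed, progress_every=progress_every
        )
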