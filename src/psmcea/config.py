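"""Schema-validated model configuration.

One YAML (or JSON) file drives the whole analysis: the cycle grid, the
two strategies' survival parameters and drug schedules, unit prices,
dosing covariates, utilities, adverse-event inputs, post-progression
policy, the discount rate and willingness-to-pay threshold, structural
toggles, deterministic sensitivity ranges and probabilistic-sensitivity
settings.  The bundled default (``data/sugemalimab_nsclc.yaml``) encodes
the published first-line sugemalimab vs chemotherapy model for metastatic
nonsquamous NSCLC and is the single source of those numbers inside the
package.

Validation is strict: unknown keys are rejected, constraint violations
name the offending field.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path
from typing import Literal, Mapping, Optional

import pydantic
import yaml
from pydantic import BaseModel, ConfigDict, Field

from .costing import (
    AEEvent,
    AEProfile,
    DosingInputs,
    PostProgressionPolicy,
    StrategySpec,
    UnitPrices,
)
from .distributions import ParametricDistribution
from .exceptions import ConfigurationError
from .outcomes import UtilityInputs
from .trace import ModelGrid

DEFAULT_CONFIG_RESOURCE = "sugemalimab_nsclc.yaml"


class _Strict(BaseModel):
    model_config = ConfigDict(extra="forbid", frozen=True)


class GridSettings(_Strict):
    horizon_years: float = Field(10.0, gt=0)
    cycle_length_days: float = Field(21.0, gt=0)


class DistributionSettings(_Strict):
    family: str
    params: dict[str, float]

    def build(self) -> ParametricDistribution:
        return ParametricDistribution(self.family, self.params)


class DosingSettings(_Strict):
    weight_kg: float = Field(65.0, gt=0)
    bsa_m2: float = Field(1.72, gt=0)
    crcl_ml_min: float = Field(70.0, gt=0)
    pemetrexed_mg_per_m2: float = Field(500.0, gt=0)
    carboplatin_auc: float = Field(5.0, gt=0)
    sugemalimab_flat_mg: float = Field(1200.0, gt=0)

    def build(self) -> DosingInputs:
        return DosingInputs(**self.model_dump())


class PriceSettings(_Strict):
    sugemalimab_per_mg: float = Field(3.08, ge=0)
    pemetrexed_per_mg: float = Field(1.672, ge=0)
    carboplatin_per_mg: float = Field(0.041, ge=0)

    def build(self) -> UnitPrices:
        return UnitPrices(**self.model_dump())


class UtilitySettings(_Strict):
    pfd: float = Field(0.71, ge=0, le=1)
    pd: float = Field(0.67, ge=0, le=1)
    dead: float = Field(0.0, ge=0, le=1)

    def build(self) -> UtilityInputs:
        return UtilityInputs(u_pfd=self.pfd, u_pd=self.pd, u_dead=self.dead)


class AESettings(_Strict):
    cost_per_episode: float = Field(ge=0)
    disutility: float = Field(ge=0)


class ToggleSettings(_Strict):
    """Structural switches left open by the source material; see docs."""

    eval_point: Literal["cycle-end", "cycle-start", "cycle-midpoint"] = "cycle-end"
    half_cycle_correction: bool = False
    ae_cost_mode: Literal["once", "per-treatment-cycle"] = "per-treatment-cycle"
    ae_disutility_mode: Literal["once", "per-cycle-scaled"] = "once"
    followup_state: Literal["pfd", "all-alive"] = "pfd"
    treatment_duration_rule: Literal[
        "until-progression", "capped-at-median"
    ] = "until-progression"
    curve_fit_loss: Literal["squared-survival", "complementary-log-log"] = (
        "squared-survival"
    )


class StrategySettings(_Strict):
    os: DistributionSettings
    pfs: DistributionSettings
    combo_cycles: int = Field(4, ge=0)
    combo_drugs: list[str]
    maintenance_drugs: list[str]
    ae_incidence: dict[str, float]
    subsequent_therapy_share: float = Field(ge=0, le=1)
    treatment_cap_cycles: Optional[float] = Field(None, gt=0)


class SharedCostSettings(_Strict):
    followup_per_cycle: float = Field(55.60, ge=0)
    subsequent_per_cycle: float = Field(854.05, ge=0)
    bsc_per_cycle: float = Field(337.50, ge=0)


class ParamRangeSettings(_Strict):
    """One deterministic/probabilistic sensitivity parameter.

    ``path`` is the dotted config location (e.g. ``prices.sugemalimab_per_mg``);
    ``distribution`` is the PSA sampling family; ``support`` optionally
    rescales a beta draw onto a non-unit interval.
    """

    path: str
    low: float
    high: float
    distribution: Literal["gamma", "beta", "normal"]
    support: Optional[tuple[float, float]] = None


class PSASettings(_Strict):
    n_draws: int = Field(10000, ge=1)
    seed: int = 20181213
    incidence_sd_fraction: float = Field(0.2, ge=0)


class ModelConfig(_Strict):
    """Full, validated model configuration."""

    grid: GridSettings = GridSettings()
    discount_rate: float = Field(0.05, ge=0)
    wtp: float = Field(37663.26, gt=0)
    time_unit: Literal["cycle"] = "cycle"
    intervention: str = "sugemalimab"
    comparator: str = "chemotherapy"
    dosing: DosingSettings = DosingSettings()
    prices: PriceSettings = PriceSettings()
    utilities: UtilitySettings = UtilitySettings()
    ae_events: dict[str, AESettings]
    costs: SharedCostSettings = SharedCostSettings()
    toggles: ToggleSettings = ToggleSettings()
    strategies: dict[str, StrategySettings]
    dsa_ranges: list[ParamRangeSettings] = []
    psa: PSASettings = PSASettings()

    @pydantic.model_validator(mode="after")
    def _check_strategies(self) -> "ModelConfig":
        for role in (self.intervention, self.comparator):
            if role not in self.strategies:
                raise ValueError(f"strategies must contain {role!r}")
        for name, strat in self.strategies.items():
            unknown = set(strat.ae_incidence) - set(self.ae_events)
            if unknown:
                raise ValueError(
                    f"strategy {name!r} has AE incidences for unknown events "
                    f"{sorted(unknown)}"
                )
            for event, inc in strat.ae_incidence.items():
                if not 0 <= inc <= 1:
                    raise ValueError(
                        f"strategy {name!r} incidence for {event!r} must be in [0, 1]"
                    )
        return self

    # -- builders ---------------------------------------------------------
    def build_grid(self) -> ModelGrid:
        return ModelGrid(**self.grid.model_dump())

    def build_ae_profile(self, strategy: str) -> AEProfile:
        strat = self.strategies[strategy]
        return AEProfile(
            {
                event: AEEvent(
                    cost_per_episode=self.ae_events[event].cost_per_episode,
                    incidence=inc,
                    disutility=self.ae_events[event].disutility,
                )
                for event, inc in strat.ae_incidence.items()
            }
        )

    def build_strategy(self, strategy: str) -> StrategySpec:
        strat = self.strategies[strategy]
        return StrategySpec(
            name=strategy,
            os_dist=strat.os.build(),
            pfs_dist=strat.pfs.build(),
            combo_drugs=strat.combo_drugs,
            maintenance_drugs=strat.maintenance_drugs,
            ae_profile=self.build_ae_profile(strategy),
            post_progression=PostProgressionPolicy(
                subsequent_therapy_share=strat.subsequent_therapy_share,
                subsequent_cost_per_cycle=self.costs.subsequent_per_cycle,
                bsc_cost_per_cycle=self.costs.bsc_per_cycle,
                followup_cost_per_cycle=self.costs.followup_per_cycle,
            ),
            combo_cycles=strat.combo_cycles,
            treatment_cap_cycles=strat.treatment_cap_cycles,
        )

    # -- parameter paths (sensitivity analyses) ---------------------------
    def resolve_path(self, path: str) -> float:
        """Current value at a dotted parameter path."""
        obj = self
        for part in path.split("."):
            if isinstance(obj, dict):
                if part not in obj:
                    raise ConfigurationError(
                        f"cannot resolve {path!r}: no key {part!r}"
                    )
                obj = obj[part]
            elif hasattr(obj, part):
                obj = getattr(obj, part)
            else:
                raise ConfigurationError(
                    f"cannot resolve {path!r}: no field {part!r} "
                    f"(valid parameter paths are listed in dsa_ranges)"
                )
        if not isinstance(obj, (int, float)) or isinstance(obj, bool):
            raise ConfigurationError(f"{path!r} is not a numeric parameter")
        return float(obj)

    def with_value(self, path: str, value: float) -> "ModelConfig":
        """A copy of this config with one dotted parameter replaced."""
        return self.with_values({path: value})

    def with_values(self, values: Mapping[str, float]) -> "ModelConfig":
        """A copy of this config with several dotted parameters replaced."""
        data = self.model_dump()
        for path, value in values.items():
            self.resolve_path(path)  # raise early on bad paths
            obj = data
            parts = path.split(".")
            for part in parts[:-1]:
                obj = obj[part]
            obj[parts[-1]] = float(value)
        return ModelConfig(**data)


def _format_validation_error(exc: pydantic.ValidationError) -> str:
    lines = []
    for err in exc.errors():
        loc = ".".join(str(p) for p in err["loc"]) or "<root>"
        lines.append(f"{loc}: {err['msg']}")
    return "; ".join(lines)


def load_config(path) -> ModelConfig:
    """Load and validate a YAML/JSON model configuration file."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"config file not found: {path}")
    raw = yaml.safe_load(path.read_text())
    if not isinstance(raw, dict):
        raise ConfigurationError(f"config file {path} is empty or not a mapping")
    try:
        return ModelConfig(**raw)
    except pydantic.ValidationError as exc:
        raise ConfigurationError(_format_validation_error(exc)) from exc


def default_config() -> ModelConfig:
    """The bundled published-model configuration."""
    ref = resources.files("psmcea").joinpath("data", DEFAULT_CONFIG_RESOURCE)
    raw = yaml.safe_load(ref.read_text())
    return ModelConfig(**raw)
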