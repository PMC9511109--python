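"""Deterministic and probabilistic sensitivity analysis.

One-way analysis re-runs the full base case at each parameter's low and
high value (all else held at base) and ranks parameters by the width of
the resulting ICER interval — the tornado ordering.

The probabilistic analysis samples every ranged parameter simultaneously
(10,000 Monte-Carlo draws in the published analysis; any count here):
gamma for costs, beta for utilities, disutilities, probabilities and the
discount rate (rescaled to its 0-8% support), and truncated normal for
the dosing covariates.  Distributions are moment-matched to the base
value with sd = (max - min) / (2 x 1.96) from the printed ranges; the
adverse-event incidences, whose ranges are not printed, get sd = 20% of
the base value.  Survival parameters are held fixed (no ranges exist for
them).  Outputs are the per-draw incremental scatter and the
cost-effectiveness acceptability curves (share of draws in which each
strategy has the higher net monetary benefit, ties counted for the
comparator).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import ModelConfig, ParamRangeSettings
from .exceptions import ConfigurationError, DomainError

#: default CEAC willingness-to-pay grid: 0..150,000 USD/QALY in steps of 2,500
DEFAULT_WTP_GRID = np.arange(0.0, 150_000.0 + 1, 2_500.0)

_Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TornadoEntry:
    """One-way sensitivity of the ICER to a single parameter."""

    path: str
    low: float
    high: float
    icer_low: float
    icer_high: float

    @property
    def width(self) -> float:
        return abs(self.icer_high - self.icer_low)


@dataclass(frozen=True)
class DSAResults:
    """Tornado table, sorted by descending ICER width."""

    base_icer: float
    entries: tuple[TornadoEntry, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "parameter": [e.path for e in self.entries],
                "low_value": [e.low for e in self.entries],
                "high_value": [e.high for e in self.entries],
                "icer_low": [e.icer_low for e in self.entries],
                "icer_high": [e.icer_high for e in self.entries],
                "width": [e.width for e in self.entries],
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    def plot_tornado(self, ax=None, top: int = 15):
        """Horizontal tornado bars around the base-case ICER."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 0.4 * min(top, len(self.entries)) + 1))
        entries = list(self.entries[:top])[::-1]
        for i, e in enumerate(entries):
            lo, hi = sorted((e.icer_low, e.icer_high))
            ax.barh(i, hi - lo, left=lo, color="#4878d0")
        ax.axvline(self.base_icer, color="k", lw=1)
        ax.set_yticks(range(len(entries)))
        ax.set_yticklabels([e.path for e in entries], fontsize=8)
        ax.set_xlabel("ICER (USD/QALY)")
        return ax


def one_way_dsa(
    config: ModelConfig, ranges: Optional[Sequence[ParamRangeSettings]] = None
) -> DSAResults:
    """One-way deterministic sensitivity analysis over ``ranges``.

    Each parameter is set to its low and high value in turn, the full
    model re-run, and the ICER recorded; entries come back sorted by
    descending ICER width.  Degenerate (zero-width) ranges reproduce the
    base-case ICER at both ends.
    """
    from .model import evaluate_config

    if ranges is None:
        ranges = config.dsa_ranges
    base = evaluate_config(config)
    if base.incremental.icer is None:
        raise DomainError("base case has no finite ICER; tornado is undefined")
    entries = []
    for r in ranges:
        if not r.low <= config.resolve_path(r.path) <= r.high:
            raise ConfigurationError(
                f"range for {r.path!r} does not bracket its base value"
            )
        icers = []
        for value in (r.low, r.high):
            res = evaluate_config(config.with_value(r.path, value))
            icers.append(
                res.incremental.icer if res.incremental.icer is not None else np.nan
            )
        entries.append(
            TornadoEntry(
                path=r.path,
                low=r.low,
                high=r.high,
                icer_low=icers[0],
                icer_high=icers[1],
            )
        )
    entries.sort(key=lambda e: -e.width)
    return DSAResults(base_icer=base.incremental.icer, entries=tuple(entries))


# -- probabilistic sampling ----------------------------------------------

def _incidence_ranges(config: ModelConfig) -> list[ParamRangeSettings]:
    """Beta ranges for the per-arm AE incidences (no printed ranges)."""
    out = []
    frac = config.psa.incidence_sd_fraction
    for arm, strat in config.strategies.items():
        for event, inc in strat.ae_incidence.items():
            half = _Z95 * frac * inc
            out.append(
                ParamRangeSettings(
                    path=f"strategies.{arm}.ae_incidence.{event}",
                    low=max(inc - half, 0.0),
                    high=min(inc + half, 1.0),
                    distribution="beta",
                )
            )
    return out


def psa_parameter_ranges(config: ModelConfig) -> list[ParamRangeSettings]:
    """All parameters sampled in the PSA: ranged ones plus AE incidences."""
    return list(config.dsa_ranges) + _incidence_ranges(config)


def _moment_matched_draws(
    r: ParamRangeSettings, base: float, n: int, rng: np.random.Generator
) -> np.ndarray:
    sd = (r.high - r.low) / (2.0 * _Z95)
    if sd == 0 or base == 0 and r.distribution == "gamma":
        return np.full(n, base)
    if r.distribution == "gamma":
        shape = (base / sd) ** 2
        scale = sd**2 / base
        return rng.gamma(shape, scale, size=n)
    if r.distribution == "beta":
        lo, hi = r.support if r.support is not None else (0.0, 1.0)
        if not lo <= base <= hi:
            raise ConfigurationError(
                f"{r.path!r}: base {base} outside beta support [{lo}, {hi}]"
            )
        m = (base - lo) / (hi - lo)
        s = sd / (hi - lo)
        if m <= 0 or m >= 1:
            return np.full(n, base)
        if m * (1 - m) <= s**2:
            raise ConfigurationError(
                f"{r.path!r}: sd {sd} implies invalid beta moments for mean {base}"
            )
        nu = m * (1 - m) / s**2 - 1.0
        return lo + (hi - lo) * rng.beta(m * nu, (1 - m) * nu, size=n)
    # normal, truncated below at 10% of base to avoid nonphysical values
    draws = rng.normal(base, sd, size=n)
    return np.maximum(draws, 0.1 * base)


def sample_parameters(
    config: ModelConfig, n_draws: int, seed: int
) -> pd.DataFrame:
    """Moment-matched parameter draws, one row per Monte-Carlo iteration.

    Deterministic given ``seed``; columns are dotted parameter paths.
    """
    if n_draws < 1:
        raise DomainError("n_draws must be >= 1")
    rng = np.random.default_rng(seed)
    cols = {}
    for r in psa_parameter_ranges(config):
        base = config.resolve_path(r.path)
        cols[r.path] = _moment_matched_draws(r, base, n_draws, rng)
    out = pd.DataFrame(cols)
    out.insert(0, "draw", np.arange(n_draws))
    return out


@dataclass(frozen=True)
class PSAResults:
    """Per-draw incremental outcomes plus acceptability summaries."""

    config: ModelConfig
    draws: pd.DataFrame
    results: pd.DataFrame  # per-draw costs/QALYs and deltas
    n_excluded: int
    seed: int

    def scatter_frame(self) -> pd.DataFrame:
        return self.results[["draw", "delta_cost", "delta_qaly"]].copy()

    def prob_cost_effective(self, wtp: float) -> dict[str, float]:
        """Share of draws in which each strategy has the higher NMB.

        Ties count for the comparator (conservative toward the
        intervention).
        """
        nmb_int = wtp * self.results["qaly_intervention"] - self.results[
            "cost_intervention"
        ]
        nmb_comp = wtp * self.results["qaly_comparator"] - self.results[
            "cost_comparator"
        ]
        p_int = float(np.mean(nmb_int > nmb_comp))
        return {
            self.config.intervention: p_int,
            self.config.comparator: 1.0 - p_int,
        }

    def ceac(self, wtp_grid: Optional[np.ndarray] = None) -> pd.DataFrame:
        """Cost-effectiveness acceptability curves on a WTP grid."""
        if wtp_grid is None:
            wtp_grid = DEFAULT_WTP_GRID
        wtp_grid = np.asarray(wtp_grid, dtype=float)
        if wtp_grid.size == 0:
            raise DomainError("wtp_grid must be nonempty")
        rows = []
        for w in wtp_grid:
            p = self.prob_cost_effective(float(w))
            rows.append(
                {
                    "wtp": float(w),
                    f"p_{self.config.intervention}": p[self.config.intervention],
                    f"p_{self.config.comparator}": p[self.config.comparator],
                }
            )
        return pd.DataFrame(rows)

    def plot_ceac(self, ax=None, wtp_grid: Optional[np.ndarray] = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        curve = self.ceac(wtp_grid)
        for name in (self.config.intervention, self.config.comparator):
            ax.plot(curve["wtp"], curve[f"p_{name}"], label=name)
        ax.axvline(self.config.wtp, color="k", ls="--", lw=1)
        ax.set_xlabel("Willingness to pay (USD/QALY)")
        ax.set_ylabel("Probability cost-effective")
        ax.legend()
        return ax

    def plot_scatter(self, ax=None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        ax.scatter(
            self.results["delta_qaly"], self.results["delta_cost"], s=4, alpha=0.4
        )
        xs = np.array(ax.get_xlim())
        ax.plot(xs, self.config.wtp * xs, "k--", lw=1, label="WTP threshold")
        ax.set_xlabel("Incremental QALYs")
        ax.set_ylabel("Incremental cost (USD)")
        ax.legend()
        return ax


def ceac(results: "PSAResults", wtp_grid: Optional[np.ndarray] = None) -> pd.DataFrame:
    """Functional alias for :meth:`PSAResults.ceac`."""
    return results.ceac(wtp_grid)


def run_psa(
    config: ModelConfig,
    n_draws: Optional[int] = None,
    seed: Optional[int] = None,
    progress_every: int = 0,
) -> PSAResults:
    """Evaluate the full model on every sampled parameter set.

    Draws producing an invalid model (a domain violation such as a
    negative cost) are excluded and counted.  Bit-reproducible for a
    given seed.
    """
    from .exceptions import PSMCEAError
    from .model import evaluate_config

    if n_draws is None:
        n_draws = config.psa.n_draws
    if seed is None:
        seed = config.psa.seed
    draws = sample_parameters(config, n_draws, seed)
    paths = [c for c in draws.columns if c != "draw"]
    rows = []
    n_excluded = 0
    for i, row in enumerate(draws.itertuples(index=False)):
        values = dict(zip(draws.columns, row))
        try:
            cfg = config.with_values({p: float(values[p]) for p in paths})
            res = evaluate_config(cfg)
        except (PSMCEAError, ValueError):
            n_excluded += 1
            continue
        ei = res.arms[config.intervention]
        ec = res.arms[config.comparator]
        rows.append(
            {
                "draw": int(values["draw"]),
                "cost_intervention": ei.total_cost,
                "qaly_intervention": ei.qalys,
                "cost_comparator": ec.total_cost,
                "qaly_comparator": ec.qalys,
                "delta_cost": ei.total_cost - ec.total_cost,
                "delta_qaly": ei.qalys - ec.qalys,
            }
        )
        if progress_every and (i + 1) % progress_every == 0:
            import logging

            logging.getLogger(__name__).info(
                "PSA: %d / %d draws evaluated", i + 1, n_draws
            )
    return PSAResults(
        config=config,
        draws=draws,
        results=pd.DataFrame(rows),
        n_excluded=n_excluded,
        seed=seed,
    )
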