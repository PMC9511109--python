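"""Synthetic trial data with known ground truth.

No individual-patient data are published for the registration trial the
model draws on, and its survival figures can only be digitized.  This
module generates the corresponding *synthetic* stand-ins: censored
pseudo-IPD drawn from known Weibull truths (arm sizes 320 and 159 as in
the trial), Kaplan-Meier estimates of those samples, and emulated
digitization of the resulting step curves (even time grid, survival
jitter, monotone projection).  Because the truth parameters are known,
the whole fitting pipeline is testable end to end.

The censoring mechanism is deliberately simple — uniform accrual over the
enrollment window followed by a single administrative cutoff — because
only the gross censoring shape matters for exercising the fitting code.
Defaults scale the trial's calendar dates to 21-day cycles: accrual over
about 24.9 cycles (Dec 2018 to May 2020) with cutoff near 39.3 cycles
(Mar 2021).  PFS and OS are simulated independently per endpoint; the
cohort engine consumes marginal curves only, and clamps where sampled
curves cross.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from lifelines import KaplanMeierFitter
from sklearn.isotonic import IsotonicRegression

from .distributions import ParametricDistribution
from .exceptions import DomainError
from .fitting import DigitizedCurve, SurvivalRecord

#: trial-shaped defaults, in 21-day cycles
DEFAULT_CUTOFF_CYCLES = 39.3
DEFAULT_ACCRUAL_CYCLES = 24.9
DEFAULT_SEED = 20181213  # first-enrollment date of the emulated trial


@dataclass(frozen=True)
class TrialArmSpec:
    """One synthetic arm: sample size, survival truths and censoring."""

    name: str
    n: int
    os_truth: ParametricDistribution
    pfs_truth: ParametricDistribution
    cutoff_cycles: float = DEFAULT_CUTOFF_CYCLES
    accrual_cycles: float = DEFAULT_ACCRUAL_CYCLES
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.n < 0:
            raise DomainError("n must be >= 0")
        if self.cutoff_cycles <= 0:
            raise DomainError("cutoff_cycles must be > 0")
        if self.accrual_cycles < 0:
            raise DomainError("accrual_cycles must be >= 0")

    def crossing_cycle(self, grid_max: float = 200.0) -> float | None:
        """First cycle at which the PFS truth exceeds the OS truth, if any.

        The two endpoints are specified marginally, so S_pfs > S_os is not
        ruled out; this validity probe reports the first grid crossing.
        """
        t = np.linspace(0.0, grid_max, 2001)[1:]
        above = self.pfs_truth.survival(t) > self.os_truth.survival(t) + 1e-12
        if not above.any():
            return None
        return float(t[int(np.argmax(above))])


def simulate_ipd(spec: TrialArmSpec, endpoint: str) -> list[SurvivalRecord]:
    """Draw censored pseudo individual-patient data for one endpoint.

    Event times come from the truth distribution by inverse-transform
    sampling; each subject's censoring time is ``cutoff - accrual_offset``
    with accrual offsets uniform on [0, accrual window].  Deterministic
    given the spec's seed (independent substreams per endpoint).
    """
    if endpoint not in ("os", "pfs"):
        raise DomainError(f"endpoint must be 'os' or 'pfs', got {endpoint!r}")
    truth = spec.os_truth if endpoint == "os" else spec.pfs_truth
    rng = np.random.default_rng([spec.seed, 0 if endpoint == "os" else 1])
    u = rng.uniform(size=spec.n)
    event_times = np.asarray(truth.quantile(u), dtype=float)
    accrual = rng.uniform(0.0, spec.accrual_cycles, size=spec.n)
    censor_times = np.maximum(spec.cutoff_cycles - accrual, 0.0)
    observed = event_times <= censor_times
    times = np.where(observed, event_times, censor_times)
    return [
        SurvivalRecord(float(t), int(e)) for t, e in zip(times, observed)
    ]


def expected_censoring_fraction(spec: TrialArmSpec, endpoint: str) -> float:
    """Analytic expected share of censored records under the spec.

    P(censored) = E_U[S(cutoff - U)] with U uniform on the accrual window,
    computed by quadrature; the closed companion to :func:`simulate_ipd`.
    """
    from scipy import integrate

    truth = spec.os_truth if endpoint == "os" else spec.pfs_truth

    def s_at_censor(u):
        return float(truth.survival(max(spec.cutoff_cycles - u, 0.0)))

    if spec.accrual_cycles == 0:
        return s_at_censor(0.0)
    value, _ = integrate.quad(s_at_censor, 0.0, spec.accrual_cycles, limit=200)
    return value / spec.accrual_cycles


def km_estimate(data: Sequence[SurvivalRecord]) -> DigitizedCurve:
    """Product-limit (Kaplan-Meier) estimate as a step curve.

    Returns the step values at distinct event times, prefixed with the
    (0, 1) anchor; censored records reduce the risk set only.
    """
    data = list(data)
    if not data:
        raise DomainError("need at least one record")
    times = np.array([r.time for r in data], dtype=float)
    events = np.array([r.event for r in data], dtype=int)
    km = KaplanMeierFitter()
    km.fit(times, event_observed=events)
    event_times = np.unique(times[(events == 1) & (times > 0)])
    sf = km.survival_function_at_times(event_times).to_numpy()
    out_t = np.concatenate([[0.0], event_times])
    out_s = np.concatenate([[1.0], sf])
    return DigitizedCurve(tuple(out_t), tuple(out_s))


def _step_survival(curve: DigitizedCurve, grid: np.ndarray) -> np.ndarray:
    """Right-continuous step-function evaluation of a KM-style curve."""
    times = np.asarray(curve.times)
    values = np.asarray(curve.survival)
    idx = np.searchsorted(times, grid, side="right") - 1
    out = np.where(idx >= 0, values[np.clip(idx, 0, len(values) - 1)], 1.0)
    return out


def emulate_digitization(
    curve: DigitizedCurve,
    n_points: int,
    jitter_sd: float,
    seed: int,
) -> DigitizedCurve:
    """Emulate manual point extraction from a published survival figure.

    Resamples the step curve on an even time grid from 0 to its last time,
    adds truncated Gaussian jitter (clipped to two standard deviations) to
    the survival readings, then restores validity by isotonic projection
    onto nonincreasing values clipped to [0, 1].
    """
    if n_points < 3:
        raise DomainError("n_points must be >= 3")
    if jitter_sd < 0:
        raise DomainError("jitter_sd must be >= 0")
    if len(curve) == 0:
        raise DomainError("curve is empty")
    grid = np.linspace(0.0, max(curve.times), n_points)
    values = _step_survival(curve, grid)
    if jitter_sd > 0:
        rng = np.random.default_rng(seed)
        noise = np.clip(
            rng.normal(0.0, jitter_sd, size=n_points), -2 * jitter_sd, 2 * jitter_sd
        )
        values = values + noise
        iso = IsotonicRegression(increasing=False, y_min=0.0, y_max=1.0)
        values = iso.fit_transform(grid, values)
    return DigitizedCurve(tuple(grid), tuple(np.clip(values, 0.0, 1.0)))


def default_arm_specs(seed: int = DEFAULT_SEED) -> dict[str, TrialArmSpec]:
    """Synthetic arms matching the emulated trial's design.

    Truth curves are the published Weibull parameters; arm sizes are the
    trial's 320 (intervention) and 159 (comparator).
    """
    from .config import default_config

    cfg = default_config()
    sizes = {cfg.intervention: 320, cfg.comparator: 159}
    out = {}
    for i, (name, n) in enumerate(sizes.items()):
        strat = cfg.strategies[name]
        out[name] = TrialArmSpec(
            name=name,
            n=n,
            os_truth=strat.os.build(),
            pfs_truth=strat.pfs.build(),
            seed=seed + i,
        )
    return out


def write_default_fixtures(
    out_dir, seed: int | None = None, n_digitized: int = 50, jitter_sd: float = 0.01
) -> list:
    """Write the synthetic pseudo-IPD and digitized-curve CSV fixtures.

    Eight files per call: ``ipd_<arm>_<endpoint>.csv`` (columns
    ``time_cycles,event``) and ``digitized_<arm>_<endpoint>.csv``
    (columns ``time_cycles,survival``) for both arms and endpoints.
    """
    from pathlib import Path

    from .fitting import records_to_csv

    out_dir = Path(out_dir)
    paths = []
    for name, spec in default_arm_specs(seed=DEFAULT_SEED if seed is None else seed).items():
        for endpoint in ("os", "pfs"):
            records = simulate_ipd(spec, endpoint)
            ipd_path = out_dir / f"ipd_{name}_{endpoint}.csv"
            records_to_csv(records, ipd_path)
            km = km_estimate(records)
            curve = emulate_digitization(
                km, n_points=n_digitized, jitter_sd=jitter_sd, seed=spec.seed + 100
            )
            curve_path = out_dir / f"digitized_{name}_{endpoint}.csv"
            curve.to_csv(curve_path)
            paths.extend([ipd_path, curve_path])
    return paths


def load_fixture(filename: str):
    """Read one bundled synthetic fixture CSV by filename.

    ``ipd_*`` files load as survival records, ``digitized_*`` files as
    curves.
    """
    from importlib import resources

    from .fitting import records_from_frame
    import pandas as pd
    import io

    ref = resources.files("psmcea").joinpath("data", "fixtures", filename)
    df = pd.read_csv(io.StringIO(ref.read_text()))
    if filename.startswith("ipd_"):
        return records_from_frame(df)
    return DigitizedCurve(tuple(df["time_cycles"]), tuple(df["survival"]))
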