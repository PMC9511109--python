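"""MLE and curve fitting, information criteria and model selection."""

import math

import numpy as np
import pytest

from psmcea import (
    DigitizedCurve,
    ParametricDistribution,
    SurvivalRecord,
    fit_mle,
    fit_to_curve,
    select_model,
)
from psmcea.exceptions import (
    DomainError,
    FlatCurveError,
    IncomparableFitsError,
    InsufficientEventsError,
)
from psmcea.fitting import records_from_csv, records_to_csv
from psmcea.simulate import TrialArmSpec, simulate_ipd


def _simulate(truth, n, seed, cutoff=40.0, accrual=24.9):
    spec = TrialArmSpec(
        "sim", n, truth, truth, cutoff_cycles=cutoff, accrual_cycles=accrual,
        seed=seed,
    )
    return simulate_ipd(spec, "os")


class TestMLE:
    def test_exponential_closed_form(self):
        """The exponential MLE is events / total time at risk."""
        truth = ParametricDistribution.exponential(0.08)
        records = _simulate(truth, 2000, seed=5)
        fit = fit_mle(records, "exponential")
        events = sum(r.event for r in records)
        at_risk = sum(r.time for r in records)
        assert fit.distribution.params["rate"] == pytest.approx(
            events / at_risk, rel=1e-5
        )

    def test_weibull_parameter_recovery(self):
        """Recover (1.36, 0.015) from 10,000 censored records."""
        truth = ParametricDistribution.weibull(1.36, 0.015)
        fit = fit_mle(_simulate(truth, 10_000, seed=11), "weibull")
        assert fit.distribution.params["shape"] == pytest.approx(1.36, rel=0.05)
        assert fit.distribution.params["rate"] == pytest.approx(0.015, rel=0.10)

    def test_against_lifelines_weibull(self):
        """Independent cross-check of the censored Weibull likelihood."""
        from lifelines import WeibullFitter

        truth = ParametricDistribution.weibull(1.2, 0.03)
        records = _simulate(truth, 1500, seed=2)
        fit = fit_mle(records, "weibull")
        wf = WeibullFitter().fit(
            np.array([r.time for r in records]),
            np.array([r.event for r in records]),
        )
        # lifelines uses S(t) = exp(-(t/lambda)^rho)
        assert fit.distribution.params["shape"] == pytest.approx(wf.rho_, rel=1e-3)
        assert fit.distribution.params["rate"] == pytest.approx(
            wf.lambda_ ** -wf.rho_, rel=1e-3
        )

    def test_information_criteria_definitions(self):
        truth = ParametricDistribution.weibull(1.3, 0.05)
        records = _simulate(truth, 300, seed=9)
        fit = fit_mle(records, "weibull")
        k, n = 2, len(records)
        assert fit.aic == pytest.approx(2 * k - 2 * fit.loglik)
        assert fit.bic == pytest.approx(k * math.log(n) - 2 * fit.loglik)
        assert fit.n_obs == n and not fit.curve_based

    def test_empty_input(self):
        with pytest.raises(InsufficientEventsError):
            fit_mle([], "weibull")

    def test_all_censored(self):
        records = [SurvivalRecord(5.0, 0)] * 20
        with pytest.raises(InsufficientEventsError):
            fit_mle(records, "exponential")

    def test_unknown_family(self):
        with pytest.raises(DomainError):
            fit_mle([SurvivalRecord(1.0, 1)] * 5, "royston")

    @pytest.mark.parametrize(
        "family", ["exponential", "gamma", "lognormal", "loglogistic", "gompertz"]
    )
    def test_every_family_fits_censored_data(self, family):
        truth = ParametricDistribution.weibull(1.2, 0.04)
        fit = fit_mle(_simulate(truth, 400, seed=13), family)
        assert np.isfinite(fit.loglik)


class TestCurveFit:
    def test_exact_points_recovered(self):
        """Noiseless points from the intervention PFS curve self-recover."""
        truth = ParametricDistribution.weibull(1.16, 0.047)
        t = np.linspace(0.5, 40, 50)
        curve = DigitizedCurve(tuple(t), tuple(truth.survival(t)))
        fit = fit_to_curve(curve, "weibull")
        assert fit.distribution.params["shape"] == pytest.approx(1.16, rel=1e-3)
        assert fit.distribution.params["rate"] == pytest.approx(0.047, rel=1e-3)
        assert fit.curve_based

    def test_cloglog_loss_also_recovers(self):
        truth = ParametricDistribution.weibull(1.29, 0.059)
        t = np.linspace(0.5, 30, 40)
        curve = DigitizedCurve(tuple(t), tuple(truth.survival(t)))
        fit = fit_to_curve(curve, "weibull", loss="complementary-log-log")
        assert fit.distribution.params["shape"] == pytest.approx(1.29, rel=1e-3)
        assert fit.distribution.params["rate"] == pytest.approx(0.059, rel=1e-3)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_jittered_points_recovered_within_ten_percent(self, seed):
        truth = ParametricDistribution.weibull(1.29, 0.059)
        rng = np.random.default_rng(seed)
        t = np.linspace(0.5, 30, 60)
        s = np.clip(truth.survival(t) + rng.uniform(-0.01, 0.01, t.size), 0, 1)
        s = np.minimum.accumulate(s)
        fit = fit_to_curve(DigitizedCurve(tuple(t), tuple(s)), "weibull")
        assert fit.distribution.params["shape"] == pytest.approx(1.29, rel=0.10)
        assert fit.distribution.params["rate"] == pytest.approx(0.059, rel=0.10)

    def test_too_few_points(self):
        with pytest.raises(DomainError):
            fit_to_curve(DigitizedCurve((1.0, 2.0), (0.9, 0.8)), "weibull")

    def test_flat_curve(self):
        curve = DigitizedCurve((1.0, 2.0, 3.0, 4.0), (1.0, 1.0, 1.0, 1.0))
        with pytest.raises(FlatCurveError):
            fit_to_curve(curve, "weibull")


class TestSelectModel:
    def _fit(self, family, aic, bic, n_obs=100, curve_based=False):
        from psmcea.fitting import FitResult

        dist = ParametricDistribution.weibull(1.0, 0.1)
        return FitResult(dist, 0.0, aic, bic, n_obs, curve_based)

    def test_single_fit(self):
        fit = self._fit("weibull", 10.0, 12.0)
        assert select_model([fit]) == [fit]

    def test_sorted_by_aic_then_bic(self):
        a = self._fit("a", 10.0, 20.0)
        b = self._fit("b", 10.0, 15.0)
        c = self._fit("c", 5.0, 99.0)
        assert select_model([a, b, c]) == [c, b, a]

    def test_incomparable_n_obs(self):
        with pytest.raises(IncomparableFitsError):
            select_model([self._fit("a", 1, 1, n_obs=10), self._fit("b", 1, 1)])

    def test_mle_and_curve_fits_not_mixed(self):
        with pytest.raises(IncomparableFitsError):
            select_model(
                [self._fit("a", 1, 1), self._fit("b", 1, 1, curve_based=True)]
            )

    def test_true_family_ranked_first_in_most_replicates(self):
        """Weibull truth (shape 1.3) beats exponential in >=80% of seeds."""
        truth = ParametricDistribution.weibull(1.3, 0.03)
        wins = 0
        n_rep = 20
        for seed in range(n_rep):
            records = _simulate(truth, 5000, seed=seed)
            fits = [fit_mle(records, f) for f in ("weibull", "exponential")]
            ranked = select_model(fits)
            wins += ranked[0].distribution.family == "weibull"
        assert wins >= 0.8 * n_rep


def test_records_csv_roundtrip(tmp_path):
    records = [SurvivalRecord(1.5, 1), SurvivalRecord(4.0, 0)]
    path = tmp_path / "records.csv"
    records_to_csv(records, path)
    assert path.read_text().splitlines()[0] == "time_cycles,event"
    assert records_from_csv(path) == records


def test_digitized_curve_csv_roundtrip(tmp_path):
    curve = DigitizedCurve((0.0, 1.0, 2.0), (1.0, 0.8, 0.5))
    path = tmp_path / "curve.csv"
    curve.to_csv(path)
    assert path.read_text().splitlines()[0] == "time_cycles,survival"
    assert DigitizedCurve.from_csv(path) == curve


def test_digitized_curve_validation():
    with pytest.raises(DomainError):
        DigitizedCurve((0.0, 0.0), (1.0, 0.9))  # non-increasing times
    with pytest.raises(DomainError):
        DigitizedCurve((0.0, 1.0), (0.8, 0.9))  # survival increases
    with pytest.raises(DomainError):
        DigitizedCurve((0.0, 1.0), (1.2, 0.9))  # out of [0, 1]
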