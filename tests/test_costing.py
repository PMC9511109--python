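"""Dosing arithmetic and discounted cost accumulation."""

import numpy as np
import pytest

from psmcea import (
    bsa_dose,
    calvert_dose,
    cycle_drug_cost,
    occupancy,
    total_cost,
)
from psmcea.costing import (
    AEEvent,
    AEProfile,
    ae_cost_total,
    cost_breakdown,
    drug_dose_mg,
    treatment_weights,
)
from psmcea.exceptions import ConfigurationError, DomainError
from psmcea.trace import build_grid


@pytest.fixture(scope="module")
def grid():
    return build_grid(10, 21)


@pytest.fixture(scope="module")
def setup(config, grid):
    """Strategies, prices, dosing and traces from the bundled config."""
    out = {}
    for arm in ("sugemalimab", "chemotherapy"):
        strat = config.build_strategy(arm)
        out[arm] = (
            strat,
            occupancy(
                strat.os_dist, strat.pfs_dist, grid,
                discount_rate=config.discount_rate,
            ),
        )
    return out, config.prices.build(), config.dosing.build()


class TestDosing:
    def test_bsa_dose(self):
        assert bsa_dose(500, 1.72) == pytest.approx(860.0)
        assert bsa_dose(500, 1.0) == 500.0
        assert bsa_dose(0, 1.72) == 0.0

    def test_calvert_dose(self):
        assert calvert_dose(5, 70) == pytest.approx(475.0)
        assert calvert_dose(5, 0) == 125.0
        assert calvert_dose(0, 70) == 0.0

    def test_unknown_drug(self, setup):
        _, _, dosing = setup
        with pytest.raises(ConfigurationError, match="docetaxel"):
            drug_dose_mg("docetaxel", dosing)


class TestCycleDrugCost:
    def test_combination_cycle(self, setup):
        strategies, prices, dosing = setup
        strat, _ = strategies["sugemalimab"]
        # 1200x3.08 + 860x1.672 + 475x0.041
        assert cycle_drug_cost(strat, prices, dosing, 1) == pytest.approx(5153.395)

    def test_maintenance_cycle(self, setup):
        strategies, prices, dosing = setup
        strat, _ = strategies["sugemalimab"]
        assert cycle_drug_cost(strat, prices, dosing, 5) == pytest.approx(5133.92)

    def test_comparator_maintenance(self, setup):
        strategies, prices, dosing = setup
        strat, _ = strategies["chemotherapy"]
        assert cycle_drug_cost(strat, prices, dosing, 5) == pytest.approx(1437.92)

    def test_invalid_cycle_index(self, setup):
        strategies, prices, dosing = setup
        with pytest.raises(DomainError):
            cycle_drug_cost(strategies["sugemalimab"][0], prices, dosing, 0)


class TestAECosts:
    def test_expected_cost_per_arm(self, setup):
        strategies, _, _ = setup
        assert strategies["chemotherapy"][0].ae_profile.expected_cost == (
            pytest.approx(800.498)
        )
        assert strategies["sugemalimab"][0].ae_profile.expected_cost == (
            pytest.approx(524.418)
        )

    def test_once_mode_applies_at_first_cycle(self, setup):
        strategies, _, _ = setup
        strat, trace = strategies["chemotherapy"]
        total = ae_cost_total(
            strat.ae_profile, "once", trace.pfd, trace.discount_factor
        )
        assert total == pytest.approx(800.498 * trace.discount_factor[0])

    def test_zero_incidence_profile(self, setup):
        _, _, _ = setup
        profile = AEProfile({"anemia": AEEvent(531.7, 0.0, 0.073)})
        assert profile.expected_cost == 0.0

    def test_invalid_mode(self, setup):
        strategies, _, _ = setup
        strat, trace = strategies["chemotherapy"]
        with pytest.raises(DomainError):
            ae_cost_total(strat.ae_profile, "weekly", trace.pfd, trace.discount_factor)


class TestTotalCost:
    def test_zero_prices_and_costs_give_zero(self, config, grid):
        cfg = config.with_values(
            {
                "prices.sugemalimab_per_mg": 0.0,
                "prices.pemetrexed_per_mg": 0.0,
                "prices.carboplatin_per_mg": 0.0,
                "costs.followup_per_cycle": 0.0,
                "costs.subsequent_per_cycle": 0.0,
                "costs.bsc_per_cycle": 0.0,
                "ae_events.anemia.cost_per_episode": 0.0,
                "ae_events.wbc_decreased.cost_per_episode": 0.0,
                "ae_events.platelet_decreased.cost_per_episode": 0.0,
            }
        )
        strat = cfg.build_strategy("sugemalimab")
        tr = occupancy(strat.os_dist, strat.pfs_dist, grid)
        assert total_cost(strat, tr, cfg.prices.build(), cfg.dosing.build()) == 0.0

    def test_monotone_in_subsequent_share(self, config, grid):
        # subsequent therapy is dearer than BSC, so a larger share costs more
        totals = []
        for share in (0.31, 0.62):
            cfg = config.with_value(
                "strategies.chemotherapy.subsequent_therapy_share", share
            )
            strat = cfg.build_strategy("chemotherapy")
            tr = occupancy(
                strat.os_dist, strat.pfs_dist, grid,
                discount_rate=cfg.discount_rate,
            )
            totals.append(
                total_cost(strat, tr, cfg.prices.build(), cfg.dosing.build())
            )
        assert totals[1] > totals[0]

    @pytest.mark.parametrize(
        "path",
        [
            "prices.sugemalimab_per_mg",
            "prices.pemetrexed_per_mg",
            "costs.followup_per_cycle",
            "costs.subsequent_per_cycle",
            "costs.bsc_per_cycle",
            "ae_events.platelet_decreased.cost_per_episode",
        ],
    )
    def test_monotone_in_unit_prices(self, config, grid, path):
        totals = []
        for factor in (1.0, 1.5):
            cfg = config.with_value(path, config.resolve_path(path) * factor)
            strat = cfg.build_strategy("sugemalimab")
            tr = occupancy(
                strat.os_dist, strat.pfs_dist, grid,
                discount_rate=cfg.discount_rate,
            )
            totals.append(
                total_cost(strat, tr, cfg.prices.build(), cfg.dosing.build())
            )
        assert totals[1] >= totals[0]

    @pytest.mark.parametrize("arm", ["sugemalimab", "chemotherapy"])
    @pytest.mark.parametrize("ae_mode", ["once", "per-treatment-cycle"])
    @pytest.mark.parametrize("rule", ["until-progression", "capped-at-median"])
    @pytest.mark.parametrize("followup", ["pfd", "all-alive"])
    def test_brute_force_loop_oracle(self, setup, arm, ae_mode, rule, followup):
        """Vectorized totals match a plain cycle-by-cycle loop to 1e-9."""
        strategies, prices, dosing = setup
        strat, trace = strategies[arm]
        total = total_cost(
            strat, trace, prices, dosing,
            ae_cost_mode=ae_mode, treatment_duration_rule=rule,
            followup_state=followup,
        )
        pp = strat.post_progression
        expected = 0.0
        for i, cycle in enumerate(trace.grid.cycle_numbers):
            df = trace.discount_factor[i]
            on_treatment = trace.pfd[i]
            if rule == "capped-at-median" and cycle > strat.treatment_cap_cycles:
                on_treatment = 0.0
            drug = cycle_drug_cost(strat, prices, dosing, int(cycle))
            followup_weight = (
                trace.pfd[i] if followup == "pfd" else trace.pfd[i] + trace.pd[i]
            )
            expected += df * (
                on_treatment * drug
                + followup_weight * pp.followup_cost_per_cycle
                + trace.pd[i]
                * (
                    pp.subsequent_therapy_share * pp.subsequent_cost_per_cycle
                    + (1 - pp.subsequent_therapy_share) * pp.bsc_cost_per_cycle
                )
            )
            if ae_mode == "per-treatment-cycle":
                expected += df * on_treatment * strat.ae_profile.expected_cost
        if ae_mode == "once":
            expected += strat.ae_profile.expected_cost * trace.discount_factor[0]
        assert total == pytest.approx(expected, rel=1e-9)

    def test_unit_price_dimension_check(self, config, grid):
        """Discount 0 and unit prices of 1/mg: drug cost = occupancy x mg."""
        cfg = config.with_values(
            {
                "prices.sugemalimab_per_mg": 1.0,
                "prices.pemetrexed_per_mg": 1.0,
                "prices.carboplatin_per_mg": 1.0,
                "discount_rate": 0.0,
            }
        )
        strat = cfg.build_strategy("sugemalimab")
        tr = occupancy(strat.os_dist, strat.pfs_dist, grid, discount_rate=0.0)
        breakdown = cost_breakdown(strat, tr, cfg.prices.build(), cfg.dosing.build())
        drug = breakdown[breakdown.component == "drug"]["discounted"].sum()
        dosing = cfg.dosing.build()
        combo_mg = sum(drug_dose_mg(d, dosing) for d in strat.combo_drugs)
        maint_mg = sum(drug_dose_mg(d, dosing) for d in strat.maintenance_drugs)
        mg_mass = np.where(tr.grid.cycle_numbers <= 4, combo_mg, maint_mg)
        assert drug == pytest.approx(float(np.sum(tr.pfd * mg_mass)), rel=1e-12)

    def test_capped_rule_requires_cap(self, setup):
        strategies, _, _ = setup
        strat, trace = strategies["sugemalimab"]
        uncapped = strat.__class__(
            **{**strat.__dict__, "treatment_cap_cycles": None}
        )
        with pytest.raises(ConfigurationError):
            treatment_weights(uncapped, trace, "capped-at-median")

    def test_breakdown_columns(self, setup):
        strategies, prices, dosing = setup
        strat, trace = strategies["chemotherapy"]
        frame = cost_breakdown(strat, trace, prices, dosing)
        assert set(frame.columns) == {
            "cycle", "state", "component", "undiscounted", "discounted",
        }
        assert set(frame.component) == {
            "drug", "followup", "subsequent_therapy", "bsc", "adverse_events",
        }
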