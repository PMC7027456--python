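"""Sensitivity drivers: price perturbations, scans, scenarios, cost of use."""

import numpy as np
import pytest

from phytomfg_tea import (
    ConfigurationError,
    cost_of_use,
    expression_scan,
    price_sensitivity,
    production_scan,
    run_pipeline,
    run_scenario,
    substrate_reuse_counterfactual,
)
from phytomfg_tea.sensitivity import STANDARD_TREATMENT_BAND


class TestPriceSensitivity:
    def test_substrate_plus_30_pct_moves_cogs_12_pct(self, base_config):
        response = price_sensitivity(base_config, "soilless plant substrate", [0.3])
        assert response[0.3] == pytest.approx(12, abs=0.5)

    def test_zero_delta_gives_zero_change(self, base_config):
        response = price_sensitivity(base_config, "transgenic seed", [0.0])
        assert response[0.0] == pytest.approx(0.0, abs=1e-9)

    def test_elution_buffer_pm_30_pct(self, base_config):
        """The 10th-largest item moves COGS by only +-0.41%."""
        response = price_sensitivity(
            base_config, "chromatography elution buffer", [0.3, -0.3]
        )
        assert response[0.3] == pytest.approx(0.41, abs=0.01)
        assert response[-0.3] == pytest.approx(-0.41, abs=0.01)

    def test_exactly_linear_in_delta(self, base_config):
        """Closed form: dCOGS% = delta x (item cost / AOC) x 100."""
        result = run_pipeline(base_config)
        share = result.cost_report.item("TFF membranes").annual_cost / result.cost_report.aoc
        deltas = [-0.25, -0.1, 0.05, 0.2]
        response = price_sensitivity(base_config, "TFF membranes", deltas)
        for delta in deltas:
            assert response[delta] == pytest.approx(100 * delta * share, rel=1e-9)

    def test_unknown_item_raises_with_ledger_listing(self, base_config):
        from phytomfg_tea import EconomicsError

        with pytest.raises(EconomicsError, match="TFF membranes"):
            price_sensitivity(base_config, "unobtainium", [0.1])


@pytest.fixture(scope="module")
def e_scan(base_config):
    return expression_scan(base_config, [0.5, 1.0, 2.0, 3.0, 4.0, 5.0])


@pytest.fixture(scope="module")
def p_scan(base_config):
    return production_scan(base_config, [100.0, 250.0, 500.0, 750.0, 1000.0])


class TestExpressionScan:

    def test_cogs_strictly_decreasing_with_diminishing_returns(self, e_scan):
        """dCOGS(0.5->1) exceeds 10 x dCOGS(4->5)."""
        values = [p.cogs_per_g for p in e_scan.points]
        assert all(a > b for a, b in zip(values, values[1:]))
        d_low = values[0] - values[1]
        d_high = values[4] - values[5]
        assert d_low > 10 * d_high

    def test_base_point_recovers_base_design(self, e_scan, base_result):
        point = next(p for p in e_scan.points if p.parameter_value == 1.0)
        assert point.cogs_per_g == pytest.approx(base_result.cost_report.cogs_per_g, rel=1e-9)
        assert point.capex_total == pytest.approx(50.1e6, rel=1e-9)

    def test_fw_follows_demand_over_grid(self, base_config):
        """fw = demand / (recovery x E x batches) at every grid point,
        e.g. 9.50e3 kg at the base point."""
        from phytomfg_tea.downstream import overall_recovery_from_config

        recovery = overall_recovery_from_config(base_config)
        batches = base_config.schedule.batches_per_year
        for demand in (250.0, 500.0, 1000.0):
            cfg = base_config.model_copy(update={"annual_demand_kg": demand})
            scan = expression_scan(cfg, [0.5, 1.0, 5.0])
            for p in scan.points:
                expected = demand * 1000 / (recovery * p.parameter_value) / batches
                assert p.fw_per_batch_kg == pytest.approx(expected, rel=1e-9)
        base_point = expression_scan(base_config, [1.0]).points[0]
        assert base_point.fw_per_batch_kg == pytest.approx(9.50e3, rel=3e-3)

    def test_upstream_per_gram_halves_when_expression_doubles(self, base_config):
        """Linearity limit: with downstream costs zeroed and only the
        biomass-driven upstream lines kept, upstream $/g scales exactly as 1/E."""
        stripped = base_config.model_copy(
            update={
                "ledger": [
                    i
                    for i in base_config.ledger
                    if i.section == "upstream" and i.scaling != "fixed"
                ]
            }
        )
        scan = expression_scan(stripped, [1.0, 2.0])
        assert scan.points[1].cogs_per_g == pytest.approx(
            scan.points[0].cogs_per_g / 2, rel=1e-9
        )

    def test_non_monotone_grid_rejected(self, base_config):
        with pytest.raises(ConfigurationError, match="strictly increasing"):
            expression_scan(base_config, [1.0, 0.5])

    def test_economics_invariants_hold_at_every_point(self, e_scan):
        for p in e_scan.points:
            assert sum(p.cogs_split.values()) == pytest.approx(p.cogs_per_g, rel=1e-9)
            assert p.aoc == pytest.approx(p.cogs_per_g * 500_000, rel=1e-9)


class TestProductionScan:

    def test_downstream_share_strictly_decreasing(self, p_scan):
        shares = [
            p.cogs_split["downstream"] / p.cogs_per_g for p in p_scan.points
        ]
        assert all(a > b for a, b in zip(shares, shares[1:]))

    def test_identity_point_recovers_base(self, p_scan, base_result):
        point = next(p for p in p_scan.points if p.parameter_value == 500.0)
        assert point.cogs_per_g == pytest.approx(
            base_result.cost_report.cogs_per_g, rel=1e-9
        )

    def test_upstream_per_gram_roughly_constant(self, p_scan):
        """Approximately linear upstream scaling keeps upstream $/g within
        15% of the base value across 100-1,000 kg/yr."""
        base_up = next(
            p.cogs_split["upstream"] for p in p_scan.points if p.parameter_value == 500.0
        )
        for p in p_scan.points:
            assert abs(p.cogs_split["upstream"] / base_up - 1) < 0.15


class TestScenarios:
    def test_spinach(self, spinach_result):
        report = spinach_result.cost_report
        assert report.cogs_per_g == pytest.approx(4.92, rel=5e-3)
        assert report.capex_total == pytest.approx(46.5e6, rel=1e-3)
        assert spinach_result.config.schedule.downstream_cycle_days == 0.67

    def test_tobacco(self, tobacco_result):
        report = tobacco_result.cost_report
        assert report.cogs_per_g == pytest.approx(3.00, rel=5e-3)
        assert report.capex_total == pytest.approx(27.5e6, rel=1e-3)
        assert tobacco_result.plan.batches_per_year == 63
        assert tobacco_result.plan.plants_per_batch == pytest.approx(13_900, rel=2e-3)

    def test_base_scenario_equals_direct_pipeline(self, base_config, base_result):
        via_scenario = run_scenario("base")
        assert via_scenario.cost_report.cogs_per_g == pytest.approx(
            base_result.cost_report.cogs_per_g, rel=1e-12
        )
        assert via_scenario.plan.fw_per_batch_kg == pytest.approx(
            base_result.plan.fw_per_batch_kg, rel=1e-12
        )


class TestCostOfUse:
    def test_meat_product_band(self):
        result = cost_of_use(6.88, "meat_product", (2.0, 10.0))
        assert result.cost_low == pytest.approx(0.01376)
        assert result.cost_high == pytest.approx(0.0688)

    def test_band_overlaps_standard_treatments(self):
        """$0.0138-0.0688/kg falls within the $0.01-0.10/kg comparator band."""
        result = cost_of_use(6.88, "meat_product", (2.0, 10.0))
        low, high = STANDARD_TREATMENT_BAND
        assert result.cost_low >= low and result.cost_high <= high

    def test_zero_rate_costs_nothing(self):
        result = cost_of_use(123.0, "meat_product", (0.0, 0.0))
        assert result.cost_low == 0.0 and result.cost_high == 0.0

    def test_wash_units(self):
        result = cost_of_use(3.0, "carcass_spray", (2.0, 10.0))
        assert result.cost_unit == "$/L wash"
        assert result.cost_high == pytest.approx(0.03)

    def test_unknown_juncture_rejected(self):
        with pytest.raises(ConfigurationError, match="juncture"):
            cost_of_use(6.88, "marinade", (2.0, 10.0))


def test_substrate_reuse_lowers_aoc_about_21_pct(base_config):
    """A single substrate reuse (half the annual substrate cost) lowers the
    annual operating cost by ~21% - computed through the ledger."""
    result = substrate_reuse_counterfactual(base_config)
    assert result["aoc_reduction_pct"] == pytest.approx(21, abs=0.5)
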