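"""Cost accounting: CAPEX scaling, OPEX rollup, COGS identities."""

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytomfg_tea import (
    CostItem,
    EconomicsError,
    EquipmentItem,
    build_cost_report,
    capex,
    cogs,
    opex,
)


def eq(name="x", section="downstream", ref_cost=1e6, ref_size=1.0, size=1.0,
       exponent=0.6, mult=2.0):
    return EquipmentItem(name, section, ref_cost, ref_size, size, exponent, mult)


class TestCapex:
    def test_reference_size_gives_reference_cost_times_multiplier(self):
        assert eq().installed_cost() == pytest.approx(2e6)

    def test_six_tenths_rule(self):
        item = eq(size=8.0)
        assert item.installed_cost() == pytest.approx(2e6 * 8**0.6)

    def test_section_totals(self):
        result = capex([eq(section="upstream"), eq(), eq()])
        assert result["upstream"] == pytest.approx(2e6)
        assert result["downstream"] == pytest.approx(4e6)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(EconomicsError, match="size"):
            eq(size=-1.0).installed_cost()

    def test_exponent_out_of_range_rejected(self):
        with pytest.raises(EconomicsError, match="exponent"):
            eq(exponent=1.4).installed_cost()

    def test_empty_list_rejected(self):
        with pytest.raises(EconomicsError, match="empty"):
            capex([])

    def test_base_fixture_reproduces_published_capex(self, base_result):
        """$19.1M upstream + $31.0M downstream = $50.1M, 62% downstream."""
        report = base_result.cost_report
        assert report.capex_by_section["upstream"] == pytest.approx(19.1e6)
        assert report.capex_by_section["downstream"] == pytest.approx(31.0e6)
        assert report.capex_total == pytest.approx(50.1e6)
        share = report.capex_by_section["downstream"] / report.capex_total
        assert 100 * share == pytest.approx(62, abs=0.5)


class TestOpex:
    def test_rollup_by_section_and_category(self):
        items = [
            CostItem("a", "upstream", "labor", "op1", 2.0, 10.0),
            CostItem("b", "upstream", "consumable", "op1", 1.0, 5.0),
            CostItem("c", "downstream", "labor", "op2", 1.0, 7.0),
        ]
        by_section, by_category, by_both, aoc = opex(items)
        assert by_section == {"upstream": 25.0, "downstream": 7.0}
        assert by_category == {"labor": 27.0, "consumable": 5.0}
        assert by_both[("upstream", "labor")] == 20.0
        assert aoc == 32.0

    def test_missing_category_is_absent_not_zero(self):
        _, by_category, _, _ = opex([CostItem("a", "upstream", "labor", "op", 1, 1)])
        assert "utility" not in by_category

    def test_negative_quantity_rejected(self):
        with pytest.raises(EconomicsError):
            CostItem("a", "upstream", "labor", "op", -1.0, 1.0)

    def test_base_sections_match_published(self, base_result):
        """Upstream $2.01M (58% of OPEX), downstream $1.43M, AOC $3.44M."""
        report = base_result.cost_report
        assert report.opex_by_section["upstream"] == pytest.approx(2.01e6, rel=1e-3)
        assert report.opex_by_section["downstream"] == pytest.approx(1.43e6, rel=1e-3)
        assert report.aoc == pytest.approx(3.44e6, rel=1e-3)
        assert report.section_shares_pct()["upstream"] == pytest.approx(58, abs=0.5)

    def test_seeding_operation_share_of_upstream(self, base_result):
        """Seeding (substrate + seeds + labor) is 79% of upstream OPEX."""
        report = base_result.cost_report
        share = report.operation_cost("seeding") / report.opex_by_section["upstream"]
        assert 100 * share == pytest.approx(79, abs=0.5)

    def test_downstream_operation_shares(self, base_result):
        """Chromatography 38% and UF/DF 35% of downstream OPEX; downstream
        labor-dependent cost 18.5% of AOC."""
        report = base_result.cost_report
        down = report.opex_by_section["downstream"]
        assert 100 * report.operation_cost("chromatography") / down == pytest.approx(
            38, abs=0.5
        )
        assert 100 * report.operation_cost("uf_df") / down == pytest.approx(35, abs=0.5)
        labor = sum(
            i.annual_cost
            for i in report.items
            if i.section == "downstream" and i.category == "labor"
        )
        assert 100 * labor / report.aoc == pytest.approx(18.5, abs=0.2)


class TestCogs:
    def test_direct_identity(self):
        value, split = cogs(1e6, 1000.0, {"upstream": 1e6})
        assert value == pytest.approx(1.0)
        assert split["upstream"] == pytest.approx(1.0)

    def test_base_cogs_split(self, base_result):
        report = base_result.cost_report
        assert report.cogs_per_g == pytest.approx(6.88, rel=1e-3)
        assert report.cogs_split["upstream"] == pytest.approx(4.02, rel=1e-3)
        assert report.cogs_split["downstream"] == pytest.approx(2.86, rel=1e-3)

    def test_zero_demand_rejected(self):
        with pytest.raises(EconomicsError):
            cogs(1e6, 0.0, {})

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(aoc=st.floats(1e4, 1e8), demand=st.floats(1.0, 1e4), k=st.floats(1.1, 10))
    def test_homogeneous_degree_minus_one_in_demand(self, aoc, demand, k):
        v1, _ = cogs(aoc, demand, {})
        v2, _ = cogs(aoc, k * demand, {})
        assert v2 == pytest.approx(v1 / k, rel=1e-12)

    def test_split_sums_to_total_and_shares_to_100(self, base_result):
        report = base_result.cost_report
        assert sum(report.cogs_split.values()) == pytest.approx(
            report.cogs_per_g, rel=1e-12
        )
        assert sum(report.section_shares_pct().values()) == pytest.approx(100, abs=0.1)
        assert sum(report.category_shares_pct().values()) == pytest.approx(100, abs=0.1)


def test_top_ten_items_cover_90_pct_of_aoc(base_result):
    """The ten largest annual cost lines collectively represent 90% of the
    annual operating cost, with the elution buffer the tenth largest."""
    report = base_result.cost_report
    top = report.top_items(10)
    assert sum(i.annual_cost for i in top) / report.aoc == pytest.approx(0.90, abs=0.005)
    assert top[0].name == "soilless plant substrate"
    assert top[-1].name == "chromatography elution buffer"


def test_substrate_unit_price_and_share(base_result):
    """~1.3 cents per plant; 41.2% of annual operating cost."""
    report = base_result.cost_report
    item = report.item("soilless plant substrate")
    assert item.unit_price == pytest.approx(0.013, abs=0.0005)
    assert report.item_share_pct("soilless plant substrate") == pytest.approx(
        41.2, abs=0.2
    )


def test_depreciation_reported_separately_not_in_cogs(base_result):
    report = base_result.cost_report
    dep = report.straight_line_depreciation(20.0)
    assert dep == pytest.approx(50.1e6 / 20)
    # COGS identity holds without any depreciation charge
    assert report.cogs_per_g == pytest.approx(report.aoc / 500_000.0, rel=1e-12)


def test_unknown_item_error_lists_ledger(base_result):
    with pytest.raises(EconomicsError, match="soilless plant substrate"):
        base_result.cost_report.item("no such item")
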