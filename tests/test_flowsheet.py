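"""Stream/unit-operation engine: conservation, recovery bookkeeping."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytomfg_tea import (
    AddedInput,
    FlowsheetValidationError,
    Stream,
    UnitOpSpec,
    chain_amp_recovery,
    cumulative_recovery,
    propagate,
    run_chain,
)

COMPS = ["water", "amp", "host_soluble_impurity", "insoluble_solids", "buffer_salts"]


def random_case(rng):
    stream = Stream({c: float(rng.uniform(0, 100)) for c in COMPS})
    op = UnitOpSpec(
        name="random",
        product_transfer={c: float(rng.uniform(0, 1)) for c in COMPS},
        added_inputs=(
            AddedInput(
                name="buf",
                ratio=float(rng.uniform(0, 2)),
                basis="input_total",
                composition={"water": 0.98, "buffer_salts": 0.02},
            ),
        ),
    )
    return op, stream


class TestPropagate:
    def test_identity_op_passes_stream_through(self):
        stream = Stream({"water": 5.0, "amp": 1.0})
        op = UnitOpSpec("noop", {"water": 1.0, "amp": 1.0})
        rec = propagate(op, stream)
        assert rec.product_stream.components == pytest.approx(stream.components)
        assert rec.waste_stream.total_mass == pytest.approx(0.0)
        assert rec.amp_recovery_this_stage == 1.0

    def test_mass_conservation_1000_random_cases(self):
        """input + additions == product + waste, component-wise, against an
        independent per-component hand summation."""
        rng = np.random.default_rng(20240917)
        for _ in range(1000):
            op, stream = random_case(rng)
            rec = propagate(op, stream)
            added_total = op.added_inputs[0].amount(stream)
            comp_added = {
                "water": added_total * 0.98,
                "buffer_salts": added_total * 0.02,
            }
            for c in COMPS:
                lhs = stream.mass(c) + comp_added.get(c, 0.0)
                rhs = rec.product_stream.mass(c) + rec.waste_stream.mass(c)
                assert rhs == pytest.approx(lhs, rel=1e-12, abs=1e-12)

    def test_negative_transfer_rejected(self):
        op = UnitOpSpec("bad", {"amp": -0.1})
        with pytest.raises(FlowsheetValidationError, match="outside"):
            propagate(op, Stream({"amp": 1.0}))

    def test_unknown_addition_basis_rejected(self):
        from phytomfg_tea import ConfigurationError

        op = UnitOpSpec(
            "bad",
            {"amp": 1.0},
            added_inputs=(
                AddedInput("buf", 0.5, "no_such_component", {"water": 1.0}),
            ),
        )
        with pytest.raises(ConfigurationError, match="unknown basis"):
            propagate(op, Stream({"amp": 1.0}))

    def test_negative_component_mass_rejected(self):
        with pytest.raises(FlowsheetValidationError, match="negative"):
            Stream({"amp": -1.0})


class TestRunChain:
    def test_two_identity_ops_preserve_input(self):
        stream = Stream({"water": 3.0, "amp": 2.0})
        ident = UnitOpSpec("noop", {"water": 1.0, "amp": 1.0})
        recs = run_chain([ident, ident], stream)
        assert recs[-1].product_stream.components == pytest.approx(stream.components)
        assert cumulative_recovery(recs) == 1.0

    def test_empty_chain_rejected(self):
        with pytest.raises(FlowsheetValidationError, match="empty"):
            run_chain([], Stream({"amp": 1.0}))

    def test_stages_feed_forward(self):
        stream = Stream({"amp": 8.0, "water": 2.0})
        half = UnitOpSpec("half", {"amp": 0.5, "water": 1.0})
        recs = run_chain([half, half, half], stream)
        assert recs[1].input_stream is recs[0].product_stream
        assert recs[-1].product_stream.mass("amp") == pytest.approx(1.0)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        fracs=st.lists(st.floats(0.01, 1.0), min_size=1, max_size=6),
        amp0=st.floats(0.1, 100.0),
    )
    def test_cumulative_recovery_is_product_of_stages(self, fracs, amp0):
        ops = [UnitOpSpec(f"s{i}", {"amp": f}) for i, f in enumerate(fracs)]
        recs = run_chain(ops, Stream({"amp": amp0}))
        expected = float(np.prod(fracs))
        assert cumulative_recovery(recs) == pytest.approx(expected, rel=1e-12)
        assert chain_amp_recovery(ops) == pytest.approx(expected, rel=1e-12)

    def test_removing_stage_divides_final_amp_by_its_recovery(self):
        rng = np.random.default_rng(7)
        fracs = rng.uniform(0.2, 0.95, size=4)
        ops = [UnitOpSpec(f"s{i}", {"amp": float(f)}) for i, f in enumerate(fracs)]
        full = run_chain(ops, Stream({"amp": 10.0}))[-1].product_stream.mass("amp")
        without = run_chain(ops[:2] + ops[3:], Stream({"amp": 10.0}))[-1]
        assert without.product_stream.mass("amp") == pytest.approx(
            full / fracs[2], rel=1e-12
        )


def test_base_chain_stage_amp_masses(base_result):
    """Per-stage AMP masses along the base chain follow the calibrated
    compositions: 9.52 -> 8.96 -> 6.71 -> 5.85 -> 5.49 kg."""
    amp = [r.product_stream.mass("amp") for r in base_result.stage_records]
    assert amp == pytest.approx([8.96, 6.7116, 5.8528, 5.4945, 5.4945], rel=2e-3)
    recov = [r.amp_recovery_this_stage for r in base_result.stage_records]
    assert recov[:4] == pytest.approx([0.941, 0.749, 0.872, 0.939], abs=1.5e-3)


def test_base_extraction_stream_matches_published_composition(base_result):
    """Screw-press extract: 11,200 kg at 0.08% AMP and 0.61% impurities."""
    ext = base_result.stage_records[0].product_stream
    assert ext.total_mass == pytest.approx(11_200, rel=1e-3)
    assert 100 * ext.fraction("amp") == pytest.approx(0.08, abs=0.005)
    assert 100 * ext.fraction("host_soluble_impurity") == pytest.approx(0.61, abs=0.005)
    # 9,520 kg FW + 4,760 kg buffer enter extraction
    rec = base_result.stage_records[0]
    assert rec.additions["extraction_buffer"] == pytest.approx(4_760, rel=1e-3)
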