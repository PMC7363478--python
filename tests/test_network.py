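"""Unit and property tests for the reactive network core."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fret
from fret import (
    EMPTY, Network, NodeError, build_benchmark_network, cond, lift,
    records_to_jsonl, sfloor, skip_repeats,
)


@pytest.fixture
def net():
    return Network()


class TestConstruction:
    def test_new_network_is_empty(self, net):
        assert len(net.nodes) == 0
        assert net.transaction_counter == 0

    def test_origin_ids_are_dense(self, net):
        sigs = [net.origin(n) for n in "abc"]
        assert [s.node_id for s in sigs] == [0, 1, 2]
        assert len(net.nodes) == 3

    def test_pristine_origin_has_no_value(self, net):
        x = net.origin("x")
        assert not x.has_value
        with pytest.raises(ValueError):
            _ = x.value

    def test_origin_name_must_be_nonempty(self, net):
        with pytest.raises(ValueError):
            net.origin("")

    def test_cross_network_combination_rejected(self):
        a = Network().origin("a")
        b = Network().origin("b")
        with pytest.raises(ValueError):
            lift(lambda x, y: x + y, a, b)

    def test_networks_are_independent(self):
        n1, n2 = Network(), Network()
        x1, x2 = n1.origin("x"), n2.origin("x")
        n1.post(x1, 1)
        assert not x2.has_value


class TestPost:
    def test_post_propagates_to_dependent(self, net):
        x = net.origin("x")
        y = x * 2
        records = net.post(x, 3)
        assert y.value == 6
        assert {r.node_id for r in records} == {x.node_id, y.node_id}

    def test_post_to_non_origin_is_error(self, net):
        x = net.origin("x")
        y = x.map(lambda v: v)
        with pytest.raises(ValueError, match="origin"):
            net.post(y, 1)

    def test_lonely_origin_single_record(self, net):
        x = net.origin("x")
        records = net.post(x, 5)
        assert len(records) == 1
        assert x.value == 5

    def test_diamond_computes_once(self, net):
        calls = []
        a = net.origin("a")
        b = a + 1
        c = a + 2
        d = lift(lambda u, v: calls.append(1) or (u + v), b, c)
        net.post(a, 1)
        assert d.value == 5  # (1+1) + (1+2), evaluated exactly once
        assert len(calls) == 1

    def test_transfer_error_names_node(self, net):
        x = net.origin("x")
        bad = x.map(lambda v: 1 / 0, name="kaboom")
        with pytest.raises(NodeError, match="kaboom"):
            net.post(x, 1)


class TestLift:
    def test_grating_phase_closed_form(self, net):
        # phase that cycles at 3 Hz: theta * freq * t with theta = 2*pi
        t = net.origin("t")
        phase = (2 * np.pi) * 3 * t
        net.post(t, 0.5)
        assert phase.value == pytest.approx(3 * np.pi)

    def test_floor_of_scaled_clock(self, net):
        t = net.origin("t")
        s = sfloor(10 * t)
        net.post(t, 0.25)
        assert s.value == 2

    def test_text_equality(self, net):
        k = net.origin("key")
        is_ctrl = k.eq("ctrl")
        net.post(k, "ctrl")
        assert is_ctrl.value is True
        net.post(k, "shift")
        assert is_ctrl.value is False

    def test_gating_on_valueless_input(self, net):
        x, y = net.origin("x"), net.origin("y")
        z = x + y
        net.post(x, 1)
        assert not z.has_value
        net.post(y, 2)
        assert z.value == 3


class TestMap:
    def test_negation(self, net):
        x = net.origin("x")
        y = x.map(lambda v: -v)
        net.post(x, 3)
        assert y.value == -3

    def test_no_emission_before_source(self, net):
        x = net.origin("x")
        y = x.map(lambda v: v)
        assert not y.has_value

    def test_seeded_random_index_range(self, net):
        rng = np.random.default_rng(42)
        x = net.origin("sampler")
        idx = x.map(lambda _: int(rng.integers(1, 11)))
        seen = []
        idx.on_value(seen.append)
        for k in range(1000):
            net.post(x, k)
        assert len(seen) == 1000
        assert all(1 <= v <= 10 for v in seen)
        assert set(seen) == set(range(1, 11))


class TestScan:
    def test_cumulative_sum(self, net):
        x = net.origin("x")
        acc = x.scan(lambda a, v: a + v, 0)
        out = []
        acc.on_value(out.append)
        for v in (1, 2, 3):
            net.post(x, v)
        assert out == [1, 3, 6]

    def test_seed_is_value_but_not_emission(self, net):
        x = net.origin("x")
        acc = x.scan(lambda a, v: a + v, 41)
        out = []
        acc.on_value(out.append)
        assert acc.value == 41  # queryable
        assert out == []        # but never emitted
        net.post(x, 1)
        assert out == [42]

    def test_one_hot_snapshot_accumulation(self, net):
        x = net.origin("x")
        acc = x.scan(np.add, np.zeros((10, 10)))
        for _ in range(2):
            snap = np.eye(10)  # one-hot per column
            net.post(x, snap)
        assert acc.value.sum() == 20


class TestBuffer:
    def test_sliding_window(self, net):
        x = net.origin("x")
        w = x.buffer(3)
        out = []
        w.on_value(lambda v: out.append(list(v)))
        for v in range(1, 6):
            net.post(x, v)
        assert out == [[1, 2, 3], [2, 3, 4], [3, 4, 5]]

    def test_silent_until_full(self, net):
        x = net.origin("x")
        w = x.buffer(4)
        net.post(x, 1)
        net.post(x, 2)
        net.post(x, 3)
        assert not w.has_value

    def test_vector_inputs_stack_to_matrix(self, net):
        x = net.origin("x")
        w = x.buffer(10)
        for k in range(10):
            one_hot = np.zeros(10)
            one_hot[k] = 1
            net.post(x, one_hot)
        assert w.value.shape == (10, 10)
        assert np.array_equal(w.value, np.eye(10))


class TestAtThen:
    def test_samples_on_truthy_trigger(self, net):
        v, trig = net.origin("v"), net.origin("trig")
        s = v.at(trig)
        net.post(v, 7)
        net.post(trig, True)
        assert s.value == 7

    def test_declines_on_falsy_trigger(self, net):
        v, trig = net.origin("v"), net.origin("trig")
        s = v.at(trig)
        net.post(v, 7)
        net.post(trig, False)
        assert not s.has_value

    def test_declines_when_value_updates_alone(self, net):
        v, trig = net.origin("v"), net.origin("trig")
        s = v.at(trig)
        net.post(v, 7)
        assert not s.has_value

    def test_declines_when_value_missing(self, net):
        v, trig = net.origin("v"), net.origin("trig")
        s = v.at(trig)
        net.post(trig, True)
        assert not s.has_value

    def test_then_constant_payload(self, net):
        trig = net.origin("trig")
        s = trig.then(42)
        out = []
        s.on_value(out.append)
        for v in (True, False, 1, 0, "go"):
            net.post(trig, v)
        assert out == [42, 42, 42]

    def test_then_true_idiom(self, net):
        scored = net.origin("anyScored")
        end_trial = scored.then(True)
        net.post(scored, True)
        assert end_trial.value is True


class TestSkipRepeats:
    def test_consecutive_dedupe(self, net):
        x = net.origin("x")
        s = x.skip_repeats()
        out = []
        s.on_value(out.append)
        for v in (0, 0, 1, 1, 0):
            net.post(x, v)
        assert out == [0, 1, 0]

    def test_sampler_ramp(self, net):
        t = net.origin("t")
        sampler = skip_repeats(sfloor(10 * t))
        out = []
        sampler.on_value(out.append)
        for k in range(7):  # t = 0, 0.05, ..., 0.30
            net.post(t, k * 0.05)
        assert out == [0, 1, 2, 3]

    def test_first_value_always_emitted(self, net):
        x = net.origin("x")
        s = x.skip_repeats()
        net.post(x, np.zeros(3))
        assert np.array_equal(s.value, np.zeros(3))

    def test_shape_mismatch_is_not_equal(self, net):
        x = net.origin("x")
        s = x.skip_repeats()
        out = []
        s.on_value(out.append)
        net.post(x, np.zeros(3))
        net.post(x, np.zeros(4))
        assert len(out) == 2


class TestCond:
    def test_clamp_pattern(self, net):
        x = net.origin("x")
        clamped = cond((x > 10, 10), (x < -10, -10), (True, x))
        out = []
        clamped.on_value(out.append)
        for v in (15, -12, 3):
            net.post(x, v)
        assert out == [10, -10, 3]

    def test_no_truthy_predicate_declines(self, net):
        x = net.origin("x")
        c = cond((x > 10, 1))
        net.post(x, 5)
        assert not c.has_value

    def test_first_true_pair_wins(self, net):
        x = net.origin("x")
        c = cond((x > 0, "first"), (x > -1, "second"))
        net.post(x, 5)
        assert c.value == "first"


class TestListeners:
    def test_fires_once_per_emission(self, net):
        x = net.origin("x")
        seen = []
        x.on_value(seen.append)
        for v in (1, 2, 3):
            net.post(x, v)
        assert seen == [1, 2, 3]

    def test_detach(self, net):
        x = net.origin("x")
        seen = []
        h = x.on_value(seen.append)
        net.post(x, 1)
        h.detach()
        net.post(x, 2)
        assert seen == [1]

    def test_reentrant_post_queued_not_nested(self, net):
        x, y = net.origin("x"), net.origin("y")
        tx_of = {}
        x.on_value(lambda v: net.post(y, v * 10))
        y.on_value(lambda v: tx_of.update(y=net.nodes[y.node_id].updated_in))
        records = net.post(x, 1)
        # x's transaction contains only x; y updated in a later transaction
        assert [r.node_id for r in records] == [x.node_id]
        assert y.value == 10
        assert net.nodes[y.node_id].updated_in > net.nodes[x.node_id].updated_in

    def test_listener_error_does_not_abort(self, net):
        x = net.origin("x")
        x.on_value(lambda v: 1 / 0)
        net.post(x, 1)  # must not raise
        assert x.value == 1


class TestSubscript:
    def test_field_selection(self, net):
        p = net.origin("keyPresses")
        key = p["Key"]
        net.post(p, {"Key": "ctrl"})
        assert key.value == "ctrl"

    def test_absent_field_declines(self, net):
        p = net.origin("p")
        key = p["Key"]
        net.post(p, {"Other": 1})
        assert not key.has_value

    def test_no_dedupe_on_unchanged_field(self, net):
        p = net.origin("p")
        key = p["Key"]
        out = []
        key.on_value(out.append)
        net.post(p, {"Key": "a"})
        net.post(p, {"Key": "a"})
        assert out == ["a", "a"]

    def test_subscriptable_attribute_access(self, net):
        p = net.origin("gameData")
        sub = p.subscriptable()
        score = sub.playerScore
        net.post(p, {"playerScore": 2})
        assert score.value == 2


# ---------------------------------------------------------------------------
# invariants on random streams and layered DAGs
# ---------------------------------------------------------------------------

def _brute_scan(stream):
    acc, out = 0, []
    for v in stream:
        acc += v
        out.append(acc)
    return out


def _brute_buffer(stream, n):
    return [list(stream[i - n:i]) for i in range(n, len(stream) + 1)]


def _brute_dedupe(stream):
    out = []
    for v in stream:
        if not out or out[-1] != v:
            out.append(v)
    return out


def test_operator_oracles_on_random_streams():
    """scan == cumulative sum, buffer == sliding window, skip_repeats ==
    consecutive dedupe, on 1000 seeded random streams."""
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        length = int(rng.integers(1, 20))
        stream = [int(v) for v in rng.integers(0, 4, size=length)]
        n = int(rng.integers(1, 6))
        net = Network()
        x = net.origin("x")
        scan_out, buf_out, dd_out = [], [], []
        x.scan(lambda a, v: a + v, 0).on_value(scan_out.append)
        x.buffer(n).on_value(lambda v: buf_out.append(list(v)))
        x.skip_repeats().on_value(dd_out.append)
        for v in stream:
            net.post(x, v)
        assert scan_out == _brute_scan(stream)
        assert buf_out == _brute_buffer(stream, n)
        assert dd_out == _brute_dedupe(stream)


@given(st.data())
@settings(max_examples=30, deadline=None, derandomize=True)
def test_operator_oracles_property(data):
    stream = data.draw(st.lists(st.integers(-3, 3), min_size=1, max_size=30))
    n = data.draw(st.integers(1, 5))
    net = Network()
    x = net.origin("x")
    scan_out, buf_out, dd_out = [], [], []
    x.scan(lambda a, v: a + v, 0).on_value(scan_out.append)
    x.buffer(n).on_value(lambda v: buf_out.append(list(v)))
    x.skip_repeats().on_value(dd_out.append)
    for v in stream:
        net.post(x, v)
    assert scan_out == _brute_scan(stream)
    assert buf_out == _brute_buffer(stream, n)
    assert dd_out == _brute_dedupe(stream)


@pytest.mark.parametrize("n_nodes,depth", [(350, 20), (120, 20), (500, 7),
                                           (50, 50)])
def test_layered_network_single_update_and_topology(n_nodes, depth):
    net = Network()
    origin, ids = build_benchmark_network(net, n_nodes, depth, seed=1)
    assert len(ids) == n_nodes
    records = net.post(origin, 1.0)
    emitted = [r.node_id for r in records]
    # every node emits exactly once
    assert sorted(emitted) == sorted(ids)
    assert len(set(emitted)) == len(emitted)
    # topological soundness: each node appears after all its inputs
    pos = {nid: i for i, nid in enumerate(emitted)}
    for nid in emitted:
        for inp in net.nodes[nid].input_ids:
            assert pos[inp] < pos[nid]


def test_benchmark_network_rejects_more_layers_than_nodes():
    with pytest.raises(ValueError):
        build_benchmark_network(Network(), 10, 20, seed=0)


def test_determinism_byte_identical_logs():
    def run():
        net = Network()
        origin, _ = build_benchmark_network(net, 80, 8, seed=9)
        rng = np.random.default_rng(5)
        all_records = []
        for _ in range(20):
            all_records += net.post(origin, float(rng.integers(0, 100)))
        return records_to_jsonl(all_records)

    assert run() == run()


def test_jsonl_export_shape(tmp_path):
    net = Network()
    x = net.origin("x")
    y = x * 2
    records = net.post(x, 3)
    path = tmp_path / "log.jsonl"
    fret.write_emission_log(records, path)
    lines = [json.loads(l) for l in path.read_text().splitlines()]
    assert lines[0] == {"node": x.node_id, "name": "x", "tx": 0, "value": 3}
    assert lines[1]["value"] == 6
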