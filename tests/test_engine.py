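"""Tests of the deferred event-driven synaptic processing (row algorithm,
postsynaptic history, delayed delivery)."""

import math

import numpy as np
import pytest

from ebcpnn.engine import (
    HistoryEntry, InputRingBuffer, PostHistory, RowEntry, SynapticRow,
    process_row, record_post_spike, rotate_ring_buffer,
)
from ebcpnn.kernel import (
    OutOfOrderError, PreTraceState, SpikeTrain, event_driven_trajectory,
    update_post_on_spike,
)
from ebcpnn.params import DerivedCoefficients, VALIDATION_AMPA

from conftest import poisson_pair


def _make_row(params, n_post=1, plastic=True, delay=1.0):
    coeffs = DerivedCoefficients.from_params(params)
    return SynapticRow(
        receptor="ampa", params=params, coeffs=coeffs,
        entries=[RowEntry(post_index=j, delay=delay, plastic=plastic)
                 for j in range(n_post)])


def _drive(row, hist, si, sj, params, ring=None, dt=1.0):
    """Feed merged spike trains through the engine (post before pre at
    simultaneous events); returns the row weights sampled at pre spikes."""
    post_state = PreTraceState()
    events = sorted([(t, 0) for t in sj.times] + [(t, 1) for t in si.times])
    weights = []
    for t, kind in events:
        if kind == 0:
            post_state = update_post_on_spike(post_state, t, params)
            record_post_spike(hist, 0, t, post_state)
        else:
            process_row(row, t, hist, ring, dt=dt)
            weights.append(row.entries[0].weight)
    return np.asarray(weights), post_state


class TestPostHistory:
    def test_first_spike_single_entry(self):
        h = PostHistory(2)
        h.record(0, 5.0, 1.0, 1.0)
        assert h.last(0) == HistoryEntry(5.0, 1.0, 1.0)
        assert h.last(1) is None

    def test_second_entry_decayed_trace(self, val_params):
        """Two spikes delta apart: the second entry's Z_j* equals the
        first decayed by exp(-delta/tau_zj) plus one."""
        h = PostHistory(1)
        s = update_post_on_spike(PreTraceState(), 10.0, val_params)
        record_post_spike(h, 0, 10.0, s)
        s = update_post_on_spike(s, 25.0, val_params)
        record_post_spike(h, 0, 25.0, s)
        z0 = h.window(0, 0.0, 10.0)[0].z_star
        z1 = h.last(0).z_star
        assert z1 == pytest.approx(
            z0 * math.exp(-15.0 / val_params.tau_zj) + 1.0, rel=1e-12)

    def test_window_is_half_open(self):
        h = PostHistory(1)
        for t in (1.0, 2.0, 3.0):
            h.record(0, t, 1.0, 1.0)
        assert [e.t for e in h.window(0, 1.0, 3.0)] == [2.0, 3.0]

    def test_out_of_order_rejected(self):
        h = PostHistory(1)
        h.record(0, 5.0, 1.0, 1.0)
        with pytest.raises(OutOfOrderError):
            h.record(0, 5.0, 1.0, 1.0)

    def test_capacity_drop_oldest_counts(self):
        h = PostHistory(1, capacity=2)
        for t in (1.0, 2.0, 3.0):
            h.record(0, t, 1.0, 1.0)
        assert h.dropped == 1
        assert [e.t for e in h.window(0, 0.0, 10.0)] == [2.0, 3.0]

    def test_prune_keeps_newest(self):
        h = PostHistory(1)
        for t in (1.0, 2.0, 3.0):
            h.record(0, t, 1.0, 1.0)
        h.prune(10.0)
        assert h.last(0).t == 3.0


class TestRingBuffer:
    def test_empty_rotation_zero(self):
        rb = InputRingBuffer(3, ("ampa",), max_delay_steps=4)
        assert np.all(rotate_ring_buffer(rb)["ampa"] == 0.0)

    def test_delivery_at_exact_delay(self):
        """A weight scheduled with delay d (after the step's rotation, as
        the simulation loop does) surfaces exactly d rotations later."""
        rb = InputRingBuffer(2, ("ampa",), max_delay_steps=5)
        rb.rotate()  # step start
        rb.schedule(1, "ampa", 3, 0.7)
        seen = [rb.rotate()["ampa"][1] for _ in range(5)]
        assert seen == [0.0, 0.0, 0.7, 0.0, 0.0]

    def test_same_slot_accumulates(self):
        rb = InputRingBuffer(1, ("ampa",), max_delay_steps=3)
        rb.rotate()
        rb.schedule(0, "ampa", 2, 0.5)
        rb.schedule(0, "ampa", 2, 0.25)
        rb.rotate()
        assert rb.rotate()["ampa"][0] == pytest.approx(0.75)

    def test_slot_consumed_once(self):
        rb = InputRingBuffer(1, ("ampa",), max_delay_steps=3)
        rb.rotate()
        rb.schedule(0, "ampa", 1, 1.0)
        assert rb.rotate()["ampa"][0] == 1.0
        for _ in range(4):
            assert rb.rotate()["ampa"][0] == 0.0

    def test_beyond_horizon_rejected(self):
        rb = InputRingBuffer(1, ("ampa",), max_delay_steps=3)
        with pytest.raises(ValueError):
            rb.schedule(0, "ampa", 4, 1.0)
        with pytest.raises(ValueError):
            rb.schedule(0, "ampa", 0, 1.0)


class TestProcessRow:
    def test_zero_traces_zero_weight_delivery_scheduled(self, val_params):
        row = _make_row(val_params)
        hist = PostHistory(1)
        rb = InputRingBuffer(1, ("ampa",), max_delay_steps=4)
        process_row(row, 10.0, hist, rb)
        assert row.entries[0].weight == 0.0
        assert row.t_old == 10.0
        assert row.s_i.z_star == 1.0

    def test_static_entry_untouched_by_history(self, val_params):
        row = _make_row(val_params, plastic=False)
        row.entries[0].weight = 0.4
        hist = PostHistory(1)
        s = update_post_on_spike(PreTraceState(), 3.0, val_params)
        record_post_spike(hist, 0, 3.0, s)
        rb = InputRingBuffer(1, ("ampa",), max_delay_steps=4)
        rb.rotate()
        process_row(row, 5.0, hist, rb)
        assert row.entries[0].weight == 0.4
        assert rb.rotate()["ampa"][0] == 0.4  # delivered one step later

    @pytest.mark.parametrize("seed", [1, 2, 3])
    def test_row_weights_match_kernel_trajectory(self, val_params, seed):
        """Weights produced by Algorithm-1 row processing at each pre
        spike equal the eagerly updated event-driven kernel (and hence the
        time-driven oracle) to near machine precision."""
        si, sj = poisson_pair(seed, 25.0, 25.0, 2000.0, grid=1.0)
        row = _make_row(val_params)
        hist = PostHistory(1)
        w_row, _ = _drive(row, hist, si, sj, val_params)
        ev = event_driven_trajectory(si, sj, val_params)
        assert np.allclose(w_row, ev["w"], rtol=1e-10, atol=1e-12)

    def test_out_of_order_spike_rejected(self, val_params):
        row = _make_row(val_params)
        row.t_old = 50.0
        with pytest.raises(OutOfOrderError):
            process_row(row, 40.0, PostHistory(1))

    def test_order_invariance_across_rows(self, val_params):
        """Processing rows of distinct presynaptic neurons in either
        order within a timestep yields identical state."""
        si_a = SpikeTrain(np.array([10.0, 30.0]))
        si_b = SpikeTrain(np.array([10.0, 30.0]))
        sj = SpikeTrain(np.array([5.0, 20.0]))

        def run(order):
            rows = {k: _make_row(val_params) for k in "ab"}
            hist = PostHistory(1)
            post = PreTraceState()
            events = sorted([(t, "post") for t in sj.times]
                            + [(t, "pre") for t in si_a.times])
            for t, kind in events:
                if kind == "post":
                    post = update_post_on_spike(post, t, val_params)
                    record_post_spike(hist, 0, t, post)
                else:
                    for k in order:
                        process_row(rows[k], t, hist)
            return rows

        fwd = run("ab")
        rev = run("ba")
        for k in "ab":
            assert fwd[k].entries[0].weight == rev[k].entries[0].weight
            assert fwd[k].entries[0].syn.pij_star == \
                rev[k].entries[0].syn.pij_star

    def test_delivery_count_one_per_entry_per_spike(self, val_params):
        """Each row entry schedules exactly one delivery per presynaptic
        spike (spike conservation)."""
        row = _make_row(val_params, n_post=3)
        hist = PostHistory(3)
        rb = InputRingBuffer(3, ("ampa",), max_delay_steps=4)
        row.entries[0].plastic = False
        row.entries[0].weight = 1.0
        row.entries[1].plastic = False
        row.entries[1].weight = 2.0
        row.entries[2].plastic = False
        row.entries[2].weight = 3.0
        rb.rotate()
        process_row(row, 1.0, hist, rb)
        out = rb.rotate()["ampa"]
        assert list(out) == [1.0, 2.0, 3.0]
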