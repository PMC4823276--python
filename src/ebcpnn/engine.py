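"""Deferred, event-driven synaptic processing.

Synapses are stored in per-presynaptic-neuron **rows** holding the
presynaptic star traces and the time of the previous presynaptic spike
(``t_old``).  Nothing is computed for a synapse between presynaptic spikes;
when one arrives, the row is processed:

1. for every synapse, postsynaptic spikes that occurred in ``(t_old, t]``
   are replayed from the target neuron's **history queue** (decaying
   ``P_ij*`` to each spike time and incrementing it by the presynaptic
   ``Z_i*`` decayed to that time);
2. the presynaptic spike itself is applied (``P_ij*`` decayed to ``t`` and
   incremented by the postsynaptic ``Z_j*``), the probabilities are
   reconstructed and the weight recomputed;
3. the weight is scheduled for delivery after the synaptic delay via a
   per-neuron **ring buffer**;
4. the row header (``s_i``, ``t_old``) is advanced.

This reference implementation favours clarity; :mod:`ebcpnn.simulator`
provides a compiled equivalent for network-scale runs.
"""

from __future__ import annotations

import math
from bisect import bisect_left, bisect_right
from dataclasses import dataclass, field
from typing import NamedTuple, Optional

import numpy as np

from .kernel import (
    FloatArithmetic, OutOfOrderError, PreTraceState, ProbabilityEstimate,
    SynapseTraceState, compute_weight, decay_trace, update_pre_on_spike,
    update_post_on_spike, update_synapse_on_pre, update_synapse_on_post,
)
from .params import BCPNNParams, DerivedCoefficients

_FLOAT = FloatArithmetic()


class HistoryEntry(NamedTuple):
    t: float
    z_star: float
    p_star: float


class PostHistory:
    """Per-neuron ordered queues of (spike time, postsynaptic trace state).

    ``capacity=None`` keeps every entry (entries older than the oldest live
    ``t_old`` may be pruned explicitly); an integer capacity emulates the
    fixed-length circular queue of memory-constrained hardware, dropping
    the oldest entry and counting the loss.
    """

    def __init__(self, n_neurons: int, capacity: Optional[int] = None) -> None:
        if capacity is not None and capacity < 1:
            raise ValueError("capacity must be at least 1")
        self.capacity = capacity
        self._times: list[list[float]] = [[] for _ in range(n_neurons)]
        self._entries: list[list[HistoryEntry]] = [[] for _ in range(n_neurons)]
        self.dropped = 0

    def record(self, j: int, t_j: float, z_star: float, p_star: float) -> None:
        times = self._times[j]
        if times and t_j <= times[-1]:
            raise OutOfOrderError(
                f"history entry at t={t_j} not after t={times[-1]}")
        times.append(t_j)
        self._entries[j].append(HistoryEntry(t_j, z_star, p_star))
        if self.capacity is not None and len(times) > self.capacity:
            times.pop(0)
            self._entries[j].pop(0)
            self.dropped += 1

    def window(self, j: int, t_old: float, t: float) -> list[HistoryEntry]:
        """Entries with ``t_old < t_j <= t`` (half-open window)."""
        times = self._times[j]
        lo = bisect_right(times, t_old)
        hi = bisect_right(times, t)
        return self._entries[j][lo:hi]

    def last(self, j: int) -> Optional[HistoryEntry]:
        entries = self._entries[j]
        return entries[-1] if entries else None

    def prune(self, oldest_t_old: float) -> None:
        """Drop entries at or before ``oldest_t_old`` (no live row can still
        need them), always keeping the newest entry per neuron."""
        for times, entries in zip(self._times, self._entries):
            if len(times) > 1:
                cut = min(bisect_right(times, oldest_t_old), len(times) - 1)
                if cut:
                    del times[:cut]
                    del entries[:cut]


def record_post_spike(history: PostHistory, j: int, t_j: float,
                      post_state: PreTraceState) -> None:
    """Append a postsynaptic spike with the trace state *after* the spike's
    own unit increments (``post_state.t_last`` must equal ``t_j``)."""
    if post_state.t_last != t_j:
        raise ValueError("post state must be updated to the spike time first")
    history.record(j, t_j, post_state.z_star, post_state.p_star)


@dataclass
class RowEntry:
    """One synapse within a row."""

    post_index: int
    delay: float                     # ms
    plastic: bool = True
    weight: float = 0.0              # nA
    syn: SynapseTraceState = field(default_factory=SynapseTraceState)


@dataclass
class SynapticRow:
    """All synapses of one (presynaptic neuron, receptor type) pair."""

    receptor: str
    params: BCPNNParams
    coeffs: DerivedCoefficients
    entries: list[RowEntry] = field(default_factory=list)
    t_old: float = 0.0
    s_i: PreTraceState = field(default_factory=PreTraceState)

    def __post_init__(self) -> None:
        self.entries.sort(key=lambda e: e.post_index)


class InputRingBuffer:
    """Per-neuron, per-receptor circular accumulators of future input.

    ``schedule`` adds a weight to the slot ``delay`` timesteps ahead;
    ``rotate`` pops the current slot (returning it zeroed afterwards) and
    advances time by one step.
    """

    def __init__(self, n_neurons: int, receptors: tuple[str, ...],
                 max_delay_steps: int, dt: float = 1.0) -> None:
        if max_delay_steps < 1:
            raise ValueError("max_delay_steps must be at least 1")
        self.dt = dt
        self.n_slots = max_delay_steps + 1
        self.head = 0
        self.t = 0.0
        self.buffers = {
            r: np.zeros((n_neurons, self.n_slots)) for r in receptors}

    def schedule(self, post: int, receptor: str, delay_steps: int,
                 weight: float) -> None:
        """Schedule a delivery ``delay_steps`` after the step currently
        being processed (i.e. after the most recent :meth:`rotate`)."""
        if not 1 <= delay_steps < self.n_slots:
            raise ValueError(
                f"delay of {delay_steps} steps outside buffer horizon "
                f"[1, {self.n_slots - 1}]")
        slot = (self.head - 1 + delay_steps) % self.n_slots
        self.buffers[receptor][post, slot] += weight

    def rotate(self) -> dict[str, np.ndarray]:
        """Consume the current slot for every neuron/receptor; must be
        called exactly once per timestep, in time order."""
        out = {}
        for r, buf in self.buffers.items():
            out[r] = buf[:, self.head].copy()
            buf[:, self.head] = 0.0
        self.head = (self.head + 1) % self.n_slots
        self.t += self.dt
        return out


def rotate_ring_buffer(buffers: InputRingBuffer) -> dict[str, np.ndarray]:
    return buffers.rotate()


def process_row(row: SynapticRow, t: float, histories: PostHistory,
                ring_buffers: Optional[InputRingBuffer] = None,
                params: Optional[BCPNNParams] = None,
                coeffs: Optional[DerivedCoefficients] = None,
                arith: FloatArithmetic = _FLOAT,
                learning: bool = True,
                deliver: bool = True,
                dt: float = 1.0) -> SynapticRow:
    """Process a presynaptic spike at time ``t`` through a synaptic row
    (Algorithm 1): replay deferred postsynaptic spikes, apply the
    presynaptic spike, recompute plastic weights, schedule deliveries and
    advance the row header.
    """
    params = params or row.params
    coeffs = coeffs or row.coeffs
    if t < row.t_old:
        raise OutOfOrderError(
            f"presynaptic spike at t={t} precedes row time {row.t_old}")
    for entry in row.entries:
        if entry.plastic and learning:
            # Deferred postsynaptic spikes in (t_old, t].
            for h in histories.window(entry.post_index, row.t_old, t):
                zi_at_tj = decay_trace(row.s_i.z_star, h.t - row.s_i.t_last,
                                       params.tau_zi, arith)
                entry.syn = update_synapse_on_post(
                    entry.syn, h.t, arith.quantize(zi_at_tj), params, arith)
            # The presynaptic spike itself.
            last = histories.last(entry.post_index)
            if last is not None:
                zj_at_t = decay_trace(last.z_star, t - last.t,
                                      params.tau_zj, arith)
                pj_at_t = decay_trace(last.p_star, t - last.t,
                                      params.tau_p, arith)
            else:
                zj_at_t = pj_at_t = 0.0
            entry.syn = update_synapse_on_pre(
                entry.syn, t, arith.quantize(zj_at_t), params, arith)
            # Reconstruct after this spike's increments (the reconstruction
            # is continuous across spikes, so the instant is a convention).
            one = arith.quantize(1.0)
            zi_at_t = arith.quantize(decay_trace(
                row.s_i.z_star, t - row.s_i.t_last, params.tau_zi, arith) + one)
            pi_at_t = arith.quantize(decay_trace(
                row.s_i.p_star, t - row.s_i.t_last, params.tau_p, arith) + one)
            est = ProbabilityEstimate(
                p_i=coeffs.a_i * (zi_at_t - pi_at_t),
                p_j=coeffs.a_j * (zj_at_t - pj_at_t),
                p_ij=coeffs.a_ij * (arith.mul(zi_at_t, zj_at_t)
                                    - entry.syn.pij_star),
            )
            entry.weight = compute_weight(est, params, arith)
            entry.syn.weight = entry.weight
        if deliver and ring_buffers is not None:
            delay_steps = max(1, int(round(entry.delay / dt)))
            ring_buffers.schedule(entry.post_index, row.receptor,
                                  delay_steps, entry.weight)
    row.s_i = update_pre_on_spike(row.s_i, t, params, arith=arith)
    row.t_old = t
    return row
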