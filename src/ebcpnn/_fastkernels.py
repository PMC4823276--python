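"""Compiled inner loops of the event-driven synapse engine.

These numba kernels implement exactly the row-processing algorithm of
:mod:`ebcpnn.engine` (replay deferred postsynaptic spikes from the history
queue, apply the presynaptic spike, advance the row header) on flat CSR
arrays, which is what makes network-scale training runs tractable.  Their
equivalence with the reference implementation and with the time-driven
oracle is asserted by the test suite.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = [
    "record_post_spikes", "process_rows_learning", "deliver_spikes",
    "finalize_weights",
]


@njit(cache=False)
def record_post_spikes(spiked, t, tau_zj, tau_p, pj_z, pj_p, pj_t,
                       hist_t, hist_z, hist_cnt, cap):
    """Advance the postsynaptic star traces of every spiking neuron to
    ``t``, apply the unit increments and push (t, Z_j*) onto the history
    ring."""
    for n in range(spiked.shape[0]):
        j = spiked[n]
        dt = t - pj_t[j]
        z = pj_z[j] * math.exp(-dt / tau_zj) + 1.0
        p = pj_p[j] * math.exp(-dt / tau_p) + 1.0
        pj_z[j] = z
        pj_p[j] = p
        pj_t[j] = t
        idx = hist_cnt[j] % cap
        hist_t[j, idx] = t
        hist_z[j, idx] = z
        hist_cnt[j] += 1


@njit(cache=False)
def process_rows_learning(spiked, t, tau_zi, tau_zj, tau_p,
                          indptr, post, pij, row_t, row_z, row_p,
                          hist_t, hist_z, hist_cnt, cap, dropped):
    """Algorithm-1 row processing for every presynaptic spike at ``t``,
    updating only the coactivation traces (weight evaluation is deferred
    to :func:`finalize_weights`, valid whenever plastic currents are gated
    out of the membrane equation during training)."""
    for n in range(spiked.shape[0]):
        i = spiked[n]
        t_old = row_t[i]
        zi0 = row_z[i]
        for k in range(indptr[i], indptr[i + 1]):
            j = post[k]
            cnt = hist_cnt[j]
            m = min(cnt, cap)
            # first history index (in absolute counting) inside (t_old, t]
            s = cnt
            while s > cnt - m and hist_t[j, (s - 1) % cap] > t_old:
                s -= 1
            if s == cnt - m and cnt > cap:
                # the window may extend past the ring capacity
                dropped[0] += 1
            x = pij[k]
            cur = t_old
            if zi0 > 0.0:
                for idx in range(s, cnt):
                    tj = hist_t[j, idx % cap]
                    x = (x * math.exp(-(tj - cur) / tau_p)
                         + zi0 * math.exp(-(tj - t_old) / tau_zi))
                    cur = tj
            if cnt > 0:
                li = (cnt - 1) % cap
                zj_t = hist_z[j, li] * math.exp(-(t - hist_t[j, li]) / tau_zj)
            else:
                zj_t = 0.0
            pij[k] = x * math.exp(-(t - cur) / tau_p) + zj_t
        # addPreSpike: advance the row header
        dt = t - t_old
        row_z[i] = zi0 * math.exp(-dt / tau_zi) + 1.0
        row_p[i] = row_p[i] * math.exp(-dt / tau_p) + 1.0
        row_t[i] = t


@njit(cache=False)
def deliver_spikes(spiked, indptr, post, delay, weight, rb, head, nslots):
    """Insert every efferent weight into the target ring buffer at the slot
    its delay selects."""
    for n in range(spiked.shape[0]):
        i = spiked[n]
        for k in range(indptr[i], indptr[i + 1]):
            rb[post[k], (head + delay[k]) % nslots] += weight[k]


@njit(cache=False)
def finalize_weights(t, tau_zi, tau_zj, tau_p, a_i, a_j, a_ij, eps, w_gain,
                     indptr, post, pij, row_t, row_z, row_p,
                     pj_z, pj_p, pj_t, hist_t, hist_z, hist_cnt, cap,
                     weight):
    """Bring every synapse up to date at time ``t`` (replaying outstanding
    postsynaptic spikes) and evaluate the BCPNN weight from the
    reconstructed probabilities."""
    eps2 = eps * eps
    n_pre = row_t.shape[0]
    for i in range(n_pre):
        t_old = row_t[i]
        zi0 = row_z[i]
        zi_t = zi0 * math.exp(-(t - t_old) / tau_zi)
        pi_t = row_p[i] * math.exp(-(t - t_old) / tau_p)
        p_i = a_i * (zi_t - pi_t)
        for k in range(indptr[i], indptr[i + 1]):
            j = post[k]
            cnt = hist_cnt[j]
            m = min(cnt, cap)
            s = cnt
            while s > cnt - m and hist_t[j, (s - 1) % cap] > t_old:
                s -= 1
            x = pij[k]
            cur = t_old
            if zi0 > 0.0:
                for idx in range(s, cnt):
                    tj = hist_t[j, idx % cap]
                    x = (x * math.exp(-(tj - cur) / tau_p)
                         + zi0 * math.exp(-(tj - t_old) / tau_zi))
                    cur = tj
            x = x * math.exp(-(t - cur) / tau_p)
            pij[k] = x
            zj_t = pj_z[j] * math.exp(-(t - pj_t[j]) / tau_zj)
            pjv = pj_p[j] * math.exp(-(t - pj_t[j]) / tau_p)
            p_j = a_j * (zj_t - pjv)
            p_ij = a_ij * (zi_t * zj_t - x)
            weight[k] = w_gain * math.log(
                (p_ij + eps2) / ((p_i + eps) * (p_j + eps)))
        row_z[i] = zi_t
        row_p[i] = pi_t
        row_t[i] = t
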