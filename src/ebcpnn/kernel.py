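"""The BCPNN learning rule.

Two equivalent formulations are implemented:

* a **time-driven** form integrating the original trace ODEs on a fine,
  fixed grid (``time_driven_oracle``).  Spikes inject impulses into the Z
  traces, which feed the P traces, from which the weight and bias are
  computed.  This form is slow but serves as ground truth.

* an **event-driven** form operating on "star traces" (``Z*``, ``P*``,
  ``P_ij*``): state variables that receive unit increments at spikes and
  decay purely exponentially in between, so they need only be evaluated at
  spike times.  The probability traces are recovered by the linear
  reconstruction ``P = a (Z* - P*)`` with coefficients from
  :class:`~ebcpnn.params.DerivedCoefficients`.

A ``rate_based_reference`` is also provided: the same ODEs driven by
normalized firing rates instead of spike trains, reconstructing the
behaviour of earlier non-spiking ("abstract") BCPNN implementations for the
validation experiment.  The exact equations of those implementations are
not public; this is the package's own reconstruction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.signal import lfilter

from .params import BCPNNParams, DerivedCoefficients

__all__ = [
    "SpikeTrain", "PreTraceState", "SynapseTraceState", "ProbabilityEstimate",
    "decay_trace", "update_pre_on_spike", "update_post_on_spike",
    "update_synapse_on_pre", "update_synapse_on_post", "reconstruct",
    "compute_weight", "compute_bias", "time_driven_oracle",
    "rate_based_reference", "event_driven_trajectory", "FloatArithmetic",
]


class OutOfOrderError(ValueError):
    """An event was applied at a time earlier than the state's last update."""


class TraceCorruptionError(ValueError):
    """A probability estimate left the domain of the logarithmic mapping."""


# ---------------------------------------------------------------------------
# Arithmetic backend
# ---------------------------------------------------------------------------

class FloatArithmetic:
    """Double-precision arithmetic backend (the default).

    The fixed-point emulation in :mod:`ebcpnn.fixed_point` provides an
    object with the same four methods, which lets every kernel operation be
    run in either mode.
    """

    def decay(self, value: float, dt: float, tau: float) -> float:
        return value * math.exp(-dt / tau)

    def mul(self, a: float, b: float) -> float:
        return a * b

    def quantize(self, x: float) -> float:
        return x

    def log(self, x: float) -> float:
        return math.log(x)


_FLOAT = FloatArithmetic()


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpikeTrain:
    """An ordered spike train (times in ms) from one source."""

    times: np.ndarray
    id: int = 0

    def __post_init__(self) -> None:
        times = np.asarray(self.times, dtype=float)
        object.__setattr__(self, "times", times)
        if times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if times.size and times[0] < 0:
            raise ValueError("spike times must be non-negative")
        if np.any(np.diff(times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)


@dataclass
class PreTraceState:
    """Star traces of one side of a synapse (Z*, P*) at time ``t_last``.

    The identical structure is used for the postsynaptic side; only the Z
    time constant differs.
    """

    z_star: float = 0.0
    p_star: float = 0.0
    t_last: float = 0.0


@dataclass
class SynapseTraceState:
    """Per-synapse coactivation star trace P_ij* and cached weight."""

    pij_star: float = 0.0
    t_last: float = 0.0
    weight: float = 0.0


@dataclass(frozen=True)
class ProbabilityEstimate:
    """Reconstructed probability traces at a common evaluation time."""

    p_i: float
    p_j: float
    p_ij: float


# ---------------------------------------------------------------------------
# Event-driven operations
# ---------------------------------------------------------------------------

def decay_trace(value: float, dt: float, tau: float,
                arith: FloatArithmetic = _FLOAT) -> float:
    """Decay ``value`` by ``exp(-dt/tau)``.

    ``dt < 0`` signals an out-of-order event and raises.
    """
    if dt < 0:
        raise OutOfOrderError(f"negative elapsed time {dt}")
    if tau <= 0:
        raise ValueError("tau must be positive")
    if dt == 0:
        return value
    return arith.decay(value, dt, tau)


def _update_primary(state: PreTraceState, t: float, tau_z: float,
                    tau_p: float, arith: FloatArithmetic) -> PreTraceState:
    dt = t - state.t_last
    if dt < 0:
        raise OutOfOrderError(
            f"spike at t={t} precedes last update at t={state.t_last}")
    one = arith.quantize(1.0)
    z = arith.quantize(decay_trace(state.z_star, dt, tau_z, arith) + one)
    p = arith.quantize(decay_trace(state.p_star, dt, tau_p, arith) + one)
    return PreTraceState(z_star=z, p_star=p, t_last=t)


def update_pre_on_spike(state: PreTraceState, t: float, params: BCPNNParams,
                        coeffs: Optional[DerivedCoefficients] = None,
                        arith: FloatArithmetic = _FLOAT) -> PreTraceState:
    """Advance a presynaptic trace state to spike time ``t``: decay both
    star traces with their own time constants, then add the unit increment."""
    return _update_primary(state, t, params.tau_zi, params.tau_p, arith)


def update_post_on_spike(state: PreTraceState, t: float, params: BCPNNParams,
                         coeffs: Optional[DerivedCoefficients] = None,
                         arith: FloatArithmetic = _FLOAT) -> PreTraceState:
    """Postsynaptic twin of :func:`update_pre_on_spike` (uses ``tau_zj``)."""
    return _update_primary(state, t, params.tau_zj, params.tau_p, arith)


def _update_synapse(state: SynapseTraceState, t: float, increment: float,
                    tau_p: float, arith: FloatArithmetic) -> SynapseTraceState:
    dt = t - state.t_last
    if dt < 0:
        raise OutOfOrderError(
            f"event at t={t} precedes last update at t={state.t_last}")
    pij = arith.quantize(
        decay_trace(state.pij_star, dt, tau_p, arith) + increment)
    return SynapseTraceState(pij_star=pij, t_last=t, weight=state.weight)


def update_synapse_on_pre(state: SynapseTraceState, t: float,
                          zj_star_at_t: float, params: BCPNNParams,
                          arith: FloatArithmetic = _FLOAT) -> SynapseTraceState:
    """Apply a presynaptic spike at ``t``: decay P_ij* over the elapsed
    interval and add the postsynaptic star trace (already decayed to ``t``
    by the caller)."""
    return _update_synapse(state, t, zj_star_at_t, params.tau_p, arith)


def update_synapse_on_post(state: SynapseTraceState, t_j: float,
                           zi_star_at_tj: float, params: BCPNNParams,
                           arith: FloatArithmetic = _FLOAT) -> SynapseTraceState:
    """Apply a postsynaptic spike at ``t_j``: symmetric to
    :func:`update_synapse_on_pre` with the presynaptic star trace as
    increment.  This symmetric increment is required for equivalence with
    the coactivation ODE, whose drive ``Z_i Z_j`` jumps at both pre- and
    postsynaptic spikes."""
    return _update_synapse(state, t_j, zi_star_at_tj, params.tau_p, arith)


def reconstruct(pre: PreTraceState, post: PreTraceState,
                syn: SynapseTraceState, t: float, params: BCPNNParams,
                coeffs: Optional[DerivedCoefficients] = None,
                arith: FloatArithmetic = _FLOAT) -> ProbabilityEstimate:
    """Reconstruct (P_i, P_j, P_ij) at time ``t`` from the star traces."""
    if coeffs is None:
        coeffs = DerivedCoefficients.from_params(params)
    zi = decay_trace(pre.z_star, t - pre.t_last, params.tau_zi, arith)
    pi = decay_trace(pre.p_star, t - pre.t_last, params.tau_p, arith)
    zj = decay_trace(post.z_star, t - post.t_last, params.tau_zj, arith)
    pj = decay_trace(post.p_star, t - post.t_last, params.tau_p, arith)
    pij = decay_trace(syn.pij_star, t - syn.t_last, params.tau_p, arith)
    return ProbabilityEstimate(
        p_i=coeffs.a_i * (zi - pi),
        p_j=coeffs.a_j * (zj - pj),
        p_ij=coeffs.a_ij * (arith.mul(zi, zj) - pij),
    )


def compute_weight(est: ProbabilityEstimate, params: BCPNNParams,
                   arith: FloatArithmetic = _FLOAT) -> float:
    """Log-odds synaptic weight, ``w_gain * ln((P_ij + eps^2) /
    ((P_i + eps)(P_j + eps)))`` in nA."""
    eps = params.eps
    num = est.p_ij + eps * eps
    den = (est.p_i + eps) * (est.p_j + eps)
    if num <= 0 or den <= 0:
        raise TraceCorruptionError(
            f"non-positive log argument: P=({est.p_i}, {est.p_j}, {est.p_ij})")
    return params.w_gain * (arith.log(num) - arith.log(den))


def compute_bias(p_j: float, params: BCPNNParams,
                 arith: FloatArithmetic = _FLOAT) -> float:
    """Intrinsic bias current ``beta_gain * ln(P_j + eps)`` in nA."""
    arg = p_j + params.eps
    if arg <= 0:
        raise TraceCorruptionError(f"non-positive bias argument {arg}")
    return params.beta_gain * arith.log(arg)


# ---------------------------------------------------------------------------
# Time-driven oracle and rate-based reference
# ---------------------------------------------------------------------------

def _euler_smooth(drive: np.ndarray, tau: float, dt: float) -> np.ndarray:
    """Explicit-Euler first-order smoothing ``tau y' = x - y`` of ``drive``
    (drive sampled at the start of each step)."""
    a = 1.0 - dt / tau
    return lfilter([0.0, dt / tau], [1.0, -a], drive)


def _spike_impulses(train: SpikeTrain, n: int, dt: float,
                    amplitude: float) -> np.ndarray:
    x = np.zeros(n)
    if len(train):
        idx = np.round(np.asarray(train.times) / dt).astype(int)
        if np.any(idx >= n):
            raise ValueError("spike train extends beyond t_end")
        np.add.at(x, idx, amplitude)
    return x


def time_driven_oracle(si: SpikeTrain, sj: SpikeTrain, params: BCPNNParams,
                       dt: float = 0.01, t_end: float = 1000.0) -> dict:
    """Fine-step explicit Euler integration of the original trace ODEs.

    A spike is a Dirac impulse of area ``1/(f_max * spike_duration)`` into
    the Z equation, i.e. an instantaneous jump of ``1/(f_max * dt_spike *
    tau_z)`` in Z, so that sustained firing at ``f_max`` drives Z toward 1.

    Returns a dict of trajectories sampled on the integration grid:
    ``t, z_i, z_j, p_i, p_j, p_ij, w, i_beta``.
    """
    n = int(round(t_end / dt)) + 1
    fdt = params.f_max_ms * params.spike_duration
    xi = _spike_impulses(si, n, dt, 1.0 / (fdt * params.tau_zi))
    xj = _spike_impulses(sj, n, dt, 1.0 / (fdt * params.tau_zj))
    # Z with impulses: Euler decay between grid points, jumps at spikes.
    z_i = lfilter([1.0], [1.0, -(1.0 - dt / params.tau_zi)], xi)
    z_j = lfilter([1.0], [1.0, -(1.0 - dt / params.tau_zj)], xj)
    p_i = _euler_smooth(z_i, params.tau_p, dt)
    p_j = _euler_smooth(z_j, params.tau_p, dt)
    p_ij = _euler_smooth(z_i * z_j, params.tau_p, dt)
    eps = params.eps
    w = params.w_gain * np.log(
        (p_ij + eps * eps) / ((p_i + eps) * (p_j + eps)))
    i_beta = params.beta_gain * np.log(p_j + eps)
    return {
        "t": np.arange(n) * dt, "z_i": z_i, "z_j": z_j,
        "p_i": p_i, "p_j": p_j, "p_ij": p_ij, "w": w, "i_beta": i_beta,
    }


def rate_based_reference(rate_i: np.ndarray, rate_j: np.ndarray,
                         params: BCPNNParams, dt: float = 1.0,
                         t_end: Optional[float] = None) -> dict:
    """Deterministic "abstract" reference: the same ODEs driven by
    normalized rates ``r(t)/f_max`` in place of the spike-train drive.

    ``rate_i`` and ``rate_j`` are firing rates in Hz sampled on the ``dt``
    grid (piecewise-constant).  Rates are clipped to
    ``[eps * f_max, f_max]``, the valid band of the probability mapping.
    """
    rate_i = np.asarray(rate_i, dtype=float)
    rate_j = np.asarray(rate_j, dtype=float)
    if rate_i.shape != rate_j.shape:
        raise ValueError("rate traces must share a shape")
    if t_end is not None:
        n = int(round(t_end / dt)) + 1
        if rate_i.size != n:
            raise ValueError("rate trace length does not match t_end/dt")
    lo = params.eps * params.f_max
    kap_i = np.clip(rate_i, lo, params.f_max) / params.f_max
    kap_j = np.clip(rate_j, lo, params.f_max) / params.f_max
    z_i = _euler_smooth(kap_i, params.tau_zi, dt)
    z_j = _euler_smooth(kap_j, params.tau_zj, dt)
    p_i = _euler_smooth(z_i, params.tau_p, dt)
    p_j = _euler_smooth(z_j, params.tau_p, dt)
    p_ij = _euler_smooth(z_i * z_j, params.tau_p, dt)
    eps = params.eps
    w = params.w_gain * np.log(
        (p_ij + eps * eps) / ((p_i + eps) * (p_j + eps)))
    i_beta = params.beta_gain * np.log(p_j + eps)
    return {
        "t": np.arange(rate_i.size) * dt,
        "p_i": p_i, "p_j": p_j, "p_ij": p_ij, "w": w, "i_beta": i_beta,
    }


def event_driven_trajectory(si: SpikeTrain, sj: SpikeTrain,
                            params: BCPNNParams,
                            coeffs: Optional[DerivedCoefficients] = None,
                            eval_times: Optional[Sequence[float]] = None,
                            arith: FloatArithmetic = _FLOAT) -> dict:
    """Run the event-driven update sequence for one synapse and evaluate
    the reconstruction at the requested times (default: every presynaptic
    spike, after that spike's increments have been applied).

    Simultaneous pre- and postsynaptic spikes are processed post-then-pre;
    by the continuity of the reconstruction the result does not depend on
    this order.
    """
    if coeffs is None:
        coeffs = DerivedCoefficients.from_params(params)
    pre = PreTraceState()
    post = PreTraceState()
    syn = SynapseTraceState()
    if eval_times is None:
        eval_times = list(si.times)

    # kind 0 = postsynaptic, 1 = presynaptic: simultaneous events sort
    # post-then-pre.
    events = sorted(
        [(t, 0) for t in sj.times] + [(t, 1) for t in si.times])
    eval_sorted = sorted(eval_times)
    out_t, out = [], {k: [] for k in ("p_i", "p_j", "p_ij", "w", "i_beta")}
    ei = 0

    def emit(upto: float, inclusive: bool) -> None:
        nonlocal ei
        while ei < len(eval_sorted) and (
                eval_sorted[ei] < upto or (inclusive and eval_sorted[ei] == upto)):
            te = eval_sorted[ei]
            est = reconstruct(pre, post, syn, te, params, coeffs, arith)
            out_t.append(te)
            out["p_i"].append(est.p_i)
            out["p_j"].append(est.p_j)
            out["p_ij"].append(est.p_ij)
            out["w"].append(compute_weight(est, params, arith))
            out["i_beta"].append(compute_bias(est.p_j, params, arith))
            ei += 1

    for k, (t, kind) in enumerate(events):
        emit(t, inclusive=False)
        if kind == 0:  # postsynaptic spike
            zi_at_t = decay_trace(pre.z_star, t - pre.t_last, params.tau_zi,
                                  arith)
            syn = update_synapse_on_post(syn, t, arith.quantize(zi_at_t),
                                         params, arith)
            post = update_post_on_spike(post, t, params, arith=arith)
        else:  # presynaptic spike
            zj_at_t = decay_trace(post.z_star, t - post.t_last, params.tau_zj,
                                  arith)
            syn = update_synapse_on_pre(syn, t, arith.quantize(zj_at_t),
                                        params, arith)
            pre = update_pre_on_spike(pre, t, params, arith=arith)
        last_at_t = k + 1 == len(events) or events[k + 1][0] != t
        if last_at_t:
            emit(t, inclusive=True)
    emit(math.inf, inclusive=False)
    return {"t": np.array(out_t),
            **{k: np.array(v) for k, v in out.items()}}
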