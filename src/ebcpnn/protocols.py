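"""Reproducible, seeded experiment protocols.

Three procedures are provided:

* ``run_validation`` — two LIF neurons joined by one plastic AMPA synapse
  are driven through five trial-structured activation patterns
  (correlated, independent, anti-correlated, both muted, post muted) and
  the weight/bias trajectories of the spiking rule are compared with a
  deterministic rate-based ("abstract") reference sharing the same trial
  schedule.

* ``run_training`` — the modular attractor network is taught a temporal
  sequence by stimulating its minicolumns one after another, with plastic
  currents gated out of the membrane equation while weights learn online.

* ``run_recall`` — a trained network is cued with a brief stimulus to the
  first sequence element and replays the sequence with learning frozen.

All stochastic inputs are homogeneous Poisson processes realized by
per-timestep Bernoulli thinning from seeded generators.  Stimulus
intensities are calibrated so that driven cells fire near the nominal
protocol rates (the probability mapping of the learning rule assumes
rates in ``[eps f_max, f_max]``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .engine import PostHistory, RowEntry, SynapticRow, process_row, \
    record_post_spike
from .kernel import (
    FloatArithmetic, PreTraceState, SpikeTrain, compute_bias, compute_weight,
    rate_based_reference, reconstruct, update_post_on_spike,
    update_synapse_on_post,
)
from .fixed_point import FixedArithmetic
from .network import Network, NetworkConfig, build
from .params import (
    BCPNNParams, DerivedCoefficients, NeuronParams, VALIDATION_AMPA,
    VALIDATION_NEURON,
)
from .simulator import AttractorSimulator, StimulusItem

__all__ = [
    "StimulusSchedule", "StimulusItem", "poisson_train",
    "calibrate_input_rate", "run_validation", "run_training", "run_recall",
    "VALIDATION_PROTOCOLS", "ValidationResult",
]

VALIDATION_PROTOCOLS = (
    "correlated", "independent", "anti_correlated", "both_muted",
    "post_muted",
)

#: Rate (Hz) of the per-cell rate-forcing Poisson stimulus sources driving
#: a minicolumn during training and recall: equal to the f_max of the
#: attractor parameter sets, so stimulated cells fire at exactly the
#: maximum rate of the probability mapping (see docs/methods.md).
DEFAULT_STIM_RATE = 20.0
DEFAULT_STIM_WEIGHT = 2.0


class StimulusSchedule(list):
    """An ordered collection of :class:`StimulusItem` entries."""


def poisson_train(rate: float, t_start: float, t_end: float, seed: int,
                  dt: float = 1.0) -> SpikeTrain:
    """Homogeneous Poisson spike train via per-timestep Bernoulli(rate*dt)
    thinning; reproducible by seed."""
    if rate < 0:
        raise ValueError("rate must be non-negative")
    rng = np.random.default_rng(seed)
    n = int(round((t_end - t_start) / dt))
    hits = np.flatnonzero(rng.random(n) < rate * dt * 1e-3)
    return SpikeTrain(t_start + (hits + 1) * dt)


# ---------------------------------------------------------------------------
# Input-rate calibration
# ---------------------------------------------------------------------------

def _lif_output_rate(input_rate: float, neuron: NeuronParams, weight: float,
                     dt: float, sim_ms: float, rng: np.random.Generator
                     ) -> float:
    """Firing rate (Hz) of one LIF neuron driven by a Poisson source of
    ``input_rate`` Hz through an AMPA synapse of ``weight`` nA."""
    steps = int(round(sim_ms / dt))
    hits = rng.random(steps) < input_rate * dt * 1e-3
    prop = math.exp(-dt / neuron.tau_m)
    dsyn = math.exp(-dt / neuron.tau_ampa)
    da = math.exp(-dt / neuron.tau_a)
    v = neuron.e_l
    i_syn = 0.0
    i_a = 0.0
    count = 0
    for s in range(steps):
        if hits[s]:
            i_syn += weight
        v_inf = neuron.e_l + neuron.r_m * (i_syn - i_a)
        v = v_inf + (v - v_inf) * prop
        i_syn *= dsyn
        i_a *= da
        if v >= neuron.v_t:
            v = neuron.v_r
            i_a += neuron.alpha
            count += 1
    return count * 1000.0 / sim_ms


def calibrate_input_rate(target_hz: float,
                         neuron: NeuronParams = VALIDATION_NEURON,
                         weight: float = 2.0, dt: float = 1.0,
                         seed: int = 12345, sim_ms: float = 20000.0,
                         max_rate: float = 5000.0) -> float:
    """Poisson input rate that makes the neuron fire near ``target_hz``.

    Bisection over the (monotone) input-output curve of the isolated cell.
    """
    if target_hz <= 0:
        return 0.0
    rng = np.random.default_rng(seed)
    lo, hi = 0.0, target_hz
    while _lif_output_rate(hi, neuron, weight, dt, sim_ms, rng) < target_hz:
        lo = hi
        hi *= 2.0
        if hi > max_rate:
            raise RuntimeError("input rate calibration failed to bracket")
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        if _lif_output_rate(mid, neuron, weight, dt, sim_ms, rng) < target_hz:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


_calibration_cache: dict = {}


def _calibrated(target_hz: float, neuron: NeuronParams, weight: float,
                dt: float) -> float:
    key = (round(target_hz, 6), neuron, weight, dt)
    if key not in _calibration_cache:
        _calibration_cache[key] = calibrate_input_rate(
            target_hz, neuron, weight, dt)
    return _calibration_cache[key]


# ---------------------------------------------------------------------------
# Validation protocol
# ---------------------------------------------------------------------------

def _trial_rates(protocol: str, n_trials: int, params: BCPNNParams,
                 rng: np.random.Generator) -> tuple[np.ndarray, np.ndarray]:
    """Nominal (pre, post) firing rates per trial.  "Muted" units fire at
    the lowest normalized rate ``eps * f_max``; uniform sampling is an
    independent fair coin between the high and low rate."""
    hi = params.f_max
    lo = params.eps * params.f_max
    coin = rng.random(n_trials) < 0.5
    coin2 = rng.random(n_trials) < 0.5
    if protocol == "correlated":
        r = np.where(coin, hi, lo)
        return r, r.copy()
    if protocol == "independent":
        return np.where(coin, hi, lo), np.where(coin2, hi, lo)
    if protocol == "anti_correlated":
        return np.where(coin, hi, lo), np.where(coin, lo, hi)
    if protocol == "both_muted":
        return np.full(n_trials, lo), np.full(n_trials, lo)
    if protocol == "post_muted":
        return np.where(coin, hi, lo), np.full(n_trials, lo)
    raise ValueError(f"unknown protocol {protocol!r}")


def _sample_synapse(row: SynapticRow, hist: PostHistory,
                    post_state: PreTraceState, t: float,
                    params: BCPNNParams, coeffs: DerivedCoefficients,
                    arith) -> tuple[float, float]:
    """Measure (w, I_beta) at an arbitrary time.

    Postsynaptic spikes since the row's last presynaptic spike are still
    deferred in the history queue, so they are replayed onto a copy of the
    synapse state before reconstructing; the row itself is left untouched.
    """
    from .kernel import SynapseTraceState, decay_trace

    syn = SynapseTraceState(pij_star=row.entries[0].syn.pij_star,
                            t_last=row.entries[0].syn.t_last)
    s_i = row.s_i
    for h in hist.window(0, row.t_old, t):
        zi_at = decay_trace(s_i.z_star, h.t - s_i.t_last, params.tau_zi,
                            arith)
        syn = update_synapse_on_post(syn, h.t, arith.quantize(zi_at),
                                     params, arith)
    est = reconstruct(s_i, post_state, syn, t, params, coeffs, arith)
    return (compute_weight(est, params, arith),
            compute_bias(est.p_j, params, arith))


@dataclass
class ValidationResult:
    """Trajectories of the validation experiment."""

    protocol: str
    t: np.ndarray                   # sample times (ms)
    w_runs: np.ndarray              # (n_repeats, n_samples) spiking weights
    ibeta_runs: np.ndarray
    w_abstract: np.ndarray          # rate-based reference on the same grid
    ibeta_abstract: np.ndarray
    rates_pre: np.ndarray           # per-trial nominal rates (Hz)
    rates_post: np.ndarray
    rasters: list = field(default_factory=list)

    @property
    def w_mean(self) -> np.ndarray:
        return self.w_runs.mean(axis=0)

    @property
    def w_std(self) -> np.ndarray:
        return self.w_runs.std(axis=0)


def run_validation(protocol: str,
                   params: BCPNNParams = VALIDATION_AMPA,
                   neuron: NeuronParams = VALIDATION_NEURON,
                   n_repeats: int = 10, n_trials: int = 10,
                   trial_ms: float = 200.0, seed: int = 0,
                   fixed_point: bool = False, input_weight: float = 2.0,
                   dt: float = 1.0,
                   deliver_plastic: bool = False) -> ValidationResult:
    """Run one validation protocol and its rate-based reference.

    The trial rate schedule is drawn once from ``seed`` and shared by all
    spiking repeats and the abstract reference; only the Poisson
    realizations differ between repeats.  The learned weight and bias are
    measured each millisecond; by default they are recorded without being
    fed back into the membrane equation, so both models see matched drive.
    """
    if protocol not in VALIDATION_PROTOCOLS:
        raise ValueError(f"unknown protocol {protocol!r}")
    rng_sched = np.random.default_rng(seed)
    rates_i, rates_j = _trial_rates(protocol, n_trials, params, rng_sched)
    coeffs = DerivedCoefficients.from_params(params)
    arith = FixedArithmetic(step=dt) if fixed_point else FloatArithmetic()

    t_end = n_trials * trial_ms
    steps = int(round(t_end / dt))
    trial_of_step = np.minimum((np.arange(steps) * dt // trial_ms).astype(int),
                               n_trials - 1)
    # calibrated input rates per trial
    in_i = np.array([_calibrated(r, neuron, input_weight, dt)
                     for r in rates_i])
    in_j = np.array([_calibrated(r, neuron, input_weight, dt)
                     for r in rates_j])

    w_runs = np.zeros((n_repeats, steps))
    ib_runs = np.zeros((n_repeats, steps))
    rasters = []
    for rep in range(n_repeats):
        rng = np.random.default_rng((seed + 1) * 1000 + rep)
        in_hits_i = rng.random(steps) < in_i[trial_of_step] * dt * 1e-3
        in_hits_j = rng.random(steps) < in_j[trial_of_step] * dt * 1e-3
        row = SynapticRow(receptor="ampa", params=params, coeffs=coeffs,
                          entries=[RowEntry(post_index=0, delay=dt)])
        hist = PostHistory(1)
        post_state = PreTraceState()
        prop = math.exp(-dt / neuron.tau_m)
        dsyn = math.exp(-dt / neuron.tau_ampa)
        da = math.exp(-dt / neuron.tau_a)
        v = [neuron.e_l, neuron.e_l]
        i_syn = [0.0, 0.0]
        i_a = [0.0, 0.0]
        pend = [0.0, 0.0]     # input PSC landing next step (1 ms delay)
        spikes_pre, spikes_post = [], []
        for s in range(steps):
            i_syn[0] += pend[0]
            i_syn[1] += pend[1]
            pend = [0.0, 0.0]
            if in_hits_i[s]:
                pend[0] = input_weight
            if in_hits_j[s]:
                pend[1] = input_weight
            t_now = (s + 1) * dt
            fired = [False, False]
            for n in (0, 1):
                v_inf = neuron.e_l + neuron.r_m * (i_syn[n] - i_a[n])
                v[n] = v_inf + (v[n] - v_inf) * prop
                i_syn[n] *= dsyn
                i_a[n] *= da
                if v[n] >= neuron.v_t:
                    v[n] = neuron.v_r
                    i_a[n] += neuron.alpha
                    fired[n] = True
            if fired[1]:  # postsynaptic spike: advance traces, record
                post_state = update_post_on_spike(post_state, t_now, params,
                                                  arith=arith)
                record_post_spike(hist, 0, t_now, post_state)
                spikes_post.append(t_now)
            if fired[0]:  # presynaptic spike: process the row
                process_row(row, t_now, hist, None, learning=True,
                            deliver=False, arith=arith, dt=dt)
                spikes_pre.append(t_now)
                if deliver_plastic:
                    pend[1] += row.entries[0].weight
            w_runs[rep, s], ib_runs[rep, s] = _sample_synapse(
                row, hist, post_state, t_now, params, coeffs, arith)
        rasters.append((np.array(spikes_pre), np.array(spikes_post)))

    # abstract reference on the same schedule
    rate_i_tr = rates_i[trial_of_step]
    rate_j_tr = rates_j[trial_of_step]
    ref = rate_based_reference(rate_i_tr, rate_j_tr, params, dt=dt)
    return ValidationResult(
        protocol=protocol, t=(np.arange(steps) + 1) * dt,
        w_runs=w_runs, ibeta_runs=ib_runs,
        w_abstract=ref["w"], ibeta_abstract=ref["i_beta"],
        rates_pre=rates_i, rates_post=rates_j, rasters=rasters)


# ---------------------------------------------------------------------------
# Sequence training and recall
# ---------------------------------------------------------------------------

def run_training(network: Network, sequence: Optional[Sequence[int]] = None,
                 epochs: int = 50, stim_ms: float = 100.0, seed: int = 0,
                 stim_rate: float = DEFAULT_STIM_RATE,
                 stim_weight: float = DEFAULT_STIM_WEIGHT,
                 history_capacity: int = 256,
                 record_vm: bool = False) -> AttractorSimulator:
    """Teach the network a sequence of minicolumn activations.

    Each epoch stimulates every sequence element for ``stim_ms`` so its
    pyramidal cells fire near f_max, with plastic AMPA/NMDA currents gated
    out of the membrane equation; the 65 Hz background and the bias
    current stay active.  Weights are evaluated and frozen onto the
    network at the end (``finalize_weights``).
    """
    cfg = network.config
    if sequence is None:
        sequence = list(range(cfg.minicolumns_per_hc))
    if any(m < 0 or m >= cfg.minicolumns_per_hc for m in sequence):
        raise ValueError("sequence indices outside the minicolumn range")
    sim = AttractorSimulator(network, seed=seed,
                             history_capacity=history_capacity,
                             record_vm=record_vm)
    schedule = StimulusSchedule()
    t = 0.0
    for _ in range(epochs):
        for m in sequence:
            schedule.append(StimulusItem(
                cells=network.minicolumn_members(m), start=t,
                duration=stim_ms, rate=stim_rate, weight=stim_weight))
            t += stim_ms
    sim.run(t, stimulus=schedule, learning=True, plastic_currents=False)
    sim.finalize_weights()
    network.sequence = list(sequence)
    return sim


def run_recall(network: Network, cue_minicolumn: int = 0,
               cue_ms: float = 50.0, duration: float = 1000.0,
               seed: int = 0, stim_rate: float = DEFAULT_STIM_RATE,
               stim_weight: float = DEFAULT_STIM_WEIGHT,
               record_vm: bool = True) -> AttractorSimulator:
    """Cue a (typically trained) network and let it run freely.

    Plastic currents are delivered with the learned weights, learning and
    the bias current are frozen, and the cue drives the chosen minicolumn
    for ``cue_ms``.  Returns the simulator with raster (and optionally
    membrane) recordings.
    """
    sim = AttractorSimulator(network, seed=seed, record_vm=record_vm)
    if getattr(network, "bias_current", None) is not None:
        sim.pyr.i_beta = network.bias_current.copy()
    cue = StimulusSchedule([StimulusItem(
        cells=network.minicolumn_members(cue_minicolumn), start=0.0,
        duration=cue_ms, rate=stim_rate, weight=stim_weight)])
    sim.run(duration, stimulus=cue, learning=False, plastic_currents=True,
            freeze_bias=True)
    return sim
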