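"""Leaky integrate-and-fire neurons with exponential PSCs, spike-frequency
adaptation and the BCPNN intrinsic bias current.

The membrane equation ``tau_m dV/dt = -(V - E_L) + R_m (I_s - I_a +
I_beta)`` is integrated with an exact exponential propagator: currents are
sampled at the start of each step and held constant, so the update is exact
for piecewise-constant input.  ``V`` is measured on an absolute scale with
the resting potential ``E_L`` equal to the reset ``V_r`` (-70 mV), the only
convention consistent with the absolute threshold values used by both
parameter presets.

There is no refractory period.  GABA weights are stored positive and
applied with negative sign to the summed current; NMDA is a plain
exponential current without voltage dependence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .kernel import compute_bias
from .params import BCPNNParams, DerivedCoefficients, NeuronParams

RECEPTORS = ("ampa", "gaba", "nmda")


@dataclass
class NeuronState:
    """State of a single neuron (used by the scalar API and unit tests)."""

    v_m: float = -70.0
    i_a: float = 0.0
    i_syn: dict = field(default_factory=lambda: dict.fromkeys(RECEPTORS, 0.0))
    i_beta: float = 0.0
    i_ext: float = 0.0
    z_star: float = 0.0
    p_star: float = 0.0


def deliver_psc(state: NeuronState, receptor: str, weight: float) -> None:
    """Add a PSC of amplitude ``weight`` (nA) to a receptor channel.

    The sign convention (GABA hyperpolarizes) is applied when currents are
    summed, not here, so weights are stored positive.
    """
    if receptor not in RECEPTORS:
        raise ValueError(f"unknown receptor {receptor!r}")
    state.i_syn[receptor] += weight


def total_current(state: NeuronState) -> float:
    return (state.i_syn["ampa"] + state.i_syn["nmda"] - state.i_syn["gaba"]
            - state.i_a + state.i_beta + state.i_ext)


def step_neuron(state: NeuronState, params: NeuronParams,
                dt: float = 1.0) -> bool:
    """Advance one neuron by ``dt`` ms; returns True if it spiked.

    Exact exponential update: the membrane relaxes toward ``e_l + r_m I``
    with the start-of-step currents, then every current decays by its own
    per-step factor.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    i_total = total_current(state)
    v_inf = params.e_l + params.r_m * i_total
    prop = math.exp(-dt / params.tau_m)
    state.v_m = v_inf + (state.v_m - v_inf) * prop
    for r in RECEPTORS:
        state.i_syn[r] *= math.exp(-dt / params.tau_syn(r))
    state.i_a *= math.exp(-dt / params.tau_a)
    if state.v_m >= params.v_t:
        state.v_m = params.v_r
        state.i_a += params.alpha
        return True
    return False


def update_bias(state: NeuronState, bcpnn: BCPNNParams, dt: float,
                spiked: bool = False,
                coeffs: DerivedCoefficients | None = None) -> None:
    """Advance the neuron's own (postsynaptic) BCPNN traces by one step and
    refresh the intrinsic bias current ``beta_gain ln(P_j + eps)``."""
    if coeffs is None:
        coeffs = DerivedCoefficients.from_params(bcpnn)
    state.z_star *= math.exp(-dt / bcpnn.tau_zj)
    state.p_star *= math.exp(-dt / bcpnn.tau_p)
    if spiked:
        state.z_star += 1.0
        state.p_star += 1.0
    p_j = coeffs.a_j * (state.z_star - state.p_star)
    state.i_beta = compute_bias(p_j, bcpnn)


class NeuronPopulation:
    """A vectorized population of identical LIF neurons.

    Holds membrane, adaptation, per-receptor synaptic currents and, when a
    plasticity parameter set is supplied, the per-neuron bias traces.
    """

    def __init__(self, n: int, params: NeuronParams,
                 bias: BCPNNParams | None = None) -> None:
        if n <= 0:
            raise ValueError("population size must be positive")
        self.n = n
        self.params = params
        self.bias_params = bias
        self._bias_coeffs = (
            DerivedCoefficients.from_params(bias) if bias is not None else None)
        self.v_m = np.full(n, params.e_l)
        self.i_a = np.zeros(n)
        self.i_syn = {r: np.zeros(n) for r in RECEPTORS}
        self.i_beta = np.zeros(n)
        self.i_ext = np.zeros(n)
        self.z_star = np.zeros(n)
        self.p_star = np.zeros(n)
        #: when set, the bias current is held at its current value (used
        #: during recall, where all learned quantities are frozen)
        self.freeze_bias = False
        if bias is not None:
            # silent neurons sit at the floor bias beta_gain ln(eps)
            self.i_beta[:] = bias.beta_gain * math.log(bias.eps)

    def deliver(self, receptor: str, amounts: np.ndarray) -> None:
        """Add accumulated PSC amplitudes (nA, positive) per neuron."""
        if receptor not in RECEPTORS:
            raise ValueError(f"unknown receptor {receptor!r}")
        self.i_syn[receptor] += amounts

    def step(self, dt: float = 1.0,
             force: np.ndarray | None = None) -> np.ndarray:
        """Advance the whole population by ``dt``; returns the indices of
        neurons that spiked.

        ``force`` lists neurons made to spike this step regardless of their
        membrane state (rate-forcing stimulus sources).
        """
        p = self.params
        i_total = (self.i_syn["ampa"] + self.i_syn["nmda"]
                   - self.i_syn["gaba"] - self.i_a + self.i_beta + self.i_ext)
        v_inf = p.e_l + p.r_m * i_total
        prop = math.exp(-dt / p.tau_m)
        self.v_m = v_inf + (self.v_m - v_inf) * prop
        for r in RECEPTORS:
            self.i_syn[r] *= math.exp(-dt / p.tau_syn(r))
        self.i_a *= math.exp(-dt / p.tau_a)
        if force is not None and force.size:
            self.v_m[force] = p.v_t
        spiked = np.flatnonzero(self.v_m >= p.v_t)
        if spiked.size:
            self.v_m[spiked] = p.v_r
            self.i_a[spiked] += p.alpha
        if self.bias_params is not None and not self.freeze_bias:
            self._step_bias(dt, spiked)
        return spiked

    def _step_bias(self, dt: float, spiked: np.ndarray) -> None:
        b = self.bias_params
        self.z_star *= math.exp(-dt / b.tau_zj)
        self.p_star *= math.exp(-dt / b.tau_p)
        if spiked.size:
            self.z_star[spiked] += 1.0
            self.p_star[spiked] += 1.0
        p_j = self._bias_coeffs.a_j * (self.z_star - self.p_star)
        self.i_beta = b.beta_gain * np.log(p_j + b.eps)
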