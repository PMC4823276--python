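"""Parameter containers for the BCPNN learning rule and the LIF neuron model.

The BCPNN rule estimates the firing probabilities of a presynaptic unit
(``P_i``), a postsynaptic unit (``P_j``) and their coactivation (``P_ij``)
from exponentially smoothed spike traces, and maps them onto a synaptic
weight ``w = w_gain * ln((P_ij + eps^2) / ((P_i + eps)(P_j + eps)))`` and an
intrinsic bias current ``I_beta = beta_gain * ln(P_j + eps)``.

All times are kept in milliseconds internally.  ``f_max`` is stored in Hz
and converted by 1e-3 wherever it multiplies a millisecond quantity, which
makes the lowest attainable probability estimate come out literally as
``eps = 1000 / (f_max * tau_p[ms])``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace


@dataclass(frozen=True)
class BCPNNParams:
    """Constants of the BCPNN learning rule.

    Parameters
    ----------
    f_max : float
        Maximum allowed firing rate in Hz.  Sustained firing at ``f_max``
        drives the probability estimates to 1.
    tau_zi, tau_zj : float
        Pre- and postsynaptic primary (Z) trace time constants in ms.  They
        set the time window within which correlations are detected.
    tau_p : float
        Probability (P) trace time constant in ms; the memory timescale.
    spike_duration : float
        Duration Delta-t assigned to a spike in ms (fixed at 1 ms).
    w_gain : float
        Weight gain in nA; scales the log-odds weight into a PSC amplitude.
    beta_gain : float
        Bias gain in nA; scales the log-probability bias into a current.
    """

    f_max: float
    tau_zi: float
    tau_zj: float
    tau_p: float
    spike_duration: float = 1.0
    w_gain: float = 1.0
    beta_gain: float = 1.0

    def __post_init__(self) -> None:
        if self.f_max <= 0:
            raise ValueError("f_max must be positive")
        for name in ("tau_zi", "tau_zj", "tau_p", "spike_duration"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.tau_p == self.tau_zi or self.tau_p == self.tau_zj:
            # a_i / a_j have a removable singularity there; no configuration
            # of interest needs it, so reject outright.
            raise ValueError("tau_p must differ from tau_zi and tau_zj")
        if not 0.0 < self.eps < 1.0:
            raise ValueError(
                "eps = 1000/(f_max*tau_p) must lie in (0, 1); "
                f"got {self.eps} for f_max={self.f_max}, tau_p={self.tau_p}"
            )

    @property
    def eps(self) -> float:
        """Lowest attainable probability estimate, 1000/(f_max * tau_p[ms])."""
        return 1000.0 / (self.f_max * self.tau_p)

    @property
    def f_max_ms(self) -> float:
        """f_max expressed per millisecond."""
        return self.f_max * 1e-3


@dataclass(frozen=True)
class DerivedCoefficients:
    """Coefficients of the closed-form (star trace) reconstruction.

    With star traces receiving unit increments at spikes, the probability
    traces of the original ODE system are recovered as

        P_i  = a_i  * (Z_i* - P_i*)
        P_j  = a_j  * (Z_j* - P_j*)
        P_ij = a_ij * (Z_i* Z_j* - P_ij*)

    ``a_j`` follows from ``a_i`` by the i<->j symmetry of the rule.  All
    values are computed with times in ms and f_max converted to 1/ms.
    """

    tau_zij: float
    a_i: float
    a_j: float
    a_ij: float

    @classmethod
    def from_params(cls, params: BCPNNParams) -> "DerivedCoefficients":
        fdt = params.f_max_ms * params.spike_duration
        tau_zij = 1.0 / (1.0 / params.tau_zi + 1.0 / params.tau_zj)
        if tau_zij == params.tau_p:
            raise ValueError("tau_zij must differ from tau_p")
        a_i = 1.0 / (fdt * (params.tau_zi - params.tau_p))
        a_j = 1.0 / (fdt * (params.tau_zj - params.tau_p))
        a_ij = 1.0 / (
            fdt * fdt * (params.tau_zi + params.tau_zj) * (tau_zij - params.tau_p)
        )
        return cls(tau_zij=tau_zij, a_i=a_i, a_j=a_j, a_ij=a_ij)


@dataclass(frozen=True)
class NeuronParams:
    """Leaky integrate-and-fire neuron with exponential PSCs and adaptation.

    The membrane potential relaxes toward ``e_l + r_m * I`` with time
    constant ``tau_m`` where ``r_m = tau_m / c_m``; crossing ``v_t`` emits a
    spike, resets to ``v_r`` and increments the (hyperpolarizing) adaptation
    current by ``alpha``.
    """

    tau_m: float = 10.0          # ms
    c_m: float = 250.0           # pF
    v_t: float = -55.4           # mV
    v_r: float = -70.0           # mV
    e_l: float = -70.0           # mV, resting potential (== v_r by convention)
    alpha: float = 0.0           # nA adaptation increment
    tau_a: float = 300.0         # ms adaptation time constant
    tau_ampa: float = 2.5        # ms
    tau_gaba: float = 5.0        # ms
    tau_nmda: float = 150.0      # ms

    def __post_init__(self) -> None:
        for name in ("tau_m", "c_m", "tau_a", "tau_ampa", "tau_gaba", "tau_nmda"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if not self.v_t > self.v_r:
            raise ValueError("v_t must exceed v_r")

    @property
    def r_m(self) -> float:
        """Input resistance in MOhm (so that MOhm * nA = mV)."""
        return 1000.0 * self.tau_m / self.c_m

    def tau_syn(self, receptor: str) -> float:
        try:
            return {"ampa": self.tau_ampa, "gaba": self.tau_gaba,
                    "nmda": self.tau_nmda}[receptor]
        except KeyError:
            raise ValueError(f"unknown receptor {receptor!r}") from None


# ---------------------------------------------------------------------------
# Named presets
# ---------------------------------------------------------------------------

#: Two-neuron validation experiment: plastic AMPA synapse.
VALIDATION_AMPA = BCPNNParams(
    f_max=50.0, tau_zi=10.0, tau_zj=10.0, tau_p=1000.0,
    w_gain=1.0, beta_gain=1.0,
)

#: Modular attractor network: auto-associative AMPA pathway.  w_gain is the
#: numerator of the 0.546/N_HC nA scaling and must be divided by the
#: hypercolumn count of the instantiated network.
ATTRACTOR_AMPA = BCPNNParams(
    f_max=20.0, tau_zi=5.0, tau_zj=5.0, tau_p=2000.0,
    w_gain=0.546, beta_gain=0.05,
)

#: Modular attractor network: temporally asymmetric NMDA pathway.  The long
#: time constant sits on the presynaptic Z trace so that P_ij* increments at
#: postsynaptic spikes (by Z_i*) strengthen forward, pre-before-post pairs
#: and sequences replay in the trained order.
ATTRACTOR_NMDA = BCPNNParams(
    f_max=20.0, tau_zi=150.0, tau_zj=5.0, tau_p=2000.0,
    w_gain=0.114, beta_gain=0.05,
)

#: Symmetric NMDA variant used for the kernel-shape comparison.
ATTRACTOR_NMDA_SYMMETRIC = replace(ATTRACTOR_NMDA, tau_zj=ATTRACTOR_NMDA.tau_zi)

#: Validation-network neuron (adaptation disabled).
VALIDATION_NEURON = NeuronParams(
    tau_m=10.0, c_m=250.0, v_t=-55.4, v_r=-70.0, e_l=-70.0,
    alpha=0.0, tau_a=300.0, tau_ampa=2.5,
)

#: Attractor-network neuron.
ATTRACTOR_NEURON = NeuronParams(
    tau_m=20.0, c_m=250.0, v_t=-50.0, v_r=-70.0, e_l=-70.0,
    alpha=0.15, tau_a=300.0, tau_ampa=5.0, tau_gaba=5.0, tau_nmda=150.0,
)

PRESETS = {
    "validation_ampa": VALIDATION_AMPA,
    "attractor_ampa": ATTRACTOR_AMPA,
    "attractor_nmda": ATTRACTOR_NMDA,
    "attractor_nmda_symmetric": ATTRACTOR_NMDA_SYMMETRIC,
}

NEURON_PRESETS = {
    "validation": VALIDATION_NEURON,
    "attractor": ATTRACTOR_NEURON,
}


def load_bcpnn_params(source) -> BCPNNParams:
    """Load a plasticity parameter set.

    ``source`` may be a preset name, a mapping of field names, or a path
    to a JSON file containing such a mapping (optionally with a
    ``"preset"`` key naming a base preset to override).
    """
    import json
    from pathlib import Path

    if isinstance(source, BCPNNParams):
        return source
    if isinstance(source, str) and source in PRESETS:
        return PRESETS[source]
    if isinstance(source, (str, Path)):
        source = json.loads(Path(source).read_text())
    if not isinstance(source, dict):
        raise TypeError(f"cannot load parameters from {source!r}")
    fields = dict(source)
    base = fields.pop("preset", None)
    if base is not None:
        return replace(PRESETS[base], **fields)
    return BCPNNParams(**fields)
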