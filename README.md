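# ebcpnn

Event-driven BCPNN synaptic plasticity and modular attractor-network
simulation in Python.

Spike-based BCPNN (Bayesian Confidence Propagation Neural Network) is a
plasticity rule that turns running estimates of firing probabilities into
synaptic weights and intrinsic excitability.  Spike trains are smoothed
by fast Z traces (correlation window, τ_z) feeding slow P traces (memory,
τ_p) that estimate P_i, P_j and the coactivation P_ij; these map onto a
log-odds synaptic weight and a log-probability bias current

    w_ij = w_gain · ln((P_ij + ε²)/((P_i + ε)(P_j + ε)))
    I_βj = β_gain · ln(P_j + ε),          ε = 1000/(f_max · τ_p[ms])

Evaluating these every timestep for every synapse is prohibitively
expensive at scale.  This package implements the event-driven
reformulation used on digital neuromorphic hardware: "star traces" with
unit spike increments and pure exponential decay, evaluated only when
spikes reach a synapse, with deferred processing of postsynaptic spike
history, per-neuron delay ring buffers, and an optional emulation of the
16-bit fixed-point trace arithmetic (6 integer / 9 fractional bits, LUT
exponentials and logarithms) such hardware uses.  On top of the kernel
sit a leaky integrate-and-fire neuron model with adaptation, a modular
cortical attractor network (hypercolumns of winner-take-all minicolumns,
plastic AMPA/NMDA pathways between all pyramidal cells), and the three
experiment protocols of the underlying study: validation of the spiking
rule against its abstract rate-based counterpart, temporal-sequence
training, and cued sequence replay.  It is intended for computational
neuroscientists studying Hebbian-Bayesian plasticity and sequential
attractor dynamics, and for implementers of event-driven learning rules
who need a bit-faithful software reference.

## Worked example

Validate the event-driven spiking rule against the deterministic
rate-based reference on the correlated and anti-correlated protocols
(two LIF neurons, one plastic AMPA synapse, ten 200 ms trials, ten
seeded repetitions):

```bash
$ ebcpnn validate --protocol correlated --seed 3
final weight: spiking +0.4384 +/- 0.0733 nA, abstract +0.3943 nA

$ ebcpnn validate --protocol anti_correlated --seed 3
final weight: spiking -2.0730 +/- 0.6763 nA, abstract -1.9041 nA
```

Correlated firing potentiates the synapse and anti-correlated firing
depresses it; the abstract reference lies within one standard deviation
of the spiking runs throughout each trajectory (the command also writes
the full trajectories to `validation_<protocol>.txt`).

Teach a 4-hypercolumn network (5,000 neurons, 3.2 million plastic
synapses) a 10-minicolumn sequence and replay it from a 50 ms cue
(about half a minute altogether):

```bash
$ ebcpnn train --n-hc 4 --epochs 10 --seed 0 --out-prefix trained
$ ebcpnn recall --n-hc 4 --seed 0 --weights trained_connectivity.csv
minicolumn peak times (ms): 145 235 395 555 765 935 1105 1335 1495 nan
```

The minicolumn population-rate peaks occur in exactly the trained order
(the tenth element falls beyond this run's 1.5 s window).  Replay in the
trained direction is carried by the temporally asymmetric NMDA pathway:
its long presynaptic Z trace (150 ms vs 5 ms postsynaptic) strengthens
forward connections between consecutive sequence elements, which
`ebcpnn kernels` renders as a minicolumn-to-minicolumn weight matrix
with a dominant superdiagonal.  With `--symmetric` (equal time
constants) the learned kernel is symmetric instead, and the aligned
membrane-potential analysis (`ebcpnn align-vm`) loses the pronounced
post-peak hyperpolarization that the asymmetric network shows when the
sequence moves on.

Analytic properties are available without simulation: `ebcpnn census`
prints the architecture census (e.g. 20,000 neurons and 5.1×10⁷ plastic
synapses at 16 hypercolumns), and `ebcpnn selftest` runs the
oracle-equivalence and fixed-point sanity checks.

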