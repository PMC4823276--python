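# Methods

## The learning rule

The package implements spike-based BCPNN (Bayesian Confidence Propagation
Neural Network) plasticity.  Pre- and postsynaptic spike trains are
smoothed by two cascaded exponential filters: fast **Z traces** (time
constants `tau_zi`, `tau_zj`, milliseconds to ~hundreds of milliseconds)
set the window within which correlations are detected, and slow **P
traces** (`tau_p`, seconds) integrate them into running probability
estimates `P_i`, `P_j` and the coactivation `P_ij`,

    tau_z dZ/dt = S/(f_max Δt) − Z,
    tau_p dP_i/dt = Z_i − P_i,   tau_p dP_ij/dt = Z_i Z_j − P_ij,

with spikes entering as Dirac impulses of area `1/(f_max Δt)` and
`Δt = 1 ms` the nominal spike duration.  Sustained firing at the maximum
rate `f_max` drives the probabilities to 1; the lowest attainable estimate
is `eps = 1000/(f_max · tau_p[ms])`.  The probabilities map onto a synaptic
weight and an intrinsic excitability (bias) current,

    w    = w_gain    · ln((P_ij + eps²) / ((P_i + eps)(P_j + eps)))   [nA]
    I_β  = beta_gain · ln(P_j + eps)                                   [nA]

(natural logarithm throughout).  Negative weights are legal and are
delivered as negative current-based PSCs.

### Event-driven (star trace) form

Because the cascade is linear, the whole state can be re-parameterized
into *star traces* that receive **unit** increments at spikes and decay
purely exponentially in between:

    Z_i*(t) = Z_i*(t_last) e^(−Δ/tau_zi) + S_i(t)
    P_i*(t) = P_i*(t_last) e^(−Δ/tau_p)  + S_i(t)
    P_ij*(t) = P_ij*(t_last) e^(−Δ/tau_p) + S_i(t) Z_j*(t) + S_j(t) Z_i*(t)

and the probabilities are recovered linearly:

    P_i  = a_i (Z_i* − P_i*),          a_i  = 1/(f_max (tau_zi − tau_p))
    P_j  = a_j (Z_j* − P_j*),          a_j  = 1/(f_max (tau_zj − tau_p))
    P_ij = a_ij (Z_i* Z_j* − P_ij*),   a_ij = 1/(f_max² (tau_zi+tau_zj)(tau_zij − tau_p))

with `tau_zij = (1/tau_zi + 1/tau_zj)^−1`.  Three derivations are worth
recording because the printed forms leave them open:

* `a_j` follows from `a_i` by the i↔j symmetry of the P_j equation.
* The grouping of `a_ij` above is the one (and the only one) that makes
  the star-trace reconstruction *exactly* equal to the ODE solution; the
  test suite asserts the equivalence against brute-force Euler
  integration at 10⁻² ms steps to better than 10⁻³ relative.
* `P_ij*` must be incremented at **both** pre- and postsynaptic spikes
  (by the opposite side's Z*): the coactivation drive `Z_i Z_j` jumps at
  both kinds of events.  With only the presynaptic term the event-driven
  and time-driven forms disagree.

Units: all times are milliseconds internally; `f_max` is stored in Hz and
converted by 10⁻³ where it multiplies millisecond quantities, which makes
the `eps` formula above hold literally.

All star traces start at 0, so initial weights are 0 and the initial bias
is `beta_gain ln(eps)`.  The reconstruction is continuous across spikes
(the increments cancel algebraically), so the instant at which a weight
is evaluated relative to a spike's increments is a convention; we
evaluate after the increments.  `tau_p = tau_z` is rejected at parameter
validation (the coefficients have a removable singularity there that no
configuration of interest needs).

### Deferred processing (the event engine)

Synapses are stored in per-presynaptic-neuron rows holding the
presynaptic star traces and the last presynaptic spike time `t_old`.
Each postsynaptic neuron pushes `(t_j, Z_j*)` onto a history queue when
it fires.  When a presynaptic spike arrives at `t`, each synapse of the
row replays the postsynaptic spikes in the half-open window `(t_old, t]`
(so a post spike simultaneous with the previous pre spike is applied
exactly once; simultaneous pre/post events at `t` are applied
post-then-pre, which the continuity property makes irrelevant), applies
the pre-spike increment, reconstructs the probabilities and recomputes
the weight, and schedules delivery through a per-neuron, per-receptor
ring buffer after the synaptic delay.  Delays are rounded to the 1 ms
grid with a 1-step minimum and apply to current delivery only; the
plasticity operates on emission times.

Two implementations share this algorithm: a reference object-oriented
one (`ebcpnn.engine`, also usable with the fixed-point arithmetic
backend) and compiled flat-array kernels (`ebcpnn._fastkernels`) used by
the network simulator.  During training the plastic currents are gated
out of the membrane equation (see Protocols), so the fast path defers
*weight evaluation* entirely to a final sweep at the end of training,
updating only the coactivation traces per spike; the tests verify that
both paths agree with the time-driven oracle synapse-by-synapse.  The
fast path's history is a 256-entry ring per neuron and pathway; overruns
are counted and are zero in all shipped configurations.  The reference
engine's history is unbounded with explicit pruning, with an optional
fixed-capacity mode (drop-oldest plus divergence counter) mirroring
memory-constrained hardware.

## Fixed-point emulation

Neuromorphic digital cores without an FPU store the traces in a signed
16-bit fixed-point word with 6 integer and 9 fractional bits (S6.9,
maximum 64 − 2⁻⁹, resolution 2⁻⁹) and evaluate transcendentals through
lookup tables.  The emulation quantizes every trace operation to that
grid: encode/multiply round to nearest (ties to even; the hardware's
rounding is unstated, so truncation is available as an option) and
saturate on overflow (wrap-around would corrupt the probability
semantics).  Exponential decay uses one precomputed table per time
constant, indexed by elapsed timesteps and truncated at the first entry
that rounds to zero; `ln` uses a 256-entry table over [1, 2) with linear
interpolation after normalizing the argument as `y·2^n`, which meets the
2⁻⁹ error budget of the fractional bits.

Under sustained firing at `f_max` the P* trace converges to
`1/(1 − e^(−1/(f_max·tau_p)))` (geometric series of unit increments), so
the format bounds the representable memory time constant:
`tau_p < 1/(f_max ln(M/(M−1)))` with `M` the format maximum — 3.17 s at
20 Hz and 1.27 s at 50 Hz for S6.9.  The opposite failure mode is
underflow: after long silent periods the decaying P* terms approach the
2⁻⁹ resolution, the relative quantization error blows up, and the log
mapping amplifies it — the fixed- and float-mode weights diverge most
for muted units, then collapse together once the traces underflow
completely.  Both effects are covered by tests.  Two practical notes:
slowly decaying per-millisecond factors (e.g. `e^(−1/2000)`) are
themselves poorly representable in S6.9, so fixed-mode traces decay
slightly too fast — a real property of this arithmetic, visible as a
small systematic weight offset; and the fixed-point mode is wired
through the kernel/engine/validation path (where the float-vs-fixed
comparison is defined), not through the compiled network simulator.

## Neuron model

Leaky integrate-and-fire with exponential current-based PSCs and
spike-frequency adaptation:

    tau_m dV/dt = −(V − E_L) + R_m (I_ampa + I_nmda − I_gaba − I_a + I_β)

with `R_m = tau_m/C_m`.  Threshold crossing emits a spike, resets `V` to
`V_r` and increments the adaptation current `I_a` by `alpha` (decay
`tau_a`).  The membrane equation is interpreted relative to a resting
potential `E_L := V_r = −70 mV` — the only convention consistent with the
absolute thresholds of both parameter sets.  Integration is an exact
exponential propagator on a 1 ms grid with currents sampled at the start
of each step; it is exact for piecewise-constant input (asserted to
1e-9 mV).  There is no refractory period and NMDA carries no voltage
dependence (both omitted in the modeled reduction).  GABA weights are
stored positive and applied negatively.  Parameter presets: the
two-neuron validation set (tau_m 10 ms, C_m 250 pF, V_t −55.4 mV,
adaptation off, tau_AMPA 2.5 ms) and the attractor set (tau_m 20 ms,
V_t −50 mV, alpha 0.15 nA, tau_a 300 ms, tau_AMPA/GABA 5 ms,
tau_NMDA 150 ms).

Each pyramidal neuron also integrates its own postsynaptic star traces
time-driven (using the AMPA plasticity time constants) to maintain the
bias current `I_β` online.

## Network architecture

`N_HC` hypercolumns on a grid (square when `N_HC` is a perfect square,
else row-major fill of the smallest enclosing square), each with 250
basket cells and 1000 pyramidal cells in 10 minicolumns.  Local circuitry
(10 % Bernoulli connectivity, autapses excluded, at most one synapse per
ordered pair and receptor): pyramidal→basket 0.4 nA AMPA, basket→pyramidal
and basket→basket 2 nA GABA — a winner-take-all motif.  All pyramidal
pairs across the network are additionally connected at 10 % by two
independent plastic pathways, AMPA (`tau_zi = tau_zj = 5 ms`,
`w_gain = 0.546/N_HC nA`) and NMDA (`w_gain = 0.114/N_HC nA`), both with
`f_max = 20 Hz`, `tau_p = 2 s`, `beta_gain = 0.05 nA`.  Delays follow
`d_norm·dist/V + 1 ms` between hypercolumn grid coordinates
(V = 0.2 mm/ms, d_norm = 0.75 mm), so local connections have 1 ms delays.

The NMDA presets deserve a note.  The temporally **asymmetric**
configuration uses `tau_zi = 150 ms, tau_zj = 5 ms`: since `P_ij*` is
incremented at postsynaptic spikes by the *presynaptic* `Z_i*`, a long
presynaptic trace strengthens pre-before-post (forward, m→m+1) pairs,
which is what chains the sequence in the trained direction.  (The
opposite assignment would strengthen backward pairs; the increment
algebra makes this unambiguous.)  The **symmetric** variant sets
`tau_zj = tau_zi = 150 ms`.

## Protocols (the synthetic-data source)

All inputs are generated: there is no external data.  Poisson sources
are realized by per-timestep Bernoulli thinning from seeded generators,
so every run is reproducible from its seed.

**Validation (two neurons).**  Two LIF cells joined by one plastic AMPA
synapse (Table-style validation parameters: `f_max = 50 Hz`,
`tau_z = 10 ms`, `tau_p = 1 s`, gains 1 nA) are driven through
one-to-one 2 nA AMPA inputs for ten 200 ms trials under five activation
patterns: correlated (both at `f_max` or both at the floor rate, one
coin per trial), independent (independent coins), anti-correlated
(exactly one high), both muted, post muted.  "Muted" means the lowest
normalized rate `eps·f_max` (= 1 Hz here); firing literally at 0.02 Hz
would be indistinguishable within 200 ms trials and break the
probability mapping.  The input Poisson rate needed to make a cell fire
at a nominal rate is calibrated once by bisection on the isolated cell's
input-output curve.  A deterministic **rate-based reference** — the same
ODEs driven by the normalized rates `r(t)/f_max`, this package's
reconstruction of the earlier non-spiking implementations — shares the
identical trial schedule.  The learned weight and bias are *measured*
every millisecond but not fed back into the membranes by default: with
`beta_gain = 1 nA` the initial bias floor (−3.9 nA, i.e. −156 mV through
40 MΩ) would silence the postsynaptic cell and destroy the rate-matched
comparison the protocol exists for.  Both feedbacks can be enabled.

**Sequence training.**  Each epoch stimulates the 10 minicolumns one
after another for 100 ms each, all hypercolumns together; 65 Hz Poisson
background runs throughout.  The stimulus is a per-cell rate-forcing
Poisson source at `f_max`: each source spike makes its target fire once,
so stimulated cells fire at exactly the nominal average rate, the
training raster is identical across plasticity configurations (a premise
of the kernel-shape comparison), and the refractory-free LIF cannot
multi-spike on strong stimulus PSCs.  (PSC-mode stimulation is
available.)  During training the plastic AMPA/NMDA currents are gated
out of the membrane equation — weights learn online without disturbing
the regime — while local WTA circuitry, background and the bias current
stay active.  At the end of training every synapse is brought up to date
and its weight frozen.  The background PSC amplitude is not specified by
the architecture; the default of 0.5 nA keeps the pyramidal baseline
near the probability floor (~0.5 Hz ≈ `eps·f_max`) without driving tonic
basket inhibition.

**Recall.**  A 50 ms forcing stimulus at `f_max` is applied to the first
minicolumn; learning and the bias current are frozen (replay analysis is
only well-defined on a fixed network) and the learned plastic currents
are delivered.  Desk-scale defaults used by the test suite: `N_HC = 4`
(5,000 neurons, 3.2×10⁶ plastic synapses) and 10 training epochs; the
full-size regime (`N_HC = 16`, 50 epochs) is a command-line option.

## Analyses

* **Kernel matrices**: mean plastic weight from minicolumn position a to
  position b, pooled over hypercolumns; asymmetry summarized as
  `‖K−Kᵀ‖_F/‖K+Kᵀ‖_F`.
* **Peak-rate times**: boxcar-smoothed (default 10 ms) population rate
  per minicolumn, argmax with earliest-bin tie-breaking; minicolumns
  below a spike-count or peak-rate threshold (default 50 Hz per cell —
  far above the ~1 Hz baseline, far below the several-hundred-Hz
  attractor bursts) are flagged missing so that background leakage does
  not produce spurious "peaks".
* **Aligned membranes**: per-cell traces aligned to their minicolumn's
  peak time, averaged within minicolumns, then across minicolumns, and
  normalized so 0 is the spike threshold and −1 the minimum of the
  averaged sample.  The after-peak behaviour is summarized by the
  **post-peak drop**: the mean over (0, +300 ms] minus the level at the
  peak.  The 300 ms window reflects this scaled-down model's ~150–200 ms
  attractor dwell time; span and smoothing are configurable.

## What the tests do and do not show

The oracle-equivalence, continuity, stationarity and representability
tests validate the arithmetic of the learning rule exhaustively — those
results transfer to any spike trains, not just the generated ones.  The
protocol-level results are statements about this particular synthetic
regime: homogeneous Poisson backgrounds, forced-rate stimulation and
current-based synapses.  In the desk-scale recall regime the attractor
dynamics are strongly oscillatory and synchronized, with deep
current-based hyperpolarization swings (current-based GABA has no
reversal potential to clamp them); replay order and the membrane-
potential signatures are robust across seeds, but absolute voltage
excursions are not biologically calibrated.  In the symmetric
configuration at this scale the cued attractor is not displaced by its
neighbours — the extreme form of the "slower post-peak decrease" — so
the symmetric/asymmetric comparison is made on the post-peak *drop*,
which is the claim the analysis is after.  Real cortical data would add
heterogeneous cells, conductance synapses, refractoriness and structured
background, none of which are modeled here.

## Numerical choices

Explicit Euler at 10⁻² ms is the ground-truth integrator (error
O(dt/tau_z); the equivalence tests also confirm the error shrinks
linearly as dt→0); the event-driven path is closed-form and exact.
Network simulation runs on a 1 ms grid.  Spike times are grid times;
simultaneous events process post-before-pre; delays round to the nearest
step with a 1-step minimum.  Degenerate parameters (`tau_p = tau_z`,
`eps ∉ (0,1)`, non-positive time constants) are rejected at construction.
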