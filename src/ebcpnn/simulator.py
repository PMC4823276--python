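"""Time-driven network simulation with event-driven plastic synapses.

Neurons advance on a fixed 1 ms grid (exact exponential propagators);
synapses are touched only when their presynaptic neuron fires, following
the deferred row-processing algorithm (see :mod:`ebcpnn.engine` for the
reference formulation and :mod:`ebcpnn._fastkernels` for the compiled
loops used here).  Spikes reach their targets through per-neuron,
per-receptor input ring buffers indexed by delay timesteps.

Training runs gate the plastic AMPA/NMDA currents out of the membrane
equation (weights are learned online but do not disturb the drive), so
weight evaluation can be deferred wholesale to ``finalize_weights``.
Recall runs deliver the frozen learned weights with learning disabled.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from . import _fastkernels as fk
from .network import Network
from .neuron import NeuronPopulation
from .params import DerivedCoefficients

__all__ = ["StimulusItem", "AttractorSimulator"]


@dataclass(frozen=True)
class StimulusItem:
    """Poisson drive to a set of cells over a time window.

    ``rate`` is the rate (Hz) of the independent per-cell Poisson source;
    each source spike injects ``weight`` nA into the AMPA channel.
    Times are relative to the start of the ``run`` call.
    """

    cells: np.ndarray
    start: float
    duration: float
    rate: float
    weight: float = 2.0
    #: "force" makes every source spike fire its target cell directly
    #: (rate-forcing source); "psc" injects an AMPA PSC of ``weight`` nA.
    mode: str = "force"

    def __post_init__(self) -> None:
        if self.start < 0 or self.duration < 0 or self.rate < 0:
            raise ValueError("stimulus times and rate must be non-negative")
        if self.mode not in ("force", "psc"):
            raise ValueError(f"unknown stimulus mode {self.mode!r}")


class _PlasticState:
    """Flat event-driven state of one plastic pathway."""

    def __init__(self, pathway, n_pre: int, n_post: int, capacity: int):
        self.pathway = pathway
        self.params = pathway.params
        self.coeffs = DerivedCoefficients.from_params(pathway.params)
        self.row_t = np.zeros(n_pre)
        self.row_z = np.zeros(n_pre)
        self.row_p = np.zeros(n_pre)
        self.pj_z = np.zeros(n_post)
        self.pj_p = np.zeros(n_post)
        self.pj_t = np.zeros(n_post)
        self.cap = capacity
        self.hist_t = np.zeros((n_post, capacity))
        self.hist_z = np.zeros((n_post, capacity))
        self.hist_cnt = np.zeros(n_post, dtype=np.int64)
        self.dropped = np.zeros(1, dtype=np.int64)


class AttractorSimulator:
    """Simulate a built :class:`~ebcpnn.network.Network`.

    Parameters
    ----------
    network : Network
        The network to simulate (mutated in place by ``finalize_weights``).
    seed : int
        Seed of the simulator's private random generator (background and
        stimulus Poisson sources).
    history_capacity : int
        Length of the per-neuron postsynaptic history ring.
    record_vm : bool
        Record every pyramidal membrane potential each step (float32).
    """

    def __init__(self, network: Network, seed: int = 0,
                 history_capacity: int = 256,
                 record_vm: bool = False) -> None:
        cfg = network.config
        self.net = network
        self.cfg = cfg
        self.dt = cfg.dt
        self.rng = np.random.default_rng(seed)
        self.pyr = NeuronPopulation(cfg.n_pyramidal, cfg.neuron_params,
                                    bias=cfg.ampa_params)
        self.basket = NeuronPopulation(cfg.n_basket, cfg.neuron_params)
        max_delay = max(int(p.delay_steps.max()) if p.n_synapses else 1
                        for p in network.pathways.values())
        self.nslots = max_delay + 2
        self.rb = {
            "pyr": {r: np.zeros((cfg.n_pyramidal, self.nslots))
                    for r in ("ampa", "gaba", "nmda")},
            "basket": {r: np.zeros((cfg.n_basket, self.nslots))
                       for r in ("ampa", "gaba")},
        }
        self.head = 0
        self.t = 0.0
        self.plastic = {
            name: _PlasticState(pw, cfg.n_pyramidal, cfg.n_pyramidal,
                                history_capacity)
            for name, pw in network.pathways.items() if pw.plastic}
        self.record_vm = record_vm
        self._raster_t: list[np.ndarray] = []
        self._raster_id: list[np.ndarray] = []
        self._vm: list[np.ndarray] = []
        self._vm_t: list[float] = []

    # ------------------------------------------------------------------
    def run(self, duration: float, stimulus: Iterable[StimulusItem] = (),
            learning: bool = True, plastic_currents: bool = False,
            freeze_bias: bool = False) -> None:
        """Advance the simulation by ``duration`` ms."""
        cfg = self.cfg
        dt = self.dt
        steps = int(round(duration / dt))
        t0 = self.t
        stim = [(item.cells.astype(np.int64),
                 int(round((t0 + item.start) / dt)),
                 int(round((t0 + item.start + item.duration) / dt)),
                 item.rate * dt * 1e-3, item.weight, item.mode)
                for item in stimulus]
        p_bg = cfg.background_rate * dt * 1e-3
        bg_w = cfg.background_weight
        self.pyr.freeze_bias = freeze_bias
        pw = self.net.pathways
        step0 = int(round(t0 / dt))

        for s in range(step0, step0 + steps):
            # 1. consume the current ring-buffer slot
            for pop_name, pop in (("pyr", self.pyr), ("basket", self.basket)):
                for r, buf in self.rb[pop_name].items():
                    inp = buf[:, self.head].copy()
                    buf[:, self.head] = 0.0
                    pop.deliver(r, inp)
            # 2. external Poisson drive
            if p_bg > 0:
                bg = self.rng.random(cfg.n_pyramidal) < p_bg
                self.pyr.i_syn["ampa"][bg] += bg_w
                if cfg.background_to_baskets:
                    bgb = self.rng.random(cfg.n_basket) < p_bg
                    self.basket.i_syn["ampa"][bgb] += bg_w
            forced: list[np.ndarray] = []
            for cells, s_lo, s_hi, prob, w, mode in stim:
                if s_lo <= s < s_hi and prob > 0:
                    hit = cells[self.rng.random(cells.size) < prob]
                    if mode == "psc":
                        self.pyr.i_syn["ampa"][hit] += w
                    else:
                        forced.append(hit)
            # 3. advance membranes
            spiked_pyr = self.pyr.step(
                dt, force=np.concatenate(forced) if forced else None)
            spiked_b = self.basket.step(dt)
            t_now = (s + 1) * dt
            # 4. event-driven synaptic processing
            if spiked_pyr.size:
                for name, st in self.plastic.items():
                    prm = st.params
                    fk.record_post_spikes(
                        spiked_pyr, t_now, prm.tau_zj, prm.tau_p,
                        st.pj_z, st.pj_p, st.pj_t,
                        st.hist_t, st.hist_z, st.hist_cnt, st.cap)
                    if learning:
                        fk.process_rows_learning(
                            spiked_pyr, t_now, prm.tau_zi, prm.tau_zj,
                            prm.tau_p, st.pathway.indptr, st.pathway.post,
                            st.pathway.pij_star, st.row_t, st.row_z,
                            st.row_p, st.hist_t, st.hist_z, st.hist_cnt,
                            st.cap, st.dropped)
                    if plastic_currents:
                        fk.deliver_spikes(
                            spiked_pyr, st.pathway.indptr, st.pathway.post,
                            st.pathway.delay_steps, st.pathway.weight,
                            self.rb["pyr"][st.pathway.receptor],
                            self.head, self.nslots)
                pb = pw["pyr_basket"]
                fk.deliver_spikes(spiked_pyr, pb.indptr, pb.post,
                                  pb.delay_steps, pb.weight,
                                  self.rb["basket"]["ampa"],
                                  self.head, self.nslots)
                self._raster_t.append(np.full(spiked_pyr.size, t_now))
                self._raster_id.append(spiked_pyr.copy())
            if spiked_b.size:
                bp = pw["basket_pyr"]
                fk.deliver_spikes(spiked_b, bp.indptr, bp.post,
                                  bp.delay_steps, bp.weight,
                                  self.rb["pyr"]["gaba"],
                                  self.head, self.nslots)
                bb = pw["basket_basket"]
                fk.deliver_spikes(spiked_b, bb.indptr, bb.post,
                                  bb.delay_steps, bb.weight,
                                  self.rb["basket"]["gaba"],
                                  self.head, self.nslots)
                self._raster_t.append(np.full(spiked_b.size, t_now))
                self._raster_id.append(spiked_b + cfg.n_pyramidal)
            if self.record_vm:
                self._vm.append(self.pyr.v_m.astype(np.float32))
                self._vm_t.append(t_now)
            self.head = (self.head + 1) % self.nslots
            self.t = t_now

    # ------------------------------------------------------------------
    def finalize_weights(self) -> None:
        """Bring all plastic synapses up to the current time and store the
        evaluated weights (and the learned bias currents) on the network."""
        for name, st in self.plastic.items():
            prm, co = st.params, st.coeffs
            fk.finalize_weights(
                self.t, prm.tau_zi, prm.tau_zj, prm.tau_p,
                co.a_i, co.a_j, co.a_ij, prm.eps, prm.w_gain,
                st.pathway.indptr, st.pathway.post, st.pathway.pij_star,
                st.row_t, st.row_z, st.row_p,
                st.pj_z, st.pj_p, st.pj_t,
                st.hist_t, st.hist_z, st.hist_cnt, st.cap,
                st.pathway.weight)
        self.net.trained = True
        self.net.bias_current = self.pyr.i_beta.copy()

    # ------------------------------------------------------------------
    def raster(self, population: Optional[str] = None
               ) -> tuple[np.ndarray, np.ndarray]:
        """Spike raster as (times_ms, neuron_ids).  Pyramidal cells come
        first in the id space; ``population`` may restrict to "pyr" or
        "basket"."""
        if self._raster_t:
            t = np.concatenate(self._raster_t)
            i = np.concatenate(self._raster_id)
            order = np.argsort(t, kind="stable")
            t, i = t[order], i[order]
        else:
            t = np.zeros(0)
            i = np.zeros(0, dtype=np.int64)
        if population == "pyr":
            keep = i < self.cfg.n_pyramidal
            return t[keep], i[keep]
        if population == "basket":
            keep = i >= self.cfg.n_pyramidal
            return t[keep], i[keep] - self.cfg.n_pyramidal
        return t, i

    def vm_traces(self) -> tuple[np.ndarray, np.ndarray]:
        """Recorded pyramidal membrane potentials: (times, [step, cell])."""
        if not self._vm:
            raise RuntimeError("run with record_vm=True to record membranes")
        return np.asarray(self._vm_t), np.vstack(self._vm)
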