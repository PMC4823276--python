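"""Construction of the modular cortical attractor architecture.

The network is a grid of hypercolumns, each containing 250 inhibitory
basket cells and 1000 excitatory pyramidal cells evenly divided into 10
minicolumns.  Within a hypercolumn, pyramidal cells excite basket cells
(AMPA, 0.4 nA) and basket cells inhibit pyramidal cells and each other
(GABA, 2 nA), all at 10 % connection probability — a winner-take-all
circuit.  All pyramidal cells across the whole network are additionally
recurrently connected through plastic BCPNN AMPA and NMDA pathways, again
at 10 %.  Conduction delays grow with the Euclidean distance between
hypercolumn grid coordinates; local connections have 1 ms delays.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .params import (
    ATTRACTOR_AMPA, ATTRACTOR_NEURON, ATTRACTOR_NMDA, BCPNNParams,
    NeuronParams,
)

__all__ = ["NetworkConfig", "Pathway", "Network", "delay_between", "build",
           "expected_counts", "event_rate_ratio"]


@dataclass(frozen=True)
class NetworkConfig:
    """Structural and synaptic constants of the modular network."""

    n_hc: int = 4
    minicolumns_per_hc: int = 10
    pyramidal_per_hc: int = 1000
    basket_per_hc: int = 250
    p_connect: float = 0.1
    w_pyr_basket: float = 0.4        # nA, AMPA
    w_basket_pyr: float = 2.0        # nA, GABA (stored positive)
    w_basket_basket: float = 2.0     # nA, GABA
    conduction_velocity: float = 0.2  # mm/ms
    d_norm: float = 0.75             # mm
    #: numerators of the w_gain scalings; divided by n_hc at build time
    ampa_gain: float = 0.546         # nA
    nmda_gain: float = 0.114         # nA
    ampa_params: BCPNNParams = ATTRACTOR_AMPA
    nmda_params: BCPNNParams = ATTRACTOR_NMDA
    neuron_params: NeuronParams = ATTRACTOR_NEURON
    background_rate: float = 65.0    # Hz Poisson drive per cell
    background_weight: float = 2.0   # nA through AMPA
    background_to_baskets: bool = True
    dt: float = 1.0                  # ms

    def __post_init__(self) -> None:
        if self.n_hc < 1:
            raise ValueError("need at least one hypercolumn")
        if not 0.0 <= self.p_connect <= 1.0:
            raise ValueError("p_connect must lie in [0, 1]")
        if self.pyramidal_per_hc % self.minicolumns_per_hc:
            raise ValueError(
                "pyramidal cells must divide evenly into minicolumns")

    @property
    def pyramidal_per_minicolumn(self) -> int:
        return self.pyramidal_per_hc // self.minicolumns_per_hc

    @property
    def n_pyramidal(self) -> int:
        return self.n_hc * self.pyramidal_per_hc

    @property
    def n_basket(self) -> int:
        return self.n_hc * self.basket_per_hc

    @property
    def n_neurons(self) -> int:
        return self.n_pyramidal + self.n_basket

    @property
    def grid_side(self) -> int:
        return math.isqrt(self.n_hc - 1) + 1 if self.n_hc > 1 else 1

    def hc_coords(self) -> np.ndarray:
        """Grid coordinates of each hypercolumn: square grid when n_hc is a
        perfect square, otherwise row-major fill of the smallest enclosing
        square."""
        side = self.grid_side
        idx = np.arange(self.n_hc)
        return np.column_stack([idx % side, idx // side]).astype(float)


def delay_between(hc_pre, hc_post, config: NetworkConfig) -> float:
    """Distance-dependent delay in ms (before timestep rounding):
    ``d_norm * |H_post - H_pre| / V + 1``."""
    dx = hc_post[0] - hc_pre[0]
    dy = hc_post[1] - hc_pre[1]
    dist = math.hypot(dx, dy)
    return config.d_norm * dist / config.conduction_velocity + 1.0


@dataclass
class Pathway:
    """One connection pathway in compressed sparse row form (rows indexed
    by presynaptic neuron within its population)."""

    name: str
    receptor: str
    pre_pop: str
    post_pop: str
    plastic: bool
    indptr: np.ndarray
    post: np.ndarray
    delay_steps: np.ndarray
    weight: np.ndarray
    params: Optional[BCPNNParams] = None
    pij_star: Optional[np.ndarray] = None

    @property
    def n_synapses(self) -> int:
        return int(self.post.size)


@dataclass
class Network:
    """A built network: populations plus synaptic pathways."""

    config: NetworkConfig
    #: per-pyramidal-cell hypercolumn / minicolumn-position / global
    #: minicolumn indices
    pyr_hc: np.ndarray = field(repr=False, default=None)
    pyr_mc: np.ndarray = field(repr=False, default=None)
    basket_hc: np.ndarray = field(repr=False, default=None)
    pathways: dict = field(default_factory=dict)
    trained: bool = False

    @property
    def n_minicolumns(self) -> int:
        return self.config.n_hc * self.config.minicolumns_per_hc

    def minicolumn_members(self, position: int) -> np.ndarray:
        """Pyramidal indices of minicolumn *position* pooled over all
        hypercolumns (positions index within-hypercolumn sequence slots)."""
        return np.flatnonzero(self.pyr_mc == position)


def _sample_pathway(rng: np.random.Generator, n_pre: int, n_post: int,
                    p: float, exclude_self: bool,
                    chunk: int = 512) -> tuple[np.ndarray, np.ndarray]:
    """Bernoulli(p) sampling of an (n_pre x n_post) adjacency, returned as
    CSR (indptr, post)."""
    counts = np.zeros(n_pre, dtype=np.int64)
    cols = []
    for lo in range(0, n_pre, chunk):
        hi = min(lo + chunk, n_pre)
        mask = rng.random((hi - lo, n_post)) < p
        if exclude_self:
            rows = np.arange(lo, hi)
            ok = rows < n_post
            mask[np.flatnonzero(ok), rows[ok]] = False
        r, c = np.nonzero(mask)
        counts[lo:hi] = np.bincount(r, minlength=hi - lo)
        cols.append(c.astype(np.int32))
    indptr = np.concatenate([[0], np.cumsum(counts)])
    post = (np.concatenate(cols) if cols else np.zeros(0, dtype=np.int32))
    return indptr, post


def _block_sample(rng, pre_hc, post_hc, n_pre_per, n_post_per, n_hc, p,
                  exclude_self):
    """Sample within-hypercolumn (block-diagonal) connectivity."""
    n_pre = n_hc * n_pre_per
    indptrs = np.zeros(n_pre + 1, dtype=np.int64)
    cols = []
    for h in range(n_hc):
        ip, c = _sample_pathway(rng, n_pre_per, n_post_per, p, exclude_self)
        base_pre = h * n_pre_per
        base_post = h * n_post_per
        indptrs[base_pre + 1: base_pre + n_pre_per + 1] = ip[1:] + indptrs[base_pre]
        cols.append((c + base_post).astype(np.int32))
    return indptrs, np.concatenate(cols) if cols else np.zeros(0, np.int32)


def build(config: NetworkConfig, rng: np.random.Generator) -> Network:
    """Instantiate populations and sample all pathways.

    Every ordered neuron pair of a pathway is an independent Bernoulli
    draw (autapses excluded); plastic pathways start with zero traces and
    zero weights.
    """
    c = config
    mc_size = c.pyramidal_per_minicolumn
    pyr_hc = np.repeat(np.arange(c.n_hc), c.pyramidal_per_hc)
    pyr_mc = np.tile(np.repeat(np.arange(c.minicolumns_per_hc), mc_size),
                     c.n_hc)
    basket_hc = np.repeat(np.arange(c.n_hc), c.basket_per_hc)

    coords = c.hc_coords()
    # hypercolumn-to-hypercolumn delay matrix, rounded to timesteps (>= 1)
    diff = coords[:, None, :] - coords[None, :, :]
    delay_ms = (c.d_norm * np.hypot(diff[..., 0], diff[..., 1])
                / c.conduction_velocity + 1.0)
    delay_steps_hc = np.maximum(1, np.round(delay_ms / c.dt)).astype(np.int16)

    net = Network(config=c, pyr_hc=pyr_hc, pyr_mc=pyr_mc, basket_hc=basket_hc)

    def hc_delays(pre_hc_arr, post_hc_arr, indptr, post):
        pre_ids = np.repeat(np.arange(len(indptr) - 1), np.diff(indptr))
        return delay_steps_hc[pre_hc_arr[pre_ids], post_hc_arr[post]]

    # Global plastic pyramidal->pyramidal pathways (independent samples).
    n_pyr = c.n_pyramidal
    for name, receptor, params, gain in (
            ("ampa_plastic", "ampa", c.ampa_params, c.ampa_gain),
            ("nmda_plastic", "nmda", c.nmda_params, c.nmda_gain)):
        indptr, post = _sample_pathway(rng, n_pyr, n_pyr, c.p_connect, True)
        scaled = replace(params, w_gain=gain / c.n_hc)
        net.pathways[name] = Pathway(
            name=name, receptor=receptor, pre_pop="pyr", post_pop="pyr",
            plastic=True, indptr=indptr, post=post,
            delay_steps=hc_delays(pyr_hc, pyr_hc, indptr, post),
            weight=np.zeros(post.size), params=scaled,
            pij_star=np.zeros(post.size))

    # Local static winner-take-all circuitry (within-hypercolumn).
    local = [
        ("pyr_basket", "ampa", "pyr", "basket", c.pyramidal_per_hc,
         c.basket_per_hc, pyr_hc, basket_hc, c.w_pyr_basket, False),
        ("basket_pyr", "gaba", "basket", "pyr", c.basket_per_hc,
         c.pyramidal_per_hc, basket_hc, pyr_hc, c.w_basket_pyr, False),
        ("basket_basket", "gaba", "basket", "basket", c.basket_per_hc,
         c.basket_per_hc, basket_hc, basket_hc, c.w_basket_basket, True),
    ]
    for (name, receptor, pre_pop, post_pop, n_pre_per, n_post_per,
         pre_hc_arr, post_hc_arr, w, excl) in local:
        indptr, post = _block_sample(rng, pre_hc_arr, post_hc_arr, n_pre_per,
                                     n_post_per, c.n_hc, c.p_connect, excl)
        net.pathways[name] = Pathway(
            name=name, receptor=receptor, pre_pop=pre_pop, post_pop=post_pop,
            plastic=False, indptr=indptr, post=post,
            delay_steps=np.ones(post.size, dtype=np.int16),
            weight=np.full(post.size, float(w)))
    return net


def expected_counts(config: NetworkConfig) -> dict:
    """Closed-form census of the architecture (no sampling).

    ``afferent_plastic_per_pyramidal`` counts both receptor types under
    this model's convention (two independent 10 % pathways over all
    pyramidal pairs).
    """
    c = config
    n_pyr, n_b = c.n_pyramidal, c.n_basket
    per_hc_pb = c.pyramidal_per_hc * c.basket_per_hc * c.p_connect
    per_hc_bp = c.basket_per_hc * c.pyramidal_per_hc * c.p_connect
    per_hc_bb = c.basket_per_hc * (c.basket_per_hc - 1) * c.p_connect
    plastic_per_pathway = n_pyr * (n_pyr - 1) * c.p_connect
    return {
        "n_hypercolumns": c.n_hc,
        "n_pyramidal": n_pyr,
        "n_basket": n_b,
        "n_neurons": n_pyr + n_b,
        "plastic_synapses_per_pathway": plastic_per_pathway,
        "plastic_synapses_total": 2 * plastic_per_pathway,
        "pyr_basket_per_hc": per_hc_pb,
        "basket_pyr_per_hc": per_hc_bp,
        "basket_basket_per_hc": per_hc_bb,
        "static_synapses_total": c.n_hc * (per_hc_pb + per_hc_bp + per_hc_bb),
        "afferent_plastic_per_pyramidal": 2 * (n_pyr - 1) * c.p_connect,
    }


def event_rate_ratio(afferents_a: float = 4.0e3, activity_a: float = 0.10,
                     afferents_b: float = 8.0e3, activity_b: float = 0.01
                     ) -> float:
    """Ratio of synaptic-event rates between two connectivity regimes.

    The event rate per cell is proportional to (afferent count x fraction
    of presynaptic cells active).  The defaults compare this model's regime
    (4.0e3 excitatory afferents, 10 % of cells active under 10-minicolumn
    winner-take-all) with a cortically realistic one (8.0e3 afferents, 1 %
    active with 100 minicolumns per hypercolumn).
    """
    return (afferents_a * activity_a) / (afferents_b * activity_b)
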