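"""Post-hoc analyses of simulation output.

* connectivity kernels: mean plastic weight between minicolumn sequence
  positions, pooled over hypercolumns;
* population peak-rate timing from spike rasters;
* peak-aligned, normalized membrane-potential averages.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .network import Network

__all__ = ["KernelMatrix", "AlignedVm", "kernel_matrix", "asymmetry_index",
           "peak_rate_times", "align_vm"]


@dataclass
class KernelMatrix:
    """Mean synaptic weight from minicolumn position a to position b."""

    receptor: str
    values: np.ndarray          # (n_mc, n_mc), nan where no synapses exist
    counts: np.ndarray

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def superdiagonal(self) -> np.ndarray:
        """Forward (m -> m+1) mean weights."""
        return np.array([self.values[m, m + 1] for m in range(self.n - 1)])

    def subdiagonal(self) -> np.ndarray:
        """Backward (m+1 -> m) mean weights."""
        return np.array([self.values[m + 1, m] for m in range(self.n - 1)])


def kernel_matrix(network: Network, receptor: str) -> KernelMatrix:
    """Average plastic weight between minicolumn positions.

    Entry (a, b) pools every existing synapse from pyramidal cells at
    within-hypercolumn position ``a`` (over all hypercolumns) to cells at
    position ``b``.  Positions with no synapses yield NaN.
    """
    name = f"{receptor}_plastic"
    if name not in network.pathways:
        raise KeyError(f"no plastic pathway for receptor {receptor!r}")
    pw = network.pathways[name]
    n_mc = network.config.minicolumns_per_hc
    pre_ids = np.repeat(np.arange(network.config.n_pyramidal),
                        np.diff(pw.indptr))
    a = network.pyr_mc[pre_ids]
    b = network.pyr_mc[pw.post]
    tot = np.zeros((n_mc, n_mc))
    cnt = np.zeros((n_mc, n_mc))
    np.add.at(tot, (a, b), pw.weight)
    np.add.at(cnt, (a, b), 1.0)
    with np.errstate(invalid="ignore"):
        vals = np.where(cnt > 0, tot / np.maximum(cnt, 1), np.nan)
    return KernelMatrix(receptor=receptor, values=vals, counts=cnt)


def asymmetry_index(kernel: KernelMatrix) -> float:
    """Frobenius-norm asymmetry ``|K - K^T| / |K + K^T|`` (0 for a
    perfectly symmetric kernel)."""
    k = np.nan_to_num(kernel.values)
    denom = np.linalg.norm(k + k.T)
    if denom == 0:
        return 0.0
    return float(np.linalg.norm(k - k.T) / denom)


def peak_rate_times(times: np.ndarray, ids: np.ndarray,
                    assignment: np.ndarray, window_ms: float = 10.0,
                    t_end: Optional[float] = None,
                    min_spikes: int = 10,
                    min_rate_hz: float = 0.0,
                    interior_ms: float = 0.0) -> np.ndarray:
    """Per-group time of maximal population firing rate.

    The rate of each group (e.g. minicolumn) is a boxcar-smoothed
    histogram of width ``window_ms``; the peak is its argmax (earliest bin
    on ties), reported at the bin centre.  Groups with fewer than
    ``min_spikes`` spikes are flagged NaN.  ``min_rate_hz`` additionally
    requires the peak per-cell rate to reach that level (used to restrict
    the analysis to groups whose attractor actually ignited, as opposed to
    background leakage).  ``interior_ms`` restricts the argmax to bins at
    least that far from both ends of the recording, so a peak can be
    required to have full surrounding coverage.
    """
    times = np.asarray(times, dtype=float)
    ids = np.asarray(ids, dtype=int)
    if times.size == 0:
        raise ValueError("empty raster")
    if t_end is None:
        t_end = float(times.max())
    n_groups = int(assignment.max()) + 1
    edges = np.arange(0.0, t_end + window_ms, window_ms)
    centres = edges[:-1] + window_ms / 2.0
    ok = centres >= 0
    if interior_ms > 0:
        ok = (centres >= interior_ms) & (centres <= t_end - interior_ms)
    out = np.full(n_groups, np.nan)
    groups = assignment[ids]
    group_sizes = np.bincount(assignment, minlength=n_groups)
    for g in range(n_groups):
        tg = times[groups == g]
        if tg.size < min_spikes:
            continue
        hist, _ = np.histogram(tg, bins=edges)
        masked = np.where(ok, hist, -1)
        best = int(np.argmax(masked))
        peak_rate = hist[best] * 1000.0 / (window_ms * max(group_sizes[g], 1))
        if peak_rate < min_rate_hz:
            continue
        out[g] = centres[best]
    return out


@dataclass
class AlignedVm:
    """Peak-aligned, averaged and normalized membrane potentials.

    The normalized scale maps the spike threshold ``V_t`` to 0 and the
    minimum of the averaged sample to -1.
    """

    t_rel: np.ndarray           # ms relative to the aligned peak
    mean: np.ndarray            # normalized mean over groups
    std: np.ndarray             # normalized s.d. over groups
    n_groups: int = 0

    def window_mean(self, lo: float, hi: float) -> float:
        """Mean of the normalized trace over ``lo < t_rel <= hi``."""
        sel = (self.t_rel > lo) & (self.t_rel <= hi)
        if not sel.any():
            raise ValueError("empty alignment window")
        return float(self.mean[sel].mean())

    def post_peak_drop(self, span: float = 300.0,
                       peak_halfwidth: float = 20.0) -> float:
        """Change of the normalized mean after the peak: mean over
        ``(0, span]`` minus the level around the peak itself.  Strongly
        negative values indicate pronounced after-peak hyperpolarization."""
        return (self.window_mean(0.0, span)
                - self.window_mean(-peak_halfwidth, peak_halfwidth))


def align_vm(vm_times: np.ndarray, vm: np.ndarray, assignment: np.ndarray,
             peak_times: np.ndarray, v_t: float,
             span_ms: float = 300.0) -> AlignedVm:
    """Align per-cell membrane traces to their group's peak-rate time,
    average within groups, then across groups, and normalize.

    ``vm`` is a (time, cell) array sampled at ``vm_times``; groups whose
    peak is NaN or whose coverage of [peak - span, peak + span] is
    incomplete are skipped (with a warning when truncation occurs).
    """
    vm_times = np.asarray(vm_times, dtype=float)
    dt = float(np.median(np.diff(vm_times)))
    half = int(round(span_ms / dt))
    curves = []
    for g, pk in enumerate(peak_times):
        if np.isnan(pk):
            continue
        cells = np.flatnonzero(assignment == g)
        if cells.size == 0:
            continue
        c = int(np.searchsorted(vm_times, pk))
        lo, hi = c - half, c + half
        if lo < 0 or hi > vm.shape[0]:
            warnings.warn(
                f"group {g}: insufficient coverage around peak {pk}; skipped")
            continue
        curves.append(vm[lo:hi, cells].mean(axis=1))
    if not curves:
        raise ValueError("no group had full coverage around its peak")
    stack = np.vstack(curves)
    mean = stack.mean(axis=0)
    lo_v = mean.min()
    scale = v_t - lo_v
    if scale <= 0:
        raise ValueError("degenerate normalization: mean never below V_t")
    norm = (stack - v_t) / scale
    t_rel = (np.arange(-half, half) + 0.5) * dt
    return AlignedVm(t_rel=t_rel, mean=norm.mean(axis=0),
                     std=norm.std(axis=0), n_groups=len(curves))
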