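"""Plain-text file formats: spike rasters, membrane traces, connectivity
tables, kernel matrices and run manifests."""

from __future__ import annotations

import json
import time
from pathlib import Path

import numpy as np
import pandas as pd

from .analysis import KernelMatrix
from .network import Network

__all__ = [
    "save_raster", "load_raster", "save_vm", "load_vm",
    "save_connectivity", "load_weights", "save_kernel", "save_manifest",
]


def save_raster(path, times: np.ndarray, ids: np.ndarray) -> None:
    """Two-column text raster: time_ms, neuron_id."""
    arr = np.column_stack([np.asarray(times), np.asarray(ids)])
    np.savetxt(path, arr, fmt="%.3f %d", header="time_ms neuron_id")


def load_raster(path) -> tuple[np.ndarray, np.ndarray]:
    arr = np.loadtxt(path, ndmin=2)
    if arr.size == 0:
        return np.zeros(0), np.zeros(0, dtype=int)
    return arr[:, 0], arr[:, 1].astype(int)


def save_vm(path, times: np.ndarray, vm: np.ndarray,
            subsample: int = 1) -> None:
    """Tabular membrane traces: first column time_ms, one column per cell.
    ``subsample`` keeps every n-th sample."""
    t = np.asarray(times)[::subsample]
    v = np.asarray(vm)[::subsample]
    df = pd.DataFrame(v, index=pd.Index(t, name="time_ms"))
    df.to_csv(path, float_format="%.3f")


def load_vm(path) -> tuple[np.ndarray, np.ndarray]:
    df = pd.read_csv(path, index_col=0)
    return df.index.to_numpy(float), df.to_numpy(float)


def save_connectivity(path, network: Network,
                      pathways: tuple[str, ...] | None = None) -> None:
    """Documented tabular synapse format: pathway, pre_id, post_id,
    receptor, delay_ms, weight_nA, pij_star."""
    rows = []
    for name, pw in network.pathways.items():
        if pathways is not None and name not in pathways:
            continue
        pre_ids = np.repeat(np.arange(len(pw.indptr) - 1), np.diff(pw.indptr))
        pij = (pw.pij_star if pw.pij_star is not None
               else np.zeros(pw.n_synapses))
        rows.append(pd.DataFrame({
            "pathway": name,
            "pre_id": pre_ids,
            "post_id": pw.post,
            "receptor": pw.receptor,
            "delay_ms": pw.delay_steps * network.config.dt,
            "weight_nA": pw.weight,
            "pij_star": pij,
        }))
    pd.concat(rows, ignore_index=True).to_csv(path, index=False,
                                              float_format="%.6g")


def load_weights(path, network: Network) -> None:
    """Restore weights (and coactivation traces) from a connectivity table
    into a structurally identical network (same config and build seed)."""
    df = pd.read_csv(path)
    for name, grp in df.groupby("pathway"):
        pw = network.pathways[name]
        if len(grp) != pw.n_synapses:
            raise ValueError(
                f"pathway {name}: {len(grp)} rows vs {pw.n_synapses} "
                "synapses; was the network rebuilt with the same seed?")
        pw.weight[:] = grp["weight_nA"].to_numpy()
        if pw.pij_star is not None:
            pw.pij_star[:] = grp["pij_star"].to_numpy()
    network.trained = True


def save_kernel(path, kernel: KernelMatrix) -> None:
    df = pd.DataFrame(kernel.values)
    df.index.name = "pre_position"
    df.to_csv(path, float_format="%.6g")


def save_manifest(path, **fields) -> None:
    """Reproducibility manifest (seeds, parameters, versions, timings)."""
    from . import __version__
    payload = {"ebcpnn_version": __version__,
               "written": time.strftime("%Y-%m-%dT%H:%M:%S"),
               **fields}
    Path(path).write_text(json.dumps(payload, indent=2, default=str) + "\n")
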