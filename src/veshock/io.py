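"""Run artefacts: VTK snapshots, HDF5 checkpoints, CSV/JSON summaries.

VTK output uses the legacy ASCII STRUCTURED_POINTS format (readable by
any VTK-based viewer); checkpoints round-trip the full simulation state
bit-exactly through HDF5 along with grid/config content hashes so a
resumed run can verify it matches its producer.
"""
from __future__ import annotations

import csv
import hashlib
import json
from pathlib import Path
from typing import Optional

import h5py
import numpy as np

from .grid import LabeledGrid
from .solver import SimState, TissueOperators


# ======================================================================
# VTK
# ======================================================================

def write_vtk_image(path, grid: LabeledGrid,
                    cell_data: Optional[dict[str, np.ndarray]] = None,
                    point_data: Optional[dict[str, np.ndarray]] = None,
                    title: str = "veshock field snapshot") -> Path:
    """Write nodal/cell fields on the structured grid as legacy ASCII VTK."""
    path = Path(path)
    dims3 = tuple(grid.node_shape) + (1,) * (3 - grid.ndim)
    h_mm = grid.spacing_um / 1000.0
    lines = ["# vtk DataFile Version 3.0", title, "ASCII",
             "DATASET STRUCTURED_POINTS",
             f"DIMENSIONS {dims3[0]} {dims3[1]} {dims3[2]}",
             "ORIGIN 0 0 0",
             f"SPACING {h_mm} {h_mm} {h_mm}"]

    def emit(fields: dict[str, np.ndarray], n: int, kind: str):
        lines.append(f"{kind} {n}")
        for name, arr in fields.items():
            arr = np.asarray(arr, dtype=float)
            lines.append(f"SCALARS {name} float 1")
            lines.append("LOOKUP_TABLE default")
            # legacy VTK expects x fastest; our arrays are C-ordered (x slowest)
            shaped = arr.reshape(grid.node_shape if kind == "POINT_DATA"
                                 else grid.dims)
            flat = shaped.transpose(*reversed(range(grid.ndim))).ravel()
            lines.extend(" ".join(f"{v:.6g}" for v in flat[i:i + 9])
                         for i in range(0, flat.size, 9))

    if point_data:
        emit(point_data, grid.n_nodes, "POINT_DATA")
    if cell_data:
        emit(cell_data, int(np.prod(grid.dims)), "CELL_DATA")
    path.write_text("\n".join(lines) + "\n")
    return path


def vm_point_field(ops: TissueOperators, vm: np.ndarray,
                   fill: float = -1000.0) -> np.ndarray:
    """Scatter a tissue-node Vm array onto the full node grid for output."""
    full = np.full(ops.grid.n_nodes, fill)
    full[ops.tissue_nodes] = vm
    return full


# ======================================================================
# checkpoints
# ======================================================================

def save_checkpoint(path, state: SimState, grid: LabeledGrid,
                    config_hash: str = "") -> Path:
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["grid_hash"] = grid.content_hash()
        f.attrs["config_hash"] = config_hash
        f.attrs["t"] = state.t
        f.create_dataset("vm", data=state.vm)
        f.create_dataset("phie", data=state.phie)
        g = f.create_group("membrane")
        for k, v in state.membrane.items():
            g.create_dataset(k, data=v)
    return path


def load_checkpoint(path, grid: Optional[LabeledGrid] = None,
                    config_hash: Optional[str] = None) -> SimState:
    """Load a checkpoint; verifies grid/config hashes when provided."""
    with h5py.File(path, "r") as f:
        if grid is not None and f.attrs["grid_hash"] != grid.content_hash():
            raise ValueError("checkpoint was produced on a different grid")
        if config_hash is not None and f.attrs["config_hash"] != config_hash:
            raise ValueError("checkpoint was produced with a different config")
        return SimState(
            vm=f["vm"][...], phie=f["phie"][...],
            membrane={k: f["membrane"][k][...] for k in f["membrane"]},
            t=float(f.attrs["t"]))


# ======================================================================
# summaries
# ======================================================================

def write_csv(path, rows: list[dict]) -> Path:
    path = Path(path)
    if not rows:
        path.write_text("")
        return path
    with open(path, "w", newline="") as f:
        w = csv.DictWriter(f, fieldnames=list(rows[0].keys()))
        w.writeheader()
        w.writerows(rows)
    return path


def write_json(path, obj) -> Path:
    path = Path(path)

    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        raise TypeError(type(o))

    path.write_text(json.dumps(obj, indent=2, sort_keys=True, default=default)
                    + "\n")
    return path


def dict_hash(obj) -> str:
    """Stable content hash of a JSON-serialisable configuration."""
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()).hexdigest()
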