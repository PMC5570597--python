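"""Rule-based myocardial fibre orientation.

Fibre direction is assigned from smooth potential fields: a Laplace solve
with Dirichlet 0/1 on the endo-/epicardial surfaces yields a normalised
transmural depth ``d`` and (from its gradient) the local transmural
direction; in 3-D a second solve between the base and apex planes yields
the apico-basal direction.  The default circumferential vector is their
cross product, then inclined about the transmural axis by an angle that
interpolates linearly from +60 deg on the endocardium (d=0) to -60 deg on
the epicardium (d=1).  Trabecular cells are overridden with the axis of
the structure they belong to.

The depth solve uses an edge-based (two-point) graph Laplacian on tissue
nodes, which is an M-matrix and therefore obeys the discrete maximum
principle: ``d`` stays in [0, 1] on any geometry.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
import scipy.sparse.linalg as spla
from scipy.sparse.csgraph import connected_components

from .grid import Label, LabeledGrid


@dataclass
class FiberField:
    """Per-tissue-cell unit fibre vectors and normalised transmural depth."""

    vectors: np.ndarray      # (*dims, ndim); zero outside tissue
    depth: np.ndarray        # (*dims); NaN outside tissue
    tissue_mask: np.ndarray  # (*dims) bool


def inclination_angle(d: np.ndarray | float, endo_deg: float = 60.0,
                      epi_deg: float = -60.0) -> np.ndarray | float:
    """Transmural fibre inclination: linear in normalised depth d."""
    return endo_deg + (epi_deg - endo_deg) * np.asarray(d, dtype=float)


# ----------------------------------------------------------------- laplace
def _tissue_node_edges(grid: LabeledGrid) -> tuple[np.ndarray, np.ndarray]:
    """Edge list (i, j flat node indices) of all tissue-cell edges."""
    dims = grid.dims
    ndim = grid.ndim
    tissue = grid.tissue_cells()
    cells = np.argwhere(tissue)
    rows, cols = [], []
    for axis in range(ndim):
        # the 2^(ndim-1) edges of each cell running along `axis`
        offs = [np.array(o) for o in np.ndindex(*(2,) * ndim) if o[axis] == 0]
        for off in offs:
            a = cells + off
            b = a.copy()
            b[:, axis] += 1
            rows.append(np.ravel_multi_index(a.T, grid.node_shape))
            cols.append(np.ravel_multi_index(b.T, grid.node_shape))
    return np.concatenate(rows), np.concatenate(cols)


def solve_laplace_depth(grid: LabeledGrid, zero_sets: list[str],
                        one_sets: list[str]) -> np.ndarray:
    """Nodal Laplace solve on tissue with Dirichlet 0/1 on named node sets.

    Returns a flat nodal array (NaN off tissue).  Raises ``ValueError``
    naming any tissue component that touches neither boundary set.
    """
    rows, cols = _tissue_node_edges(grid)
    n = grid.n_nodes
    w = np.ones_like(rows, dtype=float)
    A = sp.coo_matrix((np.concatenate([w, w]),
                       (np.concatenate([rows, cols]),
                        np.concatenate([cols, rows]))), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    L = sp.diags(deg) - A

    tnodes = grid.tissue_nodes()
    dir_val = np.full(n, np.nan)
    for name in zero_sets:
        dir_val[grid.node_sets.get(name, np.array([], dtype=int))] = 0.0
    for name in one_sets:
        dir_val[grid.node_sets.get(name, np.array([], dtype=int))] = 1.0

    # connectivity check: every tissue component must see a Dirichlet node
    sub = A[tnodes][:, tnodes]
    n_comp, comp = connected_components(sub, directed=False)
    has_dir = np.isfinite(dir_val[tnodes])
    for k in range(n_comp):
        if not has_dir[comp == k].any():
            raise ValueError(
                f"tissue component {k} ({int((comp == k).sum())} nodes) touches "
                "neither boundary node set; cannot solve for transmural depth")

    is_dir = np.isfinite(dir_val)
    free = tnodes[~is_dir[tnodes]]
    fixed = tnodes[is_dir[tnodes]]
    x = np.full(n, np.nan)
    x[fixed] = dir_val[fixed]
    if free.size:
        Lff = L[free][:, free].tocsc()
        rhs = -L[free][:, fixed] @ dir_val[fixed]
        x[free] = spla.spsolve(Lff, rhs)
    return x


def _cell_mean_and_grad(grid: LabeledGrid, nodal: np.ndarray,
                        cell_mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cell-centre mean and gradient of a nodal field over masked cells."""
    ndim = grid.ndim
    h = grid.spacing_cm
    f = nodal.reshape(grid.node_shape)
    cells = np.argwhere(cell_mask)
    corners = np.stack([f[tuple((cells + np.array(o)).T)]
                        for o in np.ndindex(*(2,) * ndim)], axis=1)
    mean = corners.mean(axis=1)
    grad = np.empty((len(cells), ndim))
    offs = list(np.ndindex(*(2,) * ndim))
    for axis in range(ndim):
        sign = np.array([1.0 if o[axis] else -1.0 for o in offs])
        grad[:, axis] = (corners * sign).sum(axis=1) / (2 ** (ndim - 1) * h)
    return mean, grad


def _normalize(v: np.ndarray, fallback: np.ndarray) -> np.ndarray:
    nrm = np.linalg.norm(v, axis=1, keepdims=True)
    bad = nrm.ravel() < 1e-12
    v = np.where(bad[:, None], fallback, v)
    nrm = np.linalg.norm(v, axis=1, keepdims=True)
    return v / nrm


def assign_fibers_rule_based(grid: LabeledGrid,
                             inclination: tuple[float, float] = (60.0, -60.0),
                             ) -> FiberField:
    """Assign per-cell unit fibre vectors by the Laplace rule.

    ``inclination`` is the (endocardial, epicardial) inclination angle pair
    in degrees, interpolated linearly in depth.
    """
    ndim = grid.ndim
    endo_sets = list(grid.meta.get(
        "endo_sets", ("endocardium", "trabecula_proximal_face",
                      "trabecula_distal_face")))
    d_nodal = solve_laplace_depth(grid, endo_sets, ["epicardium"])

    tissue = grid.tissue_cells()
    d_cell, grad_d = _cell_mean_and_grad(grid, d_nodal, tissue)
    fb = np.zeros((len(grad_d), ndim))
    fb[:, min(1, ndim - 1)] = 1.0
    e_t = _normalize(grad_d, fb)

    if ndim == 2:
        # in-plane circumferential: perpendicular to the transmural direction
        fib = np.stack([-e_t[:, 1], e_t[:, 0]], axis=1)
    else:
        w_nodal = _apicobasal_field(grid)
        _, grad_w = _cell_mean_and_grad(grid, w_nodal, tissue)
        e_l = grad_w - (grad_w * e_t).sum(axis=1, keepdims=True) * e_t
        zf = np.zeros((len(e_l), 3))
        zf[:, 2] = 1.0
        e_l = _normalize(e_l, zf)
        e_c = np.cross(e_t, e_l)
        e_c = _normalize(e_c, zf)
        alpha = np.deg2rad(inclination_angle(d_cell, *inclination))
        fib = np.cos(alpha)[:, None] * e_c + np.sin(alpha)[:, None] * e_l
        fib = _normalize(fib, e_c)

    vectors = np.zeros(grid.dims + (ndim,))
    depth = np.full(grid.dims, np.nan)
    idx = tuple(np.argwhere(tissue).T)
    vectors[idx] = fib
    depth[idx] = np.clip(d_cell, 0.0, 1.0)

    _override_trabecular_axis(grid, vectors)
    return FiberField(vectors=vectors, depth=depth, tissue_mask=tissue)


def _apicobasal_field(grid: LabeledGrid) -> np.ndarray:
    """3-D apico-basal potential: Dirichlet 0/1 on the two z-extreme planes."""
    if "base" in grid.node_sets and "apex" in grid.node_sets:
        return solve_laplace_depth(grid, ["base"], ["apex"])
    ns = grid.node_shape
    tmask = np.zeros(grid.n_nodes, dtype=bool)
    tmask[grid.tissue_nodes()] = True
    tmask = tmask.reshape(ns)
    base = np.zeros(ns, dtype=bool)
    apex = np.zeros(ns, dtype=bool)
    base[..., 0] = tmask[..., 0]
    apex[..., -1] = tmask[..., -1]
    grid.node_sets["base"] = np.flatnonzero(base.ravel())
    grid.node_sets["apex"] = np.flatnonzero(apex.ravel())
    return solve_laplace_depth(grid, ["base"], ["apex"])


def _override_trabecular_axis(grid: LabeledGrid, vectors: np.ndarray) -> None:
    trab = grid.cell_labels == Label.TISSUE_TRABECULA
    if not trab.any():
        return
    axis = grid.meta.get("trabecular_axis")
    if isinstance(axis, str) and axis == "azimuthal":
        cx, cy = grid.meta["centre"]
        cells = np.argwhere(trab).astype(float) + 0.5
        dx, dy = cells[:, 0] - cx, cells[:, 1] - cy
        r = np.hypot(dx, dy)
        tang = np.stack([-dy / r, dx / r], axis=1)
        vectors[tuple(np.argwhere(trab).T)] = tang
    else:
        v = np.asarray(axis, dtype=float)
        v = v / np.linalg.norm(v)
        vectors[trab] = v
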