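"""Synthetic labelled computational domains.

The study geometry is an endocardial wall facing a conductive blood cavity
that contains a stimulating electrode.  The anatomical feature of interest
is a *detached trabecula*: a muscular strand running parallel to the wall,
connected to it only at its two ends, with a bath-filled cleft beneath its
mid-span.  An *attached* trabecula (ridge) is the control: the same strand
fused to the wall along its whole length.

Grids are structured and axis-aligned: cell-centred integer labels on a
uniform lattice, node-centred potentials.  Cell ``(i, j, k)`` spans the
half-open box ``[i*h, (i+1)*h) x ...``; node ``(i, j, k)`` sits at
``(i*h, j*h, k*h)``.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum
from typing import Optional

import numpy as np
from scipy import ndimage


class Label(IntEnum):
    TISSUE = 1
    TISSUE_TRABECULA = 2
    BATH = 3
    CLEFT_BATH = 4
    ELECTRODE = 5
    GROUND = 6


#: labels that carry intracellular space
TISSUE_LABELS = (Label.TISSUE, Label.TISSUE_TRABECULA)
#: labels that conduct extracellularly with the bath conductivity
BATH_LABELS = (Label.BATH, Label.CLEFT_BATH, Label.ELECTRODE, Label.GROUND)


@dataclass
class LabeledGrid:
    """Structured domain: per-cell region labels plus named node sets.

    Attributes
    ----------
    spacing_um:
        edge length of every cell, in µm.
    cell_labels:
        integer array of shape ``dims`` (2-D or 3-D), values from `Label`.
    node_sets:
        named flat node-index arrays; populated by the builders with
        ``endocardium``, ``epicardium``, ``trabecula_proximal_face``,
        ``trabecula_distal_face``, ``ground_boundary``, ``electrode_nodes``.
    meta:
        builder bookkeeping (e.g. the trabecular axis used for fibres).
    """

    spacing_um: float
    cell_labels: np.ndarray
    node_sets: dict[str, np.ndarray] = field(default_factory=dict)
    meta: dict = field(default_factory=dict)

    # ------------------------------------------------------------------ basic
    @property
    def dims(self) -> tuple[int, ...]:
        return self.cell_labels.shape

    @property
    def ndim(self) -> int:
        return self.cell_labels.ndim

    @property
    def node_shape(self) -> tuple[int, ...]:
        return tuple(n + 1 for n in self.dims)

    @property
    def n_nodes(self) -> int:
        return int(np.prod(self.node_shape))

    @property
    def spacing_cm(self) -> float:
        return self.spacing_um / 1.0e4

    def node_coords_cm(self) -> np.ndarray:
        """(n_nodes, ndim) array of node coordinates in cm (C flat order)."""
        axes = [np.arange(n + 1) * self.spacing_cm for n in self.dims]
        mesh = np.meshgrid(*axes, indexing="ij")
        return np.stack([m.ravel() for m in mesh], axis=1)

    # ------------------------------------------------------------------ masks
    def tissue_cells(self) -> np.ndarray:
        return np.isin(self.cell_labels, TISSUE_LABELS)

    def bath_cells(self) -> np.ndarray:
        return np.isin(self.cell_labels, BATH_LABELS)

    def _nodes_touching(self, cell_mask: np.ndarray) -> np.ndarray:
        """Boolean node array: nodes incident to at least one masked cell."""
        out = np.zeros(self.node_shape, dtype=bool)
        for off in np.ndindex(*(2,) * self.ndim):
            sl = tuple(slice(o, o + n) for o, n in zip(off, self.dims))
            out[sl] |= cell_mask
        return out

    def tissue_nodes(self) -> np.ndarray:
        """Flat indices of nodes incident to tissue cells (sorted)."""
        return np.flatnonzero(self._nodes_touching(self.tissue_cells()).ravel())

    def bath_nodes(self) -> np.ndarray:
        return np.flatnonzero(self._nodes_touching(self.bath_cells()).ravel())

    def active_nodes(self) -> np.ndarray:
        mask = self._nodes_touching(self.tissue_cells() | self.bath_cells())
        return np.flatnonzero(mask.ravel())

    def interface_nodes(self) -> np.ndarray:
        """Flat indices of nodes on the tissue/bath interface."""
        t = self._nodes_touching(self.tissue_cells())
        b = self._nodes_touching(self.bath_cells())
        return np.flatnonzero((t & b).ravel())

    def node_index(self, *ijk: int) -> int:
        return int(np.ravel_multi_index(ijk, self.node_shape))

    # ------------------------------------------------------------- topology
    def tissue_components(self, cell_mask: Optional[np.ndarray] = None):
        """Connected components (face adjacency) of tissue cells."""
        mask = self.tissue_cells() if cell_mask is None else cell_mask
        structure = ndimage.generate_binary_structure(self.ndim, 1)
        lab, n = ndimage.label(mask, structure=structure)
        return lab, n

    def content_hash(self) -> str:
        import hashlib

        h = hashlib.sha256()
        h.update(np.float64(self.spacing_um).tobytes())
        h.update(np.ascontiguousarray(self.cell_labels, dtype=np.int8).tobytes())
        for name in sorted(self.node_sets):
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.node_sets[name], dtype=np.int64).tobytes())
        return h.hexdigest()


# ======================================================================
# slab builder
# ======================================================================

@dataclass
class SlabConfig:
    """Endocardial-wall slab inside a bath, electrode above, ground below.

    Vertical (y) layout, bottom to top: ground/bath layer | tissue wall |
    (cleft | trabecula) | bath with electrode.  All sizes in cells; spacing
    in µm.  ``nz = 0`` builds a 2-D sheet; ``nz > 0`` extrudes in z.
    """

    nx: int = 72
    nz: int = 0
    spacing_um: float = 250.0
    wall: int = 40
    bath_below: int = 2
    bath_above: int = 3
    trabecula: str = "detached"  # none | attached | detached
    trab_length: int = 20
    trab_thickness: int = 3
    cleft: int = 2
    electrode_offset: int = 4  # cells between highest tissue and electrode
    electrode_margin: int = 8  # bath cells left free at each x end
    n_trabeculae: int = 1
    seed: Optional[int] = None  # randomises trabecula placement (n_trabeculae > 1)

    @property
    def ny(self) -> int:
        stack = self.bath_below + self.wall + self.electrode_offset + 1 + self.bath_above
        if self.trabecula == "detached":
            stack += self.cleft + self.trab_thickness
        elif self.trabecula == "attached":
            stack += self.trab_thickness
        return stack


def build_slab_with_trabecula(config: SlabConfig) -> LabeledGrid:
    """Construct the wall+trabecula slab.

    Raises
    ------
    ValueError
        for degenerate configurations: a "detached" trabecula with zero
        cleft height (which would silently build an attached ridge), or a
        trabecula that does not fit inside the bath clearance.
    """
    c = config
    if c.trabecula not in ("none", "attached", "detached"):
        raise ValueError(f"unknown trabecula type {c.trabecula!r}")
    if c.trabecula == "detached" and c.cleft <= 0:
        raise ValueError("detached trabecula requires cleft height > 0 "
                         "(cleft=0 would silently produce an attached ridge)")
    if c.trabecula != "none" and c.trab_length + 2 > c.nx:
        raise ValueError("trabecula (plus end attachments) wider than the slab")
    if c.wall < 3:
        raise ValueError("wall thinner than 3 cells has no transmural resolution")

    ny = c.ny
    dims2 = (c.nx, ny)
    lab2 = np.full(dims2, int(Label.BATH), dtype=np.int8)
    if c.bath_below < 1:
        raise ValueError("need at least one bath/ground layer below the wall")
    lab2[:, 0] = Label.GROUND  # conducting, grounded outer-boundary layer
    wall_lo, wall_hi = c.bath_below, c.bath_below + c.wall
    lab2[:, wall_lo:wall_hi] = Label.TISSUE

    trab_spans: list[tuple[int, int]] = []
    if c.trabecula != "none":
        n_tr = max(1, c.n_trabeculae)
        spans = _trabecula_spans(c.nx, c.trab_length, n_tr, c.seed)
        for x0 in spans:
            x1 = x0 + c.trab_length
            if c.trabecula == "detached":
                beam_lo = wall_hi + c.cleft
                beam_hi = beam_lo + c.trab_thickness
                lab2[x0:x1, wall_hi:beam_lo] = Label.CLEFT_BATH
                lab2[x0:x1, beam_lo:beam_hi] = Label.TISSUE_TRABECULA
                # end attachments: single wall-tissue columns just outside the span
                lab2[x0 - 1, wall_hi:beam_hi] = Label.TISSUE
                lab2[x1, wall_hi:beam_hi] = Label.TISSUE
            else:  # attached ridge
                beam_lo, beam_hi = wall_hi, wall_hi + c.trab_thickness
                lab2[x0:x1, beam_lo:beam_hi] = Label.TISSUE_TRABECULA
            trab_spans.append((x0, x1))

    top_tissue = wall_hi
    if c.trabecula == "detached":
        top_tissue = wall_hi + c.cleft + c.trab_thickness
    elif c.trabecula == "attached":
        top_tissue = wall_hi + c.trab_thickness
    elec_row = top_tissue + c.electrode_offset
    if elec_row + 1 + c.bath_above > ny:
        raise ValueError("electrode does not fit inside the bath")
    ex0, ex1 = c.electrode_margin, c.nx - c.electrode_margin
    lab2[ex0:ex1, elec_row] = Label.ELECTRODE

    labels = lab2 if c.nz == 0 else np.repeat(lab2[:, :, None], c.nz, axis=2)
    grid = LabeledGrid(spacing_um=c.spacing_um, cell_labels=labels)
    grid.meta.update(
        kind="slab", wall_lo=wall_lo, wall_hi=wall_hi, trab_spans=trab_spans,
        trabecula=c.trabecula, cleft=c.cleft, trab_thickness=c.trab_thickness,
        elec_row=elec_row, trabecular_axis=_axis_vec(grid.ndim, 0),
        endo_sets=("endocardium", "trabecula_proximal_face", "trabecula_distal_face"),
    )
    _slab_node_sets(grid, c)
    return grid


def _trabecula_spans(nx: int, length: int, n: int, seed: Optional[int]) -> list[int]:
    """Start columns for n non-overlapping trabeculae (with end attachments)."""
    slot = nx // n
    if length + 4 > slot:
        raise ValueError("trabeculae do not fit side by side")
    rng = np.random.default_rng(seed)
    xs = []
    for k in range(n):
        lo, hi = k * slot + 2, (k + 1) * slot - length - 2
        xs.append(int((lo + hi) // 2 if seed is None else rng.integers(lo, hi + 1)))
    return xs


def _axis_vec(ndim: int, axis: int) -> np.ndarray:
    v = np.zeros(ndim)
    v[axis] = 1.0
    return v


def _slab_node_sets(grid: LabeledGrid, c: SlabConfig) -> None:
    ns = grid.node_shape
    iface = np.zeros(grid.n_nodes, dtype=bool)
    iface[grid.interface_nodes()] = True
    iface = iface.reshape(ns)

    coords = np.indices(ns)
    y = coords[1]
    epi = iface & (y == c.bath_below)

    prox = np.zeros(ns, dtype=bool)
    dist = np.zeros(ns, dtype=bool)
    wall_hi = grid.meta["wall_hi"]
    if c.trabecula == "detached":
        beam_lo = wall_hi + c.cleft
        beam_hi = beam_lo + c.trab_thickness
        for (x0, x1) in grid.meta["trab_spans"]:
            sl = (slice(x0 + 1, x1),)  # interior nodes only: ends touch attachments
            prox[sl[0], beam_hi] = True
            dist[sl[0], beam_lo] = True
    elif c.trabecula == "attached":
        beam_hi = wall_hi + c.trab_thickness
        for (x0, x1) in grid.meta["trab_spans"]:
            prox[x0:x1 + 1, beam_hi] = True
        # an attached ridge has no wall-facing surface: distal set stays empty
    prox &= iface
    dist &= iface

    endo = iface & ~epi & ~prox & ~dist

    elec_nodes = grid._nodes_touching(grid.cell_labels == Label.ELECTRODE)
    ground_nodes = np.zeros(ns, dtype=bool)
    ground_nodes[:, 0] = True  # outer boundary below the ground layer

    grid.node_sets = {
        "endocardium": np.flatnonzero(endo.ravel()),
        "epicardium": np.flatnonzero(epi.ravel()),
        "trabecula_proximal_face": np.flatnonzero(prox.ravel()),
        "trabecula_distal_face": np.flatnonzero(dist.ravel()),
        "electrode_nodes": np.flatnonzero(elec_nodes.ravel()),
        "ground_boundary": np.flatnonzero(ground_nodes.ravel()),
    }


# ======================================================================
# annulus builder
# ======================================================================

@dataclass
class AnnulusConfig:
    """Annular wall around a circular blood cavity with a central electrode.

    A radial-field analogue of an intracavitary catheter: the field decays
    ~1/r so it is stronger on the endocardium than on the epicardium.
    Radii in cells from the domain centre.
    """

    n: int = 64                 # square domain, n x n cells
    spacing_um: float = 250.0
    r_endo: float = 18.0
    wall: float = 8.0
    r_electrode: float = 2.5
    n_trabeculae: int = 0
    trab_thickness: float = 2.0
    cleft: float = 2.0
    trab_arc_deg: float = 40.0
    seed: Optional[int] = None


def build_annulus_cavity(config: AnnulusConfig) -> LabeledGrid:
    c = config
    if c.r_endo <= 0:
        raise ValueError("inner bath radius must be positive")
    if c.wall < 3:
        raise ValueError("wall thinner than 3 cells has no transmural resolution")
    r_epi = c.r_endo + c.wall
    if r_epi + 2 >= c.n / 2:
        raise ValueError("annulus does not fit inside the domain")

    idx = np.indices((c.n, c.n)).astype(float) + 0.5
    cx = cy = c.n / 2.0
    dx, dy = idx[0] - cx, idx[1] - cy
    r = np.hypot(dx, dy)
    theta = np.arctan2(dy, dx)

    lab = np.full((c.n, c.n), int(Label.BATH), dtype=np.int8)
    lab[(r >= c.r_endo) & (r < r_epi)] = Label.TISSUE
    lab[r < c.r_electrode] = Label.ELECTRODE
    rim = np.zeros_like(lab, dtype=bool)
    rim[0, :] = rim[-1, :] = rim[:, 0] = rim[:, -1] = True
    lab[rim] = Label.GROUND

    if c.n_trabeculae > 0:
        rng = np.random.default_rng(c.seed)
        base = rng.uniform(0, 2 * np.pi) if c.seed is not None else 0.0
        half = np.deg2rad(c.trab_arc_deg) / 2.0
        beam_hi = c.r_endo - c.cleft          # outer radius of the beam
        beam_lo = beam_hi - c.trab_thickness
        if beam_lo <= c.r_electrode + 1:
            raise ValueError("trabecula thicker than the cavity clearance")
        for k in range(c.n_trabeculae):
            th0 = base + 2 * np.pi * k / c.n_trabeculae
            dth = np.angle(np.exp(1j * (theta - th0)))
            arc = np.abs(dth) <= half
            beam = arc & (r >= beam_lo) & (r < beam_hi)
            cleft_m = arc & (r >= beam_hi) & (r < c.r_endo)
            lab[cleft_m & (lab == Label.BATH)] = Label.CLEFT_BATH
            lab[beam] = Label.TISSUE_TRABECULA
            # end attachments: radial spokes bridging the cleft at the arc ends
            for s in (-1.0, 1.0):
                spoke = (np.abs(np.angle(np.exp(1j * (theta - (th0 + s * half)))))
                         <= np.deg2rad(6.0)) & (r >= beam_lo) & (r < c.r_endo)
                lab[spoke] = Label.TISSUE
        # restore electrode/ground just in case
        lab[r < c.r_electrode] = Label.ELECTRODE
        lab[rim] = Label.GROUND

    grid = LabeledGrid(spacing_um=c.spacing_um, cell_labels=lab)
    grid.meta.update(kind="annulus", r_endo=c.r_endo, r_epi=r_epi,
                     centre=(cx, cy), trabecular_axis="azimuthal",
                     endo_sets=("endocardium", "trabecula_proximal_face",
                                "trabecula_distal_face"))
    _annulus_node_sets(grid, c)
    return grid


def _annulus_node_sets(grid: LabeledGrid, c: AnnulusConfig) -> None:
    ns = grid.node_shape
    iface = np.zeros(grid.n_nodes, dtype=bool)
    iface[grid.interface_nodes()] = True
    iface = iface.reshape(ns)

    nodes = np.indices(ns).astype(float)
    r = np.hypot(nodes[0] - c.n / 2.0, nodes[1] - c.n / 2.0)
    r_epi = c.r_endo + c.wall

    trab_touch = grid._nodes_touching(grid.cell_labels == Label.TISSUE_TRABECULA)
    epi = iface & (r >= r_epi - 0.75) & ~trab_touch
    beam_hi = c.r_endo - c.cleft
    beam_lo = beam_hi - c.trab_thickness
    prox = iface & trab_touch & (r <= beam_lo + 0.5)
    dist = iface & trab_touch & (r >= beam_hi - 0.5)
    endo = iface & ~epi & ~prox & ~dist

    elec = grid._nodes_touching(grid.cell_labels == Label.ELECTRODE)
    gnd = np.zeros(ns, dtype=bool)
    gnd[0, :] = gnd[-1, :] = gnd[:, 0] = gnd[:, -1] = True

    grid.node_sets = {
        "endocardium": np.flatnonzero(endo.ravel()),
        "epicardium": np.flatnonzero(epi.ravel()),
        "trabecula_proximal_face": np.flatnonzero(prox.ravel()),
        "trabecula_distal_face": np.flatnonzero(dist.ravel()),
        "electrode_nodes": np.flatnonzero(elec.ravel()),
        "ground_boundary": np.flatnonzero(gnd.ravel()),
    }


# ======================================================================
# strand builder (solver tests and conduction-velocity calibration)
# ======================================================================

def build_strand(n_cells: int, spacing_um: float = 250.0, width: int = 1) -> LabeledGrid:
    """All-tissue 2-D strand along x (no bath): cable tests and CV runs."""
    lab = np.full((n_cells, width), int(Label.TISSUE), dtype=np.int8)
    grid = LabeledGrid(spacing_um=spacing_um, cell_labels=lab)
    ns = grid.node_shape
    endo = np.zeros(ns, dtype=bool)
    epi = np.zeros(ns, dtype=bool)
    endo[:, -1] = True
    epi[:, 0] = True
    grid.node_sets = {
        "endocardium": np.flatnonzero(endo.ravel()),
        "epicardium": np.flatnonzero(epi.ravel()),
        "trabecula_proximal_face": np.array([], dtype=np.int64),
        "trabecula_distal_face": np.array([], dtype=np.int64),
        "electrode_nodes": np.array([], dtype=np.int64),
        "ground_boundary": np.array([], dtype=np.int64),
    }
    grid.meta.update(kind="strand", trabecular_axis=_axis_vec(2, 0))
    return grid


# ======================================================================
# detachment check
# ======================================================================

def detachment_holds(grid: LabeledGrid) -> bool:
    """True iff every trabecula is wall-connected only via its end attachments.

    Two conditions: (a) removing the attachment cells (wall-tissue cells
    face-adjacent to trabecular cells) disconnects each trabecular component
    from the wall; (b) every mid-span trabecular cell -- one not adjacent to
    an attachment -- has at least one ``CLEFT_BATH`` face neighbour on the
    wall side.  An attached ridge fails (b): its underside is fused to the
    wall, not undercut by a cleft.
    """
    trab = grid.cell_labels == Label.TISSUE_TRABECULA
    if not trab.any():
        return True
    wall = grid.cell_labels == Label.TISSUE
    structure = ndimage.generate_binary_structure(grid.ndim, 1)
    near_wall = ndimage.binary_dilation(wall, structure=structure)
    near_cleft = ndimage.binary_dilation(
        grid.cell_labels == Label.CLEFT_BATH, structure=structure)

    trab_lab, n_trab = ndimage.label(trab, structure=structure)
    for k in range(1, n_trab + 1):
        comp = trab_lab == k
        contact = comp & near_wall
        if not contact.any():
            return False  # floating strand
        # cluster contact cells tolerantly (rasterised attachments may not
        # be face-contiguous): each physical attachment is one cluster
        full = ndimage.generate_binary_structure(grid.ndim, grid.ndim)
        clustered = ndimage.binary_dilation(contact, structure=full)
        _, n_contact = ndimage.label(clustered, structure=full)
        if n_contact != 2:
            return False  # fused along its length (ridge) or single-ended
        if not (comp & near_cleft).any():
            return False  # no bath-filled cleft beneath the span

    # removing the wall cells the trabecula touches must disconnect it
    near_trab = ndimage.binary_dilation(trab, structure=structure)
    attachments = near_trab & wall
    tissue = grid.tissue_cells()
    _, n_full = grid.tissue_components()
    _, n_cut = grid.tissue_components(tissue & ~attachments)
    return n_cut >= n_full + n_trab
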