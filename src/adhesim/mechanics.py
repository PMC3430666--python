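"""Geometry and motion of ring-of-bodies model cells.

Each cell is a ring of ten boundary bodies plus a central body (the
centroid).  All distances are in simulation units (1 unit = 10 microns);
the default cell radius is 1.5 units (15 um) and the circular field has
radius 50 units (500 um).

Cells move by a combination of per-body Brownian jiggle, a shared
whole-cell Brownian step, and a persistent "leading edge" drift whose
direction is resampled at a fixed per-step probability.  Ring geometry is
maintained by iterative position-based relaxation; overlapping cells are
pushed apart stochastically (volume exclusion) and confined to the field
by radial projection.

For performance all operations act on a :class:`CellField` holding every
cell in struct-of-array form; :class:`Cell` / :class:`Body` offer a
per-cell object view for inspection and small-scale tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from . import _kernels

RED = 0
GREEN = 1
TYPE_NAMES = {RED: "RED", GREEN: "GREEN"}
TYPE_CODES = {"RED": RED, "GREEN": GREEN}

N_RING = 10
CENTROID = "CENTROID"

#: chord of a regular decagon with unit circumradius
_DECAGON_CHORD = 2.0 * np.sin(np.pi / N_RING)


@dataclass
class MotionParams:
    """Per-step motion scales, all in simulation units (1 unit = 10 um).

    sigma_body : scale of the independent random displacement of each
        ring body; sigma_centre : scale of the shared whole-cell random
        step; v_edge : leading-edge drift per step; p_new_edge :
        probability per step that a new random edge direction replaces
        the current one (mean edge lifetime = 1/p_new_edge steps).
    """

    sigma_body: float = 0.03
    sigma_centre: float = 0.04
    v_edge: float = 0.04
    p_new_edge: float = 0.08
    r_cell: float = 1.5
    R_field: float = 50.0
    ring_tol: float = 0.05      # tolerance band, fraction of r_cell
    max_relax_iter: int = 10

    def __post_init__(self) -> None:
        for name in ("sigma_body", "sigma_centre", "v_edge", "p_new_edge"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 <= self.p_new_edge <= 1:
            raise ValueError("p_new_edge must be a probability")
        if not 0 < self.r_cell < self.R_field:
            raise ValueError("need 0 < r_cell < R_field")


@dataclass
class ExclusionParams:
    """Stochastic volume exclusion between overlapping cell pairs.

    A pair with centroid separation below one cell diameter is pushed
    apart with probability ``p_repel``; on a repulsion event each cell
    moves ``k_repel`` times the overlap depth along the centroid axis.
    ENHANCED mode models increased contact repulsion (every overlap
    resolved each step).
    """

    p_repel: float = 0.25
    k_repel: float = 0.5
    mode: str = "BASIC"

    def __post_init__(self) -> None:
        if not 0 <= self.p_repel <= 1:
            raise ValueError("p_repel must be in [0, 1]")
        if self.k_repel < 0:
            raise ValueError("k_repel must be non-negative")
        if self.mode not in ("BASIC", "ENHANCED"):
            raise ValueError("mode must be BASIC or ENHANCED")

    @classmethod
    def enhanced(cls) -> "ExclusionParams":
        return cls(p_repel=1.0, k_repel=0.5, mode="ENHANCED")


@dataclass
class Body:
    """A single point mass: one of the ten ring bodies or the centroid."""

    position: np.ndarray
    cell_id: int
    ring_index: object  # 0..9 or CENTROID
    hook_age: int = 0


@dataclass
class Cell:
    """Object view of one model cell (ring of 10 bodies + centroid)."""

    id: int
    type_label: str
    centroid: Body
    ring: list
    edge_direction: np.ndarray
    edge_active: bool = True


class CellField:
    """All cells of a simulation in struct-of-array form.

    Attributes
    ----------
    ring : (n, 10, 2) float array of ring-body positions
    centroid : (n, 2) float array
    types : (n,) int array, RED=0 / GREEN=1
    edge_dir : (n, 2) unit vectors of the current leading edge
    """

    def __init__(self, centroid, types, ring=None, edge_dir=None, r_cell=1.5):
        self.centroid = np.asarray(centroid, dtype=float).reshape(-1, 2).copy()
        n = len(self.centroid)
        self.types = np.asarray(types, dtype=np.int8).reshape(n).copy()
        if ring is None:
            ring = regular_ring(self.centroid, r_cell)
        self.ring = np.asarray(ring, dtype=float).reshape(n, N_RING, 2).copy()
        if edge_dir is None:
            ang = np.zeros(n)
            edge_dir = np.column_stack([np.cos(ang), np.sin(ang)])
        self.edge_dir = np.asarray(edge_dir, dtype=float).reshape(n, 2).copy()

    @property
    def n_cells(self) -> int:
        return len(self.centroid)

    def bodies_flat(self) -> np.ndarray:
        """View of all ring bodies as a (n*10, 2) array (shares memory)."""
        return self.ring.reshape(-1, 2)

    def copy(self) -> "CellField":
        return CellField(self.centroid, self.types, self.ring, self.edge_dir)

    def translate(self, delta) -> "CellField":
        delta = np.asarray(delta, dtype=float)
        self.centroid += delta
        self.ring += delta
        return self

    def cell(self, i: int) -> Cell:
        """Object view of cell ``i`` (copies positions)."""
        ring = [
            Body(self.ring[i, j].copy(), i, j) for j in range(N_RING)
        ]
        return Cell(
            id=i,
            type_label=TYPE_NAMES[int(self.types[i])],
            centroid=Body(self.centroid[i].copy(), i, CENTROID),
            ring=ring,
            edge_direction=self.edge_dir[i].copy(),
        )


def regular_ring(centres, r_cell: float) -> np.ndarray:
    """Regular-decagon ring positions around each centre."""
    centres = np.asarray(centres, dtype=float).reshape(-1, 2)
    ang = 2 * np.pi * np.arange(N_RING) / N_RING
    offsets = r_cell * np.column_stack([np.cos(ang), np.sin(ang)])
    return centres[:, None, :] + offsets[None, :, :]


def random_move(field: CellField, params: MotionParams, rng) -> CellField:
    """Brownian update: independent jiggle of every ring body plus one
    shared random step per cell applied to all eleven bodies."""
    n = field.n_cells
    if params.sigma_body > 0:
        field.ring += rng.normal(0.0, params.sigma_body, size=(n, N_RING, 2))
    centre_step = rng.normal(0.0, params.sigma_centre, size=(n, 2)) \
        if params.sigma_centre > 0 else np.zeros((n, 2))
    field.ring += centre_step[:, None, :]
    field.centroid += centre_step
    return field


def update_leading_edge(field: CellField, params: MotionParams, rng) -> CellField:
    """Persistent directed motion: with probability ``p_new_edge`` a new
    uniform random direction replaces the current edge, then the whole
    cell drifts ``v_edge`` along it."""
    n = field.n_cells
    if params.p_new_edge > 0:
        renew = rng.random(n) < params.p_new_edge
        k = int(renew.sum())
        if k:
            ang = rng.uniform(0.0, 2 * np.pi, size=k)
            field.edge_dir[renew] = np.column_stack([np.cos(ang), np.sin(ang)])
    if params.v_edge > 0:
        step = params.v_edge * field.edge_dir
        field.centroid += step
        field.ring += step[:, None, :]
    return field


_RING_ANGLES = 2 * np.pi * np.arange(N_RING) / N_RING
_COSN = np.cos(_RING_ANGLES)
_SINN = np.sin(_RING_ANGLES)


def enforce_constraints(field: CellField, params: MotionParams) -> CellField:
    """Iterative shape-matching relaxation of ring geometry.

    Each sweep fits the rotation that best aligns the regular decagon
    of radius ``r_cell`` with the current ring (2D Procrustes) and
    moves every body a fraction of the way toward its fitted nominal
    position; sweeps repeat until the largest centroid-distance error
    is within the tolerance band or ``max_relax_iter`` sweeps have run
    (then a warning is issued and positions are returned as-is).  The
    fit preserves angular ordering by construction and untangles rings
    whose bodies have crossed.  The centroid participates as an 11th
    body: each sweep it relaxes toward the ring's centre of mass, so
    external pulls on ring bodies (hooks, collisions) translate the
    whole cell.
    """
    r = params.r_cell
    tol = params.ring_tol * r
    converged = _kernels.relax_rings(field.ring, field.centroid,
                                     _COSN, _SINN, r, tol, 0.6,
                                     params.max_relax_iter)
    if not converged:
        warnings.warn(
            "ring relaxation did not converge within max_relax_iter",
            RuntimeWarning,
            stacklevel=2,
        )
    return field


def apply_exclusion(field: CellField, params: ExclusionParams,
                    motion: MotionParams, rng) -> CellField:
    """Stochastic volume exclusion on centroid overlap.

    Every cell pair closer than one diameter is, with probability
    ``p_repel``, pushed apart rigidly along the centroid axis by
    ``k_repel`` times the overlap depth (per cell); otherwise the
    overlap is tolerated this step.
    """
    if params.p_repel == 0 or field.n_cells < 2:
        return field
    contact = 2.0 * motion.r_cell
    pairs = _kernels.neighbor_pairs(field.centroid, contact)
    if len(pairs) == 0:
        return field
    act = rng.random(len(pairs)) < params.p_repel
    pairs = pairs[act]
    if len(pairs) == 0:
        return field
    i, j = pairs[:, 0], pairs[:, 1]
    axis = field.centroid[j] - field.centroid[i]
    dist = np.linalg.norm(axis, axis=-1)
    # coincident centroids: push along a fixed axis
    unit = np.where(dist[:, None] > 1e-12,
                    axis / np.maximum(dist, 1e-12)[:, None],
                    np.array([1.0, 0.0]))
    push = params.k_repel * (contact - dist)
    disp = np.zeros_like(field.centroid)
    np.add.at(disp, i, -unit * push[:, None])
    np.add.at(disp, j, unit * push[:, None])
    field.centroid += disp
    field.ring += disp[:, None, :]
    return field


def confine_to_field(field: CellField, params: MotionParams) -> CellField:
    """Project any centroid outside the field radius back onto the
    boundary; the ring follows rigidly.  Idempotent."""
    r = np.linalg.norm(field.centroid, axis=-1)
    out = r > params.R_field
    if out.any():
        shift = field.centroid[out] * (params.R_field / r[out] - 1.0)[:, None]
        field.centroid[out] += shift
        field.ring[out] += shift[:, None, :]
    return field
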