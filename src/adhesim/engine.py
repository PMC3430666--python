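"""Simulation orchestration: initial configurations, the per-step update
schedule, replicate management and snapshot emission.

A run holds a :class:`~adhesim.mechanics.CellField` plus a
:class:`~adhesim.adhesion.HookSet` and advances them one virtual time
step at a time in a fixed sub-operation order (drift, Brownian move,
hook pull, ring relaxation, volume exclusion, confinement, hook
breakage, hook formation).  Snapshots of the typed cell centres are
collected into a :class:`FrameStack` with coordinates in microns.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field as dc_field, replace

import numpy as np
from scipy.spatial import cKDTree

from . import adhesion, mechanics
from .adhesion import AdhesionParams, HookSet
from .mechanics import (GREEN, RED, TYPE_NAMES, CellField, ExclusionParams,
                        MotionParams)

#: microns per simulation distance unit
UM_PER_UNIT = 10.0

INIT_MODES = ("RANDOM_MIX", "SPLIT_HALVES")


def max_packed_cells(R_field: float, r_cell: float) -> int:
    """Maximum number of hexagonally close-packed discs of radius
    ``r_cell`` in a circular field of radius ``R_field``.

    Each disc occupies a hexagon of area 2 r^2 sqrt(3), so the count is
    floor(pi R^2 / (2 r^2 sqrt(3))): 1007 cells of radius 15 um in a
    500 um field.  Both radii must share the same length unit.
    """
    if not (R_field > 0 and r_cell > 0):
        raise ValueError("radii must be positive")
    if r_cell >= R_field:
        raise ValueError("r_cell must be smaller than R_field")
    return int(math.floor(math.pi * R_field**2 / (2.0 * r_cell**2 * math.sqrt(3))))


@dataclass
class SimConfig:
    """Complete specification of one simulation run."""

    n_cells: int = 500
    red_fraction: float = 0.5
    motion: MotionParams = dc_field(default_factory=MotionParams)
    exclusion: ExclusionParams = dc_field(default_factory=ExclusionParams)
    adhesion: AdhesionParams = dc_field(default_factory=AdhesionParams)
    n_steps: int = 10_000
    snapshot_every: int = 100
    seed: int = 0
    init_mode: str = "RANDOM_MIX"

    def __post_init__(self) -> None:
        cap = max_packed_cells(self.motion.R_field, self.motion.r_cell)
        if self.n_cells < 1 or self.n_cells > cap:
            raise ValueError(
                f"n_cells must be in [1, {cap}] for this field geometry")
        if not 0 <= self.red_fraction <= 1:
            raise ValueError("red_fraction must be in [0, 1]")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if self.snapshot_every < 1:
            raise ValueError("snapshot_every must be >= 1")
        if self.init_mode not in INIT_MODES:
            raise ValueError(f"init_mode must be one of {INIT_MODES}")

    def replicate(self, k: int) -> "SimConfig":
        """Copy of this config with seed = base seed + k."""
        return replace(self, seed=self.seed + k)


@dataclass
class FrameStack:
    """Time-ordered snapshots of typed cell-centre positions.

    ``xy`` has shape (n_frames, n_cells, 2); coordinates are microns
    (origin at the field centre) unless ``units`` says otherwise.  Cell
    identity is positional: column i is the same cell in every frame.
    """

    times: np.ndarray          # (T,) step indices, strictly increasing
    xy: np.ndarray             # (T, N, 2)
    types: np.ndarray          # (N,) int codes RED/GREEN
    units: str = "um"

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times)
        self.xy = np.asarray(self.xy, dtype=float)
        self.types = np.asarray(self.types)
        if self.xy.ndim != 3 or self.xy.shape[0] != len(self.times):
            raise ValueError("xy must be (n_frames, n_cells, 2)")
        if self.xy.shape[1] != len(self.types):
            raise ValueError("types length must match cell count")
        if len(self.times) > 1 and not (np.diff(self.times) > 0).all():
            raise ValueError("times must be strictly increasing")
        if np.isnan(self.xy).any():
            raise ValueError("frame coordinates contain NaN")

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_cells(self) -> int:
        return self.xy.shape[1]

    def frame(self, i: int):
        """(points, labels) of frame ``i``."""
        return self.xy[i], self.types

    def type_labels(self) -> np.ndarray:
        return np.array([TYPE_NAMES[int(t)] for t in self.types])

    def tail(self, n_frames: int) -> "FrameStack":
        """The last ``n_frames`` snapshots."""
        return FrameStack(self.times[-n_frames:], self.xy[-n_frames:],
                          self.types, self.units)


def _assign_types(n_cells: int, red_fraction: float, rng) -> np.ndarray:
    n_red = int(round(red_fraction * n_cells))
    types = np.full(n_cells, GREEN, dtype=np.int8)
    types[:n_red] = RED
    rng.shuffle(types)
    return types


def _sample_disc(n: int, radius: float, rng) -> np.ndarray:
    r = radius * np.sqrt(rng.random(n))
    th = rng.uniform(0.0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _relax_overlaps(centres: np.ndarray, r_cell: float, R_max: float,
                    max_iter: int = 300) -> np.ndarray:
    """Deterministically push overlapping centres apart until hard-core
    violations are (nearly) resolved; used only at initialisation."""
    contact = 2.0 * r_cell
    for _ in range(max_iter):
        pairs = cKDTree(centres).query_pairs(contact * 0.999,
                                             output_type="ndarray")
        if len(pairs) == 0:
            break
        i, j = pairs[:, 0], pairs[:, 1]
        axis = centres[j] - centres[i]
        dist = np.linalg.norm(axis, axis=-1)
        unit = np.where(dist[:, None] > 1e-12,
                        axis / np.maximum(dist, 1e-12)[:, None],
                        np.array([1.0, 0.0]))
        push = 0.3 * (contact - dist)
        disp = np.zeros_like(centres)
        np.add.at(disp, i, -unit * push[:, None])
        np.add.at(disp, j, unit * push[:, None])
        centres += disp
        r = np.linalg.norm(centres, axis=-1)
        out = r > R_max
        if out.any():
            centres[out] *= (R_max / r[out])[:, None]
    return centres


def init_random_mix(config: SimConfig, rng) -> CellField:
    """Uniformly mixed starting state: non-overlapping cells placed
    uniformly in the field, types assigned at random in the exact
    red/green proportions."""
    m = config.motion
    centres = _sample_disc(config.n_cells, m.R_field - m.r_cell, rng)
    centres = _relax_overlaps(centres, m.r_cell, m.R_field - m.r_cell * 0.5)
    types = _assign_types(config.n_cells, config.red_fraction, rng)
    return CellField(centres, types, r_cell=m.r_cell)


def init_split_halves(config: SimConfig, rng) -> CellField:
    """Artificially segregated start: every RED cell in the left
    half-disc (x <= 0), every GREEN cell in the right (x >= 0)."""
    m = config.motion
    centres = _sample_disc(config.n_cells, m.R_field - m.r_cell, rng)
    types = _assign_types(config.n_cells, config.red_fraction, rng)
    x = centres[:, 0]
    left = types == RED
    centres[:, 0] = np.where(left, -np.abs(x), np.abs(x))
    centres = _relax_overlaps(centres, m.r_cell, m.R_field - m.r_cell * 0.5)
    # overlap relaxation may nudge border cells across the diameter;
    # restore the half-disc invariant exactly
    centres[:, 0] = np.where(left, -np.abs(centres[:, 0]),
                             np.abs(centres[:, 0]))
    return CellField(centres, types, r_cell=m.r_cell)


def init_cells(config: SimConfig, rng) -> CellField:
    if config.init_mode == "SPLIT_HALVES":
        return init_split_halves(config, rng)
    return init_random_mix(config, rng)


def step(field: CellField, hooks: HookSet, config: SimConfig, rng):
    """Advance the simulation by one virtual time step.

    Fixed sub-operation order: leading-edge drift, Brownian moves, hook
    pull, ring relaxation, volume exclusion, field confinement, hook
    breakage, hook formation.
    """
    m, ex, ad = config.motion, config.exclusion, config.adhesion
    mechanics.update_leading_edge(field, m, rng)
    mechanics.random_move(field, m, rng)
    adhesion.apply_hook_constraint(field, hooks, ad)
    mechanics.enforce_constraints(field, m)
    mechanics.apply_exclusion(field, ex, m, rng)
    mechanics.confine_to_field(field, m)
    adhesion.break_hooks(hooks, ad, rng)
    adhesion.form_hooks(field, hooks, ad, rng)
    return field, hooks


def run(config: SimConfig, progress: bool = False,
        initial: CellField | None = None,
        return_state: bool = False):
    """Execute a full simulation and return centre snapshots in microns.

    Frames are recorded at step 0, every ``snapshot_every`` steps, and
    at the final step.  The run is fully determined by ``config.seed``.
    With ``return_state`` (debug) the final full state is returned too,
    as ``(stack, field, hooks)``.
    """
    rng = np.random.default_rng(config.seed)
    field = initial.copy() if initial is not None else init_cells(config, rng)
    hooks = HookSet(field.n_cells)
    times = [0]
    snaps = [field.centroid.copy()]
    iterator = range(1, config.n_steps + 1)
    if progress:  # pragma: no cover - cosmetic
        from tqdm import tqdm
        iterator = tqdm(iterator, desc="simulate", unit="step")
    for t in iterator:
        step(field, hooks, config, rng)
        if t % config.snapshot_every == 0 or t == config.n_steps:
            times.append(t)
            snaps.append(field.centroid.copy())
    xy = np.stack(snaps) * UM_PER_UNIT
    stack = FrameStack(np.asarray(times), xy, field.types.copy(), units="um")
    if return_state:
        return stack, field, hooks
    return stack
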