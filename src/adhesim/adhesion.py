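"""Inter-cell adhesion: stochastic hooks between boundary bodies.

A hook is a breakable cross-link between ring bodies of two different
cells — the model's analogue of a cadherin-mediated junction.  Hooks
break each step with probability ``unhook`` (0 = permanent, 1 =
immediate), optionally reduced with link age by a Gaussian-in-time
strengthening rule of width ``seize`` so that links a few ``seize``
steps old are effectively permanent.  In two-population experiments
hooks form only between cells of like type (differential adhesion).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from . import _kernels
from .mechanics import CellField, N_RING


@dataclass
class AdhesionParams:
    """Hook kinetics.

    unhook : per-step breakage probability of a fresh link.
    seize : width (steps) of the Gaussian decay of ``unhook`` with link
        age; ``inf`` disables strengthening.
    hook_range : capture distance between bodies, simulation units.
    p_hook : formation probability per eligible in-range body pair.
    like_type_only : restrict links to cells of equal type (the
        differential-adhesion rule).
    k_hook : fraction of the beyond-contact separation removed per step
        by a link's pull; contact_dist is the resting separation.
    """

    unhook: float = 5e-5
    seize: float = math.inf
    hook_range: float = 0.3
    p_hook: float = 0.2
    like_type_only: bool = True
    k_hook: float = 0.5
    contact_dist: float = 0.0

    def __post_init__(self) -> None:
        if not 0 <= self.unhook <= 1:
            raise ValueError("unhook must be in [0, 1]")
        if not self.seize > 0:
            raise ValueError("seize must be positive (inf to disable)")
        if self.hook_range <= 0:
            raise ValueError("hook_range must be positive")
        if not 0 <= self.p_hook <= 1:
            raise ValueError("p_hook must be a probability")


@dataclass
class Hook:
    """One cross-link, for inspection; the engine stores hooks as arrays."""

    body_a: int  # flat body index (cell*10 + ring position)
    body_b: int
    age: int


class HookSet:
    """All hooks of a simulation as parallel arrays over flat body index.

    ``partner[b]`` is the flat index of the body linked to ``b`` (or -1)
    and ``age[b]`` the steps since that link formed (0 when unlinked).
    Each body carries at most one hook; a hook appears at both of its
    endpoints.
    """

    def __init__(self, n_cells: int):
        n = n_cells * N_RING
        self.partner = np.full(n, -1, dtype=np.int64)
        self.age = np.zeros(n, dtype=np.int64)

    @property
    def n_hooks(self) -> int:
        return int((self.partner >= 0).sum()) // 2

    def pairs(self) -> np.ndarray:
        """(m, 2) array of linked flat body pairs, each pair once."""
        a = np.where(self.partner >= 0)[0]
        a = a[self.partner[a] > a]
        return np.column_stack([a, self.partner[a]])

    def as_hooks(self) -> list:
        return [Hook(int(a), int(b), int(self.age[a]))
                for a, b in self.pairs()]

    def validate(self) -> None:
        linked = self.partner >= 0
        back = self.partner[self.partner[linked]]
        if not np.array_equal(back, np.where(linked)[0]):
            raise AssertionError("hook partner arrays are not symmetric")
        if (self.age[linked] < 1).any() or (self.age[~linked] != 0).any():
            raise AssertionError("hook age inconsistent with link state")


def effective_unhook(P, t, s):
    """Age-weakened breakage probability P' = P * exp(-t^2 / (2 s^2)).

    Equals ``P`` at formation (t = 0), decays monotonically with link
    age ``t``, and is below 3.4e-4 * P by t = 4 s — an effectively
    permanent link.  ``s = inf`` disables strengthening (P' = P for all
    ages).  Accepts scalar or array ``t``.
    """
    if not s > 0:
        raise ValueError("seize width s must be positive")
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise ValueError("link age must be non-negative")
    if math.isinf(s):
        out = np.broadcast_to(np.asarray(P, dtype=float), t.shape).copy()
    else:
        out = P * np.exp(-(t * t) / (2.0 * s * s))
    return float(out) if out.ndim == 0 else out


def form_hooks(field: CellField, hooks: HookSet, params: AdhesionParams,
               rng) -> HookSet:
    """Form new hooks between unlinked bodies of different cells.

    Candidate pairs are unlinked bodies within ``hook_range`` belonging
    to different cells (and of equal cell type when ``like_type_only``);
    each survives a ``p_hook`` coin flip, then pairs are granted in
    order of increasing separation (ties: lowest owning cell id, then
    body index) so that the nearest eligible partner wins and no body
    holds two hooks.  New hooks start with age 1.
    """
    free_idx = np.where(hooks.partner < 0)[0]
    if len(free_idx) < 2:
        return hooks
    pos = field.bodies_flat()[free_idx]
    cand = _kernels.neighbor_pairs(pos, params.hook_range)
    if len(cand) == 0:
        return hooks
    a = free_idx[cand[:, 0]]
    b = free_idx[cand[:, 1]]
    cell_a, cell_b = a // N_RING, b // N_RING
    ok = cell_a != cell_b
    if params.like_type_only:
        ok &= field.types[cell_a] == field.types[cell_b]
    if params.p_hook < 1.0:
        ok &= rng.random(len(a)) < params.p_hook
    a, b = a[ok], b[ok]
    if len(a) == 0:
        return hooks
    d = np.linalg.norm(field.bodies_flat()[a] - field.bodies_flat()[b],
                       axis=-1)
    lo = np.minimum(a, b)
    hi = np.maximum(a, b)
    order = np.lexsort((hi, lo // N_RING, d)).astype(np.int64)
    free = hooks.partner < 0
    take = _kernels.greedy_match(order, a, b, free)
    a, b = a[take], b[take]
    hooks.partner[a] = b
    hooks.partner[b] = a
    hooks.age[a] = 1
    hooks.age[b] = 1
    return hooks


def break_hooks(hooks: HookSet, params: AdhesionParams, rng) -> HookSet:
    """Break each hook independently with its age-dependent probability.

    A hook of age t breaks with probability
    ``effective_unhook(unhook, t, seize)``; survivors age by one step
    and broken hooks reset both endpoints' ages to zero.  With
    strengthening disabled the resulting lifetimes are geometric with
    mean 1/unhook.
    """
    pairs = hooks.pairs()
    if len(pairs) == 0:
        return hooks
    age = hooks.age[pairs[:, 0]]
    p = effective_unhook(params.unhook, age, params.seize)
    gone = rng.random(len(pairs)) < p
    dead = pairs[gone].ravel()
    hooks.partner[dead] = -1
    hooks.age[dead] = 0
    alive = pairs[~gone].ravel()
    hooks.age[alive] += 1
    return hooks


def apply_hook_constraint(field: CellField, hooks: HookSet,
                          params: AdhesionParams) -> CellField:
    """Pull linked body pairs together.

    Each endpoint moves toward the pair midpoint by half of
    ``k_hook * (separation - contact_dist)``; pairs at or inside the
    contact distance are left alone.
    """
    pairs = hooks.pairs()
    if len(pairs) == 0:
        return field
    flat = field.bodies_flat()
    pa, pb = flat[pairs[:, 0]], flat[pairs[:, 1]]
    delta = pb - pa
    sep = np.linalg.norm(delta, axis=-1)
    excess = np.maximum(sep - params.contact_dist, 0.0)
    move = 0.5 * params.k_hook * excess / np.maximum(sep, 1e-12)
    flat[pairs[:, 0]] += delta * move[:, None]
    flat[pairs[:, 1]] -= delta * move[:, None]
    return field
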