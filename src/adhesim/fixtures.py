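"""Synthetic labelled point patterns with controlled segregation.

These generators emulate digitized two-colour cell-centre fields — a
random monolayer (CSR), a partially clustered pattern, and a fully
split field — so the RDF/score/MSD stack can be exercised and tested
without running the simulator or touching any imaging data.  All
fixtures are deterministic under their seed, have exact label counts
and keep every point inside the circular field.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .engine import FrameStack
from .mechanics import GREEN, RED, TYPE_NAMES

PATTERNS = ("CSR", "CLUSTERED", "SPLIT_HALVES")


@dataclass
class FixtureSpec:
    """Recipe for one synthetic typed point field (coordinates in um).

    ``min_separation`` is an optional hard-core distance: 30 um (one
    cell diameter) emulates a confluent monolayer, 0 gives ideal CSR
    for normalisation tests.
    """

    n_points: int = 500
    red_fraction: float = 0.5
    field_radius: float = 500.0
    pattern: str = "CSR"
    n_clusters: int = 6
    cluster_radius: float = 40.0
    min_separation: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_points < 2:
            raise ValueError("n_points must be >= 2")
        if self.pattern not in PATTERNS:
            raise ValueError(f"pattern must be one of {PATTERNS}")
        if self.field_radius <= 0 or self.cluster_radius <= 0:
            raise ValueError("radii must be positive")
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if self.min_separation < 0:
            raise ValueError("min_separation must be non-negative")


def _labels(n: int, red_fraction: float, rng) -> np.ndarray:
    n_red = int(round(red_fraction * n))
    lab = np.full(n, GREEN, dtype=int)
    lab[:n_red] = RED
    rng.shuffle(lab)
    return lab


def _sample_disc(n: int, R: float, rng) -> np.ndarray:
    r = R * np.sqrt(rng.random(n))
    th = rng.uniform(0, 2 * np.pi, n)
    return np.column_stack([r * np.cos(th), r * np.sin(th)])


def _hard_core_disc(n: int, R: float, sep: float, rng,
                    max_tries_per_point: int = 200,
                    half: int | None = None) -> np.ndarray:
    """Dart-throwing with a hard-core distance; ``half`` = -1/+1
    restricts to the left/right half-disc.  Raises when the packing
    cannot be achieved within the retry budget."""
    pts = np.empty((n, 2))
    placed = 0
    tries = 0
    budget = max_tries_per_point * n
    while placed < n:
        if tries >= budget:
            raise ValueError(
                f"hard-core packing infeasible: placed {placed}/{n} points "
                f"at min_separation={sep}")
        cand = _sample_disc(1, R, rng)[0]
        if half is not None:
            cand[0] = half * abs(cand[0])
        tries += 1
        if placed and (np.linalg.norm(pts[:placed] - cand, axis=1) < sep).any():
            continue
        pts[placed] = cand
        placed += 1
    return pts


def generate(spec: FixtureSpec):
    """Generate one typed point field; returns (points, labels).

    CSR: uniform positions, independent labels.  CLUSTERED: cluster
    centres CSR in the field, members Gaussian around them, labels
    assigned per cluster (pure clusters).  SPLIT_HALVES: red points
    uniform in the left half-disc, green in the right.
    """
    rng = np.random.default_rng(spec.seed)
    n, R = spec.n_points, spec.field_radius
    n_red = int(round(spec.red_fraction * n))

    if spec.pattern == "CSR":
        if spec.min_separation > 0:
            pts = _hard_core_disc(n, R, spec.min_separation, rng)
        else:
            pts = _sample_disc(n, R, rng)
        labels = _labels(n, spec.red_fraction, rng)
        return pts, labels

    if spec.pattern == "SPLIT_HALVES":
        labels = np.concatenate([np.full(n_red, RED), np.full(n - n_red, GREEN)])
        if spec.min_separation > 0:
            left = _hard_core_disc(n_red, R, spec.min_separation, rng, half=-1)
            right = _hard_core_disc(n - n_red, R, spec.min_separation, rng,
                                    half=+1)
        else:
            left = _sample_disc(n_red, R, rng)
            left[:, 0] = -np.abs(left[:, 0])
            right = _sample_disc(n - n_red, R, rng)
            right[:, 0] = np.abs(right[:, 0])
        return np.vstack([left, right]), labels

    # CLUSTERED: allocate points to pure-type clusters so counts are exact
    k = spec.n_clusters
    k_red = max(1, k // 2) if n_red else 0
    k_grn = k - k_red
    if n - n_red and k_grn == 0:
        raise ValueError("need at least one cluster per present type")
    sizes = ([n_red // k_red + (i < n_red % k_red) for i in range(k_red)]
             + [(n - n_red) // k_grn + (i < (n - n_red) % k_grn)
                for i in range(k_grn)])
    cluster_type = [RED] * k_red + [GREEN] * k_grn
    centres = _sample_disc(k, max(R - spec.cluster_radius, 0.1 * R), rng)
    pts_list, lab_list = [], []
    for size, ctype, centre in zip(sizes, cluster_type, centres):
        kept = np.empty((size, 2))
        got = 0
        while got < size:
            cand = centre + rng.normal(0, spec.cluster_radius,
                                       size=(size - got, 2))
            ok = np.linalg.norm(cand, axis=1) <= R
            take = cand[ok]
            kept[got:got + len(take)] = take
            got += len(take)
        pts_list.append(kept)
        lab_list.append(np.full(size, ctype))
    pts = np.vstack(pts_list)
    labels = np.concatenate(lab_list)
    if spec.min_separation > 0:
        # thin-plate style repair: resample offending points
        tree_ok = False
        for _ in range(50):
            pairs = cKDTree(pts).query_pairs(spec.min_separation,
                                             output_type="ndarray")
            if len(pairs) == 0:
                tree_ok = True
                break
            move = np.unique(pairs[:, 1])
            pts[move] += rng.normal(0, spec.min_separation, size=(len(move), 2))
            r = np.linalg.norm(pts[move], axis=1)
            far = r > R
            pts[move[far]] *= (R / r[far])[:, None]
        if not tree_ok:
            raise ValueError("hard-core packing infeasible for clustered fixture")
    return pts, labels


def generate_frame(spec: FixtureSpec) -> pd.DataFrame:
    """Fixture as a single-frame table (columns x_um, y_um, type)."""
    pts, labels = generate(spec)
    return pd.DataFrame({
        "x_um": pts[:, 0],
        "y_um": pts[:, 1],
        "type": [TYPE_NAMES[int(l)] for l in labels],
    })


def generate_walk(n_cells: int, n_frames: int, step_sigma: float,
                  seed: int = 0, dt: float = 1.0) -> FrameStack:
    """Independent 2D Gaussian random walks as a FrameStack.

    ``step_sigma`` is the diffusive scale sqrt(D dt): per-frame
    increments have per-axis variance 2 * step_sigma^2, so the
    ground-truth MSD slope is 4 * step_sigma^2 / dt (the 2D relation
    MSD = 4 D tau).  Coordinates are emitted in the stack's raw units
    with ``units="units"``.
    """
    if n_frames < 2:
        raise ValueError("n_frames must be >= 2")
    if step_sigma < 0:
        raise ValueError("step_sigma must be non-negative")
    rng = np.random.default_rng(seed)
    steps = rng.normal(0.0, np.sqrt(2.0) * step_sigma,
                       size=(n_frames - 1, n_cells, 2))
    xy = np.concatenate([np.zeros((1, n_cells, 2)), np.cumsum(steps, axis=0)])
    times = np.arange(n_frames) * dt
    types = np.zeros(n_cells, dtype=int)
    return FrameStack(times, xy, types, units="units")
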