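"""Simulated experiments on syntaxin membrane patches.

Four in-silico assays probe what the degree of clustering means for
membrane physiology:

* **FRAP** — molecules inside a disc covering 10% of the membrane area
  are marked bleached; the return of fluorescent molecules into the disc
  reports on the exchange between clustered and mobile pools.
* **Membrane coverage** — the disk is tiled with vesicle-sized (40 nm)
  compartments and the fraction visited by at least one anchor tracks
  how fast the syntaxin pool explores the membrane.
* **Seeded aggregation** — a static, highly attractive seed mimics a
  newly docked vesicle; the first-passage time of its cluster to a
  target size measures how quickly a release site can be built.
* **Docking/priming census** — a 20×20 lattice of 30×30 nm cells counts
  all syntaxins (docking-competent) and those free or on a cluster
  boundary that stay put for >= 100 ms (priming-competent).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from . import bd_engine
from .model_core import SimulationConfig, SystemState
from .traj_analysis import identify_clusters

__all__ = [
    "FrapCurve",
    "bleach",
    "frap_curve",
    "frap",
    "CoverageCurve",
    "membrane_coverage",
    "seed_cluster_sizes",
    "seeded_aggregation",
    "aggregation_experiment",
    "CensusGrid",
    "candidate_census",
]


# ---------------------------------------------------------------------------
# FRAP
# ---------------------------------------------------------------------------

@dataclass
class FrapCurve:
    """Recovery of the fluorescent fraction inside the bleached disc.

    ``recovery`` is normalized to the pre-bleach molecule count inside
    the disc, so it starts at ~0 and, for a closed system with ideal
    mixing, plateaus at 1 minus the bleached fraction of the pool.
    """

    times_s: np.ndarray
    recovery: np.ndarray
    bleach_center: tuple
    bleach_radius: float
    pre_bleach_count: int


def bleach(state: SystemState, config: SimulationConfig,
           center: tuple = (0.0, 0.0), area_fraction: float = 0.10) -> SystemState:
    """Label molecules inside the bleach disc; dynamics are unaffected.

    The disc is concentric with the domain by default and its radius is
    chosen so it covers ``area_fraction`` of the full simulation area.
    """
    radius = config.domain_radius * np.sqrt(area_fraction)
    new = state.copy()
    d = np.linalg.norm(new.pos1[:, :2] - np.asarray(center), axis=1)
    new.labels["bleached"] = d <= radius
    return new


def frap_curve(traj, center: tuple = (0.0, 0.0),
               radius: float | None = None,
               area_fraction: float = 0.10) -> FrapCurve:
    """Compute the recovery curve from a trajectory with a bleach label."""
    if "bleached" not in traj.labels:
        raise ValueError("trajectory has no 'bleached' label")
    if radius is None:
        radius = traj.config.domain_radius * np.sqrt(area_fraction)
    bleached = traj.labels["bleached"]
    center = np.asarray(center)
    dist = np.linalg.norm(traj.anchors_xy - center, axis=-1)  # (nf, n)
    inside = dist <= radius
    pre = int(inside[0].sum())
    if pre == 0:
        raise ValueError("no molecules inside the bleach disc at t=0")
    fluorescent_inside = (inside & ~bleached[None, :]).sum(axis=1)
    return FrapCurve(
        times_s=(traj.times - traj.times[0]) * 1e-9,
        recovery=fluorescent_inside / pre,
        bleach_center=tuple(center),
        bleach_radius=float(radius),
        pre_bleach_count=pre,
    )


def frap(equilibrated_state: SystemState, config: SimulationConfig,
         duration_ns: float, center: tuple = (0.0, 0.0),
         area_fraction: float = 0.10,
         kernel_seed: int | None = None) -> FrapCurve:
    """Run a simulated FRAP experiment from an equilibrated state."""
    state = bleach(equilibrated_state, config, center, area_fraction)
    cfg = config.evolve(n_steps=int(round(duration_ns / config.dt)))
    traj = bd_engine.run(cfg, init_state=state, kernel_seed=kernel_seed)
    return frap_curve(traj, center=center, area_fraction=area_fraction)


# ---------------------------------------------------------------------------
# Membrane coverage
# ---------------------------------------------------------------------------

@dataclass
class CoverageCurve:
    """Fraction of vesicle-sized lattice cells visited by any anchor."""

    times_ms: np.ndarray
    fraction: np.ndarray
    t50_ms: float
    t75_ms: float
    n_cells: int


def _disk_cells(radius: float, cell: float):
    """Index grid and mask of lattice cells intersecting the disk."""
    n_side = int(np.ceil(2.0 * radius / cell))
    origin = -0.5 * n_side * cell
    ix = np.arange(n_side)
    x0 = origin + ix * cell
    # closest point of each cell rectangle to the disk center
    cx = np.clip(0.0, x0[:, None], x0[:, None] + cell) + np.zeros(n_side)
    cy = np.clip(0.0, x0[None, :], x0[None, :] + cell) + np.zeros((n_side, 1))
    mask = cx**2 + cy**2 <= radius**2
    return n_side, origin, mask


def membrane_coverage(traj, cell_diameter: float = 40.0) -> CoverageCurve:
    """Cumulative fraction of 40-nm compartments visited over time.

    A compartment counts as visited from the first sampled frame in
    which any anchor centre falls inside it; the denominator is the
    number of compartments intersecting the disk.
    """
    radius = traj.config.domain_radius
    n_side, origin, mask = _disk_cells(radius, cell_diameter)
    n_cells = int(mask.sum())

    xy = traj.anchors_xy
    ij = np.floor((xy - origin) / cell_diameter).astype(np.int64)
    np.clip(ij, 0, n_side - 1, out=ij)

    visited = np.zeros((n_side, n_side), dtype=bool)
    frac = np.empty(traj.n_frames)
    for f in range(traj.n_frames):
        visited[ij[f, :, 0], ij[f, :, 1]] = True
        frac[f] = np.count_nonzero(visited & mask) / n_cells

    times_ms = (traj.times - traj.times[0]) * 1e-6

    def first_time(level):
        hit = np.nonzero(frac >= level)[0]
        return float(times_ms[hit[0]]) if len(hit) else float("nan")

    return CoverageCurve(
        times_ms=times_ms,
        fraction=frac,
        t50_ms=first_time(0.50),
        t75_ms=first_time(0.75),
        n_cells=n_cells,
    )


# ---------------------------------------------------------------------------
# Seeded aggregation
# ---------------------------------------------------------------------------

def seed_cluster_sizes(traj) -> np.ndarray:
    """Size of the cluster containing the seed molecule, per frame."""
    seed_mask = traj.labels.get("seed")
    if seed_mask is None or not seed_mask.any():
        raise ValueError("trajectory has no 'seed' molecule")
    seed_idx = int(np.nonzero(seed_mask)[0][0])
    cutoff = traj.config.r_sum + 1.0
    sizes = np.empty(traj.n_frames, dtype=np.int64)
    for f in range(traj.n_frames):
        labels = identify_clusters(traj.anchors_xy[f], cutoff)
        sizes[f] = np.sum(labels == labels[seed_idx])
    return sizes


def seeded_aggregation(traj, target_sizes) -> pd.DataFrame:
    """First-passage times of the seed's cluster to each target size.

    Times are in ms from the start of the trajectory; targets never
    reached within the run are right-censored (``censored=True`` with
    the run length as the censoring time).
    """
    sizes = seed_cluster_sizes(traj)
    times_ms = (traj.times - traj.times[0]) * 1e-6
    rows = []
    for target in target_sizes:
        hit = np.nonzero(sizes >= target)[0]
        if len(hit):
            rows.append((target, float(times_ms[hit[0]]), False))
        else:
            rows.append((target, float(times_ms[-1]), True))
    return pd.DataFrame(rows, columns=["target_size", "time_ms", "censored"])


def aggregation_experiment(config: SimulationConfig, target_sizes,
                           n_replicas: int = 12,
                           equil_state: SystemState | None = None,
                           base_seed: int = 0) -> pd.DataFrame:
    """Replicated seeded-aggregation assay.

    Each replica inserts a fresh static seed (``config.seed_e_a``) at a
    random empty site of the equilibrated state and integrates
    ``config.n_steps`` steps.  Returns the per-replica first-passage
    table with a ``replica`` column; averaging and censoring handling
    are left to the caller.
    """
    if equil_state is None:
        equil_cfg = config.evolve(rng_seed=base_seed)
        equil_state = bd_engine.run(equil_cfg).frame(-1)
    frames = []
    for rep in range(n_replicas):
        rng = np.random.default_rng(base_seed + 1000 + rep)
        seeded = bd_engine.insert_seed(equil_state, config, rng)
        seeded.time = 0.0
        traj = bd_engine.run(config, init_state=seeded,
                             kernel_seed=base_seed + 2000 + rep)
        fp = seeded_aggregation(traj, target_sizes)
        fp["replica"] = rep
        frames.append(fp)
    return pd.concat(frames, ignore_index=True)


# ---------------------------------------------------------------------------
# Docking / priming census
# ---------------------------------------------------------------------------

@dataclass
class CensusGrid:
    """Docking- and priming-candidate counts on a lattice of membrane cells.

    ``docking`` holds the time-averaged number of anchors per cell;
    ``priming`` the number of distinct molecules with a qualifying
    persistent free-or-boundary episode based in the cell.
    ``in_disk`` masks cells intersecting the membrane disk; histograms
    should be restricted to it.
    """

    docking: np.ndarray
    priming: np.ndarray
    in_disk: np.ndarray
    cell_nm: float
    window_ms: float

    def histogram(self, which: str = "docking", bins=None):
        grid = self.docking if which == "docking" else self.priming
        vals = grid[self.in_disk]
        if bins is None:
            bins = np.arange(0, max(2, int(np.ceil(vals.max())) + 2))
        return np.histogram(vals, bins=bins)


def candidate_census(traj, window_ms: float = 100.0, cell_nm: float = 30.0,
                     grid_n: int = 20, boundary_max_neighbors: int = 3,
                     neighborhood_cells: int = 1) -> CensusGrid:
    """Count docking- and priming-competent syntaxins per membrane cell.

    Every syntaxin is docking-competent, so the docking count of a cell
    is the time-averaged number of anchors inside it.  A molecule is
    priming-competent in a cell when it is free or on a cluster boundary
    (at most ``boundary_max_neighbors`` anchors within the interaction
    radius) continuously for at least ``window_ms`` while staying within
    the cell or its ``neighborhood_cells``-cell surrounding ring; each
    molecule contributes at most once per base cell.
    """
    from scipy.ndimage import maximum_filter1d, minimum_filter1d

    cfg = traj.config
    half = 0.5 * grid_n * cell_nm
    nf, n = traj.n_frames, traj.n_molecules
    frame_ms = traj.frame_dt * 1e-6
    w = max(1, int(round(window_ms / frame_ms)))
    if nf < w:
        raise ValueError("trajectory shorter than the persistence window")

    xy = traj.anchors_xy
    ij = np.floor((xy + half) / cell_nm).astype(np.int64)  # (nf, n, 2)
    in_grid = np.all((ij >= 0) & (ij < grid_n), axis=-1)

    # docking: time-averaged occupancy
    docking = np.zeros((grid_n, grid_n))
    for f in range(nf):
        sel = in_grid[f]
        np.add.at(docking, (ij[f, sel, 0], ij[f, sel, 1]), 1.0)
    docking /= nf

    # free-or-boundary status per molecule-frame
    ok = np.empty((nf, n), dtype=bool)
    for f in range(nf):
        tree = cKDTree(xy[f])
        nb = tree.query_ball_point(xy[f], cfg.i_radius, return_length=True) - 1
        ok[f] = nb <= boundary_max_neighbors

    priming = np.zeros((grid_n, grid_n), dtype=np.int64)
    tol = neighborhood_cells
    n_starts = nf - w + 1
    for m in range(n):
        ci = ij[:, m, 0].astype(float)
        cj = ij[:, m, 1].astype(float)
        ok_m = ok[:, m] & in_grid[:, m]
        # windowed extrema (origin chosen so window = [t, t+w))
        ok_all = minimum_filter1d(ok_m.astype(np.int8), w, origin=-(w // 2),
                                  mode="constant", cval=0)[:n_starts].astype(bool)
        max_i = maximum_filter1d(ci, w, origin=-(w // 2), mode="nearest")[:n_starts]
        min_i = minimum_filter1d(ci, w, origin=-(w // 2), mode="nearest")[:n_starts]
        max_j = maximum_filter1d(cj, w, origin=-(w // 2), mode="nearest")[:n_starts]
        min_j = minimum_filter1d(cj, w, origin=-(w // 2), mode="nearest")[:n_starts]
        base_i = ci[:n_starts]
        base_j = cj[:n_starts]
        good = (ok_all
                & (max_i - base_i <= tol) & (base_i - min_i <= tol)
                & (max_j - base_j <= tol) & (base_j - min_j <= tol))
        cells = {(int(base_i[t]), int(base_j[t])) for t in np.nonzero(good)[0]}
        for c in cells:
            priming[c] += 1

    # disk intersection mask for the census lattice
    ix = np.arange(grid_n)
    x0 = -half + ix * cell_nm
    cx = np.clip(0.0, x0[:, None], x0[:, None] + cell_nm) + np.zeros(grid_n)
    cy = np.clip(0.0, x0[None, :], x0[None, :] + cell_nm) + np.zeros((grid_n, 1))
    in_disk = cx**2 + cy**2 <= cfg.domain_radius**2

    return CensusGrid(docking=docking, priming=priming, in_disk=in_disk,
                      cell_nm=cell_nm, window_ms=w * frame_ms)
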