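"""Cluster identification and per-trajectory statistics.

A cluster is a set of molecules each of which is in proximity of at
least one other member, where two molecules are in proximity when their
anchor centres are within ``2 r1 + 1 nm`` (contact distance plus 1 nm).
Cluster membership is the connected-component closure of that relation,
so chains of touching molecules merge into one cluster and a molecule
with no neighbor is a singleton (cluster of size 1).

Simulated clusters are mapped to an *effective diameter* so that count-
based size distributions can be compared with imaged full-width-half-
maximum diameters: a cluster of N anchors of radius r1 packed at area
fraction phi occupies area N pi r1² / phi, and the effective diameter is
that of the circle of equal area, d = 2 r1 sqrt(N / phi).  The default
packing fraction is calibrated once from the convex hull of a large
converged cluster (see :func:`calibrate_packing_fraction`).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.spatial import cKDTree

__all__ = [
    "identify_clusters",
    "ClusterTable",
    "build_cluster_table",
    "effective_diameter",
    "molecule_count_for_diameter",
    "calibrate_packing_fraction",
    "cluster_size_distribution",
    "mean_cluster_size_and_single_fraction",
    "cluster_diffusion",
    "step_lengths",
    "dissociation_and_residence",
    "KineticsSummary",
]

#: Default anchor packing fraction inside a converged cluster, calibrated
#: once with calibrate_packing_fraction on large equilibrium clusters
#: (loosely bound hexagonal-like packing at ~6.5 nm spacing).  With this
#: value a 60-nm cluster maps to ~75 molecules, matching single-molecule
#: estimates for syntaxin microdomains.
DEFAULT_PACKING_FRACTION = 0.75


def _cutoff(config) -> float:
    return config.r_sum + 1.0


def identify_clusters(anchors_xy: np.ndarray, cutoff: float) -> np.ndarray:
    """Connected components of the anchor proximity graph.

    Parameters
    ----------
    anchors_xy : (n, 2) array
        In-plane anchor coordinates of one frame (nm).
    cutoff : float
        Proximity distance (nm); membership is transitive.

    Returns
    -------
    labels : (n,) int array
        Cluster label per molecule; labels partition the molecules.
    """
    n = len(anchors_xy)
    if n == 0:
        return np.zeros(0, dtype=np.int64)
    tree = cKDTree(anchors_xy)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    adj = sparse.coo_matrix(
        (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
    )
    _, labels = sparse.csgraph.connected_components(adj, directed=False)
    return labels


def effective_diameter(n_members, r1: float,
                       packing_fraction: float = DEFAULT_PACKING_FRACTION):
    """Equal-area circle diameter (nm) of a cluster of ``n_members``."""
    return 2.0 * r1 * np.sqrt(np.asarray(n_members, dtype=float) / packing_fraction)


def molecule_count_for_diameter(diameter_nm, r1: float,
                                packing_fraction: float = DEFAULT_PACKING_FRACTION):
    """Inverse of :func:`effective_diameter` (molecules in a cluster)."""
    return packing_fraction * (np.asarray(diameter_nm, dtype=float) / (2.0 * r1)) ** 2


def calibrate_packing_fraction(traj, min_size: int = 15) -> float:
    """Anchor packing fraction measured from converged clusters.

    For every cluster of at least ``min_size`` molecules in the final
    frame, the occupied area is taken as the convex hull of the anchor
    centres dilated by r1 (hull area + perimeter·r1 + π r1²), and the
    packing fraction is N π r1² over that area.  Returns the mean.
    """
    from scipy.spatial import ConvexHull

    cfg = traj.config
    xy = traj.anchors_xy[-1]
    labels = identify_clusters(xy, _cutoff(cfg))
    fracs = []
    for lab in np.unique(labels):
        members = xy[labels == lab]
        if len(members) < min_size:
            continue
        hull = ConvexHull(members)
        area = hull.volume + hull.area * cfg.r1 + np.pi * cfg.r1**2
        fracs.append(len(members) * np.pi * cfg.r1**2 / area)
    if not fracs:
        raise ValueError(f"no cluster of >= {min_size} molecules in the final frame")
    return float(np.mean(fracs))


@dataclass
class ClusterTable:
    """Per-frame cluster assignments and per-cluster geometry.

    ``labels`` has shape (n_frames, n_molecules); ``table`` has one row
    per (frame, cluster) with columns ``frame, time_ns, cluster, size,
    cx, cy, diameter_nm``.
    """

    labels: np.ndarray
    table: pd.DataFrame
    cutoff: float


def build_cluster_table(traj, cutoff: float | None = None,
                        packing_fraction: float = DEFAULT_PACKING_FRACTION) -> ClusterTable:
    cfg = traj.config
    if cutoff is None:
        cutoff = _cutoff(cfg)
    nf, n = traj.n_frames, traj.n_molecules
    labels = np.empty((nf, n), dtype=np.int64)
    rows = []
    for f in range(nf):
        xy = traj.anchors_xy[f]
        lab = identify_clusters(xy, cutoff)
        labels[f] = lab
        sizes = np.bincount(lab)
        for c, size in enumerate(sizes):
            members = xy[lab == c]
            rows.append((
                f, traj.times[f], c, int(size),
                members[:, 0].mean(), members[:, 1].mean(),
                effective_diameter(size, cfg.r1, packing_fraction),
            ))
    table = pd.DataFrame(
        rows, columns=["frame", "time_ns", "cluster", "size", "cx", "cy",
                       "diameter_nm"],
    )
    return ClusterTable(labels=labels, table=table, cutoff=cutoff)


def _burn_in_slice(n_frames: int, burn_in: float) -> slice:
    return slice(int(np.floor(n_frames * burn_in)), n_frames)


def cluster_size_distribution(traj, by: str = "count", burn_in: float = 0.25,
                              cluster_table: ClusterTable | None = None,
                              bins=None) -> pd.Series:
    """Time-averaged cluster size distribution after burn-in.

    ``by="count"`` histograms member counts (index = cluster size,
    values = mean number of such clusters per frame).  ``by="diameter"``
    histograms effective diameters into ``bins`` (nm edges; default
    20-nm bins up to 200 nm) and returns per-bin mean counts per frame.
    """
    ct = cluster_table or build_cluster_table(traj)
    sel = _burn_in_slice(traj.n_frames, burn_in)
    frames = np.arange(traj.n_frames)[sel]
    sub = ct.table[ct.table["frame"].isin(frames)]
    n_frames_used = len(frames)
    if by == "count":
        counts = sub.groupby("size").size() / n_frames_used
        counts.name = "clusters_per_frame"
        return counts
    elif by == "diameter":
        if bins is None:
            bins = np.arange(0.0, 220.0, 20.0)
        hist, edges = np.histogram(sub["diameter_nm"], bins=bins)
        idx = pd.IntervalIndex.from_breaks(edges)
        return pd.Series(hist / n_frames_used, index=idx,
                         name="clusters_per_frame")
    raise ValueError("by must be 'count' or 'diameter'")


def mean_cluster_size_and_single_fraction(traj, burn_in: float = 0.25,
                                          cluster_table: ClusterTable | None = None):
    """(time-averaged mean cluster size, fraction of single molecules).

    Both are computed per frame and then averaged over the post-burn-in
    frames.  The single fraction is the fraction of molecules that form
    a cluster of size 1.
    """
    ct = cluster_table or build_cluster_table(traj)
    sel = _burn_in_slice(traj.n_frames, burn_in)
    mean_sizes = []
    single_fracs = []
    n = traj.n_molecules
    for f in range(traj.n_frames)[sel]:
        sizes = np.bincount(ct.labels[f])
        mean_sizes.append(sizes.mean())
        single_fracs.append(np.sum(sizes == 1) / n)
    return float(np.mean(mean_sizes)), float(np.mean(single_fracs))


# ---------------------------------------------------------------------------
# Kinetics
# ---------------------------------------------------------------------------

def _member_sets(labels_row: np.ndarray):
    """List of frozensets of molecule indices, indexed by cluster label."""
    order = np.argsort(labels_row, kind="stable")
    sets = []
    sorted_labels = labels_row[order]
    start = 0
    for i in range(1, len(order) + 1):
        if i == len(order) or sorted_labels[i] != sorted_labels[start]:
            sets.append(frozenset(order[start:i].tolist()))
            start = i
    return sets


def cluster_diffusion(traj, size_bins=None,
                      cluster_table: ClusterTable | None = None,
                      min_obs: int = 10, burn_in: float = 0.25) -> pd.DataFrame:
    """Diffusion coefficient of cluster centroids, binned by size.

    Clusters are tracked between consecutive frames by exact membership
    match, so only displacement intervals during which no molecule
    joined or left contribute — the centroid displacement is then pure
    transport, not an exchange artifact.  Centroids average the
    molecular centres of mass (anchor+head), which are free of the
    short-lag transient the swinging head imprints on anchor-only
    positions.  D is the one-lag MSD estimate ``<dr²> / (4 dt)``,
    reported in μm²/s.  Bins with fewer than ``min_obs`` displacement
    observations are reported as NaN.
    """
    ct = cluster_table or build_cluster_table(traj)
    if size_bins is None:
        size_bins = np.array([1, 2, 3, 5, 9, 17, 33, 65, 1_000_000])
    size_bins = np.asarray(size_bins)
    dt_ms = traj.frame_dt  # ns
    lo = _burn_in_slice(traj.n_frames, burn_in).start

    com_xy = 0.5 * (traj.pos1[:, :, :2] + traj.pos2[:, :, :2])
    sq_disp = [[] for _ in range(len(size_bins) - 1)]
    prev = None
    for f in range(lo, traj.n_frames):
        xy = com_xy[f]
        sets = _member_sets(ct.labels[f])
        cur = {}
        for s in sets:
            idx = np.fromiter(s, dtype=np.int64)
            cur[s] = xy[idx].mean(axis=0)
        if prev is not None:
            for s, centroid in cur.items():
                if s in prev:
                    d = centroid - prev[s]
                    b = np.searchsorted(size_bins, len(s), side="right") - 1
                    if 0 <= b < len(sq_disp):
                        sq_disp[b].append(d @ d)
        prev = cur

    rows = []
    for b in range(len(size_bins) - 1):
        obs = sq_disp[b]
        if len(obs) < min_obs:
            d_um2s = np.nan
        else:
            d_um2s = np.mean(obs) / (4.0 * dt_ms) / 1e-3  # nm²/ns -> μm²/s
        rows.append((size_bins[b], size_bins[b + 1], len(obs), d_um2s))
    return pd.DataFrame(rows, columns=["size_lo", "size_hi", "n_obs", "D_um2_s"])


def step_lengths(traj, lag_ns: float = 200_000.0, burn_in: float = 0.25) -> np.ndarray:
    """Pooled in-plane anchor displacement magnitudes at a fixed lag (nm).

    Raises ``ValueError`` when the lag is not a multiple of the frame
    spacing.  A zero lag returns all-zero lengths.
    """
    if lag_ns == 0:
        sel = _burn_in_slice(traj.n_frames, burn_in)
        return np.zeros(traj.anchors_xy[sel].shape[0] * traj.n_molecules)
    ratio = lag_ns / traj.frame_dt
    k = int(round(ratio))
    if k < 1 or abs(ratio - k) > 1e-9:
        raise ValueError("lag must be a positive multiple of the frame spacing")
    sel = _burn_in_slice(traj.n_frames, burn_in)
    xy = traj.anchors_xy[sel]
    if xy.shape[0] <= k:
        raise ValueError("trajectory too short for the requested lag")
    d = xy[k:] - xy[:-k]
    return np.linalg.norm(d, axis=-1).ravel()


@dataclass
class KineticsSummary:
    """Dissociation and residence statistics of one trajectory.

    ``dissociation_rate``: per cluster-size bin, events per particle per
    ms of exposure.  ``rate_vs_neighbors``: same, binned by the number
    of anchors within the interaction radius at the event-defining
    frame.  ``residence_times_ms``: duration of every contiguous
    cluster-membership episode, with ``residence_censored`` flagging
    episodes cut off by either end of the trajectory.
    """

    dissociation_rate: pd.DataFrame
    rate_vs_neighbors: pd.DataFrame
    residence_times_ms: np.ndarray
    residence_censored: np.ndarray


def dissociation_and_residence(traj, cluster_table: ClusterTable | None = None,
                               size_bins=None, burn_in: float = 0.0,
                               debounce_frames: int = 2) -> KineticsSummary:
    """Cluster exit kinetics of every molecule.

    A molecule *m* belonging to cluster C (|C| >= 2) at frame t has
    dissociated when, at frame t+1, its new cluster shares no member
    with C\\{m}, and this separation persists for ``debounce_frames``
    consecutive frames (suppressing contact flicker at the cluster
    boundary).  Rates are events per particle per ms, normalized by the
    particle-time spent in clusters of each size bin.

    A residence episode starts when a molecule gains at least one
    companion and continues while its companion set overlaps the
    previous frame's; episodes touching either trajectory end are
    censored.
    """
    ct = cluster_table or build_cluster_table(traj)
    if size_bins is None:
        size_bins = np.array([2, 3, 5, 9, 17, 33, 65, 1_000_000])
    size_bins = np.asarray(size_bins)
    nf, n = ct.labels.shape
    lo = _burn_in_slice(nf, burn_in).start
    frame_ms = traj.frame_dt * 1e-6  # ns -> ms

    # companion sets per frame per molecule
    comp = np.empty((nf, n), dtype=object)
    for f in range(nf):
        sets = _member_sets(ct.labels[f])
        for s in sets:
            if len(s) >= 2:
                for m in s:
                    comp[f, m] = s
    # sizes per molecule-frame
    sizes = np.zeros((nf, n), dtype=np.int64)
    for f in range(nf):
        counts = np.bincount(ct.labels[f])
        sizes[f] = counts[ct.labels[f]]

    # neighbor counts (anchors within i_radius) computed lazily per event frame
    neighbor_cache: dict[int, np.ndarray] = {}

    def neighbors(f: int) -> np.ndarray:
        if f not in neighbor_cache:
            tree = cKDTree(traj.anchors_xy[f])
            cnt = tree.query_ball_point(traj.anchors_xy[f],
                                        traj.config.i_radius,
                                        return_length=True) - 1
            neighbor_cache[f] = cnt
        return neighbor_cache[f]

    nb_max = 12
    events_size = np.zeros(len(size_bins) - 1)
    exposure_size = np.zeros(len(size_bins) - 1)
    events_nb = np.zeros(nb_max + 1)
    exposure_nb = np.zeros(nb_max + 1)

    residences = []
    censored = []

    for m in range(n):
        episode_start = None
        prev_set = None
        for f in range(lo, nf):
            s = comp[f, m]
            in_cluster = s is not None
            if in_cluster:
                b = np.searchsorted(size_bins, sizes[f, m], side="right") - 1
                if 0 <= b < len(exposure_size):
                    exposure_size[b] += frame_ms
            if episode_start is None:
                if in_cluster:
                    episode_start = f
                    prev_set = s
                continue
            # inside an episode: does it continue?
            cont = in_cluster and len((s - {m}) & (prev_set - {m})) > 0
            if cont:
                prev_set = s
                continue
            # candidate exit at frame f; debounce: the molecule must stay
            # clear of its former companions for debounce_frames frames
            former = prev_set - {m}
            clear = True
            for g in range(f, min(nf, f + debounce_frames)):
                sg = comp[g, m]
                if sg is not None and len((sg - {m}) & former) > 0:
                    clear = False
                    break
            if not clear:
                # flicker: episode continues (membership resumed)
                if in_cluster:
                    prev_set = s
                continue
            # confirmed dissociation event at transition (f-1) -> f
            size_at_exit = sizes[f - 1, m]
            b = np.searchsorted(size_bins, size_at_exit, side="right") - 1
            if 0 <= b < len(events_size):
                events_size[b] += 1
            nbc = int(min(neighbors(f - 1)[m], nb_max))
            events_nb[nbc] += 1
            residences.append((f - episode_start) * frame_ms)
            censored.append(episode_start == lo)
            episode_start = f if in_cluster else None
            prev_set = s if in_cluster else None
        if episode_start is not None:
            residences.append((nf - episode_start) * frame_ms)
            censored.append(True)

    # neighbor-count exposure
    for f in range(lo, nf):
        nbf = np.minimum(neighbors(f), nb_max)
        in_cl = sizes[f] >= 2
        for m in np.nonzero(in_cl)[0]:
            exposure_nb[nbf[m]] += frame_ms

    with np.errstate(invalid="ignore", divide="ignore"):
        rate_size = np.where(exposure_size > 0, events_size / exposure_size, np.nan)
        rate_nb = np.where(exposure_nb > 0, events_nb / exposure_nb, np.nan)

    diss = pd.DataFrame({
        "size_lo": size_bins[:-1], "size_hi": size_bins[1:],
        "n_events": events_size, "exposure_particle_ms": exposure_size,
        "rate_per_particle_per_ms": rate_size,
    })
    nbdf = pd.DataFrame({
        "n_neighbors": np.arange(nb_max + 1),
        "n_events": events_nb, "exposure_particle_ms": exposure_nb,
        "rate_per_particle_per_ms": rate_nb,
    })
    return KineticsSummary(
        dissociation_rate=diss,
        rate_vs_neighbors=nbdf,
        residence_times_ms=np.asarray(residences),
        residence_censored=np.asarray(censored, dtype=bool),
    )
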