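"""Overdamped Brownian dynamics of syntaxin dimers on a disk membrane.

The equation of motion for each particle is integrated with the
Euler–Maruyama scheme

    x(t+dt) = x(t) + (D_p / k_BT) F(x) dt + sqrt(2 D_p dt) xi,

with ``xi`` i.i.d. standard normal per coordinate.  Anchors are held on
the membrane plane by a harmonic restraint and confined to the disk by a
half-harmonic wall; static seed molecules exert forces but never move.

The per-particle diffusion coefficient ``D_p`` is chosen so that the
bonded dimer as a whole diffuses with the experimentally measured
``D_syx`` (0.2 μm²/s by default).  For two particles of equal mobility
the centre of mass diffuses at ``D_p / 2``, so the analytic choice is
``D_p = 2 D_syx``; :func:`calibrate_particle_diffusion` verifies and, if
needed, refines this against a measured mean-squared displacement.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import h5py
import numpy as np
import yaml

from . import _kernels
from .model_core import SimulationConfig, SystemState, pairwise_energy_and_forces

__all__ = [
    "Trajectory",
    "init_random",
    "step",
    "run",
    "msd",
    "fit_diffusion",
    "calibrate_particle_diffusion",
    "insert_seed",
    "save_trajectory",
    "load_trajectory",
]


@dataclass
class Trajectory:
    """Sampled two-particle positions of every molecule over a run.

    ``pos1``/``pos2`` have shape ``(n_frames, n_molecules, 3)`` in nm;
    ``times`` is in ns and strictly increasing.  ``labels`` maps tag
    names to per-molecule boolean masks (constant over the run).
    """

    times: np.ndarray
    pos1: np.ndarray
    pos2: np.ndarray
    mobile: np.ndarray
    e_a: np.ndarray
    labels: dict
    config: SimulationConfig
    meta: dict = field(default_factory=dict)

    @property
    def n_frames(self) -> int:
        return len(self.times)

    @property
    def n_molecules(self) -> int:
        return self.pos1.shape[1]

    @property
    def frame_dt(self) -> float:
        """Time between stored frames (ns)."""
        if self.n_frames > 1:
            return float(self.times[1] - self.times[0])
        return self.config.dt * self.config.sample_stride

    @property
    def anchors_xy(self) -> np.ndarray:
        """In-plane anchor coordinates, shape (n_frames, n, 2)."""
        return self.pos1[:, :, :2]

    def frame(self, idx: int) -> SystemState:
        return SystemState(
            time=float(self.times[idx]),
            pos1=self.pos1[idx].copy(),
            pos2=self.pos2[idx].copy(),
            mobile=self.mobile.copy(),
            e_a=self.e_a.copy(),
            labels={k: v.copy() for k, v in self.labels.items()},
        )

    def save(self, path) -> None:
        save_trajectory(self, path)

    def export_anchor_csv(self, path) -> None:
        """Flat CSV of anchor positions: frame, time_ns, molecule, x, y, z."""
        import pandas as pd

        nf, n = self.n_frames, self.n_molecules
        df = pd.DataFrame({
            "frame": np.repeat(np.arange(nf), n),
            "time_ns": np.repeat(self.times, n),
            "molecule": np.tile(np.arange(n), nf),
            "x_nm": self.pos1[:, :, 0].ravel(),
            "y_nm": self.pos1[:, :, 1].ravel(),
            "z_nm": self.pos1[:, :, 2].ravel(),
        })
        df.to_csv(path, index=False)


def save_trajectory(traj: Trajectory, path) -> None:
    with h5py.File(path, "w") as fh:
        fh.create_dataset("times", data=traj.times)
        fh.create_dataset("pos1", data=traj.pos1)
        fh.create_dataset("pos2", data=traj.pos2)
        fh.create_dataset("mobile", data=traj.mobile)
        fh.create_dataset("e_a", data=traj.e_a)
        lab = fh.create_group("labels")
        for name, mask in traj.labels.items():
            lab.create_dataset(name, data=mask)
        fh.attrs["config"] = yaml.safe_dump(traj.config.to_dict())
        fh.attrs["meta"] = yaml.safe_dump(traj.meta)


def load_trajectory(path) -> Trajectory:
    with h5py.File(path, "r") as fh:
        config = SimulationConfig.from_dict(yaml.safe_load(fh.attrs["config"]))
        meta = yaml.safe_load(fh.attrs["meta"]) or {}
        labels = {k: fh["labels"][k][...].astype(bool) for k in fh["labels"]}
        return Trajectory(
            times=fh["times"][...],
            pos1=fh["pos1"][...],
            pos2=fh["pos2"][...],
            mobile=fh["mobile"][...].astype(bool),
            e_a=fh["e_a"][...],
            labels=labels,
            config=config,
            meta=meta,
        )


# ---------------------------------------------------------------------------
# Initialization
# ---------------------------------------------------------------------------

def init_random(config: SimulationConfig, rng: np.random.Generator | None = None,
                max_attempts: int = 200) -> SystemState:
    """Place anchors uniformly on the disk, rejecting overlaps.

    Anchors are drawn uniformly on the disk of ``domain_radius`` and a
    draw is rejected while any previously placed anchor is closer than
    the contact distance ``2 r1``.  Heads start at bond rest length
    straight above the plane.  Raises ``RuntimeError`` when the packing
    is infeasible after bounded retries.
    """
    rng = np.random.default_rng(config.rng_seed) if rng is None else rng
    n = config.n_molecules
    min_d = config.r_sum
    radius = config.domain_radius
    # crude feasibility guard: disks of radius r1 at >= 60% packing
    if n * np.pi * config.r1**2 > 0.6 * np.pi * radius**2:
        raise RuntimeError("packing infeasible: too many molecules for the disk")

    anchors = np.empty((n, 2))
    placed = 0
    for _ in range(max_attempts * max(n, 1)):
        if placed == n:
            break
        rho = radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        cand = np.array([rho * np.cos(phi), rho * np.sin(phi)])
        if placed and np.min(np.linalg.norm(anchors[:placed] - cand, axis=1)) < min_d:
            continue
        anchors[placed] = cand
        placed += 1
    if placed < n:
        raise RuntimeError("packing infeasible: rejection sampling exhausted")

    pos1 = np.zeros((n, 3))
    pos1[:, :2] = anchors
    pos2 = pos1.copy()
    pos2[:, 2] += config.r1 + config.r2
    return SystemState(
        time=0.0,
        pos1=pos1,
        pos2=pos2,
        mobile=np.ones(n, dtype=bool),
        e_a=np.full(n, config.e_a),
        labels={},
    )


def insert_seed(state: SystemState, config: SimulationConfig,
                rng: np.random.Generator | None = None,
                max_attempts: int = 20_000) -> SystemState:
    """Add one static, highly attractive seed dimer at an empty site.

    A site is empty when no existing anchor lies within
    ``i_radius + 2 nm`` of it.  The seed is flagged immobile and tagged
    ``"seed"`` and interacts with well depth ``config.seed_e_a``.
    """
    rng = np.random.default_rng() if rng is None else rng
    clearance = config.i_radius + 2.0
    anchors = state.pos1[:, :2]
    site = None
    for _ in range(max_attempts):
        rho = config.domain_radius * np.sqrt(rng.uniform())
        phi = rng.uniform(0.0, 2.0 * np.pi)
        cand = np.array([rho * np.cos(phi), rho * np.sin(phi)])
        if len(anchors) == 0 or np.min(np.linalg.norm(anchors - cand, axis=1)) >= clearance:
            site = cand
            break
    if site is None:
        raise RuntimeError("no empty membrane site found for the seed")

    p1 = np.array([[site[0], site[1], 0.0]])
    p2 = p1 + np.array([[0.0, 0.0, config.r1 + config.r2]])
    labels = {k: np.append(v, False) for k, v in state.labels.items()}
    seed_mask = np.zeros(state.n_molecules + 1, dtype=bool)
    seed_mask[-1] = True
    labels["seed"] = labels.get("seed", np.zeros(state.n_molecules + 1, dtype=bool)) | seed_mask
    return SystemState(
        time=state.time,
        pos1=np.vstack([state.pos1, p1]),
        pos2=np.vstack([state.pos2, p2]),
        mobile=np.append(state.mobile, False),
        e_a=np.append(state.e_a, config.seed_e_a),
        labels=labels,
    )


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

def step(state: SystemState, config: SimulationConfig,
         rng: np.random.Generator | None = None) -> SystemState:
    """One Euler–Maruyama step using the reference force evaluation.

    Convenience API for small systems and tests; :func:`run` drives the
    compiled kernel instead.  With ``rng=None`` the update is purely
    deterministic (drift only), which makes the zero-force fixed point
    easy to check.
    """
    energy, f1, f2 = pairwise_energy_and_forces(state, config)
    if not (np.isfinite(f1).all() and np.isfinite(f2).all()):
        raise FloatingPointError("non-finite forces")
    d_p = config.d_particle_sim
    dt = config.dt
    noise = np.sqrt(2.0 * d_p * dt)
    new = state.copy()
    m = state.mobile
    xi1 = rng.standard_normal(f1.shape) if rng is not None else 0.0
    xi2 = rng.standard_normal(f2.shape) if rng is not None else 0.0
    disp1 = d_p * f1 * dt + noise * xi1
    disp2 = d_p * f2 * dt + noise * xi2
    new.pos1[m] += np.atleast_2d(disp1)[m] if np.ndim(disp1) else 0.0
    new.pos2[m] += np.atleast_2d(disp2)[m] if np.ndim(disp2) else 0.0
    if state.n_molecules and np.any(np.linalg.norm(np.atleast_2d(disp1)[m], axis=-1) > config.r1):
        warnings.warn("single-step displacement exceeded r1; reduce dt", stacklevel=2)
    new.time = state.time + dt
    return new


def run(config: SimulationConfig, init_state: SystemState | None = None,
        kernel_seed: int | None = None) -> Trajectory:
    """Integrate ``config.n_steps`` steps, sampling every ``sample_stride``.

    Passing ``init_state`` continues from a saved state (its labels and
    mobility flags are preserved); otherwise a random initial topology
    is drawn from ``config.rng_seed``.  The returned trajectory includes
    the initial state as frame 0.
    """
    if init_state is None:
        state = init_random(config)
    else:
        state = init_state.copy()
    n = state.n_molecules
    stride = max(1, int(config.sample_stride))
    n_frames = config.n_steps // stride + 1
    out1 = np.empty((n_frames, n, 3))
    out2 = np.empty((n_frames, n, 3))
    out_t = np.empty(n_frames)

    pos1 = state.pos1.copy()
    pos2 = state.pos2.copy()
    if kernel_seed is None:
        kernel_seed = config.rng_seed
    kernel_seed = int(kernel_seed) % (2**31)
    noise_rng = np.random.default_rng(kernel_seed)
    sigma = np.sqrt(2.0 * config.d_particle_sim * config.dt)

    # cell grid sized once here, reused across chunks (must match the
    # kernel's own sizing arithmetic in _grid_geometry)
    cutoff = max(config.i_radius, 2.0 * config.r2, config.r1 + config.r2)
    half_span = config.domain_radius + 40.0
    n_side = max(1, int(2.0 * half_span / cutoff))
    cap = int(np.sqrt(64.0 * max(n, 1))) + 1
    if n_side > cap:
        n_side = cap
    head_a = np.full(n_side * n_side, -1, dtype=np.int64)
    nxt_a = np.empty(n, dtype=np.int64)
    occ_a = np.full(n, -1, dtype=np.int64)
    head_h = np.full(n_side * n_side, -1, dtype=np.int64)
    nxt_h = np.empty(n, dtype=np.int64)
    occ_h = np.full(n, -1, dtype=np.int64)

    # Verlet pair-list state, persistent across chunks
    pair_cap = _kernels.PAIR_CAPACITY * max(n, 1)
    pairs11 = np.empty((pair_cap, 2), dtype=np.int64)
    pairs22 = np.empty((pair_cap, 2), dtype=np.int64)
    pairs21 = np.empty((pair_cap, 2), dtype=np.int64)
    counts = np.zeros(4, dtype=np.int64)  # [n11, n22, n21, valid]
    ref1 = np.zeros((n, 3))
    ref2 = np.zeros((n, 3))

    # frame 0 = initial state
    out_t[0] = state.time
    out1[0] = pos1
    out2[0] = pos2
    frame = 1

    # noise is drawn in chunks of ~4e6 values to bound memory while
    # keeping the draw vectorized
    chunk_steps = max(1, int(4_000_000 / max(1, 6 * n)))
    done = 0
    n_big = 0
    total = int(config.n_steps)
    while done < total:
        this = min(chunk_steps, total - done)
        noise = sigma * noise_rng.standard_normal((this, n, 6))
        frame, big, status = _kernels.run_chunk(
            pos1, pos2, state.mobile, state.e_a, noise, done, stride,
            config.r1, config.r2, config.k_m, config.k_rep, config.dt,
            config.d_particle_sim, config.domain_radius, config.boundary_k,
            config.bond_k, config.i_offset, out1, out2, out_t,
            state.time, frame,
            head_a, nxt_a, occ_a, head_h, nxt_h, occ_h,
            pairs11, pairs22, pairs21, counts, ref1, ref2,
        )
        if status != 0:
            raise RuntimeError("neighbor pair-list capacity exceeded")
        n_big += big
        done += this
    if n_big > 0:
        warnings.warn(
            f"{n_big} single-step displacements exceeded r1; timestep may be too large",
            stacklevel=2,
        )
    return Trajectory(
        times=out_t,
        pos1=out1,
        pos2=out2,
        mobile=state.mobile.copy(),
        e_a=state.e_a.copy(),
        labels={k: v.copy() for k, v in state.labels.items()},
        config=config,
        meta={"rng_seed": config.rng_seed, "kernel_seed": kernel_seed,
              "n_big_steps": int(n_big)},
    )


# ---------------------------------------------------------------------------
# Diffusion measurement and calibration
# ---------------------------------------------------------------------------

def msd(xy: np.ndarray, max_lag: int) -> np.ndarray:
    """Time- and molecule-averaged in-plane MSD for lags 1..max_lag.

    ``xy`` has shape ``(n_frames, n_molecules, 2)``; all time origins
    are used.  Returns an array of length ``max_lag`` in nm².
    """
    nf = xy.shape[0]
    out = np.empty(max_lag)
    for lag in range(1, max_lag + 1):
        d = xy[lag:] - xy[:-lag]
        out[lag - 1] = np.mean(np.sum(d * d, axis=-1))
    return out


def fit_diffusion(traj: Trajectory, lag_min_ns: float = 10_000.0,
                  lag_max_ns: float = 100_000.0,
                  molecules: np.ndarray | None = None,
                  mode: str = "com") -> float:
    """Diffusion coefficient (μm²/s) from the in-plane MSD slope.

    Fits ``MSD = 4 D t + b`` over frame lags between ``lag_min_ns`` and
    ``lag_max_ns``; the intercept absorbs short-time relaxation.

    ``mode="com"`` (default) uses the dimer centre of mass, which is
    what a tracked molecule reports at long times.  ``mode="anchor"``
    uses the anchor particle alone; its MSD carries a slow transient
    from the head swinging about the anchor (relaxation on the order of
    tens of μs), so anchor fits need lags well beyond that.
    """
    dt_frame = traj.frame_dt
    k_min = max(1, int(round(lag_min_ns / dt_frame)))
    k_max = max(k_min + 1, int(round(lag_max_ns / dt_frame)))
    k_max = min(k_max, traj.n_frames - 1)
    if k_max <= k_min - 1:
        raise ValueError("trajectory too short for the requested lag window")
    if mode == "com":
        xy = 0.5 * (traj.pos1[:, :, :2] + traj.pos2[:, :, :2])
    elif mode == "anchor":
        xy = traj.anchors_xy
    else:
        raise ValueError("mode must be 'com' or 'anchor'")
    if molecules is not None:
        xy = xy[:, molecules, :]
    curve = msd(xy, k_max)
    lags_ns = dt_frame * np.arange(1, k_max + 1)
    sel = lags_ns >= lag_min_ns
    slope, _ = np.polyfit(lags_ns[sel], curve[sel], 1)
    d_sim = slope / 4.0  # nm²/ns
    return d_sim / 1e-3  # μm²/s


def calibrate_particle_diffusion(config: SimulationConfig,
                                 n_steps: int = 1_000_000,
                                 n_probe: int = 32,
                                 tol: float = 0.05,
                                 max_iter: int = 6,
                                 rng_seed: int | None = None) -> float:
    """Per-particle D_p (nm²/ns) reproducing the dimer's ``d_eff``.

    Starts from the analytic centre-of-mass value ``D_p = 2 D_eff`` and
    iterates multiplicative corrections against the measured long-time
    anchor diffusion coefficient of isolated dimers (a sparse gas of
    ``n_probe`` non-interacting dimers is simulated to average the MSD).
    Raises ``RuntimeError`` if the loop does not converge.
    """
    target = config.d_eff
    d_p = 2.0 * config.d_eff_sim
    seed = config.rng_seed if rng_seed is None else rng_seed
    for it in range(max_iter):
        probe = config.evolve(
            n_molecules=n_probe,
            domain_radius=4000.0,
            e_a=0.0,
            n_steps=n_steps,
            sample_stride=1000,
            d_particle=d_p,
            rng_seed=seed + it,
        )
        traj = run(probe)
        measured = fit_diffusion(traj, lag_min_ns=5_000.0, lag_max_ns=50_000.0)
        if abs(measured - target) / target < tol:
            return d_p
        d_p *= target / measured
    raise RuntimeError("diffusion calibration did not converge")


def is_converged(traj: Trajectory, rel_tol: float = 0.05) -> bool:
    """Equilibration check: mean cluster size stable across run halves.

    The mean cluster size averaged over the first and second half of
    the trajectory must agree within ``rel_tol`` (relative).
    """
    from .traj_analysis import mean_cluster_size_and_single_fraction

    half = traj.n_frames // 2
    first = _slice_traj(traj, 0, half)
    second = _slice_traj(traj, half, traj.n_frames)
    m1, _ = mean_cluster_size_and_single_fraction(first, burn_in=0.0)
    m2, _ = mean_cluster_size_and_single_fraction(second, burn_in=0.0)
    return abs(m1 - m2) / max(m1, m2) < rel_tol


def _slice_traj(traj: Trajectory, lo: int, hi: int) -> Trajectory:
    return Trajectory(
        times=traj.times[lo:hi],
        pos1=traj.pos1[lo:hi],
        pos2=traj.pos2[lo:hi],
        mobile=traj.mobile,
        e_a=traj.e_a,
        labels=traj.labels,
        config=traj.config,
        meta=traj.meta,
    )
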