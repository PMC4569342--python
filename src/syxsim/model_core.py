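"""Domain types, unit conventions, and interaction potentials.

The model represents each Syntaxin-1A molecule as a dimer of two connected
spherical particles.  Particle 1 (radius ``r1``) is the membrane anchor
carrying the SNARE/transmembrane part; it is restrained to the membrane
plane and attracts other anchors through a short-ranged piecewise-harmonic
clustering potential of well depth ``E_a``.  Particle 2 (radius ``r2``)
models the bulky N-terminal head domain and only contributes steric
repulsion, which limits how densely anchors can pack and therefore caps
the cluster size.

Internal units
--------------
length  nm, time  ns, energy  k_BT (k_BT == 1).  Force constants are
k_BT/nm², diffusion coefficients nm²/ns.  The conventional experimental
diffusion unit converts as 1 μm²/s = 1e-3 nm²/ns.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, fields, replace

import numpy as np
import yaml

__all__ = [
    "UM2_PER_S_TO_NM2_PER_NS",
    "SimulationConfig",
    "SystemState",
    "membrane_potential",
    "repulsion_potential",
    "attraction_potential",
    "pairwise_energy_and_forces",
]

#: 1 μm²/s expressed in nm²/ns.
UM2_PER_S_TO_NM2_PER_NS = 1e-3


@dataclass
class SimulationConfig:
    """All model and integration parameters, in simulation units.

    Parameters
    ----------
    n_molecules : int
        Number of syntaxin dimers on the membrane patch.
    domain_radius : float
        Radius of the circular membrane domain (nm).
    r1, r2 : float
        Radii of the anchor and head particle (nm).  The ratio ``r2/r1``
        controls the steric cluster-size limit; ratios at or below 1
        remove the limit entirely and trigger a warning.
    d_eff : float
        Target effective diffusion coefficient of the whole dimer
        (μm²/s, the unit in which single-molecule experiments report it).
    k_m : float
        Membrane-restraint force constant on the anchor (k_BT/nm²).
    k_rep : float
        Head–head and head–anchor repulsion force constant (k_BT/nm²).
    e_a : float
        Well depth of the anchor–anchor clustering potential (k_BT).
        The repulsive core of that potential uses a force constant
        numerically equal to ``e_a`` (in k_BT/nm²).
    i_offset : float
        The clustering potential extends to ``r_sum + i_offset`` (nm).
    dt : float
        Integration timestep (ns).
    n_steps, sample_stride : int
        Number of Euler steps and the sampling interval in steps.
    rng_seed : int
        Seed of the single pseudo-random stream driving a run.
    boundary_k : float
        Half-harmonic wall stiffness confining anchors to the disk
        (k_BT/nm²).
    bond_k : float
        Harmonic bond stiffness connecting the two particles of a dimer
        (k_BT/nm²), rest length ``r1 + r2``.
    d_particle : float or None
        Per-particle diffusion coefficient (nm²/ns).  ``None`` means the
        analytic centre-of-mass value ``2 * d_eff`` (converted to
        nm²/ns); :func:`syxsim.bd_engine.calibrate_particle_diffusion`
        refines it.
    seed_e_a : float
        Well depth assigned to a static "seed" syntaxin (k_BT).
    """

    n_molecules: int = 500
    domain_radius: float = 300.0
    r1: float = 3.0
    r2: float = 3.3
    d_eff: float = 0.2
    k_m: float = 20.0
    k_rep: float = 2.0
    e_a: float = 4.0
    i_offset: float = 2.25
    dt: float = 5.0
    n_steps: int = 1_000_000
    sample_stride: int = 1_000
    rng_seed: int = 0
    boundary_k: float = 20.0
    bond_k: float = 10.0
    d_particle: float | None = None
    seed_e_a: float = 8.0

    def __post_init__(self) -> None:
        self.validate()

    # -- derived quantities -------------------------------------------------
    @property
    def r_sum(self) -> float:
        """Anchor–anchor contact distance 2·r1 (nm)."""
        return 2.0 * self.r1

    @property
    def i_radius(self) -> float:
        """Anchor–anchor interaction cutoff r_sum + i_offset (nm)."""
        return self.r_sum + self.i_offset

    @property
    def d_eff_sim(self) -> float:
        """Target dimer diffusion coefficient in nm²/ns."""
        return self.d_eff * UM2_PER_S_TO_NM2_PER_NS

    @property
    def d_particle_sim(self) -> float:
        """Per-particle diffusion coefficient in nm²/ns."""
        if self.d_particle is not None:
            return self.d_particle
        return 2.0 * self.d_eff_sim

    def validate(self) -> None:
        if self.n_molecules < 0:
            raise ValueError("n_molecules must be non-negative")
        if self.e_a < 0:
            raise ValueError("e_a must be non-negative")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.r1 <= 0 or self.r2 <= 0:
            raise ValueError("particle radii must be positive")
        if self.domain_radius <= 10.0 * self.r2:
            raise ValueError("domain_radius must exceed 10·r2")
        if self.i_offset <= 0:
            raise ValueError("i_offset must be positive")
        if self.r2 / self.r1 <= 1.0:
            warnings.warn(
                "r2/r1 <= 1 removes the steric cluster-size limit and "
                "leads to unbounded cluster growth",
                stacklevel=2,
            )

    # -- serialization ------------------------------------------------------
    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise KeyError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh) or {}
        if not isinstance(d, dict):
            raise ValueError("config file must contain a flat mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    def evolve(self, **kw) -> "SimulationConfig":
        return replace(self, **kw)


@dataclass
class SystemState:
    """Positions and tags of every dimer at one instant.

    ``pos1``/``pos2`` are ``(n, 3)`` arrays (nm) for anchor and head.
    ``mobile`` flags molecules that are integrated (static seed particles
    are ``False``).  ``e_a`` stores the per-molecule well depth so a seed
    can be more attractive than the bulk.  ``labels`` maps a tag name
    (e.g. ``"bleached"``, ``"seed"``) to a boolean mask.
    """

    time: float
    pos1: np.ndarray
    pos2: np.ndarray
    mobile: np.ndarray
    e_a: np.ndarray
    labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.pos1 = np.asarray(self.pos1, dtype=np.float64)
        self.pos2 = np.asarray(self.pos2, dtype=np.float64)
        self.mobile = np.asarray(self.mobile, dtype=bool)
        self.e_a = np.asarray(self.e_a, dtype=np.float64)
        n = len(self.pos1)
        if not (len(self.pos2) == len(self.mobile) == len(self.e_a) == n):
            raise ValueError("per-molecule arrays must have equal length")
        for mask in self.labels.values():
            if len(mask) != n:
                raise ValueError("label masks must have one entry per molecule")

    @property
    def n_molecules(self) -> int:
        return len(self.pos1)

    def label_mask(self, name: str) -> np.ndarray:
        return self.labels.get(name, np.zeros(self.n_molecules, dtype=bool))

    def copy(self) -> "SystemState":
        return SystemState(
            time=self.time,
            pos1=self.pos1.copy(),
            pos2=self.pos2.copy(),
            mobile=self.mobile.copy(),
            e_a=self.e_a.copy(),
            labels={k: v.copy() for k, v in self.labels.items()},
        )


# ---------------------------------------------------------------------------
# Potentials.  Each returns (energy, f) where f = -dU/dd is the scalar
# force along the coordinate d; all accept scalars or arrays.
# ---------------------------------------------------------------------------

def membrane_potential(d, k_m: float):
    """Harmonic restraint tying the anchor to the membrane plane.

    ``U(d) = ½ k_m d²`` with ``d`` the signed distance of particle 1 to
    the plane.  Returns ``(U, -k_m d)``.
    """
    if k_m <= 0:
        raise ValueError("k_m must be positive")
    d = np.asarray(d, dtype=np.float64)
    u = 0.5 * k_m * d * d
    f = -k_m * d
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


def repulsion_potential(d, r_sum: float, k: float):
    """Soft-core harmonic repulsion between overlapping particles.

    ``U = ½ k (d - r_sum)²`` for centre distance ``d < r_sum`` and zero
    at or beyond contact.
    """
    if r_sum <= 0:
        raise ValueError("r_sum must be positive")
    d = np.asarray(d, dtype=np.float64)
    if np.any(d < 0):
        raise ValueError("distances must be non-negative")
    overlap = d < r_sum
    delta = np.where(overlap, d - r_sum, 0.0)
    u = 0.5 * k * delta * delta
    f = -k * delta  # positive (repulsive) when delta < 0
    if u.ndim == 0:
        return float(u), float(f)
    return u, f


def attraction_potential(d, r_sum: float, i_radius: float, e_a: float,
                         k_core: float | None = None):
    """Piecewise-harmonic anchor–anchor clustering potential.

    Four branches over the centre distance ``d`` (``r = r_sum``,
    ``i = i_radius``, midpoint ``m = (i + r) / 2``)::

        d <  r       ½ k_core (d - r)² - E_a         repulsive core
        r <= d < m   2E_a/(i-r)² (d - r)² - E_a      rising attractive wall
        m <= d < i  -2E_a/(i-r)² (d - i)²            decaying tail
        d >= i       0

    The branches join C⁰/C¹-continuously: the well depth is ``-E_a`` at
    contact and the tail vanishes smoothly at the cutoff.  ``k_core``
    defaults to ``e_a`` (numerically, in k_BT/nm²).
    """
    if i_radius <= r_sum:
        raise ValueError("i_radius must exceed r_sum")
    if e_a < 0:
        raise ValueError("e_a must be non-negative")
    if k_core is None:
        k_core = e_a
    d = np.asarray(d, dtype=np.float64)
    r, i = r_sum, i_radius
    mid = 0.5 * (i + r)
    a = 2.0 * e_a / (i - r) ** 2

    u = np.zeros_like(d)
    f = np.zeros_like(d)

    core = d < r
    u = np.where(core, 0.5 * k_core * (d - r) ** 2 - e_a, u)
    f = np.where(core, -k_core * (d - r), f)

    wall = (d >= r) & (d < mid)
    u = np.where(wall, a * (d - r) ** 2 - e_a, u)
    f = np.where(wall, -2.0 * a * (d - r), f)

    tail = (d >= mid) & (d < i)
    u = np.where(tail, -a * (d - i) ** 2, u)
    f = np.where(tail, 2.0 * a * (d - i), f)

    if u.ndim == 0:
        return float(u), float(f)
    return u, f


# ---------------------------------------------------------------------------
# Reference (all-pairs, pure numpy) energy/force assembly.  The BD engine
# uses an equivalent compiled kernel; this version is the readable ground
# truth used in tests and for small systems.
# ---------------------------------------------------------------------------

def _accumulate_pair(pos_a, pos_b, i, j, f_scalar, forces_a, forces_b):
    rij = pos_a[i] - pos_b[j]
    dist = np.linalg.norm(rij)
    if dist == 0.0:
        return
    unit = rij / dist
    forces_a[i] += f_scalar * unit
    forces_b[j] -= f_scalar * unit


def pairwise_energy_and_forces(state: SystemState, config: SimulationConfig,
                               include_wall: bool = True,
                               include_bond: bool = True):
    """Total potential energy and exact force vectors for a state.

    Assembles, over all molecule pairs, the anchor–anchor clustering
    potential, head–head and head–anchor repulsions, plus the membrane
    restraint on each anchor, the intramolecular bond, and (optionally)
    the half-harmonic disk wall.  Forces are the exact negative gradient
    of the summed energy; Newton's third law holds pair by pair.

    Returns ``(energy, forces1, forces2)`` with forces in k_BT/nm.
    """
    p1, p2 = state.pos1, state.pos2
    if not (np.isfinite(p1).all() and np.isfinite(p2).all()):
        raise ValueError("non-finite coordinates")
    n = state.n_molecules
    f1 = np.zeros_like(p1)
    f2 = np.zeros_like(p2)
    energy = 0.0

    r_sum_11 = config.r_sum
    i_rad = config.i_radius
    r_sum_22 = 2.0 * config.r2
    r_sum_21 = config.r1 + config.r2

    # membrane restraint on anchors (z-direction)
    u_m, f_m = membrane_potential(p1[:, 2], config.k_m) if n else (np.zeros(0), np.zeros(0))
    if n:
        energy += float(np.sum(u_m))
        f1[:, 2] += f_m

    # intramolecular bond
    if include_bond and n:
        rest = config.r1 + config.r2
        rij = p1 - p2
        dist = np.linalg.norm(rij, axis=1)
        delta = dist - rest
        energy += float(np.sum(0.5 * config.bond_k * delta**2))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit = np.where(dist[:, None] > 0, rij / dist[:, None], 0.0)
        fb = -config.bond_k * delta[:, None] * unit
        f1 += fb
        f2 -= fb

    # disk wall on anchors (radial, in-plane)
    if include_wall and n:
        rho = np.linalg.norm(p1[:, :2], axis=1)
        out = rho > config.domain_radius
        delta = np.where(out, rho - config.domain_radius, 0.0)
        energy += float(np.sum(0.5 * config.boundary_k * delta**2))
        with np.errstate(invalid="ignore", divide="ignore"):
            unit_xy = np.where(rho[:, None] > 0, p1[:, :2] / rho[:, None], 0.0)
        f1[:, :2] += -config.boundary_k * delta[:, None] * unit_xy

    for i in range(n):
        for j in range(i + 1, n):
            # anchor-anchor clustering; a pair interacts at the stronger
            # of the two molecules' well depths (lets a seed dominate)
            e_pair = max(state.e_a[i], state.e_a[j])
            d11 = np.linalg.norm(p1[i] - p1[j])
            if d11 < i_rad and e_pair > 0:
                u, f = attraction_potential(d11, r_sum_11, i_rad, e_pair)
                energy += u
                _accumulate_pair(p1, p1, i, j, f, f1, f1)
            # head-head repulsion
            d22 = np.linalg.norm(p2[i] - p2[j])
            if d22 < r_sum_22:
                u, f = repulsion_potential(d22, r_sum_22, config.k_rep)
                energy += u
                _accumulate_pair(p2, p2, i, j, f, f2, f2)
            # head-anchor repulsion, both orderings
            d12 = np.linalg.norm(p1[i] - p2[j])
            if d12 < r_sum_21:
                u, f = repulsion_potential(d12, r_sum_21, config.k_rep)
                energy += u
                _accumulate_pair(p1, p2, i, j, f, f1, f2)
            d21 = np.linalg.norm(p2[i] - p1[j])
            if d21 < r_sum_21:
                u, f = repulsion_potential(d21, r_sum_21, config.k_rep)
                energy += u
                _accumulate_pair(p2, p1, i, j, f, f2, f1)

    return energy, f1, f2
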