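"""Ground-truth generators for images and trajectories.

Nothing in the package depends on downloaded data: synthetic STED-like
images emulate the *post-deconvolution* product of a two-color
super-resolution acquisition (Lorentzian or Gaussian spots on a pixel
grid, Poisson shot noise plus Gaussian read noise), and synthetic
trajectories with known statistics (free diffusers, frozen partitions,
two-state exchange) give every analysis stage an exactly solvable
input.

The image generator's defaults encode the study conditions the package
targets: syntaxin cluster FWHM diameters drawn from truncated normals
with means 80 nm (at AZ) and 64 nm (outside), sd 15 nm, BRP rings of
230 nm diameter built from 5 discrete spots of 25 nm FWHM, 10 nm
pixels.

Spots are rendered as Gaussians of the nominal FWHM by default.  A
Lorentzian profile is selectable, but note that a 2D Lorentzian is not
integrable: at realistic cluster densities its pooled tails raise the
inter-cluster baseline far above a fixed absolute detection threshold,
which does not happen in deconvolved data (there the far tail is set by
the narrow PSF, not by a Lorentzian of the cluster's own width).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bd_engine import Trajectory
from .model_core import SimulationConfig

__all__ = [
    "ImageSpec",
    "generate_image",
    "generate_reference_trajectory",
]


@dataclass
class ImageSpec:
    """Parameters of one synthetic two-channel image."""

    image_size_px: int = 600
    pixel_nm: float = 10.0
    n_az: int = 4
    ring_diameter_nm: float = 230.0
    spots_per_ring: int = 5
    spot_fwhm_nm: float = 25.0
    n_syx_az: int = 12
    n_syx_outside: int = 30
    syx_fwhm_mean_az_nm: float = 80.0
    syx_fwhm_mean_outside_nm: float = 64.0
    syx_fwhm_sd_nm: float = 15.0
    syx_fwhm_min_nm: float = 20.0
    peak_intensity: tuple = (60.0, 120.0)
    brp_peak_intensity: tuple = (80.0, 150.0)
    background: float = 3.0
    poisson_noise: bool = True
    read_noise_sd: float = 1.0
    profile: str = "gaussian"  # or "lorentzian"
    min_cluster_separation_nm: float = 120.0
    outside_clearance_nm: float = 150.0

    def validate(self) -> None:
        if self.image_size_px < 32 or self.pixel_nm <= 0:
            raise ValueError("invalid image geometry")
        if self.profile not in ("lorentzian", "gaussian"):
            raise ValueError("profile must be 'lorentzian' or 'gaussian'")
        if self.syx_fwhm_min_nm <= 0 or self.spot_fwhm_nm <= 0:
            raise ValueError("FWHMs must be positive")


def _render_spot(img: np.ndarray, x_nm: float, y_nm: float, fwhm_nm: float,
                 peak: float, pixel_nm: float, profile: str) -> None:
    """Add one radially symmetric spot; patch-limited for speed."""
    # render out to where the profile has decayed well below noise
    extent = 4.0 * fwhm_nm if profile == "gaussian" else 10.0 * fwhm_nm
    r_px = int(np.ceil(extent / pixel_nm))
    c0 = int(round(x_nm / pixel_nm))
    r0 = int(round(y_nm / pixel_nm))
    h, w = img.shape
    rr = np.arange(max(0, r0 - r_px), min(h, r0 + r_px + 1))
    cc = np.arange(max(0, c0 - r_px), min(w, c0 + r_px + 1))
    if len(rr) == 0 or len(cc) == 0:
        return
    yy, xx = np.meshgrid(rr * pixel_nm, cc * pixel_nm, indexing="ij")
    d2 = (yy - y_nm) ** 2 + (xx - x_nm) ** 2
    if profile == "gaussian":
        sigma = fwhm_nm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        img[np.ix_(rr, cc)] += peak * np.exp(-0.5 * d2 / sigma**2)
    else:
        img[np.ix_(rr, cc)] += peak / (1.0 + 4.0 * d2 / fwhm_nm**2)


def _truncated_normal(rng, mean, sd, lower, size):
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled))
        draw = draw[draw > lower]
        take = min(len(draw), size - filled)
        out[filled:filled + take] = draw[:take]
        filled += take
    return out


def generate_image(spec: ImageSpec, rng: np.random.Generator):
    """Render a two-channel synthetic image with full ground truth.

    Returns ``(syx_image, brp_image, ground_truth)`` where the images
    are :class:`~syxsim.sted_pipeline.StedImage` instances and the
    ground truth is a DataFrame with one row per rendered object
    (``channel, x_nm, y_nm, fwhm_nm, group, ring_id``).

    BRP rings are placed with enough clearance that rings, their padded
    AZ disks, and the AZ/outside syntaxin groups are geometrically
    unambiguous; a ``RuntimeError`` signals an infeasible request.
    """
    from .sted_pipeline import StedImage

    spec.validate()
    size_nm = spec.image_size_px * spec.pixel_nm
    ring_r = spec.ring_diameter_nm / 2.0
    margin = ring_r + 100.0

    # -- ring centres, mutually well separated ---------------------------
    ring_centers = []
    min_ring_sep = 2.0 * (ring_r + spec.outside_clearance_nm)
    for _ in range(20_000):
        if len(ring_centers) == spec.n_az:
            break
        cand = rng.uniform(margin, size_nm - margin, size=2)
        if all(np.linalg.norm(cand - c) >= min_ring_sep for c in ring_centers):
            ring_centers.append(cand)
    if len(ring_centers) < spec.n_az:
        raise RuntimeError("requested AZ density geometrically infeasible")

    truth_rows = []
    brp = np.zeros((spec.image_size_px, spec.image_size_px))
    syx = np.zeros_like(brp)

    for ring_id, center in enumerate(ring_centers):
        phase = rng.uniform(0.0, 2.0 * np.pi)
        for k in range(spec.spots_per_ring):
            ang = phase + 2.0 * np.pi * k / spec.spots_per_ring
            x = center[0] + ring_r * np.cos(ang)
            y = center[1] + ring_r * np.sin(ang)
            peak = rng.uniform(*spec.brp_peak_intensity)
            _render_spot(brp, x, y, spec.spot_fwhm_nm, peak, spec.pixel_nm,
                         spec.profile)
            truth_rows.append(("brp", x, y, spec.spot_fwhm_nm, "ring", ring_id))

    # -- syntaxin clusters ------------------------------------------------
    placed: list[np.ndarray] = []

    def place(n, group):
        fwhms = _truncated_normal(
            rng,
            spec.syx_fwhm_mean_az_nm if group == "az" else spec.syx_fwhm_mean_outside_nm,
            spec.syx_fwhm_sd_nm, spec.syx_fwhm_min_nm, n)
        count = 0
        for _ in range(50_000):
            if count == n:
                return fwhms
            if group == "az":
                if not ring_centers:
                    raise RuntimeError("AZ clusters requested but no rings")
                c = ring_centers[rng.integers(len(ring_centers))]
                rho = rng.uniform(0.0, ring_r)  # strictly inside the ring
                phi = rng.uniform(0.0, 2.0 * np.pi)
                cand = c + rho * np.array([np.cos(phi), np.sin(phi)])
            else:
                cand = rng.uniform(60.0, size_nm - 60.0, size=2)
                if ring_centers and min(
                        np.linalg.norm(cand - c) for c in ring_centers
                ) < ring_r + spec.outside_clearance_nm:
                    continue
            if placed and min(np.linalg.norm(cand - p) for p in placed) \
                    < spec.min_cluster_separation_nm:
                continue
            placed.append(cand)
            peak = rng.uniform(*spec.peak_intensity)
            _render_spot(syx, cand[0], cand[1], fwhms[count], peak,
                         spec.pixel_nm, spec.profile)
            truth_rows.append(("syntaxin", cand[0], cand[1], fwhms[count],
                               group, -1))
            count += 1
        raise RuntimeError("requested cluster density geometrically infeasible")

    place(spec.n_syx_az, "az")
    place(spec.n_syx_outside, "outside")

    for img in (syx, brp):
        img += spec.background
        if spec.poisson_noise:
            img[:] = rng.poisson(np.clip(img, 0.0, None)).astype(float)
        if spec.read_noise_sd > 0:
            img += rng.normal(0.0, spec.read_noise_sd, img.shape)
        np.clip(img, 0.0, None, out=img)

    truth = pd.DataFrame(truth_rows, columns=["channel", "x_nm", "y_nm",
                                              "fwhm_nm", "group", "ring_id"])
    return (
        StedImage(syx, pixel_nm=spec.pixel_nm, channel="syntaxin"),
        StedImage(brp, pixel_nm=spec.pixel_nm, channel="brp"),
        truth,
    )


# ---------------------------------------------------------------------------
# Reference trajectories
# ---------------------------------------------------------------------------

def _traj_from_xy(xy: np.ndarray, frame_dt_ns: float, config: SimulationConfig,
                  labels: dict | None = None) -> Trajectory:
    nf, n = xy.shape[:2]
    pos1 = np.zeros((nf, n, 3))
    pos1[:, :, :2] = xy
    pos2 = pos1.copy()
    pos2[:, :, 2] += config.r1 + config.r2
    return Trajectory(
        times=frame_dt_ns * np.arange(nf),
        pos1=pos1,
        pos2=pos2,
        mobile=np.ones(n, dtype=bool),
        e_a=np.full(n, config.e_a),
        labels=labels or {},
        config=config,
        meta={"synthetic": True},
    )


def _hex_cluster(center, n, spacing):
    """n points on a hexagonal lattice around center, within-cutoff spaced."""
    pts = [np.zeros(2)]
    shell = 1
    while len(pts) < n:
        for k in range(6 * shell):
            ang = 2.0 * np.pi * k / (6 * shell)
            pts.append(shell * spacing * np.array([np.cos(ang), np.sin(ang)]))
            if len(pts) == n:
                break
        shell += 1
    return np.asarray(pts[:n]) + center


def generate_reference_trajectory(kind: str, params: dict,
                                  rng: np.random.Generator) -> Trajectory:
    """Synthetic trajectories with exactly known statistics.

    ``kind="free-diffusers"``
        Ideal 2D Brownian walkers (params: ``n``, ``d_um2_s``,
        ``duration_ns``, ``frame_dt_ns``, ``domain_radius``); steps are
        exact Gaussian increments with radial reflection at the wall.
    ``kind="frozen-clusters"``
        A static configuration whose cluster partition is ``params["partition"]``
        (list of cluster sizes; 1 = singleton), repeated for
        ``params.get("n_frames", 2)`` frames.
    ``kind="two-state-exchange"``
        ``params["n_exchange"]`` molecules hop between a fixed cluster
        site (with ``params.get("n_core", 3)`` permanent residents) and
        a free position, with exponential rates ``k_on_per_ms`` /
        ``k_off_per_ms``; residence times are exactly exponential.
    """
    if kind == "free-diffusers":
        n = int(params.get("n", 100))
        d = float(params.get("d_um2_s", 0.2)) * 1e-3  # nm²/ns
        duration = float(params.get("duration_ns", 1e8))
        frame_dt = float(params.get("frame_dt_ns", 1e6))
        radius = float(params.get("domain_radius", 300.0))
        nf = int(duration / frame_dt) + 1
        cfg = SimulationConfig(n_molecules=n, domain_radius=radius, e_a=0.0,
                               n_steps=nf - 1, sample_stride=1)
        xy = np.empty((nf, n, 2))
        rho = radius * np.sqrt(rng.uniform(size=n))
        phi = rng.uniform(0, 2 * np.pi, size=n)
        xy[0] = np.column_stack([rho * np.cos(phi), rho * np.sin(phi)])
        sigma = np.sqrt(2.0 * d * frame_dt)
        for f in range(1, nf):
            step = rng.normal(0.0, sigma, size=(n, 2))
            nxt = xy[f - 1] + step
            # radial reflection at the disk wall
            r = np.linalg.norm(nxt, axis=1)
            out = r > radius
            if out.any():
                scale = (2.0 * radius - r[out]) / r[out]
                nxt[out] *= scale[:, None]
            xy[f] = nxt
        return _traj_from_xy(xy, frame_dt, cfg)

    if kind == "frozen-clusters":
        partition = list(params["partition"])
        n_frames = int(params.get("n_frames", 2))
        cfg = SimulationConfig(n_molecules=sum(partition), domain_radius=300.0,
                               n_steps=n_frames - 1, sample_stride=1)
        spacing = cfg.r_sum + 0.5  # within the proximity cutoff
        centers = _hex_cluster((0.0, 0.0), len(partition), 120.0)
        pts = []
        for c, size in zip(centers, partition):
            pts.append(_hex_cluster(c, size, spacing))
        xy0 = np.vstack(pts)
        xy = np.repeat(xy0[None], n_frames, axis=0)
        return _traj_from_xy(xy, float(params.get("frame_dt_ns", 1e4)), cfg)

    if kind == "two-state-exchange":
        n_ex = int(params.get("n_exchange", 20))
        n_core = int(params.get("n_core", 3))
        k_on = float(params["k_on_per_ms"])
        k_off = float(params["k_off_per_ms"])
        frame_dt = float(params.get("frame_dt_ns", 1e4))  # 10 μs
        nf = int(params.get("n_frames", 5000))
        frame_ms = frame_dt * 1e-6
        cfg = SimulationConfig(n_molecules=n_core + n_ex, domain_radius=300.0,
                               n_steps=nf - 1, sample_stride=1)
        spacing = cfg.r_sum + 0.5
        core = _hex_cluster((0.0, 0.0), n_core, spacing)
        # bound slots sit on a ring inside the proximity cutoff of the
        # first core molecule, so a bound molecule is always connected
        # to the permanent core no matter which other slots are occupied
        ang = 2.0 * np.pi * np.arange(n_ex) / n_ex
        bound_slots = core[0] + spacing * np.column_stack([np.cos(ang), np.sin(ang)])
        xy = np.empty((nf, n_core + n_ex, 2))
        xy[:, :n_core] = core
        # free positions: far from the cluster, mutually separated
        free_slots = _hex_cluster((200.0, 200.0), n_ex, 40.0)
        state = rng.uniform(size=n_ex) < k_on / (k_on + k_off)
        for f in range(nf):
            for m in range(n_ex):
                xy[f, n_core + m] = bound_slots[m] if state[m] else free_slots[m]
            p_off = 1.0 - np.exp(-k_off * frame_ms)
            p_on = 1.0 - np.exp(-k_on * frame_ms)
            u = rng.uniform(size=n_ex)
            state = np.where(state, u >= p_off, u < p_on)
        return _traj_from_xy(xy, frame_dt, cfg)

    raise ValueError(f"unknown trajectory kind: {kind!r}")
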