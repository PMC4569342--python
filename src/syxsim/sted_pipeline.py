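"""Quantification of two-channel STED images of syntaxin and Bruchpilot.

The pipeline mirrors a classic spot-analysis workflow on deconvolved
super-resolution images (10 nm/px): local-maximum detection inside a
circular window, cluster sizing by the full-width-half-maximum (FWHM)
area, grouping of Bruchpilot (BRP) spots into the ring-like active-zone
(AZ) scaffolds, and classification of syntaxin clusters as lying at or
outside active zones.

Coordinates are pixel centres, 0-based, (row, col); physical distances
are centre-to-centre in nm.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.stats import ttest_ind

__all__ = [
    "StedImage",
    "detect_maxima",
    "fwhm_size",
    "detect_and_size",
    "ActiveZone",
    "ActiveZoneSet",
    "define_active_zones",
    "classify_and_measure",
    "compare_groups",
]

#: Detection window diameters used throughout (px): syntaxin spots are
#: resolvable down to ~40 nm separation, BRP spots down to ~100 nm.
SYX_WINDOW_PX = 9
BRP_WINDOW_PX = 21

#: Default distance-bin edges (nm) for the cluster-size vs distance-to-AZ
#: summary: 8 ranges from touching the scaffold to >300 nm away.
DISTANCE_BIN_EDGES = np.array([0.0, 25.0, 50.0, 75.0, 100.0, 150.0, 200.0,
                               300.0, np.inf])


@dataclass
class StedImage:
    """A single-channel 2D intensity image with physical pixel size."""

    data: np.ndarray
    pixel_nm: float = 10.0
    channel: str = "syntaxin"
    membrane_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 2:
            raise ValueError("image must be 2D")
        if self.pixel_nm <= 0:
            raise ValueError("pixel size must be positive")

    @classmethod
    def from_tiff(cls, path, pixel_nm: float = 10.0, channel: str = "syntaxin"):
        import tifffile

        return cls(tifffile.imread(path), pixel_nm=pixel_nm, channel=channel)

    def to_tiff(self, path) -> None:
        import tifffile

        tifffile.imwrite(path, self.data.astype(np.float32))


def _disk_footprint(diameter_px: int) -> np.ndarray:
    r = diameter_px / 2.0
    c = (diameter_px - 1) / 2.0
    yy, xx = np.mgrid[:diameter_px, :diameter_px]
    return (yy - c) ** 2 + (xx - c) ** 2 <= r * r


def detect_maxima(image: StedImage, window_px: int,
                  min_intensity: float = 25.0) -> np.ndarray:
    """Centres of local intensity maxima inside a circular window.

    A pixel is a centre iff it attains the maximum of the circular
    window of diameter ``window_px`` centred on it, is strictly greater
    than at least one window pixel, and its intensity is strictly above
    ``min_intensity``.  Flat plateaus of connected equal maxima
    contribute their centroid pixel.  Returns an (m, 2) array of
    (row, col) indices.
    """
    if window_px < 3 or window_px % 2 == 0:
        raise ValueError("window_px must be odd and >= 3")
    img = image.data
    if window_px > min(img.shape):
        raise ValueError("window larger than image")
    fp = _disk_footprint(window_px)
    dil = ndimage.maximum_filter(img, footprint=fp, mode="constant", cval=-np.inf)
    ero = ndimage.minimum_filter(img, footprint=fp, mode="constant", cval=np.inf)
    cand = (img == dil) & (img > min_intensity) & (ero < img)
    if not cand.any():
        return np.zeros((0, 2), dtype=np.int64)
    # collapse connected plateaus of equal intensity to their centroid
    lab, n_lab = ndimage.label(cand)
    centers = []
    for com in ndimage.center_of_mass(cand, lab, range(1, n_lab + 1)):
        rc = (int(round(com[0])), int(round(com[1])))
        if not cand[rc]:
            # centroid fell off the plateau (concave shape): snap to the
            # nearest plateau pixel
            pts = np.argwhere(lab == lab[int(com[0]), int(com[1])] if lab[int(com[0]), int(com[1])] else cand)
            d = np.sum((pts - np.array(com)) ** 2, axis=1)
            rc = tuple(pts[np.argmin(d)])
        centers.append(rc)
    return np.array(sorted(set(centers)), dtype=np.int64)


def fwhm_size(image: StedImage, center) -> tuple | None:
    """FWHM area and equivalent-circle diameter of one detected spot.

    Rings of increasing integer pixel radius around the centre are
    scanned until the first ring whose average intensity drops below
    half the centre intensity.  The cluster area is the number of
    scanned pixels at or above the half-maximum; the diameter is that
    of a circle of equal physical area.  Returns ``(area_px, diameter_nm)``
    or ``None`` when the scan runs off the image border before
    terminating (border spots are flagged by the caller).
    """
    img = image.data
    r0, c0 = int(center[0]), int(center[1])
    half = img[r0, c0] / 2.0
    h, w = img.shape

    area = 1  # the centre pixel itself (>= half by construction)
    max_r = int(np.ceil(np.hypot(h, w)))
    for radius in range(1, max_r + 1):
        rr = np.arange(max(0, r0 - radius), min(h, r0 + radius + 1))
        cc = np.arange(max(0, c0 - radius), min(w, c0 + radius + 1))
        yy, xx = np.meshgrid(rr, cc, indexing="ij")
        dist = np.round(np.hypot(yy - r0, xx - c0)).astype(np.int64)
        ring = dist == radius
        # the full ring must fit in the image, otherwise the average is
        # not well defined -> border spot
        n_expected = int(np.sum(np.round(np.hypot(
            *np.mgrid[-radius:radius + 1, -radius:radius + 1])) == radius))
        if int(ring.sum()) < n_expected:
            return None
        vals = img[yy[ring], xx[ring]]
        area += int(np.sum(vals >= half))  # scanned pixels at/above half-max
        if vals.mean() < half:
            break
    else:
        return None
    area_nm2 = area * image.pixel_nm**2
    diameter_nm = 2.0 * np.sqrt(area_nm2 / np.pi)
    return area, diameter_nm


def detect_and_size(image: StedImage, window_px: int | None = None,
                    min_intensity: float = 25.0) -> pd.DataFrame:
    """Detect spots and size each by its FWHM area.

    Returns one row per detection: ``row, col, x_nm, y_nm, peak,
    area_px2, diameter_nm, border`` (border spots keep NaN sizes).
    """
    if window_px is None:
        window_px = SYX_WINDOW_PX if image.channel == "syntaxin" else BRP_WINDOW_PX
    centers = detect_maxima(image, window_px, min_intensity)
    rows = []
    for r, c in centers:
        res = fwhm_size(image, (r, c))
        if res is None:
            rows.append((r, c, c * image.pixel_nm, r * image.pixel_nm,
                         image.data[r, c], np.nan, np.nan, True))
        else:
            area, diam = res
            rows.append((r, c, c * image.pixel_nm, r * image.pixel_nm,
                         image.data[r, c], float(area), diam, False))
    return pd.DataFrame(
        rows, columns=["row", "col", "x_nm", "y_nm", "peak", "area_px2",
                       "diameter_nm", "border"],
    )


# ---------------------------------------------------------------------------
# Active zones
# ---------------------------------------------------------------------------

@dataclass
class ActiveZone:
    """One BRP ring and the filled padded disk derived from it."""

    members: np.ndarray          # indices into the BRP centre list
    center_nm: np.ndarray        # ring centroid (x, y) nm
    ring_radius_nm: float        # mean spot-to-centroid distance
    az_radius_nm: float          # ring radius + padding

    def contains(self, xy_nm) -> np.ndarray:
        xy = np.atleast_2d(xy_nm)
        return np.linalg.norm(xy - self.center_nm, axis=1) <= self.az_radius_nm


@dataclass
class ActiveZoneSet:
    zones: list = field(default_factory=list)
    pad_nm: float = 25.0

    def __len__(self) -> int:
        return len(self.zones)

    @property
    def total_area_um2(self) -> float:
        return float(sum(np.pi * (z.az_radius_nm * 1e-3) ** 2 for z in self.zones))

    def mask(self, shape, pixel_nm: float) -> np.ndarray:
        """Boolean AZ mask on the pixel grid (closed disks)."""
        out = np.zeros(shape, dtype=bool)
        yy, xx = np.mgrid[: shape[0], : shape[1]]
        for z in self.zones:
            d = np.hypot(xx * pixel_nm - z.center_nm[0],
                         yy * pixel_nm - z.center_nm[1])
            out |= d <= z.az_radius_nm
        return out


def _fit_circle(xy: np.ndarray):
    """Algebraic (Kasa) least-squares circle fit -> (center, radius, rms)."""
    a = np.column_stack([2.0 * xy, np.ones(len(xy))])
    b = np.sum(xy**2, axis=1)
    sol, *_ = np.linalg.lstsq(a, b, rcond=None)
    center = sol[:2]
    radius = np.sqrt(sol[2] + center @ center)
    resid = np.linalg.norm(xy - center, axis=1) - radius
    return center, radius, float(np.sqrt(np.mean(resid**2)))


def define_active_zones(brp_centers_nm: np.ndarray, pad_nm: float = 25.0,
                        linkage_nm: float = 150.0, min_ring_spots: int = 4,
                        max_fit_residual_nm: float = 30.0,
                        diameter_band_nm: tuple = (150.0, 400.0)) -> ActiveZoneSet:
    """Group BRP spots into rings and derive padded AZ disks.

    Spots are grouped by single-linkage clustering at ``linkage_nm``;
    a group qualifies as a ring when it has at least ``min_ring_spots``
    members, its least-squares circle fit has RMS residual below
    ``max_fit_residual_nm``, and the resulting AZ diameter falls inside
    the plausibility band.  The AZ disk is centred on the spot centroid
    with radius = mean spot-to-centroid distance + ``pad_nm``.
    """
    xy = np.atleast_2d(np.asarray(brp_centers_nm, dtype=float))
    if len(xy) == 0:
        raise ValueError("need at least one BRP spot")
    if len(xy) == 1:
        groups = np.array([1])
    else:
        groups = fcluster(linkage(xy, method="single"), t=linkage_nm,
                          criterion="distance")
    zones = []
    for g in np.unique(groups):
        idx = np.nonzero(groups == g)[0]
        if len(idx) < min_ring_spots:
            continue
        pts = xy[idx]
        _, _, rms = _fit_circle(pts)
        if rms >= max_fit_residual_nm:
            continue
        centroid = pts.mean(axis=0)
        ring_r = float(np.mean(np.linalg.norm(pts - centroid, axis=1)))
        az_r = ring_r + pad_nm
        if not (diameter_band_nm[0] <= 2.0 * az_r <= diameter_band_nm[1]):
            continue
        zones.append(ActiveZone(members=idx, center_nm=centroid,
                                ring_radius_nm=ring_r, az_radius_nm=az_r))
    return ActiveZoneSet(zones=zones, pad_nm=pad_nm)


# ---------------------------------------------------------------------------
# Classification and group statistics
# ---------------------------------------------------------------------------

def classify_and_measure(syx_detections: pd.DataFrame, az_set: ActiveZoneSet,
                         brp_centers_nm: np.ndarray,
                         membrane_mask: np.ndarray | None = None,
                         pixel_nm: float = 10.0,
                         distance_bins: np.ndarray = DISTANCE_BIN_EDGES):
    """Assign syntaxin clusters to AZ/outside and summarize.

    Adds ``at_az`` (centre inside any closed AZ disk) and
    ``dist_to_brp_nm`` (minimum distance to any ring-member BRP spot
    centre) to a copy of the detection table.  The summary reports
    cluster counts, group mean diameters, densities per μm² (AZ count
    over summed AZ area; outside count over membrane-minus-AZ area) and
    a size-vs-distance table over ``distance_bins``.
    """
    det = syx_detections.copy()
    if len(det) == 0:
        det["at_az"] = pd.Series(dtype=bool)
        det["dist_to_brp_nm"] = pd.Series(dtype=float)
        summary = {"n_az": 0, "n_outside": 0, "density_az_per_um2": 0.0,
                   "density_outside_per_um2": 0.0,
                   "mean_diameter_az_nm": np.nan,
                   "mean_diameter_outside_nm": np.nan}
        return det, summary, pd.DataFrame()

    xy = det[["x_nm", "y_nm"]].to_numpy()
    at_az = np.zeros(len(det), dtype=bool)
    for z in az_set.zones:
        at_az |= z.contains(xy)
    det["at_az"] = at_az

    ring_members = sorted({i for z in az_set.zones for i in z.members})
    if ring_members:
        ring_xy = np.atleast_2d(np.asarray(brp_centers_nm, dtype=float))[ring_members]
        d = np.linalg.norm(xy[:, None, :] - ring_xy[None, :, :], axis=2)
        det["dist_to_brp_nm"] = d.min(axis=1)
    else:
        det["dist_to_brp_nm"] = np.nan

    n_az = int(at_az.sum())
    n_out = int((~at_az).sum())
    az_area = az_set.total_area_um2
    density_az = n_az / az_area if az_area > 0 else 0.0
    if membrane_mask is not None:
        mem_area = float(membrane_mask.sum()) * (pixel_nm * 1e-3) ** 2
        out_area = mem_area - az_area
        density_out = n_out / out_area if out_area > 0 else 0.0
    else:
        warnings.warn("no membrane mask: outside density omitted", stacklevel=2)
        density_out = np.nan

    summary = {
        "n_az": n_az,
        "n_outside": n_out,
        "density_az_per_um2": density_az,
        "density_outside_per_um2": density_out,
        "mean_diameter_az_nm": float(det.loc[at_az, "diameter_nm"].mean()),
        "mean_diameter_outside_nm": float(det.loc[~at_az, "diameter_nm"].mean()),
    }

    binned = det.dropna(subset=["dist_to_brp_nm", "diameter_nm"]).copy()
    binned["distance_bin"] = pd.cut(binned["dist_to_brp_nm"], distance_bins,
                                    right=False)
    size_vs_distance = binned.groupby("distance_bin", observed=False)[
        "diameter_nm"].agg(["count", "mean", "median"]).reset_index()
    return det, summary, size_vs_distance


def compare_groups(sizes_a, sizes_b, equal_var: bool = True):
    """Two-sample t-test on group means with significance stars.

    Returns ``(p_value, stars)`` where stars is '', '*', '**' or '***'
    at the 0.05 / 0.01 / 0.001 levels.  Degenerate (zero-variance)
    inputs are reported as non-significant with a warning.
    """
    a = np.asarray(sizes_a, dtype=float)
    b = np.asarray(sizes_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("need at least two observations per group")
    if a.std() == 0 and b.std() == 0:
        if a.mean() == b.mean():
            warnings.warn("identical degenerate groups: p set to 1", stacklevel=2)
            return 1.0, ""
        warnings.warn("zero-variance groups: t-test undefined, "
                      "reporting non-significance", stacklevel=2)
        return np.nan, ""
    p = ttest_ind(a, b, equal_var=equal_var).pvalue
    if p < 0.001:
        stars = "***"
    elif p < 0.01:
        stars = "**"
    elif p < 0.05:
        stars = "*"
    else:
        stars = ""
    return float(p), stars
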