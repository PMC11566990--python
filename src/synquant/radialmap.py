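"""Clock-scan radial profiles and region-fraction statistics.

The clock scan samples intensity along rays from the cell centroid; each
ray's length is normalized so its boundary crossing is at 100%, and the
scan continues to 120% so signal just outside the cell is captured.  Two
summaries are derived from one profile:

* ``mean_intensity`` — the per-bin mean over rays, the curve the clock-scan
  plots show;
* ``fraction_of_total`` — the fraction of total fluorescence per radial
  bin.  Samples are weighted by the polar-coordinate area element
  (r dr dtheta), so for a spatially uniform signal the fractions reproduce
  annulus areas exactly (outer-quarter annulus of a disk = 43.75%, thirds
  = 1/9 : 3/9 : 5/9).

Region statistics (inside/outside of the contour within the 120% region,
peripheral quarter, radial thirds) consume either the profile or the pixel
grid directly; pixels whose centers lie on the contour count as inside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage, stats

from .scenegen import Scene
from .segment import CellGeometry

__all__ = [
    "RadialProfile",
    "RegionFractions",
    "radial_profile",
    "inside_outside_fraction",
    "peripheral_fraction",
    "thirds_distribution",
    "antigen_centered_actin",
    "ks_compare",
]

_MAX_RHO = 1.2
_N_BINS = 120  # 1% steps of normalized radius


@dataclass
class RadialProfile:
    """Angle-averaged intensity vs normalized radius (0–120% in 1% bins).

    ``sampled`` flags bins with at least one in-image sample; bins beyond
    the image are absent (NaN mean), not zero.  ``fraction_of_total`` sums
    to 1 over sampled bins.
    """

    bin_edges: np.ndarray
    mean_intensity: np.ndarray
    fraction_of_total: np.ndarray
    sampled: np.ndarray
    n_rays: int

    @property
    def bin_mid(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])


@dataclass
class RegionFractions:
    inside_pct: float
    outside_pct: float
    peripheral_quarter_pct: float
    thirds_pct: tuple[float, float, float]


def _pixel_rho(scene_shape, geometry: CellGeometry):
    yy, xx = np.mgrid[0 : scene_shape[0], 0 : scene_shape[1]].astype(float)
    dy, dx = yy - geometry.centroid[0], xx - geometry.centroid[1]
    r = np.hypot(dy, dx)
    rb = geometry.radius_at(np.arctan2(dy, dx))
    return r / np.maximum(rb, 1e-9)


def radial_profile(
    scene: Scene,
    geometry: CellGeometry,
    channel: str,
    n_rays: int = 360,
    z: int | None = None,
) -> RadialProfile:
    """Clock-scan profile of one channel: bilinear sampling at 1%-of-ray
    steps along ``n_rays`` rays out to 120% of each ray's boundary
    distance."""
    img = scene.channel(channel)
    img = img[geometry.mid_z if z is None else z].astype(float)
    cy, cx = geometry.centroid
    iy, ix = int(round(cy)), int(round(cx))
    if not (
        0 <= iy < img.shape[0]
        and 0 <= ix < img.shape[1]
        and geometry.cell_mask[iy, ix]
    ):
        raise ValueError("degenerate geometry: centroid lies outside the cell mask")

    angles = np.linspace(0, 2 * np.pi, n_rays, endpoint=False)
    L = geometry.radius_at(angles)  # per-ray boundary distance
    rho_mid = (np.arange(_N_BINS) + 0.5) / 100.0  # bin midpoints
    rr = rho_mid[None, :] * L[:, None]
    yy = cy + rr * np.sin(angles)[:, None]
    xx = cx + rr * np.cos(angles)[:, None]
    inside_img = (
        (yy >= 0) & (yy <= img.shape[0] - 1) & (xx >= 0) & (xx <= img.shape[1] - 1)
    )
    vals = ndimage.map_coordinates(
        img, np.stack([yy.ravel(), xx.ravel()]), order=1, mode="constant", cval=0.0
    ).reshape(rr.shape)
    vals = np.where(inside_img, vals, np.nan)

    with np.errstate(invalid="ignore"):
        mean_intensity = np.nanmean(vals, axis=0)
    sampled = np.any(inside_img, axis=0)
    mean_intensity[~sampled] = np.nan

    # polar area element: sample at (rho, theta) carries weight rho * L^2
    w = rho_mid[None, :] * (L**2)[:, None]
    contrib = np.where(inside_img, vals * w, 0.0)
    per_bin = contrib.sum(axis=0)
    total = per_bin.sum()
    fraction = per_bin / total if total > 0 else np.zeros(_N_BINS)

    return RadialProfile(
        bin_edges=np.arange(_N_BINS + 1) / 100.0,
        mean_intensity=mean_intensity,
        fraction_of_total=fraction,
        sampled=sampled,
        n_rays=n_rays,
    )


def inside_outside_fraction(
    scene: Scene,
    geometry: CellGeometry,
    channel: str,
    boundary: str = "auto",
    background: float | str = 0.0,
) -> RegionFractions:
    """Split the channel's total intensity within 120% of the per-ray cell
    radius at the cell contour.

    ``boundary`` records which contour the supplied geometry was built from
    (``cortical_actin``/``brightfield``); it does not alter the computation
    — segment with the channel you want first.  Pixels whose centers lie on
    the contour count as inside.  ``background`` is a constant subtracted
    before apportioning: 0 (default), a number, or ``"auto"`` to estimate
    it as the median intensity outside 125% of the cell radius.  The
    subtraction is not clipped at zero, so zero-mean noise cancels instead
    of biasing the sums.
    """
    if boundary not in ("auto", "cortical_actin", "brightfield"):
        raise ValueError("boundary must be 'auto', 'cortical_actin' or 'brightfield'")
    img = scene.channel(channel)[geometry.mid_z].astype(float)
    rho = _pixel_rho(img.shape, geometry)
    if background == "auto":
        far = rho > 1.25
        background = float(np.median(img[far])) if far.any() else 0.0
    img = img - float(background)
    inside = rho <= 1.0
    ring = (rho > 1.0) & (rho <= _MAX_RHO)
    s_in = img[inside].sum()
    s_out = img[ring].sum()
    total = s_in + s_out
    if total <= 0:
        raise ValueError("no signal to apportion within the 120% region")
    inside_pct = 100.0 * s_in / total
    # peripheral quarter and thirds from the same pixel map
    periph = img[(rho > 0.75) & (rho <= 1.0)].sum()
    t1 = img[rho <= 1.0 / 3.0].sum()
    t2 = img[(rho > 1.0 / 3.0) & (rho <= 2.0 / 3.0)].sum()
    t3 = img[(rho > 2.0 / 3.0) & (rho <= _MAX_RHO)].sum()
    return RegionFractions(
        inside_pct=float(inside_pct),
        outside_pct=float(100.0 - inside_pct),
        peripheral_quarter_pct=float(100.0 * periph / total),
        thirds_pct=tuple(100.0 * np.array([t1, t2, t3]) / total),
    )


def _split_bin_mass(fraction: np.ndarray, edges: np.ndarray, cut: float) -> float:
    """Mass of ``fraction`` below ``cut``, apportioning the straddling bin
    by the quadratic (area-element) sub-bin weight."""
    lo = edges[:-1]
    hi = edges[1:]
    below = fraction[hi <= cut].sum()
    j = np.flatnonzero((lo < cut) & (hi > cut))
    if j.size:
        a, b = lo[j[0]], hi[j[0]]
        below += fraction[j[0]] * (cut**2 - a**2) / (b**2 - a**2)
    return float(below)


def peripheral_fraction(profile: RadialProfile, cut: float = 0.75) -> float:
    """Percentage of total fluorescence at normalized radii in (cut, 1.0]
    (default: the peripheral quarter of the cell radius)."""
    if not 0.0 < cut < 1.0:
        raise ValueError("cut must lie strictly between 0 and 1")
    f = profile.fraction_of_total
    below_cut = _split_bin_mass(f, profile.bin_edges, cut)
    below_one = _split_bin_mass(f, profile.bin_edges, 1.0)
    return 100.0 * (below_one - below_cut)


def thirds_distribution(profile: RadialProfile) -> tuple[float, float, float]:
    """Percentage of total fluorescence in the inner, middle and outer
    radial thirds; signal beyond 100% is assigned to the outer third."""
    f = profile.fraction_of_total
    c1 = _split_bin_mass(f, profile.bin_edges, 1.0 / 3.0)
    c2 = _split_bin_mass(f, profile.bin_edges, 2.0 / 3.0)
    total = f.sum()
    return (100.0 * c1, 100.0 * (c2 - c1), 100.0 * (total - c2))


def antigen_centered_actin(
    scene: Scene,
    geometry: CellGeometry,
    spot_center: tuple[float, float],
    radius_um: float = 1.5,
    n_bins: int = 10,
) -> np.ndarray:
    """Fraction of F-actin by distance from an antigen spot, within a
    circle of ``radius_um`` around it (10 bins by default).  Sampled on a
    polar grid with area-element weights, so a uniform actin field yields
    fractions proportional to annulus areas."""
    img = scene.channel("actin")[geometry.mid_z].astype(float)
    r_px = radius_um / scene.pixel_size_um
    cy, cx = spot_center
    if (
        cy + r_px < 0
        or cy - r_px > img.shape[0] - 1
        or cx + r_px < 0
        or cx - r_px > img.shape[1] - 1
    ):
        raise ValueError("circle lies entirely outside the image")
    n_rays = 180
    n_steps = 10 * n_bins
    angles = np.linspace(0, 2 * np.pi, n_rays, endpoint=False)
    rho = (np.arange(n_steps) + 0.5) / n_steps  # of r_px
    rr = rho[None, :] * r_px
    yy = cy + rr * np.sin(angles)[:, None]
    xx = cx + rr * np.cos(angles)[:, None]
    ok = (yy >= 0) & (yy <= img.shape[0] - 1) & (xx >= 0) & (xx <= img.shape[1] - 1)
    vals = ndimage.map_coordinates(
        img, np.stack([yy.ravel(), xx.ravel()]), order=1, mode="constant", cval=0.0
    ).reshape(yy.shape)
    w = np.where(ok, rho[None, :], 0.0)
    contrib = (vals * w).reshape(n_rays, n_bins, n_steps // n_bins).sum(axis=(0, 2))
    total = contrib.sum()
    if total <= 0:
        raise ValueError("no actin signal within the circle")
    return contrib / total


def ks_compare(dist_a, dist_b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov comparison (asymptotic p-value)."""
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)
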