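"""Synthetic B-cell scene generator with per-cell ground truth.

Every quantification stage in this package (segmentation, radial clock-scan
profiling, bead-quadrant actin scoring, colocalization, nuclear-translocation
and surface-retention kinetics) is validated by parameter recovery against
scenes produced here.  A scene is a multi-channel fluorescence image of a
single roughly circular B cell (default ~7 um diameter at 0.1 um/px) with:

* a bright-field channel (filled cell body with a soft edge),
* cortical F-actin (a ridge centred on the cell boundary, plus an optional
  actin cup around an antigen-coated bead),
* a nucleus channel (soft disk covering ~25% of the cell area),
* an antigen channel made of Gaussian puncta whose intensity split across
  the cell boundary is controlled exactly (``antigen_inside_fraction``),
* a signalling channel (e.g. NF-kB) with tunable nuclear enrichment,
* an endosome/lysosome-style puncta channel whose pixelwise Pearson
  correlation with a designated partner channel is controlled exactly
  (``coloc_rho``),
* optionally a 3-um bead resting on the cell surface whose surrounding
  actin cup redistributes from the cell-proximal to the distal side as
  ``cup_clearance`` goes from 0 to 1.

The generator records the *realized* (pre-noise) values of every controlled
quantity in a :class:`GroundTruth` attached to the scene, so recovery error
of a downstream measurement can be separated from generation error.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "NoiseModel",
    "SceneConfig",
    "GroundTruth",
    "Scene",
    "PRESETS",
    "CLEARANCE_TIMECOURSES",
    "make_preset",
    "generate_scene",
    "generate_bead_timecourse",
    "generate_kinetics",
    "write_scene",
    "read_scene",
]

#: channel roles a scene may declare
CHANNEL_ROLES = frozenset(
    {
        "brightfield",
        "actin",
        "nucleus",
        "antigen",
        "signal",
        "endosome",
        "lysosome",
        "membrane",
        "bead",
    }
)

_ANTIGEN_SIGMA_PX = 2.0  # isotropic Gaussian spot width
_PUNCTA_TRUNC_SIGMAS = 4.0  # spots rendered exactly zero beyond this radius
_CUP_SIGMA_PX = 1.5
_CUP_KAPPA = 8.0  # von Mises concentration of the cup's angular density
_CORTEX_SIGMA_PX = 1.5
_KINETICS_BASELINE = 1000.0
_KINETICS_GSD = 1.3  # geometric sd of the per-cell log-normal


@dataclass(frozen=True)
class NoiseModel:
    """Photon (Poisson) noise at ``photon_scale`` expected counts per grey
    level, plus additive Gaussian background."""

    photon_scale: float = 50.0
    background_mean: float = 5.0
    background_sd: float = 2.0


@dataclass
class SceneConfig:
    """Full parameterization of one synthetic scene.

    ``antigen_radial_mode`` controls where *inside* antigen puncta sit along
    the normalized cell radius: ``"central"`` (Beta(2,2) scaled to [0,0.95],
    the centrally-accumulating control phenotype), ``"peripheral"``
    (Beta(6,2) scaled to [0,0.95], the boundary-hugging knockout phenotype),
    ``"uniform"`` (area-uniform over the cell disk) or ``"ring"`` (a narrow
    ring at ``ring_radius`` of the normalized radius).
    """

    image_size_px: tuple[int, int] = (160, 160)
    pixel_size_um: float = 0.1
    cell_radius_um: float = 3.5
    boundary_wobble: float = 0.06
    channels: tuple[str, ...] = (
        "brightfield",
        "actin",
        "nucleus",
        "antigen",
        "signal",
        "endosome",
    )
    antigen_inside_fraction: float = 0.8
    antigen_radial_mode: str = "central"
    ring_radius: float = 0.5
    n_puncta: int = 40
    antigen_total_intensity: float = 2.0e5
    cup_clearance: float = 0.0
    nuclear_fraction_param: float = 1.0
    coloc_rho: float = 0.0
    coloc_channels: tuple[str, str] = ("antigen", "endosome")
    bead_radius_um: float = 1.5
    noise_model: Optional[NoiseModel] = field(default_factory=NoiseModel)
    kinetics_anchors: Optional[tuple[tuple[float, float], ...]] = None
    n_z: int = 1
    z_step_um: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        h, w = self.image_size_px
        if h <= 0 or w <= 0:
            raise ValueError("image_size_px must be positive")
        for name in ("pixel_size_um", "cell_radius_um", "bead_radius_um"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.boundary_wobble < 0:
            raise ValueError("boundary_wobble must be non-negative")
        if not 0.0 <= self.antigen_inside_fraction <= 1.0:
            raise ValueError("antigen_inside_fraction must lie in [0, 1]")
        if not 0.0 <= self.cup_clearance <= 1.0:
            raise ValueError("cup_clearance must lie in [0, 1]")
        if not -1.0 <= self.coloc_rho <= 1.0:
            raise ValueError("coloc_rho must lie in [-1, 1]")
        if self.nuclear_fraction_param < 0:
            raise ValueError("nuclear_fraction_param must be >= 0")
        if self.n_puncta < 1:
            raise ValueError("n_puncta must be a positive integer")
        if self.antigen_radial_mode not in {"central", "peripheral", "uniform", "ring"}:
            raise ValueError(
                "antigen_radial_mode must be one of central, peripheral, uniform, ring"
            )
        if self.n_z < 1:
            raise ValueError("n_z must be >= 1")
        bad = [c for c in self.channels if c not in CHANNEL_ROLES]
        if bad:
            raise ValueError(f"unknown channel roles: {bad}")
        if len(set(self.channels)) != len(self.channels):
            raise ValueError("each channel role may appear at most once")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["noise_model"] = (
            None if self.noise_model is None else dataclasses.asdict(self.noise_model)
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        if d.get("noise_model") is not None:
            d["noise_model"] = NoiseModel(**d["noise_model"])
        d["image_size_px"] = tuple(d["image_size_px"])
        d["channels"] = tuple(d["channels"])
        d["coloc_channels"] = tuple(d["coloc_channels"])
        if d.get("kinetics_anchors") is not None:
            d["kinetics_anchors"] = tuple(tuple(a) for a in d["kinetics_anchors"])
        return cls(**d)


@dataclass
class GroundTruth:
    """Realized (pre-noise) generative quantities for one scene."""

    seed: int
    centroid: tuple[float, float]
    cell_mask: np.ndarray
    nucleus_mask: Optional[np.ndarray] = None
    realized_inside_fraction: float = float("nan")
    realized_quadrant_percentages: Optional[tuple[float, float, float, float]] = None
    realized_nuclear_ratio: float = float("nan")
    realized_coloc_rho: float = float("nan")
    bead_center: Optional[tuple[float, float]] = None
    bead_radius_px: Optional[float] = None

    def to_dict(self) -> dict:
        d = {
            "seed": self.seed,
            "centroid": list(self.centroid),
            "cell_mask": _rle_encode(self.cell_mask),
            "nucleus_mask": (
                None if self.nucleus_mask is None else _rle_encode(self.nucleus_mask)
            ),
            "realized_inside_fraction": _none_if_nan(self.realized_inside_fraction),
            "realized_quadrant_percentages": (
                None
                if self.realized_quadrant_percentages is None
                else list(self.realized_quadrant_percentages)
            ),
            "realized_nuclear_ratio": _none_if_nan(self.realized_nuclear_ratio),
            "realized_coloc_rho": _none_if_nan(self.realized_coloc_rho),
            "bead_center": None if self.bead_center is None else list(self.bead_center),
            "bead_radius_px": self.bead_radius_px,
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            seed=d["seed"],
            centroid=tuple(d["centroid"]),
            cell_mask=_rle_decode(d["cell_mask"]),
            nucleus_mask=(
                None if d["nucleus_mask"] is None else _rle_decode(d["nucleus_mask"])
            ),
            realized_inside_fraction=_nan_if_none(d["realized_inside_fraction"]),
            realized_quadrant_percentages=(
                None
                if d["realized_quadrant_percentages"] is None
                else tuple(d["realized_quadrant_percentages"])
            ),
            realized_nuclear_ratio=_nan_if_none(d["realized_nuclear_ratio"]),
            realized_coloc_rho=_nan_if_none(d["realized_coloc_rho"]),
            bead_center=(
                None if d["bead_center"] is None else tuple(d["bead_center"])
            ),
            bead_radius_px=d["bead_radius_px"],
        )


@dataclass
class Scene:
    """A multi-channel (optionally multi-plane) intensity image.

    ``planes`` has shape (n_channels, n_z, height, width); page order on
    disk is channel-major (all z of channel 0, then channel 1, ...).
    """

    planes: np.ndarray
    channel_roles: dict[int, str]
    pixel_size_um: float
    z_step_um: Optional[float] = None
    provenance: Optional[GroundTruth] = None

    def __post_init__(self) -> None:
        if self.planes.ndim != 4:
            raise ValueError("planes must have shape (C, Z, H, W)")
        if not np.all(np.isfinite(self.planes)) or np.any(self.planes < 0):
            raise ValueError("intensities must be finite and non-negative")
        roles = list(self.channel_roles.values())
        if len(set(roles)) != len(roles):
            raise ValueError("every declared role must map to exactly one channel")

    @property
    def n_channels(self) -> int:
        return self.planes.shape[0]

    @property
    def n_z(self) -> int:
        return self.planes.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[2], self.planes.shape[3]

    def has_channel(self, role: str) -> bool:
        return role in self.channel_roles.values()

    def channel_index(self, role: str) -> int:
        for i, r in self.channel_roles.items():
            if r == role:
                return i
        raise KeyError(
            f"scene has no channel with role {role!r}; "
            f"available: {sorted(self.channel_roles.values())}"
        )

    def channel(self, role: str, z: Optional[int] = None) -> np.ndarray:
        """Return one channel, either the full z-stack (z=None, shape
        (Z, H, W)) or a single plane (shape (H, W))."""
        stack = self.planes[self.channel_index(role)]
        return stack if z is None else stack[z]


# --------------------------------------------------------------------------
# presets
# --------------------------------------------------------------------------

_SOLUBLE_CHANNELS = ("brightfield", "actin", "nucleus", "antigen", "signal", "endosome")
_BEAD_CHANNELS = ("brightfield", "actin", "nucleus", "antigen", "signal", "bead")

#: the named experimental conditions the generator emulates.  The four
#: internalization presets carry the printed inside-the-cell antigen
#: fractions (~80/70% soluble, ~50/20% bead for control vs knockout); the
#: kinetics presets carry the printed surface-retention medians (60/30%
#: internalized at 5 min, 80/50% at the late timepoint).
PRESETS: dict[str, SceneConfig] = {
    "control_soluble_10min": SceneConfig(
        antigen_inside_fraction=0.80,
        antigen_radial_mode="central",
        nuclear_fraction_param=1.5,
        coloc_rho=0.6,
        channels=_SOLUBLE_CHANNELS,
    ),
    "ko_soluble_10min": SceneConfig(
        antigen_inside_fraction=0.70,
        antigen_radial_mode="peripheral",
        nuclear_fraction_param=0.4,
        coloc_rho=0.25,
        channels=_SOLUBLE_CHANNELS,
    ),
    "control_bead": SceneConfig(
        antigen_inside_fraction=0.50,
        antigen_radial_mode="central",
        cup_clearance=0.85,
        nuclear_fraction_param=1.5,
        channels=_BEAD_CHANNELS,
    ),
    "ko_bead": SceneConfig(
        antigen_inside_fraction=0.20,
        antigen_radial_mode="peripheral",
        cup_clearance=0.10,
        nuclear_fraction_param=0.4,
        channels=_BEAD_CHANNELS,
    ),
    "control_kinetics": SceneConfig(
        kinetics_anchors=((5.0, 0.40), (30.0, 0.20)),
    ),
    "ko_kinetics": SceneConfig(
        kinetics_anchors=((5.0, 0.70), (30.0, 0.50)),
    ),
    "null_uniform": SceneConfig(
        antigen_inside_fraction=1.0,
        antigen_radial_mode="uniform",
        nuclear_fraction_param=0.0,
        coloc_rho=0.0,
        channels=("brightfield", "actin", "nucleus", "antigen"),
    ),
}

#: cup_clearance trajectories used for bead time courses (actin cup clears
#: at the contact base in controls, persists in knockouts)
CLEARANCE_TIMECOURSES: dict[str, tuple[float, ...]] = {
    "control_bead": (0.05, 0.35, 0.65, 0.85),
    "ko_bead": (0.05, 0.08, 0.10, 0.12),
}


def make_preset(name: str, seed: int = 0) -> SceneConfig:
    """Return the configuration for a named experimental condition."""
    if name not in PRESETS:
        raise ValueError(
            f"unknown preset {name!r}; valid presets: {sorted(PRESETS)}"
        )
    return replace(PRESETS[name], seed=seed)


# --------------------------------------------------------------------------
# geometry and rendering primitives
# --------------------------------------------------------------------------


def _boundary_coeffs(rng: np.random.Generator, wobble: float) -> np.ndarray:
    """Amplitudes/phases for 3 low-order sinusoidal boundary modes
    (orders 2, 3, 5).  Total relative amplitude ~= wobble, keeping the
    contour star-convex."""
    orders = np.array([2, 3, 5])
    amps = rng.uniform(0.4, 1.0, 3)
    amps *= wobble / max(amps.sum(), 1e-12)
    phases = rng.uniform(0, 2 * np.pi, 3)
    return np.stack([orders.astype(float), amps, phases])


def _boundary_radius(theta: np.ndarray, r0: float, coeffs: np.ndarray) -> np.ndarray:
    orders, amps, phases = coeffs
    mod = np.ones_like(theta, dtype=float)
    for k, a, p in zip(orders, amps, phases):
        mod += a * np.cos(k * theta + p)
    return r0 * mod


@dataclass
class _Frame:
    """Per-pixel polar coordinates relative to the cell centroid."""

    centroid: tuple[float, float]
    r0: float
    coeffs: np.ndarray
    r: np.ndarray  # pixel distance to centroid
    theta: np.ndarray  # pixel angle
    rb: np.ndarray  # boundary radius at each pixel's angle
    rho: np.ndarray  # normalized radius r / rb

    @property
    def cell_mask(self) -> np.ndarray:
        return self.rho <= 1.0

    @property
    def ring_mask(self) -> np.ndarray:
        return (self.rho > 1.0) & (self.rho <= 1.2)


def _make_frame(shape, centroid, r0, coeffs) -> _Frame:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]].astype(float)
    dy, dx = yy - centroid[0], xx - centroid[1]
    r = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    rb = _boundary_radius(theta, r0, coeffs)
    return _Frame(centroid, r0, coeffs, r, theta, rb, r / np.maximum(rb, 1e-9))


def _soft_edge(d: np.ndarray, edge: float = 1.0) -> np.ndarray:
    """Logistic profile, 1 well inside (d<0), 0 well outside, 0.5 at d=0."""
    return 1.0 / (1.0 + np.exp(np.clip(d / edge, -40, 40)))


def _render_puncta(shape, centers, amps, sigma) -> np.ndarray:
    """Sum of isotropic Gaussian spots, each truncated (exactly zero) beyond
    ``_PUNCTA_TRUNC_SIGMAS`` * sigma from its center."""
    img = np.zeros(shape, dtype=float)
    w = int(np.ceil(_PUNCTA_TRUNC_SIGMAS * sigma))
    for (cy, cx), a in zip(centers, amps):
        y0, y1 = int(np.floor(cy)) - w, int(np.floor(cy)) + w + 2
        x0, x1 = int(np.floor(cx)) - w, int(np.floor(cx)) + w + 2
        y0c, y1c = max(y0, 0), min(y1, shape[0])
        x0c, x1c = max(x0, 0), min(x1, shape[1])
        if y0c >= y1c or x0c >= x1c:
            continue
        yy, xx = np.mgrid[y0c:y1c, x0c:x1c].astype(float)
        d2 = (yy - cy) ** 2 + (xx - cx) ** 2
        spot = a * np.exp(-d2 / (2 * sigma**2))
        spot[d2 > (_PUNCTA_TRUNC_SIGMAS * sigma) ** 2] = 0.0
        img[y0c:y1c, x0c:x1c] += spot
    return img


def _draw_inside_radii(rng, n, mode, ring_radius) -> np.ndarray:
    if mode == "central":
        return 0.95 * rng.beta(2.0, 2.0, n)
    if mode == "peripheral":
        return 0.95 * rng.beta(6.0, 2.0, n)
    if mode == "uniform":
        return 0.97 * np.sqrt(rng.uniform(0, 1, n))  # area-uniform over the disk
    if mode == "ring":
        return np.clip(ring_radius + rng.normal(0, 0.02, n), 0.0, 0.97)
    raise AssertionError(mode)


def _antigen_field(rng, cfg: SceneConfig, frame: _Frame):
    """Render the antigen channel so that the intensity split across the
    cell contour (within the 120% region) equals ``antigen_inside_fraction``
    exactly, by solving for the relative gain of the inside- and
    outside-placed puncta populations.

    Returns (plane, realized_inside_fraction).
    """
    t = cfg.antigen_inside_fraction
    n = cfg.n_puncta
    n_in = int(round(t * n))
    n_out = n - n_in
    if t > 0 and n_in == 0:
        n_in, n_out = 1, n - 1
    if t < 1 and n_out == 0:
        n_out, n_in = 1, n - 1

    region = frame.cell_mask | frame.ring_mask
    inside = frame.cell_mask

    def render_inside(scale: float) -> np.ndarray:
        if n_in == 0:
            return np.zeros(frame.r.shape)
        rho = _draw_inside_radii(rng_in, n_in, cfg.antigen_radial_mode, cfg.ring_radius) * scale
        ang = rng_in.uniform(0, 2 * np.pi, n_in)
        rr = rho * _boundary_radius(ang, frame.r0, frame.coeffs)
        centers = np.stack(
            [frame.centroid[0] + rr * np.sin(ang), frame.centroid[1] + rr * np.cos(ang)],
            axis=1,
        )
        return _render_puncta(frame.r.shape, centers, amps_in, _ANTIGEN_SIGMA_PX)

    def render_outside(lo: float) -> np.ndarray:
        if n_out == 0:
            return np.zeros(frame.r.shape)
        rho = rng_out.uniform(lo, 1.2, n_out)
        ang = rng_out.uniform(0, 2 * np.pi, n_out)
        rr = rho * _boundary_radius(ang, frame.r0, frame.coeffs)
        centers = np.stack(
            [frame.centroid[0] + rr * np.sin(ang), frame.centroid[1] + rr * np.cos(ang)],
            axis=1,
        )
        return _render_puncta(frame.r.shape, centers, amps_out, _ANTIGEN_SIGMA_PX)

    # frozen per-population streams so re-rendering with adjusted radial
    # scales redraws the same puncta, only displaced
    amps_in = np.exp(rng.normal(0, np.log(1.25), max(n_in, 1)))
    amps_out = np.exp(rng.normal(0, np.log(1.25), max(n_out, 1)))
    seeds = rng.integers(2**31, size=2)

    # shrink inside placement until its own inside fraction reaches the
    # target (boundary spill makes extreme fractions unreachable otherwise)
    scale = 1.0
    for _ in range(12):
        rng_in = np.random.default_rng(seeds[0])
        fin = render_inside(scale)
        s_in_i = fin[inside].sum()
        s_out_i = fin[frame.ring_mask].sum()
        f_i = s_in_i / max(s_in_i + s_out_i, 1e-300) if n_in else 0.0
        if n_in == 0 or f_i >= t and (t < 1.0 or s_out_i == 0.0):
            break
        scale *= 0.88

    lo = 1.0
    for _ in range(12):
        rng_out = np.random.default_rng(seeds[1])
        fout = render_outside(lo)
        s_in_o = fout[inside].sum()
        s_out_o = fout[frame.ring_mask].sum()
        f_o = s_in_o / max(s_in_o + s_out_o, 1e-300) if n_out else 0.0
        if n_out == 0 or f_o <= t and (t > 0.0 or s_in_o == 0.0):
            break
        lo = 1.0 + (lo - 1.0 + 0.03)

    # relative gain beta of the outside population so the region split hits t
    if n_out == 0:
        alpha, beta = 1.0, 0.0
    elif n_in == 0:
        alpha, beta = 0.0, 1.0
    else:
        num = s_in_i - t * (s_in_i + s_out_i)
        den = t * (s_in_o + s_out_o) - s_in_o
        beta = num / den if den > 0 else 0.0
        beta = max(beta, 0.0)
        alpha = 1.0
    plane = alpha * fin + beta * fout

    total = plane.sum()
    if total <= 0:
        raise RuntimeError("antigen rendering produced no intensity")
    plane *= cfg.antigen_total_intensity / total

    s_in = plane[inside].sum()
    s_ring = plane[frame.ring_mask].sum()
    realized = s_in / (s_in + s_ring)
    return plane, realized


def _von_mises_density(phi: np.ndarray, mu: float, kappa: float) -> np.ndarray:
    from scipy.special import i0

    return np.exp(kappa * np.cos(phi - mu)) / (2 * np.pi * i0(kappa))


def _cup_field(frame: _Frame, bead_center, bead_radius_px, clearance) -> np.ndarray:
    """Actin cup around the bead rim: radial Gaussian on the rim, angular
    von Mises mixture moving mass from the cell-proximal to the distal side
    as clearance goes 0 -> 1."""
    yy, xx = np.mgrid[0 : frame.r.shape[0], 0 : frame.r.shape[1]].astype(float)
    db = np.hypot(yy - bead_center[0], xx - bead_center[1])
    phib = np.arctan2(yy - bead_center[0], xx - bead_center[1])
    prox = np.arctan2(
        frame.centroid[0] - bead_center[0], frame.centroid[1] - bead_center[1]
    )
    radial = np.exp(-((db - bead_radius_px) ** 2) / (2 * _CUP_SIGMA_PX**2))
    ang = (1.0 - clearance) * _von_mises_density(phib, prox, _CUP_KAPPA)
    ang = ang + clearance * _von_mises_density(phib, prox + np.pi, _CUP_KAPPA)
    peak = _von_mises_density(np.array([0.0]), 0.0, _CUP_KAPPA)[0]
    return 180.0 * radial * ang / peak


def _quadrant_truth(cup, bead_center, axis_angle, bead_radius_px, margin=1.2):
    """Pre-noise quadrant percentages of the cup field, same sector
    convention as the scorer (proximal, lateral1, lateral2, distal)."""
    yy, xx = np.mgrid[0 : cup.shape[0], 0 : cup.shape[1]].astype(float)
    db = np.hypot(yy - bead_center[0], xx - bead_center[1])
    region = db <= margin * bead_radius_px
    phi = np.arctan2(yy - bead_center[0], xx - bead_center[1]) - axis_angle
    sector = np.floor(((np.degrees(phi) + 45.0) % 360.0) / 90.0).astype(int)
    sums = np.array(
        [cup[region & (sector == j)].sum() for j in range(4)]
    )
    total = sums.sum()
    if total <= 0:
        return None
    pct = 100.0 * sums / total
    # sector order 0,1,2,3 = proximal, ccw lateral, distal, cw lateral
    return (pct[0], pct[1], pct[3], pct[2])


# --------------------------------------------------------------------------
# scene generation
# --------------------------------------------------------------------------


def generate_scene(config: SceneConfig) -> Scene:
    """Render one scene; deterministic given ``config`` (including seed).

    Ground truth (pre-noise realized fractions, true masks, bead location)
    is attached as ``scene.provenance``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    h, w = config.image_size_px
    r0 = config.cell_radius_um / config.pixel_size_um

    centroid = (
        h / 2.0 + rng.uniform(-3, 3),
        w / 2.0 + rng.uniform(-3, 3),
    )
    coeffs = _boundary_coeffs(rng, config.boundary_wobble)
    frame = _make_frame((h, w), centroid, r0, coeffs)
    cell_mask = frame.cell_mask

    # nucleus: soft disk covering ~25% of the cell area, slightly off-center
    nuc_r = 0.5 * r0
    off = rng.uniform(0, 0.12 * r0)
    off_ang = rng.uniform(0, 2 * np.pi)
    nuc_center = (
        centroid[0] + off * np.sin(off_ang),
        centroid[1] + off * np.cos(off_ang),
    )
    yy, xx = np.mgrid[0:h, 0:w].astype(float)
    d_nuc = np.hypot(yy - nuc_center[0], xx - nuc_center[1])
    nucleus_soft = _soft_edge(d_nuc - nuc_r)
    nucleus_mask = (d_nuc <= nuc_r) & cell_mask

    truth = GroundTruth(
        seed=config.seed,
        centroid=centroid,
        cell_mask=cell_mask,
        nucleus_mask=nucleus_mask if "nucleus" in config.channels else None,
    )

    # bead geometry (needed before rendering actin)
    bead_center = None
    bead_r_px = None
    if "bead" in config.channels:
        bead_r_px = config.bead_radius_um / config.pixel_size_um
        ang = rng.uniform(0, 2 * np.pi)
        rb_at = _boundary_radius(np.array([ang]), r0, coeffs)[0]
        dist = rb_at + bead_r_px + 1.0
        bead_center = (
            centroid[0] + dist * np.sin(ang),
            centroid[1] + dist * np.cos(ang),
        )
        pad = 1.3 * bead_r_px
        if not (
            pad <= bead_center[0] <= h - 1 - pad and pad <= bead_center[1] <= w - 1 - pad
        ):
            raise ValueError(
                "cell too close to the image border to fit the requested bead"
            )
        truth.bead_center = bead_center
        truth.bead_radius_px = bead_r_px

    clean: dict[str, np.ndarray] = {}

    if "brightfield" in config.channels:
        bf = 120.0 * _soft_edge(frame.r - frame.rb)
        if bead_center is not None:
            db = np.hypot(yy - bead_center[0], xx - bead_center[1])
            bf += 100.0 * _soft_edge(db - bead_r_px)
        clean["brightfield"] = bf

    if "actin" in config.channels:
        cortex = 180.0 * np.exp(-((frame.r - frame.rb) ** 2) / (2 * _CORTEX_SIGMA_PX**2))
        cyto = 15.0 * _soft_edge(frame.r - frame.rb)
        actin = cortex + cyto
        if bead_center is not None:
            cup = _cup_field(frame, bead_center, bead_r_px, config.cup_clearance)
            actin = actin + cup
            axis = np.arctan2(
                centroid[0] - bead_center[0], centroid[1] - bead_center[1]
            )
            truth.realized_quadrant_percentages = _quadrant_truth(
                cup, bead_center, axis, bead_r_px
            )
        clean["actin"] = actin

    if "nucleus" in config.channels:
        clean["nucleus"] = 150.0 * nucleus_soft

    if "antigen" in config.channels:
        plane, realized = _antigen_field(rng, config, frame)
        clean["antigen"] = plane
        truth.realized_inside_fraction = realized

    if "signal" in config.channels:
        nu = config.nuclear_fraction_param
        base = 80.0
        sig = base * _soft_edge(frame.r - frame.rb) * (1.0 + nu * nucleus_soft)
        clean["signal"] = sig

    for role in ("endosome", "lysosome", "membrane"):
        if role not in config.channels:
            continue
        if role == "membrane":
            clean[role] = 140.0 * np.exp(
                -((frame.r - frame.rb) ** 2) / (2 * 1.2**2)
            ) + 20.0 * _soft_edge(frame.r - frame.rb)
            continue
        n_p = config.n_puncta
        rho = 0.95 * np.sqrt(rng.uniform(0, 1, n_p))
        angp = rng.uniform(0, 2 * np.pi, n_p)
        rr = rho * _boundary_radius(angp, r0, coeffs)
        centers = np.stack(
            [centroid[0] + rr * np.sin(angp), centroid[1] + rr * np.cos(angp)], axis=1
        )
        amps = 120.0 * np.exp(rng.normal(0, np.log(1.25), n_p))
        clean[role] = _render_puncta((h, w), centers, amps, _ANTIGEN_SIGMA_PX)

    if "bead" in config.channels:
        db = np.hypot(yy - bead_center[0], xx - bead_center[1])
        clean["bead"] = 150.0 * _soft_edge(db - bead_r_px)

    # enforce the requested pixelwise correlation between the designated pair
    ra, rb_role = config.coloc_channels
    if (
        ra in clean
        and rb_role in clean
        and not np.isnan(config.coloc_rho)
        and cell_mask.sum() > 10
    ):
        rho_t = config.coloc_rho
        a = clean[ra][cell_mask].astype(float)
        b = clean[rb_role][cell_mask].astype(float)
        if a.std() > 0 and b.std() > 0:
            ahat = (a - a.mean()) / a.std()
            b_res = b - b.mean() - (b - b.mean()) @ ahat / len(a) * ahat
            if b_res.std() > 0:
                bhat = (b_res - b_res.mean()) / b_res.std()
                e = rho_t * ahat + np.sqrt(max(0.0, 1 - rho_t**2)) * bhat
                scale = b.std()
                e = (e - e.min()) * scale + 1.0
                newb = np.zeros((h, w))
                newb[cell_mask] = e
                clean[rb_role] = newb
                truth.realized_coloc_rho = float(np.corrcoef(a, e)[0, 1])

    # nuclear-translocation truth, after any coloc adjustment of "signal"
    if "signal" in clean and cell_mask.sum() and nucleus_mask.sum():
        sig = clean["signal"]
        truth.realized_nuclear_ratio = float(
            sig[nucleus_mask].mean() / sig[cell_mask].mean()
        )

    # assemble stack; z-planes share structure with a mild focal attenuation
    order = [c for c in config.channels]
    nz = config.n_z
    planes = np.zeros((len(order), nz, h, w), dtype=float)
    mid = (nz - 1) / 2.0
    for ci, role in enumerate(order):
        for z in range(nz):
            att = np.exp(-((z - mid) ** 2) / (2 * max(nz / 2.0, 1.0) ** 2))
            planes[ci, z] = clean[role] * att

    nm = config.noise_model
    if nm is not None:
        p = nm.photon_scale
        noisy = rng.poisson(planes * p) / p
        noisy = noisy + rng.normal(nm.background_mean, nm.background_sd, noisy.shape)
        planes = np.round(np.clip(noisy, 0, 65535))

    return Scene(
        planes=planes,
        channel_roles={i: r for i, r in enumerate(order)},
        pixel_size_um=config.pixel_size_um,
        z_step_um=config.z_step_um if nz > 1 else None,
        provenance=truth,
    )


def generate_bead_timecourse(
    config: SceneConfig, clearances: Sequence[float]
) -> list[Scene]:
    """Scenes sharing one cell/bead geometry with the actin cup at the given
    clearance stages (same seed, so only the cup differs)."""
    if "bead" not in config.channels:
        raise ValueError("timecourse requires a bead channel")
    return [generate_scene(replace(config, cup_clearance=float(c))) for c in clearances]


# --------------------------------------------------------------------------
# flow-style kinetics
# --------------------------------------------------------------------------


def _remaining_fraction(t: np.ndarray, anchors) -> np.ndarray:
    """Median surviving surface fraction at time t: log-linear interpolation
    through (0, 1) and the condition anchors."""
    pts = [(0.0, 1.0)] + [tuple(a) for a in (anchors or [])]
    pts.sort()
    ts = np.array([p[0] for p in pts])
    logf = np.log(np.array([max(p[1], 1e-9) for p in pts]))
    return np.exp(np.interp(t, ts, logf))


def generate_kinetics(
    config: SceneConfig, n_cells: int, timepoints_min: Sequence[float]
) -> pd.DataFrame:
    """Per-cell surface-stain intensities (columns cell_id, time_min,
    intensity): log-normal (geometric sd 1.3) around the condition's decay
    curve, so the per-timepoint *median* carries the condition signal."""
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    tps = np.asarray(list(timepoints_min), dtype=float)
    if 0.0 not in tps:
        raise ValueError("timepoints must include t=0 (normalization anchor)")
    rng = np.random.default_rng(config.seed)
    med = _KINETICS_BASELINE * _remaining_fraction(tps, config.kinetics_anchors)
    rows = []
    sigma = np.log(_KINETICS_GSD)
    for i in range(n_cells):
        noise = np.exp(rng.normal(0.0, sigma, len(tps)))
        for t, m, x in zip(tps, med, noise):
            rows.append((i, float(t), float(m * x)))
    return pd.DataFrame(rows, columns=["cell_id", "time_min", "intensity"])


# --------------------------------------------------------------------------
# scene I/O: multi-page TIFF + JSON sidecar
# --------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".json")


def write_scene(scene: Scene, path) -> Path:
    """Write a 16-bit multi-page TIFF (channel-major page order) plus a JSON
    sidecar with channel roles, calibration and ground truth."""
    path = Path(path)
    c, z, h, w = scene.planes.shape
    pages = scene.planes.reshape(c * z, h, w)
    if np.any(pages > 65535):
        warnings.warn("intensities exceed 16-bit range; clipping on write")
    tifffile.imwrite(path, np.clip(np.round(pages), 0, 65535).astype(np.uint16))
    sidecar = {
        "channels": [{"index": i, "role": scene.channel_roles[i]} for i in range(c)],
        "n_z": z,
        "pixel_size_um": scene.pixel_size_um,
        "z_step_um": scene.z_step_um,
        "ground_truth": None if scene.provenance is None else scene.provenance.to_dict(),
    }
    _sidecar_path(path).write_text(json.dumps(sidecar))
    return path


def read_scene(path) -> Scene:
    """Read a scene written by :func:`write_scene`, validating the sidecar
    against the TIFF page layout."""
    path = Path(path)
    sidecar_file = _sidecar_path(path)
    if not sidecar_file.exists():
        raise FileNotFoundError(f"missing sidecar {sidecar_file}")
    meta = json.loads(sidecar_file.read_text())
    pages = tifffile.imread(path)
    if pages.ndim == 2:
        pages = pages[None]
    chans = meta["channels"]
    nz = meta.get("n_z", 1)
    if any("role" not in ch or ch["role"] is None for ch in chans):
        raise ValueError("sidecar declares a channel without a role")
    if len(chans) * nz != pages.shape[0]:
        raise ValueError(
            f"sidecar declares {len(chans)} channels x {nz} z-planes but the "
            f"TIFF has {pages.shape[0]} pages"
        )
    planes = pages.reshape(len(chans), nz, pages.shape[1], pages.shape[2]).astype(float)
    truth = meta.get("ground_truth")
    return Scene(
        planes=planes,
        channel_roles={ch["index"]: ch["role"] for ch in chans},
        pixel_size_um=meta["pixel_size_um"],
        z_step_um=meta.get("z_step_um"),
        provenance=None if truth is None else GroundTruth.from_dict(truth),
    )


# --------------------------------------------------------------------------
# helpers
# --------------------------------------------------------------------------


def _rle_encode(mask: np.ndarray) -> dict:
    flat = np.asarray(mask, dtype=bool).ravel()
    if flat.size == 0:
        return {"shape": list(mask.shape), "runs": []}
    change = np.flatnonzero(np.diff(flat.astype(np.int8))) + 1
    starts = np.concatenate([[0], change])
    ends = np.concatenate([change, [flat.size]])
    runs = [
        [int(s), int(e - s)] for s, e, v in zip(starts, ends, flat[starts]) if v
    ]
    return {"shape": list(mask.shape), "runs": runs}


def _rle_decode(d: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(d["shape"])), dtype=bool)
    for s, n in d["runs"]:
        flat[s : s + n] = True
    return flat.reshape(d["shape"])


def _none_if_nan(x: float):
    return None if x is None or (isinstance(x, float) and np.isnan(x)) else float(x)


def _nan_if_none(x) -> float:
    return float("nan") if x is None else float(x)
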