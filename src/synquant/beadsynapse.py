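"""Actin reorganization around an antigen-coated bead and the synaptic
interface ROI.

The quadrant score cuts a disk around the bead (the bead plus a margin
capturing rim-hugging cup fluorescence) into four 90-degree sectors
oriented along the bead-to-cell-centroid axis and reports each sector's
share of total actin.  Clearance of the phagocytic/endocytic actin cup
shows up as proximal share moving distal over time; the clearance index is
the drop in proximal share from the first to the last timepoint.

The synaptic interface ROI is a rectangle between the cell and the bead:
width a quarter of the cell diameter (R_eq / 2), long axis along the
bead-to-cell axis with length equal to the bead diameter, centered midway
between the bead center and the nearest cell-contour point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib.path import Path as MplPath

from .scenegen import Scene
from .segment import Bead, CellGeometry

__all__ = [
    "QuadrantScore",
    "SynapticROI",
    "quadrant_actin",
    "quadrant_timecourse",
    "synaptic_interface_roi",
    "interface_mfi",
]


@dataclass
class QuadrantScore:
    """Sector percentages (proximal, lateral1, lateral2, distal; sum 100)
    of a channel's fluorescence on the bead disk plus margin."""

    percentages: tuple[float, float, float, float]
    axis_angle: float
    region: np.ndarray


@dataclass
class SynapticROI:
    rectangle: np.ndarray  # 4 (row, col) vertices, closed implicitly
    width_px: float
    length_px: float
    center: tuple[float, float]
    axis_angle: float


def _sector_index(phi_rel: np.ndarray) -> np.ndarray:
    """0 proximal, 1 ccw lateral, 2 distal, 3 cw lateral; ties on the
    45-degree boundaries go counter-clockwise (to the higher sector)."""
    return (np.floor(((np.degrees(phi_rel) + 45.0) % 360.0) / 90.0)).astype(int)


def quadrant_actin(
    scene: Scene,
    geometry: CellGeometry,
    bead: Bead,
    margin: float = 1.2,
    channel: str = "actin",
) -> QuadrantScore:
    """Percentage of the channel's fluorescence in each of four bead-
    centered 90-degree sectors; the proximal sector is centered on the
    bead-to-cell-centroid axis."""
    img = scene.channel(channel)[geometry.mid_z].astype(float)
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]].astype(float)
    db = np.hypot(yy - bead.center[0], xx - bead.center[1])
    region = db <= margin * bead.radius_px
    axis = np.arctan2(
        geometry.centroid[0] - bead.center[0],
        geometry.centroid[1] - bead.center[1],
    )
    phi = np.arctan2(yy - bead.center[0], xx - bead.center[1]) - axis
    sector = _sector_index(phi)
    sums = np.array([img[region & (sector == j)].sum() for j in range(4)])
    total = sums.sum()
    if total <= 0:
        raise ValueError("zero actin intensity on the bead region")
    pct = 100.0 * sums / total
    return QuadrantScore(
        percentages=(float(pct[0]), float(pct[1]), float(pct[3]), float(pct[2])),
        axis_angle=float(axis),
        region=region,
    )


def quadrant_timecourse(
    scenes,
    geometries,
    beads,
    margin: float = 1.2,
):
    """Quadrant scores for a time-ordered series of scenes of one cell.

    Returns (scores, clearance_index): clearance index is the proximal
    percentage at the first timepoint minus at the last.
    """
    scenes = list(scenes)
    if len(scenes) < 2:
        raise ValueError("a timecourse needs at least 2 timepoints")
    geometries = list(geometries)
    beads = list(beads)
    if not (len(scenes) == len(geometries) == len(beads)):
        raise ValueError("scenes, geometries and beads must align")
    scores = [
        quadrant_actin(s, g, b, margin=margin)
        for s, g, b in zip(scenes, geometries, beads)
    ]
    clearance = scores[0].percentages[0] - scores[-1].percentages[0]
    return scores, float(clearance)


def synaptic_interface_roi(geometry: CellGeometry, bead: Bead) -> SynapticROI:
    """Rectangle between cell and bead: width R_eq/2 (a quarter of the cell
    diameter), length 2 x bead radius along the bead-to-cell axis, centered
    midway between the bead center and the nearest cell-contour point."""
    by, bx = bead.center
    iy, ix = int(round(by)), int(round(bx))
    if (
        0 <= iy < geometry.cell_mask.shape[0]
        and 0 <= ix < geometry.cell_mask.shape[1]
        and geometry.cell_mask[iy, ix]
    ):
        raise ValueError("bead center lies inside the cell mask; no interface axis")
    d = np.hypot(
        geometry.contour[:, 0] - by, geometry.contour[:, 1] - bx
    )
    nearest = geometry.contour[int(np.argmin(d))]
    center = ((nearest[0] + by) / 2.0, (nearest[1] + bx) / 2.0)
    axis = np.arctan2(geometry.centroid[0] - by, geometry.centroid[1] - bx)
    u = np.array([np.sin(axis), np.cos(axis)])  # along bead->cell, (row, col)
    v = np.array([-u[1], u[0]])  # across
    half_l = bead.radius_px
    half_w = geometry.equivalent_radius_px / 4.0
    c = np.array(center)
    rect = np.stack(
        [
            c + half_l * u + half_w * v,
            c + half_l * u - half_w * v,
            c - half_l * u - half_w * v,
            c - half_l * u + half_w * v,
        ]
    )
    return SynapticROI(
        rectangle=rect,
        width_px=2 * half_w,
        length_px=2 * half_l,
        center=center,
        axis_angle=float(axis),
    )


def interface_mfi(
    scene: Scene, roi: SynapticROI, channel: str, z: int = 0
) -> float:
    """Mean intensity of the pixels whose centers fall inside the ROI
    rectangle."""
    img = scene.channel(channel)[z].astype(float)
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    pts = np.stack([yy.ravel(), xx.ravel()], axis=1)
    path = MplPath(roi.rectangle)
    inside = path.contains_points(pts).reshape(img.shape)
    if not inside.any():
        raise ValueError("ROI contains no pixel centers")
    return float(img[inside].mean())
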