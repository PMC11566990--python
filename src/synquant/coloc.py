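"""Pixel-intensity colocalization statistics (Pearson and Manders) within
whole-cell or sub-cellular ROIs.

Pearson is the plain product-moment correlation over ROI pixel pairs with
no thresholding; if either channel is constant within the ROI the result
is flagged undefined rather than reported as 0.  Manders' split
coefficients use per-channel thresholds: M1 is the fraction of channel A's
intensity found where channel B is above its threshold, and symmetrically
for M2.  Thresholds default to per-channel Otsu within the ROI.

Multi-plane input is pooled over the planes intersecting the ROI (the
per-plane alternative is available via ``per_plane=True`` on
:func:`pearson`).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from skimage import filters as skfilters

from .scenegen import Scene

__all__ = ["ColocResult", "pearson", "manders"]


@dataclass
class ColocResult:
    pearson_r: float = float("nan")
    pearson_defined: bool = False
    manders_m1: float = float("nan")
    manders_m2: float = float("nan")
    m1_defined: bool = False
    m2_defined: bool = False
    thresholds_used: Optional[tuple[float, float]] = None
    n_pixels: int = 0
    roi_id: str = ""


def _roi_values(scene: Scene, role: str, roi_mask: np.ndarray) -> np.ndarray:
    stack = scene.channel(role)  # (Z, H, W)
    if roi_mask.shape != stack.shape[1:]:
        raise ValueError("roi_mask shape must match the image planes")
    return stack[:, roi_mask].ravel().astype(float)


def pearson(
    scene: Scene,
    channel_a: str,
    channel_b: str,
    roi_mask: np.ndarray,
    roi_id: str = "",
    per_plane: bool = False,
) -> ColocResult:
    """Pearson correlation between two channels over ROI pixels, pooled
    across z-planes (or averaged per plane with ``per_plane=True``)."""
    if roi_mask.sum() < 2:
        raise ValueError("Pearson needs at least 2 ROI pixels")
    a = _roi_values(scene, channel_a, roi_mask)
    b = _roi_values(scene, channel_b, roi_mask)
    res = ColocResult(n_pixels=int(a.size), roi_id=roi_id)
    if per_plane:
        stack_a = scene.channel(channel_a)
        stack_b = scene.channel(channel_b)
        rs = []
        for z in range(stack_a.shape[0]):
            va = stack_a[z][roi_mask].astype(float)
            vb = stack_b[z][roi_mask].astype(float)
            if va.std() > 0 and vb.std() > 0:
                rs.append(np.corrcoef(va, vb)[0, 1])
        if rs:
            res.pearson_r = float(np.mean(rs))
            res.pearson_defined = True
        return res
    if a.std() == 0 or b.std() == 0:
        return res  # undefined, flagged — not 0
    res.pearson_r = float(np.corrcoef(a, b)[0, 1])
    res.pearson_defined = True
    return res


def manders(
    scene: Scene,
    channel_a: str,
    channel_b: str,
    roi_mask: np.ndarray,
    thresholds: str | tuple[float, float] = "otsu",
    roi_id: str = "",
) -> ColocResult:
    """Manders' split coefficients M1 (share of A where B is above its
    threshold) and M2 (symmetric).  ``thresholds`` is ``"otsu"`` (per
    channel, within the ROI) or a fixed ``(tA, tB)`` pair."""
    if roi_mask.sum() < 2:
        raise ValueError("Manders needs at least 2 ROI pixels")
    a = _roi_values(scene, channel_a, roi_mask)
    b = _roi_values(scene, channel_b, roi_mask)
    if isinstance(thresholds, str):
        if thresholds != "otsu":
            raise ValueError("thresholds must be 'otsu' or a (tA, tB) pair")
        ta = skfilters.threshold_otsu(a) if a.max() > a.min() else a.max()
        tb = skfilters.threshold_otsu(b) if b.max() > b.min() else b.max()
    else:
        ta, tb = float(thresholds[0]), float(thresholds[1])
    res = ColocResult(
        n_pixels=int(a.size), roi_id=roi_id, thresholds_used=(float(ta), float(tb))
    )
    sa, sb = a.sum(), b.sum()
    if sa > 0:
        res.manders_m1 = float(a[b > tb].sum() / sa)
        res.m1_defined = True
    if sb > 0:
        res.manders_m2 = float(b[a > ta].sum() / sb)
        res.m2_defined = True
    return res
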