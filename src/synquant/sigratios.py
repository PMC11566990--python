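"""Nuclear-translocation ratio and flow-style surface-retention kinetics.

The translocation ratio is the MFI of a signalling channel (e.g. NF-kB)
in the nucleus mask divided by its MFI over the whole cell, computed on
the nucleus-area-maximal z-plane.  A ratio of 1 means no enrichment; a
uniform channel gives exactly 1.

Surface-retention kinetics summarize per-cell surface-stain intensities:
the per-timepoint *median* over cells (robust to the log-normal intensity
tail) is background-subtracted, normalized to t = 0 and expressed as the
percentage of receptor remaining on the surface; its complement is the
internalized percentage.  Values outside [0, 100] (noise can push the
normalized median above 100) are reported raw with a warning, never
clamped.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .scenegen import Scene
from .segment import CellGeometry

__all__ = ["TranslocationResult", "SurfaceKinetics", "nuclear_ratio", "surface_remaining"]


@dataclass
class TranslocationResult:
    nuclear_mfi: float
    cell_mfi: float
    ratio: float


@dataclass
class SurfaceKinetics:
    time_min: np.ndarray
    median_intensity: np.ndarray
    pct_remaining: np.ndarray

    @property
    def pct_internalized(self) -> np.ndarray:
        return 100.0 - self.pct_remaining

    def at(self, t: float) -> tuple[float, float]:
        """(pct_remaining, pct_internalized) at timepoint t."""
        i = int(np.flatnonzero(np.isclose(self.time_min, t))[0])
        return float(self.pct_remaining[i]), float(self.pct_internalized[i])


def nuclear_ratio(
    scene: Scene, geometry: CellGeometry, channel: str = "signal"
) -> TranslocationResult:
    """Nuclear MFI over whole-cell MFI of ``channel`` on the mid plane."""
    if geometry.nucleus_mask is None or not geometry.nucleus_mask.any():
        raise ValueError("empty nucleus mask; segment the nucleus first")
    img = scene.channel(channel)[geometry.mid_z].astype(float)
    cell_mfi = float(img[geometry.cell_mask].mean())
    if cell_mfi <= 0:
        raise ValueError("zero cell MFI; ratio undefined")
    nuc_mfi = float(img[geometry.nucleus_mask].mean())
    return TranslocationResult(
        nuclear_mfi=nuc_mfi, cell_mfi=cell_mfi, ratio=nuc_mfi / cell_mfi
    )


def surface_remaining(
    kinetics: pd.DataFrame, background: float = 0.0
) -> SurfaceKinetics:
    """Percentage of surface stain remaining per timepoint.

    ``kinetics`` must have columns ``cell_id``, ``time_min``, ``intensity``
    and include t = 0 (the normalization anchor).
    """
    required = {"cell_id", "time_min", "intensity"}
    missing = required - set(kinetics.columns)
    if missing:
        raise ValueError(f"kinetics table is missing columns: {sorted(missing)}")
    med = kinetics.groupby("time_min")["intensity"].median().sort_index()
    times = med.index.to_numpy(dtype=float)
    if not np.any(np.isclose(times, 0.0)):
        raise ValueError("kinetics table lacks t=0; normalization impossible")
    m0 = float(med.iloc[int(np.flatnonzero(np.isclose(times, 0.0))[0])]) - background
    if m0 <= 0:
        raise ValueError("t=0 median does not exceed background")
    pct = 100.0 * (med.to_numpy() - background) / m0
    if np.any((pct < 0) | (pct > 100 + 1e-9)):
        warnings.warn(
            "pct_remaining outside [0, 100]; reporting raw values (not clamped)"
        )
    return SurfaceKinetics(
        time_min=times,
        median_intensity=med.to_numpy(dtype=float),
        pct_remaining=pct,
    )
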