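"""Batch orchestration: simulate -> segment -> quantify -> report.

A run takes either named simulation presets or a directory of scenes
(TIFF + JSON sidecar), scores every cell, and writes a per-cell CSV, a
descriptive summary CSV (n, mean, SEM per condition) and a JSON manifest
(config, seed, package version) that fully determines the outputs.

Per-cell failures are isolated: a cell that cannot be scored is logged and
skipped; the run fails only if every cell fails.  All randomness flows
from one root seed, split per cell by a counter-based scheme
(``SeedSequence([root, condition_index, cell_index])``), so per-cell
results do not depend on batch ordering.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .beadsynapse import quadrant_actin
from .coloc import pearson
from .radialmap import inside_outside_fraction, ks_compare, radial_profile
from .scenegen import Scene, generate_scene, make_preset, read_scene
from .segment import detect_beads, segment_cell, segment_nucleus
from .sigratios import nuclear_ratio

__all__ = ["RunConfig", "analyze_scene", "run", "summarize", "cell_seed"]

log = logging.getLogger("synquant")

_DEFAULT_SCORES = (
    "inside_outside",
    "peripheral",
    "thirds",
    "nuclear_ratio",
    "pearson",
    "quadrants",
)


@dataclass
class RunConfig:
    presets: tuple[str, ...] = ()
    input_dir: Optional[str] = None
    n_cells: int = 20
    seed: int = 0
    out_dir: str = "synquant_out"
    boundary: str = "auto"  # auto | brightfield | cortical_actin
    scores: tuple[str, ...] = _DEFAULT_SCORES
    bead_radius_um: float = 1.5
    log_level: str = "INFO"

    def validate(self) -> None:
        if not self.presets and self.input_dir is None:
            raise ValueError("config must name presets or an input directory")
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        unknown = set(self.scores) - set(_DEFAULT_SCORES)
        if unknown:
            raise ValueError(f"unknown scores: {sorted(unknown)}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["presets"] = tuple(d.get("presets", ()))
        d["scores"] = tuple(d.get("scores", _DEFAULT_SCORES))
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict()))


def cell_seed(root: int, condition_index: int, cell_index: int) -> int:
    """Counter-based per-cell seed below 2**31, independent of ordering."""
    ss = np.random.SeedSequence([int(root), int(condition_index), int(cell_index)])
    return int(ss.generate_state(1)[0] % (2**31))


def analyze_scene(
    scene: Scene,
    scores: Sequence[str] = _DEFAULT_SCORES,
    boundary: str = "auto",
    bead_radius_um: float = 1.5,
) -> dict:
    """Score one scene; returns a flat record of the requested statistics."""
    beads = (
        detect_beads(scene, bead_radius_um) if scene.has_channel("bead") else []
    )
    if boundary == "auto":
        boundary = "cortical_actin" if beads else "brightfield"
    chan = "actin" if boundary == "cortical_actin" else "brightfield"
    geom = segment_cell(scene, chan, beads=beads or None)
    if scene.has_channel("nucleus"):
        geom = segment_nucleus(scene, geom)

    row: dict = {"boundary": boundary, "n_beads": len(beads)}
    if "inside_outside" in scores or "peripheral" in scores or "thirds" in scores:
        if scene.has_channel("antigen"):
            rf = inside_outside_fraction(
                scene, geom, "antigen", boundary=boundary, background="auto"
            )
            if "inside_outside" in scores:
                row["inside_pct"] = rf.inside_pct
                row["outside_pct"] = rf.outside_pct
            if "peripheral" in scores:
                row["peripheral_quarter_pct"] = rf.peripheral_quarter_pct
            if "thirds" in scores:
                row["thirds_1"], row["thirds_2"], row["thirds_3"] = rf.thirds_pct
            prof = radial_profile(scene, geom, "antigen")
            for i, v in enumerate(prof.fraction_of_total):
                row[f"profile_{i:03d}"] = v
    if "nuclear_ratio" in scores and scene.has_channel("signal") and geom.nucleus_mask is not None:
        row["nuclear_ratio"] = nuclear_ratio(scene, geom, "signal").ratio
    if (
        "pearson" in scores
        and scene.has_channel("antigen")
        and scene.has_channel("endosome")
    ):
        res = pearson(scene, "antigen", "endosome", geom.cell_mask)
        if res.pearson_defined:
            row["pearson_antigen_endosome"] = res.pearson_r
    if "quadrants" in scores and beads:
        qs = quadrant_actin(scene, geom, beads[0])
        (
            row["proximal_pct"],
            row["lateral1_pct"],
            row["lateral2_pct"],
            row["distal_pct"],
        ) = qs.percentages
    return row


def run(config: RunConfig) -> dict:
    """Execute a batch run; returns paths of the emitted artifacts."""
    config.validate()
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    jobs: list[tuple[str, str, object]] = []  # (condition, cell_id, scene source)
    if config.presets:
        for pi, name in enumerate(config.presets):
            for i in range(config.n_cells):
                jobs.append((name, f"{name}_{i:04d}", (pi, i)))
    else:
        paths = sorted(Path(config.input_dir).glob("*.tif")) + sorted(
            Path(config.input_dir).glob("*.tiff")
        )
        if not paths:
            raise ValueError(f"no scenes found in {config.input_dir}")
        for p in paths:
            jobs.append((Path(config.input_dir).name, p.stem, p))

    rows = []
    for condition, cell_id, src in jobs:
        try:
            if isinstance(src, tuple):
                pi, i = src
                cfg = make_preset(condition, seed=cell_seed(config.seed, pi, i))
                scene = generate_scene(cfg)
            else:
                scene = read_scene(src)
            row = analyze_scene(
                scene,
                scores=config.scores,
                boundary=config.boundary,
                bead_radius_um=config.bead_radius_um,
            )
            row.update({"condition": condition, "cell_id": cell_id})
            rows.append(row)
        except Exception:  # noqa: BLE001 — per-cell isolation is deliberate
            log.exception("cell %s failed; skipping", cell_id)
    if not rows:
        raise RuntimeError("all cells failed")

    front = ["condition", "cell_id"]
    per_cell = pd.DataFrame(rows)
    per_cell = per_cell[front + [c for c in per_cell.columns if c not in front]]
    per_cell_path = out / "per_cell.csv"
    per_cell.to_csv(per_cell_path, index=False)

    summary = summarize(per_cell, "condition")
    summary_path = out / "summary.csv"
    summary.to_csv(summary_path, index=False)

    cfg_dict = config.to_dict()
    manifest = {
        "config": cfg_dict,
        "seed": config.seed,
        "synquant_version": __version__,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg_dict, sort_keys=True).encode()
        ).hexdigest(),
        "n_cells_scored": int(len(per_cell)),
    }
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2))
    return {
        "per_cell": per_cell_path,
        "summary": summary_path,
        "manifest": manifest_path,
    }


def summarize(
    per_cell: pd.DataFrame | str | Path,
    group_column: str = "condition",
    ks_groups: Optional[tuple[str, str]] = None,
    ks_column: Optional[str] = None,
) -> pd.DataFrame:
    """Descriptive per-group summary (n, mean, SEM of every numeric score).

    If ``ks_groups`` and ``ks_column`` are given, a two-sample KS
    comparison of that column between the two named groups is appended as
    ``ks_D``/``ks_p`` columns on the first group's row.
    """
    if not isinstance(per_cell, pd.DataFrame):
        per_cell = pd.read_csv(per_cell)
    if group_column not in per_cell.columns:
        raise ValueError(f"group column {group_column!r} not present")
    numeric = per_cell.select_dtypes(include=[np.number]).columns
    numeric = [c for c in numeric if not c.startswith("profile_")]
    out_rows = []
    for g, sub in per_cell.groupby(group_column):
        rec: dict = {group_column: g, "n": len(sub)}
        for c in numeric:
            vals = sub[c].dropna().to_numpy()
            rec[f"{c}_mean"] = vals.mean() if vals.size else np.nan
            rec[f"{c}_sem"] = (
                vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            )
        out_rows.append(rec)
    summary = pd.DataFrame(out_rows)
    if ks_groups and ks_column:
        a = per_cell.loc[per_cell[group_column] == ks_groups[0], ks_column].dropna()
        b = per_cell.loc[per_cell[group_column] == ks_groups[1], ks_column].dropna()
        d, p = ks_compare(a.to_numpy(), b.to_numpy())
        summary["ks_D"] = np.nan
        summary["ks_p"] = np.nan
        summary.loc[summary[group_column] == ks_groups[0], ["ks_D", "ks_p"]] = [d, p]
    return summary
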