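"""End-to-end reproducible pipeline over replicate discs.

Mirrors the replicate workflow of a tissue experiment: three
independently rendered synthetic "discs" are segmented, assigned to
virtual cells and binned; replicates are registered along the
developmental axis by their mRNA profiles and pooled; pooled bins are
summarized with bootstrap confidence intervals. Every run is fully
determined by its config + root seed, and each output CSV embeds a
header comment with the config hash and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import cells as cells_mod
from . import segmentation as seg
from . import spatial_stats as stats
from .stack import Calibration
from .synthetic import SceneSpec, render_stack


@dataclass
class RunConfig:
    """Serializable description of a full pipeline run."""

    out_dir: str = "burstfish_run"
    seed: int = 0
    n_replicates: int = 3
    # synthetic scene (per replicate; seeds derived from the root seed)
    scene: dict = field(default_factory=lambda: dict(
        shape=(16, 384, 384), n_mature_spots=0, n_transcription_sites=25,
        n_nuclei=40, nucleus_radius=14.0, site_multiplier_range=(4.0, 8.0),
        min_spot_separation=12.0))
    # expression profile: expected mRNAs per cell as a function of the
    # distance from the landmark along the chosen axis
    profile: dict = field(default_factory=lambda: dict(
        kind="gradient", amplitude=8.0, length_scale=150.0))
    # spatial analysis
    axis: str = "ap"
    landmark: float = 0.0
    bin_width: float = 64.0
    site_fraction_mode: str = "all"
    bootstrap_resamples: int = 1000
    max_registration_offset: int = 5
    # per-replicate lateral shift of the profile (px), exercising
    # registration; length n_replicates (padded with zeros)
    replicate_shift_px: list = field(default_factory=list)
    # segmentation
    min_pixels: int = 8
    link_radius: float = 4.0
    site_factor: float = 2.5
    detection_units: float = 2.0
    # cells
    expected_nucleus_radius: float | None = None   # default: scene radius
    physical_units: bool = True

    def __post_init__(self) -> None:
        # canonical YAML-safe form: sequences as lists
        for key in ("shape", "site_multiplier_range"):
            if key in self.scene:
                self.scene[key] = list(self.scene[key])
        self.replicate_shift_px = [float(v)
                                   for v in self.replicate_shift_px]

    def to_yaml(self, path=None) -> str:
        text = yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        return cls(**data)

    @property
    def config_hash(self) -> str:
        """Hash of the scientific parameters (output location excluded)."""
        d = dataclasses.asdict(self)
        d.pop("out_dir")
        text = yaml.safe_dump(d, sort_keys=True)
        return hashlib.sha256(text.encode()).hexdigest()[:16]


def _profile_fn(cfg: RunConfig, shift: float):
    kind = cfg.profile.get("kind", "gradient")
    amp = float(cfg.profile.get("amplitude", 12.0))
    if kind == "uniform":
        return lambda x, y: amp
    if kind == "gradient":
        length = float(cfg.profile.get("length_scale", 150.0))

        def fn(x, y):
            coord = x if cfg.axis == "ap" else y
            d = abs(coord - cfg.landmark - shift)
            return amp * math.exp(-d / length)
        return fn
    raise ValueError(f"unknown profile kind {kind!r}")


def _write_csv(df: pd.DataFrame, path: Path, cfg: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(f"# config_hash={cfg.config_hash} seed={cfg.seed}\n")
        df.to_csv(fh, index=False, float_format="%.6g")


def cells_to_df(vcells: list) -> pd.DataFrame:
    rows = []
    for c in vcells:
        rows.append({
            "nucleus": c.index,
            "x": float(c.centroid[0]), "y": float(c.centroid[1]),
            "z": float(c.centroid[2]),
            "n_mrna": c.mrna_count, "n_sites": c.site_count,
            "nascent_units": ";".join(f"{u:.4f}"
                                      for u in c.nascent_units),
        })
    return pd.DataFrame(rows)


def cells_from_df(df: pd.DataFrame) -> list:
    out = []
    for _, row in df.iterrows():
        units = str(row.get("nascent_units", "") or "")
        vals = np.array([float(v) for v in units.split(";") if v],
                        dtype=float)
        out.append(cells_mod.VirtualCell(
            index=int(row["nucleus"]),
            centroid=np.array([row["x"], row["y"], row["z"]]),
            mrna_indices=np.arange(int(row["n_mrna"])),
            site_indices=np.arange(int(row["n_sites"])),
            nascent_units=vals))
    return out


def process_replicate(cfg: RunConfig, replicate: int) -> dict:
    """Render, segment and assign one synthetic disc.

    Returns a dict with the virtual cells, spatial bins, QC record and
    ground truth of the replicate.
    """
    shifts = list(cfg.replicate_shift_px) + [0.0] * cfg.n_replicates
    shift = float(shifts[replicate])
    scene_seed = int(np.random.SeedSequence(
        (cfg.seed, replicate)).generate_state(1)[0] % (2 ** 31))
    spec = SceneSpec(expression_profile=_profile_fn(cfg, shift),
                     seed=scene_seed, **cfg.scene)
    fish, nuclear, truth = render_stack(spec)

    scan = seg.scan_thresholds(fish, seg.auto_cutoff_range(fish),
                               cfg.min_pixels)
    cutoff = scan.require()
    mature = seg.segment_mature(fish, cutoff, cfg.min_pixels,
                                cfg.link_radius)
    sites = seg.segment_sites(fish, mature, cfg.site_factor,
                              cfg.detection_units, cfg.min_pixels,
                              cfg.link_radius)

    radius = cfg.expected_nucleus_radius or cfg.scene.get(
        "nucleus_radius", cells_mod.DEFAULT_NUCLEUS_RADIUS)
    masks = cells_mod.segment_nuclei_2d(nuclear, expected_radius=radius)
    nuclei = cells_mod.stack_nuclei_3d(masks)
    if not nuclei:
        raise seg.QualityError(
            f"replicate {replicate}: no 3D nuclei recovered")
    nz, ny, nx = fish.shape
    cal = Calibration(pixel_nm=spec.pixel_nm, z_step_nm=spec.z_step_nm)
    tess = cells_mod.tessellate(
        np.array([n.centroid for n in nuclei]),
        bounding_box=((0, nx - 1), (0, ny - 1), (0, nz - 1)),
        z_aspect=cal.z_aspect if cfg.physical_units else 1.0)
    vcells, drops = cells_mod.build_virtual_cells(
        tess,
        np.array([s.centroid for s in mature]).reshape(-1, 3),
        np.array([s.centroid for s in sites]).reshape(-1, 3),
        np.array([s.nascent_units for s in sites]))

    bins = stats.bin_cells(vcells, cfg.axis, cfg.landmark, cfg.bin_width)
    qc = {
        "replicate": replicate,
        "scene_seed": scene_seed,
        "plateau_cutoffs": list(scan.plateau_cutoffs),
        "selected_cutoff": float(cutoff),
        "n_2d_counts": [int(c) for c in scan.counts],
        "n_mature_spots": len(mature),
        "n_sites": len(sites),
        "n_nuclei": len(nuclei),
        "drops": drops,
        "true_mature": int(len(truth.mature_centroids)),
        "true_sites": int(len(truth.site_centroids)),
    }
    return {"cells": vcells, "bins": bins, "qc": qc, "truth": truth,
            "mature": mature, "sites": sites}


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the replicate workflow and write outputs.

    Produces per-replicate ``cells_r<k>.csv``, a pooled per-bin
    ``bin_summary.csv``, and ``qc.json`` under ``cfg.out_dir``.
    Returns the in-memory results (replicates, offsets, pooled bins,
    summaries).
    """
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    reps = [process_replicate(cfg, r) for r in range(cfg.n_replicates)]
    for r, rep in enumerate(reps):
        _write_csv(cells_to_df(rep["cells"]), out / f"cells_r{r}.csv",
                   cfg)

    profiles = [stats.mrna_profile(rep["bins"]) for rep in reps]
    if len(reps) >= 2:
        offsets = stats.register_replicates(
            profiles, max_offset=cfg.max_registration_offset)
    else:
        offsets = [0]
    pooled = stats.pool_replicates([rep["bins"] for rep in reps],
                                   offsets)

    rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, 977)))
    rows = []
    for b in pooled:
        if b.n_cells < 2:
            continue
        summary = stats.summarize_bin(
            b, site_fraction_mode=cfg.site_fraction_mode, with_ci=True,
            n_resamples=cfg.bootstrap_resamples,
            seed=int(rng.integers(2 ** 31)))
        row = {
            "axis": b.axis, "side": b.side or "", "bin": b.index,
            "n_cells": summary.n_cells,
            "median_mrna": summary.median_mrna,
            "fraction_with_site": summary.fraction_with_site,
            "median_nascent": (summary.median_nascent
                               if summary.median_nascent is not None
                               else float("nan")),
            "fano": summary.fano,
        }
        for stat_name, (lo, hi) in summary.ci.items():
            row[f"{stat_name}_ci_lo"] = lo
            row[f"{stat_name}_ci_hi"] = hi
        rows.append(row)
    summary_df = pd.DataFrame(rows)
    _write_csv(summary_df, out / "bin_summary.csv", cfg)

    qc = {
        "config_hash": cfg.config_hash,
        "seed": cfg.seed,
        "replicates": [rep["qc"] for rep in reps],
        "registration_offsets": [int(o) for o in offsets],
        "pooled_cells": int(sum(b.n_cells for b in pooled)),
        "parameters": dataclasses.asdict(cfg),
    }
    (out / "qc.json").write_text(json.dumps(qc, indent=2, sort_keys=True))
    return {"replicates": reps, "offsets": offsets, "pooled": pooled,
            "summary": summary_df, "qc": qc}


__all__ = ["RunConfig", "run_pipeline", "process_replicate",
           "cells_to_df", "cells_from_df"]
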