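"""Ground-truthed synthetic smFISH scenes.

Renders 3D two-channel stacks with the statistical structure the
quantification pipeline assumes: a large population of dim,
near-uniform diffraction-limited mature-mRNA spots, a smaller
population of brighter, variable transcription sites confined to
nuclei, and a nuclear channel of non-overlapping disks stacked through
z ("pancake" nuclei). Every rendered object is recorded in a
:class:`GroundTruth` so detection, linking, cell assignment and
spatial statistics can all be scored against known truth.

The lateral point-spread function is Gaussian with sigma derived from
the ~600 nm full-width-half-maximum of a diffraction-limited spot.
Axially, each optical section is 700 nm thick at 345 nm spacing, so
adjacent sections capture nearly the full signal of an axially
confined emitter while farther sections capture almost none; the
axial profile is therefore modelled as a flat-topped "section
capture" weight that places a spot at near-full amplitude in its 2-3
nearest sections and essentially zero elsewhere. This reproduces the
two properties segmentation relies on: spots appear in 2-3
consecutive sections, and the 2D object count is flat over a broad
cutoff range (the threshold plateau). Shot noise is approximated as
additive Gaussian noise on a constant background.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable

import numpy as np
import pandas as pd

from .stack import (MAX_INTENSITY_12BIT, Calibration, ImageStack3D)

#: lateral sigma (nm) from a 600 nm FWHM: FWHM = 2 sqrt(2 ln 2) sigma
PSF_LATERAL_SIGMA_NM = 600.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))
#: sections within this distance (in section units) of a spot center
#: capture its signal; 1.25 puts a spot in 2-3 consecutive sections
AXIAL_CAPTURE_SECTIONS = 1.25
#: fractional amplitude roll-off across the capture window (the
#: outermost captured section renders at 1 - this fraction)
AXIAL_CAPTURE_ROLLOFF = 0.07

DEPOSITED_COLUMNS = ("x", "y", "z", "intensity")


@dataclass
class SceneSpec:
    """Declarative description of a synthetic two-channel scene.

    Distances are in x-y pixels unless suffixed ``_nm``; z positions
    are in section units. ``expression_profile``, when given, maps an
    ``(x, y)`` nucleus position to the expected number of mRNAs for
    that cell (a morphogen-graded scene); when ``None`` mature spots
    are placed uniformly at random and ``n_mature_spots`` is used
    directly.
    """

    shape: tuple[int, int, int] = (20, 512, 512)  # (z, y, x)
    pixel_nm: float = 76.0
    z_step_nm: float = 345.0
    n_mature_spots: int = 300
    mature_amplitude: float = 300.0
    mature_amplitude_cv: float = 0.05
    n_transcription_sites: int = 0
    site_multiplier_range: tuple[float, float] = (2.5, 8.0)
    n_nuclei: int = 0
    nucleus_radius: float = 16.0
    nucleus_z_extent: int = 6
    nucleus_amplitude: float = 1200.0
    background: float = 100.0
    noise_sigma: float = 4.0
    psf_lateral_sigma_nm: float = PSF_LATERAL_SIGMA_NM
    axial_capture_sections: float = AXIAL_CAPTURE_SECTIONS
    min_spot_separation: float = 16.0
    expression_profile: Callable[[float, float], float] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if any(s <= 0 for s in self.shape):
            raise ValueError("scene shape must be positive")
        if self.z_step_nm <= 0 or self.pixel_nm <= 0:
            raise ValueError("calibration must be positive")
        if self.n_mature_spots < 0 or self.n_transcription_sites < 0:
            raise ValueError("object counts must be non-negative")
        lo, hi = self.site_multiplier_range
        if lo < 1.0 or hi < lo:
            raise ValueError("site multipliers must be >= 1 and ordered")
        if self.n_transcription_sites > 0 and self.n_nuclei == 0:
            raise ValueError("transcription sites require nuclei to sit in")

    @property
    def calibration(self) -> Calibration:
        return Calibration(pixel_nm=self.pixel_nm, z_step_nm=self.z_step_nm)

    @property
    def psf_sigma_xy_px(self) -> float:
        return self.psf_lateral_sigma_nm / self.pixel_nm


@dataclass
class GroundTruth:
    """True object inventory of a rendered scene.

    Centroids are ``(x, y, z)`` with x-y in pixels (subvoxel) and z in
    section units. ``mature_cell`` / ``site_cell`` give the index of
    the owning nucleus (-1 when the scene has no nuclei).
    """

    mature_centroids: np.ndarray      # (n, 3)
    mature_amplitudes: np.ndarray     # (n,)
    site_centroids: np.ndarray        # (m, 3)
    site_units: np.ndarray            # (m,) true nascent units (amplitude multiple)
    nucleus_centroids: np.ndarray     # (k, 3)
    mature_cell: np.ndarray           # (n,) int
    site_cell: np.ndarray             # (m,) int


class SceneInfeasibleError(ValueError):
    """Raised when the requested objects cannot be placed without
    violating the separation constraints of the scene volume."""


def _place_separated(rng: np.random.Generator, n: int,
                     shape: tuple[int, int, int], min_sep: float,
                     margin: float, z_margin: float = 1.5,
                     max_attempts_per_point: int = 200,
                     avoid: np.ndarray | None = None) -> np.ndarray:
    """Uniform random (x, y, z) positions with lateral separation.

    Two points may share x-y proximity only if separated by >= 4
    sections in z, so that each renders as an isolated spot. Points in
    ``avoid`` (e.g. transcription sites already placed) are kept at
    the same separation but not returned.
    """
    nz, ny, nx = shape
    placed: list[tuple[float, float, float]] = []
    cell = max(min_sep, 1.0)
    grid: dict[tuple[int, int], list[int]] = {}
    n_avoid = 0
    if avoid is not None and len(avoid):
        for ax, ay, az in np.asarray(avoid, dtype=float):
            grid.setdefault((int(ax // cell), int(ay // cell)),
                            []).append(len(placed))
            placed.append((ax, ay, az))
            n_avoid += 1
    for i in range(n):
        for _ in range(max_attempts_per_point):
            x = rng.uniform(margin, nx - 1 - margin)
            y = rng.uniform(margin, ny - 1 - margin)
            z = rng.uniform(z_margin, nz - 1 - z_margin)
            gx, gy = int(x // cell), int(y // cell)
            ok = True
            for dx in (-1, 0, 1):
                for dy in (-1, 0, 1):
                    for j in grid.get((gx + dx, gy + dy), ()):
                        px, py, pz = placed[j]
                        if (math.hypot(px - x, py - y) < min_sep
                                and abs(pz - z) < 4.0):
                            ok = False
                            break
                    if not ok:
                        break
                if not ok:
                    break
            if ok:
                grid.setdefault((gx, gy), []).append(len(placed))
                placed.append((x, y, z))
                break
        else:
            raise SceneInfeasibleError(
                f"could not place spot {i + 1}/{n} with separation "
                f">= {min_sep} px in a {shape} volume; reduce the spot "
                f"count or enlarge the scene")
    return np.asarray(placed[n_avoid:], dtype=float).reshape(n, 3)


def _place_nuclei(rng: np.random.Generator, spec: SceneSpec) -> np.ndarray:
    """Non-overlapping nucleus centroids (x, y, z)."""
    nz, ny, nx = spec.shape
    r = spec.nucleus_radius
    min_sep = 2 * r + 6.0
    margin = r + 2.0
    zc = (nz - 1) / 2.0
    placed: list[tuple[float, float, float]] = []
    for i in range(spec.n_nuclei):
        for _ in range(400):
            x = rng.uniform(margin, nx - 1 - margin)
            y = rng.uniform(margin, ny - 1 - margin)
            if all(math.hypot(px - x, py - y) >= min_sep
                   for px, py, _ in placed):
                placed.append((x, y, zc + rng.uniform(-1.0, 1.0)))
                break
        else:
            raise SceneInfeasibleError(
                f"could not place nucleus {i + 1}/{spec.n_nuclei} "
                f"(radius {r} px) without overlap; reduce n_nuclei or "
                f"enlarge the scene")
    return np.asarray(placed, dtype=float).reshape(spec.n_nuclei, 3)


def _axial_capture(dz: np.ndarray, capture: float,
                   rolloff: float = AXIAL_CAPTURE_ROLLOFF) -> np.ndarray:
    """Per-section amplitude weight for a spot at axial offset ``dz``
    (section units): near-full amplitude inside the capture window,
    zero outside (thick overlapping sections capture an axially
    confined emitter almost completely or not at all)."""
    d = np.abs(dz)
    w = np.where(d <= capture, 1.0 - rolloff * (d / capture) ** 2, 0.0)
    return w


def _add_gaussian_blob(img: np.ndarray, x: float, y: float, z: float,
                       amplitude: float, sigma_xy: float,
                       capture: float) -> None:
    """Add a laterally Gaussian, axially section-captured spot."""
    nz, ny, nx = img.shape
    rxy = int(math.ceil(4 * sigma_xy))
    rz = int(math.ceil(capture)) + 1
    x0, x1 = max(0, int(x) - rxy), min(nx, int(x) + rxy + 1)
    y0, y1 = max(0, int(y) - rxy), min(ny, int(y) + rxy + 1)
    z0, z1 = max(0, int(z) - rz), min(nz, int(z) + rz + 1)
    if x0 >= x1 or y0 >= y1 or z0 >= z1:
        return
    xs = np.arange(x0, x1, dtype=float) - x
    ys = np.arange(y0, y1, dtype=float) - y
    zs = np.arange(z0, z1, dtype=float) - z
    gx = np.exp(-xs ** 2 / (2 * sigma_xy ** 2))
    gy = np.exp(-ys ** 2 / (2 * sigma_xy ** 2))
    gz = _axial_capture(zs, capture)
    img[z0:z1, y0:y1, x0:x1] += (amplitude
                                 * gz[:, None, None]
                                 * gy[None, :, None]
                                 * gx[None, None, :])


def _nearest_nucleus(points: np.ndarray, nuclei: np.ndarray,
                     z_aspect: float) -> np.ndarray:
    if len(nuclei) == 0:
        return np.full(len(points), -1, dtype=int)
    if len(points) == 0:
        return np.zeros(0, dtype=int)
    scale = np.array([1.0, 1.0, z_aspect])
    d = np.linalg.norm(points[:, None, :] * scale
                       - nuclei[None, :, :] * scale, axis=2)
    return np.argmin(d, axis=1)


def render_stack(spec: SceneSpec) -> tuple[ImageStack3D, ImageStack3D, GroundTruth]:
    """Render a scene into (FISH channel, nuclear channel, ground truth).

    Deterministic for a fixed spec + seed (bit-identical uint16 stacks).
    Mature spots are 3D Gaussian blobs of near-uniform amplitude; sites
    are brighter blobs (``multiplier x`` mature amplitude) placed inside
    nuclei; both channels are clipped to the 12-bit range.
    """
    rng = np.random.default_rng(spec.seed)
    nz, ny, nx = spec.shape
    sigma_xy = spec.psf_sigma_xy_px
    capture = spec.axial_capture_sections

    nuclei = (_place_nuclei(rng, spec) if spec.n_nuclei
              else np.zeros((0, 3)))

    # --- transcription sites first: inside nuclei, brighter; mature
    # spots then keep the separation distance from them ---
    if spec.n_transcription_sites > spec.n_nuclei:
        raise SceneInfeasibleError(
            "more transcription sites requested than nuclei to host them")
    if spec.n_transcription_sites == 0:
        site_idx = np.zeros(0, dtype=int)
    elif spec.expression_profile is not None:
        # frequency modulation: a nucleus hosts a site with
        # probability proportional to its local expression level
        w = np.array([max(float(spec.expression_profile(cx, cy)), 0.0)
                      for cx, cy, _ in nuclei])
        if w.sum() <= 0:
            w = np.ones(len(nuclei))
        site_idx = rng.choice(spec.n_nuclei,
                              size=spec.n_transcription_sites,
                              replace=False, p=w / w.sum())
    else:
        site_idx = rng.choice(spec.n_nuclei,
                              size=spec.n_transcription_sites,
                              replace=False)
    site_pts = []
    for i in site_idx:
        cx, cy, cz = nuclei[i]
        jit = spec.nucleus_radius * 0.3
        site_pts.append((cx + rng.uniform(-jit, jit),
                         cy + rng.uniform(-jit, jit),
                         cz + rng.uniform(-1.0, 1.0)))
    sites = np.asarray(site_pts, dtype=float).reshape(len(site_pts), 3)
    site_units = rng.uniform(*spec.site_multiplier_range,
                             size=len(sites))

    # --- mature mRNA positions ---
    if spec.expression_profile is not None:
        # per-cell Poisson counts from the profile; RNAs scattered
        # around the nucleus but still respecting spot separation so
        # each renders as a resolvable diffraction-limited spot (RNAs
        # that cannot fit are dropped; truth records what rendered)
        pts: list[tuple[float, float, float]] = []
        cell_of: list[int] = []
        scatter = max(spec.nucleus_radius + 4.0, 1.0)
        sep = spec.min_spot_separation
        grid: dict[tuple[int, int], list[int]] = {}
        cell_w = max(sep, 1.0)
        for (sx, sy, sz) in sites:
            grid.setdefault((int(sx // cell_w), int(sy // cell_w)),
                            []).append(len(pts))
            pts.append((sx, sy, sz))
            cell_of.append(-2)      # placeholder: site, removed below
        for i, (cx, cy, cz) in enumerate(nuclei):
            lam = max(float(spec.expression_profile(cx, cy)), 0.0)
            k = rng.poisson(lam)
            for _ in range(k):
                for _attempt in range(60):
                    ang = rng.uniform(0, 2 * math.pi)
                    rad = scatter * math.sqrt(rng.uniform())
                    x = min(max(cx + rad * math.cos(ang), 1.0), nx - 2.0)
                    y = min(max(cy + rad * math.sin(ang), 1.0), ny - 2.0)
                    z = min(max(cz + rng.uniform(-4.5, 4.5), 1.5),
                            nz - 2.5)
                    gx, gy = int(x // cell_w), int(y // cell_w)
                    ok = True
                    for dxg in (-1, 0, 1):
                        for dyg in (-1, 0, 1):
                            for j in grid.get((gx + dxg, gy + dyg), ()):
                                px, py, pz = pts[j]
                                if (math.hypot(px - x, py - y) < sep
                                        and abs(pz - z) < 4.0):
                                    ok = False
                                    break
                            if not ok:
                                break
                        if not ok:
                            break
                    if ok:
                        grid.setdefault((gx, gy), []).append(len(pts))
                        pts.append((x, y, z))
                        cell_of.append(i)
                        break
        keep = [j for j, c in enumerate(cell_of) if c >= 0]
        mature = np.asarray([pts[j] for j in keep],
                            dtype=float).reshape(len(keep), 3)
        mature_cell = np.asarray([cell_of[j] for j in keep], dtype=int)
    else:
        mature = _place_separated(rng, spec.n_mature_spots, spec.shape,
                                  spec.min_spot_separation,
                                  margin=4 * sigma_xy + 1, avoid=sites)
        mature_cell = _nearest_nucleus(mature, nuclei,
                                       spec.calibration.z_aspect)
    amps = spec.mature_amplitude * np.clip(
        rng.normal(1.0, spec.mature_amplitude_cv, size=len(mature)),
        0.2, None)

    # --- render FISH channel ---
    fish = np.full(spec.shape, float(spec.background), dtype=np.float64)
    for (x, y, z), a in zip(mature, amps):
        _add_gaussian_blob(fish, x, y, z, a, sigma_xy, capture)
    for (x, y, z), m in zip(sites, site_units):
        _add_gaussian_blob(fish, x, y, z, m * spec.mature_amplitude,
                           sigma_xy, capture)
    if spec.noise_sigma > 0:
        fish += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    fish = np.clip(np.round(fish), 0, MAX_INTENSITY_12BIT).astype(np.uint16)

    # --- render nuclear channel: disks stacked through z ---
    nuc = np.full(spec.shape, float(spec.background), dtype=np.float64)
    if spec.n_nuclei:
        yy, xx = np.mgrid[0:ny, 0:nx]
        half = spec.nucleus_z_extent // 2
        for (cx, cy, cz) in nuclei:
            disk = ((xx - cx) ** 2 + (yy - cy) ** 2
                    <= spec.nucleus_radius ** 2)
            z0 = max(0, int(round(cz)) - half)
            z1 = min(nz, z0 + spec.nucleus_z_extent)
            nuc[z0:z1][:, disk] += spec.nucleus_amplitude
    if spec.noise_sigma > 0:
        nuc += rng.normal(0.0, spec.noise_sigma, size=spec.shape)
    nuc = np.clip(np.round(nuc), 0, MAX_INTENSITY_12BIT).astype(np.uint16)

    truth = GroundTruth(
        mature_centroids=mature,
        mature_amplitudes=amps,
        site_centroids=sites,
        site_units=site_units,
        nucleus_centroids=nuclei,
        mature_cell=mature_cell,
        site_cell=site_idx.astype(int),
    )
    cal = spec.calibration
    return (ImageStack3D(fish, role="fish", calibration=cal),
            ImageStack3D(nuc, role="nuclear", calibration=cal),
            truth)


def emit_deposited_csv(objects, path=None) -> pd.DataFrame:
    """Write objects in the deposited per-disc CSV format.

    One row per object with columns ``x, y, z, intensity``: x-y
    centroid in pixels, z in section units, integrated fluorescence
    intensity. ``objects`` may be an iterable of ``(x, y, z,
    intensity)`` tuples, of objects exposing ``centroid`` and
    ``intensity`` attributes, or a :class:`GroundTruth` (mature spots,
    with amplitude standing in for intensity).
    """
    rows: list[tuple[float, float, float, float]] = []
    if isinstance(objects, GroundTruth):
        for (x, y, z), a in zip(objects.mature_centroids,
                                objects.mature_amplitudes):
            rows.append((x, y, z, a))
    else:
        for obj in objects:
            if hasattr(obj, "centroid"):
                x, y, z = obj.centroid
                rows.append((float(x), float(y), float(z),
                             float(obj.intensity)))
            else:
                x, y, z, inten = obj
                rows.append((float(x), float(y), float(z), float(inten)))
    df = pd.DataFrame(rows, columns=list(DEPOSITED_COLUMNS))
    if path is not None:
        df.to_csv(path, index=False)
    return df


def read_deposited_csv(path) -> pd.DataFrame:
    """Read a deposited-format CSV (x, y, z, intensity)."""
    df = pd.read_csv(path, comment="#")
    missing = set(DEPOSITED_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"deposited CSV missing columns: {sorted(missing)}")
    return df[list(DEPOSITED_COLUMNS)]
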