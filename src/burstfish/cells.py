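"""Virtual cells: nuclei, Voronoi tessellation, RNA assignment.

Wing-disc epithelial cell boundaries are invisible to smFISH, so
cells are approximated by the Voronoi region of each nucleus
centroid: every voxel belongs to the nearest nucleus. Nuclei are
segmented per 2D section (a classical smoothing/threshold/watershed
pipeline) and stacked through z into "pancake" objects by greedy
maximal-overlap linking; single-section objects are disregarded. The
bounded 3D Voronoi diagram is built as a halfspace intersection per
centroid (bisector planes with every other centroid, clipped by the
image box), and spots are assigned by convex-polytope membership.

Assignment is wrong at the local scale for cells whose RNAs stray
across the bisector, but per-bin trends over hundreds of cells are
robust, which is the level at which the statistics are computed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.spatial import ConvexHull, HalfspaceIntersection
from skimage import feature, filters, morphology, segmentation as skseg

DEFAULT_NUCLEUS_RADIUS = 32.0


@dataclass
class Nucleus3D:
    """A stacked 3D nucleus object."""

    index: int
    centroid: np.ndarray          # (x, y, z); x-y pixels, z sections
    n_pixels: int
    sections: tuple[int, ...]     # z-sections spanned
    section_coords: dict = field(default_factory=dict)  # z -> (rows, cols)


@dataclass
class VoronoiCell:
    """Bounded convex Voronoi polytope owned by one nucleus."""

    index: int
    centroid: np.ndarray          # owning nucleus centroid (original units)
    vertices: np.ndarray          # polytope vertices (tessellation units)
    halfspaces: np.ndarray        # (m, 4) rows [a b c d]: ax+by+cz+d <= 0
    volume: float


@dataclass
class VirtualCell:
    """A nucleus with its assigned mRNAs and transcription sites."""

    index: int
    centroid: np.ndarray
    mrna_indices: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=int))
    site_indices: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=int))
    nascent_units: np.ndarray = field(
        default_factory=lambda: np.zeros(0, dtype=float))

    @property
    def mrna_count(self) -> int:
        return len(self.mrna_indices)

    @property
    def site_count(self) -> int:
        return len(self.site_indices)


def segment_nuclei_2d(nuclear_stack, expected_radius: float = DEFAULT_NUCLEUS_RADIUS
                      ) -> list[np.ndarray]:
    """Label nuclei in each z-section.

    Per section: Gaussian smoothing, Otsu thresholding (with a
    contrast guard so blank sections yield no labels), and
    marker-based watershed splitting of touching nuclei using the
    expected nuclear radius to space the markers.
    """
    out: list[np.ndarray] = []
    sigma = max(expected_radius / 8.0, 1.0)
    min_area = int(0.15 * np.pi * expected_radius ** 2)
    for z in range(nuclear_stack.n_sections):
        section = np.asarray(nuclear_stack.section(z), dtype=float)
        labels = np.zeros(section.shape, dtype=np.int32)
        smoothed = filters.gaussian(section, sigma=sigma,
                                    preserve_range=True)
        lo, hi = np.percentile(smoothed, [1, 99])
        if hi - lo < 1e-6 or hi < 1.2 * max(lo, 1e-9):
            out.append(labels)       # no nuclear contrast in this section
            continue
        thr = filters.threshold_otsu(smoothed)
        mask = smoothed > thr
        mask = morphology.remove_small_objects(mask, max_size=min_area - 1)
        if not mask.any():
            out.append(labels)
            continue
        dist = ndimage.distance_transform_edt(mask)
        peaks = feature.peak_local_max(
            dist, min_distance=max(int(0.8 * expected_radius), 1),
            labels=mask, exclude_border=False)
        markers = np.zeros(section.shape, dtype=np.int32)
        for i, (r, c) in enumerate(peaks, start=1):
            markers[r, c] = i
        if markers.max() == 0:
            labels, _ = ndimage.label(mask)
        else:
            labels = skseg.watershed(-dist, markers, mask=mask)
        labels = morphology.remove_small_objects(labels, max_size=min_area - 1)
        out.append(labels.astype(np.int32))
    return out


def stack_nuclei_3d(section_masks: list[np.ndarray]) -> list[Nucleus3D]:
    """Join per-section 2D nucleus labels into 3D "pancake" objects.

    Greedy forward pass: for each object in section z (in label
    order), the object in section z+1 with the highest pixel overlap
    inherits its 3D identity. An object in z+1 already claimed by an
    earlier object keeps its first claim (two nuclei that both
    maximally overlap one object therefore merge chains at that
    object; first claim wins, deterministically). Objects that end up
    in a single section are disregarded.
    """
    n_sections = len(section_masks)
    # per-section {label -> global id}
    ids: list[dict[int, int]] = [dict() for _ in range(n_sections)]
    next_id = 0
    for z in range(n_sections):
        labels_here = np.unique(section_masks[z])
        labels_here = labels_here[labels_here > 0]
        for lab in labels_here:
            if lab not in ids[z]:
                ids[z][int(lab)] = next_id
                next_id += 1
        if z + 1 >= n_sections:
            break
        nxt = section_masks[z + 1]
        claimed: set[int] = set()
        for lab in labels_here:
            overlap = nxt[section_masks[z] == lab]
            overlap = overlap[overlap > 0]
            if overlap.size == 0:
                continue
            vals, counts = np.unique(overlap, return_counts=True)
            partner = int(vals[np.argmax(counts)])
            if partner in claimed or partner in ids[z + 1]:
                continue
            ids[z + 1][partner] = ids[z][int(lab)]
            claimed.add(partner)

    # gather members per global id
    members: dict[int, list[tuple[int, np.ndarray, np.ndarray]]] = {}
    for z in range(n_sections):
        for lab, gid in ids[z].items():
            rows, cols = np.nonzero(section_masks[z] == lab)
            members.setdefault(gid, []).append((z, rows, cols))

    nuclei: list[Nucleus3D] = []
    for gid in sorted(members):
        secs = members[gid]
        zs = sorted(s[0] for s in secs)
        if len(zs) < 2:
            continue                      # single-section object: dropped
        n_px = sum(len(s[1]) for s in secs)
        sx = sum(s[2].sum() for s in secs)
        sy = sum(s[1].sum() for s in secs)
        sz = sum(s[0] * len(s[1]) for s in secs)
        centroid = np.array([sx / n_px, sy / n_px, sz / n_px])
        nuclei.append(Nucleus3D(
            index=len(nuclei), centroid=centroid, n_pixels=n_px,
            sections=tuple(zs),
            section_coords={s[0]: (s[1], s[2]) for s in secs}))
    return nuclei


@dataclass
class Tessellation:
    """A polytope-bounded 3D Voronoi diagram.

    ``scale`` converts (x, y, z) pixel/section coordinates into the
    units the diagram was computed in: with physical units the z axis
    is stretched by the z-spacing / pixel-size ratio, so "nearest
    centroid" is nearest in real space despite anisotropic voxels.
    """

    cells: list[VoronoiCell]
    bounding_box: np.ndarray      # (3, 2) [lo, hi] per axis, original units
    scale: np.ndarray             # (3,) coordinate scaling

    def assign(self, points: np.ndarray, tol: float = 1e-9
               ) -> tuple[np.ndarray, int]:
        """Assign each (x, y, z) point to a Voronoi cell.

        Returns ``(assignment, n_dropped)`` where ``assignment[i]`` is
        the owning cell index or -1 for points outside the bounding
        box. Membership is a convex-polytope facet test; a point on a
        shared facet goes to the cell with the lowest nucleus index
        (cells are tested in index order).
        """
        pts = np.atleast_2d(np.asarray(points, dtype=float))
        if pts.size == 0:
            return np.zeros(0, dtype=int), 0
        lo, hi = self.bounding_box[:, 0], self.bounding_box[:, 1]
        in_box = np.all((pts >= lo - tol) & (pts <= hi + tol), axis=1)
        scaled = pts * self.scale
        assignment = np.full(len(pts), -1, dtype=int)
        todo = in_box.copy()
        for cell in self.cells:
            if not todo.any():
                break
            A, b = cell.halfspaces[:, :3], cell.halfspaces[:, 3]
            inside = np.all(scaled[todo] @ A.T + b <= tol, axis=1)
            idx = np.nonzero(todo)[0][inside]
            assignment[idx] = cell.index
            todo[idx] = False
        return assignment, int(np.count_nonzero(~in_box))


def tessellate(centroids: np.ndarray, bounding_box,
               z_aspect: float = 1.0) -> Tessellation:
    """Bounded 3D Voronoi diagram from nucleus centroids.

    ``centroids`` is ``(k, 3)`` in (x, y, z) pixel/section units;
    ``bounding_box`` is ``((x0, x1), (y0, y1), (z0, z1))`` in the same
    units (default use: the image volume extent). ``z_aspect``
    stretches z before tessellation (pass
    ``calibration.z_aspect`` for physical-unit diagrams, 1.0 for raw
    pixel/section coordinates). Each cell is the intersection of the
    box with the bisector halfspaces against every other centroid.
    Duplicate centroids are merged with a warning.
    """
    pts = np.atleast_2d(np.asarray(centroids, dtype=float))
    if pts.shape[0] < 1:
        raise ValueError("need at least one centroid")
    box = np.asarray(bounding_box, dtype=float)
    if box.shape != (3, 2):
        raise ValueError("bounding_box must be ((x0,x1),(y0,y1),(z0,z1))")
    if np.any(pts < box[:, 0]) or np.any(pts > box[:, 1]):
        raise ValueError("bounding box must contain all centroids")

    uniq, keep = np.unique(np.round(pts, 9), axis=0, return_index=True)
    if len(uniq) < len(pts):
        warnings.warn("duplicate nucleus centroids merged before "
                      "tessellation", stacklevel=2)
        pts = pts[np.sort(keep)]

    scale = np.array([1.0, 1.0, float(z_aspect)])
    sp = pts * scale
    sbox = box * scale[:, None]

    # box faces as halfspaces ax+by+cz+d <= 0
    face_rows = []
    for axis in range(3):
        lo_n = np.zeros(4)
        lo_n[axis] = -1.0
        lo_n[3] = sbox[axis, 0]
        hi_n = np.zeros(4)
        hi_n[axis] = 1.0
        hi_n[3] = -sbox[axis, 1]
        face_rows += [lo_n, hi_n]
    faces = np.array(face_rows)

    cells: list[VoronoiCell] = []
    for i in range(len(sp)):
        rows = [faces]
        others = np.delete(sp, i, axis=0)
        if len(others):
            normals = others - sp[i]
            mids = (others + sp[i]) / 2.0
            offs = -(normals * mids).sum(axis=1)
            rows.append(np.column_stack([normals, offs]))
        hs = np.vstack(rows)
        # a centroid on a box face is not strictly interior to its
        # polytope; nudge it inward (far less than centroid spacing)
        extent = sbox[:, 1] - sbox[:, 0]
        eps = 1e-7 * extent
        interior = np.clip(sp[i], sbox[:, 0] + eps, sbox[:, 1] - eps)
        hsi = HalfspaceIntersection(hs, interior)
        verts = hsi.intersections
        vol = float(ConvexHull(verts).volume)
        cells.append(VoronoiCell(index=i, centroid=pts[i],
                                 vertices=verts, halfspaces=hs,
                                 volume=vol))
    return Tessellation(cells=cells, bounding_box=box, scale=scale)


def build_virtual_cells(tess: Tessellation,
                        mrna_points: np.ndarray,
                        site_points: np.ndarray | None = None,
                        site_units: np.ndarray | None = None
                        ) -> tuple[list[VirtualCell], dict]:
    """Assign mRNA and site centroids to Voronoi cells.

    Returns the virtual cells plus a drop report
    ``{"mrna_dropped": n, "site_dropped": m}`` counting points outside
    the bounding box.
    """
    mrna_points = np.atleast_2d(np.asarray(mrna_points, dtype=float)) \
        if mrna_points is not None and np.size(mrna_points) else np.zeros((0, 3))
    site_points = np.atleast_2d(np.asarray(site_points, dtype=float)) \
        if site_points is not None and np.size(site_points) else np.zeros((0, 3))
    if site_units is None:
        site_units = np.zeros(len(site_points))
    site_units = np.asarray(site_units, dtype=float)

    mrna_assign, mrna_drop = tess.assign(mrna_points)
    site_assign, site_drop = tess.assign(site_points)

    cells_out: list[VirtualCell] = []
    for cell in tess.cells:
        m_idx = np.nonzero(mrna_assign == cell.index)[0]
        s_idx = np.nonzero(site_assign == cell.index)[0]
        cells_out.append(VirtualCell(
            index=cell.index, centroid=cell.centroid,
            mrna_indices=m_idx, site_indices=s_idx,
            nascent_units=site_units[s_idx]))
    report = {"mrna_dropped": mrna_drop, "site_dropped": site_drop}
    return cells_out, report


def nuclei_from_label_stack(label_stack) -> list[Nucleus3D]:
    """Build nuclei from a precomputed per-section label TIFF stack
    (each nuclear object is a distinct 'level'), via the same greedy
    overlap stacking."""
    masks = [np.asarray(label_stack.section(z), dtype=np.int32)
             for z in range(label_stack.n_sections)]
    return stack_nuclei_3d(masks)


__all__ = [
    "Nucleus3D", "VoronoiCell", "VirtualCell", "Tessellation",
    "segment_nuclei_2d", "stack_nuclei_3d", "tessellate",
    "build_virtual_cells", "nuclei_from_label_stack",
    "DEFAULT_NUCLEUS_RADIUS",
]
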