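"""Single-cell segmentation inside colony masks.

The central stage of the pipeline.  Each colony is cut into connected "cell
objects" (groups of touching cells) by adaptive thresholding; every object is
then classified by the topology of its morphological skeleton:

* **collinear** (no skeleton junctions) — a single cell or an end-to-end chain
  of cells.  The object's width profile along its centerline is scanned for
  "deep valleys" (bow-tie constrictions at division septa): a local width
  minimum whose ratio to the nearest flanking maxima is at or below the valley
  threshold on both sides marks a cut point.
* **complex** (skeleton junctions present) — several cells in a 2-D packing.
  Watershed on the negated distance transform proposes candidate cells
  (over-segmented on purpose), a "puzzle solving" pass re-merges fragments
  that show no bow-tie and stay rod-shaped, and the surviving candidate
  centres seed a Gaussian-mixture re-segmentation of the object: the object is
  re-encoded as a 2-D point cloud (density proportional to the distance
  transform, so points concentrate along medial axes) and fitted with the
  MML-selecting mixture of :mod:`microcolony.gmm`; every mixture component of
  the best model is one segmented cell.

Colonies are processed independently, and a failure in one object quarantines
that object without aborting the frame.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

from .config import SegmentationConfig, SpeciesConfig, min_fragment_area, point_budget
from .gmm import MMLGaussianMixture, initial_mixture

__all__ = [
    "CellObject",
    "DistanceCurve",
    "DataCloud",
    "SegmentedCell",
    "adaptive_threshold",
    "mask_multiply",
    "extract_cell_objects",
    "classify_object",
    "distance_curve",
    "find_deep_valleys",
    "split_collinear",
    "watershed_candidates",
    "solidity",
    "puzzle_solve",
    "generate_points",
    "fit_gmm_mml",
    "assign_pixels",
    "merge_small_fragments",
    "compute_skeleton",
    "segment_frame",
    "point_budget",
    "min_fragment_area",
]

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types


@dataclass
class CellObject:
    """A connected set of touching cells inside one colony."""

    colony_id: int
    mask: np.ndarray                 # local binary mask
    offset: tuple[int, int]          # (row, col) of mask[0, 0] in the frame
    skeleton: np.ndarray | None = None
    junctions: list[tuple[int, int]] = field(default_factory=list)
    klass: str | None = None         # "collinear" | "complex"

    @property
    def area(self) -> int:
        return int(self.mask.sum())

    def global_pixels(self) -> tuple[np.ndarray, np.ndarray]:
        rows, cols = np.nonzero(self.mask)
        return rows + self.offset[0], cols + self.offset[1]


@dataclass
class DistanceCurve:
    centerline: np.ndarray           # (n, 2) ordered local pixel coords
    widths: np.ndarray               # per-centerline-point local width, px
    valley_indices: list[int] = field(default_factory=list)


@dataclass
class DataCloud:
    """Point-cloud encoding of a complex object."""

    points: np.ndarray               # (N, 2) as (row, col)
    per_pixel_weights: np.ndarray    # pi(i), sums to 1
    distances: np.ndarray            # EDT value d_i per object pixel
    pixel_coords: np.ndarray         # (M, 2) local coords of object pixels
    point_owner: np.ndarray          # index into pixel_coords per point
    candidate_centers: np.ndarray    # (C, 2)

    @property
    def n_points(self) -> int:
        return len(self.points)


@dataclass
class SegmentedCell:
    cell_instant_id: int
    colony_id: int
    frame: int
    rows: np.ndarray                 # global pixel rows
    cols: np.ndarray                 # global pixel cols
    centroid: tuple[float, float]    # (row, col) px
    area_px: int
    area_um2: float
    length_um: float
    width_um: float
    orientation: float               # radians, major-axis angle
    dist_to_colony_centroid_um: float
    on_colony_boundary: bool = False
    fluor_total: float | None = None
    fluor_mean: float | None = None
    undersized: bool = False


# ---------------------------------------------------------------------------
# thresholding and object extraction


def adaptive_threshold(frame: np.ndarray, window_px: int, offset: float,
                       dark_cells: bool = True) -> np.ndarray:
    """Local-mean adaptive threshold.

    Foreground is the cell-polarity side of (local mean − offset): dark cells
    in phase contrast / bright field, bright cells in fluorescence.
    """
    frame = np.asarray(frame, dtype=np.float64)
    if window_px >= min(frame.shape):
        raise ValueError("adaptive window must be smaller than the frame")
    local_mean = ndi.uniform_filter(frame, size=window_px)
    if dark_cells:
        return frame < local_mean - offset
    return frame > local_mean + offset


def mask_multiply(binary: np.ndarray, colony_mask: np.ndarray) -> np.ndarray:
    """Suppress thresholding artifacts outside the colony mask."""
    if binary.shape != colony_mask.shape:
        raise ValueError("shape mismatch")
    return binary & colony_mask


def extract_cell_objects(binary: np.ndarray, colony_id: int = 0,
                         min_px: int = 4) -> list[CellObject]:
    """8-connected components of the colony-masked binary image."""
    lab, n = ndi.label(binary, structure=np.ones((3, 3), dtype=int))
    objects = []
    for sl, i in zip(ndi.find_objects(lab), range(1, n + 1)):
        local = lab[sl] == i
        if int(local.sum()) < min_px:
            continue
        objects.append(CellObject(colony_id=colony_id, mask=local,
                                  offset=(sl[0].start, sl[1].start)))
    return objects


# ---------------------------------------------------------------------------
# skeleton classification


_NEIGH = np.ones((3, 3), dtype=int)
_NEIGH[1, 1] = 0


def _skeleton_degrees(skel: np.ndarray) -> np.ndarray:
    return ndi.convolve(skel.astype(int), _NEIGH, mode="constant")


def _prune_spurs(skel: np.ndarray, max_len: int) -> np.ndarray:
    """Remove skeleton side-branches shorter than ``max_len`` pixels.

    Boundary noise grows short spurs on an otherwise linear skeleton, which
    would flip a collinear object to complex; branches are eaten back from
    their free endpoints, junction-adjacent trunk pixels stay.
    """
    skel = skel.copy()
    for _ in range(max(max_len, 0)):
        deg = _skeleton_degrees(skel)
        endpoints = skel & (deg <= 1)
        # only trim endpoints that belong to a branch attached to a junction
        if not endpoints.any():
            break
        junctions = skel & (deg > 2)
        if not junctions.any():
            break
        # distance (in skeleton steps) from endpoints: trim one layer
        skel = skel & ~endpoints
    # trimming may leave junction stubs: a final thinning pass re-normalizes
    from skimage.morphology import skeletonize

    return skeletonize(skel) if skel.any() else skel


def compute_skeleton(obj: CellObject, spur_len_px: int) -> None:
    """Morphological skeleton, pruned of short spurs; fills obj in place."""
    from skimage.morphology import skeletonize

    skel = skeletonize(obj.mask)
    if skel.sum() >= 3:
        deg = _skeleton_degrees(skel)
        if (skel & (deg > 2)).any():
            pruned = _prune_spurs(skel, spur_len_px)
            if pruned.any():
                skel = pruned
    obj.skeleton = skel
    deg = _skeleton_degrees(skel)
    jr, jc = np.nonzero(skel & (deg > 2))
    obj.junctions = list(zip(jr.tolist(), jc.tolist()))


def classify_object(obj: CellObject, spur_len_px: int = 0) -> str:
    """collinear (no skeleton junctions) vs complex (junctions present)."""
    if obj.area < 4:
        obj.klass = "collinear"  # degenerate: single-cell candidate
        obj.skeleton = np.zeros_like(obj.mask)
        obj.junctions = []
        return obj.klass
    if obj.skeleton is None:
        compute_skeleton(obj, spur_len_px)
    obj.klass = "complex" if obj.junctions else "collinear"
    return obj.klass


# ---------------------------------------------------------------------------
# collinear path: centerline, width profile, deep valleys


def _ordered_centerline(skel: np.ndarray) -> np.ndarray | None:
    """Order a junction-free skeleton from one endpoint to the other."""
    deg = _skeleton_degrees(skel)
    ends = np.argwhere(skel & (deg == 1))
    if len(ends) == 0:
        return None  # cycle or single pixel
    start = tuple(ends[0])
    pixels = {tuple(p) for p in np.argwhere(skel)}
    path = [start]
    seen = {start}
    cur = start
    while True:
        nxt = None
        for dr in (-1, 0, 1):
            for dc in (-1, 0, 1):
                if dr == 0 and dc == 0:
                    continue
                cand = (cur[0] + dr, cur[1] + dc)
                if cand in pixels and cand not in seen:
                    nxt = cand
                    break
            if nxt:
                break
        if nxt is None:
            break
        path.append(nxt)
        seen.add(nxt)
        cur = nxt
    return np.array(path)


def _ray_to_boundary(mask: np.ndarray, p: np.ndarray, direction: np.ndarray,
                     max_dist: float, step: float = 0.25) -> float:
    """Distance from p to the mask boundary along ``direction``."""
    h, w = mask.shape
    s = step
    while s <= max_dist:
        r = p[0] + s * direction[0]
        c = p[1] + s * direction[1]
        ri, ci = int(round(r)), int(round(c))
        if ri < 0 or ci < 0 or ri >= h or ci >= w or not mask[ri, ci]:
            return s
        s += step
    return max_dist


def distance_curve(obj: CellObject, max_width_px: float | None = None) -> DistanceCurve | None:
    """Width profile along the ordered centerline of a collinear object.

    At each centerline point the local width is the distance between the two
    boundary crossings of the line normal to the local centerline tangent
    (diametric / antipodal boundary pixels); the profile is smoothed with a
    3-point moving average.  Returns None for degenerate objects (centerline
    shorter than 5 px): those are single-cell candidates.
    """
    if obj.skeleton is None or obj.klass != "collinear":
        raise ValueError("requires a classified collinear object")
    line = _ordered_centerline(obj.skeleton)
    if line is None or len(line) < 5:
        return None
    n = len(line)
    if max_width_px is None:
        max_width_px = 4.0 * max(obj.mask.shape)
    widths = np.empty(n)
    for i in range(n):
        a = line[max(0, i - 2)]
        b = line[min(n - 1, i + 2)]
        tangent = (b - a).astype(float)
        norm = np.hypot(*tangent)
        if norm < 1e-9:
            tangent = np.array([1.0, 0.0])
            norm = 1.0
        tangent /= norm
        normal = np.array([-tangent[1], tangent[0]])
        p = line[i].astype(float)
        widths[i] = (_ray_to_boundary(obj.mask, p, normal, max_width_px)
                     + _ray_to_boundary(obj.mask, p, -normal, max_width_px))
    smoothed = np.convolve(widths, np.ones(3) / 3.0, mode="same")
    smoothed[0] = widths[:2].mean()
    smoothed[-1] = widths[-2:].mean()
    return DistanceCurve(centerline=line, widths=smoothed)


def _runs(values: np.ndarray):
    """Compress equal-valued runs to (start, end_inclusive, value)."""
    runs = []
    start = 0
    for i in range(1, len(values) + 1):
        if i == len(values) or values[i] != values[start]:
            runs.append((start, i - 1, values[start]))
            start = i
    return runs


def find_deep_valleys(widths: np.ndarray, t_valley: float) -> list[int]:
    """Deep-valley (bow-tie) detection on a width profile.

    A local minimum qualifies iff its ratio to the nearest flanking local
    maxima is ≤ t_valley on *both* sides.  Plateaus count once, at their
    middle index; boundary runs can serve as flanking maxima but not as
    minima.  Returns ordered centerline indices.
    """
    widths = np.asarray(widths, dtype=float)
    if len(widths) < 3:
        return []
    runs = _runs(widths)
    k = len(runs)
    is_min = [False] * k
    is_max = [False] * k
    for j, (s, e, v) in enumerate(runs):
        left = runs[j - 1][2] if j > 0 else None
        right = runs[j + 1][2] if j + 1 < k else None
        if left is not None and right is not None:
            is_min[j] = v < left and v < right
            is_max[j] = v > left and v > right
        elif left is None and right is not None:
            is_max[j] = v > right   # boundary run: max candidate only
        elif right is None and left is not None:
            is_max[j] = v > left
    valleys = []
    for j in range(k):
        if not is_min[j]:
            continue
        v = runs[j][2]
        left_max = next((runs[i][2] for i in range(j - 1, -1, -1) if is_max[i]), None)
        right_max = next((runs[i][2] for i in range(j + 1, k) if is_max[i]), None)
        if left_max is None or right_max is None:
            continue
        if v / left_max <= t_valley and v / right_max <= t_valley:
            s, e, _ = runs[j]
            valleys.append((s + e) // 2)
    return valleys


def split_collinear(obj: CellObject, curve: DistanceCurve,
                    valley_indices: list[int],
                    min_area_px: float = 0.0) -> list[np.ndarray]:
    """Cut the object at each deep valley, normal to the centerline.

    Pixels are partitioned by their nearest centerline point; cuts that would
    produce a fragment below the minimum credible cell area are ignored (and
    logged).  Returns local boolean masks, ordered along the centerline.
    """
    rows, cols = np.nonzero(obj.mask)
    if not valley_indices:
        return [obj.mask.copy()]
    line = curve.centerline
    d2 = ((rows[:, None] - line[None, :, 0]) ** 2
          + (cols[:, None] - line[None, :, 1]) ** 2)
    nearest = d2.argmin(axis=1)
    cuts = sorted(valley_indices)
    while True:
        seg_of_pixel = np.searchsorted([c + 0.5 for c in cuts], nearest)
        areas = np.bincount(seg_of_pixel, minlength=len(cuts) + 1)
        small = [s for s, a in enumerate(areas) if a < min_area_px]
        if not small or not cuts:
            break
        # drop the cut adjacent to the smallest offending fragment
        s = min(small, key=lambda s: areas[s])
        drop = cuts[s] if s < len(cuts) else cuts[-1]
        log.debug("collinear cut at centerline %d dropped (fragment %d px)",
                  drop, int(areas[s]))
        cuts.remove(drop)
        if not cuts:
            return [obj.mask.copy()]
    masks = []
    for s in range(len(cuts) + 1):
        m = np.zeros_like(obj.mask)
        sel = seg_of_pixel == s
        m[rows[sel], cols[sel]] = True
        if m.any():
            masks.append(m)
    return masks


# ---------------------------------------------------------------------------
# complex path: watershed, solidity, puzzle solving


def watershed_candidates(mask: np.ndarray, h: float = 0.5):
    """Watershed fragments of a complex object.

    Watershed on the negated Euclidean distance transform, with markers from
    h-maxima suppression (h = 1 px by default) of the EDT; deliberately
    over-segments.  Returns (label image, fragment centroids (C, 2)).
    """
    from skimage.morphology import h_maxima
    from skimage.segmentation import watershed

    edt = ndi.distance_transform_edt(mask)
    peaks = h_maxima(edt, h)
    markers, n = ndi.label(peaks, structure=np.ones((3, 3), dtype=int))
    if n == 0:
        markers = mask.astype(int)
    labels = watershed(-edt, markers=markers, mask=mask)
    centroids = np.array(ndi.center_of_mass(mask, labels,
                                            range(1, labels.max() + 1)))
    return labels, centroids


def solidity(mask: np.ndarray) -> float:
    """Region area over convex-hull area, in (0, 1]."""
    from skimage.morphology import convex_hull_image

    area = int(mask.sum())
    if area == 0:
        raise ValueError("empty region")
    if area <= 2:
        return 1.0
    hull = convex_hull_image(mask)
    return area / float(hull.sum())


def _touching(lab: np.ndarray, a: int, b: int) -> bool:
    grown = ndi.binary_dilation(lab == a, structure=np.ones((3, 3), dtype=bool))
    return bool((grown & (lab == b)).any())


def _mergeable(merged: np.ndarray, boundary_px: np.ndarray,
               t_valley: float, species: SpeciesConfig) -> bool:
    """No bow-tie across the shared boundary, and still rod-shaped.

    A merged candidate must (a) keep a junction-free skeleton, (b) have an
    inscribed radius compatible with a single cell (otherwise two side-by-side
    rods would merge into one "fat" cell), and (c) show no deep valley of the
    width profile near the shared fragment boundary.
    """
    tmp = CellObject(colony_id=0, mask=merged, offset=(0, 0))
    spur = int(round(species.cell_width_px))
    if classify_object(tmp, spur) == "complex":
        return False
    edt = ndi.distance_transform_edt(merged)
    if edt.max() > 0.80 * species.cell_width_px:
        return False
    # a rod cannot credibly exceed about twice the expected cell length:
    # division would have intervened first
    pts = np.argwhere(merged)
    ext = pts.max(axis=0) - pts.min(axis=0)
    if math.hypot(*ext) > 2.2 * species.cell_length_px:
        return False
    curve = distance_curve(tmp)
    if curve is None:
        return True
    valleys = find_deep_valleys(curve.widths, t_valley)
    if not valleys:
        return True
    # a valley only blocks the merge when it sits near the shared boundary
    limit = max(2.0, species.cell_width_px)
    for v in valleys:
        p = curve.centerline[v]
        d = np.hypot(boundary_px[:, 0] - p[0], boundary_px[:, 1] - p[1])
        if d.min() <= limit:
            return False
    return True


def puzzle_solve(labels: np.ndarray, t_valley: float,
                 species: SpeciesConfig) -> np.ndarray:
    """Iteratively merge over-segmented watershed fragments.

    Every fragment is examined against its touching neighbours; a pair merges
    when the combined region shows no bow-tie point across their shared
    boundary (and remains rod-shaped).  Among feasible merges the one with
    maximal post-merge solidity wins (tie: smaller neighbour area, then lower
    fragment id).  Merged regions are re-enqueued; each merge strictly reduces
    the fragment count, so termination is guaranteed.
    """
    labels = labels.copy()
    queue = sorted(int(v) for v in np.unique(labels) if v != 0)
    alive = set(queue)
    struct = np.ones((3, 3), dtype=bool)
    while queue:
        a = queue.pop(0)
        if a not in alive:
            continue
        region_a = labels == a
        grown = ndi.binary_dilation(region_a, structure=struct)
        neighbours = sorted(set(labels[grown & (labels != a) & (labels != 0)].tolist()))
        best = None
        for b in neighbours:
            region_b = labels == b
            merged = region_a | region_b
            shared = np.argwhere(grown & region_b)
            if not _mergeable(merged, shared, t_valley, species):
                continue
            sol = solidity(merged)
            key = (-sol, int(region_b.sum()), b)
            if best is None or key < best[0]:
                best = (key, b, merged)
        if best is None:
            continue
        _, b, merged = best
        labels[merged] = a
        alive.discard(b)
        queue.append(a)
    return labels


# ---------------------------------------------------------------------------
# point-cloud encoding and mixture segmentation


def _apportion(weights: np.ndarray, n: int) -> np.ndarray:
    """Largest-remainder apportionment of n draws by the given weights."""
    quota = weights * n
    base = np.floor(quota).astype(int)
    rem = n - base.sum()
    if rem > 0:
        order = np.argsort(-(quota - base), kind="stable")
        base[order[:rem]] += 1
    return base


def generate_points(mask: np.ndarray, n_points: int,
                    rng: np.random.Generator,
                    candidate_centers: np.ndarray,
                    sigma2: float = 0.3) -> DataCloud:
    """Encode an object as a 2-D point cloud weighted by the EDT.

    Each object pixel i with distance-transform value d_i gets a mixing weight
    pi(i) = d_i / Σ_j d_j and emits its (largest-remainder) share of the N
    draws from a Gaussian centred on the pixel with covariance sigma2·I, so
    point density peaks along the medial axes where cells are.  Draws are
    clipped to the mask's bounding box.
    """
    edt = ndi.distance_transform_edt(mask)
    coords = np.argwhere(mask)
    d = edt[coords[:, 0], coords[:, 1]].astype(float)
    weights = d / d.sum()
    counts = _apportion(weights, n_points)
    owner = np.repeat(np.arange(len(coords)), counts)
    centers = coords[owner].astype(float)
    pts = centers + rng.normal(0.0, math.sqrt(sigma2), size=centers.shape)
    pts[:, 0] = np.clip(pts[:, 0], 0, mask.shape[0] - 1)
    pts[:, 1] = np.clip(pts[:, 1], 0, mask.shape[1] - 1)
    return DataCloud(points=pts, per_pixel_weights=weights, distances=d,
                     pixel_coords=coords, point_owner=owner,
                     candidate_centers=np.atleast_2d(candidate_centers))


def fit_gmm_mml(cloud: DataCloud, cfg: SegmentationConfig) -> MMLGaussianMixture:
    """Fit the MML mixture from the nearest-centre hard initialization."""
    w, mu, cov, _ = initial_mixture(cloud.points, cloud.candidate_centers)
    est = MMLGaussianMixture(max_iter=cfg.em_max_iter, tol=cfg.em_tol)
    return est.fit(cloud.points, w, mu, cov)


def assign_pixels(cloud: DataCloud, model: MMLGaussianMixture,
                  mask: np.ndarray) -> np.ndarray:
    """Pixel-level cell regions from the fitted mixture.

    Points take their arg-max-responsibility component; a pixel follows the
    majority vote of the points it generated, pixels that emitted none follow
    the component density at their own centre.
    """
    comp_of_point = model.predict(cloud.points)
    n_pix = len(cloud.pixel_coords)
    c = model.n_components_
    votes = np.zeros((n_pix, c), dtype=int)
    np.add.at(votes, (cloud.point_owner, comp_of_point), 1)
    pixel_comp = votes.argmax(axis=1)
    silent = votes.sum(axis=1) == 0
    if silent.any():
        pixel_comp[silent] = model.predict(cloud.pixel_coords[silent].astype(float))
    out = np.zeros(mask.shape, dtype=np.int32)
    out[cloud.pixel_coords[:, 0], cloud.pixel_coords[:, 1]] = pixel_comp + 1
    return out


def merge_small_fragments(labels: np.ndarray, min_area: float,
                          species: SpeciesConfig | None = None) -> np.ndarray:
    """Merge sub-minimum regions into the touching neighbour that maximizes
    post-merge solidity; isolated small regions survive as undersized cells.
    Iterates until stable."""
    labels = labels.copy()
    struct = np.ones((3, 3), dtype=bool)
    while True:
        ids, areas = np.unique(labels[labels > 0], return_counts=True)
        small = [int(i) for i, a in zip(ids, areas) if a < min_area]
        changed = False
        for s in small:
            region = labels == s
            if not region.any():
                continue
            grown = ndi.binary_dilation(region, structure=struct)
            neighbours = sorted(set(labels[grown & (labels != s) & (labels > 0)].tolist()))
            if not neighbours:
                continue  # isolated undersized single-cell: keep
            best = max(neighbours,
                       key=lambda b: (solidity(region | (labels == b)), -b))
            labels[region] = best
            changed = True
        if not changed:
            return labels


# ---------------------------------------------------------------------------
# geometry and orchestration


def _region_geometry(rows: np.ndarray, cols: np.ndarray, local_mask: np.ndarray,
                     cal: float):
    """(length_um, width_um, orientation) of one cell region.

    Length is the tip-to-tip extent (max pairwise boundary distance plus one
    pixel for pixel footprint); width is twice the mean medial-axis depth of
    the distance transform; orientation from the second central moments.
    """
    from skimage.morphology import skeletonize

    pts = np.column_stack([rows, cols]).astype(float)
    if len(pts) == 1:
        return cal, cal, 0.0
    if len(pts) > 8:
        try:
            from scipy.spatial import ConvexHull

            hull = ConvexHull(pts, qhull_options="QJ")
            pts_h = pts[hull.vertices]
        except Exception:
            pts_h = pts
    else:
        pts_h = pts
    d = np.sqrt(((pts_h[:, None, :] - pts_h[None, :, :]) ** 2).sum(-1))
    length_px = float(d.max()) + 1.0
    edt = ndi.distance_transform_edt(local_mask)
    skel = skeletonize(local_mask)
    if skel.any():
        width_px = 2.0 * float(edt[skel].mean()) + 1.0
    else:
        width_px = 2.0 * float(edt.max()) + 1.0
    width_px = min(width_px, length_px)
    rc = pts - pts.mean(axis=0)
    cov = rc.T @ rc / len(rc)
    evals, evecs = np.linalg.eigh(cov)
    major = evecs[:, int(np.argmax(evals))]
    orientation = float(np.arctan2(major[0], major[1]))
    return length_px * cal, width_px * cal, orientation


def _segment_object(obj: CellObject, species: SpeciesConfig,
                    cfg: SegmentationConfig,
                    rng: np.random.Generator) -> list[np.ndarray]:
    """One cell object -> list of local cell masks."""
    a_min = min_fragment_area(species)
    spur = int(round(species.cell_width_px))
    classify_object(obj, spur)
    if obj.klass == "collinear":
        curve = distance_curve(obj)
        if curve is None:
            return [obj.mask.copy()]
        valleys = find_deep_valleys(curve.widths, cfg.t_valley)
        return split_collinear(obj, curve, valleys, min_area_px=a_min)
    # complex path
    ws_labels, _ = watershed_candidates(obj.mask)
    merged = puzzle_solve(ws_labels, cfg.t_valley, species)
    merged = merge_small_fragments(merged, a_min, species)
    ids = [int(v) for v in np.unique(merged) if v != 0]
    centers = np.array(ndi.center_of_mass(obj.mask, merged, ids))
    c = len(ids)
    if c <= 1:
        return [obj.mask.copy()]
    n = point_budget(c, species)
    cloud = generate_points(obj.mask, n, rng, centers, cfg.point_sigma2)
    try:
        model = fit_gmm_mml(cloud, cfg)
    except ValueError:
        return [merged == i for i in ids]
    cells = assign_pixels(cloud, model, obj.mask)
    # mixture regions may be disconnected: keep connected parts separate and
    # let the small-fragment pass reabsorb slivers
    relabeled = np.zeros_like(cells)
    nxt = 1
    for i in range(1, cells.max() + 1):
        part, k = ndi.label(cells == i, structure=np.ones((3, 3), dtype=int))
        for j in range(1, k + 1):
            relabeled[part == j] = nxt
            nxt += 1
    relabeled = merge_small_fragments(relabeled, a_min, species)
    return [relabeled == i for i in np.unique(relabeled) if i != 0]


def _refine_boundaries(frame: np.ndarray, colony_mask: np.ndarray,
                       region_labels: np.ndarray, binary: np.ndarray,
                       dark_cells: bool, species: SpeciesConfig,
                       cfg: SegmentationConfig) -> np.ndarray:
    """Recover the full extent of each segmented cell.

    Adaptive thresholding erodes cells to their dark cores (and can pinch one
    cell into two where neighbours press on it).  The cores are grown back
    over a cell-support mask — colony pixels darker than the midpoint between
    the core and background intensity levels — by a seeded watershed on the
    intensity image, so inter-cell ridges stay put as boundaries.  A final
    puzzle-solving pass over the grown regions rejoins fragments whose union
    is a single valley-free rod.
    """
    from skimage.segmentation import watershed

    core = binary & colony_mask
    if not core.any() or region_labels.max() == 0:
        return region_labels
    inside = frame[core]
    ring = ndi.binary_dilation(colony_mask, iterations=3) & ~colony_mask
    outside = frame[ring] if ring.any() else frame[~colony_mask]
    lo = float(np.median(inside))
    hi = float(np.median(outside)) if outside.size else float(frame.max())
    if not dark_cells:
        lo, hi = hi, lo
    cut = lo + 0.6 * (hi - lo)
    support = colony_mask & ((frame < cut) if dark_cells else (frame > cut))
    support |= region_labels > 0
    relief = frame if dark_cells else -frame
    grown = watershed(relief, markers=region_labels, mask=support)
    return _merge_split_cores(grown, relief, species, abs(hi - lo))


def _merge_split_cores(labels: np.ndarray, relief: np.ndarray,
                       species: SpeciesConfig, contrast: float) -> np.ndarray:
    """Rejoin regions that are two halves of one pinched cell.

    Touching grown regions merge when their union is still a plausible single
    rod AND the shared boundary carries no bright intensity ridge: a genuine
    cell-cell contact shows up as a ridge (cells shade darker toward their
    medial axis), whereas an artificial pinch inside one cell does not.
    """
    labels = labels.copy()
    struct = np.ones((3, 3), dtype=bool)
    queue = sorted(int(v) for v in np.unique(labels) if v != 0)
    alive = set(queue)
    while queue:
        a = queue.pop(0)
        if a not in alive:
            continue
        region_a = labels == a
        grown = ndi.binary_dilation(region_a, structure=struct)
        neighbours = sorted(set(labels[grown & (labels != a) & (labels != 0)].tolist()))
        best = None
        for b in neighbours:
            region_b = labels == b
            merged = region_a | region_b
            # rod-shape guards as in puzzle solving
            tmp = CellObject(colony_id=0, mask=merged, offset=(0, 0))
            if classify_object(tmp, int(round(species.cell_width_px))) == "complex":
                continue
            edt = ndi.distance_transform_edt(merged)
            if edt.max() > 0.80 * species.cell_width_px:
                continue
            pts = np.argwhere(merged)
            ext = pts.max(axis=0) - pts.min(axis=0)
            if math.hypot(*ext) > 2.2 * species.cell_length_px:
                continue
            shared = grown & region_b
            interior = merged & (edt > 1.0)
            if not shared.any() or not interior.any():
                continue
            # darkest fifth of the boundary: a completed division leaves a
            # bright cleavage line all the way across, while a mere septum
            # constriction (still one cell) keeps a dark waist centre
            ridge = (float(np.percentile(relief[shared], 20))
                     - float(np.median(relief[interior])))
            if ridge > 0.22 * contrast:
                continue  # bright ridge: genuine cell-cell boundary
            key = (ridge, int(region_b.sum()), b)
            if best is None or key < best[0]:
                best = (key, b, merged)
        if best is None:
            continue
        _, b, merged = best
        labels[merged] = a
        alive.discard(b)
        queue.append(a)
    return labels


def segment_frame(frame: np.ndarray, colonies, species: SpeciesConfig,
                  cfg: SegmentationConfig, frame_index: int = 0,
                  fluor_frame: np.ndarray | None = None,
                  rng: np.random.Generator | None = None,
                  colony_track_ids: dict[int, int] | None = None,
                  refine: bool = True) -> list[SegmentedCell]:
    """Segment all cells of a preprocessed frame, colony by colony.

    Per-object failures quarantine the object (with a log record) and never
    abort the frame.
    """
    if rng is None:
        rng = np.random.default_rng(cfg.rng_seed)
    dark = species.modality != "fluorescence"
    window = cfg.adaptive_window_px
    if window <= 0:
        # just above the cell width: the local mean then tracks the bright
        # ridges between touching cells instead of averaging them away
        window = int(round(1.7 * species.cell_width_px))
    if window % 2 == 0:
        window += 1
    binary = adaptive_threshold(frame, window, cfg.adaptive_offset, dark_cells=dark)
    cells: list[SegmentedCell] = []
    next_id = 1
    a_min = min_fragment_area(species)
    for colony in colonies:
        local_binary = mask_multiply(binary, colony.mask)
        colony_boundary = colony.mask & ~ndi.binary_erosion(
            colony.mask, structure=np.ones((3, 3), dtype=bool))
        objects = extract_cell_objects(local_binary, colony.colony_id)
        track_id = (colony_track_ids or {}).get(colony.colony_id, colony.colony_id)
        canvas = np.zeros(frame.shape, dtype=np.int32)
        n_regions = 0
        for obj in objects:
            try:
                masks = _segment_object(obj, species, cfg, rng)
            except Exception:  # pragma: no cover - quarantine path
                log.exception("object at %s quarantined", obj.offset)
                continue
            for m in masks:
                r, c = np.nonzero(m)
                if r.size == 0:
                    continue
                n_regions += 1
                canvas[r + obj.offset[0], c + obj.offset[1]] = n_regions
        if n_regions == 0:
            continue
        if refine:
            canvas = _refine_boundaries(frame, colony.mask, canvas, binary,
                                        dark, species, cfg)
            canvas = merge_small_fragments(canvas, a_min, species)
        for sl, rid in zip(ndi.find_objects(canvas), range(1, canvas.max() + 1)):
            if sl is None:
                continue
            local = canvas[sl] == rid
            rows, cols = np.nonzero(local)
            if rows.size == 0:
                continue
            rows = rows + sl[0].start
            cols = cols + sl[1].start
            cy, cx = float(rows.mean()), float(cols.mean())
            length_um, width_um, orient = _region_geometry(rows, cols, local,
                                                           species.cal_factor)
            dist = math.hypot(cy - colony.centroid[0], cx - colony.centroid[1])
            fl_t = fl_m = None
            if fluor_frame is not None:
                vals = fluor_frame[rows, cols]
                fl_t, fl_m = float(vals.sum()), float(vals.mean())
            cells.append(SegmentedCell(
                cell_instant_id=next_id, colony_id=track_id,
                frame=frame_index, rows=rows, cols=cols,
                centroid=(cy, cx), area_px=int(rows.size),
                area_um2=rows.size * species.cal_factor ** 2,
                length_um=length_um, width_um=width_um, orientation=orient,
                dist_to_colony_centroid_um=dist * species.cal_factor,
                on_colony_boundary=bool(colony_boundary[rows, cols].any()),
                fluor_total=fl_t, fluor_mean=fl_m,
                undersized=rows.size < a_min))
            next_id += 1
    return cells
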