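"""Synthetic bacterial cell movies with exact ground truth.

Emulates time-lapse microscopy of rod-shaped bacteria growing in dense 2-D
micro-colonies: each cell is a spherocylinder (a rectangle capped by two
semicircles) that elongates exponentially, constricts into a "bow tie" at the
septum just before division, and splits into two daughters of roughly equal
length.  Crowding is resolved by iterative pairwise repulsion, so colonies
pack into the dense touching-cell regime that makes single-cell segmentation
hard.  Rendering applies a modality-dependent intensity model (dark cells with
a bright halo for phase contrast), Gaussian blur, a multiplicative
illumination gradient and additive Gaussian noise, while the matched label
masks and lineage records stay exact.

All randomness flows through one ``numpy.random.Generator`` keyed by
``SimParams.seed``: identical parameters reproduce a bit-identical movie.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "SimParams",
    "SimCellState",
    "SimMovie",
    "simulate_movie",
    "ground_truth_counts",
    "save_movie",
]


@dataclass
class SimCellState:
    """Ground-truth state of one simulated cell."""

    cell_id: int
    parent_id: int | None
    center: np.ndarray          # (x, y) um
    orientation: float          # radians
    length: float               # um, tip-to-tip
    width: float                # um
    birth_time: float           # min
    k_true: float               # 1/min elongation rate
    l0_true: float              # um birth length
    division_length: float      # um

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        if not (self.length >= self.width > 0):
            raise ValueError("require length >= width > 0")
        if self.k_true <= 0:
            raise ValueError("k_true must be positive")
        if self.division_length <= self.l0_true:
            raise ValueError("division_length must exceed birth length")

    @property
    def axis(self) -> np.ndarray:
        return np.array([np.cos(self.orientation), np.sin(self.orientation)])

    def endpoints(self) -> tuple[np.ndarray, np.ndarray]:
        """Endpoints of the cylinder axis (pole-cap centres)."""
        half = 0.5 * max(self.length - self.width, 0.0)
        return self.center - half * self.axis, self.center + half * self.axis


@dataclass
class SimParams:
    seed: int = 0
    cal_factor: float = 0.125          # um / pixel
    sampling_period: float = 5.0       # min
    n_frames: int = 20
    image_shape: tuple[int, int] = (512, 512)
    n_founders: int = 1
    founder_positions: list[tuple[float, float]] | str = "random"
    cell_width: float = 1.1            # um
    k_mean: float = np.log(2.0) / 25.0  # 1/min -> ~25 min doubling
    k_cv: float = 0.15
    division_length_mean: float = 7.0  # um
    division_length_cv: float = 0.10
    division_jitter: float = 0.02      # sd of 50/50 split fraction
    constriction_depth: float = 0.65   # septum width / full width
    psf_sigma: float = 1.0             # px
    noise_sigma: float = 0.05          # fraction of dynamic range
    illumination_gradient: float = 0.10
    modality: str = "phase-contrast"
    max_cells: int = 0                 # stop once a frame holds >= this many (0 = never)
    max_overlap_frac: float = 0.05     # relaxation target, fraction of width

    def __post_init__(self) -> None:
        if not 0.0 < self.constriction_depth < 1.0:
            raise ValueError("constriction_depth must lie in (0, 1)")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")

    # -- flat key=value round-trip ----------------------------------------

    def save(self, path: str | Path) -> None:
        import dataclasses

        lines = []
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if isinstance(v, np.floating):
                v = float(v)
            elif isinstance(v, np.integer):
                v = int(v)
            lines.append(f"{f.name} = {v!r}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "SimParams":
        import ast

        kw = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            kw[key.strip()] = ast.literal_eval(value.strip())
        if "image_shape" in kw:
            kw["image_shape"] = tuple(kw["image_shape"])
        return cls(**kw)


@dataclass
class SimMovie:
    frames: list[np.ndarray]
    label_masks: list[np.ndarray]
    lineage_truth: list[tuple[int, int, int]]   # (parent_id, child_id, division_frame)
    colony_truth: list[dict[int, int]]          # per frame: cell_id -> colony_id
    colony_merges: list[tuple[int, int, int]]   # (frame, colony_a, colony_b)
    cell_states: list[dict[int, SimCellState]]  # per frame snapshot
    params: SimParams
    truncated: bool = False

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    def founders(self) -> list[int]:
        children = {c for _, c, _ in self.lineage_truth}
        ids = set()
        for frame in self.colony_truth:
            ids.update(frame)
        return sorted(i for i in ids if i not in children)


# ---------------------------------------------------------------------------
# growth and division


def _sample_gamma(rng: np.random.Generator, mean: float, cv: float) -> float:
    """One draw from a gamma distribution parameterized by mean and CV."""
    if cv <= 0:
        return mean
    shape = 1.0 / cv**2
    return float(rng.gamma(shape, mean / shape))


def _new_life(rng: np.random.Generator, p: SimParams, l0: float) -> tuple[float, float]:
    """Sample (k, division_length) for a newborn with birth length l0."""
    k = max(_sample_gamma(rng, p.k_mean, p.k_cv), 0.2 * p.k_mean)
    lf = _sample_gamma(rng, p.division_length_mean, p.division_length_cv)
    lf = max(lf, 1.2 * l0)  # a cell always has room to grow before dividing
    return k, lf


def _make_founders(rng: np.random.Generator, p: SimParams) -> list[SimCellState]:
    h, w = p.image_shape
    extent_x = w * p.cal_factor
    extent_y = h * p.cal_factor
    if p.founder_positions == "random":
        # keep founders in the central half so colonies have room to grow
        xs = rng.uniform(0.25 * extent_x, 0.75 * extent_x, size=p.n_founders)
        ys = rng.uniform(0.25 * extent_y, 0.75 * extent_y, size=p.n_founders)
        positions = list(zip(xs, ys))
    else:
        positions = [tuple(q) for q in p.founder_positions]
        if len(positions) != p.n_founders:
            raise ValueError("founder_positions length must equal n_founders")
    cells = []
    for i, (x, y) in enumerate(positions, start=1):
        l0 = max(_sample_gamma(rng, 0.5 * p.division_length_mean,
                               p.division_length_cv), 1.2 * p.cell_width)
        k, lf = _new_life(rng, p, l0)
        cells.append(SimCellState(
            cell_id=i, parent_id=None, center=np.array([x, y]),
            orientation=float(rng.uniform(0, np.pi)), length=l0,
            width=p.cell_width, birth_time=0.0, k_true=k, l0_true=l0,
            division_length=lf))
    return cells


def _divide(cell: SimCellState, rng: np.random.Generator, p: SimParams,
            next_id: int, now: float) -> list[SimCellState]:
    frac = float(np.clip(rng.normal(0.5, p.division_jitter), 0.35, 0.65))
    lens = (frac * cell.length, (1.0 - frac) * cell.length)
    u = cell.axis
    daughters = []
    offsets = (-0.5 * (cell.length - lens[0]), 0.5 * (cell.length - lens[1]))
    for j, (ld, off) in enumerate(zip(lens, offsets)):
        ld = max(ld, 1.05 * cell.width)
        k, lf = _new_life(rng, p, ld)
        daughters.append(SimCellState(
            cell_id=next_id + j, parent_id=cell.cell_id,
            center=cell.center + off * u,
            orientation=cell.orientation + float(rng.normal(0.0, 0.03)),
            length=ld, width=cell.width, birth_time=now,
            k_true=k, l0_true=ld, division_length=lf))
    return daughters


# ---------------------------------------------------------------------------
# overlap relaxation


def _segment_distances(p1, q1, p2, q2):
    """Vectorized closest-point distance between segment pairs.

    Arguments are (n, 2) arrays of segment endpoints.  Returns (dist, c1, c2)
    with the closest points on either segment.
    """
    d1 = q1 - p1
    d2 = q2 - p2
    r = p1 - p2
    a = np.einsum("ij,ij->i", d1, d1)
    e = np.einsum("ij,ij->i", d2, d2)
    b = np.einsum("ij,ij->i", d1, d2)
    c = np.einsum("ij,ij->i", d1, r)
    f = np.einsum("ij,ij->i", d2, r)
    denom = a * e - b * b
    s = np.where(denom > 1e-12, np.clip((b * f - c * e) / np.where(denom > 1e-12, denom, 1.0), 0, 1), 0.0)
    t = np.where(e > 1e-12, (b * s + f) / np.where(e > 1e-12, e, 1.0), 0.0)
    t = np.clip(t, 0.0, 1.0)
    s = np.where(a > 1e-12, np.clip((b * t - c) / np.where(a > 1e-12, a, 1.0), 0, 1), 0.0)
    c1 = p1 + s[:, None] * d1
    c2 = p2 + t[:, None] * d2
    return np.linalg.norm(c1 - c2, axis=1), c1, c2


def _relax(cells: list[SimCellState], p: SimParams, max_sweeps: int = 80) -> None:
    """Push overlapping spherocylinders apart along their contact normals."""
    n = len(cells)
    if n < 2:
        return
    for _ in range(max_sweeps):
        centers = np.array([c.center for c in cells])
        ends_a = np.empty((n, 2))
        ends_b = np.empty((n, 2))
        for i, c in enumerate(cells):
            a, b = c.endpoints()
            ends_a[i], ends_b[i] = a, b
        lengths = np.array([c.length for c in cells])
        widths = np.array([c.width for c in cells])
        ii, jj = np.triu_indices(n, k=1)
        # coarse prefilter on centre distance
        reach = 0.5 * (lengths[ii] + lengths[jj]) + 0.5 * (widths[ii] + widths[jj])
        d_centers = np.linalg.norm(centers[ii] - centers[jj], axis=1)
        close = d_centers < reach
        ii, jj = ii[close], jj[close]
        if ii.size == 0:
            return
        dist, c1, c2 = _segment_distances(ends_a[ii], ends_b[ii], ends_a[jj], ends_b[jj])
        touch = 0.5 * (widths[ii] + widths[jj])
        overlap = touch - dist
        tol = p.max_overlap_frac * 0.5 * (widths[ii] + widths[jj])
        active = overlap > tol
        if not np.any(active):
            return
        disp = np.zeros((n, 2))
        vec = c1[active] - c2[active]
        norm = np.linalg.norm(vec, axis=1)
        # coincident closest points: push along a fixed direction
        bad = norm < 1e-9
        vec[bad] = (1.0, 0.0)
        norm[bad] = 1.0
        unit = vec / norm[:, None]
        push = 0.55 * overlap[active]
        np.add.at(disp, ii[active], 0.5 * push[:, None] * unit)
        np.add.at(disp, jj[active], -0.5 * push[:, None] * unit)
        for i, c in enumerate(cells):
            c.center = c.center + disp[i]


# ---------------------------------------------------------------------------
# rendering


def _render(cells: list[SimCellState], p: SimParams,
            rng: np.random.Generator, constricting: set[int]):
    """Draw one frame; returns (intensity float image, uint16 label mask)."""
    from scipy.ndimage import gaussian_filter

    h, w = p.image_shape
    cal = p.cal_factor
    labels = np.zeros((h, w), dtype=np.uint16)
    depth = np.full((h, w), -np.inf)      # penetration depth buffer, um
    halo = np.zeros((h, w), dtype=bool)

    for cell in cells:
        a, b = cell.endpoints()
        r0 = 0.5 * cell.width
        pad = r0 + 3 * cal
        lo_x = int(max(np.floor((min(a[0], b[0]) - pad) / cal), 0))
        hi_x = int(min(np.ceil((max(a[0], b[0]) + pad) / cal) + 1, w))
        lo_y = int(max(np.floor((min(a[1], b[1]) - pad) / cal), 0))
        hi_y = int(min(np.ceil((max(a[1], b[1]) + pad) / cal) + 1, h))
        if lo_x >= hi_x or lo_y >= hi_y:
            continue
        xs = (np.arange(lo_x, hi_x) + 0.5) * cal
        ys = (np.arange(lo_y, hi_y) + 0.5) * cal
        gx, gy = np.meshgrid(xs, ys)
        d = b - a
        denom = float(d @ d)
        if denom < 1e-12:
            t = np.zeros_like(gx)
        else:
            t = np.clip(((gx - a[0]) * d[0] + (gy - a[1]) * d[1]) / denom, 0.0, 1.0)
        px = a[0] + t * d[0]
        py = a[1] + t * d[1]
        dist = np.hypot(gx - px, gy - py)
        radius = np.full_like(dist, r0)
        if cell.cell_id in constricting:
            # Gaussian notch: local width scaled to constriction_depth at the
            # septum, over roughly the middle 15% of the centerline
            notch = 1.0 - (1.0 - p.constriction_depth) * np.exp(-((t - 0.5) / 0.0375) ** 2)
            radius = r0 * notch
        pen = radius - dist
        inside = pen > 0
        sl = np.s_[lo_y:hi_y, lo_x:hi_x]
        win_depth = depth[sl]
        win_lab = labels[sl]
        take = inside & (pen > win_depth)
        win_depth[take] = pen[take]
        win_lab[take] = cell.cell_id
        if p.modality == "phase-contrast":
            ring = (~inside) & (dist - radius < 2.0 * cal)
            halo[sl] |= ring

    fg = labels > 0
    # interior shading: cells are darkest along their medial axis and
    # brighten toward the surface, so contact lines between touching cells
    # and constricted septa carry a (faint, blurred) intensity cue — as in
    # real phase-contrast imagery
    rel = np.clip(depth / (0.5 * p.cell_width), 0.0, 1.0)
    if p.modality == "fluorescence":
        img = np.full((h, w), 0.10)
        img[fg] = 0.25 + 0.60 * rel[fg]
    else:
        img = np.full((h, w), 0.75)
        if p.modality == "phase-contrast":
            img[halo & ~fg] = 0.92
        img[fg] = 0.55 - 0.45 * rel[fg]
    if p.illumination_gradient:
        gx = np.linspace(-0.5, 0.5, w)[None, :]
        img = img * (1.0 + p.illumination_gradient * gx)
    if p.psf_sigma > 0:
        img = gaussian_filter(img, p.psf_sigma)
    if p.noise_sigma > 0:
        img = img + rng.normal(0.0, p.noise_sigma, size=img.shape)
    return np.clip(img, 0.0, 1.0), labels


def _touches_border(labels: np.ndarray) -> bool:
    return bool(labels[0, :].any() or labels[-1, :].any()
                or labels[:, 0].any() or labels[:, -1].any())


def _merge_pairs(labels: np.ndarray, colony_of: dict[int, int]) -> set[tuple[int, int]]:
    """Colony pairs whose masks touch (4-adjacency) in this frame."""
    pairs: set[tuple[int, int]] = set()
    cmap = np.zeros(int(labels.max()) + 1, dtype=np.int32)
    for cid, col in colony_of.items():
        cmap[cid] = col
    colmap = cmap[labels]
    for sa, sb in (((np.s_[:-1, :], np.s_[1:, :])), ((np.s_[:, :-1], np.s_[:, 1:]))):
        a, b = colmap[sa], colmap[sb]
        m = (a > 0) & (b > 0) & (a != b)
        if m.any():
            lo = np.minimum(a[m], b[m])
            hi = np.maximum(a[m], b[m])
            pairs.update(zip(lo.tolist(), hi.tolist()))
    return pairs


# ---------------------------------------------------------------------------
# main loop


def simulate_movie(params: SimParams) -> SimMovie:
    """Simulate a cell movie; see module docstring for the growth model."""
    p = params
    rng = np.random.default_rng(p.seed)
    cells = _make_founders(rng, p)
    colony_of_cell = {c.cell_id: i + 1 for i, c in enumerate(cells)}
    next_id = len(cells) + 1

    frames: list[np.ndarray] = []
    masks: list[np.ndarray] = []
    colony_truth: list[dict[int, int]] = []
    merges: list[tuple[int, int, int]] = []
    snapshots: list[dict[int, SimCellState]] = []
    lineage: list[tuple[int, int, int]] = []
    truncated = False
    dt = p.sampling_period

    for f in range(p.n_frames):
        now = f * dt
        # grow
        for c in cells:
            c.length = c.l0_true * np.exp(c.k_true * (now - c.birth_time))
        # divide (possibly repeatedly if a frame interval spans the threshold)
        newborns: list[SimCellState] = []
        survivors: list[SimCellState] = []
        for c in cells:
            if c.length >= c.division_length:
                ds = _divide(c, rng, p, next_id, now)
                next_id += 2
                for d in ds:
                    colony_of_cell[d.cell_id] = colony_of_cell[c.cell_id]
                    lineage.append((c.cell_id, d.cell_id, f))
                newborns.extend(ds)
            else:
                survivors.append(c)
        cells = survivors + newborns
        _relax(cells, p)
        # who will constrict: dividing within the next frame interval
        constricting = {
            c.cell_id for c in cells
            if c.l0_true * np.exp(c.k_true * (now + dt - c.birth_time)) >= c.division_length
        }
        img, labels = _render(cells, p, rng, constricting)
        if _touches_border(labels):
            truncated = True
            break
        frames.append(img)
        masks.append(labels)
        frame_colonies = {c.cell_id: colony_of_cell[c.cell_id] for c in cells}
        colony_truth.append(frame_colonies)
        snapshots.append({c.cell_id: replace(c, center=c.center.copy()) for c in cells})
        for a, b in _merge_pairs(labels, frame_colonies):
            merges.append((f, a, b))
        if p.max_cells and len(cells) >= p.max_cells:
            break

    # drop lineage entries for divisions never rendered
    n_frames = len(frames)
    lineage = [(a, b, fr) for a, b, fr in lineage if fr < n_frames]
    return SimMovie(frames=frames, label_masks=masks, lineage_truth=lineage,
                    colony_truth=colony_truth, colony_merges=merges,
                    cell_states=snapshots, params=p, truncated=truncated)


def ground_truth_counts(movie: SimMovie, frame: int) -> dict[int, int]:
    """Per-colony cell counts at a frame, from the exact labels."""
    if not 0 <= frame < movie.n_frames:
        raise IndexError(f"frame {frame} out of range [0, {movie.n_frames})")
    counts: dict[int, int] = {}
    present = set(np.unique(movie.label_masks[frame]))
    for cid, col in movie.colony_truth[frame].items():
        if cid in present:
            counts[col] = counts.get(col, 0) + 1
    return counts


# ---------------------------------------------------------------------------
# export


def save_movie(movie: SimMovie, out_dir: str | Path) -> None:
    """Write frames + masks (multi-page uint16 TIFF), truth CSVs and params."""
    import tifffile

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stack = np.stack([(f * 65535).astype(np.uint16) for f in movie.frames])
    tifffile.imwrite(out / "frames.tif", stack)
    tifffile.imwrite(out / "labels.tif", np.stack(movie.label_masks))
    with open(out / "lineage_truth.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["parent_id", "child_id", "division_frame"])
        wr.writerows(movie.lineage_truth)
    with open(out / "colony_truth.csv", "w", newline="") as fh:
        wr = csv.writer(fh)
        wr.writerow(["frame", "cell_id", "colony_id"])
        for f, mapping in enumerate(movie.colony_truth):
            for cid, col in sorted(mapping.items()):
                wr.writerow([f, cid, col])
    movie.params.save(out / "params.cfg")
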