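"""Colony mask construction and colony tracking.

A colony is a connected foreground region of the background-corrected frame;
each colony is processed independently downstream (divide and conquer).
Tracking links colonies across frames by the centroid-in-bounding-box rule and
records appear / merge / exit events — colonies can merge or drift out of the
field of view in long movies.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Colony",
    "ColonyTrack",
    "estimate_background",
    "build_colony_mask",
    "extract_colonies",
    "track_colonies",
    "track_movie_colonies",
    "colony_growth_curves",
]


@dataclass
class Colony:
    colony_id: int
    frame: int                       # 0-based internally; reports are 1-based
    mask: np.ndarray                 # binary, full-frame
    bbox: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col), half-open
    centroid: tuple[float, float]    # (row, col) px
    area_px: int
    cal_factor: float = 1.0
    cell_count: int | None = None

    @property
    def area_um2(self) -> float:
        return self.area_px * self.cal_factor**2

    def contains_point(self, row: float, col: float) -> bool:
        r0, c0, r1, c1 = self.bbox
        return r0 <= row < r1 and c0 <= col < c1


@dataclass
class ColonyTrack:
    track_id: int
    members: dict[int, int] = field(default_factory=dict)  # frame -> colony_id
    events: list[tuple[int, str, int | None]] = field(default_factory=list)
    # events: (frame, "appear"|"merge_into"|"exit", other track id or None)

    @property
    def last_frame(self) -> int:
        return max(self.members)

    def closed(self) -> bool:
        return any(ev in ("merge_into", "exit") for _, ev, _ in self.events)


def estimate_background(frame: np.ndarray, ball_radius_px: int,
                        dark_cells: bool = True) -> np.ndarray:
    """Rolling-ball estimate of the smooth background illumination field.

    The ball radius must exceed the cell scale so the ball rolls over cells
    rather than into them; subtracting the estimate flattens large-scale
    illumination.  For optical modalities cells are *dark* on a bright
    background, so the ball is rolled on the inverted image.
    """
    from skimage.restoration import rolling_ball
    from skimage.transform import rescale, resize
    from scipy.ndimage import uniform_filter

    frame = np.asarray(frame, dtype=np.float64)
    work = -frame if dark_cells else frame
    # the ball's vertical extent is in intensity units: stretch intensities
    # (x64) so the ball cannot sink into a cell-width gap, while staying
    # supple enough to follow illumination gradients.
    # The background is smooth by construction, so estimating it at quarter
    # resolution loses nothing and cuts the rolling-ball cost ~16x.
    factor = 4 if ball_radius_px >= 16 else 1
    if factor > 1:
        small = rescale(work, 1.0 / factor, anti_aliasing=True)
        bg_small = rolling_ball(small * 64.0,
                                radius=max(ball_radius_px // factor, 2)) / 64.0
        bg_work = resize(bg_small, work.shape)
    else:
        bg_work = rolling_ball(work * 64.0, radius=ball_radius_px) / 64.0
    bg = -bg_work if dark_cells else bg_work
    # the ball underside is piecewise spherical; light smoothing removes the
    # residual scallops without reintroducing cell-scale structure
    return uniform_filter(bg, size=max(3, ball_radius_px // 2))


def build_colony_mask(corrected: np.ndarray, min_area_px: float = 0.0,
                      dark_cells: bool = True) -> np.ndarray:
    """Binary colony mask from a background-corrected frame.

    Union of Otsu's global foreground and filled Canny edge contours, followed
    by morphological closing and hole filling; connected components below
    ``min_area_px`` (the single-cell area floor) are rejected as specks.
    Returns an all-false mask when the frame carries no structure.
    """
    from scipy import ndimage as ndi
    from skimage import feature, filters, morphology

    corrected = np.asarray(corrected, dtype=np.float64)
    if np.ptp(corrected) < 1e-6:
        return np.zeros(corrected.shape, dtype=bool)
    thr = filters.threshold_otsu(corrected)
    otsu_fg = corrected < thr if dark_cells else corrected > thr
    # guard against Otsu splitting a structure-free frame in half
    if otsu_fg.mean() > 0.5:
        otsu_fg = np.zeros_like(otsu_fg)
    edges = feature.canny(corrected, sigma=2.0)
    filled_edges = ndi.binary_fill_holes(morphology.closing(
        edges, morphology.disk(2)))
    mask = otsu_fg | filled_edges
    mask = morphology.closing(mask, morphology.disk(3))
    mask = ndi.binary_fill_holes(mask)
    # err outward: the mask is a region of interest that downstream stages
    # intersect with, and blur pushes faint cell rims below Otsu's cut
    mask = morphology.dilation(mask, morphology.disk(2))
    if min_area_px > 0:
        lab, n = ndi.label(mask)
        areas = np.bincount(lab.ravel())
        keep = areas >= min_area_px
        keep[0] = False
        mask = keep[lab]
    return mask


def extract_colonies(mask: np.ndarray, frame: int, cal_factor: float = 1.0,
                     min_area_px: float = 0.0) -> list[Colony]:
    """Connected components of a colony mask as Colony records."""
    from scipy import ndimage as ndi

    lab, n = ndi.label(mask)
    colonies = []
    cid = 0
    for i in range(1, n + 1):
        region = lab == i
        area = int(region.sum())
        if area < min_area_px:
            continue
        cid += 1
        rows, cols = np.nonzero(region)
        bbox = (int(rows.min()), int(cols.min()), int(rows.max()) + 1, int(cols.max()) + 1)
        colonies.append(Colony(
            colony_id=cid, frame=frame, mask=region, bbox=bbox,
            centroid=(float(rows.mean()), float(cols.mean())),
            area_px=area, cal_factor=cal_factor))
    return colonies


def track_colonies(prev: list[Colony], curr: list[Colony]):
    """Match colonies of consecutive frames.

    A previous colony matches the current colony whose bounding box contains
    its centroid.  Ambiguity (centroid inside several boxes) is resolved by
    maximal mask overlap, tie to the smaller colony_id.  Returns
    (matching: prev_id -> curr_id, events) where events are
    ("appear", curr_id), ("merge", curr_id, [prev ids]), ("exit", prev_id).
    """
    matching: dict[int, int] = {}
    for pc in prev:
        candidates = [cc for cc in curr if cc.contains_point(*pc.centroid)]
        if not candidates:
            continue
        if len(candidates) > 1:
            candidates.sort(key=lambda cc: (-int((pc.mask & cc.mask).sum()), cc.colony_id))
        matching[pc.colony_id] = candidates[0].colony_id
    events: list[tuple] = []
    matched_curr = set(matching.values())
    for cc in curr:
        if cc.colony_id not in matched_curr:
            events.append(("appear", cc.colony_id))
    by_target: dict[int, list[int]] = {}
    for pid, cid in matching.items():
        by_target.setdefault(cid, []).append(pid)
    for cid, pids in sorted(by_target.items()):
        if len(pids) >= 2:
            events.append(("merge", cid, sorted(pids)))
    for pc in prev:
        if pc.colony_id not in matching:
            events.append(("exit", pc.colony_id))
    return matching, events


def track_movie_colonies(colonies_by_frame: list[list[Colony]]) -> list[ColonyTrack]:
    """Full-movie colony tracking.

    Track ids are persistent; when tracks merge the surviving track is the one
    with the lowest id, and the absorbed tracks close with a ``merge_into``
    event (pre-merge history is retained).
    """
    tracks: list[ColonyTrack] = []
    if not colonies_by_frame:
        return tracks
    track_of: dict[int, int] = {}  # colony_id in current frame -> track_id
    for cid in sorted(c.colony_id for c in colonies_by_frame[0]):
        t = ColonyTrack(track_id=len(tracks) + 1)
        t.members[0] = cid
        t.events.append((0, "appear", None))
        tracks.append(t)
        track_of[cid] = t.track_id
    by_id = {t.track_id: t for t in tracks}
    for f in range(1, len(colonies_by_frame)):
        prev, curr = colonies_by_frame[f - 1], colonies_by_frame[f]
        matching, events = track_colonies(prev, curr)
        new_track_of: dict[int, int] = {}
        # group previous tracks by the current colony they map to
        by_target: dict[int, list[int]] = {}
        for pid, cid in matching.items():
            by_target.setdefault(cid, []).append(track_of[pid])
        for cid, tids in by_target.items():
            tids = sorted(set(tids))
            survivor = by_id[tids[0]]
            survivor.members[f] = cid
            new_track_of[cid] = survivor.track_id
            for tid in tids[1:]:
                by_id[tid].events.append((f, "merge_into", survivor.track_id))
        for ev in events:
            if ev[0] == "appear":
                t = ColonyTrack(track_id=len(tracks) + 1)
                t.members[f] = ev[1]
                t.events.append((f, "appear", None))
                tracks.append(t)
                by_id[t.track_id] = t
                new_track_of[ev[1]] = t.track_id
            elif ev[0] == "exit":
                by_id[track_of[ev[1]]].events.append((f, "exit", None))
        track_of = new_track_of
    return tracks


def colony_growth_curves(track: ColonyTrack,
                         colonies_by_frame: list[list[Colony]],
                         sampling_period: float = 1.0):
    """Per-frame (time_min, area_um2, cell_count) rows for one track."""
    import pandas as pd

    rows = []
    for f in sorted(track.members):
        cid = track.members[f]
        colony = next(c for c in colonies_by_frame[f] if c.colony_id == cid)
        rows.append({
            "frame": f + 1,  # 1-based in reports
            "time_min": f * sampling_period,
            "area_px": colony.area_px,
            "area_um2": colony.area_um2,
            "cell_count": colony.cell_count,
        })
    return pd.DataFrame(rows)
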