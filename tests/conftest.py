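"""Shared fixtures: synthetic movies and drawn shapes.

Heavy artifacts (simulated movies, a fully segmented small movie) are
session-scoped so the suite pays for them once.
"""

from __future__ import annotations

import numpy as np
import pytest

from microcolony.config import PipelineConfig
from microcolony.pipeline import run_pipeline
from microcolony.preprocess import FrameStack
from microcolony.simulate import SimParams, simulate_movie


def draw_rod(shape, length, width, center, theta=0.0, septa=()):
    """Boolean spherocylinder mask; septa = [(axial_frac, depth), ...]."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    # theta = 0 lays the rod along the columns (x axis)
    dy, dx = yy - center[0], xx - center[1]
    t = dx * np.cos(theta) + dy * np.sin(theta)
    half = (length - width) / 2.0
    tc = np.clip(t, -half, half)
    px, py = tc * np.cos(theta), tc * np.sin(theta)
    dist = np.hypot(dy - py, dx - px)
    r = np.full(dist.shape, width / 2.0)
    for pos, depth in septa:
        s = t / max(length - width, 1e-9) + 0.5
        r = r * (1.0 - (1.0 - depth) * np.exp(-((s - pos) / 0.04) ** 2))
    return dist <= r


@pytest.fixture(scope="session")
def rod():
    return draw_rod


@pytest.fixture(scope="session")
def small_movie():
    """One founder grown to ~28 cells; ~26 noisy phase-contrast frames."""
    return simulate_movie(SimParams(seed=3, n_frames=40, n_founders=1,
                                    founder_positions=[(32.0, 32.0)],
                                    max_cells=28))


@pytest.fixture(scope="session")
def clean_movie():
    """Blur-free, noise-free, flat-illumination render of a small colony."""
    return simulate_movie(SimParams(seed=3, n_frames=40, n_founders=1,
                                    founder_positions=[(32.0, 32.0)],
                                    max_cells=24, psf_sigma=0.0,
                                    noise_sigma=0.0, illumination_gradient=0.0))


@pytest.fixture(scope="session")
def three_colony_movie():
    """Three well-separated founders (the multi-colony regime)."""
    return simulate_movie(SimParams(
        seed=4, n_frames=22, n_founders=3,
        founder_positions=[(18.0, 18.0), (46.0, 18.0), (32.0, 46.0)]))


@pytest.fixture(scope="session")
def pipeline_result(small_movie, tmp_path_factory):
    """Full pipeline over the small movie, persisted to a temp run dir."""
    out = tmp_path_factory.mktemp("run")
    stack = FrameStack(frames=small_movie.frames, cal_factor=0.125,
                       sampling_period=5.0)
    res = run_pipeline(stack, PipelineConfig(), out_dir=out)
    return res


@pytest.fixture(scope="session")
def perfect_cells_by_frame(small_movie):
    """SegmentedCell-like records taken directly from ground-truth labels.

    Serves as an error-free segmentation for tracker tests.
    """
    from scipy import ndimage as ndi

    class Det:
        pass

    frames = []
    for f, mask in enumerate(small_movie.label_masks):
        cells = []
        for lab in np.unique(mask):
            if lab == 0:
                continue
            rows, cols = np.nonzero(mask == lab)
            d = Det()
            d.cell_instant_id = int(lab)
            d.colony_id = small_movie.colony_truth[f][int(lab)]
            d.frame = f
            d.rows, d.cols = rows, cols
            d.centroid = (float(rows.mean()), float(cols.mean()))
            d.area_px = int(rows.size)
            cells.append(d)
        frames.append(cells)
    return frames
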