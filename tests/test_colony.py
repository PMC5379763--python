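"""Colony masking, tracking and growth curves."""

import numpy as np
import pytest
from scipy import ndimage as ndi

from microcolony.colony import (build_colony_mask, colony_growth_curves,
                                estimate_background, extract_colonies,
                                track_colonies, track_movie_colonies)
from microcolony.config import SpeciesConfig, min_fragment_area
from microcolony.preprocess import preprocess_frame


class TestBackground:
    def test_constant_frame(self):
        frame = np.full((64, 64), 0.5)
        assert np.abs(estimate_background(frame, 20) - frame).max() < 1e-6

    def test_linear_gradient_recovered(self):
        grad = np.linspace(0.6, 0.8, 128)[None, :] * np.ones((128, 1))
        bg = estimate_background(grad, 40)
        assert np.abs(bg - grad)[:, 5:-5].max() < 0.02

    def test_cell_excluded_from_background(self):
        grad = np.linspace(0.6, 0.8, 128)[None, :] * np.ones((128, 1))
        img = grad.copy()
        img[60:68, 60:88] = 0.3  # one dark cell
        bg = estimate_background(img, 40)
        assert np.abs(bg[62:66, 64:84] - grad[62:66, 64:84]).max() < 0.03

    def test_correction_flattens_flat_regions(self):
        grad = np.linspace(0.55, 0.8, 160)[None, :] * np.ones((160, 1))
        corr = grad - estimate_background(grad, 40)
        assert np.ptp(corr[20:140, 20:140]) < 0.05


class TestColonyMask:
    def test_blank_frame_empty_mask(self):
        assert not build_colony_mask(np.full((64, 64), 0.7)).any()

    def test_single_colony_jaccard(self, small_movie):
        f = small_movie.n_frames - 1
        pp = preprocess_frame(small_movie.frames[f])
        corr = np.clip(pp - estimate_background(pp, 44) + np.median(pp), 0, 1)
        mask = build_colony_mask(corr, min_area_px=60)
        truth = ndi.binary_dilation(small_movie.label_masks[f] > 0,
                                    iterations=int(small_movie.params.psf_sigma) + 1)
        truth = ndi.binary_fill_holes(truth)
        jac = (mask & truth).sum() / (mask | truth).sum()
        assert jac >= 0.9

    def test_three_colonies_three_components(self, three_colony_movie):
        f = three_colony_movie.n_frames - 1
        pp = preprocess_frame(three_colony_movie.frames[f])
        corr = np.clip(pp - estimate_background(pp, 44) + np.median(pp), 0, 1)
        mask = build_colony_mask(corr, min_area_px=60)
        _, n = ndi.label(mask)
        assert n == 3

    def test_coverage_and_leakage(self, small_movie):
        f = small_movie.n_frames - 1
        truth = small_movie.label_masks[f] > 0
        pp = preprocess_frame(small_movie.frames[f])
        corr = np.clip(pp - estimate_background(pp, 44) + np.median(pp), 0, 1)
        mask = build_colony_mask(corr, min_area_px=60)
        assert (mask & truth).sum() / truth.sum() >= 0.99
        assert (mask & ~truth).sum() / (~truth).sum() <= 0.05

    def test_masks_disjoint_within_frame(self, three_colony_movie):
        f = three_colony_movie.n_frames - 1
        pp = preprocess_frame(three_colony_movie.frames[f])
        corr = np.clip(pp - estimate_background(pp, 44) + np.median(pp), 0, 1)
        mask = build_colony_mask(corr, min_area_px=60)
        colonies = extract_colonies(mask, f, 0.125, 60)
        total = np.zeros(mask.shape, dtype=int)
        for c in colonies:
            total += c.mask.astype(int)
        assert total.max() <= 1


def _colonies_from_labels(label_mask, colony_of, frame):
    """Ground-truth colonies for tracking tests."""
    masks = {}
    for cid, col in colony_of.items():
        region = label_mask == cid
        if region.any():
            masks.setdefault(col, np.zeros(label_mask.shape, bool))
            masks[col] |= region
    out = []
    for col, m in sorted(masks.items()):
        rows, cols = np.nonzero(m)
        from microcolony.colony import Colony

        out.append(Colony(colony_id=col, frame=frame, mask=m,
                          bbox=(rows.min(), cols.min(), rows.max() + 1,
                                cols.max() + 1),
                          centroid=(rows.mean(), cols.mean()),
                          area_px=int(m.sum()), cal_factor=0.125))
    return out


class TestTracking:
    def test_identity_matching_no_events(self, three_colony_movie):
        f = three_colony_movie.n_frames - 1
        cols = _colonies_from_labels(three_colony_movie.label_masks[f],
                                     three_colony_movie.colony_truth[f], f)
        matching, events = track_colonies(cols, cols)
        assert matching == {c.colony_id: c.colony_id for c in cols}
        assert events == []

    def test_merge_event_detected(self):
        """Two colonies whose masks fuse produce a merge with both prior ids."""
        a = np.zeros((64, 64), bool)
        b = np.zeros((64, 64), bool)
        a[20:30, 10:28] = True
        b[20:30, 36:54] = True
        fused = np.zeros((64, 64), bool)
        fused[18:32, 8:56] = True
        prev = extract_colonies(a | b, 0)
        curr = extract_colonies(fused, 1)
        _, events = track_colonies(prev, curr)
        merges = [e for e in events if e[0] == "merge"]
        assert merges == [("merge", 1, [1, 2])]

    def test_appear_and_exit_events(self):
        a = np.zeros((64, 64), bool)
        a[10:20, 10:20] = True
        b = np.zeros((64, 64), bool)
        b[40:50, 40:50] = True
        prev = extract_colonies(a, 0)
        curr = extract_colonies(b, 1)
        _, events = track_colonies(prev, curr)
        assert ("appear", 1) in events
        assert ("exit", 1) in events

    def test_track_events_close_tracks(self):
        frames = []
        a = np.zeros((64, 64), bool)
        a[20:30, 10:28] = True
        b = np.zeros((64, 64), bool)
        b[20:30, 36:54] = True
        fused = np.zeros((64, 64), bool)
        fused[18:32, 8:56] = True
        frames.append(extract_colonies(a | b, 0))
        frames.append(extract_colonies(fused, 1))
        frames.append(extract_colonies(fused, 2))
        tracks = track_movie_colonies(frames)
        assert len(tracks) == 2
        survivor = next(t for t in tracks if 2 in t.members)
        absorbed = next(t for t in tracks if t is not survivor)
        assert survivor.track_id == 1  # lowest id survives
        assert any(ev == "merge_into" for _, ev, _ in absorbed.events)
        # no membership after the merge event
        merge_frame = next(f for f, ev, _ in absorbed.events
                           if ev == "merge_into")
        assert all(f < merge_frame for f in absorbed.members)

    def test_merged_area_conserved(self):
        a = np.zeros((64, 64), bool)
        a[20:30, 10:28] = True
        b = np.zeros((64, 64), bool)
        b[20:30, 36:54] = True
        fused = a | b
        fused[20:30, 28:36] = True  # thin bridge closing the gap
        prev = extract_colonies(a | b, 0)
        curr = extract_colonies(fused, 1)
        pre_total = sum(c.area_px for c in prev)
        assert curr[0].area_px == pytest.approx(pre_total, rel=0.30)


class TestGrowthCurves:
    def test_exponential_count_curve(self, pipeline_result):
        import pandas as pd

        track = pipeline_result.colony_tracks[0]
        df = colony_growth_curves(track, pipeline_result.colonies_by_frame,
                                  sampling_period=5.0)
        assert (df["frame"].diff().dropna() > 0).all()
        sub = df[df["cell_count"] > 0]
        y = np.log(sub["cell_count"].to_numpy(dtype=float))
        t = sub["time_min"].to_numpy(dtype=float)
        r = np.corrcoef(t, y)[0, 1]
        assert r ** 2 >= 0.90

    def test_static_series_constant(self):
        fused = np.zeros((64, 64), bool)
        fused[18:32, 8:56] = True
        frames = [extract_colonies(fused, f) for f in range(3)]
        tracks = track_movie_colonies(frames)
        df = colony_growth_curves(tracks[0], frames, sampling_period=5.0)
        assert df["area_px"].nunique() == 1
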