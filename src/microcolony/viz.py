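"""Segmentation overlays: cell contours and attribute colormaps."""

from __future__ import annotations

from pathlib import Path

import numpy as np

__all__ = ["render_overlay", "render_overlays"]


def render_overlay(frame: np.ndarray, cells, attribute: str | None = None,
                   out_path: str | Path | None = None):
    """One frame with cell contours, optionally filled by a numeric attribute.

    Returns the matplotlib figure (saved and closed when ``out_path`` given).
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 7))
    ax.imshow(frame, cmap="gray", vmin=0, vmax=1)
    if attribute is not None:
        values = []
        for c in cells:
            v = getattr(c, attribute, None)
            if v is None:
                available = sorted(k for k in vars(cells[0])
                                   if isinstance(getattr(cells[0], k), (int, float)))
                raise ValueError(
                    f"unknown or unset attribute {attribute!r}; available: {available}")
            values.append(float(v))
        vmin, vmax = (min(values), max(values)) if values else (0, 1)
        span = (vmax - vmin) or 1.0
        cmap = plt.get_cmap("viridis")
        fill = np.zeros(frame.shape + (4,))
        for c, v in zip(cells, values):
            rgba = cmap((v - vmin) / span)
            fill[c.rows, c.cols] = (*rgba[:3], 0.6)
        ax.imshow(fill)
        sm = plt.cm.ScalarMappable(cmap=cmap,
                                   norm=plt.Normalize(vmin=vmin, vmax=vmax))
        fig.colorbar(sm, ax=ax, label=attribute, fraction=0.046)
    # contours
    canvas = np.zeros(frame.shape, dtype=np.int32)
    for i, c in enumerate(cells, start=1):
        canvas[c.rows, c.cols] = i
    from skimage.segmentation import find_boundaries

    edges = find_boundaries(canvas, mode="inner")
    ys, xs = np.nonzero(edges)
    ax.scatter(xs, ys, s=0.2, c="lime", marker=".")
    ax.set_axis_off()
    if out_path is not None:
        fig.savefig(out_path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig


def render_overlays(frames, cells_by_frame, attribute: str | None,
                    out_dir: str | Path) -> list[Path]:
    """Overlay image per frame, named frame_0001.png etc (1-based)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, (frame, cells) in enumerate(zip(frames, cells_by_frame), start=1):
        p = out / f"frame_{i:04d}.png"
        render_overlay(frame, cells, attribute, p)
        paths.append(p)
    return paths
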