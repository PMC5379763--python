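"""Detection-quality metrics against ground-truth label masks.

Cells are counted, not outlined: a detection is a true positive when it and a
ground-truth cell mutually contain each other's centroid (robust to boundary
wiggle, while splits and merges still surface as FP/FN).  Artifacts — noise
blobs or fragments of over-segmented cells — are false positives; missed true
cells are false negatives.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["EvalReport", "match_detections", "metrics"]


@dataclass
class EvalReport:
    TP: int
    FP: int
    FN: int
    TPR: float      # recall
    PPV: float      # precision
    F: float        # harmonic mean of TPR and PPV
    scope: str = "frame"

    def as_percentages(self) -> dict[str, float]:
        return {"recall_pct": round(100 * self.TPR, 1),
                "precision_pct": round(100 * self.PPV, 1),
                "f_measure_pct": round(100 * self.F, 1)}


def match_detections(detected, truth_mask: np.ndarray,
                     shape: tuple[int, int] | None = None,
                     mutual: bool = True):
    """Match detected cells to ground-truth labels by mutual centroid
    containment.

    A detection claims a truth label iff the detection's centroid falls
    inside that (unclaimed) label's region AND the label's centroid falls
    inside the detection's pixel set; each truth label is claimed at most
    once.  Returns (TP, FP, FN).

    ``detected`` is a list of objects with ``rows``/``cols``/``centroid``
    attributes (e.g. SegmentedCell) or of (rows, cols) tuples.  With
    ``mutual=False`` only the forward test is applied — for detections known
    only by their centroid (e.g. re-scored from an exported table).
    """
    truth_mask = np.asarray(truth_mask)
    if shape is not None and truth_mask.shape != shape:
        raise ValueError("truth mask shape mismatch")
    from scipy import ndimage as ndi

    labels = [int(v) for v in np.unique(truth_mask) if v != 0]
    centroids = ndi.center_of_mass(truth_mask > 0, truth_mask, labels)
    truth_centroid = dict(zip(labels, centroids))
    claimed: set[int] = set()
    tp = 0
    for det in detected:
        if hasattr(det, "rows"):
            rows, cols, centroid = det.rows, det.cols, det.centroid
        else:
            rows, cols = det
            centroid = (float(np.mean(rows)), float(np.mean(cols)))
        ri = int(round(centroid[0]))
        ci = int(round(centroid[1]))
        if not (0 <= ri < truth_mask.shape[0] and 0 <= ci < truth_mask.shape[1]):
            continue
        lab = int(truth_mask[ri, ci])
        if lab == 0 or lab in claimed:
            continue
        tr, tc = truth_centroid[lab]
        tri, tci = int(round(tr)), int(round(tc))
        if not mutual or np.any((rows == tri) & (cols == tci)):
            claimed.add(lab)
            tp += 1
    n_det = sum(1 for _ in detected) if not hasattr(detected, "__len__") else len(detected)
    fp = n_det - tp
    fn = len(labels) - tp
    return tp, fp, fn


def metrics(tp: int, fp: int, fn: int, scope: str = "frame") -> EvalReport:
    """TPR = TP/(TP+FN), PPV = TP/(TP+FP), F = 2·PPV·TPR/(PPV+TPR)."""
    if min(tp, fp, fn) < 0:
        raise ValueError("counts must be non-negative")
    if tp + fn == 0:
        raise ValueError("no ground-truth cells (TP+FN = 0)")
    tpr = tp / (tp + fn)
    ppv = tp / (tp + fp) if tp + fp > 0 else float("nan")
    if np.isnan(ppv) or ppv + tpr == 0:
        f = 0.0 if not np.isnan(ppv) else float("nan")
    else:
        f = 2.0 * ppv * tpr / (ppv + tpr)
    return EvalReport(TP=tp, FP=fp, FN=fn, TPR=tpr, PPV=ppv, F=f, scope=scope)
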