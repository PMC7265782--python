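"""Cell-level detection: mask -> centroids, and point-set matching metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.measure import label, regionprops

#: Minimum component area kept as a detection (~10% of a 32 px disc).
DEFAULT_MIN_AREA = 80

#: Matching radius: half the nominal 32 px lymphocyte diameter.
DEFAULT_RADIUS = 16.0


@dataclass
class DetectionResult:
    """One-to-one matching of predicted vs ground-truth centers."""

    tp_pairs: list  # list of (pred_idx, truth_idx)
    fp: list  # unmatched prediction indices
    fn: list  # unmatched truth indices
    precision: float
    recall: float
    f1: float
    undefined: dict = field(default_factory=dict)  # flags for 0/0 conventions

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)


def extract_detections(mask: np.ndarray, min_area: int = DEFAULT_MIN_AREA):
    """Reduce a binary mask to component centroids with area >= min_area.

    Touching nuclei merged into one component yield a single centroid; that
    is a documented limitation of centroid-based extraction.
    """
    lab = label(mask.astype(bool), connectivity=2)
    centers = [
        p.centroid for p in regionprops(lab) if p.area >= min_area
    ]
    return np.asarray(centers, dtype=float).reshape(-1, 2)


def evaluate_detections(
    pred, truth, radius: float = DEFAULT_RADIUS
) -> DetectionResult:
    """Greedy one-to-one matching within ``radius``; precision/recall/F1.

    Candidate pairs are taken in ascending distance order (ties broken by
    (pred index, truth index)); each prediction and each ground-truth point
    is matched at most once. Empty-denominator metrics are reported as 0
    with a flag in ``undefined``.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pred = np.asarray(pred, dtype=float).reshape(-1, 2)
    truth = np.asarray(truth, dtype=float).reshape(-1, 2)
    candidates = []
    for i in range(len(pred)):
        d = np.hypot(*(truth - pred[i]).T) if len(truth) else np.empty(0)
        for j in np.nonzero(d <= radius)[0]:
            candidates.append((d[j], i, int(j)))
    candidates.sort()
    used_p, used_t = set(), set()
    tp_pairs = []
    for _d, i, j in candidates:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        tp_pairs.append((i, j))
    fp = [i for i in range(len(pred)) if i not in used_p]
    fn = [j for j in range(len(truth)) if j not in used_t]
    tp = len(tp_pairs)
    undefined = {}
    if tp + len(fp) > 0:
        precision = tp / (tp + len(fp))
    else:
        precision, undefined["precision"] = 0.0, "no predictions"
    if tp + len(fn) > 0:
        recall = tp / (tp + len(fn))
    else:
        recall, undefined["recall"] = 0.0, "no ground truth"
    if precision + recall > 0:
        f1 = 2 * precision * recall / (precision + recall)
    else:
        f1, undefined["f1"] = 0.0, "zero precision and recall"
    return DetectionResult(tp_pairs, fp, fn, precision, recall, f1, undefined)
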