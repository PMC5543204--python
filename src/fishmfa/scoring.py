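"""HER2/CEP-17 dot counting, status classification, and evaluation metrics.

HER2 status is scored from the average per-nucleus ratio of red (HER2 gene)
to green (CEP-17 centromere) signals inside well-segmented, non-overlapping
interphase nuclei: a mean ratio above 2.2 is HER2 positive, below 1.8 HER2
negative, and anything between (boundaries included) is equivocal and needs
further examination.

Segmentation quality is summarized by the count-ratio accuracy
``segmented / true`` — the number of machine-segmented nuclei over the
number an expert (or, for synthetic scenes, the generator) provides.  For
synthetic benchmarks a segmented region only counts if it overlaps a true
nucleus at IoU >= 0.5, which is what a human evaluator implicitly enforces.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.morphology import disk, white_tophat

__all__ = [
    "DotParams",
    "DotCounts",
    "Her2Result",
    "MatchReport",
    "count_dots",
    "classify_her2",
    "accuracy",
    "match_regions",
]

HER2_POSITIVE_RATIO = 2.2
HER2_NEGATIVE_RATIO = 1.8


@dataclass(frozen=True)
class DotParams:
    """Dot-detection knobs.

    Signals are isolated per channel with a small white top-hat; within each
    nucleus, pixels above both the ``quantile`` of the in-nucleus top-hat
    response and the absolute ``min_response`` floor form candidate blobs,
    and connected components with area in [min_area, max_area] count as
    dots.  The absolute floor keeps noise quantiles in dot-free nuclei from
    producing phantom signals.
    """

    tophat_radius: int = 5
    quantile: float = 0.95
    min_response: float = 0.1
    min_area: int = 1
    max_area: int = 50

    def __post_init__(self) -> None:
        if not (0.0 < self.quantile < 1.0):
            raise ValueError("quantile must lie in (0, 1)")
        if self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1")
        if self.min_area < 1 or self.max_area < self.min_area:
            raise ValueError("invalid dot area bounds")


@dataclass
class DotCounts:
    """Per-nucleus red (HER2) and green (CEP-17) dot tallies."""

    labels: np.ndarray  # nucleus ids, shape (n,)
    red_counts: np.ndarray
    green_counts: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.red_counts < 0) or np.any(self.green_counts < 0):
            raise ValueError("dot counts must be non-negative")

    def as_dict(self) -> dict[int, tuple[int, int]]:
        return {
            int(l): (int(r), int(g))
            for l, r, g in zip(self.labels, self.red_counts, self.green_counts)
        }


@dataclass
class Her2Result:
    """Outcome of HER2 scoring over the scorable nuclei."""

    ratios: np.ndarray  # per scorable nucleus
    mean_ratio: float
    category: str  # positive | negative | equivocal
    n_scorable: int


@dataclass
class MatchReport:
    """Greedy one-to-one IoU matching between two label maps."""

    pairs: list[tuple[int, int, float]]  # (predicted label, true label, IoU)
    n_detected: int
    n_missed: int
    n_spurious: int

    @property
    def detected_true_labels(self) -> list[int]:
        return [t for _, t, _ in self.pairs]


class UnscorableError(ValueError):
    """No nucleus carries a green (CEP-17) signal; the ratio is undefined."""


def _channel_response(channel: np.ndarray, radius: int) -> np.ndarray:
    return white_tophat(np.asarray(channel, dtype=float), disk(radius))


def count_dots(
    rgb: np.ndarray,
    labels: np.ndarray,
    params: DotParams = DotParams(),
) -> DotCounts:
    """Count red and green dots inside each labeled nucleus.

    Counting is confined to the nucleus mask: signals outside every nucleus
    are never counted.  Counts are invariant to relabeling of the map.
    """
    from scipy import ndimage as ndi

    arr = np.asarray(rgb, dtype=float)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError("expected an (M, N, 3) RGB image")
    lab = np.asarray(labels)
    if lab.shape != arr.shape[:2]:
        raise ValueError("label map shape differs from image shape")
    ids = np.unique(lab)
    ids = ids[ids > 0]
    if ids.size == 0:
        return DotCounts(
            labels=np.empty(0, dtype=int),
            red_counts=np.empty(0, dtype=int),
            green_counts=np.empty(0, dtype=int),
        )
    responses = {
        "red": _channel_response(arr[..., 0], params.tophat_radius),
        "green": _channel_response(arr[..., 1], params.tophat_radius),
    }
    red = np.zeros(ids.size, dtype=int)
    green = np.zeros(ids.size, dtype=int)
    for i, nucleus_id in enumerate(ids):
        mask = lab == nucleus_id
        for name, out in (("red", red), ("green", green)):
            resp = responses[name]
            thr = max(float(np.quantile(resp[mask], params.quantile)), params.min_response)
            blobs = mask & (resp >= thr)
            comp, n = ndi.label(blobs)
            if n == 0:
                continue
            areas = np.bincount(comp.ravel())[1:]
            out[i] = int(
                np.sum((areas >= params.min_area) & (areas <= params.max_area))
            )
    return DotCounts(labels=ids.astype(int), red_counts=red, green_counts=green)


def classify_her2(counts: DotCounts, aggregation: str = "mean_of_ratios") -> Her2Result:
    """HER2 status from red/green tallies.

    Nuclei without any green signal are excluded (their ratio is
    undefined).  ``aggregation`` is either the mean of per-nucleus ratios
    (the usual "average ratio") or ``"pooled"`` — total red over total green.
    The decision rule: mean ratio > 2.2 positive, < 1.8 negative, otherwise
    (boundaries included) equivocal.
    """
    scorable = counts.green_counts > 0
    if not np.any(scorable):
        raise UnscorableError("no nucleus with green (CEP-17) signals to score")
    ratios = counts.red_counts[scorable] / counts.green_counts[scorable]
    if aggregation == "mean_of_ratios":
        mean_ratio = float(ratios.mean())
    elif aggregation == "pooled":
        mean_ratio = float(
            counts.red_counts[scorable].sum() / counts.green_counts[scorable].sum()
        )
    else:
        raise ValueError("aggregation must be 'mean_of_ratios' or 'pooled'")
    if mean_ratio > HER2_POSITIVE_RATIO:
        category = "positive"
    elif mean_ratio < HER2_NEGATIVE_RATIO:
        category = "negative"
    else:
        category = "equivocal"
    return Her2Result(
        ratios=ratios,
        mean_ratio=mean_ratio,
        category=category,
        n_scorable=int(scorable.sum()),
    )


def accuracy(segmented_count: int, true_count: int) -> float:
    """Count-ratio segmentation accuracy: segmented / true (true > 0)."""
    if true_count <= 0:
        raise ValueError("accuracy undefined for true_count <= 0")
    return segmented_count / true_count


def match_regions(
    predicted: np.ndarray, truth: np.ndarray, iou_min: float = 0.5
) -> MatchReport:
    """Greedy one-to-one matching of predicted to true regions by IoU.

    Candidate pairs are ranked by descending IoU; each predicted and each
    true region participates in at most one pair; pairs below ``iou_min``
    are discarded.  Unmatched true regions are misses, unmatched predicted
    regions are spurious.
    """
    pred = np.asarray(predicted)
    true = np.asarray(truth)
    if pred.shape != true.shape:
        raise ValueError("label map shapes differ")
    if not (0.0 < iou_min <= 1.0):
        raise ValueError("iou_min must lie in (0, 1]")
    pred_ids = np.unique(pred)
    pred_ids = pred_ids[pred_ids > 0]
    true_ids = np.unique(true)
    true_ids = true_ids[true_ids > 0]
    candidates = []
    pred_areas = {int(p): int((pred == p).sum()) for p in pred_ids}
    true_areas = {int(t): int((true == t).sum()) for t in true_ids}
    # only pairs that actually overlap can have IoU > 0
    overlap: dict[tuple[int, int], int] = {}
    both = (pred > 0) & (true > 0)
    for p, t in zip(pred[both].ravel(), true[both].ravel()):
        overlap[(int(p), int(t))] = overlap.get((int(p), int(t)), 0) + 1
    for (p, t), inter in overlap.items():
        union = pred_areas[p] + true_areas[t] - inter
        iou = inter / union
        if iou >= iou_min:
            candidates.append((iou, p, t))
    candidates.sort(key=lambda x: (-x[0], x[1], x[2]))
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int, float]] = []
    for iou, p, t in candidates:
        if p in used_p or t in used_t:
            continue
        used_p.add(p)
        used_t.add(t)
        pairs.append((p, t, float(iou)))
    return MatchReport(
        pairs=pairs,
        n_detected=len(pairs),
        n_missed=int(len(true_ids) - len(pairs)),
        n_spurious=int(len(pred_ids) - len(pairs)),
    )
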