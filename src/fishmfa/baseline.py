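"""Intensity-thresholding baseline ("OTHER") segmentation pipeline.

The comparison front-end follows the classical recipe for FISH nuclei:
optional square-root intensity compression, morphological opening, white
top-hat background flattening, and a global threshold (Otsu by default, or
a fixed level).  Everything downstream of binarization — hole filling,
opening, watershed splitting, geometric region filtering — is the *same
code path* as the IMFA pipeline, so accuracy differences between the two
are attributable solely to the binarization front-end.

Global intensity thresholds are the weak point under uneven illumination:
with a strong lateral ramp, dim-side nuclei fall below any threshold that
still excludes bright-side background.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.filters import threshold_otsu
from skimage.morphology import disk, opening, white_tophat

from .segmentation import (
    SegmentationParams,
    SegmentationResult,
    extract_blue,
    filter_regions,
    refine_mask,
    split_touching,
)

__all__ = ["BaselineParams", "fixed_threshold_binarize", "otsu_threshold", "baseline_segment"]


@dataclass(frozen=True)
class BaselineParams:
    """Front-end knobs plus the shared post-processing parameters.

    ``tophat_radius`` is at the 1016 x 896 reference resolution and scales
    linearly with image side, like the shared geometric parameters.  With
    ``use_sqrt_transform`` and ``use_tophat`` both off and
    ``threshold_mode='fixed'`` the front-end degenerates to simple global
    thresholding of the blue channel.
    """

    use_sqrt_transform: bool = True
    use_tophat: bool = True
    tophat_radius: int = 40
    threshold_mode: str = "otsu"
    fixed_threshold: float = 0.2
    shared: SegmentationParams = field(default_factory=SegmentationParams)

    def __post_init__(self) -> None:
        if self.tophat_radius < 1:
            raise ValueError("tophat_radius must be >= 1")
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError("threshold_mode must be 'otsu' or 'fixed'")
        if not (0.0 <= self.fixed_threshold <= 1.0):
            raise ValueError("fixed_threshold must lie in [0, 1]")


def fixed_threshold_binarize(img: np.ndarray, t: float) -> np.ndarray:
    """Simple global binarization: mask = (intensity >= t), t in [0, 1]."""
    if not (0.0 <= t <= 1.0):
        raise ValueError("threshold must lie in [0, 1]")
    return np.asarray(img, dtype=float) >= t


def otsu_threshold(img: np.ndarray) -> float:
    """Otsu's between-class-variance-maximizing global threshold.

    Accepts float images in [0, 1] or integer images; the histogram
    convention follows scikit-image (256 bins over the data range).
    """
    return float(threshold_otsu(np.asarray(img)))


def baseline_segment(
    rgb: np.ndarray, params: BaselineParams = BaselineParams()
) -> SegmentationResult:
    """Segment nuclei with the intensity-thresholding front-end.

    Blue channel -> optional sqrt transform -> opening -> optional white
    top-hat -> global threshold, then the shared refine / split / filter
    stages.  The result mirrors :func:`fishmfa.segmentation.segment_nuclei`
    (``alpha_image`` and ``alpha_threshold`` are ``None`` here).
    """
    blue = extract_blue(rgb)
    img = np.sqrt(blue) if params.use_sqrt_transform else blue
    shared = params.shared
    if shared.opening_radius > 0:
        img = opening(img, disk(shared.opening_radius))
    if params.use_tophat:
        r = max(1, int(round(params.tophat_radius * shared.linear_scale(blue.shape))))
        img = white_tophat(img, disk(r))
    if params.threshold_mode == "otsu":
        t = otsu_threshold(img)
    else:
        t = params.fixed_threshold
    initial = img >= t
    refined = refine_mask(initial, shared)
    labels0 = split_touching(refined, shared)
    final, stats = filter_regions(labels0, shared)
    return SegmentationResult(
        labels=final,
        regions=stats,
        alpha_image=None,
        alpha_threshold=None,
        initial_mask=initial,
        refined_mask=refined,
        params=shared,
    )
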