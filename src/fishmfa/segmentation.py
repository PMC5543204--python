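"""Nuclei segmentation by inverse multifractal analysis (IMFA).

The pipeline follows the semi-automatic procedure for DAPI-stained FISH
fields: extract the blue channel, build the alpha-image (per-pixel Hölder
exponents), hard-threshold it at alpha_T = factor * alpha_min (default factor
1.1; useful range roughly 1.05-1.14), fill holes and open the binary mask,
split touching nuclei with a distance-transform / marker-controlled
watershed, and reject small, non-oval and border regions.  Because Hölder
exponents respond to local intensity *structure* rather than absolute
brightness, the initial binarization is insensitive to slowly varying
(multiplicative) illumination — the regime in which global intensity
thresholds fail.

The interactive refinement loop of the original procedure (inspect, adjust
the threshold, drop non-nuclei) is realized by re-running with a different
``alpha_threshold_factor`` and by :func:`drop_labels`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.measure import regionprops
from skimage.morphology import disk
from skimage.segmentation import find_boundaries, watershed

from .multifractal import INTENSITY_FLOOR, AlphaImage, ScaleSet, compute_alpha_image

__all__ = [
    "SegmentationParams",
    "RegionStats",
    "SegmentationResult",
    "extract_blue",
    "threshold_alpha",
    "refine_mask",
    "split_touching",
    "filter_regions",
    "segment_nuclei",
    "overlay_contours",
    "drop_labels",
]

#: Resolution the pixel-unit defaults (areas, window ladders) refer to.
REFERENCE_SHAPE = (1016, 896)


@dataclass(frozen=True)
class SegmentationParams:
    """Tunables of the IMFA pipeline, with defaults at 1016 x 896.

    ``min_area`` and ``scale_ladder`` are expressed at the reference
    resolution and are scaled to the image actually processed (areas with
    the pixel-count ratio, window sides with the linear ratio): nuclei
    imaged at half resolution cover a quarter of the pixels, and the
    analysis windows must straddle the nucleus rim at whatever sampling the
    image has.
    """

    alpha_threshold_factor: float = 1.1
    opening_radius: int = 2
    min_area: int = 400
    max_eccentricity: float = 0.95
    reject_border: bool = True
    watershed_min_peak_distance: int = 10
    scale_ladder: tuple[int, ...] = (1, 13, 29, 45, 61)
    intensity_floor: float = INTENSITY_FLOOR

    def __post_init__(self) -> None:
        if self.alpha_threshold_factor <= 1.0:
            raise ValueError("alpha_threshold_factor must exceed 1 (alpha_T > alpha_min)")
        if self.min_area < 1:
            raise ValueError("min_area must be >= 1")
        if not (0.0 < self.max_eccentricity < 1.0):
            raise ValueError("max_eccentricity must lie in (0, 1)")
        if self.opening_radius < 0:
            raise ValueError("opening_radius must be >= 0")

    # -- resolution scaling -------------------------------------------
    def linear_scale(self, shape: tuple[int, int]) -> float:
        return math.sqrt(
            (shape[0] * shape[1]) / (REFERENCE_SHAPE[0] * REFERENCE_SHAPE[1])
        )

    def effective_min_area(self, shape: tuple[int, int]) -> int:
        ratio = (shape[0] * shape[1]) / (REFERENCE_SHAPE[0] * REFERENCE_SHAPE[1])
        return max(1, int(round(self.min_area * ratio)))

    def effective_scales(self, shape: tuple[int, int]) -> ScaleSet:
        lin = self.linear_scale(shape)
        sides = []
        for s in self.scale_ladder:
            v = max(1, int(round(s * lin)))
            if v % 2 == 0:
                v += 1
            if v not in sides:
                sides.append(v)
        if len(sides) < 2:
            sides = [1, 3]
        return ScaleSet(tuple(sorted(sides)))


@dataclass
class RegionStats:
    """Geometry of one candidate region and the filter verdict.

    ``label`` is the region's id in the *returned* label map for retained
    regions and 0 for rejected ones; the centroid identifies rejected
    regions.  ``rejection_reason`` is ``None`` for retained regions,
    otherwise the first failing filter in the fixed order
    small -> non_oval -> border.
    """

    label: int
    area: int
    eccentricity: float
    touches_border: bool
    centroid: tuple[float, float]
    rejection_reason: str | None


@dataclass
class SegmentationResult:
    """Final label map plus every intermediate needed for audit."""

    labels: np.ndarray
    regions: list[RegionStats]
    alpha_image: AlphaImage | None
    alpha_threshold: float | None
    initial_mask: np.ndarray
    refined_mask: np.ndarray
    params: SegmentationParams

    @property
    def n_nuclei(self) -> int:
        return int(self.labels.max())


def extract_blue(rgb: np.ndarray) -> np.ndarray:
    """Blue channel of an RGB image, unit-normalized to [0, 1] floats.

    Accepts float arrays in [0, 1] or integer arrays (8/16-bit), shape
    (M, N, 3).
    """
    arr = np.asarray(rgb)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (M, N, 3) RGB image, got shape {arr.shape}")
    blue = arr[..., 2]
    if np.issubdtype(blue.dtype, np.integer):
        return blue.astype(float) / float(np.iinfo(blue.dtype).max)
    blue = blue.astype(float)
    if blue.min() < 0 or blue.max() > 1:
        raise ValueError("float RGB images must be unit-normalized to [0, 1]")
    return blue


def threshold_alpha(alpha_img: AlphaImage, factor: float) -> np.ndarray:
    """Initial binarization: keep pixels with alpha <= factor * alpha_min.

    Pixels above the threshold are background; the survivors are candidate
    nuclei.  Masks are nested in ``factor``: a higher threshold selects
    more detail.
    """
    if factor <= 1.0:
        raise ValueError("threshold factor must exceed 1")
    return alpha_img.alpha <= factor * alpha_img.alpha_min


def refine_mask(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Close small gaps, fill interior holes, then open.

    The initial alpha-threshold mask outlines nuclei as rings (the rim is
    where local regularity drops fastest); a closing with the same disk as
    the opening bridges one-to-few-pixel ring gaps so that hole filling can
    recover the full nucleus body.  The final opening removes specks and
    thin spurs.
    """
    m = np.asarray(mask, dtype=bool)
    if params.opening_radius > 0:
        selem = disk(params.opening_radius)
        m = ndi.binary_closing(m, structure=selem)
    filled = ndi.binary_fill_holes(m)
    if params.opening_radius == 0:
        return filled
    return ndi.binary_opening(filled, structure=disk(params.opening_radius))


def split_touching(mask: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Split touching nuclei with a marker-controlled watershed.

    Markers are distance-transform maxima separated by at least
    ``watershed_min_peak_distance`` pixels; the watershed floods the negated
    distance inside the mask.  Components that received no marker (smaller
    than the peak separation) are kept whole.  Labels are contiguous 1..K.
    """
    m = np.asarray(mask, dtype=bool)
    if not m.any():
        return np.zeros(m.shape, dtype=np.int32)
    distance = ndi.distance_transform_edt(m)
    # slight smoothing removes spurious ridge maxima caused by boundary
    # wiggles, which would oversplit convex nuclei
    smoothed = ndi.gaussian_filter(distance, sigma=2.0)
    peaks = peak_local_max(
        smoothed,
        min_distance=params.watershed_min_peak_distance,
        exclude_border=False,
        labels=m,
    )
    markers = np.zeros(m.shape, dtype=np.int32)
    for i, (r, c) in enumerate(peaks, start=1):
        markers[r, c] = i
    labels = watershed(-distance, markers=markers, mask=m)
    # components without any marker would vanish; keep them whole
    leftover = m & (labels == 0)
    if leftover.any():
        extra, n_extra = ndi.label(leftover)
        labels = labels + np.where(extra > 0, extra + labels.max(), 0)
    return _relabel_contiguous(labels)


def _relabel_contiguous(labels: np.ndarray) -> np.ndarray:
    ids = np.unique(labels)
    ids = ids[ids > 0]
    out = np.zeros_like(labels, dtype=np.int32)
    for new, old in enumerate(ids, start=1):
        out[labels == old] = new
    return out


def filter_regions(
    labels: np.ndarray, params: SegmentationParams
) -> tuple[np.ndarray, list[RegionStats]]:
    """Reject small, non-oval and border regions; relabel survivors.

    Each rejected region carries exactly one reason — the first failing
    filter in the order small -> non_oval -> border.  Survivors are
    relabeled 1..K in raster order of their centroids, which makes the
    numbering reproducible.
    """
    lab = np.asarray(labels)
    M, N = lab.shape
    min_area = params.effective_min_area((M, N))
    keep: list[tuple[tuple[float, float], int]] = []
    stats: list[RegionStats] = []
    for rp in regionprops(lab):
        touches = (
            rp.bbox[0] == 0 or rp.bbox[1] == 0 or rp.bbox[2] == M or rp.bbox[3] == N
        )
        reason = None
        if rp.area < min_area:
            reason = "small"
        elif rp.eccentricity > params.max_eccentricity:
            reason = "non_oval"
        elif params.reject_border and touches:
            reason = "border"
        stats.append(
            RegionStats(
                label=0,
                area=int(rp.area),
                eccentricity=float(rp.eccentricity),
                touches_border=bool(touches),
                centroid=(float(rp.centroid[0]), float(rp.centroid[1])),
                rejection_reason=reason,
            )
        )
        if reason is None:
            keep.append((rp.centroid, rp.label))
    keep.sort(key=lambda t: (t[0][0], t[0][1]))
    out = np.zeros_like(lab, dtype=np.int32)
    old_to_new = {}
    for new, (_, old) in enumerate(keep, start=1):
        out[lab == old] = new
        old_to_new[old] = new
    # point retained stats at their new label (match by centroid order)
    retained = [s for s in stats if s.rejection_reason is None]
    retained.sort(key=lambda s: (s.centroid[0], s.centroid[1]))
    for new, s in enumerate(retained, start=1):
        s.label = new
    return out, stats


def segment_nuclei(
    rgb: np.ndarray,
    params: SegmentationParams = SegmentationParams(),
    scales: ScaleSet | None = None,
) -> SegmentationResult:
    """Full IMFA segmentation of an RGB FISH image.

    Composes blue-channel extraction, alpha-image computation, hard
    thresholding at alpha_T = factor * alpha_min, morphological refinement,
    watershed splitting and geometric filtering.  Deterministic for fixed
    inputs and parameters.
    """
    blue = extract_blue(rgb)
    if scales is None:
        scales = params.effective_scales(blue.shape)
    alpha_img = compute_alpha_image(blue, scales=scales, floor=params.intensity_floor)
    initial = threshold_alpha(alpha_img, params.alpha_threshold_factor)
    refined = refine_mask(initial, params)
    labels0 = split_touching(refined, params)
    final, stats = filter_regions(labels0, params)
    return SegmentationResult(
        labels=final,
        regions=stats,
        alpha_image=alpha_img,
        alpha_threshold=params.alpha_threshold_factor * alpha_img.alpha_min,
        initial_mask=initial,
        refined_mask=refined,
        params=params,
    )


def drop_labels(labels: np.ndarray, ids: list[int] | tuple[int, ...]) -> np.ndarray:
    """Remove listed regions (manual rejection); other ids are unchanged."""
    out = np.array(labels, copy=True)
    out[np.isin(out, list(ids))] = 0
    return out


CONTOUR_COLOR = (255, 255, 0)  # yellow

# 3 x 5 bitmap digits for label numerals
_DIGITS = {
    "0": ("111", "101", "101", "101", "111"),
    "1": ("010", "110", "010", "010", "111"),
    "2": ("111", "001", "111", "100", "111"),
    "3": ("111", "001", "111", "001", "111"),
    "4": ("101", "101", "111", "001", "001"),
    "5": ("111", "100", "111", "001", "111"),
    "6": ("111", "100", "111", "101", "111"),
    "7": ("111", "001", "010", "010", "010"),
    "8": ("111", "101", "111", "101", "111"),
    "9": ("111", "101", "111", "001", "111"),
}


def _draw_number(img: np.ndarray, text: str, row: int, col: int, color) -> None:
    c0 = col
    for ch in text:
        glyph = _DIGITS.get(ch)
        if glyph is None:
            continue
        for dr, line in enumerate(glyph):
            for dc, bit in enumerate(line):
                if bit == "1":
                    r, c = row + dr, c0 + dc
                    if 0 <= r < img.shape[0] and 0 <= c < img.shape[1]:
                        img[r, c] = color
        c0 += 4


def overlay_contours(rgb: np.ndarray, labels: np.ndarray) -> np.ndarray:
    """Superimpose region contours and label numerals on the RGB image.

    Returns an 8-bit copy with inner region boundaries drawn in a fixed
    color and each region's number at its centroid; all other pixels keep
    their original values.
    """
    arr = np.asarray(rgb)
    if arr.shape[:2] != labels.shape:
        raise ValueError("image and label map shapes differ")
    if np.issubdtype(arr.dtype, np.floating):
        out = np.clip(arr * 255.0 + 0.5, 0, 255).astype(np.uint8)
    else:
        out = arr.astype(np.uint8).copy()
    if labels.max() == 0:
        return out
    boundary = find_boundaries(labels, mode="inner")
    out[boundary] = CONTOUR_COLOR
    for rp in regionprops(np.asarray(labels)):
        r, c = int(rp.centroid[0]), int(rp.centroid[1])
        _draw_number(out, str(rp.label), r - 2, c - 1, CONTOUR_COLOR)
    return out
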