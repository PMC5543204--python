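"""Per-pixel Hölder exponents, multifractal spectra and box-counting dimension.

The local (Hölder) exponent of a measure mu at a pixel is the limiting ratio
ln mu(B_eps) / ln eps over boxes B_eps of shrinking normalized side eps.  For a
grayscale image the measure of a box is taken as the sum of pixel intensities
inside it, normalized by the total intensity of the image ("sum capacity").
At finite resolution the exponent is estimated as the slope of a least-squares
line of ln mu against ln eps over a small set of window sizes centred on the
pixel.  The matrix of exponents — the *alpha-image* — is in one-to-one
correspondence with the image pixels: smooth, locally dense structure maps to
low alpha, singular or rough structure to high alpha.  The global counterpart,
the multifractal (singularity) spectrum f(alpha), is the box-counting
dimension of the set of pixels sharing a given exponent.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage as ndi

__all__ = [
    "INTENSITY_FLOOR",
    "ScaleSet",
    "MeasureStack",
    "AlphaImage",
    "MfSpectrum",
    "as_gray_image",
    "compute_measures",
    "compute_alpha_image",
    "compute_spectrum",
    "box_counting_dimension",
    "rescale_for_display",
    "multiplicative_cascade",
    "sierpinski_carpet",
]

#: One gray level on 8-bit data, added to every pixel before normalization so
#: that every box measure is strictly positive (ln mu must be defined).
INTENSITY_FLOOR = 1.0 / 255.0

#: Embedding dimension of an image: f(alpha) and alpha of a uniform measure
#: are bounded by the dimension of the plane.
EMBEDDING_DIM = 2.0


@dataclass(frozen=True)
class ScaleSet:
    """Odd, centred window sides used for the log-log regressions.

    Parameters
    ----------
    window_sides
        Ordered box side lengths in pixels.  At least two distinct odd
        values are required so a slope can be fitted.
    normalization_length
        Length L dividing the sides to obtain normalized eps <= 1.  When
        ``None`` (default) L = max(M, N) of the image the scales are
        applied to.
    """

    window_sides: tuple[int, ...] = (1, 3, 5, 7)
    normalization_length: int | None = None

    def __post_init__(self) -> None:
        sides = tuple(int(s) for s in self.window_sides)
        if len(set(sides)) < 2:
            raise ValueError("at least 2 distinct window sides are required")
        if any(s < 1 or s % 2 == 0 for s in sides):
            raise ValueError(f"window sides must be odd and >= 1, got {sides}")
        if list(sides) != sorted(sides):
            raise ValueError("window sides must be in increasing order")
        object.__setattr__(self, "window_sides", sides)
        if self.normalization_length is not None and self.normalization_length < max(sides):
            raise ValueError("normalization_length smaller than the largest window")

    def length_for(self, shape: tuple[int, int]) -> int:
        if self.normalization_length is not None:
            return int(self.normalization_length)
        return int(max(shape))

    def epsilons(self, shape: tuple[int, int]) -> np.ndarray:
        """Normalized box sides eps_k = side_k / L, all in (0, 1]."""
        L = self.length_for(shape)
        eps = np.asarray(self.window_sides, dtype=float) / L
        if np.any(eps > 1.0):
            raise ValueError("window side exceeds the normalization length")
        return eps

    def validate_for(self, shape: tuple[int, int]) -> None:
        if max(self.window_sides) > min(shape):
            raise ValueError(
                f"largest window {max(self.window_sides)} exceeds image extent {min(shape)}"
            )


@dataclass
class MeasureStack:
    """Normalized window measures mu_k(m, n), one grid per scale."""

    measures: np.ndarray  # (n_scales, M, N)
    scales: ScaleSet
    floor: float

    def __post_init__(self) -> None:
        if np.any(self.measures <= 0):
            raise ValueError("box measures must be strictly positive")


@dataclass
class AlphaImage:
    """Grid of per-pixel Hölder exponents with cached extremes."""

    alpha: np.ndarray
    source_shape: tuple[int, int] = None  # type: ignore[assignment]
    alpha_min: float = field(init=False)
    alpha_max: float = field(init=False)

    def __post_init__(self) -> None:
        self.alpha = np.asarray(self.alpha, dtype=float)
        if self.alpha.ndim != 2:
            raise ValueError("alpha grid must be 2-D")
        if not np.all(np.isfinite(self.alpha)):
            raise ValueError("alpha grid contains non-finite values")
        if self.source_shape is None:
            self.source_shape = self.alpha.shape
        elif tuple(self.source_shape) != self.alpha.shape:
            raise ValueError("alpha grid shape differs from source image shape")
        self.alpha_min = float(self.alpha.min())
        self.alpha_max = float(self.alpha.max())


@dataclass
class MfSpectrum:
    """Sampled multifractal spectrum (alpha, f(alpha)).

    ``f_values`` holds NaN for bins that were empty at every scale; no value
    is fabricated for them.  ``box_counts`` retains the raw per-scale,
    per-bin counts N_eps(alpha_i) for audit.
    """

    alpha_bins: np.ndarray
    f_values: np.ndarray
    box_counts: np.ndarray  # (n_scales, n_bins)
    scales: ScaleSet

    @property
    def n_bins(self) -> int:
        return len(self.alpha_bins)

    def peak(self) -> tuple[float, float]:
        """(alpha, f) at the spectrum mode; NaN bins ignored.

        Ties in f (several bins reaching the embedding dimension) are broken
        by the finest-scale box count, so the reported peak is the most
        populous exponent class.
        """
        fmax = np.nanmax(self.f_values)
        tied = np.flatnonzero(np.nan_to_num(self.f_values, nan=-np.inf) >= fmax - 1e-9)
        i = int(tied[np.argmax(self.box_counts[0, tied])])
        return float(self.alpha_bins[i]), float(self.f_values[i])


def as_gray_image(img: np.ndarray) -> np.ndarray:
    """Validate and return a unit-normalized 2-D float image.

    Intensities must lie in [0, 1] and both sides must be >= 8 pixels —
    smaller inputs offer too few scales for the regressions.
    """
    arr = np.asarray(img, dtype=float)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if arr.shape[0] < 8 or arr.shape[1] < 8:
        raise ValueError(f"image too small for multiscale analysis: {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError("image contains non-finite values")
    if arr.min() < 0.0 or arr.max() > 1.0:
        raise ValueError("intensities must be unit-normalized to [0, 1]")
    return arr


def _window_sums(img: np.ndarray, side: int) -> np.ndarray:
    # uniform_filter returns the window mean; 'mirror' reflects without
    # repeating the edge pixel (matches np.pad mode='reflect').
    return ndi.uniform_filter(img, size=side, mode="mirror") * float(side * side)


def compute_measures(
    img: np.ndarray,
    scales: ScaleSet = ScaleSet(),
    floor: float = INTENSITY_FLOOR,
) -> MeasureStack:
    """Normalized sum-capacity measures over centred windows at every scale.

    mu_k(m, n) = (sum of floored intensities in the side-k window centred at
    (m, n)) / (total floored intensity of the image).  Windows reaching
    outside the image are mirror-padded.  The additive ``floor`` guarantees
    mu > 0 on images with true zeros; pass ``floor=0`` for inputs that are
    already strictly positive measures.
    """
    arr = as_gray_image(img)
    scales.validate_for(arr.shape)
    scales.epsilons(arr.shape)  # raises if a side exceeds L
    floored = arr + float(floor)
    total = floored.sum()
    if total <= 0:
        raise ValueError("image has zero total measure; use a positive floor")
    stack = np.stack([_window_sums(floored, s) / total for s in scales.window_sides])
    return MeasureStack(measures=stack, scales=scales, floor=float(floor))


def _slope(x: np.ndarray, y: np.ndarray, axis: int = 0) -> np.ndarray:
    """Least-squares line slope of y against x (x broadcast along axis)."""
    xm = x.mean()
    dx = x - xm
    denom = float((dx * dx).sum())
    shape = [1] * y.ndim
    shape[axis] = len(x)
    dxr = dx.reshape(shape)
    ym = y.mean(axis=axis, keepdims=True)
    return ((y - ym) * dxr).sum(axis=axis) / denom


def compute_alpha_image(
    img: np.ndarray,
    scales: ScaleSet = ScaleSet(),
    floor: float = INTENSITY_FLOOR,
) -> AlphaImage:
    """Estimate the alpha-image: per-pixel slope of ln mu_k against ln eps_k.

    A constant positive image yields alpha = 2 everywhere (the measure is
    uniform, mu proportional to eps^2).
    """
    stack = compute_measures(img, scales=scales, floor=floor)
    eps = scales.epsilons(img.shape)
    log_eps = np.log(eps)
    log_mu = np.log(stack.measures)
    alpha = _slope(log_eps, log_mu, axis=0)
    return AlphaImage(alpha=alpha, source_shape=img.shape)


def _tile_means(arr: np.ndarray, side: int) -> np.ndarray:
    """Means of disjoint side x side tiles; the ragged edge is dropped."""
    m = (arr.shape[0] // side) * side
    n = (arr.shape[1] // side) * side
    if m == 0 or n == 0:
        return np.empty((0, 0))
    blocks = arr[:m, :n].reshape(m // side, side, n // side, side)
    return blocks.mean(axis=(1, 3))


def compute_spectrum(
    alpha_img: AlphaImage,
    scales: ScaleSet = ScaleSet(),
    n_bins: int = 100,
) -> MfSpectrum:
    """Histogram-method multifractal spectrum from an alpha-image.

    The alpha range is split into ``n_bins`` equal bins.  For each scale the
    image is tiled into disjoint eps x eps boxes, each box carries the mean
    alpha of its pixels, and the boxes falling in each bin are counted.
    f(alpha_i) is the slope of ln N_eps(alpha_i) against -ln eps; estimates
    are clamped at the embedding dimension 2 (a subset of the plane cannot
    have a larger box dimension; finite-scale regressions can overshoot).
    Bins empty at every scale are NaN.  A constant alpha-image collapses to a
    single occupied bin.
    """
    if n_bins < 10:
        raise ValueError("n_bins must be >= 10")
    a = alpha_img.alpha
    lo, hi = alpha_img.alpha_min, alpha_img.alpha_max
    degenerate = hi - lo < 1e-12
    if degenerate:
        edges = np.array([lo - 0.5, lo + 0.5])
        centers = np.array([lo])
        nb = 1
    else:
        edges = np.linspace(lo, hi, n_bins + 1)
        centers = 0.5 * (edges[:-1] + edges[1:])
        nb = n_bins
    eps = scales.epsilons(a.shape)
    counts = np.zeros((len(eps), nb), dtype=float)
    for k, side in enumerate(scales.window_sides):
        box_alpha = _tile_means(a, side).ravel()
        idx = np.clip(np.searchsorted(edges, box_alpha, side="right") - 1, 0, nb - 1)
        counts[k] = np.bincount(idx, minlength=nb)
    x = -np.log(eps)
    f = np.full(nb, np.nan)
    for i in range(nb):
        occ = counts[:, i] > 0
        if occ.sum() >= 2:
            f[i] = _slope(x[occ], np.log(counts[occ, i]))
    f = np.minimum(f, EMBEDDING_DIM)
    return MfSpectrum(alpha_bins=centers, f_values=f, box_counts=counts, scales=scales)


def box_counting_dimension(mask: np.ndarray, scales: ScaleSet = ScaleSet()) -> float:
    """Box-counting dimension of a binary mask.

    D_b is the slope of ln N(eps) against -ln eps, where N(eps) counts
    disjoint eps x eps tiles containing at least one true pixel (partial
    edge tiles included).
    """
    m = np.asarray(mask, dtype=bool)
    if m.ndim != 2:
        raise ValueError("mask must be 2-D")
    if not m.any():
        raise ValueError("box-counting dimension undefined for an empty mask")
    scales.validate_for(m.shape)
    eps = scales.epsilons(m.shape)
    counts = []
    for side in scales.window_sides:
        pm = (-m.shape[0]) % side
        pn = (-m.shape[1]) % side
        padded = np.pad(m, ((0, pm), (0, pn)), mode="constant")
        blocks = padded.reshape(
            padded.shape[0] // side, side, padded.shape[1] // side, side
        )
        counts.append(int(blocks.any(axis=(1, 3)).sum()))
    return float(_slope(-np.log(eps), np.log(np.asarray(counts, dtype=float))))


#: An alpha_max plateau larger than this many pixels is structure, not an
#: isolated singularity, and is never clipped for display.
ISOLATED_SINGULARITY_MAX_AREA = 4


def rescale_for_display(
    alpha_img: AlphaImage,
    clip_isolated_singularities: bool = False,
) -> np.ndarray:
    """Map [alpha_min, alpha_max] linearly onto [0, 1] for visualization.

    A handful of isolated maximal-alpha pixels can compress every other
    value toward black.  With ``clip_isolated_singularities`` set, connected
    components of alpha_max pixels no larger than
    ``ISOLATED_SINGULARITY_MAX_AREA`` are remapped to mid-gray (0.5) and the
    remaining range is stretched to [0, 1].  A constant alpha-image maps to
    all-0.5 by convention.
    """
    a = alpha_img.alpha
    lo, hi = alpha_img.alpha_min, alpha_img.alpha_max
    if hi - lo < 1e-12:
        return np.full(a.shape, 0.5)
    if not clip_isolated_singularities:
        return (a - lo) / (hi - lo)
    at_max = np.abs(a - hi) <= 1e-9
    labels, _ = ndi.label(at_max, structure=np.ones((3, 3), dtype=int))
    areas = np.bincount(labels.ravel())
    small = np.zeros_like(at_max)
    for lab in range(1, len(areas)):
        if areas[lab] <= ISOLATED_SINGULARITY_MAX_AREA:
            small |= labels == lab
    if not small.any():
        return (a - lo) / (hi - lo)
    remaining_max = a[~small].max() if (~small).any() else lo
    if remaining_max - lo < 1e-12:
        out = np.full(a.shape, 0.5)
        out[small] = 0.5
        return out
    out = np.clip((a - lo) / (remaining_max - lo), 0.0, 1.0)
    out[small] = 0.5
    return out


def multiplicative_cascade(
    weights: tuple[float, float, float, float] = (0.4, 0.3, 0.2, 0.1),
    depth: int = 9,
) -> np.ndarray:
    """Deterministic 2-D multinomial multiplicative cascade measure.

    Starting from a unit mass, each cell is split into a 2 x 2 block whose
    quadrants carry fractions ``weights`` of the parent mass.  The quadrant
    layout is rotated by 180 degrees at every other level so that the
    extreme construction paths land in the interior of the grid rather than
    at its corners, where centred-window estimators are distorted by border
    padding.  After ``depth`` levels the 2^depth x 2^depth grid holds an
    exactly normalized measure whose Hölder exponents, on dyadic boxes, are
    -(1/j) sum log2 of the weights along the construction path; the extremes
    are -log2(max w) and -log2(min w).  A standard oracle for multifractal
    estimators.
    """
    w = np.asarray(weights, dtype=float)
    if w.shape != (4,) or np.any(w <= 0) or abs(w.sum() - 1.0) > 1e-12:
        raise ValueError("weights must be 4 positive fractions summing to 1")
    block = w.reshape(2, 2)
    arr = np.ones((1, 1))
    for level in range(depth):
        b = block if level % 2 == 0 else block[::-1, ::-1]
        arr = np.kron(arr, b)
    return arr


def sierpinski_carpet(depth: int = 5) -> np.ndarray:
    """Boolean Sierpinski-carpet mask of side 3**depth (dimension log8/log3)."""
    cell = np.ones((3, 3), dtype=bool)
    cell[1, 1] = False
    arr = np.ones((1, 1), dtype=bool)
    for _ in range(depth):
        arr = np.kron(arr, cell)
    return arr
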