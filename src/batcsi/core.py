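"""Core per-slice image computations.

Implements the four numeric stages of the water/fat analysis:

1. 12-bit -> 8-bit display conversion (affine rescale with round-half-up),
2. elementwise water-to-oil ratio with an explicit zero-fat policy,
3. ROI masking (periprostatic annulus),
4. top-fraction extraction of the largest ratio elements,

plus rendering helpers (ratio image, RGB contour overlay).

Conventions: (row, col) indexing, 0-based, row-major throughout. All
matrices are 2-D numpy arrays; masks are boolean arrays of the same shape.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np

logger = logging.getLogger(__name__)

#: Intensity ceiling of the raw 12-bit data.
MAX_RAW_LEVEL = 4095

Channel = Literal["water", "fat"]
Provenance = Literal["full", "roi_masked", "brown_extracted"]


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RawImageMatrix:
    """One 12-bit signal channel (water-only or fat-only) for a slice."""

    values: np.ndarray
    channel: Channel

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.size == 0:
            raise ValueError("image matrix must be a non-empty 2-D array")
        if self.channel not in ("water", "fat"):
            raise ValueError(f"unknown channel {self.channel!r}")
        if v.min() < 0 or v.max() > MAX_RAW_LEVEL:
            raise ValueError(
                f"intensities must lie in [0, {MAX_RAW_LEVEL}]; "
                f"got range [{v.min()}, {v.max()}]"
            )
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class RoiMask:
    """Annulus-style region of interest with its bounding contours.

    ``in_roi`` is True exactly for pixels inside the outer contour and
    outside the inner one.  Contours are ordered (row, col) pixel paths;
    the inner path is empty when the region has no hole.
    """

    in_roi: np.ndarray
    outer_contour: tuple[tuple[int, int], ...] = ()
    inner_contour: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        m = np.asarray(self.in_roi, dtype=bool)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        object.__setattr__(self, "in_roi", m)
        object.__setattr__(self, "outer_contour", tuple(map(tuple, self.outer_contour)))
        object.__setattr__(self, "inner_contour", tuple(map(tuple, self.inner_contour)))

    @property
    def shape(self) -> tuple[int, int]:
        return self.in_roi.shape  # type: ignore[return-value]

    @property
    def n_in_roi(self) -> int:
        return int(self.in_roi.sum())


@dataclass(frozen=True)
class RatioMatrix:
    """Nonnegative water-to-oil ratio grid with processing provenance."""

    values: np.ndarray
    provenance: Provenance = "full"
    n_capped: int = 0

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2:
            raise ValueError("ratio matrix must be 2-D")
        if not np.all(np.isfinite(v)) or v.min() < 0:
            raise ValueError("ratio values must be finite and nonnegative")
        object.__setattr__(self, "values", v)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class ConversionSpec:
    """Affine range mapping used for 8-bit display conversion."""

    x_min: float = 0.0
    x_max: float = float(MAX_RAW_LEVEL)
    out_max: int = 255

    def __post_init__(self) -> None:
        if not self.x_max > self.x_min:
            raise ValueError(
                f"degenerate conversion range: x_max ({self.x_max}) must "
                f"exceed x_min ({self.x_min})"
            )
        if self.out_max < 1:
            raise ValueError("out_max must be >= 1")


@dataclass(frozen=True)
class ExtractionSpec:
    """Policy for retaining the top fraction of in-ROI ratio elements."""

    retain_fraction: float = 0.01
    denominator: Literal["roi_elements", "all_elements"] = "roi_elements"
    count_rounding: Literal["ceil", "floor", "round"] = "ceil"

    def __post_init__(self) -> None:
        if not (0.0 < self.retain_fraction <= 1.0):
            raise ValueError(
                f"retain_fraction must be in (0, 1], got {self.retain_fraction}"
            )

    def retained_count(self, n: int) -> int:
        """Number of elements to retain out of ``n`` (always >= 1)."""
        raw = self.retain_fraction * n
        if self.count_rounding == "ceil":
            k = math.ceil(raw)
        elif self.count_rounding == "floor":
            k = math.floor(raw)
        else:
            k = round(raw)
        return max(1, min(k, n))


@dataclass(frozen=True)
class RatioPolicy:
    """Handling of zero fat signal in the elementwise quotient.

    The quotient is undefined where the fat channel is 0.  Voxels with
    water > 0 there are the very high-water voxels the method targets, so
    they are kept and capped at ``zero_fat_cap`` instead of dropped;
    0/0 (no tissue signal at all) is defined as 0.
    """

    zero_fat_cap: float = 1000.0
    zero_zero_value: float = field(default=0.0, init=False)

    def __post_init__(self) -> None:
        if not self.zero_fat_cap > 0:
            raise ValueError("zero_fat_cap must be positive")


# ---------------------------------------------------------------------------
# Operations
# ---------------------------------------------------------------------------


def _round_half_up(x: np.ndarray) -> np.ndarray:
    # np.round is round-half-to-even; display conversion uses half-up on
    # nonnegative operands so integer edge cases are reproducible.
    return np.floor(x + 0.5)


def rescale_intensity(
    matrix: np.ndarray | RawImageMatrix | RatioMatrix,
    spec: ConversionSpec = ConversionSpec(),
) -> np.ndarray:
    """Affinely map values in [x_min, x_max] onto integers 0..out_max.

    Each element maps to ``round((x - x_min)/(x_max - x_min) * out_max)``.
    Values outside the declared range are clipped first (and logged).
    Returns a uint8 array when ``out_max <= 255``.
    """
    if isinstance(matrix, (RawImageMatrix, RatioMatrix)):
        matrix = matrix.values
    x = np.asarray(matrix, dtype=float)
    n_clipped = int(np.count_nonzero((x < spec.x_min) | (x > spec.x_max)))
    if n_clipped:
        logger.warning("rescale_intensity: clipped %d out-of-range values", n_clipped)
        x = np.clip(x, spec.x_min, spec.x_max)
    scaled = (x - spec.x_min) / (spec.x_max - spec.x_min) * spec.out_max
    out = _round_half_up(scaled)
    dtype = np.uint8 if spec.out_max <= 255 else np.uint16
    return out.astype(dtype)


def water_oil_ratio(
    water: RawImageMatrix,
    fat: RawImageMatrix,
    policy: RatioPolicy = RatioPolicy(),
) -> RatioMatrix:
    """Elementwise water/fat quotient with the zero-fat policy applied.

    Raises on shape mismatch or swapped channel tags.  The number of
    capped (fat == 0, water > 0) elements is recorded on the result.
    """
    if water.channel != "water" or fat.channel != "fat":
        raise ValueError(
            f"expected (water, fat) channels, got "
            f"({water.channel!r}, {fat.channel!r})"
        )
    if water.shape != fat.shape:
        raise ValueError(f"shape mismatch: water {water.shape} vs fat {fat.shape}")
    w = water.values.astype(float)
    f = fat.values.astype(float)
    out = np.zeros_like(w)
    pos_fat = f > 0
    out[pos_fat] = w[pos_fat] / f[pos_fat]
    capped = (~pos_fat) & (w > 0)
    out[capped] = policy.zero_fat_cap
    # fat == 0 and water == 0 stays at policy.zero_zero_value == 0
    n_capped = int(capped.sum())
    if n_capped:
        logger.info("water_oil_ratio: capped %d zero-fat elements", n_capped)
    return RatioMatrix(out, provenance="full", n_capped=n_capped)


def apply_roi(ratio: RatioMatrix, mask: RoiMask) -> RatioMatrix:
    """Zero every element outside the ROI; in-ROI elements pass unchanged."""
    if ratio.provenance != "full":
        raise ValueError(f"expected a full ratio matrix, got {ratio.provenance!r}")
    if ratio.shape != mask.shape:
        raise ValueError(f"shape mismatch: ratio {ratio.shape} vs mask {mask.shape}")
    out = np.where(mask.in_roi, ratio.values, 0.0)
    return RatioMatrix(out, provenance="roi_masked", n_capped=ratio.n_capped)


def extract_brown_fat(
    prwo: RatioMatrix,
    mask: RoiMask,
    spec: ExtractionSpec = ExtractionSpec(),
) -> tuple[RatioMatrix, list[tuple[int, int]]]:
    """Retain the top ``retain_fraction`` of elements, zero the rest.

    Elements are ranked from large to small; ties at the cutoff are broken
    by ascending row-major index so the retained set is deterministic.
    The denominator of the fraction is the in-ROI element count by default
    (``all_elements`` uses H*W instead).  Returns the extracted matrix and
    the retained (row, col) indices in rank order.
    """
    if prwo.provenance != "roi_masked":
        raise ValueError(
            f"expected an ROI-masked ratio matrix, got {prwo.provenance!r}"
        )
    if prwo.shape != mask.shape:
        raise ValueError(f"shape mismatch: ratio {prwo.shape} vs mask {mask.shape}")
    n_roi = mask.n_in_roi
    if n_roi == 0:
        raise ValueError("empty ROI: no elements to extract from")

    n_denom = n_roi if spec.denominator == "roi_elements" else prwo.values.size
    k = spec.retained_count(n_denom)
    k = min(k, n_roi)

    h, w = prwo.shape
    flat_idx = np.flatnonzero(mask.in_roi.ravel())
    vals = prwo.values.ravel()[flat_idx]
    # stable sort on descending value; stability preserves row-major order
    # among ties, which implements the tie-break policy.
    order = np.argsort(-vals, kind="stable")
    keep_flat = flat_idx[order[:k]]

    out = np.zeros_like(prwo.values)
    out.ravel()[keep_flat] = prwo.values.ravel()[keep_flat]
    retained = [(int(i // w), int(i % w)) for i in keep_flat]
    return (
        RatioMatrix(out, provenance="brown_extracted", n_capped=prwo.n_capped),
        retained,
    )


def render_ratio_image(ratio: RatioMatrix) -> np.ndarray:
    """Render a ratio matrix to 8-bit using its own min/max as the range.

    A constant matrix has no defined affine map and renders as all-zero
    (logged).
    """
    lo = float(ratio.values.min())
    hi = float(ratio.values.max())
    if hi == lo:
        logger.warning(
            "render_ratio_image: constant matrix (value %g); rendering all-zero", lo
        )
        return np.zeros(ratio.shape, dtype=np.uint8)
    return rescale_intensity(ratio.values, ConversionSpec(x_min=lo, x_max=hi))


def overlay_contours(image: np.ndarray, mask: RoiMask) -> np.ndarray:
    """Replicate a grayscale image to RGB and paint the ROI contours.

    Outer contour pixels become pure green, inner contour pixels pure red;
    everything else is the unmodified grayscale triplet.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError("expected a 2-D grayscale image")
    if img.shape != mask.shape:
        raise ValueError(f"shape mismatch: image {img.shape} vs mask {mask.shape}")
    rgb = np.stack([img, img, img], axis=-1).astype(np.uint8)
    for r, c in mask.outer_contour:
        rgb[r, c] = (0, 255, 0)
    for r, c in mask.inner_contour:
        rgb[r, c] = (255, 0, 0)
    return rgb


# ---------------------------------------------------------------------------
# Contour tracing (shared by the phantom generator and the mask reader)
# ---------------------------------------------------------------------------


def trace_contours(
    in_roi: np.ndarray,
) -> tuple[tuple[tuple[int, int], ...], tuple[tuple[int, int], ...]]:
    """Extract (outer, inner) boundary pixel paths from a boolean ROI.

    Outer contour: ROI pixels 4-adjacent to the unbounded exterior.
    Inner contour: ROI pixels 4-adjacent to an enclosed hole.  Each path
    is ordered by angle around the ROI centroid, giving a closed circuit
    for annulus-like regions.
    """
    from scipy import ndimage

    m = np.asarray(in_roi, dtype=bool)
    filled = ndimage.binary_fill_holes(m)
    hole = filled & ~m
    exterior = ~filled

    struct = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)
    near_ext = ndimage.binary_dilation(exterior, structure=struct) & m
    near_hole = ndimage.binary_dilation(hole, structure=struct) & m

    def _order(b: np.ndarray) -> tuple[tuple[int, int], ...]:
        rr, cc = np.nonzero(b)
        if rr.size == 0:
            return ()
        cr, ccen = rr.mean(), cc.mean()
        ang = np.arctan2(rr - cr, cc - ccen)
        order = np.lexsort((cc, rr, ang))
        return tuple((int(r), int(c)) for r, c in zip(rr[order], cc[order]))

    return _order(near_ext), _order(near_hole)


def make_roi_mask(in_roi: np.ndarray) -> RoiMask:
    """Build an :class:`RoiMask` with traced contours from a boolean grid."""
    outer, inner = trace_contours(in_roi)
    return RoiMask(np.asarray(in_roi, dtype=bool), outer, inner)


def pooled_roi_values(
    ratio: RatioMatrix, mask: RoiMask
) -> np.ndarray:
    """Return the in-ROI ratio values as a flat array (row-major order)."""
    return ratio.values[mask.in_roi]
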