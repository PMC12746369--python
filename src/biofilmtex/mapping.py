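"""Spatially resolved texture analysis: sliding-window Haralick maps.

A square window slides over the image; within each window the five
Haralick statistics are computed per directional offset and averaged over
the offsets (the same convention as the whole-image directional summary).
The resulting per-window-centre grid is a :class:`TextureMap`, which can
be rendered as a red→green overlay on the grey micrograph.

The window computation is exact: per offset, co-occurrence counts inside
every window are obtained from integral images of the per-pair indicator
planes, so each window's counts equal a brute-force enumeration of the
pixel pairs wholly contained in it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .glcm import (
    ANGLES,
    FEATURE_NAMES,
    EmptyGLCMError,
    GreyImage,
    OffsetSpec,
    default_offsets,
    quantize,
)

__all__ = [
    "WindowSpec",
    "TextureMap",
    "OverlayImage",
    "sliding_window_map",
    "render_feature_overlay",
]


@dataclass(frozen=True)
class WindowSpec:
    """Geometry of the sliding window.

    side
        Odd window side in pixels (default 21 px, about 5 µm at
        0.25 µm/pixel — a few cell widths).
    stride
        Step between computed centres; skipped centres are filled with the
        nearest computed value.
    boundary
        "valid" leaves a missing border of (side-1)/2 pixels;
        "reflect" mirror-pads the image so the map covers every pixel.
    """

    side: int = 21
    stride: int = 1
    boundary: str = "valid"

    def __post_init__(self) -> None:
        if self.side < 3 or self.side % 2 == 0:
            raise ValueError("window side must be odd and >= 3")
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if self.boundary not in ("valid", "reflect"):
            raise ValueError("boundary must be 'valid' or 'reflect'")

    @property
    def half(self) -> int:
        return (self.side - 1) // 2


@dataclass(frozen=True)
class TextureMap:
    """One Haralick feature evaluated at every window centre.

    ``values`` has the shape of the source image; entries outside the
    validity ``mask`` are NaN.  With the "valid" boundary the mask excludes
    a border of ``(side-1)/2`` pixels.  A NaN *inside* the mask marks a
    window where the feature itself is undefined (zero-variance
    correlation), not a missing window.
    """

    values: np.ndarray
    mask: np.ndarray
    feature: str
    window: WindowSpec
    provenance: dict = field(default_factory=dict)

    def mean_defined(self) -> float:
        """Mean of the defined (finite, in-mask) map values."""
        vals = self.values[self.mask]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            return float("nan")
        return float(vals.mean())


@dataclass(frozen=True)
class OverlayImage:
    """An RGB composite with a record of where each channel came from."""

    rgb: np.ndarray  # H x W x 3, values in [0, 1]
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        arr = np.asarray(self.rgb, dtype=np.float64)
        if arr.ndim != 3 or arr.shape[2] != 3:
            raise ValueError("overlay must be H x W x 3")
        if arr.size and (arr.min() < 0 or arr.max() > 1):
            raise ValueError("overlay channels must lie in [0, 1]")
        object.__setattr__(self, "rgb", arr)


def _box_sums(
    plane: np.ndarray, tops: np.ndarray, lefts: np.ndarray, h: int, w: int
) -> np.ndarray:
    """Sums of `plane` over h x w boxes at every (top, left) grid point."""
    H, W = plane.shape
    S = np.zeros((H + 1, W + 1), dtype=np.int64)
    S[1:, 1:] = plane.cumsum(axis=0).cumsum(axis=1)
    A = tops[:, None]
    B = lefts[None, :]
    return S[A + h, B + w] - S[A, B + w] - S[A + h, B] + S[A, B]


def _window_counts(
    levels: np.ndarray,
    L: int,
    offset: OffsetSpec,
    tops: np.ndarray,
    lefts: np.ndarray,
    side: int,
) -> tuple[np.ndarray, int]:
    """Per-window GLCM counts for one offset.

    Returns an array of shape (len(tops), len(lefts), L, L) of exact pair
    counts, plus the constant number of in-window pairs N.
    """
    dr, dc = offset.displacement
    h = side - abs(dr)
    w = side - abs(dc)
    if h < 1 or w < 1:
        raise EmptyGLCMError(
            f"window side {side} admits no pairs at offset {offset.angle} deg,"
            f" d={offset.distance}"
        )
    H, W = levels.shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    ref = levels[r0:r1, c0:c1]
    nb = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    codes = np.full((H, W), -1, dtype=np.int32)
    codes[r0:r1, c0:c1] = (ref * L + nb).astype(np.int32)

    # reference pixels of in-window pairs occupy a shifted h x w sub-box
    box_tops = tops + max(0, -dr)
    box_lefts = lefts + max(0, -dc)
    counts = np.empty((len(tops), len(lefts), L, L), dtype=np.int64)
    for k in range(L * L):
        ind = (codes == k).astype(np.int64)
        counts[:, :, k // L, k % L] = _box_sums(ind, box_tops, box_lefts, h, w)
    return counts, h * w


def _features_from_counts(
    counts: np.ndarray, total: np.ndarray | int, entropy_base: float
) -> dict[str, np.ndarray]:
    """Vectorized Haralick statistics from per-window count matrices."""
    L = counts.shape[-1]
    p = counts / np.asarray(total, dtype=np.float64)
    idx = np.arange(L, dtype=np.float64)
    di = idx[:, None] - idx[None, :]

    contrast = np.einsum("...ij,ij->...", p, di**2)
    homogeneity = np.einsum("...ij,ij->...", p, 1.0 / (1.0 + np.abs(di)))
    energy = (p**2).sum(axis=(-2, -1))
    with np.errstate(divide="ignore", invalid="ignore"):
        logp = np.where(p > 0, np.log(p), 0.0)
    entropy = -(p * logp).sum(axis=(-2, -1)) / math.log(entropy_base)

    p_i = p.sum(axis=-1)
    p_j = p.sum(axis=-2)
    mu_i = p_i @ idx
    mu_j = p_j @ idx
    s_ii = p_i @ idx**2
    s_jj = p_j @ idx**2
    s_ij = np.einsum("...ij,i,j->...", p, idx, idx)
    var_i = s_ii - mu_i**2
    var_j = s_jj - mu_j**2
    with np.errstate(divide="ignore", invalid="ignore"):
        correlation = (s_ij - mu_i * mu_j) / np.sqrt(var_i * var_j)
    correlation = np.where((var_i <= 0) | (var_j <= 0), np.nan, correlation)

    return {
        "contrast": contrast,
        "correlation": correlation,
        "energy": energy,
        "homogeneity": homogeneity,
        "entropy": entropy,
    }


def _nearest_fill(grid: np.ndarray, centres_r: np.ndarray, centres_c: np.ndarray,
                  out_rows: np.ndarray, out_cols: np.ndarray) -> np.ndarray:
    """Expand a strided centre grid to all centres by nearest neighbour."""
    ri = np.abs(out_rows[:, None] - centres_r[None, :]).argmin(axis=1)
    ci = np.abs(out_cols[:, None] - centres_c[None, :]).argmin(axis=1)
    return grid[np.ix_(ri, ci)]


def sliding_window_map(
    image: GreyImage,
    feature: str,
    window: WindowSpec | None = None,
    n_levels: int = 8,
    offsets: Sequence[OffsetSpec] | None = None,
    intensity_range: tuple[float, float] | None = None,
    symmetric: bool = False,
    entropy_base: float = math.e,
) -> TextureMap:
    """Compute one Haralick feature over a sliding window.

    The image is quantized once (by default over its own min/max; pass a
    fixed ``intensity_range`` for cross-image comparability) and the
    feature is computed per window and per offset, then averaged over the
    offsets.  The value is placed at the window centre.  With
    ``stride > 1`` the skipped centres are filled with the nearest
    computed value.

    The value at any centre equals ``directional_summary`` applied to that
    window extracted as a standalone image with the same quantization
    range (up to floating-point summation order).
    """
    if feature not in FEATURE_NAMES:
        raise KeyError(f"unknown feature {feature!r}")
    window = window or WindowSpec()
    offsets = tuple(offsets) if offsets is not None else default_offsets()
    for off in offsets:
        if window.side < off.distance + 2:
            raise ValueError(
                f"window side {window.side} must be >= d+2 for offset "
                f"d={off.distance}"
            )
    H, W = image.shape
    if window.side > min(H, W):
        raise ValueError(
            f"window side {window.side} exceeds image size {H}x{W}"
        )
    half = window.half
    if intensity_range is None:
        intensity_range = image.intensity_range()

    if window.boundary == "reflect":
        padded = np.pad(image.pixels, half, mode="reflect")
        levels = quantize(
            GreyImage(padded, image.pixel_size), n_levels, intensity_range
        ).levels
        centre_rows = np.arange(0, H, window.stride)  # in original coords
        centre_cols = np.arange(0, W, window.stride)
        tops = centre_rows  # padded coords: centre + half - half
        lefts = centre_cols
        out_rows = np.arange(H)
        out_cols = np.arange(W)
    else:
        levels = quantize(image, n_levels, intensity_range).levels
        centre_rows = np.arange(half, H - half, window.stride)
        centre_cols = np.arange(half, W - half, window.stride)
        tops = centre_rows - half
        lefts = centre_cols - half
        out_rows = np.arange(half, H - half)
        out_cols = np.arange(half, W - half)

    acc = np.zeros((len(tops), len(lefts)), dtype=np.float64)
    for off in offsets:
        counts, n_pairs = _window_counts(
            levels, n_levels, off, tops, lefts, window.side
        )
        if symmetric:
            counts = counts + counts.transpose(0, 1, 3, 2)
            n_pairs *= 2
        feats = _features_from_counts(counts, n_pairs, entropy_base)
        acc += feats[feature]
    grid = acc / len(offsets)

    values = np.full((H, W), np.nan)
    mask = np.zeros((H, W), dtype=bool)
    filled = _nearest_fill(grid, centre_rows, centre_cols, out_rows, out_cols)
    values[np.ix_(out_rows, out_cols)] = filled
    mask[np.ix_(out_rows, out_cols)] = True

    return TextureMap(
        values=values,
        mask=mask,
        feature=feature,
        window=window,
        provenance={
            "n_levels": n_levels,
            "offsets": [(o.angle, o.distance) for o in offsets],
            "intensity_range": tuple(intensity_range),
            "symmetric": symmetric,
            "entropy_base": entropy_base,
        },
    )


def render_feature_overlay(
    base: GreyImage,
    tmap: TextureMap,
    bounds: tuple[float, float] | None = None,
    alpha: float = 0.5,
    low_colour: tuple[float, float, float] = (1.0, 0.0, 0.0),
    high_colour: tuple[float, float, float] = (0.0, 1.0, 0.0),
) -> OverlayImage:
    """Blend a red→green rendering of a texture map onto the grey base.

    Map values are mapped linearly from ``low_colour`` (red) at the lower
    bound to ``high_colour`` (green) at the upper bound; by default the
    bounds are the 2nd–98th percentile of the defined map values and are
    recorded in the overlay's provenance.  Pixels with missing map values
    show the grey base only; ``alpha`` is the blend weight of the colour
    layer.
    """
    if base.shape != tmap.values.shape:
        raise ValueError(
            f"base {base.shape} and map {tmap.values.shape} shapes differ"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    lo_px, hi_px = base.intensity_range()
    grey = (
        (base.pixels - lo_px) / (hi_px - lo_px)
        if hi_px > lo_px
        else np.zeros(base.shape)
    )
    rgb = np.repeat(grey[:, :, None], 3, axis=2)

    defined = tmap.mask & np.isfinite(tmap.values)
    if bounds is None:
        vals = tmap.values[defined]
        if vals.size:
            bounds = (
                float(np.percentile(vals, 2)),
                float(np.percentile(vals, 98)),
            )
        else:
            bounds = (0.0, 1.0)
    lo, hi = bounds
    span = hi - lo if hi > lo else 1.0
    t = np.clip((tmap.values - lo) / span, 0.0, 1.0)
    low = np.asarray(low_colour, dtype=np.float64)
    high = np.asarray(high_colour, dtype=np.float64)
    colour = low[None, None, :] + t[:, :, None] * (high - low)[None, None, :]
    out = rgb.copy()
    out[defined] = (1 - alpha) * rgb[defined] + alpha * colour[defined]
    return OverlayImage(
        rgb=np.clip(out, 0.0, 1.0),
        provenance={
            "feature": tmap.feature,
            "bounds": (float(lo), float(hi)),
            "alpha": alpha,
            "low_colour": tuple(low_colour),
            "high_colour": tuple(high_colour),
            "window": (tmap.window.side, tmap.window.stride, tmap.window.boundary),
        },
    )
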