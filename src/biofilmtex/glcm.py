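"""Grey-level co-occurrence matrices and Haralick texture statistics.

The quantities computed here describe the spatial texture of a greyscale
micrograph.  An image is first quantized to ``L`` grey levels; for a fixed
pixel displacement (an :class:`OffsetSpec`) the grey-level co-occurrence
matrix (GLCM) counts how often a reference pixel of level *i* has a
neighbour of level *j*.  After normalizing the counts to a joint
probability distribution ``p(i, j)``, five scalar statistics are read off:

* contrast      ``sum (i - j)^2 p(i, j)`` — local intensity variation
* correlation   ``sum (i - mu_i)(j - mu_j) p(i, j) / (sigma_i sigma_j)``
* energy        ``sum p(i, j)^2`` (angular second moment) — uniformity
* homogeneity   ``sum p(i, j) / (1 + |i - j|)`` — local similarity
* entropy       ``-sum p(i, j) ln p(i, j)`` — randomness (nats by default)

Texture is orientation dependent, so the matrices are computed at the four
standard directions (0°, 45°, 90°, 135°) and summarised by the mean and the
population standard deviation over the four offsets
(:func:`directional_summary`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ANGLES",
    "FEATURE_NAMES",
    "EmptyGLCMError",
    "GreyImage",
    "QuantizedImage",
    "OffsetSpec",
    "GLCM",
    "HaralickFeatures",
    "DirectionalSummary",
    "default_offsets",
    "quantize",
    "compute_glcm",
    "normalize_glcm",
    "haralick_features",
    "directional_summary",
]

#: The four standard GLCM directions, in degrees.
ANGLES: tuple[int, ...] = (0, 45, 90, 135)

#: Canonical feature ordering used in tables and maps.
FEATURE_NAMES: tuple[str, ...] = (
    "contrast",
    "correlation",
    "energy",
    "homogeneity",
    "entropy",
)

#: Default physical pixel size of the micrographs, µm per pixel.
DEFAULT_PIXEL_SIZE = 0.25


class EmptyGLCMError(ValueError):
    """Raised when an image admits no pixel pair for a requested offset."""


@dataclass(frozen=True)
class GreyImage:
    """A 2-D greyscale micrograph with an optional physical pixel size.

    Parameters
    ----------
    pixels
        2-D array of finite intensities (any integer or float dtype).
    pixel_size
        Physical size of one pixel in µm (default 0.25).
    """

    pixels: np.ndarray
    pixel_size: float = DEFAULT_PIXEL_SIZE

    def __post_init__(self) -> None:
        arr = np.asarray(self.pixels, dtype=np.float64)
        if arr.ndim != 2:
            raise ValueError(f"expected a 2-D image, got ndim={arr.ndim}")
        if arr.shape[0] < 1 or arr.shape[1] < 1:
            raise ValueError("image must have H >= 1 and W >= 1")
        if not np.all(np.isfinite(arr)):
            raise ValueError("image contains non-finite intensities")
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        object.__setattr__(self, "pixels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]

    def intensity_range(self) -> tuple[float, float]:
        """(min, max) of the pixel intensities."""
        return float(self.pixels.min()), float(self.pixels.max())


@dataclass(frozen=True)
class QuantizedImage:
    """An image reduced to integer grey levels in ``[0, L-1]``."""

    levels: np.ndarray
    n_levels: int

    def __post_init__(self) -> None:
        arr = np.asarray(self.levels)
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError("quantized levels must be integers")
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if arr.size and (arr.min() < 0 or arr.max() >= self.n_levels):
            raise ValueError("levels out of range [0, L-1]")
        object.__setattr__(self, "levels", arr)

    @property
    def shape(self) -> tuple[int, int]:
        return self.levels.shape


@dataclass(frozen=True)
class OffsetSpec:
    """One directional pixel displacement for GLCM construction.

    The displacement convention follows the MATLAB GRAYCOMATRIX mapping, in
    (row, col) coordinates with the row index increasing downward:

    ========  ==============
    angle     (drow, dcol)
    ========  ==============
    0°        (0, +d)
    45°       (-d, +d)
    90°       (-d, 0)
    135°      (-d, -d)
    ========  ==============
    """

    angle: int
    distance: int = 1

    def __post_init__(self) -> None:
        if self.angle not in ANGLES:
            raise ValueError(f"angle must be one of {ANGLES}, got {self.angle}")
        if self.distance < 1:
            raise ValueError("distance must be >= 1")

    @property
    def displacement(self) -> tuple[int, int]:
        d = self.distance
        return {0: (0, d), 45: (-d, d), 90: (-d, 0), 135: (-d, -d)}[self.angle]


def default_offsets(distance: int = 1) -> tuple[OffsetSpec, ...]:
    """The four standard offsets at a common distance."""
    return tuple(OffsetSpec(a, distance) for a in ANGLES)


@dataclass(frozen=True)
class GLCM:
    """An L×L co-occurrence matrix, as raw counts or probabilities."""

    matrix: np.ndarray
    kind: str  # "counts" | "probabilities"
    offset: OffsetSpec
    symmetric: bool = False

    def __post_init__(self) -> None:
        arr = np.asarray(self.matrix, dtype=np.float64)
        if arr.ndim != 2 or arr.shape[0] != arr.shape[1]:
            raise ValueError("GLCM matrix must be square")
        if self.kind not in ("counts", "probabilities"):
            raise ValueError("kind must be 'counts' or 'probabilities'")
        if arr.size and arr.min() < 0:
            raise ValueError("GLCM entries must be non-negative")
        if self.kind == "probabilities":
            total = arr.sum()
            if total > 0 and abs(total - 1.0) > 1e-9:
                raise ValueError("probability GLCM must sum to 1 +- 1e-9")
        object.__setattr__(self, "matrix", arr)

    @property
    def n_levels(self) -> int:
        return self.matrix.shape[0]


# correlation is undefined on a zero-variance matrix; NaN is the marker
UNDEFINED = float("nan")


@dataclass(frozen=True)
class HaralickFeatures:
    """The five texture statistics of one normalized GLCM."""

    contrast: float
    correlation: float  # NaN when either marginal variance is zero
    energy: float
    homogeneity: float
    entropy: float

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in FEATURE_NAMES}

    def __getitem__(self, name: str) -> float:
        if name not in FEATURE_NAMES:
            raise KeyError(name)
        return getattr(self, name)


def quantize(
    image: GreyImage,
    n_levels: int = 8,
    intensity_range: tuple[float, float] | None = None,
) -> QuantizedImage:
    """Quantize a greyscale image to ``n_levels`` linear bins.

    ``[lo, hi]`` is split into ``n_levels`` equal bins; intensities at or
    below ``lo`` map to level 0 and at or above ``hi`` to ``n_levels - 1``
    (the linear-scaling convention of MATLAB's GRAYCOMATRIX).  If
    ``intensity_range`` is omitted the image's own min/max is used; a
    constant image maps entirely to level 0.

    For comparing texture statistics across images, pass a common fixed
    ``intensity_range`` so that grey levels mean the same thing everywhere.
    """
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    if intensity_range is None:
        lo, hi = image.intensity_range()
    else:
        lo, hi = float(intensity_range[0]), float(intensity_range[1])
        if not (math.isfinite(lo) and math.isfinite(hi)):
            raise ValueError("intensity_range must be finite")
    if hi <= lo:
        levels = np.zeros(image.shape, dtype=np.intp)
    else:
        scaled = (image.pixels - lo) / (hi - lo) * n_levels
        levels = np.clip(np.floor(scaled).astype(np.intp), 0, n_levels - 1)
    return QuantizedImage(levels=levels, n_levels=n_levels)


def compute_glcm(
    q: QuantizedImage, offset: OffsetSpec, symmetric: bool = False
) -> GLCM:
    """Count co-occurrences of grey-level pairs at one displacement.

    Entry (i, j) counts ordered pairs whose reference pixel has level *i*
    and whose neighbour, at the offset's displacement, has level *j*.
    Pairs whose neighbour falls outside the image are skipped.  With
    ``symmetric=True`` each pair is also accumulated in reversed order,
    which makes the matrix equal to its transpose.
    """
    dr, dc = offset.displacement
    H, W = q.shape
    r0, r1 = max(0, -dr), H - max(0, dr)
    c0, c1 = max(0, -dc), W - max(0, dc)
    if r1 <= r0 or c1 <= c0:
        raise EmptyGLCMError(
            f"no pixel pairs exist for offset {offset.angle} deg, "
            f"d={offset.distance} on a {H}x{W} image"
        )
    L = q.n_levels
    ref = q.levels[r0:r1, c0:c1]
    nb = q.levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
    codes = ref.ravel() * L + nb.ravel()
    counts = np.bincount(codes, minlength=L * L).reshape(L, L).astype(np.float64)
    if symmetric:
        counts = counts + counts.T
    return GLCM(matrix=counts, kind="counts", offset=offset, symmetric=symmetric)


def normalize_glcm(g: GLCM) -> GLCM:
    """Convert a counts GLCM to a joint probability matrix (sum = 1)."""
    if g.kind != "counts":
        raise ValueError("normalize_glcm expects a counts GLCM")
    total = g.matrix.sum()
    if total <= 0:
        raise ValueError("cannot normalize a GLCM with zero total count")
    return GLCM(
        matrix=g.matrix / total,
        kind="probabilities",
        offset=g.offset,
        symmetric=g.symmetric,
    )


def _correlation_from_moments(
    mu_i: float, mu_j: float, s_ii: float, s_jj: float, s_ij: float
) -> float:
    # moment form keeps the whole-matrix and windowed code paths consistent
    var_i = s_ii - mu_i * mu_i
    var_j = s_jj - mu_j * mu_j
    if var_i <= 0 or var_j <= 0:
        return UNDEFINED
    return (s_ij - mu_i * mu_j) / math.sqrt(var_i * var_j)


def haralick_features(
    P: GLCM, entropy_base: float = math.e
) -> HaralickFeatures:
    """Compute the five Haralick statistics of a normalized GLCM.

    Entropy uses the natural logarithm by default (``entropy_base=math.e``);
    pass ``entropy_base=2`` for bits.  Correlation on a matrix with a
    zero-variance marginal is undefined and reported as NaN.
    """
    if P.kind != "probabilities":
        raise ValueError("haralick_features expects a normalized GLCM")
    p = P.matrix
    L = P.n_levels
    idx = np.arange(L, dtype=np.float64)
    di = idx[:, None] - idx[None, :]

    contrast = float((di**2 * p).sum())
    energy = float((p**2).sum())
    homogeneity = float((p / (1.0 + np.abs(di))).sum())
    pos = p[p > 0]
    entropy = float(-(pos * np.log(pos)).sum()) / math.log(entropy_base)

    p_i = p.sum(axis=1)
    p_j = p.sum(axis=0)
    mu_i = float((idx * p_i).sum())
    mu_j = float((idx * p_j).sum())
    s_ii = float((idx**2 * p_i).sum())
    s_jj = float((idx**2 * p_j).sum())
    s_ij = float((np.outer(idx, idx) * p).sum())
    correlation = _correlation_from_moments(mu_i, mu_j, s_ii, s_jj, s_ij)

    return HaralickFeatures(
        contrast=contrast,
        correlation=correlation,
        energy=energy,
        homogeneity=homogeneity,
        entropy=entropy,
    )


@dataclass(frozen=True)
class DirectionalSummary:
    """Per-feature mean and standard deviation over the four offsets.

    The standard deviation is the population convention (divide by the
    number of offsets, 4).  A NaN correlation at any offset propagates to
    NaN mean/std, never silently to zero.
    """

    per_offset: Mapping[int, HaralickFeatures]  # angle -> features
    n_levels: int = 8
    distance: int = 1
    symmetric: bool = False
    entropy_base: float = math.e

    def _values(self, feature: str) -> np.ndarray:
        if feature not in FEATURE_NAMES:
            raise KeyError(feature)
        return np.array(
            [self.per_offset[a][feature] for a in sorted(self.per_offset)]
        )

    def mean(self, feature: str) -> float:
        return float(np.mean(self._values(feature)))

    def std(self, feature: str) -> float:
        return float(np.std(self._values(feature)))  # ddof=0

    def to_frame(self) -> pd.DataFrame:
        """Long-form table: one row per feature, columns mean/std."""
        rows = [
            {"feature": f, "mean": self.mean(f), "std": self.std(f)}
            for f in FEATURE_NAMES
        ]
        return pd.DataFrame(rows).set_index("feature")

    def format_cell(self, feature: str, decimals: int = 3) -> str:
        """Render one feature as a ``mean ± std`` table cell."""
        m, s = self.mean(feature), self.std(feature)
        if math.isnan(m):
            return "undefined"
        return f"{m:.{decimals}f} ± {s:.{decimals}f}"

    def __str__(self) -> str:
        cells = ", ".join(f"{f}: {self.format_cell(f)}" for f in FEATURE_NAMES)
        return f"DirectionalSummary({cells})"


def directional_summary(
    image: GreyImage,
    n_levels: int = 8,
    distance: int = 1,
    symmetric: bool = False,
    intensity_range: tuple[float, float] | None = None,
    entropy_base: float = math.e,
) -> DirectionalSummary:
    """Whole-image Haralick analysis over the four standard directions.

    Quantizes the image, computes one GLCM per direction at the given
    distance, and summarises each feature by its mean and population
    standard deviation over the four directional values.
    """
    q = quantize(image, n_levels=n_levels, intensity_range=intensity_range)
    per_offset: dict[int, HaralickFeatures] = {}
    for angle in ANGLES:
        off = OffsetSpec(angle, distance)
        try:
            g = compute_glcm(q, off, symmetric=symmetric)
        except EmptyGLCMError as exc:
            raise EmptyGLCMError(
                f"offset {angle} deg, d={distance}: {exc}"
            ) from exc
        per_offset[angle] = haralick_features(
            normalize_glcm(g), entropy_base=entropy_base
        )
    return DirectionalSummary(
        per_offset=per_offset,
        n_levels=n_levels,
        distance=distance,
        symmetric=symmetric,
        entropy_base=entropy_base,
    )
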