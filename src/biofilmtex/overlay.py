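"""Two-channel cross-modality composites.

Places two micrographs of the same field into different colour channels
(typically SHeM in red, optical in blue) so that features visible in one
modality but masked in the other stand out as single-colour regions —
e.g. cell clusters that the EPS overlayer hides from the helium beam
appear blue-only.  Inputs are assumed pre-aligned up to an integer
translation; each image is min–max normalized independently because the
modalities have incommensurate intensity scales.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Tuple

import numpy as np

from .glcm import GreyImage
from .mapping import OverlayImage

__all__ = ["ChannelAssignment", "channel_overlay"]

_CHANNELS = {"red": 0, "green": 1, "blue": 2}


@dataclass(frozen=True)
class ChannelAssignment:
    """Which colour channel each image occupies, plus an optional shift.

    ``shift`` is an integer (row, col) translation applied to image B
    before compositing, for manual registration.
    """

    a_channel: str = "red"
    b_channel: str = "blue"
    shift: Tuple[int, int] = (0, 0)

    def __post_init__(self) -> None:
        if self.a_channel not in _CHANNELS or self.b_channel not in _CHANNELS:
            raise ValueError(f"channels must be one of {sorted(_CHANNELS)}")
        if self.a_channel == self.b_channel:
            raise ValueError("images must occupy distinct channels")
        dr, dc = self.shift
        if dr != int(dr) or dc != int(dc):
            raise ValueError("shift must be integer (row, col)")


def _normalize(pixels: np.ndarray) -> np.ndarray:
    lo, hi = pixels.min(), pixels.max()
    if hi <= lo:
        return np.zeros_like(pixels, dtype=np.float64)
    return (pixels - lo) / (hi - lo)


def channel_overlay(
    a: GreyImage, b: GreyImage, assign: ChannelAssignment | None = None
) -> OverlayImage:
    """Composite two greyscale images into separate colour channels.

    The output frame is image A's frame.  Image B is translated by
    ``assign.shift`` (positive rows shift B downward); the translated
    overlap with A's frame must be non-empty.  Each image is min–max
    normalized into its channel; regions outside an image's support are
    zero in that channel.  Normalization bounds and the translation are
    recorded in the overlay's provenance.
    """
    assign = assign or ChannelAssignment()
    if a.pixel_size != b.pixel_size:
        raise ValueError(
            f"pixel sizes differ ({a.pixel_size} vs {b.pixel_size} um/px); "
            "resample before overlaying"
        )
    H, W = a.shape
    dr, dc = int(assign.shift[0]), int(assign.shift[1])
    Hb, Wb = b.shape
    # overlap of B's translated frame with A's frame
    r0, r1 = max(0, dr), min(H, Hb + dr)
    c0, c1 = max(0, dc), min(W, Wb + dc)
    if r0 >= r1 or c0 >= c1:
        raise ValueError(f"translation {assign.shift} leaves no overlap")

    rgb = np.zeros((H, W, 3), dtype=np.float64)
    rgb[:, :, _CHANNELS[assign.a_channel]] = _normalize(a.pixels)
    b_norm = _normalize(b.pixels)
    rgb[r0:r1, c0:c1, _CHANNELS[assign.b_channel]] = b_norm[
        r0 - dr : r1 - dr, c0 - dc : c1 - dc
    ]
    return OverlayImage(
        rgb=rgb,
        provenance={
            "a_channel": assign.a_channel,
            "b_channel": assign.b_channel,
            "shift": (dr, dc),
            "a_bounds": (float(a.pixels.min()), float(a.pixels.max())),
            "b_bounds": (float(b.pixels.min()), float(b.pixels.max())),
            "overlap": (r0, r1, c0, c1),
        },
    )
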