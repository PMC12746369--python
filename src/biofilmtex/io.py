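"""Reading and writing micrographs, texture maps and feature tables.

Greyscale 8/16-bit TIFF and PNG are read natively; RGB inputs are
converted to luminance with a warning.  Texture maps are written as
32-bit float TIFF with a JSON sidecar recording the analysis parameters;
overlays as 8-bit PNG; feature tables as CSV.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import Iterable, Mapping

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .glcm import DEFAULT_PIXEL_SIZE, DirectionalSummary, FEATURE_NAMES, GreyImage
from .mapping import OverlayImage, TextureMap

__all__ = [
    "read_image",
    "write_image",
    "write_texture_map",
    "read_texture_map_sidecar",
    "write_overlay",
    "feature_table",
    "write_feature_table",
]

_LUMA = np.array([0.2126, 0.7152, 0.0722])


def read_image(path: str | Path, pixel_size: float = DEFAULT_PIXEL_SIZE) -> GreyImage:
    """Read a TIFF/PNG micrograph as a :class:`GreyImage`.

    RGB(A) inputs are converted to luminance (Rec. 709 weights) with a
    warning; the alpha channel, if any, is dropped.
    """
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        arr = tifffile.imread(path)
    else:
        arr = iio.imread(path)
    arr = np.asarray(arr)
    if arr.ndim == 3:
        if arr.shape[2] == 4:
            arr = arr[:, :, :3]
        if arr.shape[2] == 3:
            warnings.warn(
                f"{path.name}: RGB input converted to luminance", stacklevel=2
            )
            arr = arr.astype(np.float64) @ _LUMA
        else:
            raise ValueError(f"{path.name}: unsupported channel count {arr.shape[2]}")
    elif arr.ndim != 2:
        raise ValueError(f"{path.name}: expected a 2-D image, got ndim={arr.ndim}")
    return GreyImage(arr.astype(np.float64), pixel_size=pixel_size)


def write_image(path: str | Path, image: GreyImage, bit_depth: int = 16) -> None:
    """Write a [0, 1]-scaled greyscale image as 8- or 16-bit TIFF/PNG."""
    if bit_depth not in (8, 16):
        raise ValueError("bit_depth must be 8 or 16")
    lo, hi = image.intensity_range()
    scaled = (image.pixels - lo) / (hi - lo) if hi > lo else np.zeros(image.shape)
    maxval = 2**bit_depth - 1
    data = np.round(scaled * maxval).astype(np.uint8 if bit_depth == 8 else np.uint16)
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(path, data)
    else:
        iio.imwrite(path, data)


def write_texture_map(path: str | Path, tmap: TextureMap) -> None:
    """Write a texture map as float32 TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, tmap.values.astype(np.float32))
    sidecar = {
        "feature": tmap.feature,
        "window": {
            "side": tmap.window.side,
            "stride": tmap.window.stride,
            "boundary": tmap.window.boundary,
        },
        **{k: _jsonable(v) for k, v in tmap.provenance.items()},
    }
    with open(path.with_suffix(path.suffix + ".json"), "w") as fh:
        json.dump(sidecar, fh, indent=2)


def read_texture_map_sidecar(path: str | Path) -> dict:
    """Load the JSON sidecar written next to a texture-map TIFF."""
    path = Path(path)
    with open(path.with_suffix(path.suffix + ".json")) as fh:
        return json.load(fh)


def write_overlay(path: str | Path, overlay: OverlayImage) -> None:
    """Write an RGB overlay as 8-bit PNG."""
    data = np.round(np.clip(overlay.rgb, 0, 1) * 255).astype(np.uint8)
    iio.imwrite(Path(path), data)


def feature_table(
    summaries: Mapping[tuple[str, str, str], DirectionalSummary]
) -> pd.DataFrame:
    """Long-form feature table from summaries keyed by (image, condition, modality)."""
    rows = []
    for (image, condition, modality), summ in summaries.items():
        for f in FEATURE_NAMES:
            rows.append(
                {
                    "image": image,
                    "condition": condition,
                    "modality": modality,
                    "feature": f,
                    "mean": summ.mean(f),
                    "std": summ.std(f),
                    "L": summ.n_levels,
                    "d": summ.distance,
                    "symmetric": summ.symmetric,
                }
            )
    return pd.DataFrame(rows)


def write_feature_table(
    path: str | Path,
    summaries: Mapping[tuple[str, str, str], DirectionalSummary],
) -> None:
    feature_table(summaries).to_csv(Path(path), index=False)


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    if isinstance(v, np.generic):
        return v.item()
    return v
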