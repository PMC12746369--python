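"""Synthetic biofilm micrograph generator with ground truth.

Emulates fields of rod-shaped bacterial cells growing in clusters, an
optional smooth extracellular-polymeric-substance (EPS) overlayer that
veils cell texture, and three imaging-modality appearance profiles:

* ``optical``  — strong optical blur, weak noise: low texture contrast,
  high homogeneity/energy;
* ``sem``      — intermediate blur, mild edge emphasis, moderate noise;
* ``shem``     — minimal blur, strong edge emphasis and higher
  high-frequency noise: high contrast, low energy, emulating the
  texture statistics of scanning-helium micrographs.

The generator is phenomenological: it reproduces the texture statistics
of the three modalities, not their image-formation physics.  The study
conditions are ``native`` (high EPS coverage, strong veil) and ``treated``
(DNase-like disruption: low coverage, scattered cells, debris fragments).
Everything is deterministic under the scene seed.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
from scipy.ndimage import gaussian_filter

from .glcm import DEFAULT_PIXEL_SIZE, GreyImage

__all__ = [
    "MODALITIES",
    "SceneParams",
    "SceneTruth",
    "render_scene",
    "apply_eps_veil",
    "modality_transform",
    "simulate_micrograph",
    "generate_study",
    "regenerate_study",
]

MODALITIES = ("optical", "sem", "shem")

# appearance profiles: gaussian blur sigma (px), tone-curve gamma,
# unsharp-mask gain, additive gaussian noise sigma ([0, 1] intensity units);
# gamma > 1 compresses the dark background into a narrow band, which is what
# makes low-contrast optical images texturally uniform (high energy)
_PROFILES: dict[str, dict[str, float]] = {
    "optical": {"blur": 1.2, "gamma": 3.0, "sharpen": 0.0, "noise": 0.003},
    "sem": {"blur": 1.0, "gamma": 1.5, "sharpen": 0.5, "noise": 0.015},
    "shem": {"blur": 0.3, "gamma": 1.0, "sharpen": 1.2, "noise": 0.050},
    "identity": {"blur": 0.0, "gamma": 1.0, "sharpen": 0.0, "noise": 0.0},
}

# how opaque the EPS layer is to each modality: helium scatters off the
# outermost surface (fully veiled), optical/SEM largely see through it
EPS_OPACITY: dict[str, float] = {
    "optical": 0.50,
    "sem": 0.55,
    "shem": 1.0,
    "identity": 1.0,
}


@dataclass(frozen=True)
class SceneParams:
    """Full parameterization of one synthetic biofilm scene.

    Lengths are physical (µm) and converted through ``pixel_size``
    (µm/pixel).  The default field is 400x400 px = 100x100 µm at
    0.25 µm/pixel.  ``fragment_density`` is debris fragments per 100 µm²
    (nonzero only for the DNase-treated condition).  ``seed`` fixes the
    whole scene bit-for-bit.
    """

    shape: tuple[int, int] = (400, 400)
    pixel_size: float = DEFAULT_PIXEL_SIZE
    n_cells: int = 60
    cell_length_um: float = 4.0
    cell_width_um: float = 0.6
    n_clusters: int = 4
    cluster_spread_um: float = 12.0
    eps_coverage: float = 0.9
    veil_strength: float = 0.85
    fragment_density: float = 0.0
    residue_amplitude: float = 0.0
    modality: str = "shem"
    noise_sigma: float = 0.01
    blur_sigma: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("eps_coverage", "veil_strength"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        if min(self.shape) < 1 or self.pixel_size <= 0:
            raise ValueError("field dimensions must be positive")
        if self.n_cells < 0 or self.n_clusters < 1:
            raise ValueError("n_cells >= 0 and n_clusters >= 1 required")
        if self.fragment_density < 0:
            raise ValueError("fragment_density must be >= 0")
        if self.residue_amplitude < 0:
            raise ValueError("residue_amplitude must be >= 0")
        if self.modality not in _PROFILES:
            raise ValueError(f"unknown modality {self.modality!r}")

    @classmethod
    def native(cls, modality: str = "shem", seed: int = 0, **kw: Any) -> "SceneParams":
        """Untreated biofilm: near-complete smooth EPS veil, tight clusters."""
        defaults = dict(
            eps_coverage=0.9,
            veil_strength=0.85,
            fragment_density=0.0,
            cluster_spread_um=12.0,
        )
        defaults.update(kw)
        return cls(modality=modality, seed=seed, **defaults)

    @classmethod
    def treated(cls, modality: str = "shem", seed: int = 0, **kw: Any) -> "SceneParams":
        """DNase-treated biofilm: sparse veil, scattered cells, debris."""
        defaults = dict(
            eps_coverage=0.2,
            veil_strength=0.5,
            fragment_density=2.0,
            residue_amplitude=0.18,
            cluster_spread_um=25.0,
        )
        defaults.update(kw)
        return cls(modality=modality, seed=seed, **defaults)

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["shape"] = list(self.shape)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "SceneParams":
        d = dict(d)
        d["shape"] = tuple(d["shape"])
        return cls(**d)


@dataclass(frozen=True)
class SceneTruth:
    """Ground truth for one rendered scene."""

    cell_mask: np.ndarray  # bool, True on cell (or fragment) body
    eps_mask: np.ndarray  # bool, True where the EPS layer sits
    cells: tuple[dict, ...]  # per-object geometry records

    def __post_init__(self) -> None:
        if self.cell_mask.shape != self.eps_mask.shape:
            raise ValueError("truth masks must share the image shape")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int], sigma: float) -> np.ndarray:
    """Unit-variance low-frequency gaussian random field."""
    f = gaussian_filter(rng.standard_normal(shape), sigma)
    s = f.std()
    return f / s if s > 0 else f


def _render_rod(
    canvas: np.ndarray,
    mask: np.ndarray,
    centre: tuple[float, float],
    theta: float,
    length_px: float,
    radius_px: float,
    brightness: float,
) -> None:
    """Draw one capsule-shaped rod with cylindrical (Lambertian-like) shading."""
    H, W = canvas.shape
    cy, cx = centre
    hl = max(length_px / 2.0 - radius_px, 0.0)  # half-length of the axis segment
    ay, ax = cy - hl * math.sin(theta), cx - hl * math.cos(theta)
    by, bx = cy + hl * math.sin(theta), cx + hl * math.cos(theta)
    pad = int(math.ceil(radius_px)) + 2
    r0 = max(int(math.floor(min(ay, by))) - pad, 0)
    r1 = min(int(math.ceil(max(ay, by))) + pad + 1, H)
    c0 = max(int(math.floor(min(ax, bx))) - pad, 0)
    c1 = min(int(math.ceil(max(ax, bx))) + pad + 1, W)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    # point-to-segment distance
    vy, vx = by - ay, bx - ax
    vv = vy * vy + vx * vx
    if vv > 0:
        t = np.clip(((yy - ay) * vy + (xx - ax) * vx) / vv, 0.0, 1.0)
    else:
        t = np.zeros_like(yy, dtype=float)
    dy = yy - (ay + t * vy)
    dx = xx - (ax + t * vx)
    dist = np.sqrt(dy * dy + dx * dx)
    inside = dist <= radius_px
    if not inside.any():
        return
    h = np.sqrt(np.clip(1.0 - (dist / radius_px) ** 2, 0.0, 1.0))
    val = (0.55 + 0.30 * h) * brightness
    sub = canvas[r0:r1, c0:c1]
    np.copyto(sub, np.maximum(sub, np.where(inside, val, 0.0)))
    mask[r0:r1, c0:c1] |= inside


def _eps_mask(rng: np.random.Generator, shape: tuple[int, int], coverage: float) -> np.ndarray:
    """Smooth random region covering the requested area fraction exactly."""
    if coverage <= 0:
        return np.zeros(shape, dtype=bool)
    if coverage >= 1:
        return np.ones(shape, dtype=bool)
    f = _smooth_field(rng, shape, sigma=12.0)
    thr = np.quantile(f, 1.0 - coverage)
    return f >= thr


def render_scene(params: SceneParams) -> tuple[GreyImage, SceneTruth]:
    """Render the raw (unveiled) scene and its ground truth.

    Rod-shaped cells are placed in gaussian clusters and drawn as shaded
    capsules over a gently varying background; debris fragments (short
    rods) are added at ``fragment_density``, and ``residue_amplitude``
    adds the mid-frequency mottle of sub-resolution disrupted-matrix
    debris.  The EPS mask is generated
    here at ``params.eps_coverage`` but the veil is *not* applied — see
    :func:`apply_eps_veil`.  Deterministic given ``params.seed``.
    """
    rng = np.random.default_rng(params.seed)
    H, W = params.shape
    px = params.pixel_size

    length_px = params.cell_length_um / px
    radius_px = params.cell_width_um / (2.0 * px)
    margin = length_px / 2.0 + 2.0
    if params.n_cells > 0 and 2 * margin >= min(H, W):
        raise ValueError(
            f"cells of length {params.cell_length_um} um cannot fit a "
            f"{H}x{W} px field at {px} um/px"
        )

    canvas = 0.30 + 0.05 * _smooth_field(rng, (H, W), 15.0) \
        + 0.02 * _smooth_field(rng, (H, W), 4.0)
    cell_mask = np.zeros((H, W), dtype=bool)
    cells: list[dict] = []

    spread_px = params.cluster_spread_um / px
    centres = rng.uniform(margin, [H - margin, W - margin], size=(params.n_clusters, 2))
    for _ in range(params.n_cells):
        k = rng.integers(params.n_clusters)
        cy, cx = np.clip(
            centres[k] + rng.normal(0.0, spread_px, size=2),
            margin,
            [H - margin, W - margin],
        )
        theta = rng.uniform(0.0, math.pi)
        brightness = rng.uniform(0.85, 1.05)
        _render_rod(canvas, cell_mask, (cy, cx), theta, length_px, radius_px, brightness)
        cells.append(
            {
                "kind": "cell",
                "centre": (float(cy), float(cx)),
                "theta": float(theta),
                "length_um": params.cell_length_um,
                "width_um": params.cell_width_um,
            }
        )

    area_um2 = H * W * px * px
    n_frag = int(round(params.fragment_density * area_um2 / 100.0))
    for _ in range(n_frag):
        fy = rng.uniform(2.0, H - 2.0)
        fx = rng.uniform(2.0, W - 2.0)
        theta = rng.uniform(0.0, math.pi)
        flen = rng.uniform(0.8, 2.5) / px
        frad = 0.25 / px
        brightness = rng.uniform(0.7, 1.0)
        _render_rod(canvas, cell_mask, (fy, fx), theta, flen, frad, brightness)
        cells.append(
            {
                "kind": "fragment",
                "centre": (float(fy), float(fx)),
                "theta": float(theta),
                "length_um": float(flen * px),
                "width_um": float(2 * frad * px),
            }
        )

    if params.residue_amplitude > 0:
        # sub-resolution debris of the disrupted matrix: mid-frequency mottle
        canvas = canvas + params.residue_amplitude * _smooth_field(rng, (H, W), 2.5)

    if params.blur_sigma > 0:
        canvas = gaussian_filter(canvas, params.blur_sigma)
    if params.noise_sigma > 0:
        canvas = canvas + rng.normal(0.0, params.noise_sigma, size=(H, W))
    canvas = np.clip(canvas, 0.0, 1.0)

    eps = _eps_mask(rng, (H, W), params.eps_coverage)
    truth = SceneTruth(cell_mask=cell_mask, eps_mask=eps, cells=tuple(cells))
    return GreyImage(canvas, pixel_size=px), truth


def apply_eps_veil(
    image: GreyImage,
    truth: SceneTruth,
    strength: float,
    coverage: float | None = None,
) -> GreyImage:
    """Blend the EPS region toward a smooth, flattened surface.

    Within ``truth.eps_mask`` the image is pulled toward a heavily blurred
    and intensity-flattened version of itself, proportionally to
    ``strength`` in [0, 1]; strength 0 returns the image unchanged, and
    full coverage at strength 1 yields a near-featureless surface (high
    windowed energy).  ``coverage``, if given, is validated against the
    mask's actual area fraction (within 2%).
    """
    if not 0.0 <= strength <= 1.0:
        raise ValueError("strength must lie in [0, 1]")
    frac = float(truth.eps_mask.mean())
    if coverage is not None:
        if not 0.0 <= coverage <= 1.0:
            raise ValueError("coverage must lie in [0, 1]")
        if abs(frac - coverage) > 0.02:
            raise ValueError(
                f"truth EPS mask covers {frac:.3f}, not the requested "
                f"{coverage:.3f} +- 0.02"
            )
    if strength == 0.0 or frac == 0.0:
        return GreyImage(image.pixels.copy(), image.pixel_size)

    soft = gaussian_filter(truth.eps_mask.astype(np.float64), 2.0)
    smooth = gaussian_filter(image.pixels, 8.0)
    level = float((smooth * truth.eps_mask).sum() / truth.eps_mask.sum())
    flat = level + 0.12 * (smooth - level)  # faint residual topography
    w = strength * soft
    out = image.pixels * (1.0 - w) + flat * w
    return GreyImage(np.clip(out, 0.0, 1.0), image.pixel_size)


def modality_transform(image: GreyImage, profile: str, seed: int = 0) -> GreyImage:
    """Apply one modality's appearance profile (blur, edge emphasis, noise).

    On a fixed reference scene the profiles order whole-image Haralick
    contrast as optical < sem < shem and energy the other way round.  The
    ``identity`` profile returns the image unchanged.  The noise
    realization is fixed by ``seed``.
    """
    if profile not in _PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; choose from {sorted(_PROFILES)}"
        )
    if profile == "identity":
        return GreyImage(image.pixels.copy(), image.pixel_size)
    prof = _PROFILES[profile]
    lo, hi = image.intensity_range()
    x = (image.pixels - lo) / (hi - lo) if hi > lo else np.zeros(image.shape)
    b = gaussian_filter(x, prof["blur"]) if prof["blur"] > 0 else x
    if prof["gamma"] != 1.0:
        b = np.clip(b, 0.0, 1.0) ** prof["gamma"]
    if prof["sharpen"] > 0:
        b = b + prof["sharpen"] * (b - gaussian_filter(b, 2.0))
    if prof["noise"] > 0:
        rng = np.random.default_rng(seed)
        b = b + rng.normal(0.0, prof["noise"], size=image.shape)
    return GreyImage(np.clip(b, 0.0, 1.0), image.pixel_size)


_MODALITY_CODE = {"optical": 1, "sem": 2, "shem": 3, "identity": 4}


def _child_seed(*entropy: int) -> int:
    """Derive a reproducible sub-seed below 2**31."""
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def simulate_micrograph(
    condition: str,
    modality: str,
    seed: int = 0,
    params: SceneParams | None = None,
) -> tuple[GreyImage, SceneTruth]:
    """Render one condition under one modality: scene → veil → transform.

    The veil strength is scaled by the modality's EPS opacity (helium is
    fully blocked by the EPS layer; optical and SEM largely penetrate it).
    """
    if condition not in ("native", "treated"):
        raise ValueError("condition must be 'native' or 'treated'")
    if params is None:
        maker = SceneParams.native if condition == "native" else SceneParams.treated
        params = maker(modality=modality, seed=seed)
    raw, truth = render_scene(params)
    veiled = apply_eps_veil(
        raw, truth, strength=params.veil_strength * EPS_OPACITY[modality]
    )
    out = modality_transform(
        veiled, modality, seed=_child_seed(params.seed, _MODALITY_CODE[modality])
    )
    return out, truth


def _write_tiff16(path: Path, image: GreyImage) -> None:
    import tifffile

    data = np.round(np.clip(image.pixels, 0.0, 1.0) * 65535).astype(np.uint16)
    tifffile.imwrite(path, data)


def _write_mask_png(path: Path, mask: np.ndarray) -> None:
    import imageio.v3 as iio

    iio.imwrite(path, (mask.astype(np.uint8) * 255))


def _build_study(seed: int) -> dict[str, Any]:
    """The parameter set of one full study, derived from the master seed."""
    conditions = {}
    for ci, condition in enumerate(("native", "treated")):
        scene_seed = _child_seed(seed, ci)
        maker = SceneParams.native if condition == "native" else SceneParams.treated
        conditions[condition] = maker(seed=scene_seed).to_dict()
    return {"seed": int(seed), "conditions": conditions}


def _realize_study(study: dict[str, Any], out_dir: Path) -> dict[str, Any]:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    files: dict[str, str] = {}
    for condition, pdict in study["conditions"].items():
        base_params = SceneParams.from_dict(pdict)
        raw, truth = render_scene(base_params)
        _write_mask_png(out_dir / f"{condition}_cell_mask.png", truth.cell_mask)
        _write_mask_png(out_dir / f"{condition}_eps_mask.png", truth.eps_mask)
        files[f"{condition}_cell_mask"] = f"{condition}_cell_mask.png"
        files[f"{condition}_eps_mask"] = f"{condition}_eps_mask.png"
        for modality in MODALITIES:
            veiled = apply_eps_veil(
                raw,
                truth,
                strength=base_params.veil_strength * EPS_OPACITY[modality],
            )
            img = modality_transform(
                veiled,
                modality,
                seed=_child_seed(base_params.seed, _MODALITY_CODE[modality]),
            )
            name = f"{condition}_{modality}.tif"
            _write_tiff16(out_dir / name, img)
            files[f"{condition}_{modality}"] = name
    manifest = dict(study)
    manifest["files"] = files
    manifest["pixel_size_um"] = DEFAULT_PIXEL_SIZE
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


def generate_study(seed: int, out_dir: str | Path) -> dict[str, Any]:
    """Write the full synthetic study to ``out_dir``.

    Produces native + treated scenes under all three modality profiles
    (6 × 16-bit TIFF), the two truth mask pairs (PNG), and a JSON manifest
    holding every parameter and seed.  Regenerating from the manifest
    (:func:`regenerate_study`) is bit-identical.
    """
    return _realize_study(_build_study(seed), Path(out_dir))


def regenerate_study(manifest_path: str | Path, out_dir: str | Path) -> dict[str, Any]:
    """Re-render a study from its manifest, bit-identically."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    study = {"seed": manifest["seed"], "conditions": manifest["conditions"]}
    return _realize_study(study, Path(out_dir))
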