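# Methods

## Co-occurrence matrices and Haralick statistics

A greyscale micrograph is quantized to `L` grey levels by linear binning
of an intensity range `[lo, hi]` into `L` equal bins, clamping values at
or beyond the endpoints (the MATLAB GRAYCOMATRIX linear-scaling
convention: with `L = 8` over `[0, 255]`, bin edges fall at multiples of
32). By default `[lo, hi]` is the image's own min/max; for any
comparison *across* images (condition tables, trend analyses) a fixed
common range should be passed instead, because per-image min–max makes
grey levels mean different things in different images and is sensitive
to single extreme pixels. The package's comparison examples and the
acceptance script use the fixed range `(0, 1)` of the simulated
intensity scale.

Co-occurrence counting uses the four standard directions with the
displacement convention 0° → (0, +d), 45° → (−d, +d), 90° → (−d, 0),
135° → (−d, −d) in (row, col) coordinates, rows increasing downward.
Pairs whose neighbour leaves the image are skipped; an offset with no
valid pair raises an explicit error naming the offset. Accumulation is
asymmetric by default (each ordered pair counted once), with a
`symmetric` flag that also accumulates the reversed pair. Note that
scikit-image's diagonal displacements carry the opposite row sign; the
two conventions coincide under symmetric accumulation, which is how the
test suite cross-checks against it.

From the normalized matrix `p(i, j)` the five statistics are computed
exactly as defined in the package README. Numerical conventions:

* `0 · ln 0 ≡ 0` in the entropy sum; entropy is reported in nats
  (natural log) by default, configurable via `entropy_base` (use 2 for
  bits).
* Correlation is computed from raw moments
  (`cov = Σ ij p − μᵢ μⱼ`); when either marginal variance is zero the
  value is undefined and reported as NaN — never silently 0. NaN
  propagates through offset averages and maps.
* Directional summaries use the population standard deviation
  (divide by the number of offsets, 4). The std therefore measures
  anisotropy of the texture, not sampling error.

Defaults `L = 8`, `d = 1`, asymmetric accumulation correspond to the
common toolchain defaults for this analysis; all are configurable.

## Sliding-window texture maps

A square window of odd side `s` (default 21 px ≈ 5 µm at the default
0.25 µm/pixel — a few cell widths) slides over the image with stride 1.
Within each window the per-offset co-occurrence counts are obtained
exactly via integral images of the `L²` pair-indicator planes, so each
window's counts equal brute-force enumeration of the pairs wholly
contained in it; features are computed per offset and averaged over
offsets, matching the whole-image convention. The map value sits at the
window centre. Consequently the map value at any centre equals the
directional summary of that window extracted as a standalone image and
quantized over the same range — to floating-point summation order,
i.e. within ~1e−12.

Boundary handling is valid-only by default (a missing border of
`(s−1)/2` pixels, no padding artefacts); reflect-padding is available
when full coverage matters. With stride > 1, skipped centres are filled
with the nearest computed value.

Feature-map overlays render the base image in grey and the map linearly
from red (low) to green (high) between stated bounds, by default the
2nd–98th percentile of the defined map values; the bounds, colours and
blend weight are recorded in the overlay's provenance so a colour bar
can be reconstructed. Rendering is monotone: a higher map value never
yields a redder pixel.

## Condition comparison and the noise-injection experiment

`compare_conditions` assembles (modality × condition) summaries into a
mean ± std table, signed treated − native deltas, and trend flags for
contrast and energy. Entropy is included as an extra column alongside
the four classical statistics. No hypothesis testing is attached: with
one field per condition the directional std measures anisotropy, and a
formal test would need replicate fields.

The noise experiment makes "loss of textural uniformity" operational as
the drop in mean windowed energy. Zero-mean Gaussian noise with
standard deviation `a · (max − min)` is added for each amplitude `a`,
clipped back to the original intensity range; amplitude 0 reproduces
the input bit-for-bit. The global root-mean-square intensity change
(as a fraction of the dynamic range) quantifies how little the image
itself changes, while the energy map — quantized over the *original*
image's range for comparability — quantifies how much the texture
statistic changes. On the simulated native SHeM surface, amplitude 0.05
changes the image by only ~5% RMS yet roughly halves the mean windowed
energy.

## The synthetic scene generator

The generator is phenomenological: it emulates the *texture statistics*
of the three modalities, not helium-, electron- or photon-optics. What
it renders:

* **Cells.** Rod-shaped capsules (default 4.0 × 0.6 µm, a realistic
  shape for *C. difficile*-like rods) with cylindrical Lambertian-style
  shading, placed in Gaussian clusters (default 4 clusters, 12 µm
  spread native / 25 µm treated) on a gently varying background, then
  lightly blurred (σ = 0.8 px) with sensor noise (σ = 0.01).
* **EPS veil.** A smooth random region covering exactly the requested
  area fraction (native default 0.9) within which the image is blended
  toward a heavily blurred, intensity-flattened surface proportionally
  to the veil strength (native default 0.85). Full veil at full
  coverage drives every window to the energy maximum of 1, so the
  "veiled is smoother" comparison is strict only where the unveiled
  window was not already perfectly uniform.
* **Treatment.** The treated condition lowers EPS coverage to 0.2 and
  strength to 0.5, scatters the clusters, and adds debris: discrete
  fragments (short rods, 2 per 100 µm²) plus a mid-frequency "residue
  mottle" field (amplitude 0.18, correlation length ≈ 2.5 px)
  representing sub-resolution fragments of the disrupted matrix. The
  mottle matters because 1-px-wide fragments alone are erased by the
  optical blur and would leave the optical modality blind to the
  treatment.
* **Modality profiles.** Each profile applies blur, a tone-curve gamma,
  unsharp-mask edge emphasis and additive noise:
  optical (blur 1.2 px, γ = 3, no sharpening, noise 0.003),
  SEM (blur 1.0, γ = 1.5, sharpen 0.5, noise 0.015),
  SHeM (blur 0.3, γ = 1, sharpen 1.2, noise 0.05), plus an `identity`
  profile. The γ > 1 of the optical profile compresses the dark
  background into a narrow band, which is what makes a low-contrast
  optical image texturally uniform (high energy); the constants were
  chosen so that, on a reference scene, whole-image contrast orders
  optical < SEM < SHeM and energy the reverse — the ordering these
  modalities show on real biofilm surfaces.
* **EPS opacity per modality.** In the full study pipeline the veil
  strength is multiplied by a modality opacity (optical 0.50, SEM 0.55,
  SHeM 1.0): helium scatters off the outermost EPS surface, whereas
  optical and SEM partially penetrate it. This is what makes
  SHeM-vs-optical channel overlays informative (features visible in
  blue only are EPS-masked in the helium image) while every modality
  still registers the treatment trend.

Everything is driven by `numpy.random.default_rng(seed)` in a fixed
order, so a scene, a study and its manifest regenerate bit-identically.
Derived seeds (per condition and modality) come from
`numpy.random.SeedSequence` and stay below 2³¹.

What the generator does **not** emulate: real EPS chemistry and
hydration, three-dimensional structure and confocal sectioning, imaging
artefacts such as SEM charging or optical interference fringes, and
instrument-specific noise spectra. Passing trend tests therefore shows
that the pipeline recovers treatment- and modality-dependent texture
differences *of the kind described*, not that it reproduces any
particular instrument's numbers.

## Two-channel overlays

Cross-modality composites place each min–max-normalized image in its
own colour channel (SHeM red, optical blue by convention). Inputs are
assumed pre-aligned; only a manual integer (row, col) translation is
offered, recorded in provenance together with the normalization bounds.
Automatic or subpixel registration is deliberately out of scope.

## Problem sizes and determinism

The default synthetic field is 400 × 400 px (100 × 100 µm). Trend and
ordering analyses use 20 seeds per comparison; the acceptance script
completes in under a minute on one CPU at these sizes. All stochastic
steps take explicit seeds; the test suite is fully deterministic
(hypothesis runs derandomized).

## Known limitations

* Quantization, window size, stride, symmetry and entropy base are
  conventions, not measured facts; absolute feature values depend on
  them, which is why cross-image comparisons should fix the
  quantization range and all parameters.
* Correlation is undefined (NaN) on uniform windows, so correlation
  maps of smooth images are largely undefined rather than zero.
* The generator's realism is statistical; its parameter defaults are
  design choices documented above, not fitted to any micrograph.
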