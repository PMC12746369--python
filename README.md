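# biofilmtex

Texture quantification of bacterial-biofilm micrographs with grey-level
co-occurrence matrices (GLCMs) and Haralick statistics.

Biofilms encase their cells in an extracellular polymeric substance (EPS)
matrix. Surface-sensitive imaging (scanning helium microscopy, SHeM) sees
the smooth EPS overlayer itself, while optical and scanning electron
microscopy (SEM) largely see through it to the cells beneath. Texture
statistics turn that qualitative difference into numbers: a veiled,
uniform surface has low GLCM contrast and high energy; a disrupted
surface of exposed cells and debris has the opposite signature. This
package is for microscopists and image analysts who want to quantify
such surface texture, compare it across imaging modalities and
treatment conditions (e.g. native vs DNase-treated biofilms), and map it
spatially.

## The statistics

An image is quantized to `L` grey levels (default `L = 8`). For a pixel
displacement `(Δr, Δc)` the co-occurrence matrix counts level pairs, and
after normalization to a joint distribution `p(i, j)` the five Haralick
statistics are:

| statistic   | definition |
|-------------|------------|
| contrast    | Σᵢⱼ (i−j)² p(i,j) |
| correlation | Σᵢⱼ (i−μᵢ)(j−μⱼ) p(i,j) / (σᵢ σⱼ) |
| energy      | Σᵢⱼ p(i,j)² |
| homogeneity | Σᵢⱼ p(i,j) / (1+\|i−j\|) |
| entropy     | −Σᵢⱼ p(i,j) ln p(i,j) |

Each is computed at the four standard directions (0°, 45°, 90°, 135°,
distance 1) and summarised as mean ± standard deviation over the four
offsets. A sliding window (default 21 px ≈ 5 µm at 0.25 µm/pixel)
produces spatially resolved texture maps that can be rendered as
red→green overlays on the grey micrograph.

Because the original micrographs are not publicly deposited, the package
ships a seeded synthetic generator (`biofilmtex.simulate`) that renders
rod-shaped cells in clusters, an optional smooth EPS veil, debris
fragments for the treated condition, and the three modality appearance
profiles — with ground-truth masks, so the whole pipeline is testable
end to end.

## Worked example

```python
from biofilmtex import simulate_micrograph, directional_summary, compare_conditions

summaries = {}
for cond in ("native", "treated"):
    for mod in ("optical", "sem", "shem"):
        img, _ = simulate_micrograph(cond, mod, seed=1)
        summaries[(mod, cond)] = directional_summary(img, intensity_range=(0, 1))

table = compare_conditions(summaries)
print(table.formatted())
print(table.deltas.round(3))
```

prints

```
modality                     optical            sem           shem
condition feature
native    contrast     0.008 ± 0.001  0.153 ± 0.007  0.500 ± 0.009
          correlation  0.669 ± 0.055  0.707 ± 0.013  0.290 ± 0.013
          energy       0.973 ± 0.001  0.512 ± 0.002  0.299 ± 0.001
          homogeneity  0.996 ± 0.001  0.926 ± 0.002  0.788 ± 0.001
          entropy      0.091 ± 0.004  1.115 ± 0.008  1.675 ± 0.002
treated   contrast     0.063 ± 0.011  0.308 ± 0.053  0.933 ± 0.144
          correlation  0.850 ± 0.027  0.883 ± 0.020  0.822 ± 0.028
          energy       0.760 ± 0.006  0.190 ± 0.010  0.068 ± 0.004
          homogeneity  0.970 ± 0.005  0.860 ± 0.018  0.723 ± 0.017
          entropy      0.616 ± 0.021  2.108 ± 0.062  3.037 ± 0.061

          contrast  correlation  energy  homogeneity  entropy
modality
optical      0.055        0.181  -0.213       -0.026    0.525
sem          0.156        0.176  -0.322       -0.066    0.993
shem         0.433        0.532  -0.231       -0.065    1.363
```

Reading the table: contrast rises from optical to SEM to SHeM (the
helium image is the most surface-textured) and energy falls the same
way; and for every modality the treated condition raises contrast and
lowers energy (positive contrast delta, negative energy delta) — the
texture signature of a disrupted, less uniform biofilm surface.

The standard deviation column is the spread over the four directional
offsets, so it measures texture anisotropy, not replicate error.

A command-line interface mirrors the library:

```sh
biofilmtex simulate --seed 1 --out study/
biofilmtex compare --study study/
biofilmtex map study/native_shem.tif --feature energy --out energy.tif --overlay-out energy.png
biofilmtex overlay --red study/native_shem.tif --blue study/native_optical.tif --out fig2d.png
biofilmtex noise-test study/native_shem.tif --amplitudes 0,0.01,0.05,0.10 --seed 1
```

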