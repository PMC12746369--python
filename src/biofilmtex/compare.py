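"""Whole-image condition/modality comparison and the noise-robustness test.

:func:`compare_conditions` assembles directional Haralick summaries into
a comparison table keyed by (modality, condition) — the mean ± std layout
used for whole-image texture tables — together with signed
native→treated deltas and trend flags (contrast up/down, energy
up/down).

:func:`noise_injection_test` probes how fragile textural uniformity is:
zero-mean Gaussian noise of increasing amplitude (expressed as a
fraction of the image's dynamic range) is added, and both the global RMS
intensity change and the mean windowed energy are recorded.  A small
amplitude barely changes the image globally yet collapses the windowed
energy, which is the operational reading of "loss of textural
uniformity" used here.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .glcm import FEATURE_NAMES, DirectionalSummary, GreyImage
from .mapping import WindowSpec, sliding_window_map

__all__ = [
    "ComparisonTable",
    "NoiseTestResult",
    "compare_conditions",
    "noise_injection_test",
]

#: Features whose native→treated trend is flagged in comparison tables.
TREND_FEATURES = ("contrast", "energy")


@dataclass(frozen=True)
class ComparisonTable:
    """Texture summaries by (modality, condition), with treatment deltas.

    ``deltas`` holds treated mean − native mean per modality and feature;
    ``trends`` flags the direction ("increase"/"decrease"/"unchanged")
    for contrast and energy per modality.
    """

    table: pd.DataFrame  # long form: modality, condition, feature, mean, std
    deltas: pd.DataFrame  # index modality, columns features
    trends: dict[str, dict[str, str]]
    native_label: str = "native"
    treated_label: str = "treated"

    def formatted(self, decimals: int = 3) -> pd.DataFrame:
        """Wide 'mean ± std' table: rows (condition, feature), cols modality."""
        df = self.table.copy()
        df["cell"] = [
            "undefined" if math.isnan(m) else f"{m:.{decimals}f} ± {s:.{decimals}f}"
            for m, s in zip(df["mean"], df["std"])
        ]
        wide = df.pivot_table(
            index=["condition", "feature"],
            columns="modality",
            values="cell",
            aggfunc="first",
        )
        order = [
            (c, f)
            for c in (self.native_label, self.treated_label)
            for f in FEATURE_NAMES
        ]
        return wide.reindex([idx for idx in order if idx in wide.index])


@dataclass(frozen=True)
class NoiseTestResult:
    """Outcome of the noise-injection robustness experiment.

    ``rms_change`` is the root-mean-square intensity change as a fraction
    of the image's dynamic range; ``mean_energy`` is the mean defined
    value of the windowed energy map, both per amplitude.
    """

    amplitudes: tuple[float, ...]
    rms_change: tuple[float, ...]
    mean_energy: tuple[float, ...]
    seed: int
    window: WindowSpec = field(default_factory=WindowSpec)
    n_levels: int = 8

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "amplitude": self.amplitudes,
                "rms_change": self.rms_change,
                "mean_energy": self.mean_energy,
            }
        )


def compare_conditions(
    summaries: Mapping[tuple[str, str], DirectionalSummary],
    native_label: str = "native",
    treated_label: str = "treated",
) -> ComparisonTable:
    """Build the comparison table from per-(modality, condition) summaries.

    Deltas are treated mean − native mean, exactly; a modality missing
    either condition is reported in the long table but omitted from the
    delta rows with a warning.
    """
    rows = []
    for (modality, condition), summ in summaries.items():
        for f in FEATURE_NAMES:
            rows.append(
                {
                    "modality": modality,
                    "condition": condition,
                    "feature": f,
                    "mean": summ.mean(f),
                    "std": summ.std(f),
                }
            )
    table = pd.DataFrame(rows)

    modalities = sorted({m for m, _ in summaries})
    delta_rows = {}
    trends: dict[str, dict[str, str]] = {}
    for modality in modalities:
        nat = summaries.get((modality, native_label))
        tre = summaries.get((modality, treated_label))
        if nat is None or tre is None:
            missing = native_label if nat is None else treated_label
            warnings.warn(
                f"modality {modality!r} lacks condition {missing!r}; "
                "delta row omitted",
                stacklevel=2,
            )
            continue
        deltas = {f: tre.mean(f) - nat.mean(f) for f in FEATURE_NAMES}
        delta_rows[modality] = deltas
        trends[modality] = {
            f: "increase" if deltas[f] > 0 else "decrease" if deltas[f] < 0 else "unchanged"
            for f in TREND_FEATURES
        }
    deltas_df = pd.DataFrame.from_dict(delta_rows, orient="index")
    deltas_df.index.name = "modality"
    return ComparisonTable(
        table=table,
        deltas=deltas_df,
        trends=trends,
        native_label=native_label,
        treated_label=treated_label,
    )


def noise_injection_test(
    image: GreyImage,
    amplitudes: Sequence[float],
    window: WindowSpec | None = None,
    n_levels: int = 8,
    seed: int = 0,
) -> NoiseTestResult:
    """Measure windowed-energy loss under additive Gaussian noise.

    For each amplitude *a* (fraction of the image's dynamic range),
    zero-mean Gaussian noise of standard deviation ``a * range`` is added
    and clipped back to the original intensity range; amplitude 0
    reproduces the input exactly.  The energy map of every noisy image is
    quantized over the *original* image's intensity range so that grey
    levels stay comparable across amplitudes.  Noise realizations are
    independent per amplitude but fixed by ``seed``.
    """
    amps = sorted(float(a) for a in amplitudes)
    if amps and amps[0] < 0:
        raise ValueError("noise amplitudes must be >= 0")
    window = window or WindowSpec()
    lo, hi = image.intensity_range()
    dyn = hi - lo if hi > lo else 1.0
    children = np.random.SeedSequence(seed).spawn(len(amps))

    rms_list: list[float] = []
    energy_list: list[float] = []
    for amp, child in zip(amps, children):
        if amp == 0.0:
            noisy = image.pixels
        else:
            rng = np.random.default_rng(child)
            noisy = np.clip(
                image.pixels + rng.normal(0.0, amp * dyn, size=image.shape),
                lo,
                hi,
            )
        rms = float(np.sqrt(np.mean((noisy - image.pixels) ** 2))) / dyn
        emap = sliding_window_map(
            GreyImage(noisy, image.pixel_size),
            "energy",
            window=window,
            n_levels=n_levels,
            intensity_range=(lo, hi),
        )
        rms_list.append(rms)
        energy_list.append(emap.mean_defined())

    return NoiseTestResult(
        amplitudes=tuple(amps),
        rms_change=tuple(rms_list),
        mean_energy=tuple(energy_list),
        seed=seed,
        window=window,
        n_levels=n_levels,
    )
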