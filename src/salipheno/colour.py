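"""CIELab colour scoring of plant silhouettes.

Foreground pixels of an sRGB photograph are converted to CIELab (illuminant
D65, 2-degree observer) and summarised per plant as the mean L*, a*, b*.
Colour change under treatment is the total colour difference

    deltaE = sqrt(dL*^2 + da*^2 + db*^2)

against the per-population mean colour of the untreated (0 mM) control
plants, so every plant — controls included — carries a deltaE score.
"""

from __future__ import annotations

from typing import Sequence, Tuple

import numpy as np
import pandas as pd
from skimage import color as skcolor

__all__ = ["rgb_to_lab", "delta_e", "cohort_delta_e", "lab_to_rgb8"]

LabTriplet = Tuple[float, float, float]


def rgb_to_lab(image: np.ndarray, mask: np.ndarray,
               summary: str = "mean") -> LabTriplet:
    """Mean (or median) CIELab coordinates over the foreground pixels.

    ``image`` is 8-bit sRGB H x W x 3; the sRGB transfer function, the
    sRGB/D65 primaries matrix and the D65 white point (Xn=95.047, Yn=100,
    Zn=108.883) define the conversion.
    """
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.shape[:2] != mask.shape:
        raise ValueError("image and mask dimensions differ")
    if not mask.any():
        raise ValueError("colour undefined on an empty mask")
    pixels = image[mask].astype(np.float64) / 255.0
    lab = skcolor.rgb2lab(pixels.reshape(-1, 1, 3)).reshape(-1, 3)
    if summary == "mean":
        out = lab.mean(axis=0)
    elif summary == "median":
        out = np.median(lab, axis=0)
    else:
        raise ValueError(f"unknown summary {summary!r}")
    return float(out[0]), float(out[1]), float(out[2])


def lab_to_rgb8(lab: np.ndarray) -> np.ndarray:
    """CIELab triplets -> 8-bit sRGB (gamut-clipped), N x 3."""
    lab = np.asarray(lab, dtype=np.float64).reshape(-1, 3)
    rgb = skcolor.lab2rgb(lab.reshape(-1, 1, 3)).reshape(-1, 3)
    return np.clip(np.round(rgb * 255.0), 0, 255).astype(np.uint8)


def delta_e(sample: Sequence[float], reference: Sequence[float]) -> float:
    """Euclidean (CIE76) total colour difference between two Lab triplets."""
    s = np.asarray(sample, dtype=float)
    r = np.asarray(reference, dtype=float)
    if s.shape != (3,) or r.shape != (3,):
        raise ValueError("Lab triplets must have three components")
    if not (np.isfinite(s).all() and np.isfinite(r).all()):
        raise ValueError("Lab triplets must be finite")
    return float(np.sqrt(((s - r) ** 2).sum()))


def cohort_delta_e(records: pd.DataFrame, *, control_treatment: float = 0,
                   population_col: str = "population",
                   treatment_col: str = "treatment_mM") -> pd.Series:
    """Per-plant deltaE against the population's control-mean colour.

    ``records`` needs columns L_star, a_star, b_star plus the design labels.
    The reference for each population is the mean (L*, a*, b*) of its
    ``control_treatment`` plants; a population without controls is an error.
    """
    for col in ("L_star", "a_star", "b_star", population_col, treatment_col):
        if col not in records.columns:
            raise ValueError(f"missing column {col!r}")
    out = pd.Series(np.nan, index=records.index, name="deltaE")
    for pop, group in records.groupby(population_col):
        controls = group[group[treatment_col] == control_treatment]
        if controls.empty:
            raise ValueError(f"population {pop!r} has no "
                             f"{control_treatment} mM control plants")
        ref = controls[["L_star", "a_star", "b_star"]].mean().to_numpy()
        diffs = group[["L_star", "a_star", "b_star"]].to_numpy() - ref
        out.loc[group.index] = np.sqrt((diffs ** 2).sum(axis=1))
    return out
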