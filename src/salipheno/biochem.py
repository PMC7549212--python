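"""Standard-curve inversions and pigment equations.

Turns raw spectrophotometric absorbances into the biochemical variables of
the salinity-response analysis: proline (P, mg/g fresh weight), hydrogen
peroxide (HP, nM/g fresh weight), chlorophyll a and b, total chlorophyll and
carotenoids (80 %-acetone extract equations).

Unit bookkeeping for P and HP is made explicit through extraction-protocol
parameters (extract volume, sample mass, assay dilution) whose defaults
encode the wet-lab protocol the assays assume; every conversion is therefore
testable in isolation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Tuple

import numpy as np
import pandas as pd

__all__ = [
    "StandardCurve",
    "AbsorbanceReading",
    "BiochemRecord",
    "PROLINE_CURVE",
    "H2O2_CURVE",
    "invert_standard_curve",
    "proline_content",
    "h2o2_content",
    "chlorophyll_a",
    "chlorophyll_b",
    "carotenoids",
    "total_chlorophyll",
    "process_readings",
]


@dataclass(frozen=True)
class StandardCurve:
    """Linear calibration ``absorbance = slope * concentration + intercept``.

    ``valid_range`` is the concentration interval the curve was fitted on;
    inversions outside it are flagged with a warning, never rejected.
    """

    slope: float
    intercept: float
    r2: float = float("nan")
    valid_range: Tuple[float, float] = (0.0, float("inf"))

    def __post_init__(self) -> None:
        if self.slope == 0:
            raise ValueError("standard curve slope must be non-zero")
        lo, hi = self.valid_range
        if not lo < hi:
            raise ValueError("valid_range must be a non-empty interval")


#: Acidic-ninhydrin proline calibration, 0-40 ug/ml.
PROLINE_CURVE = StandardCurve(slope=0.0467, intercept=-0.0734, r2=0.963,
                              valid_range=(0.0, 40.0))
#: Potassium-iodide H2O2 calibration, 0-40 mM.
H2O2_CURVE = StandardCurve(slope=0.0188, intercept=0.046, r2=0.987,
                           valid_range=(0.0, 40.0))


@dataclass(frozen=True)
class AbsorbanceReading:
    """One pigment assay: absorbances at 663, 646 and 470 nm plus the
    extraction volume (ml of 80 % acetone) and fresh sample mass (mg)."""

    A663: float
    A646: float
    A470: float
    acetone_ml: float = 5.0
    sample_mg: float = 100.0

    def __post_init__(self) -> None:
        if min(self.A663, self.A646, self.A470) < 0:
            raise ValueError("absorbances must be non-negative")
        if self.acetone_ml <= 0 or self.sample_mg <= 0:
            raise ValueError("acetone_ml and sample_mg must be positive")


@dataclass(frozen=True)
class BiochemRecord:
    P: float
    HP: float
    Cha: float
    Chb: float
    TC: float
    Carot: float


def invert_standard_curve(curve: StandardCurve, absorbance: float) -> float:
    """Concentration from absorbance, ``x = (y - intercept) / slope``.

    Emits a warning (does not fail) when the inverted concentration lies
    outside the curve's fitted range.
    """
    x = (absorbance - curve.intercept) / curve.slope
    lo, hi = curve.valid_range
    if not lo <= x <= hi:
        warnings.warn(
            f"inverted concentration {x:.4g} outside calibrated range "
            f"[{lo:g}, {hi:g}]", stacklevel=2)
    return x


def proline_content(absorbance: float, *, curve: StandardCurve = PROLINE_CURVE,
                    extract_ml: float = 2.5, sample_g: float = 0.5) -> float:
    """Proline in mg per g fresh weight.

    The assay concentration (ug/ml) read off the standard curve is scaled to
    tissue content:  P = x * extract_ml / sample_g / 1000.  Defaults encode
    0.5 g fresh tissue homogenised at 5 ul/mg (2.5 ml extract).
    """
    x = invert_standard_curve(curve, absorbance)
    return x * extract_ml / sample_g / 1000.0


def h2o2_content(absorbance: float, *, curve: StandardCurve = H2O2_CURVE,
                 extract_ml: float = 5.0, sample_g: float = 0.5,
                 assay_dilution: float = 6.0) -> float:
    """Hydrogen peroxide in nM (nmol) per g fresh weight.

    The assay concentration (mM) is scaled back through the reaction dilution
    (0.5 ml supernatant in a 3.0 ml reaction by default, factor 6) and the
    extract volume:  HP = x * assay_dilution * extract_ml / sample_g * 1000.
    """
    x = invert_standard_curve(curve, absorbance)
    return x * assay_dilution * extract_ml / sample_g * 1000.0


def chlorophyll_a(reading: AbsorbanceReading) -> float:
    """Chlorophyll a per mg sample, 80 %-acetone coefficients."""
    value = (12.21 * reading.A663 - 2.81 * reading.A646) \
        * reading.acetone_ml / reading.sample_mg
    if value < 0:
        warnings.warn("negative chlorophyll a content", stacklevel=2)
    return value


def chlorophyll_b(reading: AbsorbanceReading) -> float:
    """Chlorophyll b per mg sample, 80 %-acetone coefficients."""
    value = (20.13 * reading.A646 - 2.81 * reading.A663) \
        * reading.acetone_ml / reading.sample_mg
    if value < 0:
        warnings.warn("negative chlorophyll b content", stacklevel=2)
    return value


def carotenoids(reading: AbsorbanceReading, cha: float, chb: float) -> float:
    """Carotenoid content from A470 corrected for both chlorophylls.

    ``cha``/``chb`` are the already mass-scaled contents returned by
    :func:`chlorophyll_a` / :func:`chlorophyll_b` for the same reading.
    """
    return ((1000.0 * reading.A470 - 3.27 * cha - 104.0 * chb) / 227.0) \
        * reading.acetone_ml / reading.sample_mg


def total_chlorophyll(cha: float, chb: float) -> float:
    """Total chlorophyll, the exact sum of a and b contents."""
    return cha + chb


def process_readings(df: pd.DataFrame, *, proline_extract_ml: float = 2.5,
                     proline_sample_g: float = 0.5,
                     h2o2_extract_ml: float = 5.0,
                     h2o2_sample_g: float = 0.5,
                     h2o2_assay_dilution: float = 6.0) -> pd.DataFrame:
    """Append P, HP, Cha, Chb, TC, Carot to a table of raw assay columns.

    Expects columns A663, A646, A470, acetone_ml, sample_mg, proline_abs,
    h2o2_abs; returns a copy with the six derived variables appended.
    """
    required = {"A663", "A646", "A470", "acetone_ml", "sample_mg",
                "proline_abs", "h2o2_abs"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    out = df.copy()
    cha, chb, tc, carot, p, hp = [], [], [], [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for row in df.itertuples(index=False):
            reading = AbsorbanceReading(row.A663, row.A646, row.A470,
                                        row.acetone_ml, row.sample_mg)
            a = chlorophyll_a(reading)
            b = chlorophyll_b(reading)
            cha.append(a)
            chb.append(b)
            tc.append(total_chlorophyll(a, b))
            carot.append(carotenoids(reading, a, b))
            p.append(proline_content(row.proline_abs,
                                     extract_ml=proline_extract_ml,
                                     sample_g=proline_sample_g))
            hp.append(h2o2_content(row.h2o2_abs,
                                   extract_ml=h2o2_extract_ml,
                                   sample_g=h2o2_sample_g,
                                   assay_dilution=h2o2_assay_dilution))
    out["P"] = np.asarray(p)
    out["HP"] = np.asarray(hp)
    out["Cha"] = np.asarray(cha)
    out["Chb"] = np.asarray(chb)
    out["TC"] = np.asarray(tc)
    out["Carot"] = np.asarray(carot)
    return out
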