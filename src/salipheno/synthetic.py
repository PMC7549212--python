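"""Synthetic cohort generator for the two-population x five-treatment design.

No raw images are distributed with the study this analysis chain targets, so
every stage is exercised against synthetic plants whose ground truth is
known. The generator emulates:

* plant silhouettes — a stochastic recursive branching model (L-system-like):
  a vertical main stem, first-order laterals at sampled heights and angles,
  and outward-bending sub-branches down to a treatment-dependent recursion
  depth. Complexity (branching depth, branch number, height, spread) peaks
  at the 400 mM NaCl optimum and falls at the extremes; succulence (stem
  diameter) rises monotonically with salinity;
* colour — plant pixels sampled around a treatment-dependent CIELab centre
  that drifts monotonically lighter (L* up), less green (a* up towards 0)
  and more yellow (b* up) with salinity, rendered on a pure-white light-box
  background so band thresholding of the greyscale image is meaningful;
* biochemistry — proline and H2O2 assay concentrations mapped through the
  linear standard curves to absorbances, and pigment absorbances (A663,
  A646, A470) declining with salinity;
* RAPD markers — per-primer monomorphic and polymorphic bands with
  population-structured frequencies.

The industrial-site population (I) is programmed as the more salt-tolerant:
its biomass traits exceed the natural-site population (C) by a margin that
widens with salinity, while C shows the larger colour shift. All draws are
keyed on (seed, population, treatment, replicate), so identical configs give
bit-identical cohorts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from PIL import Image, ImageDraw
from scipy import ndimage

from .colour import lab_to_rgb8
from .rapd import BandMatrix

__all__ = [
    "GeneratorConfig",
    "GroundTruth",
    "AssaySample",
    "generate_plant_image",
    "generate_cohort",
    "generate_biochem",
    "generate_band_matrix",
    "generate_validation_fractal",
    "koch_segments",
    "default_response_curves",
    "default_biochem_curves",
]

Curve = Dict[int, Tuple[float, float]]


def default_response_curves() -> Dict[str, Curve]:
    """Treatment -> (mean, sd) for the morphological traits, in pixels of the
    default 512 x 512 frame. Height, branch number, branching depth and the
    lateral spread factor are unimodal with the optimum at 400 mM; stem
    diameter (succulence) rises monotonically with salinity."""
    return {
        "height_px": {0: (210, 12), 200: (265, 14), 400: (300, 15),
                      800: (255, 14), 1000: (185, 12)},
        # branch numbers vary between replicate plants with a CV of ~20-35%,
        # in line with inter-individual variation in branched halophytes
        "branch_count": {0: (2, 0.7), 200: (4, 1.0), 400: (7, 1.4),
                         800: (4, 1.0), 1000: (2, 0.7)},
        # succulence: stems thicken monotonically with salinity
        "stem_diameter_px": {0: (8, 0.5), 200: (12, 0.6), 400: (18, 0.7),
                             800: (19, 0.8), 1000: (20, 0.8)},
        # sub-branching orders beyond the first-order laterals (0 = plain
        # unbranched laterals)
        "branching_depth": {0: (1, 0), 200: (3, 0), 400: (4, 0),
                            800: (3, 0), 1000: (1, 0)},
        "area_scale": {0: (0.85, 0.05), 200: (1.0, 0.05), 400: (1.18, 0.05),
                       800: (0.95, 0.05), 1000: (0.75, 0.05)},
        # CIELab colour centre: L* up, a* up towards 0, b* up with salinity.
        # Light enough that plant pixels stay inside the 135-240 greyscale
        # segmentation band on the white light-box background.
        "lab_L": {0: (70, 1.5), 200: (72, 1.5), 400: (74, 1.5),
                  800: (76, 1.5), 1000: (78, 1.5)},
        "lab_a": {0: (-20, 1.2), 200: (-16.5, 1.2), 400: (-13, 1.2),
                  800: (-9.5, 1.2), 1000: (-6, 1.2)},
        "lab_b": {0: (27, 1.2), 200: (30, 1.2), 400: (33, 1.2),
                  800: (36, 1.2), 1000: (39, 1.2)},
    }


def default_biochem_curves() -> Dict[str, Curve]:
    """Treatment -> (mean, sd) for the assay-scale biochemical variables:
    proline in ug/ml (ninhydrin assay, calibrated 0-40), H2O2 in mM (KI
    assay, calibrated 0-40) and the three pigment absorbances. Proline rises
    with salinity, H2O2 surges at extreme salinity, pigments decline."""
    return {
        "proline": {0: (5, 0.8), 200: (9, 1.0), 400: (14, 1.3),
                    800: (22, 1.8), 1000: (30, 2.2)},
        "h2o2": {0: (4, 0.5), 200: (4.5, 0.5), 400: (6, 0.7),
                 800: (13, 1.2), 1000: (24, 2.0)},
        "A663": {0: (0.90, 0.04), 200: (0.78, 0.04), 400: (0.65, 0.035),
                 800: (0.50, 0.03), 1000: (0.35, 0.03)},
        "A646": {0: (0.46, 0.02), 200: (0.40, 0.02), 400: (0.33, 0.018),
                 800: (0.26, 0.015), 1000: (0.18, 0.015)},
        "A470": {0: (0.50, 0.02), 200: (0.44, 0.02), 400: (0.37, 0.018),
                 800: (0.29, 0.015), 1000: (0.20, 0.015)},
    }


def default_band_config() -> Tuple[Tuple[str, int, int], ...]:
    """(primer, monomorphic bands, polymorphic bands) per primer."""
    return (("K01", 5, 3), ("M02", 6, 6), ("OPB11", 6, 6))


def default_geometry() -> Dict[str, float]:
    """Branching-geometry constants of the silhouette model.

    Laterals attach between ``attach_lo`` and ``attach_hi`` of the stem
    height (lower ones steeper, 30-60 degrees from the vertical, so
    same-side laterals diverge); each recursion level spawns ``n_children``
    shorter, thinner children per branch that fan outward on their parent's
    side of the vertical — never back over the stem — with drooping children
    (past 90 degrees) shortened so neighbouring crowns do not fuse.
    Calibrated so the default cohort's silhouette density peaks near FD 1.85
    at the 400 mM optimum while every trait stays recoverable from the
    rendered mask.
    """
    return {
        "attach_lo": 0.45, "attach_hi": 0.92,
        "angle_lo": 30.0, "angle_hi": 60.0,
        "branch_len_factor": 0.65,
        "n_children": 3,
        "child_frac_lo": 0.4, "child_frac_hi": 0.85,
        "child_len_decay": 0.70,
        "width_decay": 0.92,
        "bend_lo": 12.0, "bend_hi": 40.0,
        "min_angle": 18.0, "max_angle": 100.0,
        "droop_len_factor": 0.5,
        "lateral_width_factor": 0.6,
        # articulated succulent segments: periodic bulges along every stroke
        "bead_period": 2.0, "bead_bulge": 1.32,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Design and calibration of the synthetic study.

    The defaults ARE the emulated study conditions: 2 populations x
    5 NaCl treatments x 12 replicates = 120 plants, with trait response
    curves calibrated so the optimum sits at 400 mM. ``i_advantage`` is the
    multiplicative edge of the tolerant I population on biomass traits,
    widening with salinity; ``colour_drift_scale`` scales each population's
    colour excursion from its control centre (C shifts more).
    """

    seed: int = 0
    image_size: Tuple[int, int] = (512, 512)
    populations: Tuple[str, ...] = ("C", "I")
    treatments: Tuple[int, ...] = (0, 200, 400, 800, 1000)
    replicates: int = 12
    response_curves: Dict[str, Curve] = field(
        default_factory=default_response_curves)
    biochem_curves: Dict[str, Curve] = field(
        default_factory=default_biochem_curves)
    # the tolerant population's biomass edge is smallest near the shared
    # 400 mM optimum and widens towards both stress extremes, largest at
    # 1000 mM — so the populations' trait profiles converge at the optimum
    # and separate most under severe stress
    i_advantage: Dict[int, float] = field(default_factory=lambda: {
        0: 1.22, 200: 1.12, 400: 1.07, 800: 1.20, 1000: 1.40})
    colour_drift_scale: Dict[str, float] = field(default_factory=lambda: {
        "C": 1.35, "I": 1.0})
    pixel_lab_sd: float = 2.0
    assay_noise_sd: float = 0.002
    geometry: Dict[str, float] = field(default_factory=default_geometry)
    band_config: Tuple[Tuple[str, int, int], ...] = field(
        default_factory=default_band_config)
    individuals_per_population: int = 30
    private_bands_per_population: int = 0

    def __post_init__(self) -> None:
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        for curves in (self.response_curves, self.biochem_curves):
            for trait, curve in curves.items():
                for t, (_, sd) in curve.items():
                    if sd < 0:
                        raise ValueError(f"negative sd for {trait} at {t} mM")
        # the growth optimum: complexity traits peak at 400 mM when the
        # design includes that contrast (weak inequality, so flat sweeps of
        # a single knob remain valid configs)
        for trait in ("height_px", "area_scale", "branching_depth"):
            curve = self.response_curves.get(trait, {})
            if all(t in curve for t in (0, 400, 1000)):
                if not (curve[400][0] >= curve[0][0]
                        and curve[400][0] >= curve[1000][0]):
                    raise ValueError(
                        f"{trait} response must peak at 400 mM")
        # monotone colour drift: L* and b* increase, a* increases towards 0
        for trait in ("lab_L", "lab_a", "lab_b"):
            curve = self.response_curves.get(trait, {})
            ts = sorted(set(curve) & set(self.treatments))
            means = [curve[t][0] for t in ts]
            if any(b < a for a, b in zip(means, means[1:])):
                raise ValueError(f"{trait} must be non-decreasing in salinity")

    def with_(self, **kwargs) -> "GeneratorConfig":
        return replace(self, **kwargs)


@dataclass(frozen=True)
class GroundTruth:
    """Per-plant generative parameters retained for recovery tests."""

    population: str
    treatment: int
    replicate: int
    true_height: float
    true_branch_count: int
    true_stem_diameter: int
    true_lab_mean: Tuple[float, float, float]
    branching_depth: int
    true_area: int  # realised foreground pixel count of the exact mask


@dataclass(frozen=True)
class AssaySample:
    """Raw assay read-out plus the concealed truth behind it."""

    population: str
    treatment: int
    replicate: int
    proline_abs: float
    h2o2_abs: float
    A663: float
    A646: float
    A470: float
    acetone_ml: float
    sample_mg: float
    true_proline_conc: float  # ug/ml on the ninhydrin assay scale
    true_h2o2_conc: float     # mM on the KI assay scale


def _rng(config: GeneratorConfig, stream: int, population: str,
         treatment: int, replicate: int) -> np.random.Generator:
    p = config.populations.index(population)
    t = config.treatments.index(treatment)
    ss = np.random.SeedSequence(config.seed,
                                spawn_key=(stream, p, t, replicate))
    return np.random.default_rng(ss)


def _curve_value(curve: Curve, treatment: int,
                 rng: Optional[np.random.Generator]) -> float:
    mean, sd = curve[treatment]
    if rng is None or sd == 0:
        return float(mean)
    return float(rng.normal(mean, sd))


def _stroke(draw: ImageDraw.ImageDraw, x0: float, y0: float,
            x1: float, y1: float, width: float,
            geo: Mapping[str, float]) -> None:
    """A branch segment: a stroke with periodic bulges.

    The bulges emulate the articulated succulent segments of the shoot; they
    also give the silhouette boundary its fine-scale texture. Bulge spacing
    and amplitude scale with stroke width, so the bead pattern is
    self-similar across branch orders.
    """
    w = max(1, round(width))
    draw.line([(x0, y0), (x1, y1)], fill=255, width=w)
    period = geo.get("bead_period", 0.0)
    bulge = geo.get("bead_bulge", 1.0)
    if period <= 0 or bulge <= 1.0 or w < 3:
        return
    length = float(np.hypot(x1 - x0, y1 - y0))
    step = max(period * w, 2.0)
    r = 0.5 * w * bulge
    n = int(length // step)
    for k in range(n + 1):
        t = min(k * step / max(length, 1e-9), 1.0)
        cx = x0 + t * (x1 - x0)
        cy = y0 + t * (y1 - y0)
        draw.ellipse([cx - r, cy - r, cx + r, cy + r], fill=255)


def _draw_branch(draw: ImageDraw.ImageDraw, x0: float, y0: float,
                 angle: float, length: float, width: float,
                 depth_left: int, rng: np.random.Generator,
                 geo: Mapping[str, float]) -> None:
    """Draw one branch segment and recurse into its children.

    Children fan outward on the parent's side of the vertical, with their
    angle from the vertical clamped to [min_angle, max_angle] degrees:
    never re-approaching the stem (no crown blobs over the main axis) and
    never rising steeply enough for chained children to overtake the apex.
    """
    x1 = x0 + length * np.sin(angle)
    y1 = y0 - length * np.cos(angle)
    _stroke(draw, x0, y0, x1, y1, width, geo)
    if depth_left <= 1 or length < 6:
        return
    n_children = int(geo["n_children"])
    fracs = np.linspace(geo.get("child_frac_lo", 0.4),
                        geo.get("child_frac_hi", 0.85), n_children)
    sgn = 1.0 if angle >= 0 else -1.0
    for i, frac in enumerate(fracs):
        side = 1 if i % 2 == 0 else -1
        bend = rng.uniform(geo["bend_lo"], geo["bend_hi"])
        mag = abs(np.rad2deg(angle)) + side * bend
        mag = float(np.clip(mag, geo["min_angle"], geo["max_angle"]))
        child_angle = sgn * np.deg2rad(mag)
        cx = x0 + frac * (x1 - x0)
        cy = y0 + frac * (y1 - y0)
        child_len = length * geo["child_len_decay"] * rng.uniform(0.85, 1.05)
        if mag > 85.0:
            # drooping children fill the wedge below their parent but must
            # stop short of the next lateral down, or crowns fuse
            child_len *= geo.get("droop_len_factor", 0.6)
        _draw_branch(draw, cx, cy, child_angle, child_len,
                     width * geo["width_decay"], depth_left - 1, rng, geo)


def generate_plant_image(config: GeneratorConfig, population: str,
                         treatment: int, replicate: int
                         ) -> Tuple[np.ndarray, np.ndarray, GroundTruth]:
    """One synthetic plant: (RGB image, exact binary mask, ground truth).

    Deterministic given (config.seed, population, treatment, replicate).
    Raises when the sampled height cannot fit the image frame.
    """
    if population not in config.populations:
        raise ValueError(f"unknown population {population!r}")
    if treatment not in config.treatments:
        raise ValueError(f"unknown treatment {treatment!r}")
    rng = _rng(config, 0, population, treatment, replicate)
    curves = config.response_curves
    adv = config.i_advantage.get(treatment, 1.0) if population == "I" else 1.0

    height = _curve_value(curves["height_px"], treatment, rng) * adv
    height = max(10.0, height)
    n_branches = round(_curve_value(curves["branch_count"], treatment, rng)
                       * adv)
    n_branches = max(0, n_branches)
    stem_w = round(_curve_value(curves["stem_diameter_px"], treatment, rng)
                   * (1.0 + (adv - 1.0) * 0.5))
    stem_w = max(2, stem_w)
    depth = int(round(_curve_value(curves["branching_depth"], treatment,
                                   rng)))
    depth = max(0, depth)
    area_scale = max(0.2, _curve_value(curves["area_scale"], treatment, rng))

    drift = config.colour_drift_scale.get(population, 1.0)
    centre0 = np.array([curves["lab_L"][config.treatments[0]][0],
                        curves["lab_a"][config.treatments[0]][0],
                        curves["lab_b"][config.treatments[0]][0]])
    centre_t = np.array([
        _curve_value(curves["lab_L"], treatment, None),
        _curve_value(curves["lab_a"], treatment, None),
        _curve_value(curves["lab_b"], treatment, None)])
    sds = np.array([curves["lab_L"][treatment][1],
                    curves["lab_a"][treatment][1],
                    curves["lab_b"][treatment][1]])
    lab_centre = centre0 + drift * (centre_t - centre0) + rng.normal(0, sds)
    if population == "I":
        lab_centre[0] += 1.0

    h_img, w_img = config.image_size
    margin = 6
    if height > h_img - 2 * margin:
        raise ValueError(
            f"sampled height {height:.0f} px does not fit an image of "
            f"{h_img} rows (margin {margin} px); enlarge image_size")

    canvas = Image.new("L", (w_img, h_img), 0)
    draw = ImageDraw.Draw(canvas)
    geo = config.geometry
    base_x = w_img / 2 + rng.uniform(-5, 5)
    base_y = h_img - 1 - margin
    top_y = base_y - height + 1
    _stroke(draw, base_x, base_y, base_x, top_y, stem_w, geo)
    drawn_branches = 0
    if n_branches > 0:
        fracs = np.linspace(geo["attach_lo"], geo["attach_hi"], n_branches)
        fracs = fracs + rng.uniform(-0.012, 0.012, size=n_branches)
        lo, hi = geo["angle_lo"], geo["angle_hi"]
        for i, f in enumerate(fracs):
            side = 1 if i % 2 == 0 else -1
            # lower laterals spread steeper than upper ones, so same-side
            # laterals diverge instead of crossing (fewer enclosed pockets)
            rel = (f - geo["attach_lo"]) / max(geo["attach_hi"]
                                               - geo["attach_lo"], 1e-9)
            mean_angle = hi - (hi - lo) * rel
            angle = side * np.deg2rad(float(np.clip(
                mean_angle + rng.uniform(-4, 4), lo, hi)))
            y_attach = base_y - f * (height - 1)
            remaining = (base_y - top_y) * (1 - f)
            length = min(geo["branch_len_factor"] * area_scale * remaining
                         * rng.uniform(0.8, 1.0), 0.75 * remaining)
            if length < 4:
                continue
            _draw_branch(draw, base_x, y_attach, angle, length,
                         max(2.0, stem_w * geo["lateral_width_factor"]),
                         depth + 1, rng, geo)
            drawn_branches += 1

    # the silhouette is the region inside the borderline: small pockets
    # enclosed between overlapping branches belong to the plant, exactly as
    # the downstream segmentation (hole fill on) and area definition treat it
    mask = ndimage.binary_fill_holes(np.asarray(canvas, dtype=np.uint8) > 0)
    truth = GroundTruth(
        population=population, treatment=treatment, replicate=replicate,
        true_height=float(round(height)), true_branch_count=drawn_branches,
        true_stem_diameter=int(stem_w),
        true_lab_mean=tuple(float(v) for v in lab_centre),
        branching_depth=depth, true_area=int(mask.sum()))

    image = np.full((h_img, w_img, 3), 255, dtype=np.uint8)
    n_fg = int(mask.sum())
    if n_fg:
        lab_pix = lab_centre + rng.normal(0.0, config.pixel_lab_sd,
                                          size=(n_fg, 3))
        image[mask] = lab_to_rgb8(lab_pix)
    return image, mask, truth


def generate_cohort(config: GeneratorConfig
                    ) -> List[Tuple[np.ndarray, np.ndarray, GroundTruth]]:
    """The full factorial cohort: populations x treatments x replicates."""
    out = []
    for pop in config.populations:
        for treatment in config.treatments:
            for rep in range(1, config.replicates + 1):
                out.append(generate_plant_image(config, pop, treatment, rep))
    return out


def generate_biochem(config: GeneratorConfig, population: str,
                     treatment: int, replicate: int) -> AssaySample:
    """Assay read-outs for one plant, via the measurement model.

    True assay concentrations are drawn from ``biochem_curves`` and pushed
    through the linear standard curves (proline: y = 0.0467x - 0.0734;
    H2O2: y = 0.0188x + 0.046) plus read noise; pigment absorbances are
    drawn directly. Negative absorbances are clamped to 0 with a warning.
    """
    from .biochem import H2O2_CURVE, PROLINE_CURVE

    if population not in config.populations:
        raise ValueError(f"unknown population {population!r}")
    if treatment not in config.treatments:
        raise ValueError(f"unknown treatment {treatment!r}")
    rng = _rng(config, 1, population, treatment, replicate)
    curves = config.biochem_curves

    proline = _curve_value(curves["proline"], treatment, rng)
    if population == "I":
        proline *= 1.15  # the tolerant population accumulates more osmolyte
    h2o2 = _curve_value(curves["h2o2"], treatment, rng)
    if population == "C":
        h2o2 *= 1.10  # oxidative stress bites the natural population earlier
    proline = max(0.0, proline)
    h2o2 = max(0.0, h2o2)

    pig_adv = 1.06 if population == "I" else 1.0
    a663 = _curve_value(curves["A663"], treatment, rng) * pig_adv
    a646 = _curve_value(curves["A646"], treatment, rng) * pig_adv
    a470 = _curve_value(curves["A470"], treatment, rng) * pig_adv

    noise = config.assay_noise_sd
    p_abs = PROLINE_CURVE.slope * proline + PROLINE_CURVE.intercept
    h_abs = H2O2_CURVE.slope * h2o2 + H2O2_CURVE.intercept
    if noise > 0:
        p_abs += rng.normal(0, noise)
        h_abs += rng.normal(0, noise)
    values = {"proline_abs": p_abs, "h2o2_abs": h_abs,
              "A663": a663, "A646": a646, "A470": a470}
    for name, v in values.items():
        if v < 0:
            warnings.warn(f"negative sampled absorbance for {name}; "
                          "clamped to 0", stacklevel=2)
            values[name] = 0.0
    return AssaySample(
        population=population, treatment=treatment, replicate=replicate,
        proline_abs=float(values["proline_abs"]),
        h2o2_abs=float(values["h2o2_abs"]),
        A663=float(values["A663"]), A646=float(values["A646"]),
        A470=float(values["A470"]), acetone_ml=5.0, sample_mg=100.0,
        true_proline_conc=float(proline), true_h2o2_conc=float(h2o2))


def generate_band_matrix(config: GeneratorConfig) -> BandMatrix:
    """Population-structured RAPD presence/absence matrix.

    Monomorphic bands are present in every individual of both populations;
    polymorphic bands get per-population frequencies in (0, 1), with a
    coin-flip deciding whether a band is strongly divergent between the
    populations. A designated polymorphic band that happens to come out
    fixed and identical everywhere has one individual flipped, so the
    designed polymorphism is always realised. ``private_bands_per_population``
    adds bands fixed present in one population and absent in the other
    (off by default), for strongly structured matrices.
    """
    rng = np.random.default_rng(np.random.SeedSequence(config.seed,
                                                       spawn_key=(2,)))
    n = config.individuals_per_population
    pops = config.populations
    ids = [f"{p}{i}" for p in pops for i in range(1, n + 1)]
    pop_labels = pd.Series([i[0] for i in ids], index=ids, name="population")

    columns: Dict[str, np.ndarray] = {}
    primers: Dict[str, str] = {}
    for primer, n_mono, n_poly in config.band_config:
        if n_mono + n_poly < 1:
            raise ValueError(f"primer {primer} must have at least one band")
        idx = 1
        for _ in range(n_mono):
            band = f"{primer}_{idx}"
            columns[band] = np.ones(len(ids), dtype=int)
            primers[band] = primer
            idx += 1
        for _ in range(n_poly):
            band = f"{primer}_{idx}"
            if rng.random() < 0.5:  # divergent band
                f_c, f_i = rng.uniform(0.6, 0.9), rng.uniform(0.1, 0.4)
                if rng.random() < 0.5:
                    f_c, f_i = f_i, f_c
            else:
                f_c, f_i = rng.uniform(0.3, 0.7), rng.uniform(0.3, 0.7)
            freqs = dict(zip(pops, (f_c, f_i)))
            col = np.concatenate([
                (rng.random(n) < freqs[p]).astype(int) for p in pops])
            halves = [col[k * n:(k + 1) * n] for k in range(len(pops))]
            if all(h.min() == h.max() for h in halves) \
                    and col.min() == col.max():
                col[rng.integers(0, len(col))] ^= 1
            columns[band] = col
            primers[band] = primer
            idx += 1
    if config.private_bands_per_population:
        for k, pop in enumerate(pops):
            for j in range(config.private_bands_per_population):
                band = f"PVT{pop}_{j + 1}"
                col = np.zeros(len(ids), dtype=int)
                col[k * n:(k + 1) * n] = 1
                columns[band] = col
                primers[band] = f"PVT{pop}"
    values = pd.DataFrame(columns, index=ids)
    return BandMatrix(values=values, populations=pop_labels, primers=primers)


def koch_segments(depth: int) -> List[Tuple[complex, complex]]:
    """Koch-curve segment list in unit coordinates; 4**depth segments."""
    pts = [0 + 0j, 1 + 0j]
    rot = np.exp(1j * np.pi / 3)
    for _ in range(depth):
        new = [pts[0]]
        for a, b in zip(pts, pts[1:]):
            d = (b - a) / 3
            new.extend([a + d, a + d + d * rot, a + 2 * d, b])
        pts = new
    return list(zip(pts, pts[1:]))


def generate_validation_fractal(kind: str, depth: int, size: int
                                ) -> np.ndarray:
    """Deterministic oracle shapes of known fractal dimension.

    kinds: ``line`` (FD 1), ``filled_square`` (FD 2),
    ``sierpinski_triangle`` (FD log3/log2, exact box counts when size =
    2**depth) and ``koch_curve`` (FD log4/log3).
    """
    if size < 2 or size & (size - 1):
        raise ValueError("size must be a power of 2")
    if kind == "line":
        mask = np.zeros((size, size), dtype=bool)
        mask[size // 2, :] = True
        return mask
    if kind == "filled_square":
        return np.ones((size, size), dtype=bool)
    if kind == "sierpinski_triangle":
        blocks = 1 << depth
        if blocks > size:
            raise ValueError("size must be >= 2**depth")
        bx, by = np.meshgrid(np.arange(blocks), np.arange(blocks))
        keep = (bx & by) == 0
        cell = size // blocks
        return np.kron(keep, np.ones((cell, cell), dtype=bool))
    if kind == "koch_curve":
        from skimage.draw import line as sk_line

        mask = np.zeros((size, size), dtype=bool)
        y0 = int(size * 0.75)
        for a, b in koch_segments(depth):
            r0 = int(round(y0 - a.imag * (size - 1)))
            c0 = int(round(a.real * (size - 1)))
            r1 = int(round(y0 - b.imag * (size - 1)))
            c1 = int(round(b.real * (size - 1)))
            rr, cc = sk_line(r0, c0, r1, c1)
            mask[rr, cc] = True
        return mask
    raise ValueError(f"unknown validation fractal kind {kind!r}")
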