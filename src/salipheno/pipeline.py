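"""End-to-end orchestration: generate -> measure -> score -> analyse.

``run_all`` produces one reproducible bundle from a generator config: the
120-plant per-plant table (morphometry + colour + biochemistry), the
10 x 12 trait matrix, PCA with between-population distances, per-trait
ANOVA reports and the RAPD classification/dendrogram, optionally written to
a run directory (CSV/JSON/Newick plus a manifest echoing the config and its
hash). ``measure_images`` applies the measurement half to user-supplied
photographs on disk.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
import pandas as pd
from PIL import Image

from . import biochem, colour, morphometry, rapd, stats
from .fractal import fractal_dimension
from .synthetic import (AssaySample, GeneratorConfig, generate_band_matrix,
                        generate_biochem, generate_plant_image)

__all__ = ["ResultBundle", "run_all", "measure_plant", "measure_images",
           "write_bundle"]

logger = logging.getLogger("salipheno")


@dataclass
class ResultBundle:
    per_plant: pd.DataFrame
    trait_matrix: pd.DataFrame
    pca: stats.PCAResult
    distances: pd.Series
    anova: Dict[str, stats.AnovaReport]
    band_matrix: rapd.BandMatrix
    band_classification: rapd.BandClassification
    dendrogram: rapd.Dendrogram
    config: GeneratorConfig
    warnings: List[str]


def measure_plant(image: np.ndarray, scale: float = 1.0,
                  t_low: int = 135, t_high: int = 240,
                  spur_prune_px: float = 5.0) -> Dict[str, float]:
    """Segment one photograph and extract A, B, S, H, FD plus mean Lab."""
    grey = morphometry.to_greyscale(image)
    mask = morphometry.segment(grey, t_low, t_high)
    if not mask.any():
        raise morphometry.EmptyMaskError("segmentation produced no foreground")
    lab = colour.rgb_to_lab(image, mask)
    return {
        "A": morphometry.projected_area(mask, scale),
        "B": morphometry.count_branches(mask, spur_prune_px),
        "S": morphometry.shoot_diameter(mask, scale),
        "H": morphometry.shoot_height(mask, scale),
        "FD": fractal_dimension(mask).fd,
        "L_star": lab[0], "a_star": lab[1], "b_star": lab[2],
    }


def _biochem_columns(sample: AssaySample) -> Dict[str, float]:
    reading = biochem.AbsorbanceReading(sample.A663, sample.A646,
                                        sample.A470, sample.acetone_ml,
                                        sample.sample_mg)
    cha = biochem.chlorophyll_a(reading)
    chb = biochem.chlorophyll_b(reading)
    return {
        "P": biochem.proline_content(sample.proline_abs),
        "HP": biochem.h2o2_content(sample.h2o2_abs),
        "Cha": cha,
        "Chb": chb,
        "TC": biochem.total_chlorophyll(cha, chb),
        "Carot": biochem.carotenoids(reading, cha, chb),
    }


def run_all(config: GeneratorConfig,
            outdir: Optional[Path] = None) -> ResultBundle:
    """Execute the full chain; identical config implies identical bundle."""
    collected: List[str] = []
    rows = []
    logger.info("generating and measuring %d plants",
                len(config.populations) * len(config.treatments)
                * config.replicates)
    for pop in config.populations:
        for treatment in config.treatments:
            for rep in range(1, config.replicates + 1):
                image, mask, truth = generate_plant_image(config, pop,
                                                          treatment, rep)
                with warnings.catch_warnings(record=True) as caught:
                    warnings.simplefilter("always")
                    measured = measure_plant(image)
                    assay = generate_biochem(config, pop, treatment, rep)
                    measured.update(_biochem_columns(assay))
                for w in caught:
                    collected.append(f"{pop}_{treatment}_{rep}: {w.message}")
                row = {"id": f"{pop}_{treatment}_{rep}", "population": pop,
                       "treatment_mM": treatment, "replicate": rep,
                       **measured,
                       "true_height": truth.true_height,
                       "true_branch_count": truth.true_branch_count,
                       "true_stem_diameter": truth.true_stem_diameter,
                       "true_area": truth.true_area,
                       "branching_depth": truth.branching_depth,
                       "true_proline_conc": assay.true_proline_conc,
                       "true_h2o2_conc": assay.true_h2o2_conc}
                rows.append(row)
    per_plant = pd.DataFrame(rows)
    per_plant["deltaE"] = colour.cohort_delta_e(
        per_plant, control_treatment=config.treatments[0])

    logger.info("multivariate analysis")
    trait_matrix = stats.build_trait_matrix(per_plant)
    pca_result = stats.pca(trait_matrix)
    distances = stats.population_distances(pca_result, config.populations,
                                           config.treatments)
    anova_reports = {}
    if config.replicates >= 2:
        for trait in stats.TRAIT_COLUMNS:
            anova_reports[trait] = stats.two_way_anova(per_plant, trait)

    logger.info("RAPD analysis")
    band_matrix = generate_band_matrix(config)
    classification = rapd.classify_bands(band_matrix)
    distances_j = rapd.jaccard_distance_matrix(band_matrix)
    dendrogram = rapd.upgma(distances_j)

    bundle = ResultBundle(per_plant=per_plant, trait_matrix=trait_matrix,
                          pca=pca_result, distances=distances,
                          anova=anova_reports, band_matrix=band_matrix,
                          band_classification=classification,
                          dendrogram=dendrogram, config=config,
                          warnings=collected)
    if outdir is not None:
        write_bundle(bundle, Path(outdir))
    return bundle


def _config_dict(config: GeneratorConfig) -> dict:
    return json.loads(json.dumps(dataclasses.asdict(config), default=str))


def write_bundle(bundle: ResultBundle, outdir: Path) -> None:
    """Write the bundle as CSV/JSON/Newick files plus a manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle.per_plant.to_csv(outdir / "per_plant.csv", index=False)
    bundle.trait_matrix.to_csv(outdir / "trait_matrix.csv")
    pca_payload = {
        "eigenvalues": bundle.pca.eigenvalues.tolist(),
        "variance_pct": bundle.pca.variance_pct.tolist(),
        "retained": bundle.pca.retained,
        "loadings": bundle.pca.loadings.to_dict(),
        "scores": bundle.pca.scores.to_dict(),
    }
    (outdir / "pca.json").write_text(json.dumps(pca_payload, indent=2))
    bundle.distances.rename_axis("treatment_mM").to_csv(
        outdir / "population_distances.csv")
    anova_payload = {
        trait: {
            "anova": report.anova_table.to_dict(),
            "letters": {p: {str(k): v for k, v in lt.items()}
                        for p, lt in report.letters.items()},
            "between_populations": {
                str(t): {"p_adj": float(row["p_adj"]),
                         "significant": bool(row["significant"])}
                for t, row in report.between_populations.iterrows()},
        }
        for trait, report in bundle.anova.items()
    }
    (outdir / "anova.json").write_text(json.dumps(anova_payload, indent=2,
                                                  default=str))
    bundle.band_matrix.values.to_csv(outdir / "band_matrix.csv")
    classification = {
        "overall": bundle.band_classification.overall.to_dict(),
        "per_primer_polymorphic":
            bundle.band_classification.per_primer_polymorphic,
        "n_polymorphic": bundle.band_classification.n_polymorphic,
    }
    (outdir / "rapd_classification.json").write_text(
        json.dumps(classification, indent=2))
    (outdir / "dendrogram.nwk").write_text(
        rapd.write_newick(bundle.dendrogram) + "\n")
    stats.plot_scores(bundle.pca, outdir / "scores_pc12.png")
    if bundle.pca.scores.shape[1] >= 3:
        stats.plot_scores(bundle.pca, outdir / "scores_3d.png", three_d=True)
    cfg = _config_dict(bundle.config)
    manifest = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
        "n_plants": int(len(bundle.per_plant)),
        "warnings": bundle.warnings,
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))


def measure_images(image_dir: Path, scale: float = 1.0,
                   t_low: int = 135, t_high: int = 240) -> pd.DataFrame:
    """Measure every PNG/TIFF named ``<pop>_<treatment>_<rep>.*`` in a
    directory; files that fail to parse or segment are reported and skipped.
    """
    image_dir = Path(image_dir)
    rows = []
    paths = sorted(p for p in image_dir.iterdir()
                   if p.suffix.lower() in {".png", ".tif", ".tiff"})
    for path in paths:
        parts = path.stem.split("_")
        if len(parts) != 3:
            logger.warning("unparseable filename %s (want pop_treatment_rep)",
                           path.name)
            continue
        pop, treatment, rep = parts
        try:
            image = np.asarray(Image.open(path).convert("RGB"))
            measured = measure_plant(image, scale, t_low, t_high)
        except morphometry.EmptyMaskError as exc:
            logger.warning("%s: %s", path.name, exc)
            rows.append({"id": path.stem, "population": pop,
                         "treatment_mM": int(treatment),
                         "replicate": int(rep), "flagged": True})
            continue
        rows.append({"id": path.stem, "population": pop,
                     "treatment_mM": int(treatment), "replicate": int(rep),
                     "flagged": False, **measured})
    return pd.DataFrame(rows)
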