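"""The 246-feature registry.

The pipeline's patient-level phenotype is a fixed, ordered vector of 246
named features:

* 150 nuclear features — 75 per-nucleus base descriptors (10 morphology,
  7 intensity histogram, 31 texture, 27 color) computed on tumor nuclei in
  the whole-tumor region, each aggregated over nuclei by mean and sample
  standard deviation. Category counts at patient level are therefore
  morphology 20, histogram 14, texture 62, color 54.
* 28 density/homogeneity features — 7 spatial statistics for each of
  {tumor, lymphocyte} nuclei in each of {tumor core (CT), tumor periphery
  (PT)}.
* 64 interaction features — 8 statistics of the tumor-cell neighbor-count
  matrix for each of {tumor, lymphocyte} neighbor classes, at radii 50 and
  100 px, in CT and PT.
* 4 composite features (registry flag ``reconciliation``) — the
  lymphocyte:tumor count ratio and total nucleus count in CT and PT.

The registry is the single source of truth for feature names and ordering;
``feature_names()`` is what extractors and downstream stages consume.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

MORPHOLOGY_BASE = [
    "area",
    "perimeter",
    "equivalent_diameter",
    "major_axis",
    "minor_axis",
    "eccentricity",
    "solidity",
    "extent",
    "circularity",
    "aspect_ratio",
]

HISTOGRAM_BASE = [
    "intensity_mean",
    "intensity_sd",
    "intensity_skewness",
    "intensity_kurtosis",
    "intensity_entropy",
    "intensity_p10",
    "intensity_p90",
]

HARALICK_STATS = [
    "energy",
    "contrast",
    "correlation",
    "variance",
    "homogeneity",
    "sum_average",
    "sum_variance",
    "sum_entropy",
    "entropy",
    "difference_variance",
    "difference_entropy",
    "imc1",
    "imc2",
]

GRADIENT_STATS = ["mean", "sd", "skewness", "p90", "otsu_fraction"]

TEXTURE_BASE = [f"glcm_d{d}_{s}" for d in (1, 2) for s in HARALICK_STATS] + [
    f"gradient_{s}" for s in GRADIENT_STATS
]

COLOR_STATS = ["mean", "sd", "skewness", "entropy", "p10", "median", "p90", "min", "max"]
COLOR_BASE = [f"color_{c}_{s}" for c in ("r", "g", "b") for s in COLOR_STATS]

NUCLEUS_BASE = MORPHOLOGY_BASE + HISTOGRAM_BASE + TEXTURE_BASE + COLOR_BASE

_BASE_CATEGORY = (
    {n: "morphology" for n in MORPHOLOGY_BASE}
    | {n: "histogram" for n in HISTOGRAM_BASE}
    | {n: "texture" for n in TEXTURE_BASE}
    | {n: "color" for n in COLOR_BASE}
)

DENSITY_STATS = [
    "density",
    "uniformity_mean",
    "uniformity_sd",
    "uniformity_cv",
    "fraction_empty",
    "morisita",
    "nn_dist_mean",
]

INTERACTION_STATS = [
    "mean",
    "sd",
    "median",
    "max",
    "skewness",
    "q75",
    "fraction_zero",
    "entropy",
]

REGIONS = {"CT": "tumor_core", "PT": "tumor_periphery"}
RADII = (50, 100)


def _interaction_name(neighbor_class: str, stat: str, radius: int, region: str) -> str:
    # r = 50 is the unsuffixed default radius, so the Fig.-style name
    # tumor_lymph_relation_mean_CT is the lymphocyte-count mean at r=50, core.
    short = "lymph" if neighbor_class == "lymphocyte" else "tumor"
    name = f"tumor_{short}_relation_{stat}_{region}"
    if radius != 50:
        name += f"_r{radius}"
    return name


def build_registry() -> pd.DataFrame:
    """Ordered table of all 246 features: name, category, region, formula id."""
    rows: list[dict] = []
    for base in NUCLEUS_BASE:
        for agg in ("mean", "sd"):
            rows.append(
                {
                    "name": f"tumor_{base}_{agg}",
                    "category": _BASE_CATEGORY[base],
                    "region": "whole_tumor",
                    "formula_id": f"nucleus.{base}.{agg}",
                    "flag": "",
                }
            )
    for cls in ("tumor", "lymphocyte"):
        short = "lymph" if cls == "lymphocyte" else "tumor"
        for region in REGIONS:
            for stat in DENSITY_STATS:
                rows.append(
                    {
                        "name": f"{short}_{stat}_{region}",
                        "category": "density_homogeneity",
                        "region": REGIONS[region],
                        "formula_id": f"quadrat.{cls}.{stat}",
                        "flag": "",
                    }
                )
    for region in REGIONS:
        for radius in RADII:
            for cls in ("tumor", "lymphocyte"):
                for stat in INTERACTION_STATS:
                    rows.append(
                        {
                            "name": _interaction_name(cls, stat, radius, region),
                            "category": "interaction",
                            "region": REGIONS[region],
                            "formula_id": f"interaction.{cls}.r{radius}.{stat}",
                            "flag": "",
                        }
                    )
    for region in REGIONS:
        rows.append(
            {
                "name": f"lymph_tumor_ratio_{region}",
                "category": "composite",
                "region": REGIONS[region],
                "formula_id": "composite.lymph_tumor_ratio",
                "flag": "reconciliation",
            }
        )
        rows.append(
            {
                "name": f"total_nuclei_{region}",
                "category": "composite",
                "region": REGIONS[region],
                "formula_id": "composite.total_nuclei",
                "flag": "reconciliation",
            }
        )
    reg = pd.DataFrame(rows)
    assert len(reg) == 246, f"registry has {len(reg)} features, expected 246"
    assert reg["name"].is_unique
    return reg


_REGISTRY = build_registry()


def registry() -> pd.DataFrame:
    return _REGISTRY.copy()


def feature_names(category: str | None = None) -> list[str]:
    reg = _REGISTRY
    if category is not None:
        reg = reg[reg["category"] == category]
    return reg["name"].tolist()


def category_counts() -> dict[str, int]:
    return _REGISTRY["category"].value_counts().to_dict()


def write_registry_tsv(path: str | Path) -> None:
    _REGISTRY.to_csv(path, sep="\t", index=False)
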