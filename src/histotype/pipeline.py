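"""End-to-end orchestration: extract -> cluster -> igp -> stats -> survival.

Each stage is runnable standalone through the library (or the CLI); this
module strings them together over a cohort directory and writes all
outputs as CSV/JSON plus a manifest capturing the configuration and seeds,
so any run is reproducible from its manifest alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cellmap import read_cellmap, read_clinical
from .cluster import ConsensusCluster, classify_to_centroids, igp
from .features import extract_all, prepare_features
from .registry import RADII, write_registry_tsv
from .spatial import DEFAULT_QUADRAT_SIDE
from .stats import cox_ph, feature_subtype_tests, km_logrank

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Tunable parameters of one pipeline run."""

    radii: tuple[float, ...] = RADII
    quadrat_side: float = DEFAULT_QUADRAT_SIDE
    k_range: tuple[int, ...] = (2, 3, 4, 5, 6)
    n_resamples: int = 10_000
    feature_fraction: float = 0.8
    item_fraction: float = 0.8
    delta_min: float = 0.1
    seed: int = 0
    bh_alpha: float = 0.05
    validation_fraction: float = 0.0  # 0 disables the discovery/validation split
    baseline_stage: str = "pT1"
    baseline_grade: str = "G1"
    baseline_sex: str = "female"

    def __post_init__(self) -> None:
        radii = tuple(float(r) for r in self.radii)
        if any(r <= 0 for r in radii) or list(radii) != sorted(radii):
            raise ValueError("radii must be positive and sorted")
        if not (0 < self.feature_fraction <= 1):
            raise ValueError("feature_fraction must be in (0, 1]")
        self.radii = radii


def _iter_cohort(cohort_dir: Path):
    for d in sorted((cohort_dir / "cohort").iterdir()):
        geojson = d / "cells.geojson"
        if not geojson.exists():
            continue
        cellmap = read_cellmap(geojson)
        import imageio.v3 as iio

        image = np.asarray(iio.imread(d / "patch.png"))
        yield cellmap, image


def extract_stage(cohort_dir: str | Path, config: RunConfig, out_dir: Path) -> pd.DataFrame:
    rows = []
    for cellmap, image in _iter_cohort(Path(cohort_dir)):
        rows.append(
            extract_all(cellmap, image, quadrat_side=config.quadrat_side, radii=config.radii)
        )
        logger.info("extracted %s", cellmap.specimen_id)
    F = pd.DataFrame(rows)
    F.index.name = "specimen_id"
    F.to_csv(out_dir / "features.csv")
    write_registry_tsv(out_dir / "feature_registry.tsv")
    return F


def cluster_stage(F: pd.DataFrame, config: RunConfig, out_dir: Path, tag: str = ""):
    F = prepare_features(F)
    est = ConsensusCluster(
        k_range=config.k_range,
        n_resamples=config.n_resamples,
        feature_fraction=config.feature_fraction,
        item_fraction=config.item_fraction,
        delta_min=config.delta_min,
        random_state=config.seed,
    ).fit(F)
    suffix = f"_{tag}" if tag else ""
    for k, M in est.consensus_.items():
        pd.DataFrame(M, index=F.index, columns=F.index).to_csv(
            out_dir / f"consensus_k{k}{suffix}.csv"
        )
    labels = pd.DataFrame(
        {"specimen_id": F.index, "subtype": est.labels_}
    )
    labels.to_csv(out_dir / f"subtypes{suffix}.csv", index=False)
    report = {
        "optimal_k": int(est.optimal_k_),
        "cdf_areas": {int(k): v for k, v in est.cdf_areas_.items()},
        "delta_areas": {int(k): v for k, v in est.delta_areas_.items()},
        "params": {
            "n_resamples": config.n_resamples,
            "feature_fraction": config.feature_fraction,
            "item_fraction": config.item_fraction,
            "delta_min": config.delta_min,
            "seed": config.seed,
        },
    }
    (out_dir / f"clustering_report{suffix}.json").write_text(json.dumps(report, indent=2))
    return est


def run_pipeline(cohort_dir: str | Path, out_dir: str | Path, config: RunConfig | None = None) -> Path:
    """Run all stages over a cohort directory; returns the run directory.

    A missing clinical table skips the statistics and survival stages with
    a warning; earlier stages still complete.
    """
    config = config or RunConfig()
    cohort_dir = Path(cohort_dir)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    F = extract_stage(cohort_dir, config, out)

    rng = np.random.default_rng(config.seed)
    if config.validation_fraction > 0:
        n = len(F)
        is_val = rng.permutation(n) < int(round(config.validation_fraction * n))
        F_disc, F_val = F[~is_val], F[is_val]
        est = cluster_stage(F_disc, config, out, tag="discovery")
        # one shared preprocessing pass so discovery and validation keep
        # identical feature columns for classification
        P = prepare_features(F)
        Fd, Fv = P.loc[F_disc.index], P.loc[F_val.index]
        try:
            igp_res = igp(Fd, est.labels_, Fv, random_state=config.seed)
            igp_out = {
                "igp": {str(g): v for g, v in igp_res.igp.items()},
                "p_values": {str(g): v for g, v in igp_res.p_values.items()},
            }
            (out / "igp.json").write_text(json.dumps(igp_out, indent=2))
            val_labels = igp_res.val_labels
        except ValueError as exc:
            logger.warning("IGP stage skipped: %s (validation specimens still "
                           "classified to nearest centroid)", exc)
            val_labels = classify_to_centroids(Fd, est.labels_, Fv)
        labels = pd.Series(index=F.index, dtype=float)
        labels[F_disc.index] = est.labels_
        labels[F_val.index] = val_labels
        labels = labels.astype(int)
    else:
        est = cluster_stage(F, config, out)
        labels = pd.Series(est.labels_, index=F.index)

    clinical_path = cohort_dir / "clinical.csv"
    if clinical_path.exists():
        clinical = read_clinical(clinical_path).set_index("specimen_id")
        clinical = clinical.loc[[s for s in F.index if s in clinical.index]]
        sub = labels.loc[clinical.index]

        try:
            tests = feature_subtype_tests(F.loc[clinical.index], sub.to_numpy())
            tests.to_csv(out / "feature_subtype_tests.csv")
        except ValueError as exc:
            logger.warning("feature-subtype stage skipped: %s", exc)

        surv = {}
        try:
            fit = km_logrank(clinical, sub.to_numpy())
            for g, tab in fit.km.items():
                tab.to_csv(out / f"km_group{g}.csv", index=False)
            surv = {
                "logrank_statistic": fit.logrank_statistic,
                "logrank_df": fit.logrank_df,
                "logrank_p": fit.logrank_p,
            }
        except ValueError as exc:
            logger.warning("survival stage skipped: %s", exc)
        clin2 = clinical.copy()
        clin2["subtype"] = sub.astype(str).to_numpy()
        try:
            cox = cox_ph(
                clin2,
                ["subtype", "stage", "grade", "sex"],
                baselines={
                    "subtype": str(sorted(sub.unique())[0]),
                    "stage": config.baseline_stage,
                    "grade": config.baseline_grade,
                    "sex": config.baseline_sex,
                },
            )
            cox.cox.to_csv(out / "cox.csv")
        except (ValueError, RuntimeError) as exc:
            logger.warning("Cox stage skipped: %s", exc)
        (out / "survival.json").write_text(json.dumps(surv, indent=2))
    else:
        logger.warning("no clinical.csv in %s; stats/survival stages skipped", cohort_dir)

    manifest = {
        "version": __version__,
        "cohort_dir": str(cohort_dir),
        "config": dataclasses.asdict(config),
    }
    (out / "run_manifest.json").write_text(json.dumps(manifest, indent=2))
    return out
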