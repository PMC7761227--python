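"""Assembly of the full 246-feature phenotype per specimen and cohort.

``extract_all`` concatenates the 150 nuclear features (tumor nuclei in the
whole-tumor region, mean/SD aggregation), the 28 density/homogeneity
features, the 64 interaction features, and the 4 composite features into a
single named row in registry order. ``CellMapFeaturizer`` is the
scikit-learn transformer view of the same computation over a cohort.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .cellmap import CellMap, read_cellmap
from .nuclei import aggregate_patient, nucleus_descriptor_table
from .registry import RADII, feature_names
from .spatial import DEFAULT_QUADRAT_SIDE, spatial_features

logger = logging.getLogger(__name__)


def extract_all(
    cellmap: CellMap,
    image: np.ndarray,
    quadrat_side: float = DEFAULT_QUADRAT_SIDE,
    radii: tuple[float, ...] = RADII,
) -> pd.Series:
    """246-feature phenotype row for one specimen.

    Sub-stage failures surface as missing values with a log entry rather
    than aborting the specimen.
    """
    from .cellmap import assign_roi

    names = feature_names()
    out = pd.Series(np.nan, index=names, name=cellmap.specimen_id, dtype=float)
    flags = assign_roi(cellmap)
    try:
        rows = nucleus_descriptor_table(cellmap, image, flags=flags)
        nuclear = aggregate_patient(rows, cellmap.specimen_id)
        out[nuclear.index] = nuclear.values
    except (ValueError, KeyError) as exc:
        logger.warning("specimen %s: nuclear features missing (%s)",
                       cellmap.specimen_id, exc)
    try:
        spat = spatial_features(
            cellmap, quadrat_side=quadrat_side, radii=radii, flags=flags
        )
        out[spat.index] = spat.values
    except (ValueError, KeyError) as exc:
        logger.warning("specimen %s: spatial features missing (%s)",
                       cellmap.specimen_id, exc)
    return out


def prepare_features(F: pd.DataFrame) -> pd.DataFrame:
    """Make a feature matrix clustering-ready.

    Missing entries (sub-stage failures on degenerate specimens, e.g. too
    few lymphocytes for a nearest-neighbor distance) are imputed with the
    feature's cohort median; features that are constant across the cohort
    carry no rank information and are dropped. Both actions are logged.
    """
    F = F.copy()
    n_missing = int(F.isna().to_numpy().sum())
    if n_missing:
        logger.info("imputing %d missing feature values with cohort medians", n_missing)
        F = F.fillna(F.median())
    constant = F.columns[F.nunique(dropna=False) <= 1]
    if len(constant):
        logger.info("dropping %d constant features: %s", len(constant), list(constant))
        F = F.drop(columns=constant)
    return F


def _load_image(path: str | Path) -> np.ndarray:
    import imageio.v3 as iio

    return np.asarray(iio.imread(path))


class CellMapFeaturizer(BaseEstimator, TransformerMixin):
    """Transform a cohort of cell maps into the n x 246 feature matrix.

    Parameters
    ----------
    quadrat_side : float
        Side length (px) of the quadrat grid for the homogeneity features.
    radii : tuple of float
        Interaction radii in px.

    ``transform`` accepts a list of ``(CellMap, image)`` pairs, a list of
    ``CellMap`` objects whose ``image_ref`` points at a readable raster, or
    a list of GeoJSON paths; it returns a DataFrame indexed by specimen id
    with the 246 registry columns.
    """

    def __init__(
        self,
        quadrat_side: float = DEFAULT_QUADRAT_SIDE,
        radii: tuple[float, ...] = RADII,
    ):
        self.quadrat_side = quadrat_side
        self.radii = radii

    def fit(self, X, y=None):
        self.feature_names_out_ = feature_names()
        return self

    def transform(self, X) -> pd.DataFrame:
        rows = []
        for item in X:
            if isinstance(item, tuple):
                cellmap, image = item
            else:
                cellmap = item if isinstance(item, CellMap) else read_cellmap(item)
                if cellmap.image_ref is None:
                    raise ValueError(
                        f"specimen {cellmap.specimen_id}: no image supplied and "
                        "no image_ref set"
                    )
                image = _load_image(cellmap.image_ref)
            rows.append(
                extract_all(
                    cellmap, image, quadrat_side=self.quadrat_side, radii=tuple(self.radii)
                )
            )
        return pd.DataFrame(rows)

    def fit_transform(self, X, y=None, **kwargs) -> pd.DataFrame:
        return self.fit(X).transform(X)

    def get_feature_names_out(self, input_features=None):
        return np.asarray(feature_names(), dtype=object)


def extract_cohort(
    items,
    quadrat_side: float = DEFAULT_QUADRAT_SIDE,
    radii: tuple[float, ...] = RADII,
) -> pd.DataFrame:
    """Functional wrapper over :class:`CellMapFeaturizer`."""
    return CellMapFeaturizer(quadrat_side=quadrat_side, radii=radii).fit_transform(items)
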