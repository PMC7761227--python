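"""Spatial phenotype of the tumor–immune microenvironment.

Three families of patient-level features are computed from the cell map in
the tumor core (CT) and tumor periphery (PT):

* **Density / homogeneity (28)** — per cell class (tumor, lymphocyte) and
  region: overall density (cells per 10^4 px^2) and quadrat-count
  statistics on a square grid (mean, SD, coefficient of variation,
  fraction of empty quadrats, Morisita aggregation index) plus the mean
  nearest-neighbor distance. Only quadrats with at least half their area
  inside the ROI enter the statistics. Under complete spatial randomness
  the Morisita index is ~1 and the quadrat CV ~ 1/sqrt(mean count);
  clustered infiltrates push both up.

* **Interaction (64)** — each tumor nucleus is a focal point; the numbers
  of tumor and of lymphocyte nuclei whose centroids lie within 50 or 100
  px (Euclidean, centroid to centroid, focal excluded) form the spatial
  interaction matrix, summarized by 8 statistics per neighbor class,
  radius, and region.

* **Composite (4)** — lymphocyte:tumor count ratio and total nucleus count
  per region.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from shapely.geometry import box

from .cellmap import CellClass, CellMap, ROIKind, assign_roi
from .registry import DENSITY_STATS, INTERACTION_STATS, RADII, _interaction_name

logger = logging.getLogger(__name__)

DEFAULT_QUADRAT_SIDE = 96.0
MIN_COVERAGE = 0.5

_REGION_BY_CODE = {"CT": ROIKind.TUMOR_CORE, "PT": ROIKind.TUMOR_PERIPHERY}


def _entropy_bits(counts: np.ndarray) -> float:
    """Shannon entropy (bits) of the empirical distribution of counts."""
    _, freq = np.unique(counts, return_counts=True)
    p = freq / freq.sum()
    return float(-(p * np.log2(p)).sum())


def _skewness(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    sd = x.std()
    if sd == 0:
        return 0.0
    return float(np.mean(((x - x.mean()) / sd) ** 3))


# ---------------------------------------------------------------------------
# quadrat grid / density & homogeneity
# ---------------------------------------------------------------------------

@dataclass
class QuadratGrid:
    """Quadrat counts of one cell class within one ROI.

    Quadrats tile the ROI bounding box; ``coverage`` is the fraction of
    each quadrat's area inside the ROI polygon and only quadrats with
    coverage >= 0.5 are retained.
    """

    roi_kind: ROIKind
    side: float
    counts: np.ndarray  # retained quadrats only
    coverage: np.ndarray

    @property
    def n_quadrats(self) -> int:
        return len(self.counts)


def quadrat_grid(
    cellmap: CellMap,
    roi_kind: ROIKind,
    cell_class: CellClass,
    side: float = DEFAULT_QUADRAT_SIDE,
    flags: pd.DataFrame | None = None,
) -> QuadratGrid:
    """Count nuclei of one class per quadrat over the ROI."""
    roi_kind = ROIKind(roi_kind)
    cell_class = CellClass(cell_class)
    roi_poly = cellmap.roi(roi_kind).shapely
    if flags is None:
        flags = assign_roi(cellmap)
    member_ids = set(
        flags.index[(flags["cell_class"] == cell_class.value) & flags[roi_kind.value]]
    )
    pts = np.asarray(
        [n.centroid for n in cellmap.nuclei if n.id in member_ids], dtype=float
    ).reshape(-1, 2)

    minx, miny, maxx, maxy = roi_poly.bounds
    nx = max(int(np.ceil((maxx - minx) / side)), 1)
    ny = max(int(np.ceil((maxy - miny) / side)), 1)

    counts = []
    coverages = []
    cell_area = side * side
    for iy in range(ny):
        for ix in range(nx):
            x0, y0 = minx + ix * side, miny + iy * side
            q = box(x0, y0, x0 + side, y0 + side)
            cov = roi_poly.intersection(q).area / cell_area
            if cov < MIN_COVERAGE:
                continue
            if len(pts):
                inside = (
                    (pts[:, 0] >= x0)
                    & (pts[:, 0] < x0 + side)
                    & (pts[:, 1] >= y0)
                    & (pts[:, 1] < y0 + side)
                )
                counts.append(int(inside.sum()))
            else:
                counts.append(0)
            coverages.append(cov)
    return QuadratGrid(
        roi_kind=roi_kind,
        side=side,
        counts=np.asarray(counts, dtype=float),
        coverage=np.asarray(coverages, dtype=float),
    )


def morisita_index(counts: np.ndarray) -> float:
    """Morisita aggregation index over quadrat counts (1 under CSR)."""
    counts = np.asarray(counts, dtype=float)
    q = len(counts)
    n = counts.sum()
    if q < 2 or n < 2:
        return np.nan
    return float(q * (counts * (counts - 1)).sum() / (n * (n - 1)))


def density_homogeneity(
    cellmap: CellMap,
    roi_kind: ROIKind,
    cell_class: CellClass,
    quadrat_side: float = DEFAULT_QUADRAT_SIDE,
    flags: pd.DataFrame | None = None,
) -> dict[str, float]:
    """7 density/homogeneity statistics for one class in one region.

    density is in cells per 10^4 px^2 of ROI area; nn_dist_mean is the
    mean nearest-neighbor distance in px (NaN and logged when fewer than
    two cells are present).
    """
    roi_kind = ROIKind(roi_kind)
    cell_class = CellClass(cell_class)
    roi_poly = cellmap.roi(roi_kind).shapely
    if roi_poly.area == 0:
        raise ValueError(f"ROI {roi_kind.value} has zero area")
    if flags is None:
        flags = assign_roi(cellmap)
    member_ids = set(
        flags.index[(flags["cell_class"] == cell_class.value) & flags[roi_kind.value]]
    )
    pts = np.asarray(
        [n.centroid for n in cellmap.nuclei if n.id in member_ids], dtype=float
    ).reshape(-1, 2)

    grid = quadrat_grid(cellmap, roi_kind, cell_class, quadrat_side, flags=flags)
    c = grid.counts
    qmean = float(c.mean()) if len(c) else np.nan
    qsd = float(c.std(ddof=1)) if len(c) > 1 else np.nan
    cv = qsd / qmean if qmean else np.nan

    if len(pts) >= 2:
        tree = cKDTree(pts)
        d, _ = tree.query(pts, k=2)
        nn = float(d[:, 1].mean())
    else:
        logger.info(
            "specimen %s: <2 %s cells in %s, NN distance missing",
            cellmap.specimen_id,
            cell_class.value,
            roi_kind.value,
        )
        nn = np.nan

    return {
        "density": float(len(pts) / roi_poly.area * 1e4),
        "uniformity_mean": qmean,
        "uniformity_sd": qsd,
        "uniformity_cv": float(cv) if cv == cv else np.nan,
        "fraction_empty": float((c == 0).mean()) if len(c) else np.nan,
        "morisita": morisita_index(c),
        "nn_dist_mean": nn,
    }


# ---------------------------------------------------------------------------
# tumor-cell-centered interaction matrix
# ---------------------------------------------------------------------------

@dataclass
class InteractionMatrix:
    """Neighbor counts around each tumor nucleus in one ROI at one radius."""

    roi_kind: ROIKind
    radius: float
    nucleus_ids: np.ndarray
    tumor_neighbors: np.ndarray
    lymphocyte_neighbors: np.ndarray

    def __len__(self) -> int:
        return len(self.nucleus_ids)


def interaction_matrix(
    cellmap: CellMap,
    roi_kind: ROIKind,
    radius: float,
    flags: pd.DataFrame | None = None,
) -> InteractionMatrix:
    """Count tumor and lymphocyte neighbors within ``radius`` px of each
    tumor nucleus in the ROI (centroid distance, focal nucleus excluded).

    Uses a k-d tree; the counts are identical to the naive all-pairs scan.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    roi_kind = ROIKind(roi_kind)
    if flags is None:
        flags = assign_roi(cellmap)
    in_roi = flags[flags[roi_kind.value]]
    by_id = {n.id: n for n in cellmap.nuclei}

    tumor_ids = in_roi.index[in_roi["cell_class"] == CellClass.TUMOR.value].to_numpy()
    lymph_ids = in_roi.index[
        in_roi["cell_class"] == CellClass.LYMPHOCYTE.value
    ].to_numpy()
    t_pts = np.asarray([by_id[i].centroid for i in tumor_ids], float).reshape(-1, 2)
    l_pts = np.asarray([by_id[i].centroid for i in lymph_ids], float).reshape(-1, 2)

    if len(t_pts) == 0:
        empty = np.zeros(0, dtype=int)
        return InteractionMatrix(roi_kind, radius, tumor_ids, empty, empty.copy())

    focal_tree = cKDTree(t_pts)
    t_counts = (
        np.asarray(focal_tree.query_ball_point(t_pts, r=radius, return_length=True))
        - 1  # remove self
    )
    if len(l_pts):
        l_tree = cKDTree(l_pts)
        l_counts = np.asarray(
            l_tree.query_ball_point(t_pts, r=radius, return_length=True)
        )
    else:
        l_counts = np.zeros(len(t_pts), dtype=int)
    return InteractionMatrix(
        roi_kind=roi_kind,
        radius=radius,
        nucleus_ids=tumor_ids,
        tumor_neighbors=t_counts.astype(int),
        lymphocyte_neighbors=l_counts.astype(int),
    )


def interaction_matrix_naive(
    cellmap: CellMap,
    roi_kind: ROIKind,
    radius: float,
    flags: pd.DataFrame | None = None,
) -> InteractionMatrix:
    """Reference all-pairs implementation (O(n^2)); used as a test oracle."""
    roi_kind = ROIKind(roi_kind)
    if flags is None:
        flags = assign_roi(cellmap)
    in_roi = flags[flags[roi_kind.value]]
    by_id = {n.id: n for n in cellmap.nuclei}
    tumor_ids = in_roi.index[in_roi["cell_class"] == CellClass.TUMOR.value].to_numpy()
    lymph_ids = in_roi.index[
        in_roi["cell_class"] == CellClass.LYMPHOCYTE.value
    ].to_numpy()
    t_pts = np.asarray([by_id[i].centroid for i in tumor_ids], float).reshape(-1, 2)
    l_pts = np.asarray([by_id[i].centroid for i in lymph_ids], float).reshape(-1, 2)
    nt = len(t_pts)
    t_counts = np.zeros(nt, dtype=int)
    l_counts = np.zeros(nt, dtype=int)
    for i in range(nt):
        if nt:
            d = np.hypot(*(t_pts - t_pts[i]).T)
            t_counts[i] = int((d <= radius).sum()) - 1
        if len(l_pts):
            d = np.hypot(*(l_pts - t_pts[i]).T)
            l_counts[i] = int((d <= radius).sum())
    return InteractionMatrix(roi_kind, radius, tumor_ids, t_counts, l_counts)


def interaction_features(M: InteractionMatrix) -> dict[str, float]:
    """8 statistics per neighbor class of one interaction matrix (16 total)."""
    out: dict[str, float] = {}
    region = {v: k for k, v in _REGION_BY_CODE.items()}[M.roi_kind]
    for cls, counts in (
        ("tumor", M.tumor_neighbors),
        ("lymphocyte", M.lymphocyte_neighbors),
    ):
        names = {s: _interaction_name(cls, s, int(M.radius), region) for s in INTERACTION_STATS}
        if len(M) == 0:
            logger.info("empty interaction matrix (%s, r=%g)", M.roi_kind.value, M.radius)
            out.update({n: np.nan for n in names.values()})
            continue
        c = counts.astype(float)
        out[names["mean"]] = float(c.mean())
        out[names["sd"]] = float(c.std(ddof=1)) if len(c) > 1 else np.nan
        out[names["median"]] = float(np.median(c))
        out[names["max"]] = float(c.max())
        out[names["skewness"]] = _skewness(c)
        out[names["q75"]] = float(np.percentile(c, 75))
        out[names["fraction_zero"]] = float((c == 0).mean())
        out[names["entropy"]] = _entropy_bits(counts)
    return out


# ---------------------------------------------------------------------------
# composite + assembled 96-feature spatial vector
# ---------------------------------------------------------------------------

def composite_features(
    cellmap: CellMap, flags: pd.DataFrame | None = None
) -> dict[str, float]:
    """Lymphocyte:tumor ratio and total nucleus count in CT and PT."""
    if flags is None:
        flags = assign_roi(cellmap)
    out: dict[str, float] = {}
    for code, kind in _REGION_BY_CODE.items():
        in_roi = flags[flags[kind.value]]
        n_t = int((in_roi["cell_class"] == CellClass.TUMOR.value).sum())
        n_l = int((in_roi["cell_class"] == CellClass.LYMPHOCYTE.value).sum())
        if n_t == 0:
            logger.info("specimen %s: no tumor cells in %s, ratio missing",
                        cellmap.specimen_id, kind.value)
            out[f"lymph_tumor_ratio_{code}"] = np.nan
        else:
            out[f"lymph_tumor_ratio_{code}"] = n_l / n_t
        out[f"total_nuclei_{code}"] = float(len(in_roi))
    return out


def spatial_features(
    cellmap: CellMap,
    quadrat_side: float = DEFAULT_QUADRAT_SIDE,
    radii: tuple[float, ...] = RADII,
    flags: pd.DataFrame | None = None,
) -> pd.Series:
    """All 96 spatial features (28 density/homogeneity + 64 interaction +
    4 composite) of one specimen, in registry order."""
    if flags is None:
        flags = assign_roi(cellmap)
    out: dict[str, float] = {}
    for cls in (CellClass.TUMOR, CellClass.LYMPHOCYTE):
        short = "lymph" if cls == CellClass.LYMPHOCYTE else "tumor"
        for code, kind in _REGION_BY_CODE.items():
            vals = density_homogeneity(cellmap, kind, cls, quadrat_side, flags=flags)
            for stat in DENSITY_STATS:
                out[f"{short}_{stat}_{code}"] = vals[stat]
    for code, kind in _REGION_BY_CODE.items():
        for r in radii:
            M = interaction_matrix(cellmap, kind, r, flags=flags)
            out.update(interaction_features(M))
    out.update(composite_features(cellmap, flags=flags))
    return pd.Series(out, name=cellmap.specimen_id)
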