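"""Single-cell map data model and GeoJSON I/O.

A *cell map* is the per-specimen output of nucleus segmentation and
classification on an H&E image: one polygon, centroid, and cell class
(tumor / lymphocyte / other) per nucleus, together with the three regions
of interest used throughout the analysis — the whole tumor, the tumor
core, and the tumor periphery (an annular band at the tumor edge).

Coordinates are 0-based pixels, x to the right and y down, matching raster
indexing of the accompanying image patch. Polygon rings are closed (first
vertex repeated). Point-in-polygon tests count the boundary as inside.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Point, Polygon
from shapely.prepared import prep

logger = logging.getLogger(__name__)

__all__ = [
    "CellClass",
    "ROIKind",
    "Nucleus",
    "ROI",
    "CellMap",
    "ClinicalRecord",
    "read_cellmap",
    "write_cellmap",
    "assign_roi",
    "read_clinical",
    "write_clinical",
]


class CellClass(str, Enum):
    """The three cell classes distinguished on H&E."""

    TUMOR = "tumor"
    LYMPHOCYTE = "lymphocyte"
    OTHER = "other"


class ROIKind(str, Enum):
    WHOLE_TUMOR = "whole_tumor"
    TUMOR_CORE = "tumor_core"
    TUMOR_PERIPHERY = "tumor_periphery"


class CellMapValidationError(ValueError):
    """Raised when a cell map violates its structural invariants."""


def _close_ring(ring: np.ndarray) -> np.ndarray:
    ring = np.asarray(ring, dtype=float)
    if ring.ndim != 2 or ring.shape[1] != 2:
        raise CellMapValidationError("polygon ring must be an (n, 2) array")
    if not np.allclose(ring[0], ring[-1]):
        ring = np.vstack([ring, ring[0]])
    return ring


@dataclass
class Nucleus:
    """One segmented nucleus.

    Parameters
    ----------
    id : int
        Identifier unique within the specimen.
    polygon : (n, 2) array
        Closed pixel-coordinate ring (first vertex repeated at the end).
    centroid : (x, y)
        Pixel coordinates of the nucleus centroid.
    cell_class : CellClass
    """

    id: int
    polygon: np.ndarray
    centroid: tuple[float, float]
    cell_class: CellClass

    def __post_init__(self) -> None:
        self.polygon = _close_ring(self.polygon)
        if len(self.polygon) < 4:  # closed ring: >= 3 distinct vertices
            raise CellMapValidationError(
                f"nucleus {self.id}: polygon needs at least 3 vertices"
            )
        self.cell_class = CellClass(self.cell_class)
        shp = self.shapely
        if not shp.is_valid:
            raise CellMapValidationError(
                f"nucleus {self.id}: polygon is self-intersecting or degenerate"
            )
        if shp.area <= 0:
            raise CellMapValidationError(f"nucleus {self.id}: polygon area is zero")
        x, y = self.centroid
        minx, miny, maxx, maxy = shp.bounds
        if not (minx <= x <= maxx and miny <= y <= maxy):
            raise CellMapValidationError(
                f"nucleus {self.id}: centroid outside polygon bounding box"
            )

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, Nucleus):
            return NotImplemented
        return (
            self.id == other.id
            and self.cell_class == other.cell_class
            and np.allclose(self.polygon, other.polygon)
            and np.allclose(self.centroid, other.centroid)
        )


@dataclass
class ROI:
    """A region of interest: whole tumor, tumor core, or tumor periphery.

    The periphery may be an annulus, stored as an outer ring plus one inner
    ring (hole).
    """

    kind: ROIKind
    polygon: np.ndarray
    holes: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.kind = ROIKind(self.kind)
        self.polygon = _close_ring(self.polygon)
        self.holes = [_close_ring(h) for h in self.holes]

    @property
    def shapely(self) -> Polygon:
        return Polygon(self.polygon, holes=self.holes or None)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ROI):
            return NotImplemented
        return (
            self.kind == other.kind
            and np.allclose(self.polygon, other.polygon)
            and len(self.holes) == len(other.holes)
            and all(np.allclose(a, b) for a, b in zip(self.holes, other.holes))
        )


@dataclass
class CellMap:
    """All nuclei and ROIs of one specimen."""

    specimen_id: str
    nuclei: list[Nucleus]
    rois: list[ROI]
    pixel_size_um: float = 0.25
    image_ref: str | None = None

    def __post_init__(self) -> None:
        if not self.specimen_id:
            raise CellMapValidationError("specimen_id must be nonempty")
        if self.pixel_size_um <= 0:
            raise CellMapValidationError("pixel_size_um must be positive")
        ids = [n.id for n in self.nuclei]
        if len(set(ids)) != len(ids):
            raise CellMapValidationError("duplicate nucleus ids")

    def roi(self, kind: ROIKind) -> ROI:
        kind = ROIKind(kind)
        for r in self.rois:
            if r.kind == kind:
                return r
        raise KeyError(f"ROI {kind.value!r} not present in specimen {self.specimen_id}")

    def centroids(self, cell_class: CellClass | None = None) -> np.ndarray:
        """(n, 2) centroid array, optionally restricted to one class."""
        pts = [
            n.centroid
            for n in self.nuclei
            if cell_class is None or n.cell_class == CellClass(cell_class)
        ]
        return np.asarray(pts, dtype=float).reshape(-1, 2)

    def class_counts(self) -> dict[str, int]:
        counts = {c.value: 0 for c in CellClass}
        for n in self.nuclei:
            counts[n.cell_class.value] += 1
        return counts

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CellMap):
            return NotImplemented
        return (
            self.specimen_id == other.specimen_id
            and np.isclose(self.pixel_size_um, other.pixel_size_um)
            and self.image_ref == other.image_ref
            and self.nuclei == other.nuclei
            and self.rois == other.rois
        )


@dataclass
class ClinicalRecord:
    """Per-patient clinical covariates and overall-survival outcome."""

    specimen_id: str
    os_time: float
    os_event: int
    stage: str = "unknown"
    grade: str = "unknown"
    sex: str = "unknown"
    extra_labels: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.os_time < 0:
            raise CellMapValidationError("os_time must be nonnegative")
        if self.os_event not in (0, 1):
            raise CellMapValidationError("os_event must be 0 or 1")


# ---------------------------------------------------------------------------
# GeoJSON I/O
# ---------------------------------------------------------------------------

def _ring_to_coords(ring: np.ndarray) -> list[list[float]]:
    return [[float(x), float(y)] for x, y in ring]


def write_cellmap(cellmap: CellMap, path: str | Path) -> None:
    """Write a cell map as a GeoJSON FeatureCollection (lossless round-trip)."""
    features = []
    for n in cellmap.nuclei:
        features.append(
            {
                "type": "Feature",
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [_ring_to_coords(n.polygon)],
                },
                "properties": {
                    "feature_type": "nucleus",
                    "id": int(n.id),
                    "cell_class": n.cell_class.value,
                    "centroid": [float(n.centroid[0]), float(n.centroid[1])],
                },
            }
        )
    for r in cellmap.rois:
        coords = [_ring_to_coords(r.polygon)] + [_ring_to_coords(h) for h in r.holes]
        features.append(
            {
                "type": "Feature",
                "geometry": {"type": "Polygon", "coordinates": coords},
                "properties": {"feature_type": "roi", "roi_kind": r.kind.value},
            }
        )
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "properties": {
            "crs": "pixel",
            "specimen_id": cellmap.specimen_id,
            "pixel_size_um": cellmap.pixel_size_um,
            "image_ref": cellmap.image_ref,
        },
    }
    Path(path).write_text(json.dumps(doc), encoding="utf-8")


def read_cellmap(path: str | Path) -> CellMap:
    """Read and validate a cell-map GeoJSON FeatureCollection."""
    try:
        doc = json.loads(Path(path).read_text(encoding="utf-8"))
    except json.JSONDecodeError as exc:
        raise CellMapValidationError(f"malformed GeoJSON in {path}: {exc}") from exc
    if doc.get("type") != "FeatureCollection":
        raise CellMapValidationError(f"{path}: not a GeoJSON FeatureCollection")

    meta = doc.get("properties", {})
    nuclei: list[Nucleus] = []
    rois: list[ROI] = []
    for feat in doc.get("features", []):
        props = feat.get("properties", {})
        geom = feat.get("geometry", {})
        if geom.get("type") != "Polygon":
            raise CellMapValidationError("only Polygon geometries are supported")
        rings = [np.asarray(r, dtype=float) for r in geom["coordinates"]]
        if props.get("feature_type") == "roi" or "roi_kind" in props:
            try:
                kind = ROIKind(props["roi_kind"])
            except (KeyError, ValueError) as exc:
                raise CellMapValidationError(f"bad roi_kind in {path}: {exc}") from exc
            rois.append(ROI(kind=kind, polygon=rings[0], holes=rings[1:]))
        else:
            if "cell_class" not in props:
                raise CellMapValidationError(
                    f"nucleus feature id={props.get('id')} is missing cell_class"
                )
            try:
                cls = CellClass(props["cell_class"])
            except ValueError as exc:
                raise CellMapValidationError(
                    f"nucleus id={props.get('id')}: unknown cell_class "
                    f"{props['cell_class']!r}"
                ) from exc
            centroid = props.get("centroid")
            if centroid is None:
                shp = Polygon(rings[0])
                centroid = (shp.centroid.x, shp.centroid.y)
            nuclei.append(
                Nucleus(
                    id=int(props["id"]),
                    polygon=rings[0],
                    centroid=(float(centroid[0]), float(centroid[1])),
                    cell_class=cls,
                )
            )
    return CellMap(
        specimen_id=meta.get("specimen_id", Path(path).stem),
        nuclei=nuclei,
        rois=rois,
        pixel_size_um=float(meta.get("pixel_size_um") or 0.25),
        image_ref=meta.get("image_ref"),
    )


# ---------------------------------------------------------------------------
# ROI assignment
# ---------------------------------------------------------------------------

def assign_roi(cellmap: CellMap) -> pd.DataFrame:
    """Flag each nucleus for membership in each ROI.

    Membership is a point-in-polygon test on the centroid; the polygon
    boundary counts as inside. Returns a DataFrame indexed by nucleus id
    with boolean columns ``whole_tumor``, ``tumor_core``, ``tumor_periphery``
    and the ``cell_class`` of each nucleus. Nuclei outside all ROIs are
    flagged (all False), never dropped; their count is logged.
    """
    for kind in ROIKind:
        cellmap.roi(kind)  # raises if absent

    ids = [n.id for n in cellmap.nuclei]
    out = pd.DataFrame(
        {
            "cell_class": pd.Categorical(
                [n.cell_class.value for n in cellmap.nuclei],
                categories=[c.value for c in CellClass],
            )
        },
        index=pd.Index(ids, name="nucleus_id"),
    )
    pts = cellmap.centroids()
    for kind in ROIKind:
        poly = prep(cellmap.roi(kind).shapely)
        if len(pts):
            # prepared.intersects counts the boundary as inside
            flags = np.fromiter(
                (poly.intersects(Point(x, y)) for x, y in pts), bool, count=len(pts)
            )
        else:
            flags = np.zeros(0, dtype=bool)
        out[kind.value] = flags

    n_outside = int((~out[[k.value for k in ROIKind]].any(axis=1)).sum())
    if n_outside:
        logger.info(
            "specimen %s: %d nuclei outside all ROIs (kept, flagged)",
            cellmap.specimen_id,
            n_outside,
        )
    return out


# ---------------------------------------------------------------------------
# Clinical table I/O
# ---------------------------------------------------------------------------

_CLINICAL_COLUMNS = ["specimen_id", "os_time", "os_event", "stage", "grade", "sex"]


def read_clinical(path: str | Path) -> pd.DataFrame:
    """Read the per-patient clinical CSV.

    Required columns: specimen_id, os_time, os_event, stage, grade, sex.
    Any additional columns are kept as external label sets (molecular
    subtype assignments etc.).
    """
    df = pd.read_csv(path, dtype={"specimen_id": str})
    missing = [c for c in _CLINICAL_COLUMNS if c not in df.columns]
    if missing:
        raise CellMapValidationError(f"clinical table missing columns: {missing}")
    if (df["os_time"] < 0).any():
        raise CellMapValidationError("os_time must be nonnegative")
    if not df["os_event"].isin([0, 1]).all():
        raise CellMapValidationError("os_event must be 0/1")
    return df


def write_clinical(records: Sequence[ClinicalRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        row = {
            "specimen_id": r.specimen_id,
            "os_time": r.os_time,
            "os_event": r.os_event,
            "stage": r.stage,
            "grade": r.grade,
            "sex": r.sex,
        }
        row.update(r.extra_labels)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)
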