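"""Synthetic H&E-like cohorts with planted imaging subtypes.

The generator emulates the statistical structure the analysis pipeline is
built to detect, at desk scale:

* **Tumor cells** follow either a homogeneous Poisson process (spatially
  uniform growth) or a Thomas cluster process (Poisson parents, Gaussian-
  scattered offspring — heterogeneous, nested growth).
* **Lymphocytes** follow an inhomogeneous Poisson process whose intensity
  is modulated by proximity to tumor cells:
  lambda(x) = lambda0 * max(eps, 1 + alpha * sum_i exp(-|x - t_i|^2 / 2h^2)),
  so alpha > 0 plants tumor–immune colocalization and alpha < 0 exclusion,
  with a clamping floor eps = 0.05 keeping the intensity nonnegative.
* **Nuclei** are 32-gon ellipses whose equivalent diameter is log-normal
  (subtype-specific median — the nuclear-size axis of the subtypes),
  eccentricity U(0, 0.8), uniform orientation.
* **Rendering** paints an eosin-pink background and hematoxylin-dark
  nuclei with smoothed intra-nuclear texture plus Gaussian pixel noise.
* **Survival** is exponential with a subtype-specific hazard and
  independent uniform censoring, planting the prognostic ordering
  (subtype 1 best; 2 and 3 comparable and worse, hazard ratio 2 vs 1).

The three default subtypes mirror the qualitative signature the pipeline
targets: S1 — low tumor density, spatially uniform, heavy colocalized
lymphocyte infiltrate, small nuclei; S2 — denser clustered tumor, sparse
lymphocytes, intermediate nuclei; S3 — densest and most heterogeneous
tumor, sparse lymphocytes, largest nuclei.

Everything is reproducible from one master seed via spawned per-specimen
seed sequences, recorded in the cohort manifest.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.spatial import cKDTree
from skimage.draw import polygon as draw_polygon

from .cellmap import CellClass, CellMap, ClinicalRecord, Nucleus, ROI, ROIKind, write_cellmap

logger = logging.getLogger(__name__)

EXCLUSION_FLOOR = 0.05
MAX_EXPECTED_POINTS = 100_000
MAX_PATCH_SIDE = 4096

BACKGROUND_RGB = (230, 180, 200)
CLASS_RGB = {
    CellClass.TUMOR: (90, 60, 140),
    CellClass.LYMPHOCYTE: (50, 40, 110),
    CellClass.OTHER: (150, 120, 160),
}


@dataclass
class SubtypeSpec:
    """Point-process, nuclear-size, and hazard parameters of one subtype.

    Intensities are in cells per 10^4 px^2. For the Thomas process the
    realized tumor intensity is parent_intensity * offspring_mean.
    """

    name: str
    tumor_process: str = "poisson"  # "poisson" | "thomas"
    tumor_intensity: float = 3.5  # Poisson intensity (ignored for thomas)
    parent_intensity: float = 0.3
    offspring_mean: float = 20.0
    offspring_sigma: float = 40.0  # px
    lymph_base_intensity: float = 1.0
    colocalization_alpha: float = 0.0
    colocalization_bandwidth: float = 20.0  # px
    other_intensity: float = 1.0
    nucleus_median_diameter: float = 12.0  # px, tumor nuclei
    nucleus_sigma_log: float = 0.12
    lymph_median_diameter: float = 7.0
    lymph_sigma_log: float = 0.08
    other_median_diameter: float = 9.0
    other_sigma_log: float = 0.10
    hazard: float = 0.01  # events per month

    def expected_tumor_intensity(self) -> float:
        if self.tumor_process == "thomas":
            return self.parent_intensity * self.offspring_mean
        return self.tumor_intensity


def default_subtypes() -> dict[str, SubtypeSpec]:
    """The three planted subtypes (see module docstring)."""
    return {
        "S1": SubtypeSpec(
            name="S1",
            tumor_process="poisson",
            tumor_intensity=3.5,
            lymph_base_intensity=1.8,
            colocalization_alpha=1.5,
            colocalization_bandwidth=20.0,
            nucleus_median_diameter=12.0,
            hazard=0.010,
        ),
        "S2": SubtypeSpec(
            name="S2",
            tumor_process="thomas",
            parent_intensity=0.45,
            offspring_mean=12.0,
            offspring_sigma=70.0,
            lymph_base_intensity=1.5,
            colocalization_alpha=-0.2,  # immune-excluded phenotype
            colocalization_bandwidth=30.0,
            nucleus_median_diameter=13.8,
            hazard=0.020,
        ),
        "S3": SubtypeSpec(
            name="S3",
            tumor_process="thomas",
            parent_intensity=0.22,
            offspring_mean=36.0,
            offspring_sigma=25.0,
            lymph_base_intensity=0.7,
            colocalization_alpha=0.0,
            nucleus_median_diameter=15.6,
            hazard=0.020,
        ),
    }


@dataclass
class CohortSpec:
    """Cohort-level geometry, size, and rendering parameters."""

    n_per_subtype: int = 20
    patch_size: int = 896
    whole_margin: float = 12.0  # inset of the whole-tumor ROI from the patch edge
    core_margin: float = 250.0  # erosion of whole tumor -> tumor core
    periphery_band: float = 150.0  # width of the outer periphery band
    seed: int = 0
    noise_sigma: float = 8.0
    texture_amplitude: float = 10.0
    censor_max: float = 120.0  # months
    subtypes: dict[str, SubtypeSpec] = field(default_factory=default_subtypes)

    def __post_init__(self) -> None:
        if self.core_margin <= self.periphery_band:
            raise ValueError(
                "core_margin must exceed periphery_band so that tumor core "
                "and periphery are disjoint"
            )
        if self.patch_size > MAX_PATCH_SIDE:
            raise ValueError(f"patch_size > {MAX_PATCH_SIDE} refused")


# ---------------------------------------------------------------------------
# ROI geometry (rectangular surrogate for manual delineation)
# ---------------------------------------------------------------------------

def _rect_ring(x0: float, y0: float, x1: float, y1: float) -> np.ndarray:
    return np.array([[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]], dtype=float)


def build_rois(spec: CohortSpec) -> list[ROI]:
    """Whole tumor = inset rectangle; core = erosion by core_margin;
    periphery = the outer band of width periphery_band (annulus)."""
    s = spec.patch_size
    m = spec.whole_margin
    whole = (m, m, s - m, s - m)
    cm = spec.core_margin
    core = (m + cm, m + cm, s - m - cm, s - m - cm)
    b = spec.periphery_band
    inner = (m + b, m + b, s - m - b, s - m - b)
    return [
        ROI(kind=ROIKind.WHOLE_TUMOR, polygon=_rect_ring(*whole)),
        ROI(kind=ROIKind.TUMOR_CORE, polygon=_rect_ring(*core)),
        ROI(
            kind=ROIKind.TUMOR_PERIPHERY,
            polygon=_rect_ring(*whole),
            holes=[_rect_ring(*inner)],
        ),
    ]


# ---------------------------------------------------------------------------
# point patterns
# ---------------------------------------------------------------------------

@dataclass
class PointPattern:
    """Cell positions and classes before nuclear shapes are attached."""

    points: np.ndarray  # (n, 2)
    classes: np.ndarray  # (n,) of CellClass values (str)
    window: tuple[float, float, float, float]  # x0, y0, x1, y1


def _poisson_points(rng, intensity_per_1e4, window) -> np.ndarray:
    x0, y0, x1, y1 = window
    area = (x1 - x0) * (y1 - y0)
    lam = intensity_per_1e4 / 1e4 * area
    if lam > MAX_EXPECTED_POINTS:
        raise ValueError(f"expected point count {lam:.0f} exceeds the desk-scale guard")
    n = rng.poisson(lam)
    pts = np.column_stack(
        [rng.uniform(x0, x1, size=n), rng.uniform(y0, y1, size=n)]
    )
    return pts


def _thomas_points(rng, spec: SubtypeSpec, window) -> np.ndarray:
    x0, y0, x1, y1 = window
    pad = 4.0 * spec.offspring_sigma
    ext_area = (x1 - x0 + 2 * pad) * (y1 - y0 + 2 * pad)
    lam_parent = spec.parent_intensity / 1e4 * ext_area
    if lam_parent * spec.offspring_mean > MAX_EXPECTED_POINTS:
        raise ValueError("expected point count exceeds the desk-scale guard")
    n_par = rng.poisson(lam_parent)
    parents = np.column_stack(
        [
            rng.uniform(x0 - pad, x1 + pad, size=n_par),
            rng.uniform(y0 - pad, y1 + pad, size=n_par),
        ]
    )
    n_off = rng.poisson(spec.offspring_mean, size=n_par)
    pts = np.repeat(parents, n_off, axis=0)
    pts = pts + rng.normal(0.0, spec.offspring_sigma, size=pts.shape)
    keep = (
        (pts[:, 0] >= x0) & (pts[:, 0] < x1) & (pts[:, 1] >= y0) & (pts[:, 1] < y1)
    )
    return pts[keep]


def _colocalization_factor(
    pts: np.ndarray, tumor_pts: np.ndarray, alpha: float, h: float
) -> np.ndarray:
    """max(eps, 1 + alpha * sum of Gaussian kernels from tumor cells)."""
    if alpha == 0 or len(tumor_pts) == 0 or len(pts) == 0:
        return np.ones(len(pts))
    tree = cKDTree(tumor_pts)
    pairs = tree.query_ball_point(pts, r=4.0 * h)
    s = np.zeros(len(pts))
    for i, idx in enumerate(pairs):
        if idx:
            d2 = ((tumor_pts[idx] - pts[i]) ** 2).sum(axis=1)
            s[i] = np.exp(-d2 / (2.0 * h * h)).sum()
    return np.maximum(EXCLUSION_FLOOR, 1.0 + alpha * s)


def simulate_pointpattern(
    spec: SubtypeSpec,
    window: tuple[float, float, float, float],
    seed,
) -> PointPattern:
    """Simulate tumor, lymphocyte, and other-cell positions in a window.

    Lymphocytes are drawn by thinning a homogeneous dominating process at
    the supremum of the modulated intensity.
    """
    rng = np.random.default_rng(seed)
    if spec.tumor_process == "thomas":
        tumor = _thomas_points(rng, spec, window)
    elif spec.tumor_process == "poisson":
        tumor = _poisson_points(rng, spec.tumor_intensity, window)
    else:
        raise ValueError(f"unknown tumor process {spec.tumor_process!r}")

    # dominating intensity for the thinning step
    alpha, h = spec.colocalization_alpha, spec.colocalization_bandwidth
    if alpha > 0 and len(tumor):
        probe = _colocalization_factor(tumor, tumor, alpha, h)
        sup = float(probe.max()) * 1.1 + 1.0
    else:
        sup = 1.0
    cand = _poisson_points(rng, spec.lymph_base_intensity * sup, window)
    if len(cand):
        fac = _colocalization_factor(cand, tumor, alpha, h)
        accept = rng.uniform(size=len(cand)) < np.minimum(fac / sup, 1.0)
        lymph = cand[accept]
    else:
        lymph = cand

    other = _poisson_points(rng, spec.other_intensity, window)

    points = np.vstack([tumor, lymph, other])
    classes = np.concatenate(
        [
            np.full(len(tumor), CellClass.TUMOR.value),
            np.full(len(lymph), CellClass.LYMPHOCYTE.value),
            np.full(len(other), CellClass.OTHER.value),
        ]
    )
    return PointPattern(points=points, classes=classes, window=window)


# ---------------------------------------------------------------------------
# nuclear shapes
# ---------------------------------------------------------------------------

_N_VERTICES = 32
_PHI = np.linspace(0.0, 2.0 * np.pi, _N_VERTICES, endpoint=False)


def _ellipse_ring(cx, cy, ed, ecc, theta) -> np.ndarray:
    """Closed 32-gon approximating an ellipse of equivalent diameter ed."""
    r = ed / 2.0
    q = (1.0 - ecc * ecc) ** 0.25
    a, b = r / q, r * q
    x = a * np.cos(_PHI)
    y = b * np.sin(_PHI)
    ct, st = np.cos(theta), np.sin(theta)
    ring = np.column_stack([cx + ct * x - st * y, cy + st * x + ct * y])
    return np.vstack([ring, ring[0]])


def attach_nuclei(
    pattern: PointPattern,
    spec: SubtypeSpec,
    seed,
    specimen_id: str = "synthetic",
    rois: list[ROI] | None = None,
    pixel_size_um: float = 0.25,
) -> CellMap:
    """Give each cell an elliptical nucleus polygon.

    Tumor equivalent diameters are log-normal with the subtype's median;
    lymphocyte and other nuclei use their own (smaller) size models.
    Overlapping nuclei are allowed (and logged in aggregate).
    """
    rng = np.random.default_rng(seed)
    size_model = {
        CellClass.TUMOR.value: (spec.nucleus_median_diameter, spec.nucleus_sigma_log),
        CellClass.LYMPHOCYTE.value: (spec.lymph_median_diameter, spec.lymph_sigma_log),
        CellClass.OTHER.value: (spec.other_median_diameter, spec.other_sigma_log),
    }
    nuclei = []
    for i, ((x, y), cls) in enumerate(zip(pattern.points, pattern.classes)):
        med, slog = size_model[cls]
        ed = med * np.exp(rng.normal(0.0, slog)) if slog > 0 else med
        ecc = rng.uniform(0.0, 0.8)
        theta = rng.uniform(0.0, np.pi)
        nuclei.append(
            Nucleus(
                id=i,
                polygon=_ellipse_ring(x, y, ed, ecc, theta),
                centroid=(float(x), float(y)),
                cell_class=CellClass(cls),
            )
        )
    return CellMap(
        specimen_id=specimen_id,
        nuclei=nuclei,
        rois=rois or [],
        pixel_size_um=pixel_size_um,
    )


# ---------------------------------------------------------------------------
# rendering
# ---------------------------------------------------------------------------

def render_patch(
    cellmap: CellMap,
    size: int,
    seed,
    noise_sigma: float = 8.0,
    texture_amplitude: float = 10.0,
) -> np.ndarray:
    """Render an H&E-like RGB uint8 patch from the nucleus polygons.

    Eosin-pink background, hematoxylin-dark nuclei per class, smoothed
    noise texture inside nuclei, Gaussian pixel noise everywhere.
    """
    if size > MAX_PATCH_SIDE:
        raise ValueError(f"patch size {size} > {MAX_PATCH_SIDE} refused")
    rng = np.random.default_rng(seed)
    img = np.empty((size, size, 3), dtype=float)
    img[..., :] = BACKGROUND_RGB

    inside = np.zeros((size, size), dtype=bool)
    for nuc in cellmap.nuclei:
        ring = nuc.polygon
        rr, cc = draw_polygon(ring[:, 1], ring[:, 0], shape=(size, size))
        img[rr, cc] = CLASS_RGB[nuc.cell_class]
        inside[rr, cc] = True

    if texture_amplitude > 0 and inside.any():
        field = gaussian_filter(
            rng.standard_normal(size=(size, size), dtype=np.float32), sigma=2.0
        )
        sd = field.std()
        if sd > 0:
            img += (texture_amplitude * field / sd * inside)[..., None]
    if noise_sigma > 0:
        img += noise_sigma * rng.standard_normal(size=img.shape, dtype=np.float32)
    return np.clip(img, 0, 255).astype(np.uint8)


# ---------------------------------------------------------------------------
# cohort assembly
# ---------------------------------------------------------------------------

@dataclass
class SyntheticCohort:
    """Lazy synthetic cohort: clinical table, truth labels, and per-specimen
    generation recipes (regenerated on demand, bit-identical per manifest)."""

    spec: CohortSpec
    clinical: pd.DataFrame
    truth: pd.DataFrame  # specimen_id -> subtype
    manifest: dict
    _recipes: list[tuple[str, str, int]] = field(repr=False, default_factory=list)

    def specimen_ids(self) -> list[str]:
        return [r[0] for r in self._recipes]

    def specimen(self, specimen_id: str) -> tuple[CellMap, np.ndarray]:
        for sid, subtype, entropy in self._recipes:
            if sid == specimen_id:
                return _generate_specimen(self.spec, self.spec.subtypes[subtype], sid, entropy)
        raise KeyError(specimen_id)

    def specimens(self):
        """Yield (CellMap, image) pairs one at a time."""
        for sid, subtype, entropy in self._recipes:
            yield _generate_specimen(self.spec, self.spec.subtypes[subtype], sid, entropy)

    def write(self, out_dir: str | Path) -> None:
        """Write the cohort directory layout: per-specimen GeoJSON + PNG,
        clinical.csv, truth.csv, manifest.json."""
        import imageio.v3 as iio

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for cellmap, image in self.specimens():
            d = out / "cohort" / cellmap.specimen_id
            d.mkdir(parents=True, exist_ok=True)
            iio.imwrite(d / "patch.png", image)
            cellmap.image_ref = str(d / "patch.png")
            write_cellmap(cellmap, d / "cells.geojson")
        self.clinical.to_csv(out / "clinical.csv", index=False)
        self.truth.to_csv(out / "truth.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _generate_specimen(
    cohort_spec: CohortSpec, subtype: SubtypeSpec, specimen_id: str, entropy
) -> tuple[CellMap, np.ndarray]:
    seeds = np.random.SeedSequence(entropy).spawn(3)
    m = cohort_spec.whole_margin
    s = cohort_spec.patch_size
    window = (m, m, s - m, s - m)
    pattern = simulate_pointpattern(subtype, window, seeds[0])
    cellmap = attach_nuclei(
        pattern, subtype, seeds[1], specimen_id=specimen_id, rois=build_rois(cohort_spec)
    )
    image = render_patch(
        cellmap,
        size=s,
        seed=seeds[2],
        noise_sigma=cohort_spec.noise_sigma,
        texture_amplitude=cohort_spec.texture_amplitude,
    )
    return cellmap, image


_STAGES = (["pT1", "pT2", "pT3", "pT4"], [0.45, 0.27, 0.23, 0.05])
_GRADES = (["G1", "G2", "G3", "G4"], [0.13, 0.47, 0.35, 0.05])
_SEXES = (["female", "male"], [0.34, 0.66])


def simulate_cohort(spec: CohortSpec | None = None) -> SyntheticCohort:
    """Simulate a full cohort: planted subtypes, specimens, and clinical
    records with subtype-linked exponential survival."""
    spec = spec or CohortSpec()
    if spec.n_per_subtype < 2:
        raise ValueError("need n_per_subtype >= 2")
    master = np.random.SeedSequence(spec.seed)
    names = sorted(spec.subtypes)
    n_total = spec.n_per_subtype * len(names)
    children = master.spawn(n_total + 1)
    clin_rng = np.random.default_rng(children[-1])

    recipes = []
    records = []
    truth_rows = []
    i = 0
    for subtype_name in names:
        sub = spec.subtypes[subtype_name]
        for j in range(spec.n_per_subtype):
            sid = f"{subtype_name}_{j:03d}"
            seed_int = int(children[i].generate_state(1)[0])
            recipes.append((sid, subtype_name, seed_int))
            t_event = clin_rng.exponential(1.0 / sub.hazard)
            t_cens = clin_rng.uniform(0.0, spec.censor_max)
            records.append(
                ClinicalRecord(
                    specimen_id=sid,
                    os_time=float(min(t_event, t_cens)),
                    os_event=int(t_event <= t_cens),
                    stage=str(clin_rng.choice(_STAGES[0], p=_STAGES[1])),
                    grade=str(clin_rng.choice(_GRADES[0], p=_GRADES[1])),
                    sex=str(clin_rng.choice(_SEXES[0], p=_SEXES[1])),
                )
            )
            truth_rows.append({"specimen_id": sid, "subtype": subtype_name})
            i += 1

    clinical = pd.DataFrame(
        [
            {
                "specimen_id": r.specimen_id,
                "os_time": r.os_time,
                "os_event": r.os_event,
                "stage": r.stage,
                "grade": r.grade,
                "sex": r.sex,
            }
            for r in records
        ]
    )
    truth = pd.DataFrame(truth_rows)
    manifest = {
        "seed": spec.seed,
        "n_per_subtype": spec.n_per_subtype,
        "patch_size": spec.patch_size,
        "subtypes": {k: asdict(v) for k, v in spec.subtypes.items()},
        "specimen_seeds": {sid: int(ent) for sid, _, ent in recipes},
    }
    return SyntheticCohort(
        spec=spec, clinical=clinical, truth=truth, manifest=manifest, _recipes=recipes
    )
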