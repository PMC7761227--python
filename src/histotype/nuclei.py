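"""Per-nucleus morphometry, intensity, texture, and color descriptors.

Each tumor nucleus in the whole-tumor region yields a 75-long descriptor
row: 10 morphology features from the polygon itself, 7 first-order
intensity-histogram features, 31 texture features (13 Haralick statistics
from a 32-level gray-level co-occurrence matrix at offsets 1 and 2, plus
5 Sobel-gradient statistics), and 27 color features (9 statistics per RGB
channel). Patient-level aggregation (mean and sample SD over nuclei) turns
these into the 150 nuclear features of the phenotype.

Conventions
-----------
* Images are indexed ``image[y, x]``; grayscale is the luminance
  0.299 R + 0.587 G + 0.114 B of the RGB patch.
* Within-nucleus pixel statistics use the population (n-denominator) SD;
  skewness and excess kurtosis of constant pixel sets are defined as 0.
* Histogram and color entropies are Shannon entropies in bits over 32
  equal bins on [0, 255].
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from skimage.draw import polygon as draw_polygon
from skimage.filters import sobel, threshold_otsu

from .cellmap import CellClass, CellMap, Nucleus, ROIKind, assign_roi
from .registry import COLOR_BASE, HARALICK_STATS, NUCLEUS_BASE, TEXTURE_BASE

logger = logging.getLogger(__name__)

N_GRAY_LEVELS = 32
_GLCM_OFFSETS = (1, 2)


# ---------------------------------------------------------------------------
# small statistical helpers (population moments, constant-input conventions)
# ---------------------------------------------------------------------------

def _population_moments(x: np.ndarray) -> tuple[float, float, float, float]:
    """mean, population sd, skewness, excess kurtosis; skew/kurt 0 if sd==0
    (constant input detected exactly)."""
    from ._kernels import population_moments

    return population_moments(np.ascontiguousarray(x, dtype=np.float64))


def _bin_entropy(x: np.ndarray, bins: int = 32, lo: float = 0, hi: float = 255) -> float:
    """Shannon entropy (bits) over equal bins; inputs outside [lo, hi] clip."""
    from ._kernels import entropy_bits

    return float(entropy_bits(np.ascontiguousarray(x, dtype=np.float64), bins, lo, hi))


def _sorted_percentiles(v_sorted: np.ndarray, qs: np.ndarray) -> np.ndarray:
    """Linear-interpolation percentiles of an already sorted 1-D array
    (matches numpy's default method)."""
    n = v_sorted.size
    pos = (n - 1) * np.asarray(qs, dtype=float) / 100.0
    lo = np.floor(pos).astype(np.intp)
    hi = np.ceil(pos).astype(np.intp)
    frac = pos - lo
    return v_sorted[lo] * (1.0 - frac) + v_sorted[hi] * frac


# ---------------------------------------------------------------------------
# morphology (pure polygon geometry; no raster involved)
# ---------------------------------------------------------------------------

def _polygon_moments(ring: np.ndarray):
    """Signed area, centroid, and central second moments of a closed ring."""
    x, y = ring[:-1, 0], ring[:-1, 1]
    x1, y1 = ring[1:, 0], ring[1:, 1]
    cross = x * y1 - x1 * y
    a = cross.sum() / 2.0
    if a == 0:
        raise ValueError("degenerate polygon with zero area")
    cx = ((x + x1) * cross).sum() / (6 * a)
    cy = ((y + y1) * cross).sum() / (6 * a)
    # second moments about the origin
    sxx = ((x**2 + x * x1 + x1**2) * cross).sum() / 12.0
    syy = ((y**2 + y * y1 + y1**2) * cross).sum() / 12.0
    sxy = ((x * y1 + 2 * x * y + 2 * x1 * y1 + x1 * y) * cross).sum() / 24.0
    area = abs(a)
    sign = np.sign(a)
    mu20 = sign * sxx / area - cx**2  # var(x)
    mu02 = sign * syy / area - cy**2  # var(y)
    mu11 = sign * sxy / area - cx * cy
    return area, (cx, cy), (mu20, mu02, mu11)


def morphology_features(nucleus: Nucleus) -> dict[str, float]:
    """10 geometry descriptors computed from the polygon (not a raster).

    Axis lengths follow the ellipse-of-equal-second-moments convention
    (full axis = 4 sqrt(eigenvalue of the coordinate covariance)).
    """
    ring = nucleus.polygon
    area, _, (mu20, mu02, mu11) = _polygon_moments(ring)
    seg = np.diff(ring, axis=0)
    perimeter = float(np.hypot(seg[:, 0], seg[:, 1]).sum())

    cov = np.array([[mu20, mu11], [mu11, mu02]])
    ev = np.linalg.eigvalsh(cov)
    l2, l1 = float(max(ev[0], 0.0)), float(max(ev[1], 0.0))
    major = 4.0 * np.sqrt(l1)
    minor = 4.0 * np.sqrt(l2)
    ecc = float(np.sqrt(1.0 - l2 / l1)) if l1 > 0 else 0.0

    verts = ring[:-1]
    try:
        hull_area = ConvexHull(verts).volume
    except QhullError:
        hull_area = area
    bbox_area = float(np.ptp(verts[:, 0]) * np.ptp(verts[:, 1]))

    return {
        "area": float(area),
        "perimeter": perimeter,
        "equivalent_diameter": float(2.0 * np.sqrt(area / np.pi)),
        "major_axis": float(major),
        "minor_axis": float(minor),
        "eccentricity": ecc,
        "solidity": float(area / hull_area) if hull_area > 0 else np.nan,
        "extent": float(area / bbox_area) if bbox_area > 0 else np.nan,
        "circularity": float(4.0 * np.pi * area / perimeter**2),
        "aspect_ratio": float(major / minor) if minor > 0 else np.nan,
    }


# ---------------------------------------------------------------------------
# pixel access
# ---------------------------------------------------------------------------

def rgb_to_gray(image: np.ndarray) -> np.ndarray:
    """Luminance conversion; passes 2-D input through unchanged."""
    image = np.asarray(image)
    if image.ndim == 2:
        return image.astype(float)
    return (
        0.299 * image[..., 0] + 0.587 * image[..., 1] + 0.114 * image[..., 2]
    ).astype(float)


def _nucleus_crop(nucleus: Nucleus, shape: tuple[int, int]):
    """Bounding-box crop window and in-crop mask for a nucleus polygon."""
    ring = nucleus.polygon
    h, w = shape
    x0 = max(int(np.floor(ring[:, 0].min())), 0)
    x1 = min(int(np.ceil(ring[:, 0].max())) + 1, w)
    y0 = max(int(np.floor(ring[:, 1].min())), 0)
    y1 = min(int(np.ceil(ring[:, 1].max())) + 1, h)
    if x1 <= x0 or y1 <= y0:
        return None
    rr, cc = draw_polygon(ring[:, 1] - y0, ring[:, 0] - x0, shape=(y1 - y0, x1 - x0))
    mask = np.zeros((y1 - y0, x1 - x0), dtype=bool)
    mask[rr, cc] = True
    if not mask.any():
        return None
    return (slice(y0, y1), slice(x0, x1)), mask


# ---------------------------------------------------------------------------
# first-order intensity histogram
# ---------------------------------------------------------------------------

def histogram_features(
    nucleus: Nucleus, image: np.ndarray, _crop=None
) -> dict[str, float]:
    """7 first-order statistics of the gray intensities inside the polygon."""
    if _crop is None:
        gray = rgb_to_gray(image)
        c = _nucleus_crop(nucleus, gray.shape)
        if c is None:
            raise ValueError(f"nucleus {nucleus.id}: empty pixel mask")
        win, mask = c
        vals = gray[win][mask]
    else:
        vals = _crop
    if vals.size == 0:
        raise ValueError(f"nucleus {nucleus.id}: empty pixel mask")
    m, sd, skew, kurt = _population_moments(vals)
    p10, p90 = _sorted_percentiles(np.sort(vals), np.array([10.0, 90.0]))
    return {
        "intensity_mean": m,
        "intensity_sd": sd,
        "intensity_skewness": skew,
        "intensity_kurtosis": kurt,
        "intensity_entropy": _bin_entropy(vals),
        "intensity_p10": float(p10),
        "intensity_p90": float(p90),
    }


# ---------------------------------------------------------------------------
# texture: Haralick statistics of the GLCM + gradient statistics
# ---------------------------------------------------------------------------

_GL_I = np.arange(N_GRAY_LEVELS, dtype=float)
_GL_II, _GL_JJ = np.meshgrid(_GL_I, _GL_I, indexing="ij")
_GL_DIFF2 = (_GL_II - _GL_JJ) ** 2
_GL_INV_DIFF = 1.0 / (1.0 + _GL_DIFF2)
_GL_SUM_IDX = (_GL_II + _GL_JJ).astype(np.intp).ravel()
_GL_ABSDIFF_IDX = np.abs(_GL_II - _GL_JJ).astype(np.intp).ravel()


def _haralick_from_glcm(P: np.ndarray) -> dict[str, float]:
    """13 Haralick statistics from a normalized symmetric GLCM.

    Degenerate conventions: correlation is 0 when a marginal is constant;
    the information measures of correlation are 0 when the marginal
    entropy is 0.
    """
    from ._kernels import haralick13

    vals = haralick13(np.ascontiguousarray(P, dtype=np.float64))
    return {name: float(v) for name, v in zip(HARALICK_STATS, vals)}


def _haralick_from_glcm_reference(P: np.ndarray) -> dict[str, float]:
    """Array-based implementation of the same statistics (test oracle)."""
    n = P.shape[0]
    i = _GL_I
    ii, jj = _GL_II, _GL_JJ
    px = P.sum(axis=1)  # symmetric: px == py
    mu = float((i * px).sum())
    var = float(((i - mu) ** 2 * px).sum())

    energy = float((P**2).sum())
    contrast = float((_GL_DIFF2 * P).sum())
    homogeneity = float((_GL_INV_DIFF * P).sum())
    if var > 0:
        correlation = float((((ii - mu) * (jj - mu) * P).sum()) / var)
    else:
        correlation = 0.0

    nz = P > 0
    entropy = float(-(P[nz] * np.log2(P[nz])).sum())

    k_sum = np.arange(2 * n - 1, dtype=float)
    p_sum = np.bincount(_GL_SUM_IDX, weights=P.ravel(), minlength=2 * n - 1)
    sum_average = float((k_sum * p_sum).sum())
    sum_variance = float(((k_sum - sum_average) ** 2 * p_sum).sum())
    nzs = p_sum > 0
    sum_entropy = float(-(p_sum[nzs] * np.log2(p_sum[nzs])).sum())

    k_diff = np.arange(n, dtype=float)
    p_diff = np.bincount(_GL_ABSDIFF_IDX, weights=P.ravel(), minlength=n)
    diff_mean = float((k_diff * p_diff).sum())
    difference_variance = float(((k_diff - diff_mean) ** 2 * p_diff).sum())
    nzd = p_diff > 0
    difference_entropy = float(-(p_diff[nzd] * np.log2(p_diff[nzd])).sum())

    nzx = px > 0
    hx = float(-(px[nzx] * np.log2(px[nzx])).sum())
    pxy = np.outer(px, px)
    nz2 = (P > 0) & (pxy > 0)
    hxy1 = float(-(P[nz2] * np.log2(pxy[nz2])).sum())
    nz3 = pxy > 0
    hxy2 = float(-(pxy[nz3] * np.log2(pxy[nz3])).sum())
    imc1 = (entropy - hxy1) / hx if hx > 0 else 0.0
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (hxy2 - entropy)))))

    return {
        "energy": energy,
        "contrast": contrast,
        "correlation": correlation,
        "variance": var,
        "homogeneity": homogeneity,
        "sum_average": sum_average,
        "sum_variance": sum_variance,
        "sum_entropy": sum_entropy,
        "entropy": entropy,
        "difference_variance": difference_variance,
        "difference_entropy": difference_entropy,
        "imc1": float(imc1),
        "imc2": imc2,
    }


def _masked_glcm(levels: np.ndarray, mask: np.ndarray, distance: int) -> np.ndarray:
    """Direction-pooled symmetric normalized GLCM over masked pixels.

    Only pixel pairs with both ends inside the mask contribute. The
    compiled loop is equivalent to building the co-occurrence matrix with
    a sentinel level for outside-mask pixels and discarding its
    row/column.
    """
    from ._kernels import glcm_counts

    pooled = glcm_counts(
        np.ascontiguousarray(levels), np.ascontiguousarray(mask), int(distance)
    )
    total = pooled.sum()
    if total == 0:
        return np.zeros((N_GRAY_LEVELS, N_GRAY_LEVELS))
    return pooled / total


def _masked_glcm_reference(levels: np.ndarray, mask: np.ndarray, distance: int) -> np.ndarray:
    """Vectorized construction of the same GLCM (cross-check in tests).

    Offsets are exact grid steps of ``distance`` pixels along the four
    directions (0, 45, 90, 135 degrees), i.e. diagonal neighbors move
    ``distance`` pixels on each axis.
    """
    h, w = levels.shape
    d = int(distance)
    P = np.zeros((N_GRAY_LEVELS, N_GRAY_LEVELS))
    for dr, dc in ((0, d), (-d, d), (-d, 0), (-d, -d)):
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        a = levels[r0:r1, c0:c1]
        b = levels[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        m = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        if m.any():
            idx = a[m].astype(np.intp) * N_GRAY_LEVELS + b[m].astype(np.intp)
            counts = np.bincount(idx, minlength=N_GRAY_LEVELS**2).reshape(
                N_GRAY_LEVELS, N_GRAY_LEVELS
            )
            P += counts + counts.T
    total = P.sum()
    if total == 0:
        return np.zeros((N_GRAY_LEVELS, N_GRAY_LEVELS))
    return P / total


def quantize_gray(gray: np.ndarray) -> np.ndarray:
    """Quantize [0, 255] intensities to 32 gray levels (bin width 8)."""
    return np.clip(np.asarray(gray) // 8, 0, N_GRAY_LEVELS - 1).astype(np.uint8)


def texture_features(
    nucleus: Nucleus,
    image: np.ndarray,
    otsu_threshold: float | None = None,
    _ctx=None,
) -> dict[str, float]:
    """31 texture descriptors: 13 Haralick stats at offsets 1 and 2, plus
    5 Sobel-gradient statistics inside the mask.

    ``otsu_threshold`` is the Otsu cut of the Sobel magnitude of the whole
    patch; it is computed on the fly when not supplied. Masks smaller than
    4 pixels yield an all-NaN row (logged).
    """
    if _ctx is None:
        gray = rgb_to_gray(image)
        c = _nucleus_crop(nucleus, gray.shape)
        if c is None or c[1].sum() < 4:
            logger.info("nucleus %s: mask too small for texture", nucleus.id)
            return {name: np.nan for name in TEXTURE_BASE}
        win, mask = c
        levels = quantize_gray(gray[win])
        grad_patch = sobel(gray)
        if otsu_threshold is None:
            otsu_threshold = float(threshold_otsu(grad_patch))
        grad = grad_patch[win][mask]
    else:
        levels, mask, grad, otsu_threshold = _ctx
        if mask.sum() < 4:
            logger.info("nucleus %s: mask too small for texture", nucleus.id)
            return {name: np.nan for name in TEXTURE_BASE}

    out: dict[str, float] = {}
    for d in _GLCM_OFFSETS:
        stats = _haralick_from_glcm(_masked_glcm(levels, mask, d))
        for name in HARALICK_STATS:
            out[f"glcm_d{d}_{name}"] = stats[name]

    gm, gsd, gskew, _ = _population_moments(grad)
    out["gradient_mean"] = gm
    out["gradient_sd"] = gsd
    out["gradient_skewness"] = gskew
    out["gradient_p90"] = float(_sorted_percentiles(np.sort(grad), np.array([90.0]))[0])
    out["gradient_otsu_fraction"] = float(np.mean(grad > otsu_threshold))
    return out


# ---------------------------------------------------------------------------
# color
# ---------------------------------------------------------------------------

def color_features(nucleus: Nucleus, image: np.ndarray, _crop=None) -> dict[str, float]:
    """27 color descriptors: 9 statistics per RGB channel inside the mask."""
    if _crop is None:
        image = np.asarray(image)
        if image.ndim != 3 or image.shape[-1] != 3:
            raise ValueError(
                "color_features needs an RGB patch; use histogram_features "
                "for grayscale input"
            )
        c = _nucleus_crop(nucleus, image.shape[:2])
        if c is None:
            raise ValueError(f"nucleus {nucleus.id}: empty pixel mask")
        win, mask = c
        channels = [image[win][mask][:, k].astype(float) for k in range(3)]
    else:
        channels = _crop
    out: dict[str, float] = {}
    for cname, vals in zip("rgb", channels):
        m, sd, skew, _ = _population_moments(vals)
        v = np.sort(vals)
        p10, med, p90 = _sorted_percentiles(v, np.array([10.0, 50.0, 90.0]))
        out[f"color_{cname}_mean"] = m
        out[f"color_{cname}_sd"] = sd
        out[f"color_{cname}_skewness"] = skew
        out[f"color_{cname}_entropy"] = _bin_entropy(vals)
        out[f"color_{cname}_p10"] = float(p10)
        out[f"color_{cname}_median"] = float(med)
        out[f"color_{cname}_p90"] = float(p90)
        out[f"color_{cname}_min"] = float(v[0])
        out[f"color_{cname}_max"] = float(v[-1])
    return out


# ---------------------------------------------------------------------------
# batch extraction and patient-level aggregation
# ---------------------------------------------------------------------------

def nucleus_descriptor_table(
    cellmap: CellMap, image: np.ndarray, flags: pd.DataFrame | None = None
) -> pd.DataFrame:
    """75-column descriptor row for every tumor nucleus in the whole tumor.

    The image is converted to luminance once; the Sobel magnitude and its
    patch-level Otsu threshold are shared across nuclei.
    """
    image = np.asarray(image)
    rgb = image.ndim == 3
    gray = rgb_to_gray(image)
    levels_full = quantize_gray(gray)
    grad_full = sobel(gray)
    try:
        otsu = float(threshold_otsu(grad_full))
    except ValueError:  # constant gradient image
        otsu = float(grad_full.flat[0])

    if flags is None:
        flags = assign_roi(cellmap)
    in_whole = set(flags.index[flags[ROIKind.WHOLE_TUMOR.value]])
    rows = []
    index = []
    for nuc in cellmap.nuclei:
        if nuc.cell_class != CellClass.TUMOR or nuc.id not in in_whole:
            continue
        row = morphology_features(nuc)
        c = _nucleus_crop(nuc, gray.shape)
        if c is None:
            row.update({name: np.nan for name in NUCLEUS_BASE if name not in row})
        else:
            win, mask = c
            vals = gray[win][mask]
            row.update(histogram_features(nuc, image, _crop=vals))
            row.update(
                texture_features(
                    nuc, image, _ctx=(levels_full[win], mask, grad_full[win][mask], otsu)
                )
            )
            if rgb:
                pix = image[win][mask].astype(float)
                row.update(
                    color_features(nuc, image, _crop=[pix[:, k] for k in range(3)])
                )
            else:
                row.update({name: np.nan for name in COLOR_BASE})
        rows.append(row)
        index.append(nuc.id)
    return pd.DataFrame(rows, index=pd.Index(index, name="nucleus_id"), columns=NUCLEUS_BASE)


def aggregate_patient(rows: pd.DataFrame, specimen_id: str = "") -> pd.Series:
    """Mean and sample SD (n-1) of each base descriptor over tumor nuclei.

    Missing per-nucleus values are excluded pairwise; requires at least two
    nuclei overall. Output is the 150-entry nuclear feature vector in
    registry order.
    """
    if len(rows) < 2:
        raise ValueError(
            f"specimen {specimen_id!r}: need >= 2 tumor nuclei to aggregate, "
            f"got {len(rows)}"
        )
    n_missing = int(rows.isna().any(axis=1).sum())
    if n_missing:
        logger.info(
            "specimen %s: %d nuclei with missing descriptors (pairwise excluded)",
            specimen_id,
            n_missing,
        )
    out: dict[str, float] = {}
    for base in NUCLEUS_BASE:
        col = rows[base]
        out[f"tumor_{base}_mean"] = float(col.mean())
        out[f"tumor_{base}_sd"] = float(col.std(ddof=1))
    return pd.Series(out, name=specimen_id or None)
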