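import numpy as np
import pytest

from histotype import CellClass, CellMap, Nucleus, ROI, ROIKind


def square_ring(cx: float, cy: float, half: float) -> np.ndarray:
    return np.array(
        [
            [cx - half, cy - half],
            [cx + half, cy - half],
            [cx + half, cy + half],
            [cx - half, cy + half],
            [cx - half, cy - half],
        ],
        dtype=float,
    )


def rect_ring(x0, y0, x1, y1) -> np.ndarray:
    return np.array(
        [[x0, y0], [x1, y0], [x1, y1], [x0, y1], [x0, y0]], dtype=float
    )


def make_rois(size: float = 1000.0, core_margin: float = 300.0, band: float = 150.0):
    whole = rect_ring(0, 0, size, size)
    core = rect_ring(core_margin, core_margin, size - core_margin, size - core_margin)
    inner = rect_ring(band, band, size - band, size - band)
    return [
        ROI(kind=ROIKind.WHOLE_TUMOR, polygon=whole),
        ROI(kind=ROIKind.TUMOR_CORE, polygon=core),
        ROI(kind=ROIKind.TUMOR_PERIPHERY, polygon=rect_ring(0, 0, size, size), holes=[inner]),
    ]


def make_cellmap(points, classes, size: float = 1000.0, half: float = 4.0, **kw):
    nuclei = [
        Nucleus(
            id=i,
            polygon=square_ring(x, y, half),
            centroid=(float(x), float(y)),
            cell_class=CellClass(c),
        )
        for i, ((x, y), c) in enumerate(zip(points, classes))
    ]
    return CellMap(
        specimen_id=kw.pop("specimen_id", "spec1"),
        nuclei=nuclei,
        rois=make_rois(size),
        **kw,
    )


@pytest.fixture
def simple_cellmap():
    """2 tumor nuclei, 1 lymphocyte: one tumor in the core, the others in
    the periphery band."""
    pts = [(500, 500), (50, 50), (60, 950)]
    classes = ["tumor", "tumor", "lymphocyte"]
    return make_cellmap(pts, classes)


@pytest.fixture(scope="session")
def random_cellmap():
    rng = np.random.default_rng(7)
    n = 400
    pts = rng.uniform(20, 980, size=(n, 2))
    classes = rng.choice(["tumor", "lymphocyte", "other"], size=n, p=[0.5, 0.3, 0.2])
    return make_cellmap(pts, classes)


@pytest.fixture(scope="session")
def small_cohort_features():
    """A 30-specimen synthetic cohort's 246-feature matrix (computed once
    per session; used by clustering and statistics tests)."""
    import pandas as pd

    from histotype import CohortSpec, extract_all, simulate_cohort

    cohort = simulate_cohort(CohortSpec(n_per_subtype=10, seed=42))
    F = pd.DataFrame([extract_all(cm, img) for cm, img in cohort.specimens()])
    return cohort, F
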