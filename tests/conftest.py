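import numpy as np
import pandas as pd
import pytest

import jzquant as jz


@pytest.fixture(scope="session")
def frame300():
    return jz.TissueFrame(half_width_um=300.0)


@pytest.fixture(scope="session")
def small_epithelium():
    """64-cell noise-free epithelium with 2x ML polarity, shared across tests."""
    return jz.gen_epithelium(jz.EpitheliumGenParams(n_cells=64, seed=2))


@pytest.fixture()
def simple_tracks():
    """Two straight tracks in one embryo."""
    rows = []
    for tid, (x0, vx) in {"a": (50.0, -10.0), "b": (-50.0, -5.0)}.items():
        for k, t in enumerate([0.0, 30.0, 60.0]):
            rows.append(("E1", tid, t, x0 + vx * k, 1.0 * k, 2.0 * k))
    return jz.TrackTable(
        pd.DataFrame(rows, columns=["embryo_id", "track_id", "time_min", "x_um", "y_um", "z_um"])
    )


def disk_pair(radius: int, pad: int = 5, pixel_size: float = 1.0):
    """Rasterised disk label image with one empty channel."""
    n = 2 * radius + 2 * pad
    yy, xx = np.mgrid[0:n, 0:n]
    c = n // 2
    lbl = (((xx - c) ** 2 + (yy - c) ** 2) <= radius * radius).astype(np.int32)
    return jz.LabelledImagePair(lbl, {"ch": np.zeros((n, n))}, pixel_size)


def random_convex_cell(rng, radius=10.0, n_pts=12, pad=4, return_hull=False):
    """Label image of one rasterised random convex polygon (optionally with
    the exact hull vertices, (x, y))."""
    from scipy.spatial import ConvexHull
    from skimage.draw import polygon as draw_polygon

    pts = rng.normal(scale=radius, size=(n_pts, 2))
    hull = pts[ConvexHull(pts).vertices]
    hull -= hull.min(axis=0) - pad
    size = int(np.ceil(hull.max())) + pad
    rr, cc = draw_polygon(hull[:, 1], hull[:, 0], shape=(size, size))
    lbl = np.zeros((size, size), dtype=np.int32)
    lbl[rr, cc] = 1
    return (lbl, hull) if return_hull else lbl
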