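"""Per-cell geometry and intensity scoring on segmented 2-D projections.

Covers: cell extraction from label images, per-cell and cortical mean
intensities, reference-channel normalisation, the polar-coordinate cortex
mask (interior region within a fraction of the centroid-to-boundary radius),
junction orientation/classification and the ML/AP polarity ratio, apical
enrichment fractions, and apical-area dynamics (normalisation, alignment at
maximal area, aggregation, ingression detection, first-vs-last cortical
change).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from shapely.geometry import Point, Polygon

from .config import TissueFrame
from .io import JunctionTable, LabelledImagePair, ValidationError

__all__ = [
    "CellShape",
    "CortexMask",
    "extract_cells",
    "cell_mean_intensity",
    "normalize_by_reference",
    "cortex_mask",
    "cortical_mean_intensity",
    "junction_orientation",
    "classify_junction",
    "polarity_ratio",
    "call_enrichment",
    "apical_enrichment_fraction",
    "normalize_align_series",
    "aggregate_constriction",
    "detect_ingression",
    "cortical_change",
]

log = logging.getLogger("jzquant")


@dataclass(frozen=True)
class CellShape:
    """Segmented cell outline: label, centroid, boundary polygon and area.

    Coordinates are micrometres; the polygon is the traced outer contour of
    the label's pixel set (simple, closed implicitly).
    """

    label: int
    centroid_um: tuple[float, float]  # (x, y)
    polygon_um: np.ndarray  # (N, 2) of (x, y)
    area_um2: float
    region: str | None = None


@dataclass(frozen=True)
class CortexMask:
    """Interior pixel set of a cell within a radial fraction of the boundary."""

    label: int
    rows: np.ndarray
    cols: np.ndarray
    radial_fraction: float

    @property
    def n_pixels(self) -> int:
        return len(self.rows)


def extract_cells(pair: LabelledImagePair) -> list[CellShape]:
    """One :class:`CellShape` per label; labels with < 4 pixels are skipped.

    Area is pixel count x pixel_size^2; the boundary is the longest traced
    contour of the label mask; the centroid is the pixel centroid.
    """
    from skimage import measure

    px = pair.pixel_size_um
    out: list[CellShape] = []
    n_skipped = 0
    for prop in measure.regionprops(pair.label_image):
        if prop.area < 4:
            n_skipped += 1
            continue
        mask = pair.label_image == prop.label
        # pad so contours of border-touching cells still close
        padded = np.pad(mask.astype(float), 1)
        contours = measure.find_contours(padded, 0.5)
        contour = max(contours, key=len) - 1.0  # (row, col), undo padding
        poly_px = np.column_stack([contour[:, 1], contour[:, 0]])  # (x, y)
        cy, cx = prop.centroid
        out.append(
            CellShape(
                label=int(prop.label),
                centroid_um=(cx * px, cy * px),
                polygon_um=poly_px * px,
                area_um2=float(prop.area) * px * px,
            )
        )
    if n_skipped:
        log.warning("extract_cells: skipped %d label(s) with < 4 pixels", n_skipped)
    return out


def cell_mean_intensity(
    pair: LabelledImagePair, channel: str, cells: list[CellShape] | None = None
) -> pd.Series:
    """Mean channel intensity over each label's pixel set (background excluded)."""
    img = pair.channels[channel]
    labels = [c.label for c in cells] if cells is not None else list(pair.labels)
    if not labels:
        return pd.Series(dtype=float, name=channel)
    means = ndimage.mean(img, labels=pair.label_image, index=labels)
    return pd.Series(means, index=pd.Index(labels, name="label"), name=channel)


def normalize_by_reference(target: pd.Series, reference: pd.Series) -> pd.Series:
    """Elementwise target / reference over the shared cell index.

    Cells whose reference mean is <= 0 are excluded with a warning.
    """
    if not target.index.equals(reference.index):
        common = target.index.intersection(reference.index)
        if len(common) != len(target) or len(common) != len(reference):
            raise ValidationError("target and reference must cover the same cells")
        target, reference = target.loc[common], reference.loc[common]
    bad = reference <= 0
    if bad.any():
        log.warning("normalize_by_reference: excluded %d cell(s) with reference <= 0", int(bad.sum()))
    return (target[~bad] / reference[~bad]).rename(f"{target.name}_over_{reference.name}")


# ---------------------------------------------------------------------------
# polar-coordinate cortex


def _first_crossing_radii(vec: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Distance from the origin to the first polygon-boundary crossing along
    each direction in ``vec`` (rows are (x, y) offsets; polygon relative to
    the same origin).  Exact ray-segment intersection over all edges."""
    a = poly
    b = np.roll(poly, -1, axis=0)
    e = b - a  # (E, 2)
    r = np.linalg.norm(vec, axis=1)
    out = np.full(len(vec), np.inf)
    nz = r > 0
    d = np.zeros_like(vec)
    d[nz] = vec[nz] / r[nz, None]
    # chunk pixels to bound memory on large cells
    idx_nz = np.flatnonzero(nz)
    for start in range(0, len(idx_nz), 4096):
        sel = idx_nz[start : start + 4096]
        dd = d[sel]  # (M, 2)
        # solve t*d = a + s*e ; cross(d, e) s.t. denominators
        denom = dd[:, 0, None] * e[None, :, 1] - dd[:, 1, None] * e[None, :, 0]  # (M, E)
        with np.errstate(divide="ignore", invalid="ignore"):
            s = (dd[:, 0, None] * (-a[None, :, 1]) - dd[:, 1, None] * (-a[None, :, 0])) / denom
            t = (a[None, :, 0] * e[None, :, 1] - a[None, :, 1] * e[None, :, 0]) / denom
        valid = (np.abs(denom) > 1e-12) & (s >= 0.0) & (s <= 1.0) & (t > 0.0)
        t = np.where(valid, t, np.inf)
        out[sel] = t.min(axis=1)
    return out


def cortex_mask(
    cell: CellShape, pair: LabelledImagePair, radial_fraction: float = 0.8
) -> CortexMask:
    """Pixels of a cell within ``radial_fraction`` of the per-angle
    centroid-to-boundary radius.

    A pixel at angle theta and distance r from the centroid belongs to the
    cortex-interior mask iff r <= radial_fraction * R(theta), where R(theta)
    is the distance to the first boundary crossing along the ray at theta
    (rays cast against the traced boundary polygon; for non-star-shaped cells
    distal lobes beyond the first crossing are under-covered by design).  A
    centroid outside the polygon falls back to the pole of inaccessibility.
    """
    if not 0 < radial_fraction < 1:
        raise ValidationError("radial_fraction must be in (0, 1)")
    px = pair.pixel_size_um
    poly_px = cell.polygon_um / px
    if len(poly_px) < 3:
        raise ValidationError(f"degenerate polygon for label {cell.label}")
    centre = np.array(cell.centroid_um) / px
    shp = Polygon(poly_px)
    if shp.area == 0:
        raise ValidationError(f"degenerate polygon for label {cell.label}")
    if not shp.contains(Point(centre)):
        # extreme concavity: pole of inaccessibility keeps the transform defined
        import shapely

        centre = np.array(
            shapely.get_coordinates(shapely.maximum_inscribed_circle(shp))[0]
        )
        log.warning("cortex_mask: centroid outside polygon for label %d; using pole", cell.label)

    rows, cols = np.nonzero(pair.label_image == cell.label)
    vec = np.column_stack([cols - centre[0], rows - centre[1]]).astype(float)
    r = np.linalg.norm(vec, axis=1)
    R = _first_crossing_radii(vec, poly_px - centre[None, :])
    keep = r <= radial_fraction * R
    keep |= r == 0
    return CortexMask(cell.label, rows[keep], cols[keep], radial_fraction)


def cortical_mean_intensity(
    pair: LabelledImagePair, channel: str, cortex: CortexMask
) -> float:
    """Mean channel intensity over the cortex-interior pixel set."""
    if cortex.n_pixels == 0:
        raise ValidationError(f"empty cortex mask for label {cortex.label}")
    return float(pair.channels[channel][cortex.rows, cortex.cols].mean())


# ---------------------------------------------------------------------------
# junction polarity


def junction_orientation(
    p0: tuple[float, float], p1: tuple[float, float], frame: TissueFrame | None = None
) -> float:
    """Acute angle (degrees, [0, 90]) between the junction chord and the ML
    axis.  Endpoints are (ml, ap) coordinates in micrometres."""
    d_ml = p1[0] - p0[0]
    d_ap = p1[1] - p0[1]
    if d_ml == 0 and d_ap == 0:
        raise ValidationError("coincident junction endpoints")
    return float(np.degrees(np.arctan2(abs(d_ap), abs(d_ml))))


def classify_junction(angle_deg: float, threshold_deg: float = 45.0) -> str:
    """ML if the chord angle is strictly less than the threshold, else AP
    (a chord at exactly the threshold counts as AP)."""
    return "ML" if angle_deg < threshold_deg else "AP"


def polarity_ratio(
    junctions: JunctionTable, threshold_deg: float = 45.0
) -> pd.DataFrame:
    """Per-ROI ML/AP polarity ratio.

    ratio = mean(ML-junction intensities) / mean(AP-junction intensities);
    a ratio > 1 indicates ML enrichment.  ROIs missing either class get a NaN
    ratio and ``flagged=True``.
    """
    df = junctions.df
    cls = np.where(df["angle_deg"].to_numpy(dtype=float) < threshold_deg, "ML", "AP")
    work = df.assign(cls=cls)
    rows = []
    for roi, sub in work.groupby("roi_id", sort=True):
        ml = sub.loc[sub["cls"] == "ML", "mean_intensity"]
        ap = sub.loc[sub["cls"] == "AP", "mean_intensity"]
        ok = len(ml) > 0 and len(ap) > 0
        rows.append(
            {
                "roi_id": roi,
                "n_ml": len(ml),
                "n_ap": len(ap),
                "ml_mean": ml.mean() if len(ml) else np.nan,
                "ap_mean": ap.mean() if len(ap) else np.nan,
                "ratio": (ml.mean() / ap.mean()) if ok else np.nan,
                "flagged": not ok,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# apical enrichment


def call_enrichment(cortical_means: pd.Series, k_mad: float = 3.0) -> pd.Series:
    """Boolean apical-enrichment call: cortical mean above the population
    median by more than ``k_mad`` median absolute deviations.

    An explicit, reproducible rule standing in for by-eye scoring of apical
    actomyosin patches.
    """
    x = cortical_means.to_numpy(dtype=float)
    med = np.median(x)
    mad = np.median(np.abs(x - med))
    return pd.Series(x > med + k_mad * mad, index=cortical_means.index, name="enriched")


def apical_enrichment_fraction(flags: pd.Series, regions: pd.Series) -> pd.DataFrame:
    """Percentage of flagged (enriched) cells per region, with counts.

    Regions present in ``regions`` but empty after alignment are flagged
    undefined (NaN percentage).
    """
    df = pd.DataFrame({"flag": flags, "region": regions})
    rows = []
    for region, sub in df.groupby("region", sort=True):
        n = len(sub)
        rows.append(
            {
                "region": region,
                "n": n,
                "n_flagged": int(sub["flag"].sum()),
                "pct": 100.0 * sub["flag"].mean() if n else np.nan,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# apical-area dynamics


def normalize_align_series(series: pd.DataFrame) -> pd.DataFrame:
    """Normalise a per-cell area series by its maximum and align time to the
    (earliest) maximal-area timepoint.

    Input columns: ``cell_id, time_min, area_um2``.  Output adds
    ``norm_area`` (fraction of max, 1.0 at aligned time 0) and
    ``aligned_min`` (negative during the preceding non-constriction phase).
    Requires >= 3 timepoints per cell and strictly positive maxima.
    """
    out = []
    for cell, sub in series.groupby("cell_id", sort=True):
        sub = sub.sort_values("time_min")
        if len(sub) < 3:
            raise ValidationError(f"cell {cell}: need >= 3 timepoints")
        area = sub["area_um2"].to_numpy(dtype=float)
        if (area < 0).any() or area.max() <= 0:
            raise ValidationError(f"cell {cell}: areas must be non-negative with positive max")
        i_max = int(np.argmax(area))  # ties -> earliest
        t = sub["time_min"].to_numpy(dtype=float)
        out.append(
            sub.assign(norm_area=area / area.max(), aligned_min=t - t[i_max])
        )
    return pd.concat(out, ignore_index=True)


def aggregate_constriction(aligned: pd.DataFrame, min_n: int = 3) -> pd.DataFrame:
    """Mean +/- sem of the normalised area per aligned timepoint.

    Timepoints with fewer than ``min_n`` contributing cells are suppressed.
    """
    if aligned.empty:
        raise ValidationError("empty aligned series")
    rows = []
    for t, sub in aligned.groupby("aligned_min", sort=True):
        n = len(sub)
        if n < min_n:
            continue
        vals = sub["norm_area"].to_numpy(dtype=float)
        sem = float(np.std(vals, ddof=1) / np.sqrt(n)) if n > 1 else np.nan
        rows.append({"aligned_min": t, "n": n, "mean_norm_area": float(vals.mean()), "sem": sem})
    return pd.DataFrame(rows)


def detect_ingression(cell_series: pd.DataFrame, area_fraction: float = 0.1):
    """Ingression time of a single cell's normalised series, or None.

    The ingression time is the first timepoint at which the normalised area
    is below the threshold and never recovers to or above it (persistence
    rule, robust to segmentation flicker).  A series ending with the label
    disappearing satisfies persistence trivially at its final collapse.
    """
    sub = cell_series.sort_values("time_min")
    norm = sub["norm_area"].to_numpy(dtype=float)
    t = sub["time_min"].to_numpy(dtype=float)
    below = norm < area_fraction
    if not below.any():
        return None
    # last index at/above threshold; ingression only if some points follow it
    above_idx = np.flatnonzero(~below)
    if len(above_idx) == 0:
        return float(t[0])
    last_above = above_idx[-1]
    if last_above == len(norm) - 1:
        return None
    return float(t[last_above + 1])


def cortical_change(first: pd.Series, last: pd.Series) -> pd.DataFrame:
    """Paired first/last cortical means per cell with their difference.

    Cells missing either endpoint are excluded with a warning.  Output is
    ready for a paired comparison.
    """
    common = first.index.intersection(last.index)
    n_dropped = max(len(first), len(last)) - len(common)
    if n_dropped:
        log.warning("cortical_change: excluded %d cell(s) missing an endpoint", n_dropped)
    f = first.loc[common].astype(float)
    l = last.loc[common].astype(float)
    return pd.DataFrame({"start": f, "end": l, "change": l - f})
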