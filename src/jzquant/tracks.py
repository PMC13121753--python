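"""Trajectory-derived statistics.

Registration to a moving landmark, origin subtraction, toward-midline and
ventral displacement components, region classification, decile displacement
profiles, displacement-weighted polar directionality histograms, paired
position histograms, and tissue width/length over time.

Conventions
-----------
* Toward-midline displacement = |x_start - midline| - |x_end - midline|
  (positive means the cell ended nearer the midline; well defined for
  midline-crossing tracks).
* Ventral displacement = ventral_sign * (z_end - z_start).
* Polar angles are degrees in [0, 360), 0 deg along +ML, counterclockwise,
  bins half-open [lo, hi).  In the transverse (XZ) plane the second
  coordinate is the ventral component, so ventral motion maps to (0, 180).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import AnalysisConfig, TissueFrame
from .io import TrackTable, ValidationError

__all__ = [
    "PolarHistogram",
    "register_to_reference",
    "zero_origin",
    "displacement_components",
    "classify_region",
    "displacement_profile",
    "polar_histogram",
    "position_histogram",
    "tissue_dimensions",
    "infer_half_width",
]

log = logging.getLogger("jzquant")

_AX_COL = {"x": "x_um", "y": "y_um", "z": "z_um"}


@dataclass(frozen=True)
class PolarHistogram:
    """Displacement-weighted directionality histogram.

    ``weight`` per bin is count x mean displacement magnitude (i.e. the sum of
    magnitudes in the bin); counts sum to the number of contributing vectors.
    """

    bin_edges_deg: np.ndarray
    counts: np.ndarray
    mean_magnitude_um: np.ndarray
    weight: np.ndarray
    plane: str
    n_excluded_zero: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_deg": self.bin_edges_deg[:-1],
                "bin_hi_deg": self.bin_edges_deg[1:],
                "count": self.counts,
                "mean_magnitude_um": self.mean_magnitude_um,
                "weight": self.weight,
            }
        )


def register_to_reference(tracks: TrackTable, reference: pd.DataFrame) -> TrackTable:
    """Subtract a per-timepoint landmark position from every track position.

    ``reference`` must have columns ``time_min, x_um, y_um, z_um``; positions
    at intermediate times are linearly interpolated.  After registration the
    landmark maps to the origin at all times.
    """
    ref = reference.sort_values("time_min")
    t = tracks.df["time_min"].to_numpy(dtype=float)
    rt = ref["time_min"].to_numpy(dtype=float)
    if t.min() < rt.min() - 1e-9 or t.max() > rt.max() + 1e-9:
        bad = t[(t < rt.min() - 1e-9) | (t > rt.max() + 1e-9)][0]
        raise ValidationError(f"timepoint {bad} outside reference span [{rt.min()}, {rt.max()}]")
    df = tracks.df.copy()
    for col in ("x_um", "y_um", "z_um"):
        df[col] = df[col].to_numpy(dtype=float) - np.interp(t, rt, ref[col].to_numpy(dtype=float))
    return TrackTable(df)


def zero_origin(tracks: TrackTable) -> TrackTable:
    """Subtract each track's starting location from every timepoint.

    Idempotent; inter-timepoint step vectors are unchanged.
    """
    df = tracks.df.copy()
    for col in ("x_um", "y_um", "z_um"):
        df[col] = df[col] - df.groupby(["embryo_id", "track_id"])[col].transform("first")
    return TrackTable(df)


def classify_region(x, frame: TissueFrame):
    """Region label (medial / intermediate / lateral) of an ML position.

    ``thirds``: d = |x - midline| / half_width; medial if d < 1/3, lateral if
    d > 2/3.  ``fixed_band``: medial within the band of the midline, lateral
    within the band of the lateral edge.  Positions beyond the half-width are
    clamped (with a warning).  Vectorised over ``x``.
    """
    d_abs = frame.ml_distance(x)
    n_out = int(np.sum(d_abs > frame.half_width_um))
    if n_out:
        log.warning("classify_region: clamped %d position(s) beyond half_width", n_out)
        d_abs = np.minimum(d_abs, frame.half_width_um)
    if frame.region_scheme == "thirds":
        d = d_abs / frame.half_width_um
        out = np.where(d < 1 / 3, "medial", np.where(d > 2 / 3, "lateral", "intermediate"))
    else:
        band = frame.fixed_band_um
        out = np.where(
            d_abs <= band,
            "medial",
            np.where(d_abs >= frame.half_width_um - band, "lateral", "intermediate"),
        )
    return out if np.ndim(x) else str(out)


def infer_half_width(tracks: TrackTable, frame: TissueFrame) -> float:
    """Default per-embryo half-width: 95th percentile of |x - midline| of
    starting positions (robust to stray tracks)."""
    starts = tracks.groupby_track().first()
    return float(np.percentile(frame.ml_distance(starts["x_um"]), 95))


def displacement_components(tracks: TrackTable, frame: TissueFrame) -> pd.DataFrame:
    """Per-track displacement records.

    Columns: start position, toward_midline_um, ventral_um, net 3-D
    displacement magnitude, normalised start distance and region label.
    Zero-duration tracks cannot occur (the container requires >= 2
    timepoints with strictly increasing times).
    """
    g = tracks.groupby_track()
    first = g.first()
    last = g.last()
    mid = frame.midline_x
    toward = np.abs(first["x_um"] - mid) - np.abs(last["x_um"] - mid)
    ventral = frame.ventral_sign * (last["z_um"] - first["z_um"])
    net = np.sqrt(
        (last["x_um"] - first["x_um"]) ** 2
        + (last["y_um"] - first["y_um"]) ** 2
        + (last["z_um"] - first["z_um"]) ** 2
    )
    start_d = frame.ml_distance(first["x_um"])
    rec = pd.DataFrame(
        {
            "x_start_um": first["x_um"],
            "y_start_um": first["y_um"],
            "z_start_um": first["z_um"],
            "toward_midline_um": toward,
            "ventral_um": ventral,
            "net_um": net,
            "start_distance_norm": np.minimum(start_d / frame.half_width_um, 1.0),
            "region": classify_region(first["x_um"].to_numpy(), frame),
        }
    ).reset_index()
    return rec


def _sem(x: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    if len(x) < 2:
        return np.nan
    return float(np.std(x, ddof=1) / np.sqrt(len(x)))


def displacement_profile(
    records: pd.DataFrame,
    frame: TissueFrame,
    component: str = "toward_midline",
    n_bins: int = 10,
) -> pd.DataFrame:
    """Mean +/- sem displacement binned by normalised start distance.

    Bins partition (0, 1] into ``n_bins`` equal intervals (a start exactly at
    the midline falls in the first bin); empty bins are reported with n = 0
    and NaN mean.  Bin counts sum to the number of records.
    """
    col = {"toward_midline": "toward_midline_um", "ventral": "ventral_um"}[component]
    d = records["start_distance_norm"].to_numpy(dtype=float)
    idx = np.clip(np.ceil(d * n_bins).astype(int) - 1, 0, n_bins - 1)
    vals = records[col].to_numpy(dtype=float)
    rows = []
    for b in range(n_bins):
        sel = vals[idx == b]
        rows.append(
            {
                "bin_lo_pct": 100.0 * b / n_bins,
                "bin_hi_pct": 100.0 * (b + 1) / n_bins,
                "n": len(sel),
                "mean_um": float(np.mean(sel)) if len(sel) else np.nan,
                "sem_um": _sem(sel),
            }
        )
    return pd.DataFrame(rows)


def polar_histogram(
    tracks: TrackTable,
    plane: str = "XY",
    config: AnalysisConfig | None = None,
    frame: TissueFrame | None = None,
) -> PolarHistogram:
    """Displacement-weighted polar directionality histogram.

    ``plane="XY"`` uses the in-plane (ML, AP) projection, ``plane="XZ"`` the
    transverse (ML, ventral) projection where the second coordinate is
    ``ventral_sign * z`` so the ventral direction is the upper half-plane.
    Default mode ``net`` gives each track one vote at the angle of its net
    displacement vector; mode ``step`` bins every inter-frame step.  Per-bin
    weight = count x mean vector magnitude.  Zero-magnitude vectors are
    excluded with a logged count; if every vector is zero there is no
    direction information and an error is raised.
    """
    config = config or AnalysisConfig()
    frame = frame or TissueFrame()
    if plane not in ("XY", "XZ"):
        raise ValidationError("plane must be 'XY' or 'XZ'")
    c2 = "y_um" if plane == "XY" else "z_um"
    sign2 = 1.0 if plane == "XY" else float(frame.ventral_sign)

    if config.polar_mode == "net":
        g = tracks.groupby_track()
        u = (g["x_um"].last() - g["x_um"].first()).to_numpy(dtype=float)
        v = sign2 * (g[c2].last() - g[c2].first()).to_numpy(dtype=float)
    else:
        df = tracks.df
        du = df.groupby(["embryo_id", "track_id"])["x_um"].diff().dropna()
        dv = df.groupby(["embryo_id", "track_id"])[c2].diff().dropna()
        u = du.to_numpy(dtype=float)
        v = sign2 * dv.to_numpy(dtype=float)

    mag = np.hypot(u, v)
    nonzero = mag > 0
    n_zero = int((~nonzero).sum())
    if n_zero:
        log.warning("polar_histogram: excluded %d zero-magnitude vector(s)", n_zero)
    if not nonzero.any():
        raise ValidationError("no direction information: all displacement vectors are zero")
    ang = np.degrees(np.arctan2(v[nonzero], u[nonzero])) % 360.0
    mag = mag[nonzero]

    width = config.polar_bin_deg
    n_bins = int(round(360.0 / width))
    idx = np.minimum((ang / width).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=mag, minlength=n_bins)
    with np.errstate(invalid="ignore"):
        means = np.where(counts > 0, sums / np.maximum(counts, 1), 0.0)
    return PolarHistogram(
        bin_edges_deg=np.arange(n_bins + 1) * width,
        counts=counts,
        mean_magnitude_um=means,
        weight=counts * means,
        plane="in-plane XY" if plane == "XY" else "transverse XZ",
        n_excluded_zero=n_zero,
    )


def position_histogram(
    positions_a: np.ndarray,
    positions_b: np.ndarray,
    bin_width_um: float,
    frame: TissueFrame,
    labels: tuple[str, str] = ("initial", "final"),
) -> pd.DataFrame:
    """Histograms of ML distance to the midline at two labelled timepoints
    over common bins (suitable for a KS comparison of the raw distances)."""
    da = frame.ml_distance(positions_a)
    db = frame.ml_distance(positions_b)
    top = max(da.max() if len(da) else 0.0, db.max() if len(db) else 0.0)
    edges = np.arange(0.0, top + bin_width_um, bin_width_um)
    if len(edges) < 2:
        edges = np.array([0.0, bin_width_um])
    ca, _ = np.histogram(da, bins=edges)
    cb, _ = np.histogram(db, bins=edges)
    return pd.DataFrame(
        {
            "bin_lo_um": edges[:-1],
            "bin_hi_um": edges[1:],
            f"count_{labels[0]}": ca,
            f"count_{labels[1]}": cb,
        }
    )


def tissue_dimensions(
    node: pd.DataFrame,
    plate_left: pd.DataFrame,
    plate_right: pd.DataFrame,
    streak_tip: pd.DataFrame,
    frame: TissueFrame | None = None,
) -> pd.DataFrame:
    """Tissue width and length per timepoint.

    Width is the ML distance between the bilateral plate borders at node
    level; length is the AP distance between the node and the streak anterior
    tip.  Each landmark table carries ``time_min`` plus coordinate columns;
    timepoints missing any landmark are skipped with a warning.
    """
    frame = frame or TissueFrame()
    ml = _AX_COL[frame.ml_axis]
    ap = _AX_COL[frame.ap_axis]
    sets = {
        "node": node.set_index("time_min"),
        "plate_left": plate_left.set_index("time_min"),
        "plate_right": plate_right.set_index("time_min"),
        "streak_tip": streak_tip.set_index("time_min"),
    }
    common = sorted(set.intersection(*(set(s.index) for s in sets.values())))
    all_times = sorted(set.union(*(set(s.index) for s in sets.values())))
    skipped = [t for t in all_times if t not in common]
    if skipped:
        log.warning("tissue_dimensions: skipped %d timepoint(s) with missing landmarks", len(skipped))
    rows = []
    for t in common:
        width = abs(sets["plate_right"].loc[t, ml] - sets["plate_left"].loc[t, ml])
        length = abs(sets["node"].loc[t, ap] - sets["streak_tip"].loc[t, ap])
        rows.append({"time_min": t, "width_um": width, "length_um": length})
    return pd.DataFrame(rows)
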