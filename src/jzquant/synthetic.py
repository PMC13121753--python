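"""Synthetic data with known ground truth for every pipeline stage.

The generators emulate the statistical structure of the live-imaging and
staining data the analytics consume:

* ``gen_tracks`` — nuclear trajectories with a mediolateral convergence
  gradient (per-cell toward-midline drift proportional to normalised start
  distance), a medially restricted ventral drift (ingression), and isotropic
  Gaussian step noise.
* ``gen_epithelium`` — a Voronoi-like tessellated epithelium with junctional
  intensity that can be planar-polarised by a set ML/AP factor, cortical
  intensity patches in a chosen cell subset, and nuclear signal drawn as
  background plus a positive offset in a known subset.
* ``gen_nuclear_field`` — a field of nuclei on a noisy background for testing
  the positivity classifier at scale.
* ``gen_constriction_set`` — per-cell apical-area series with a
  non-constriction plateau, a constriction phase and optional ingression
  (area collapsing to zero).
* ``gen_depth_sections`` — dorsal/ventral distance pairs whose relative depth
  follows a requested mixture over tissue thirds.

Every generator is deterministic under a fixed seed and returns a
``GroundTruth`` sufficient to predict each downstream estimator without
re-simulation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .config import TissueFrame
from .io import JunctionTable, LabelledImagePair, TrackTable, ValidationError

__all__ = [
    "TrackGenParams",
    "EpitheliumGenParams",
    "GroundTruth",
    "gen_tracks",
    "gen_epithelium",
    "gen_nuclear_field",
    "gen_constriction_set",
    "gen_depth_sections",
]


@dataclass
class GroundTruth:
    """Container for generator ground truth.

    ``params`` echoes the generating parameters; ``per_item`` is a tidy table
    of per-track / per-cell / per-junction truth; ``arrays`` holds raster
    truth (e.g. nuclear label images) that stays out of the JSON export.
    """

    kind: str
    params: dict
    per_item: pd.DataFrame
    arrays: dict = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "kind": self.kind,
            "params": {k: _jsonable(v) for k, v in self.params.items()},
            "per_item": self.per_item.to_dict(orient="list"),
        }
        Path(path).write_text(json.dumps(payload, indent=1, default=_jsonable))


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return float(v)
    if isinstance(v, np.ndarray):
        return v.tolist()
    return v


# ---------------------------------------------------------------------------
# trajectories


@dataclass(frozen=True)
class TrackGenParams:
    """Parameters of the trajectory generator.

    Defaults model a 3 h confocal acquisition at 5 min intervals of a tissue
    extending 300 um to each side of the midline.  Toward-midline drift speed
    of a cell starting at normalised distance d is ``v_conv_um_per_min * d``
    (a linear convergence gradient); ventral drift ``v_ing_um_per_min``
    applies only while the cell lies within ``medial_band_um`` of the midline.
    """

    n_tracks: int = 300
    duration_min: float = 180.0
    dt_min: float = 5.0
    half_width_um: float = 300.0
    ap_extent_um: float = 200.0
    v_conv_um_per_min: float = 0.18
    v_ing_um_per_min: float = 0.035
    medial_band_um: float = 100.0
    diffusion_sigma_um: float = 1.0
    embryo_id: str = "E1"
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.dt_min > 0:
            raise ValidationError("dt_min must be > 0")
        if self.n_tracks < 1:
            raise ValidationError("n_tracks must be >= 1")
        for name in ("v_conv_um_per_min", "v_ing_um_per_min", "diffusion_sigma_um"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        if self.medial_band_um > self.half_width_um:
            raise ValidationError("medial_band_um must not exceed half_width_um")


def gen_tracks(params: TrackGenParams) -> tuple[TrackTable, GroundTruth]:
    """Simulate convergent/ingressing trajectories.

    Starts are uniform over [-half_width, half_width] x [0, ap_extent] with z
    at the dorsal surface (z = 0, increasing ventrally).  Each step adds
    drift * dt plus isotropic Gaussian noise.  Ground truth records, per
    track, the drift speed and the noise-free (drift-integral) predictions of
    toward-midline and ventral displacement over the full duration.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    n_steps = int(round(p.duration_min / p.dt_min))
    times = np.arange(n_steps + 1) * p.dt_min

    x0 = rng.uniform(-p.half_width_um, p.half_width_um, size=p.n_tracks)
    y0 = rng.uniform(0.0, p.ap_extent_um, size=p.n_tracks)
    d0 = np.abs(x0) / p.half_width_um
    v_cell = p.v_conv_um_per_min * d0

    def _integrate(noise):
        x = np.empty((p.n_tracks, n_steps + 1))
        y = np.empty_like(x)
        z = np.empty_like(x)
        x[:, 0], y[:, 0], z[:, 0] = x0, y0, 0.0
        for k in range(n_steps):
            xc = x[:, k]
            dx = -np.sign(xc) * v_cell * p.dt_min
            dz = np.where(np.abs(xc) < p.medial_band_um, p.v_ing_um_per_min * p.dt_min, 0.0)
            x[:, k + 1] = xc + dx + noise[:, k, 0]
            y[:, k + 1] = y[:, k] + noise[:, k, 1]
            z[:, k + 1] = z[:, k] + dz + noise[:, k, 2]
        return x, y, z

    x, y, z = _integrate(rng.normal(0.0, p.diffusion_sigma_um, size=(p.n_tracks, n_steps, 3)))

    track_ids = np.array([f"t{i:04d}" for i in range(p.n_tracks)])
    df = pd.DataFrame(
        {
            "embryo_id": np.repeat(p.embryo_id, p.n_tracks * (n_steps + 1)),
            "track_id": np.repeat(track_ids, n_steps + 1),
            "time_min": np.tile(times, p.n_tracks),
            "x_um": x.ravel(),
            "y_um": y.ravel(),
            "z_um": z.ravel(),
        }
    )

    # noise-free drift integrals: identical step recursion with zero noise
    x_nf, _, z_nf = _integrate(np.zeros((p.n_tracks, n_steps, 3)))
    expected_toward = np.abs(x_nf[:, 0]) - np.abs(x_nf[:, -1])
    expected_ventral = z_nf[:, -1] - z_nf[:, 0]

    truth = GroundTruth(
        kind="tracks",
        params={
            "n_tracks": p.n_tracks,
            "duration_min": p.duration_min,
            "dt_min": p.dt_min,
            "half_width_um": p.half_width_um,
            "ap_extent_um": p.ap_extent_um,
            "v_conv_um_per_min": p.v_conv_um_per_min,
            "v_ing_um_per_min": p.v_ing_um_per_min,
            "medial_band_um": p.medial_band_um,
            "diffusion_sigma_um": p.diffusion_sigma_um,
            "embryo_id": p.embryo_id,
            "seed": p.seed,
        },
        per_item=pd.DataFrame(
            {
                "embryo_id": p.embryo_id,
                "track_id": track_ids,
                "x_start_um": x0,
                "y_start_um": y0,
                "start_distance_norm": d0,
                "drift_um_per_min": v_cell,
                "expected_toward_midline_um": expected_toward,
                "expected_ventral_um": expected_ventral,
            }
        ),
    )
    return TrackTable(df), truth


# ---------------------------------------------------------------------------
# epithelium


@dataclass(frozen=True)
class EpitheliumGenParams:
    """Parameters of the tessellated-epithelium generator.

    Junction intensity along mediolateral junctions is ``ml_polarity_factor``
    times the anteroposterior base intensity.  ``cortical_fraction`` and
    ``positive_fraction`` may be scalars or per-region mappings over
    {"medial", "intermediate", "lateral"} (regions are image-x thirds about
    the image centre).  The positive nuclear offset is expressed in units of
    the background SD.
    """

    n_cells: int = 100
    image_shape: tuple[int, int] = (256, 256)
    pixel_size_um: float = 0.5
    cell_diameter_um: float = 12.0
    junction_width_px: int = 2
    junction_base_intensity: float = 100.0
    ml_polarity_factor: float = 2.0
    cortical_fraction: float | Mapping[str, float] = 0.5
    cortical_offset: float = 100.0
    nuclear_bg_mean: float = 100.0
    nuclear_bg_sd: float = 10.0
    positive_fraction: float | Mapping[str, float] = 0.4
    positive_offset_sd: float = 5.0
    noise_sd: float = 0.0
    angle_threshold_deg: float = 45.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ml_polarity_factor < 1:
            raise ValidationError("ml_polarity_factor must be >= 1")
        for name in ("junction_base_intensity", "cortical_offset", "nuclear_bg_mean",
                     "nuclear_bg_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValidationError(f"{name} must be >= 0")
        for name in ("cortical_fraction", "positive_fraction"):
            v = getattr(self, name)
            vals = v.values() if isinstance(v, Mapping) else [v]
            if any(not 0 <= f <= 1 for f in vals):
                raise ValidationError(f"{name} must lie in [0, 1]")
        h, w = self.image_shape
        diam_px = self.cell_diameter_um / self.pixel_size_um
        if self.n_cells * diam_px**2 > 4 * h * w or diam_px < 3:
            raise ValidationError(
                f"cell diameter {self.cell_diameter_um} um incompatible with "
                f"image {self.image_shape} at {self.pixel_size_um} um/px"
            )


def _fraction_for(region: str, spec: float | Mapping[str, float]) -> float:
    if isinstance(spec, Mapping):
        return float(spec.get(region, 0.0))
    return float(spec)


def gen_epithelium(
    params: EpitheliumGenParams,
) -> tuple[LabelledImagePair, JunctionTable, GroundTruth]:
    """Generate a labelled epithelium with junction/cortical/nuclear channels.

    The tessellation is Voronoi from jittered grid seeds, giving convex cells
    so the polar-coordinate cortex definition is well posed.  Shared
    boundaries are painted with the ML or AP intensity according to their true
    chord angle; boundary pixels claimed by more than one junction (vertices)
    take the maximum and are excluded from the per-junction intensity
    measurement.  Noise is additive Gaussian, clipped at zero.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    h, w = p.image_shape

    # jittered grid seeds -> Voronoi labels
    n_cols = max(1, int(round(np.sqrt(p.n_cells * w / h))))
    n_rows = max(1, int(np.ceil(p.n_cells / n_cols)))
    sx, sy = w / n_cols, h / n_rows
    jitter = 0.25
    cx = (np.arange(n_cols) + 0.5)[None, :] * sx
    cy = (np.arange(n_rows) + 0.5)[:, None] * sy
    seeds_x = (cx + rng.uniform(-jitter, jitter, size=(n_rows, n_cols)) * sx).ravel()
    seeds_y = (cy + rng.uniform(-jitter, jitter, size=(n_rows, n_cols)) * sy).ravel()
    seeds = np.column_stack([seeds_y, seeds_x])
    yy, xx = np.mgrid[0:h, 0:w]
    _, nearest = cKDTree(seeds).query(np.column_stack([yy.ravel(), xx.ravel()]))
    labels = (nearest + 1).astype(np.int32).reshape(h, w)
    n_cells = len(seeds)

    # per-cell region by image-x thirds about the centre
    centroid_x = np.array([xx[labels == l].mean() for l in range(1, n_cells + 1)])
    centroid_y = np.array([yy[labels == l].mean() for l in range(1, n_cells + 1)])
    dist_norm = np.abs(centroid_x - w / 2) / (w / 2)
    regions = np.where(dist_norm < 1 / 3, "medial", np.where(dist_norm > 2 / 3, "lateral", "intermediate"))

    # shared boundaries -> junction pixel sets
    pair_pixels: dict[tuple[int, int], set[tuple[int, int]]] = {}

    def _collect(a_lbl, b_lbl, a_idx, b_idx):
        diff = a_lbl != b_lbl
        for (r, c), la, lb in zip(
            np.argwhere(diff), a_lbl[diff].ravel(), b_lbl[diff].ravel()
        ):
            key = (min(la, lb), max(la, lb))
            s = pair_pixels.setdefault(key, set())
            s.add(a_idx(r, c))
            s.add(b_idx(r, c))

    _collect(labels[:, :-1], labels[:, 1:], lambda r, c: (r, c), lambda r, c: (r, c + 1))
    _collect(labels[:-1, :], labels[1:, :], lambda r, c: (r, c), lambda r, c: (r + 1, c))

    # dilate to requested width
    extra = max(0, (p.junction_width_px - 2) // 2)
    if extra:
        from scipy.ndimage import binary_dilation

        for key, pix in pair_pixels.items():
            m = np.zeros((h, w), bool)
            rows, cols = zip(*pix)
            m[list(rows), list(cols)] = True
            m = binary_dilation(m, iterations=extra)
            pair_pixels[key] = set(map(tuple, np.argwhere(m)))

    claimed = np.zeros((h, w), dtype=np.int16)
    for pix in pair_pixels.values():
        rows, cols = zip(*pix)
        claimed[list(rows), list(cols)] += 1

    junction = np.zeros((h, w))
    records = []
    for (la, lb), pix in sorted(pair_pixels.items()):
        if len(pix) < 3:
            continue
        coords = np.array(sorted(pix), dtype=float)  # (row, col)
        centred = coords - coords.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        d_row, d_col = vt[0]
        angle = float(np.degrees(np.arctan2(abs(d_row), abs(d_col))))
        is_ml = angle < p.angle_threshold_deg
        value = p.junction_base_intensity * (p.ml_polarity_factor if is_ml else 1.0)
        rows, cols = coords[:, 0].astype(int), coords[:, 1].astype(int)
        junction[rows, cols] = np.maximum(junction[rows, cols], value)
        excl = claimed[rows, cols] == 1
        proj = centred @ vt[0]
        lo, hi = coords[np.argmin(proj)], coords[np.argmax(proj)]
        records.append(
            {
                "roi_id": "roi1",
                "junction_id": f"{la}-{lb}",
                "angle_deg": angle,
                "true_class": "ML" if is_ml else "AP",
                "painted_value": value,
                "x0_um": lo[1] * p.pixel_size_um,
                "y0_um": lo[0] * p.pixel_size_um,
                "x1_um": hi[1] * p.pixel_size_um,
                "y1_um": hi[0] * p.pixel_size_um,
                "channel": "junction",
                "_rows": rows[excl],
                "_cols": cols[excl],
            }
        )

    # cortical channel: interior patches in a per-region chosen subset
    cortical = np.zeros((h, w))
    cortical_true = np.zeros(n_cells, dtype=bool)
    for region in ("medial", "intermediate", "lateral"):
        idx = np.flatnonzero(regions == region)
        frac = _fraction_for(region, p.cortical_fraction)
        n_pick = int(round(frac * len(idx)))
        pick = rng.choice(idx, size=n_pick, replace=False) if n_pick else np.array([], int)
        cortical_true[pick] = True
    r_patch = 0.5 * np.sqrt(sx * sy / np.pi)
    for i in np.flatnonzero(cortical_true):
        mask = (labels == i + 1) & (
            (yy - centroid_y[i]) ** 2 + (xx - centroid_x[i]) ** 2 <= (2 * r_patch) ** 2
        )
        cortical[mask] += p.cortical_offset

    # nuclear channel: background + positive offsets; nuclei are centroid disks
    nuclear = rng.normal(p.nuclear_bg_mean, p.nuclear_bg_sd, size=(h, w))
    nuclear_labels = np.zeros((h, w), dtype=np.int32)
    positive_true = np.zeros(n_cells, dtype=bool)
    for region in ("medial", "intermediate", "lateral"):
        idx = np.flatnonzero(regions == region)
        frac = _fraction_for(region, p.positive_fraction)
        n_pick = int(round(frac * len(idx)))
        pick = rng.choice(idx, size=n_pick, replace=False) if n_pick else np.array([], int)
        positive_true[pick] = True
    r_nuc = max(2.0, 0.2 * min(sx, sy))
    for i in range(n_cells):
        disk = (yy - centroid_y[i]) ** 2 + (xx - centroid_x[i]) ** 2 <= r_nuc**2
        disk &= labels == i + 1
        nuclear_labels[disk] = i + 1
        if positive_true[i]:
            nuclear[disk] += p.positive_offset_sd * p.nuclear_bg_sd

    if p.noise_sd > 0:
        junction = junction + rng.normal(0.0, p.noise_sd, size=(h, w))
        cortical = cortical + rng.normal(0.0, p.noise_sd, size=(h, w))
    junction = np.clip(junction, 0.0, None)
    cortical = np.clip(cortical, 0.0, None)
    nuclear = np.clip(nuclear, 0.0, None)

    for rec in records:
        rows, cols = rec.pop("_rows"), rec.pop("_cols")
        rec["mean_intensity"] = float(junction[rows, cols].mean()) if len(rows) else rec["painted_value"]
    jdf = pd.DataFrame.from_records(records)
    jtable = JunctionTable(
        jdf[
            ["roi_id", "junction_id", "angle_deg", "mean_intensity", "channel",
             "x0_um", "y0_um", "x1_um", "y1_um"]
        ]
    )

    pair = LabelledImagePair(
        labels,
        {"junction": junction, "cortical": cortical, "nuclear": nuclear},
        p.pixel_size_um,
    )
    truth = GroundTruth(
        kind="epithelium",
        params={
            "n_cells": n_cells,
            "image_shape": list(p.image_shape),
            "pixel_size_um": p.pixel_size_um,
            "ml_polarity_factor": p.ml_polarity_factor,
            "junction_base_intensity": p.junction_base_intensity,
            "cortical_offset": p.cortical_offset,
            "nuclear_bg_mean": p.nuclear_bg_mean,
            "nuclear_bg_sd": p.nuclear_bg_sd,
            "positive_offset_sd": p.positive_offset_sd,
            "noise_sd": p.noise_sd,
            "seed": p.seed,
        },
        per_item=pd.DataFrame(
            {
                "label": np.arange(1, n_cells + 1),
                "region": regions,
                "cortical_true": cortical_true,
                "positive_true": positive_true,
                "centroid_x_px": centroid_x,
                "centroid_y_px": centroid_y,
            }
        ),
        arrays={
            "nuclear_labels": nuclear_labels,
            "junction_truth": jdf[["junction_id", "angle_deg", "true_class", "painted_value"]],
        },
    )
    return pair, jtable, truth


def gen_nuclear_field(
    n_nuclei: int = 1000,
    nucleus_radius_px: int = 3,
    spacing_px: int = 10,
    bg_mean: float = 100.0,
    bg_sd: float = 10.0,
    positive_fraction: float = 0.4,
    positive_offset_sd: float = 5.0,
    seed: int = 0,
) -> tuple[LabelledImagePair, GroundTruth]:
    """Grid of nuclear disks on Gaussian background, for classifier testing.

    The returned pair's label image is the *nuclear* segmentation; the single
    channel is the nuclear stain (background mean + SD, positives offset by
    ``positive_offset_sd`` background SDs).
    """
    if not 0 <= positive_fraction <= 1:
        raise ValidationError("positive_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    n_cols = int(np.ceil(np.sqrt(n_nuclei)))
    n_rows = int(np.ceil(n_nuclei / n_cols))
    h, w = n_rows * spacing_px, n_cols * spacing_px
    img = np.clip(rng.normal(bg_mean, bg_sd, size=(h, w)), 0.0, None)
    labels = np.zeros((h, w), dtype=np.int32)
    yy, xx = np.mgrid[0:h, 0:w]
    positive = np.zeros(n_nuclei, dtype=bool)
    pick = rng.choice(n_nuclei, size=int(round(positive_fraction * n_nuclei)), replace=False)
    positive[pick] = True
    for i in range(n_nuclei):
        r, c = divmod(i, n_cols)
        cy0 = r * spacing_px + spacing_px // 2
        cx0 = c * spacing_px + spacing_px // 2
        disk = (yy - cy0) ** 2 + (xx - cx0) ** 2 <= nucleus_radius_px**2
        labels[disk] = i + 1
        if positive[i]:
            img[disk] += positive_offset_sd * bg_sd
    pair = LabelledImagePair(labels, {"nuclear": img}, 1.0)
    truth = GroundTruth(
        kind="nuclear_field",
        params={
            "n_nuclei": n_nuclei,
            "bg_mean": bg_mean,
            "bg_sd": bg_sd,
            "positive_fraction": positive_fraction,
            "positive_offset_sd": positive_offset_sd,
            "seed": seed,
        },
        per_item=pd.DataFrame({"label": np.arange(1, n_nuclei + 1), "positive_true": positive}),
    )
    return pair, truth


# ---------------------------------------------------------------------------
# apical-area series


def gen_constriction_set(
    n_cells: int = 48,
    pre_phase_min: float = 30.0,
    constriction_rate: float = 1.0 / 90.0,
    ingressing_fraction: float = 0.4,
    noise_sd: float = 0.02,
    seed: int = 0,
    dt_min: float = 6.0,
    duration_min: float = 150.0,
    ingression_area_fraction: float = 0.1,
    floor_fraction: float = 0.35,
    group: str = "control",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Per-cell apical-area time series with plateau, constriction, ingression.

    Each cell holds a slowly rising plateau (maximum attained at
    ``pre_phase_min``), then shrinks linearly at ``constriction_rate``
    (fraction of the maximal area per minute).  A fraction of cells ingress:
    their area decays through zero and the series records the true time at
    which the noise-free normalised area first drops below
    ``ingression_area_fraction``.  Non-ingressing cells stop shrinking at
    ``floor_fraction`` of their maximum.  Noise is Gaussian in units of the
    maximal area.
    """
    if constriction_rate < 0 or noise_sd < 0:
        raise ValidationError("rates and noise must be >= 0")
    if not 0 <= ingressing_fraction <= 1:
        raise ValidationError("ingressing_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    times = np.arange(0.0, duration_min + 0.5 * dt_min, dt_min)
    a_max = rng.uniform(80.0, 120.0, size=n_cells)
    n_ing = int(round(ingressing_fraction * n_cells))
    ingressing = np.zeros(n_cells, dtype=bool)
    ingressing[rng.choice(n_cells, size=n_ing, replace=False)] = True

    rows = []
    true_t_ing = np.full(n_cells, np.nan)
    pre_slope = 0.2 * constriction_rate  # gentle rise so the max is attained at t0
    for i in range(n_cells):
        rel = np.where(
            times <= pre_phase_min,
            1.0 - pre_slope * (pre_phase_min - times),
            1.0 - constriction_rate * (times - pre_phase_min),
        )
        if not ingressing[i]:
            rel = np.maximum(rel, floor_fraction)
        rel = np.clip(rel, 0.0, None)
        if ingressing[i]:
            below = rel < ingression_area_fraction
            if below.any():
                true_t_ing[i] = times[int(np.argmax(below))]
        noisy = rel + rng.normal(0.0, noise_sd, size=rel.shape) if noise_sd > 0 else rel
        area = np.clip(noisy, 0.0, None) * a_max[i]
        # ingressed cells disappear from the segmentation after collapse
        keep = np.ones_like(times, dtype=bool)
        if ingressing[i]:
            gone = rel <= 0
            if gone.any():
                first_gone = int(np.argmax(gone))
                keep[first_gone + 1 :] = False
                area[first_gone] = 0.0
        for t, a in zip(times[keep], area[keep]):
            rows.append((f"c{i:03d}", t, a, group))

    df = pd.DataFrame(rows, columns=["cell_id", "time_min", "area_um2", "group"])
    truth = GroundTruth(
        kind="constriction",
        params={
            "n_cells": n_cells,
            "pre_phase_min": pre_phase_min,
            "constriction_rate": constriction_rate,
            "ingressing_fraction": ingressing_fraction,
            "noise_sd": noise_sd,
            "dt_min": dt_min,
            "ingression_area_fraction": ingression_area_fraction,
            "seed": seed,
        },
        per_item=pd.DataFrame(
            {
                "cell_id": [f"c{i:03d}" for i in range(n_cells)],
                "max_area_um2": a_max,
                "ingressing_true": ingressing,
                "true_max_time_min": pre_phase_min,
                "true_ingression_time_min": true_t_ing,
            }
        ),
    )
    return df, truth


# ---------------------------------------------------------------------------
# depth sections


def gen_depth_sections(
    n_cells: int = 400,
    weights: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3),
    thickness_um: float = 60.0,
    seed: int = 0,
    group: str = "control",
    embryo_id: str = "E1",
) -> tuple[pd.DataFrame, GroundTruth]:
    """Dorsal/ventral distance pairs with relative depth following a mixture
    over the dorsal/middle/ventral thirds (relative depth uniform within the
    selected third)."""
    w = np.asarray(weights, dtype=float)
    if (w < 0).any():
        raise ValidationError("mixture weights must be >= 0")
    if not np.isclose(w.sum(), 1.0):
        raise ValidationError("mixture weights must sum to 1")
    rng = np.random.default_rng(seed)
    third = rng.choice(3, size=n_cells, p=w)
    rel = (third + rng.uniform(0.0, 1.0, size=n_cells)) * (100.0 / 3.0)
    d = rel / 100.0 * thickness_um
    v = thickness_um - d
    df = pd.DataFrame(
        {
            "cell_id": [f"c{i:04d}" for i in range(n_cells)],
            "d_um": d,
            "v_um": v,
            "group": group,
            "embryo_id": embryo_id,
        }
    )
    truth = GroundTruth(
        kind="depth",
        params={
            "n_cells": n_cells,
            "weights": list(w),
            "thickness_um": thickness_um,
            "seed": seed,
        },
        per_item=pd.DataFrame(
            {"cell_id": df["cell_id"], "third_true": third, "relative_depth_true": rel}
        ),
    )
    return df, truth
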