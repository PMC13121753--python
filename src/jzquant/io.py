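"""Table and image containers plus readers/writers.

All tables travel as pandas DataFrames wrapped in thin validated containers;
rasters are 2-D numpy arrays (y-down, row-major, pixel centres at integer
coordinates) read and written as TIFF via tifffile.  Coordinates are
micrometres everywhere outside image operations; the pixel<->um conversion
happens only through ``LabelledImagePair.pixel_size_um``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "TrackTable",
    "LabelledImagePair",
    "JunctionTable",
    "FormatError",
    "ValidationError",
    "read_tracks",
    "write_tracks",
    "read_image_pair",
    "write_image_pair",
    "read_junctions",
    "write_junctions",
    "read_depth_table",
    "write_depth_table",
]

log = logging.getLogger("jzquant")


class FormatError(ValueError):
    """File does not match the expected schema/format."""


class ValidationError(ValueError):
    """Data violates a container invariant."""


TRACK_COLUMNS = ["embryo_id", "track_id", "time_min", "x_um", "y_um", "z_um"]


@dataclass(frozen=True)
class TrackTable:
    """Registered 3-D trajectories keyed by (embryo_id, track_id, time_min).

    Invariants: the key triple is unique, every track has at least two
    timepoints, and time is strictly increasing within a track.  Rows are kept
    canonically sorted by the key so that loading is order-insensitive.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in TRACK_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"track table missing column(s): {', '.join(missing)}")
        if df[["time_min", "x_um", "y_um", "z_um"]].isna().any().any():
            raise ValidationError("track table contains missing numeric values")
        if (df["time_min"] < 0).any():
            raise ValidationError("time_min must be >= 0")
        key = ["embryo_id", "track_id", "time_min"]
        if df.duplicated(key).any():
            dup = df[df.duplicated(key, keep=False)].iloc[0]
            raise ValidationError(
                "duplicate (embryo_id, track_id, time_min): "
                f"({dup['embryo_id']}, {dup['track_id']}, {dup['time_min']})"
            )
        sizes = df.groupby(["embryo_id", "track_id"], sort=False).size()
        if (sizes < 2).any():
            raise ValidationError("every track must have >= 2 timepoints")
        df = df.sort_values(key, kind="mergesort").reset_index(drop=True)
        object.__setattr__(self, "df", df)

    @property
    def n_tracks(self) -> int:
        return self.df.groupby(["embryo_id", "track_id"]).ngroups

    def groupby_track(self):
        return self.df.groupby(["embryo_id", "track_id"], sort=True)


@dataclass(frozen=True)
class LabelledImagePair:
    """Integer label image (0 = background) with aligned intensity channels."""

    label_image: np.ndarray
    channels: Mapping[str, np.ndarray]
    pixel_size_um: float

    def __post_init__(self) -> None:
        lbl = np.asarray(self.label_image)
        if lbl.ndim != 2:
            raise ValidationError("label image must be 2-D")
        if not np.issubdtype(lbl.dtype, np.integer):
            raise FormatError("label image must have an integer dtype")
        if (lbl < 0).any():
            raise ValidationError("labels must be non-negative")
        bad = {
            name: np.asarray(ch).shape
            for name, ch in self.channels.items()
            if np.asarray(ch).shape != lbl.shape
        }
        if bad:
            raise ValidationError(
                f"channel shape mismatch vs label {lbl.shape}: "
                + ", ".join(f"{k}={v}" for k, v in bad.items())
            )
        if not self.pixel_size_um > 0:
            raise ValidationError("pixel_size_um must be > 0")
        object.__setattr__(self, "label_image", lbl)
        object.__setattr__(
            self, "channels", {k: np.asarray(v, dtype=float) for k, v in self.channels.items()}
        )

    @property
    def labels(self) -> np.ndarray:
        lab = np.unique(self.label_image)
        return lab[lab > 0]


JUNCTION_COLUMNS = ["roi_id", "junction_id", "angle_deg", "mean_intensity", "channel"]


@dataclass(frozen=True)
class JunctionTable:
    """Overdrawn junction segments with orientation and mean intensity.

    ``angle_deg`` is the acute angle of the junction chord to the ML axis, in
    [0, 90].  Endpoint columns (``x0_um, y0_um, x1_um, y1_um``) are optional;
    when present the angle may be recomputed from them.
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        missing = [c for c in JUNCTION_COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"junction table missing column(s): {', '.join(missing)}")
        ang = df["angle_deg"].to_numpy(dtype=float)
        if np.isnan(ang).any() or (ang < 0).any() or (ang > 90).any():
            raise ValidationError("angle_deg must lie in [0, 90]")
        inten = df["mean_intensity"].to_numpy(dtype=float)
        if not np.isfinite(inten).all() or (inten < 0).any():
            raise ValidationError("mean_intensity must be finite and >= 0")
        object.__setattr__(self, "df", df.reset_index(drop=True))


# ---------------------------------------------------------------------------
# readers / writers


def read_tracks(path: str | Path, frame=None) -> TrackTable:
    """Read a track CSV, dropping tracks with fewer than two timepoints.

    The CSV must carry the columns ``embryo_id, track_id, time_min, x_um,
    y_um, z_um`` (an optional ``group`` column is preserved).  The number of
    dropped single-timepoint tracks is logged.
    """
    df = pd.read_csv(path, dtype={"embryo_id": str, "track_id": str})
    missing = [c for c in TRACK_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    df = df.astype({c: float for c in ("time_min", "x_um", "y_um", "z_um")})
    sizes = df.groupby(["embryo_id", "track_id"], sort=False)["time_min"].transform("size")
    n_short = int(df.loc[sizes < 2].groupby(["embryo_id", "track_id"]).ngroups)
    if n_short:
        log.warning("read_tracks: dropped %d track(s) with < 2 timepoints", n_short)
        df = df.loc[sizes >= 2]
    return TrackTable(df)


def write_tracks(table: TrackTable, path: str | Path) -> None:
    cols = TRACK_COLUMNS + [c for c in table.df.columns if c not in TRACK_COLUMNS]
    table.df.to_csv(path, index=False, columns=cols, float_format="%.17g")


def read_image_pair(
    label_path: str | Path,
    channel_paths: Mapping[str, str | Path],
    pixel_size_um: float,
) -> LabelledImagePair:
    """Read a label TIFF and named channel TIFFs into a shape-checked pair."""
    lbl = tifffile.imread(label_path)
    lbl = np.asarray(lbl)
    if not np.issubdtype(lbl.dtype, np.integer):
        if not np.allclose(lbl, np.round(lbl)):
            raise FormatError(f"{label_path}: labels are not integer-valued")
        lbl = np.round(lbl).astype(np.int32)
    channels = {name: tifffile.imread(p) for name, p in channel_paths.items()}
    return LabelledImagePair(lbl, channels, pixel_size_um)


def write_image_pair(pair: LabelledImagePair, label_path: str | Path, channel_paths: Mapping[str, str | Path]) -> None:
    tifffile.imwrite(label_path, pair.label_image.astype(np.uint16))
    for name, p in channel_paths.items():
        tifffile.imwrite(p, pair.channels[name].astype(np.float32))


def read_junctions(path: str | Path) -> JunctionTable:
    df = pd.read_csv(path, dtype={"roi_id": str, "junction_id": str, "channel": str})
    return JunctionTable(df)


def write_junctions(table: JunctionTable, path: str | Path) -> None:
    table.df.to_csv(path, index=False, float_format="%.17g")


DEPTH_COLUMNS = ["cell_id", "d_um", "v_um"]


def read_depth_table(path: str | Path) -> pd.DataFrame:
    """Read a transverse-section depth CSV (cell_id, d_um, v_um[, group, embryo_id])."""
    df = pd.read_csv(path, dtype={"cell_id": str})
    missing = [c for c in DEPTH_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing column(s): {', '.join(missing)}")
    d = df["d_um"].to_numpy(dtype=float)
    v = df["v_um"].to_numpy(dtype=float)
    if (d < 0).any() or (v < 0).any():
        raise ValidationError("d_um and v_um must be >= 0")
    if ((d + v) <= 0).any():
        raise ValidationError("d_um + v_um must be > 0 for every cell")
    return df


def write_depth_table(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False, float_format="%.17g")
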