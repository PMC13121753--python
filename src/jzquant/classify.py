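"""Background-referenced nuclear positivity and dorsoventral depth statistics.

A nucleus is called positive when its mean stain intensity exceeds the mean
of the extranuclear background by more than ``k`` background standard
deviations (default k = 2, strict inequality).  Depth along the dorsoventral
axis is expressed as relative depth D/(D+V) x 100 % (0 % = dorsal surface)
and summarised as 10 %-binned histograms and third-occupancy fractions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import LabelledImagePair, ValidationError

__all__ = [
    "BackgroundStats",
    "background_stats",
    "classify_positive",
    "positive_fraction_by_region",
    "relative_depth",
    "depth_histogram",
    "depth_third_fractions",
]


@dataclass(frozen=True)
class BackgroundStats:
    """Mean and population SD of the stain over extranuclear pixels."""

    mean: float
    sd: float
    n_pixels: int
    channel: str

    def __post_init__(self) -> None:
        if self.sd < 0:
            raise ValidationError("background SD must be >= 0")
        if self.n_pixels <= 0:
            raise ValidationError("background pixel count must be > 0")

    def threshold(self, k: float = 2.0) -> float:
        return self.mean + k * self.sd


def background_stats(
    pair: LabelledImagePair,
    channel: str,
    nuclear_labels: np.ndarray,
    min_pixels: int = 100,
) -> BackgroundStats:
    """Background mean and population SD over pixels outside every nucleus."""
    img = pair.channels[channel]
    nuclear_labels = np.asarray(nuclear_labels)
    if nuclear_labels.shape != img.shape:
        raise ValidationError("nuclear label image shape mismatch")
    bg = img[nuclear_labels == 0]
    if bg.size < min_pixels:
        raise ValidationError(f"only {bg.size} background pixels (need >= {min_pixels})")
    return BackgroundStats(float(bg.mean()), float(bg.std(ddof=0)), int(bg.size), channel)


def classify_positive(
    nuclear_means: pd.Series, bg: BackgroundStats, k: float = 2.0
) -> pd.Series:
    """Per-nucleus positivity: mean intensity strictly above mean_bg + k*sd_bg."""
    if not k > 0:
        raise ValidationError("k must be > 0")
    return (nuclear_means > bg.threshold(k)).rename("positive")


def positive_fraction_by_region(
    positives: pd.Series,
    regions: pd.Series,
    restrict_to: pd.Series | None = None,
) -> pd.DataFrame:
    """Percentage of positive cells per region, optionally restricted to a
    marked subpopulation (e.g. electroporated cells).

    Regions whose restricted population is empty are reported with NaN
    percentage and ``flagged=True``.
    """
    df = pd.DataFrame({"positive": positives, "region": regions})
    if restrict_to is not None:
        df = df[restrict_to.reindex(df.index, fill_value=False)]
    rows = []
    for region, sub in df.groupby("region", sort=True):
        n = len(sub)
        rows.append(
            {
                "region": region,
                "n": n,
                "n_positive": int(sub["positive"].sum()),
                "pct": 100.0 * sub["positive"].mean() if n else np.nan,
                "flagged": n == 0,
            }
        )
    return pd.DataFrame(rows)


def relative_depth(d_um, v_um):
    """Relative depth D/(D+V) x 100 % (0 % at the dorsal surface).

    Vectorised; requires D, V >= 0 and D + V > 0.
    """
    d = np.asarray(d_um, dtype=float)
    v = np.asarray(v_um, dtype=float)
    if (d < 0).any() or (v < 0).any():
        raise ValidationError("D and V must be >= 0")
    if ((d + v) <= 0).any():
        raise ValidationError("D + V must be > 0")
    out = d / (d + v) * 100.0
    return out if out.ndim else float(out)


def depth_histogram(
    depths_pct, bin_pct: float = 10.0, reference_pct=None
) -> pd.DataFrame:
    """Counts of relative depths per bin [0, 10), ..., [90, 100].

    The final bin is closed at 100 so totals are conserved.  When a
    ``reference_pct`` sample is given, each bin also carries the normalised
    frequency ratio (group relative frequency / reference relative
    frequency), NaN where the reference bin is empty.
    """
    depths = np.asarray(depths_pct, dtype=float)
    if (depths < 0).any() or (depths > 100).any():
        raise ValidationError("relative depths must lie in [0, 100]")
    n_bins = int(round(100.0 / bin_pct))
    edges = np.arange(n_bins + 1) * bin_pct
    idx = np.minimum((depths / bin_pct).astype(int), n_bins - 1)
    counts = np.bincount(idx, minlength=n_bins)
    out = pd.DataFrame(
        {"bin_lo_pct": edges[:-1], "bin_hi_pct": edges[1:], "count": counts}
    )
    if reference_pct is not None:
        ref = np.asarray(reference_pct, dtype=float)
        ridx = np.minimum((ref / bin_pct).astype(int), n_bins - 1)
        rcounts = np.bincount(ridx, minlength=n_bins)
        freq = counts / counts.sum() if counts.sum() else counts * np.nan
        rfreq = rcounts / rcounts.sum() if rcounts.sum() else rcounts * np.nan
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = np.where(rfreq > 0, freq / rfreq, np.nan)
        out["count_reference"] = rcounts
        out["freq_ratio"] = ratio
    return out


def depth_third_fractions(depths_pct) -> pd.DataFrame:
    """Fractions of cells in the dorsal / middle / ventral thirds of the
    relative-depth axis ([0, 100/3), [100/3, 200/3), [200/3, 100])."""
    depths = np.asarray(depths_pct, dtype=float)
    if depths.size == 0:
        raise ValidationError("empty depth sample")
    if (depths < 0).any() or (depths > 100).any():
        raise ValidationError("relative depths must lie in [0, 100]")
    lo, hi = 100.0 / 3.0, 200.0 / 3.0
    dorsal = depths < lo
    ventral = depths >= hi
    middle = ~dorsal & ~ventral
    n = depths.size
    return pd.DataFrame(
        {
            "third": ["dorsal", "middle", "ventral"],
            "n": [int(dorsal.sum()), int(middle.sum()), int(ventral.sum())],
            "fraction": [dorsal.mean(), middle.mean(), ventral.mean()],
        }
    )
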