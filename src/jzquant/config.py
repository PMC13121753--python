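"""Coordinate conventions and analysis parameters.

Every spatial operation in the pipeline consults a :class:`TissueFrame`, which
pins down where the embryonic midline sits, which coordinate axis is
mediolateral (ML), anteroposterior (AP) and dorsoventral (DV), which DV
direction is ventral, and how the tissue is partitioned into medial /
intermediate / lateral regions.  :class:`AnalysisConfig` collects the scalar
knobs of the downstream quantifications (polar-histogram bin width, cortex
radial fraction, positivity threshold in background SDs, ...).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["TissueFrame", "AnalysisConfig", "load_config", "ConfigError"]


class ConfigError(ValueError):
    """Raised for invalid configuration values or unknown keys."""


_AXES = ("x", "y", "z")


@dataclass(frozen=True)
class TissueFrame:
    """Coordinate frame of the imaged tissue.

    Parameters
    ----------
    midline_x
        ML coordinate of the embryonic midline, in micrometres.
    half_width_um
        Midline-to-lateral-edge extent used to normalise start distances.
    ml_axis, ap_axis, dv_axis
        Which raw coordinate carries each tissue axis.
    ventral_sign
        +1 if increasing DV coordinate means deeper (more ventral), else -1.
    region_scheme
        ``"thirds"`` splits each half into three equal sections; ``"fixed_band"``
        uses a band of ``fixed_band_um`` at the midline (medial) and at each
        lateral edge (lateral).
    fixed_band_um
        Band width for the ``"fixed_band"`` scheme, micrometres.
    """

    midline_x: float = 0.0
    half_width_um: float = 300.0
    ml_axis: str = "x"
    ap_axis: str = "y"
    dv_axis: str = "z"
    ventral_sign: int = 1
    region_scheme: str = "thirds"
    fixed_band_um: float = 100.0

    def __post_init__(self) -> None:
        if self.half_width_um <= 0:
            raise ConfigError("half_width_um must be > 0")
        for name in ("ml_axis", "ap_axis", "dv_axis"):
            if getattr(self, name) not in _AXES:
                raise ConfigError(f"{name} must be one of {_AXES}")
        if len({self.ml_axis, self.ap_axis, self.dv_axis}) != 3:
            raise ConfigError("ml/ap/dv axes must be distinct")
        if self.ventral_sign not in (-1, 1):
            raise ConfigError("ventral_sign must be +1 or -1")
        if self.region_scheme not in ("thirds", "fixed_band"):
            raise ConfigError("region_scheme must be 'thirds' or 'fixed_band'")
        if self.fixed_band_um <= 0:
            raise ConfigError("fixed_band_um must be > 0")
        if self.region_scheme == "fixed_band" and self.fixed_band_um > self.half_width_um:
            raise ConfigError("fixed_band_um must not exceed half_width_um")

    def ml_distance(self, x) -> "float":
        """Absolute ML distance to the midline (vectorised)."""
        import numpy as np

        return np.abs(np.asarray(x, dtype=float) - self.midline_x)


@dataclass(frozen=True)
class AnalysisConfig:
    """Scalar parameters of the quantifications.

    Defaults follow the conventions of the analysis: 20 deg polar bins,
    10-bin start-position profiles, cortex at 80 % of the centroid-to-boundary
    radius, positivity at background mean + 2 SD, ML/AP junction split at
    45 deg, ingression when the normalised apical area drops below 10 %, and
    10 % relative-depth bins.
    """

    polar_bin_deg: float = 20.0
    profile_bins: int = 10
    cortex_radial_fraction: float = 0.8
    classifier_k_sd: float = 2.0
    junction_angle_threshold_deg: float = 45.0
    ingression_area_fraction: float = 0.1
    depth_bin_pct: float = 10.0
    polar_mode: str = "net"
    unpaired_variance: str = "welch"
    enrichment_k_mad: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        positive = {
            "polar_bin_deg": self.polar_bin_deg,
            "profile_bins": self.profile_bins,
            "classifier_k_sd": self.classifier_k_sd,
            "junction_angle_threshold_deg": self.junction_angle_threshold_deg,
            "ingression_area_fraction": self.ingression_area_fraction,
            "depth_bin_pct": self.depth_bin_pct,
            "enrichment_k_mad": self.enrichment_k_mad,
        }
        for key, value in positive.items():
            if not value > 0:
                raise ConfigError(f"{key} must be > 0 (got {value!r})")
        if not 0.0 < self.cortex_radial_fraction < 1.0:
            raise ConfigError(
                f"cortex_radial_fraction must be in (0, 1) (got {self.cortex_radial_fraction!r})"
            )
        if abs(360.0 / self.polar_bin_deg - round(360.0 / self.polar_bin_deg)) > 1e-9:
            raise ConfigError(f"polar_bin_deg must divide 360 (got {self.polar_bin_deg!r})")
        if self.polar_mode not in ("net", "step"):
            raise ConfigError("polar_mode must be 'net' or 'step'")
        if self.unpaired_variance not in ("welch", "pooled"):
            raise ConfigError("unpaired_variance must be 'welch' or 'pooled'")
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML or JSON file.

    Absent keys take their defaults; unknown keys are rejected so that a typo
    never silently falls back to a default.  An empty file yields the default
    configuration.
    """
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() == ".json":
        data = json.loads(text) if text.strip() else {}
    else:
        data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config root must be a mapping, got {type(data).__name__}")
    known = {f.name for f in dataclasses.fields(AnalysisConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ConfigError(f"unknown config keys: {', '.join(unknown)}")
    return AnalysisConfig(**data)
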