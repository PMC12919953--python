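"""Run configuration for the quantification pipeline.

Every field has a default so a minimal config file is ``{}``. The file format
is a single flat YAML or JSON document whose keys mirror the dataclass fields
(and the CLI flags) one-to-one.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["AnalysisConfig"]

_THRESHOLD_METHODS = ("otsu", "quantile")
_WEIGHT_MODES = ("area", "intensity")
_REFERENCE_MODES = ("fixed_angle", "target_point")
_ROSE_WEIGHT_MODES = ("uniform", "mass")


@dataclass(frozen=True)
class AnalysisConfig:
    """Knobs of the puncta-to-polarity pipeline.

    Attributes
    ----------
    threshold_method : {"otsu", "quantile"}
        Global threshold on the log-normalized image.
    threshold_quantile : float
        Quantile used when ``threshold_method == "quantile"``; in (0, 1).
    min_cluster_area, max_cluster_area : int
        Inclusive size filter for puncta clusters, in pixels.
    connectivity : {4, 8}
        Pixel connectivity for cluster labeling. Puncta are blobs; 8 keeps
        diagonal contacts together.
    weight_mode : {"area", "intensity"}
        Weight of each cluster's unit vector in the per-cell polarity average.
    n_bins : int
        Rose-plot bin count; bins are 360/n_bins wide, first bin centered on
        the reference direction.
    reference_mode : {"fixed_angle", "target_point"}
        Global reference direction (midline-style geometry) or per-cell
        direction toward a point (wound-style geometry).
    reference_angle_deg : float
        Reference angle for ``fixed_angle`` mode, degrees, y-down convention.
    reference_point : tuple[float, float] | None
        (x, y) target for ``target_point`` mode.
    include_border_cells : bool
        Whether cells touching the image border enter the pooled statistics.
    normalize_percentiles : tuple[float, float]
        Percentile clip applied after log1p, before min-max rescaling.
    rose_weight_mode : {"uniform", "mass"}
        Per-cell weight in pooled histograms: 1 per defined cell, or the
        cell's total cluster size/intensity.
    """

    threshold_method: str = "otsu"
    threshold_quantile: float = 0.95
    min_cluster_area: int = 4
    max_cluster_area: int = 400
    connectivity: int = 8
    weight_mode: str = "area"
    n_bins: int = 8
    reference_mode: str = "fixed_angle"
    reference_angle_deg: float = 0.0
    reference_point: tuple[float, float] | None = None
    include_border_cells: bool = True
    normalize_percentiles: tuple[float, float] = (1.0, 99.9)
    rose_weight_mode: str = "uniform"

    def __post_init__(self) -> None:
        if self.threshold_method not in _THRESHOLD_METHODS:
            raise ValueError(
                f"threshold_method must be one of {_THRESHOLD_METHODS}, "
                f"got {self.threshold_method!r}"
            )
        if not 0.0 < self.threshold_quantile < 1.0:
            raise ValueError("threshold_quantile must lie strictly in (0, 1)")
        if self.min_cluster_area > self.max_cluster_area:
            raise ValueError("min_cluster_area must not exceed max_cluster_area")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.weight_mode not in _WEIGHT_MODES:
            raise ValueError(f"weight_mode must be one of {_WEIGHT_MODES}")
        if self.n_bins < 2:
            raise ValueError("n_bins must be at least 2")
        if self.reference_mode not in _REFERENCE_MODES:
            raise ValueError(f"reference_mode must be one of {_REFERENCE_MODES}")
        if self.reference_mode == "target_point" and self.reference_point is None:
            raise ValueError("target_point mode requires reference_point=(x, y)")
        lo, hi = self.normalize_percentiles
        if not 0.0 <= lo < hi <= 100.0:
            raise ValueError("normalize_percentiles must satisfy 0 <= lo < hi <= 100")
        if self.rose_weight_mode not in _ROSE_WEIGHT_MODES:
            raise ValueError(f"rose_weight_mode must be one of {_ROSE_WEIGHT_MODES}")

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        data = dict(data)
        for key in ("reference_point", "normalize_percentiles"):
            if key in data and data[key] is not None:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def from_file(cls, path: str | Path) -> "AnalysisConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) if text.strip() else {}
        if data is None:
            data = {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        if out["reference_point"] is not None:
            out["reference_point"] = list(out["reference_point"])
        out["normalize_percentiles"] = list(out["normalize_percentiles"])
        return out

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def replace(self, **changes) -> "AnalysisConfig":
        return dataclasses.replace(self, **changes)
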