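"""Readers and writers for images, masks, tables, and summaries.

Conventions: pixel centers at integer coordinates, origin at top-left,
x = column, y = row. Rasters travel as single-channel TIFF or PNG; tables as
RFC-4180 CSV with a header row; summaries and config echoes as JSON. I/O
never relabels masks or rescales values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile

from .config import AnalysisConfig

__all__ = [
    "read_intensity_image",
    "read_label_mask",
    "validate_label_mask",
    "MaskValidation",
    "write_results",
    "write_field",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "cell_id",
    "centroid_x",
    "centroid_y",
    "n_clusters",
    "polarity_dx",
    "polarity_dy",
    "polarity_angle_deg",
    "reference_angle_deg",
    "relative_angle_deg",
    "mean_intensity",
    "total_cluster_area",
    "defined",
    "excluded",
    "exclusion_reason",
]


def _read_raster(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        return tifffile.imread(path)
    return iio.imread(path)


def read_intensity_image(path: str | Path) -> np.ndarray:
    """Load a grayscale 8/16-bit image as a 2-D float array, values unchanged."""
    arr = _read_raster(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2-D image, got shape {arr.shape}; "
            "multi-channel or stack input is not supported"
        )
    out = np.asarray(arr, dtype=float)
    if np.any(out < 0) or not np.all(np.isfinite(out)):
        raise ValueError(f"{path}: intensity image must be finite and nonnegative")
    return out


@dataclass
class MaskValidation:
    """What a label mask contains, reported without modifying the mask."""

    labels: list[int]
    n_cells: int
    label_gaps: list[int]
    border_labels: list[int]


def validate_label_mask(mask: np.ndarray) -> MaskValidation:
    labels = np.unique(mask)
    labels = labels[labels > 0].astype(int)
    gaps = []
    if labels.size:
        gaps = sorted(set(range(1, int(labels.max()) + 1)) - set(labels.tolist()))
    border = np.unique(
        np.concatenate([mask[0, :], mask[-1, :], mask[:, 0], mask[:, -1]])
    )
    border = border[border > 0].astype(int)
    return MaskValidation(
        labels=labels.tolist(),
        n_cells=int(labels.size),
        label_gaps=gaps,
        border_labels=border.tolist(),
    )


def read_label_mask(path: str | Path) -> tuple[np.ndarray, MaskValidation]:
    """Load a Cellpose-style label mask (0 = background) plus a validation report.

    Labels are returned exactly as stored — gaps and non-contiguous ids are
    reported, never rewritten. Float rasters are accepted only when integral.
    """
    arr = _read_raster(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path}: expected a single-channel 2-D label mask, got shape {arr.shape}"
        )
    if np.issubdtype(arr.dtype, np.floating):
        if not np.all(np.isfinite(arr)) or np.any(arr != np.round(arr)):
            raise ValueError(f"{path}: label mask has non-integral values")
        arr = arr.astype(np.int64)
    if np.any(arr < 0):
        raise ValueError(f"{path}: label mask has negative labels")
    mask = arr.astype(np.int32)
    return mask, validate_label_mask(mask)


def _json_default(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def write_results(
    table: pd.DataFrame,
    histogram,
    test,
    path_prefix: str | Path,
    config: AnalysisConfig | None = None,
    extra: dict | None = None,
) -> dict[str, Path]:
    """Write the per-cell CSV and the JSON summary.

    ``{prefix}_cells.csv`` holds one row per cell; ``{prefix}_summary.json``
    holds histogram edges/weights/counts, the chi-square result, the config
    echo and the software version.
    """
    from . import __version__

    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    csv_path = prefix.with_name(prefix.name + "_cells.csv")
    json_path = prefix.with_name(prefix.name + "_summary.json")

    out = table.copy()
    for col in RESULT_COLUMNS:
        if col not in out.columns:
            out[col] = np.nan
    out = out[RESULT_COLUMNS]
    out.to_csv(csv_path, index=False, lineterminator="\r\n")

    summary = {
        "software_version": __version__,
        "n_cells": int(len(table)),
        "histogram": {
            "n_bins": int(histogram.n_bins),
            "bin_edges_deg": np.asarray(histogram.bin_edges_deg).tolist(),
            "weights": np.asarray(histogram.weights).tolist(),
            "counts": np.asarray(histogram.counts).tolist(),
            "total_cells": int(histogram.total_cells),
        },
        "uniformity_test": {
            "statistic": test.statistic,
            "df": test.df,
            "p_value": test.p_value,
            "expected_per_bin": test.expected_per_bin,
            "low_expected_warning": bool(test.low_expected_warning),
            "defined": bool(test.defined),
        },
        "config": config.to_dict() if config is not None else None,
    }
    if extra:
        summary.update(extra)
    try:
        json_path.write_text(json.dumps(summary, indent=2, default=_json_default, allow_nan=True))
    except OSError as exc:
        raise OSError(f"cannot write summary to {json_path}: {exc}") from exc
    return {"cells_csv": csv_path, "summary_json": json_path}


def write_field(image, mask, truth, spec, out_dir: str | Path, stem: str) -> dict[str, Path]:
    """Write one synthetic field: 16-bit TIFFs, ground-truth CSV, spec JSON."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    img16 = np.clip(np.round(image), 0, 65535).astype(np.uint16)
    if mask.max() > 65535:
        raise ValueError("label mask exceeds 16-bit range")
    mask16 = mask.astype(np.uint16)
    paths = {
        "image": out_dir / f"{stem}_image.tif",
        "mask": out_dir / f"{stem}_mask.tif",
        "truth": out_dir / f"{stem}_truth.csv",
        "spec": out_dir / f"{stem}_spec.json",
    }
    tifffile.imwrite(paths["image"], img16)
    tifffile.imwrite(paths["mask"], mask16)
    rows = [
        {
            "cell_id": r.cell_id,
            "punctum_index": r.punctum_index,
            "angle_deg": r.angle_deg,
            "x": r.x,
            "y": r.y,
        }
        for r in truth.records
    ]
    pd.DataFrame(rows, columns=["cell_id", "punctum_index", "angle_deg", "x", "y"]).to_csv(
        paths["truth"], index=False, lineterminator="\r\n"
    )
    paths["spec"].write_text(json.dumps(dataclasses.asdict(spec), indent=2, default=_json_default))
    return paths
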