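"""Model/Results interface over the full quantification pipeline.

``PunctaPolarityModel`` is built from one or more (image, mask) pairs — one
pair per field of view or embryo — plus an :class:`AnalysisConfig`. ``fit()``
runs detection, per-cell polarity, cross-field pooling, binning and the
chi-square uniformity test, and returns a ``PunctaPolarityResults`` carrying
the per-cell table, the angular histogram, the test, a run manifest, and
summary/plot/save methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import angular, detection, io as pio, polarity
from .config import AnalysisConfig
from .polarity import CellPolarity, ReferenceField

__all__ = ["PunctaPolarityModel", "PunctaPolarityResults", "RunManifest", "FieldCounts", "run_pipeline"]


@dataclass
class FieldCounts:
    """Per-field bookkeeping; reconciles against stage outputs."""

    n_cells: int = 0
    clusters_found: int = 0
    clusters_size_filtered: int = 0
    clusters_background_dropped: int = 0
    clusters_kept: int = 0
    cells_defined: int = 0
    cells_undefined: int = 0
    cells_excluded: int = 0


@dataclass
class RunManifest:
    """Machine-readable log of record for one fit."""

    n_fields: int
    config: dict
    software_version: str
    fields: list[FieldCounts] = field(default_factory=list)
    input_paths: list[dict] = field(default_factory=list)
    output_paths: dict = field(default_factory=dict)
    seeds: list[int] = field(default_factory=list)

    def reconciles(self) -> bool:
        """Counts are internally consistent at every stage."""
        for fc in self.fields:
            if fc.n_cells != fc.cells_defined + fc.cells_undefined + fc.cells_excluded:
                return False
            if fc.clusters_found != (
                fc.clusters_kept + fc.clusters_size_filtered + fc.clusters_background_dropped
            ):
                return False
        return True


class PunctaPolarityModel:
    """Planar polarity of puncta relative to a reference force direction.

    Parameters
    ----------
    pairs : list of (image, mask)
        One tuple per field: a 2-D nonnegative intensity image (the protein
        channel) and a same-shape integer label mask (0 = background, cells
        1..N, Cellpose convention).
    config : AnalysisConfig, optional
        Pipeline knobs; defaults reproduce the standard workflow (log1p +
        percentile normalization, global Otsu threshold, 8-connectivity,
        size filter [4, 400] px, area weighting, 8 bins).
    """

    def __init__(self, pairs, config: AnalysisConfig | None = None):
        self.config = config or AnalysisConfig()
        self.pairs = []
        for i, (image, mask) in enumerate(pairs):
            image = np.asarray(image, dtype=float)
            mask = np.asarray(mask)
            if image.ndim != 2 or mask.ndim != 2:
                raise ValueError(f"pair {i}: image and mask must be 2-D")
            if image.shape != mask.shape:
                raise ValueError(
                    f"pair {i}: image shape {image.shape} does not match "
                    f"mask shape {mask.shape}"
                )
            if not np.issubdtype(mask.dtype, np.integer):
                raise ValueError(f"pair {i}: label mask must be integer-valued")
            self.pairs.append((image, mask))
        if not self.pairs:
            raise ValueError("at least one (image, mask) pair is required")
        self._input_paths: list[dict] = []

    @classmethod
    def from_paths(cls, image_paths, mask_paths, config: AnalysisConfig | None = None):
        """Build the model from TIFF/PNG files on disk."""
        image_paths = list(image_paths)
        mask_paths = list(mask_paths)
        if len(image_paths) != len(mask_paths):
            raise ValueError(
                f"{len(image_paths)} images but {len(mask_paths)} masks"
            )
        pairs = []
        for ip, mp in zip(image_paths, mask_paths):
            image = pio.read_intensity_image(ip)
            mask, _ = pio.read_label_mask(mp)
            if image.shape != mask.shape:
                raise ValueError(
                    f"image {ip} shape {image.shape} does not match "
                    f"mask {mp} shape {mask.shape}"
                )
            pairs.append((image, mask))
        model = cls(pairs, config=config)
        model._input_paths = [
            {"image": str(ip), "mask": str(mp)} for ip, mp in zip(image_paths, mask_paths)
        ]
        return model

    def _reference(self) -> ReferenceField:
        cfg = self.config
        if cfg.reference_mode == "fixed_angle":
            return ReferenceField.fixed(cfg.reference_angle_deg)
        return ReferenceField.toward(cfg.reference_point)

    def _fit_field(self, image: np.ndarray, mask: np.ndarray, reference: ReferenceField):
        cfg = self.config
        normalized = detection.log_normalize(image, cfg.normalize_percentiles)
        binary = detection.threshold_image(
            normalized, method=cfg.threshold_method, quantile=cfg.threshold_quantile
        )
        clusters = detection.find_clusters(
            binary, connectivity=cfg.connectivity, intensity_image=normalized
        )
        counts = FieldCounts(clusters_found=len(clusters))
        kept = detection.filter_clusters_by_size(
            clusters, cfg.min_cluster_area, cfg.max_cluster_area
        )
        counts.clusters_size_filtered = len(clusters) - len(kept)
        assigned = detection.assign_clusters_to_cells(kept, mask)
        counts.clusters_background_dropped = len(kept) - len(assigned)
        counts.clusters_kept = len(assigned)

        by_cell: dict[int, list] = {}
        for cl in assigned:
            by_cell.setdefault(cl.cell_id, []).append(cl)

        report = pio.validate_label_mask(mask)
        border = set(report.border_labels)
        centroids = polarity.all_cell_centroids(mask)
        mean_int = detection.cell_mean_intensity(image, mask)
        counts.n_cells = report.n_cells

        cells: list[CellPolarity] = []
        rows = []
        for cell_id in report.labels:
            centroid = centroids[cell_id]
            cp = polarity.cell_polarity_vector(
                centroid, by_cell.get(cell_id, []), cfg.weight_mode, cell_id=cell_id
            )
            ref = polarity.reference_angle_at(reference, centroid)
            cp.reference_angle_deg = ref
            excluded = False
            reason = ""
            if not cfg.include_border_cells and cell_id in border:
                excluded, reason = True, "border"
            elif not math.isfinite(ref):
                excluded, reason = True, "undefined_reference"
            if cp.defined and not excluded:
                cp.relative_angle_deg = polarity.relative_angle(cp.polarity_angle_deg, ref)
                counts.cells_defined += 1
            elif excluded:
                cp.defined = False
                counts.cells_excluded += 1
            else:
                counts.cells_undefined += 1
            cells.append(cp)
            rows.append(
                {
                    "cell_id": cell_id,
                    "centroid_x": centroid[0],
                    "centroid_y": centroid[1],
                    "n_clusters": cp.n_clusters,
                    "polarity_dx": cp.polarity_vector[0],
                    "polarity_dy": cp.polarity_vector[1],
                    "polarity_angle_deg": cp.polarity_angle_deg,
                    "reference_angle_deg": ref,
                    "relative_angle_deg": cp.relative_angle_deg,
                    "mean_intensity": float(mean_int.get(cell_id, np.nan)),
                    "total_cluster_area": float(sum(c.area for c in by_cell.get(cell_id, []))),
                    "defined": cp.defined,
                    "excluded": excluded,
                    "exclusion_reason": reason,
                }
            )
        return cells, rows, counts

    def fit(self) -> "PunctaPolarityResults":
        """Run the pipeline on every field and pool the polarity statistics."""
        from . import __version__

        reference = self._reference()
        per_field_cells = []
        all_rows = []
        manifest = RunManifest(
            n_fields=len(self.pairs),
            config=self.config.to_dict(),
            software_version=__version__,
            input_paths=self._input_paths,
        )
        for idx, (image, mask) in enumerate(self.pairs):
            cells, rows, counts = self._fit_field(image, mask, reference)
            for row in rows:
                row["field"] = idx
            per_field_cells.append(cells)
            all_rows.extend(rows)
            manifest.fields.append(counts)

        pooled = polarity.pool_fields(
            per_field_cells, rose_weight_mode=self.config.rose_weight_mode
        )
        hist = angular.bin_angles(pooled.angles_deg, pooled.weights, self.config.n_bins)
        test = angular.chi_square_uniformity(hist)
        table = pd.DataFrame(all_rows, columns=["field"] + pio.RESULT_COLUMNS)
        return PunctaPolarityResults(
            model=self,
            cells=table,
            per_field_cells=per_field_cells,
            pooled=pooled,
            histogram=hist,
            uniformity=test,
            manifest=manifest,
        )


class PunctaPolarityResults:
    """Estimates, test result and diagnostics from a fitted model.

    Attributes
    ----------
    cells : pandas.DataFrame
        One row per cell per field: centroid, polarity vector and angles,
        mean raw intensity, cluster bookkeeping, exclusion flags.
    pooled : PooledPolarity
        Defined cells' relative angles pooled across fields.
    histogram : AngularHistogram
    uniformity : UniformityTest
    manifest : RunManifest
    """

    def __init__(self, model, cells, per_field_cells, pooled, histogram, uniformity, manifest):
        self.model = model
        self.cells = cells
        self.per_field_cells = per_field_cells
        self.pooled = pooled
        self.histogram = histogram
        self.uniformity = uniformity
        self.manifest = manifest

    @property
    def n_defined(self) -> int:
        return self.pooled.n

    def mean_resultant(self) -> tuple[float, float]:
        """(R, mean angle deg) of the pooled relative angles."""
        if self.pooled.n == 0:
            return math.nan, math.nan
        return polarity.mean_resultant(self.pooled.angles_deg)

    def summary(self) -> str:
        """Human-readable fit summary, statsmodels-style."""
        lines = ["Puncta planar-polarity quantification", "=" * 46]
        cfg = self.model.config
        lines.append(f"fields:            {self.manifest.n_fields}")
        lines.append(f"cells total:       {int(sum(f.n_cells for f in self.manifest.fields))}")
        lines.append(f"cells pooled:      {self.pooled.n} (defined polarity)")
        lines.append(f"reference mode:    {cfg.reference_mode}")
        lines.append(f"weight mode:       {cfg.weight_mode}")
        lines.append(f"bins:              {cfg.n_bins} x {360.0 / cfg.n_bins:.1f} deg")
        r, mean = self.mean_resultant()
        if math.isfinite(r):
            lines.append(f"mean resultant R:  {r:.3f} at {mean:+.1f} deg")
        t = self.uniformity
        if t.defined:
            lines.append(
                f"chi-square:        {t.statistic:.3f} (df={t.df}), p = {t.p_value:.3g}"
            )
            if t.low_expected_warning:
                lines.append("warning: expected count per bin < 5")
        else:
            lines.append("chi-square:        undefined (no pooled cells)")
        return "\n".join(lines)

    def plot_rose(self, path=None, ax=None, **kwargs):
        """Render the pooled rose plot (see :func:`angular.render_rose_plot`)."""
        return angular.render_rose_plot(self.histogram, self.uniformity, path=path, ax=ax, **kwargs)

    def save(self, path_prefix) -> dict:
        """Write the per-cell CSV, JSON summary and manifest next to the prefix."""
        import dataclasses as dc
        import json
        from pathlib import Path

        paths = pio.write_results(
            self.cells,
            self.histogram,
            self.uniformity,
            path_prefix,
            config=self.model.config,
        )
        manifest_path = Path(str(path_prefix) + "_manifest.json")
        self.manifest.output_paths = {k: str(v) for k, v in paths.items()}
        manifest_path.write_text(json.dumps(dc.asdict(self.manifest), indent=2))
        paths["manifest_json"] = manifest_path
        return paths


def run_pipeline(image_paths, mask_paths, config: AnalysisConfig | None = None,
                 output_prefix=None, rose_path=None) -> PunctaPolarityResults:
    """Convenience end-to-end entry point over file paths.

    Reads the pairs, fits the model, optionally writes tables/summary and the
    rose plot, and returns the results object.
    """
    model = PunctaPolarityModel.from_paths(image_paths, mask_paths, config=config)
    results = model.fit()
    if output_prefix is not None:
        results.save(output_prefix)
    if rose_path is not None:
        results.plot_rose(path=rose_path)
    return results
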