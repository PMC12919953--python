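"""Puncta detection: log-normalization, thresholding, clustering, assignment.

The protein channel is log-transformed (log1p), percentile-normalized to
[0, 1], and globally thresholded into a binary mask; connected components of
the mask become puncta clusters, which are size-filtered and assigned to the
cell holding the plurality of their pixels. Cluster intensity is measured on
the normalized image (the domain the threshold sees); per-cell mean intensity
for group comparisons is measured on the raw image.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "PunctaCluster",
    "log_normalize",
    "otsu_threshold",
    "threshold_image",
    "find_clusters",
    "filter_clusters_by_size",
    "assign_clusters_to_cells",
    "cell_mean_intensity",
]

logger = logging.getLogger(__name__)

N_OTSU_BINS = 256


@dataclass
class PunctaCluster:
    """One detected punctum: a connected foreground component.

    ``centroid`` is the unweighted mean (x, y) of member pixels;
    ``integrated_intensity`` sums the normalized image over those pixels.
    ``cell_id`` is None until assignment.
    """

    cluster_id: int
    centroid: tuple[float, float]
    area: int
    integrated_intensity: float
    rows: np.ndarray
    cols: np.ndarray
    cell_id: int | None = None


def log_normalize(image: np.ndarray, percentiles=(1.0, 99.9)) -> np.ndarray:
    """log1p then percentile-clipped min-max rescale to [0, 1].

    The lower/upper clip percentiles of log1p(I) map to 0/1; values outside
    are clipped. Rank order of pixel values is weakly preserved. A constant
    image yields all zeros (documented degenerate result).
    """
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("intensity image must be nonnegative")
    logged = np.log1p(image)
    lo, hi = np.percentile(logged, percentiles)
    if hi <= lo:
        return np.zeros_like(logged)
    return np.clip((logged - lo) / (hi - lo), 0.0, 1.0)


def otsu_threshold(image: np.ndarray, nbins: int = N_OTSU_BINS) -> float:
    """Otsu's threshold over an nbins-level histogram of a [0, 1] image.

    Candidate split t puts bins 0..t in the background class; the returned
    threshold is the upper edge of bin t maximizing the between-class variance
    w0*w1*(mu0-mu1)^2 (computed via cumulative histogram moments). Ties break
    toward the lowest threshold. Foreground is ``value > threshold``.
    """
    flat = np.asarray(image, dtype=float).ravel()
    edges = np.linspace(0.0, 1.0, nbins + 1)
    hist, _ = np.histogram(flat, bins=edges)
    hist = hist.astype(float)
    total = hist.sum()
    centers = (edges[:-1] + edges[1:]) / 2.0
    w0 = np.cumsum(hist)[:-1]
    w1 = total - w0
    mass0 = np.cumsum(hist * centers)[:-1]
    mass1 = (hist * centers).sum() - mass0
    with np.errstate(divide="ignore", invalid="ignore"):
        mu0 = np.where(w0 > 0, mass0 / w0, 0.0)
        mu1 = np.where(w1 > 0, mass1 / w1, 0.0)
        var_between = w0 * w1 * (mu0 - mu1) ** 2
    best = int(np.argmax(var_between))
    return float(edges[best + 1])


def threshold_image(image: np.ndarray, method: str = "otsu", quantile: float = 0.95) -> np.ndarray:
    """Binary foreground mask of a normalized [0, 1] image.

    ``otsu``: maximize between-class variance over 256 levels. ``quantile``:
    pixels strictly above the given quantile are foreground. A constant image
    yields an empty mask under both methods.
    """
    image = np.asarray(image, dtype=float)
    if image.min() == image.max():
        return np.zeros(image.shape, dtype=bool)
    if method == "otsu":
        thr = otsu_threshold(image)
    elif method == "quantile":
        if not 0.0 < quantile < 1.0:
            raise ValueError("quantile must lie strictly in (0, 1)")
        thr = float(np.quantile(image, quantile))
    else:
        raise ValueError(f"unknown threshold method {method!r}")
    return image > thr


_STRUCTURES = {
    4: ndimage.generate_binary_structure(2, 1),
    8: ndimage.generate_binary_structure(2, 2),
}


def find_clusters(
    mask: np.ndarray,
    connectivity: int = 8,
    intensity_image: np.ndarray | None = None,
) -> list[PunctaCluster]:
    """Connected components of a binary mask as puncta clusters.

    ``intensity_image`` (normally the log-normalized image) supplies the
    integrated intensity; when absent it is recorded as nan.
    """
    if connectivity not in _STRUCTURES:
        raise ValueError("connectivity must be 4 or 8")
    mask = np.asarray(mask, dtype=bool)
    labeled, n = ndimage.label(mask, structure=_STRUCTURES[connectivity])
    clusters: list[PunctaCluster] = []
    if n == 0:
        return clusters
    objects = ndimage.find_objects(labeled)
    for i, sl in enumerate(objects, start=1):
        sub = labeled[sl] == i
        rows, cols = np.nonzero(sub)
        rows = rows + sl[0].start
        cols = cols + sl[1].start
        if intensity_image is not None:
            intensity = float(np.asarray(intensity_image)[rows, cols].sum())
        else:
            intensity = float("nan")
        clusters.append(
            PunctaCluster(
                cluster_id=i,
                centroid=(float(cols.mean()), float(rows.mean())),
                area=int(rows.size),
                integrated_intensity=intensity,
                rows=rows,
                cols=cols,
            )
        )
    return clusters


def filter_clusters_by_size(clusters, min_area: int, max_area: float) -> list[PunctaCluster]:
    """Keep clusters with min_area <= area <= max_area (inclusive both ends)."""
    if min_area > max_area:
        raise ValueError("min_area must not exceed max_area")
    kept = [c for c in clusters if min_area <= c.area <= max_area]
    removed = len(clusters) - len(kept)
    if removed:
        logger.info("size filter removed %d of %d clusters", removed, len(clusters))
    return kept


def assign_clusters_to_cells(clusters, label_mask: np.ndarray) -> list[PunctaCluster]:
    """Assign each cluster to the cell holding the plurality of its pixels.

    Ties break toward the smaller label. Clusters whose plurality label is
    background (0) are dropped (and counted in the log).
    """
    label_mask = np.asarray(label_mask)
    assigned: list[PunctaCluster] = []
    dropped = 0
    for cl in clusters:
        votes = np.bincount(label_mask[cl.rows, cl.cols].astype(np.int64))
        winner = int(np.argmax(votes))  # first max = smallest label on ties
        if winner == 0:
            dropped += 1
            continue
        cl.cell_id = winner
        assigned.append(cl)
    if dropped:
        logger.info("dropped %d clusters with background plurality", dropped)
    return assigned


def cell_mean_intensity(image: np.ndarray, mask: np.ndarray) -> pd.Series:
    """Arithmetic mean of raw image values over each cell's pixels.

    Indexed by cell id; cells absent from the mask are absent from the output.
    """
    image = np.asarray(image, dtype=float)
    mask = np.asarray(mask)
    if image.shape != mask.shape:
        raise ValueError(f"image shape {image.shape} != mask shape {mask.shape}")
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return pd.Series(dtype=float, name="mean_intensity")
    means = ndimage.mean(image, labels=mask, index=labels)
    return pd.Series(means, index=labels.astype(int), name="mean_intensity")
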