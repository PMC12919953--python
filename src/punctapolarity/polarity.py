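"""Per-cell polarity vectors relative to a reference force direction.

Each cell's polarity is the weighted mean of unit vectors pointing from the
cell centroid toward the centroids of its puncta clusters. The weight of each
unit vector is the cluster's pixel area or its integrated fluorescence
intensity; the distance of a cluster from the centroid carries no weight. A
cell's polarity angle is then expressed relative to a reference direction —
either one fixed angle for the whole field (midline-style geometry) or the
per-cell direction toward a target point (wound-style geometry).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .angles import angle_of, circular_mean, wrap_deg

__all__ = [
    "ReferenceField",
    "CellPolarity",
    "PooledPolarity",
    "cell_centroid",
    "cell_polarity_vector",
    "reference_angle_at",
    "relative_angle",
    "pool_fields",
    "mean_resultant",
]

logger = logging.getLogger(__name__)

#: polarity magnitudes below this mark the cell "undefined" instead of
#: assigning a noise angle
DEGENERACY_TOL = 1e-6


@dataclass(frozen=True)
class ReferenceField:
    """Reference direction against which polarity angles are measured.

    ``fixed_angle`` mode: one global angle (e.g. toward the dorsal midline).
    ``target_point`` mode: per-cell angle from the cell centroid toward a
    fixed (x, y) point (e.g. a wound site).
    """

    mode: str
    angle_deg: float | None = None
    target: tuple[float, float] | None = None

    def __post_init__(self):
        if self.mode not in ("fixed_angle", "target_point"):
            raise ValueError(f"unknown reference mode {self.mode!r}")
        if self.mode == "fixed_angle":
            if self.angle_deg is None:
                raise ValueError("fixed_angle mode requires angle_deg")
            object.__setattr__(self, "angle_deg", wrap_deg(self.angle_deg))
        else:
            if self.target is None:
                raise ValueError("target_point mode requires target=(x, y)")
            object.__setattr__(self, "target", (float(self.target[0]), float(self.target[1])))

    @classmethod
    def fixed(cls, angle_deg: float) -> "ReferenceField":
        return cls(mode="fixed_angle", angle_deg=angle_deg)

    @classmethod
    def toward(cls, target: tuple[float, float]) -> "ReferenceField":
        return cls(mode="target_point", target=target)


@dataclass
class CellPolarity:
    """One cell's weighted mean polarity vector.

    ``polarity_vector`` is dimensionless with magnitude in [0, 1] (a convex
    combination of unit vectors). ``defined`` is False when the cell has no
    clusters, zero total weight, or a polarity magnitude below the degeneracy
    tolerance; angle fields are then nan.
    """

    cell_id: int
    cell_centroid: tuple[float, float]
    polarity_vector: tuple[float, float] = (0.0, 0.0)
    polarity_angle_deg: float = math.nan
    reference_angle_deg: float = math.nan
    relative_angle_deg: float = math.nan
    weight_total: float = 0.0
    n_clusters: int = 0
    defined: bool = False

    @property
    def magnitude(self) -> float:
        return float(np.hypot(*self.polarity_vector))


def cell_centroid(mask: np.ndarray, cell_id: int) -> tuple[float, float]:
    """Unweighted mean (x, y) of the pixels labeled ``cell_id``."""
    rows, cols = np.nonzero(mask == cell_id)
    if rows.size == 0:
        raise ValueError(f"label {cell_id} not present in mask")
    return float(cols.mean()), float(rows.mean())


def all_cell_centroids(mask: np.ndarray) -> dict[int, tuple[float, float]]:
    """Centroids of every nonzero label, as {cell_id: (x, y)}."""
    labels = np.unique(mask)
    labels = labels[labels > 0]
    if labels.size == 0:
        return {}
    coms = ndimage.center_of_mass(np.ones_like(mask, dtype=float), mask, labels)
    return {int(lab): (float(c), float(r)) for lab, (r, c) in zip(labels, coms)}


def cell_polarity_vector(
    cell_centroid: tuple[float, float],
    clusters,
    weight_mode: str = "area",
    cell_id: int = -1,
) -> CellPolarity:
    """Weighted mean of unit vectors from the cell centroid to cluster centroids.

    ``weight_mode`` selects the cluster weight: pixel area or integrated
    intensity. Clusters whose centroid coincides with the cell centroid are
    skipped (their direction is undefined) and logged.
    """
    if weight_mode not in ("area", "intensity"):
        raise ValueError("weight_mode must be 'area' or 'intensity'")
    gx, gy = cell_centroid
    sx = sy = total = 0.0
    used = 0
    for cl in clusters:
        cx, cy = cl.centroid
        dx, dy = cx - gx, cy - gy
        norm = math.hypot(dx, dy)
        if norm < 1e-12:
            logger.debug("cell %s: cluster at centroid skipped", cell_id)
            continue
        w = float(cl.area) if weight_mode == "area" else float(cl.integrated_intensity)
        if w <= 0:
            continue
        sx += w * dx / norm
        sy += w * dy / norm
        total += w
        used += 1
    pol = CellPolarity(cell_id=cell_id, cell_centroid=(gx, gy), n_clusters=len(clusters))
    if used == 0 or total <= 0:
        return pol
    vx, vy = sx / total, sy / total
    pol.polarity_vector = (vx, vy)
    pol.weight_total = total
    if math.hypot(vx, vy) < DEGENERACY_TOL:
        return pol
    pol.polarity_angle_deg = angle_of(vx, vy)
    pol.defined = True
    return pol


def reference_angle_at(reference: ReferenceField, cell_centroid: tuple[float, float]) -> float:
    """Reference direction at a cell, degrees.

    Returns nan in target-point mode when the target coincides with the
    centroid (undefined direction; the caller excludes the cell).
    """
    if reference.mode == "fixed_angle":
        return float(reference.angle_deg)
    tx, ty = reference.target
    dx, dy = tx - cell_centroid[0], ty - cell_centroid[1]
    if math.hypot(dx, dy) < 1e-12:
        logger.warning("reference target coincides with cell centroid %s", cell_centroid)
        return math.nan
    return angle_of(dx, dy)


def relative_angle(polarity_angle_deg: float, reference_angle_deg: float) -> float:
    """polarity minus reference, wrapped to (-180, 180]; 0 = toward the reference."""
    return wrap_deg(polarity_angle_deg - reference_angle_deg)


@dataclass
class PooledPolarity:
    """Defined cells' relative angles pooled across fields (e.g. embryos)."""

    angles_deg: np.ndarray
    weights: np.ndarray
    field_of_origin: np.ndarray
    cells_per_field: list[int] = field(default_factory=list)

    @property
    def n(self) -> int:
        return int(self.angles_deg.size)


def pool_fields(per_field_cells, configs=None, rose_weight_mode: str = "uniform") -> PooledPolarity:
    """Concatenate defined cells' relative angles across fields.

    ``per_field_cells`` is a list (one entry per field/embryo) of lists of
    :class:`CellPolarity`. When ``configs`` is given, all entries must be
    equal — pooling across differently-configured runs is an error. With
    ``rose_weight_mode='uniform'`` each defined cell contributes weight 1, so
    fields with more puncta do not dominate; ``'mass'`` weights each cell by
    its total cluster size/intensity.
    """
    if configs is not None:
        first = configs[0]
        for i, cfg in enumerate(configs[1:], start=1):
            if cfg != first:
                raise ValueError(f"config of field {i} differs from field 0; cannot pool")
    angles, weights, origin, counts = [], [], [], []
    for idx, cells in enumerate(per_field_cells):
        n_def = 0
        for cp in cells:
            if not cp.defined or not math.isfinite(cp.relative_angle_deg):
                continue
            angles.append(cp.relative_angle_deg)
            weights.append(1.0 if rose_weight_mode == "uniform" else cp.weight_total)
            origin.append(idx)
            n_def += 1
        counts.append(n_def)
    return PooledPolarity(
        angles_deg=np.asarray(angles, dtype=float),
        weights=np.asarray(weights, dtype=float),
        field_of_origin=np.asarray(origin, dtype=int),
        cells_per_field=counts,
    )


def mean_resultant(angles_deg) -> tuple[float, float]:
    """Mean resultant length R in [0, 1] and mean direction of pooled angles."""
    a = np.asarray(angles_deg, dtype=float)
    if a.size == 0:
        raise ValueError("mean_resultant of empty input is undefined")
    return circular_mean(a)
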