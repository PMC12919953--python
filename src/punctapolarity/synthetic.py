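"""Synthetic polarized epithelium: label fields, puncta images, ground truth.

The generator emulates the two geometries the pipeline targets: a confluent
field of convex-ish cells whose puncta are angularly biased toward one global
direction (midline-style neural plate), or toward a fixed point (wound-style
re-epithelialization). Cells are Voronoi regions of jittered-grid seed points;
puncta are isotropic Gaussian spots clipped to their owning cell, placed at a
von Mises-distributed angle around the cell centroid; additive Gaussian noise
sits on a constant background. Every draw flows from one seeded generator, so
outputs are bitwise reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
from scipy import ndimage
from scipy.spatial import cKDTree

from .angles import wrap_deg
from .polarity import ReferenceField, reference_angle_at

__all__ = [
    "FieldSpec",
    "GroundTruth",
    "PunctumRecord",
    "generate_label_field",
    "generate_puncta_image",
    "generate_dataset",
    "draw_angles",
]

#: minimum mean pixels per cell for a plausible confluent tessellation
MIN_PIXELS_PER_CELL = 25


@dataclass(frozen=True)
class FieldSpec:
    """Parameters of one simulated field.

    Intensities are in arbitrary camera units on a 16-bit-like scale.
    ``bias_kappa`` is the von Mises concentration of puncta angles around the
    reference direction (0 = uniform). ``radial_fraction_range`` places each
    punctum at a uniform fraction of the centroid-to-boundary distance along
    its drawn angle.
    """

    image_height: int = 256
    image_width: int = 256
    n_cells: int = 150
    mean_puncta_per_cell: float = 6.0
    punctum_sigma: float = 1.5
    punctum_amplitude: float = 1000.0
    background_level: float = 100.0
    noise_sigma: float = 20.0
    bias_mu: float = 0.0
    bias_kappa: float = 1.5
    radial_fraction_range: tuple[float, float] = (0.2, 0.8)
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        if self.bias_kappa < 0:
            raise ValueError("bias_kappa must be >= 0")
        lo, hi = self.radial_fraction_range
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("radial_fraction_range must satisfy 0 <= low <= high <= 1")
        if self.mean_puncta_per_cell < 0:
            raise ValueError("mean_puncta_per_cell must be >= 0")
        for name in ("punctum_amplitude", "background_level", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.punctum_sigma <= 0:
            raise ValueError("punctum_sigma must be > 0")

    def replace(self, **changes) -> "FieldSpec":
        return replace(self, **changes)


@dataclass(frozen=True)
class PunctumRecord:
    """Ground truth for one rendered punctum."""

    cell_id: int
    punctum_index: int
    angle_deg: float
    x: float
    y: float


@dataclass
class GroundTruth:
    """Per-cell true puncta angles and reference angles for one field."""

    records: list[PunctumRecord]
    reference_angles: dict[int, float]  # cell_id -> reference direction, deg
    bias_mu: float
    bias_kappa: float
    seed: int

    def angles_for_cell(self, cell_id: int) -> list[float]:
        return [r.angle_deg for r in self.records if r.cell_id == cell_id]

    @property
    def pooled_angles(self) -> np.ndarray:
        return np.asarray([r.angle_deg for r in self.records], dtype=float)

    @property
    def pooled_relative_angles(self) -> np.ndarray:
        return wrap_deg(
            np.asarray(
                [r.angle_deg - self.reference_angles[r.cell_id] for r in self.records],
                dtype=float,
            )
        )


def draw_angles(rng: np.random.Generator, n: int, mu_deg: float, kappa: float) -> np.ndarray:
    """Draw n angles (degrees, wrapped) from von Mises(mu, kappa); kappa=0 is uniform."""
    if n == 0:
        return np.empty(0, dtype=float)
    sample = rng.vonmises(math.radians(mu_deg), kappa, size=n)
    return np.atleast_1d(wrap_deg(np.degrees(sample)))


def generate_label_field(spec: FieldSpec) -> np.ndarray:
    """Tessellate the field into ``n_cells`` convex-ish confluent cells.

    Voronoi regions of jittered-grid seed points (jitter <= 40% of the grid
    pitch), rasterized by nearest-seed assignment; border cells are allowed.
    Labels are contiguous ``1..K`` with no gaps (K can fall below ``n_cells``
    if a seed captures no pixel, which is rare). Deterministic for a fixed
    ``spec.seed``.
    """
    h, w = spec.image_height, spec.image_width
    if h * w < MIN_PIXELS_PER_CELL * spec.n_cells:
        raise ValueError(
            f"image {h}x{w} too small for {spec.n_cells} cells "
            f"(needs >= {MIN_PIXELS_PER_CELL} px per cell)"
        )
    rng = np.random.default_rng(spec.seed)
    if spec.n_cells == 1:
        return np.ones((h, w), dtype=np.int32)

    aspect = w / h
    ncols = max(1, int(round(math.sqrt(spec.n_cells * aspect))))
    nrows = max(1, math.ceil(spec.n_cells / ncols))
    while nrows * ncols < spec.n_cells:
        ncols += 1
    pitch_x, pitch_y = w / ncols, h / nrows
    grid = np.array(
        [((c + 0.5) * pitch_x, (r + 0.5) * pitch_y) for r in range(nrows) for c in range(ncols)]
    )
    keep = rng.choice(len(grid), size=spec.n_cells, replace=False)
    keep.sort()
    seeds = grid[keep]
    jitter = rng.uniform(-0.4, 0.4, size=seeds.shape) * np.array([pitch_x, pitch_y])
    seeds = seeds + jitter
    seeds[:, 0] = np.clip(seeds[:, 0], 0.0, w - 1.0)
    seeds[:, 1] = np.clip(seeds[:, 1], 0.0, h - 1.0)

    yy, xx = np.mgrid[0:h, 0:w]
    pixels = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    _, nearest = cKDTree(seeds).query(pixels)
    labels = nearest.reshape(h, w).astype(np.int32) + 1

    # compress out any label that captured no pixel so ids stay gap-free
    present = np.unique(labels)
    if present.size < spec.n_cells:
        remap = np.zeros(spec.n_cells + 1, dtype=np.int32)
        remap[present] = np.arange(1, present.size + 1)
        labels = remap[labels]
    return labels


def _ray_extent(mask: np.ndarray, cell_id: int, origin: tuple[float, float], angle_deg: float) -> float:
    """Distance from origin to the cell boundary along the given direction.

    Marches in half-pixel steps and returns the last distance whose rounded
    pixel still carries ``cell_id``. Returns 0 when even the origin pixel
    falls outside the cell.
    """
    h, w = mask.shape
    dx = math.cos(math.radians(angle_deg))
    dy = math.sin(math.radians(angle_deg))
    ox, oy = origin
    step = 0.5
    max_steps = int(2 * (h + w))
    last_inside = -1.0
    for i in range(max_steps):
        d = i * step
        px, py = ox + d * dx, oy + d * dy
        r, c = int(round(py)), int(round(px))
        if not (0 <= r < h and 0 <= c < w) or mask[r, c] != cell_id:
            break
        last_inside = d
    return max(last_inside, 0.0)


def _render_spot(image, mask, cell_id, x, y, sigma, amplitude):
    """Add a Gaussian spot at (x, y), clipped to the owning cell's pixels."""
    h, w = image.shape
    rad = int(math.ceil(4 * sigma))
    r0, r1 = max(0, int(round(y)) - rad), min(h, int(round(y)) + rad + 1)
    c0, c1 = max(0, int(round(x)) - rad), min(w, int(round(x)) + rad + 1)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    spot = amplitude * np.exp(-((xx - x) ** 2 + (yy - y) ** 2) / (2 * sigma**2))
    spot[mask[r0:r1, c0:c1] != cell_id] = 0.0
    image[r0:r1, c0:c1] += spot


def generate_puncta_image(
    mask: np.ndarray,
    spec: FieldSpec,
    reference: Optional[ReferenceField] = None,
    rng: Optional[np.random.Generator] = None,
) -> tuple[np.ndarray, GroundTruth]:
    """Render biased puncta onto a label field and record the ground truth.

    Per cell: a Poisson(``mean_puncta_per_cell``) number of puncta; each
    punctum's angle about the cell centroid is von Mises(mu = reference angle
    at that cell, kappa = ``bias_kappa``); its radius is a uniform fraction
    (``radial_fraction_range``) of the centroid-to-boundary distance along
    that angle. Cells too small to host a punctum simply record zero puncta.
    """
    if mask.shape != (spec.image_height, spec.image_width):
        raise ValueError(
            f"mask shape {mask.shape} does not match spec "
            f"({spec.image_height}, {spec.image_width})"
        )
    if reference is None:
        reference = ReferenceField.fixed(spec.bias_mu)
    if rng is None:
        rng = np.random.default_rng(spec.seed)

    labels = np.unique(mask)
    labels = labels[labels > 0]
    image = np.zeros(mask.shape, dtype=float)
    records: list[PunctumRecord] = []
    ref_angles: dict[int, float] = {}
    lo, hi = spec.radial_fraction_range

    if labels.size:
        coms = ndimage.center_of_mass(np.ones_like(mask, dtype=float), mask, labels)
    else:
        coms = []
    for cell_id, (cy, cx) in zip(labels, coms):
        cell_id = int(cell_id)
        mu = reference_angle_at(reference, (cx, cy))
        if not math.isfinite(mu):
            continue
        ref_angles[cell_id] = mu
        n_puncta = int(rng.poisson(spec.mean_puncta_per_cell))
        angles = draw_angles(rng, n_puncta, mu, spec.bias_kappa)
        fracs = rng.uniform(lo, hi, size=n_puncta)
        idx = 0
        for ang, frac in zip(angles, fracs):
            extent = _ray_extent(mask, cell_id, (cx, cy), ang)
            if extent <= 0:
                continue  # cell too small along this direction: no punctum
            r = frac * extent
            px = cx + r * math.cos(math.radians(ang))
            py = cy + r * math.sin(math.radians(ang))
            if mask[int(round(py)), int(round(px))] != cell_id:
                continue
            _render_spot(image, mask, cell_id, px, py, spec.punctum_sigma, spec.punctum_amplitude)
            records.append(PunctumRecord(cell_id, idx, float(ang), float(px), float(py)))
            idx += 1

    image += spec.background_level
    if spec.noise_sigma > 0:
        image += rng.normal(0.0, spec.noise_sigma, size=image.shape)
    np.clip(image, 0.0, None, out=image)
    truth = GroundTruth(
        records=records,
        reference_angles=ref_angles,
        bias_mu=spec.bias_mu,
        bias_kappa=spec.bias_kappa,
        seed=spec.seed,
    )
    return image, truth


def generate_field(
    spec: FieldSpec, reference: Optional[ReferenceField] = None
) -> tuple[np.ndarray, np.ndarray, GroundTruth]:
    """Label mask, intensity image and ground truth for one field."""
    mask = generate_label_field(spec)
    image, truth = generate_puncta_image(mask, spec, reference)
    return image, mask, truth


def generate_dataset(
    spec: FieldSpec,
    reference: Optional[ReferenceField] = None,
    n_fields: int = 1,
) -> list[tuple[np.ndarray, np.ndarray, GroundTruth]]:
    """n_fields independent fields with per-field seeds seed, seed+1, ...

    Each entry is ``(image, mask, truth)`` and is exactly what a single
    ``generate_field`` call with the derived seed produces, so datasets are
    reproducible piecemeal.
    """
    if n_fields < 1:
        raise ValueError("n_fields must be >= 1")
    out = []
    for i in range(n_fields):
        out.append(generate_field(spec.replace(seed=spec.seed + i), reference))
    return out
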