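"""Rose-plot histograms and the chi-square uniformity test.

Relative polarity angles are binned into sectors of 360/n_bins degrees with
the first bin centered on the reference direction (0 deg). Uniformity of the
angular distribution is tested with Pearson's chi-square against equal
expected counts per bin; the test runs on unweighted per-cell counts (one
cell = one observation) for distributional validity, while size/intensity
weighting affects only the rendered wedge radii.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "AngularHistogram",
    "UniformityTest",
    "bin_angles",
    "chi_square_uniformity",
    "render_rose_plot",
]


@dataclass
class AngularHistogram:
    """Binned angular distribution: the rose plot's data."""

    n_bins: int
    bin_edges_deg: np.ndarray  # n_bins + 1 ascending edges spanning 360 deg
    weights: np.ndarray  # n_bins nonnegative reals
    counts: np.ndarray  # n_bins nonnegative ints
    total_cells: int

    @property
    def bin_centers_deg(self) -> np.ndarray:
        return (self.bin_edges_deg[:-1] + self.bin_edges_deg[1:]) / 2.0


@dataclass
class UniformityTest:
    """Chi-square goodness-of-fit of angular counts against uniformity."""

    statistic: float
    df: int
    p_value: float
    expected_per_bin: float
    low_expected_warning: bool
    defined: bool = True


def bin_angles(relative_angles_deg, weights=None, n_bins: int = 8) -> AngularHistogram:
    """Accumulate angles into circular bins, first bin centered on 0 deg.

    Bins are left-closed, right-open, width 360/n_bins, with edges at
    +-180/n_bins around zero; the wrap seam closes the circle so every angle
    in (-180, 180] lands in exactly one bin. Empty input yields an all-zero
    histogram.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    angles = np.asarray(relative_angles_deg, dtype=float)
    if weights is None:
        w = np.ones_like(angles)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != angles.shape:
            raise ValueError("weights must match angles in shape")
    width = 360.0 / n_bins
    half = width / 2.0
    edges = -half + width * np.arange(n_bins + 1)
    counts = np.zeros(n_bins, dtype=int)
    mass = np.zeros(n_bins, dtype=float)
    if angles.size:
        shifted = (angles + half) % 360.0
        idx = np.floor(shifted / width).astype(int) % n_bins
        np.add.at(counts, idx, 1)
        np.add.at(mass, idx, w)
    return AngularHistogram(
        n_bins=n_bins,
        bin_edges_deg=edges,
        weights=mass,
        counts=counts,
        total_cells=int(angles.size),
    )


def chi_square_uniformity(histogram: AngularHistogram) -> UniformityTest:
    """Pearson chi-square of observed bin counts against equal expectation.

    statistic = sum_b (O_b - E)^2 / E with E = total/n_bins; df = n_bins - 1;
    p from the upper tail. ``low_expected_warning`` flags E < 5, where the
    chi-square approximation degrades. Zero cells yield an undefined test.
    """
    n = histogram.total_cells
    k = histogram.n_bins
    if n == 0:
        return UniformityTest(
            statistic=math.nan,
            df=k - 1,
            p_value=math.nan,
            expected_per_bin=0.0,
            low_expected_warning=True,
            defined=False,
        )
    expected = n / k
    stat = float(((histogram.counts - expected) ** 2 / expected).sum())
    df = k - 1
    p = float(stats.chi2.sf(stat, df))
    return UniformityTest(
        statistic=stat,
        df=df,
        p_value=p,
        expected_per_bin=expected,
        low_expected_warning=expected < 5,
    )


def render_rose_plot(
    histogram: AngularHistogram,
    test: UniformityTest | None = None,
    path=None,
    ax=None,
    weighted: bool = True,
    sqrt_radius: bool = False,
    title: str | None = None,
):
    """Polar wedge plot of the angular distribution.

    0 deg sits at the right, pointing toward the reference; the display
    negates y (counterclockwise positive) so plots read in the conventional
    mathematical orientation. Wedge radius is proportional to bin weight (or
    its square root with ``sqrt_radius``). Saved files carry no timestamps,
    so identical inputs produce identical files.
    """
    import matplotlib

    if path is not None and ax is None:
        matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    created = False
    if ax is None:
        fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(4, 4))
        created = True
    else:
        fig = ax.figure

    radii = histogram.weights if weighted else histogram.counts.astype(float)
    if sqrt_radius:
        radii = np.sqrt(radii)
    # negate angles for display only: image y points down, screen y points up
    theta = np.radians(-histogram.bin_centers_deg)
    width = 2 * np.pi / histogram.n_bins
    ax.bar(theta, radii, width=width, bottom=0.0, align="center",
           edgecolor="black", linewidth=0.5, alpha=0.75)
    ax.set_theta_zero_location("E")
    ax.set_theta_direction(1)
    annotation = f"n = {histogram.total_cells}"
    if test is not None and test.defined:
        annotation += f"\np = {test.p_value:.3g}"
    ax.set_title(title or "", fontsize=10)
    ax.text(0.02, 0.02, annotation, transform=ax.transAxes, fontsize=9, va="bottom")
    if path is not None:
        path = str(path)
        metadata = {"Date": None} if path.endswith(".svg") else {"Software": "punctapolarity"}
        try:
            with matplotlib.rc_context({"svg.hashsalt": "punctapolarity"}):
                fig.savefig(path, dpi=150, metadata=metadata)
        except (OSError, PermissionError) as exc:
            raise OSError(f"cannot write rose plot to {path}: {exc}") from exc
        finally:
            if created:
                plt.close(fig)
    return ax
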