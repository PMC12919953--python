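# Methods

## The quantification model

The pipeline estimates, per segmented cell, a planar polarity vector from
the spatial arrangement of fluorescent puncta, and summarizes a population
of cells by the distribution of polarity angles relative to a reference
force direction.

**Detection.** The raw channel I is transformed to log(1 + I) and linearly
rescaled so the 1st/99.9th percentiles of the transformed values map to 0/1
(values outside are clipped). The log compresses the heavy-tailed intensity
distribution of punctate staining; the percentile clip makes the rescaling
robust to isolated hot pixels. A single global threshold — Otsu's
between-class-variance maximizer over a 256-level histogram by default, or a
configurable quantile — produces a binary mask; thresholding is global, not
per-cell, so dim and bright cells are treated identically (a per-cell
threshold would inflate puncta counts in dim cells). Connected components
(8-connectivity by default, since puncta are blobs and diagonal contact
should not split them) become clusters, filtered to an inclusive pixel-area
band of [4, 400] px — excluding single-pixel noise below and junction-scale
smears above. Each cluster is assigned to the cell label holding the
plurality of its pixels, ties toward the smaller label; clusters whose
plurality is background are dropped and counted.

**Polarity.** With g the unweighted centroid of a cell's pixels and cᵢ the
cluster centroids, the polarity vector is the weighted mean of the *unit*
vectors (cᵢ − g)/‖cᵢ − g‖ — cluster distance from the centroid carries no
weight, only cluster size (default) or integrated intensity does. The
magnitude is therefore in [0, 1]. Cells with no clusters, zero total weight,
or magnitude below 1e-6 are marked undefined rather than being assigned a
noise angle. Integrated intensity for weighting is measured on the
normalized image (the domain the threshold sees); per-cell mean intensity
exported for group comparisons is measured on the raw image so it remains
acquisition-scaled.

**Reference and pooling.** The reference direction is either one fixed
angle per field (tissue-axis geometries such as a midline) or the per-cell
direction toward a target point (wound geometries); the relative angle is
polarity minus reference wrapped to (−180°, 180°], so 0° means "toward the
reference". Cells touching the image border are included by default
(wound-margin cells are precisely border-adjacent in crops); exclusion is
configurable. Defined cells are pooled across fields; by default each cell
contributes weight 1 to the rose histogram so fields with more puncta do not
dominate, with an option to weight cells by their total cluster mass.

**Statistics.** Relative angles fall into n_bins = 8 sectors of 45°, the
first centered on 0°; bins are left-closed/right-open with the wrap seam
closing the circle. Eight bins keep the expected count per bin ≥ 5 for
population sizes of roughly 60–300 cells. The chi-square uniformity test
runs on *unweighted* per-cell counts (one cell, one observation) for
distributional validity — weighting affects only the rendered wedges;
statistic Σ(O−E)²/E, df = n_bins − 1, upper-tail p from the chi-square
distribution, with a warning flag when E < 5. The mean resultant length R
and mean direction are reported as descriptive statistics. No
multiple-testing correction is applied across fields or conditions; every
p-value is recorded per analysis.

## Synthetic data

The generator emulates a confluent epithelium: Voronoi regions of
jittered-grid seed points (jitter ≤ 40% of the grid pitch) rasterized by
nearest-seed assignment give convex-ish, confluent, border-touching cells;
generation fails explicitly below ~25 px per cell. Puncta counts per cell
are Poisson (default mean 6); each punctum's angle about the cell centroid
is von Mises with mean equal to the local reference direction and
concentration κ (κ = 0 uniform), its radius a uniform fraction (default
0.2–0.8) of the centroid-to-boundary distance along that angle. Puncta are
isotropic Gaussian spots (default σ = 1.5 px, amplitude 1000) clipped to the
owning cell — keeping cluster-to-cell assignment unambiguous in ground truth
— over a constant background (100) with additive Gaussian noise (σ = 20).
Defaults for spot count and size are chosen for test convenience at desk
scale, not measured biology. All draws flow from a single seeded generator;
multi-field datasets derive per-field seeds arithmetically (seed, seed+1,
…) so they are reproducible piecemeal.

What the generator does **not** emulate: optical blur of the whole field,
Poisson shot noise (additive Gaussian only — it does not change what the
pipeline must demonstrate), uneven illumination, junctional background
staining, cell-size heterogeneity beyond grid jitter, segmentation errors,
or mechanically emergent polarity (bias is imposed statistically). Passing
tests therefore show the pipeline recovers known polarity from spot-like
signal under realistic counting noise — not that detection is robust to
every artifact of real microscopy.

## Numerical choices

- Angles: degrees, image coordinates (y down), atan2 convention, wrapped to
  (−180°, 180°]; rose plots negate y for display only.
- Histogram bin assignment: floor((angle + half-width)/width) mod n_bins;
  an angle exactly on an interior edge goes to the higher bin.
- Otsu: 256 equal bins on [0, 1]; threshold is the upper edge of the last
  background bin; ties break toward the lowest threshold; a constant image
  yields an empty mask.
- Quantile thresholding uses linear-interpolation quantiles; foreground is
  strictly above the threshold.
- Cluster and cell centroids are unweighted pixel-coordinate means;
  subpixel.
- Degenerate inputs: empty masks yield empty tables; a cluster centroid
  coinciding with the cell centroid is skipped; a target point coinciding
  with a cell centroid excludes that cell; zero pooled cells yield an
  undefined test, reported as such.
- Rose plots are saved without timestamps (and with a fixed SVG hash salt),
  so identical inputs produce byte-identical files.

## Statistical calibration

Type-I error and power of the binned test are estimated on generator ground
truth: replicates draw per-cell puncta angles from the angular model
(Poisson counts, von Mises angles) and compute each cell's polarity angle as
the direction of the mean unit vector — the same estimator the image
pipeline applies to detected clusters — skipping rasterization so hundreds
of replicates run in seconds. At κ = 0 with 200 cells the rejection rate at
α = 0.05 sits within the binomial band around the nominal level over 500
replicates; at κ = 1.5 with 150 cells power at α = 0.001 exceeds 95%.

Problem sizes used throughout the validation suite (256×256 px fields,
25–200 cells, ~6 puncta/cell, 1–3 fields per analysis) were chosen as the
smallest sizes at which the statistical properties above are measurable;
they mirror the cell counts typical of confocal fields of embryonic
epithelium (tens to a few hundred cells per field, a few fields pooled per
condition).

## Design notes and limitations

- Translation invariance of the geometry holds exactly only when the
  threshold is invariant: global Otsu and percentile normalization are
  functions of the whole histogram, so padding a field with background
  pixels can move the threshold by a histogram bin and relabel fringe
  pixels. The invariance test therefore uses full-range normalization and a
  quantile threshold inside the constant background plateau of a noise-free
  field, where the threshold is provably unchanged by padding. Rotation by
  90° permutes pixels without changing the histogram, so equivariance holds
  under the default configuration.
- "Well-separated" puncta means no neighbor within 4σ (6 px at the default
  σ = 1.5): closer spots can merge into one connected component under any
  threshold-based detector, which is a property of the method, not a
  defect. Noise-free detection fidelity is asserted for separated puncta.
- Polarity is vectorial; nematic (180°-periodic) order is out of scope.
- Segmentation is consumed, never produced; masks with label gaps are
  reported but not repaired.
- The pipeline is unit-agnostic (pixels and camera units only); no physical
  pixel size or bit depth is assumed.
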