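# punctapolarity

Quantification of planar cell polarity (PCP) from fluorescent protein
puncta in epithelial tissue.

Many cortical and junctional proteins concentrate in discrete bright spots
("puncta") whose placement around each cell reports the cell's planar
polarity — toward a wound edge, toward the dorsal midline of a neural plate,
or toward apically constricting neighbors. Given a single-channel
fluorescence image and a matching cell segmentation (Cellpose-style label
mask, 0 = background), this package:

1. log-transforms and percentile-normalizes the protein channel, thresholds
   it (Otsu by default) into a binary mask, and extracts size-filtered
   connected components as puncta clusters assigned to cells;
2. computes, for each cell with centroid **g** and cluster centroids
   **c**ᵢ, the polarity vector

   **p** = Σᵢ wᵢ (**c**ᵢ − **g**)/‖**c**ᵢ − **g**‖ / Σᵢ wᵢ,

   a convex combination of unit vectors (‖**p**‖ ≤ 1) weighted by cluster
   area or integrated intensity;
3. expresses each polarity angle relative to a reference force direction —
   one fixed angle per field, or the per-cell direction toward a target
   point such as a wound site — so 0° always means "toward the reference";
4. pools defined cells across fields (embryos), bins the relative angles
   into a circular (rose-plot) histogram with the first bin centered on the
   reference, and tests angular uniformity with Pearson's chi-square
   statistic, χ² = Σ_b (O_b − E)²/E with E = n/n_bins and df = n_bins − 1.

A synthetic-epithelium generator (Voronoi cells on a jittered grid, von
Mises-biased Gaussian puncta over noisy background, full ground truth) makes
every stage testable without microscopy data.

Audience: cell and developmental biologists quantifying puncta-based planar
polarity downstream of a Cellpose segmentation, and anyone needing a
ground-truthed simulator for validating such pipelines.

## Worked example

```python
from punctapolarity import (FieldSpec, PunctaPolarityModel, ReferenceField,
                            generate_dataset)

# two simulated fields, 100 cells each, puncta biased toward 0 deg (kappa=2)
spec = FieldSpec(n_cells=100, bias_kappa=2.0, seed=5)
fields = generate_dataset(spec, ReferenceField.fixed(0.0), n_fields=2)

model = PunctaPolarityModel([(img, mask) for img, mask, _ in fields])
results = model.fit()
print(results.summary())
results.plot_rose("rose.png")
results.save("results/run")      # per-cell CSV + JSON summary + manifest
```

prints

```
Puncta planar-polarity quantification
==============================================
fields:            2
cells total:       200
cells pooled:      199 (defined polarity)
reference mode:    fixed_angle
weight mode:       area
bins:              8 x 45.0 deg
mean resultant R:  0.913 at +0.2 deg
chi-square:        550.789 (df=7), p = 9.55e-115
```

199 of 200 cells had detectable puncta and a well-defined polarity vector.
The mean resultant length R = 0.913 (1 = perfectly aligned, 0 = balanced)
points within a fraction of a degree of the imposed bias direction, and the
chi-square test overwhelmingly rejects angular uniformity — the simulated
polarization is recovered by the full detection pipeline.

The same interface runs on real data from files:

```bash
puncta-polarity analyze \
    --image embryo1.tif --mask embryo1_masks.tif \
    --image embryo2.tif --mask embryo2_masks.tif \
    --reference-mode target_point --reference-point 310,240 \
    --out results/wound --rose results/wound_rose.png
```

`puncta-polarity simulate` writes synthetic fields (images, masks,
ground-truth CSV) and `puncta-polarity calibrate` reports the type-I error
and power of the uniformity test on simulated polarity.

## Conventions

Angles are in degrees in image coordinates (x right, y down),
θ = atan2(dy, dx) wrapped to (−180°, 180°]; rose plots negate y for display
so they read counterclockwise. Pixel centers sit at integer coordinates,
origin top-left. Label masks are never relabeled; gaps in the id sequence
are reported, not repaired. See `docs/methods.md` for the full model
description, parameter defaults, and limitations.
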