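# fluortex

Texture-based screening of oral-cavity autofluorescence images.

Under blue-light excitation, healthy oral mucosa fluoresces brightly while
dysplastic tissue (oral mucosal lesions and potentially malignant disorders)
absorbs the excitation and appears dark.  `fluortex` turns such images into a
grid of 64×64-pixel super-pixels and classifies each one as *standard* or
*anomalous* tissue, producing a region-of-interest map fine-grained enough to
guide a biopsy.  It is aimed at researchers building computer-aided screening
tools for direct-fluorescence visualization devices (e.g. VELscope), whose
circular aperture often intrudes into the captured frame and must be removed
before analysis.

## Pipeline

1. **Grayscale conversion** (Rec. 601 luma) of the input RGB frame.
2. **Device removal** — Deriche–Canny edge detection (recursive IIR gradient
   filters, non-maximum suppression, hysteresis) followed by a circular Hough
   transform.  If a circle covering ≥ 35 % of a candidate circumference is
   found, the frame is cropped to the aperture and the exterior blanked;
   otherwise it passes through unchanged.
3. **Quadtree super-pixelization** — fixed-depth subdivision into 64×64
   windows (a 1792×1792 frame yields a 28×28 grid).  A window is labeled
   anomalous only when *every* pixel lies inside the clinician-delineated
   lesion mask, so flagged windows are safe biopsy targets.
4. **Texture features** — a 256×256 gray-level co-occurrence matrix (GLCM)
   per super-pixel at the 0° distance-1 offset, without requantization, and
   ten Haralick statistics: angular second moment, contrast, correlation,
   variance, inverse difference moment, sum average, sum variance, sum
   entropy, entropy and difference variance.
5. **Feature ranking** — each feature *f* is scored by the Fisher separation

   Δ² = (μ₁ − μ₂)² / C,  C = (n₁C₁ + n₂C₂)/(n₁ + n₂),

   between the two classes (pooled population covariance); classification
   uses the top-8 ranked features by default.
6. **Classification and evaluation** — 1-nearest-neighbor on z-scored
   features, grouped five-fold cross-validation (train on the other images
   of the test image's group), and the screening metrics
   sensitivity = TP/(TP+FN), specificity = TN/(TN+FP),
   accuracy = (TP+TN)/(TP+TN+FP+FN).

Because no public clinical dataset exists for this modality, the package
ships a seeded synthetic-scene generator (`fluortex.synth`) that emulates the
two statistics the GLCM responds to — bright smooth background, darker
rougher lesions — plus an optional device aperture, with exact ground truth.

## Worked example

```python
import tempfile
from fluortex import (PipelineConfig, generate_benchmark, extract_manifest_features,
                      rank_features, select_top, grouped_cv)

with tempfile.TemporaryDirectory() as tmp:
    manifest = generate_benchmark(tmp, n_images=10, n_groups=2, seed=0, size=256)
    features = extract_manifest_features(manifest, PipelineConfig())

ranking = rank_features(features)
print(ranking.to_frame().to_string(index=False))
report = grouped_cv(features, select_top(ranking, 8), k=1)
print(report.summary().split("\n\n")[-1])
```

prints

```
 rank             feature      score
    1         sum_average 122.758937
    2        sum_variance 107.203224
    3         correlation  76.164388
    4                 idm  58.286164
    5             entropy  36.379853
    6                 asm  10.317827
    7         sum_entropy   4.323889
    8            contrast   2.560786
    9            variance   0.131082
   10 difference_variance   0.028313

 sensitivity: 100.0 +/- 0.0 %
 specificity: 100.0 +/- 0.0 %
    accuracy: 100.0 +/- 0.0 %
```

The ranking table is the per-feature class separation Δ² (larger = less
overlap between standard and anomalous super-pixels); on these synthetic
scenes the intensity-linked features (sum average ≈ twice the window mean)
dominate, and the grouped five-fold evaluation classifies all 160
super-pixels correctly.  On clinical images the separation is far smaller
and fold-to-fold spread correspondingly larger.

The same workflow is scriptable from a shell:

```sh
fluortex synth bench --n-images 10 --n-groups 2 --size 256 --seed 0
fluortex train bench/manifest.csv --out-dir training
fluortex test bench/scene_00.png bench/scene_00_mask.png \
    --train-features training/features.csv
```

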