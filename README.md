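# histosample

Gradient-guided quasi-Monte-Carlo adaptive tile sampling for whole-slide
histopathology image analysis.

## The problem

Whole-slide images (WSIs) are gigapixel scans of stained tissue. A tile
classifier — a model that scores a small square patch (here 101 × 101 px)
for the presence of invasive carcinoma — cannot be applied at every pixel
position of a slide: even a 32:1-downsampled slide has millions of valid
tile positions, and dense classification takes hours. `histosample`
implements the alternative: classify only a few thousand adaptively chosen
tiles and interpolate a full-resolution probability map from them.

The sampling loop alternates exploration and exploitation. With a budget of
*T* iterations × *N* tiles:

1. iteration 1 classifies *N* tile centres drawn from a low-discrepancy
   (Sobol or Halton) sequence or uniformly at random;
2. each later iteration interpolates a probability map *P* from **all**
   samples classified so far (piecewise-cubic Clough–Tocher interpolation),
   computes the gradient magnitude
   |∇P| = √((∂P/∂x)² + (∂P/∂y)²),
   draws 2*N* fresh candidates from the base sampler and classifies the *N*
   with the largest |∇P| — concentrating effort on tumour/benign boundaries,
   where the map is most uncertain.

Classified centres are cached and never re-scored, so the loop performs
exactly *T·N* classifier calls. Thresholding the final map yields a binary
invasive-region prediction, scored against ground truth by the Dice
coefficient 2|P∩G| / (|P|+|G|) and the usual confusion-derived rates (PPV,
NPV, TPR, TNR, FPR, FNR).

The tile classifier is pluggable. Shipped implementations:

* a **ground-truth oracle** for synthetic slides (probability = masked
  fraction of the tile footprint, optionally label-noise-contaminated) —
  the test double that lets sampling strategies be compared in isolation;
* **hand-crafted features + softmax**: colour/intensity first-order
  statistics (CF, 14 channels × 4 statistics = 56-d) or per-channel colour
  histograms (CH, 8 bins × 3 = 24-d) feeding a two-class softmax model with
  L2 weight decay trained by minibatch SGD.

Because real cohorts are access-restricted, the package includes a
synthetic-slide generator: H&E-like images with near-white glass
background, pink benign-tissue texture and purple, irregularly shaped
"invasive" blobs whose union is the ground-truth mask.

## Worked example

```python
import numpy as np
from histosample import (
    SyntheticSlideSpec, generate_slide, make_noisy_oracle,
    AdaptiveConfig, SamplerConfig, run_adaptive, run_dense,
    threshold_map, confusion_report,
)

spec = SyntheticSlideSpec(height=1024, width=1024, seed=0)
slide = generate_slide(spec)                      # H&E-like image + mask
oracle = make_noisy_oracle(slide, label_noise=0.1, flip_seed=7)

config = AdaptiveConfig(
    t_iterations=20, n_per_iter=100,
    sampler=SamplerConfig(kind="grad_qmc_halton"), seed=1,
)
result = run_adaptive(slide, oracle, config)
report = confusion_report(threshold_map(result.final_map, 0.5), slide.mask)
print(f"samples classified: {len(result.samples)}")
print(f"Dice at t=0.5:      {report.dice:.3f}")
print(f"TPR / TNR:          {report.tpr:.3f} / {report.tnr:.3f}")

dense = run_dense(slide, oracle, tile_size_k=101)
dense_dice = confusion_report(threshold_map(dense, 0.5), slide.mask).dice
print(f"dense Dice (~850k tiles): {dense_dice:.3f}")
```

prints

```
samples classified: 2000
Dice at t=0.5:      0.753
TPR / TNR:          0.860 / 0.924
dense Dice (~850k tiles): 0.701
```

Reading: 2000 adaptively placed tiles (0.2 % of the ~850 000 dense
positions) recover the invasive region with Dice 0.75 against a tile oracle
whose labels are 10 % noise-contaminated. Dense per-tile classification
under the same noisy oracle actually scores *lower* (0.70) because
interpolation from scattered samples smooths classification noise; with a
noiseless oracle, dense sampling is the ceiling (Dice ≈ 0.96) and the
adaptive run matches it.

The same pipeline is scriptable from the shell:

```sh
histosample synth --seed 7 --out slide/
histosample build-tiles --image slide/slide.png --mask slide/mask.png --out tiles/
histosample train --tiles tiles/ --features CF --out model.json
histosample predict --image slide/slide.png --model model.json \
    --sampler grad_qmc_halton --iters 20 --per-iter 100 --seed 7 --out mapdir/
histosample evaluate --map mapdir/map.tif --mask slide/mask.png --out report.json
```

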