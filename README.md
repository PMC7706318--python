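# paddycount

Rice plant density estimation from dot-annotated field images by
**blockwise classification counting**.

Counting transplanted rice from nadir field photographs is a
count-supervision problem: each plant is annotated with a single dot at its
root, and the goal is a per-image total. The standard pipeline regresses a
Gaussian-smoothed density map or local patch counts, but patch counts in
paddy imagery are severely imbalanced — most 32×32 patches are empty or
nearly empty, a few are dense. `paddycount` instead quantizes patch counts
into log-spaced intervals and trains a fully convolutional classifier to
predict the interval of every (overlapping) patch:

- **Encode** — dots → density map `D` (per-dot unit-mass Gaussian, σ = 4) →
  patch counts `N(b_j) = Σ_{k∈b_j} D_k` on a 32-px block / 8-px stride grid
  → classes `C(N) = max(⌊(ln N − q)/s⌋ + 2, 1)` with `C(0) = 0`
  (defaults s = 0.1, q = −2).
- **Model** — a staged backbone tapped at strides 8/16/32, a top-down
  fusion decoder that weights deep semantics 2:1 over shallow detail, and a
  redundant head (4×4 unpadded average pooling + 1×1 convolution + softmax)
  scoring one class per 32×32 patch at stride 8.
- **Decode** — argmax class → interval-midpoint count
  `(Nt(C) + Nt(C+1))/2`, `Nt(C) = e^{q+(C−2)s}` → spread each patch count
  over its pixels and average overlaps by coverage (`deredundancy`) → the
  image total is the sum of the pixel count map.

Everything runs on CPU: the network stack is a small numpy autodiff engine
(`paddycount.nnkit`), a `tiny` backbone trains in minutes, and a seeded
synthetic paddy-scene generator stands in for field data so the whole
pipeline is testable end to end. See `docs/methods.md` for the model
details and design choices.

## Worked example

```python
import numpy as np
from paddycount import render_scene, SceneSpec
from paddycount.codec import (QuantizerSpec, rasterize_dots, density_from_dots,
    count_map_from_density, class_map_from_count_map, dequantize_class_map,
    deredundancy)

scene = render_scene(SceneSpec(size=(256, 256), n_plants=50, seed=13))
dots = rasterize_dots(scene.annotation, scene.image.shape[:2])
density = density_from_dots(dots)                        # sigma = 4
counts = count_map_from_density(density, block=32, stride=8)
quant = QuantizerSpec.for_max_count(counts.values.max()) # s = 0.1, q = -2
classes = class_map_from_count_map(counts, quant)
decoded = deredundancy(dequantize_class_map(classes))

print(f"dots: {len(scene.annotation)}")
print(f"density mass: {density.sum():.6f}")
print(f"patch grid: {counts.values.shape}, c_max = {quant.c_max}")
print(f"decoded total: {decoded.total():.2f}")
```

prints

```
dots: 50
density mass: 50.000000
patch grid: (29, 29), c_max = 34
decoded total: 50.61
```

The density map carries exactly one unit of mass per plant; the 256² scene
yields a 29×29 grid of overlapping patches ((256 − 32)/8 + 1 per side); and
round-tripping the *ground-truth* classes through midpoint dequantization
and deredundancy recovers the 50 plants to 1.2% — within the analytic
roundtrip bound (e^s − 1)/2 ≈ 5.3%.

Training and evaluation run the same way from the shell:

```sh
paddycount synth --n 64 --seed 0 --out data/
paddycount train --data data/ --seed 0 --out run/     # YAML-configurable
paddycount infer --model run/last.ckpt --images data/ --out preds.csv
paddycount eval  --model run/last.ckpt --data data/ --out report.json
```

`paddycount.benchmark.run_study(seed=0)` packages the desk-scale experiment
used by the test suite: 64 training / 16 held-out synthetic scenes (256²,
10–60 plants), the tiny backbone trained 30 epochs in classification mode
and in the local-count regression ablation. At seed 0 the classifier counts
held-out scenes to MAE 1.57 (rMAE 6.1%, R² 0.97) and beats the identically
trained regression ablation (MAE 2.82, rMAE 12.2%).

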