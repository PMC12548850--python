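# fruitfusion

Multimodal RGB-D fusion pipeline for fruit detection in orchard imagery.

Detecting apples (and similar red fruit) from color images alone degrades
under changing illumination and foliage clutter.  This package implements
a fusion pipeline for RGB-D captures that enriches the detector's input
instead of its architecture:

1. **Point-cloud cleaning** — multi-frame accumulated clouds are voxel
   downsampled (first point per cell) and filtered by statistical outlier
   removal: a point is dropped when its mean distance `d_i` to its k = 30
   nearest neighbors exceeds `mean(d) + 2·std(d)`.
2. **3D→2D alignment** — a pinhole chain maps cloud points to corrected
   pixels: `u = x·fx/z + cx`, `v = y·fy/z + cy`, mirror flip
   `u' = mw − 1 − u`, then calibration offsets
   `(uo, vo) = (u' + xoffset, v + yoffset)`.
3. **Key-feature extraction** — the R−G chroma difference (red-fruit
   excess, negatives clipped) and the Laplacian edge magnitude are each
   min-max normalized and fused 6:4 into a key-feature band
   `F = 0.6·chroma + 0.4·edge`.
4. **8-channel composition** — bands `[R, G, B, F, D, X, Y, Z]`: color,
   key feature, decoded Z16 depth (millimeters → meters, 4 m range), and
   per-pixel cloud coordinates (nearest-depth-wins, zero-filled).
5. **Anchor optimization** — anchor adequacy via the size-ratio metric
   `r = max(w/wa, wa/w, h/ha, ha/h)` (AAT / Best Possible Recall gate),
   k-means re-estimation on label dimensions, and elitist genetic
   refinement with a threshold-gated `1/r` fitness.
6. **Multi-channel detector** — a compact anchor-based single-stage
   network (NumPy, explicit backprop) whose 6×6×m×32 input layer accepts
   m = 3…8 channels, trained with SGD (batch 4, lr 0.01 with linear 0.01
   decay, momentum 0.937 / 0.8 warm-up) and evaluated with
   P = TP/(TP+FP), R = TP/(TP+FN), F1 = 2PR/(P+R).

Because no orchard dataset ships with the package, a synthetic-scene
module renders pinhole-consistent stand-ins (red spheres over green/brown
clutter, per-scene illumination gain, partial occlusion; labels omitted
for fruit more than 80% obscured) so every stage — and the channel
comparison experiment — is exercisable end to end.

## Worked example

```python
import numpy as np
from fruitfusion import (SceneParams, generate_scene, PipelineConfig,
                         run_preprocess, inject_cloud_noise,
                         remove_outliers, f1)

scene = generate_scene(SceneParams(seed=7))      # rgb, depth, cloud, labels
print("labels:", len(scene.labels))

noisy, truth = inject_cloud_noise(scene.cloud, n_outliers=50,
                                  displacement=1.0, seed=7)
cleaned, removed = remove_outliers(noisy)
print(f"injected 50 outliers, filter removed {len(removed)}, "
      f"{len(set(removed) & set(truth))} of them true outliers")

img = run_preprocess(scene, PipelineConfig())    # the 8-band container
print("container bands:", img.bands.shape,
      "| zero-filled XYZ px:", img.meta["xyz_pixels_zero"])
print(f"F1 at P=95.8, R=96.0: {f1(95.8, 96.0):.2f}")
```

prints

```
labels: 6
injected 50 outliers, filter removed 51, 47 of them true outliers
container bands: (120, 212, 8) | zero-filled XYZ px: 852
F1 at P=95.8, R=96.0: 95.90
```

The scene has six labeled fruits; the 30-neighbor 2-sigma filter removes
47 of the 50 injected far points (plus 4 genuine stragglers of the noisy
cloud); preprocessing composes the 120×212×8 container with 852 of 25 440
XYZ pixels zero-filled; and the harmonic mean of 95.8% precision and
96.0% recall is an F1 of 95.90%.

## Command line

One verb per stage (see `fruitfusion --help`):

```sh
fruitfusion synth --n 200 --seed 0 --out data/           # synthetic dataset
fruitfusion pc-clean --in raw.ply --voxel 0.005 --k 30 --sigma 2.0 --out clean.ply
fruitfusion features --in img.png --out-key key.png
fruitfusion fuse --rgb a.png --depth a_d.png --cloud a.ply --out a.mcc
fruitfusion verify-align --cloud scene.ply --boxes labels.txt --out marked.ply
fruitfusion anchors --labels data/labels --img-size 212x120 --out anchors.yaml
fruitfusion train --data data/ --epochs 15 --out weights.npz
fruitfusion eval --weights weights.npz --data data/ --split test --iou 0.5
fruitfusion experiment --n-scenes 200 --channels RGB,XYZ,D,F --out rows.json
```

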