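# metacam

Consensus ensembles of class activation maps, with ROAD-based adaptive
thresholding, systematic CAM-group ablation grids, and the Cumulative
Residual Effect summary statistic.

## The problem

Class activation maps (CAMs) explain a CNN's prediction as a heat-map over
image pixels — typically a weighted sum of the feature maps `A_k` at a
chosen convolutional layer:

    L_c = ReLU( Σ_k α_k^c · A_k )

Dozens of weighting schemes exist (GradCAM, GradCAM++, XGradCAM, HiResCAM,
LayerCAM, ScoreCAM, AblationCAM, EigenCAM, FullGrad, ...), and which one is
"right" depends on the image, the target class, and the model.  For
practitioners in high-stakes imaging domains — medical imagery, biometric
identification — that instability is a real obstacle: a single method can
confidently highlight the wrong subject.

This package implements a consensus ensemble: the component maps are
normalized to [0, 1], summed pixelwise, and thresholded to the **top-k% of
pixels in agreement** — a pixel survives only if the components jointly
rank it highly:

    M_ij = Σ_n L_n,ij   if Σ_n L_n,ij ≥ t    else 0

where `t` is the (100−k)-th percentile of the summed map.  A component that
highlights the wrong region is simply outvoted; even a *random* map can
help, by forcing the threshold to keep only the highest-consensus pixels.

Faithfulness is measured with ROAD (Remove-and-Debias): the most / least
relevant p% of pixels are replaced by noisy linear imputation (each masked
pixel tied to the weighted average of its 8-neighborhood: 1/6 edge, 1/12
corner) and the model's confidence gap is averaged over p ∈ {20, 40, 60, 80}:

    ROAD = mean_p ( C_LRP(p) − C_MRP(p) ) / 2   ∈ [−0.5, 0.5]

Because the best k is instance-specific, an adaptive search scores the
consensus at every k on a grid and returns the argmax — and the same
search applied to a single CAM refines that individual method.

To decide *which* methods belong in the ensemble, the package enumerates
all 2^n inclusion/exclusion patterns of n method groups (64 experiments
for the default six groups), scores each, and attributes performance to
groups through the **Cumulative Residual Effect**: each experiment's
residual from the median score is summed into every group it includes.

## Worked example

```python
import numpy as np
import metacam as mc
from metacam.road import RoadConfig

model, acc = mc.train_tiny_model(seed=0)          # ~15 s on one CPU
print(f"held-out accuracy: {acc:.3f}")

scene = mc.gen_scene(seed=42, with_decoy=True)    # two-subject scene
cls = int(np.argmax(model.logits(scene.image)))

maps = []
for name in ("gradcam", "hirescam", "layercam", "scorecam", "eigencam", "randomcam"):
    r = mc.compute_cam(name, model, scene.image, class_index=cls, seed=0)
    if r.valid:
        maps.append(r.map)

search = mc.adaptive_threshold_search(
    maps, model, scene.image, cls,
    k_grid=(10, 20, 30, 40), road_config=RoadConfig(seed=0),
)
for k, s in sorted(search.scores_by_k.items()):
    print(f"k={k:>3}%  ROAD={s:+.3f}")
print(f"best k: {search.best_k}%")
```

Output:

```
held-out accuracy: 0.990
k= 10%  ROAD=+0.380
k= 20%  ROAD=+0.400
k= 30%  ROAD=+0.399
k= 40%  ROAD=+0.417
best k: 40%
```

Every consensus map here scores strongly positive: perturbing the pixels
the ensemble keeps collapses the model's confidence, while perturbing the
pixels it discards barely moves it.  `search.best_map` is the thresholded
map at the best k, ready to overlay (`metacam.io.save_heatmap_png`).

The same machinery is available from a shell:

```
metacam fixtures train --out model.npz --seed 0
metacam fixtures scenes --out scenes/ --seed 42 --n 1
metacam run --image scenes/scene_000.png --model model.npz \
            --cams gradcam,hirescam,layercam --k auto --seed 0 --out out/
metacam grid --image scenes/scene_000.png --model model.npz --out grid/
metacam cre --grid-csv grid/grid.csv --out cre/
```

Every output directory receives the resolved configuration and seed, so
each reported number is recomputable from the directory contents alone.

## Scope notes

Saliency maps serialize losslessly to `.npy` and lossily to 8-bit PNG
heatmaps (visualization only).  The preprocessing pipeline implements the
standard 256-resize / 224-center-crop / channel-standardization convention
for real photographs; fixture images bypass it.  Object-localization (IoU)
scoring is used only on synthetic fixtures where the ground truth is
planted by construction — on natural images a model may legitimately use
context pixels, so IoU against object masks is not a faithfulness metric,
and ROAD is the arbiter throughout.
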