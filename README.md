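# icgflow

Quantitative blood-flow analysis for indocyanine green video angiography
(ICG-VA), the near-infrared fluorescence imaging used during STA–MCA bypass
surgery for moyamoya disease. As the dye bolus washes in, vessels brighten
in the order the blood reaches them; `icgflow` turns that dark-to-bright
video into quantitative statements a neurosurgeon can act on:

- **Vessel segmentation** — a multi-task U-Net with a shared encoder and two
  decoders that simultaneously segment *all* vessels and the *recipient*
  vessel (the cortical artery receiving the bypass), trained with the joint
  loss `L_total = α·L_all + β·L_receip` (per-head negative log likelihood),
  four-fold flip augmentation and five-view test-time averaging, evaluated
  by Dice and Jaccard.
- **Pre/post registration** — SIFT keypoints (difference-of-Gaussian
  extrema, 128-d descriptors) on the segmented vessel maps, Lowe's ratio
  test at 0.8, RANSAC homography; a registration is accepted when the
  warped and fixed vessel masks overlap in ≥ 35% of the vessel pixels with
  ≥ 10 correspondences.
- **Flow direction** — pyramidal Horn–Schunck optical flow minimizing
  `E = Σ (I_x u + I_y v + I_t)² + λ(u_x² + u_y² + v_x² + v_y²)` with λ = 2,
  a 4-level Gaussian pyramid and an energy-difference stopping rule of 0.1;
  flow vectors projected on the vessel centerline classify each vessel as
  *forward*, *reverse* or *middle-to-both-sides* (the post-bypass pattern
  where dye enters at the anastomosis and runs toward both ends), and
  pre-vs-post verdicts become *changed*/*unchanged*.
- **Perfusion mapping** — ROI time–luminance curves, delay time (time to
  maximum brightness) and per-pixel time-to-peak color maps on a red →
  blue-purple ramp (early-filling red, late-filling blue-purple).
- **Agreement statistics** — Cohen's kappa with the conventional
  interpretation bands, percent agreement, a paired t-test with a normal
  Q–Q pre-check for delay-time differences.
- **Synthetic phantoms** — a first-class generator of ICG-like videos with
  known vessel trees, arrival-time maps, flow directions and pre/post
  geometric transforms, so every stage is testable without clinical data.

## Worked example

```python
import numpy as np
from icgflow.stats import cohen_kappa, percent_agreement
from icgflow.synthetic import (generate_vessel_tree, make_arrival_map,
                               WashInSpec, generate_icg_video)
from icgflow.opticalflow import vessel_flow_direction
from icgflow.perfusion import perfusion_color_map

# agreement between two direction readers, postoperative 3x3 table
post = np.array([[64, 3, 2], [1, 18, 3], [5, 2, 22]])
res = cohen_kappa(post)
print(f"kappa = {res.kappa:.3f} ({res.interpretation}); "
      f"agreement = {100 * percent_agreement(post):.0f}%")

# synthetic post-bypass video: dye enters at the anastomosis
tree = generate_vessel_tree(seed=7, shape=(128, 128), n_branches=3)
spec = WashInSpec(make_arrival_map(tree, "middle_to_both_sides"),
                  direction="middle_to_both_sides", noise_seed=7)
video, truth = generate_icg_video(tree, spec)
label = vessel_flow_direction(video, tree.recipient_mask,
                              centerline=tree.centerline)
print(f"video: {video.n_frames} frames at {video.fps:.0f} fps")
print(f"direction: {label.category} (confidence {label.confidence:.2f})")
pmap = perfusion_color_map(video, tree.mask)
print(f"time-to-peak range on vessels: {pmap.t_lo:.2f}-{pmap.t_hi:.2f} s")
```

prints

```
kappa = 0.768 (substantial); agreement = 87%
video: 145 frames at 25 fps
direction: middle_to_both_sides (confidence 0.83)
time-to-peak range on vessels: 1.96-5.76 s
```

The kappa of 0.768 means the two readers agree substantially beyond chance
on the three-way direction call; the classifier recovers the simulated
middle-to-both-sides pattern with 83% of the flow-vector votes concordant,
and the perfusion map spans the ~4 s the dye front needs to traverse the
tree.

## Command line

```bash
icgflow simulate --seed 1 --shape 128 128 --branches 3 \
    --direction forward --out sim/            # synthetic video + truth
icgflow segment train --images imgs/ --labels-all la/ --labels-receip lr/ \
    --out model.npz
icgflow register --moving pre_mask.png --fixed post_mask.png --out reg/
icgflow flow --video video/ --mask mask.png --out flowdir/
icgflow perfusion --video video/ --mask mask.png --rois rois.json --out perf/
icgflow agree --table table.csv
icgflow ttest --pairs pairs.csv
icgflow run --config run.yaml                 # full pre/post pipeline
```

Videos are read from numbered PNG directories, TIFF stacks, NPY stacks, or
any container imageio can open (frame rate defaults to 25 fps when the
source does not carry one).

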