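# Methods

This note records the models implemented in `icgflow`, the parameter
choices that matter, what the synthetic phantoms do and do not emulate, and
the numerical decisions taken where the design was genuinely open.

## Synthetic ICG phantoms

Clinical ICG-VA is 8-bit grayscale video at 25 frames/s in which a vessel
tree brightens as the dye bolus arrives. The generator reproduces the
features the downstream stages depend on and nothing else.

**Vessel tree.** A main (recipient) vessel spans the frame with a monotone
column coordinate; side branches leave it with monotone row coordinates.
Monotonicity guarantees simple, 8-connected centerlines. Tubes are drawn by
dilating each centerline with a disk (radius 2–3 px for the main vessel,
1–2 px for branches at 128×128), giving the large diameter differences real
cortical vasculature shows.

**Arrival model.** Arrival time is linear in arc-length along the main
centerline: increasing for *forward* flow, decreasing for *reverse*, and
V-shaped around the anastomosis (default: mid-arc) for
*middle-to-both-sides*. Side branches fill outward from their attachment at
the same front speed. Every mask pixel inherits the arrival of its nearest
centerline pixel; where a branch overlaps its parent near the attachment
the earlier candidate time wins, which is the physically correct rule for a
front that reaches a shared pixel twice. Defaults: transit time 4 s over
the main vessel, wash-in starting 0.5 s into the video — a front speed of
roughly 1.2 px/frame at 128×128, comfortably inside the small-displacement
regime optical flow assumes.

**Photometry.** Pixel brightness is
`baseline + (peak − baseline) · ramp((t − arrival) / rise_time)` with
baseline 20, peak 200, rise 1 s, plus clipped additive Gaussian noise
(σ = 2 by default — "moderate" sensor noise for 8-bit video). `ramp` is a
cubic smoothstep rather than a logistic: the logistic never actually
attains its plateau, which would make "time of maximum brightness"
ill-defined at the frame level, while the smoothstep keeps the sigmoidal
shape and makes the true time-to-peak exactly `arrival + rise_time`. That
exactness is what lets perfusion outputs be checked against generator truth
to within one frame.

**Pre/post pairs.** The postoperative acquisition is the preoperative
geometry warped by a stated similarity (rotation ≤ 45°, scale 0.5–2,
translation), emulating microscope repositioning, with independent wash-in
dynamics; the exact 3×3 homography is part of the ground truth.

**What the phantoms do not emulate:** tissue background texture,
microscope auto-dimming, dye recirculation, motion/pulsation, and
photorealistic vessel appearance. Passing tests demonstrate algorithmic
correctness under the modeled physics, not clinical-grade performance.

## Segmentation

The network is a U-Net with one shared encoder and two structurally
identical decoders (all vessels / recipient vessel). Encoder: four levels
of two 3×3 convolutions and 2×2 max pooling, channel widths 16/32/64/128;
a two-convolution bottleneck at width 128; decoders upsample with learned
2×2 up-convolutions, concatenate the matching encoder features, and end in
a 1×1 convolution to two-class logits. Inputs not divisible by 16 are
reflection-padded and cropped back. The whole network is NumPy with
hand-written backpropagation (channels-last layout; convolutions as one
matrix product per kernel tap), verified against finite differences.

The loss is `L_total = α·L_all + β·L_receip` with α = β = 1 by default and
each term the per-pixel mean negative log likelihood of the true label
under the head's softmax. Normalizing per pixel keeps α, β independent of
image and batch size. Training uses Adam, batch 32, and a step learning
rate of 0.01 / 0.001 / 0.0001 from iterations 0 / 20 / 100, for 150
iterations total.

Two additions proved necessary for that short schedule to converge from a
cold start: per-image input standardization (zero mean, unit variance) and
batch normalization after every 3×3 convolution (batch statistics during
training, running averages at inference). Without them the foreground
probability plateaus around 0.4 after 150 iterations and the 0.5-threshold
masks are empty; with them the scaled-down benchmark (40 training images at
64×64, four-fold augmented to 160, 8 held-out) reaches all-vessel Dice
≈ 1.0 and recipient Dice ≈ 0.94. One such run takes about 7 minutes on one
CPU core.

Augmentation is the four-image family {original, horizontal, vertical,
diagonal flip}, with "diagonal" implemented as the transpose; labels are
transformed identically. Test-time averaging uses five views — those four
plus a 180° rotation (the composition of the two axis flips) — each mapped
back to the original orientation before the probabilities are averaged.
All five views are involutions. Binarization threshold: 0.5 on the
averaged probabilities.

The stable frame for segmentation (the dye-saturated frame) is the first
frame whose smoothed mean brightness reaches 99% of the dark-to-plateau
range; the initial dark phase is unchanging too, which is why a
"no-change" rule alone would pick frame 0. A video still rising at its end
yields the last frame with a warning.

## Registration

Registration runs on the segmented vessel maps, Gaussian-blurred with
σ = 2 px so difference-of-Gaussian extrema exist on what is otherwise a
binary image. Keypoints and 128-d descriptors come from scikit-image's
SIFT; descriptors are L2-normalized. Matching keeps a correspondence iff
the nearest-to-second-nearest descriptor distance ratio is strictly below
0.8; a candidate set with fewer than two descriptors yields no matches
(the ratio is undefined without a second neighbour).

The homography is fit by RANSAC (3 px inlier residual, 2000 trials, seeded)
followed by a least-squares refit on the inliers. By default the model is
constrained to a **similarity** (rotation + isotropic zoom + shift),
returned as a 3×3 homography: the dominant viewpoint change between two
acquisitions of the same cortex is exactly that, and an unconstrained
8-parameter projective fit from keypoints concentrated on the vessels is
poorly conditioned away from them — on the synthetic benchmark it misses
the 2 px corner-reprojection target in most pairs, while the similarity
model meets it in 20/20. `model="projective"` lifts the constraint.

Success rule: vessel overlap ≥ 35% **and** ≥ 10 ratio-test
correspondences. Overlap is intersection over the *smaller* of the two
vessel areas, so a zoomed acquisition is not penalized for the area it
does not see; the union-denominator alternative is stricter and was not
used.

## Optical flow and direction

Horn–Schunck flow minimizes the brightness-constancy residual plus a
global smoothness penalty weighted by λ, solved by the classical Jacobi
iteration `u ← ū − I_x(I_x ū + I_y v̄ + I_t)/(λ² + I_x² + I_y²)` from zero
flow, with gradients from the standard 2×2×2 averaging stencils (applied
as correlation — an off-the-shelf convolution mirrors the kernel and flips
the sign of every odd stencil). λ = 2. Iteration stops when the energy,
summed over the domain with intensities in native 8-bit units, decreases
by less than 0.1 between sweeps, with a 200-sweep cap per level. The
calibration matters: on unit-scaled intensities λ² = 4 swamps the squared
image gradients (~10⁻³) and convergence to a 2 px displacement takes
thousands of sweeps, while on the 8-bit scale the same constants recover a
±2 px synthetic shift to ~0.2 px in ~30 sweeps. Inputs already in [0, 1]
are rescaled by 255 so the defaults keep their meaning.

Large motions are handled coarse-to-fine over a 4-level Gaussian pyramid
(smooth with σ = 1, take every second pixel). Flow from a coarser level is
doubled, used to warp the second frame, and refined. The upsampling maps
fine pixel (i, j) to coarse (i/2, j/2) exactly — the cell-centered
alternative shifts the field half a pixel per level, which measurably
biases direction votes.

**Direction classification.** Frame pairs are taken from the middle 50% of
the 10%→90% brightness rise (the early and late phases carry little
directional signal). Each vessel pixel's flow vector is projected on the
local centerline tangent (tangents from a σ = 3 px smoothed centerline).
Two exclusions keep the vote meaningful: flow magnitudes below the 10th
percentile within the mask, and pixels outside the active wash-in front
(per-pair temporal change below 25% of its maximum within the mask) —
saturated or still-dark segments contribute only noise-driven vectors, and
including them dilutes the vote to the point of misclassification. With
`s` the mean sign of the surviving projections: `s > 0.3` → forward,
`s < −0.3` → reverse; otherwise, if the 16-bin arc-length profile of mean
sign (ignoring bins with |mean| ≤ 0.3) crosses zero exactly once from
negative to positive, → middle-to-both-sides; else indeterminate. When no
centerline is supplied it is extracted as the skeleton's longest path,
oriented canonically along its dominant image axis so pre and post runs of
the same vessel agree. On 30 synthetic videos (10 per category, moderate
noise, fixed seeds) the classifier scores 30/30.

## Perfusion

ROI curves are the mean brightness per frame; delay time is the time of
the first frame attaining the maximum of the curve after a centered
5-frame moving average (0.2 s at 25 fps — raw argmax on noisy video is
unstable; ties break to the earliest frame). The perfusion map applies the
same computation pixelwise and maps time-to-peak linearly onto a red →
yellow → green → cyan → blue → purple ramp between the 1st and 99th
percentiles within the mask; background stays black. The commercial LUT
being unknown, the ramp matches the qualitative convention (first-filling
red, last-filling blue-purple), not exact RGB values. Delay times are
measured from the first frame of the recording; `colorbar_lookup` inverts
a rendered color to its relative ramp position (nearest entry, Euclidean
RGB, earliest position on ties).

## Agreement statistics

Cohen's kappa is `(P_o − P_e)/(1 − P_e)` from the k×k contingency table,
with interpretation bands at 0.2/0.4/0.6/0.8
(slight/fair/moderate/substantial/almost perfect). The preoperative
comparison has only two observed categories, so its table is 2×2. A
Fleiss-style asymptotic standard error is reported but not used as a gate
(variance conventions differ between implementations). The paired t-test
and the normal Q–Q summary (Blom plotting positions, straightness
correlation) implement the textbook formulas and are cross-checked against
scipy in the tests. Percent agreement is the diagonal mass. One recorded
discrepancy: the narrative count of consistent preoperative readings (107)
differs by one from the preoperative table's diagonal sum (108); all
computations here use the tables as printed.

## Problem sizes and determinism

Synthetic benchmarks run at 128×128 (flow, direction, perfusion), 256×256
(registration, 20 pairs) and 64×64 (segmentation training, 40+8 images,
150 iterations) — sizes chosen so the whole suite completes in minutes on
one CPU core while leaving every algorithmic property testable. All
randomness flows through explicit integer seeds (generator trees, noise,
RANSAC, training batches); fixed seeds reproduce videos bit-for-bit and
training loss traces exactly.

## Known limitations

- The clinical figures (Dice 0.80/Jaccard 0.73, 81% registration success,
  89/87% software agreement) require the original patient videos and are
  not reproducible here; the synthetic analogues test the machinery, not
  clinical performance.
- Horn–Schunck assumes brightness constancy; global illumination changes
  (e.g., microscope auto-dimming) bias the flow and are not modeled.
- The direction rule assumes one dominant vessel per mask; interleaved
  vessels with opposing flows would need per-branch masks.
- Velocities are in px/frame; no calibration to physical units is
  attempted (direction is the clinical readout).
- Registration assumes a near-planar cortex under similarity-dominated
  viewpoint change; strong perspective or deformation is out of scope.
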