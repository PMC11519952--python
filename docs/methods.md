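# Methods

This note records the models, parameter choices and numerical conventions
behind `thyroscan`, and what the synthetic experiments do and do not show.

## Phantom and imaging model

The phantom is an isotropic voxel grid (default 0.5 mm spacing, 64 × 40 ×
56 mm along superior–inferior / depth / lateral axes) of per-voxel
echogenicity mean, speckle standard deviation, attenuation coefficient
(1/mm), a tissue-class label and a nodule-id label. One thyroid lobe is an
ellipsoid with CT-derived adult morphometry — height 47.6 mm, unilateral
width 14.8 mm, thickness 15.2 mm — flanked by a cartilage tube (dark,
strongly attenuating) and a carotid cross-section (anechoic). Tissue
acoustics (gland 120 gray levels at 22% relative speckle std, muscle 90 at
25%, cartilage 35, carotid 18) were chosen once to give a plausible B-mode
appearance and a gland that is clearly brighter than strap muscle; solid
nodule tissue speckles at 15% relative std, reflecting the homogeneous
texture of real nodules relative to parenchyma.

Imaging is deliberately 2-D and image-level — no RF or wave simulation —
because every downstream algorithm consumes B-mode frames. A frame is one
transverse slice under the probe footprint (40 mm linear array):

```
I = clip(echo · T(depth) · C_force · C_tilt · S, 0, 255)   quantized round-half-up
```

with `T` the two-way exponential depth attenuation, `C_force = min(f/2 N, 1)`
(the saturation knee at 2 N reproduces the observed insensitivity of image
quality to force above 2 N), `C_tilt` a Gaussian in total tilt magnitude
(width 8°), and `S` unit-mean gamma speckle whose shape matches the voxel's
relative std. A tilted probe additionally lifts one footprint edge: the
lifted columns receive extra depth-proportional attenuation (up to
0.25/mm at 15° tilt). This term matters: it makes poor orientation degrade
the image *structurally* (dropout with depth) rather than by global gain
alone, which is what ties entropy and the confidence map together (both
fall as tilt grows) and gives the orientation optimizer a real objective.

Nodules are ellipsoids (lateral width = superior–inferior extent; depth
axis free, so depth/width sets the taller-than-wide axis). The anechoic
core covers a normalized in-plane radius `ρ < √c`, which makes the in-slice
cystic area fraction equal the requested `c` in every slice. Echogenic foci
render at 245 gray levels as 1 mm punctate spots (Poisson, default
0.08/mm² per slice), a single ~3 mm central macrocalcification, or a
peripheral rim at `ρ > 0.8`. Boundary irregularity modulates the radius
with 4–6 seeded cosine harmonics.

Panorama stitching estimates pairwise lateral shifts by exhaustive 1-D
normalized cross-correlation of column-mean profiles (minimum 8-column
overlap; ties broken toward the smallest |shift|; peak below the
correlation threshold 0.2 aborts) and blends with linear feathering. On
frames sliced from one wide image the recovered shifts are exact; the
published system does not describe its stitcher, so this one is the
package's own choice.

## Quality metrics

Entropy is the Shannon entropy of the exact 256-bin gray histogram
(base-2, 0·log 0 := 0); no smoothing, so an 8-bit image is bounded by
8 bits. The confidence map solves the random-walk Dirichlet problem on the
4-connected lattice (top row fixed to 1, bottom to 0) with edge weights
`exp(−β|Δg|)` vertically and `exp(−β(|Δg| + γ))` horizontally, where `g` is
the intensity normalized by the *image mean* and attenuated by
`exp(−α·depth)`. Defaults α = 2, β = 9, γ = 0.06 (the cited random-walk
formulation publishes no values for this setting). Mean-normalization is a
deliberate choice: it makes the map respond to structure (shadows,
dropout) rather than overall gain, which is what produces the observed
positive association between mean confidence and entropy across tilts.
Centering error is `(centroid column − image centre) / (half width)`,
negative when the gland sits left; an empty gland mask raises a distinct
"not visible" error rather than returning 0. The orientation-error
reference direction is an explicit argument (the original description
leaves it unstated). LRIS is the left-half over right-half mean intensity;
the middle column of odd-width images belongs to neither half.

## Segmentation losses

The suite implements soft IoU as Σmin/Σmax with ε = 10⁻⁶ smoothing (binary
masks recover set IoU exactly); the Gaussian feature weight; the
nearest-gland-boundary distance weight (boundary = mask pixels 4-adjacent
to non-mask; outside distances computed by the exact Euclidean distance
transform of the complement, which provably equals the nearest-boundary
distance); and the combination `L_iou + α L_feat + β L_dist` with defaults
α = 1.0, β = 0.01 (the distance term carries pixel units under the raw-sum
mode; the default normalization divides by predicted mass and is
scale-free). Two notational ambiguities in the published equations are
resolved as: the Gaussian weight is evaluated on image intensity (not the
binary gt mask), and the distance loss weighs the nodule prediction (not
the gland prediction); both remain switchable in `LossConfig`.

The demo segmenter is intentionally minimal: a per-pixel linear-logistic
model over nine handcrafted features (local intensity statistics,
deviation from the gland pseudo-label's gray statistics, and gland
geometry terms), trained by central-difference gradients with normalized
steps and backtracking line search, which is monotone by construction and
needs no autograd framework. It exists to exercise the losses end to end;
it is not a stand-in for a convolutional segmenter, and its published
counterpart's training regimen (batch 8, ADAM, 40 epochs, pre-training and
transfer on clinical datasets) is out of scope here.

## Search environment and DQN

The search task abstracts probe positioning as a sliding window (default
width 100 px, stride 20 px) over a panorama with a labelled goal window.
Actions are LEFT / RIGHT / STAY; an episode succeeds when the agent STAYs
within the goal tolerance (10 px). The published system states neither its
reward nor its action granularity, so the defaults — +10 terminal bonus,
−0.1 step cost, distance-difference shaping — are configuration of this
package, not claims about the original. Optional goal drift (random walk)
emulates patient motion, and shadow augmentation emulates partial contact.

The DQN is standard (replay 5000, batch 32, γ 0.95, Adam 10⁻³, target sync
every 250 steps, ε linear 1 → 0.05 over the exploration stage) with a
two-layer numpy MLP over 16 × 16 downsampled crops. Training runs used
here are 8 000 steps with a 3 000-step exploration stage — a scaled-down
schedule appropriate to the small synthetic panoramas (the original
explores for 30 000 steps on real image sequences). At this scale the
greedy policy matches tabular value iteration on the position abstraction
at ≥ 90% of states.

## Orientation optimization

The tilt objective (image entropy) is modelled with a GP (squared-
exponential kernel, lengthscale 2°, jitter 10⁻⁸, optional marginal-
likelihood fitting) and maximized by expected improvement evaluated on a
dense 0.5° grid, which is exact and deterministic at this scale. The
budget is 5 evaluations: 2 seeded quasi-random (Sobol) initial points and
3 acquisition steps; already-evaluated points are excluded from the
acquisition argmax, so a ≤ 5-point discrete domain is simply exhausted. By
default one tilt axis (rotation about the probe long axis) is optimized;
two-axis bounds are supported.

## Control and the virtual scan

Force control follows the wrench-compensation chain: the sensor wrench is
gravity-compensated, mapped to the probe frame, projected onto
`S_y = (0 1 0 0 0 0)`, and servoed with `v = −(λ_f/k)(t_f − t_f*)`.
Defaults: λ_f = 5 s⁻¹, assumed stiffness k = 300 N/m (validated to the
human-tissue range 125–500 N/m), setpoint 3.0 N inside the 2.0–4.0 N
comfort window, hard stop 4.5 N. Positive `S_y` presses into tissue, so
excess force commands retraction. Against a matched spring contact with
explicit Euler at the 10 Hz control tick, the force error contracts exactly
by `(1 − λ_f Δt)` per tick — the closed form used as the oracle in tests —
and λ_f Δt = 0.5 < 1 guarantees stability.

The scan area derives from morphometry: length = mean gland height + 3 sd
(4.76 + 3 × 0.57 = 6.47 cm, the 3σ rule), width = probe width + mean
unilateral gland width (4.0 + 1.48 = 5.48 cm). The in-plane sweep advances
2 mm per waypoint until the gland area fraction falls below the visibility
threshold (default 1% of the frame — the original threshold is never
quantified), then reverses; each waypoint applies a lateral correction of
0.8 × centering error × half footprint. The out-of-plane phase begins with
a 60° probe rotation and covers exactly 12 mm centred on each recorded
nodule. Because the imaging model is 2-D transverse, the rotated view is
re-rendered with the same transverse renderer; the rotation lives in the
plan and event log.

The end-to-end state machine is TS (lateral raster search; a trained
search policy can replace the raster) → BO (budget 5, entropy objective)
→ IPS with force servo and centering → OPS re-scan → matching → TI-RADS
scoring. Nodules seen in both views are matched when their IPS and OPS
centroid estimates agree within half the nodule width (the original states
position matching without a metric). The motion guard terminates on > 2 cm
lateral displacement within any 1 s window or > 5 cm anterior–posterior
excursion of the (optional) patient-drift trace. One tick = 0.1 s; every
tick logs force, pose, entropy, mean confidence (solved on a 24 × 24
downsampled copy for speed; the mean is insensitive to this) and centering
error, so a record is one complete, seed-reproducible time series.

## TI-RADS extraction and scoring

Gland gray statistics use the smoothed-histogram rule: the 256-bin gland
histogram is smoothed (window 5), its mean count ("line average") selects
the modal gray levels, and μ_g/σ_g are computed over gland pixels at those
levels. The statistics are computed on parenchyma *excluding* the nodule
under evaluation, since a large anechoic nodule would otherwise
contribute its own mode and shift the bands. Band cut-points (in σ_g units
around μ_g) are: cystic < −2.5, hypo [−2.5, −1), iso [−1, +1], hyper
(+1, +3], calcification > +3 — the class names are published, the
cut-points are not, so all are configurable.

Component scores: composition from the cystic pixel fraction (≥ 0.9
cystic/0, ≤ 0.1 solid/2, else mixed/1); echogenicity from the dominant
band (anechoic 0, hyper/iso 1, hypo 2; "very hypoechoic" 3 needs a
configured muscle reference and is off by default); shape from
bounding-box depth/width in mm (> 1 → 3, ties → 0); margin from the
moment-fitted-ellipse IoU (< 0.85 → irregular/2) with the boundary-normal
gray-std statistic (5 inner + mid + 5 outer samples along the outward
normal of the signed distance field, nearest-neighbour, clipped at the
border) reported alongside — how the two margin factors combine into the
single ACR point is unspecified, so the shape factor gates and the std is
informational; foci from clustered calcification-band pixels (none 0;
peripheral 2 when most foci pixels hug the boundary *and* cover most of
it; any cluster above 2 mm equivalent diameter 1; else punctate 3). The
total maps to TR1 (≤ 1, the total 1 being unreachable from valid ACR
components), TR2 (2), TR3 (3), TR4 (4–6), TR5 (≥ 7), with the standard
size thresholds for follow-up/FNA per level.

The bundled 24-nodule two-rater table reproduces a published comparison;
recomputing totals gives 11 agreements, 8 differences of 1, 4 of 2 and one
of 4. The accompanying narrative counts 10 agreements — the printed rows
support 11 — so only the internally consistent counts (8 and 4) are
asserted.

## What the synthetic experiments do and do not show

The phantom gives every test perfect ground truth and controlled class
labels, so the suites demonstrate *internal correctness* — the losses
match brute-force oracles exactly, the servo matches its closed form to
1e-9, the scorer recovers the generating composition/echogenicity/shape
classes on ≥ 90% of seeded nodules — under this imaging model. They do not
demonstrate clinical performance: real B-mode images have anisotropic
speckle, refraction and reverberation artifacts, operator-dependent gain,
and nodule appearances far outside these parametric families, and real
scanning involves segmentation networks whose errors propagate into
centering and detection. Published clinical figures (segmentation IoU
gains on hospital datasets, patient entropy values, scan durations,
significance tests) depend on that data and hardware and are out of scope.

## Numerical conventions

Quantization rounds half up to 8 bits. Masks are 0-based, half-open pixel
boxes; image row 0 is the transducer face. Soft IoU uses ε = 10⁻⁶;
duplicate BO candidates are never re-evaluated; panorama ties prefer the
smallest |shift|; `g_std = 0` degrades the Gaussian weight to the
indicator of `I ≠ g_avg`; an exactly square nodule (aspect 1.0) scores
shape 0. All randomness flows through `numpy.random.default_rng` seeds;
one global seed fans out to fixed per-module child seeds (CRC-32 of the
module name XOR the seed, below 2³¹).
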