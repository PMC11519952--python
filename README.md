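# thyroscan

A desk-scale, fully synthetic re-creation of the computational stack of an
autonomous robotic thyroid-ultrasound scanner. The robot hardware — arm,
force/torque sensor, linear probe, depth camera — is replaced by a voxel
neck phantom and a virtual probe, and everything that runs *on top of* the
hardware is implemented as tested, reusable Python components:

- **phantom** (`thyroscan.phantom`): voxel tissue maps with a thyroid lobe,
  trachea cartilage and carotid, controllable nodules (cystic fraction,
  echogenicity offset, boundary irregularity, echogenic foci patterns),
  B-mode-like frame rendering with speckle / depth attenuation /
  force- and tilt-dependent coupling, shadow augmentation, and panorama
  stitching by 1-D normalized cross-correlation with linear feathering.
- **quality** (`thyroscan.quality`): Shannon image entropy (256-bin, base 2),
  a random-walk confidence map (graph-Laplacian Dirichlet problem, top row
  = 1, bottom row = 0), gland centering error, orientation error, and
  left-right intensity symmetry (LRIS).
- **seg losses** (`thyroscan.losses`): the weakly supervised nodule-
  segmentation loss suite — Gaussian feature weight
  `W_gauss = 1 − exp(−(I − g_avg)² / (2 g_std²))`, feature loss (soft IoU of
  the weighted prediction), nearest-gland-boundary distance loss, soft IoU
  loss, and the combination `L = L_iou + α L_feat + β L_dist` — plus a tiny
  demo segmenter trained directly on these losses.
- **search** (`thyroscan.search`): the panoramic sliding-window search task
  as a reset/step environment (LEFT / RIGHT / STAY, goal window, optional
  shadowing and goal drift) and a numpy DQN (replay buffer, ε-greedy with
  linear decay, target network).
- **orient** (`thyroscan.orient`): Gaussian-process Bayesian optimization of
  probe tilt with image entropy as objective, expected-improvement
  acquisition on a dense angle grid, budget N = 5.
- **control** (`thyroscan.control`): wrench gravity compensation
  `ᵖH = ᵖF_f (H − ᶠF_g ᵍH_g)`, contact force `t_f = S_y ᵖH`, the
  proportional force servo `v = −(λ_f/k)(t_f − t_f*) S_yᵀ`, iterative
  sideway rotation correction `R_n = R_step R_{n−1}`, scan-range derivation
  (3σ rule over gland morphometry), in-plane / out-of-plane sweep planning
  (60° rotation, 12 mm span), a patient-motion guard (2 cm/1 s lateral,
  5 cm anterior–posterior), and the end-to-end virtual scan state machine
  TS → BO → IPS → OPS → scoring.
- **tirads** (`thyroscan.tirads`): ACR TI-RADS feature extraction from image
  + masks (smoothed gland histogram statistics, σ-band pixel
  classification, moment-based ellipse fit, boundary-normal margin
  statistic, foci clustering), the five component scores, total → TR level
  mapping, size-conditioned FNA / follow-up recommendations, and two-rater
  comparison reports (a 24-nodule robot-vs-clinician example table is
  bundled).

Who is it for: anyone studying image-servoed robotic ultrasound or
rule-based TI-RADS scoring who wants a reproducible, hardware-free sandbox
with ground truth for every pixel.

## Worked example

Run a full virtual scan of a seeded one-nodule phantom and summarize it:

```bash
$ thyroscan scan --seed 1 --out runs/demo
{"run": {"version": "0.1.0", "seed": 1, "config_hash": "50efd431a5b5"}}
{"completed": true, "n_matched_nodules": 1, "written": {...}}

$ thyroscan report runs/demo
{"completed": true, "n_ticks": 70, "n_matched_nodules": 1,
 "median_abs_centering_error": 0.0, "mean_entropy_bits": 6.4947}
```

The scan searched laterally until the gland filled more than 1% of the
frame, tuned the probe tilt by budget-5 Bayesian optimization, swept the
lobe axis with the force servo holding ~3 N while centering the gland
(median |centering error| 0.0 over the in-plane sweep), re-scanned the
detected nodule out-of-plane after a 60° rotation over 12 mm, matched the
two views by position, and scored the nodule:

```
{'composition': 2, 'echogenicity': 2, 'margin': 0, 'shape': 0, 'foci': 0,
 'total': 4, 'level': 4, 'category': 'moderately suspicious',
 'recommendation': 'no FNA'}
```

i.e. a solid (2), hypoechoic (2) nodule with a smooth margin (0), wider
than tall (0), with no echogenic foci (0): total 4 → TR4, and at 8 mm it is
below the 10 mm follow-up threshold, so no FNA is advised.

Comparing the two raters of the bundled 24-nodule score table:

```bash
$ thyroscan compare
{"differences": [...], "histogram": {"0": 11, "1": 8, "2": 4, "4": 1},
 "agreement_count": 11}
```

Eleven nodules get identical totals from both raters, eight differ by one
point and four by two.

Other subcommands: `simulate` (phantom + frame files), `score` (TI-RADS on
saved frames), `train-search` (DQN on a synthetic panorama),
`optimize-orientation` (BO trace), `losses-demo` (hybrid vs IoU-only
training), `report`.

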