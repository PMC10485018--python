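# Methods

## The problem

Dose- and time-limited scanning microscopy measures a sample pixel by
pixel; a full raster scan spends most of its budget on regions that
carry no information (empty background, flat interiors).  `fastscan`
implements a self-driving alternative: after a small quasi-random seed
scan, a supervised decision engine repeatedly predicts, for every
unmeasured grid position, how much the image reconstruction would
improve if that position were measured next, and steers the (simulated)
instrument to the most informative batch.  The toolkit closes the loop
entirely in software: a synthetic flake-and-bubble sample plays the
specimen, so every component can be exercised and scored against ground
truth with no hardware.

## Model and procedure

Let A ∈ R^N be the ground-truth image on the scan grid and
Y^k = {(s^i, a_{s^i})} the first k measurements.  From Y^k the toolkit
builds an estimate Â^k (inverse-distance-weighted interpolation inside
the loop; biharmonic inpainting for final images) and defines the
distortion D(A, Â^k) = ‖A − Â^k‖² (squared L2).  The *reduction in
distortion* of measuring location s is

    R^{k,s} = D(A, Â^k) − D(A, Â^{k,s}),

where Â^{k,s} includes the new measurement.  Since A is unknown at run
time, the selector scores candidates by the *expected* reduction in
distortion (ERD), modeled as a learned function g(v^{k,s}) of a
6-dimensional local feature vector:

| feature | meaning |
|---|---|
| ∇x, ∇y | central-difference gradients of the interpolant at the pixel |
| σ1, σ2 | d⁻²-weighted mean absolute / squared deviation of the estimate from the nearby measured values |
| L | Euclidean distance to the nearest measured point |
| ρ | measured fraction of the disc of radius r around the pixel |

g is a fully connected network (5 hidden layers × 50 ReLU units) applied
to a 50-dimensional random-Fourier-feature (RBF) expansion of the
standardized features, trained with Adam (learning rate 10⁻³, 100
epochs, minibatches of 1000) on (v, R) pairs harvested from random
masks of a single generic photographic test image (the 512×512
grayscale camera image bundled with scikit-image, downscaled to
128×128) at ten coverage levels spanning 1%–80%.  The model is therefore
*sample-agnostic*: it never sees a flake image during training.

Each loop iteration: IDW-reconstruct → predict ERD for all unmeasured
pixels → take the 50 highest-ERD pixels → order them into a short open
motor path (exact dynamic programming for ≤ 8 points, else
nearest-neighbor construction plus 2-opt/or-opt) → measure → repeat,
until a coverage budget or an ERD-plateau rule is met.  The scan starts
from a deterministic 2-D Hammersley set covering 1% of the grid.

## Key parameters

| parameter | default | notes |
|---|---|---|
| initial fraction | 0.01 | Hammersley seed scan |
| batch size | 50 | points per decision round |
| neighbors k | 10 | IDW and feature computation |
| IDW power | 2 | conventional Shepard weight |
| neighborhood radius r | 2 × mean spacing | recomputed each iteration; see below |
| RBF dimension / γ | 50 / 1⁄12 | γ by the median-distance heuristic |
| RD window | half-width 3L, clamped to [3, 30] px | locality approximation |
| training set | 10 levels × 10 masks × 2000 pixels | 200k pairs |
| max coverage | 0.35 | mirrors the live-experiment budget |
| stopping | coverage_only (erd_plateau available) | window 5, rel. tol. 0.05 |

Design notes on the open choices:

- **Neighbor ties.** On integer grids many candidate neighbors are at
  bit-identical distances.  All neighbor sets use a *closed* k-NN rule —
  every point tied with the k-th distance is included — so results do
  not depend on the search tree's arbitrary tie order, and the one-point
  RD update below stays exact.
- **Exact one-point RD update.** Adding a measurement can only shrink a
  pixel's k-th-neighbor distance, and every point inside the new cutoff
  is already in the cached (tie-padded) neighbor arrays; RD training
  targets are therefore computed without rebuilding the spatial tree,
  and agree with a from-scratch reconstruction to ~1e-15.
- **RD locality.** The influence region of an added IDW point scales
  with its nearest-neighbor distance L; RD is evaluated in a square
  window of half-width 3L (clamped to [3, 30] px) around the candidate.
  On 20×20 states the windowed values rank-correlate with full-image RD
  above 0.9; a window at least the grid size reproduces it exactly.
- **Neighborhood radius.** r = 2 × √(N_pixels/N_measured).  A disc of
  this radius contains ~12 measurements at any coverage, so the density
  feature ρ actually varies; substantially smaller radii leave the disc
  empty and the feature degenerate.
- **Kernel scale.** Features are standardized before the RBF expansion,
  so typical squared pairwise distances are ≈ 2×6; γ = 1/12 places the
  Gaussian kernel's length scale at that magnitude (median heuristic).
- **Zero-evidence candidates.** A candidate whose feature vector is
  exactly (0, 0, 0, 0, L, ρ) — all nearby measurements agree with a
  locally flat interpolant — never occurs in the photographic training
  domain, so the network's output there is uninformative extrapolation.
  Predicted ERD for such candidates is set to the regression's
  zero-deviation limit, 0.  With measurement noise the rule is inert
  (deviations are never exactly zero); on noise-free synthetic samples
  it keeps the ERD ranking over empty background meaningful.
- **Negative ERD.** Training targets keep their sign (the true signed
  objective); predictions are clipped at 0 only for selection.
- **Stopping.** The live criterion in this class of experiments is
  visual; the numeric default runs to 35% coverage, and an ERD-plateau
  rule (relative change of summed ERD over a 5-iteration window below
  5%) is available.
- **Routing.** Open path, not a cycle: the motors continue from a
  batch's last point into the next batch.  Euclidean metric in pixel
  units; motor kinematics are not modeled.  Batches of ≤ 8 points are
  solved exactly (Held–Karp); pure 2-opt can stall >10% above optimum
  on small adversarial instances.

## The simulated instrument

`synthetic_sample` emulates a dark-field scanning-diffraction
experiment on a 2-D material film:

- **Scenes** contain a configurable number of irregular polygonal flakes
  with discrete thickness levels (brighter = thicker) on an exactly-zero
  background, decorated with bubbles whose rims are depressed by a
  contrast factor (the tilted film diffracts outside the detector ROI).
- **Diffraction stacks** attach to every scan position a 2-D Gaussian
  detector peak whose total intensity equals the dark-field value and
  whose center is displaced from the nominal position by a gain times
  the local gradient of a spherical-cap film-height field (bubbles are
  height bumps).  Flat regions give an unshifted peak; the horizontal
  centroid shift (CoMx) therefore changes sign across each bubble's
  vertical midline.  ROI-integrating the stack reproduces the
  generating dark-field image, which ties the two simulators together.
- **Noise** is optional (off by default): additive Gaussian or scaled
  Poisson counting noise, clipped at zero.

What the simulator does *not* emulate: real diffraction geometry
(Ewald sphere, 2θ), asymmetric CoMx-vs-CoMy detail, detector hot
pixels (a median-clip filter hook exists but is off for synthetic
data), drift, or dose effects.  Passing tests on these scenes show the
decision loop, reconstruction, routing, and CoM analysis are correct
and that adaptive sampling beats static masks on sparse scenes — they
do not certify performance on any particular real instrument or
contrast mechanism.

## Evaluation sizes

All quality comparisons run at desk scale, chosen so the full
verification suite completes in minutes on one CPU: five seeded
150×100-pixel flake scenes scanned to 60% coverage with checkpoints at
10/30/60%, static low-discrepancy and uniform-random baselines matched
point-for-point, a 64×64 single-bubble diffraction stack (24×24
detector) for the CoM study, and a 128×128 training image.  Metrics:
NRMSE (RMSE normalized by the ground-truth range) and SSIM (7×7
windows, data range 1.0), both on biharmonic-inpainted final images;
in-loop metrics use the IDW estimate.

## Known limitations

- Per-pixel RD is a noisy target: its far-field component is
  unpredictable from local features, which bounds the achievable rank
  correlation between predicted ERD and actual RD well below 1 (the
  selector only needs the top of the ranking, which is much easier).
  Rank agreement is also weaker on very small evaluation grids.
- The Hammersley-seeded scan can miss isolated features smaller than
  the initial inter-point spacing; they are found late (the
  exploration–exploitation tradeoff) or not within the budget.
- IDW is a convex combination — it never extrapolates beyond the
  measured value range; biharmonic inpainting can.
- Timing-based scaling checks measure a real machine and inherit its
  jitter; they compare best-of-3 runs.
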