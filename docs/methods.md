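# Methods

`cmbdetect` implements a two-stage detector for cerebral microbleeds
(CMBs) on susceptibility-weighted (SWI-like) 3D volumes, together with a
synthetic phantom generator that stands in for clinical data. This note
records the model, the choices that were genuinely open, and what the
synthetic benchmark does and does not establish.

## The detection problem

A CMB is a 2–10 mm round or ovoid hypointense focus, often surrounded by
a thin bright rim of less paramagnetic tissue. Its dominant mimic is a
venous vessel: locally indistinguishable in a single slice, but
continuous across many slices, whereas a CMB is confined to a few. The
detector therefore splits the work: a sensitivity-oriented localization
stage proposes every hypointense focus, and a discrimination stage
rejects the mimics.

## Preprocessing

Order: brain masking → bias correction → intensity normalization.

* **Masking** zeroes everything outside a supplied binary brain mask
  (mask creation itself is out of scope; the phantom generator emits its
  own).
* **Bias correction** estimates a smooth multiplicative gain field by
  least-squares regression of log-intensity on a separable cosine basis
  (order ≤ `basis_order` per axis, default 2, i.e. 27 coefficients). The
  fit uses only voxels within a factor 1.5 of the median intensity so
  focal structures (lesions, vessels) do not attract the field, and a
  30 000-voxel random subsample for speed. The corrected volume
  preserves the arithmetic mean inside the mask. A `skip_bias` hook
  accepts volumes corrected externally (e.g. by N4).
* **Normalization** finds the modal bin `h_p` of the histogram of
  strictly positive intensities (256 uniform bins between 0 and the
  maximum; ties break toward the lower bin) and maps `i -> i / (2 h_p)`,
  so the tissue peak lands at 0.5 on every scan regardless of scanner
  scaling. Values above 1 are *not* clipped: the bright rim is a
  discriminative feature. The bin count is a free choice (the procedure
  is tested at 128/256/512 bins); zeros are always excluded so the
  background cannot become the mode.

## Stage 1 — dual 3D U-Net localization

A depth-3 3D U-Net (two 2×2×2 max-pool stages, skip connections by
concatenation, batch normalization after every convolution, stride-2
kernel-2 transposed-convolution upsampling, 1×1×1 sigmoid head) maps a
20×20×16-voxel window to a same-sized CMB-probability map. The window is
20×20 in-plane × 16 slices, matching the anisotropy of SWI acquisitions
(thicker slices ⇒ shorter window axis).

Inference slides the window over the volume with stride 3 per axis; the
final window per axis is clamped to the volume border (no padding, so no
fabricated intensities). Overlapping per-window predictions are stitched
by arithmetic mean, which keeps the stitched map in [0, 1] and therefore
keeps the fixed thresholds meaningful.

Two U-Nets with identical architecture are trained, one with batch size
20 and one with 30 (and different parameter initializations). Their
prediction volumes are combined by dividing each by its own maximum and
averaging; candidates are the 26-connected components of the combined
map at threshold **0.2**, each summarized by its probability-weighted
centroid (rounded to the nearest voxel) and scored by the component
maximum; the component's peak-probability voxel is kept alongside,
because the centroid of an elongated or merged component can sit
millimetres off the lesion. The ensemble exists because either net
alone occasionally misses a lesion the other finds. Training must run
the batch-30 net to convergence: under-converged diffuse maps, once
max-normalized, bridge clustered lesions into a single component.

Training patches: one window per annotated lesion, centered on it, with
a voxel-wise target of 1 inside the annotated sphere; deterministic
augmentation (in-plane flips, ±90° in-plane rotations, ±1-voxel shifts
re-extracted from the source volume — 11 patches per lesion); plus
random negative windows whose centers are at least 10 mm from every
lesion center (the sampler relaxes the margin stepwise in lesion-dense
brains where 10 mm is infeasible, but never below 5.5 mm, just beyond
the 5 mm match tolerance), half of them centered on vessel voxels when
ground truth records vessels. The
vessel-targeted half exists because uniform negatives almost never
sample a vessel, and the U-Net then floods tubes with high probability.
Loss is voxel-wise binary cross-entropy with the positive class
up-weighted by the negative:positive voxel ratio, capped at 12 — enough
to counter the >99 % background imbalance without lifting the background
probability floor. Optimizer: Adam; learning rate, epochs and batch size
live in `NetConfig`.

## Mimic mining and stage 2 — dual 3D CNN discrimination

After stage-1 training, both U-Nets run over the *training* scans; the
combined map is thresholded at the permissive **0.15**, and every
candidate farther than the match tolerance from all true lesion centers
is recorded as a mimic — a hard negative that the first stage believes
in. Mining deliberately runs on training scans only: mining validation
scans would leak labels into the second stage.

The stage-2 classifier is a 3D CNN (conv–BN–ReLU ×2, one 2×2×2 max-pool,
conv–BN–ReLU, flatten, two dense layers, sigmoid scalar) that scores the
20×20×16 window around a candidate for "CMB at center". The max-pool
provides the slack for small mis-centerings. Its training set is: every
lesion window with augmentation including one- *and* two-voxel shifts
(candidate centroids are not perfectly centered, so the classifier must
tolerate ±2 voxels); the mined mimics (capped at 3× the number of
augmented positives, by seeded subsampling); and the random negatives.
Two CNNs (batch sizes 20/30) are trained; a candidate's stage-2 score is
the mean of their outputs on the window centered at the candidate's
peak-probability voxel (mined mimic windows use the same centering, and
a candidate whose peak falls on a lesion is never used as a negative),
and detections are those at or above the stage-2 threshold (default
operating point 0.5; the threshold is the quantity swept to trace the
sensitivity / FP-per-scan trade-off).

Stage 2 can only remove detections, never add them.

## Cross-validation

`run_cv` implements leave-two-out cross-validation: a seeded random
partition into folds of two validation scans (one fold of one scan if
the count is odd). Each fold retrains all four networks from scratch on
its training scans, mines mimics on those same scans, and evaluates on
the two held-out scans. Per-scan confusion counts pool across folds;
pooled TP+FN equals the total annotation count by construction.

## Evaluation

A detection hits an annotation if their distance in physical millimetres
(voxel spacing applied per axis) is at most the tolerance; the default
tolerance is 5 mm — half the maximum clinical CMB diameter — and is
reported with every result. Matching is greedy nearest-first and
one-to-one, with ties broken by the lower coordinate tuple, so results
are independent of detection order; greedy matching can in principle
differ from optimal assignment, which we accept for determinism.
Sensitivity is |TP| / (|TP|+|FN|); the false-positive rate is unmatched
detections averaged over scans.

## The phantom generator

Each phantom is an ellipsoidal "brain" (semi-axes 45 % of the grid) of
homogeneous tissue at `tissue_mean` (arbitrary units, default 100),
containing:

* **CMBs** — spheres with diameter drawn from `cmb_diameter_range`
  (default 2–6 mm: inside the clinical 2–10 mm band, with the upper end
  sized so several lesions fit the reduced default grid), core intensity
  `tissue_mean·(1−cmb_contrast)` (default contrast 0.6) and a 1 mm
  bright shell at `tissue_mean·(1+rim_gain)` (default 0.3). Centers are
  integer voxels sampled from the set that clears the brain boundary and
  all vessels by radius + rim + 0.5 mm, with pairwise center separation
  of the summed radii plus both rims.
* **Vessels** — tubes of radius 0.5–1.5 mm around random-walk
  centerlines with bounded curvature, biased along z so each tube spans
  at least 3× the maximum CMB diameter in z (the multi-slice continuity
  that lets a reader — and stage 2 — tell vessel from lesion). Vessel
  lumen intensity equals the CMB core intensity: the mimic is exactly as
  dark as the lesion.
* **Bias field** — a random low-order (≤2 per axis) separable cosine
  combination scaled to peak-to-trough `bias_amplitude` (default 0.2,
  mean ≈ 1), applied multiplicatively.
* **Noise** — additive Gaussian (default SD 4, i.e. 4 % of tissue),
  clipped at zero. Outside the mask everything is exactly 0.

Defaults: 64×64×48 voxels at 0.5×0.5×1.0 mm. The default contrast and
noise levels are free choices (no public reference values exist for the
restricted clinical data) picked to be conservative: the lesion-to-noise
contrast (60 % drop vs 4 % noise) is comfortable, but vessels are
exactly as dark as lesions, so discrimination is never trivial.

What the phantom does **not** emulate: susceptibility physics (no phase,
no blooming), anatomy (no cortex/ventricles/air interfaces), calcified
or hemorrhagic mimics other than vessels, intensity texture within
tissue. Passing the benchmark therefore shows that the *mechanism* works
— a sensitive first stage whose mined errors teach a second stage to
remove most false positives at minimal sensitivity cost — not that the
clinical numbers of any real cohort would be reproduced.

## Numerical and engineering choices

The networks are implemented in a small numpy/numba layer library
(`cmbdetect.nn`) written for this package: 3D convolution with hand-
derived backward passes, batch normalization, max pooling, transposed
convolution, dense layers, Adam, and weighted BCE-with-logits. Internals
are float32, batch-last `(C, X, Y, Z, N)` so the convolution kernels
vectorize over the window batch; a pure-numpy path is used if numba is
absent. Everything is seeded: initialization, data order, negative
sampling, fold assignment. Two runs with identical seeds produce
bit-identical parameters, predictions and detection files. Batch-norm
inference uses running statistics (momentum 0.9); max-pool gradient ties
split evenly; He initialization throughout.

Desk-scale problem sizes used by the test suite and benchmark: U-Nets
with base width 2 (4 at depth 2, 8 at the bottleneck) trained 15
epochs, CNNs with base width 4 trained 6 epochs, 12 training + 3
held-out phantoms. These are the
package's reduced presets; the full-width architectures (U-Net base 16,
CNN base 32) are the defaults in `NetConfig` and are exercised by the
same code paths.

## Known limitations

* Greedy (not optimal) matching; differences are possible when many
  detections crowd one annotation.
* The bias corrector shares its basis family with the phantom's bias
  generator; on real data (where the field is not a low-order cosine)
  residual bias would be larger — the N4 import hook exists for that.
* Stage-2 windows for candidates within half a window of the border are
  clamped, so the candidate is then not exactly centered.
* The mimic-mining threshold (0.15), stage-1 threshold (0.2) and window
  geometry are fixed constants of the method; only the stage-2 threshold
  is an operating point to sweep.
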