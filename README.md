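# cmbdetect

Two-stage detection of cerebral microbleeds (CMBs) in susceptibility-
weighted (SWI-like) 3D MRI volumes, built to be trainable on small
cohorts, plus a synthetic phantom generator so the whole pipeline can be
developed, trained and tested without access to clinical data.

## Who this is for

Researchers and engineers working on automated CMB screening who need a
complete, deterministic reference pipeline: preprocessing, a
high-sensitivity localization stage, hard-negative mining, and a
false-positive-reduction stage — with every stage testable against
ground truth.

## The method

CMBs are 2–10 mm round/ovoid hypointense foci; their dominant mimic is
a venous vessel, equally dark but continuous across many slices. The
pipeline:

1. **Preprocessing** — brain masking, smooth multiplicative bias-field
   correction, then histogram-peak normalization: with `h_p` the modal
   intensity of the strictly positive voxels,

   `histnorm(i) = i / (2 · h_p)`

   which maps the tissue peak to 0.5 on every scan regardless of
   scanner scaling.
2. **Stage 1: dual 3D U-Net** — a depth-3 U-Net (batch-normalized,
   sigmoid voxel output) scores 20×20×16-voxel windows slid over the
   volume with stride 3; overlapping window predictions are stitched by
   averaging. Two U-Nets, trained with batch sizes 20 and 30, have
   their prediction volumes max-normalized and averaged; candidates are
   the 26-connected components above threshold 0.2, one candidate per
   component at its probability-weighted centroid.
3. **Mimic mining** — the trained U-Net pair is run over the *training*
   scans at the permissive threshold 0.15; every candidate that does
   not hit a true lesion is saved as a "mimic", a hard negative.
4. **Stage 2: dual 3D CNN** — a batch-normalized 3D CNN scores the
   20×20×16 window around each candidate for "CMB at center"; it is
   trained on augmented lesion windows (flips, in-plane ±90°
   rotations, 1–2-voxel shifts), the mined mimics, and random
   negatives. Two CNNs (batch 20/30) are averaged; detections are
   candidates at or above the stage-2 threshold.

Evaluation reports **sensitivity** (fraction of annotated CMBs matched
within 5 mm, one-to-one) and **false positives per scan**. A
leave-two-out cross-validation driver (`run_cv`) retrains all four
networks per fold and never lets validation scans feed training or
mimic mining. See `docs/methods.md` for every design choice and the
phantom's scope.

## Worked example

`examples/02_preprocess_and_normalize.py` — the normalization property
on two phantoms whose scanners differ 10× in intensity scale:

```
tissue_mean=   100: raw peak h_p= 101.17  normalized peak=0.5000 (bin width 0.0028)
tissue_mean=  1000: raw peak h_p=1003.79  normalized peak=0.5000 (bin width 0.0026)
```

Both scans land on the same intensity scale: the histogram peak maps to
0.5 within one bin width, so the networks never see scanner-specific
scaling.

`examples/04_train_and_detect.py` trains a reduced two-stage detector
(6 phantom scans, small networks) and applies it to a held-out phantom:

```
mined 5 stage-1 false positives as CNN hard negatives
trained 2 U-Nets (batch 20/30) + 2 CNNs in 192s
held-out scan: 5 true CMBs, 5 detections
  true positives:  4
  false negatives: 1
  false positives: 1
```

Four of five lesions are found at one false positive; the mined mimics
are what let the CNN reject the vessel candidates stage 1 proposed (the
acceptance benchmark, with twice the training data, reaches full
sensitivity at 0.7 false positives per scan). The other examples cover
phantom generation (`01`), sliding-window stitching (`03`), and
cross-validation bookkeeping (`05`).

A `cmbdetect` command-line tool wraps the same library for shell use:
`cmbdetect simulate | preprocess | train | detect | evaluate | crossval`
(NIfTI volumes in/out, TSV annotations and detections).

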