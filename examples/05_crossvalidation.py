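"""Leave-two-out cross-validation (LOTCV) on a miniature cohort.

Every fold holds out two whole scans; the four networks (dual U-Net +
dual CNN) are retrained from scratch on the remaining scans, and mimic
mining only ever sees the fold's training scans, so no label leaks into
validation.
"""

from cmbdetect import PhantomSpec, generate_dataset
from cmbdetect.models import dual_configs
from cmbdetect.pipeline import PipelineConfig, run_cv
from cmbdetect.preprocess import PreprocessConfig

spec = PhantomSpec(grid_shape=(32, 32, 16), n_cmbs=2,
                   cmb_diameter_range=(2.0, 3.0), n_vessels=0, seed=0)
data = generate_dataset(4, spec, seed=7)
cfg = PipelineConfig(stage2_threshold=0.0, stride=6, n_negatives_per_scan=4,
                     negative_margin_mm=4.0,
                     preprocess=PreprocessConfig(skip_bias=True))
unet_cfgs = dual_configs(base_filters=2, epochs=2, seed=0, learning_rate=3e-3)
cnn_cfgs = dual_configs(base_filters=2, epochs=2, seed=5)

result = run_cv(data, cfg, unet_cfgs, cnn_cfgs, seed=3)
print(f"{len(result.folds)} folds over {len(data)} scans")
for k, (fold, res) in enumerate(zip(result.folds, result.per_fold)):
    print(f"fold {k}: validate on scans {fold.val_indices} -> "
          f"sensitivity {res.sensitivity:.2f}, FP/scan {res.fp_per_scan:.1f}")
print(f"pooled: sensitivity {result.pooled.sensitivity:.2f}, "
      f"FP/scan {result.pooled.fp_per_scan:.1f} over {result.pooled.n_cmbs} CMBs")
# with 2-epoch toy networks the numbers are weak; the point of this
# example is the fold bookkeeping: every scan is validated exactly once
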