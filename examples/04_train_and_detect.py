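"""Train a reduced two-stage detector on a small phantom cohort and run
it on a held-out scan.

Uses deliberately small networks so the example finishes in a few
minutes on a laptop CPU; the acceptance benchmark uses the same
machinery at larger scale.
"""

import time

from cmbdetect import PhantomSpec, generate_dataset
from cmbdetect.models import dual_configs
from cmbdetect.evaluation import match_detections
from cmbdetect.pipeline import PipelineConfig, run_pipeline, train_two_stage

t0 = time.time()
spec = PhantomSpec()
train = generate_dataset(6, spec, seed=1, n_cmbs_range=(3, 6), n_vessels_range=(2, 3))
vol, mask, gt = generate_dataset(1, spec, seed=99, n_cmbs_range=(3, 6),
                                 n_vessels_range=(2, 3))[0]

cfg = PipelineConfig()
unet_cfgs = dual_configs(base_filters=2, epochs=12, seed=0, learning_rate=3e-3)
cnn_cfgs = dual_configs(base_filters=4, epochs=4, seed=10)
bundle, _, mimics = train_two_stage(train, cfg, unet_cfgs, cnn_cfgs, seed=0)
print(f"mined {mimics.total} stage-1 false positives as CNN hard negatives")
print(f"trained 2 U-Nets (batch 20/30) + 2 CNNs in {time.time() - t0:.0f}s")

dets = run_pipeline(vol, mask, bundle, cfg)
mr = match_detections(dets, gt, cfg.tolerance_mm, vol.voxel_spacing)
print(f"held-out scan: {len(gt.cmb_centers)} true CMBs, {len(dets)} detections")
print(f"  true positives:  {len(mr.true_positives)}")
print(f"  false negatives: {len(mr.false_negatives)}")
print(f"  false positives: {len(mr.false_positives)}")
# stage 1 aims for sensitivity; stage 2 (trained on mined stage-1 false
# positives) prunes vessel look-alikes without discarding true lesions
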