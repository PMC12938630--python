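"""Two-stage inference and the cross-validation driver.

Stage 1 runs the dual U-Net sliding-window ensemble and extracts
candidates from the combined prediction at threshold 0.2; stage 2 scores
a 20x20x16 window around each candidate with the dual CNN and keeps those
above the decision threshold. Stage 2 can therefore only remove
detections, never add them.

Training follows the leave-two-out cross-validation (LOTCV) scheme: every
fold holds out two whole scans, and mimic mining for the fold's CNNs uses
only that fold's training scans, so no validation voxel or coordinate
ever leaks into training.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .evaluation import EvalResult, MatchResult, aggregate, match_detections
from .models import (
    MimicSet,
    NetConfig,
    TrainedModel,
    build_cnn,
    build_unet,
    dual_configs,
    mine_mimics,
    predict_volume,
    train_model,
)
from .patching import (
    Candidate,
    DEFAULT_STRIDE,
    DEFAULT_WINDOW,
    PredictionVolume,
    Patch,
    augment_patch,
    extract_candidates,
    extract_patch,
    sample_training_patches,
)
from .preprocess import PreprocessConfig, preprocess_scan
from .synthetic import GroundTruth
from .volume import BrainMask, ScanVolume

__all__ = [
    "Detection",
    "PipelineConfig",
    "ModelBundle",
    "CVFold",
    "combine_predictions",
    "stage1_detect",
    "stage2_discriminate",
    "run_pipeline",
    "make_lotcv_folds",
    "run_cv",
    "train_two_stage",
    "build_stage1_training_set",
    "build_stage2_training_set",
    "preprocess_for_pipeline",
    "write_detections",
    "read_detections",
]


@dataclass(frozen=True)
class Detection:
    coordinate: tuple[int, int, int]
    stage1_score: float
    stage2_score: float


@dataclass(frozen=True)
class PipelineConfig:
    """All thresholds and geometry of the two-stage detector.

    ``stage1_threshold`` (0.2) extracts candidates from the combined
    U-Net map; ``mimic_threshold`` (0.15) is the permissive threshold
    used only while mining hard negatives; ``stage2_threshold`` is the
    CNN operating point (the quantity swept for the FROC trade-off).
    """

    stage1_threshold: float = 0.2
    mimic_threshold: float = 0.15
    stage2_threshold: float = 0.5
    stride: int = DEFAULT_STRIDE
    window_shape: tuple[int, int, int] = DEFAULT_WINDOW
    tolerance_mm: float = 5.0
    n_negatives_per_scan: int = 40
    negative_margin_mm: float = 10.0
    mimic_ratio_cap: float = 3.0
    preprocess: PreprocessConfig = field(default_factory=PreprocessConfig)

    def __post_init__(self) -> None:
        for name in ("stage1_threshold", "mimic_threshold"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not (0 <= self.stage2_threshold <= 1):
            raise ValueError("stage2_threshold must be in [0, 1]")


@dataclass
class ModelBundle:
    """The four trained networks of one pipeline instance."""

    unets: tuple[TrainedModel, TrainedModel]
    cnns: tuple[TrainedModel, TrainedModel]


@dataclass(frozen=True)
class CVFold:
    train_indices: tuple[int, ...]
    val_indices: tuple[int, ...]


def combine_predictions(p1: PredictionVolume, p2: PredictionVolume) -> PredictionVolume:
    """Normalize each map by its own maximum, then average.

    An all-zero map passes through as zero (so combining with it halves
    the other map rather than dividing by zero). The operation is
    symmetric and keeps values in [0, 1].
    """
    if p1.shape != p2.shape:
        raise ValueError(f"shape mismatch {p1.shape} vs {p2.shape}")

    def unit(p: np.ndarray) -> np.ndarray:
        m = p.max()
        return p / m if m > 0 else p

    combined = 0.5 * (unit(p1.probabilities) + unit(p2.probabilities))
    return PredictionVolume(combined, provenance=f"combine({p1.provenance},{p2.provenance})")


def preprocess_for_pipeline(
    vol: ScanVolume, mask: BrainMask, cfg: PipelineConfig
) -> ScanVolume:
    return preprocess_scan(vol, mask, cfg.preprocess)


def stage1_detect(
    pre_vol: ScanVolume,
    unet_pair: tuple[TrainedModel, TrainedModel],
    cfg: PipelineConfig,
) -> list[Candidate]:
    """Dual sliding-window U-Net inference, combination, candidate
    extraction at the stage-1 threshold."""
    p1 = predict_volume(unet_pair[0], pre_vol, cfg.stride)
    p2 = predict_volume(unet_pair[1], pre_vol, cfg.stride)
    return extract_candidates(combine_predictions(p1, p2), cfg.stage1_threshold)


def _centered_block(
    vol: ScanVolume, center: tuple[int, int, int], window: tuple[int, int, int]
) -> np.ndarray:
    origin = tuple(
        int(np.clip(c - w // 2, 0, n - w)) for c, w, n in zip(center, window, vol.shape)
    )
    sl = tuple(slice(o, o + w) for o, w in zip(origin, window))
    return vol.intensities[sl]


def stage2_discriminate(
    pre_vol: ScanVolume,
    candidates: list[Candidate],
    cnn_pair: tuple[TrainedModel, TrainedModel],
    cfg: PipelineConfig,
    threshold: float | None = None,
) -> list[Detection]:
    """Score the window around each candidate with both CNNs (mean) and
    keep detections at or above the stage-2 threshold.

    The window is centered on the candidate's peak-probability voxel
    (falling back to the centroid when no peak was recorded): a merged
    or elongated stage-1 component can put the centroid millimetres off
    the lesion, and the classifier scores "CMB at the window center".
    Windows at the brain border are clamped to the nearest valid origin,
    so the candidate may sit slightly off-center there.
    """
    thr = cfg.stage2_threshold if threshold is None else threshold
    if not candidates:
        return []
    window = cfg.window_shape
    blocks = np.stack(
        [
            _centered_block(pre_vol, c.peak or c.coordinate, window)
            for c in candidates
        ]
    )[..., None].astype(np.float32)
    s1 = cnn_pair[0].predict_patches(blocks)
    s2 = cnn_pair[1].predict_patches(blocks)
    scores = 0.5 * (s1 + s2)
    return [
        Detection(c.coordinate, c.score, float(s))
        for c, s in zip(candidates, scores)
        if s >= thr
    ]


def run_pipeline(
    vol: ScanVolume,
    mask: BrainMask,
    models: ModelBundle,
    cfg: PipelineConfig,
) -> list[Detection]:
    """Full inference on one raw scan: preprocess, stage 1, stage 2.

    Deterministic given the models and config; failures name the stage.
    """
    try:
        pre = preprocess_for_pipeline(vol, mask, cfg)
    except Exception as e:  # pragma: no cover - defensive
        raise RuntimeError(f"preprocessing failed: {e}") from e
    try:
        candidates = stage1_detect(pre, models.unets, cfg)
    except Exception as e:
        raise RuntimeError(f"stage-1 detection failed: {e}") from e
    try:
        return stage2_discriminate(pre, candidates, models.cnns, cfg)
    except Exception as e:
        raise RuntimeError(f"stage-2 discrimination failed: {e}") from e


# ---------------------------------------------------------------------------
# training drivers
# ---------------------------------------------------------------------------


def build_stage1_training_set(
    pre_scans: list[ScanVolume],
    gts: list[GroundTruth],
    masks: list[BrainMask],
    cfg: PipelineConfig,
    seed: int,
) -> list[Patch]:
    """Per scan: one augmented positive patch per lesion plus random safe
    negatives, with voxel-sphere targets for the U-Net."""
    patches: list[Patch] = []
    for i, (vol, gt, mask) in enumerate(zip(pre_scans, gts, masks)):
        scan_patches = sample_training_patches(
            vol,
            gt,
            n_negatives=cfg.n_negatives_per_scan,
            seed=seed + i,
            window=cfg.window_shape,
            margin_mm=cfg.negative_margin_mm,
            mask=mask.mask,
        )
        for p in scan_patches:
            if p.label == 1:
                patches.extend(augment_patch(p))
            else:
                patches.append(p)
    return patches


def build_stage2_training_set(
    pre_scans: list[ScanVolume],
    gts: list[GroundTruth],
    mimics: MimicSet,
    cfg: PipelineConfig,
    seed: int,
) -> list[Patch]:
    """Augmented positive patches, mined mimics as hard negatives (capped
    at ``mimic_ratio_cap`` times the positives), plus random negatives.

    Positive augmentation includes one- and two-voxel shifts so the CNN
    tolerates the mis-centering of stage-1 candidate centroids. Too many
    mimics teach the CNN to reject any lesion with nearby hypointense
    tissue — which is exactly how clustered lesions get missed — hence
    the cap, enforced by seeded subsampling.
    """
    rng = np.random.default_rng(seed)
    window = cfg.window_shape
    positives: list[Patch] = []
    negatives: list[Patch] = []
    for i, (vol, gt) in enumerate(zip(pre_scans, gts)):
        for c in gt.cmb_centers:
            origin = tuple(
                int(np.clip(cc - w // 2, 0, n - w))
                for cc, w, n in zip(c, window, vol.shape)
            )
            p = extract_patch(vol, origin, window)
            p.label = 1
            positives.extend(augment_patch(p, shifts=(1, 2)))
        pool = vol.intensities > 0
        neg = sample_training_patches(
            vol, gt, n_negatives=cfg.n_negatives_per_scan, seed=seed + 7919 + i,
            window=window, margin_mm=cfg.negative_margin_mm, mask=pool,
        )
        negatives.extend([p for p in neg if p.label == 0])

    mimic_patches: list[Patch] = []
    for vol, coords in zip(pre_scans, mimics.per_scan):
        for c in coords:
            origin = tuple(
                int(np.clip(cc - w // 2, 0, n - w))
                for cc, w, n in zip(c, window, vol.shape)
            )
            p = extract_patch(vol, origin, window)
            p.label = 0
            mimic_patches.append(p)
    cap = int(cfg.mimic_ratio_cap * len(positives))
    if len(mimic_patches) > cap:
        keep = rng.choice(len(mimic_patches), size=cap, replace=False)
        mimic_patches = [mimic_patches[k] for k in sorted(keep)]

    out = positives + mimic_patches + negatives
    for p in out:
        p.target = None  # CNN training uses scalar labels only
        p.source = None
    return out


def train_two_stage(
    data: list[tuple[ScanVolume, BrainMask, GroundTruth]],
    cfg: PipelineConfig,
    unet_cfgs: tuple[NetConfig, NetConfig],
    cnn_cfgs: tuple[NetConfig, NetConfig],
    seed: int = 0,
) -> tuple[ModelBundle, list[ScanVolume]]:
    """Train the full four-network bundle on a set of raw scans.

    Order: preprocess; train the dual U-Nets; mine mimics on these same
    training scans with the combined stage-1 prediction at the mimic
    threshold; train the dual CNNs on positives + mimics + negatives.
    Returns the bundle, the preprocessed training scans, and the mined
    mimic set (one coordinate list per training scan).
    """
    vols, masks, gts = zip(*data)
    pre = [preprocess_for_pipeline(v, m, cfg) for v, m in zip(vols, masks)]

    s1_patches = build_stage1_training_set(list(pre), list(gts), list(masks), cfg, seed)
    unets = tuple(
        train_model(build_unet(c), s1_patches) for c in unet_cfgs
    )

    mimics = mine_mimics(
        unets, list(pre), list(gts),
        threshold=cfg.mimic_threshold, stride=cfg.stride,
        tolerance_mm=cfg.tolerance_mm,
    )
    s2_patches = build_stage2_training_set(list(pre), list(gts), mimics, cfg, seed + 1)
    cnns = tuple(train_model(build_cnn(c), s2_patches) for c in cnn_cfgs)
    return ModelBundle(unets=unets, cnns=cnns), pre, mimics


def make_lotcv_folds(n_scans: int, seed: int) -> list[CVFold]:
    """Seeded random partition into folds of two validation scans each
    (the last fold holds one scan if the count is odd)."""
    if n_scans < 3:
        raise ValueError("leave-two-out cross-validation needs at least 3 scans")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n_scans)
    folds = []
    for start in range(0, n_scans, 2):
        val = tuple(int(i) for i in order[start : start + 2])
        train = tuple(int(i) for i in order if int(i) not in val)
        folds.append(CVFold(train_indices=train, val_indices=val))
    return folds


@dataclass
class CVResult:
    folds: list[CVFold]
    per_fold: list[EvalResult]
    pooled: EvalResult
    match_results: list[MatchResult]
    # per fold: the scan indices whose voxels fed training and whose
    # prediction maps fed mimic mining (always the fold's train indices)
    mimic_source_indices: list[tuple[int, ...]]
    mimics_per_fold: list[MimicSet]


def run_cv(
    data: list[tuple[ScanVolume, BrainMask, GroundTruth]],
    cfg: PipelineConfig,
    unet_cfgs: tuple[NetConfig, NetConfig],
    cnn_cfgs: tuple[NetConfig, NetConfig],
    seed: int = 0,
) -> CVResult:
    """Leave-two-out cross-validation of the whole two-stage detector.

    For each fold the four networks are trained from scratch on the
    training scans only (including mimic mining), then applied to the two
    held-out scans. Per-scan match results are pooled across folds; by
    construction pooled TP+FN equals the total annotation count.
    """
    folds = make_lotcv_folds(len(data), seed)
    all_matches: list[MatchResult] = []
    per_fold: list[EvalResult] = []
    mimic_sources: list[tuple[int, ...]] = []
    mimics_per_fold: list[MimicSet] = []
    for k, fold in enumerate(folds):
        assert set(fold.train_indices).isdisjoint(fold.val_indices)
        train_data = [data[i] for i in fold.train_indices]
        bundle, _, mimics = train_two_stage(
            train_data, cfg, unet_cfgs, cnn_cfgs, seed=seed + 31 * k
        )
        assert len(mimics.per_scan) == len(fold.train_indices)
        mimic_sources.append(fold.train_indices)
        mimics_per_fold.append(mimics)
        fold_matches = []
        for i in fold.val_indices:
            vol, mask, gt = data[i]
            dets = run_pipeline(vol, mask, bundle, cfg)
            fold_matches.append(
                match_detections(dets, gt, cfg.tolerance_mm, vol.voxel_spacing)
            )
        per_fold.append(aggregate(fold_matches))
        all_matches.extend(fold_matches)
    return CVResult(
        folds, per_fold, aggregate(all_matches), all_matches,
        mimic_sources, mimics_per_fold,
    )


def write_detections(dets: list[Detection], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x\ty\tz\tstage1_score\tstage2_score\n")
        for d in dets:
            x, y, z = d.coordinate
            fh.write(f"{x}\t{y}\t{z}\t{d.stage1_score!r}\t{d.stage2_score!r}\n")


def read_detections(path: str | Path) -> list[Detection]:
    out: list[Detection] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            x, y, z, s1, s2 = line.strip().split("\t")
            out.append(Detection((int(x), int(y), int(z)), float(s1), float(s2)))
    return out
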