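"""Stage-1 U-Net and stage-2 CNN: construction, training, inference,
serialization, and hard-negative ("mimic") mining.

The detector deliberately trains *two* copies of each network that differ
only in batch size (20 and 30) and initialization; their predictions are
combined downstream, which recovers lesions that one copy misses.

Mimic mining is the bridge between the stages: the trained U-Net pair is
run over training scans, candidates are extracted from the combined
prediction at a permissive threshold (0.15), and every candidate that
does not correspond to a true lesion is recorded as a hard negative for
the discrimination CNN.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np

from .nn import CNN3D, UNet3D, Adam, BatchNorm, bce_with_logits
from .patching import (
    DEFAULT_STRIDE,
    DEFAULT_WINDOW,
    Patch,
    PredictionVolume,
    enumerate_windows,
    extract_candidates,
    stitch_predictions,
)
from .synthetic import GroundTruth
from .volume import ScanVolume

__all__ = [
    "NetConfig",
    "TrainedModel",
    "MimicSet",
    "build_unet",
    "build_cnn",
    "train_model",
    "predict_volume",
    "mine_mimics",
    "filter_false_positives",
    "save_model",
    "load_model",
    "dual_configs",
]


@dataclass(frozen=True)
class NetConfig:
    """Hyper-parameters for one network.

    ``batch_size`` 20/30 are the canonical dual-ensemble presets; other
    values are allowed for reduced test configurations. ``pos_weight``
    scales the positive-voxel loss term of the U-Net against the heavy
    class imbalance (well over 99% of voxels are background); ``None``
    derives it from the training targets.
    """

    window_shape: tuple[int, int, int] = DEFAULT_WINDOW
    base_filters: int = 16
    depth: int = 3
    batch_size: int = 20
    epochs: int = 10
    learning_rate: float = 1e-3
    seed: int = 0
    loss_name: str = "bce"
    pos_weight: float | None = None

    def __post_init__(self) -> None:
        if self.depth != 3:
            raise ValueError("only depth-3 U-Nets are supported")
        if any(w % 2 ** (self.depth - 1) for w in self.window_shape):
            raise ValueError(
                f"window {self.window_shape} not divisible by {2 ** (self.depth - 1)}"
            )
        if self.batch_size < 1 or self.epochs < 0 or self.learning_rate <= 0:
            raise ValueError("invalid batch_size/epochs/learning_rate")


@dataclass
class TrainedModel:
    """A (possibly untrained) network plus its config and history."""

    kind: str  # "unet" | "cnn"
    net: UNet3D | CNN3D
    config: NetConfig
    history: list[dict] = field(default_factory=list)

    def predict_patches(self, x: np.ndarray, chunk: int = 64) -> np.ndarray:
        """Eval-mode forward pass over ``(N, X, Y, Z, 1)`` blocks, chunked."""
        outs = [self.net.predict(x[i : i + chunk]) for i in range(0, len(x), chunk)]
        return np.concatenate(outs, axis=0)


@dataclass
class MimicSet:
    """Per-scan stage-1 false-positive coordinates (hard negatives)."""

    per_scan: list[list[tuple[int, int, int]]]

    @property
    def total(self) -> int:
        return sum(len(s) for s in self.per_scan)


def dual_configs(
    base_filters: int,
    epochs: int,
    seed: int,
    window_shape: tuple[int, int, int] = DEFAULT_WINDOW,
    learning_rate: float = 1e-3,
) -> tuple[NetConfig, NetConfig]:
    """The canonical pair: identical nets trained with batch sizes 20 and 30."""
    common = dict(
        window_shape=window_shape,
        base_filters=base_filters,
        epochs=epochs,
        learning_rate=learning_rate,
    )
    return (
        NetConfig(batch_size=20, seed=seed, **common),
        NetConfig(batch_size=30, seed=seed + 1, **common),
    )


def build_unet(cfg: NetConfig) -> TrainedModel:
    return TrainedModel("unet", UNet3D(cfg.base_filters, seed=cfg.seed), cfg)


def build_cnn(cfg: NetConfig) -> TrainedModel:
    return TrainedModel(
        "cnn", CNN3D(cfg.base_filters, seed=cfg.seed, window=cfg.window_shape), cfg
    )


def _training_arrays(model: TrainedModel, patches: list[Patch]):
    x = np.stack([p.intensities for p in patches])[..., None].astype(np.float32)
    labels = np.array([p.label for p in patches], dtype=np.float32)
    if labels.min() == labels.max():
        raise ValueError("training set contains a single class; need both")
    if model.kind == "unet":
        missing = [i for i, p in enumerate(patches) if p.target is None]
        if missing:
            raise ValueError(f"U-Net patches without voxel targets: {missing[:5]}")
        y = np.stack([p.target for p in patches])[..., None].astype(np.float32)
    else:
        y = labels
    return x, y, labels


def train_model(model: TrainedModel, patches: list[Patch], cfg: NetConfig | None = None) -> TrainedModel:
    """Seeded minibatch training with Adam on weighted BCE-with-logits.

    For the U-Net the loss is voxel-wise with a positive-class weight
    (derived from the target imbalance unless set in the config); for the
    CNN it is the plain patch-level BCE. Data order, initialization and
    hence final parameters are fully determined by the config seed.
    """
    cfg = cfg or model.config
    x, y, labels = _training_arrays(model, patches)
    if model.kind == "unet":
        pos = float(y.sum())
        if cfg.pos_weight is not None:
            pw = cfg.pos_weight
        else:
            pw = min((y.size - pos) / max(pos, 1.0), 12.0)
    else:
        pw = cfg.pos_weight if cfg.pos_weight is not None else 1.0

    opt = Adam(model.net.params(), lr=cfg.learning_rate)
    rng = np.random.default_rng(cfg.seed)
    n = len(patches)
    for epoch in range(cfg.epochs):
        order = rng.permutation(n)
        losses = []
        correct = 0
        total = 0
        for start in range(0, n, cfg.batch_size):
            idx = order[start : start + cfg.batch_size]
            logits = model.net.forward(x[idx], train=True)
            if model.kind == "unet":
                yb = y[idx]
            else:
                yb = y[idx]
            loss, grad = bce_with_logits(logits, yb, pos_weight=pw)
            model.net.backward(grad)
            opt.step(model.net.grads())
            losses.append(loss)
            pred = (logits > 0).astype(np.float32)
            correct += float((pred == yb).sum())
            total += yb.size
        model.history.append(
            {"epoch": epoch, "loss": float(np.mean(losses)), "accuracy": correct / total}
        )
    return model


def predict_volume(
    model: TrainedModel,
    vol: ScanVolume,
    stride: int = DEFAULT_STRIDE,
    chunk: int = 64,
) -> PredictionVolume:
    """Sliding-window U-Net inference over a preprocessed scan.

    Windows of the config's window shape are enumerated with the given
    stride, each is pushed through the net, and the per-window probability
    maps are stitched (mean over overlaps) into a scan-shaped volume.
    """
    if model.kind != "unet":
        raise ValueError("predict_volume requires a U-Net model")
    window = model.config.window_shape
    if any(n < w for n, w in zip(vol.shape, window)):
        raise ValueError(f"volume {vol.shape} smaller than window {window}")
    origins = enumerate_windows(vol.shape, window, stride)
    data = vol.intensities.astype(np.float32)
    preds: list[tuple[tuple[int, int, int], np.ndarray]] = []
    for start in range(0, len(origins), chunk):
        batch_orig = origins[start : start + chunk]
        blocks = np.stack(
            [
                data[o[0] : o[0] + window[0], o[1] : o[1] + window[1], o[2] : o[2] + window[2]]
                for o in batch_orig
            ]
        )[..., None]
        probs = model.net.predict(blocks)[..., 0]
        preds.extend(zip(batch_orig, probs))
    return stitch_predictions(preds, vol.shape, provenance=f"unet(bs={model.config.batch_size})")


def filter_false_positives(
    candidates,
    gt: GroundTruth,
    spacing: tuple[float, float, float],
    tolerance_mm: float = 5.0,
) -> list[tuple[int, int, int]]:
    """Keep only candidates farther than ``tolerance_mm`` (in physical
    units) from every true lesion center.

    Both the centroid and (when present) the peak-probability voxel must
    clear the tolerance — a merged component whose peak sits on a lesion
    must never be recorded as a hard negative. The returned coordinate
    is the peak when available, since that is where the discrimination
    window will be centered.
    """
    sp = np.asarray(spacing)
    centers = np.asarray(gt.cmb_centers, dtype=float).reshape(-1, 3)
    out = []
    for c in candidates:
        coord = c.coordinate if hasattr(c, "coordinate") else tuple(c)
        peak = getattr(c, "peak", None) or tuple(coord)
        if centers.size:
            d = min(
                np.sqrt((((centers - pos) * sp) ** 2).sum(axis=1)).min()
                for pos in (coord, peak)
            )
            if d <= tolerance_mm:
                continue
        out.append(tuple(peak))
    return out


def mine_mimics(
    unet_pair: tuple[TrainedModel, TrainedModel],
    scans: list[ScanVolume],
    gts: list[GroundTruth],
    threshold: float = 0.15,
    stride: int = DEFAULT_STRIDE,
    tolerance_mm: float = 5.0,
) -> MimicSet:
    """Collect stage-1 false positives as hard negatives, per scan.

    The combined U-Net prediction of each (preprocessed) scan is
    thresholded permissively; candidates within ``tolerance_mm`` of a true
    lesion center are discarded, everything else is a mimic.
    """
    from .pipeline import combine_predictions  # avoid a module cycle

    per_scan: list[list[tuple[int, int, int]]] = []
    for vol, gt in zip(scans, gts):
        p1 = predict_volume(unet_pair[0], vol, stride)
        p2 = predict_volume(unet_pair[1], vol, stride)
        combined = combine_predictions(p1, p2)
        cands = extract_candidates(combined, threshold)
        per_scan.append(
            filter_false_positives(cands, gt, vol.voxel_spacing, tolerance_mm)
        )
    return MimicSet(per_scan)


def _net_state(net) -> list[np.ndarray]:
    arrays = list(net.params())
    for layer in net._blocks:
        if isinstance(layer, BatchNorm):
            arrays += [layer.running_mean, layer.running_var]
    return arrays


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Serialize parameters, batch-norm statistics, config and history."""
    arrays = {f"a{i}": a for i, a in enumerate(_net_state(model.net))}
    meta = json.dumps(
        {"kind": model.kind, "config": asdict(model.config), "history": model.history}
    )
    np.savez(path, meta=np.frombuffer(meta.encode(), dtype=np.uint8), **arrays)


def load_model(path: str | Path) -> TrainedModel:
    """Rebuild a model; round-trip predictions are bit-identical."""
    path = Path(path)
    if not path.exists() and path.with_suffix(path.suffix + ".npz").exists():
        path = path.with_suffix(path.suffix + ".npz")
    with np.load(path) as zf:
        meta = json.loads(bytes(zf["meta"]).decode())
        cfg_d = meta["config"]
        cfg_d["window_shape"] = tuple(cfg_d["window_shape"])
        cfg = NetConfig(**cfg_d)
        model = build_unet(cfg) if meta["kind"] == "unet" else build_cnn(cfg)
        model.history = meta["history"]
        state = _net_state(model.net)
        for i, target in enumerate(state):
            target[...] = zf[f"a{i}"]
    return model
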