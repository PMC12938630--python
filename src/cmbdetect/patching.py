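"""Sliding windows, patch extraction, prediction stitching, candidates,
and training-patch augmentation.

The detector never sees a whole scan at once: a 20x20x16-voxel window
slides over the volume with stride 3 per axis, the per-window network
outputs are stitched back into a full-scan probability volume by
averaging overlaps, and candidate lesions are the 26-connected components
above a probability threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product
from pathlib import Path

import numpy as np
from scipy import ndimage
from skimage.measure import label as cc_label

from .synthetic import GroundTruth
from .volume import ScanVolume

__all__ = [
    "DEFAULT_WINDOW",
    "DEFAULT_STRIDE",
    "Patch",
    "PredictionVolume",
    "Candidate",
    "enumerate_windows",
    "extract_patch",
    "stitch_predictions",
    "extract_candidates",
    "augment_patch",
    "sample_training_patches",
    "write_candidates",
    "read_candidates",
]

DEFAULT_WINDOW: tuple[int, int, int] = (20, 20, 16)
DEFAULT_STRIDE: int = 3


@dataclass
class Patch:
    """A window-shaped intensity block cut from a scan.

    ``origin`` is the minimum-corner voxel coordinate; ``center`` is
    ``origin + window//2``. ``label`` (0/1) marks negative/positive
    training patches; ``target`` optionally carries the voxel-wise
    segmentation target for U-Net training; ``source`` keeps a reference
    to the scan the patch came from so shift augmentations can be
    re-extracted instead of padded.
    """

    intensities: np.ndarray
    origin: tuple[int, int, int]
    label: int | None = None
    target: np.ndarray | None = None
    source: ScanVolume | None = field(default=None, repr=False)

    @property
    def center(self) -> tuple[int, int, int]:
        return tuple(o + s // 2 for o, s in zip(self.origin, self.intensities.shape))


@dataclass
class PredictionVolume:
    """Per-voxel CMB probability grid aligned to a scan."""

    probabilities: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        p = np.asarray(self.probabilities, dtype=np.float64)
        if p.ndim != 3:
            raise ValueError("prediction volume must be 3D")
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ValueError("probabilities must lie in [0, 1]")
        self.probabilities = p

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.probabilities.shape  # type: ignore[return-value]


@dataclass(frozen=True)
class Candidate:
    """One suprathreshold connected component.

    ``coordinate`` is the probability-weighted centroid (the reported
    location); ``peak`` is the component's maximum-probability voxel —
    elongated or merged components can place the centroid millimetres
    off the lesion, so the discrimination window is centered on the peak.
    """

    coordinate: tuple[int, int, int]
    score: float
    component_size: int
    peak: tuple[int, int, int] | None = None


def _axis_origins(n: int, w: int, s: int) -> list[int]:
    if w > n:
        raise ValueError(f"window {w} exceeds volume extent {n}")
    origins = list(range(0, n - w + 1, s))
    if origins[-1] != n - w:
        origins.append(n - w)  # clamped final window, no padding
    return origins


def enumerate_windows(
    shape: tuple[int, int, int],
    window: tuple[int, int, int] = DEFAULT_WINDOW,
    stride: int = DEFAULT_STRIDE,
) -> list[tuple[int, int, int]]:
    """All window origins: per-axis arithmetic progression plus a final
    clamped origin, Cartesian product across axes. Every voxel is covered."""
    if stride < 1:
        raise ValueError("stride must be >= 1")
    per_axis = [_axis_origins(n, w, stride) for n, w in zip(shape, window)]
    return list(product(*per_axis))


def extract_patch(
    vol: ScanVolume,
    origin: tuple[int, int, int],
    window: tuple[int, int, int] = DEFAULT_WINDOW,
) -> Patch:
    """Copy the window-shaped sub-block starting at ``origin``."""
    for o, w, n in zip(origin, window, vol.shape):
        if o < 0 or o + w > n:
            raise ValueError(f"origin {origin} + window {window} exceeds shape {vol.shape}")
    sl = tuple(slice(o, o + w) for o, w in zip(origin, window))
    return Patch(vol.intensities[sl].copy(), tuple(origin), source=vol)


def stitch_predictions(
    window_preds: list[tuple[tuple[int, int, int], np.ndarray]],
    shape: tuple[int, int, int],
    provenance: str = "",
) -> PredictionVolume:
    """Overlay per-window predictions into a full volume.

    Each voxel becomes the arithmetic mean of every window prediction
    covering it; voxels covered by no window stay 0.
    """
    acc = np.zeros(shape)
    cnt = np.zeros(shape)
    for origin, block in window_preds:
        block = np.asarray(block)
        sl = tuple(slice(o, o + w) for o, w in zip(origin, block.shape))
        if any(s.stop > n for s, n in zip(sl, shape)):
            raise ValueError(f"block at {origin} with shape {block.shape} exceeds {shape}")
        acc[sl] += block
        cnt[sl] += 1
    out = np.divide(acc, cnt, out=np.zeros(shape), where=cnt > 0)
    return PredictionVolume(out, provenance=provenance)


def extract_candidates(pred: PredictionVolume, threshold: float) -> list[Candidate]:
    """26-connected components of ``p >= threshold``; one candidate per
    component at its probability-weighted centroid, scored by the
    component's maximum probability."""
    if not (0 < threshold < 1):
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    binary = pred.probabilities >= threshold
    if not binary.any():
        return []
    labels = cc_label(binary, connectivity=3)  # 26-connectivity in 3D
    out: list[Candidate] = []
    idx = range(1, labels.max() + 1)
    centroids = ndimage.center_of_mass(pred.probabilities, labels, index=idx)
    maxima = ndimage.maximum(pred.probabilities, labels, index=idx)
    peaks = ndimage.maximum_position(pred.probabilities, labels, index=idx)
    sizes = ndimage.sum_labels(binary, labels, index=idx)
    for com, mx, pk, sz in zip(
        np.atleast_2d(centroids), np.atleast_1d(maxima), np.atleast_2d(peaks), np.atleast_1d(sizes)
    ):
        coord = tuple(
            int(np.clip(round(c), 0, n - 1)) for c, n in zip(com, pred.shape)
        )
        out.append(
            Candidate(
                coordinate=coord,
                score=float(mx),
                component_size=int(sz),
                peak=tuple(int(v) for v in pk),
            )
        )
    return out


def _inplane_flip(arr: np.ndarray, axis: int) -> np.ndarray:
    return np.flip(arr, axis=axis).copy()


def _inplane_rot(arr: np.ndarray, k: int) -> np.ndarray:
    # rotate in the x-y plane; z (slices) untouched
    return np.rot90(arr, k=k, axes=(0, 1)).copy()


def augment_patch(p: Patch, shifts: tuple[int, ...] = (1,)) -> list[Patch]:
    """Deterministic augmentation set for a labeled training patch.

    In-plane flips along x and y, in-plane +-90 degree rotations, and
    small shifts along each axis re-extracted from the source volume (so
    the lesion stays near the center and no intensities are fabricated).
    With the default single-voxel shifts an interior patch yields
    1 + 2 + 2 + 6 = 11 patches, original included; ``shifts=(1, 2)``
    adds the two-voxel shifts (17 patches). Shifts that would leave the
    volume are skipped.
    """
    if p.intensities.shape[0] != p.intensities.shape[1]:
        raise ValueError("in-plane rotation requires a square in-plane window")
    window = p.intensities.shape

    def mk(arr: np.ndarray, target: np.ndarray | None, origin=p.origin) -> Patch:
        return Patch(arr, tuple(origin), label=p.label, target=target, source=p.source)

    out = [mk(p.intensities.copy(), None if p.target is None else p.target.copy())]
    for ax in (0, 1):
        out.append(
            mk(
                _inplane_flip(p.intensities, ax),
                None if p.target is None else _inplane_flip(p.target, ax),
            )
        )
    for k in (1, 3):
        out.append(
            mk(
                _inplane_rot(p.intensities, k),
                None if p.target is None else _inplane_rot(p.target, k),
            )
        )
    if p.source is not None:
        for axis in range(3):
            for mag in shifts:
                for delta in (-mag, mag):
                    origin = list(p.origin)
                    origin[axis] += delta
                    if origin[axis] < 0 or origin[axis] + window[axis] > p.source.shape[axis]:
                        continue  # shift would exceed the volume; skipped
                    shifted = extract_patch(p.source, tuple(origin), window)
                    target = None
                    if p.target is not None:
                        # the window moved; the target (defined in volume
                        # space) shifts the opposite way in the patch frame
                        target = np.roll(p.target, -delta, axis=axis)
                        edge = [slice(None)] * 3
                        edge[axis] = (
                            slice(-mag, None) if delta > 0 else slice(0, mag)
                        )
                        target[tuple(edge)] = 0
                    out.append(mk(shifted.intensities, target, origin=tuple(origin)))
    return out


def _clamped_origin(
    center: tuple[int, int, int],
    window: tuple[int, int, int],
    shape: tuple[int, int, int],
) -> tuple[int, int, int]:
    return tuple(
        int(np.clip(c - w // 2, 0, n - w)) for c, w, n in zip(center, window, shape)
    )


def _sphere_target(
    origin: tuple[int, int, int],
    window: tuple[int, int, int],
    centers: list[tuple[int, int, int]],
    radii_mm: list[float],
    spacing: tuple[float, float, float],
) -> np.ndarray:
    """Voxel-label target: 1 inside any annotated sphere, clipped to the patch."""
    grids = np.meshgrid(*[np.arange(o, o + w) for o, w in zip(origin, window)], indexing="ij")
    target = np.zeros(window)
    for c, r in zip(centers, radii_mm):
        d2 = sum(((g - cc) * s) ** 2 for g, cc, s in zip(grids, c, spacing))
        target[d2 <= r**2] = 1.0
    return target


def sample_training_patches(
    vol: ScanVolume,
    gt: GroundTruth,
    n_negatives: int,
    seed: int,
    window: tuple[int, int, int] = DEFAULT_WINDOW,
    margin_mm: float = 10.0,
    mask: np.ndarray | None = None,
) -> list[Patch]:
    """One positive patch per annotated CMB plus random safe negatives.

    Positives are centered on each CMB (window clamped at the border) and
    carry a sphere-of-annotated-radius voxel target. Negatives are drawn
    at random in-mask voxels whose (clamped) window centers lie at least
    ``margin_mm`` from every CMB center. In small, lesion-dense brains
    the requested margin can exclude the entire mask; the sampler then
    relaxes it stepwise, but never below 5.5 mm (just beyond the 5 mm
    match tolerance) so negatives remain true negatives.
    """
    rng = np.random.default_rng(seed)
    spacing = tuple(vol.voxel_spacing)
    patches: list[Patch] = []
    for c in gt.cmb_centers:
        origin = _clamped_origin(c, window, vol.shape)
        p = extract_patch(vol, origin, window)
        p.label = 1
        p.target = _sphere_target(origin, window, gt.cmb_centers, gt.cmb_radii, spacing)
        patches.append(p)

    in_mask = mask if mask is not None else vol.intensities > 0
    coords = np.argwhere(in_mask)
    if coords.shape[0] == 0:
        raise ValueError("cannot place negatives: empty mask")
    # half the negatives target vessel voxels (the dominant mimic) when
    # ground truth records any; the rest are uniform in-mask draws
    vessel_coords = (
        np.asarray(sorted(gt.vessel_voxel_set)) if gt.vessel_voxel_set else None
    )
    centers_arr = np.asarray(gt.cmb_centers, dtype=float).reshape(-1, 3)
    sp = np.asarray(spacing)

    def place_at(margin: float) -> list[Patch] | None:
        out: list[Patch] = []
        for attempt in range(200 * max(n_negatives, 1)):
            if len(out) >= n_negatives:
                return out
            if vessel_coords is not None and attempt % 2 == 0:
                c = vessel_coords[rng.integers(0, vessel_coords.shape[0])]
            else:
                c = coords[rng.integers(0, coords.shape[0])]
            origin = _clamped_origin(tuple(int(v) for v in c), window, vol.shape)
            # margin is enforced on the effective (clamped) window center
            c_eff = np.asarray(origin) + np.asarray(window) // 2
            if centers_arr.size:
                d = np.sqrt((((centers_arr - c_eff) * sp) ** 2).sum(axis=1)).min()
                if d < margin:
                    continue
            p = extract_patch(vol, origin, window)
            p.label = 0
            # honest voxel target: annotated spheres are marked even if
            # one grazes the window edge (normally all zero)
            p.target = _sphere_target(
                origin, window, gt.cmb_centers, gt.cmb_radii, spacing
            )
            out.append(p)
        return out if len(out) >= n_negatives else None

    floor = min(margin_mm, 5.5)
    margin = margin_mm
    margins = []
    while margin > floor:
        margins.append(margin)
        margin *= 0.75
    margins.append(floor)
    negatives = None
    for margin in margins:
        negatives = place_at(margin)
        if negatives is not None:
            break
    if negatives is None:
        raise ValueError(
            f"could not place {n_negatives} negatives even at the "
            f"{floor:.1f} mm margin floor (mask too small or too crowded)"
        )
    return patches + negatives


def write_candidates(cands: list[Candidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("x\ty\tz\tscore\tsize\n")
        for c in cands:
            x, y, z = c.coordinate
            fh.write(f"{x}\t{y}\t{z}\t{c.score!r}\t{c.component_size}\n")


def read_candidates(path: str | Path) -> list[Candidate]:
    out: list[Candidate] = []
    with open(path) as fh:
        fh.readline()
        for line in fh:
            if not line.strip():
                continue
            x, y, z, score, size = line.strip().split("\t")
            out.append(Candidate((int(x), int(y), int(z)), float(score), int(size)))
    return out
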