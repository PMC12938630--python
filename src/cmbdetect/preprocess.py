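"""Preprocessing: brain masking, bias correction, histogram-peak normalization.

The normalization is the anchor of the whole pipeline: after detecting the
modal intensity ``h_p`` of the strictly-positive voxels, every intensity is
mapped ``i -> i / (2 * h_p)``, so the tissue peak lands at 0.5 regardless
of scanner scaling. Values above 1 are deliberately not clipped — the
bright rim around a microbleed is a discriminative feature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .volume import BrainMask, ScanVolume

__all__ = [
    "HistogramPeak",
    "PreprocessConfig",
    "apply_brain_mask",
    "correct_bias",
    "find_histogram_peak",
    "normalize_intensity",
    "preprocess_scan",
]


@dataclass(frozen=True)
class HistogramPeak:
    """Modal bin of the positive-intensity histogram (``h_p``)."""

    value: float
    bin_width: float
    n_bins: int

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"histogram peak must be positive, got {self.value}")


@dataclass(frozen=True)
class PreprocessConfig:
    n_bins: int = 256
    bias_basis_order: int = 2
    skip_bias: bool = False


def apply_brain_mask(vol: ScanVolume, mask: BrainMask) -> ScanVolume:
    """Zero every voxel outside the mask; in-mask voxels are untouched."""
    if vol.shape != mask.shape:
        raise ValueError(f"volume shape {vol.shape} != mask shape {mask.shape}")
    return ScanVolume(np.where(mask.mask, vol.intensities, 0.0), vol.voxel_spacing)


def _cosine_design(shape: tuple[int, int, int], order: int, idx: np.ndarray) -> np.ndarray:
    """Separable cosine basis evaluated at the voxels in ``idx`` (N x 3)."""
    coords = idx / (np.asarray(shape) - 1)  # normalized to [0, 1]
    cols = []
    for kx in range(order + 1):
        for ky in range(order + 1):
            for kz in range(order + 1):
                cols.append(
                    np.cos(np.pi * kx * coords[:, 0])
                    * np.cos(np.pi * ky * coords[:, 1])
                    * np.cos(np.pi * kz * coords[:, 2])
                )
    return np.stack(cols, axis=1)


def correct_bias(
    vol: ScanVolume,
    mask: BrainMask,
    basis_order: int = 2,
    max_fit_voxels: int = 30000,
    seed: int = 0,
) -> tuple[ScanVolume, np.ndarray]:
    """Estimate and divide out a smooth multiplicative gain field.

    The log of the in-mask positive intensities is regressed against a
    low-order separable cosine basis by least squares; the exponentiated
    fit, mean-normalized inside the mask, is the estimated field. The fit
    uses only voxels within a band around the median intensity (and a
    random subsample for speed), so focal structures — lesions, vessels —
    do not drag the smooth field toward themselves. The corrected volume
    preserves the arithmetic mean intensity inside the mask.

    Returns the corrected volume and the estimated field (1 outside mask).
    """
    if basis_order < 1 or basis_order > 3:
        raise ValueError("basis_order must be in 1..3")
    if vol.shape != mask.shape:
        raise ValueError("volume/mask shape mismatch")
    data = vol.intensities
    inside = mask.mask & (data > 0)
    n_params = (basis_order + 1) ** 3
    idx_all = np.argwhere(inside)
    if idx_all.shape[0] < 10 * n_params:
        raise ValueError(
            f"mask has {idx_all.shape[0]} usable voxels, too few to fit "
            f"{n_params} basis coefficients"
        )
    # tissue band: within a factor 1.5 of the median intensity
    med = np.median(data[inside])
    in_band = inside & (data >= med / 1.5) & (data <= med * 1.5)
    idx_fit = np.argwhere(in_band)
    if idx_fit.shape[0] < 10 * n_params:
        idx_fit = idx_all
    rng = np.random.default_rng(seed)
    if idx_fit.shape[0] > max_fit_voxels:
        sel = rng.choice(idx_fit.shape[0], size=max_fit_voxels, replace=False)
        idx_fit = idx_fit[np.sort(sel)]
    X = _cosine_design(vol.shape, basis_order, idx_fit.astype(float))
    y = np.log(data[tuple(idx_fit.T)])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)

    X_all = _cosine_design(vol.shape, basis_order, idx_all.astype(float))
    log_field = X_all @ coef
    field_in = np.exp(log_field - log_field.mean())  # strictly positive

    field = np.ones(vol.shape)
    field[tuple(idx_all.T)] = field_in
    corrected = data.copy()
    corrected[tuple(idx_all.T)] = data[tuple(idx_all.T)] / field_in
    # preserve the arithmetic mean inside the mask
    before = data[mask.mask].mean()
    after = corrected[mask.mask].mean()
    if after > 0:
        corrected[mask.mask] *= before / after
    return ScanVolume(np.clip(corrected, 0.0, None), vol.voxel_spacing), field


def find_histogram_peak(vol: ScanVolume, n_bins: int = 256) -> HistogramPeak:
    """Locate ``h_p``: the modal bin center over strictly-positive voxels.

    Zero background is excluded from the histogram; ties break toward the
    lower bin.
    """
    positive = vol.intensities[vol.intensities > 0]
    if positive.size == 0:
        raise ValueError("volume has no positive intensities; cannot find h_p")
    counts, edges = np.histogram(positive, bins=n_bins, range=(0.0, positive.max()))
    mode = int(np.argmax(counts))  # argmax returns the first (lower) modal bin
    width = edges[1] - edges[0]
    return HistogramPeak(value=float(edges[mode] + width / 2), bin_width=float(width), n_bins=n_bins)


def normalize_intensity(vol: ScanVolume, h_p: HistogramPeak) -> ScanVolume:
    """Linear map ``i -> i / (2 * h_p)``; the histogram peak moves to 0.5."""
    return ScanVolume(vol.intensities / (2.0 * h_p.value), vol.voxel_spacing)


def preprocess_scan(
    vol: ScanVolume,
    mask: BrainMask,
    config: PreprocessConfig | None = None,
) -> ScanVolume:
    """Mask, bias-correct, and peak-normalize a scan, in that order.

    A config with ``skip_bias=True`` accepts volumes that were already
    bias-corrected externally (e.g. by N4).
    """
    cfg = config or PreprocessConfig()
    out = apply_brain_mask(vol, mask)
    if not cfg.skip_bias:
        out, _ = correct_bias(out, mask, basis_order=cfg.bias_basis_order)
    peak = find_histogram_peak(out, n_bins=cfg.n_bins)
    return normalize_intensity(out, peak)
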