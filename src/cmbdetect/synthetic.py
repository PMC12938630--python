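"""SWI-like phantom generator with ground-truth microbleed annotations.

Real susceptibility-weighted scans of microbleed cohorts are rarely
shareable, so every stage of the detection pipeline is developed against
synthetic volumes that reproduce the *qualitative* reading criteria for
cerebral microbleeds (CMBs):

* a CMB is a 2-10 mm round/ovoid hypointense focus, often surrounded by a
  thin bright (less paramagnetic) rim;
* its main mimic, a venous vessel, is a hypointense tube that stays
  visible across many consecutive slices, whereas a CMB is confined to a
  few;
* scans carry a smooth multiplicative gain (bias) field and noise, and
  everything outside the brain mask is exactly zero.

No susceptibility physics is simulated; intensities are in arbitrary
units and only the geometry/contrast relations above are guaranteed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .volume import BrainMask, ScanVolume

__all__ = [
    "PhantomSpec",
    "GroundTruth",
    "PlacementError",
    "generate_phantom",
    "generate_dataset",
    "write_annotations",
    "read_annotations",
]


class PlacementError(RuntimeError):
    """Raised when a lesion or vessel cannot be placed inside the brain."""


@dataclass(frozen=True)
class PhantomSpec:
    """Full parameterization of one synthetic scan.

    Attributes
    ----------
    grid_shape
        Voxels per axis ``(nx, ny, nz)``; z is the slice axis. Must be at
        least the analysis window (20, 20, 16) per axis.
    voxel_spacing
        mm per voxel per axis.
    n_cmbs
        Number of microbleeds to place.
    cmb_diameter_range
        Closed interval of CMB diameters in mm; must stay inside the
        clinical 2-10 mm band. The default upper end (6 mm) is sized to
        the reduced default grid so several lesions fit without touching.
    cmb_contrast
        Fractional intensity drop of the CMB core versus tissue, in (0, 1].
    rim_gain
        Fractional intensity rise of the bright 1-2 voxel shell around a
        CMB versus tissue, >= 0.
    n_vessels
        Number of tubular vessel mimics.
    vessel_radius_range
        Tube radius interval in mm.
    tissue_mean
        Mean tissue intensity, arbitrary units.
    noise_sd
        Standard deviation of additive Gaussian noise, same units.
    bias_amplitude
        Peak-to-trough fractional modulation of the multiplicative bias
        field (0 disables it).
    seed
        Seed controlling every random draw; identical specs reproduce
        bit-identical phantoms.
    """

    grid_shape: tuple[int, int, int] = (64, 64, 48)
    voxel_spacing: tuple[float, float, float] = (0.5, 0.5, 1.0)
    n_cmbs: int = 5
    cmb_diameter_range: tuple[float, float] = (2.0, 6.0)
    cmb_contrast: float = 0.6
    rim_gain: float = 0.3
    n_vessels: int = 3
    vessel_radius_range: tuple[float, float] = (0.5, 1.5)
    tissue_mean: float = 100.0
    noise_sd: float = 4.0
    bias_amplitude: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if any(g < w for g, w in zip(self.grid_shape, (20, 20, 16))):
            raise ValueError(
                f"grid_shape {self.grid_shape} smaller than the 20x20x16 analysis window"
            )
        lo, hi = self.cmb_diameter_range
        if not (0 < lo <= hi):
            raise ValueError(f"invalid cmb_diameter_range {self.cmb_diameter_range}")
        if not (0 < self.cmb_contrast <= 1):
            raise ValueError(f"cmb_contrast must be in (0, 1], got {self.cmb_contrast}")
        if self.rim_gain < 0 or self.noise_sd < 0 or self.bias_amplitude < 0:
            raise ValueError("rim_gain, noise_sd and bias_amplitude must be >= 0")
        if self.n_cmbs < 0 or self.n_vessels < 0:
            raise ValueError("counts must be >= 0")


@dataclass
class GroundTruth:
    """Voxel-level truth for one phantom.

    ``cmb_centers`` are 0-based integer voxel coordinates (x, y, z);
    ``cmb_radii`` are in mm and aligned with the centers;
    ``vessel_voxel_set`` holds every voxel occupied by a vessel tube.
    """

    cmb_centers: list[tuple[int, int, int]] = field(default_factory=list)
    cmb_radii: list[float] = field(default_factory=list)
    vessel_voxel_set: set[tuple[int, int, int]] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.cmb_centers) != len(self.cmb_radii):
            raise ValueError("cmb_centers and cmb_radii must have equal length")


# rim thickness in mm; rendered shell ends up 1-2 voxels thick at
# 0.5-1.0 mm spacing, matching how bright rims appear around CMBs on SWI
_RIM_MM = 1.0


def _ellipsoid_mask(shape: tuple[int, int, int]) -> np.ndarray:
    center = (np.asarray(shape) - 1) / 2.0
    semi = np.asarray(shape) * 0.45
    grids = np.meshgrid(*[np.arange(n) for n in shape], indexing="ij")
    q = sum(((g - c) / s) ** 2 for g, c, s in zip(grids, center, semi))
    return q <= 1.0


def _cosine_bias_field(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Smooth multiplicative field, peak-to-trough = bias_amplitude, mean ~1."""
    if spec.bias_amplitude == 0:
        return np.ones(spec.grid_shape)
    axes = [np.linspace(0.0, 1.0, n) for n in spec.grid_shape]
    raw = np.zeros(spec.grid_shape)
    for kx in range(3):
        for ky in range(3):
            for kz in range(3):
                if kx == ky == kz == 0:
                    continue
                c = rng.normal(0.0, 1.0 / (1 + kx + ky + kz))
                raw = raw + c * np.multiply.outer(
                    np.multiply.outer(
                        np.cos(np.pi * kx * axes[0]), np.cos(np.pi * ky * axes[1])
                    ),
                    np.cos(np.pi * kz * axes[2]),
                )
    lo, hi = raw.min(), raw.max()
    unit = (raw - lo) / (hi - lo)  # in [0, 1]
    return 1.0 + spec.bias_amplitude * (unit - 0.5)


def _walk_vessel(
    spec: PhantomSpec,
    rng: np.random.Generator,
    mask: np.ndarray,
    required_span_mm: float,
) -> tuple[np.ndarray, float] | None:
    """One random-walk centerline (mm coords) spanning required_span_mm in z.

    Returns None if the walk exits the brain before reaching the span.
    """
    spacing = np.asarray(spec.voxel_spacing)
    extent = np.asarray(spec.grid_shape) * spacing
    radius = rng.uniform(*spec.vessel_radius_range)

    # start in the central part of the brain, low z, heading mostly +z
    start = np.array(
        [
            rng.uniform(0.35, 0.65) * extent[0],
            rng.uniform(0.35, 0.65) * extent[1],
            rng.uniform(0.08, 0.25) * extent[2],
        ]
    )
    direction = np.array([rng.normal(0, 0.15), rng.normal(0, 0.15), 1.0])
    direction /= np.linalg.norm(direction)

    step = float(min(spacing))
    points = [start.copy()]
    pos = start.copy()
    max_steps = int(3 * extent[2] / step)
    for _ in range(max_steps):
        # bounded-curvature perturbation, z-component kept dominant
        direction[:2] += rng.normal(0, 0.08, size=2)
        direction[2] = max(direction[2], 0.4)
        direction /= np.linalg.norm(direction)
        pos = pos + direction * step
        vox = pos / spacing
        if np.any(vox < 0) or np.any(vox > np.asarray(spec.grid_shape) - 1):
            break
        points.append(pos.copy())
        if pos[2] - start[2] >= required_span_mm:
            return np.asarray(points), radius
    return None


def _rasterize_tube(
    centerline: np.ndarray,
    radius_mm: float,
    spec: PhantomSpec,
    mask: np.ndarray,
) -> np.ndarray:
    spacing = np.asarray(spec.voxel_spacing)
    occ = np.zeros(spec.grid_shape, dtype=bool)
    half = np.ceil(radius_mm / spacing).astype(int) + 1
    for p in centerline:
        c = p / spacing
        lo = np.maximum(np.floor(c - half).astype(int), 0)
        hi = np.minimum(np.ceil(c + half).astype(int) + 1, np.asarray(spec.grid_shape))
        sub = np.meshgrid(*[np.arange(l, h) for l, h in zip(lo, hi)], indexing="ij")
        d2 = sum(((g - cc) * s) ** 2 for g, cc, s in zip(sub, c, spacing))
        occ[lo[0] : hi[0], lo[1] : hi[1], lo[2] : hi[2]] |= d2 <= radius_mm**2
    return occ & mask


def generate_phantom(spec: PhantomSpec) -> tuple[ScanVolume, BrainMask, GroundTruth]:
    """Render one phantom scan with its mask and ground truth.

    The brain is an ellipsoid of homogeneous tissue. Vessels are drawn
    first; CMB cores and rims are painted last so a CMB center voxel holds
    exactly ``tissue_mean * (1 - cmb_contrast)`` before bias and noise.
    The whole brain is then modulated by the bias field, perturbed by
    additive Gaussian noise (clipped at zero), and masked.
    """
    rng = np.random.default_rng(spec.seed)
    mask = _ellipsoid_mask(spec.grid_shape)
    spacing = np.asarray(spec.voxel_spacing)

    vol = np.where(mask, spec.tissue_mean, 0.0)

    # --- vessels -------------------------------------------------------
    required_span = 3.0 * spec.cmb_diameter_range[1]
    vessel_occ = np.zeros(spec.grid_shape, dtype=bool)
    for i in range(spec.n_vessels):
        tube = None
        for _ in range(60):
            walk = _walk_vessel(spec, rng, mask, required_span)
            if walk is None:
                continue
            centerline, radius = walk
            cand = _rasterize_tube(centerline, radius, spec, mask)
            z_slices = np.unique(np.nonzero(cand)[2])
            if z_slices.size * spec.voxel_spacing[2] > spec.cmb_diameter_range[1]:
                tube = cand
                break
        if tube is None:
            raise PlacementError(
                f"vessel {i}: could not realize a tube spanning "
                f"{required_span:.0f} mm in z inside the brain"
            )
        vessel_occ |= tube
    vol[vessel_occ] = spec.tissue_mean * (1.0 - spec.cmb_contrast)

    # mm distance to the nearest vessel voxel, for CMB placement
    if vessel_occ.any():
        vessel_dist = ndimage.distance_transform_edt(~vessel_occ, sampling=spacing)
    else:
        vessel_dist = np.full(spec.grid_shape, np.inf)

    # mm distance to the mask boundary (inside only)
    inner_dist = ndimage.distance_transform_edt(mask, sampling=spacing)

    # --- CMBs ----------------------------------------------------------
    centers: list[tuple[int, int, int]] = []
    radii: list[float] = []
    grids = np.meshgrid(*[np.arange(n) for n in spec.grid_shape], indexing="ij")
    for i in range(spec.n_cmbs):
        diameter = rng.uniform(*spec.cmb_diameter_range)
        r = diameter / 2.0
        # sample only from voxels where the sphere+rim fits and clears vessels
        need = r + _RIM_MM + 0.5
        admissible = np.argwhere((inner_dist >= need) & (vessel_dist >= need))
        if admissible.shape[0] == 0:
            raise PlacementError(
                f"CMB {i} (radius {r:.1f} mm): no voxel clears the brain "
                "boundary and vessels"
            )
        placed = False
        for _ in range(500):
            c = tuple(int(v) for v in admissible[rng.integers(0, admissible.shape[0])])
            ok = True
            for prev, pr in zip(centers, radii):
                d = np.linalg.norm((np.asarray(c) - np.asarray(prev)) * spacing)
                if d < r + pr + 2 * _RIM_MM:
                    ok = False
                    break
            if not ok:
                continue
            d_mm2 = sum(
                ((g - cc) * s) ** 2 for g, cc, s in zip(grids, c, spacing)
            )
            rim = (d_mm2 > r**2) & (d_mm2 <= (r + _RIM_MM) ** 2)
            core = d_mm2 <= r**2
            vol[rim & mask] = spec.tissue_mean * (1.0 + spec.rim_gain)
            vol[core] = spec.tissue_mean * (1.0 - spec.cmb_contrast)
            centers.append(c)
            radii.append(r)
            placed = True
            break
        if not placed:
            raise PlacementError(
                f"CMB {i} (radius {r:.1f} mm): no admissible center after 500 tries "
                "(brain too small or too crowded)"
            )

    # --- bias, noise, masking -----------------------------------------
    vol = vol * _cosine_bias_field(spec, rng)
    if spec.noise_sd > 0:
        vol = vol + rng.normal(0.0, spec.noise_sd, size=spec.grid_shape)
    vol = np.clip(vol, 0.0, None)
    vol[~mask] = 0.0

    gt = GroundTruth(
        cmb_centers=centers,
        cmb_radii=radii,
        vessel_voxel_set={tuple(idx) for idx in np.argwhere(vessel_occ)},
    )
    return ScanVolume(vol, spec.voxel_spacing), BrainMask(mask), gt


def generate_dataset(
    n_scans: int,
    spec: PhantomSpec,
    seed: int,
    n_cmbs_range: tuple[int, int] | None = None,
    n_vessels_range: tuple[int, int] | None = None,
) -> list[tuple[ScanVolume, BrainMask, GroundTruth]]:
    """Draw a cohort of independent phantoms.

    Each scan gets its own sub-seed derived from ``seed``; optionally the
    CMB and vessel counts are drawn uniformly per scan from the given
    inclusive ranges (emulating cohorts with between 1 and 13 annotated
    lesions per subject).
    """
    if n_scans < 1:
        raise ValueError("n_scans must be >= 1")
    rng = np.random.default_rng(seed)
    sub_seeds = rng.integers(0, 2**31 - 1, size=n_scans)
    out = []
    for s in sub_seeds:
        kwargs: dict = {"seed": int(s)}
        if n_cmbs_range is not None:
            kwargs["n_cmbs"] = int(rng.integers(n_cmbs_range[0], n_cmbs_range[1] + 1))
        if n_vessels_range is not None:
            kwargs["n_vessels"] = int(
                rng.integers(n_vessels_range[0], n_vessels_range[1] + 1)
            )
        out.append(generate_phantom(dataclasses.replace(spec, **kwargs)))
    return out


def write_annotations(gt: GroundTruth, path: str | Path) -> None:
    """Write CMB annotations as TSV with columns x, y, z, radius_mm."""
    with open(path, "w") as fh:
        fh.write("x\ty\tz\tradius_mm\n")
        for (x, y, z), r in zip(gt.cmb_centers, gt.cmb_radii):
            fh.write(f"{x}\t{y}\t{z}\t{r!r}\n")


def read_annotations(path: str | Path) -> GroundTruth:
    """Read a TSV written by :func:`write_annotations` (vessels not stored)."""
    centers: list[tuple[int, int, int]] = []
    radii: list[float] = []
    with open(path) as fh:
        header = fh.readline().strip().split("\t")
        if header != ["x", "y", "z", "radius_mm"]:
            raise ValueError(f"unexpected annotation header {header!r} in {path}")
        for line in fh:
            if not line.strip():
                continue
            x, y, z, r = line.strip().split("\t")
            centers.append((int(x), int(y), int(z)))
            radii.append(float(r))
    return GroundTruth(cmb_centers=centers, cmb_radii=radii)
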