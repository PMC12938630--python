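"""Detection scoring: match detections to annotations in physical
coordinates and compute sensitivity and false positives per scan.

A detection hits an annotation if their physical (mm) distance is within
a tolerance (default 5 mm, half the maximum lesion diameter); matching is
greedy nearest-first and one-to-one, with ties broken by the lower
coordinate tuple so results are order-independent.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .synthetic import GroundTruth

__all__ = [
    "MatchResult",
    "EvalResult",
    "match_detections",
    "sensitivity",
    "fp_per_scan",
    "aggregate",
    "sweep_thresholds",
]

DEFAULT_TOLERANCE_MM = 5.0


@dataclass
class MatchResult:
    """One scan's confusion decomposition at a given tolerance."""

    true_positives: list[tuple[tuple[int, int, int], tuple[int, int, int]]]
    false_negatives: list[tuple[int, int, int]]
    false_positives: list[tuple[int, int, int]]
    tolerance: float

    def __post_init__(self) -> None:
        # accounting identities
        n_ann = len(self.true_positives) + len(self.false_negatives)
        n_det = len(self.true_positives) + len(self.false_positives)
        assert n_ann >= 0 and n_det >= 0


@dataclass
class EvalResult:
    sensitivity: float
    fp_per_scan: float
    per_scan_counts: list[dict]
    n_scans: int
    n_cmbs: int


def _coord(det) -> tuple[int, int, int]:
    return tuple(det.coordinate) if hasattr(det, "coordinate") else tuple(det)


def match_detections(
    dets: Sequence,
    gt: GroundTruth,
    tolerance_mm: float = DEFAULT_TOLERANCE_MM,
    spacing: tuple[float, float, float] = (0.5, 0.5, 1.0),
) -> MatchResult:
    """Greedy one-to-one matching by increasing physical distance.

    ``dets`` may be Candidate/Detection objects or bare coordinate tuples.
    """
    if tolerance_mm <= 0:
        raise ValueError("tolerance must be positive")
    if spacing is None:
        raise ValueError("voxel spacing is required for mm distances")
    det_coords = [_coord(d) for d in dets]
    ann_coords = [tuple(c) for c in gt.cmb_centers]
    sp = np.asarray(spacing, dtype=float)

    pairs = []
    for i, d in enumerate(det_coords):
        for j, a in enumerate(ann_coords):
            dist = float(np.linalg.norm((np.asarray(d) - np.asarray(a)) * sp))
            if dist <= tolerance_mm:
                pairs.append((dist, d, a, i, j))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))

    used_d: set[int] = set()
    used_a: set[int] = set()
    tps = []
    for dist, d, a, i, j in pairs:
        if i in used_d or j in used_a:
            continue
        used_d.add(i)
        used_a.add(j)
        tps.append((d, a))
    fns = [a for j, a in enumerate(ann_coords) if j not in used_a]
    fps = [d for i, d in enumerate(det_coords) if i not in used_d]
    return MatchResult(tps, fns, fps, tolerance_mm)


def sensitivity(m: MatchResult | Iterable[MatchResult]) -> float:
    """Fraction of annotations hit: |TP| / (|TP| + |FN|), pooled if given
    several per-scan results."""
    results = [m] if isinstance(m, MatchResult) else list(m)
    tp = sum(len(r.true_positives) for r in results)
    fn = sum(len(r.false_negatives) for r in results)
    if tp + fn == 0:
        raise ValueError("no annotations; sensitivity undefined")
    return tp / (tp + fn)


def fp_per_scan(results: Iterable[MatchResult]) -> float:
    """Mean unmatched detections per scan."""
    results = list(results)
    if not results:
        raise ValueError("no scans")
    return sum(len(r.false_positives) for r in results) / len(results)


def aggregate(results: list[MatchResult]) -> EvalResult:
    per_scan = [
        {
            "tp": len(r.true_positives),
            "fn": len(r.false_negatives),
            "fp": len(r.false_positives),
        }
        for r in results
    ]
    n_cmbs = sum(c["tp"] + c["fn"] for c in per_scan)
    return EvalResult(
        sensitivity=sensitivity(results),
        fp_per_scan=fp_per_scan(results),
        per_scan_counts=per_scan,
        n_scans=len(results),
        n_cmbs=n_cmbs,
    )


def sweep_thresholds(
    data: list[tuple],
    models,
    cfg,
    thresholds: Sequence[float],
    out_csv: str | Path | None = None,
) -> pd.DataFrame:
    """Trace the sensitivity / FP-per-scan trade-off over the stage-2
    decision threshold.

    ``data`` is a list of ``(raw ScanVolume, BrainMask, GroundTruth)``;
    stage 1 and the CNN scoring run once per scan, then each threshold
    only re-filters the cached stage-2 scores, so both columns are
    monotone non-increasing in the threshold by construction.
    """
    from . import pipeline  # local import to avoid a module cycle

    scored = []  # per scan: (list[(coord, s2)], gt, spacing)
    for vol, mask, gt in data:
        pre = pipeline.preprocess_for_pipeline(vol, mask, cfg)
        cands = pipeline.stage1_detect(pre, models.unets, cfg)
        dets = pipeline.stage2_discriminate(pre, cands, models.cnns, cfg, threshold=0.0)
        scored.append((dets, gt, vol.voxel_spacing))

    rows = []
    for thr in thresholds:
        results = []
        for dets, gt, spacing in scored:
            keep = [d for d in dets if d.stage2_score >= thr]
            results.append(match_detections(keep, gt, cfg.tolerance_mm, spacing))
        rows.append(
            {
                "threshold": thr,
                "sensitivity": sensitivity(results),
                "fp_per_scan": fp_per_scan(results),
            }
        )
    df = pd.DataFrame(rows)
    if out_csv is not None:
        df.to_csv(out_csv, index=False)
    return df
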