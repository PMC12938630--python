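"""Sliding windows, stitching, candidate extraction, augmentation."""

from collections import deque
from itertools import product

import numpy as np
import pytest

from cmbdetect import (
    GroundTruth,
    PredictionVolume,
    ScanVolume,
    augment_patch,
    enumerate_windows,
    extract_candidates,
    extract_patch,
    sample_training_patches,
    stitch_predictions,
)
from cmbdetect.patching import read_candidates, write_candidates


def brute_force_origins(n, w, s):
    """Oracle: walk the axis, clamp the final origin."""
    out, o = [], 0
    while o + w < n:
        out.append(o)
        o += s
    out.append(n - w)
    return sorted(set(out))


def brute_force_stitch(preds, shape):
    acc = np.zeros(shape)
    cnt = np.zeros(shape)
    for origin, block in preds:
        for idx in product(*[range(s) for s in block.shape]):
            tgt = tuple(o + i for o, i in zip(origin, idx))
            acc[tgt] += block[idx]
            cnt[tgt] += 1
    with np.errstate(invalid="ignore"):
        out = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    return out


def brute_force_components(binary):
    """26-connected components by BFS."""
    seen = np.zeros(binary.shape, bool)
    comps = []
    offsets = [d for d in product((-1, 0, 1), repeat=3) if d != (0, 0, 0)]
    for start in map(tuple, np.argwhere(binary)):
        if seen[start]:
            continue
        comp, queue = [], deque([start])
        seen[start] = True
        while queue:
            v = queue.popleft()
            comp.append(v)
            for d in offsets:
                nb = tuple(a + b for a, b in zip(v, d))
                if all(0 <= c < s for c, s in zip(nb, binary.shape)):
                    if binary[nb] and not seen[nb]:
                        seen[nb] = True
                        queue.append(nb)
        comps.append(comp)
    return comps


class TestEnumerateWindows:
    def test_window_fills_volume(self):
        assert enumerate_windows((20, 20, 16), (20, 20, 16), 3) == [(0, 0, 0)]

    def test_exact_x_origins(self):
        origins = enumerate_windows((26, 20, 16), (20, 20, 16), 3)
        assert sorted({o[0] for o in origins}) == [0, 3, 6]
        assert len(origins) == 3

    def test_clamped_final_origin(self):
        origins = enumerate_windows((25, 20, 16), (20, 20, 16), 3)
        assert sorted({o[0] for o in origins}) == [0, 3, 5]

    @pytest.mark.parametrize("trial", range(25))
    def test_matches_bruteforce_and_covers(self, trial, rng):
        r = np.random.default_rng(1000 + trial)
        shape = tuple(int(r.integers(6, 30)) for _ in range(3))
        window = tuple(int(r.integers(2, s + 1)) for s in shape)
        # coverage requires the stride not to exceed the window extent
        stride = int(r.integers(1, max(min(window), 2)))
        origins = enumerate_windows(shape, window, stride)
        for ax in range(3):
            assert sorted({o[ax] for o in origins}) == brute_force_origins(
                shape[ax], window[ax], stride
            )
        covered = np.zeros(shape, bool)
        for o in origins:
            covered[tuple(slice(a, a + w) for a, w in zip(o, window))] = True
        assert covered.all()

    def test_window_too_large(self):
        with pytest.raises(ValueError):
            enumerate_windows((10, 10, 10), (20, 20, 16), 3)


class TestExtractPatch:
    def test_equals_direct_slicing(self, rng):
        vol = ScanVolume(rng.random((30, 28, 20)))
        p = extract_patch(vol, (4, 3, 2))
        np.testing.assert_array_equal(
            p.intensities, vol.intensities[4:24, 3:23, 2:18]
        )
        assert p.center == (4 + 10, 3 + 10, 2 + 8)

    def test_overlapping_patches_share_values(self, rng):
        vol = ScanVolume(rng.random((30, 28, 20)))
        p1 = extract_patch(vol, (0, 0, 0))
        p2 = extract_patch(vol, (3, 0, 0))
        np.testing.assert_array_equal(
            p1.intensities[3:, :, :], p2.intensities[:-3, :, :]
        )

    def test_out_of_range_origin(self, rng):
        vol = ScanVolume(rng.random((30, 28, 20)))
        with pytest.raises(ValueError):
            extract_patch(vol, (15, 0, 0))


class TestStitchPredictions:
    def test_single_window_identity(self, rng):
        block = rng.random((4, 4, 4))
        out = stitch_predictions([((0, 0, 0), block)], (4, 4, 4))
        np.testing.assert_array_equal(out.probabilities, block)

    def test_mean_of_two(self):
        b1 = np.full((2, 2, 2), 0.2)
        b2 = np.full((2, 2, 2), 0.4)
        out = stitch_predictions([((0, 0, 0), b1), ((0, 0, 0), b2)], (2, 2, 2))
        np.testing.assert_allclose(out.probabilities, 0.3)

    def test_uncovered_voxels_zero(self):
        out = stitch_predictions([((0, 0, 0), np.ones((2, 2, 2)))], (4, 4, 4))
        assert out.probabilities[3, 3, 3] == 0

    @pytest.mark.parametrize("trial", range(100))
    def test_bit_equal_to_bruteforce(self, trial):
        r = np.random.default_rng(5000 + trial)
        shape = tuple(int(r.integers(4, 12)) for _ in range(3))
        window = tuple(int(r.integers(2, min(s, 5) + 1)) for s in shape)
        stride = int(r.integers(1, 4))
        origins = enumerate_windows(shape, window, stride)
        preds = [(o, r.random(window)) for o in origins]
        fast = stitch_predictions(preds, shape).probabilities
        slow = brute_force_stitch(preds, shape)
        np.testing.assert_array_equal(fast, slow)


class TestExtractCandidates:
    def test_all_zero_prediction(self):
        pred = PredictionVolume(np.zeros((10, 10, 8)))
        assert extract_candidates(pred, 0.5) == []

    def test_single_sphere_centroid(self):
        prob = np.zeros((16, 16, 12))
        g = np.meshgrid(*[np.arange(n) for n in prob.shape], indexing="ij")
        d2 = (g[0] - 8) ** 2 + (g[1] - 7) ** 2 + (g[2] - 6) ** 2
        prob[d2 <= 9] = 0.9
        cands = extract_candidates(PredictionVolume(prob), 0.5)
        assert len(cands) == 1
        assert cands[0].coordinate == (8, 7, 6)
        assert cands[0].score == pytest.approx(0.9)
        comps = brute_force_components(prob >= 0.5)
        assert cands[0].component_size == len(comps[0])

    def test_two_separated_spheres(self):
        prob = np.zeros((24, 16, 12))
        for cx in (5, 18):
            g = np.meshgrid(*[np.arange(n) for n in prob.shape], indexing="ij")
            d2 = (g[0] - cx) ** 2 + (g[1] - 8) ** 2 + (g[2] - 6) ** 2
            prob[d2 <= 4] = 0.8
        cands = extract_candidates(PredictionVolume(prob), 0.5)
        assert len(cands) == len(brute_force_components(prob >= 0.5)) == 2

    def test_diagonal_touch_is_connected(self):
        # 26-connectivity joins voxels sharing only a corner
        prob = np.zeros((6, 6, 6))
        prob[2, 2, 2] = prob[3, 3, 3] = 0.9
        assert len(extract_candidates(PredictionVolume(prob), 0.5)) == 1

    def test_suprathreshold_set_monotone_in_threshold(self, rng):
        prob = rng.random((12, 12, 10))
        pred = PredictionVolume(prob)
        sets = []
        for thr in (0.3, 0.5, 0.7):
            sets.append(prob >= thr)
        assert (sets[1] <= sets[0]).all() and (sets[2] <= sets[1]).all()

    def test_round_trip_tsv(self, tmp_path, rng):
        prob = np.zeros((12, 12, 10))
        prob[4:6, 4:6, 4:6] = 0.75
        cands = extract_candidates(PredictionVolume(prob), 0.5)
        path = tmp_path / "cands.tsv"
        write_candidates(cands, path)
        back = read_candidates(path)
        assert [c.coordinate for c in back] == [c.coordinate for c in cands]
        assert [c.score for c in back] == pytest.approx([c.score for c in cands])


class TestAugmentPatch:
    def _interior_patch(self, rng):
        vol = ScanVolume(rng.random((40, 40, 30)))
        p = extract_patch(vol, (10, 10, 7))
        p.label = 1
        p.target = (rng.random((20, 20, 16)) > 0.9).astype(float)
        return p

    def test_interior_patch_yields_eleven(self, rng):
        out = augment_patch(self._interior_patch(rng))
        assert len(out) == 11  # original + 2 flips + 2 rotations + 6 shifts

    def test_labels_and_shapes_preserved(self, rng):
        for q in augment_patch(self._interior_patch(rng)):
            assert q.label == 1
            assert q.intensities.shape == (20, 20, 16)
            assert q.target.shape == (20, 20, 16)

    def test_flip_is_involution(self, rng):
        p = self._interior_patch(rng)
        out = augment_patch(p)
        flipped_x = out[1]
        np.testing.assert_array_equal(
            np.flip(flipped_x.intensities, axis=0), p.intensities
        )

    def test_rotation_pair_is_identity(self, rng):
        p = self._interior_patch(rng)
        out = augment_patch(p)
        plus90, minus90 = out[3], out[4]
        np.testing.assert_array_equal(
            np.rot90(plus90.intensities, k=-1, axes=(0, 1)), p.intensities
        )
        np.testing.assert_array_equal(
            np.rot90(minus90.intensities, k=1, axes=(0, 1)), p.intensities
        )

    def test_shifts_reextracted_not_padded(self, rng):
        vol = ScanVolume(rng.random((40, 40, 30)))
        p = extract_patch(vol, (10, 10, 7))
        p.label = 1
        shifted = augment_patch(p)[5:]
        for q in shifted:
            np.testing.assert_array_equal(
                q.intensities,
                vol.intensities[
                    q.origin[0] : q.origin[0] + 20,
                    q.origin[1] : q.origin[1] + 20,
                    q.origin[2] : q.origin[2] + 16,
                ],
            )

    def test_border_patch_skips_out_of_range_shifts(self, rng):
        vol = ScanVolume(rng.random((20, 40, 30)))
        p = extract_patch(vol, (0, 10, 7))  # x shifts impossible both ways
        p.label = 0
        out = augment_patch(p)
        assert len(out) == 9  # 11 minus the two x shifts


class TestSampleTrainingPatches:
    def _phantom_parts(self, default_phantom):
        from cmbdetect import preprocess_scan

        vol, mask, gt = default_phantom
        return preprocess_scan(vol, mask), mask, gt

    def test_counts(self, default_phantom):
        pre, mask, gt = self._phantom_parts(default_phantom)
        patches = sample_training_patches(pre, gt, n_negatives=20, seed=0, mask=mask.mask)
        pos = [p for p in patches if p.label == 1]
        neg = [p for p in patches if p.label == 0]
        assert len(pos) == len(gt.cmb_centers)
        assert len(neg) == 20

    def test_negative_margin_respected(self, default_phantom):
        pre, mask, gt = self._phantom_parts(default_phantom)
        patches = sample_training_patches(
            pre, gt, n_negatives=20, seed=1, margin_mm=10.0, mask=mask.mask
        )
        sp = np.asarray(pre.voxel_spacing)
        centers = np.asarray(gt.cmb_centers, float)
        for p in patches:
            if p.label == 0:
                d = np.sqrt((((centers - p.center) * sp) ** 2).sum(axis=1)).min()
                assert d >= 10.0

    def test_positive_targets_are_spheres(self, default_phantom):
        pre, mask, gt = self._phantom_parts(default_phantom)
        patches = sample_training_patches(pre, gt, n_negatives=5, seed=2, mask=mask.mask)
        for p in patches:
            if p.label == 1:
                assert p.target.sum() > 0
                assert set(np.unique(p.target)) <= {0.0, 1.0}

    def test_seeded_determinism(self, default_phantom):
        pre, mask, gt = self._phantom_parts(default_phantom)
        a = sample_training_patches(pre, gt, n_negatives=10, seed=3, mask=mask.mask)
        b = sample_training_patches(pre, gt, n_negatives=10, seed=3, mask=mask.mask)
        assert [p.origin for p in a] == [p.origin for p in b]
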