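"""Metric arithmetic, signed distances, boundary loss, loss mixing."""

import numpy as np
import pytest

from s5utis.losses_metrics import (
    ConfusionCounts, DistanceMap, boundary_loss, combined_loss, confusion,
    cross_entropy, dice, evaluate_pairs, miou, pixel_accuracy, signed_distance,
)
from s5utis.nn.tensor import Tensor


FIXTURE = ConfusionCounts(TP=6, TN=6, FP=2, FN=2)


def _fixture_masks():
    """4x4 pair realizing (TP, TN, FP, FN) = (6, 6, 2, 2)."""
    truth = np.array([[1, 1, 1, 1],
                      [1, 1, 1, 1],
                      [0, 0, 0, 0],
                      [0, 0, 0, 0]])
    pred = np.array([[1, 1, 1, 1],
                     [1, 1, 0, 0],
                     [1, 1, 0, 0],
                     [0, 0, 0, 0]])
    return pred, truth


class TestConfusion:
    def test_perfect_all_ones(self):
        m = np.ones((4, 4), dtype=int)
        assert confusion(m, m) == ConfusionCounts(16, 0, 0, 0)

    def test_total_disagreement(self):
        t = np.zeros((4, 4), dtype=int)
        t[:2] = 1
        c = confusion(1 - t, t)
        assert c.TP == 0 and c.TN == 0 and c.FP == 8 and c.FN == 8

    def test_hand_built_fixture(self):
        pred, truth = _fixture_masks()
        assert confusion(pred, truth) == FIXTURE

    def test_counts_sum_to_total(self):
        rng = np.random.default_rng(0)
        p = (rng.random((9, 7)) < 0.5).astype(int)
        t = (rng.random((9, 7)) < 0.5).astype(int)
        assert confusion(p, t).total == 63

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            confusion(np.zeros((2, 2), dtype=int), np.zeros((3, 3), dtype=int))

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            confusion(np.full((2, 2), 2), np.zeros((2, 2), dtype=int))


class TestScores:
    def test_dice(self):
        assert dice(ConfusionCounts(5, 3, 0, 0)) == 1.0
        assert dice(FIXTURE) == 12 / 16 == 0.75
        assert dice(ConfusionCounts(0, 4, 3, 2)) == 0.0
        assert dice(ConfusionCounts(0, 4, 0, 0)) == 1.0  # both regions empty

    def test_miou(self):
        assert miou(ConfusionCounts(5, 3, 0, 0)) == 1.0
        assert miou(FIXTURE) == 0.5 * (6 / 10 + 6 / 10)
        assert miou(ConfusionCounts(8, 0, 8, 0)) == 0.5 * (8 / 16 + 0.0)

    def test_pixel_accuracy(self):
        assert pixel_accuracy(ConfusionCounts(5, 3, 0, 0)) == 1.0
        assert pixel_accuracy(FIXTURE) == 0.75
        assert pixel_accuracy(ConfusionCounts(0, 0, 8, 8)) == 0.0

    def test_all_one_iff_exact_match(self):
        rng = np.random.default_rng(1)
        t = (rng.random((8, 8)) < 0.4).astype(int)
        c = confusion(t, t)
        assert dice(c) == miou(c) == pixel_accuracy(c) == 1.0
        p = t.copy()
        p[0, 0] ^= 1
        c = confusion(p, t)
        assert dice(c) < 1.0 and miou(c) < 1.0 and pixel_accuracy(c) < 1.0

    def test_monotone_in_tp_at_fixed_totals(self):
        # moving one pixel from FN to TP can only improve overlap scores
        base = ConfusionCounts(4, 6, 3, 3)
        better = ConfusionCounts(5, 6, 3, 2)
        assert dice(better) >= dice(base)
        assert miou(better) >= miou(base)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(2)
        p = (rng.random((6, 6)) < 0.5).astype(int)
        t = (rng.random((6, 6)) < 0.5).astype(int)
        perm = rng.permutation(36)
        c1 = confusion(p, t)
        c2 = confusion(p.ravel()[perm].reshape(6, 6), t.ravel()[perm].reshape(6, 6))
        assert c1 == c2

    def test_matches_double_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            p = (rng.random((16, 16)) < rng.uniform(0.2, 0.8)).astype(int)
            t = (rng.random((16, 16)) < rng.uniform(0.2, 0.8)).astype(int)
            tp = tn = fp = fn = 0
            for i in range(16):
                for j in range(16):
                    if p[i, j] and t[i, j]:
                        tp += 1
                    elif p[i, j] and not t[i, j]:
                        fp += 1
                    elif not p[i, j] and t[i, j]:
                        fn += 1
                    else:
                        tn += 1
            assert confusion(p, t) == ConfusionCounts(tp, tn, fp, fn)


def _brute_force_phi(mask: np.ndarray) -> np.ndarray:
    """Exhaustive nearest-boundary-pixel search (independent oracle)."""
    H, W = mask.shape
    boundary = []
    for i in range(H):
        for j in range(W):
            if not mask[i, j]:
                continue
            neigh = [(i - 1, j), (i + 1, j), (i, j - 1), (i, j + 1)]
            if any(not (0 <= a < H and 0 <= b < W) or not mask[a, b] for a, b in neigh):
                boundary.append((i, j))
    phi = np.zeros((H, W))
    for i in range(H):
        for j in range(W):
            d = min(np.hypot(i - a, j - b) for a, b in boundary)
            phi[i, j] = -d if mask[i, j] else d
    return phi


def _square_mask():
    m = np.zeros((8, 8), dtype=int)
    m[2:6, 2:6] = 1
    return m


class TestSignedDistance:
    def test_single_pixel_sign_structure(self):
        m = np.zeros((5, 5), dtype=int)
        m[2, 2] = 1
        phi = signed_distance(m).phi
        assert phi[2, 2] <= 0.0
        for a, b in [(1, 2), (3, 2), (2, 1), (2, 3)]:
            assert phi[a, b] > 0.0

    def test_square_matches_brute_force(self):
        m = _square_mask()
        np.testing.assert_allclose(signed_distance(m).phi, _brute_force_phi(m),
                                   atol=1e-12)

    def test_random_masks_match_brute_force(self):
        rng = np.random.default_rng(4)
        for _ in range(3):
            m = (rng.random((10, 10)) < 0.4).astype(int)
            if m.sum() in (0, m.size):
                continue
            np.testing.assert_allclose(signed_distance(m).phi, _brute_force_phi(m),
                                       atol=1e-12)

    def test_lipschitz(self):
        phi = signed_distance(_square_mask()).phi
        assert np.abs(np.diff(phi, axis=0)).max() <= 1.0 + 1e-12
        assert np.abs(np.diff(phi, axis=1)).max() <= 1.0 + 1e-12

    def test_degenerate_mask_warns_and_zeroes(self):
        with pytest.warns(UserWarning, match="degenerate"):
            phi = signed_distance(np.zeros((4, 4), dtype=int)).phi
        np.testing.assert_array_equal(phi, 0.0)

    def test_non_binary_rejected(self):
        with pytest.raises(ValueError):
            signed_distance(np.full((4, 4), 3))


class TestBoundaryLoss:
    def test_zero_probs(self):
        phi = signed_distance(_square_mask())
        assert boundary_loss(np.zeros((8, 8)), phi) == 0.0

    def test_indicator_of_truth_is_negative(self):
        m = _square_mask()
        phi = signed_distance(m)
        val = boundary_loss(m.astype(float), phi)
        ref = phi.phi[m.astype(bool)].sum() / m.size
        assert val < 0.0
        np.testing.assert_allclose(val, ref)

    def test_overlap_increase_strictly_decreases_loss(self):
        rng = np.random.default_rng(5)
        m = _square_mask()
        phi = signed_distance(m)
        probs = rng.uniform(0.1, 0.9, size=(8, 8))
        inside = np.argwhere((m == 1) & (phi.phi < 0))
        outside = np.argwhere(m == 0)
        for _ in range(5):
            ii = tuple(inside[rng.integers(len(inside))])
            oo = tuple(outside[rng.integers(len(outside))])
            moved = probs.copy()
            moved[ii], moved[oo] = max(probs[ii], probs[oo]), min(probs[ii], probs[oo])
            if moved[ii] == probs[ii]:
                continue
            assert boundary_loss(moved, phi) < boundary_loss(probs, phi)

    def test_shape_mismatch(self):
        with pytest.raises(ValueError):
            boundary_loss(np.zeros((4, 4)), DistanceMap(phi=np.zeros((5, 5))))

    def test_probability_range_checked(self):
        with pytest.raises(ValueError):
            boundary_loss(np.full((4, 4), 1.5), DistanceMap(phi=np.zeros((4, 4))))


class TestCombinedLoss:
    def _logits_and_truth(self, seed=6):
        rng = np.random.default_rng(seed)
        logits = Tensor(rng.normal(size=(2, 2, 8, 8)))
        truth = np.stack([_square_mask(), _square_mask()])
        return logits, truth

    def test_alpha_one_is_plain_ce_bitwise(self):
        logits, truth = self._logits_and_truth()
        assert combined_loss(logits, truth, alpha=1.0).item() == \
            cross_entropy(logits, truth).item()

    def test_alpha_zero_is_boundary_of_softmax(self):
        logits, truth = self._logits_and_truth()
        val = combined_loss(logits, truth, alpha=0.0).item()
        z = logits.data
        p = np.exp(z) / np.exp(z).sum(axis=1, keepdims=True)
        phi = np.stack([signed_distance(t).phi for t in truth])
        np.testing.assert_allclose(val, (p[:, 1] * phi).mean(), rtol=1e-12)

    def test_linear_in_alpha(self):
        logits, truth = self._logits_and_truth()
        v = [combined_loss(logits, truth, alpha=a).item() for a in (0.0, 0.5, 1.0)]
        np.testing.assert_allclose(v[1], 0.5 * (v[0] + v[2]), rtol=1e-10)

    def test_alpha_bounds(self):
        logits, truth = self._logits_and_truth()
        with pytest.raises(ValueError):
            combined_loss(logits, truth, alpha=1.5)

    def test_gradient_flows(self):
        logits, truth = self._logits_and_truth()
        logits.requires_grad = True
        combined_loss(logits, truth, alpha=0.5).backward()
        assert logits.grad is not None and np.abs(logits.grad).max() > 0


class TestEvaluatePairs:
    def test_micro_vs_macro(self):
        pred, truth = _fixture_masks()
        perfect = truth
        rep_micro = evaluate_pairs([(pred, truth), (perfect, truth)], average="micro")
        rep_macro = evaluate_pairs([(pred, truth), (perfect, truth)], average="macro")
        assert rep_macro["aggregate"]["dice"] == 0.5 * (0.75 + 1.0)
        pooled = confusion(np.concatenate([pred, perfect]), np.concatenate([truth, truth]))
        assert rep_micro["aggregate"]["dice"] == dice(pooled)

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            evaluate_pairs([])

    def test_unknown_average_rejected(self):
        with pytest.raises(ValueError):
            evaluate_pairs([(np.ones((2, 2), int), np.ones((2, 2), int))], average="median")
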