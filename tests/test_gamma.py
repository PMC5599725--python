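"""Discriminative-ROI discovery: BD score oracle, region growing, validation."""

import itertools

import numpy as np
import pytest
from scipy.special import gammaln

from icnmhe import (
    GammaParams,
    build_cpt,
    discretize_zmap,
    fit_gamma,
    grow_roi,
    log_bd_score,
    roi_state,
    threshold_grid,
    validate_model,
)
from icnmhe.gamma import DegenerateLabelsError, roi_volume


def polya_urn_log_score(states, labels, alpha_ess=2.0):
    """Independent oracle: log product of sequential predictive probabilities.

    Processing subjects in order, each class observation is predicted from the
    Dirichlet posterior of its state cell (alpha_ess/2 per class per cell).
    """
    a = alpha_ess / 2.0
    counts = {}  # (state, class) -> count
    totals = {}  # state -> count
    log_p = 0.0
    for s, c in zip(states, labels):
        num = a + counts.get((s, c), 0)
        den = 2 * a + totals.get(s, 0)
        log_p += np.log(num / den)
        counts[(s, c)] = counts.get((s, c), 0) + 1
        totals[s] = totals.get(s, 0) + 1
    return log_p


class TestDiscretize:
    def test_strictly_larger_than_threshold(self):
        z = np.array([[[1.0, 2.6, 3.1, 2.3, 2.0]]])
        m = discretize_zmap(z, 2.5)
        np.testing.assert_array_equal(m.data[0, 0], [False, True, True, False, False])
        m2 = discretize_zmap(z, 2.0)
        np.testing.assert_array_equal(m2.data[0, 0], [False, True, True, True, False])

    def test_default_threshold_grid_is_the_nine_values(self):
        grid = threshold_grid()
        assert grid == (1.0, 1.25, 1.5, 1.75, 2.0, 2.25, 2.5, 2.75, 3.0)
        assert len(grid) == 9
        assert all(b > a for a, b in zip(grid, grid[1:]))


class TestLogBDScore:
    def test_perfectly_aligned_states_frozen_value(self):
        # sequential-predictive oracle gives exactly ln(1/9)
        got = log_bd_score([1, 1, 0, 0], [0, 0, 1, 1], alpha_ess=2.0)
        assert got == pytest.approx(np.log(1 / 9), abs=1e-12)

    def test_constant_states_frozen_value(self):
        got = log_bd_score([1, 1, 1, 1], [0, 0, 1, 1], alpha_ess=2.0)
        assert got == pytest.approx(np.log(1 / 30), abs=1e-12)

    def test_subject_order_invariance(self):
        rng = np.random.default_rng(0)
        states = rng.integers(0, 2, 12)
        labels = np.array([0, 1] * 6)
        base = log_bd_score(states, labels)
        for _ in range(5):
            perm = rng.permutation(12)
            assert log_bd_score(states[perm], labels[perm]) == pytest.approx(base, abs=1e-12)

    @pytest.mark.parametrize("n", [2, 4, 6, 8])
    def test_matches_polya_urn_oracle_exhaustively(self, n):
        labels = tuple(i % 2 for i in range(n))
        for states in itertools.product([0, 1], repeat=n):
            expected = polya_urn_log_score(states, labels)
            got = log_bd_score(states, labels)
            assert got == pytest.approx(expected, abs=1e-9)

    @pytest.mark.parametrize("n", [4, 6, 8])
    def test_label_vector_attains_global_maximum(self, n):
        # the state vector equal to the labels maximizes the score over all 2^n
        labels = tuple(i % 2 for i in range(n))
        best = max(
            log_bd_score(s, labels) for s in itertools.product([0, 1], repeat=n)
        )
        assert log_bd_score(labels, labels) == pytest.approx(best, abs=1e-9)

    def test_single_class_labels_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            log_bd_score([0, 1, 0, 1], [1, 1, 1, 1])


class TestGrowRoi:
    def _stack(self, volumes):
        return np.asarray(volumes, dtype=bool)

    def test_isolated_rep_voxel_roi_is_singleton(self):
        # two subjects; rep voxel's vector is (1, 0); everything else (0, 0)
        maps = np.zeros((2, 5, 5, 5), dtype=bool)
        maps[0, 2, 2, 2] = True
        roi = grow_roi((2, 2, 2), maps, kappa_sim=0.9)
        assert roi.sum() == 1 and roi[2, 2, 2]

    def test_identical_block_becomes_full_roi(self):
        maps = np.zeros((4, 7, 7, 7), dtype=bool)
        maps[:2, 2:5, 2:5, 2:5] = True  # 3x3x3 block identical across subjects
        roi = grow_roi((3, 3, 3), maps, kappa_sim=0.9)
        assert roi.sum() == 27
        assert roi[2:5, 2:5, 2:5].all()

    def test_disconnected_twin_block_excluded(self):
        maps = np.zeros((4, 13, 7, 7), dtype=bool)
        maps[:2, 1:4, 2:5, 2:5] = True
        maps[:2, 8:11, 2:5, 2:5] = True  # identical but spatially separate
        roi = grow_roi((2, 3, 3), maps, kappa_sim=0.9)
        assert roi.sum() == 27
        assert not roi[8:11].any()


class TestRoiState:
    @pytest.mark.parametrize(
        "ones,total,expected", [(20, 27, 1), (13, 27, 0), (5, 10, 1)]
    )
    def test_majority_rule_with_boundary(self, ones, total, expected):
        data = np.zeros((total, 1, 1), dtype=bool)
        data[:ones] = True
        roi = np.ones_like(data, dtype=bool)
        assert roi_state(data, roi, tau=0.5) == expected

    def test_empty_roi_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            roi_state(np.ones((2, 2, 2), dtype=bool), np.zeros((2, 2, 2), dtype=bool))


class TestCPT:
    def test_laplace_smoothing(self):
        # state 1: 2 NMHE, 0 MHE with add-1 smoothing
        cpt = build_cpt([1, 1, 0, 0], [0, 0, 1, 1], smoothing=1.0)
        assert cpt[1, 1] == pytest.approx(0.25)  # P(MHE | state 1)
        assert cpt[1, 0] == pytest.approx(0.75)

    def test_unsmoothed_frequencies(self):
        cpt = build_cpt([0, 0, 0, 0], [1, 1, 1, 0], smoothing=0.0)
        assert cpt[0, 1] == pytest.approx(0.75)  # P(MHE | state 0)

    def test_rows_sum_to_one(self):
        rng = np.random.default_rng(1)
        for _ in range(10):
            states = rng.integers(0, 2, 10)
            labels = rng.integers(0, 2, 10)
            cpt = build_cpt(states, labels, smoothing=rng.uniform(0, 2))
            np.testing.assert_allclose(cpt.sum(axis=1), 1.0)


class TestValidation:
    def test_p_never_below_plus_one_floor(self):
        rng = np.random.default_rng(2)
        maps = rng.random((10, 4, 4, 4)) > 0.7
        labels = np.array([0, 1] * 5, dtype=bool)
        p = validate_model(
            observed_score=-1e9, maps=maps, labels=labels,
            params=GammaParams(n_permutations=99, seed=0),
        )
        assert p >= 1 / 100

    def test_perfect_separation_reaches_the_floor(self):
        # 32/42 split: no label permutation can reproduce a perfectly
        # separating voxel, so p attains its minimum 1/(B+1)
        labels = np.zeros(74, dtype=bool)
        labels[:32] = True
        maps = np.zeros((74, 6, 6, 6), dtype=bool)
        maps[~labels, 2, 2, 2] = True  # one perfectly separating voxel
        model = fit_gamma(maps, labels, GammaParams(n_permutations=199, seed=1))
        assert model.n_rois >= 1
        assert model.p_values[0] == pytest.approx(1 / 200)


class TestFitGamma:
    def test_planted_region_recovered(self, planted_zmaps):
        zmaps, labels, mask, planted = planted_zmaps
        name = sorted(zmaps)[planted.icn]
        maps = zmaps[name] > 2.0
        model = fit_gamma(
            maps, labels, GammaParams(seed=0), mask=mask, icn=name, threshold=2.0
        )
        assert model.n_rois >= 1
        roi = roi_volume(model.rois[0], mask.shape)
        star = roi_volume(planted.voxels, mask.shape)
        jaccard = (roi & star).sum() / (roi | star).sum()
        assert jaccard >= 0.5

    def test_rois_disjoint_and_inside_mask(self, planted_zmaps):
        zmaps, labels, mask, planted = planted_zmaps
        name = sorted(zmaps)[planted.icn]
        model = fit_gamma(
            zmaps[name] > 1.0, labels,
            GammaParams(seed=3, n_permutations=99), mask=mask,
        )
        seen = np.zeros(mask.shape, dtype=bool)
        for r in model.rois:
            vol = roi_volume(r, mask.shape)
            assert not (vol & seen).any()
            assert (vol <= mask).all()
            seen |= vol
        for rep, r in zip(model.representative_voxels, model.rois):
            assert any((np.asarray(rep) == row).all() for row in r)

    def test_perfect_voxel_selected_first(self):
        labels = np.array([0, 0, 0, 1, 1, 1] * 3, dtype=bool)
        rng = np.random.default_rng(4)
        maps = rng.random((18, 5, 5, 5)) > 0.5
        maps[:, 1, 1, 1] = labels  # plant a perfectly aligned voxel
        model = fit_gamma(maps, labels, GammaParams(n_permutations=99, seed=0))
        assert model.n_rois >= 1
        assert (1, 1, 1) in [tuple(v) for v in model.rois[0].tolist()] or \
            model.representative_voxels[0] == (1, 1, 1)

    def test_degenerate_labels_rejected(self):
        maps = np.zeros((4, 3, 3, 3), dtype=bool)
        with pytest.raises(DegenerateLabelsError):
            fit_gamma(maps, np.ones(4, dtype=bool), GammaParams(n_permutations=99))

    def test_model_json_roundtrip(self, planted_zmaps):
        from icnmhe.gamma import GammaModel

        zmaps, labels, mask, planted = planted_zmaps
        name = sorted(zmaps)[planted.icn]
        model = fit_gamma(
            zmaps[name] > 2.0, labels,
            GammaParams(seed=0, n_permutations=99), mask=mask,
            icn=name, threshold=2.0,
        )
        back = GammaModel.from_json(model.to_json())
        assert back.icn == model.icn and back.n_rois == model.n_rois
        for a, b in zip(back.rois, model.rois):
            np.testing.assert_array_equal(a, b)
        np.testing.assert_allclose(back.cpt, model.cpt)
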