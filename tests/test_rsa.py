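"""Representational similarity: RSMs, residualisation, shift statistic."""

import numpy as np
import pandas as pd
import pytest

from seqsleep.preprocess import WindowedEpochSet
from seqsleep.rsa import (
    category_specificity,
    compute_rsm_timecourse,
    eeg_successor_similarity,
    model_rsm,
    representational_shift,
    residualize,
    upper_tri,
    winsorized_fisher_z,
)


def _windowed(patterns_by_image, n_windows=2):
    """One trial per image with a constant-in-time channel pattern."""
    images = list(patterns_by_image)
    data = np.stack([patterns_by_image[i] for i in images])[:, :, None]
    data = np.repeat(data, n_windows, axis=2)
    trials = pd.DataFrame(
        {
            "image": images,
            "category": ["object"] * len(images),
            "subcategory": ["x"] * len(images),
            "session": ["pre"] * len(images),
            "correct": [True] * len(images),
            "is_target": [False] * len(images),
        }
    )
    return WindowedEpochSet(
        data=data,
        window_centers=np.linspace(0.1, 0.2, n_windows),
        window_len=0.02,
        step=0.012,
        trials=trials,
    )


class TestEEGRSM:
    def test_identical_patterns_correlate_one(self):
        p = np.array([1.0, 3.0, 2.0, 5.0])
        tc = compute_rsm_timecourse(_windowed({"a": p, "b": p.copy(), "c": p[::-1]}))
        ab = tc.values[0][0, 1]
        assert ab == pytest.approx(1.0)

    def test_rank_reversal_correlates_minus_one(self):
        p = np.array([1.0, 3.0, 2.0, 5.0])
        tc = compute_rsm_timecourse(_windowed({"a": p, "b": -p, "c": p + 1}))
        assert tc.values[0][0, 1] == pytest.approx(-1.0)

    def test_three_images_match_hand_rank_correlation(self):
        # 4-channel patterns; expected Spearman computed by ranking each
        # pattern and applying the Pearson formula by hand
        pats = {
            "a": np.array([2.0, 1.0, 4.0, 3.0]),  # ranks 2 1 4 3
            "b": np.array([1.0, 2.0, 3.0, 4.0]),  # ranks 1 2 3 4
            "c": np.array([4.0, 3.0, 1.0, 2.0]),  # ranks 4 3 1 2
        }

        def hand_spearman(x, y):
            rx = np.argsort(np.argsort(x)) + 1.0
            ry = np.argsort(np.argsort(y)) + 1.0
            return float(
                np.sum((rx - rx.mean()) * (ry - ry.mean()))
                / np.sqrt(np.sum((rx - rx.mean()) ** 2) * np.sum((ry - ry.mean()) ** 2))
            )

        tc = compute_rsm_timecourse(_windowed(pats))
        mat = tc.values[0]
        keys = list(pats)
        for i in range(3):
            for j in range(i + 1, 3):
                assert mat[i, j] == pytest.approx(
                    hand_spearman(pats[keys[i]], pats[keys[j]]), abs=1e-12
                )
        assert np.allclose(mat, mat.T)

    def test_too_few_images_rejected(self):
        p = np.arange(4.0)
        with pytest.raises(ValueError, match="3 images"):
            compute_rsm_timecourse(_windowed({"a": p, "b": p + 1}))


class TestModelRSM:
    def test_current_identical_features(self, design, features):
        m = model_rsm(features, rank=1, mapping="current")
        assert np.allclose(np.diag(m.values), 1.0)
        assert np.all(np.abs(upper_tri(m.values)) <= 1.0)

    def test_successor_mapping_uses_successor_features(self, design, features):
        m = model_rsm(features, 3, "successor", design)
        # entries equal the current-mapping correlation of the successors
        cur = model_rsm(features, 3, "current")
        i, j = 0, 5
        si = design.neighbor(m.images[i], +1)
        sj = design.neighbor(m.images[j], +1)
        ci, cj = cur.images.index(si), cur.images.index(sj)
        assert m.values[i, j] == pytest.approx(cur.values[ci, cj], abs=1e-12)

    def test_images_without_successor_dropped(self, design, features):
        with pytest.warns(RuntimeWarning, match="no successor"):
            m = model_rsm(features, 1, "successor", design)
        assert len(m.images) < len(design.images)
        assert all(design.neighbor(i, +1) is not None for i in m.images)


class TestCategorySpecificity:
    def test_block_matrix(self):
        m = np.full((4, 4), 0.2)
        m[:2, :2] = 0.8
        m[2:, 2:] = 0.8
        np.fill_diagonal(m, 1.0)
        assert category_specificity(m, ["A", "A", "B", "B"]) == pytest.approx(0.6)

    def test_constant_matrix_zero(self):
        m = np.full((4, 4), 0.3)
        assert category_specificity(m, ["A", "A", "B", "B"]) == pytest.approx(0.0)

    def test_single_category_rejected(self):
        with pytest.raises(ValueError, match="2 categories"):
            category_specificity(np.eye(3), ["A", "A", "A"])


class TestResidualize:
    def test_exact_linear_relation_gives_zero(self):
        model = np.array([0.1, 0.4, 0.2, 0.8, 0.5])
        eeg = 0.3 + 2.0 * model
        assert np.allclose(residualize(eeg, model), 0.0)

    def test_orthogonal_model_returns_centered_eeg(self):
        eeg = np.array([1.0, -1.0, 1.0, -1.0])
        model = np.array([1.0, 1.0, -1.0, -1.0])  # zero covariance with eeg
        assert np.allclose(residualize(eeg, model), eeg - eeg.mean())

    def test_hand_ols_solution(self):
        # y = [1, 2, 4], x = [0, 1, 3]: OLS slope 0.9286..., intercept 1.095
        x = np.array([0.0, 1.0, 3.0])
        y = np.array([1.0, 2.0, 4.0])
        xc = x - x.mean()
        beta = np.sum(xc * (y - y.mean())) / np.sum(xc**2)
        alpha = y.mean() - beta * x.mean()
        assert np.allclose(residualize(y, x), y - alpha - beta * x)

    def test_residuals_exactly_uncorrelated_with_regressor(self):
        rng = np.random.default_rng(0)
        model = rng.normal(size=100)
        eeg = 0.4 * model + rng.normal(size=100)
        r = residualize(eeg, model)
        assert abs(np.corrcoef(r, model)[0, 1]) < 1e-10

    def test_zero_variance_regressor_warns(self):
        eeg = np.array([1.0, 2.0, 3.0])
        with pytest.warns(RuntimeWarning, match="zero-variance"):
            r = residualize(eeg, np.ones(3))
        assert np.allclose(r, eeg - eeg.mean())


class TestShift:
    def test_increasing_deltas_hit_winsor_ceiling(self):
        z = representational_shift(np.array([0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7]))
        assert z == pytest.approx(np.arctanh(0.99), abs=1e-12)

    def test_decreasing_deltas_antisymmetric(self):
        inc = representational_shift(np.linspace(0, 1, 7))
        dec = representational_shift(np.linspace(1, 0, 7))
        assert dec == pytest.approx(-inc)
        assert dec == pytest.approx(-np.arctanh(0.99))

    def test_constant_deltas_zero_with_warning(self):
        with pytest.warns(RuntimeWarning, match="constant"):
            assert representational_shift(np.full(7, 0.3)) == 0.0

    def test_winsorisation_bounds(self):
        assert winsorized_fisher_z(1.0) == pytest.approx(np.arctanh(0.99))
        assert winsorized_fisher_z(-1.0) == pytest.approx(-np.arctanh(0.99))
        assert winsorized_fisher_z(0.5) == pytest.approx(np.arctanh(0.5))


class TestSuccessorSimilarity:
    def test_full_mask_equals_no_mask(self, design, features, small_wake):
        from seqsleep.preprocess import preprocess_pipeline

        pre, _ = small_wake
        ws = preprocess_pipeline(pre)
        with_mask, _, _ = eeg_successor_similarity(
            {"pre": ws}, features, design, remembered_images=list(design.images)
        )
        without, _, _ = eeg_successor_similarity({"pre": ws}, features, design)
        assert np.allclose(with_mask["pre"], without["pre"])

    def test_too_few_remembered_rejected(self, design, features, small_wake):
        from seqsleep.preprocess import preprocess_pipeline

        pre, _ = small_wake
        ws = preprocess_pipeline(pre)
        with pytest.raises(ValueError, match="remembered"):
            eeg_successor_similarity(
                {"pre": ws}, features, design,
                remembered_images=list(design.images[:2]),
            )

    def test_values_bounded(self, design, features, small_wake):
        from seqsleep.preprocess import preprocess_pipeline

        pre, _ = small_wake
        ws = preprocess_pipeline(pre)
        sims, centers, imgs = eeg_successor_similarity({"pre": ws}, features, design)
        assert sims["pre"].shape == (7, ws.n_windows)
        assert np.all(np.abs(sims["pre"]) <= 1.0)
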