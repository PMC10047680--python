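"""Fisher ranking and stacked-autoencoder compression."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from popgraph.errors import ValidationError
from popgraph.feature_selection import (
    fisher_score,
    sae_encode,
    sae_fit,
    select_top_k,
)
from popgraph.fixtures import FixtureConfig, make_atlas, make_cohort
from popgraph.radiomics import extract_subject


def fisher_oracle(X, y):
    """Direct per-feature two-group computation.

    Uses the same numerically-zero-denominator convention as the
    implementation: within-class variance below the floating-point
    summation noise floor counts as zero.
    """
    mu = X.mean(axis=0)
    n = X.shape[0]
    out = np.zeros(X.shape[1])
    for j in range(X.shape[1]):
        num = den = 0.0
        for c in np.unique(y):
            xc = X[y == c, j]
            num += xc.size * (xc.mean() - mu[j]) ** 2
            den += xc.size * xc.var()
        floor = n * (np.finfo(float).eps * n * np.abs(X[:, j]).max()) ** 2
        out[j] = num / den if den > floor else 0.0
    return out


class TestFisherScore:
    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(
        X=arrays(np.float64, (10, 5),
                 elements=st.floats(-50, 50, allow_nan=False)),
        flips=st.integers(0, 2**8 - 1),
    )
    def test_matches_direct_formula_oracle(self, X, flips):
        y = np.array([0, 0] + [(flips >> i) & 1 for i in range(8)])
        if np.unique(y).size < 2 or (y == 1).sum() < 2:
            y[-2:] = 1
        r = fisher_score(X, y)
        assert np.allclose(r.scores, fisher_oracle(X, y), atol=1e-12)

    def test_scale_invariance_and_ordering(self, rng):
        X = rng.standard_normal((12, 6))
        y = (rng.random(12) > 0.5).astype(int)
        y[:2], y[-2:] = 0, 1
        r1 = fisher_score(X, y)
        r2 = fisher_score(X * np.array([1, 10, 100, 2, 5, 0.1]), y)
        assert np.allclose(r1.scores, r2.scores, rtol=1e-9)
        assert np.array_equal(r1.order, r2.order)
        assert np.all(np.diff(r1.scores[r1.order]) <= 1e-15)

    def test_degenerate_features_score_zero(self):
        # identical in both classes; constant-within-class but shifted
        X = np.ones((6, 2))
        X[3:, 1] = 5.0
        y = np.array([0, 0, 0, 1, 1, 1])
        assert np.array_equal(fisher_score(X, y).scores, [0.0, 0.0])

    def test_single_class_rejected(self, rng):
        with pytest.raises(ValidationError):
            fisher_score(rng.standard_normal((4, 3)), np.zeros(4))

    def test_tie_break_toward_lower_index(self):
        X = np.zeros((4, 3))
        y = np.array([0, 0, 1, 1])
        assert np.array_equal(fisher_score(X, y).order, [0, 1, 2])


class TestSelectTopK:
    def test_k_equals_n_features_is_pure_permutation(self, rng):
        X = rng.standard_normal((10, 7))
        y = np.array([0] * 5 + [1] * 5)
        r = fisher_score(X, y)
        Xs, kept = select_top_k(r, X, 7)
        assert sorted(kept) == list(range(7))
        assert np.array_equal(Xs, X[:, kept])

    def test_k_one_returns_best_column(self, rng):
        X = rng.standard_normal((10, 4))
        y = np.array([0] * 5 + [1] * 5)
        X[:, 2] = y * 10.0 + 0.01 * rng.standard_normal(10)
        r = fisher_score(X, y)
        _, kept = select_top_k(r, X, 1)
        assert kept[0] == 2

    def test_oversized_k_rejected(self, rng):
        X = rng.standard_normal((6, 3))
        r = fisher_score(X, np.array([0, 0, 0, 1, 1, 1]))
        with pytest.raises(ValidationError):
            select_top_k(r, X, 4)

    def test_planted_rois_rank_at_top_on_cohort(self):
        """Structural features of shifted ROIs dominate the ranking."""
        cfg = FixtureConfig(
            grid_shape=(12, 14, 12), n_timepoints=8,
            n_regions_per_hemisphere=3, effect_size=6.0, seed=21,
        )
        atlas = make_atlas(cfg)
        planted = [1, 4]
        subjects, labels = make_cohort(cfg, 16, shifted_rois=planted, atlas=atlas)
        X = np.stack([extract_subject(s.smri, atlas).values for s in subjects])
        rois = np.array(
            [r for r, _, _ in extract_subject(subjects[0].smri, atlas).index]
        )
        ranking = fisher_score(X, labels)
        k = int(0.4 * X.shape[1])
        top_rois = set(rois[ranking.order[:k]])
        assert set(planted) <= top_rois
        # planted-ROI features sit above the 0.9 quantile more than chance
        q90 = np.quantile(ranking.scores, 0.9)
        frac_planted_high = (ranking.scores[np.isin(rois, planted)] > q90).mean()
        frac_other_high = (ranking.scores[~np.isin(rois, planted)] > q90).mean()
        assert frac_planted_high > frac_other_high


class TestSAE:
    @pytest.fixture(scope="class")
    def low_rank(self):
        rng = np.random.default_rng(3)
        F = rng.standard_normal((40, 3)) @ rng.standard_normal((3, 60))
        model = sae_fit(F, seed=1, epochs=300, learning_rate=3e-3,
                        layer_sizes=(60, 32, 16, 10, 6))
        return F, model

    def test_four_levels_and_bounded_embedding(self, low_rank):
        F, model = low_rank
        assert model.n_levels == 4
        E = sae_encode(model, F)
        assert E.shape == (40, 6)
        assert E.min() >= 0 and E.max() <= 1

    def test_finetune_descends(self, low_rank):
        _, model = low_rank
        assert model.finetune_losses[-1] <= model.finetune_losses[0]
        for log in model.pretrain_losses:
            assert log[-1] <= log[0]

    def test_retains_most_of_truncated_factorisation_variance(self, low_rank):
        """Reconstruction keeps >= 0.9 of what an exact rank-d SVD keeps."""
        from popgraph.feature_selection import _forward_full

        F, model = low_rank
        rngx = np.where(F.max(0) - F.min(0) > 0, F.max(0) - F.min(0), 1.0)
        xs = (F - F.min(0)) / rngx
        recon, _ = _forward_full(model, xs)
        ss = ((xs - xs.mean(0)) ** 2).sum()
        ev_sae = 1 - ((xs - recon) ** 2).sum() / ss
        xc = xs - xs.mean(0)
        u, s, vt = np.linalg.svd(xc, full_matrices=False)
        svd_rec = u[:, :6] * s[:6] @ vt[:6] + xs.mean(0)
        ev_svd = 1 - ((xs - svd_rec) ** 2).sum() / ss
        assert ev_sae >= 0.9 * ev_svd

    def test_same_seed_same_weights(self, rng):
        F = rng.standard_normal((12, 20))
        m1 = sae_fit(F, seed=5, epochs=20, layer_sizes=(20, 10, 8, 6, 4))
        m2 = sae_fit(F, seed=5, epochs=20, layer_sizes=(20, 10, 8, 6, 4))
        for a, b in zip(m1.enc_w + m1.dec_w, m2.enc_w + m2.dec_w):
            assert np.array_equal(a, b)

    def test_encode_deterministic_and_shape_checked(self, low_rank, rng):
        F, model = low_rank
        assert np.array_equal(sae_encode(model, F), sae_encode(model, F))
        from popgraph.errors import ShapeError

        with pytest.raises(ShapeError):
            sae_encode(model, rng.standard_normal((3, 61)))

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValidationError):
            sae_fit(rng.standard_normal((5, 20)))
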