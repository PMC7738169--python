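"""RSA, embedding-decoding, and category-decoding kernels."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import funcsearchlight as fs
from funcsearchlight.kernels import design_from_events


def retained_count_oracle(t: int, b: int) -> int:
    """Enumerate upper-triangular TR pairs separated by more than b."""
    return sum(1 for i in range(t) for j in range(i + 1, t) if j - i > b)


class TestBufferedRsm:
    def test_retained_count_t25_buffer10(self, rng):
        r = fs.buffered_rsm(rng.standard_normal((6, 25)), buffer_trs=10)
        assert r.n_retained == 105
        assert r.n_retained == retained_count_oracle(25, 10)

    def test_buffer_zero_keeps_all_pairs(self, rng):
        r = fs.buffered_rsm(rng.standard_normal((6, 12)), buffer_trs=0)
        assert r.n_retained == 12 * 11 // 2

    @settings(max_examples=40, deadline=None)
    @given(t=st.integers(3, 40), b=st.integers(0, 38))
    def test_retained_count_matches_enumeration(self, t, b):
        if b >= t - 1:
            b = t - 2
        rng = np.random.default_rng(t * 100 + b)
        r = fs.buffered_rsm(rng.standard_normal((4, t)), buffer_trs=b)
        assert r.n_retained == retained_count_oracle(t, b)

    def test_rsm_properties(self, rng):
        r = fs.buffered_rsm(rng.standard_normal((8, 15)), buffer_trs=3)
        np.testing.assert_allclose(r.rsm, r.rsm.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(r.rsm), 1.0)
        ii, jj = np.nonzero(r.retained_mask)
        assert np.all(jj - ii > 3)

    def test_constant_tr_reports_index(self, rng):
        pats = rng.standard_normal((5, 10))
        pats[:, 4] = 2.0
        with pytest.raises(ValueError, match=r"\[4\]"):
            fs.buffered_rsm(pats, buffer_trs=2)


class TestRsaSimilarity:
    def test_identical_rsms_give_one(self, rng):
        r = fs.buffered_rsm(rng.standard_normal((6, 20)), buffer_trs=5)
        assert fs.rsa_similarity(r, r) == pytest.approx(1.0)

    def test_mean_flipped_rsm_gives_minus_one(self, rng):
        from dataclasses import replace

        r = fs.buffered_rsm(rng.standard_normal((6, 20)), buffer_trs=5)
        vals = r.retained_values
        flipped_rsm = r.rsm.copy()
        flipped_rsm[r.retained_mask] = 2 * vals.mean() - vals
        flipped = replace(r, rsm=flipped_rsm)
        assert fs.rsa_similarity(r, flipped) == pytest.approx(-1.0)

    def test_brain_equal_to_model_signal_scores_one(self, rng):
        feats = fs.FeatureSeries(rng.standard_normal((10, 30)), label="layer")
        brain = fs.buffered_rsm(feats.values, buffer_trs=4)  # one voxel per unit
        model = fs.buffered_rsm(feats.values, buffer_trs=4)
        assert fs.rsa_similarity(brain, model) == pytest.approx(1.0, abs=1e-6)

    def test_monotone_linear_transform_invariance(self, rng):
        from dataclasses import replace

        a = fs.buffered_rsm(rng.standard_normal((6, 18)), buffer_trs=3)
        b = fs.buffered_rsm(rng.standard_normal((6, 18)), buffer_trs=3)
        base = fs.rsa_similarity(a, b)
        scaled = replace(b, rsm=0.3 * b.rsm + 0.2)
        assert fs.rsa_similarity(a, scaled) == pytest.approx(base, abs=1e-12)

    def test_mismatched_buffer_rejected(self, rng):
        a = fs.buffered_rsm(rng.standard_normal((6, 18)), buffer_trs=3)
        b = fs.buffered_rsm(rng.standard_normal((6, 18)), buffer_trs=4)
        with pytest.raises(ValueError, match="buffer"):
            fs.rsa_similarity(a, b)


class TestEmbeddingDecode:
    def test_perfect_predictions_score_one(self, rng):
        actual = rng.standard_normal((100, 20))  # t=100, f=20
        assert fs.bin_ranking_accuracy(actual, actual, n_bins=25) == 1.0

    def test_linearly_decodable_brain_scores_one(self, rng):
        t_train, t_test, f, m = 60, 50, 12, 30
        emb = rng.standard_normal((f, t_train + t_test))
        mapping = rng.standard_normal((m, f))
        brain = mapping @ emb  # noise-free linear encoding
        acc = fs.embedding_decode(
            brain[:, :t_train], emb[:, :t_train],
            brain[:, t_train:], emb[:, t_train:],
            ridge_penalty=1e-6, n_bins=25,
        )
        assert acc == 1.0

    def test_joint_rotation_leaves_accuracy_nearly_unchanged(self, rng):
        t_train, t_test, f, m = 60, 50, 12, 30
        emb = rng.standard_normal((f, t_train + t_test))
        brain = rng.standard_normal((m, f)) @ emb + 0.8 * rng.standard_normal((m, t_train + t_test))
        q, _ = np.linalg.qr(rng.standard_normal((f, f)))
        args = dict(ridge_penalty=1.0, n_bins=25)
        a1 = fs.embedding_decode(brain[:, :t_train], emb[:, :t_train],
                                 brain[:, t_train:], emb[:, t_train:], **args)
        a2 = fs.embedding_decode(brain[:, :t_train], q @ emb[:, :t_train],
                                 brain[:, t_train:], q @ emb[:, t_train:], **args)
        assert abs(a1 - a2) <= 0.08

    def test_indivisible_binning_rejected(self, rng):
        with pytest.raises(ValueError, match="divisible"):
            fs.bin_ranking_accuracy(
                rng.standard_normal((23, 5)), rng.standard_normal((23, 5)), n_bins=25
            )

    def test_noise_predictions_near_chance(self, rng):
        """Null bin-ranking accuracy approximates 1/n_bins."""
        actual = rng.standard_normal((500, 100))
        accs = [
            fs.bin_ranking_accuracy(rng.standard_normal((500, 100)), actual, n_bins=25)
            for _ in range(300)
        ]
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 0.04) < 4 * se + 1e-12


class TestCategoryDecode:
    def test_separable_categories_decode_perfectly(self):
        design = fs.synthetic_localizer_design(
            n_voxels=20, effect_sd=10.0, noise_sd=0.1, seed=3
        )
        acc = fs.category_decode(design, member_ids=np.arange(20), n_folds=3)
        assert acc == 1.0

    def test_permuted_labels_near_chance(self):
        rng = np.random.default_rng(17)
        design = fs.synthetic_localizer_design(n_voxels=15, effect_sd=0.0, seed=4)
        accs = []
        for _ in range(60):
            perm = fs.LocalizerDesign(
                examples=design.examples,
                labels=rng.permutation(design.labels),
                run_ids=design.run_ids,
            )
            accs.append(fs.category_decode(perm, np.arange(15), n_folds=3))
        se = np.std(accs, ddof=1) / np.sqrt(len(accs))
        assert abs(np.mean(accs) - 1 / 6) < 4 * se + 1e-12

    def test_balanced_48_example_folds(self):
        design = fs.synthetic_localizer_design(n_voxels=10, seed=0)
        assert design.examples.shape[0] == 48
        from sklearn.model_selection import StratifiedKFold

        for _, test_idx in StratifiedKFold(n_splits=3).split(design.examples, design.labels):
            assert len(test_idx) == 16
            _, counts = np.unique(design.labels[test_idx], return_counts=True)
            # 8 blocks per category cannot split evenly into 3 folds; stratification
            # keeps per-category counts within one of each other
            assert counts.max() - counts.min() <= 1

    def test_too_few_examples_per_category_rejected(self):
        design = fs.synthetic_localizer_design(
            n_voxels=5, blocks_per_category_per_run=1, n_runs=2, seed=0
        )
        with pytest.raises(ValueError, match="stratification"):
            fs.category_decode(design, np.arange(5), n_folds=3)

    def test_unbalanced_design_rejected(self, rng):
        with pytest.raises(ValueError, match="balanced"):
            fs.LocalizerDesign(
                examples=rng.standard_normal((5, 4)),
                labels=np.array(["a", "a", "a", "b", "b"]),
                run_ids=np.zeros(5),
            )


def test_design_from_events_block_averaging(rng):
    import pandas as pd

    data = rng.standard_normal((6, 40))
    bold = fs.MaskedBold(
        data=data, coords=np.argwhere(np.ones((6, 1, 1))), tr_seconds=2.0, subject_id="s"
    )
    events = pd.DataFrame(
        {
            "onset_tr": [0, 10, 20, 30],
            "duration_trs": [4, 4, 4, 4],
            "category": ["a", "b", "a", "b"],
            "run": [0, 0, 1, 1],
        }
    )
    design = design_from_events(bold, events, hrf_shift_trs=2)
    np.testing.assert_allclose(design.examples[0], data[:, 2:6].mean(axis=1))
    np.testing.assert_allclose(design.examples[2], data[:, 22:26].mean(axis=1))
    assert design.n_categories == 2
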