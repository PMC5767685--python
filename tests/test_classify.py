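"""Decoding contracts: z-scoring, ANOVA feature selection, training-pattern
synthesis, SVM decoding, the permutation null, and BH FDR arithmetic."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from partwhole.classify import (
    CHANCE,
    anova_feature_select,
    build_training_patterns,
    classify_subject_roi,
    decode_person_emotions,
    group_test_and_fdr,
    permutation_null,
    person_test_set,
    training_run_feature_mask,
    zscore_patterns,
)
from partwhole.config import CONDITIONS, EMOTIONS, DesignSpec, ScenarioConfig
from partwhole.datasets import VolumePatternSet
from partwhole.errors import StructuralError
from partwhole.glm import extract_condition_volumes
from partwhole.simulate import generate_condition_patterns, generate_timeseries


def _volume_set(n_per_cond=4, n_voxels=30, sep=2.0, seed=0, n_runs=4):
    """Hand-built separable volume set: emotion-specific voxel offsets."""
    rng = np.random.default_rng(seed)
    centers = {emo: sep * rng.standard_normal(n_voxels) for emo in EMOTIONS}
    vols = {}
    for r in range(n_runs):
        conds = CONDITIONS if r < 3 else [c for c in CONDITIONS if c[0] == "person"]
        for bt, emo in conds:
            vols[(0, r, "EBA", bt, emo)] = centers[emo] + rng.standard_normal(
                (n_per_cond, n_voxels)
            )
    return VolumePatternSet(
        volumes=vols, roi_names=("EBA",), n_subjects=1, n_runs=n_runs
    )


class TestZScore:
    def test_pooled_run_columns_are_standardised(self):
        vols = _volume_set()
        z = zscore_patterns(vols)
        stacked = np.vstack(
            [z.get(0, 0, "EBA", bt, emo) for bt, emo in CONDITIONS]
        )
        np.testing.assert_allclose(stacked.mean(axis=0), 0.0, atol=1e-10)
        np.testing.assert_allclose(stacked.std(axis=0), 1.0, atol=1e-10)

    def test_constant_voxel_zeroed_with_warning(self):
        vols = _volume_set()
        for k in vols.volumes:
            if k[1] == 0:
                vols.volumes[k][:, 5] = 7.0  # constant across run-0 volumes
        with pytest.warns(UserWarning, match="zero-variance"):
            z = zscore_patterns(vols)
        assert np.all(z.get(0, 0, "EBA", "face", "anger")[:, 5] == 0.0)

    def test_two_volume_voxel_maps_to_plus_minus_one(self):
        vols = VolumePatternSet(
            volumes={(0, 0, "EBA", "face", "anger"): np.array([[1.0], [3.0]])},
            roi_names=("EBA",),
            n_subjects=1,
            n_runs=1,
        )
        z = zscore_patterns(vols)
        np.testing.assert_allclose(
            z.get(0, 0, "EBA", "face", "anger").ravel(), [-1.0, 1.0]
        )


class TestFeatureSelection:
    def test_null_voxels_retained_near_alpha_level(self, rng):
        n_vox = 2000
        X = rng.standard_normal((180, n_vox))
        labels = np.repeat([f"c{i}" for i in range(9)], 20)
        mask = anova_feature_select(X, labels, p_threshold=0.05)
        # binomial 99% interval around 5% of 2000
        lo = 100 - 2.576 * np.sqrt(2000 * 0.05 * 0.95)
        hi = 100 + 2.576 * np.sqrt(2000 * 0.05 * 0.95)
        assert lo <= mask.n_selected <= hi

    def test_strong_condition_effects_always_retained(self, rng):
        X = rng.standard_normal((90, 50))
        labels = np.repeat([f"c{i}" for i in range(9)], 10)
        X[:, :25] += 2.0 * np.repeat(np.arange(9), 10)[:, None]  # condition effect
        mask = anova_feature_select(X, labels)
        assert mask.mask[:25].all()

    def test_threshold_one_keeps_all_finite_variance_voxels(self, rng):
        X = rng.standard_normal((40, 20))
        labels = np.repeat(["a", "b"], 20)
        mask = anova_feature_select(X, labels, p_threshold=1.0)
        assert mask.n_selected == 20

    def test_all_rejected_raises(self):
        X = np.zeros((20, 5))
        labels = np.repeat(["a", "b"], 10)
        with pytest.raises(StructuralError, match="rejected all"):
            anova_feature_select(X, labels, p_threshold=0.05)

    def test_single_label_rejected(self, rng):
        with pytest.raises(StructuralError, match="2 condition"):
            anova_feature_select(rng.standard_normal((10, 3)), np.repeat("a", 10))


class TestTrainingPatterns:
    def test_mean_equals_weighted_mean_at_half(self):
        vols = _volume_set()
        Xm, ym = build_training_patterns(vols, 0, "EBA", "mean")
        Xw, yw = build_training_patterns(vols, 0, "EBA", "weighted_mean", alpha=0.5)
        np.testing.assert_array_equal(Xm, Xw)
        np.testing.assert_array_equal(ym, yw)

    def test_exemplar_count_from_design_arithmetic(self):
        # paper-shaped extraction: 3 runs x 20 volumes per condition
        cfg = ScenarioConfig(
            n_voxels=10, n_subjects=1, n_runs=4, roi_names=("EBA",), seed=2
        )
        ds = generate_condition_patterns(cfg)
        ts = generate_timeseries(ds, DesignSpec(), noise_sd=0.2, seed=3)
        vols = extract_condition_volumes(ts)
        X, y = build_training_patterns(vols, 0, "EBA", "face")
        assert X.shape[0] == 180  # 3 emotions x 60
        for emo in EMOTIONS:
            assert int((y == emo).sum()) == 60

    def test_unknown_type_and_missing_alpha_raise(self):
        vols = _volume_set()
        with pytest.raises(StructuralError, match="training_type"):
            build_training_patterns(vols, 0, "EBA", "betas")
        with pytest.raises(StructuralError, match="alpha"):
            build_training_patterns(vols, 0, "EBA", "weighted_mean")


class TestDecoding:
    def test_separable_mean_trained_accuracy_high(self):
        vols = zscore_patterns(_volume_set(n_per_cond=20, n_voxels=60, sep=1.5))
        accs = classify_subject_roi(vols, 0, "EBA", alpha=0.5)
        assert accs["mean"] >= 0.90

    def test_permutation_null_centers_on_chance(self):
        vols = zscore_patterns(_volume_set(n_per_cond=10, n_voxels=40, sep=1.0))
        mask = training_run_feature_mask(vols, 0, "EBA")
        X, y = build_training_patterns(vols, 0, "EBA", "mean")
        test_X, test_y = person_test_set(vols, 0, "EBA")
        accs = permutation_null(X, y, test_X, test_y, mask, n_permutations=100, seed=5)
        assert abs(accs.mean() - CHANCE) < 0.03

    def test_duplicated_test_set_gives_identical_accuracy(self):
        vols = zscore_patterns(_volume_set(n_per_cond=6))
        mask = training_run_feature_mask(vols, 0, "EBA")
        X, y = build_training_patterns(vols, 0, "EBA", "face")
        test_X, test_y = person_test_set(vols, 0, "EBA")
        a1 = decode_person_emotions(X, y, test_X, test_y, mask)
        a2 = decode_person_emotions(
            X, y, np.vstack([test_X, test_X]), np.concatenate([test_y, test_y]), mask
        )
        assert a1 == a2

    def test_single_class_training_rejected(self, rng):
        with pytest.raises(StructuralError, match="single class"):
            decode_person_emotions(
                rng.standard_normal((10, 4)),
                np.repeat("anger", 10),
                rng.standard_normal((5, 4)),
                np.repeat("anger", 5),
            )

    def test_feature_mask_ignores_test_run_content(self):
        vols = zscore_patterns(_volume_set(n_per_cond=8, seed=3))
        mask1 = training_run_feature_mask(vols, 0, "EBA")
        # corrupt the held-out run: the mask must not change (leakage guard)
        rng = np.random.default_rng(0)
        for emo in EMOTIONS:
            vols.volumes[(0, 3, "EBA", "person", emo)] = rng.standard_normal(
                vols.get(0, 3, "EBA", "person", emo).shape
            )
        mask2 = training_run_feature_mask(vols, 0, "EBA")
        assert np.array_equal(mask1.mask, mask2.mask)


class TestGroupFdr:
    @staticmethod
    def _acc_table(p_per_cell, n_rois=7, n_types=4):
        rng = np.random.default_rng(0)
        rows = []
        for roi in range(n_rois):
            for t in range(n_types):
                for s in range(5):
                    rows.append(
                        {
                            "subject": s,
                            "roi": f"roi{roi}",
                            "training_type": f"type{t}",
                            "accuracy": 1 / 3 + rng.normal(0.1, 0.02),
                        }
                    )
        return pd.DataFrame(rows)

    def test_seven_rois_four_types_gives_28_comparisons(self):
        out = group_test_and_fdr(self._acc_table(None))
        assert len(out) == 28
        assert out.attrs["n_comparisons"] == 28

    def test_bh_all_equal_small_p_all_significant(self):
        # 28 tests all with raw p = 0.01 at q = 0.05: BH keeps every one
        from statsmodels.stats.multitest import multipletests

        reject, p_adj, *_ = multipletests([0.01] * 28, alpha=0.05, method="fdr_bh")
        assert reject.all()
        np.testing.assert_allclose(p_adj, 0.01)

    def test_single_test_adjusted_equals_raw(self):
        from statsmodels.stats.multitest import multipletests

        _, p_adj, *_ = multipletests([0.037], alpha=0.05, method="fdr_bh")
        assert p_adj[0] == pytest.approx(0.037)

    @settings(derandomize=True, max_examples=30)
    @given(st.lists(st.floats(1e-6, 1.0), min_size=2, max_size=28))
    def test_bh_monotone_and_never_below_raw(self, ps):
        from statsmodels.stats.multitest import multipletests

        _, p_adj, *_ = multipletests(ps, alpha=0.05, method="fdr_bh")
        order = np.argsort(ps)
        assert np.all(np.diff(p_adj[order]) >= -1e-12)
        assert np.all(p_adj >= np.asarray(ps) - 1e-12)

    def test_missing_subject_cell_rejected(self):
        tab = self._acc_table(None)
        with pytest.raises(StructuralError, match="missing"):
            group_test_and_fdr(tab.drop(tab.index[0]))
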