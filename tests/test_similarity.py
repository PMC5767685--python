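"""Pattern-similarity contracts: synthetic means, Fisher z, cross-run
correlations, RSM structure, and the Category × Emotion ANOVA."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import full_cells_from_run_vectors, make_pattern_dataset
from partwhole.config import CONDITIONS, EMOTIONS
from partwhole.errors import DomainError, StructuralError
from partwhole.similarity import (
    R_CLIP,
    build_rsm,
    category_emotion_anova,
    correlation_table,
    cross_run_correlation,
    fisher_z,
    group_average_rsm,
    synthetic_mean,
)
from partwhole.stats import rm_anova_two_way


class TestSyntheticMean:
    def test_elementwise_average(self):
        np.testing.assert_array_equal(
            synthetic_mean([1, 3, 5], [3, 1, 1]), [2.0, 2.0, 3.0]
        )

    def test_idempotent_on_identical_patterns(self, rng):
        v = rng.standard_normal(40)
        np.testing.assert_array_equal(synthetic_mean(v, v), v)

    def test_equals_weighted_mean_at_half(self, rng):
        from partwhole.weights import weighted_mean

        f, b = rng.standard_normal(100), rng.standard_normal(100)
        np.testing.assert_array_equal(synthetic_mean(f, b), weighted_mean(f, b, 0.5))

    def test_length_mismatch_raises(self):
        with pytest.raises(StructuralError, match="mismatch"):
            synthetic_mean([1, 2], [1, 2, 3])


class TestFisherZ:
    def test_zero_is_fixed_point(self):
        assert fisher_z(0.0) == 0.0

    def test_half_matches_closed_form(self):
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)

    def test_unit_correlation_clipped_finite(self):
        z = fisher_z(1.0)
        assert np.isfinite(z)
        assert z == pytest.approx(np.arctanh(R_CLIP))

    def test_out_of_domain_raises(self):
        with pytest.raises(DomainError):
            fisher_z(1.5)

    @settings(derandomize=True, max_examples=50)
    @given(
        st.floats(-1, 1, allow_nan=False),
        st.floats(-1, 1, allow_nan=False),
    )
    def test_strictly_increasing(self, a, b):
        if a < b:
            assert fisher_z(a) < fisher_z(b) or (
                # both clipped to the same bound
                min(abs(a), abs(b)) >= R_CLIP
            )


def _three_run_dataset(vectors_by_run):
    """vectors_by_run[(run)] -> dict of per-condition vectors; fill others."""
    rng = np.random.default_rng(0)
    run_vectors = {}
    for r in range(3):
        for bt, emo in CONDITIONS:
            run_vectors[(r, bt, emo)] = vectors_by_run.get(
                (r, bt, emo), rng.standard_normal(8)
            )
    return make_pattern_dataset(full_cells_from_run_vectors(run_vectors))


class TestCrossRunCorrelation:
    def test_identical_patterns_hit_clip_maximum(self):
        v = np.array([1.0, 2.0, -1.0, 3.0, 0.5, -2.0, 1.5, 0.0])
        ds = _three_run_dataset({(r, "person", "anger"): v for r in range(3)})
        res = cross_run_correlation(ds, 0, "EBA", "anger", "person", "person")
        assert res.z == pytest.approx(np.arctanh(R_CLIP))
        assert res.n_comparisons == 3  # same category: one direction per run pair

    def test_collinear_cross_category_gives_clipped_z(self):
        base = np.array([1.0, 2.0, 3.0, 4.0])
        ds = make_pattern_dataset(
            full_cells_from_run_vectors(
                {
                    (r, bt, emo): (
                        base if (bt, emo) == ("face", "fear") and r == 0
                        else 2 * base if (bt, emo) == ("person", "fear") and r == 1
                        else base + np.random.default_rng(r * 10 + 1).standard_normal(4)
                    )
                    for r in range(3)
                    for bt, emo in CONDITIONS
                }
            )
        )
        x = ds.get(0, 0, "EBA", "face", "fear")
        y = ds.get(0, 1, "EBA", "person", "fear")
        r = np.corrcoef(x, y)[0, 1]
        assert r == pytest.approx(1.0)
        assert fisher_z(r) == pytest.approx(np.arctanh(R_CLIP))

    def test_orthogonal_patterns_give_near_zero_z(self, rng):
        V = 402
        # patterns with disjoint support are orthogonal across runs
        cells = {}
        for r in range(3):
            v = np.zeros(V)
            v[r * (V // 3) : (r + 1) * (V // 3)] = rng.standard_normal(V // 3)
            cells[(0, r, "EBA", "person", "fear")] = v
        ds = make_pattern_dataset(cells)
        res = cross_run_correlation(ds, 0, "EBA", "fear", "person", "person")
        assert abs(res.z) < 2 / np.sqrt(V - 3)

    def test_distinct_categories_average_six_directed_comparisons(self):
        ds = _three_run_dataset({})
        res = cross_run_correlation(ds, 0, "EBA", "anger", "face", "person")
        assert res.n_comparisons == 6

    def test_zero_variance_pattern_skips_pair_with_warning(self):
        ds = _three_run_dataset({(0, "face", "anger"): np.ones(8)})
        with pytest.warns(UserWarning, match="zero-variance"):
            res = cross_run_correlation(ds, 0, "EBA", "anger", "face", "person")
        assert res.n_comparisons == 4  # run-0 face enters 2 of the 6 comparisons


class TestRSM:
    def test_symmetry_and_category_labels(self):
        ds = _three_run_dataset({})
        rsm = build_rsm(ds, 0, "EBA", "anger")
        assert list(rsm.index) == ["face", "body", "person", "synthetic"]
        np.testing.assert_allclose(rsm.to_numpy(), rsm.to_numpy().T)

    def test_permutation_equivariance(self):
        ds = _three_run_dataset({})
        rsm = build_rsm(ds, 0, "EBA", "fear", categories=("face", "body", "person"))
        perm = ("person", "face", "body")
        rsm_p = build_rsm(ds, 0, "EBA", "fear", categories=perm)
        reordered = rsm.loc[list(perm), list(perm)]
        np.testing.assert_allclose(rsm_p.to_numpy(), reordered.to_numpy())

    def test_group_average_identity_and_cancellation(self):
        ds = _three_run_dataset({})
        m = build_rsm(ds, 0, "EBA", "anger")
        assert group_average_rsm([m]).equals(m)
        np.testing.assert_allclose(group_average_rsm([m, -m]).to_numpy(), 0.0)

    def test_part_based_data_ranks_synthetic_above_parts(self, part_based_dataset):
        ds = part_based_dataset
        wins = 0
        for s in range(20):
            rsm = build_rsm(ds, s, "EBA", "anger")
            ps = rsm.loc["person", "synthetic"]
            if ps > rsm.loc["person", "face"] and ps > rsm.loc["person", "body"]:
                wins += 1
        assert wins >= 18


class TestCategoryEmotionAnova:
    @staticmethod
    def _null_cube(rng, n=20):
        # within-subject correlated cells, no Category/Emotion effect
        subj = rng.standard_normal((n, 1, 1))
        return subj + rng.standard_normal((n, 2, 3))

    def test_type_i_error_calibrated_at_5pct(self):
        rng = np.random.default_rng(2024)
        rejections = 0
        n_rep = 1000
        for _ in range(n_rep):
            tab = rm_anova_two_way(self._null_cube(rng), ("category", "emotion"))
            if tab.loc[tab["source"] == "category", "p"].iloc[0] < 0.05:
                rejections += 1
        assert rejections / n_rep == pytest.approx(0.05, abs=0.015)

    def test_category_offset_detected_interaction_null(self):
        rng = np.random.default_rng(7)
        ps_cat, ps_int = [], []
        for _ in range(20):
            cube = self._null_cube(rng)
            cube[:, 1, :] += 1.0  # constant additive Category offset
            tab = rm_anova_two_way(cube, ("category", "emotion"))
            ps_cat.append(tab.loc[tab["source"] == "category", "p"].iloc[0])
            ps_int.append(tab.loc[tab["source"] == "category x emotion", "p"].iloc[0])
        assert np.median(ps_cat) < 0.01
        assert np.mean(np.asarray(ps_int) < 0.05) < 0.3  # interaction stays null

    def test_identical_cells_flagged_degenerate(self):
        cube = np.ones((5, 2, 3))
        tab = rm_anova_two_way(cube)
        assert tab["degenerate"].all()
        assert tab["F"].isna().all()

    def test_matches_pingouin_on_random_instances(self, rng):
        pingouin = pytest.importorskip("pingouin")
        for _ in range(5):
            cube = rng.standard_normal((12, 2, 3)) + rng.standard_normal((12, 1, 1))
            mine = rm_anova_two_way(cube, ("A", "B"))
            rows = [
                {"subject": s, "A": f"a{i}", "B": f"b{j}", "y": cube[s, i, j]}
                for s in range(12)
                for i in range(2)
                for j in range(3)
            ]
            theirs = pingouin.rm_anova(
                data=pd.DataFrame(rows), dv="y", within=["A", "B"], subject="subject",
                detailed=True,
            )
            for src_mine, src_pg in (("A", "A"), ("B", "B"), ("A x B", "A * B")):
                f_mine = mine.loc[mine["source"] == src_mine, "F"].iloc[0]
                f_pg = theirs.loc[theirs["Source"] == src_pg, "F"].iloc[0]
                assert f_mine == pytest.approx(f_pg, rel=1e-6)

    def test_unbalanced_table_rejected(self, part_based_dataset):
        corr = correlation_table(part_based_dataset, rois=("EBA",))
        drop_idx = corr[
            (corr["cat_a"] == "person") & (corr["cat_b"] == "synthetic")
        ].index[0]
        broken = corr.drop(drop_idx)
        with pytest.raises(StructuralError, match="unbalanced|empty"):
            category_emotion_anova(broken, "EBA", "person_face_vs_synthetic")

    def test_part_based_generation_yields_category_main_effect(self, part_based_dataset):
        corr = correlation_table(part_based_dataset, rois=("EBA",))
        tab = category_emotion_anova(corr, "EBA", "person_face_vs_synthetic")
        p = tab.loc[tab["source"] == "category", "p"].iloc[0]
        assert p < 0.05
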