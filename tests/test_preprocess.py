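import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from adenomet.preprocess import (
    PathwayProfiles,
    aggregate_pathways,
    arcsine_sqrt_transform,
    filter_genera,
    filter_metabolites,
    log10_transform,
    scale_impute,
    subpathway_pc1,
)

from conftest import make_annotation, make_table


class TestScaleImpute:
    def test_median_scaling_and_min_imputation(self):
        det = np.array([[True], [True], [True], [False]])
        t = make_table([[2.0], [4.0], [6.0], [0.0]], detected=det)
        out = scale_impute(t)
        np.testing.assert_allclose(out.values[:, 0], [0.5, 1.0, 1.5, 0.5])
        np.testing.assert_array_equal(out.detected, det)
        assert out.scale_tag == "scaled_imputed"

    def test_constant_feature_becomes_ones(self):
        t = make_table(np.full((5, 1), 7.0))
        np.testing.assert_allclose(scale_impute(t).values, 1.0)

    def test_detected_median_is_one_on_random_table(self):
        rng = np.random.default_rng(1)
        vals = rng.lognormal(0, 1, (20, 50))
        det = rng.random((20, 50)) > 0.2
        det[0] = True  # ensure every feature detected at least once
        out = scale_impute(make_table(vals, detected=det))
        for j in range(out.n_features):
            med = np.median(out.values[out.detected[:, j], j])
            assert med == pytest.approx(1.0, abs=1e-9)

    def test_never_detected_feature_dropped(self):
        det = np.array([[True, False], [True, False]])
        t = make_table([[1.0, 1.0], [2.0, 2.0]], detected=det)
        out = scale_impute(t)
        assert out.feature_ids == ["f0"]

    def test_then_log10_is_finite(self):
        rng = np.random.default_rng(2)
        vals = rng.lognormal(0, 2, (15, 30))
        det = rng.random((15, 30)) > 0.4
        det[0] = True
        lg = log10_transform(scale_impute(make_table(vals, detected=det)))
        assert np.isfinite(lg.values).all()


class TestFilters:
    def _prev_table(self, n_detected, n_samples=204):
        det = np.zeros((n_samples, 1), bool)
        det[:n_detected, 0] = True
        vals = np.where(det, 1.0, np.nan)
        return make_table(vals, detected=det, tag="scaled_imputed")

    def test_prevalence_boundary_is_inclusive(self):
        annot = make_annotation(["f0"], ["S"], ["sub"])
        t163 = self._prev_table(163)   # 163/204 = 0.799 -> dropped
        with pytest.raises(ValueError):
            filter_metabolites(t163, annot, t163.sample_ids, 0.8)
        t164 = self._prev_table(164)   # 164/204 = 0.8039 -> retained
        out = filter_metabolites(t164, annot, t164.sample_ids, 0.8)
        assert out.feature_ids == ["f0"]

    def test_unknown_identity_dropped(self):
        t = make_table(np.ones((10, 2)), tag="scaled_imputed")
        annot = make_annotation(["f0", "f1"], ["S", ""], ["sub", ""],
                                known=[True, False])
        out = filter_metabolites(t, annot, t.sample_ids, 0.5)
        assert out.feature_ids == ["f0"]

    def test_carcinoma_samples_do_not_influence_filter(self):
        # feature detected in all of the first 8 samples, none of the rest
        det = np.zeros((12, 1), bool)
        det[:8, 0] = True
        t = make_table(np.where(det, 1.0, np.nan), detected=det,
                       tag="scaled_imputed")
        annot = make_annotation(["f0"], ["S"], ["sub"])
        subset = t.sample_ids[:8]
        out = filter_metabolites(t, annot, subset, 0.8)
        assert out.feature_ids == ["f0"]
        assert out.n_samples == 12   # subset only drives the filter

    def test_genus_prevalence_boundary(self):
        vals = np.zeros((204, 2))
        vals[:40, 0] = 0.1   # 0.196 -> dropped
        vals[:41, 1] = 0.1   # 0.201 -> retained
        g = make_table(vals)
        out = filter_genera(g, g.sample_ids, 0.2)
        assert out.feature_ids == ["f1"]

    def test_filtering_idempotent(self):
        rng = np.random.default_rng(4)
        vals = rng.random((30, 10))
        vals[vals < 0.4] = 0
        g = make_table(vals)
        once = filter_genera(g, g.sample_ids, 0.3)
        twice = filter_genera(once, once.sample_ids, 0.3)
        assert twice.feature_ids == once.feature_ids
        np.testing.assert_array_equal(twice.values, once.values)


class TestTransforms:
    def test_log10_values(self):
        t = make_table([[1.0, 1000.0]], tag="scaled_imputed")
        out = log10_transform(t)
        np.testing.assert_allclose(out.values, [[0.0, 3.0]])

    def test_log10_round_trip(self):
        rng = np.random.default_rng(5)
        vals = rng.lognormal(0, 1, (6, 8))
        out = log10_transform(make_table(vals, tag="scaled_imputed"))
        np.testing.assert_allclose(10 ** out.values, vals, rtol=1e-12)

    def test_log10_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            log10_transform(make_table([[0.0, 1.0]], tag="scaled_imputed"))

    @pytest.mark.parametrize("x,expected", [
        (0.0, 0.0),
        (1.0, np.pi / 2),
        (0.25, np.pi / 6),
    ])
    def test_arcsine_sqrt_closed_forms(self, x, expected):
        out = arcsine_sqrt_transform(make_table([[x]]))
        assert out.values[0, 0] == pytest.approx(expected, abs=1e-12)

    def test_arcsine_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            arcsine_sqrt_transform(make_table([[1.5]]))

    @settings(derandomize=True, max_examples=50)
    @given(st.floats(min_value=0, max_value=1))
    def test_arcsine_monotone_and_bounded(self, x):
        out = arcsine_sqrt_transform(make_table([[x, min(1.0, x + 1e-3)]]))
        a, b = out.values[0]
        assert 0 <= a <= np.pi / 2 + 1e-12
        assert b >= a


class TestPathways:
    def _table_and_annot(self, sizes, n_samples=12, seed=0):
        rng = np.random.default_rng(seed)
        fids, supers, subs = [], [], []
        for k, size in enumerate(sizes):
            for i in range(size):
                fids.append(f"p{k}_m{i}")
                supers.append(f"S{k % 2}")
                subs.append(f"sub{k}")
        t = make_table(rng.normal(size=(n_samples, len(fids))),
                       feature_ids=fids, tag="log10")
        return t, make_annotation(fids, supers, subs)

    def test_min_size_excludes_small_pathways(self):
        t, annot = self._table_and_annot([4, 5, 6, 7])
        profs = aggregate_pathways(t, annot, "subpathway", min_size=5)
        assert sorted(p.pathway_id for p in profs) == ["sub1", "sub2", "sub3"]

    def test_member_order_lexicographic(self):
        t, annot = self._table_and_annot([6])
        prof = aggregate_pathways(t, annot, "subpathway", 5)[0]
        assert prof.member_feature_ids == sorted(prof.member_feature_ids)

    def test_pc1_perfectly_correlated_members(self):
        rng = np.random.default_rng(7)
        signal = rng.normal(size=20)
        members = np.column_stack([2.0 * signal + 1.0, 0.5 * signal,
                                   3.0 * signal - 2.0, signal, 1.5 * signal])
        prof = PathwayProfiles("sub", "subpathway",
                               [f"m{i}" for i in range(5)], members,
                               [f"s{i}" for i in range(20)])
        out = subpathway_pc1(prof, 0.2)
        assert out.pc1_var_explained == pytest.approx(1.0)
        r = np.corrcoef(out.pc1_scores, members.mean(axis=1))[0, 1]
        assert r == pytest.approx(1.0, abs=1e-9)
        assert abs(out.pc1_scores.mean()) < 1e-8

    def test_sign_flip_makes_representation_deterministic(self):
        rng = np.random.default_rng(8)
        X = rng.normal(size=(15, 6))
        prof_pos = PathwayProfiles("a", "subpathway",
                                   [f"m{i}" for i in range(6)], X,
                                   [f"s{i}" for i in range(15)])
        prof_neg = PathwayProfiles("a", "subpathway",
                                   [f"m{i}" for i in range(6)], -X,
                                   [f"s{i}" for i in range(15)])
        out_pos = subpathway_pc1(prof_pos, 0.0)
        out_neg = subpathway_pc1(prof_neg, 0.0)
        # flipping every member profile flips the mean profile too, so the
        # anchored scores are exactly negated, never arbitrary
        np.testing.assert_allclose(out_pos.pc1_scores, -out_neg.pc1_scores,
                                   atol=1e-8)

    def test_low_variance_pc1_excluded(self):
        rng = np.random.default_rng(9)
        X = rng.normal(size=(30, 8))   # isotropic noise: PC1 well under 50%
        prof = PathwayProfiles("a", "subpathway",
                               [f"m{i}" for i in range(8)], X,
                               [f"s{i}" for i in range(30)])
        assert subpathway_pc1(prof, 0.5) is None

    def test_zero_variance_excluded(self):
        X = np.ones((10, 5))
        prof = PathwayProfiles("a", "subpathway",
                               [f"m{i}" for i in range(5)], X,
                               [f"s{i}" for i in range(10)])
        assert subpathway_pc1(prof, 0.2) is None
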