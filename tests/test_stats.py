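"""Vertexwise ANCOVA, cluster formation, permutation FWE, scalar tests."""

import numpy as np
import pandas as pd
import pytest

import surfreho as sr
from surfreho.reho import reho_surface
from surfreho.stats import (CohortDesign, GlmResult, cluster_fwe,
                            fit_vertex_glm, form_clusters,
                            group_compare_scalars, pearson_corr,
                            sex_ratio_chi2)


def make_design(n_pat=8, n_con=8, seed=0):
    rng = np.random.default_rng(seed)
    n = n_pat + n_con
    return CohortDesign(pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(n)],
        "group": ["patient"] * n_pat + ["control"] * n_con,
        "age": rng.normal(35, 10, n),
        "sex": rng.choice(["M", "F"], n),
        "education": rng.normal(13, 3, n),
        "mcbbr": rng.normal(0.6, 0.05, n),
        "rmsfd": np.abs(rng.normal(0.14, 0.04, n)),
    }))


class TestDesign:
    def test_design_matrix_shape_and_coding(self):
        d = make_design()
        X, names = d.design_matrix()
        assert X.shape == (16, 7)
        assert names == ["intercept", "group", "age", "sex", "education",
                         "mcbbr", "rmsfd"]
        np.testing.assert_array_equal(X[:, 1], [1] * 8 + [0] * 8)

    def test_duplicated_covariate_rank_deficiency(self):
        d = make_design()
        d.table["age2"] = d.table["age"]
        dup = CohortDesign(d.table, covariate_columns=("age", "age2", "sex"))
        with pytest.raises(ValueError, match="rank-deficient"):
            dup.design_matrix()

    def test_missing_column_rejected(self):
        with pytest.raises(ValueError, match="missing"):
            CohortDesign(pd.DataFrame({"subject_id": ["a"], "group": ["patient"]}))


class TestVertexGlm:
    def test_parameter_recovery_of_injected_group_shift(self, rng):
        d = make_design(12, 12, seed=1)
        effect = 0.2
        Y = rng.normal(0.5, 0.05, size=(24, 40))
        Y[:12, :10] -= effect  # patients lower at the first 10 vertices
        res = fit_vertex_glm(Y, d)
        assert res.df == 24 - 7
        se = np.sqrt(np.var(res.coef[10:]))  # spread of null coefficients
        assert np.mean(res.coef[:10]) == pytest.approx(-effect, abs=2 * se)
        assert np.all(res.p > 0) and np.all(res.p <= 1)

    def test_constant_shift_changes_no_t(self, rng):
        d = make_design(6, 6, seed=2)
        Y = rng.normal(size=(12, 30))
        r0 = fit_vertex_glm(Y, d)
        r1 = fit_vertex_glm(Y + 5.0, d)
        np.testing.assert_allclose(r1.t, r0.t, atol=1e-8)

    def test_nan_vertices_propagate(self, rng):
        d = make_design(5, 5, seed=3)
        Y = rng.normal(size=(10, 8))
        Y[3, 2] = np.nan
        res = fit_vertex_glm(Y, d)
        assert np.isnan(res.t[2]) and np.isfinite(res.t[[0, 1, 3]]).all()

    def test_too_few_per_group_rejected(self, rng):
        d = make_design(1, 9, seed=4)
        with pytest.raises(ValueError, match="2 subjects per group"):
            fit_vertex_glm(rng.normal(size=(10, 5)), d)


class TestClusterFormation:
    def _result_from_t(self, mesh, tvals, df=20):
        from scipy import stats as sps
        p = 2 * sps.t.sf(np.abs(tvals), df)
        return GlmResult(coef=np.sign(tvals) * np.abs(tvals), t=tvals, p=p,
                         df=df, sigma2=np.ones_like(tvals))

    def test_no_suprathreshold_gives_empty(self, ico2):
        res = self._result_from_t(ico2, np.zeros(ico2.n_vertices))
        assert form_clusters(res, ico2) == []

    def test_two_planted_patches_recovered(self, ico2):
        t = np.zeros(ico2.n_vertices)
        patch_a = sr.k_ring(ico2, 20, 1)
        patch_b = sr.k_ring(ico2, 130, 1)
        assert not set(patch_a) & set(patch_b)
        t[patch_a] = 6.0
        t[patch_b] = -6.0
        clusters = form_clusters(self._result_from_t(ico2, t), ico2)
        assert len(clusters) == 2
        by_sign = {c.sign: set(c.vertices.tolist()) for c in clusters}
        assert by_sign["positive"] == set(patch_a.tolist())
        assert by_sign["negative"] == set(patch_b.tolist())
        areas = sr.vertex_areas(ico2)
        pos = next(c for c in clusters if c.sign == "positive")
        assert pos.extent_area == pytest.approx(areas[patch_a].sum())
        assert pos.extent_vertices == len(patch_a)

    def test_adjacent_opposite_signs_split(self, ico2):
        t = np.zeros(ico2.n_vertices)
        ring = sr.k_ring(ico2, 50, 1)
        half = len(ring) // 2
        t[ring[:half]] = 5.0
        t[ring[half:]] = -5.0
        clusters = form_clusters(self._result_from_t(ico2, t), ico2)
        signs = sorted(c.sign for c in clusters)
        assert "positive" in signs and "negative" in signs


class TestClusterFwe:
    def _cohort_maps(self, ico2, seed, effect=False):
        rois = []
        if effect:
            rois = [sr.default_effect_roi(ico2, 0.1, 0.45, rings=2)]
        spec = sr.SyntheticSpec(n_patients=10, n_controls=10, n_frames=100,
                                effect_rois=rois, seed=seed)
        coh = sr.simulate_cohort(ico2, spec)
        nb = sr.build_neighborhoods(ico2, "ring1")
        maps = [reho_surface(s.bold, nb) for s in coh.subjects]
        return maps, CohortDesign(coh.phenotype), rois

    def test_determinism(self, ico2):
        maps, design, _ = self._cohort_maps(ico2, 11)
        a = cluster_fwe(maps, design, ico2, n_perm=100, seed=5)
        b = cluster_fwe(maps, design, ico2, n_perm=100, seed=5)
        np.testing.assert_array_equal(a.null_max_extents, b.null_max_extents)
        assert [c.corrected_p for c in a.clusters] == [c.corrected_p for c in b.clusters]

    def test_strong_effect_detected_at_floor_p(self, ico2):
        maps, design, rois = self._cohort_maps(ico2, 12, effect=True)
        rep = cluster_fwe(maps, design, ico2, n_perm=100, seed=0)
        neg = rep.significant_clusters("negative")
        assert len(neg) >= 1
        # an extent exceeding every permutation maximum hits the formula floor
        if neg[0].extent_area > rep.null_max_extents.max():
            assert neg[0].corrected_p == pytest.approx(1 / 101)

    def test_corrected_p_monotone_in_extent(self, ico2):
        maps, design, _ = self._cohort_maps(ico2, 13, effect=True)
        rep = cluster_fwe(maps, design, ico2, n_perm=100, seed=1)
        ordered = sorted(rep.clusters, key=lambda c: c.extent_area)
        ps = [c.corrected_p for c in ordered]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_alpha_resolution_warning(self, ico2):
        maps, design, _ = self._cohort_maps(ico2, 14)
        rep = cluster_fwe(maps, design, ico2, alpha=0.001, n_perm=100, seed=0)
        assert rep.warnings


class TestScalarComparisons:
    def test_pearson_perfect_line(self):
        x = np.array([1.0, 2, 3, 4, 5])
        r, p = pearson_corr(x, 2 * x + 1)
        assert r == pytest.approx(1.0)

    def test_pearson_hand_computed_four_points(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([2.0, 1, 4, 3])
        # covariance formula oracle
        r_ref = (np.sum((x - x.mean()) * (y - y.mean()))
                 / np.sqrt(np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)))
        r, _ = pearson_corr(x, y)
        assert r == pytest.approx(r_ref, abs=1e-12)

    def test_pearson_null_p_uniform(self, rng):
        ps = []
        for _ in range(1000):
            x = rng.standard_normal(33)
            y = rng.standard_normal(33)
            ps.append(pearson_corr(x, y)[1])
        from scipy import stats as sps
        assert sps.kstest(ps, "uniform").pvalue > 0.01

    def test_pearson_constant_rejected(self):
        with pytest.raises(ValueError):
            pearson_corr(np.ones(5), np.arange(5.0))

    def test_identical_groups_t_zero(self):
        d = make_design(4, 4, seed=5)
        vals = np.tile(np.array([1.0, 2, 3, 4]), 2)
        t, p = group_compare_scalars(d, vals)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_pooled_t_matches_textbook_formula(self, rng):
        d = make_design(6, 9, seed=6)
        vals = rng.standard_normal(15)
        a, b = vals[:6], vals[6:]
        sp2 = ((5 * a.var(ddof=1) + 8 * b.var(ddof=1)) / 13)
        t_ref = (a.mean() - b.mean()) / np.sqrt(sp2 * (1 / 6 + 1 / 9))
        t, _ = group_compare_scalars(d, vals)
        assert t == pytest.approx(t_ref, rel=1e-12)

    def test_chi2_identical_ratio_zero(self):
        t = pd.DataFrame({
            "subject_id": [f"s{i}" for i in range(8)],
            "group": ["patient"] * 4 + ["control"] * 4,
            "sex": ["M", "M", "F", "F"] * 2,
            "age": 30.0, "education": 12.0, "mcbbr": 0.6, "rmsfd": 0.1,
        })
        chi2, p = sex_ratio_chi2(CohortDesign(t))
        assert chi2 == pytest.approx(0.0)
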