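"""Voxelwise GLM, cluster inference, FDR and scalar statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from mtvbm.glm import (
    GLMDesign,
    anova_from_summary,
    cluster_threshold,
    design_from_records,
    fdr_adjust,
    glm_fit,
    interaction_analysis,
    permutation_cluster_pvalues,
    spearman_rho,
)
from mtvbm.phantom import SubjectRecord
from oracles import flood_fill_extents, spearman_oracle


def _records(n_per_group, rng, med=False):
    recs = []
    for g in ("control", "patient"):
        for i in range(n_per_group):
            recs.append(
                SubjectRecord(
                    id=f"{g}{i}", group=g,
                    age=rng.normal(33, 9), tiv=rng.normal(1450, 130),
                    bdi=rng.normal(10, 7), stai=rng.normal(45, 11),
                    med_months=max(0.0, rng.normal(30, 40)) if g == "patient" else 0.0,
                )
            )
    return recs


class TestDesign:
    def test_collinear_columns_named(self):
        x = np.ones((10, 3))
        x[:, 1] = np.arange(10)
        x[:, 2] = 2 * np.arange(10)  # collinear with column 1
        with pytest.raises(ValueError, match="x2"):
            GLMDesign(matrix=x, names=["intercept", "x1", "x2"],
                      contrast=np.array([0.0, 1.0, 0.0]))

    def test_design_from_records_shape_and_contrast(self, rng):
        recs = _records(5, rng)
        d = design_from_records(recs)
        assert d.matrix.shape == (10, 6)
        assert d.names[:2] == ["intercept", "group_patient"]
        assert d.contrast[d.names.index("group_patient")] == -1.0


class TestGlmFit:
    def test_known_truth_group_coefficient(self, rng):
        """y = 2*group + noise recovers the group effect within 3 SE."""
        n = 200
        group = np.repeat([0.0, 1.0], n // 2)
        y = (2.0 * group + rng.standard_normal(n))[None, :]
        x = np.column_stack([np.ones(n), group])
        design = GLMDesign(matrix=x, names=["intercept", "group"],
                           contrast=np.array([0.0, 1.0]))
        res = glm_fit(y, design, two_sided=True)
        beta = np.linalg.lstsq(x, y.ravel(), rcond=None)[0][1]
        se = beta / res.values[0]
        assert abs(beta - 2.0) < 3 * se

    def test_matches_closed_form_two_sample_t(self, rng):
        """On a group-only design the GLM t equals the pooled two-sample t."""
        a = rng.normal(0.0, 1.0, 15)
        b = rng.normal(0.7, 1.0, 15)
        y = np.concatenate([a, b])[None, :]
        x = np.column_stack([np.ones(30), np.repeat([0.0, 1.0], 15)])
        design = GLMDesign(matrix=x, names=["i", "g"], contrast=np.array([0.0, 1.0]))
        res = glm_fit(y, design, two_sided=True)
        ref = stats.ttest_ind(b, a, equal_var=True)
        assert res.values[0] == pytest.approx(ref.statistic, rel=1e-10)
        assert res.p[0] == pytest.approx(ref.pvalue, rel=1e-10)

    def test_zero_residual_saturates(self):
        y = np.full((1, 10), 3.0)
        x = np.ones((10, 1))
        design = GLMDesign(matrix=x, names=["i"], contrast=np.array([1.0]))
        res = glm_fit(y, design)
        assert np.isinf(res.values[0])
        assert res.p[0] == 0.0
        assert res.saturated[0]

    def test_type_one_error_calibration(self, rng):
        """Null data at alpha=0.05 rejects ~5% of voxels."""
        n, v = 40, 4000
        y = rng.standard_normal((v, n))
        x = np.column_stack([np.ones(n), np.repeat([0.0, 1.0], n // 2)])
        design = GLMDesign(matrix=x, names=["i", "g"], contrast=np.array([0.0, 1.0]))
        res = glm_fit(y, design, two_sided=True)
        frac = (res.p < 0.05).mean()
        # 3 binomial SEs around 0.05
        assert abs(frac - 0.05) < 3 * np.sqrt(0.05 * 0.95 / v)


class TestClusterThreshold:
    def test_empty_table_when_nothing_survives(self):
        table = cluster_threshold(np.ones((5, 5, 5)))
        assert len(table) == 0

    def test_corner_touching_voxels_are_two_clusters_at_18(self):
        p = np.ones((4, 4, 4))
        p[1, 1, 1] = 1e-5
        p[2, 2, 2] = 1e-5  # shares only a corner: 26-connected, not 18
        table = cluster_threshold(p, p_form=0.001, connectivity=18)
        assert len(table) == 2
        table26 = cluster_threshold(p, p_form=0.001, connectivity=26)
        assert len(table26) == 1

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_extents_match_flood_fill_oracle(self, rng, connectivity):
        mask = rng.random((20, 20, 20)) < 0.3
        p = np.where(mask, 1e-6, 0.5)
        table = cluster_threshold(p, p_form=0.001, connectivity=connectivity)
        assert sorted(table["extent"]) == flood_fill_extents(mask, connectivity)

    def test_peak_tie_break_lowest_linear_index(self):
        p = np.ones((4, 4, 4))
        stat = np.zeros((4, 4, 4))
        p[1, 1, 1] = p[1, 1, 2] = 1e-5
        stat[1, 1, 1] = stat[1, 1, 2] = 5.0  # tied peaks
        table = cluster_threshold(p, stat, p_form=0.001)
        assert (table.loc[0, ["peak_i", "peak_j", "peak_k"]].tolist()) == [1, 1, 1]


class TestPermutationClusters:
    def _setup(self, rng, n=20, shape=(12, 12, 12), effect=0.0):
        mask = np.ones(shape, dtype=bool)
        group = np.repeat([0.0, 1.0], n // 2)
        y = rng.standard_normal((mask.sum(), n))
        if effect:
            y[:100, :] -= effect * group[None, :]  # control > patient block
        x = np.column_stack([np.ones(n), group])
        design = GLMDesign(matrix=x, names=["i", "g"], contrast=np.array([0.0, -1.0]))
        return y, design, mask

    def test_rejects_and_warns_on_low_permutation_counts(self, rng):
        y, design, mask = self._setup(rng)
        with pytest.raises(ValueError):
            permutation_cluster_pvalues(y, design, mask, n_perm=10)
        with pytest.warns(UserWarning):
            permutation_cluster_pvalues(y, design, mask, n_perm=30, seed=0)

    def test_extreme_cluster_gets_minimum_pvalue(self, rng):
        """A cluster larger than every permutation maximum lands at
        p = 1/(n_perm+1)."""
        y, design, mask = self._setup(rng, effect=4.0)
        table = permutation_cluster_pvalues(y, design, mask, n_perm=99, seed=1)
        assert len(table) >= 1
        assert table["p_unc"].min() == pytest.approx(1 / 100)

    def test_null_minimum_p_roughly_uniform(self, rng):
        """Under the null the smallest cluster p is approximately uniform
        on its support: P(min p <= 0.2) stays near 0.2."""
        hits, runs = 0, 25
        for r in range(runs):
            local = np.random.default_rng(100 + r)
            y, design, mask = self._setup(local)
            table = permutation_cluster_pvalues(y, design, mask, n_perm=79, seed=r)
            if len(table) and table["p_unc"].min() <= 0.2:
                hits += 1
        se = np.sqrt(0.2 * 0.8 / runs)
        assert abs(hits / runs - 0.2) < 3 * se + 1 / runs

    def test_reproducible_given_seed(self, rng):
        y, design, mask = self._setup(rng, effect=1.0)
        t1 = permutation_cluster_pvalues(y, design, mask, n_perm=49, seed=9)
        t2 = permutation_cluster_pvalues(y, design, mask, n_perm=49, seed=9)
        pd.testing.assert_frame_equal(t1, t2)


class TestFdrAdjust:
    def test_single_pvalue_unchanged(self):
        assert fdr_adjust([0.02])[0] == pytest.approx(0.02)

    def test_hand_computed_step_up_example(self):
        """BH on {0.01, 0.02, 0.03}: 0.03*3/3=0.03, min(0.02*3/2, .03)=0.03,
        min(0.01*3/1, .03)=0.03."""
        np.testing.assert_allclose(
            fdr_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03]
        )

    def test_equal_pvalues_unchanged(self):
        np.testing.assert_allclose(fdr_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            fdr_adjust([0.5, 1.5])


class TestInteraction:
    def test_identical_modalities_have_no_interaction(self, rng):
        recs = _records(10, rng)
        design = design_from_records(recs, covariates=())
        y = rng.standard_normal((500, 20))
        res = interaction_analysis(y, y, design)
        assert np.all(res.p == 1.0) or not np.any(res.p < 0.001)

    def test_effect_in_one_modality_localizes(self, rng):
        """A group effect present only in the first modality produces an
        interaction cluster inside the affected block."""
        recs = _records(15, rng)
        design = design_from_records(recs, covariates=())
        mask = np.ones((10, 10, 10), dtype=bool)
        group = np.array([1.0 if r.group == "patient" else 0.0 for r in recs])
        y_t1 = rng.standard_normal((1000, 30))
        y_mt = y_t1 + rng.standard_normal((1000, 30)) * 0.5
        y_mt[:60] -= 1.5 * group[None, :]
        table = interaction_analysis(
            y_mt, y_t1, design, mask=mask, n_perm=99, seed=0
        )
        assert len(table) >= 1
        labels = table.attrs["cluster_labels"]
        sig = table[table["p_fdr"] < 0.05]
        assert len(sig) >= 1
        hit = labels.ravel()[:60] > 0
        assert hit.any()

    def test_equal_effects_cancel(self, rng):
        """The same group effect in both modalities leaves a null
        interaction."""
        recs = _records(15, rng)
        design = design_from_records(recs, covariates=())
        group = np.array([1.0 if r.group == "patient" else 0.0 for r in recs])
        base = rng.standard_normal((500, 30))
        effect = np.zeros((500, 30))
        effect[:50] = -1.5 * group[None, :]
        y_mt = base + effect + rng.standard_normal((500, 30)) * 0.3
        y_t1 = base + effect + rng.standard_normal((500, 30)) * 0.3
        res = interaction_analysis(y_mt, y_t1, design)
        assert (res.p < 0.001).mean() < 0.01

    def test_mismatched_subjects_rejected(self, rng):
        recs = _records(5, rng)
        design = design_from_records(recs, covariates=())
        with pytest.raises(ValueError):
            interaction_analysis(
                rng.standard_normal((10, 10)), rng.standard_normal((10, 9)), design
            )


class TestAnovaFromSummary:
    def test_matched_age_groups(self):
        """Age summaries of two matched groups of 30 give F(1,58) = 0.20."""
        f, df1, df2, p = anova_from_summary(33.7, 9.51, 30, 32.6, 9.54, 30)
        assert (df1, df2) == (1, 58)
        assert f == pytest.approx(0.20, abs=0.005)
        assert p == pytest.approx(0.66, abs=0.01)

    def test_identical_groups_give_zero(self):
        f, *_ = anova_from_summary(5.0, 2.0, 12, 5.0, 2.0, 12)
        assert f == 0.0

    def test_depression_scores_reconstruction(self):
        """Printed means/SDs reconstruct F = 16.88 (the source's 17.01 came
        from unrounded data; the gap is rounding of the printed summaries)."""
        f, *_ = anova_from_summary(13.7, 8.57, 30, 5.6, 6.57, 30)
        assert f == pytest.approx(16.88, abs=0.01)

    def test_equals_anova_on_realizing_dataset(self):
        """A two-point dataset realizing the summaries gives the same F."""
        m1, s1, n1, m2, s2, n2 = 10.0, 3.0, 8, 12.5, 4.0, 8

        def realize(mean, sd, n):
            # n/2 points at mean-d, n/2 at mean+d with d chosen to give sd
            d = sd * np.sqrt((n - 1) / n)
            return np.concatenate([np.full(n // 2, mean - d), np.full(n // 2, mean + d)])

        a, b = realize(m1, s1, n1), realize(m2, s2, n2)
        ref = stats.f_oneway(a, b)
        f, _, _, p = anova_from_summary(m1, s1, n1, m2, s2, n2)
        assert f == pytest.approx(ref.statistic, rel=1e-10)
        assert p == pytest.approx(ref.pvalue, rel=1e-10)

    def test_degenerate_zero_variance(self):
        f, *_ = anova_from_summary(5.0, 0.0, 5, 5.0, 0.0, 5)
        assert f == 0.0


class TestSpearman:
    def test_monotone_sequences(self):
        x = np.arange(10.0)
        assert spearman_rho(x, x**3)[0] == pytest.approx(1.0)
        assert spearman_rho(x, -x)[0] == pytest.approx(-1.0)

    def test_ties_match_rank_formula_oracle(self):
        x = np.array([1.0, 2.0, 2.0, 3.0, 5.0, 6.0, 7.0, 8.0])
        y = np.array([3.0, 1.0, 4.0, 4.0, 2.0, 6.0, 5.0, 8.0])
        rho, _ = spearman_rho(x, y)
        assert rho == pytest.approx(spearman_oracle(x, y), rel=1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            spearman_rho([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
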