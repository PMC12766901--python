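"""Scalar statistics against library oracles; GLM maps against reductions."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from limbiccog.group_inference import (
    anova_oneway_map,
    bonferroni,
    chi_square_2x2,
    cluster_correct,
    design_matrix,
    group_contrast,
    partial_correlation,
    two_sample_t,
    two_sample_t_summary,
    voxelwise_glm,
)
from limbiccog.imaging_io import BrainMask, MetricMap


def _maps_from_matrix(Y, shape=(4, 4, 4)):
    mask = BrainMask(np.ones(shape, dtype=bool))
    out = []
    for row in Y:
        data = np.zeros(shape)
        data[mask.data] = row
        out.append(MetricMap(data, "reho", mask))
    return out, mask


class TestScalarTests:
    def test_pooled_t_matches_scipy_on_samples(self, rng):
        a, b = rng.standard_normal(20) + 0.5, rng.standard_normal(30)
        got = two_sample_t(a, b)
        want_t, want_p = stats.ttest_ind(a, b, equal_var=True)
        assert got.t == pytest.approx(want_t, abs=1e-12)
        assert got.p == pytest.approx(want_p, abs=1e-12)
        assert got.dof == 48

    def test_identical_groups_give_zero(self):
        assert two_sample_t_summary(5.0, 1.0, 10, 5.0, 1.0, 10).t == 0.0

    def test_degenerate_zero_variance(self):
        assert two_sample_t_summary(3.0, 0.0, 5, 3.0, 0.0, 5).t == 0.0
        with pytest.raises(ValueError, match="degenerate"):
            two_sample_t_summary(3.0, 0.0, 5, 4.0, 0.0, 5)

    def test_chi_square_matches_hand_formula(self, rng):
        table = np.array([[13, 17], [8, 29]])
        got, _ = chi_square_2x2(table)
        expected = table.sum(axis=1)[:, None] * table.sum(axis=0)[None, :] / table.sum()
        want = float(np.sum((table - expected) ** 2 / expected))
        assert got == pytest.approx(want, abs=1e-12)

    def test_chi_square_proportional_table_is_zero(self):
        got, p = chi_square_2x2([[10, 20], [30, 60]])
        assert got == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_chi_square_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            chi_square_2x2([[0, 0], [5, 5]])


class TestPartialCorrelation:
    def test_no_covariates_equals_pearson(self, rng):
        x, y = rng.standard_normal(40), rng.standard_normal(40)
        r, p = partial_correlation(x, y)
        want_r, want_p = stats.pearsonr(x, y)
        assert r == pytest.approx(want_r, abs=1e-12)
        assert p == pytest.approx(want_p, abs=1e-9)

    def test_y_linear_in_covariates_gives_zero(self, rng):
        cov = rng.standard_normal((30, 2))
        x = rng.standard_normal(30)
        y = 2.0 * cov[:, 0] - cov[:, 1] + 3.0
        r, p = partial_correlation(x, y, cov)
        assert r == 0.0 and p == 1.0

    def test_matches_pingouin(self, rng):
        import pingouin as pg

        n = 50
        cov = rng.standard_normal((n, 3))
        x = rng.standard_normal(n) + cov @ [0.5, -0.2, 0.1]
        y = 0.4 * x + rng.standard_normal(n) + cov @ [0.3, 0.1, -0.4]
        r, p = partial_correlation(x, y, cov)
        df = pd.DataFrame({"x": x, "y": y, "c1": cov[:, 0], "c2": cov[:, 1], "c3": cov[:, 2]})
        ref = pg.partial_corr(df, x="x", y="y", covar=["c1", "c2", "c3"])
        assert r == pytest.approx(float(ref["r"].iloc[0]), abs=1e-10)
        assert p == pytest.approx(float(ref["p_val"].iloc[0]), abs=1e-10)

    def test_matches_precision_matrix(self, rng):
        n = 200
        z = rng.standard_normal((n, 4))
        x = z[:, 0] + 0.5 * z[:, 2]
        y = z[:, 1] + 0.5 * z[:, 2] + 0.3 * x
        data = np.column_stack([x, y, z[:, 2], z[:, 3]])
        prec = np.linalg.inv(np.cov(data.T))
        want = -prec[0, 1] / np.sqrt(prec[0, 0] * prec[1, 1])
        r, _ = partial_correlation(x, y, data[:, 2:])
        assert r == pytest.approx(want, abs=1e-10)


class TestBonferroni:
    def test_single_test_identity(self):
        adj, rej = bonferroni([0.03])
        assert adj[0] == pytest.approx(0.03)
        assert rej[0]

    def test_ten_tests(self):
        adj, rej = bonferroni([0.01] + [0.5] * 9)
        assert adj[0] == pytest.approx(0.10)
        assert not rej[0]

    def test_adjusted_never_below_raw(self, rng):
        p = rng.random(25)
        adj, _ = bonferroni(p)
        assert np.all(adj >= p - 1e-15)
        assert np.all(adj <= 1.0)


class TestVoxelwiseGlm:
    def test_two_group_contrast_reduces_to_two_sample_t(self, rng):
        Y = rng.standard_normal((20, 64))
        Y[:10] += 0.8
        Y = Y.astype(np.float32).astype(np.float64)  # maps store float32
        groups = ["BD"] * 10 + ["HC"] * 10
        maps, _ = _maps_from_matrix(Y)
        X, names = design_matrix(groups)
        c = group_contrast(names, "BD", "HC")
        tmap, dof = voxelwise_glm(maps, X, c)
        assert dof == 18
        got = tmap.in_mask_values()
        want = np.array([two_sample_t(Y[:10, v], Y[10:, v]).t for v in range(64)])
        np.testing.assert_allclose(got, want, atol=1e-10)

    def test_contrast_orthogonal_to_effect_near_zero(self, rng):
        Y = rng.standard_normal((24, 64))
        groups = ["BD"] * 12 + ["HC"] * 12
        cov = pd.DataFrame({"age": np.tile([20.0, 30.0], 12)})
        Y += 0.5 * cov["age"].to_numpy()[:, None] / 10  # age effect only
        maps, _ = _maps_from_matrix(Y)
        X, names = design_matrix(groups, cov)
        c = group_contrast(names, "BD", "HC")
        tmap, _ = voxelwise_glm(maps, X, c)
        assert abs(tmap.in_mask_values().mean()) < 0.35

    def test_rank_deficiency_names_columns(self, rng):
        Y = rng.standard_normal((10, 8))
        maps, _ = _maps_from_matrix(Y, (2, 2, 2))
        groups = ["BD"] * 5 + ["HC"] * 5
        cov = pd.DataFrame({"dup": [1.0 if g == "HC" else 0.0 for g in groups]})
        with pytest.raises(ValueError, match="dup"):
            design_matrix(groups, cov)


class TestAnova:
    def test_f_equals_t_squared_when_two_groups_collapse(self, rng):
        Y = rng.standard_normal((18, 27)).astype(np.float32).astype(np.float64)
        maps, _ = _maps_from_matrix(Y, (3, 3, 3))
        groups3 = ["BD"] * 6 + ["HC"] * 6 + ["Improved"] * 6
        fmap, posthoc = anova_oneway_map(maps, groups3)
        # scalar oracle per voxel
        for v in [0, 13, 26]:
            want = stats.f_oneway(Y[:6, v], Y[6:12, v], Y[12:, v]).statistic
            # maps are stored float32; agreement is to storage precision
            assert fmap.in_mask_values()[v] == pytest.approx(want, rel=1e-6)
        assert set(posthoc) == {("BD", "HC"), ("BD", "Improved"), ("HC", "Improved")}

    def test_posthoc_isolates_shifted_group(self, rng):
        Y = rng.standard_normal((30, 8)) * 0.3
        Y[20:] += 3.0  # third group shifted
        maps, _ = _maps_from_matrix(Y, (2, 2, 2))
        groups = ["BD"] * 10 + ["HC"] * 10 + ["Improved"] * 10
        fmap, posthoc = anova_oneway_map(maps, groups)
        assert np.all(fmap.in_mask_values() > 0)
        t_bd_hc = posthoc[("BD", "HC")].in_mask_values()
        t_bd_imp = posthoc[("BD", "Improved")].in_mask_values()
        assert np.all(np.abs(t_bd_imp) > np.abs(t_bd_hc))


class TestClusterCorrect:
    def _planted_maps(self, rng, effect=2.0, n_per=12):
        Y = rng.standard_normal((2 * n_per, 6 * 6 * 6))
        vol = np.zeros((6, 6, 6), dtype=bool)
        vol[1:4, 1:4, 1:4] = True
        Y[:n_per, vol.ravel()] += effect
        maps, mask = _maps_from_matrix(Y, (6, 6, 6))
        groups = ["BD"] * n_per + ["HC"] * n_per
        X, names = design_matrix(groups)
        return maps, X, group_contrast(names, "BD", "HC"), vol

    def test_planted_effect_reaches_minimum_p(self, rng):
        maps, X, c, vol = self._planted_maps(rng, effect=3.0)
        tmap, result = cluster_correct(maps, X, c, voxel_p=0.01, n_perm=199,
                                       rng=np.random.default_rng(0))
        sig = result.significant(0.05)
        assert sig, "planted effect must produce a significant cluster"
        assert sig[0].corrected_p == pytest.approx(1.0 / 200.0)
        # the top cluster sits inside the planted block
        assert vol[sig[0].peak_voxel]

    def test_contrast_sign_flip_mirrors_clusters(self, rng):
        maps, X, c, _ = self._planted_maps(rng, effect=3.0)
        _, res_pos = cluster_correct(maps, X, c, voxel_p=0.01, n_perm=100,
                                     rng=np.random.default_rng(1))
        _, res_neg = cluster_correct(maps, X, -c, voxel_p=0.01, n_perm=100,
                                     rng=np.random.default_rng(1))
        got = sorted((cl.extent, -np.sign(cl.peak_stat)) for cl in res_neg.clusters)
        want = sorted((cl.extent, np.sign(cl.peak_stat)) for cl in res_pos.clusters)
        assert got == want

    def test_corrected_p_monotone_in_extent(self, rng):
        maps, X, c, _ = self._planted_maps(rng, effect=1.2)
        _, result = cluster_correct(maps, X, c, voxel_p=0.05, n_perm=100,
                                    rng=np.random.default_rng(2))
        extents = [cl.extent for cl in result.clusters]
        ps = [cl.corrected_p for cl in result.clusters]
        # clusters are sorted by decreasing extent; p must be non-decreasing
        assert extents == sorted(extents, reverse=True)
        assert ps == sorted(ps)

    def test_no_suprathreshold_voxels_is_empty_not_error(self, rng):
        Y = rng.standard_normal((8, 27)) * 1e-3
        maps, _ = _maps_from_matrix(Y, (3, 3, 3))
        groups = ["BD"] * 4 + ["HC"] * 4
        X, names = design_matrix(groups)
        c = group_contrast(names, "BD", "HC")
        _, result = cluster_correct(maps, X, c, voxel_p=0.0001, n_perm=100,
                                    rng=np.random.default_rng(3))
        assert result.clusters == []
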