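import numpy as np
import pandas as pd
import pytest

from cogmorph import glm, synth


def make_cohort(morph: dict, covariates: pd.DataFrame, g: np.ndarray, label="test"):
    """Hand-built CohortDataset for targeted model checks."""
    n = len(g)
    return synth.CohortDataset(
        label=label,
        morphometry=morph,
        tests=np.zeros((n, 3)),
        covariates=covariates,
        true_g=g,
        mesh_id="",
    )


def basic_covariates(n, rng):
    return pd.DataFrame(
        {
            "age": 60 + 8 * rng.standard_normal(n),
            "sex": (rng.random(n) < 0.5).astype(float),
            "site": np.zeros(n, dtype=int),
            "hp_x": rng.standard_normal(n),
            "hp_y": rng.standard_normal(n),
            "hp_z": rng.standard_normal(n),
        }
    )


class TestVertexAssociation:
    def test_outcome_equal_to_predictor_gives_unit_beta(self, rng):
        n = 50
        g = rng.standard_normal(n)
        morph = {"volume": np.tile(g[:, None], (1, 10))}
        cohort = make_cohort(morph, basic_covariates(n, rng), g)
        amap = glm.vertex_association(cohort, "volume", "g", [], g_scores=g)
        np.testing.assert_allclose(amap.beta, 1.0, atol=1e-12)
        assert np.nanmax(amap.se) < 1e-10

    def test_standardized_beta_equals_pearson_r(self, rng):
        n, v = 120, 30
        g = rng.standard_normal(n)
        y = 0.3 * g[:, None] + rng.standard_normal((n, v))
        cohort = make_cohort({"volume": y}, basic_covariates(n, rng), g)
        amap = glm.vertex_association(cohort, "volume", "g", [], g_scores=g)
        expected = [np.corrcoef(g, y[:, j])[0, 1] for j in range(v)]
        np.testing.assert_allclose(amap.beta, expected, atol=1e-10)

    def test_closed_form_standardized_slope(self, rng):
        # x = [-1, 0, 1], y = [1, 2, 4]: r = 1.5 / (1 * 1.52753) = 0.9820
        x = np.array([-1.0, 0.0, 1.0])
        y = np.array([1.0, 2.0, 4.0])
        cov = pd.DataFrame({"age": x, "sex": np.zeros(3), "site": np.zeros(3, int),
                            "hp_x": x, "hp_y": x, "hp_z": x})
        cohort = make_cohort({"thickness": y[:, None]}, cov, x)
        res = glm.global_association(cohort, "thickness", "g", [], g_scores=x)
        assert abs(res.beta - 0.9820) < 5e-5

    def test_permutation_null_is_centred(self, rng):
        n = 80
        g = rng.standard_normal(n)
        y = rng.standard_normal((n, 1))
        cov = basic_covariates(n, rng)
        betas = []
        for _ in range(500):
            perm = rng.permutation(g)
            cohort = make_cohort({"volume": y.copy()}, cov, perm)
            amap = glm.vertex_association(cohort, "volume", "g", [], g_scores=perm)
            betas.append(amap.beta[0])
        betas = np.asarray(betas)
        assert abs(betas.mean()) < 2.0 * betas.std(ddof=1) / np.sqrt(len(betas))

    def test_affine_rescaling_of_measure_is_irrelevant(self, rng):
        n = 60
        g = rng.standard_normal(n)
        y = 0.2 * g[:, None] + rng.standard_normal((n, 5))
        cov = basic_covariates(n, rng)
        a = glm.vertex_association(make_cohort({"volume": y}, cov, g), "volume", "g", [], g_scores=g)
        b = glm.vertex_association(
            make_cohort({"volume": 1000.0 + 7.5 * y}, cov, g), "volume", "g", [], g_scores=g
        )
        np.testing.assert_allclose(a.beta, b.beta, atol=1e-10)
        np.testing.assert_allclose(a.se, b.se, atol=1e-10)

    def test_orthogonal_covariate_leaves_beta_unchanged(self, rng):
        n = 100
        g = rng.standard_normal(n)
        g = g - g.mean()
        # build a covariate exactly orthogonal to the z-scored predictor
        raw = rng.standard_normal(n)
        zg = g / g.std(ddof=1)
        ortho = raw - (raw @ zg) / (zg @ zg) * zg
        ortho = ortho - ortho.mean()
        cov = basic_covariates(n, rng)
        cov["hp_x"] = ortho
        y = 0.3 * g[:, None] + rng.standard_normal((n, 4))
        without = glm.vertex_association(make_cohort({"volume": y}, cov, g), "volume", "g", [], g_scores=g)
        with_cov = glm.vertex_association(
            make_cohort({"volume": y}, cov, g), "volume", "g", ["hp_x"], g_scores=g
        )
        np.testing.assert_allclose(without.beta, with_cov.beta, atol=1e-10)

    def test_rank_deficient_design_names_columns(self, rng):
        n = 50
        g = rng.standard_normal(n)
        cov = basic_covariates(n, rng)
        cov["hp_y"] = cov["hp_x"]  # exact duplicate
        cohort = make_cohort({"volume": rng.standard_normal((n, 3))}, cov, g)
        with pytest.raises(glm.CollinearityError, match="hp_"):
            glm.vertex_association(cohort, "volume", "g", ["hp_x", "hp_y"], g_scores=g)

    def test_minimum_sample_size_enforced(self, rng):
        n = 10
        g = rng.standard_normal(n)
        cohort = make_cohort({"volume": rng.standard_normal((n, 3))}, basic_covariates(n, rng), g)
        with pytest.raises(ValueError, match="at least 20"):
            glm.vertex_association(cohort, "volume", "g", [], g_scores=g)

    def test_masked_vertices_stay_missing(self, rng):
        n = 40
        g = rng.standard_normal(n)
        y = rng.standard_normal((n, 6))
        y[:, 2] = np.nan
        cohort = make_cohort({"volume": y}, basic_covariates(n, rng), g)
        amap = glm.vertex_association(cohort, "volume", "g", [], g_scores=g)
        assert np.isnan(amap.beta[2]) and np.isnan(amap.se[2])
        assert np.isfinite(amap.beta[[0, 1, 3, 4, 5]]).all()

    def test_sex_contrast_direction(self, rng):
        n = 200
        sex = (rng.random(n) < 0.5).astype(float)
        cov = basic_covariates(n, rng)
        cov["sex"] = sex
        y = (0.8 * sex + rng.standard_normal(n))[:, None]  # larger in males
        cohort = make_cohort({"volume": y}, cov, rng.standard_normal(n))
        amap = glm.vertex_association(cohort, "volume", "sex", [])
        assert amap.beta[0] > 0.2


class TestGlobalAssociation:
    def test_null_aggregate_within_two_se(self, rng):
        n = 500
        g = rng.standard_normal(n)
        y = rng.standard_normal((n, 40))
        cohort = make_cohort({"volume": y}, basic_covariates(n, rng), g)
        res = glm.global_association(cohort, "volume", "g", [], g_scores=g)
        assert abs(res.beta) < 2.0 * res.se

    def test_noise_free_global_amplitude_recovered(self, rng):
        n = 100
        g = rng.standard_normal(n)
        y = 0.178 * np.tile(g[:, None], (1, 25))
        cohort = make_cohort({"thickness": y}, basic_covariates(n, rng), g)
        res = glm.global_association(cohort, "thickness", "g", [], g_scores=g, standardize=False)
        assert abs(res.beta - 0.178) < 1e-12

    def test_sum_vs_mean_aggregation(self, rng):
        n = 60
        g = rng.standard_normal(n)
        y = np.abs(rng.standard_normal((n, 8))) + 1.0
        cov = basic_covariates(n, rng)
        vol = glm.global_association(make_cohort({"volume": y}, cov, g), "volume", "g", [], g_scores=g)
        thk = glm.global_association(make_cohort({"thickness": y}, cov, g), "thickness", "g", [], g_scores=g)
        # sum and mean differ by a constant factor, so standardized betas agree
        assert abs(vol.beta - thk.beta) < 1e-10


class TestAllometry:
    def test_isometric_subjects_have_unit_slope(self, rng):
        n, v = 100, 40
        scale = np.exp(0.2 * rng.standard_normal(n))
        base = np.linspace(0.5, 1.5, v)
        area = scale[:, None] * base[None, :]
        cohort = make_cohort({"area": area}, basic_covariates(n, rng), rng.standard_normal(n))
        amap = glm.allometric_map(cohort)
        np.testing.assert_allclose(amap.beta, 1.0, atol=1e-10)

    def test_quadratic_vertex_has_slope_two(self, rng):
        n = 80
        scale = np.exp(0.2 * rng.standard_normal(n))
        area = np.column_stack([scale, scale, scale**2])
        # total area is dominated by columns 0-1 which scale linearly; use many
        # linear columns so ln(total) = ln(scale) + const exactly
        area = np.column_stack([np.tile(scale[:, None], (1, 30)), scale**2])
        cohort = make_cohort({"area": area}, basic_covariates(n, rng), rng.standard_normal(n))
        amap = glm.allometric_map(cohort)
        # ln(total) = ln(30*scale + scale^2) is not exactly linear; check the
        # planted linear columns instead and the quadratic one approximately
        assert np.all(np.abs(amap.beta[:30] - 1.0) < 0.05)
        assert amap.beta[30] > 1.5

    def test_planted_slopes_recovered(self, rng):
        n, v = 2000, 50
        slopes = np.linspace(0.8, 1.2, v)
        log_total_signal = 0.15 * rng.standard_normal(n)
        log_area = slopes[None, :] * log_total_signal[:, None] + 0.05 * rng.standard_normal((n, v))
        # anchor total area: add a large isometric block so ln(total) tracks the signal
        anchor = np.exp(log_total_signal)[:, None] * np.full((1, 200), 1.0)
        area = np.hstack([np.exp(log_area), anchor * (v / 200.0)])
        cohort = make_cohort({"area": area}, basic_covariates(n, rng), rng.standard_normal(n))
        amap = glm.allometric_map(cohort)
        est = amap.beta[:v]
        assert np.max(np.abs(est - slopes)) < 0.05

    def test_non_positive_area_rejected(self, rng):
        n = 50
        area = np.abs(rng.standard_normal((n, 5))) + 0.1
        area[0, 0] = -1.0
        cohort = make_cohort({"area": area}, basic_covariates(n, rng), rng.standard_normal(n))
        with pytest.raises(ValueError, match="positive"):
            glm.allometric_map(cohort)
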