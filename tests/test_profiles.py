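import numpy as np
import pytest

from cogmorph import synth
from cogmorph.profiles import (
    build_stack,
    category_abs_r_test,
    congruence,
    metabolism_pc1,
    pca,
    varimax,
)
from cogmorph.surface import VertexMap


def orthonormal_columns(n, k, rng):
    q, _ = np.linalg.qr(rng.standard_normal((n, k + 1)))
    q = q - q.mean(axis=0)
    q, _ = np.linalg.qr(q)
    return q[:, :k]


def maps_with_compound_symmetry(n_maps, r, n_vertices, rng):
    """Maps with exactly equal pairwise correlation r (shared + unique parts)."""
    basis = orthonormal_columns(n_vertices, n_maps + 1, rng)
    common = basis[:, 0]
    maps = []
    for j in range(n_maps):
        vals = np.sqrt(r) * common + np.sqrt(1.0 - r) * basis[:, j + 1]
        maps.append(VertexMap(vals, np.ones(n_vertices, bool), name=f"m{j}"))
    return maps


class TestBuildStack:
    def test_identical_maps_give_unit_correlations(self, rng):
        vals = rng.standard_normal(300)
        maps = [VertexMap(vals.copy(), np.ones(300, bool), name=f"m{j}") for j in range(2)]
        stack = build_stack(maps)
        np.testing.assert_allclose(stack.correlation_matrix(), 1.0, atol=1e-12)

    def test_intersection_mask(self, rng):
        a = VertexMap(rng.standard_normal(100), np.ones(100, bool))
        small_mask = np.ones(100, bool)
        small_mask[:30] = False
        vb = rng.standard_normal(100)
        vb[:30] = np.nan
        b = VertexMap(vb, small_mask)
        stack = build_stack([a, b])
        assert stack.n_valid == 70

    def test_columns_standardized(self, mesh3, rng):
        load, noise = synth.simple_structure_loadings(5, 2, rng)
        maps, _, _ = synth.simulate_profiles(mesh3, 5, 2, load, noise, seed=1)
        stack = build_stack(maps)
        np.testing.assert_allclose(stack.matrix.mean(axis=0), 0.0, atol=1e-8)
        np.testing.assert_allclose(stack.matrix.std(axis=0, ddof=1), 1.0, atol=1e-8)

    def test_zero_variance_map_rejected(self, rng):
        a = VertexMap(rng.standard_normal(50), np.ones(50, bool), name="ok")
        b = VertexMap(np.full(50, 2.0), np.ones(50, bool), name="flat")
        with pytest.raises(ValueError, match="flat"):
            build_stack([a, b])


class TestPCA:
    def test_compound_symmetry_closed_form(self, rng):
        # 3 maps with pairwise r = 0.8: PC1 share = (1 + 2*0.8) / 3 = 86.67%
        maps = maps_with_compound_symmetry(3, 0.8, 400, rng)
        res = pca(build_stack(maps), n_retain=1)
        assert abs(res.pct_variance[0] - 100.0 * (1 + 2 * 0.8) / 3) < 0.01

    def test_noise_free_rank_k_stack(self, mesh3, rng):
        load, _ = synth.simple_structure_loadings(8, 4, rng)
        maps, _, _ = synth.simulate_profiles(mesh3, 8, 4, load, 0.0, seed=2)
        res = pca(build_stack(maps), n_retain=4)
        assert res.pct_variance[:4].sum() > 100.0 - 1e-8
        assert res.eigenvalues[4] < 1e-10

    def test_eigenvalues_match_power_iteration_oracle(self, mesh3, rng):
        load, noise = synth.simple_structure_loadings(6, 2, rng)
        maps, _, _ = synth.simulate_profiles(mesh3, 6, 2, load, noise, seed=3)
        stack = build_stack(maps)
        res = pca(stack, n_retain=2)
        # brute-force power iteration with deflation on the correlation matrix
        c = stack.correlation_matrix()
        eigs = []
        mat = c.copy()
        for _ in range(6):
            v = np.ones(6) / np.sqrt(6)
            for _ in range(10000):
                w = mat @ v
                nrm = np.linalg.norm(w)
                if nrm == 0:
                    break
                v_new = w / nrm
                if np.linalg.norm(v_new - v) < 1e-14:
                    v = v_new
                    break
                v = v_new
            lam = float(v @ mat @ v)
            eigs.append(lam)
            mat = mat - lam * np.outer(v, v)
        np.testing.assert_allclose(res.eigenvalues, sorted(eigs, reverse=True), atol=1e-8)

    def test_variance_preserved_under_rotation(self, mesh3, rng):
        load, noise = synth.simple_structure_loadings(10, 3, rng)
        maps, _, _ = synth.simulate_profiles(mesh3, 10, 3, load, noise, seed=4)
        res = pca(build_stack(maps), n_retain=3)
        assert abs(
            (res.loadings**2).sum() - (res.rotated_loadings**2).sum()
        ) < 1e-8

    def test_pct_variance_sums_to_100(self, mesh3, rng):
        load, noise = synth.simple_structure_loadings(7, 2, rng)
        maps, _, _ = synth.simulate_profiles(mesh3, 7, 2, load, noise, seed=5)
        res = pca(build_stack(maps), n_retain=2)
        assert abs(res.pct_variance.sum() - 100.0) < 1e-8

    def test_noise_free_reconstruction_from_rotated_scores(self, mesh3, rng):
        load, _ = synth.simple_structure_loadings(6, 3, rng)
        maps, _, _ = synth.simulate_profiles(mesh3, 6, 3, load, 0.0, seed=6)
        stack = build_stack(maps)
        res = pca(stack, n_retain=3)
        # rescale unit-SD scores back to raw regression scores for reconstruction
        w = res.rotated_loadings @ np.linalg.inv(res.rotated_loadings.T @ res.rotated_loadings)
        raw_scores = stack.matrix @ w
        recon = raw_scores @ res.rotated_loadings.T
        assert np.max(np.abs(recon - stack.matrix)) < 1e-6


class TestVarimax:
    def test_single_component_unchanged(self, rng):
        lam = rng.standard_normal((8, 1))
        rotated, rot = varimax(lam)
        np.testing.assert_allclose(np.abs(rotated), np.abs(lam))
        assert rot.shape == (1, 1)

    def test_simple_structure_is_fixed_point(self):
        lam = np.zeros((6, 2))
        lam[:3, 0] = 0.8
        lam[3:, 1] = 0.7
        rotated, rot = varimax(lam)
        np.testing.assert_allclose(np.abs(rotated), np.abs(lam), atol=1e-8)

    def test_rotation_matrix_orthogonal(self, rng):
        lam = rng.standard_normal((12, 4))
        rotated, rot = varimax(lam)
        np.testing.assert_allclose(rot.T @ rot, np.eye(4), atol=1e-10)
        np.testing.assert_allclose(lam @ rot, rotated, atol=1e-10)

    def test_communalities_preserved(self, rng):
        lam = rng.standard_normal((10, 3))
        rotated, _ = varimax(lam)
        np.testing.assert_allclose(
            (rotated**2).sum(axis=1), (lam**2).sum(axis=1), atol=1e-8
        )

    def test_criterion_not_decreased(self, rng):
        from cogmorph.profiles import _varimax_criterion

        for trial in range(5):
            lam = rng.standard_normal((9, 3))
            rotated, _ = varimax(lam, kaiser_normalize=False)
            assert _varimax_criterion(rotated) >= _varimax_criterion(lam) - 1e-12

    def test_planted_rotation_matches_grid_search_oracle(self):
        """k=2: a simple-structure matrix rotated by 30 degrees; varimax must
        find the criterion-maximizing angle to within 0.001 degrees of a
        0.01-degree brute-force grid search."""
        from cogmorph.profiles import _varimax_criterion

        base = np.zeros((8, 2))
        base[:4, 0] = np.array([0.9, 0.8, 0.7, 0.75])
        base[4:, 1] = np.array([0.85, 0.7, 0.8, 0.65])
        theta = np.deg2rad(30.0)
        g = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        lam = base @ g

        angles = np.deg2rad(np.arange(0.0, 90.0, 0.01))
        crits = []
        for a in angles:
            r = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
            crits.append(_varimax_criterion(lam @ r))
        best_angle = angles[int(np.argmax(crits))]

        rotated, rot = varimax(lam, kaiser_normalize=False)
        found = np.arctan2(rot[1, 0], rot[0, 0]) % (np.pi / 2)
        assert abs(np.rad2deg(found) - np.rad2deg(best_angle % (np.pi / 2))) < 1e-3
        # and the recovered structure matches the planted one up to sign/permutation
        matched = max(
            abs(congruence(rotated[:, i], base[:, j])) for i in range(2) for j in range(2)
        )
        assert matched > 0.999


class TestCongruence:
    def test_identical_vectors(self, rng):
        x = rng.standard_normal(10)
        assert congruence(x, x) == pytest.approx(1.0)

    def test_negated_vectors(self, rng):
        x = rng.standard_normal(10)
        assert congruence(x, -x) == pytest.approx(-1.0)

    def test_hand_example(self):
        assert congruence(np.array([1.0, 0.0]), np.array([1.0, 1.0])) == pytest.approx(
            0.7071, abs=5e-5
        )

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError, match="zero vector"):
            congruence(np.zeros(3), np.ones(3))


class TestMetabolismPC1:
    def test_identical_maps(self, rng):
        vals = rng.standard_normal(200)
        maps = [VertexMap(vals.copy(), np.ones(200, bool), name=f"met{j}") for j in range(3)]
        _, load, pct = metabolism_pc1(maps)
        assert pct == pytest.approx(100.0)
        np.testing.assert_allclose(load, load[0], atol=1e-10)

    def test_compound_symmetry_share(self, rng):
        maps = maps_with_compound_symmetry(3, 0.8, 500, rng)
        _, load, pct = metabolism_pc1(maps)
        assert abs(pct - 86.6667) < 0.01
        assert np.all(load > 0.5)

    def test_orientation_tracks_input_direction(self, rng):
        # the convention "higher score = higher metabolism" follows the
        # inputs: negating all three maps keeps every loading positive and
        # flips the score map exactly
        maps = maps_with_compound_symmetry(3, 0.7, 300, rng)
        neg = [VertexMap(-m.values, m.mask.copy(), m.name) for m in maps]
        pc_a, load_a, _ = metabolism_pc1(maps)
        pc_b, load_b, _ = metabolism_pc1(neg)
        assert np.all(load_a > 0) and np.all(load_b > 0)
        np.testing.assert_allclose(
            pc_a.values[pc_a.mask], -pc_b.values[pc_b.mask], atol=1e-8
        )

    def test_wrong_map_count_rejected(self, rng):
        maps = maps_with_compound_symmetry(4, 0.5, 100, rng)
        with pytest.raises(ValueError, match="exactly 3"):
            metabolism_pc1(maps)


class TestCategoryTest:
    def test_identical_groups_give_zero_t(self):
        # both groups see the |r| multiset {0.1, 0.2, 0.3}
        c = np.eye(6)
        for (i, j), v in zip([(0, 1), (0, 2), (1, 2)], [0.1, 0.2, 0.3]):
            c[i, j] = c[j, i] = v
            c[i + 3, j + 3] = c[j + 3, i + 3] = v
        cats = ["receptor"] * 3 + ["functional"] * 3
        t, df, p, summary = category_abs_r_test(c, cats)
        assert t == pytest.approx(0.0, abs=1e-12)
        assert summary["group_a_mean"] == summary["other_mean"]

    def test_group_means_match_enumeration_oracle(self, rng):
        m = 7
        a = rng.standard_normal((m, m))
        c = np.corrcoef(a)
        cats = ["receptor"] * 4 + ["microstructure"] * 3
        t, df, p, summary = category_abs_r_test(c, cats)
        recep = [abs(c[i, j]) for i in range(4) for j in range(i + 1, 4)]
        other = [abs(c[i, j]) for i in range(4, m) for j in range(i + 1, m)]
        assert summary["group_a_mean"] == pytest.approx(np.mean(recep))
        assert summary["other_mean"] == pytest.approx(np.mean(other))
        assert summary["group_a_n_pairs"] == len(recep)
        assert summary["other_n_pairs"] == len(other)

    def test_single_pair_group_rejected(self, rng):
        c = np.corrcoef(rng.standard_normal((4, 4)))
        cats = ["receptor"] * 2 + ["functional"] * 2
        with pytest.raises(ValueError, match="at least 2"):
            category_abs_r_test(c, cats)


class TestPlantedRecovery:
    def test_rotated_components_match_planted_patterns(self, mesh4, rng):
        load, noise = synth.simple_structure_loadings(33, 4, rng, signal_share=0.6)
        maps, planted, _ = synth.simulate_profiles(mesh4, 33, 4, load, noise, seed=7)
        res = pca(build_stack(maps), n_retain=4)
        used = set()
        for j in range(4):
            phis = [
                abs(congruence(res.rotated_loadings[:, i], planted[:, j]))
                for i in range(4)
            ]
            best = int(np.argmax(phis))
            assert phis[best] >= 0.9
            used.add(best)
        assert used == {0, 1, 2, 3}  # a one-to-one matching
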