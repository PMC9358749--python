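"""TPS, sliding, GPA, and the randomization statistics."""

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from surfmorph import StudySimSpec, phantom
from surfmorph.gm import (
    SlidingScheme,
    apply_template,
    bending_energy_matrix,
    centroid_size,
    centroid_size_anova,
    gpa,
    pairwise_posthoc,
    pca_shape,
    procrustes_anova,
    read_landmark_table,
    read_tps_file,
    slide_semilandmarks,
    tps_fit,
    write_landmark_table,
)


class TestTPS:
    def test_identity(self, rng):
        src = rng.uniform(-1, 1, (12, 3))
        warp, E = tps_fit(src, src)
        np.testing.assert_allclose(warp(src), src, atol=1e-9)
        assert E < 1e-9

    def test_affine_has_zero_energy(self, rng):
        src = rng.uniform(-1, 1, (12, 3))
        A = rng.normal(size=(3, 3))
        b = rng.normal(size=3)
        _, E = tps_fit(src, src @ A.T + b)
        assert abs(E) < 1e-9

    def test_interpolates_exactly(self, rng):
        src = rng.uniform(-1, 1, (10, 3))
        dst = src + 0.1 * rng.normal(size=(10, 3))
        warp, _ = tps_fit(src, dst)
        assert np.abs(warp(src) - dst).max() < 1e-9

    def test_energy_matches_quadrature_oracle(self, rng):
        """Kernel-form bending energy vs numerical quadrature of the functional.

        The oracle integrates the squared second derivatives of the
        displacement spline (analytic Hessian of the |r| kernel) on a dense
        grid over a box several times the landmark extent.
        """
        src = rng.uniform(-1, 1, (10, 3))
        dst = src + 0.1 * rng.normal(size=(10, 3))
        _, E = tps_fit(src, dst)
        # displacement-spline weights
        k = len(src)
        d = np.linalg.norm(src[:, None] - src[None], axis=-1)
        L = np.zeros((k + 4, k + 4))
        L[:k, :k] = d
        P = np.concatenate([np.ones((k, 1)), src], axis=1)
        L[:k, k:] = P
        L[k:, :k] = P.T
        W = np.linalg.solve(L, np.concatenate([dst - src, np.zeros((4, 3))]))[:k]
        def quadrature(n, half=6.0):
            xs = np.linspace(-half, half, n)
            h = xs[1] - xs[0]
            rho = 1.5 * h  # exclusion radius around the kernel singularities
            total = 0.0
            for z in xs:
                X, Y = np.meshgrid(xs, xs, indexing="ij")
                p = np.stack([X.ravel(), Y.ravel(), np.full(X.size, z)], axis=-1)
                diff = p[:, None, :] - src[None]
                r = np.maximum(np.linalg.norm(diff, axis=-1), 1e-9)
                keep = r.min(axis=1) > rho
                u = diff[keep] / r[keep][..., None]
                Hs = (np.eye(3)[None, None] - u[..., :, None] * u[..., None, :]) / r[
                    keep
                ][..., None, None]
                for dd in range(3):
                    Hd = np.einsum("i,pijk->pjk", W[:, dd], Hs)
                    total += (Hd**2).sum() * h**3
            # each excluded ball contributes int |H_i|^2 dV = 8 pi w_i^2 rho
            return total + 8 * np.pi * rho * (W**2).sum(), h

        # Richardson extrapolation across three resolutions (error ~ C h^p)
        from scipy.optimize import brentq

        (T1, h1), (T2, h2), (T3, h3) = quadrature(72), quadrature(96), quadrature(144)

        def extrapolated(p):
            Ea = T2 - (T1 - T2) / ((h1 / h2) ** p - 1)
            Eb = T3 - (T2 - T3) / ((h2 / h3) ** p - 1)
            return Ea, Eb

        p_fit = brentq(lambda p: np.subtract(*extrapolated(p)), 0.5, 3.5)
        oracle = extrapolated(p_fit)[1]
        assert E == pytest.approx(oracle, rel=0.02)

    def test_energy_matrix_consistent_with_kernel_form(self, rng):
        src = rng.uniform(-1, 1, (10, 3))
        dst = src + 0.1 * rng.normal(size=(10, 3))
        _, E = tps_fit(src, dst)
        Be = bending_energy_matrix(src)
        E_mat = float(np.einsum("id,ij,jd->", dst, Be, dst))
        assert E_mat == pytest.approx(E, rel=1e-9, abs=1e-12)
        # PSD on random configurations
        ev = np.linalg.eigvalsh(Be)
        assert ev.min() > -1e-8 * max(ev.max(), 1.0)

    def test_degenerate_source_raises(self):
        src = np.zeros((6, 3))
        src[:, :2] = np.random.default_rng(0).uniform(size=(6, 2))  # coplanar
        with pytest.raises(ValueError):
            tps_fit(src, src + 0.1)


class TestApplyTemplate:
    def test_identity_target(self, small_spec, small_mesh):
        tpl = phantom.define_phantom_template(small_spec)
        fixed = tpl.points[tpl.roles == "fixed"]
        cfg = apply_template(tpl, fixed, small_mesh)
        # template points already lie on the surface: recovered up to mesh facets
        err = np.linalg.norm(cfg.coords - tpl.points, axis=1)
        assert np.median(err) < 0.2

    def test_rigidly_moved_target(self, small_spec, small_mesh):
        tpl = phantom.define_phantom_template(small_spec)
        R = Rotation.from_euler("xyz", [10, 20, 30], degrees=True).as_matrix()
        t = np.array([5.0, -3.0, 8.0])
        moved_mesh = small_mesh.transformed(R, t)
        fixed = tpl.points[tpl.roles == "fixed"] @ R.T + t
        cfg = apply_template(tpl, fixed, moved_mesh)
        expected = tpl.points @ R.T + t
        err = np.linalg.norm(cfg.coords - expected, axis=1)
        # TPS reproduces rigid maps exactly; residual is the mesh-facet projection
        assert np.median(err) < 0.2

    def test_warped_target_placement_error(self, small_spec, small_mesh):
        """Known smooth deformation: semilandmarks land near their true images."""
        from surfmorph.gm import tps_fit as _fit

        tpl = phantom.define_phantom_template(small_spec)
        rng = np.random.default_rng(5)
        ctrl = np.array(
            [[x, y, z] for x in (-15, 15) for y in (-15, 15) for z in (-10, 30, 70)],
            dtype=float,
        )
        warp, _ = _fit(ctrl, ctrl + rng.normal(0, 1.0, ctrl.shape))
        warped_mesh = small_mesh.with_vertices(warp(small_mesh.vertices))
        true_pts = warp(tpl.points)
        fixed_true = true_pts[tpl.roles == "fixed"]
        cfg = apply_template(tpl, fixed_true, warped_mesh)
        edge = small_spec.mesh_resolution
        err = np.linalg.norm(cfg.coords - true_pts, axis=1)
        assert err.mean() < 2 * edge

    def test_missing_fixed_rejected(self, small_spec, small_mesh):
        tpl = phantom.define_phantom_template(small_spec)
        with pytest.raises(ValueError):
            apply_template(tpl, np.zeros((3, 3)), small_mesh)


@pytest.fixture(scope="module")
def setup():
    spec = phantom.PhantomSpec(shaft_length=60.0, mesh_resolution=1.2, seed=1)
    tpl = phantom.define_phantom_template(spec)
    idx = tpl.subset("proximal")
    from surfmorph.pipeline import _template_subset

    sub = _template_subset(tpl, idx)
    return sub, SlidingScheme.from_template(sub)


class TestSliding:
    def test_reference_config_does_not_move(self, setup):
        sub, scheme = setup
        X, info = slide_semilandmarks(
            sub.points, scheme, sub.points, surface_normals=sub.normals()
        )
        # already at the energy minimum of the identity deformation
        assert info["energy_after"] <= info["energy_before"] + 1e-9
        assert np.abs(X - sub.points).max() < 1e-6

    def test_energy_never_increases(self, setup):
        """Tangential least-squares step cannot increase bending energy."""
        sub, scheme = setup
        rng = np.random.default_rng(2)
        for _ in range(50):
            jitter = rng.normal(0, 0.3, sub.points.shape)
            X0 = sub.points + jitter
            _, info = slide_semilandmarks(
                X0, scheme, sub.points, surface_normals=sub.normals()
            )
            assert info["energy_after"] <= info["energy_before"] * (1 + 1e-9) + 1e-12

    def test_projection_returns_to_mesh(self, setup, small_mesh):
        sub, scheme = setup
        rng = np.random.default_rng(3)
        X0 = sub.points + rng.normal(0, 0.2, sub.points.shape)
        X, _ = slide_semilandmarks(X0, scheme, sub.points, target_mesh=small_mesh)
        from surfmorph.spatial import ClosestPointQuery

        q = ClosestPointQuery(small_mesh)
        moving = scheme.roles != "fixed"
        _, d, _ = q.query(X[moving])
        assert d.max() < 1e-6


class TestGPA:
    def test_identical_pair(self, rng):
        X = rng.normal(size=(10, 3))
        fit = gpa([X, X.copy()])
        assert np.linalg.norm(fit.coords[0] - fit.coords[1]) < 1e-12
        np.testing.assert_allclose(fit.consensus, fit.coords[0], atol=1e-9)

    def test_similarity_invariance(self, rng):
        """Rotated/translated/scaled inputs give identical superimposed shapes."""
        shapes = [rng.normal(size=(12, 3)) for _ in range(6)]
        fit0 = gpa(shapes)
        moved = []
        for X in shapes:
            R = Rotation.random(random_state=rng.integers(1 << 30)).as_matrix()
            s = rng.uniform(0.5, 2.0)
            t = rng.normal(size=3)
            moved.append(s * X @ R.T + t)
        fit1 = gpa(moved)
        np.testing.assert_allclose(fit0.coords, fit1.coords, atol=1e-9)

    def test_unit_centroid_size_contract(self, rng):
        shapes = [rng.normal(size=(15, 3)) for _ in range(5)]
        fit = gpa(shapes)
        for Y in fit.coords:
            assert centroid_size(Y) == pytest.approx(1.0, abs=1e-12)
            np.testing.assert_allclose(Y.mean(axis=0), 0, atol=1e-12)

    def test_rotation_against_quaternion_grid_oracle(self, rng):
        """SVD Procrustes rotation vs a brute-force 1-degree rotation search."""
        from surfmorph.gm import _procrustes_rotation

        for _ in range(5):
            X = rng.normal(size=(8, 3))
            ref = rng.normal(size=(8, 3))
            X -= X.mean(0)
            ref -= ref.mean(0)
            R_opt = _procrustes_rotation(X, ref)
            best = np.inf
            # coarse axis-angle grid (5 deg) then refine 1 deg around the best
            def search(axes, angles, best, R_best):
                for ax in axes:
                    for ang in angles:
                        R = Rotation.from_rotvec(ax * ang).as_matrix()
                        err = ((X @ R - ref) ** 2).sum()
                        if err < best:
                            best, R_best = err, R
                return best, R_best

            axes = rng.normal(size=(300, 3))
            axes /= np.linalg.norm(axes, axis=1, keepdims=True)
            best, R_best = search(axes, np.deg2rad(np.arange(0, 181, 5)), np.inf, None)
            rv = Rotation.from_matrix(R_best).as_rotvec()
            ax0 = rv / max(np.linalg.norm(rv), 1e-12)
            fine_axes = ax0 + 0.05 * rng.normal(size=(200, 3))
            fine_axes /= np.linalg.norm(fine_axes, axis=1, keepdims=True)
            ang0 = np.linalg.norm(rv)
            best, R_best = search(
                fine_axes, ang0 + np.deg2rad(np.arange(-5, 5.1, 0.5)), best, R_best
            )
            err_opt = ((X @ R_opt - ref) ** 2).sum()
            assert err_opt <= best + 1e-9

    def test_mismatched_k_rejected(self, rng):
        with pytest.raises(ValueError):
            gpa([rng.normal(size=(10, 3)), rng.normal(size=(12, 3))])


class TestCentroidSize:
    def test_known_value(self):
        pts = np.array([[1, 1, 0], [1, -1, 0], [-1, 1, 0], [-1, -1, 0]], dtype=float)
        assert centroid_size(pts) == pytest.approx(np.sqrt(8))

    def test_homogeneity(self, rng):
        X = rng.normal(size=(20, 3))
        assert centroid_size(2 * X) == pytest.approx(2 * centroid_size(X))


class TestPCA:
    def test_trace_conservation(self, rng):
        shapes = [rng.normal(size=(10, 3)) for _ in range(8)]
        fit = gpa(shapes)
        scores, ev, _ = pca_shape(fit)
        Y = fit.flat()
        total_var = ((Y - Y.mean(0)) ** 2).sum() / (len(Y) - 1)
        assert ev.sum() == pytest.approx(total_var, rel=1e-9)
        assert (np.diff(ev) <= 1e-12).all()

    def test_scores_match_svd_oracle(self, rng):
        shapes = [rng.normal(size=(10, 3)) for _ in range(8)]
        fit = gpa(shapes)
        scores, _, _ = pca_shape(fit)
        Yc = fit.flat() - fit.flat().mean(0)
        U, s, _ = np.linalg.svd(Yc, full_matrices=False)
        np.testing.assert_allclose(np.abs(scores[:, :5]), np.abs(U[:, :5] * s[:5]), atol=1e-9)


class TestProcrustesAnova:
    def test_ss_decomposition(self, rng):
        Y = rng.normal(size=(24, 30))
        labels = np.repeat(["a", "b", "c", "d"], 6)
        tab = procrustes_anova(Y, labels, n_perm=50, seed=0)
        ss_e, ss_r, ss_t = tab.ss
        assert ss_e + ss_r == pytest.approx(ss_t, rel=1e-9)
        assert tab.rsq == pytest.approx(ss_e / ss_t)

    def test_degenerate_identical_data(self):
        Y = np.tile(np.arange(12.0), (8, 1))
        labels = np.repeat(["a", "b"], 4)
        tab = procrustes_anova(Y, labels, n_perm=20, seed=0)
        assert tab.rsq == 0.0
        assert np.isnan(tab.f)

    def test_detects_strong_effect(self, rng):
        Y = rng.normal(size=(20, 12))
        labels = np.repeat(["a", "b"], 10)
        Y[10:] += 2.0
        tab = procrustes_anova(Y, labels, n_perm=500, seed=1)
        assert tab.p < 0.01
        assert tab.z > 2

    def test_reproducible(self, rng):
        Y = rng.normal(size=(16, 9))
        labels = np.repeat(["a", "b"], 8)
        t1 = procrustes_anova(Y, labels, n_perm=100, seed=7)
        t2 = procrustes_anova(Y, labels, n_perm=100, seed=7)
        assert t1.p == t2.p and t1.z == t2.z

    def test_single_level_rejected(self, rng):
        with pytest.raises(ValueError):
            procrustes_anova(rng.normal(size=(6, 9)), ["a"] * 6)


class TestPairwise:
    def test_identical_groups(self):
        base = np.arange(15.0)
        Y = np.tile(base, (8, 1))
        labels = np.repeat(["a", "b"], 4)
        tab = pairwise_posthoc(Y, labels, n_perm=100, seed=0)
        assert tab.d[0] < 1e-10
        assert tab.p[0] == pytest.approx(1.0)

    def test_shared_permutations_reproducible(self, rng):
        Y = rng.normal(size=(24, 18))
        labels = np.tile(["a", "b", "c", "d"], 6)
        t1 = pairwise_posthoc(Y, labels, n_perm=200, seed=3)
        t2 = pairwise_posthoc(Y, labels, n_perm=200, seed=3)
        np.testing.assert_array_equal(t1.ucl95, t2.ucl95)
        np.testing.assert_array_equal(t1.p, t2.p)

    def test_device_effect_ordering(self, small_spec):
        """Replicate pair is closer than any inter-method pair when a device
        offset is injected with small operator jitter."""
        tpl = phantom.define_phantom_template(small_spec)
        sim = StudySimSpec(
            n_specimens=13, device_offset=0.3, device_noise_sd=0.05,
            operator_sd=0.05, seed=21,
        )
        cfgs = phantom.simulate_landmark_study(tpl, sim)
        idx = tpl.subset("proximal")
        fit = gpa([c.coords[idx] for c in cfgs])
        labels = np.array([c.method for c in cfgs])
        tab = pairwise_posthoc(fit, labels, n_perm=200, seed=0)
        pairs = ["-".join(p) for p in tab.pairs]
        d = dict(zip(pairs, tab.d))
        replicate = d["LASER-LASER-REP"]
        inter = [v for k, v in d.items() if k != "LASER-LASER-REP" and k != "CT-HMH-CT-MIA"]
        assert all(replicate < v for v in inter)


class TestCentroidSizeAnova:
    def test_textbook_example(self):
        F, p, _ = centroid_size_anova([1, 2, 3, 2, 3, 4], ["a"] * 3 + ["b"] * 3)
        assert F == pytest.approx(1.5)

    def test_equal_groups_f_zero(self):
        F, p, _ = centroid_size_anova([1, 2, 3, 1, 2, 3], ["a"] * 3 + ["b"] * 3)
        assert F == pytest.approx(0.0, abs=1e-12)

    def test_ss_decomposition_and_scipy_agreement(self, rng):
        from scipy.stats import f_oneway

        y = rng.normal(size=30)
        labels = np.repeat(["a", "b", "c"], 10)
        F, p, table = centroid_size_anova(y, labels)
        ref = f_oneway(y[:10], y[10:20], y[20:])
        assert F == pytest.approx(ref.statistic, rel=1e-9)
        assert p == pytest.approx(ref.pvalue, rel=1e-9)
        assert table["SS"].sum() == pytest.approx(((y - y.mean()) ** 2).sum(), rel=1e-12)


class TestLandmarkIO:
    def test_roundtrip(self, tmp_path, small_spec):
        tpl = phantom.define_phantom_template(small_spec)
        sim = StudySimSpec(n_specimens=2, seed=1)
        cfgs = phantom.simulate_landmark_study(tpl, sim)
        path = tmp_path / "landmarks.tsv"
        write_landmark_table(cfgs, tpl, path)
        back = read_landmark_table(path, template=tpl)
        assert len(back) == len(cfgs)
        for a, b in zip(cfgs, back):
            np.testing.assert_allclose(a.coords, b.coords, atol=1e-12)
            assert (a.specimen, a.method) == (b.specimen, b.method)

    def test_tps_file_reader(self, tmp_path):
        content = "LM3=3\n0.0 1.0 2.0\n3 4 5\n6 7 8\nID=spec1\nLM3=3\n1 1 1\n2 2 2\n3 3 3\nID=spec2\n"
        path = tmp_path / "f.tps"
        path.write_text(content)
        out = read_tps_file(path)
        assert len(out) == 2
        assert out[0][0] == "spec1"
        np.testing.assert_allclose(out[1][1], [[1, 1, 1], [2, 2, 2], [3, 3, 3]])
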