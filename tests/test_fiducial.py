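import numpy as np
import pytest
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation

from sysphantom.fiducial import (LocalizationResult, SimilarityTransform,
                                 compute_distortion, compute_uniformity,
                                 fit_similarity, locate_spheres,
                                 render_kernel, volume_distortion)
from sysphantom.io import ImageVolume
from sysphantom.simulate import sphere_occupancy


def paint_spheres(centers, shape, spacing=(1.0, 1.0, 1.0), signal=100.0,
                  background=5.0, radius=5.0, sigma=0.0, seed=0, oversample=3):
    data = np.full(shape, background)
    for c in np.atleast_2d(centers):
        sl, frac = sphere_occupancy(c, radius, (0, 0, 0), spacing, shape,
                                    oversample)
        data[sl] = data[sl] * (1 - frac) + signal * frac
    if sigma > 0:
        rng = np.random.default_rng(seed)
        data = np.hypot(data + rng.normal(0, sigma, shape),
                        rng.normal(0, sigma, shape))
    return ImageVolume(data, spacing)


class TestLocalization:
    def test_kernel_at_lattice_point_zero_offset(self):
        """An image that IS the kernel at a voxel center: exact recovery."""
        c = np.array([[16.0, 16.0, 16.0]])  # a voxel center on the 1 mm grid
        vol = paint_spheres(c, (33, 33, 33))
        loc = locate_spheres(vol, c, search_mm=6.0)
        assert np.allclose(loc.apparent, c, atol=1e-4)

    def test_subvoxel_offset_recovered_within_0p05mm(self, rng):
        offs = rng.uniform(-0.5, 0.5, (8, 3))
        centers = np.array([[16.0, 16.0, 16.0]]) + offs
        for c in centers:
            vol = paint_spheres(c, (33, 33, 33))
            loc = locate_spheres(vol, [np.round(c)], search_mm=6.0)
            err = np.linalg.norm(loc.apparent[0] - c)
            assert err < 0.05

    def test_mean_error_below_0p1mm_at_snr50(self, rng):
        """>= 20 spheres, 1 mm voxels, SNR >= 50: mean error < 0.1 mm."""
        centers = []
        for gx in range(4):
            for gy in range(6):
                centers.append([14 + 22 * gx, 10 + 14 * gy, 12.0])
        centers = np.array(centers) + rng.uniform(-0.5, 0.5, (24, 3))
        vol = paint_spheres(centers, (96, 96, 24), sigma=2.0, seed=3)
        loc = locate_spheres(vol, np.round(centers), search_mm=6.0)
        err = np.linalg.norm(loc.apparent - centers, axis=1)
        assert err.mean() < 0.1

    def test_edge_peak_flagged(self):
        c = np.array([[16.0, 16.0, 16.0]])
        vol = paint_spheres(c, (33, 33, 33))
        # nominal far off: true sphere outside the search window -> edge flag
        loc = locate_spheres(vol, [[26.0, 26.0, 16.0]], search_mm=4.0)
        assert bool(loc.table.flag[0])

    def test_voxels_above_2mm_rejected(self):
        vol = ImageVolume(np.zeros((8, 8, 8)), (3.0, 3.0, 3.0))
        with pytest.raises(ValueError, match="<= 2 mm"):
            locate_spheres(vol, [[4, 4, 4]])


class TestSimilarityFit:
    def test_identity(self, rng):
        P = rng.normal(0, 50, (10, 3))
        tr = fit_similarity(P, P)
        assert np.allclose(tr.rotation, np.eye(3), atol=1e-12)
        assert np.allclose(tr.translation, 0, atol=1e-12)
        assert tr.scale == pytest.approx(1.0)

    def test_pure_shift(self, rng):
        P = rng.normal(0, 50, (10, 3))
        tr = fit_similarity(P, P + [3.0, -2.0, 1.0])
        assert np.allclose(tr.translation, [3.0, -2.0, 1.0], atol=1e-12)
        assert tr.scale == pytest.approx(1.0)

    def test_scale_and_rotation_to_machine_precision(self, rng):
        P = rng.normal(0, 50, (10, 3))
        R0 = Rotation.random(random_state=12).as_matrix()
        tr = fit_similarity(P, 1.01 * P @ R0.T)
        assert tr.scale == pytest.approx(1.01, abs=1e-12)
        assert np.allclose(tr.rotation, R0, atol=1e-10)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_similarity(np.zeros((3, 3)), np.zeros((3, 3)))

    def test_reflection_disallowed(self, rng):
        P = rng.normal(0, 50, (12, 3))
        A = P.copy()
        A[:, 0] *= -1.0        # mirrored target
        tr = fit_similarity(P, A)
        assert np.linalg.det(tr.rotation) == pytest.approx(1.0)

    def test_matches_nonlinear_least_squares_oracle(self, rng):
        """Closed-form solution equals brute-force optimization on random
        noisy 10-point instances."""

        def oracle(P, A):
            def resid(p):
                rot = Rotation.from_rotvec(p[:3]).as_matrix()
                s = np.exp(p[3])
                return (A - (s * P @ rot.T + p[4:])).ravel()

            best = None
            for seed_rv in ([0.0, 0, 0], [0.5, -0.3, 0.2]):
                sol = least_squares(resid, x0=[*seed_rv, 0.0, 0, 0, 0],
                                    xtol=1e-15, ftol=1e-15)
                if best is None or sol.cost < best.cost:
                    best = sol
            return best

        for _ in range(10):
            P = rng.normal(0, 40, (10, 3))
            R0 = Rotation.from_rotvec(rng.normal(0, 0.2, 3)).as_matrix()
            A = 1.02 * P @ R0.T + rng.normal(0, 20, 3) + rng.normal(0, 0.5, (10, 3))
            tr = fit_similarity(P, A)
            sol = oracle(P, A)
            rot = Rotation.from_rotvec(sol.x[:3]).as_matrix()
            assert np.allclose(tr.rotation, rot, atol=1e-7)
            assert tr.scale == pytest.approx(np.exp(sol.x[3]), rel=1e-8)
            assert np.allclose(tr.translation, sol.x[4:], atol=1e-6)


def _loc_from_points(P, A, flags=None):
    import pandas as pd
    n = len(P)
    tab = pd.DataFrame({
        "id": np.arange(1, n + 1), "group": "fiducial_internal",
        "nx": P[:, 0], "ny": P[:, 1], "nz": P[:, 2],
        "ax": A[:, 0], "ay": A[:, 1], "az": A[:, 2],
        "peak": 1.0, "intensity": 1.0,
        "flag": np.zeros(n, bool) if flags is None else flags,
    })
    return LocalizationResult(tab, 5.0)


class TestDistortionReport:
    def test_mean_residual_absorbed_by_fit(self, rng):
        P = rng.normal(0, 60, (30, 3))
        A = P + rng.normal(0, 0.3, (30, 3))
        tr = fit_similarity(P, A)
        rep = compute_distortion(_loc_from_points(P, A), tr)
        assert np.allclose(rep.delta.mean(axis=0), 0, atol=1e-9)

    def test_sign_convention_positive_x(self, rng):
        """A sphere displaced +1 mm in x beyond the global fit reports a
        positive x-component of distortion."""
        P = rng.normal(0, 60, (30, 3))
        A = P.copy()
        A[5, 0] += 1.0
        tr = fit_similarity(P, A)
        rep = compute_distortion(_loc_from_points(P, A), tr)
        assert rep.table.loc[5, "dx"] > 0.5


class TestUniformityAndVolume:
    def test_uniform_bias_all_near_one(self, rng):
        centers = np.array([[12.0, 12, 12], [28, 12, 12], [12, 28, 12],
                            [28, 28, 12]]) + rng.uniform(-0.3, 0.3, (4, 3))
        vol = paint_spheres(centers, (40, 40, 24))
        loc = locate_spheres(vol, np.round(centers), search_mm=5.0)
        uni = compute_uniformity(loc)
        assert np.nanmax(uni.table.normalized) == pytest.approx(1.0)
        assert np.nanmin(uni.table.normalized) > 0.98

    def test_linear_bias_monotone_ordering(self, rng):
        centers = np.array([[12.0, 10, 12], [12, 30, 12], [12, 50, 12],
                            [12, 70, 12]])
        vol = paint_spheres(centers, (24, 80, 24))
        grad = 1.0 + 0.01 * np.arange(80)
        vol.data *= grad[None, :, None]
        loc = locate_spheres(vol, centers, search_mm=5.0)
        uni = compute_uniformity(loc)
        vals = uni.table.normalized.to_numpy()
        assert np.all(np.diff(vals) > 0)

    def test_flagged_sphere_excluded_from_normalization(self, rng):
        P = rng.normal(0, 60, (6, 3))
        import pandas as pd
        loc = _loc_from_points(P, P, flags=np.array([0, 0, 0, 0, 0, 1], bool))
        loc.table.loc[5, "intensity"] = 10.0   # brightest but flagged
        uni = compute_uniformity(loc)
        assert np.nanmax(uni.table.normalized) == pytest.approx(1.0)
        assert np.isnan(uni.table.normalized.iloc[5])

    def test_volume_ratio_near_one_and_scaling(self, rng):
        c = np.array([[16.0, 16.0, 16.0]])
        vol = paint_spheres(c, (33, 33, 33))
        loc = locate_spheres(vol, c, search_mm=5.0)
        vd = volume_distortion(vol, loc)
        assert vd.volume_ratio[0] == pytest.approx(1.0, abs=0.05)
        # locally scaled render: radius x 1.1 -> volume ratio 1.1^3
        vol2 = paint_spheres(c, (33, 33, 33), radius=5.5)
        loc2 = locate_spheres(vol2, c, search_mm=5.0)
        vd2 = volume_distortion(vol2, loc2)
        assert vd2.volume_ratio[0] == pytest.approx(1.1 ** 3, rel=0.06)

    def test_flagged_sphere_reports_missing_ratio(self):
        c = np.array([[16.0, 16.0, 16.0]])
        vol = paint_spheres(c, (33, 33, 33))
        loc = locate_spheres(vol, c, search_mm=5.0)
        loc.table.loc[0, "flag"] = True
        vd = volume_distortion(vol, loc)
        assert np.isnan(vd.volume_ratio[0])
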