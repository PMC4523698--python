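import numpy as np
import pytest

from vesselvote import (
    ScalarVolume,
    build_scale_space,
    eigendecompose,
    hessian_at_scale,
    make_scale_ladder,
    select_tokens,
    vesselness,
)
from vesselvote.scale_space import VesselnessParams, eigendecompose_field

from conftest import gaussian_tube_volume


class TestScaleLadder:
    def test_paper_defaults_ten_scales(self):
        lad = make_scale_ladder(1.0, 4.5, 10)
        assert len(lad) == 10
        assert lad[0] == 1.0 and lad[-1] == 4.5
        assert np.allclose(np.diff(np.log(lad.sigmas)), lad.log_step)

    def test_two_point_ladder(self):
        lad = make_scale_ladder(2.0, 2.0 * np.e, 2)
        assert np.allclose(lad.sigmas, [2.0, 2.0 * np.e])

    def test_midpoint_is_geometric_mean(self):
        lad = make_scale_ladder(1.0, 4.0, 3)
        assert np.allclose(lad.sigmas, [1.0, 2.0, 4.0])

    @pytest.mark.parametrize("args", [(0.0, 2.0, 5), (-1.0, 2.0, 5), (3.0, 2.0, 5),
                                      (1.0, 2.0, 1)])
    def test_bad_arguments_raise(self, args):
        with pytest.raises(ValueError):
            make_scale_ladder(*args)


class TestHessian:
    def test_constant_volume_zero_hessian(self):
        vol = ScalarVolume(np.full((10, 10, 10), 7.0))
        H = hessian_at_scale(vol, 1.5)
        assert np.abs(H).max() < 1e-10

    def test_quadratic_second_derivative(self):
        # I = x^2 along axis 0: d2I/dx2 = 2, everything else 0 (interior)
        x = np.arange(24.0)
        vol = ScalarVolume(np.broadcast_to((x**2)[:, None, None], (24, 24, 24)).copy())
        H = hessian_at_scale(vol, 1.5, gamma=0.0)
        core = H[8:16, 8:16, 8:16]
        assert np.allclose(core[..., 0, 0], 2.0, atol=0.05)
        assert np.abs(core[..., 0, 1]).max() < 1e-8
        assert np.abs(core[..., 1, 1]).max() < 1e-8

    def test_tube_cross_section_curvature_signs(self):
        vol = gaussian_tube_volume(sd=2.0)
        H = hessian_at_scale(vol, 2.0)
        h = H[15, 15, 20]  # near axis (axis at 15.5)
        k, _ = eigendecompose_field(h)
        assert k[1] < 0 and k[2] < 0      # cross-tube curvatures negative
        assert abs(k[0]) < 0.1 * abs(k[2])  # along-tube ~ 0

    def test_symmetry_exact(self):
        rng = np.random.default_rng(0)
        vol = ScalarVolume(rng.normal(size=(12, 12, 12)))
        H = hessian_at_scale(vol, 1.2)
        assert np.array_equal(H, np.swapaxes(H, -1, -2))

    def test_nonpositive_sigma_raises(self):
        vol = ScalarVolume(np.zeros((10, 10, 10)))
        with pytest.raises(ValueError):
            hessian_at_scale(vol, 0.0)

    def test_spacing_awareness(self):
        # the same physical field sampled anisotropically gives the same
        # physical Hessian at matching physical points
        sd = 3.0
        v1 = gaussian_tube_volume(shape=(32, 32, 16), spacing=(1.0, 1.0, 1.0), sd=sd)
        v2 = gaussian_tube_volume(shape=(64, 64, 16), spacing=(0.5, 0.5, 1.0),
                                  sd=sd, axis_xy=(15.75, 15.75))
        H1 = hessian_at_scale(v1, 2.0)[15, 15, 8]
        H2 = hessian_at_scale(v2, 2.0)[31, 31, 8]
        # discrete kernels at 2 vs 4 voxel sigmas differ at the ~2% level
        assert np.allclose(H1, H2, atol=0.05 * np.abs(H1).max())


def _char_poly_eigen(H):
    """Independent oracle: eigenvalues via the characteristic polynomial."""
    c2 = -np.trace(H)
    c1 = 0.5 * (np.trace(H) ** 2 - np.trace(H @ H))
    c0 = -np.linalg.det(H)
    roots = np.roots([1.0, c2, c1, c0])
    return np.sort_complex(roots).real


class TestEigendecompose:
    def test_diagonal_absolute_ordering(self):
        e = eigendecompose(np.diag([-5.0, -4.0, 0.1]))
        assert np.allclose(e.kappas, [0.1, -4.0, -5.0])

    def test_zero_matrix_canonical_basis(self):
        e = eigendecompose(np.zeros((3, 3)))
        assert np.allclose(e.kappas, 0)
        assert np.allclose(e.vecs, np.eye(3))

    def test_nonsymmetric_raises(self):
        M = np.array([[1.0, 2.0, 0], [0, 1, 0], [0, 0, 1.0]])
        with pytest.raises(ValueError):
            eigendecompose(M)

    def test_matches_characteristic_polynomial_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            A = rng.normal(size=(3, 3))
            H = 0.5 * (A + A.T)
            e = eigendecompose(H)
            expect = _char_poly_eigen(H)
            assert np.allclose(np.sort(e.kappas), expect, atol=1e-8)
            # residuals and orthonormality
            for kap, v in zip(e.kappas, e.vecs):
                assert np.linalg.norm(H @ v - kap * v) <= 1e-8 * max(1, np.abs(H).max())
            assert np.allclose(e.vecs @ e.vecs.T, np.eye(3), atol=1e-10)

    def test_sign_convention_deterministic(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(3, 3))
        H = 0.5 * (A + A.T)
        e = eigendecompose(H)
        for v in e.vecs:
            assert v[np.argmax(np.abs(v))] > 0


class TestVesselness:
    def test_zero_when_sign_condition_fails(self):
        assert vesselness(np.array([0.0, 3.0, 5.0]), c=1.0, smooth_c=0.0) == 0.0
        assert vesselness(np.array([0.0, -3.0, 5.0]), c=1.0, smooth_c=0.0) == 0.0

    def test_tube_outscores_blob(self):
        c = 3.0
        tube = vesselness(np.array([0.0, -c, -c]), c=2.0, smooth_c=0.0)
        blob = vesselness(np.array([-c, -c, -c]), c=2.0, smooth_c=0.0)
        assert tube > blob > 0

    def test_range_and_smoothness(self):
        rng = np.random.default_rng(5)
        k = rng.normal(size=(1000, 3)) * 4
        k = np.sort(np.abs(k), axis=1) * np.sign(k)  # |.|-ordered-ish
        nu = vesselness(np.sort(np.abs(k), axis=1) * -1, c=2.0, smooth_c=0.0)
        assert np.all(nu >= 0) and np.all(nu <= 1)

    def test_centerline_dominates_background(self, tube_volume, tube_scale_space):
        nu = tube_scale_space.nu_max
        center = nu[15, 15, 20]
        background = nu[2, 2, 20]
        assert center > 10 * max(background, 1e-12)

    def test_invariant_to_intensity_offset(self, ladder10):
        vol = gaussian_tube_volume()
        shifted = ScalarVolume(vol.data + 11.0, spacing=vol.spacing)
        ss1 = build_scale_space(vol, ladder10)
        ss2 = build_scale_space(shifted, ladder10)
        assert np.allclose(ss1.nu_max, ss2.nu_max, atol=1e-12)


class TestScaleSpaceBuild:
    def test_constant_volume(self, ladder10):
        vol = ScalarVolume(np.full((10, 10, 10), 3.0))
        ss = build_scale_space(vol, ladder10)
        assert np.all(ss.nu_max == 0)
        assert np.all(ss.M == ladder10[0])  # tie-break to smallest scale

    def test_optimal_scale_consistency(self, tube_scale_space):
        ss = tube_scale_space
        idx = ss.sigma_idx
        assert np.allclose(ss.nu_max,
                           np.take_along_axis(ss.nu, idx[None], axis=0)[0])
        assert np.allclose(ss.M, np.asarray(ss.ladder.sigmas)[idx])
        assert np.all(ss.nu_max == ss.nu.max(axis=0))

    def test_scale_recovery_on_centerline(self, tube_scale_space, ladder10):
        # gamma=1 selection picks sigma ~ profile sd (2.0 mm) on-axis
        M = tube_scale_space.M[15, 15, 5:35]
        step = np.exp(ladder10.log_step)
        assert np.all((M >= 2.0 / step) & (M <= 2.0 * step))

    def test_thick_tube_selects_larger_scale(self, ladder10):
        thin = gaussian_tube_volume(sd=1.5)
        thick = gaussian_tube_volume(sd=3.0)
        M_thin = np.median(build_scale_space(thin, ladder10).M[15, 15, 5:35])
        M_thick = np.median(build_scale_space(thick, ladder10).M[15, 15, 5:35])
        assert M_thick > M_thin

    def test_scale_covariance(self):
        # doubling tube size and the ladder doubles the selected scale
        lad1 = make_scale_ladder(1.0, 4.0, 7)
        lad2 = make_scale_ladder(2.0, 8.0, 7)
        v1 = gaussian_tube_volume(sd=1.5)
        v2 = gaussian_tube_volume(shape=(64, 64, 40), sd=3.0, axis_xy=(31.5, 31.5))
        M1 = np.median(build_scale_space(v1, lad1).M[15, 15, 5:35])
        M2 = np.median(build_scale_space(v2, lad2).M[31, 31, 5:35])
        ratio = M2 / M1
        step = np.exp(lad1.log_step)
        assert 2.0 / step <= ratio <= 2.0 * step


class TestSelectTokens:
    def test_constant_volume_empty(self, ladder10):
        vol = ScalarVolume(np.full((10, 10, 10), 3.0))
        ss = build_scale_space(vol, ladder10)
        tokens = select_tokens(ss, vol)
        assert len(tokens) == 0

    def test_superset_of_positive_vesselness(self, tube_volume, tube_scale_space):
        tokens = select_tokens(tube_scale_space, tube_volume)
        assert np.all(tokens.mask[tube_scale_space.nu_max > 0])

    def test_inverted_tube_centerline_excluded(self, ladder10):
        vol = gaussian_tube_volume()
        inv = ScalarVolume(vol.data.max() - vol.data, spacing=vol.spacing)
        ss = build_scale_space(inv, ladder10)
        tokens = select_tokens(ss, inv)
        assert not tokens.mask[15, 15, 10:30].any()

    def test_centerline_admitted(self, tube_volume, tube_scale_space):
        tokens = select_tokens(tube_scale_space, tube_volume)
        centerline = tokens.mask[15, 15, 2:38]
        assert centerline.mean() >= 0.95

    def test_mask_restricts(self, tube_volume, tube_scale_space):
        m = np.zeros(tube_volume.shape, dtype=bool)
        m[:, :, :20] = True
        tokens = select_tokens(tube_scale_space, tube_volume, mask=m)
        assert np.all(tokens.sites[:, 2] < 20)

    def test_token_eigensystem_matches_optimal_scale(self, tube_volume,
                                                     tube_scale_space):
        tokens = select_tokens(tube_scale_space, tube_volume, min_nu_rel=0.05)
        i = len(tokens) // 2
        site = tokens.sites[i]
        sig = tokens.M[i]
        H = hessian_at_scale(tube_volume, sig)[tuple(site)]
        k, _ = eigendecompose_field(H)
        assert np.allclose(k, tokens.kappas[i], atol=1e-10)
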