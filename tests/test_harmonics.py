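"""Reciprocal-space core: amplitudes, intensities, Wigner rotations.

The independent oracle throughout is the Debye formula
I(s) = sum_jk w_j w_k sinc(s r_jk), which needs no harmonic expansion.
"""

import numpy as np
import pytest
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation
from scipy.special import spherical_jn

from harmalign.geometry import RigidTransform, apply_transform, max_diameter
from harmalign.harmonics import (_spherical_jn_all, cross_intensity,
                                 default_s_grid, intensity,
                                 partial_amplitudes,
                                 partial_amplitudes_from_map,
                                 rotate_amplitudes, shannon_smax, sph_harm,
                                 translate_and_rotate_amplitudes)
from harmalign.models import DensityMap, PointModel
from harmalign.models_io import map_to_points
from harmalign.proximity import ncc

from conftest import random_point_model


def debye_intensity(model: PointModel, s_grid: np.ndarray) -> np.ndarray:
    """Brute-force exact orientational average (the independent oracle)."""
    rjk = cdist(model.coords, model.coords)
    out = np.empty(len(s_grid))
    for i, s in enumerate(s_grid):
        x = s * rjk
        sinc = np.where(x == 0, 1.0, np.sin(x) / np.where(x == 0, 1.0, x))
        out[i] = model.weights @ sinc @ model.weights
    return out


class TestSphHarm:
    def test_y00_constant(self):
        for theta, phi in [(0.1, 0.2), (1.0, -2.0), (3.0, 0.0)]:
            assert sph_harm(0, 0, theta, phi) == pytest.approx(
                1 / np.sqrt(4 * np.pi))

    def test_y10_at_pole(self):
        assert sph_harm(1, 0, 0.0, 0.0).real == pytest.approx(
            np.sqrt(3 / (4 * np.pi)))

    def test_invalid_m_rejected(self):
        with pytest.raises(ValueError):
            sph_harm(1, 2, 0.0, 0.0)

    def test_orthonormality_by_quadrature(self):
        # Gauss-Legendre in cos(theta) x uniform phi integrates |Y_21|^2
        # exactly (polynomial integrand, periodic azimuth)
        nodes, wts = np.polynomial.legendre.leggauss(12)
        theta = np.arccos(nodes)
        phi = np.linspace(0, 2 * np.pi, 64, endpoint=False)
        vals = sph_harm(2, 1, theta[:, None], phi[None, :])
        integral = ((np.abs(vals) ** 2).sum(axis=1) * (2 * np.pi / 64)
                    ) @ wts
        assert integral == pytest.approx(1.0, abs=1e-6)


class TestSphericalBessel:
    @pytest.mark.parametrize("L", [2, 5, 15])
    def test_matches_scipy(self, L):
        rng = np.random.default_rng(1)
        x = np.concatenate([[0.0], rng.uniform(0, 1, 500),
                            rng.uniform(1, 2 * L + 5, 500),
                            rng.uniform(2 * L + 5, 80, 300)])
        mine = _spherical_jn_all(L, x)
        ref = np.array([spherical_jn(l, x) for l in range(L + 1)])
        assert np.max(np.abs(mine - ref)
                      / np.maximum(np.abs(ref), 1e-12)) < 1e-8


class TestPartialAmplitudes:
    def test_point_at_origin_is_pure_monopole(self):
        m = PointModel([[0.0, 0.0, 0.0]], [1.0])
        a = partial_amplitudes(m, 4, np.linspace(0, 0.5, 8))
        mono = a.coeffs[a.lm_index(0, 0)]
        assert np.allclose(mono, mono[0])  # constant in s
        rest = np.delete(a.coeffs, a.lm_index(0, 0), axis=0)
        assert np.abs(rest).max() == 0.0

    def test_axial_model_has_only_m0(self):
        m = PointModel([[0, 0, z] for z in (1.0, 2.5, -3.0)], [1, 1, 1])
        a = partial_amplitudes(m, 5, np.linspace(0, 0.5, 6))
        for l in range(6):
            for mm in range(-l, l + 1):
                if mm != 0:
                    assert np.abs(a.coeffs[a.lm_index(l, mm)]).max() < 1e-14

    def test_real_density_symmetry(self):
        m = random_point_model(12, n=25)
        a = partial_amplitudes(m, 6, np.linspace(0, 0.4, 10))
        for l in range(7):
            for mm in range(l + 1):
                lhs = a.coeffs[a.lm_index(l, -mm)]
                rhs = (-1) ** mm * np.conj(a.coeffs[a.lm_index(l, mm)])
                np.testing.assert_allclose(lhs, rhs, rtol=1e-9, atol=1e-12)

    def test_map_path_equals_two_step_path(self):
        rng = np.random.default_rng(4)
        dmap = DensityMap(rng.uniform(0, 1, (6, 6, 6)), 2.0,
                          origin=[-6.0, -6.0, -6.0])
        s = np.linspace(0, 0.3, 8)
        via_map = partial_amplitudes_from_map(dmap, 0.5, 4, s)
        via_points = partial_amplitudes(map_to_points(dmap, 0.5), 4, s)
        np.testing.assert_allclose(via_map.coeffs, via_points.coeffs,
                                   atol=1e-12)


class TestIntensity:
    def test_single_point_forward_scattering(self):
        m = PointModel([[0.0, 0.0, 0.0]], [2.0])
        curve = intensity(partial_amplitudes(m, 3, np.linspace(0, 1, 5)))
        np.testing.assert_allclose(curve.values, 4.0)

    def test_forward_scattering_identity(self):
        m = random_point_model(13, n=35)
        curve = intensity(partial_amplitudes(m, 5, np.linspace(0, 0.4, 6)))
        assert curve.values[0] == pytest.approx(m.weights.sum() ** 2,
                                                rel=1e-9)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_debye_oracle_at_converged_L(self, seed):
        m = random_point_model(seed, n=20, extent=10.0)
        d_max = max_diameter(m)
        s = default_s_grid(shannon_smax(d_max, 7), 5)
        computed = intensity(partial_amplitudes(m, 16, s)).values
        expected = debye_intensity(m, s)
        assert np.max(np.abs(computed - expected) / expected) < 0.01


class TestCrossIntensity:
    def test_self_cross_equals_intensity(self):
        m = random_point_model(14, n=15)
        a = partial_amplitudes(m, 5, np.linspace(0, 0.4, 8))
        np.testing.assert_allclose(cross_intensity(a, a).values,
                                   intensity(a).values, rtol=1e-12)

    def test_symmetric(self):
        a = partial_amplitudes(random_point_model(15), 4,
                               np.linspace(0, 0.3, 6))
        b = partial_amplitudes(random_point_model(16), 4,
                               np.linspace(0, 0.3, 6))
        np.testing.assert_allclose(cross_intensity(a, b).values,
                                   cross_intensity(b, a).values)

    def test_cauchy_schwarz_pointwise(self):
        a = partial_amplitudes(random_point_model(17), 5,
                               np.linspace(0, 0.5, 10))
        b = partial_amplitudes(random_point_model(18), 5,
                               np.linspace(0, 0.5, 10))
        iab = cross_intensity(a, b).values
        assert np.all(iab ** 2 <= intensity(a).values * intensity(b).values
                      + 1e-9)

    def test_far_shifted_copy_decorrelates(self):
        m = random_point_model(19, n=30)
        d_max = max_diameter(m)
        s = default_s_grid(shannon_smax(d_max, 7), 12)
        a = partial_amplitudes(m, 12, s)
        shifted = m.replace_coords(m.coords + [10 * d_max, 0, 0])
        b = partial_amplitudes(shifted, 12, s)
        iab = np.abs(cross_intensity(a, b).values[1:])
        ia = intensity(a).values[1:]
        assert np.median(iab / ia) < 0.2

    def test_grid_mismatch_rejected(self):
        a = partial_amplitudes(random_point_model(20), 4,
                               np.linspace(0, 0.3, 6))
        b = partial_amplitudes(random_point_model(20), 4,
                               np.linspace(0, 0.4, 6))
        with pytest.raises(ValueError):
            cross_intensity(a, b)


class TestParseval:
    def test_merged_intensity_decomposition(self):
        """I_merged = I_A + I_B + 2 I_AB for models in a common frame."""
        for seed in (21, 22):
            ma = random_point_model(seed, n=15, centered=False)
            mb = random_point_model(seed + 50, n=12, centered=False)
            s = np.linspace(0, 0.4, 12)
            a = partial_amplitudes(ma, 6, s)
            b = partial_amplitudes(mb, 6, s)
            merged = PointModel(np.vstack([ma.coords, mb.coords]),
                                np.concatenate([ma.weights, mb.weights]))
            lhs = intensity(partial_amplitudes(merged, 6, s)).values
            rhs = (intensity(a).values + intensity(b).values
                   + 2 * cross_intensity(a, b).values)
            np.testing.assert_allclose(lhs, rhs, rtol=1e-8)


class TestRotateAmplitudes:
    def test_identity_rotation(self):
        a = partial_amplitudes(random_point_model(23), 5,
                               np.linspace(0, 0.4, 8))
        out = rotate_amplitudes(a, np.eye(3))
        np.testing.assert_allclose(out.coeffs, a.coeffs, atol=1e-12)

    def test_z_rotation_changes_phase_only(self):
        a = partial_amplitudes(random_point_model(24), 5,
                               np.linspace(0, 0.4, 8))
        rot = Rotation.from_euler("z", 0.9).as_matrix()
        out = rotate_amplitudes(a, rot)
        np.testing.assert_allclose(np.abs(out.coeffs), np.abs(a.coeffs),
                                   rtol=1e-10, atol=1e-14)

    @pytest.mark.parametrize("seed", [1, 2, 3, 4])
    def test_agrees_with_recompute_from_rotated_coords(self, seed):
        m = random_point_model(25, n=20)
        a = partial_amplitudes(m, 5, np.linspace(0, 0.4, 10))
        r = Rotation.random(random_state=seed).as_matrix()
        via_wigner = rotate_amplitudes(a, r)
        via_coords = partial_amplitudes(m.replace_coords(m.coords @ r.T), 5,
                                        a.s_grid)
        scale = np.abs(a.coeffs).max()
        assert np.abs(via_wigner.coeffs - via_coords.coeffs).max() \
            <= 1e-8 * scale

    def test_gimbal_poles(self):
        m = random_point_model(26, n=15)
        a = partial_amplitudes(m, 5, np.linspace(0, 0.4, 6))
        for r in (np.diag([1.0, -1.0, -1.0]), np.diag([-1.0, -1.0, 1.0]),
                  Rotation.from_euler("zy", [0.4, np.pi]).as_matrix()):
            via_wigner = rotate_amplitudes(a, r)
            via_coords = partial_amplitudes(
                m.replace_coords(m.coords @ r.T), 5, a.s_grid)
            assert np.abs(via_wigner.coeffs
                          - via_coords.coeffs).max() < 1e-10

    def test_intensity_rotation_invariance(self):
        a = partial_amplitudes(random_point_model(27), 6,
                               np.linspace(0, 0.4, 8))
        r = Rotation.random(random_state=9).as_matrix()
        np.testing.assert_allclose(intensity(rotate_amplitudes(a, r)).values,
                                   intensity(a).values, rtol=1e-10)

    def test_improper_matrix_rejected(self):
        a = partial_amplitudes(random_point_model(28), 3,
                               np.linspace(0, 0.3, 5))
        with pytest.raises(ValueError):
            rotate_amplitudes(a, np.diag([1.0, 1.0, -1.0]))


class TestTranslateAndRotate:
    def test_pure_rotation_equals_wigner_path(self):
        m = random_point_model(29, n=18)
        a = partial_amplitudes(m, 5, np.linspace(0, 0.4, 8))
        r = Rotation.random(random_state=11).as_matrix()
        t = RigidTransform(rotation=r)
        out = translate_and_rotate_amplitudes(m, a, t)
        np.testing.assert_allclose(out.coeffs,
                                   rotate_amplitudes(a, r).coeffs,
                                   atol=1e-10)

    def test_translated_origin_point_is_axial(self):
        m = PointModel([[0.0, 0.0, 0.0]], [1.0])
        a = partial_amplitudes(m, 5, np.linspace(0, 0.5, 8))
        out = translate_and_rotate_amplitudes(
            m, a, RigidTransform(translation=[0, 0, 7.0]))
        for l in range(6):
            for mm in range(-l, l + 1):
                coeff = out.coeffs[out.lm_index(l, mm)]
                if mm != 0:
                    assert np.abs(coeff).max() < 1e-14
        # l=0 matches the explicit spherical wave j_0(s d) / sqrt(4 pi)
        expected = (np.sqrt(2 / np.pi) * spherical_jn(0, a.s_grid * 7.0)
                    / np.sqrt(4 * np.pi))
        np.testing.assert_allclose(out.coeffs[0], expected, atol=1e-12)

    def test_matches_full_recompute(self):
        m = random_point_model(30, n=20)
        a = partial_amplitudes(m, 5, np.linspace(0, 0.4, 8))
        t = RigidTransform(Rotation.random(random_state=12).as_matrix(),
                           [3.0, -2.0, 1.0])
        out = translate_and_rotate_amplitudes(m, a, t)
        direct = partial_amplitudes(apply_transform(m, t), 5, a.s_grid)
        np.testing.assert_allclose(out.coeffs, direct.coeffs, atol=1e-12)

    def test_mirror_changes_ncc_of_chiral_model(self, chiral_tetra):
        s = np.linspace(0, 0.6, 12)
        a = partial_amplitudes(chiral_tetra, 5, s)
        mirrored = translate_and_rotate_amplitudes(
            chiral_tetra, a, RigidTransform(mirror=True))
        assert abs(ncc(a, mirrored) - 1.0) > 1e-3


class TestShannon:
    def test_seven_channels_of_100A(self):
        assert shannon_smax(100.0, 7) == pytest.approx(7 * np.pi / 100)

    def test_unit_case(self):
        assert shannon_smax(np.pi, 1) == pytest.approx(1.0)

    def test_inverse_proportionality(self):
        assert shannon_smax(50.0, 7) == pytest.approx(
            2 * shannon_smax(100.0, 7))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            shannon_smax(-1.0, 7)
        with pytest.raises(ValueError):
            shannon_smax(10.0, 0)
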