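import numpy as np
import pytest

from nuctract.contour import Contour
from nuctract.elasticity import (
    ElasticParams,
    PointMapping,
    StrainField,
    energy_density,
    stress_from_strain,
    traction,
)
from nuctract.errors import ContourError, IncompressibilityError, MeshError
from nuctract.geometry import centroid, frames
from nuctract.solid import SolidModel, interior_deformation
from nuctract.synth import make_deformation_pair, make_shape


def centred(contour):
    return contour.translated(-centroid(contour))


def affine_mapping(contour, A):
    init = centred(contour)
    return PointMapping(init, Contour(init.points @ np.asarray(A).T))


@pytest.fixture
def circle48():
    return make_shape("circle", radius=5.0, n_points=48)


class TestInteriorDeformation:
    def test_zero_fraction(self, circle48):
        pair = make_deformation_pair(circle48, "dilation", 0.1)
        u = interior_deformation(pair.mapping, 0.0)
        np.testing.assert_array_equal(u, 0.0)

    def test_boundary_identity(self, circle48):
        pair = make_deformation_pair(circle48, "dilation", 0.1)
        np.testing.assert_array_equal(
            interior_deformation(pair.mapping, 1.0), pair.mapping.u)

    def test_linear_rule(self):
        # u_k = (2, -4) at the boundary -> (1, -2) halfway along the spoke
        c = make_shape("circle", radius=5.0, n_points=32)
        mapping = PointMapping(c, c.translated([2.0, -4.0]))
        u = interior_deformation(mapping, 0.5)
        np.testing.assert_allclose(u, np.tile([1.0, -2.0], (32, 1)))

    def test_fraction_out_of_range(self, circle48):
        pair = make_deformation_pair(circle48, "dilation", 0.1)
        with pytest.raises(ValueError):
            interior_deformation(pair.mapping, 1.5)


class TestStrain:
    def test_zero_map(self, circle48, params):
        mapping = PointMapping(circle48, circle48)
        eps = SolidModel(params).strain(mapping)
        assert np.abs(eps.tensors).max() == 0.0

    @pytest.mark.parametrize("convention,quad", [
        ("green-lagrange", 0.5), ("as-printed", 0.25)])
    def test_affine_stretch_oracle(self, circle48, convention, quad):
        # u = (a x, -a y): symbolic strain eps_xx = a + quad*a^2, exact per point
        a = 0.1
        mapping = affine_mapping(circle48, [[1 + a, 0], [0, 1 - a]])
        model = SolidModel(ElasticParams(strain_convention=convention))
        eps = model.strain(mapping).tensors
        np.testing.assert_allclose(eps[..., 0, 0], a + quad * a * a, atol=1e-3)
        np.testing.assert_allclose(eps[..., 1, 1], -a + quad * a * a, atol=1e-3)
        np.testing.assert_allclose(eps[..., 0, 1], 0.0, atol=1e-3)

    def test_rigid_rotation_green_lagrange(self, circle48, gl_params):
        th = np.radians(5.0)
        R = [[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]]
        eps = SolidModel(gl_params).strain(affine_mapping(circle48, R))
        assert np.abs(eps.tensors).max() < 1e-6

    def test_trace_free_by_closure(self, circle48, rng, params):
        model = SolidModel(params)
        for _ in range(10):
            A = np.eye(2) + 0.1 * rng.standard_normal((2, 2))
            eps = model.strain(affine_mapping(circle48, A))
            assert np.abs(eps.trace).max() < 1e-12

    def test_mesh_too_coarse(self, params):
        with pytest.raises(MeshError):
            SolidModel(params, n_rings=2)


class TestStress:
    def test_incompressible_diagonal_example(self):
        e = 0.01
        eps = StrainField(np.diag([e, -e, 0.0])[None])
        sig = stress_from_strain(eps, ElasticParams(E=5000.0, nu=0.5))
        expected = (2.0 * 5000.0 / 3.0) * np.diag([e, -e, 0.0])
        np.testing.assert_allclose(sig.tensors[0], expected, rtol=1e-12)

    def test_zero_strain(self, params):
        sig = stress_from_strain(StrainField(np.zeros((4, 3, 3))), params)
        assert np.abs(sig.tensors).max() == 0.0

    def test_doubling_E_doubles_stress_exactly(self, rng):
        t = rng.standard_normal((5, 3, 3)) * 0.01
        t = 0.5 * (t + np.swapaxes(t, -1, -2))
        t[..., 2, 2] = -(t[..., 0, 0] + t[..., 1, 1])
        eps = StrainField(t)
        s1 = stress_from_strain(eps, ElasticParams(E=5000.0)).tensors
        s2 = stress_from_strain(eps, ElasticParams(E=10000.0)).tensors
        np.testing.assert_array_equal(s2, 2.0 * s1)

    def test_compressible_branch(self):
        eps = StrainField(np.diag([0.01, 0.02, 0.03])[None])
        E, nu = 1000.0, 0.3
        sig = stress_from_strain(eps, ElasticParams(E=E, nu=nu)).tensors[0]
        tr = 0.06
        expected = E / (1 + nu) * (np.diag([0.01, 0.02, 0.03])
                                   + nu / (1 - 2 * nu) * tr * np.eye(3))
        np.testing.assert_allclose(sig, expected, rtol=1e-12)

    def test_incompressibility_violation(self):
        eps = StrainField(np.diag([0.01, 0.01, 0.0])[None])
        with pytest.raises(IncompressibilityError):
            stress_from_strain(eps, ElasticParams(nu=0.5))


class TestEnergyDensity:
    def test_zero(self, params):
        eps = StrainField(np.zeros((3, 3, 3)))
        sig = stress_from_strain(eps, params)
        assert np.abs(energy_density(eps, sig)).max() == 0.0

    def test_diagonal_example(self):
        e, E = 0.01, 5000.0
        eps = StrainField(np.diag([e, -e, 0.0])[None])
        sig = stress_from_strain(eps, ElasticParams(E=E, nu=0.5))
        f = energy_density(eps, sig)[0]
        assert f == pytest.approx((2 * E / 3) * e * e, rel=1e-12)

    def test_brute_force_contraction_oracle(self, rng, params):
        t = rng.standard_normal((6, 3, 3)) * 0.02
        t = 0.5 * (t + np.swapaxes(t, -1, -2))
        t[..., 2, 2] = -(t[..., 0, 0] + t[..., 1, 1])
        eps = StrainField(t)
        sig = stress_from_strain(eps, params)
        f = energy_density(eps, sig)
        for k in range(6):
            brute = 0.0
            for i in range(3):
                for j in range(3):
                    brute += 0.5 * sig.tensors[k, i, j] * eps.tensors[k, i, j]
            assert f[k] == pytest.approx(brute, rel=1e-12)

    def test_mismatched_sizes(self, params):
        eps = StrainField(np.zeros((3, 3, 3)))
        sig = stress_from_strain(StrainField(np.zeros((4, 3, 3))), params)
        with pytest.raises(MeshError):
            energy_density(eps, sig)


class TestTraction:
    def test_isotropic_stress(self, circle48):
        fr = frames(circle48)
        p = 100.0
        sig = stress_from_strain(
            StrainField(np.tile(np.diag([0.01, 0.01, -0.02]), (48, 1, 1))),
            ElasticParams(nu=0.5))
        t = traction(sig, fr)
        sxx = sig.tensors[0, 0, 0]
        np.testing.assert_allclose(t, sxx * fr.normal, atol=1e-12)
        k = int(np.argmax(circle48.points[:, 0]))
        np.testing.assert_allclose(t[k], [sxx, 0.0], atol=1e-12)

    def test_zero_stress(self, circle48, params):
        fr = frames(circle48)
        sig = stress_from_strain(StrainField(np.zeros((48, 3, 3))), params)
        assert np.abs(traction(sig, fr)).max() == 0.0

    def test_matrix_vector_oracle(self, rng, circle48, params):
        fr = frames(circle48)
        t3 = rng.standard_normal((48, 3, 3)) * 0.01
        t3 = 0.5 * (t3 + np.swapaxes(t3, -1, -2))
        t3[..., 2, 2] = -(t3[..., 0, 0] + t3[..., 1, 1])
        sig = stress_from_strain(StrainField(t3), params)
        t = traction(sig, fr)
        for k in range(0, 48, 7):
            expect = sig.tensors[k, :2, :2] @ fr.normal[k]
            np.testing.assert_allclose(t[k], expect, atol=1e-12)

    def test_non_unit_normal_rejected(self, circle48):
        from nuctract.geometry import FrameField

        fr = frames(circle48)
        with pytest.raises(ContourError):
            FrameField(points=fr.points, s1=fr.s1, normal=2.0 * fr.normal,
                       tangent=fr.tangent, phi=fr.phi, curvature=fr.curvature,
                       total_length=fr.total_length)


class TestModelLevel:
    def test_radial_stress_constant_along_spokes(self, params):
        circ = make_shape("circle", radius=5.0, n_points=64)
        ell = make_shape("ellipse", a=6.0, b=4.0, n_points=64)
        from nuctract.annealing import initial_mapping

        mapping = initial_mapping(centred(circ), centred(ell), n=64)
        model = SolidModel(params)
        sig = model.stress(model.strain(mapping)).tensors
        p = mapping.initial.points - centroid(mapping.initial)
        rhat = p / np.linalg.norm(p, axis=1, keepdims=True)
        srr = np.einsum("rkij,ki,kj->rk", sig[:, :, :2, :2], rhat, rhat)
        assert np.abs(srr - srr[0]).max() < 1e-9 * max(np.abs(srr).max(), 1.0)

    def test_translation_pair_energy_negligible(self, circle48, params):
        from nuctract.ensemble import align_pair
        from nuctract.geometry import area

        pair = align_pair(circle48, circle48.translated([2.0, 0.0]))
        mapping = PointMapping(pair.initial, pair.target)
        model = SolidModel(params)
        scale = params.E * area(circle48) * 1.0
        assert model.total_energy(mapping) < 1e-10 * scale

    def test_total_energy_matches_bound_energy(self, circle48, params):
        pair = make_deformation_pair(circle48, "area-preserving-affine", 0.1)
        model = SolidModel(params)
        e1 = model.total_energy(pair.mapping)
        e2 = model.bind_energy(pair.mapping.initial)(pair.mapping.target.points)
        assert e1 == e2

    def test_traction_E_linearity_bitwise(self, circle48):
        pair = make_deformation_pair(circle48, "area-preserving-affine", 0.08)
        t1 = SolidModel(ElasticParams(E=5000.0)).traction_profile(pair.mapping)
        t2 = SolidModel(ElasticParams(E=10000.0)).traction_profile(pair.mapping)
        np.testing.assert_array_equal(t2.traction_vec, 2.0 * t1.traction_vec)

    def test_profile_dataframe_schema(self, circle48, params):
        pair = make_deformation_pair(circle48, "dilation", 0.05)
        df = SolidModel(params).traction_profile(pair.mapping).to_dataframe()
        assert list(df.columns) == ["s1_um", "x_um", "y_um", "tx_Pa", "ty_Pa",
                                    "tmag_Pa", "f_J_per_m3", "model"]
        assert (df["model"] == "solid").all()
        np.testing.assert_allclose(
            df["tmag_Pa"], np.hypot(df["tx_Pa"], df["ty_Pa"]))
        assert (df["f_J_per_m3"] >= 0).all()
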