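"""Sphere fitting, rim selection and acetabular frame estimation."""

import numpy as np
import pytest
import trimesh

import acetrec.synthetic_anatomy as syn
from acetrec.acetabular_frame import (AcetabularFrame, N_RIM_POINTS,
                                      compute_frame, excision_sphere,
                                      fit_sphere, frame_from_mesh,
                                      select_rim_points)
from acetrec.errors import CupNotFoundError, DegenerateGeometryError


def _sphere_points(centre, radius, n, rng):
    v = rng.normal(size=(n, 3))
    v /= np.linalg.norm(v, axis=1)[:, None]
    return np.asarray(centre) + radius * v


class TestFitSphere:
    def test_exact_recovery(self, rng):
        pts = _sphere_points((1.0, 2.0, 3.0), 25.0, 19, rng)
        centre, radius = fit_sphere(pts)
        assert np.allclose(centre, [1, 2, 3], atol=1e-9)
        assert radius == pytest.approx(25.0, abs=1e-9)

    def test_noisy_radius_bias_below_one_percent(self, rng):
        radii = []
        for _ in range(100):
            pts = _sphere_points((1.0, 2.0, 3.0), 25.0, 19, rng)
            pts += rng.normal(0, 0.5, pts.shape)
            radii.append(fit_sphere(pts)[1])
        assert np.mean(radii) == pytest.approx(25.0, rel=0.01)

    def test_coplanar_rejected(self, rng):
        pts = np.column_stack([rng.uniform(-5, 5, 8), rng.uniform(-5, 5, 8),
                               np.zeros(8)])
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(pts)

    def test_too_few_points_rejected(self):
        with pytest.raises(DegenerateGeometryError):
            fit_sphere(np.eye(3))


class TestRimSelection:
    def test_nineteen_points_on_analytic_rim(self, phantom, default_params):
        rim = select_rim_points(phantom.native_mesh)
        assert rim.shape == (N_RIM_POINTS, 3)
        # distance to the analytic rim circle (radius r in the top-face plane)
        r = default_params.cup_radius
        z = rim[:, 2] - default_params.cup_centre[2]
        radial = np.linalg.norm(rim[:, :2] - np.asarray(default_params.cup_centre[:2]),
                                axis=1)
        dist = np.sqrt((radial - r) ** 2 + z**2)
        assert dist.max() < 1.0

    def test_convex_surface_has_no_cup(self):
        ellipsoid = trimesh.creation.icosphere(4, radius=1.0)
        ellipsoid.apply_scale([40.0, 30.0, 20.0])
        with pytest.raises(CupNotFoundError):
            select_rim_points(ellipsoid)


class TestFrame:
    def test_polar_axis_matches_phantom(self, phantom, default_params):
        fr = frame_from_mesh(phantom.native_mesh)
        angle = np.degrees(np.arccos(np.clip(
            fr.polar_axis @ np.asarray(default_params.polar_axis), -1, 1)))
        assert angle < 2.0
        assert fr.radius == pytest.approx(default_params.cup_radius, rel=0.02)
        assert np.linalg.norm(fr.hjc - default_params.cup_centre) < 1.0

    def test_axes_orthonormal(self, phantom):
        fr = frame_from_mesh(phantom.native_mesh)
        M = np.column_stack([fr.anterior_axis, fr.superior_axis, fr.polar_axis])
        assert np.allclose(M.T @ M, np.eye(3), atol=1e-9)
        assert fr.polar_axis @ fr.plane_normal > 0.9

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_rigid_equivariance(self, phantom, seed):
        rng = np.random.default_rng(seed)
        angle = rng.uniform(0.05, np.pi / 12)
        axis = rng.normal(size=3)
        T = trimesh.transformations.rotation_matrix(angle, axis,
                                                    point=rng.uniform(-10, 10, 3))
        R = T[:3, :3]
        moved = phantom.native_mesh.copy()
        moved.apply_transform(T)
        fr0 = frame_from_mesh(phantom.native_mesh)
        fr1 = frame_from_mesh(moved, body_axes_hint=R @ [0.0, 1.0, 0.0])
        for a0, a1 in ((fr0.polar_axis, fr1.polar_axis),
                       (fr0.superior_axis, fr1.superior_axis),
                       (fr0.anterior_axis, fr1.anterior_axis)):
            ang = np.degrees(np.arccos(np.clip((R @ a0) @ a1, -1, 1)))
            assert ang < 2.0

    def test_collinear_rim_rejected(self):
        rim = np.column_stack([np.linspace(0, 10, 19), np.zeros(19), np.zeros(19)])
        with pytest.raises(DegenerateGeometryError):
            compute_frame(rim, (np.zeros(3), 25.0))


class TestExcisionSphere:
    def test_radius_factor(self):
        fr = AcetabularFrame(hjc=(1, 2, 3), radius=25.0,
                             polar_axis=(0, 0, 1), superior_axis=(0, 1, 0))
        sph = excision_sphere(fr)
        assert fr.excision_radius == 62.5
        # centre and radius from the mesh itself
        assert np.allclose(sph.vertices.mean(axis=0), [1, 2, 3], atol=1e-6)
        assert sph.is_watertight
        expected = 4.0 / 3.0 * np.pi * 62.5**3
        assert sph.volume == pytest.approx(expected, rel=0.005)
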