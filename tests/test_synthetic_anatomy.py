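"""Phantom construction, defect carving and the voxel oracle."""

import numpy as np
import pytest
import trimesh

import acetrec.synthetic_anatomy as syn
from acetrec.errors import InvalidParameterError, NonWatertightMeshError


class TestPhantom:
    def test_watertight_and_positive_volume(self, phantom):
        m = phantom.native_mesh
        assert m.is_watertight and m.is_winding_consistent
        assert m.volume > 0

    def test_block_minus_hemisphere_volume(self):
        # 80 x 80 x 60 mm block with a 25 mm hemispherical cup
        params = syn.PhantomParams(block_half_extents=(40.0, 40.0, 30.0))
        case = syn.make_phantom(params)
        _, vol = syn.voxel_oracle(case.native_mesh, pitch=0.5)
        expected = 80 * 80 * 60 - (2.0 / 3.0) * np.pi * 25.0**3
        assert vol == pytest.approx(expected, rel=0.01)

    def test_deterministic_rebuild(self, default_params):
        a = syn.make_phantom(default_params, seed=3).native_mesh
        b = syn.make_phantom(default_params, seed=3).native_mesh
        assert np.array_equal(a.vertices, b.vertices)
        assert np.array_equal(a.faces, b.faces)

    def test_cup_not_contained_rejected(self):
        with pytest.raises(InvalidParameterError):
            syn.PhantomParams(block_half_extents=(30.0, 30.0, 30.0),
                              cup_radius=29.5)

    def test_truth_frame_matches_params(self, phantom, default_params):
        fr = phantom.truth_frame
        assert np.allclose(fr.hjc, default_params.cup_centre)
        assert fr.radius == default_params.cup_radius
        assert np.allclose(fr.polar_axis, default_params.polar_axis)

    def test_posed_phantom_membership_consistent(self):
        p = np.array([0.1, 0.0, 1.0]) / np.sqrt(1.01)
        s = np.array([0.0, 1.0, 0.0])  # already orthogonal to the tilted polar
        params = syn.PhantomParams(cup_centre=(5.0, -3.0, 10.0),
                                   polar_axis=tuple(p), superior_axis=tuple(s))
        case = syn.make_phantom(params)
        # the hip joint centre lies in the joint space (outside bone)
        assert not case.native_inside(np.array([params.cup_centre]))[0]
        # a point one radius medially along -p is bone
        probe = np.asarray(params.cup_centre) - 1.5 * params.cup_radius * p
        assert case.native_inside(probe[None])[0]


class TestCarve:
    def test_empty_spec_is_identity(self, phantom):
        carved = syn.carve_defect(phantom, syn.DefectSpec(), pitch=2.0)
        assert carved.truth_defect_volume_cm3 == 0.0
        assert np.array_equal(carved.pathological_mesh.vertices,
                              phantom.native_mesh.vertices)

    def test_interior_sphere_volume(self, phantom):
        # 10 mm sphere placed deep in the bone, clear of the cup cavity
        spec = syn.DefectSpec([syn.DefectPrimitive.sphere((0, 0, -45.0), 10.0)])
        carved = syn.carve_defect(phantom, spec, pitch=0.5)
        expected = 4.0 / 3.0 * np.pi * 10.0**3 / 1000.0
        assert carved.truth_defect_volume_cm3 == pytest.approx(expected, rel=0.01)
        assert carved.pathological_mesh.is_watertight

    def test_union_less_than_sum(self, phantom):
        s1 = syn.DefectPrimitive.sphere((0, 0, -45.0), 10.0)
        s2 = syn.DefectPrimitive.sphere((8.0, 0, -45.0), 10.0)
        v1 = syn.carve_defect(phantom, syn.DefectSpec([s1]), pitch=1.0) \
            .truth_defect_volume_cm3
        v_union = syn.carve_defect(phantom, syn.DefectSpec([s1, s2]), pitch=1.0) \
            .truth_defect_volume_cm3
        assert v1 < v_union < 2 * v1 + 1e-9

    def test_carving_monotone_in_primitives(self, phantom):
        base = [syn.DefectPrimitive.sphere((0, 0, -45.0), 8.0)]
        more = base + [syn.DefectPrimitive.sphere((0, 15.0, -40.0), 9.0)]
        v_base = syn.carve_defect(phantom, syn.DefectSpec(base), pitch=1.0) \
            .truth_defect_volume_cm3
        v_more = syn.carve_defect(phantom, syn.DefectSpec(more), pitch=1.0) \
            .truth_defect_volume_cm3
        assert v_more >= v_base

    def test_non_overlapping_primitive_dropped_with_warning(self, phantom):
        far = syn.DefectPrimitive.sphere((0, 0, 55.0), 3.0)  # in the air
        with pytest.warns(UserWarning, match="dropped"):
            carved = syn.carve_defect(phantom, syn.DefectSpec([far]), pitch=2.0)
        assert carved.truth_defect_volume_cm3 == 0.0

    def test_primitive_outside_excision_ball_rejected(self, phantom):
        far = syn.DefectPrimitive.sphere((0, 0, -200.0), 5.0)
        with pytest.raises(InvalidParameterError):
            syn.carve_defect(phantom, syn.DefectSpec([far]), pitch=2.0)

    def test_pathological_inside_native(self, medium_case):
        grid = medium_case.truth_defect_mask
        pts = grid.centers()[:: 97]
        patho = medium_case.patho_inside(pts)
        native = medium_case.native_inside(pts)
        assert not np.any(patho & ~native)
        # truth defect = native AND NOT patho, exactly
        truth = medium_case.defect_inside(pts)
        assert np.array_equal(truth, native & ~patho)


class TestPopulation:
    def test_zero_members(self):
        meshes, params = syn.sample_population(0)
        assert meshes == [] and params == []

    def test_57_members_share_topology(self, population):
        meshes, _ = population
        assert len(meshes) == 57
        v0, f0 = len(meshes[0].vertices), meshes[0].faces
        assert all(len(m.vertices) == v0 for m in meshes)
        assert all(np.array_equal(m.faces, f0) for m in meshes)

    def test_radius_marginal_mean(self):
        _, params = syn.sample_population(200, seed=11)
        radii = [p.cup_radius for p in params]
        assert np.mean(radii) == pytest.approx(25.0, abs=0.5)


class TestVoxelOracle:
    def test_unit_sphere_volume(self, unit_sphere_mesh):
        _, vol = syn.voxel_oracle(unit_sphere_mesh, pitch=0.02)
        assert vol == pytest.approx(4.0 / 3.0 * np.pi, rel=0.01)

    def test_concentric_difference(self):
        outer = trimesh.creation.icosphere(4, radius=2.0)
        inner = trimesh.creation.icosphere(4, radius=1.0)
        _, vol = syn.voxel_oracle(outer, inner, op="difference", pitch=0.04)
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 7.0, rel=0.01)

    def test_disjoint_intersection_zero(self):
        a = trimesh.creation.box(extents=[2, 2, 2])
        b = trimesh.creation.box(extents=[2, 2, 2])
        b.apply_translation([10, 0, 0])
        _, vol = syn.voxel_oracle(a, b, op="intersection", pitch=0.25)
        assert vol == 0.0

    def test_non_watertight_rejected(self):
        box = trimesh.creation.box(extents=[5, 5, 5])
        bad = trimesh.Trimesh(vertices=box.vertices, faces=box.faces[:-2],
                              process=False)
        with pytest.raises(NonWatertightMeshError, match="mesh_a"):
            syn.voxel_oracle(bad, pitch=0.5)
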