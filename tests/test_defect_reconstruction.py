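"""Clustering, alpha-shape surfacing, Boolean refinement, ray generation."""

import numpy as np
import pytest
import trimesh

from acetrec.acetabular_frame import AcetabularFrame
from acetrec.defect_reconstruction import (cluster_points, generate_rays,
                                           reconstruct_surface, refine_booleans)
from acetrec.errors import DegenerateGeometryError, InvalidParameterError
from acetrec.synthetic_anatomy import voxel_oracle


@pytest.fixture(scope="module")
def frame():
    return AcetabularFrame(hjc=(0, 0, 0), radius=25.0,
                           polar_axis=(0, 0, 1), superior_axis=(0, 1, 0))


class TestGenerateRays:
    def test_spacing_one_degree_count(self, frame):
        rays = generate_rays(frame, 1.0)
        assert 35_000 <= len(rays.directions) <= 48_000
        assert rays.max_range == pytest.approx(62.5)
        assert np.allclose(np.linalg.norm(rays.directions, axis=1), 1, atol=1e-12)

    def test_doubling_spacing_quarters_count(self, frame):
        n1 = len(generate_rays(frame, 1.0).directions)
        n2 = len(generate_rays(frame, 2.0).directions)
        assert n2 == pytest.approx(n1 / 4, rel=0.01)

    def test_spacing_bounds(self, frame):
        with pytest.raises(InvalidParameterError):
            generate_rays(frame, 0.05)
        with pytest.raises(InvalidParameterError):
            generate_rays(frame, 15.0)


class TestClustering:
    def test_single_blob_kept(self, rng):
        pts = rng.uniform(0, 10.0, (1000, 3))  # ~1 point/mm^3, well connected
        clusters = cluster_points(pts, linkage_radius=2.0, min_size=200)
        assert len(clusters) == 1 and len(clusters[0]) == 1000

    def test_small_blob_discarded(self, rng):
        pts = rng.normal(0, 2.0, (199, 3))
        with pytest.warns(UserWarning, match="below 200"):
            clusters = cluster_points(pts, linkage_radius=3.0, min_size=200)
        assert clusters == []

    def test_two_separated_blobs(self, rng):
        a = rng.normal(0, 2.0, (300, 3))
        b = rng.normal(0, 2.0, (400, 3)) + [50.0, 0, 0]
        clusters = cluster_points(np.vstack([a, b]), linkage_radius=5.0,
                                  min_size=200)
        assert sorted(len(c) for c in clusters) == [300, 400]
        # brute-force check: clusters never straddle the 50 mm gap
        for c in clusters:
            xs = np.vstack([a, b])[c][:, 0]
            assert xs.max() - xs.min() < 40


class TestAlphaShape:
    def test_dense_sphere_volume(self, rng):
        v = rng.normal(size=(4000, 3))
        v /= np.linalg.norm(v, axis=1)[:, None]
        radii = 10.0 * np.cbrt(rng.uniform(0, 1, 4000))
        pts = v * radii[:, None]
        mesh = reconstruct_surface(pts, alpha=3.0)
        vol = mesh.metadata["tet_volume"]
        assert vol == pytest.approx(4.0 / 3.0 * np.pi * 1000.0, rel=0.10)

    def test_alpha_infinity_is_convex_hull(self, rng):
        pts = rng.uniform(-10, 10, (500, 3))
        mesh = reconstruct_surface(pts, alpha=None)
        hull = trimesh.convex.convex_hull(pts)
        assert mesh.metadata["tet_volume"] == pytest.approx(hull.volume, rel=1e-6)

    def test_planar_cluster_rejected(self, rng):
        pts = np.column_stack([rng.uniform(0, 10, 300), rng.uniform(0, 10, 300),
                               np.zeros(300)])
        with pytest.raises(DegenerateGeometryError):
            reconstruct_surface(pts, alpha=2.0)


class TestRefineBooleans:
    def test_disjoint_defect_unchanged(self):
        defect = trimesh.creation.icosphere(4, radius=8.0)
        patho = trimesh.creation.box(extents=[10, 10, 10])
        patho.apply_translation([40, 0, 0])
        native = trimesh.creation.box(extents=[60, 60, 60])
        dm = refine_booleans(defect, patho, native, pitch=0.4,
                             min_component_cm3=0.0)
        _, oracle_vol = voxel_oracle(defect, pitch=0.4)
        assert dm.volume_cm3 * 1000 == pytest.approx(oracle_vol, rel=0.005 + 0.02)
        assert dm.mesh.is_watertight

    def test_intersection_shrinks(self):
        defect = trimesh.creation.icosphere(4, radius=10.0)
        native = trimesh.creation.box(extents=[20, 20, 10])  # clips the sphere
        patho = trimesh.creation.box(extents=[1, 1, 1])
        patho.apply_translation([50, 0, 0])
        dm = refine_booleans(defect, patho, native, pitch=0.5)
        assert dm.volume_cm3 < defect.volume / 1000.0

    def test_empty_defect_passthrough(self):
        dm = refine_booleans(trimesh.Trimesh(), trimesh.creation.box(),
                             trimesh.creation.box(), pitch=0.5)
        assert dm.is_empty and dm.volume_cm3 == 0.0

class TestEndToEnd:
    def test_defect_contained_in_native_disjoint_from_patho(
            self, medium_reconstruction, medium_case):
        """Voxel check of the set-algebra contract, one-voxel band allowed."""
        dm = medium_reconstruction.defect
        grid = voxel_oracle(dm.mesh, pitch=1.0)[0]
        pts = grid.centers()[grid.mask.ravel()]
        in_native = medium_case.native_inside(pts)
        in_patho = medium_case.patho_inside(pts)
        # violations are confined to a one-voxel boundary band
        assert (~in_native).mean() < 0.08
        assert in_patho.mean() < 0.08

    def test_defect_volume_below_excision_ball(self, medium_reconstruction):
        frame = medium_reconstruction.frame
        bound = 4.0 / 3.0 * np.pi * frame.excision_radius**3 / 1000.0
        assert 0 < medium_reconstruction.defect.volume_cm3 < bound

    def test_no_defect_input_yields_no_defect(self, ssm_model, population):
        """A defect-free training member reconstructs to (near) nothing."""
        import warnings

        from acetrec.defect_reconstruction import reconstruct_defect

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = reconstruct_defect(population[0][7], ssm_model,
                                     angular_spacing=2.0)
        assert res.defect.volume_cm3 < 1.0

    def test_finer_spacing_does_not_worsen_recovery(self, ssm_model,
                                                    medium_case,
                                                    medium_reconstruction):
        """Refining 2 deg -> 1 deg keeps the volume error within a small
        margin of the coarse run (convergence toward the oracle truth)."""
        import warnings

        from acetrec.defect_reconstruction import reconstruct_defect

        truth = medium_case.truth_defect_volume_cm3
        err_coarse = abs(medium_reconstruction.defect.volume_cm3 - truth)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fine = reconstruct_defect(medium_case.pathological_mesh, ssm_model,
                                      angular_spacing=1.0)
        err_fine = abs(fine.defect.volume_cm3 - truth)
        assert err_fine <= err_coarse + 0.02 * truth

    def test_deterministic_given_fixed_inputs(self, ssm_model, medium_case):
        import warnings

        from acetrec.defect_reconstruction import reconstruct_defect

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            a = reconstruct_defect(medium_case.pathological_mesh, ssm_model,
                                   angular_spacing=3.0)
            b = reconstruct_defect(medium_case.pathological_mesh, ssm_model,
                                   angular_spacing=3.0)
        assert a.defect.volume_cm3 == b.defect.volume_cm3
        assert np.array_equal(a.defect.mesh.vertices, b.defect.mesh.vertices)


class TestBooleanOracle:
    @pytest.mark.parametrize("case_idx", range(3))
    def test_boolean_volumes_match_voxel_oracle(self, case_idx, rng):
        # randomized sphere triples: |(A - B) ∩ C| via pipeline vs oracle
        rng = np.random.default_rng(100 + case_idx)
        a = trimesh.creation.icosphere(4, radius=rng.uniform(8, 12))
        b = trimesh.creation.icosphere(4, radius=rng.uniform(5, 9))
        b.apply_translation(rng.uniform(-6, 6, 3))
        c = trimesh.creation.icosphere(4, radius=rng.uniform(10, 14))
        c.apply_translation(rng.uniform(-3, 3, 3))
        dm = refine_booleans(a, b, c, pitch=0.4, min_component_cm3=0.0)
        ga, _ = voxel_oracle(a, pitch=0.5)
        gb = voxel_oracle(a, b, op="difference", pitch=0.5)[0]
        from acetrec import voxel
        mask_c = voxel.rasterize(c, gb.origin, gb.pitch, gb.mask.shape, axis=2)
        oracle_vol = float((gb.mask & mask_c).sum()) * 0.5**3
        shell = a.area * 0.5 / 1000.0  # one-voxel-shell bound, cm3
        assert abs(dm.volume_cm3 - oracle_vol / 1000.0) \
            <= 0.03 * max(oracle_vol / 1000.0, 1e-9) + shell
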