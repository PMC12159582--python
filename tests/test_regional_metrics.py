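"""Acetabular regions and ADV/RDV/DD computation."""

import numpy as np
import pytest
import trimesh

from acetrec.acetabular_frame import AcetabularFrame
from acetrec.regional_metrics import (REGION_NAMES, Region, compute_dd,
                                      compute_rdv, define_regions,
                                      region_membership, regional_volume)


@pytest.fixture(scope="module")
def frame():
    return AcetabularFrame(hjc=(0, 0, 0), radius=25.0,
                           polar_axis=(0, 0, 1), superior_axis=(0, 1, 0))


class TestRegions:
    def test_extents_from_radius(self, frame):
        # superior to 2.2r = 55, antero/posterior to 1.9r = 47.5,
        # medial cylinder radius 0.86r = 21.5
        assert region_membership("superior", frame, np.array([[0, 54.9, 0]]))[0]
        assert not region_membership("superior", frame, np.array([[0, 55.1, 0]]))[0]
        assert region_membership("anterior", frame, np.array([[47.4, 0, 0]]))[0]
        assert not region_membership("anterior", frame, np.array([[47.6, 0, 0]]))[0]
        assert region_membership("medial_wall", frame, np.array([[21.4, 0, -10]]))[0]
        assert not region_membership("medial_wall", frame, np.array([[21.6, 0, -10]]))[0]

    def test_region_meshes_watertight(self, frame):
        for region in define_regions(frame):
            mesh = region.mesh(pitch=2.0)
            assert mesh.is_watertight
            assert mesh.volume > 0

    def test_anterior_posterior_mirror(self, frame):
        pt = np.array([[30.0, 5.0, 2.0]])
        assert region_membership("anterior", frame, pt)[0]
        assert region_membership("posterior", frame, -pt * [1, 1, -1])[0]
        flipped = AcetabularFrame(hjc=frame.hjc, radius=frame.radius,
                                  polar_axis=frame.polar_axis,
                                  superior_axis=frame.superior_axis,
                                  anterior_axis=-frame.anterior_axis)
        assert region_membership("posterior", flipped, pt)[0]

    def test_dominant_axis_rule(self, frame):
        # superior component must dominate |anterior| for the superior sector
        assert region_membership("superior", frame, np.array([[10.0, 20.0, 5.0]]))[0]
        assert not region_membership("superior", frame, np.array([[20.0, 10.0, 5.0]]))[0]


class TestRegionalVolume:
    def test_solid_inside_region(self, frame):
        ball = trimesh.creation.icosphere(4, radius=5.0)
        ball.apply_translation([0, 30.0, 0])  # well inside superior sector
        region = define_regions(frame)["superior"]
        vol = regional_volume(ball, region, pitch=0.4)
        assert vol == pytest.approx(ball.volume / 1000.0, rel=0.02)

    def test_disjoint_zero(self, frame):
        ball = trimesh.creation.icosphere(3, radius=5.0)
        ball.apply_translation([0, -40.0, 30.0])  # inferior, outside all
        region = define_regions(frame)["superior"]
        assert regional_volume(ball, region, pitch=0.5) == 0.0

    def test_half_sphere_on_boundary(self, frame):
        # 10 mm sphere centred on the superior/anterior boundary plane of the
        # anterior sector: the plane ds = da through the HJC bisects it
        c = np.array([40.0, 0.0, 0.0])
        ball = trimesh.creation.icosphere(4, radius=5.0)
        ball.apply_translation(c)
        # rotate so the boundary plane cuts through the centre: place on plane
        # da = ds -> point (a, a, 0) direction
        ball2 = trimesh.creation.icosphere(5, radius=5.0)
        ball2.apply_translation([30.0 / np.sqrt(2), 30.0 / np.sqrt(2), 0.0])
        region = define_regions(frame)["anterior"]
        vol = regional_volume(ball2, region, pitch=0.15)
        assert vol == pytest.approx(0.5 * ball2.volume / 1000.0, rel=0.02)


class TestRDV:
    def test_full_loss_is_100(self):
        assert compute_rdv(10.0, 10.0) == pytest.approx(100.0)

    def test_no_defect_zero(self):
        assert compute_rdv(0.0, 10.0) == 0.0

    def test_zero_native_undefined(self):
        with pytest.warns(UserWarning):
            assert compute_rdv(1.0, 0.0) is None


class TestDD:
    def test_identical_solids_zero_depth(self, frame):
        dirs = np.array([[0, 0, -1.0], [0, 1.0, 0]])
        out = compute_dd(dirs, frame.hjc, first_native_hit=[25.0, 25.0],
                         defect_t_end=[25.0, 25.0],
                         interval_midpoints_t=[[], []], frame=frame)
        assert all(v == (0.0, 0) for v in out.values())

    def test_depth_definition_and_region_assignment(self, frame):
        # one defect ray along -polar: native entry 25, defect ends at 40
        dirs = np.array([[0, 0, -1.0]])
        out = compute_dd(dirs, frame.hjc, first_native_hit=[25.0],
                         defect_t_end=[40.0],
                         interval_midpoints_t=[[32.5]], frame=frame)
        depth, n = out["medial_wall"]
        assert n == 1 and depth == pytest.approx(15.0)
        assert out["superior"] == (0.0, 0)

    def test_depth_floored_at_zero(self, frame):
        dirs = np.array([[0, 0, -1.0]])
        out = compute_dd(dirs, frame.hjc, first_native_hit=[30.0],
                         defect_t_end=[28.0], interval_midpoints_t=[[29.0]],
                         frame=frame)
        assert out["total"] == (0.0, 0)


class TestScaling:
    def test_metric_scaling_laws(self, frame):
        """Scaling the whole scene by 2: RDV invariant, ADV x8, DD x2."""
        from acetrec.acetabular_frame import AcetabularFrame
        from acetrec.regional_metrics import compute_regional_metrics

        native = trimesh.creation.icosphere(3, radius=20.0)
        defect = trimesh.creation.icosphere(3, radius=8.0)
        defect.apply_translation([0, 12.0, 0])  # superior bite
        ray = {"directions": np.array([[0.0, 1.0, 0.0]]),
               "origin": frame.hjc, "first_native_hit": np.array([12.0]),
               "defect_t_end": np.array([20.0]),
               "interval_midpoints_t": [np.array([16.0])]}
        m1 = compute_regional_metrics(defect, native, frame, ray_data=ray,
                                      pitch=0.8)
        native2, defect2 = native.copy(), defect.copy()
        native2.apply_scale(2.0)
        defect2.apply_scale(2.0)
        frame2 = AcetabularFrame(hjc=frame.hjc, radius=2 * frame.radius,
                                 polar_axis=frame.polar_axis,
                                 superior_axis=frame.superior_axis)
        ray2 = {"directions": ray["directions"], "origin": frame2.hjc,
                "first_native_hit": 2 * ray["first_native_hit"],
                "defect_t_end": 2 * ray["defect_t_end"],
                "interval_midpoints_t": [2 * ray["interval_midpoints_t"][0]]}
        m2 = compute_regional_metrics(defect2, native2, frame2, ray_data=ray2,
                                      pitch=1.6)
        r1, r2 = m1.table.loc["superior"], m2.table.loc["superior"]
        assert r2["adv_cm3"] == pytest.approx(8 * r1["adv_cm3"], rel=0.03)
        assert r2["rdv_pct"] == pytest.approx(r1["rdv_pct"], rel=0.03)
        assert r2["dd_mm"] == pytest.approx(2 * r1["dd_mm"], rel=1e-9)


class TestDDMonotonicity:
    def test_deeper_carve_increases_depth(self):
        """Doubling the medial carve depth strictly increases regional DD."""
        import acetrec.synthetic_anatomy as syn

        params = syn.PhantomParams()
        phantom = syn.make_phantom(params)
        p = np.asarray(params.polar_axis)
        c = np.asarray(params.cup_centre, float)
        r = params.cup_radius
        shallow = syn.DefectSpec([syn.DefectPrimitive.sphere(c - 1.1 * r * p,
                                                             0.5 * r)])
        deep = syn.DefectSpec([syn.DefectPrimitive.sphere(c - 1.4 * r * p,
                                                          0.8 * r)])
        dd = []
        for spec in (shallow, deep):
            case = syn.carve_defect(phantom, spec, pitch=1.5)
            regional = syn.compute_truth_regional(case, dd_spacing_deg=4.0,
                                                  dd_step=0.5)
            dd.append(regional["medial_wall"]["dd_mm"])
        assert dd[1] > dd[0]
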