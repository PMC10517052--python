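import numpy as np
import pytest
import trimesh

from pahemo.errors import DomainError, MeshIntegrityError
from pahemo.geometry import (
    Centerline,
    bifurcation_angle,
    compute_centerline,
    measure_segment,
)
from pahemo.mesh import SurfaceMesh



@pytest.fixture(scope="module")
def cylinder_centerline(cylinder_r5_l80):
    return compute_centerline(
        cylinder_r5_l80, [0, 0, -40], [[0, 0, 40]], ["AXIS"]
    )[0]


class TestComputeCenterline:
    def test_straight_cylinder_recovers_axis_and_radius(self, cylinder_centerline):
        cl = cylinder_centerline
        off_axis = np.linalg.norm(cl.points[:, :2], axis=1)
        assert off_axis.max() < 0.1  # well inside 2 % of R = 5
        assert np.all(np.abs(cl.radii - 5.0) < 0.02 * 5.0)

    def test_ninety_degree_bend_arc_length(self):
        tor = trimesh.creation.torus(
            major_radius=30, minor_radius=5, major_sections=256, minor_sections=64
        )
        sm = SurfaceMesh.from_trimesh(tor)
        cl = compute_centerline(sm, [30, 0, 0], [[0, 30, 0]], ["ARC"], pitch=0.8)[0]
        assert cl.length == pytest.approx(np.pi / 2 * 30, rel=0.02)
        assert np.all(np.abs(cl.radii - 5.0) < 0.02 * 5.0)

    def test_synthetic_pa_branches_track_construction_axes(self, synthetic_pa):
        mesh = synthetic_pa.mesh
        truth = {c.branch: c for c in synthetic_pa.centerlines}
        source = truth["MPA"].points[0]
        targets = [truth["LPA"].points[-1], truth["RPA"].points[-1]]
        lines = compute_centerline(mesh, source, targets, ["LPA", "RPA"])
        for cl in lines:
            t = truth[cl.branch]
            a, b = t.points[0], t.points[-1]
            u = (b - a) / np.linalg.norm(b - a)
            # RMS distance of the branch part of the path to its axis
            sel = cl.points[cl.points @ [0, 0, 1] > a[2] + 5]
            rel = sel - a
            perp = rel - np.outer(rel @ u, u)
            rms = np.sqrt((np.linalg.norm(perp, axis=1) ** 2).mean())
            assert rms < 1.0

    def test_open_mesh_rejected(self):
        sm = SurfaceMesh(
            np.array([[0.0, 0, 0], [1, 0, 0], [0, 1, 0]]), np.array([[0, 1, 2]])
        )
        with pytest.raises(MeshIntegrityError):
            compute_centerline(sm, [0, 0, 0], [[1, 0, 0]])


class TestMeasureSegment:
    def test_full_cylinder(self, cylinder_r5_l80, cylinder_centerline):
        seg = measure_segment(
            cylinder_centerline,
            (0.0, cylinder_centerline.length),
            cylinder_r5_l80,
            label="MPA",
        )
        assert seg.length_mm == pytest.approx(80.0, rel=0.01)
        assert seg.diameter_mm == pytest.approx(10.0, rel=0.01)
        assert seg.area_cm2 == pytest.approx(2 * np.pi * 5 * 80 / 100, rel=0.005)

    def test_tapering_tube_mean_of_end_diameters(self):
        # linear taper 5 -> 3 mm: arithmetic mean of inscribed diameters = 8 mm
        z = np.linspace(0.0, 60.0, 121)
        radii = np.interp(z, [0, 60], [5.0, 3.0])
        cl = Centerline(np.column_stack([np.zeros_like(z), np.zeros_like(z), z]), radii)
        seg = measure_segment(cl, (0.0, cl.length))
        assert seg.diameter_mm == pytest.approx(8.0, rel=1e-6)

    def test_empty_interval_rejected(self, cylinder_centerline):
        with pytest.raises(DomainError):
            measure_segment(cylinder_centerline, (10.0, 10.0))

    def test_rigid_invariance(self, cylinder_r5_l80, cylinder_centerline):
        from scipy.spatial.transform import Rotation

        rot = Rotation.from_euler("xyz", [20, -35, 50], degrees=True).as_matrix()
        t = np.array([12.0, -4.0, 7.0])
        mesh2 = cylinder_r5_l80.transformed(rot, t)
        cl2 = Centerline(
            cylinder_centerline.points @ rot.T + t,
            cylinder_centerline.radii,
            cylinder_centerline.branch,
        )
        s0 = measure_segment(cylinder_centerline, (5.0, 70.0), cylinder_r5_l80, "MPA")
        s1 = measure_segment(cl2, (5.0, 70.0), mesh2, "MPA")
        assert s1.length_mm == pytest.approx(s0.length_mm, rel=1e-9)
        assert s1.diameter_mm == pytest.approx(s0.diameter_mm, rel=1e-9)
        assert s1.area_cm2 == pytest.approx(s0.area_cm2, rel=1e-9)


class TestBifurcationAngle:
    @staticmethod
    def straight_line(direction, origin=(0.0, 0.0, 0.0), length=30.0, radius=4.0):
        d = np.asarray(direction, dtype=float)
        d = d / np.linalg.norm(d)
        s = np.linspace(0, length, 31)
        pts = np.asarray(origin) + np.outer(s, d)
        return Centerline(pts, np.full(len(s), radius))

    def test_orthogonal_axes(self):
        left = self.straight_line([1, 0, 0])
        right = self.straight_line([0, 1, 0])
        m = bifurcation_angle(left, right, [0, 0, 0])
        assert m.angle_deg == pytest.approx(90.0, abs=1e-9)

    def test_hundred_degrees(self):
        a = np.radians(100.0)
        left = self.straight_line([1, 0, 0])
        right = self.straight_line([np.cos(a), np.sin(a), 0])
        m = bifurcation_angle(left, right, [0, 0, 0])
        assert m.angle_deg == pytest.approx(100.0, abs=0.1)

    def test_antiparallel_rejected(self):
        left = self.straight_line([1, 0, 0])
        right = self.straight_line([-1, 0, 0])
        with pytest.raises(DomainError):
            bifurcation_angle(left, right, [0, 0, 0])

    def test_symmetric_in_arguments(self, synthetic_pa):
        truth = {c.branch: c for c in synthetic_pa.centerlines}
        j = truth["MPA"].points[-1]
        a = bifurcation_angle(truth["LPA"], truth["RPA"], j)
        b = bifurcation_angle(truth["RPA"], truth["LPA"], j)
        assert a.angle_deg == pytest.approx(b.angle_deg, abs=1e-12)
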