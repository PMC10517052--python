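import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from pahemo.errors import DegeneracyError, DomainError, PlacementError
from pahemo.geometry import Centerline
from pahemo.implantation import (
    NonOptimalReason,
    PlacementClass,
    RigidTransform,
    classify_placement,
    contact_and_exposed_area,
    make_sensor_body,
    place_device,
    register_rigid,
)


@pytest.fixture(scope="module")
def device_cloud(sensor_body):
    rng = np.random.default_rng(0)
    idx = rng.choice(len(sensor_body.mesh.vertices), 200, replace=False)
    return sensor_body.mesh.vertices[idx]


class TestRegisterRigid:
    def test_identical_clouds_identity(self, device_cloud):
        tf, rms, trace = register_rigid(device_cloud, device_cloud)
        assert rms == pytest.approx(0.0, abs=1e-12)
        assert np.allclose(tf.rotation, np.eye(3), atol=1e-9)
        assert np.allclose(tf.translation, 0.0, atol=1e-9)

    def test_recovers_constructed_transform(self, device_cloud):
        rot = Rotation.from_euler("z", 25, degrees=True).as_matrix()
        gt = RigidTransform(rot, [3.0, -2.0, 5.0])
        tf, rms, _ = register_rigid(device_cloud, gt.apply(device_cloud))
        residual = tf.compose(gt.inverse())
        assert np.abs(residual.rotation - np.eye(3)).max() < 1e-6
        assert np.abs(residual.translation).max() < 1e-6
        assert rms < 1e-9

    def test_noisy_target_rms_bounded(self, device_cloud):
        rng = np.random.default_rng(42)
        rot = Rotation.from_euler("y", 10, degrees=True).as_matrix()
        gt = RigidTransform(rot, [1.0, 0.5, -2.0])
        noisy = gt.apply(device_cloud) + rng.normal(0, 0.1, device_cloud.shape)
        pre_rms = float(
            np.sqrt(np.mean(np.sum((device_cloud - noisy) ** 2, axis=1)))
        )
        _, rms, _ = register_rigid(device_cloud, noisy)
        assert rms <= pre_rms
        assert rms <= 0.2

    def test_rms_trace_monotone_non_increasing(self, device_cloud):
        rot = Rotation.from_euler("x", 30, degrees=True).as_matrix()
        gt = RigidTransform(rot, [5.0, 1.0, 0.0])
        _, _, trace = register_rigid(device_cloud, gt.apply(device_cloud))
        assert all(b <= a + 1e-12 for a, b in zip(trace, trace[1:]))

    def test_collinear_source_rejected(self):
        pts = np.outer(np.linspace(0, 1, 10), [1.0, 2.0, 3.0])
        with pytest.raises(DegeneracyError):
            register_rigid(pts, pts + 1.0)

    def test_improper_rotation_rejected(self):
        with pytest.raises(DomainError):
            RigidTransform(np.diag([1.0, 1.0, -1.0]), np.zeros(3))


class TestPlaceDevice:
    def test_interior_device_volume_conserved(self, cylinder_r12_l60, sensor_body):
        fused = place_device(
            cylinder_r12_l60, sensor_body, RigidTransform.identity(), pitch=0.4
        )
        expected = cylinder_r12_l60.tm.volume - sensor_body.mesh.tm.volume
        assert fused.fluid_volume_mm3 == pytest.approx(expected, rel=0.01)
        assert fused.fluid_volume_mm3 <= cylinder_r12_l60.tm.volume
        fused.mesh.audit()

    def test_device_outside_lumen_rejected(self, cylinder_r12_l60, sensor_body):
        far = RigidTransform(np.eye(3), [100.0, 0.0, 0.0])
        with pytest.raises(PlacementError):
            place_device(cylinder_r12_l60, sensor_body, far)

    def test_wall_apposed_device_area_split(self, cylinder_r12_l60, sensor_body):
        rot = Rotation.from_euler("y", -90, degrees=True).as_matrix()
        pose = RigidTransform(rot, [11.0, 0.0, 0.0])
        fused = place_device(cylinder_r12_l60, sensor_body, pose, snap=True, pitch=0.4)
        contact, exposed = contact_and_exposed_area(fused)
        assert contact > 0
        assert exposed < sensor_body.total_area_cm2

    def test_interior_device_fully_exposed(self, cylinder_r12_l60, sensor_body):
        fused = place_device(
            cylinder_r12_l60, sensor_body, RigidTransform.identity(), pitch=0.4
        )
        contact, exposed = contact_and_exposed_area(fused)
        assert contact == pytest.approx(0.0, abs=1e-9)
        assert exposed == pytest.approx(sensor_body.total_area_cm2, rel=1e-9)

    def test_exposed_plus_contact_is_total(self, cylinder_r12_l60, sensor_body):
        rot = Rotation.from_euler("y", -90, degrees=True).as_matrix()
        pose = RigidTransform(rot, [11.0, 0.0, 0.0])
        fused = place_device(cylinder_r12_l60, sensor_body, pose, pitch=0.4)
        contact, exposed = contact_and_exposed_area(fused)
        assert contact + exposed == pytest.approx(sensor_body.total_area_cm2, rel=1e-9)

    def test_half_embedded_slab_split(self, sensor_body):
        # centre the body on a flat wall: exactly half the surface embedded
        import trimesh

        from pahemo.mesh import SurfaceMesh

        box = SurfaceMesh.from_trimesh(trimesh.creation.box(extents=(30, 30, 30)))
        rot = Rotation.from_euler("y", -90, degrees=True).as_matrix()
        pose = RigidTransform(rot, [15.0, 0.0, 0.0])  # wall plane x = 15
        fused = place_device(box, sensor_body, pose, pitch=0.3)
        _, exposed = contact_and_exposed_area(fused)
        assert exposed == pytest.approx(0.5 * sensor_body.total_area_cm2, rel=0.02)


@pytest.fixture(scope="module")
def tube_centerline():
    z = np.linspace(-30, 30, 61)
    return Centerline(
        np.column_stack([np.zeros_like(z), np.zeros_like(z), z]),
        np.full_like(z, 12.0),
        branch="LPA",
    )


class TestClassifyPlacement:
    def test_flush_device_is_optimal(self, cylinder_r12_l60, sensor_body, tube_centerline):
        rot = Rotation.from_euler("y", -90, degrees=True).as_matrix()
        pose = RigidTransform(rot, [11.0, 0.0, 0.0])
        fused = place_device(cylinder_r12_l60, sensor_body, pose, snap=True, pitch=0.4)
        dp = classify_placement(fused, sensor_body, centerlines=[tube_centerline])
        assert dp.placement_class == PlacementClass.OPTIMAL
        assert dp.reasons == frozenset()
        assert not dp.in_mpa

    def test_skewed_device_flagged(self, cylinder_r12_l60, sensor_body, tube_centerline):
        rot = Rotation.from_euler("y", 60, degrees=True).as_matrix()
        fused = place_device(cylinder_r12_l60, sensor_body, RigidTransform(rot, [0, 0, 0]),
                             pitch=0.4)
        dp = classify_placement(fused, sensor_body, centerlines=[tube_centerline])
        assert dp.placement_class == PlacementClass.NON_OPTIMAL
        assert NonOptimalReason.SKEWED in dp.reasons

    def test_mpa_flag_independent_of_optimality(self, cylinder_r12_l60, sensor_body):
        z = np.linspace(-30, 30, 61)
        mpa_cl = Centerline(
            np.column_stack([np.zeros_like(z), np.zeros_like(z), z]),
            np.full_like(z, 12.0),
            branch="MPA",
        )
        rot = Rotation.from_euler("y", -90, degrees=True).as_matrix()
        pose = RigidTransform(rot, [11.0, 0.0, 0.0])
        fused = place_device(cylinder_r12_l60, sensor_body, pose, snap=True, pitch=0.4)
        dp = classify_placement(fused, sensor_body, centerlines=[mpa_cl])
        assert dp.placement_class == PlacementClass.OPTIMAL
        assert dp.in_mpa

    def test_classification_deterministic(self, cylinder_r12_l60, sensor_body, tube_centerline):
        rot = Rotation.from_euler("y", 60, degrees=True).as_matrix()
        fused = place_device(cylinder_r12_l60, sensor_body, RigidTransform(rot, [0, 0, 0]),
                             pitch=0.4)
        a = classify_placement(fused, sensor_body, centerlines=[tube_centerline])
        b = classify_placement(fused, sensor_body, centerlines=[tube_centerline])
        assert a.placement_class == b.placement_class
        assert a.reasons == b.reasons
        assert a.contact_area_cm2 == b.contact_area_cm2
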