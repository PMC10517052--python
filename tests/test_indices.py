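import numpy as np
import pytest

from pahemo.errors import DomainError, ProbePlacementError
from pahemo.fields import WallFieldSeries
from pahemo.geometry import Centerline
from pahemo.indices import (
    index_map,
    osi,
    pressure_drop,
    rrt,
    surface_average,
    tawss,
    thresholded_area,
)
from pahemo.mesh import Region
from pahemo.synthetic import TubeSpec, fourier_decompose, womersley_wall_series

from _oracles import osi_loop, tawss_loop, weighted_mean_loop
from conftest import make_labelled_cylinder


def series_from_history(history: np.ndarray) -> WallFieldSeries:
    """Wrap per-step WSS vectors of a single face into a tiny tube series."""
    mesh = make_labelled_cylinder(5.0, 10.0, sections=8)
    wss = np.tile(history[None, :, :], (len(mesh.faces), 1, 1))
    return WallFieldSeries(mesh, wss, dt_s=0.01)


class TestTawss:
    def test_constant_vector(self):
        hist = np.tile([1.5, 0.0, 0.0], (8, 1))
        assert tawss(series_from_history(hist))[0] == pytest.approx(1.5)

    def test_alternating_sign_mean_of_magnitudes(self):
        hist = np.array([[2.0, 0, 0], [-2.0, 0, 0]] * 4)
        # mean of magnitudes, not magnitude of the mean
        assert tawss(series_from_history(hist))[0] == pytest.approx(2.0)

    def test_matches_loop_oracle_on_womersley_series(self, case01_waveform, viscosity):
        dec = fourier_decompose(case01_waveform, 10)
        series = womersley_wall_series(
            TubeSpec(10.0, 40.0), dec, viscosity, 32, with_pressure=False
        )
        np.testing.assert_allclose(
            tawss(series), tawss_loop(series.wss), rtol=1e-12, atol=1e-15
        )


class TestOsi:
    def test_constant_direction_is_zero(self):
        hist = np.tile([0.7, 0.7, 0.0], (16, 1))
        assert osi(series_from_history(hist))[0] == pytest.approx(0.0, abs=1e-14)

    def test_zero_mean_harmonic_is_half(self):
        t = np.arange(32) / 32
        hist = np.column_stack(
            [np.sin(2 * np.pi * t), np.zeros_like(t), np.zeros_like(t)]
        )
        assert osi(series_from_history(hist))[0] == pytest.approx(0.5, abs=1e-12)

    def test_three_quarters_one_direction(self):
        hist = np.array([[1.0, 0, 0]] * 12 + [[-1.0, 0, 0]] * 4)
        # |sum| = 8, sum |.| = 16 -> OSI = 0.5 (1 - 0.5) = 0.25
        assert osi(series_from_history(hist))[0] == pytest.approx(0.25)

    def test_all_zero_history_guarded(self):
        hist = np.zeros((8, 3))
        assert osi(series_from_history(hist))[0] == 0.0

    def test_matches_loop_oracle(self, case01_waveform, viscosity):
        rng = np.random.default_rng(5)
        mesh = make_labelled_cylinder(5.0, 10.0, sections=8)
        wss = rng.normal(0, 1.0, (len(mesh.faces), 24, 3))
        series = WallFieldSeries(mesh, wss, 0.01)
        np.testing.assert_allclose(
            osi(series), osi_loop(series.wss), rtol=1e-12, atol=1e-15
        )

    def test_bounds_and_triangle_inequality(self):
        rng = np.random.default_rng(12)
        mesh = make_labelled_cylinder(5.0, 10.0, sections=8)
        wss = rng.normal(0, 2.0, (len(mesh.faces), 40, 3))
        series = WallFieldSeries(mesh, wss, 0.01)
        o = osi(series)
        tw = tawss(series)
        assert ((o >= 0) & (o <= 0.5)).all()
        mean_vec = np.linalg.norm(series.wss.mean(axis=1), axis=1)
        assert (tw >= mean_vec - 1e-12).all()

    def test_invariant_under_cyclic_time_shift(self):
        rng = np.random.default_rng(3)
        mesh = make_labelled_cylinder(5.0, 10.0, sections=8)
        wss = rng.normal(0, 1.0, (len(mesh.faces), 20, 3))
        shifted = np.roll(wss, 7, axis=1)
        a = WallFieldSeries(mesh, wss, 0.01)
        b = WallFieldSeries(mesh, shifted, 0.01)
        np.testing.assert_allclose(osi(a), osi(b), rtol=1e-12)
        np.testing.assert_allclose(tawss(a), tawss(b), rtol=1e-12)


class TestRrt:
    @pytest.mark.parametrize(
        "osi_v,tawss_v,expected",
        [(0.0, 2.0, 0.5), (0.25, 1.0, 2.0)],
    )
    def test_formula(self, osi_v, tawss_v, expected):
        assert rrt(np.array([tawss_v]), np.array([osi_v]))[0] == pytest.approx(expected)

    def test_undefined_reported_as_nan(self):
        out = rrt(np.array([2.0, 0.0]), np.array([0.5, 0.1]))
        assert np.isnan(out).all()


class TestSurfaceAverage:
    def test_uniform_field(self, cylinder_r5_l80):
        vals = np.full(len(cylinder_r5_l80.faces), 3.7)
        assert surface_average(vals, cylinder_r5_l80, "ALL") == pytest.approx(3.7)

    def test_two_equal_area_halves(self, cylinder_r5_l80):
        mask = cylinder_r5_l80.face_centroids[:, 2] > 0
        vals = np.where(mask, 3.0, 1.0)
        lateral = cylinder_r5_l80.region_mask(Region.MPA)
        # lateral faces split symmetrically at z = 0
        avg = surface_average(vals, cylinder_r5_l80, Region.MPA)
        assert avg == pytest.approx(2.0, rel=1e-9)

    def test_matches_weighted_loop_oracle(self, synthetic_pa):
        rng = np.random.default_rng(8)
        vals = rng.uniform(0, 5, len(synthetic_pa.mesh.faces))
        mask = synthetic_pa.mesh.region_mask(Region.LPA)
        expected = weighted_mean_loop(
            vals[mask], synthetic_pa.mesh.face_areas[mask]
        )
        assert surface_average(vals, synthetic_pa.mesh, Region.LPA) == pytest.approx(
            expected, rel=1e-12
        )

    def test_empty_region_rejected(self, cylinder_r5_l80):
        with pytest.raises(DomainError):
            surface_average(
                np.zeros(len(cylinder_r5_l80.faces)), cylinder_r5_l80, Region.DEVICE
            )


class TestThresholdedArea:
    def test_uniform_below(self, cylinder_r5_l80):
        vals = np.full(len(cylinder_r5_l80.faces), 0.3)
        area = thresholded_area(vals, cylinder_r5_l80, "ALL", 0.5, "below")
        from pahemo.mesh import surface_area

        assert area == pytest.approx(surface_area(cylinder_r5_l80, "ALL"))

    def test_exact_threshold_excluded(self, cylinder_r5_l80):
        vals = np.full(len(cylinder_r5_l80.faces), 0.5)
        assert thresholded_area(vals, cylinder_r5_l80, "ALL", 0.5, "below") == 0.0

    def test_below_plus_above_plus_equal_partition(self, cylinder_r5_l80):
        rng = np.random.default_rng(4)
        vals = rng.uniform(0, 1, len(cylinder_r5_l80.faces))
        from pahemo.mesh import surface_area

        below = thresholded_area(vals, cylinder_r5_l80, "ALL", 0.5, "below")
        above = thresholded_area(vals, cylinder_r5_l80, "ALL", 0.5, "above")
        total = surface_area(cylinder_r5_l80, "ALL")
        # continuous field: ties have measure zero
        assert below + above == pytest.approx(total, rel=1e-12)

    def test_matches_brute_force_scan(self, synthetic_pa):
        rng = np.random.default_rng(10)
        vals = rng.uniform(0, 1, len(synthetic_pa.mesh.faces))
        mask = synthetic_pa.mesh.region_mask(Region.RPA)
        brute = sum(
            a
            for v, a, m in zip(vals, synthetic_pa.mesh.face_areas, mask)
            if m and v < 0.5
        ) / 100.0
        got = thresholded_area(vals, synthetic_pa.mesh, Region.RPA, 0.5, "below")
        assert got == pytest.approx(brute, rel=1e-12)


class TestPressureDrop:
    @staticmethod
    def steady_poiseuille_series(q_mls=100.0, radius=10.0, length=60.0, mu=0.0035):
        from pahemo.synthetic import HarmonicDecomposition, womersley_wall_series

        tube = TubeSpec(radius, length)
        dec = HarmonicDecomposition(2 * np.pi / 0.6, [q_mls + 0j])
        from pahemo.boundary import ViscosityModel

        model = ViscosityModel(mu_inf_pas=mu)
        return womersley_wall_series(tube, dec, model, 8)

    @staticmethod
    def axis_centerline(length=60.0, radius=10.0):
        z = np.linspace(0, length, int(length) + 1)
        return Centerline(
            np.column_stack([np.zeros_like(z), np.zeros_like(z), z]),
            np.full_like(z, radius),
        )

    def test_steady_poiseuille_closed_form(self):
        series = self.steady_poiseuille_series()
        cl = self.axis_centerline()
        # probes 10 mm either side of mid-tube: stations 20 mm apart
        drop = pressure_drop(series, cl, (30.0, 30.0), offset_mm=10.0)
        expected_pa = 8 * 0.0035 * 0.02 * 100e-6 / (np.pi * 0.01**4)
        assert drop.dp_mmhg == pytest.approx(expected_pa / 133.322, rel=0.02)

    def test_zero_flow_zero_drop(self):
        series = self.steady_poiseuille_series(q_mls=0.0)
        cl = self.axis_centerline()
        assert pressure_drop(series, cl, (25.0, 35.0)).dp_mmhg == pytest.approx(0.0)

    def test_negative_drop_is_legal(self):
        # static pressure rising downstream (cross-section recovery):
        # the signed drop must come out negative, not clipped
        base = self.steady_poiseuille_series()
        series = WallFieldSeries(base.mesh, base.wss, base.dt_s, -base.pressure)
        drop = pressure_drop(series, self.axis_centerline(), (25.0, 35.0))
        assert drop.dp_mmhg < 0

    def test_probe_outside_domain_rejected(self):
        series = self.steady_poiseuille_series()
        cl = self.axis_centerline()
        with pytest.raises(ProbePlacementError):
            pressure_drop(series, cl, (2.0, 58.0), offset_mm=10.0)

    def test_missing_pressure_rejected(self):
        series = self.steady_poiseuille_series()
        series = WallFieldSeries(series.mesh, series.wss, series.dt_s, None)
        with pytest.raises(DomainError):
            pressure_drop(series, self.axis_centerline(), (25.0, 35.0))


class TestIndexMapRigidInvariance:
    def test_indices_invariant_under_rigid_motion(self, case01_waveform, viscosity):
        from scipy.spatial.transform import Rotation

        dec = fourier_decompose(case01_waveform, 8)
        series = womersley_wall_series(
            TubeSpec(8.0, 30.0), dec, viscosity, 24, with_pressure=False
        )
        rot = Rotation.from_euler("xz", [30, -60], degrees=True).as_matrix()
        mesh2 = series.mesh.transformed(rot, [5.0, -2.0, 9.0])
        wss2 = series.wss @ rot.T
        series2 = WallFieldSeries(mesh2, wss2, series.dt_s)
        np.testing.assert_allclose(tawss(series), tawss(series2), rtol=1e-12)
        np.testing.assert_allclose(osi(series), osi(series2), rtol=1e-10, atol=1e-12)
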