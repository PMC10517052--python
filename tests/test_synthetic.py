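import numpy as np
import pytest

from pahemo.boundary import FlowWaveform
from pahemo.errors import DomainError
from pahemo.geometry import compute_centerline, measure_segment, bifurcation_angle
from pahemo.implantation import RigidTransform
from pahemo.indices import osi, tawss
from pahemo.mesh import Region
from pahemo.synthetic import (
    CohortGenSpec,
    HarmonicDecomposition,
    MetricSpec,
    TubeSpec,
    fourier_decompose,
    generate_cohort_metrics,
    generate_synthetic_pa,
    make_tube_mesh,
    perturb_wake,
    womersley_velocity,
    womersley_wall_series,
    womersley_wall_shear,
)

from _oracles import fd_wall_shear


class TestFourierDecompose:
    def test_constant_flow_is_harmonic_zero(self):
        wf = FlowWaveform(0.6, 0.001, np.full(600, 80.0))
        dec = fourier_decompose(wf, 8)
        assert dec.amplitudes_mls[0] == pytest.approx(80.0)
        assert np.abs(dec.amplitudes_mls[1:]).max() < 1e-10

    def test_pure_sinusoid_amplitude(self):
        t = 0.001 * np.arange(600)
        wf = FlowWaveform(0.6, 0.001, 80 + 40 * np.sin(2 * np.pi * t / 0.6))
        dec = fourier_decompose(wf, 8)
        assert abs(dec.amplitudes_mls[1]) == pytest.approx(40.0, abs=1e-9)

    def test_waveform_round_trip_rms(self, case01_waveform):
        dec = fourier_decompose(case01_waveform, 12)
        assert dec.reconstruction_rms_mls < 0.01 * case01_waveform.q_mls.max()

    def test_nyquist_guard(self, case01_waveform):
        with pytest.raises(DomainError):
            fourier_decompose(case01_waveform, case01_waveform.n_samples)


class TestWomersley:
    def test_steady_flow_matches_poiseuille(self, viscosity):
        dec = HarmonicDecomposition(2 * np.pi / 0.6, [100.0 + 0j])
        tau = womersley_wall_shear(dec, 10.0, viscosity, 16)
        expected = 4 * viscosity.mu_inf_pas * 100e-6 / (np.pi * 0.01**3)
        assert np.allclose(tau, expected, rtol=1e-12)

    def test_quasi_steady_limit_tracks_poiseuille(self, viscosity):
        # heart rate scaled down 100x: alpha << 1, tau(t) ~ 4 mu Q(t)/(pi R^3)
        period = 60.0
        t = np.linspace(0, period, 256, endpoint=False)
        q = 100 + 30 * np.sin(2 * np.pi * t / period)
        wf = FlowWaveform(period, period / 256, q)
        dec = fourier_decompose(wf, 4)
        tau = womersley_wall_shear(dec, 5.0, viscosity, 256)
        quasi = 4 * viscosity.mu_inf_pas * (q * 1e-6) / (np.pi * 0.005**3)
        assert np.abs(tau - quasi).max() < 0.01 * np.abs(quasi).max()

    def test_matches_finite_difference_oracle(self, case01_waveform, viscosity):
        dec = fourier_decompose(case01_waveform, 12)
        tau = womersley_wall_shear(dec, 10.7, viscosity, 200)
        oracle = fd_wall_shear(dec, 10.7, viscosity, 200)
        rel_rms = np.sqrt(np.mean((tau - oracle) ** 2)) / np.sqrt(np.mean(oracle**2))
        assert rel_rms < 0.02

    def test_flow_consistency_of_velocity_profile(self, case01_waveform, viscosity):
        dec = fourier_decompose(case01_waveform, 12)
        r = np.linspace(0, 10.0, 600)
        u = womersley_velocity(dec, 10.0, viscosity, r, 64)
        r_m = r / 1000.0
        q_int = np.trapezoid(2 * np.pi * r_m[:, None] * u, r_m, axis=0) * 1e6
        t = (dec.period_s / 64) * np.arange(64)
        q_ref = dec.evaluate(t)
        assert np.abs(q_int - q_ref).max() < 0.005 * np.abs(q_ref).max()

    def test_series_on_tube_mesh(self, case01_waveform, viscosity):
        tube = TubeSpec(10.0, 80.0)
        dec = fourier_decompose(case01_waveform, 12)
        series = womersley_wall_series(tube, dec, viscosity, 64)
        lateral = series.mesh.region_mask(Region.MPA)
        tau = womersley_wall_shear(dec, 10.0, viscosity, 64)
        # uniform around the circumference, axial direction
        assert np.allclose(series.wss[lateral, :, 2], tau[None, :], rtol=1e-12)
        assert np.allclose(series.wss[lateral, :, :2], 0.0)


class TestPerturbWake:
    @pytest.fixture()
    def tube_series(self, case01_waveform, viscosity):
        tube = TubeSpec(10.0, 120.0)
        dec = fourier_decompose(case01_waveform, 10)
        return womersley_wall_series(tube, dec, viscosity, 48, with_pressure=False)

    @pytest.fixture()
    def wall_pose(self):
        return RigidTransform(np.eye(3), [9.0, 0.0, 30.0])

    def test_zero_amplitude_is_identity(self, tube_series, wall_pose):
        out = perturb_wake(tube_series, wall_pose, amplitude_pa=0.0, seed=3)
        assert np.array_equal(out.wss, tube_series.wss)

    def test_mean_wss_conserved_and_osi_increases(self, tube_series, wall_pose):
        out = perturb_wake(tube_series, wall_pose, amplitude_pa=0.8, seed=3)
        changed = np.any(out.wss != tube_series.wss, axis=(1, 2))
        assert changed.any()
        # temporal mean conserved on every face to 1e-12
        assert np.abs(
            out.wss.mean(axis=1) - tube_series.wss.mean(axis=1)
        ).max() < 1e-12
        osi_before = osi(tube_series)
        osi_after = osi(out)
        assert (osi_after[changed] > osi_before[changed]).all()
        assert np.allclose(osi_after[~changed], osi_before[~changed])
        # TAWSS outside the wake unchanged
        assert np.allclose(tawss(out)[~changed], tawss(tube_series)[~changed])

    def test_same_seed_reproducible(self, tube_series, wall_pose):
        a = perturb_wake(tube_series, wall_pose, amplitude_pa=0.8, seed=11)
        b = perturb_wake(tube_series, wall_pose, amplitude_pa=0.8, seed=11)
        assert np.array_equal(a.wss, b.wss)

    def test_nonpositive_wake_length_rejected(self, tube_series, wall_pose):
        with pytest.raises(DomainError):
            perturb_wake(tube_series, wall_pose, wake_length_mm=0.0)


class TestGenerateSyntheticPA:
    def test_requested_trunk_diameter_recovered(self):
        pa = generate_synthetic_pa(trunk_diameter_mm=23.8, n_side_branches=0, seed=1)
        source = pa.centerlines[0].points[0]
        target = pa.centerlines[0].points[-1] - [0, 0, 8.0]
        cl = compute_centerline(pa.mesh, source, [target], ["MPA"])[0]
        seg = measure_segment(cl, (5.0, cl.length - 8.0), pa.mesh, "MPA")
        assert seg.diameter_mm == pytest.approx(23.8, rel=0.02)

    def test_requested_angle_recovered(self):
        pa = generate_synthetic_pa(branch_angle_deg=80.0, n_side_branches=0, seed=1)
        truth = {c.branch: c for c in pa.centerlines}
        source = truth["MPA"].points[0]
        lines = compute_centerline(
            pa.mesh,
            source,
            [truth["LPA"].points[-1], truth["RPA"].points[-1]],
            ["LPA", "RPA"],
        )
        j = truth["MPA"].points[-1]
        m = bifurcation_angle(lines[0], lines[1], j, fit_length=25.0)
        assert m.angle_deg == pytest.approx(80.0, abs=2.0)

    def test_no_side_branches_gives_two_outlets(self):
        pa = generate_synthetic_pa(n_side_branches=0, seed=5)
        outlet_faces = pa.mesh.region_mask(Region.CAP_OUTLET)
        sub = pa.mesh.tm.submesh([np.flatnonzero(outlet_faces)], append=True)
        import trimesh

        comps = trimesh.graph.connected_components(sub.face_adjacency, min_len=1,
                                                   nodes=np.arange(len(sub.faces)))
        assert len(comps) == 2
        assert len(pa.ostia) == 0

    def test_watertight_and_fully_labelled(self, synthetic_pa):
        synthetic_pa.mesh.audit()
        assert all(l is not None for l in synthetic_pa.mesh.labels)

    def test_bit_reproducible_under_seed(self):
        a = generate_synthetic_pa(seed=9)
        b = generate_synthetic_pa(seed=9)
        assert np.array_equal(a.mesh.vertices, b.mesh.vertices)
        assert np.array_equal(a.mesh.faces, b.mesh.faces)


class TestGenerateCohortMetrics:
    def test_zero_sd_all_identical(self):
        spec = CohortGenSpec(
            n_animals=6,
            metrics={"tawss": MetricSpec(2.35, 0.0, shift_mean=0.1)},
            seed=1,
        )
        df = generate_cohort_metrics(spec)
        assert df["tawss_pre"].nunique() == 1
        assert np.allclose(df["tawss_post"] - df["tawss_pre"], 0.1)

    def test_seeded_reproducibility(self):
        spec = CohortGenSpec(
            n_animals=10,
            metrics={"tawss": MetricSpec(2.35, 0.47, 0.10, 0.06)},
            seed=77,
        )
        a = generate_cohort_metrics(spec)
        b = generate_cohort_metrics(spec)
        assert a.equals(b)

    def test_infeasible_truncation_rejected(self):
        with pytest.raises(DomainError):
            CohortGenSpec(
                n_animals=5, metrics={"bad": MetricSpec(-10.0, 1.0)}, seed=0
            )

    def test_null_shift_rarely_significant(self):
        # type-I behaviour on a small seed grid (the full calibration runs
        # in the acceptance suite)
        from scipy import stats as sps

        hits = 0
        n_rep = 200
        for s in range(n_rep):
            spec = CohortGenSpec(
                n_animals=10,
                metrics={"m": MetricSpec(2.35, 0.47, 0.0, 0.06)},
                seed=s,
            )
            df = generate_cohort_metrics(spec)
            p = sps.ttest_rel(df["m_post"], df["m_pre"]).pvalue
            hits += p < 0.05
        assert 0.01 <= hits / n_rep <= 0.10
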