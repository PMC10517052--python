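"""End-to-end per-case pipeline and cohort orchestration.

Stage order mirrors the study workflow: geometry → virtual implantation →
boundary conditions → synthetic flow → wall-shear indices → statistics.
The flow stage maps the analytic pulsatile-tube wall-shear solution onto
the branches of the (synthetic) pulmonary-artery surface, with the cycle
flow split between the left and right branch by cross-sectional area, so
every downstream index is computed from a physically consistent field.

All randomness derives from one config seed, expanded deterministically
per stage; identical configs produce byte-identical report JSON.
"""

from __future__ import annotations

import json
import time
import zlib
from dataclasses import asdict, dataclass, field as dc_field
from pathlib import Path

import numpy as np

from . import __version__
from .boundary import ViscosityModel, synthesize_waveform
from .errors import ConfigurationError
from .fields import WallFieldSeries
from .geometry import bifurcation_angle, measure_segment
from .implantation import (
    RigidTransform,
    classify_placement,
    make_sensor_body,
    place_device,
)
from .indices import area_metrics, index_map, pressure_drop, surface_average
from .mesh import Region, surface_area
from .synthetic import (
    TubeSpec,
    fourier_decompose,
    generate_synthetic_pa,
    perturb_wake,
    womersley_pressure_gradient,
    womersley_wall_shear,
)


def stage_seed(seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2^31."""
    return (int(seed) ^ zlib.crc32(stage.encode())) % (2**31 - 1)


@dataclass
class CaseConfig:
    """Everything one pipeline run needs; all entropy is explicit."""

    case_id: str = "case01"
    # animal profile
    hr_bpm: float = 99.0
    co_lpm: float = 4.7
    qmax_mls: float = 245.0
    weight_kg: float = 62.0
    # geometry (synthetic generator)
    trunk_diameter_mm: float = 23.8
    branch_diameters_mm: tuple = (13.6, 14.9)
    branch_angle_deg: float = 80.0
    trunk_length_mm: float = 60.0
    branch_length_mm: float = 70.0
    n_side_branches: int = 2
    mesh_pitch_mm: float = 0.9
    # device
    device_enabled: bool = True
    device_host: str = "LPA"
    device_position_fraction: float = 0.4
    device_tilt_deg: float = 0.0
    device_length_mm: float = 15.0
    device_width_mm: float = 3.4
    device_height_mm: float = 2.0
    boolean_pitch_mm: float = 0.6
    gap_threshold_mm: float = 1.0
    # flow
    n_steps: int = 80
    n_harmonics: int = 12
    wake_amplitude_pa: float = 1.0
    turbulence_intensity: float = 0.05
    # rheology
    viscosity: ViscosityModel = dc_field(default_factory=ViscosityModel)
    # probes
    probe_offset_mm: float = 10.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.device_host not in ("LPA", "RPA", "MPA"):
            raise ConfigurationError("device_host must be LPA, RPA or MPA")
        if not (0.0 < self.device_position_fraction < 1.0):
            raise ConfigurationError("device_position_fraction must lie in (0, 1)")

    def to_json(self) -> dict:
        d = asdict(self)
        d["branch_diameters_mm"] = list(self.branch_diameters_mm)
        return d

    @classmethod
    def from_json(cls, obj: dict) -> "CaseConfig":
        obj = dict(obj)
        if "viscosity" in obj and isinstance(obj["viscosity"], dict):
            obj["viscosity"] = ViscosityModel.from_json(obj["viscosity"])
        if "branch_diameters_mm" in obj:
            obj["branch_diameters_mm"] = tuple(obj["branch_diameters_mm"])
        known = set(cls.__dataclass_fields__)
        unknown = set(obj) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**obj)


@dataclass
class RunLog:
    """Timestamped per-stage records (kept outside the numeric report)."""

    case_id: str
    version: str = __version__
    records: list = dc_field(default_factory=list)

    def record(self, stage: str, **info) -> None:
        self.records.append({"stage": stage, "wall_time_s": time.time(), **info})

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {"case_id": self.case_id, "version": self.version, "records": self.records},
                fh,
                indent=2,
            )


def _device_pose_on_branch(pa, config: CaseConfig) -> RigidTransform:
    """Pose aligning the device long axis with the host centerline, contact
    face toward the outer wall, centre offset so the body touches the wall."""
    cl = next(c for c in pa.centerlines if c.branch == config.device_host)
    s = config.device_position_fraction * cl.length
    centre, radius = cl.at(s)
    centre = centre[0]
    radius = float(radius[0])
    tang = cl.points[-1] - cl.points[0]
    tang = tang / np.linalg.norm(tang)
    # outward direction: perpendicular to the tangent, in the bifurcation
    # plane for main branches (pointing away from the trunk axis)
    ref = np.array([0.0, 1.0, 0.0])
    outward = np.cross(tang, ref)
    outward /= np.linalg.norm(outward)
    if config.device_host == "LPA" and outward[0] < 0:
        outward = -outward
    if config.device_host == "RPA" and outward[0] > 0:
        outward = -outward
    # local frame: long axis x -> tangent; contact normal -z -> outward
    x = tang
    z = -outward
    y = np.cross(z, x)
    y /= np.linalg.norm(y)
    z = np.cross(x, y)
    rot = np.column_stack([x, y, z])
    if config.device_tilt_deg != 0.0:
        a = np.radians(config.device_tilt_deg)
        tilt = np.array(
            [[np.cos(a), 0, np.sin(a)], [0, 1, 0], [-np.sin(a), 0, np.cos(a)]]
        )
        rot = rot @ tilt
    offset = radius - config.device_height_mm / 2.0
    translation = centre + outward * max(offset, 0.0)
    return RigidTransform(rot, translation)


def _branch_axes(pa) -> dict:
    axes = {}
    for cl in pa.centerlines:
        t = cl.points[-1] - cl.points[0]
        axes[cl.branch] = t / np.linalg.norm(t)
    return axes


def _map_flow_to_mesh(mesh, pa, waveform, config: CaseConfig,
                      device_span=None) -> WallFieldSeries:
    """Per-branch analytic wall-shear and pressure mapped onto mesh faces."""
    model = config.viscosity
    dec = fourier_decompose(waveform, config.n_harmonics)
    n = config.n_steps

    r_trunk = config.trunk_diameter_mm / 2.0
    r_l, r_r = (d / 2.0 for d in config.branch_diameters_mm)
    a_l, a_r = r_l**2, r_r**2
    split_l = a_l / (a_l + a_r)

    def harmonics_scaled(fraction):
        from .synthetic import HarmonicDecomposition

        return HarmonicDecomposition(dec.omega_rad_s, dec.amplitudes_mls * fraction)

    tau = {
        "MPA": womersley_wall_shear(dec, r_trunk, model, n),
        "LPA": womersley_wall_shear(harmonics_scaled(split_l), r_l, model, n),
        "RPA": womersley_wall_shear(harmonics_scaled(1 - split_l), r_r, model, n),
    }
    dpdz = {
        "MPA": womersley_pressure_gradient(dec, r_trunk, model, n),
        "LPA": womersley_pressure_gradient(harmonics_scaled(split_l), r_l, model, n),
        "RPA": womersley_pressure_gradient(harmonics_scaled(1 - split_l), r_r, model, n),
    }
    axes = _branch_axes(pa)
    cl_by_branch = {c.branch: c for c in pa.centerlines}
    junction_z = config.trunk_length_mm

    cent = mesh.face_centroids
    wss = np.zeros((len(mesh.faces), n, 3))
    pres = np.zeros((len(mesh.faces), n))
    p_junction = dpdz["MPA"] * (junction_z / 1000.0)

    host_tau = tau.get(config.device_host, tau["MPA"])
    for fi, lab in enumerate(mesh.labels):
        name = lab.value if hasattr(lab, "value") else str(lab)
        if name in ("CAP_INLET", "CAP_OUTLET"):
            continue
        if name == "DEVICE":
            # the protruding body locally accelerates near-wall flow
            ax = axes.get(config.device_host, axes["MPA"])
            wss[fi] = np.outer(1.3 * host_tau, ax)
            s_axial = cent[fi] @ axes["MPA"]
            pres[fi] = p_junction * min(s_axial / junction_z, 1.0)
            continue
        if name == "BRANCH":
            # side branches carry little flow: weak, host-scaled shear
            host = "LPA" if cent[fi][0] >= 0 else "RPA"
            wss[fi] = np.outer(0.1 * tau[host], axes[host])
            pres[fi] = p_junction
            continue
        ax = axes[name]
        wss[fi] = np.outer(tau[name], ax)
        if name == "MPA":
            z = cent[fi][2]
            pres[fi] = dpdz["MPA"] * (np.clip(z, 0, junction_z) / 1000.0)
        else:
            cl = cl_by_branch[name]
            s_along = (cent[fi] - cl.points[0]) @ ax
            pres[fi] = p_junction + dpdz[name] * (max(s_along, 0.0) / 1000.0)
    dt = waveform.period_s / n
    return WallFieldSeries(mesh, wss, dt, pres)


def run_pipeline(config: CaseConfig, out_dir=None) -> dict:
    """Run geometry → implantation → flow → indices for one case.

    Returns the per-case report dict; when ``out_dir`` is given, writes
    ``<case>_report.json`` (deterministic bytes) and ``<case>_runlog.json``.
    """
    log = RunLog(config.case_id)
    report: dict = {"case_id": config.case_id, "config": config.to_json()}

    # --- geometry
    pa = generate_synthetic_pa(
        trunk_diameter_mm=config.trunk_diameter_mm,
        branch_diameters_mm=config.branch_diameters_mm,
        branch_angle_deg=config.branch_angle_deg,
        trunk_length_mm=config.trunk_length_mm,
        branch_length_mm=config.branch_length_mm,
        n_side_branches=config.n_side_branches,
        pitch=config.mesh_pitch_mm,
        seed=stage_seed(config.seed, "geometry"),
    )
    log.record("geometry", faces=len(pa.mesh.faces))
    cl = {c.branch: c for c in pa.centerlines}
    segments = {}
    for name in ("MPA", "LPA", "RPA"):
        c = cl[name]
        seg = measure_segment(c, (0.0, c.length), pa.mesh, label=name, ostia=[
            o for o in pa.ostia if o.host == name
        ])
        segments[name] = {
            "length_mm": seg.length_mm,
            "diameter_mm": seg.diameter_mm,
            "area_cm2": seg.area_cm2,
            "side_branches": seg.side_branch_count,
        }
    alpha = bifurcation_angle(cl["LPA"], cl["RPA"], cl["MPA"].points[-1])
    report["geometry"] = {
        "segments": segments,
        "bifurcation_angle_deg": alpha.angle_deg,
        "pa_surface_area_cm2": surface_area(pa.mesh, "ALL"),
    }

    # --- boundary conditions
    waveform = synthesize_waveform(
        config.hr_bpm,
        config.co_lpm,
        config.qmax_mls,
        seed=stage_seed(config.seed, "waveform"),
    )
    report["inflow"] = {
        "period_s": waveform.period_s,
        "stroke_volume_ml": waveform.stroke_volume_ml,
        "co_lpm": waveform.co_lpm,
        "qmax_mls": float(waveform.q_mls.max()),
        "turbulence_intensity": config.turbulence_intensity,
        "outlet_pressure": "constant",
    }
    log.record("boundary_conditions")

    # --- pre-implantation flow + indices
    series_pre = _map_flow_to_mesh(pa.mesh, pa, waveform, config)
    imap_pre = index_map(series_pre)
    pre_metrics = area_metrics(imap_pre, "PA")
    report["pre"] = {
        "tawss_pa": surface_average(imap_pre.tawss, pa.mesh, "PA"),
        "osi": surface_average(imap_pre.osi, pa.mesh, "PA"),
        "low_wss_area_cm2": pre_metrics.low_wss_area_cm2,
        "high_osi_area_cm2": pre_metrics.high_osi_area_cm2,
        "pa_area_cm2": pre_metrics.total_area_cm2,
    }
    log.record("flow_pre", steps=config.n_steps)

    # --- implantation + post flow
    if config.device_enabled:
        device = make_sensor_body(
            config.device_length_mm, config.device_width_mm, config.device_height_mm
        )
        pose = _device_pose_on_branch(pa, config)
        fused = place_device(
            pa.mesh, device, pose, snap=True, pitch=config.boolean_pitch_mm
        )
        placement = classify_placement(
            fused,
            device,
            centerlines=pa.centerlines,
            gap_threshold_mm=config.gap_threshold_mm,
            ostia=pa.ostia,
        )
        log.record("implantation", fused_faces=len(fused.mesh.faces))

        host_cl = cl[config.device_host]
        s_mid = config.device_position_fraction * host_cl.length
        span = (s_mid - config.device_length_mm / 2.0, s_mid + config.device_length_mm / 2.0)

        series_post = _map_flow_to_mesh(fused.mesh, pa, waveform, config)
        series_post = perturb_wake(
            series_post,
            fused.pose,
            device_length_mm=config.device_length_mm,
            amplitude_pa=config.wake_amplitude_pa,
            flow_axis=_branch_axes(pa)[config.device_host],
            seed=stage_seed(config.seed, "wake"),
        )
        imap_post = index_map(series_post)
        post_metrics = area_metrics(imap_post, "PA")
        dev_metrics = area_metrics(imap_post, Region.DEVICE)
        dp = pressure_drop(series_post, host_cl, span, offset_mm=config.probe_offset_mm)
        report["device"] = {
            "host": config.device_host,
            "placement_class": placement.placement_class.value,
            "reasons": sorted(r.value for r in placement.reasons),
            "in_mpa": placement.in_mpa,
            "contact_area_cm2": placement.contact_area_cm2,
            "exposed_area_cm2": placement.exposed_area_cm2,
            "tawss_pa": surface_average(imap_post.tawss, fused.mesh, Region.DEVICE),
            "osi": surface_average(imap_post.osi, fused.mesh, Region.DEVICE),
            "low_wss_area_cm2": dev_metrics.low_wss_area_cm2,
            "high_osi_area_cm2": dev_metrics.high_osi_area_cm2,
            "pressure_drop_mmhg": dp.dp_mmhg,
        }
        report["post"] = {
            "tawss_pa": surface_average(imap_post.tawss, fused.mesh, "PA"),
            "osi": surface_average(imap_post.osi, fused.mesh, "PA"),
            "low_wss_area_cm2": post_metrics.low_wss_area_cm2,
            "high_osi_area_cm2": post_metrics.high_osi_area_cm2,
        }
        log.record("flow_post")

    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        write_report(report, out_dir / f"{config.case_id}_report.json")
        log.save(out_dir / f"{config.case_id}_runlog.json")
    return report


def write_report(report: dict, path) -> None:
    """Serialise a report with deterministic bytes."""
    with open(path, "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
        fh.write("\n")


def default_cohort_configs(seed: int = 0, n_cases: int = 10) -> list[CaseConfig]:
    """Ten synthetic cases emulating the cohort's parameter spread."""
    from .fixtures import load_animal_profiles, load_geometry_table

    profiles = load_animal_profiles()
    geo = load_geometry_table()
    configs = []
    for i in range(n_cases):
        p = profiles[i % len(profiles)]
        g = geo.iloc[i % len(geo)]
        configs.append(
            CaseConfig(
                case_id=f"case{i + 1:02d}",
                hr_bpm=p.hr_bpm,
                co_lpm=p.co_lpm,
                qmax_mls=p.qmax_mls,
                weight_kg=p.weight_kg,
                trunk_diameter_mm=float(g.mpa_d_mm),
                branch_diameters_mm=(float(g.lpa_d_mm), float(g.rpa_d_mm)),
                branch_angle_deg=float(g.alpha_deg),
                device_host="LPA" if i % 2 == 0 else "RPA",
                device_tilt_deg=15.0 if i % 3 == 0 else 0.0,
                seed=stage_seed(seed, f"case{i}"),
            )
        )
    return configs


def run_cohort(configs, out_dir=None) -> dict:
    """Run every case and aggregate a cohort summary."""
    from .stats import paired_compare

    reports = [run_pipeline(c, out_dir=out_dir) for c in configs]
    pre = np.array([r["pre"]["tawss_pa"] for r in reports])
    summary: dict = {
        "n_cases": len(reports),
        "pre_tawss_mean_pa": float(pre.mean()),
        "pre_tawss_sd_pa": float(pre.std(ddof=1)) if len(pre) > 1 else 0.0,
    }
    with_dev = [r for r in reports if "post" in r]
    if len(with_dev) >= 3:
        pre_d = np.array([r["pre"]["tawss_pa"] for r in with_dev])
        post_d = np.array([r["post"]["tawss_pa"] for r in with_dev])
        cmp_res = paired_compare(pre_d, post_d, method="t")
        summary["post_tawss_mean_pa"] = float(post_d.mean())
        summary["tawss_paired_p"] = cmp_res.p_value
        summary["tawss_effect_size"] = cmp_res.effect_size
        summary["device_tawss_mean_pa"] = float(
            np.mean([r["device"]["tawss_pa"] for r in with_dev])
        )
        summary["pressure_drop_mean_mmhg"] = float(
            np.mean([r["device"]["pressure_drop_mmhg"] for r in with_dev])
        )
    out = {"cases": reports, "summary": summary}
    if out_dir is not None:
        write_report(out["summary"], Path(out_dir) / "cohort_summary.json")
    return out
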