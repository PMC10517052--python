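"""Synthetic flow and geometry generation.

This module stands in for a transient 3-D flow solver so every
post-processing and statistics stage is testable against exact oracles:

* harmonic (Fourier) decomposition of periodic inflow waveforms,
* the exact laminar pulsatile-tube (Womersley) wall-shear and pressure-
  gradient solution per harmonic, Newtonian at the high-shear viscosity,
* a device-wake perturbation adding a zero-temporal-mean oscillatory
  tangential WSS component downstream of an implanted sensor,
* a parametric bifurcating pulmonary-artery surface with ground-truth
  centerlines and branch ostia,
* a seeded cohort-metric generator emulating paired pre/post tables.

The synthetic flow is laminar, Newtonian and straight-tube analytic by
construction; it deliberately does not reproduce turbulent 3-D fields —
its contract is physical plausibility plus exactness against closed forms.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd
from scipy import special, stats

from .boundary import FlowWaveform, ViscosityModel
from .errors import DomainError, GeometryError, NumericError
from .fields import WallFieldSeries
from .geometry import Centerline
from .implantation import DevicePose, RigidTransform
from .mesh import Region, SurfaceMesh
from .spatial import analytic_sdf_grid, extract_surface

# ---------------------------------------------------------------------------
# harmonic decomposition


@dataclass
class HarmonicDecomposition:
    """Complex flow-rate harmonics: Q(t) = Re Σ_k c_k · exp(i k ω t).

    ``c[0]`` is the (real) mean flow in mL/s; ``omega`` is the fundamental
    angular frequency in rad/s.
    """

    omega_rad_s: float
    amplitudes_mls: np.ndarray
    reconstruction_rms_mls: float = 0.0

    def __post_init__(self) -> None:
        self.amplitudes_mls = np.asarray(self.amplitudes_mls, dtype=complex).ravel()
        if self.omega_rad_s <= 0:
            raise DomainError("omega must be positive")

    @property
    def n_harmonics(self) -> int:
        return len(self.amplitudes_mls) - 1

    @property
    def period_s(self) -> float:
        return 2.0 * np.pi / self.omega_rad_s

    def evaluate(self, t_s: np.ndarray) -> np.ndarray:
        t = np.asarray(t_s, dtype=float)
        k = np.arange(len(self.amplitudes_mls))
        phases = np.exp(1j * self.omega_rad_s * np.outer(t, k))
        return (phases * self.amplitudes_mls).real.sum(axis=1)


def fourier_decompose(waveform: FlowWaveform, n_harmonics: int = 12) -> HarmonicDecomposition:
    """Decompose a periodic equidistant waveform into K flow harmonics."""
    q = waveform.q_mls
    n = len(q)
    if n_harmonics < 0 or n_harmonics > n // 2:
        raise DomainError(
            f"harmonic count {n_harmonics} exceeds the Nyquist limit {n // 2}"
        )
    spec = np.fft.rfft(q) / n
    c = np.zeros(n_harmonics + 1, dtype=complex)
    c[0] = spec[0].real
    upper = min(n_harmonics, len(spec) - 1)
    c[1 : upper + 1] = 2.0 * spec[1 : upper + 1]
    omega = 2.0 * np.pi / waveform.period_s
    dec = HarmonicDecomposition(omega, c)
    recon = dec.evaluate(waveform.t_s)
    dec.reconstruction_rms_mls = float(np.sqrt(np.mean((recon - q) ** 2)))
    return dec


# ---------------------------------------------------------------------------
# Womersley tube flow


@dataclass
class TubeSpec:
    """Straight rigid circular tube (mm) for the analytic flow stand-in."""

    radius_mm: float
    length_mm: float
    axis: np.ndarray = dc_field(default_factory=lambda: np.array([0.0, 0.0, 1.0]))

    def __post_init__(self) -> None:
        if self.radius_mm <= 0 or self.length_mm <= 0:
            raise DomainError("tube radius and length must be positive")
        self.axis = np.asarray(self.axis, dtype=float)
        n = np.linalg.norm(self.axis)
        if n < 1e-12:
            raise DomainError("tube axis must be a nonzero vector")
        self.axis = self.axis / n

    def womersley_number(self, omega_rad_s: float, model: ViscosityModel) -> float:
        """α = R·sqrt(ω ρ / μ∞), dimensionless."""
        nu = model.mu_inf_pas / model.density_kg_m3
        return float(self.radius_mm / 1000.0 * np.sqrt(omega_rad_s / nu))


def _womersley_coefficients(harmonics: HarmonicDecomposition, radius_mm: float,
                            model: ViscosityModel):
    """Per-harmonic complex wall-shear (Pa) and pressure-gradient (Pa/m)
    amplitudes for prescribed flow-rate harmonics.

    Harmonic 0 is the Poiseuille solution τ = 4 μ Q /(π R³),
    dp/dz = −8 μ Q /(π R⁴); harmonics k ≥ 1 use the exact Bessel-function
    solution with Λ = i^{3/2} α_k.
    """
    mu = model.mu_inf_pas
    rho = model.density_kg_m3
    R = radius_mm / 1000.0
    c = harmonics.amplitudes_mls * 1e-6  # m³/s, complex
    omega = harmonics.omega_rad_s

    tau = np.zeros(len(c), dtype=complex)
    dpdz = np.zeros(len(c), dtype=complex)
    tau[0] = 4.0 * mu * c[0] / (np.pi * R**3)
    dpdz[0] = -8.0 * mu * c[0] / (np.pi * R**4)
    with np.errstate(over="raise", invalid="raise"):
        for k in range(1, len(c)):
            alpha = R * np.sqrt(k * omega * rho / mu)
            Lam = 1j**1.5 * alpha
            try:
                j0 = special.jv(0, Lam)
                j1 = special.jv(1, Lam)
                denom = j0 - 2.0 * j1 / Lam
                tau[k] = -(mu * c[k] / (np.pi * R**3)) * (Lam * j1) / denom
                G = 1j * rho * k * omega * c[k] / (np.pi * R**2 * (1.0 - 2.0 * j1 / (Lam * j0)))
                dpdz[k] = -G
            except FloatingPointError as exc:
                raise NumericError(
                    f"Bessel evaluation failed at harmonic {k} (alpha={alpha:.1f})"
                ) from exc
            if not (np.isfinite(tau[k]) and np.isfinite(dpdz[k])):
                raise NumericError(f"non-finite Womersley coefficient at harmonic {k}")
    return tau, dpdz


def womersley_wall_shear(
    harmonics: HarmonicDecomposition,
    radius_mm: float,
    model: ViscosityModel,
    n_steps: int,
) -> np.ndarray:
    """Exact Womersley wall-shear history τ(t) (Pa) over one period.

    Positive values point in the direction of mean flow (the traction the
    fluid exerts on the wall).
    """
    if n_steps < 2:
        raise DomainError("need at least 2 time steps")
    tau_k, _ = _womersley_coefficients(harmonics, radius_mm, model)
    t = (harmonics.period_s / n_steps) * np.arange(n_steps)
    k = np.arange(len(tau_k))
    phases = np.exp(1j * harmonics.omega_rad_s * np.outer(t, k))
    return (phases * tau_k).real.sum(axis=1)


def womersley_pressure_gradient(
    harmonics: HarmonicDecomposition,
    radius_mm: float,
    model: ViscosityModel,
    n_steps: int,
) -> np.ndarray:
    """Axial pressure-gradient history dp/dz (Pa/m) over one period."""
    _, dpdz_k = _womersley_coefficients(harmonics, radius_mm, model)
    t = (harmonics.period_s / n_steps) * np.arange(n_steps)
    k = np.arange(len(dpdz_k))
    phases = np.exp(1j * harmonics.omega_rad_s * np.outer(t, k))
    return (phases * dpdz_k).real.sum(axis=1)


def womersley_velocity(
    harmonics: HarmonicDecomposition,
    radius_mm: float,
    model: ViscosityModel,
    r_mm: np.ndarray,
    n_steps: int,
) -> np.ndarray:
    """Axial velocity u(r, t) (m/s): rows = radii, columns = time steps."""
    mu = model.mu_inf_pas
    rho = model.density_kg_m3
    R = radius_mm / 1000.0
    r = np.asarray(r_mm, dtype=float).ravel() / 1000.0
    if (r < 0).any() or (r > R + 1e-12).any():
        raise DomainError("radial positions must lie in [0, R]")
    c = harmonics.amplitudes_mls * 1e-6
    omega = harmonics.omega_rad_s
    t = (harmonics.period_s / n_steps) * np.arange(n_steps)

    u = np.zeros((len(r), n_steps))
    # harmonic 0: Poiseuille profile
    u += (2.0 * c[0].real / (np.pi * R**2) * (1.0 - (r / R) ** 2))[:, None]
    for k in range(1, len(c)):
        alpha = R * np.sqrt(k * omega * rho / mu)
        Lam = 1j**1.5 * alpha
        j0R = special.jv(0, Lam)
        prof = 1.0 - special.jv(0, Lam * r / R) / j0R
        # amplitude from flow-rate: u_hat = G/(i rho w k) * prof
        G = 1j * rho * k * omega * c[k] / (
            np.pi * R**2 * (1.0 - 2.0 * special.jv(1, Lam) / (Lam * j0R))
        )
        u_hat = G / (1j * rho * k * omega) * prof
        u += (u_hat[:, None] * np.exp(1j * k * omega * t)[None, :]).real
    return u


def _rotation_from_z(axis: np.ndarray) -> np.ndarray:
    """Rotation matrix taking +z onto ``axis`` (Rodrigues)."""
    z = np.array([0.0, 0.0, 1.0])
    v = np.cross(z, axis)
    c = float(np.dot(z, axis))
    if np.linalg.norm(v) < 1e-12:
        return np.eye(3) if c > 0 else np.diag([1.0, -1.0, -1.0])
    vx = np.array([[0, -v[2], v[1]], [v[2], 0, -v[0]], [-v[1], v[0], 0]])
    return np.eye(3) + vx + vx @ vx / (1.0 + c)


def make_tube_mesh(
    tube: TubeSpec,
    sections: int = 64,
    axial_segments: int = 40,
    label: Region = Region.MPA,
) -> SurfaceMesh:
    """Labelled capped-cylinder mesh spanning ``[0, length]`` along the axis.

    Lateral faces carry ``label``; the end disks are CAP_INLET (z = 0) and
    CAP_OUTLET.  Axial segmentation controls the station resolution of
    per-face pressure sampling.
    """
    R = tube.radius_mm
    L = tube.length_mm
    ns, na = int(sections), int(axial_segments)
    theta = 2.0 * np.pi * np.arange(ns) / ns
    ring = np.stack([R * np.cos(theta), R * np.sin(theta)], axis=1)
    verts = []
    for j in range(na + 1):
        z = L * j / na
        verts.append(np.column_stack([ring, np.full(ns, z)]))
    verts = np.concatenate(verts)
    faces = []
    labels = []
    for j in range(na):
        base0 = j * ns
        base1 = (j + 1) * ns
        for i in range(ns):
            i2 = (i + 1) % ns
            faces.append([base0 + i, base0 + i2, base1 + i])
            faces.append([base0 + i2, base1 + i2, base1 + i])
            labels += [label, label]
    c0 = len(verts)
    verts = np.vstack([verts, [[0.0, 0.0, 0.0], [0.0, 0.0, L]]])
    top = na * ns
    for i in range(ns):
        i2 = (i + 1) % ns
        faces.append([c0, i2, i])  # inlet cap, normal -z
        labels.append(Region.CAP_INLET)
        faces.append([c0 + 1, top + i, top + i2])  # outlet cap, normal +z
        labels.append(Region.CAP_OUTLET)
    rot = _rotation_from_z(tube.axis)
    verts = verts @ rot.T
    return SurfaceMesh(verts, np.asarray(faces), np.asarray(labels, dtype=object))


def womersley_wall_series(
    tube: TubeSpec,
    harmonics: HarmonicDecomposition,
    model: ViscosityModel,
    n_steps: int,
    mesh: SurfaceMesh | None = None,
    with_pressure: bool = True,
    inlet_pressure_pa: float = 0.0,
) -> WallFieldSeries:
    """Analytic WSS (and pressure) series on a tube surface.

    Every lateral face receives the axial WSS vector ``axis · τ(t)`` —
    uniform around the circumference, exact per harmonic.  The optional
    pressure field integrates the harmonic pressure gradients along the
    axis from the inlet.
    """
    mesh = mesh if mesh is not None else make_tube_mesh(tube)
    tau = womersley_wall_shear(harmonics, tube.radius_mm, model, n_steps)
    lateral = ~(mesh.region_mask(Region.CAP_INLET) | mesh.region_mask(Region.CAP_OUTLET))
    wss = np.zeros((len(mesh.faces), n_steps, 3))
    wss[lateral] = tube.axis[None, None, :] * tau[None, :, None]
    pressure = None
    if with_pressure:
        dpdz = womersley_pressure_gradient(harmonics, tube.radius_mm, model, n_steps)
        z_m = (mesh.face_centroids @ tube.axis) / 1000.0
        pressure = inlet_pressure_pa + np.outer(z_m - z_m.min(), dpdz)
    dt = harmonics.period_s / n_steps
    return WallFieldSeries(mesh, wss, dt, pressure)


# ---------------------------------------------------------------------------
# device wake perturbation


def perturb_wake(
    series: WallFieldSeries,
    pose: DevicePose | RigidTransform,
    device_length_mm: float = 15.0,
    wake_length_mm: float | None = None,
    amplitude_pa: float = 1.0,
    angular_width_deg: float = 120.0,
    flow_axis=(0.0, 0.0, 1.0),
    oscillation_harmonic: int = 2,
    seed: int = 0,
) -> WallFieldSeries:
    """Add an oscillatory, zero-temporal-mean tangential WSS wake.

    Faces inside a cylinder sector downstream of the device tail receive an
    added circumferential WSS oscillation whose amplitude tapers linearly
    with downstream distance; the temporal mean of the added component is
    exactly zero on every face, so TAWSS direction sums and mean-WSS vectors
    are conserved while OSI inside the wake increases.
    """
    if wake_length_mm is None:
        wake_length_mm = 3.0 * device_length_mm
    if wake_length_mm <= 0:
        raise DomainError("wake length must be positive")
    if amplitude_pa == 0.0:
        return series.copy()

    tf = pose.transform if isinstance(pose, DevicePose) else pose
    axis = np.asarray(flow_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    centre = tf.apply(np.zeros(3))
    tail = centre + 0.5 * device_length_mm * axis

    cent = series.mesh.face_centroids
    rel = cent - tail
    s = rel @ axis
    radial = rel - np.outer(s, axis)
    rn = np.linalg.norm(radial, axis=1)

    # angular sector around the device's circumferential position
    dev_radial = centre - (centre @ axis) * axis
    if np.linalg.norm(dev_radial) < 1e-9:
        in_sector = np.ones(len(cent), dtype=bool)
    else:
        ref = dev_radial / np.linalg.norm(dev_radial)
        with np.errstate(invalid="ignore"):
            cosang = np.where(rn > 1e-9, (radial @ ref) / np.maximum(rn, 1e-12), 1.0)
        in_sector = cosang >= np.cos(np.radians(angular_width_deg / 2.0))

    in_wake = (s > 0) & (s <= wake_length_mm) & in_sector
    out = series.copy()
    if not in_wake.any():
        return out

    n = series.n_steps
    rng = np.random.default_rng(seed)
    idx = np.flatnonzero(in_wake)
    taper = 1.0 - s[idx] / wake_length_mm
    phases = rng.uniform(0.0, 2.0 * np.pi, size=len(idx))
    tangential = np.cross(np.broadcast_to(axis, (len(idx), 3)), radial[idx])
    tn = np.linalg.norm(tangential, axis=1, keepdims=True)
    tangential = np.divide(tangential, tn, out=np.zeros_like(tangential), where=tn > 1e-12)

    t_idx = np.arange(n)
    osc = np.sin(
        2.0 * np.pi * oscillation_harmonic * t_idx[None, :] / n + phases[:, None]
    )
    osc -= osc.mean(axis=1, keepdims=True)  # exact zero temporal mean
    added = (amplitude_pa * taper)[:, None, None] * osc[:, :, None] * tangential[:, None, :]
    out.wss[idx] = out.wss[idx] + added
    return out


# ---------------------------------------------------------------------------
# synthetic pulmonary-artery geometry


@dataclass
class Ostium:
    """Branch take-off opening on a host vessel wall."""

    center: np.ndarray
    normal: np.ndarray
    radius: float
    host: str

    def __post_init__(self) -> None:
        self.center = np.asarray(self.center, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)


def _segment_sdf(a, b, radius):
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    L = np.linalg.norm(ab)
    u = ab / L

    def sdf(p):
        rel = np.atleast_2d(p) - a
        x = rel @ u
        perp = rel - np.outer(x, u)
        dr = np.linalg.norm(perp, axis=1) - radius
        dx = np.maximum(x - L, -x)  # distance beyond either end plane
        outside = np.linalg.norm(
            np.stack([np.maximum(dr, 0.0), np.maximum(dx, 0.0)], axis=1), axis=1
        )
        inside = np.minimum(np.maximum(dr, dx), 0.0)
        return outside + inside

    return sdf


@dataclass
class SyntheticPA:
    """Generated bifurcation geometry with ground truth for oracles."""

    mesh: SurfaceMesh
    centerlines: list
    ostia: list
    segments: dict
    params: dict


def generate_synthetic_pa(
    trunk_diameter_mm: float = 23.8,
    branch_diameters_mm: tuple = (13.6, 14.9),
    branch_angle_deg: float = 80.0,
    trunk_length_mm: float = 60.0,
    branch_length_mm: float = 70.0,
    n_side_branches: int = 2,
    side_branch_diameter_mm: float = 4.0,
    pitch: float = 0.7,
    seed: int = 0,
) -> SyntheticPA:
    """Parametric bifurcating PA: trunk (MPA) splitting into LPA and RPA.

    The trunk runs along +z from the inlet at the origin; the branches leave
    the junction symmetrically in the x-z plane separated by the requested
    bifurcation angle.  Optional small side branches (labelled BRANCH) leave
    the two main branches at seeded positions.  Ground-truth centerlines,
    segment dimensions and ostium loops are returned for use as oracles.
    """
    if min(trunk_diameter_mm, *branch_diameters_mm) <= 0:
        raise DomainError("diameters must be positive")
    if not (0.0 < branch_angle_deg < 180.0):
        raise DomainError("branch angle must lie in (0, 180) degrees")
    rt = trunk_diameter_mm / 2.0
    r_lpa, r_rpa = (d / 2.0 for d in branch_diameters_mm)
    if max(r_lpa, r_rpa) >= trunk_length_mm:
        raise GeometryError("self-intersecting parameter set: branches exceed trunk")

    junction = np.array([0.0, 0.0, trunk_length_mm])
    half = np.radians(branch_angle_deg / 2.0)
    dir_lpa = np.array([np.sin(half), 0.0, np.cos(half)])
    dir_rpa = np.array([-np.sin(half), 0.0, np.cos(half)])

    # overlap the branch roots into the trunk so the union is connected
    root = junction - 0.25 * rt * np.array([0.0, 0.0, 1.0])
    parts = {
        "MPA": (_segment_sdf([0, 0, 0], junction, rt), [0, 0, 0], junction, rt),
        "LPA": (
            _segment_sdf(root, root + branch_length_mm * dir_lpa, r_lpa),
            root,
            root + branch_length_mm * dir_lpa,
            r_lpa,
        ),
        "RPA": (
            _segment_sdf(root, root + branch_length_mm * dir_rpa, r_rpa),
            root,
            root + branch_length_mm * dir_rpa,
            r_rpa,
        ),
    }

    rng = np.random.default_rng(seed)
    ostia: list[Ostium] = []
    rb = side_branch_diameter_mm / 2.0
    for i in range(int(n_side_branches)):
        host = ("LPA", "RPA")[i % 2]
        _, a, b, r_host = parts[host]
        u = (b - a) / np.linalg.norm(b - a)
        frac = rng.uniform(0.6, 0.85)
        along = a + frac * np.linalg.norm(b - a) * u
        # outward direction perpendicular to the host axis, tilted downstream
        perp = np.cross(u, [0.0, 1.0, 0.0])
        perp /= np.linalg.norm(perp)
        sign = 1.0 if rng.random() < 0.5 else -1.0
        out_dir = sign * perp + 0.4 * u
        out_dir /= np.linalg.norm(out_dir)
        start = along
        end = along + (r_host + 10.0) * out_dir
        parts[f"BRANCH_{i}"] = (_segment_sdf(start, end, rb), start, end, rb)
        ostium_center = along + r_host * out_dir
        ostia.append(Ostium(ostium_center, out_dir, rb, host))

    sdfs = [p[0] for p in parts.values()]

    def union_sdf(p):
        return np.min(np.stack([s(p) for s in sdfs], axis=0), axis=0)

    all_pts = np.concatenate([[p[1], p[2]] for p in parts.values()])
    pad = max(rt, r_lpa, r_rpa)
    bounds = (all_pts.min(axis=0) - pad, all_pts.max(axis=0) + pad)
    from .spatial import grid_for_bounds

    origin, shape = grid_for_bounds(bounds, pitch)
    grid = analytic_sdf_grid(union_sdf, origin, pitch, shape)
    verts, faces = extract_surface(grid)
    mesh = SurfaceMesh(verts, faces)

    # labels: nearest part; caps: faces on the flat end disks
    cent = mesh.face_centroids
    part_vals = np.stack([p[0](cent) for p in parts.values()], axis=0)
    nearest = np.abs(part_vals).argmin(axis=0)
    names = list(parts.keys())
    labels = np.empty(len(faces), dtype=object)
    for i, nm in enumerate(names):
        region = Region(nm) if nm in ("MPA", "LPA", "RPA") else Region.BRANCH
        labels[nearest == i] = region
    nrm = mesh.face_normals
    # inlet cap: trunk inlet plane z=0
    inlet = (np.abs(cent[:, 2]) < 1.5 * pitch) & (nrm[:, 2] < -0.8)
    labels[inlet] = Region.CAP_INLET
    for nm, (sdf_p, a, b, r) in parts.items():
        if nm == "MPA":
            continue
        u = (b - a) / np.linalg.norm(b - a)
        d_end = (cent - b) @ u
        rel = cent - b
        d_perp = np.linalg.norm(rel - np.outer(rel @ u, u), axis=1)
        outlet = (np.abs(d_end) < 1.5 * pitch) & (nrm @ u > 0.8) & (d_perp < r + pitch)
        labels[outlet] = Region.CAP_OUTLET

    # stray rim faces can satisfy a cap criterion in isolation: demote cap
    # components much smaller than an end disk back to their vessel label
    import trimesh as _trimesh

    adjacency = mesh.tm.face_adjacency
    for cap in (Region.CAP_INLET, Region.CAP_OUTLET):
        cap_idx = np.flatnonzero([l == cap for l in labels])
        if len(cap_idx) == 0:
            continue
        in_cap = np.zeros(len(faces), dtype=bool)
        in_cap[cap_idx] = True
        pair_ok = in_cap[adjacency].all(axis=1)
        comps = _trimesh.graph.connected_components(
            adjacency[pair_ok], min_len=1, nodes=cap_idx
        )
        for comp in comps:
            if len(comp) < 0.05 * len(cap_idx):
                for fi in comp:
                    labels[fi] = (
                        Region(names[nearest[fi]])
                        if names[nearest[fi]] in ("MPA", "LPA", "RPA")
                        else Region.BRANCH
                    )
    mesh.labels = labels
    mesh.sdf = union_sdf  # type: ignore[attr-defined]

    centerlines = []
    segments = {}
    for nm, (sdf_p, a, b, r) in parts.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        npts = max(int(np.linalg.norm(b - a) / 1.0), 2)
        pts = a + np.linspace(0, 1, npts)[:, None] * (b - a)
        branch_name = nm if nm in ("MPA", "LPA", "RPA") else nm
        centerlines.append(Centerline(pts, np.full(npts, r), branch=branch_name))
        segments[nm] = {"length_mm": float(np.linalg.norm(b - a)), "diameter_mm": 2.0 * r}

    params = {
        "trunk_diameter_mm": trunk_diameter_mm,
        "branch_diameters_mm": tuple(branch_diameters_mm),
        "branch_angle_deg": branch_angle_deg,
        "trunk_length_mm": trunk_length_mm,
        "branch_length_mm": branch_length_mm,
        "n_side_branches": int(n_side_branches),
        "pitch": pitch,
        "seed": int(seed),
    }
    return SyntheticPA(mesh, centerlines, ostia, segments, params)


# ---------------------------------------------------------------------------
# cohort-metric generator


@dataclass
class MetricSpec:
    """Paired pre/post generating law for one cohort metric."""

    mean: float
    sd: float
    shift_mean: float = 0.0
    shift_sd: float = 0.0

    def __post_init__(self) -> None:
        if self.sd < 0 or self.shift_sd < 0:
            raise DomainError("standard deviations must be non-negative")


@dataclass
class CohortGenSpec:
    """Specification of a synthetic paired cohort table."""

    n_animals: int
    metrics: dict
    device_metrics: dict = dc_field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_animals < 2:
            raise DomainError("need at least 2 animals")
        for name, m in {**self.metrics, **self.device_metrics}.items():
            if m.sd > 0 and m.mean / m.sd < -4.0:
                raise DomainError(
                    f"infeasible positive truncation for metric {name!r} "
                    f"(mean {m.mean} far below zero)"
                )


def _truncated_positive_normal(rng, mean, sd, size):
    if sd == 0:
        return np.full(size, float(mean))
    a = (0.0 - mean) / sd
    return stats.truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def generate_cohort_metrics(spec: CohortGenSpec) -> pd.DataFrame:
    """Draw a paired pre/post cohort table.

    Pre values are positive-truncated normal draws; post values add a
    normal paired shift.  Device metrics (one per animal-device, two
    devices per animal) are drawn from their own truncated-normal law.
    Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_animals
    data = {"case": [f"Animal {i + 1:02d}" for i in range(n)]}
    for name, m in spec.metrics.items():
        pre = _truncated_positive_normal(rng, m.mean, m.sd, n)
        post = pre + (
            rng.normal(m.shift_mean, m.shift_sd, size=n)
            if m.shift_sd > 0
            else np.full(n, m.shift_mean)
        )
        data[f"{name}_pre"] = pre
        data[f"{name}_post"] = post
    df = pd.DataFrame(data)
    for name, m in spec.device_metrics.items():
        df[f"{name}_dev1"] = _truncated_positive_normal(rng, m.mean, m.sd, n)
        df[f"{name}_dev2"] = _truncated_positive_normal(rng, m.mean, m.sd, n)
    df.attrs["provenance"] = "generated"
    df.attrs["seed"] = spec.seed
    return df
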