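"""Subject-specific inflow boundary conditions.

Heart rate and cardiac output from body weight (table lookup over the
packaged porcine cohort, or a log-log allometric fit), a constrained
synthetic MPA flow waveform, the Carreau-Yasuda shear-thinning blood
rheology, and the peak-systolic Reynolds number that places the flow in
the transitional/turbulent regime.

Units: weight kg, HR beats/min, CO L/min, flow mL/s, viscosity Pa·s,
density kg/m³, lengths mm.  The canonical waveform sampling step is
Δt = 1 ms.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import CubicSpline

from .errors import ConfigurationError, ConstraintError, DomainError

DT_CANONICAL_S = 0.001
BLOOD_DENSITY_KG_M3 = 1050.0

#: Relative tolerance of the waveform constraints (mean flow, peak, SV).
WAVEFORM_RTOL = 0.005


@dataclass(frozen=True)
class AnimalProfile:
    """One cohort animal: weight and hemodynamic baseline."""

    case_id: str
    weight_kg: float
    hr_bpm: float
    co_lpm: float
    qmax_mls: float

    def __post_init__(self) -> None:
        for name in ("weight_kg", "hr_bpm", "co_lpm", "qmax_mls"):
            if getattr(self, name) <= 0:
                raise DomainError(f"{name} must be positive")

    @property
    def period_s(self) -> float:
        return 60.0 / self.hr_bpm

    @property
    def stroke_volume_ml(self) -> float:
        return self.co_lpm * 1000.0 / self.hr_bpm

    @property
    def mean_flow_mls(self) -> float:
        return self.co_lpm * 1000.0 / 60.0


def read_profiles(path) -> list[AnimalProfile]:
    """Read a profile CSV (case,weight_kg,hr_bpm,co_lpm,qmax_mls)."""
    rows = list(csv.DictReader(open(path)))
    if not rows:
        raise ConfigurationError(f"profile table {path} is empty")
    return [
        AnimalProfile(
            case_id=r["case"],
            weight_kg=float(r["weight_kg"]),
            hr_bpm=float(r["hr_bpm"]),
            co_lpm=float(r["co_lpm"]),
            qmax_mls=float(r["qmax_mls"]),
        )
        for r in rows
    ]


@dataclass
class FlowWaveform:
    """Periodic volumetric inflow over exactly one cardiac cycle.

    ``q_mls[i]`` is the flow at ``t = i * dt_s``; the sample at ``t = T`` is
    not stored (it equals the sample at 0 by periodicity).
    """

    period_s: float
    dt_s: float
    q_mls: np.ndarray

    def __post_init__(self) -> None:
        self.q_mls = np.asarray(self.q_mls, dtype=float).ravel()
        if self.period_s <= 0 or self.dt_s <= 0:
            raise DomainError("period and dt must be positive")
        if len(self.q_mls) < 2:
            raise DomainError("waveform needs at least 2 samples")

    @property
    def n_samples(self) -> int:
        return len(self.q_mls)

    @property
    def t_s(self) -> np.ndarray:
        return self.dt_s * np.arange(self.n_samples)

    @property
    def mean_mls(self) -> float:
        return float(self.q_mls.mean())

    @property
    def stroke_volume_ml(self) -> float:
        return float(self.q_mls.mean() * self.period_s)

    @property
    def co_lpm(self) -> float:
        return self.mean_mls * 60.0 / 1000.0

    def resample(self, dt_s: float) -> "FlowWaveform":
        """Periodic cubic resampling to a different time step."""
        n_new = max(2, int(round(self.period_s / dt_s)))
        t_ext = np.concatenate([self.t_s, [self.period_s]])
        q_ext = np.concatenate([self.q_mls, [self.q_mls[0]]])
        cs = CubicSpline(t_ext, q_ext, bc_type="periodic")
        t_new = (self.period_s / n_new) * np.arange(n_new)
        return FlowWaveform(self.period_s, self.period_s / n_new, cs(t_new))

    def to_csv(self, path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["t_s", "q_mls"])
            for t, q in zip(self.t_s, self.q_mls):
                w.writerow([f"{t:.9g}", f"{q:.9g}"])

    @classmethod
    def from_csv(cls, path) -> "FlowWaveform":
        rows = list(csv.DictReader(open(path)))
        t = np.array([float(r["t_s"]) for r in rows])
        q = np.array([float(r["q_mls"]) for r in rows])
        dt = float(np.median(np.diff(t)))
        return cls(period_s=dt * len(t), dt_s=dt, q_mls=q)


@dataclass(frozen=True)
class ViscosityModel:
    """Carreau-Yasuda shear-thinning viscosity with blood defaults.

    μ(γ̇) = μ∞ + (μ0 − μ∞)·[1 + (λ·γ̇)^a]^((n−1)/a).  The default
    coefficients are the porcine/human blood set of the rheology literature
    commonly used for large-vessel CFD.
    """

    density_kg_m3: float = BLOOD_DENSITY_KG_M3
    mu0_pas: float = 0.16
    mu_inf_pas: float = 0.0035
    lambda_s: float = 8.2
    a: float = 0.64
    n: float = 0.2128

    def __post_init__(self) -> None:
        if not (self.mu0_pas > self.mu_inf_pas > 0):
            raise DomainError("need mu0 > mu_inf > 0")
        if self.lambda_s <= 0 or self.density_kg_m3 <= 0:
            raise DomainError("lambda and density must be positive")

    def to_json(self) -> dict:
        return {
            "density_kg_m3": self.density_kg_m3,
            "mu0_pas": self.mu0_pas,
            "mu_inf_pas": self.mu_inf_pas,
            "lambda_s": self.lambda_s,
            "a": self.a,
            "n": self.n,
        }

    @classmethod
    def from_json(cls, obj: dict) -> "ViscosityModel":
        return cls(**obj)


@dataclass
class InletSpec:
    """Inlet waveform plus the metadata the flow model assumes."""

    waveform: FlowWaveform
    turbulence_intensity: float = 0.05
    outlet_pressure: str = "constant"

    def __post_init__(self) -> None:
        if not (0.0 < self.turbulence_intensity < 1.0):
            raise DomainError("turbulence intensity must lie in (0, 1)")


# ---------------------------------------------------------------------------
# operations


def estimate_hr_co(
    weight_kg: float,
    mode: str = "lookup",
    profiles: list[AnimalProfile] | None = None,
) -> tuple[float, float]:
    """Estimate (HR, CO) from body weight.

    ``lookup`` returns the nearest-weight row of the profile table (ties go
    to the lowest case id); ``allometric`` fits power laws
    ``HR = c_H · W^b_H`` and ``CO = c_C · W^b_C`` to the table by least
    squares in log space and evaluates them.
    """
    if weight_kg <= 0:
        raise DomainError("weight must be positive")
    if profiles is None:
        from .fixtures import load_animal_profiles

        profiles = load_animal_profiles()
    if not profiles:
        raise ConfigurationError("profile table is empty")

    if mode == "lookup":
        best = min(profiles, key=lambda p: (abs(p.weight_kg - weight_kg), p.case_id))
        return best.hr_bpm, best.co_lpm
    if mode == "allometric":
        w = np.log([p.weight_kg for p in profiles])
        A = np.stack([np.ones_like(w), w], axis=1)
        bh = np.linalg.lstsq(A, np.log([p.hr_bpm for p in profiles]), rcond=None)[0]
        bc = np.linalg.lstsq(A, np.log([p.co_lpm for p in profiles]), rcond=None)[0]
        lw = np.log(weight_kg)
        return float(np.exp(bh[0] + bh[1] * lw)), float(np.exp(bc[0] + bc[1] * lw))
    raise ConfigurationError(f"unknown mode {mode!r}")


def synthesize_waveform(
    hr_bpm: float,
    co_lpm: float,
    qmax_mls: float,
    duty_fraction: float = 0.40,
    dip_depth_fraction: float = 0.05,
    dip_duration_fraction: float = 0.15,
    dt_s: float = DT_CANONICAL_S,
    seed: int | None = None,
) -> FlowWaveform:
    """Synthesize a single-peak pulsatile MPA inflow waveform.

    The waveform family is a smooth template: a half-cosine systolic lobe of
    duration ``duty_fraction · T`` peaking at ``qmax_mls``, an
    early-diastolic dicrotic dip reaching ``-dip_depth_fraction · qmax``,
    and a flat late-diastolic baseline.  The baseline level is solved in
    closed form from the discrete sample sums so the cycle mean matches the
    cardiac output exactly; when that solution is infeasible the systolic
    duty fraction is adjusted by bisection instead.  A seeded ±10 % jitter
    of the duty fraction emulates inter-animal curve-shape variability.
    """
    if min(hr_bpm, co_lpm, qmax_mls) <= 0:
        raise DomainError("hr, co and qmax must be positive")
    period = 60.0 / hr_bpm
    q_mean = co_lpm * 1000.0 / 60.0
    if qmax_mls <= q_mean:
        raise ConstraintError(
            f"infeasible: Qmax ({qmax_mls:.1f} mL/s) must exceed the mean flow "
            f"CO*1000/60 ({q_mean:.1f} mL/s)"
        )
    if seed is not None:
        rng = np.random.default_rng(seed)
        duty_fraction *= 1.0 + 0.1 * (2.0 * rng.random() - 1.0)

    n = max(8, int(round(period / dt_s)))
    dt = period / n  # exact coverage of one period
    t = dt * np.arange(n)
    q_dip = -dip_depth_fraction * qmax_mls

    def build(duty):
        ts = duty * period
        td = dip_duration_fraction * period
        bump = np.zeros(n)
        sys_mask = t < ts
        bump[sys_mask] = 0.5 * (1.0 - np.cos(2.0 * np.pi * t[sys_mask] / ts))
        dip = np.zeros(n)
        dip_mask = (t >= ts) & (t < ts + td)
        dip[dip_mask] = 0.5 * (1.0 - np.cos(2.0 * np.pi * (t[dip_mask] - ts) / td))
        # Q = A*qb + B with A = 1 - bump - dip, B = qmax*bump + qdip*dip
        A = 1.0 - bump - dip
        B = qmax_mls * bump + q_dip * dip
        qb = (q_mean - B.mean()) / A.mean()
        return qb, A * qb + B

    lo_frac, hi_frac = 0.05, 0.85

    def feasible(duty):
        qb, q = build(duty)
        return (q_dip - 1e-9 <= qb <= 0.6 * qmax_mls) and abs(q.max() - qmax_mls) <= (
            WAVEFORM_RTOL * qmax_mls
        )

    duty = float(np.clip(duty_fraction, lo_frac, hi_frac))
    if not feasible(duty):
        # bisect on the duty fraction: larger duty -> larger systolic volume
        # -> lower baseline; find the edge of feasibility
        lo, hi = lo_frac, hi_frac
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            qb, _ = build(mid)
            if qb < q_dip:
                hi = mid
            elif qb > 0.6 * qmax_mls:
                lo = mid
            else:
                duty = mid
                break
            if hi - lo < 1e-6:
                duty = 0.5 * (lo + hi)
                break
        else:
            duty = 0.5 * (lo + hi)
        if not feasible(duty):
            raise ConstraintError(
                "infeasible constraint set: no duty fraction satisfies "
                f"mean={q_mean:.1f} mL/s with Qmax={qmax_mls:.1f} mL/s"
            )
    _, q = build(duty)
    return FlowWaveform(period_s=period, dt_s=dt, q_mls=q)


def carreau_yasuda_viscosity(shear_rate, model: ViscosityModel | None = None):
    """Dynamic viscosity (Pa·s) at shear rate γ̇ (1/s)."""
    model = model or ViscosityModel()
    g = np.asarray(shear_rate, dtype=float)
    if (g < 0).any():
        raise DomainError("shear rate must be non-negative")
    mu = model.mu_inf_pas + (model.mu0_pas - model.mu_inf_pas) * (
        1.0 + (model.lambda_s * g) ** model.a
    ) ** ((model.n - 1.0) / model.a)
    return mu if mu.ndim else float(mu)


def reynolds_peak(qmax_mls: float, diameter_mm: float, model: ViscosityModel | None = None) -> float:
    """Peak-systolic Reynolds number Re = ρ·v·D/μ∞ (bulk velocity, SI units)."""
    model = model or ViscosityModel()
    if qmax_mls < 0 or diameter_mm <= 0:
        raise DomainError("Qmax must be >= 0 and diameter > 0")
    d_m = diameter_mm / 1000.0
    q_m3s = qmax_mls * 1e-6
    v = q_m3s / (np.pi * d_m**2 / 4.0)
    return float(model.density_kg_m3 * v * d_m / model.mu_inf_pas)
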