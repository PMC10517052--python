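"""Wall-shear-derived hemodynamic indices.

Time-averaged wall shear stress (TAWSS), oscillatory shear index (OSI),
relative residence time (RRT), area-weighted surface averages, thresholded
risk areas (low-WSS, high-OSI) and the trans-device static pressure drop.

Definitions over N equidistant time steps covering one cardiac cycle:

    TAWSS = (1/N) Σ_t ‖WSS_t‖
    OSI   = ½ (1 − ‖Σ_t WSS_t‖ / Σ_t ‖WSS_t‖)      in [0, 0.5]
    RRT   = 1 / ((1 − 2·OSI) · TAWSS)

OSI is 0 for a direction-constant history and 0.5 for a zero-mean harmonic
oscillation.  Thresholds use strict inequalities (WSS < 0.5 Pa low-shear,
OSI > 0.2 high-oscillation).  Values live at face centroids.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ProbePlacementError
from .fields import WallFieldSeries
from .geometry import Centerline
from .mesh import MM2_PER_CM2, Region, SurfaceMesh

LOW_WSS_THRESHOLD_PA = 0.5
HIGH_OSI_THRESHOLD = 0.2
PA_PER_MMHG = 133.322
PRESSURE_PROBE_OFFSET_MM = 10.0


@dataclass
class IndexMap:
    """Per-face TAWSS (Pa), OSI (-) and RRT (1/Pa) on one mesh.

    RRT entries are NaN where undefined (OSI = 0.5 or TAWSS = 0).
    """

    mesh: SurfaceMesh
    tawss: np.ndarray
    osi: np.ndarray
    rrt: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.tawss = np.asarray(self.tawss, dtype=float)
        self.osi = np.asarray(self.osi, dtype=float)
        if (self.tawss < 0).any():
            raise DomainError("TAWSS must be non-negative")
        if ((self.osi < -1e-12) | (self.osi > 0.5 + 1e-12)).any():
            raise DomainError("OSI must lie in [0, 0.5]")


@dataclass
class AreaMetrics:
    """Thresholded risk areas on a region, cm²."""

    region: str
    low_wss_area_cm2: float
    high_osi_area_cm2: float
    total_area_cm2: float
    low_wss_threshold_pa: float = LOW_WSS_THRESHOLD_PA
    high_osi_threshold: float = HIGH_OSI_THRESHOLD

    def __post_init__(self) -> None:
        for a in (self.low_wss_area_cm2, self.high_osi_area_cm2):
            if a < -1e-12 or a > self.total_area_cm2 + 1e-9:
                raise DomainError("thresholded area outside [0, total]")


@dataclass
class PressureDrop:
    """Trans-device pressure drop, mmHg (positive: upstream > downstream)."""

    dp_mmhg: float
    upstream_s_mm: float
    downstream_s_mm: float


def tawss(series: WallFieldSeries) -> np.ndarray:
    """Per-face temporal mean of the WSS magnitude (Pa)."""
    return np.linalg.norm(series.wss, axis=2).mean(axis=1)


def osi(series: WallFieldSeries) -> np.ndarray:
    """Per-face oscillatory shear index.

    Faces with an all-zero WSS history get OSI = 0 (division guard).
    """
    sum_vec = np.linalg.norm(series.wss.sum(axis=1), axis=1)
    sum_mag = np.linalg.norm(series.wss, axis=2).sum(axis=1)
    out = np.zeros(len(sum_mag))
    ok = sum_mag > 0
    out[ok] = 0.5 * (1.0 - sum_vec[ok] / sum_mag[ok])
    # clip the numerical negatives that appear when sum_vec ~ sum_mag
    return np.clip(out, 0.0, 0.5)


def rrt(tawss_pa: np.ndarray, osi_values: np.ndarray) -> np.ndarray:
    """Relative residence time 1/((1−2·OSI)·TAWSS); NaN where undefined."""
    tw = np.asarray(tawss_pa, dtype=float)
    os_ = np.asarray(osi_values, dtype=float)
    denom = (1.0 - 2.0 * os_) * tw
    out = np.full(denom.shape, np.nan)
    ok = denom > 0
    out[ok] = 1.0 / denom[ok]
    return out


def index_map(series: WallFieldSeries, with_rrt: bool = True) -> IndexMap:
    tw = tawss(series)
    os_ = osi(series)
    return IndexMap(series.mesh, tw, os_, rrt(tw, os_) if with_rrt else None)


def _region_mask(mesh: SurfaceMesh, region) -> np.ndarray:
    if isinstance(region, str) and region.upper() == "ALL":
        return np.asarray(
            [l not in (Region.CAP_INLET, Region.CAP_OUTLET) for l in mesh.labels],
            dtype=bool,
        )
    if isinstance(region, str) and region.upper() == "PA":
        return np.asarray(
            [l in (Region.MPA, Region.LPA, Region.RPA, Region.BRANCH) for l in mesh.labels],
            dtype=bool,
        )
    return mesh.region_mask(region)


def surface_average(values: np.ndarray, mesh: SurfaceMesh, region="ALL",
                    weighted: bool = True) -> float:
    """Area-weighted (default) mean of a per-face field over a region."""
    mask = _region_mask(mesh, region)
    if not mask.any():
        raise DomainError(f"region {region!r} has no faces")
    vals = np.asarray(values, dtype=float)[mask]
    if not weighted:
        return float(vals.mean())
    w = mesh.face_areas[mask]
    return float((vals * w).sum() / w.sum())


def thresholded_area(values: np.ndarray, mesh: SurfaceMesh, region="ALL",
                     threshold: float = LOW_WSS_THRESHOLD_PA,
                     direction: str = "below") -> float:
    """Area (cm²) where the face value is strictly below/above a threshold."""
    if not np.isfinite(threshold):
        raise DomainError("threshold must be finite")
    mask = _region_mask(mesh, region)
    if not mask.any():
        raise DomainError(f"region {region!r} has no faces")
    vals = np.asarray(values, dtype=float)[mask]
    areas = mesh.face_areas[mask]
    if direction == "below":
        sel = vals < threshold
    elif direction == "above":
        sel = vals > threshold
    else:
        raise DomainError("direction must be 'below' or 'above'")
    return float(areas[sel].sum() / MM2_PER_CM2)


def area_metrics(imap: IndexMap, region="PA") -> AreaMetrics:
    """Low-WSS and high-OSI areas of a region with its total area."""
    mask = _region_mask(imap.mesh, region)
    if not mask.any():
        raise DomainError(f"region {region!r} has no faces")
    total = float(imap.mesh.face_areas[mask].sum() / MM2_PER_CM2)
    return AreaMetrics(
        region=str(region),
        low_wss_area_cm2=thresholded_area(imap.tawss, imap.mesh, region,
                                          LOW_WSS_THRESHOLD_PA, "below"),
        high_osi_area_cm2=thresholded_area(imap.osi, imap.mesh, region,
                                           HIGH_OSI_THRESHOLD, "above"),
        total_area_cm2=total,
    )


def pressure_drop(
    series: WallFieldSeries,
    centerline: Centerline,
    device_span_mm: tuple[float, float],
    offset_mm: float = PRESSURE_PROBE_OFFSET_MM,
    station_half_width_mm: float = 1.5,
    time_average: bool = True,
) -> PressureDrop:
    """Static pressure drop across a device.

    Probes sit ``offset_mm`` up- and downstream of the device span (given as
    an arc-length interval on the centerline).  Each probe averages the
    per-face static pressure over the faces whose nearest centerline station
    falls within a thin band, emulating a cross-section average; the drop is
    the (cycle-averaged) upstream minus downstream value, in mmHg.  Negative
    values are legal (pressure recovery over an expanding cross-section).
    """
    if series.pressure is None:
        raise DomainError("series carries no pressure field")
    s_up = device_span_mm[0] - offset_mm
    s_dn = device_span_mm[1] + offset_mm
    al = centerline.arc_length
    if s_up < al[0] - 1e-9 or s_dn > al[-1] + 1e-9:
        raise ProbePlacementError(
            f"probe stations {s_up:.1f}/{s_dn:.1f} mm fall outside the "
            f"centerline extent [{al[0]:.1f}, {al[-1]:.1f}] mm"
        )
    cent = series.mesh.face_centroids
    # nearest centerline station per face
    d2 = ((cent[:, None, :] - centerline.points[None, :, :]) ** 2).sum(axis=2)
    s_face = al[d2.argmin(axis=1)]

    def probe(s0):
        sel = np.abs(s_face - s0) <= station_half_width_mm
        if not sel.any():
            raise ProbePlacementError(f"no faces near probe station {s0:.1f} mm")
        p = series.pressure[sel]
        p_t = p.mean(axis=0)  # cross-section average per step
        return float(p_t.mean()) if time_average else float(p_t.max())

    dp_pa = probe(s_up) - probe(s_dn)
    return PressureDrop(
        dp_mmhg=dp_pa / PA_PER_MMHG,
        upstream_s_mm=s_up,
        downstream_s_mm=s_dn,
    )
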