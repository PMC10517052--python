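"""Wall-field time series: per-face WSS vectors and static pressure.

The container mirrors what a transient flow solver exports for
post-processing: one wall-shear-stress vector (Pa) per surface face at N
equidistant time steps covering exactly one cardiac cycle, plus an
optional per-face static pressure (Pa).

Canonical on-disk form is a long CSV (``face,t,wss_x,wss_y,wss_z,p``)
next to the mesh file; a legacy-VTK text export is provided for
visualisation of derived index maps.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass

import numpy as np

from .errors import DomainError, FormatError
from .mesh import SurfaceMesh


@dataclass
class WallFieldSeries:
    """Per-face WSS vectors (and optional pressure) over one cycle.

    ``wss[f, i]`` is the WSS vector (Pa) of face ``f`` at time ``i * dt_s``;
    the sample at the period is not duplicated.
    """

    mesh: SurfaceMesh
    wss: np.ndarray
    dt_s: float
    pressure: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.wss = np.asarray(self.wss, dtype=float)
        if self.wss.ndim != 3 or self.wss.shape[2] != 3:
            raise DomainError("wss must have shape (faces, steps, 3)")
        if self.wss.shape[0] != len(self.mesh.faces):
            raise DomainError("one WSS history per mesh face required")
        if self.wss.shape[1] < 2:
            raise DomainError("at least 2 time steps required")
        if self.dt_s <= 0:
            raise DomainError("dt must be positive")
        if not np.isfinite(self.wss).all():
            raise DomainError("WSS contains non-finite values")
        if self.pressure is not None:
            self.pressure = np.asarray(self.pressure, dtype=float)
            if self.pressure.shape != self.wss.shape[:2]:
                raise DomainError("pressure must have shape (faces, steps)")
            if not np.isfinite(self.pressure).all():
                raise DomainError("pressure contains non-finite values")

    @property
    def n_steps(self) -> int:
        return self.wss.shape[1]

    @property
    def t_s(self) -> np.ndarray:
        return self.dt_s * np.arange(self.n_steps)

    @property
    def period_s(self) -> float:
        return self.dt_s * self.n_steps

    def copy(self) -> "WallFieldSeries":
        return WallFieldSeries(
            self.mesh,
            self.wss.copy(),
            self.dt_s,
            None if self.pressure is None else self.pressure.copy(),
        )

    # -- I/O ---------------------------------------------------------------
    def to_csv(self, path) -> None:
        """Long-format CSV: one row per (face, step)."""
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["face", "t_s", "wss_x", "wss_y", "wss_z", "p"])
            t = self.t_s
            for f in range(self.wss.shape[0]):
                for i in range(self.n_steps):
                    p = "" if self.pressure is None else f"{self.pressure[f, i]:.9g}"
                    w.writerow(
                        [f, f"{t[i]:.9g}"]
                        + [f"{v:.9g}" for v in self.wss[f, i]]
                        + [p]
                    )

    @classmethod
    def from_csv(cls, path, mesh: SurfaceMesh) -> "WallFieldSeries":
        rows = list(csv.DictReader(open(path)))
        if not rows:
            raise FormatError(f"{path} contains no field samples")
        faces = np.array([int(r["face"]) for r in rows])
        times = np.array([float(r["t_s"]) for r in rows])
        n_faces = faces.max() + 1
        ts = np.unique(times)
        n_steps = len(ts)
        if n_faces * n_steps != len(rows):
            raise FormatError("field CSV is not a complete (face x step) grid")
        dt = float(np.median(np.diff(ts)))
        wss = np.zeros((n_faces, n_steps, 3))
        has_p = any(r["p"] not in ("", None) for r in rows)
        pres = np.zeros((n_faces, n_steps)) if has_p else None
        step_of = {t: i for i, t in enumerate(ts)}
        for r in rows:
            f = int(r["face"])
            i = step_of[float(r["t_s"])]
            wss[f, i] = [float(r["wss_x"]), float(r["wss_y"]), float(r["wss_z"])]
            if has_p:
                pres[f, i] = float(r["p"])
        return cls(mesh, wss, dt, pres)


def export_vtk(mesh: SurfaceMesh, cell_data: dict, path) -> None:
    """Write a legacy-VTK (ASCII) polydata file with per-face scalars."""
    v = mesh.vertices
    f = mesh.faces
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\npahemo surface fields\nASCII\n")
        fh.write("DATASET POLYDATA\n")
        fh.write(f"POINTS {len(v)} float\n")
        for p in v:
            fh.write(f"{p[0]:.9g} {p[1]:.9g} {p[2]:.9g}\n")
        fh.write(f"POLYGONS {len(f)} {4 * len(f)}\n")
        for tri in f:
            fh.write(f"3 {tri[0]} {tri[1]} {tri[2]}\n")
        if cell_data:
            fh.write(f"CELL_DATA {len(f)}\n")
            for name, values in cell_data.items():
                values = np.asarray(values, dtype=float)
                fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
                for val in values:
                    fh.write(f"{val:.9g}\n" if np.isfinite(val) else "nan\n")
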