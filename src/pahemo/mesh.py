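"""Labelled triangulated surface meshes.

The geometric substrate of every pipeline stage is a watertight triangulated
surface in millimetres with one region label per face.  Labels distinguish
the vessel segments (MPA/LPA/RPA), side branches, the blood-exposed device
surface and the inlet/outlet caps that close the fluid domain.

STL carries no attributes, so labels are persisted in a sidecar CSV
(``face_index,label``); PLY embeds them as an integer face property.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import numpy as np
import trimesh

from .errors import DomainError, FormatError, MeshIntegrityError


class Region(str, Enum):
    """Face region labels used throughout the package."""

    MPA = "MPA"
    LPA = "LPA"
    RPA = "RPA"
    BRANCH = "BRANCH"
    DEVICE = "DEVICE"
    CAP_INLET = "CAP_INLET"
    CAP_OUTLET = "CAP_OUTLET"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


#: Labels excluded from luminal surface-area accounting.
CAP_REGIONS = frozenset({Region.CAP_INLET, Region.CAP_OUTLET})

MM2_PER_CM2 = 100.0


@dataclass
class SurfaceMesh:
    """Triangulated surface with per-face region labels.

    Parameters
    ----------
    vertices : (V, 3) float array, millimetres.
    faces : (F, 3) int array of vertex indices.
    labels : (F,) array of :class:`Region`.
    """

    vertices: np.ndarray
    faces: np.ndarray
    labels: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise FormatError("vertices must be an (V, 3) array")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise FormatError("faces must be an (F, 3) array")
        if self.labels is None:
            self.labels = np.full(len(self.faces), Region.MPA, dtype=object)
        else:
            self.labels = np.asarray(
                [Region(l) for l in np.asarray(self.labels).ravel()], dtype=object
            )
        if len(self.labels) != len(self.faces):
            raise FormatError("labels must have one entry per face")
        self._trimesh: trimesh.Trimesh | None = None

    # -- trimesh bridge ----------------------------------------------------
    @property
    def tm(self) -> trimesh.Trimesh:
        """The underlying :class:`trimesh.Trimesh` (cached, not processed)."""
        if self._trimesh is None:
            self._trimesh = trimesh.Trimesh(
                vertices=self.vertices, faces=self.faces, process=False
            )
        return self._trimesh

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh, labels=None) -> "SurfaceMesh":
        return cls(np.asarray(tm.vertices), np.asarray(tm.faces), labels)

    # -- derived quantities ------------------------------------------------
    @property
    def face_areas(self) -> np.ndarray:
        """Per-face area in mm² (exactly ``0.5 * |cross product|``)."""
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        return 0.5 * np.linalg.norm(cross, axis=1)

    @property
    def face_centroids(self) -> np.ndarray:
        return self.vertices[self.faces].mean(axis=1)

    @property
    def face_normals(self) -> np.ndarray:
        v = self.vertices
        f = self.faces
        cross = np.cross(v[f[:, 1]] - v[f[:, 0]], v[f[:, 2]] - v[f[:, 0]])
        n = np.linalg.norm(cross, axis=1, keepdims=True)
        return cross / np.where(n > 0, n, 1.0)

    def region_mask(self, region) -> np.ndarray:
        region = Region(region)
        return np.asarray([l == region for l in self.labels], dtype=bool)

    def is_watertight(self) -> bool:
        """Every edge shared by exactly two faces and no zero-area face."""
        return bool(self.tm.is_watertight) and bool((self.face_areas > 0).all())

    def audit(self) -> None:
        """Raise :class:`MeshIntegrityError` unless usable as a fluid domain."""
        if not self.tm.is_watertight:
            raise MeshIntegrityError(
                "mesh is not watertight (an edge is not shared by exactly 2 faces)"
            )
        if not (self.face_areas > 0).all():
            raise MeshIntegrityError("mesh contains zero-area faces")

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "SurfaceMesh":
        """Rigidly transformed copy (labels preserved)."""
        v = self.vertices @ np.asarray(rotation).T + np.asarray(translation)
        return SurfaceMesh(v, self.faces.copy(), self.labels.copy())

    def copy(self) -> "SurfaceMesh":
        return SurfaceMesh(self.vertices.copy(), self.faces.copy(), self.labels.copy())


# ---------------------------------------------------------------------------
# I/O


def _label_sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".labels.csv")


def save_mesh(mesh: SurfaceMesh, path, file_type: str | None = None) -> None:
    """Write STL (binary) or PLY; labels go to a sidecar ``.labels.csv``.

    For PLY the labels are *also* embedded as a per-face ``region`` property
    via the sidecar-independent trimesh metadata path is not reliable across
    readers, so the sidecar is always written and is canonical.
    """
    path = Path(path)
    kind = (file_type or path.suffix.lstrip(".")).lower()
    if kind not in ("stl", "ply"):
        raise FormatError(f"unsupported mesh format: {kind!r}")
    mesh.tm.export(path, file_type=kind)
    with open(_label_sidecar(path), "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["face_index", "label"])
        for i, lab in enumerate(mesh.labels):
            w.writerow([i, str(lab)])


def load_mesh(path) -> SurfaceMesh:
    """Read STL/PLY written by :func:`save_mesh` (sidecar labels optional)."""
    path = Path(path)
    try:
        tm = trimesh.load_mesh(path, process=False)
    except Exception as exc:  # trimesh raises many types on malformed input
        raise FormatError(f"could not parse mesh file {path}: {exc}") from exc
    if not isinstance(tm, trimesh.Trimesh) or len(tm.faces) == 0:
        raise FormatError(f"{path} does not contain a triangulated surface")
    # STL stores an un-indexed triangle soup: re-index shared vertices so
    # watertightness is restored (face order is preserved, keeping the
    # sidecar labels aligned)
    tm.merge_vertices()
    labels = None
    sidecar = _label_sidecar(path)
    if sidecar.exists():
        rows = list(csv.reader(open(sidecar)))
        if rows and rows[0][0] == "face_index":
            rows = rows[1:]
        labels = np.empty(len(tm.faces), dtype=object)
        labels[:] = Region.MPA
        for idx, lab in rows:
            labels[int(idx)] = Region(lab)
    return SurfaceMesh.from_trimesh(tm, labels)


def surface_area(mesh: SurfaceMesh, region="ALL") -> float:
    """Total area of a labelled region in cm²; caps are always excluded.

    ``region='ALL'`` sums every non-cap label, so it equals the sum of
    the per-label areas (partition additivity).
    """
    areas = mesh.face_areas
    if isinstance(region, str) and region.upper() == "ALL":
        mask = np.asarray([l not in CAP_REGIONS for l in mesh.labels], dtype=bool)
    else:
        try:
            region = Region(region)
        except ValueError as exc:
            raise DomainError(f"unknown region label: {region!r}") from exc
        if region in CAP_REGIONS:
            raise DomainError("cap regions are excluded from surface-area accounting")
        mask = mesh.region_mask(region)
    return float(areas[mask].sum() / MM2_PER_CM2)
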