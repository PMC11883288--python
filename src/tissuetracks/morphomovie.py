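"""Data model and I/O for the growing-domain mesh sequence (the "morphomovie").

A morphomovie is an ordered sequence of 2D triangle meshes, one per
developmental hour, describing a growing tissue domain.  Within each hour the
mesh vertices may be displaced in fine substeps (10 developmental minutes by
default) to follow the changing outline; at every hour boundary the deformed
domain is re-triangulated ("remeshed") to restore a uniform element size.  The
last substep frame of hour ``t`` and the fresh mesh of hour ``t + 1`` therefore
describe the same instant of the domain.

Meshes are stored one file per timepoint (ASCII OFF or PLY, z coordinate
accepted and dropped) and tied together by a small JSON manifest::

    {
      "meshes": ["mesh_00.off", "mesh_01.off", ...],
      "substeps": [["sub_00_1.off", ...], ...],   # optional, per hour
      "minutes_per_substep": 10,                   # optional
      "stages": {"0": "mE10:13", ...}              # optional, cosmetic
    }

Coordinates are 2D Cartesian, y-up, in arbitrary but movie-consistent units.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

from .errors import MeshFormatError, ValidationError

#: relative tolerance for the hand-over between the deformed end-of-hour
#: configuration and the next hour's fresh mesh (outline areas must agree)
HANDOVER_AREA_RTOL = 0.02

#: triangles with absolute area below this are considered degenerate
DEGENERATE_AREA_TOL = 1e-14


def triangle_signed_areas(vertices: np.ndarray, triangles: np.ndarray) -> np.ndarray:
    """Signed area of each triangle (positive for counter-clockwise winding)."""
    p = vertices[triangles]  # (m, 3, 2)
    a, b, c = p[:, 0], p[:, 1], p[:, 2]
    return 0.5 * ((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
                  - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))


@dataclass
class Mesh:
    """One triangulated snapshot of the domain at an integer hour.

    Invariants (enforced by :meth:`validate`): all triangle indices valid, all
    triangles counter-clockwise and non-degenerate.  Winding is normalised in
    place on construction.
    """

    vertices: np.ndarray      # (n, 2) float
    triangles: np.ndarray     # (m, 3) int
    timepoint: int = 0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError(
                f"hour {self.timepoint}: vertices must be (n, 2), got {self.vertices.shape}")
        self.triangles = np.asarray(self.triangles, dtype=np.int64)
        if self.triangles.ndim != 2 or self.triangles.shape[1] != 3:
            raise ValidationError(
                f"hour {self.timepoint}: triangles must be (m, 3), got {self.triangles.shape}")
        self.validate()

    def validate(self) -> None:
        n = len(self.vertices)
        if self.triangles.size and (self.triangles.min() < 0 or self.triangles.max() >= n):
            raise ValidationError(f"hour {self.timepoint}: triangle index out of range")
        areas = triangle_signed_areas(self.vertices, self.triangles)
        flipped = areas < 0
        if flipped.any():  # normalise winding to counter-clockwise
            self.triangles[flipped] = self.triangles[flipped][:, ::-1]
            areas = np.abs(areas)
        bad = np.flatnonzero(np.abs(areas) <= DEGENERATE_AREA_TOL)
        if bad.size:
            raise ValidationError(
                f"degenerate triangle (hour {self.timepoint}, index {int(bad[0])}): "
                f"area {areas[bad[0]]:.3e}")

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    def triangle_points(self, index: Optional[int] = None) -> np.ndarray:
        """Corner coordinates of one triangle (3, 2) or of all (m, 3, 2)."""
        if index is None:
            return self.vertices[self.triangles]
        return self.vertices[self.triangles[index]]

    def centroids(self) -> np.ndarray:
        return self.vertices[self.triangles].mean(axis=1)


@dataclass(frozen=True)
class TriangleRef:
    """Reference to one triangle of one hourly mesh."""

    timepoint: int
    index: int

    def resolve(self, movie: "Morphomovie") -> np.ndarray:
        return movie.hourly_meshes[self.timepoint].triangle_points(self.index)


def mesh_area(mesh: Mesh) -> float:
    """Total domain area: sum of (unsigned) triangle areas."""
    return float(np.abs(triangle_signed_areas(mesh.vertices, mesh.triangles)).sum())


def _polygon_area(points: np.ndarray, triangles: np.ndarray) -> float:
    return float(np.abs(triangle_signed_areas(points, triangles)).sum())


@dataclass
class Morphomovie:
    """The full mesh sequence: hourly meshes plus optional substep frames."""

    hourly_meshes: list
    substeps: Optional[list] = None          # per hour: list of (n, 2) vertex frames
    minutes_per_substep: int = 10
    stage_labels: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        tps = [m.timepoint for m in self.hourly_meshes]
        if tps != list(range(len(tps))):
            raise ValidationError(f"hourly mesh timepoints must be 0..T-1 without gaps, got {tps}")
        if self.substeps is not None:
            if len(self.substeps) > len(self.hourly_meshes):
                raise ValidationError("more substep groups than hours")
            for t, frames in enumerate(self.substeps):
                mesh = self.hourly_meshes[t]
                for k, fr in enumerate(frames):
                    fr = np.asarray(fr, dtype=float)
                    if fr.shape != mesh.vertices.shape:
                        raise ValidationError(
                            f"hour {t} substep {k}: vertex count {fr.shape} does not match "
                            f"hourly mesh {mesh.vertices.shape}")
                if frames and t + 1 < len(self.hourly_meshes):
                    end_area = _polygon_area(np.asarray(frames[-1], float), mesh.triangles)
                    next_area = mesh_area(self.hourly_meshes[t + 1])
                    if abs(end_area - next_area) / next_area > HANDOVER_AREA_RTOL:
                        raise ValidationError(
                            f"hour {t}: last substep area {end_area:.4g} disagrees with hour "
                            f"{t + 1} mesh area {next_area:.4g} beyond {HANDOVER_AREA_RTOL:.0%}")

    @property
    def n_hours(self) -> int:
        return len(self.hourly_meshes)

    def end_of_hour_vertices(self, t: int) -> np.ndarray:
        """Vertex positions of mesh ``t`` at the end of its hour.

        The last substep frame when substeps are present, else the hourly
        positions themselves.  Connectivity is always that of hour ``t``.
        """
        if self.substeps is not None and t < len(self.substeps) and self.substeps[t]:
            return np.asarray(self.substeps[t][-1], dtype=float)
        return self.hourly_meshes[t].vertices


# ---------------------------------------------------------------------------
# Mesh file I/O (ASCII OFF and PLY)
# ---------------------------------------------------------------------------

def _read_tokens(path: str) -> list:
    with open(path) as fh:
        out = []
        for line in fh:
            line = line.split("#", 1)[0]
            out.extend(line.split())
    return out


def read_mesh_file(path: str, timepoint: int = 0) -> Mesh:
    """Read one ASCII OFF or PLY mesh file; z coordinates are dropped."""
    if not os.path.exists(path):
        raise IOError(f"mesh file for hour {timepoint} not found: {path}")
    with open(path) as fh:
        head = fh.read(4)
    if head.lower().startswith("ply"):
        verts, tris = _read_ply(path)
    else:
        verts, tris = _read_off(path)
    return Mesh(vertices=verts, triangles=tris, timepoint=timepoint)


def _read_off(path: str):
    tok = _read_tokens(path)
    if not tok or tok[0].upper() != "OFF":
        raise MeshFormatError(f"{path}: missing OFF header")
    nv, nf = int(tok[1]), int(tok[2])
    pos = 4
    coords = np.array(tok[pos:pos + 3 * nv], dtype=float).reshape(nv, 3)
    pos += 3 * nv
    tris = []
    for _ in range(nf):
        k = int(tok[pos])
        if k != 3:
            raise MeshFormatError(f"{path}: only triangle faces supported, got {k}-gon")
        tris.append([int(tok[pos + 1]), int(tok[pos + 2]), int(tok[pos + 3])])
        pos += k + 1
    return coords[:, :2], np.array(tris, dtype=np.int64).reshape(-1, 3)


def _read_ply(path: str):
    with open(path) as fh:
        lines = [ln.strip() for ln in fh]
    if not lines or lines[0].lower() != "ply":
        raise MeshFormatError(f"{path}: missing ply header")
    nv = nf = None
    n_vert_props = 0
    in_vertex = False
    i = 1
    for i, ln in enumerate(lines[1:], start=1):
        parts = ln.split()
        if not parts:
            continue
        if parts[0] == "format" and parts[1] != "ascii":
            raise MeshFormatError(f"{path}: only ASCII PLY supported")
        if parts[0] == "element":
            in_vertex = parts[1] == "vertex"
            if parts[1] == "vertex":
                nv = int(parts[2])
            elif parts[1] == "face":
                nf = int(parts[2])
        elif parts[0] == "property" and in_vertex and parts[1] != "list":
            n_vert_props += 1
        elif parts[0] == "end_header":
            break
    if nv is None or nf is None:
        raise MeshFormatError(f"{path}: incomplete PLY header")
    body = lines[i + 1:]
    verts = np.array([body[j].split()[:min(3, n_vert_props)] for j in range(nv)], dtype=float)
    tris = []
    for j in range(nv, nv + nf):
        parts = body[j].split()
        if int(parts[0]) != 3:
            raise MeshFormatError(f"{path}: only triangle faces supported")
        tris.append([int(parts[1]), int(parts[2]), int(parts[3])])
    return verts[:, :2], np.array(tris, dtype=np.int64).reshape(-1, 3)


def write_mesh_file(path: str, vertices: np.ndarray, triangles: np.ndarray) -> None:
    """Write an ASCII OFF file (z = 0) with full float precision."""
    vertices = np.asarray(vertices, dtype=float)
    with open(path, "w") as fh:
        fh.write("OFF\n")
        fh.write(f"{len(vertices)} {len(triangles)} 0\n")
        for x, y in vertices:
            fh.write(f"{x:.17g} {y:.17g} 0\n")
        for a, b, c in triangles:
            fh.write(f"3 {a} {b} {c}\n")


# ---------------------------------------------------------------------------
# Manifest I/O
# ---------------------------------------------------------------------------

def load_morphomovie(manifest_path: str) -> Morphomovie:
    """Load and validate a morphomovie from its JSON manifest."""
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    base = os.path.dirname(os.path.abspath(manifest_path))

    meshes = []
    for t, rel in enumerate(manifest["meshes"]):
        meshes.append(read_mesh_file(os.path.join(base, rel), timepoint=t))

    substeps = None
    if manifest.get("substeps"):
        substeps = []
        for t, frame_paths in enumerate(manifest["substeps"]):
            frames = []
            for rel in frame_paths:
                fr = read_mesh_file(os.path.join(base, rel), timepoint=t)
                if not np.array_equal(fr.triangles, meshes[t].triangles):
                    raise ValidationError(
                        f"hour {t}: substep frame {rel} connectivity differs from hourly mesh")
                frames.append(fr.vertices)
            substeps.append(frames)

    stages = {int(k): v for k, v in manifest.get("stages", {}).items()}
    return Morphomovie(
        hourly_meshes=meshes,
        substeps=substeps,
        minutes_per_substep=int(manifest.get("minutes_per_substep", 10)),
        stage_labels=stages,
    )


def save_morphomovie(movie: Morphomovie, out_dir: str,
                     manifest_name: str = "morphomovie.json") -> str:
    """Write all mesh/substep files plus the manifest; returns manifest path."""
    os.makedirs(out_dir, exist_ok=True)
    mesh_rel = []
    for mesh in movie.hourly_meshes:
        rel = f"mesh_{mesh.timepoint:03d}.off"
        write_mesh_file(os.path.join(out_dir, rel), mesh.vertices, mesh.triangles)
        mesh_rel.append(rel)
    manifest = {
        "meshes": mesh_rel,
        "minutes_per_substep": movie.minutes_per_substep,
    }
    if movie.substeps is not None:
        sub_rel = []
        for t, frames in enumerate(movie.substeps):
            rels = []
            for k, fr in enumerate(frames):
                rel = f"sub_{t:03d}_{k + 1:02d}.off"
                write_mesh_file(os.path.join(out_dir, rel),
                                np.asarray(fr, float), movie.hourly_meshes[t].triangles)
                rels.append(rel)
            sub_rel.append(rels)
        manifest["substeps"] = sub_rel
    if movie.stage_labels:
        manifest["stages"] = {str(k): v for k, v in sorted(movie.stage_labels.items())}
    path = os.path.join(out_dir, manifest_name)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=1)
    return path
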