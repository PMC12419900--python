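"""Volumetric mass properties of segmented body models.

A body is represented as a set of closed, consistently oriented triangle
meshes (segments), each with its own density, plus two anatomical landmarks:
the acetabulum (hip socket) and the glenoid (shoulder socket).  Volume and
centre of mass of each segment are obtained by signed-tetrahedron summation
over the faces (divergence theorem); the whole-body centre of mass is the
mass-weighted mean of the segment centres.

The non-dimensional *relative centre of mass* is the anteroposterior
displacement of the whole-body centre of mass from the acetabulum, divided
by the glenoacetabular distance (both measured as projections onto the
anteroposterior axis): 0 at the acetabulum, 1 at the glenoid.
"""

from __future__ import annotations

import json
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import trimesh

__all__ = [
    "SegmentMesh",
    "BodyModel",
    "MassProperties",
    "MeshError",
    "segment_mass_properties",
    "body_mass_properties",
    "relative_com",
    "load_segment_mesh",
    "load_body",
    "body_row",
]


class MeshError(ValueError):
    """Raised for open, degenerate or inconsistently oriented meshes."""


@dataclass
class SegmentMesh:
    """One closed triangle mesh with a homogeneous density.

    Parameters
    ----------
    name : str
        Segment label (e.g. ``"torso"``, ``"head"``).
    vertices : (n, 3) array
        Vertex coordinates, in consistent length units.
    faces : (m, 3) int array
        Triangles as vertex-index triples with consistent outward winding.
    density : float
        Mass per unit volume; defaults to 1.0 when not supplied.
    """

    name: str
    vertices: np.ndarray
    faces: np.ndarray
    density: float = 1.0

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, dtype=float)
        self.faces = np.asarray(self.faces, dtype=np.int64)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 3:
            raise MeshError(f"segment {self.name!r}: vertices must be (n, 3)")
        if self.faces.ndim != 2 or self.faces.shape[1] != 3:
            raise MeshError(f"segment {self.name!r}: faces must be (m, 3) triangles")
        if self.faces.size and self.faces.max() >= len(self.vertices):
            raise MeshError(f"segment {self.name!r}: face index out of range")
        if self.density <= 0:
            raise MeshError(f"segment {self.name!r}: density must be > 0")


@dataclass
class BodyModel:
    """A segmented body with acetabulum/glenoid landmarks.

    ``ap_axis`` is the anteroposterior unit vector (positive anterior); the
    glenoid must lie anterior to the acetabulum along it.
    """

    segments: list[SegmentMesh]
    acetabulum: np.ndarray
    glenoid: np.ndarray
    ap_axis: np.ndarray = field(default_factory=lambda: np.array([1.0, 0.0, 0.0]))
    name: str = "body"

    def __post_init__(self) -> None:
        if not self.segments:
            raise ValueError("body must contain at least one segment")
        self.acetabulum = np.asarray(self.acetabulum, dtype=float)
        self.glenoid = np.asarray(self.glenoid, dtype=float)
        axis = np.asarray(self.ap_axis, dtype=float)
        norm = np.linalg.norm(axis)
        if norm == 0:
            raise ValueError("ap_axis must be a non-zero vector")
        self.ap_axis = axis / norm
        ga = float(np.dot(self.glenoid - self.acetabulum, self.ap_axis))
        if ga <= 0:
            raise ValueError(
                "glenoacetabular anteroposterior projection must be strictly "
                f"positive (got {ga:g}); check landmark order and ap_axis"
            )


@dataclass(frozen=True)
class MassProperties:
    mass: float
    volume: float
    com: np.ndarray


def _check_closed_oriented(segment: SegmentMesh) -> None:
    """Verify every edge is shared by exactly two faces, once per direction.

    A consistently oriented closed 2-manifold traverses each undirected edge
    exactly twice, in opposite directions.  A boundary edge (seen once) means
    the mesh is open; an edge seen twice in the same direction means mixed
    winding, which is reported rather than silently repaired.
    """
    directed = Counter()
    for a, b, c in segment.faces:
        for u, v in ((a, b), (b, c), (c, a)):
            directed[(int(u), int(v))] += 1
    for (u, v), cnt in directed.items():
        if cnt > 1:
            raise MeshError(
                f"segment {segment.name!r}: edge ({u}, {v}) traversed {cnt} "
                "times in the same direction (non-manifold or mixed winding)"
            )
        if directed.get((v, u), 0) != 1:
            raise MeshError(
                f"segment {segment.name!r}: boundary edge ({u}, {v}) — mesh is open"
            )


def _signed_volume_moment(vertices: np.ndarray, faces: np.ndarray) -> tuple[float, np.ndarray]:
    """Signed volume and first moment by tetrahedron decomposition.

    Each face (p0, p1, p2) together with the origin forms a tetrahedron of
    signed volume det(p0, p1, p2)/6 and centroid (p0+p1+p2)/4; summing gives
    the enclosed volume and volume-weighted first moment, independent of the
    choice of origin for a closed surface.
    """
    p0 = vertices[faces[:, 0]]
    p1 = vertices[faces[:, 1]]
    p2 = vertices[faces[:, 2]]
    vols = np.einsum("ij,ij->i", p0, np.cross(p1, p2)) / 6.0
    centroids = (p0 + p1 + p2) / 4.0
    return float(vols.sum()), vols @ centroids


def segment_mass_properties(segment: SegmentMesh) -> MassProperties:
    """Mass, volume and centre of mass of a single closed segment.

    The face winding sign convention is normalized: if the net signed volume
    is negative the whole mesh is treated as inward-wound and flipped once.
    Mixed winding within a mesh is an error.
    """
    _check_closed_oriented(segment)
    volume, moment = _signed_volume_moment(segment.vertices, segment.faces)
    if volume < 0:
        volume, moment = -volume, -moment
    scale = float(np.abs(segment.vertices).max()) or 1.0
    if volume <= 1e-12 * scale**3:
        raise MeshError(f"segment {segment.name!r}: zero net volume after orientation repair")
    com = moment / volume
    return MassProperties(mass=segment.density * volume, volume=volume, com=com)


def body_mass_properties(body: BodyModel) -> MassProperties:
    """Whole-body mass and centre of mass from per-segment properties."""
    props = [segment_mass_properties(s) for s in body.segments]
    mass = sum(p.mass for p in props)
    volume = sum(p.volume for p in props)
    if mass <= 0:
        raise ValueError("total body mass is zero")
    com = sum(p.mass * p.com for p in props) / mass
    return MassProperties(mass=mass, volume=volume, com=com)


def relative_com(body: BodyModel) -> float:
    """Relative centre of mass: AP displacement from the acetabulum over
    glenoacetabular distance.

    Both displacements are projections onto the stored anteroposterior axis,
    so dorsoventral and mediolateral offsets do not contribute.  The value is
    0 at the acetabulum and 1 at the glenoid; values outside [0, 1] are
    legitimate for extreme mass distributions and are returned unaltered.
    """
    props = body_mass_properties(body)
    ap = body.ap_axis
    num = float(np.dot(props.com - body.acetabulum, ap))
    den = float(np.dot(body.glenoid - body.acetabulum, ap))
    return num / den


# ---------------------------------------------------------------------------
# I/O


def load_segment_mesh(path: str | Path, name: str | None = None, density: float = 1.0) -> SegmentMesh:
    """Read one OBJ or PLY mesh as a segment; quads are triangulated on read."""
    mesh = trimesh.load_mesh(str(path), process=False)
    return SegmentMesh(
        name=name or Path(path).stem,
        vertices=np.asarray(mesh.vertices, dtype=float),
        faces=np.asarray(mesh.faces, dtype=np.int64),
        density=density,
    )


def load_body(mesh_dir: str | Path, sidecar: str | Path) -> BodyModel:
    """Assemble a BodyModel from a directory of meshes plus a JSON/YAML sidecar.

    The sidecar supplies landmarks and per-segment densities keyed by segment
    (file stem) name::

        {"acetabulum": [x, y, z], "glenoid": [x, y, z],
         "ap_axis": [1, 0, 0],
         "densities": {"torso": 1.0, "lungs": 0.3}}
    """
    sidecar = Path(sidecar)
    text = sidecar.read_text()
    if sidecar.suffix in (".yaml", ".yml"):
        import yaml

        meta = yaml.safe_load(text)
    else:
        meta = json.loads(text)
    densities = meta.get("densities", {})
    mesh_dir = Path(mesh_dir)
    segments = []
    for path in sorted(list(mesh_dir.glob("*.obj")) + list(mesh_dir.glob("*.ply"))):
        segments.append(load_segment_mesh(path, density=float(densities.get(path.stem, 1.0))))
    if not segments:
        raise FileNotFoundError(f"no OBJ/PLY meshes found in {mesh_dir}")
    return BodyModel(
        segments=segments,
        acetabulum=np.asarray(meta["acetabulum"], dtype=float),
        glenoid=np.asarray(meta["glenoid"], dtype=float),
        ap_axis=np.asarray(meta.get("ap_axis", [1.0, 0.0, 0.0]), dtype=float),
        name=meta.get("taxon", mesh_dir.stem),
    )


def body_row(body: BodyModel) -> dict:
    """One output record per body: taxon, mass, com coordinates, relative CoM."""
    props = body_mass_properties(body)
    return {
        "taxon": body.name,
        "mass": props.mass,
        "com_x": props.com[0],
        "com_y": props.com[1],
        "com_z": props.com[2],
        "relative_com": relative_com(body),
    }
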