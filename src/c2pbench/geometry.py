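"""Geometry primitives shared by the whole benchmark.

The benchmark aligns a *complete* organ surface cloud ``X`` (M points, from a
preoperative model) with a *partial* cloud ``Y`` (N points, N << M, emulating an
intraoperative reconstruction) under an unknown rigid transform.  This module
provides the point-cloud / mesh / rigid-transform containers, PLY/OBJ I/O,
area-weighted surface sampling, normal estimation, the isotropic [-1, 1]
normalization used throughout, and farthest point sampling.

Frames
------
Clouds carry a ``frame`` tag: ``"metric_mm"`` (millimetres, the scale at which
anatomical magnitudes such as deformation amplitude are specified) or
``"normalized"`` (organ scaled into the [-1, 1] cube).  A
:class:`NormalizationMap` converts coordinates and magnitudes both ways.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import trimesh
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

__all__ = [
    "PointCloud",
    "TriangleMesh",
    "RigidTransform",
    "NormalizationMap",
    "GeometryError",
    "FormatError",
    "load_mesh",
    "save_mesh",
    "load_cloud",
    "save_cloud",
    "sample_surface",
    "sample_surface_points",
    "estimate_normals",
    "normalize_isotropic",
    "normalize_with_reference",
    "apply_rigid",
    "farthest_point_sampling",
]

FRAME_METRIC = "metric_mm"
FRAME_NORMALIZED = "normalized"


class GeometryError(ValueError):
    """Degenerate or invalid geometric input."""


class FormatError(ValueError):
    """Unreadable or malformed geometry file."""


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PointCloud:
    """Ordered set of 3-D points with optional unit normals.

    Parameters
    ----------
    points : (N, 3) float array
        Coordinates, finite.
    normals : (N, 3) float array, optional
        Per-point unit outward normals.
    frame : str
        ``"metric_mm"`` or ``"normalized"``.
    """

    points: np.ndarray
    normals: np.ndarray | None = None
    frame: str = FRAME_METRIC

    def __post_init__(self) -> None:
        pts = np.ascontiguousarray(np.asarray(self.points, dtype=np.float64))
        if pts.ndim != 2 or pts.shape[1] != 3:
            raise GeometryError(f"points must be (N, 3), got {pts.shape}")
        if not np.isfinite(pts).all():
            raise GeometryError("points contain non-finite coordinates")
        object.__setattr__(self, "points", pts)
        if self.normals is not None:
            nrm = np.ascontiguousarray(np.asarray(self.normals, dtype=np.float64))
            if nrm.shape != pts.shape:
                raise GeometryError(
                    f"normals shape {nrm.shape} does not match points {pts.shape}"
                )
            lengths = np.linalg.norm(nrm, axis=1)
            if not np.allclose(lengths, 1.0, atol=1e-6):
                raise GeometryError("normals must be unit length (within 1e-6)")
            object.__setattr__(self, "normals", nrm)

    def __len__(self) -> int:
        return self.points.shape[0]

    @property
    def has_normals(self) -> bool:
        return self.normals is not None

    def select(self, indices: np.ndarray) -> "PointCloud":
        """Subset cloud by (ordered) point indices."""
        idx = np.asarray(indices, dtype=np.intp)
        return PointCloud(
            self.points[idx],
            None if self.normals is None else self.normals[idx],
            self.frame,
        )

    def with_frame(self, frame: str) -> "PointCloud":
        return replace(self, frame=frame)


@dataclass(frozen=True)
class TriangleMesh:
    """Triangle surface mesh: ``vertices`` (V, 3) in mm and ``faces`` (F, 3)."""

    vertices: np.ndarray
    faces: np.ndarray

    def __post_init__(self) -> None:
        v = np.ascontiguousarray(np.asarray(self.vertices, dtype=np.float64))
        f = np.ascontiguousarray(np.asarray(self.faces, dtype=np.int64))
        if v.ndim != 2 or v.shape[1] != 3:
            raise GeometryError(f"vertices must be (V, 3), got {v.shape}")
        if not np.isfinite(v).all():
            raise GeometryError("vertices contain non-finite coordinates")
        if f.ndim != 2 or f.shape[1] != 3:
            raise GeometryError(f"faces must be (F, 3), got {f.shape}")
        if f.size and (f.min() < 0 or f.max() >= len(v)):
            raise GeometryError("face index out of range")
        degenerate = (f[:, 0] == f[:, 1]) | (f[:, 1] == f[:, 2]) | (f[:, 0] == f[:, 2])
        if degenerate.any():
            raise GeometryError(f"{int(degenerate.sum())} degenerate faces present")
        object.__setattr__(self, "vertices", v)
        object.__setattr__(self, "faces", f)

    @property
    def n_vertices(self) -> int:
        return self.vertices.shape[0]

    @property
    def n_faces(self) -> int:
        return self.faces.shape[0]

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def bounds(self) -> np.ndarray:
        """(2, 3) array of per-axis min / max."""
        return np.vstack([self.vertices.min(axis=0), self.vertices.max(axis=0)])


def clean_mesh(vertices: np.ndarray, faces: np.ndarray) -> TriangleMesh:
    """Drop degenerate faces and unreferenced vertices, preserving order."""
    faces = np.asarray(faces, dtype=np.int64)
    keep = ~(
        (faces[:, 0] == faces[:, 1])
        | (faces[:, 1] == faces[:, 2])
        | (faces[:, 0] == faces[:, 2])
    )
    faces = faces[keep]
    used = np.zeros(len(vertices), dtype=bool)
    used[faces.ravel()] = True
    remap = np.cumsum(used) - 1
    return TriangleMesh(np.asarray(vertices)[used], remap[faces])


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion p -> R p + t, R in SO(3)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.ascontiguousarray(np.asarray(self.rotation, dtype=np.float64))
        t = np.ascontiguousarray(np.asarray(self.translation, dtype=np.float64)).reshape(3)
        if R.shape != (3, 3):
            raise GeometryError(f"rotation must be 3x3, got {R.shape}")
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise GeometryError("rotation is not orthogonal within 1e-9")
        if not np.isclose(np.linalg.det(R), 1.0, atol=1e-9):
            raise GeometryError("rotation determinant is not +1 within 1e-9")
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_matrix(cls, matrix: np.ndarray) -> "RigidTransform":
        M = np.asarray(matrix, dtype=np.float64)
        if M.shape != (4, 4):
            raise GeometryError(f"homogeneous matrix must be 4x4, got {M.shape}")
        return cls(M[:3, :3], M[:3, 3])

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M

    def apply(self, points: np.ndarray) -> np.ndarray:
        return np.asarray(points) @ self.rotation.T + self.translation

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """self o other: apply ``other`` first, then ``self``."""
        return RigidTransform(
            self.rotation @ other.rotation,
            self.rotation @ other.translation + self.translation,
        )

    def __matmul__(self, other: "RigidTransform") -> "RigidTransform":
        return self.compose(other)

    def inverse(self) -> "RigidTransform":
        Rt = self.rotation.T
        return RigidTransform(Rt, -Rt @ self.translation)

    def rotation_angle_deg(self) -> float:
        """Geodesic rotation angle in degrees."""
        return float(
            np.degrees(np.linalg.norm(Rotation.from_matrix(self.rotation).as_rotvec()))
        )

    def to_json(self) -> str:
        return json.dumps({"matrix": self.as_matrix().tolist()})

    @classmethod
    def from_json(cls, text: str) -> "RigidTransform":
        return cls.from_matrix(np.array(json.loads(text)["matrix"]))


def invert(transform: RigidTransform) -> RigidTransform:
    """Inverse rigid motion (functional alias of :meth:`RigidTransform.inverse`)."""
    return transform.inverse()


@dataclass(frozen=True)
class NormalizationMap:
    """Isotropic mm <-> normalized-unit map: x_norm = (x_mm - offset) / scale."""

    scale: float
    offset: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale) or self.scale <= 0:
            raise GeometryError("scale must be a positive finite number")
        object.__setattr__(
            self, "offset", np.asarray(self.offset, dtype=np.float64).reshape(3)
        )

    def forward(self, points_mm: np.ndarray) -> np.ndarray:
        return (np.asarray(points_mm) - self.offset) / self.scale

    def inverse(self, points_norm: np.ndarray) -> np.ndarray:
        return np.asarray(points_norm) * self.scale + self.offset

    def magnitude_to_normalized(self, value_mm: float) -> float:
        """Convert a length in mm to normalized units."""
        return value_mm / self.scale

    def magnitude_to_mm(self, value_norm: float) -> float:
        return value_norm * self.scale

    def apply_to_cloud(self, cloud: PointCloud) -> PointCloud:
        return PointCloud(self.forward(cloud.points), cloud.normals, FRAME_NORMALIZED)

    def to_dict(self) -> dict:
        return {"scale": float(self.scale), "offset": self.offset.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "NormalizationMap":
        return cls(float(d["scale"]), np.asarray(d["offset"], dtype=np.float64))


# ---------------------------------------------------------------------------
# file I/O
# ---------------------------------------------------------------------------


def load_mesh(path: str | Path) -> TriangleMesh:
    """Load a PLY or OBJ triangle mesh, preserving vertex order from the file."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"mesh file does not exist: {path}")
    try:
        loaded = trimesh.load(path, process=False, force="mesh")
    except Exception as exc:  # pragma: no cover - error text varies by backend
        raise FormatError(f"cannot parse mesh file {path}: {exc}") from exc
    if not isinstance(loaded, trimesh.Trimesh) or len(loaded.faces) == 0:
        raise FormatError(f"file {path} does not contain a triangle mesh")
    try:
        return TriangleMesh(np.asarray(loaded.vertices), np.asarray(loaded.faces))
    except GeometryError:
        return clean_mesh(np.asarray(loaded.vertices), np.asarray(loaded.faces))


_PLY_MESH_HEADER = """ply
format binary_little_endian 1.0
element vertex {v}
property double x
property double y
property double z
element face {f}
property list uchar int vertex_indices
end_header
"""


def save_mesh(mesh: TriangleMesh, path: str | Path) -> None:
    """Write a mesh as binary little-endian PLY at full double precision."""
    path = Path(path)
    with open(path, "wb") as fh:
        fh.write(
            _PLY_MESH_HEADER.format(v=mesh.n_vertices, f=mesh.n_faces).encode("ascii")
        )
        fh.write(np.ascontiguousarray(mesh.vertices, dtype="<f8").tobytes())
        faces = np.empty(
            mesh.n_faces, dtype=[("n", "u1"), ("idx", "<i4", (3,))]
        )
        faces["n"] = 3
        faces["idx"] = mesh.faces
        fh.write(faces.tobytes())


_PLY_CLOUD_HEADER = """ply
format binary_little_endian 1.0
element vertex {n}
property double x
property double y
property double z
{normal_props}end_header
"""


def save_cloud(cloud: PointCloud, path: str | Path) -> None:
    """Write a point cloud as binary little-endian PLY (x,y,z[,nx,ny,nz])."""
    path = Path(path)
    normal_props = (
        "property double nx\nproperty double ny\nproperty double nz\n"
        if cloud.has_normals
        else ""
    )
    header = _PLY_CLOUD_HEADER.format(n=len(cloud), normal_props=normal_props)
    data = (
        np.hstack([cloud.points, cloud.normals])
        if cloud.has_normals
        else cloud.points
    )
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(np.ascontiguousarray(data, dtype="<f8").tobytes())


def load_cloud(path: str | Path, frame: str = FRAME_METRIC) -> PointCloud:
    """Read a PLY point cloud (ASCII or binary little-endian, x,y,z[,nx,ny,nz])."""
    path = Path(path)
    if not path.exists():
        raise FormatError(f"cloud file does not exist: {path}")
    with open(path, "rb") as fh:
        raw = fh.read()
    end = raw.find(b"end_header\n")
    if not raw.startswith(b"ply") or end < 0:
        raise FormatError(f"{path} is not a PLY file")
    header = raw[: end + len(b"end_header\n")].decode("ascii", errors="replace")
    body = raw[end + len(b"end_header\n") :]
    fmt = None
    n = None
    props: list[tuple[str, str]] = []
    in_vertex = False
    for line in header.splitlines():
        tok = line.split()
        if not tok:
            continue
        if tok[0] == "format":
            fmt = tok[1]
        elif tok[0] == "element":
            in_vertex = tok[1] == "vertex"
            if in_vertex:
                n = int(tok[2])
        elif tok[0] == "property" and in_vertex:
            props.append((tok[1], tok[2]))
    if fmt not in ("ascii", "binary_little_endian") or n is None:
        raise FormatError(f"unsupported PLY dialect in {path} (format element: {fmt})")
    names = [p[1] for p in props]
    for required in ("x", "y", "z"):
        if required not in names:
            raise FormatError(f"{path}: vertex element lacks property '{required}'")
    np_types = {"float": "<f4", "float32": "<f4", "double": "<f8", "float64": "<f8"}
    try:
        dtype = np.dtype([(name, np_types[typ]) for typ, name in props])
    except KeyError as exc:
        raise FormatError(f"{path}: unsupported property type {exc}") from exc
    if fmt == "ascii":
        table = np.loadtxt(body.decode("ascii").splitlines(), ndmin=2)
        if table.shape != (n, len(props)):
            raise FormatError(f"{path}: expected {n}x{len(props)} ASCII values")
        cols = {name: table[:, i] for i, name in enumerate(names)}
    else:
        expected = n * dtype.itemsize
        if len(body) < expected:
            raise FormatError(f"{path}: truncated binary body")
        rec = np.frombuffer(body[:expected], dtype=dtype)
        cols = {name: rec[name].astype(np.float64) for name in names}
    points = np.column_stack([cols["x"], cols["y"], cols["z"]])
    normals = None
    if all(k in cols for k in ("nx", "ny", "nz")):
        normals = np.column_stack([cols["nx"], cols["ny"], cols["nz"]])
    return PointCloud(points, normals, frame)


# ---------------------------------------------------------------------------
# sampling / normals
# ---------------------------------------------------------------------------


def sample_surface(
    mesh: TriangleMesh, n: int, seed: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Area-weighted surface sampling with barycentric bookkeeping.

    Returns ``(points, face_indices, barycentric)`` so the identical sample
    locations can be re-evaluated on a deformed copy of the same mesh (same
    connectivity), giving index-exact correspondences across deformation.
    """
    if n < 4:
        raise ValueError(f"need at least 4 sample points, got {n}")
    if mesh.n_faces == 0:
        raise GeometryError("cannot sample an empty mesh")
    rng = np.random.default_rng(seed)
    tri = mesh.vertices[mesh.faces]  # (F, 3, 3)
    cross = np.cross(tri[:, 1] - tri[:, 0], tri[:, 2] - tri[:, 0])
    areas = 0.5 * np.linalg.norm(cross, axis=1)
    total = areas.sum()
    if total <= 0:
        raise GeometryError("mesh has zero surface area")
    face_idx = rng.choice(mesh.n_faces, size=n, p=areas / total)
    # uniform barycentric via the square-root trick
    r1 = np.sqrt(rng.random(n))
    r2 = rng.random(n)
    bary = np.column_stack([1.0 - r1, r1 * (1.0 - r2), r1 * r2])
    points = np.einsum("nk,nkd->nd", bary, tri[face_idx])
    return points, face_idx, bary


def sample_surface_points(mesh: TriangleMesh, n: int, seed: int) -> PointCloud:
    """Area-weighted random surface point cloud (deterministic per seed)."""
    points, _, _ = sample_surface(mesh, n, seed)
    return PointCloud(points, frame=FRAME_METRIC)


def barycentric_points(
    mesh: TriangleMesh, face_idx: np.ndarray, bary: np.ndarray
) -> np.ndarray:
    """Re-evaluate barycentric samples on (a deformed copy of) ``mesh``."""
    tri = mesh.vertices[mesh.faces[face_idx]]
    return np.einsum("nk,nkd->nd", bary, tri)


def estimate_normals(
    cloud: PointCloud, k: int = 16, orient_outward: bool = True
) -> PointCloud:
    """Per-point unit normals by local principal-axis fit of k nearest neighbours.

    Orientation: normals are flipped to point away from the cloud centroid
    (reasonable for convex-ish organ surfaces); pass ``orient_outward=False``
    to keep the raw PCA sign.
    """
    if k < 3:
        raise ValueError(f"k must be >= 3, got {k}")
    pts = cloud.points
    if len(pts) < k:
        raise ValueError(f"cloud has {len(pts)} points, fewer than k={k}")
    tree = cKDTree(pts)
    _, idx = tree.query(pts, k=k)
    nbrs = pts[idx]  # (N, k, 3)
    centered = nbrs - nbrs.mean(axis=1, keepdims=True)
    cov = np.einsum("nki,nkj->nij", centered, centered)
    _, vecs = np.linalg.eigh(cov)
    normals = vecs[:, :, 0]  # smallest-eigenvalue direction
    if orient_outward:
        outward = pts - pts.mean(axis=0)
        flip = np.einsum("ni,ni->n", normals, outward) < 0
        normals[flip] *= -1.0
    normals /= np.linalg.norm(normals, axis=1, keepdims=True)
    return PointCloud(pts, normals, cloud.frame)


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_isotropic(cloud: PointCloud) -> tuple[PointCloud, NormalizationMap]:
    """Center at the bounding-box center and scale by half the largest extent.

    Every output coordinate lies in [-1, 1] and the widest axis spans exactly
    [-1, 1].  A single isotropic scale is used so rigid ground truth remains
    rigid in the normalized frame.
    """
    lo = cloud.points.min(axis=0)
    hi = cloud.points.max(axis=0)
    extent = hi - lo
    if extent.max() <= 0:
        raise GeometryError("cloud has zero extent on all axes")
    nmap = NormalizationMap(scale=float(extent.max() / 2.0), offset=(lo + hi) / 2.0)
    return nmap.apply_to_cloud(cloud), nmap


def normalize_with_reference(
    complete: PointCloud, partial: PointCloud
) -> tuple[PointCloud, PointCloud, NormalizationMap]:
    """Normalize both clouds with the map computed from the COMPLETE cloud only.

    Mirrors the preprocessing used for externally acquired pairs, where the
    complete preoperative cloud defines the min/max range; partial points
    outside the complete bounding box may land outside [-1, 1] (no clipping).
    """
    complete_n, nmap = normalize_isotropic(complete)
    return complete_n, nmap.apply_to_cloud(partial), nmap


def apply_rigid(cloud: PointCloud, transform: RigidTransform) -> PointCloud:
    """Apply p -> R p + t to points; normals are rotated only."""
    normals = None
    if cloud.normals is not None:
        normals = cloud.normals @ transform.rotation.T
    return PointCloud(transform.apply(cloud.points), normals, cloud.frame)


# ---------------------------------------------------------------------------
# farthest point sampling
# ---------------------------------------------------------------------------


def farthest_point_sampling(points: np.ndarray, n: int, start: int = 0) -> np.ndarray:
    """Greedy max-min subsampling.

    The first index is ``start``; each subsequent index maximizes the distance
    to the already-selected set, with ties broken by lowest index.  Fully
    deterministic given ``start``.
    """
    pts = np.asarray(points, dtype=np.float64)
    m = len(pts)
    if n > m:
        raise ValueError(f"cannot select {n} points from {m}")
    if not (0 <= start < m):
        raise ValueError(f"start index {start} out of range for {m} points")
    if n <= 0:
        return np.empty(0, dtype=np.intp)
    selected = np.empty(n, dtype=np.intp)
    selected[0] = start
    dist = np.linalg.norm(pts - pts[start], axis=1)
    dist[start] = -1.0  # never reselect
    for i in range(1, n):
        nxt = int(np.argmax(dist))  # argmax takes the lowest index on ties
        selected[i] = nxt
        dist = np.minimum(dist, np.linalg.norm(pts - pts[nxt], axis=1))
        dist[nxt] = -1.0
    return selected
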