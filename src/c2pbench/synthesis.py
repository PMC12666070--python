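"""Synthetic complete-to-partial registration pairs with full ground truth.

One benchmark pair emulates a laparoscopic registration instance:

1. sample a complete surface cloud from a (phantom) liver mesh at rest;
2. pick one lobe at random and push it with an ARAP deformation (uniform
   displacement up to ``deform_max`` mm along x and z, emulating small
   intraoperative tissue shifts);
3. place a virtual endoscope and keep a contiguous visible patch of the
   deformed surface (``crop_ratio`` of all points, each passing the
   normal-to-camera angle test);
4. normalize both clouds into [-1, 1] with the *source* cloud's isotropic map;
5. rigidly perturb the partial target (rotation up to ``rot_max`` degrees
   about its centroid, translation up to ``trans_max`` mm) and add per
   coordinate Gaussian noise (``noise_sigma``, normalized units).

Every stage is driven by the single pair seed, so a pair regenerates
bit-identically; the ground-truth transform, index-exact correspondences,
per-point overlap labels and landmark pairs (chosen by farthest point
sampling from the cropped-out region, hence never part of the registration
input) are all retained.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .arap import arap_deform
from .geometry import (
    FRAME_NORMALIZED,
    GeometryError,
    NormalizationMap,
    PointCloud,
    RigidTransform,
    TriangleMesh,
    barycentric_points,
    estimate_normals,
    farthest_point_sampling,
    normalize_isotropic,
    sample_surface,
)

__all__ = [
    "GenerationConfig",
    "CameraSpec",
    "PairRecord",
    "DatasetManifest",
    "VisibilityError",
    "select_lobe_handles",
    "sample_camera",
    "visibility_crop",
    "sample_rigid_perturbation",
    "sample_deformation_displacement",
    "add_gaussian_noise",
    "select_landmarks",
    "generate_pair",
    "build_manifest",
    "generate_dataset",
    "save_pair",
    "load_pair",
    "pair_seed",
]


class VisibilityError(RuntimeError):
    """Too few camera-facing points to extract the requested patch."""


@dataclass(frozen=True)
class GenerationConfig:
    """Pair-generation parameters (defaults are the benchmark conditions).

    Magnitudes with physical meaning (``deform_max``, ``trans_max``) are in mm
    and are converted through the pair's normalization map where needed;
    ``noise_sigma`` is in normalized units since noise emulates reconstruction
    error at the network's input scale.
    """

    n_source_points: int = 3500
    crop_ratio: float = 0.15
    visibility_angle_max: float = 80.0
    deform_max: float = 25.0
    rot_max: float = 45.0
    trans_max: float = 50.0
    noise_sigma: float = 0.01
    n_landmarks: int = 20
    master_seed: int = 0
    handle_margin: float = 0.3
    normal_k: int = 16
    polar_range: tuple[float, float] = (15.0, 75.0)
    azimuth_range: tuple[float, float] = (0.0, 360.0)
    radius_factor: float = 2.5
    arap_iters: int = 10

    def __post_init__(self) -> None:
        if not 0 < self.crop_ratio < 1:
            raise ValueError(f"crop_ratio must be in (0, 1), got {self.crop_ratio}")
        if not 0 < self.visibility_angle_max < 90:
            raise ValueError("visibility_angle_max must be in (0, 90) degrees")
        for name in ("deform_max", "rot_max", "trans_max", "noise_sigma"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    def to_dict(self) -> dict:
        return {
            "n_source_points": self.n_source_points,
            "crop_ratio": self.crop_ratio,
            "visibility_angle_max": self.visibility_angle_max,
            "deform_max": self.deform_max,
            "rot_max": self.rot_max,
            "trans_max": self.trans_max,
            "noise_sigma": self.noise_sigma,
            "n_landmarks": self.n_landmarks,
            "master_seed": self.master_seed,
            "handle_margin": self.handle_margin,
            "normal_k": self.normal_k,
            "polar_range": list(self.polar_range),
            "azimuth_range": list(self.azimuth_range),
            "radius_factor": self.radius_factor,
            "arap_iters": self.arap_iters,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GenerationConfig":
        d = dict(d)
        for key in ("polar_range", "azimuth_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)


@dataclass(frozen=True)
class CameraSpec:
    """Virtual endoscope: a position (mm) looking toward the organ."""

    position: np.ndarray
    look_direction: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.position, dtype=np.float64).reshape(3)
        look = np.asarray(self.look_direction, dtype=np.float64).reshape(3)
        if not np.isclose(np.linalg.norm(look), 1.0, atol=1e-9):
            raise GeometryError("look_direction must be a unit vector")
        object.__setattr__(self, "position", pos)
        object.__setattr__(self, "look_direction", look)


@dataclass
class PairRecord:
    """One benchmark instance with full ground truth (normalized frame)."""

    source: PointCloud
    target: PointCloud
    gt_transform: RigidTransform
    correspondence: np.ndarray  # target index i -> source index correspondence[i]
    overlap_labels: np.ndarray  # per-source-point binary visibility flags
    landmarks_source: np.ndarray
    landmarks_target: np.ndarray
    norm_map: NormalizationMap
    seed: int
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.correspondence = np.asarray(self.correspondence, dtype=np.int64)
        self.overlap_labels = np.asarray(self.overlap_labels, dtype=np.uint8)
        if self.correspondence.max(initial=-1) >= len(self.source):
            raise GeometryError("correspondence index out of range")
        if int(self.overlap_labels.sum()) != len(self.target):
            raise GeometryError("overlap label sum must equal target size")


@dataclass
class DatasetManifest:
    """Split description: every pair's identity, seed and archive path."""

    split: str
    config: GenerationConfig
    entries: list[dict]  # {"source_id", "target_index", "seed", "path"}

    def to_json(self) -> str:
        return json.dumps(
            {
                "split": self.split,
                "config": self.config.to_dict(),
                "entries": self.entries,
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "DatasetManifest":
        d = json.loads(text)
        return cls(d["split"], GenerationConfig.from_dict(d["config"]), d["entries"])


# ---------------------------------------------------------------------------
# pipeline stages
# ---------------------------------------------------------------------------


def select_lobe_handles(
    mesh: TriangleMesh, lobe_choice: str, margin: float = 0.3
) -> tuple[np.ndarray, np.ndarray]:
    """Split the mesh through its centroid along the widest axis.

    ``handles`` are the vertices of the chosen half lying beyond ``margin`` of
    that half's extent; ``anchors`` are the symmetric set in the opposite half.
    """
    if lobe_choice not in ("left", "right"):
        raise ValueError(f"lobe_choice must be 'left' or 'right', got {lobe_choice!r}")
    v = mesh.vertices
    axis = int(np.argmax(v.max(axis=0) - v.min(axis=0)))
    coord = v[:, axis] - v[:, axis].mean()
    sign = 1.0 if lobe_choice == "right" else -1.0
    side = sign * coord  # positive on the chosen side
    half_extent = side.max()
    opp_extent = (-side).max()
    handles = np.flatnonzero(side > margin * half_extent)
    anchors = np.flatnonzero(-side > margin * opp_extent)
    if handles.size == 0 or anchors.size == 0:
        raise GeometryError("empty handle or anchor set (degenerate split)")
    return handles, anchors


def sample_deformation_displacement(seed: int, deform_max: float = 25.0) -> np.ndarray:
    """Seeded handle displacement: independent uniform on [-deform_max,
    +deform_max] mm along x and z, zero along y."""
    rng = np.random.default_rng(seed)
    dx, dz = rng.uniform(-deform_max, deform_max, size=2)
    return np.array([dx, 0.0, dz])


def sample_camera(
    mesh_bounds: np.ndarray,
    seed: int,
    polar_range: tuple[float, float] = (15.0, 75.0),
    azimuth_range: tuple[float, float] = (0.0, 360.0),
    radius_factor: float = 2.5,
) -> CameraSpec:
    """Seeded virtual-endoscope pose in spherical coordinates about the organ.

    Polar and azimuth ranges (degrees) bound the viewpoint to plausible
    intraoperative directions; radius is ``radius_factor`` times the organ's
    bounding-sphere radius.  The camera always looks at the bounds center.
    """
    lo, hi = np.asarray(mesh_bounds, dtype=np.float64)
    if not (0.0 <= polar_range[0] <= polar_range[1] <= 180.0):
        raise ValueError(f"polar_range must lie within [0, 180], got {polar_range}")
    if not (0.0 <= azimuth_range[0] <= azimuth_range[1] <= 360.0):
        raise ValueError(f"azimuth_range must lie within [0, 360], got {azimuth_range}")
    center = (lo + hi) / 2.0
    radius = radius_factor * float(np.linalg.norm(hi - lo) / 2.0)
    rng = np.random.default_rng(seed)
    polar = np.radians(rng.uniform(*polar_range))
    azimuth = np.radians(rng.uniform(*azimuth_range))
    offset = radius * np.array(
        [np.sin(polar) * np.cos(azimuth), np.sin(polar) * np.sin(azimuth), np.cos(polar)]
    )
    position = center + offset
    look = center - position
    return CameraSpec(position, look / np.linalg.norm(look))


def visibility_crop(
    cloud: PointCloud,
    camera: CameraSpec,
    crop_ratio: float,
    angle_max: float = 80.0,
) -> np.ndarray:
    """Indices of the contiguous visible patch seen by ``camera``.

    Candidates are points whose outward normal makes an angle below
    ``angle_max`` degrees with the direction to the camera; from these,
    ``round(crop_ratio * len(cloud))`` points are retained as a connected
    patch grown by Euclidean nearest-neighbour accretion from the candidate
    closest to the camera (one endoscopic view, not a scattered thinning).
    """
    if cloud.normals is None:
        raise GeometryError("visibility_crop requires point normals")
    if not 0 < crop_ratio < 1:
        raise ValueError(f"crop_ratio must be in (0, 1), got {crop_ratio}")
    n_keep = int(round(crop_ratio * len(cloud)))
    to_cam = camera.position - cloud.points
    to_cam /= np.linalg.norm(to_cam, axis=1, keepdims=True)
    cos_angle = np.einsum("ni,ni->n", cloud.normals, to_cam)
    candidates = np.flatnonzero(cos_angle > np.cos(np.radians(angle_max)))
    if candidates.size < n_keep or candidates.size == 0:
        raise VisibilityError(
            f"only {candidates.size} camera-facing points, need {n_keep}"
        )
    cand_pts = cloud.points[candidates]
    cam_dist = np.linalg.norm(cand_pts - camera.position, axis=1)
    patch = np.empty(n_keep, dtype=np.intp)
    patch[0] = int(np.argmin(cam_dist))
    dist = np.linalg.norm(cand_pts - cand_pts[patch[0]], axis=1)
    dist[patch[0]] = np.inf  # selected points never re-enter
    for i in range(1, n_keep):
        nxt = int(np.argmin(dist))
        patch[i] = nxt
        dist = np.minimum(dist, np.linalg.norm(cand_pts - cand_pts[nxt], axis=1))
        dist[patch[: i + 1]] = np.inf
    return candidates[patch]


def sample_rigid_perturbation(
    seed: int, rot_max: float = 45.0, trans_max: float = 50.0
) -> RigidTransform:
    """Seeded rigid perturbation: rotation with uniform axis and uniform angle
    on [0, rot_max] degrees; translation components independent uniform on
    [-trans_max, trans_max] (caller's units)."""
    if not 0 <= rot_max <= 180:
        raise ValueError(f"rot_max must be in [0, 180], got {rot_max}")
    if trans_max < 0:
        raise ValueError(f"trans_max must be >= 0, got {trans_max}")
    rng = np.random.default_rng(seed)
    axis = rng.normal(size=3)
    axis /= np.linalg.norm(axis)
    angle = np.radians(rng.uniform(0.0, rot_max))
    from scipy.spatial.transform import Rotation

    R = Rotation.from_rotvec(axis * angle).as_matrix()
    t = rng.uniform(-trans_max, trans_max, size=3)
    return RigidTransform(R, t)


def _about_point(transform: RigidTransform, center: np.ndarray) -> RigidTransform:
    """Re-express a rotation-about-``center`` + translation as a RigidTransform."""
    c = np.asarray(center, dtype=np.float64)
    R = transform.rotation
    return RigidTransform(R, c - R @ c + transform.translation)


def add_gaussian_noise(cloud: PointCloud, sigma: float, seed: int) -> PointCloud:
    """Independent zero-mean Gaussian perturbation of every coordinate."""
    if sigma < 0:
        raise ValueError(f"sigma must be >= 0, got {sigma}")
    if sigma == 0:
        return cloud
    rng = np.random.default_rng(seed)
    noisy = cloud.points + rng.normal(0.0, sigma, size=cloud.points.shape)
    return PointCloud(noisy, cloud.normals, cloud.frame)


def select_landmarks(
    source_points: np.ndarray,
    deformed_points: np.ndarray,
    visible_indices: np.ndarray,
    n: int,
    start: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Landmark pairs from the cropped-out region, spread by FPS.

    Returns ``(landmarks_source, landmarks_deformed, indices)``; the indices
    are disjoint from ``visible_indices`` by construction, so landmarks are
    never part of the registration input.
    """
    source_points = np.asarray(source_points)
    mask = np.ones(len(source_points), dtype=bool)
    mask[np.asarray(visible_indices, dtype=np.intp)] = False
    hidden = np.flatnonzero(mask)
    if hidden.size < n:
        raise ValueError(f"only {hidden.size} cropped-out points, need {n} landmarks")
    rel = farthest_point_sampling(source_points[hidden], n, start)
    idx = hidden[rel]
    return source_points[idx], np.asarray(deformed_points)[idx], idx


# ---------------------------------------------------------------------------
# full pair pipeline
# ---------------------------------------------------------------------------


def _stage_seeds(seed: int, n: int = 6) -> list[int]:
    """Deterministic per-stage substreams of the single pair seed."""
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s) for s in state]


def generate_pair(
    mesh: TriangleMesh, config: GenerationConfig, seed: int
) -> PairRecord:
    """Run the full generation pipeline for one pair (see module docstring)."""
    s_sample, s_lobe, s_disp, s_cam, s_pert, s_noise = _stage_seeds(seed)

    # (1) complete source cloud at rest, with barycentric bookkeeping
    src_mm, face_idx, bary = sample_surface(mesh, config.n_source_points, s_sample)

    # (2) seeded lobe deformation
    lobe = "right" if np.random.default_rng(s_lobe).random() < 0.5 else "left"
    displacement = sample_deformation_displacement(s_disp, config.deform_max)
    if np.any(displacement != 0.0):
        handles, anchors = select_lobe_handles(mesh, lobe, config.handle_margin)
        deformed_mesh = arap_deform(
            mesh, handles, anchors, displacement, n_iters=config.arap_iters
        )
    else:
        deformed_mesh = mesh
    deformed_mm = barycentric_points(deformed_mesh, face_idx, bary)

    # (3) virtual-endoscope visibility crop of the deformed surface
    deformed_cloud = estimate_normals(PointCloud(deformed_mm), k=config.normal_k)
    visible = None
    camera = None
    for attempt in range(10):
        camera = sample_camera(
            deformed_mesh.bounds(),
            s_cam + attempt,
            config.polar_range,
            config.azimuth_range,
            config.radius_factor,
        )
        try:
            visible = visibility_crop(
                deformed_cloud, camera, config.crop_ratio, config.visibility_angle_max
            )
            break
        except VisibilityError:
            continue
    if visible is None:
        raise VisibilityError(
            f"no viable camera after 10 attempts (pair seed {seed})"
        )

    # (4) ground-truth overlap labels and index-exact correspondence
    overlap = np.zeros(config.n_source_points, dtype=np.uint8)
    overlap[visible] = 1
    correspondence = np.asarray(visible, dtype=np.int64)

    # (5) landmarks from the cropped-out region
    lm_src_mm, lm_tgt_mm, lm_idx = select_landmarks(
        src_mm, deformed_mm, visible, config.n_landmarks
    )

    # (6) normalize everything with the SOURCE cloud's isotropic map
    source_norm, nmap = normalize_isotropic(PointCloud(src_mm))
    source_norm = estimate_normals(source_norm, k=config.normal_k)
    target_pts = nmap.forward(deformed_mm[visible])
    target_normals = deformed_cloud.normals[visible]
    lm_src = nmap.forward(lm_src_mm)
    lm_tgt = nmap.forward(lm_tgt_mm)

    # (7) seeded rigid perturbation (mm bounds -> normalized units), applied
    # about the target centroid so the translation bound is meaningful
    pert = sample_rigid_perturbation(
        s_pert, config.rot_max, nmap.magnitude_to_normalized(config.trans_max)
    )
    gt = _about_point(pert, target_pts.mean(axis=0))
    target_pts = gt.apply(target_pts)
    target_normals = target_normals @ gt.rotation.T
    lm_tgt = gt.apply(lm_tgt)

    # (8) reconstruction noise on the target only
    target = add_gaussian_noise(
        PointCloud(target_pts, target_normals, FRAME_NORMALIZED),
        config.noise_sigma,
        s_noise,
    )

    return PairRecord(
        source=source_norm,
        target=target,
        gt_transform=gt,
        correspondence=correspondence,
        overlap_labels=overlap,
        landmarks_source=lm_src,
        landmarks_target=lm_tgt,
        norm_map=nmap,
        seed=int(seed),
        provenance={
            "lobe": lobe,
            "displacement_mm": displacement.tolist(),
            "camera_position": camera.position.tolist(),
            "camera_look": camera.look_direction.tolist(),
            "crop_ratio": config.crop_ratio,
            "landmark_indices": lm_idx.tolist(),
        },
    )


# ---------------------------------------------------------------------------
# dataset assembly and archives
# ---------------------------------------------------------------------------


def pair_seed(master_seed: int, source_id: str | int, target_index: int) -> int:
    """Stable 63-bit per-pair seed hashed from (master seed, source, index)."""
    digest = hashlib.blake2b(
        f"{master_seed}:{source_id}:{target_index}".encode(), digest_size=8
    ).digest()
    return int.from_bytes(digest, "little") & ((1 << 63) - 1)


def build_manifest(
    split: str,
    source_ids: list,
    targets_per_source: int,
    config: GenerationConfig,
) -> DatasetManifest:
    """Enumerate a split's pairs (seeds and paths) without generating geometry."""
    if targets_per_source < 1:
        raise ValueError("targets_per_source must be >= 1")
    if not source_ids:
        raise ValueError("need at least one source mesh")
    entries = [
        {
            "source_id": str(sid),
            "target_index": t,
            "seed": pair_seed(config.master_seed, sid, t),
            "path": f"{sid}/pair_{t:05d}.npz",
        }
        for sid in source_ids
        for t in range(targets_per_source)
    ]
    return DatasetManifest(split, config, entries)


def save_pair(record: PairRecord, path: str | Path) -> None:
    """Write a pair archive (compressed arrays + JSON provenance sidecar)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    np.savez_compressed(
        path,
        source=record.source.points,
        source_normals=record.source.normals
        if record.source.normals is not None
        else np.empty((0, 3)),
        target=record.target.points,
        target_normals=record.target.normals
        if record.target.normals is not None
        else np.empty((0, 3)),
        gt_matrix=record.gt_transform.as_matrix(),
        correspondence=record.correspondence,
        overlap_labels=record.overlap_labels,
        landmarks_source=record.landmarks_source,
        landmarks_target=record.landmarks_target,
        norm_scale=np.array([record.norm_map.scale]),
        norm_offset=record.norm_map.offset,
    )
    sidecar = {"seed": record.seed, "provenance": record.provenance}
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def load_pair(path: str | Path) -> PairRecord:
    path = Path(path)
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    sidecar_path = path.with_suffix(".json")
    sidecar = json.loads(sidecar_path.read_text()) if sidecar_path.exists() else {}

    def _cloud(points_key: str, normals_key: str) -> PointCloud:
        normals = arrays[normals_key]
        return PointCloud(
            arrays[points_key],
            normals if len(normals) else None,
            FRAME_NORMALIZED,
        )

    return PairRecord(
        source=_cloud("source", "source_normals"),
        target=_cloud("target", "target_normals"),
        gt_transform=RigidTransform.from_matrix(arrays["gt_matrix"]),
        correspondence=arrays["correspondence"],
        overlap_labels=arrays["overlap_labels"],
        landmarks_source=arrays["landmarks_source"],
        landmarks_target=arrays["landmarks_target"],
        norm_map=NormalizationMap(float(arrays["norm_scale"][0]), arrays["norm_offset"]),
        seed=int(sidecar.get("seed", -1)),
        provenance=sidecar.get("provenance", {}),
    )


def generate_dataset(
    meshes: dict,
    targets_per_source: int,
    config: GenerationConfig,
    out_dir: str | Path,
    split: str = "test",
) -> DatasetManifest:
    """Generate and write every pair of a split.

    ``meshes`` maps source ids to :class:`TriangleMesh`; per-pair seeds come
    from the manifest so the dataset regenerates byte-identically.
    """
    out_dir = Path(out_dir)
    meshes = {str(k): v for k, v in meshes.items()}
    manifest = build_manifest(split, list(meshes.keys()), targets_per_source, config)
    for entry in manifest.entries:
        target_path = out_dir / entry["path"]
        if target_path.exists():
            continue  # resumable: already generated under the same seeds
        record = generate_pair(meshes[entry["source_id"]], config, entry["seed"])
        save_pair(record, target_path)
    (out_dir / f"manifest_{split}.json").write_text(manifest.to_json())
    return manifest
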