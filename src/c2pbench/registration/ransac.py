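"""RANSAC pose estimation from putative correspondences, with ICP polish.

Three-point correspondence hypotheses are solved in closed form (Kabsch); a
correspondence is an inlier when its post-transform distance falls below
``max_corr_dist``.  The highest-inlier-count model wins (ties broken by
lower inlier RMS), is refit on all its inliers, and is optionally polished
by ICP — the classical recovery route for methods that output
correspondences rather than poses.
"""

from __future__ import annotations

import numpy as np

from ..geometry import GeometryError, PointCloud, RigidTransform
from .icp import icp_register
from .kabsch import weighted_kabsch_umeyama
from .result import CorrespondenceSet, RegistrationResult

__all__ = ["ransac_pose"]


def ransac_pose(
    source: PointCloud,
    target: PointCloud,
    corrs: CorrespondenceSet,
    max_corr_dist: float = 0.05,
    n_iters: int = 10_000,
    refine: bool = True,
    seed: int = 0,
) -> RegistrationResult:
    """Robust rigid pose from correspondences (3-point Kabsch hypotheses)."""
    if len(corrs) < 3:
        raise ValueError(f"need at least 3 correspondences, got {len(corrs)}")
    src = source.points[corrs.source_indices]
    tgt = target.points[corrs.target_indices]
    K = len(src)
    rng = np.random.default_rng(seed)
    best_T: RigidTransform | None = None
    best_count = 0
    best_rms = np.inf
    for _ in range(n_iters):
        pick = rng.choice(K, size=3, replace=False)
        try:
            T = weighted_kabsch_umeyama(src[pick], tgt[pick])
        except GeometryError:
            continue  # collinear minimal sample
        d = np.linalg.norm(T.apply(src) - tgt, axis=1)
        inl = d < max_corr_dist
        count = int(inl.sum())
        if count < 3:
            continue
        rms = float(np.sqrt(np.mean(d[inl] ** 2)))
        if count > best_count or (count == best_count and rms < best_rms):
            best_count, best_rms, best_T = count, rms, T
            if count == K:
                break
    if best_T is None:
        return RegistrationResult(
            transform=RigidTransform.identity(),
            n_iterations=n_iters,
            final_residual=float("inf"),
            converged=False,
            flags=["ransac_no_consensus"],
        )
    # refit on the consensus set
    d = np.linalg.norm(best_T.apply(src) - tgt, axis=1)
    inl = d < max_corr_dist
    if inl.sum() >= 3:
        try:
            best_T = weighted_kabsch_umeyama(src[inl], tgt[inl])
        except GeometryError:
            pass
    flags = []
    if refine:
        polished = icp_register(source, target, init=best_T)
        best_T = polished.transform
        flags = [f"icp_refined_{polished.n_iterations}_iters"]
    d = np.linalg.norm(best_T.apply(src) - tgt, axis=1)
    inl = d < max_corr_dist
    return RegistrationResult(
        transform=best_T,
        n_iterations=n_iters,
        final_residual=float(np.sqrt(np.mean(d[inl] ** 2))) if inl.any() else float("inf"),
        correspondences=CorrespondenceSet(corrs.pairs[inl], corrs.weights[inl]),
        converged=True,
        flags=flags,
    )
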