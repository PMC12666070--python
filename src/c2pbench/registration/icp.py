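"""Point-to-point iterative closest point with SVD pose updates.

Correspondences are formed target -> source (each point of the sparse
partial target claims its nearest point of the dense transformed source),
which avoids the many-to-one collapse that source -> target pairing causes
in the complete-to-partial setting.  Each iteration solves the closed-form
Kabsch problem on the current pairing; the paired-point RMS residual is
non-increasing by construction.
"""

from __future__ import annotations

import numpy as np
from scipy.spatial import cKDTree

from ..geometry import GeometryError, PointCloud, RigidTransform
from .kabsch import weighted_kabsch_umeyama
from .result import RegistrationResult

__all__ = ["icp_register"]


def icp_register(
    source: PointCloud,
    target: PointCloud,
    threshold: float = 0.001,
    max_iter: int = 30,
    init: RigidTransform | None = None,
) -> RegistrationResult:
    """Register ``source`` onto ``target`` by point-to-point ICP.

    Parameters
    ----------
    threshold : float
        Convergence threshold on the residual improvement between
        iterations (same units as the clouds).
    max_iter : int
        Maximum number of pairing + pose-update iterations; ``0`` returns
        the initialization untouched.
    init : RigidTransform, optional
        Initial pose (identity by default).
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("both clouds must be non-empty")
    transform = RigidTransform.identity() if init is None else init
    src = source.points
    tgt = target.points
    residuals: list[float] = []
    flags: list[str] = []
    prev_res = np.inf
    n_done = 0
    for n_done in range(1, max_iter + 1):
        moved = transform.apply(src)
        tree = cKDTree(moved)
        dist, nn = tree.query(tgt, k=1)
        res = float(np.sqrt(np.mean(dist**2)))
        residuals.append(res)
        try:
            transform = weighted_kabsch_umeyama(src[nn], tgt)
        except GeometryError:
            flags.append("degenerate_correspondences")
            break
        if prev_res - res < threshold:
            break
        prev_res = res
    # residual under the final pose
    if max_iter > 0:
        dist, _ = cKDTree(transform.apply(src)).query(tgt, k=1)
        final = float(np.sqrt(np.mean(dist**2)))
    else:
        final = float("nan")
        n_done = 0
    return RegistrationResult(
        transform=transform,
        n_iterations=n_done,
        final_residual=final,
        converged="degenerate_correspondences" not in flags,
        flags=flags,
        history=np.asarray(residuals),
    )
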