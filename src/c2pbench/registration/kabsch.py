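"""Weighted Kabsch-Umeyama closed-form rigid alignment.

Minimizes sum_i w_i || R s_i + t - y_i ||^2 over R in SO(3), t in R^3 via the
SVD of the weighted cross-covariance, with the determinant-sign correction
that enforces a proper rotation.  No scale is estimated (the benchmark's
clouds share one normalization).
"""

from __future__ import annotations

import numpy as np

from ..geometry import GeometryError, RigidTransform

__all__ = ["weighted_kabsch_umeyama"]


def weighted_kabsch_umeyama(
    src_points: np.ndarray,
    tgt_points: np.ndarray,
    weights: np.ndarray | None = None,
) -> RigidTransform:
    """Closed-form weighted least-squares rigid transform src -> tgt.

    Raises :class:`GeometryError` when the weighted point support is
    (near-)collinear, which leaves the rotation underdetermined.
    """
    src = np.asarray(src_points, dtype=np.float64).reshape(-1, 3)
    tgt = np.asarray(tgt_points, dtype=np.float64).reshape(-1, 3)
    if src.shape != tgt.shape:
        raise ValueError(f"point sets differ in shape: {src.shape} vs {tgt.shape}")
    if len(src) < 3:
        raise ValueError(f"need at least 3 point pairs, got {len(src)}")
    if weights is None:
        w = np.ones(len(src))
    else:
        w = np.asarray(weights, dtype=np.float64).reshape(-1)
        if len(w) != len(src):
            raise ValueError("weights length must match point count")
        if (w < 0).any():
            raise ValueError("weights must be non-negative")
    wsum = w.sum()
    if wsum <= 0:
        raise ValueError("weight sum must be positive")
    w = w / wsum
    mu_s = w @ src
    mu_t = w @ tgt
    src_c = src - mu_s
    tgt_c = tgt - mu_t
    H = (src_c * w[:, None]).T @ tgt_c  # weighted cross-covariance (src x tgt)
    U, s, Vt = np.linalg.svd(H)
    if s[1] <= max(s[0] * 1e-9, 1e-15):
        raise GeometryError("collinear point support: rotation underdetermined")
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = mu_t - R @ mu_s
    return RigidTransform(R, t)
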