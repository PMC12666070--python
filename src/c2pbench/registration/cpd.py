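"""Rigid coherent point drift (CPD) without scale.

The moving source points act as centroids of an isotropic Gaussian mixture
fitted to the fixed target points, with a uniform outlier component of
mixing weight ``outlier_w``.  EM alternates posterior responsibilities
(E-step) with a closed-form rigid update and isotropic variance update
(M-step); the negative log-likelihood is non-increasing per step.
"""

from __future__ import annotations

import numpy as np

from ..geometry import PointCloud, RigidTransform
from .result import RegistrationResult

__all__ = ["cpd_rigid_register"]


def cpd_rigid_register(
    source: PointCloud,
    target: PointCloud,
    max_iter: int = 50,
    tol: float = 0.001,
    outlier_w: float = 0.1,
    sigma2_init: float | None = None,
) -> RegistrationResult:
    """Rigid CPD registration of ``source`` (GMM centroids) onto ``target``.

    Stops when the negative log-likelihood improves by less than ``tol`` or
    after ``max_iter`` EM steps; a variance collapse below 1e-12 (perfect
    overlay) returns the converged result with a ``variance_collapse`` flag.

    The initial variance defaults to the mean squared nearest-neighbour
    distance from target to source (times 3 per-axis slack).  The classic
    all-pairs initialization makes every centroid responsible for every
    point, which in the complete-to-partial setting drives a global
    mean-shift of the whole organ onto the visible patch; a
    locality-scale start keeps the EM in the basin of the initialization.
    """
    if len(source) == 0 or len(target) == 0:
        raise ValueError("both clouds must be non-empty")
    if not 0 <= outlier_w < 1:
        raise ValueError(f"outlier_w must be in [0, 1), got {outlier_w}")
    Y = source.points  # M moving centroids
    X = target.points  # N data points
    M, N = len(Y), len(X)
    R = np.eye(3)
    t = np.zeros(3)
    TY = Y
    diff2 = _sq_dists(TY, X)
    if sigma2_init is None:
        sigma2 = float(diff2.min(axis=0).mean())
    else:
        sigma2 = float(sigma2_init)
    sigma2 = max(sigma2, 1e-10)
    nll_hist: list[float] = []
    flags: list[str] = []
    n_done = 0
    for n_done in range(1, max_iter + 1):
        # --- E-step
        P = np.exp(-diff2 / (2.0 * sigma2))  # (M, N)
        gauss_norm = (2.0 * np.pi * sigma2) ** 1.5
        col = P.sum(axis=0)
        c = gauss_norm * outlier_w / max(1.0 - outlier_w, 1e-12) * M / N
        denom = col + c
        nll = -float(
            np.sum(np.log((1.0 - outlier_w) / (M * gauss_norm) * col
                          + outlier_w / N + 1e-300))
        )
        nll_hist.append(nll)
        P = P / denom
        # --- M-step (closed-form rigid, scale fixed at 1)
        P1 = P.sum(axis=1)  # per-source
        Pt1 = P.sum(axis=0)  # per-target
        Np = P1.sum()
        if Np <= 0:
            flags.append("all_outliers")
            break
        mu_x = (Pt1 @ X) / Np
        mu_y = (P1 @ Y) / Np
        Xc = X - mu_x
        Yc = Y - mu_y
        A = Xc.T @ P.T @ Yc  # (3, 3) cross term
        U, s, Vt = np.linalg.svd(A)
        C = np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))])
        R = U @ C @ Vt
        t = mu_x - R @ mu_y
        trXX = float(np.einsum("n,ni,ni->", Pt1, Xc, Xc))
        trYY = float(np.einsum("m,mi,mi->", P1, Yc, Yc))
        trAR = float((A * R).sum())  # tr(A^T R)
        sigma2_new = (trXX + trYY - 2.0 * trAR) / (3.0 * Np)
        TY = Y @ R.T + t
        diff2 = _sq_dists(TY, X)
        if sigma2_new < 1e-12:
            flags.append("variance_collapse")
            sigma2 = max(sigma2_new, 1e-12)
            break
        sigma2 = sigma2_new
        if len(nll_hist) > 1 and abs(nll_hist[-2] - nll_hist[-1]) < tol:
            break
    dist = np.sqrt(diff2.min(axis=0))
    return RegistrationResult(
        transform=RigidTransform(R, t),
        n_iterations=n_done,
        final_residual=float(np.sqrt(np.mean(dist**2))),
        converged=True,
        flags=flags,
        history=np.asarray(nll_hist),
    )


def _sq_dists(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """(len(A), len(B)) matrix of squared Euclidean distances."""
    return np.maximum(
        np.sum(A**2, axis=1)[:, None] + np.sum(B**2, axis=1)[None, :] - 2.0 * A @ B.T,
        0.0,
    )
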