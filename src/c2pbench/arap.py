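"""As-rigid-as-possible (ARAP) surface deformation.

Classic local-global ARAP: with per-vertex rotations ``R_i`` the energy

    E(q, R) = sum_i sum_{j in N(i)} w_ij || (q_i - q_j) - R_i (p_i - p_j) ||^2

is minimized by alternating (a) a local step fitting each ``R_i`` by a 3x3
orthogonal Procrustes problem over the vertex one-ring, and (b) a global step
solving the sparse Laplacian system for the free vertex positions ``q``.
Handles are pinned at rest + displacement, anchors at rest; both are hard
constraints.  Edge weights are cotangent weights clamped at zero (obtuse
triangles can produce negative cotangents; clamping keeps every subproblem a
true minimization, so the energy is non-increasing across iterations).
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .geometry import GeometryError, TriangleMesh

__all__ = ["arap_deform", "arap_energy", "cotangent_weights"]


def cotangent_weights(mesh: TriangleMesh) -> sp.csr_matrix:
    """Symmetric per-edge cotangent weight matrix, clamped at zero."""
    v, f = mesh.vertices, mesh.faces
    rows, cols, vals = [], [], []
    for a, b, c in ((0, 1, 2), (1, 2, 0), (2, 0, 1)):
        # angle at corner c contributes to edge (a, b)
        u1 = v[f[:, a]] - v[f[:, c]]
        u2 = v[f[:, b]] - v[f[:, c]]
        cross = np.linalg.norm(np.cross(u1, u2), axis=1)
        cot = np.einsum("ij,ij->i", u1, u2) / np.maximum(cross, 1e-12)
        w = 0.5 * np.maximum(cot, 0.0)
        rows.append(f[:, a])
        cols.append(f[:, b])
        vals.append(w)
    rows = np.concatenate(rows)
    cols = np.concatenate(cols)
    vals = np.concatenate(vals)
    W = sp.coo_matrix(
        (np.concatenate([vals, vals]), (np.concatenate([rows, cols]), np.concatenate([cols, rows]))),
        shape=(mesh.n_vertices, mesh.n_vertices),
    ).tocsr()
    W.sum_duplicates()
    return W


def _fit_rotations(
    rest: np.ndarray, cur: np.ndarray, rows: np.ndarray, cols: np.ndarray, w: np.ndarray
) -> np.ndarray:
    """Per-vertex best-fit rotations over weighted one-ring edge sets."""
    n = len(rest)
    e_rest = rest[rows] - rest[cols]
    e_cur = cur[rows] - cur[cols]
    contrib = np.einsum("e,ei,ej->eij", w, e_rest, e_cur)
    S = np.zeros((n, 3, 3))
    np.add.at(S, rows, contrib)
    # R_i = V U^T maximizing tr(R S_i) with S_i = U diag(s) V^T, det corrected
    U, _, Vt = np.linalg.svd(S)
    R = np.einsum("nji,nkj->nik", Vt, U)  # V @ U^T
    flip = np.linalg.det(R) < 0
    if flip.any():
        Vt_f = Vt[flip].copy()
        Vt_f[:, -1, :] *= -1.0  # flip smallest-singular-value direction
        R[flip] = np.einsum("nji,nkj->nik", Vt_f, U[flip])
    return R


def arap_energy(
    rest: np.ndarray,
    cur: np.ndarray,
    rotations: np.ndarray,
    rows: np.ndarray,
    cols: np.ndarray,
    w: np.ndarray,
) -> float:
    """Evaluate the ARAP energy for given positions and per-vertex rotations."""
    e_rest = rest[rows] - rest[cols]
    e_cur = cur[rows] - cur[cols]
    rot_e = np.einsum("eij,ej->ei", rotations[rows], e_rest)
    diff = e_cur - rot_e
    return float(np.sum(w * np.einsum("ei,ei->e", diff, diff)))


def arap_deform(
    mesh: TriangleMesh,
    handles: np.ndarray,
    anchors: np.ndarray,
    displacement: np.ndarray,
    n_iters: int = 10,
    return_energy: bool = False,
) -> TriangleMesh | tuple[TriangleMesh, np.ndarray]:
    """Deform ``mesh`` by translating ``handles`` while pinning ``anchors``.

    Parameters
    ----------
    handles, anchors : index arrays
        Disjoint, non-empty vertex index sets.  Handles are constrained to
        rest + ``displacement``; anchors stay at rest.
    displacement : (3,) array
        Handle translation, in the mesh's units (mm).
    n_iters : int
        Local-global iterations (>= 1).
    return_energy : bool
        Also return the per-iteration ARAP energy sequence (non-increasing).
    """
    handles = np.asarray(handles, dtype=np.intp)
    anchors = np.asarray(anchors, dtype=np.intp)
    if n_iters < 1:
        raise ValueError("n_iters must be >= 1")
    if handles.size == 0:
        raise GeometryError("handle set must be non-empty")
    if np.intersect1d(handles, anchors).size:
        raise GeometryError("handles and anchors must be disjoint")
    displacement = np.asarray(displacement, dtype=np.float64).reshape(3)

    rest = mesh.vertices
    n = mesh.n_vertices
    W = cotangent_weights(mesh)
    Wc = W.tocoo()
    rows, cols, w = Wc.row, Wc.col, Wc.data

    constrained = np.concatenate([handles, anchors])
    constrained_pos = np.vstack([rest[handles] + displacement, rest[anchors]])
    free_mask = np.ones(n, dtype=bool)
    free_mask[constrained] = False
    free = np.flatnonzero(free_mask)

    L = sp.diags(np.asarray(W.sum(axis=1)).ravel()) - W
    lu = None
    if free.size:
        L_ff = L[free][:, free].tocsc()
        L_fc = L[free][:, constrained].tocsr()
        try:
            lu = splu(L_ff)
        except RuntimeError as exc:
            raise GeometryError(f"singular ARAP system (disconnected mesh?): {exc}") from exc

    cur = rest.copy()
    cur[constrained] = constrained_pos
    energies = []
    for _ in range(n_iters):
        R = _fit_rotations(rest, cur, rows, cols, w)
        if free.size:
            # b_i = sum_j (w_ij / 2) (R_i + R_j)(p_i - p_j)
            e_rest = rest[rows] - rest[cols]
            Rsum = R[rows] + R[cols]
            contrib = 0.5 * w[:, None] * np.einsum("eij,ej->ei", Rsum, e_rest)
            b = np.zeros((n, 3))
            np.add.at(b, rows, contrib)
            rhs = b[free] - L_fc @ constrained_pos
            sol = lu.solve(rhs)
            if not np.isfinite(sol).all():
                raise GeometryError("singular ARAP system (disconnected mesh?)")
            cur[free] = sol
        energies.append(arap_energy(rest, cur, R, rows, cols, w))

    deformed = TriangleMesh(cur, mesh.faces)
    if return_energy:
        return deformed, np.asarray(energies)
    return deformed
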