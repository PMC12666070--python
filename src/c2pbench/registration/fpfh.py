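"""Fast point feature histogram (FPFH) descriptors and mutual matching.

A non-learned, rotation-invariant stand-in for learned feature extractors:
for every point, angular Darboux-frame relations (alpha, phi, theta) between
the point and its radius neighbours are binned into three 11-bin histograms
(SPFH); the FPFH re-weights each point's SPFH with its neighbours' inverse
distance-weighted SPFHs.  Correspondences are mutual nearest neighbours in
descriptor space, weighted by normalized descriptor similarity.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from scipy.spatial import cKDTree
from sklearn.neighbors import NearestNeighbors

from ..geometry import PointCloud, estimate_normals
from .result import CorrespondenceSet

__all__ = ["compute_fpfh", "descriptor_correspondences"]

_N_BINS = 11


def _pair_features(
    p: np.ndarray, n: np.ndarray, i: np.ndarray, j: np.ndarray
) -> np.ndarray:
    """Darboux angular features (alpha, phi, theta) for point pairs (i, j)."""
    d = p[j] - p[i]
    dist = np.linalg.norm(d, axis=1)
    d_unit = d / dist[:, None]
    # choose the pair's source point as the one whose normal is closer to the
    # line; the comparison is quantized because locally spherical geometry
    # ties it exactly and float jitter must not flip the Darboux frame
    cos_i = np.abs(np.einsum("ki,ki->k", n[i], d_unit))
    cos_j = np.abs(np.einsum("ki,ki->k", n[j], -d_unit))
    swap = (cos_j - cos_i) > 1e-9
    s = np.where(swap, j, i)
    t = np.where(swap, i, j)
    d_st = p[t] - p[s]
    d_st /= np.linalg.norm(d_st, axis=1, keepdims=True)
    u = n[s]
    v = np.cross(d_st, u)
    v_norm = np.linalg.norm(v, axis=1, keepdims=True)
    v = v / np.maximum(v_norm, 1e-12)
    w = np.cross(u, v)
    nt = n[t]
    alpha = np.einsum("ki,ki->k", v, nt)  # in [-1, 1]
    phi = np.einsum("ki,ki->k", u, d_st)  # in [-1, 1]
    theta = np.arctan2(
        np.einsum("ki,ki->k", w, nt), np.einsum("ki,ki->k", u, nt)
    )  # in [-pi, pi]
    return np.column_stack([alpha, phi, theta])


def _bin(values: np.ndarray, lo: float, hi: float) -> np.ndarray:
    idx = ((values - lo) / (hi - lo) * _N_BINS).astype(np.intp)
    return np.clip(idx, 0, _N_BINS - 1)


def compute_fpfh(cloud: PointCloud, radius: float, k_normals: int = 16) -> np.ndarray:
    """(N, 33) FPFH descriptors from ``radius``-neighbourhoods.

    Normals are estimated if the cloud lacks them.  Raises ``ValueError`` if
    any point has an empty neighbourhood (radius too small).
    """
    if radius <= 0:
        raise ValueError(f"radius must be positive, got {radius}")
    if cloud.normals is None:
        cloud = estimate_normals(cloud, k=min(k_normals, len(cloud)))
    p = cloud.points
    n = cloud.normals
    N = len(p)
    tree = cKDTree(p)
    pairs = tree.query_pairs(radius, output_type="ndarray")
    counts = np.zeros(N, dtype=np.int64)
    if len(pairs):
        np.add.at(counts, pairs[:, 0], 1)
        np.add.at(counts, pairs[:, 1], 1)
    if (counts == 0).any():
        raise ValueError(
            f"radius {radius} leaves {(counts == 0).sum()} points with empty "
            "neighbourhoods"
        )
    i, j = pairs[:, 0], pairs[:, 1]
    feats = _pair_features(p, n, i, j)
    # separate 11-bin histograms per feature (33 dims), pair feature shared by both ends
    spfh = np.zeros((N, 3 * _N_BINS))
    for f_idx in range(3):
        lo, hi = ((-1.0, 1.0), (-1.0, 1.0), (-np.pi, np.pi))[f_idx]
        b = _bin(feats[:, f_idx], lo, hi) + f_idx * _N_BINS
        np.add.at(spfh, (i, b), 1.0)
        np.add.at(spfh, (j, b), 1.0)
    spfh /= np.maximum(counts[:, None], 1)

    # FPFH: own SPFH plus inverse-distance-weighted neighbour SPFHs
    dists = np.linalg.norm(p[i] - p[j], axis=1)
    inv = 1.0 / np.maximum(dists, 1e-12)
    W = sp.coo_matrix(
        (np.concatenate([inv, inv]), (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(N, N),
    ).tocsr()
    fpfh = spfh + (W @ spfh) / np.maximum(counts[:, None], 1)
    # normalize each 11-bin block to unit L1 for scale-free matching
    for f_idx in range(3):
        block = fpfh[:, f_idx * _N_BINS : (f_idx + 1) * _N_BINS]
        block /= np.maximum(block.sum(axis=1, keepdims=True), 1e-12)
    return fpfh


def descriptor_correspondences(
    source: PointCloud, target: PointCloud, radius: float
) -> CorrespondenceSet:
    """Mutual-nearest-neighbour FPFH matches between the two clouds."""
    desc_s = compute_fpfh(source, radius)
    desc_t = compute_fpfh(target, radius)
    nn_s = NearestNeighbors(n_neighbors=1).fit(desc_s)
    d_ts, s_of_t = nn_s.kneighbors(desc_t)  # for each target, best source
    nn_t = NearestNeighbors(n_neighbors=1).fit(desc_t)
    _, t_of_s = nn_t.kneighbors(desc_s)  # for each source, best target
    s_of_t = s_of_t[:, 0]
    t_of_s = t_of_s[:, 0]
    t_idx = np.arange(len(desc_t))
    mutual = t_of_s[s_of_t] == t_idx
    pairs = np.column_stack([s_of_t[mutual], t_idx[mutual]])
    sim = 1.0 / (1.0 + d_ts[mutual, 0])
    return CorrespondenceSet(pairs, sim)
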