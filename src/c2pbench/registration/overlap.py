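"""Complete-to-partial overlap head and training losses (pure operations).

In complete-to-partial registration the partial cloud is by definition fully
contained in the complete one, so its per-point overlap probability is
identically 1; only the complete cloud's keypoints need a predicted score.
The head is a single linear layer + sigmoid over conditioned keypoint
features; it and the three training losses are plain array functions so any
feature extractor (learned or synthetic) can drive them.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["OverlapHeadParams", "overlap_head", "compute_losses"]


@dataclass(frozen=True)
class OverlapHeadParams:
    """Linear overlap head: score = sigmoid(features @ w1 + b1)."""

    w1: np.ndarray
    b1: float

    def __post_init__(self) -> None:
        w = np.asarray(self.w1, dtype=np.float64).reshape(-1)
        if not np.isfinite(w).all() or not np.isfinite(self.b1):
            raise ValueError("overlap head parameters must be finite")
        object.__setattr__(self, "w1", w)
        object.__setattr__(self, "b1", float(self.b1))


def overlap_head(
    features: np.ndarray, params: OverlapHeadParams, n_partial: int
) -> tuple[np.ndarray, np.ndarray]:
    """Overlap scores for complete-cloud keypoints; exact 1s for the partial.

    ``features`` is the (K, D) conditioned feature matrix of the complete
    cloud's keypoints.  Complete-cloud scores are strictly in (0, 1); the
    partial cloud's scores are fixed at exactly 1 by construction.
    """
    F = np.asarray(features, dtype=np.float64)
    if F.ndim != 2 or F.shape[1] != len(params.w1):
        raise ValueError(
            f"features must be (K, {len(params.w1)}), got {F.shape}"
        )
    if not np.isfinite(F).all():
        raise ValueError("features contain non-finite values")
    if n_partial < 0:
        raise ValueError("n_partial must be >= 0")
    logits = F @ params.w1 + params.b1
    scores = 1.0 / (1.0 + np.exp(-logits))
    eps = np.finfo(np.float64).tiny
    scores = np.clip(scores, eps, 1.0 - np.finfo(np.float64).epsneg)
    return scores, np.ones(n_partial)


def compute_losses(
    pred_keypoints: np.ndarray,
    gt_keypoints: np.ndarray,
    overlap_scores: np.ndarray,
    features_a: np.ndarray,
    features_b: np.ndarray,
    gt_correspondence: np.ndarray,
    gt_overlap: np.ndarray,
    loss_weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
    feature_margin_pos: float = 0.1,
    feature_margin_neg: float = 1.0,
) -> tuple[float, float, float, float]:
    """Total and per-term training losses for the correspondence decoder.

    * registration loss: overlap-confidence-weighted mean absolute error
      between predicted transformed keypoint positions and ground truth;
    * feature loss: contrastive margin loss pulling true-match feature pairs
      below ``feature_margin_pos`` and pushing non-matches beyond
      ``feature_margin_neg`` (in feature-space Euclidean distance);
    * overlap loss: binary cross-entropy of predicted scores vs labels.

    Returns ``(total, registration, feature, overlap)``, all >= 0.
    """
    pred = np.asarray(pred_keypoints, dtype=np.float64)
    gt = np.asarray(gt_keypoints, dtype=np.float64)
    conf = np.asarray(overlap_scores, dtype=np.float64)
    if pred.shape != gt.shape or len(conf) != len(pred):
        raise ValueError("keypoint / confidence shapes are inconsistent")
    fa = np.asarray(features_a, dtype=np.float64)
    fb = np.asarray(features_b, dtype=np.float64)
    matches = np.asarray(gt_correspondence, dtype=np.int64).reshape(-1, 2)
    labels = np.asarray(gt_overlap, dtype=np.float64).reshape(-1)
    w_reg, w_feat, w_ov = loss_weights
    if min(loss_weights) < 0:
        raise ValueError("loss weights must be >= 0")

    # (i) registration loss: confidence-weighted mean absolute position error
    abs_err = np.abs(pred - gt).mean(axis=1)
    denom = conf.sum()
    reg_loss = float((conf * abs_err).sum() / denom) if denom > 0 else 0.0

    # (ii) contrastive feature loss over the match matrix
    d = np.linalg.norm(fa[:, None, :] - fb[None, :, :], axis=2)
    pos_mask = np.zeros(d.shape, dtype=bool)
    pos_mask[matches[:, 0], matches[:, 1]] = True
    pos = np.maximum(d[pos_mask] - feature_margin_pos, 0.0)
    neg = np.maximum(feature_margin_neg - d[~pos_mask], 0.0)
    feat_loss = float(
        (pos.mean() if pos.size else 0.0) + (neg.mean() if neg.size else 0.0)
    )

    # (iii) overlap loss: binary cross-entropy
    scores = np.asarray(overlap_scores, dtype=np.float64).reshape(-1)
    if len(scores) != len(labels):
        raise ValueError("overlap scores / labels length mismatch")
    eps = 1e-300
    ov_loss = float(
        -np.mean(
            labels * np.log(scores + eps) + (1.0 - labels) * np.log(1.0 - scores + eps)
        )
    )

    total = float(w_reg * reg_loss + w_feat * feat_loss + w_ov * ov_loss)
    return total, reg_loss, feat_loss, ov_loss
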