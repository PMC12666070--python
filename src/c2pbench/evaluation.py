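"""Benchmark metrics and aggregation.

Registration quality is reported with the conventions of the
partial-to-partial registration literature:

* ``MAE(R)`` — mean absolute error over the three Euler angles (fixed z-y-x
  convention) between predicted and ground-truth rotation, in degrees.  A
  geodesic (single-angle) variant is emitted alongside for transparency.
* ``MAE(t)`` — mean absolute error over the three translation components,
  converted to mm through the pair's normalization map.
* ``TRE`` — target registration error: mean Euclidean distance in mm between
  predicted-transformed source landmarks and their intraoperative
  counterparts.  Landmarks come from cropped-out regions, so TRE evaluated
  at the ground-truth transform isolates the residual non-rigid component.
* correspondence precision / recall against the generator's ground-truth map.

Aggregation mirrors the benchmark's summary-table layout: mean and sample
standard deviation per method and partiality level.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.transform import Rotation

from .geometry import NormalizationMap, RigidTransform
from .registration import CorrespondenceSet

__all__ = [
    "MetricsRecord",
    "mae_rotation",
    "geodesic_rotation_error",
    "mae_translation",
    "target_registration_error",
    "match_precision_recall",
    "evaluate_pair",
    "aggregate_results",
]


@dataclass
class MetricsRecord:
    """Per-pair metric values (all non-negative)."""

    pair_id: str
    method: str
    crop_ratio: float
    mae_rotation: float
    mae_translation: float
    tre: float
    geodesic_rotation: float = float("nan")
    precision: float = float("nan")
    recall: float = float("nan")

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def mae_rotation(pred: RigidTransform, gt: RigidTransform) -> float:
    """Mean absolute Euler-angle error in degrees (z-y-x convention).

    Each angle difference is wrapped to [-180, 180] before taking the
    absolute value; the result is symmetric in its arguments.
    """
    e_pred = Rotation.from_matrix(pred.rotation).as_euler("zyx", degrees=True)
    e_gt = Rotation.from_matrix(gt.rotation).as_euler("zyx", degrees=True)
    diff = (e_pred - e_gt + 180.0) % 360.0 - 180.0
    return float(np.mean(np.abs(diff)))


def geodesic_rotation_error(pred: RigidTransform, gt: RigidTransform) -> float:
    """Single geodesic angle (degrees) between the two rotations."""
    return (pred.inverse() @ gt).rotation_angle_deg()


def mae_translation(
    pred: RigidTransform, gt: RigidTransform, norm_map: NormalizationMap
) -> float:
    """Mean absolute translation-component error, converted to mm."""
    diff = np.abs(pred.translation - gt.translation)
    return float(norm_map.magnitude_to_mm(float(np.mean(diff))))


def target_registration_error(
    landmarks_source: np.ndarray,
    landmarks_target: np.ndarray,
    pred: RigidTransform,
    norm_map: NormalizationMap,
) -> float:
    """Mean landmark-pair distance in mm after applying the predicted pose."""
    ls = np.asarray(landmarks_source, dtype=np.float64).reshape(-1, 3)
    lt = np.asarray(landmarks_target, dtype=np.float64).reshape(-1, 3)
    if len(ls) != len(lt) or len(ls) == 0:
        raise ValueError(
            f"landmark counts must match and be >= 1, got {len(ls)} vs {len(lt)}"
        )
    d = np.linalg.norm(pred.apply(ls) - lt, axis=1)
    return float(norm_map.magnitude_to_mm(float(d.mean())))


def match_precision_recall(
    predicted: CorrespondenceSet, gt_map: np.ndarray
) -> tuple[float, float]:
    """Precision and recall of predicted correspondences.

    ``gt_map[i]`` is the ground-truth source index of target point ``i``.  A
    prediction is correct when its source index equals exactly the mapped
    one.  With zero predictions the precision is reported as 0 (flagged by
    the caller via the empty set), recall as 0.
    """
    gt_map = np.asarray(gt_map, dtype=np.int64)
    if len(gt_map) == 0:
        raise ValueError("ground-truth correspondence map is empty")
    if len(predicted) == 0:
        return 0.0, 0.0
    correct = int(np.sum(gt_map[predicted.target_indices] == predicted.source_indices))
    return correct / len(predicted), correct / len(gt_map)


def evaluate_pair(
    record,
    pred: RigidTransform,
    method: str = "",
    pair_id: str = "",
    correspondences: CorrespondenceSet | None = None,
) -> MetricsRecord:
    """All metrics of one prediction against a generated pair record."""
    precision = recall = float("nan")
    if correspondences is not None:
        precision, recall = match_precision_recall(
            correspondences, record.correspondence
        )
    return MetricsRecord(
        pair_id=pair_id,
        method=method,
        crop_ratio=float(record.provenance.get("crop_ratio", float("nan"))),
        mae_rotation=mae_rotation(pred, record.gt_transform),
        mae_translation=mae_translation(pred, record.gt_transform, record.norm_map),
        tre=target_registration_error(
            record.landmarks_source, record.landmarks_target, pred, record.norm_map
        ),
        geodesic_rotation=geodesic_rotation_error(pred, record.gt_transform),
        precision=precision,
        recall=recall,
    )


def aggregate_results(records: list[MetricsRecord]) -> pd.DataFrame:
    """Summary table: mean and sample (n-1) std per method x crop ratio.

    Single-record cells report std 0; the frame has one row per method and
    hierarchical columns (crop ratio, metric, mean/std), mirroring the
    benchmark's summary-table layout.
    """
    if not records:
        raise ValueError("no metric records to aggregate")
    df = pd.DataFrame([r.to_dict() for r in records])
    metrics = ["tre", "mae_rotation", "mae_translation"]
    grouped = df.groupby(["method", "crop_ratio"])[metrics].agg(["mean", "std"])
    grouped = grouped.fillna(0.0)  # single-record cells: std := 0
    table = grouped.unstack("crop_ratio")
    # columns ordered as (crop_ratio, metric, stat)
    table = table.reorder_levels([2, 0, 1], axis=1).sort_index(axis=1)
    return table
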