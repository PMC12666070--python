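"""Result containers shared by every registration method."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..geometry import GeometryError, RigidTransform

__all__ = ["CorrespondenceSet", "RegistrationResult"]


@dataclass
class CorrespondenceSet:
    """Predicted point correspondences with confidence weights in [0, 1].

    ``pairs`` is a (K, 2) integer array of (source index, target index).
    """

    pairs: np.ndarray
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        pairs = np.asarray(self.pairs, dtype=np.int64).reshape(-1, 2)
        self.pairs = pairs
        if self.weights is None:
            self.weights = np.ones(len(pairs))
        else:
            w = np.asarray(self.weights, dtype=np.float64).reshape(-1)
            if len(w) != len(pairs):
                raise GeometryError("weights length must match pair count")
            if w.size and (w.min() < 0 or w.max() > 1):
                raise GeometryError("weights must lie in [0, 1]")
            self.weights = w

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def source_indices(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def target_indices(self) -> np.ndarray:
        return self.pairs[:, 1]


@dataclass
class RegistrationResult:
    """Estimated transform plus solver diagnostics."""

    transform: RigidTransform
    n_iterations: int = 0
    final_residual: float = float("nan")
    correspondences: CorrespondenceSet | None = None
    converged: bool = True
    flags: list[str] = field(default_factory=list)
    history: np.ndarray | None = None  # per-iteration objective values
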