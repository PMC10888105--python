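"""Weighted soft-voting combination and the log-loss objective.

A weighted ensemble forms, for each sample, the convex combination
``y_pred = sum_m beta_m * P_m`` of the per-model class-probability rows,
with non-negative model weights ``beta`` summing to one.  The objective
minimized when fitting the weights is the multiclass cross-entropy
``-(1/N) sum_n log p_n[y_n]`` of the combined probabilities.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError

#: Per-row probability sums must be within this of 1 for a PredictionSet.
ROW_SUM_TOL = 1e-6
#: Weight sums must be within this of 1 for a WeightVector.
WEIGHT_SUM_TOL = 1e-9


@dataclass(frozen=True)
class PredictionSet:
    """Aligned stack of per-model class-probability matrices.

    Parameters
    ----------
    model_ids
        M unique model names.
    probabilities
        Array of shape (M, N, C); each row of each model's (N, C) matrix is
        a probability vector (non-negative, summing to 1 within ``ROW_SUM_TOL``).
    sample_ids
        Optional N sample identifiers shared by all models.
    """

    model_ids: tuple[str, ...]
    probabilities: np.ndarray
    sample_ids: tuple[str, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probabilities, dtype=float)
        if probs.ndim != 3:
            raise ValidationError(
                f"probabilities must be (M, N, C), got shape {probs.shape}"
            )
        object.__setattr__(self, "probabilities", probs)
        object.__setattr__(self, "model_ids", tuple(str(m) for m in self.model_ids))
        m, n, c = probs.shape
        if len(self.model_ids) != m:
            raise ValidationError(
                f"{len(self.model_ids)} model_ids for {m} probability matrices"
            )
        if len(set(self.model_ids)) != m:
            raise ValidationError("model_ids must be unique")
        if m < 1 or n < 1 or c < 2:
            raise ValidationError(f"need M>=1, N>=1, C>=2; got M={m}, N={n}, C={c}")
        if self.sample_ids is not None:
            sids = tuple(str(s) for s in self.sample_ids)
            if len(sids) != n:
                raise ValidationError(f"{len(sids)} sample_ids for N={n} samples")
            object.__setattr__(self, "sample_ids", sids)
        if np.any(probs < 0):
            raise ValidationError("probabilities contain negative entries")
        row_sums = probs.sum(axis=2)
        bad = np.abs(row_sums - 1.0) > ROW_SUM_TOL
        if np.any(bad):
            mi, ni = np.argwhere(bad)[0]
            raise ValidationError(
                f"model {self.model_ids[mi]!r} row {ni} sums to "
                f"{row_sums[mi, ni]:.8f}, not 1"
            )

    @property
    def n_models(self) -> int:
        return self.probabilities.shape[0]

    @property
    def n_samples(self) -> int:
        return self.probabilities.shape[1]

    @property
    def n_classes(self) -> int:
        return self.probabilities.shape[2]


@dataclass(frozen=True)
class WeightVector:
    """M non-negative ensemble weights summing to one (the simplex constraint)."""

    weights: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=float)
        if w.ndim != 1 or w.size < 1:
            raise ValidationError(f"weights must be a 1-D vector, got shape {w.shape}")
        if np.any(w < 0):
            raise ValidationError("weights must be non-negative")
        if abs(w.sum() - 1.0) > WEIGHT_SUM_TOL:
            raise ValidationError(f"weights sum to {w.sum():.12f}, not 1")
        object.__setattr__(self, "weights", w)

    def __len__(self) -> int:
        return self.weights.size


def validate_labels(labels: np.ndarray, n_classes: int, n_samples: int | None = None) -> np.ndarray:
    """Coerce ``labels`` to an integer vector and check it indexes ``n_classes``."""
    y = np.asarray(labels)
    if y.ndim != 1:
        raise ValidationError(f"labels must be 1-D, got shape {y.shape}")
    if not np.issubdtype(y.dtype, np.integer):
        yi = y.astype(int)
        if np.any(yi != y):
            raise ValidationError("labels must be integers")
        y = yi
    if y.size and (y.min() < 0 or y.max() >= n_classes):
        raise ValidationError(
            f"labels must lie in [0, {n_classes}); got range [{y.min()}, {y.max()}]"
        )
    if n_samples is not None and y.size != n_samples:
        raise ValidationError(f"{y.size} labels for {n_samples} samples")
    return y


def combine(preds: PredictionSet, w: WeightVector) -> np.ndarray:
    """Weighted combination of the per-model probability matrices.

    Returns the (N, C) matrix whose entry (n, c) is
    ``sum_m w_m * P_m[n, c]``.  Because the weights lie on the simplex and
    each model's rows are probability vectors, the output rows are again
    probability vectors.
    """
    if len(w) != preds.n_models:
        raise ValidationError(
            f"{len(w)} weights for {preds.n_models} models"
        )
    return np.tensordot(w.weights, preds.probabilities, axes=1)


def log_loss(labels: np.ndarray, probs: np.ndarray, eps: float = 1e-15) -> float:
    """Multiclass cross-entropy of ``probs`` against integer ``labels``.

    ``-(1/N) * sum_n log(clip(p_n[y_n], eps, 1 - eps))``.  The clip keeps
    the value finite when a true-class probability underflows to 0.
    """
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.size == 0:
        raise ValidationError(f"probs must be a non-empty (N, C) matrix, got {probs.shape}")
    if not 0 < eps < 0.5:
        raise ValidationError(f"eps must be in (0, 0.5), got {eps}")
    n, c = probs.shape
    y = validate_labels(labels, c, n)
    p_true = probs[np.arange(n), y]
    return float(-np.mean(np.log(np.clip(p_true, eps, 1.0 - eps))))


def predict_labels(probs: np.ndarray) -> np.ndarray:
    """Hard labels by per-row argmax; ties go to the lowest class index."""
    probs = np.asarray(probs, dtype=float)
    if probs.ndim != 2 or probs.size == 0:
        raise ValidationError(f"probs must be a non-empty (N, C) matrix, got {probs.shape}")
    return np.argmax(probs, axis=1)
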