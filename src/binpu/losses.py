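"""The composite training objective: binary cross-entropy plus a
weighted-positive penalty.

The total loss is

    L = L_BCE + lambda * L_WP

where L_BCE is the mean binary cross-entropy over all N rows of a batch
(truly positive, pseudo-positive and pseudo-negative together) and L_WP
penalizes prediction error on the *truly positive* rows only:

    L_WP = (1/|Dp|) * sum over Dp of (ln(yhat + 1) - ln(y + 1))^2

with y = 1 on those rows, so each term is (ln(yhat + 1) - ln 2)^2.  The
extra term pulls the predicted probability of known positives toward 1
regardless of how noisy the pseudo labels are, which is the point of the
weighting: curated positives are the only labels that are certain.

Natural logarithms are used throughout; a change of base only rescales
every component by a constant.  Predictions are clipped to
[epsilon, 1 - epsilon] before any logarithm since BCE is unbounded at
{0, 1}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ParameterError

LN2 = float(np.log(2.0))


@dataclass(frozen=True)
class LossConfig:
    """Weight of the positive-penalty term and the log-clipping constant."""

    lambda_wp: float = 1.0
    epsilon: float = 1e-7
    # batch-local |Dp| (default) vs. a fixed global count as the WP normalizer
    global_dp_size: Optional[int] = None

    def __post_init__(self) -> None:
        if self.lambda_wp < 0:
            raise ParameterError(f"lambda_wp must be >= 0, got {self.lambda_wp}")
        if not (0.0 < self.epsilon < 0.5):
            raise ParameterError(f"epsilon must be in (0, 0.5), got {self.epsilon}")


@dataclass(frozen=True)
class LossBreakdown:
    total: float
    bce: float
    weighted_positive: float
    n_total: int
    n_true_positive: int


def _validate(y_true: np.ndarray, y_pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    y_true = np.asarray(y_true, dtype=float).ravel()
    y_pred = np.asarray(y_pred, dtype=float).ravel()
    if y_true.shape != y_pred.shape:
        raise ParameterError(
            f"length mismatch: {y_true.size} labels vs {y_pred.size} predictions"
        )
    if y_true.size == 0:
        raise ParameterError("empty batch")
    if not np.isin(y_true, (0.0, 1.0)).all():
        raise ParameterError("labels must be binary (0/1)")
    if ((y_pred < 0) | (y_pred > 1)).any():
        raise ParameterError("predictions must lie in [0, 1]")
    return y_true, y_pred


def _clip(y_pred: np.ndarray, epsilon: float) -> np.ndarray:
    return np.clip(y_pred, epsilon, 1.0 - epsilon)


def bce_loss(
    y_true,
    y_pred,
    epsilon: float = 1e-7,
    sample_weight=None,
) -> float:
    """Mean binary cross-entropy, -(1/N) sum [y ln yhat + (1-y) ln(1-yhat)].

    ``sample_weight`` multiplies each row's contribution (the normalizer
    stays N, so weight w makes a row count exactly w-fold).
    """
    y_true, y_pred = _validate(y_true, y_pred)
    p = _clip(y_pred, epsilon)
    per_row = -(y_true * np.log(p) + (1.0 - y_true) * np.log(1.0 - p))
    if sample_weight is not None:
        w = np.asarray(sample_weight, dtype=float).ravel()
        if w.shape != y_true.shape:
            raise ParameterError("sample_weight length mismatch")
        per_row = per_row * w
    return float(per_row.mean())


def weighted_positive_loss(y_true_pos, y_pred_pos) -> float:
    """Mean over the truly-positive slice of (ln(yhat+1) - ln(y+1))^2.

    The slice must contain only truly positive rows (y = 1); an empty
    slice returns 0 with a warning rather than raising, so batches that
    happen to contain no curated positives still have a defined loss.
    """
    y_true_pos = np.asarray(y_true_pos, dtype=float).ravel()
    y_pred_pos = np.asarray(y_pred_pos, dtype=float).ravel()
    if y_true_pos.shape != y_pred_pos.shape:
        raise ParameterError("length mismatch in the truly-positive slice")
    if y_true_pos.size == 0:
        warnings.warn("weighted_positive_loss over an empty slice; returning 0")
        return 0.0
    if not (y_true_pos == 1.0).all():
        raise ParameterError(
            "the weighted-positive slice must contain only truly positive rows"
        )
    if ((y_pred_pos < 0) | (y_pred_pos > 1)).any():
        raise ParameterError("predictions must lie in [0, 1]")
    diff = np.log1p(y_pred_pos) - LN2
    return float(np.mean(diff**2))


def composite_loss(
    y_true,
    y_pred,
    truly_positive_mask,
    config: LossConfig = LossConfig(),
    sample_weight=None,
) -> LossBreakdown:
    """Total loss L = BCE over all rows + lambda * WP over the Dp rows.

    ``truly_positive_mask`` flags the curated-positive rows inside the
    batch; pseudo-positives never enter the WP term.
    """
    y_true, y_pred = _validate(y_true, y_pred)
    mask = np.asarray(truly_positive_mask, dtype=bool).ravel()
    if mask.shape != y_true.shape:
        raise ParameterError("truly_positive_mask length mismatch")
    bce = bce_loss(y_true, y_pred, epsilon=config.epsilon, sample_weight=sample_weight)
    if mask.any():
        wp = weighted_positive_loss(y_true[mask], y_pred[mask])
        if config.global_dp_size is not None:
            # renormalize the batch-local mean to a fixed global |Dp|
            wp = wp * mask.sum() / config.global_dp_size
    else:
        wp = 0.0
    total = bce + config.lambda_wp * wp
    return LossBreakdown(
        total=total,
        bce=bce,
        weighted_positive=wp,
        n_total=int(y_true.size),
        n_true_positive=int(mask.sum()),
    )


def loss_gradient(
    y_true,
    y_pred,
    truly_positive_mask,
    config: LossConfig = LossConfig(),
    sample_weight=None,
) -> np.ndarray:
    """Analytic per-row dL/dyhat for the composite loss.

    For every row the BCE contribution is -(y/yhat - (1-y)/(1-yhat)) / N
    (evaluated at the clipped prediction; the gradient is zero where the
    clip is active, matching the flat clipped loss).  Truly-positive rows
    additionally receive

        lambda * 2 (ln(yhat+1) - ln 2) / ((yhat+1) * |Dp_batch|).
    """
    y_true, y_pred = _validate(y_true, y_pred)
    mask = np.asarray(truly_positive_mask, dtype=bool).ravel()
    if mask.shape != y_true.shape:
        raise ParameterError("truly_positive_mask length mismatch")
    if mask.any() and not (y_true[mask] == 1.0).all():
        raise ParameterError(
            "the weighted-positive slice must contain only truly positive rows"
        )
    n = y_true.size
    p = _clip(y_pred, config.epsilon)
    grad = -(y_true / p - (1.0 - y_true) / (1.0 - p)) / n
    if sample_weight is not None:
        w = np.asarray(sample_weight, dtype=float).ravel()
        if w.shape != y_true.shape:
            raise ParameterError("sample_weight length mismatch")
        grad = grad * w
    # clipped region is flat: kill the BCE gradient outside [eps, 1-eps]
    active = (y_pred >= config.epsilon) & (y_pred <= 1.0 - config.epsilon)
    grad = np.where(active, grad, 0.0)
    if config.lambda_wp > 0 and mask.any():
        n_dp = config.global_dp_size if config.global_dp_size is not None else int(mask.sum())
        # the WP term is finite on all of [0, 1]; no clipping needed
        yp = y_pred[mask]
        wp_grad = 2.0 * (np.log1p(yp) - LN2) / ((yp + 1.0) * n_dp)
        grad[mask] = grad[mask] + config.lambda_wp * wp_grad
    return grad
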