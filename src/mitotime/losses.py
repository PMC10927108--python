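"""Training losses.

All four losses operate on sigmoid-activated predictions clamped to
``[eps, 1-eps]`` before any logarithm (eps = 1e-7):

* :func:`tracking_loss` — pixelwise binary cross-entropy between the
  decoder reconstruction and the input image masked to the center cell,
  normalized by the pixel count and averaged over channels and batch.
* :func:`classification_loss` — binary cross-entropy between the per-class
  sigmoid scores and a one-hot stage target, normalized by the number of
  classes.
* :func:`cross_entropy_loss` — the positive-class term only, also
  normalized by the number of classes (used by the frame-independent
  classifier).  Note the 1/N_class factor: this is a deliberate departure
  from the conventional softmax cross-entropy; it rescales the loss but
  leaves the argmax decision rule untouched.
* :func:`total_loss` — ``L_track + lambda_wt * L_cls`` for the recurrent
  models (the baseline's total loss is the classification term alone).

Inputs may be plain arrays or autograd tensors; gradients flow through the
prediction argument when it is a :class:`~mitotime.nn.Tensor` that requires
them.
"""

from __future__ import annotations

import numpy as np

from .nn import functional as F
from .nn.tensor import Tensor, as_tensor

__all__ = [
    "EPS",
    "tracking_loss",
    "classification_loss",
    "cross_entropy_loss",
    "total_loss",
    "one_hot",
]

EPS = 1e-7


def one_hot(labels: np.ndarray, n_class: int) -> np.ndarray:
    """1-based stage labels -> one-hot float array (..., n_class)."""
    labels = np.asarray(labels)
    if labels.min() < 1 or labels.max() > n_class:
        raise ValueError(f"labels must lie in 1..{n_class}")
    return np.eye(n_class, dtype=np.float32)[labels - 1]


def _target_array(y) -> np.ndarray:
    return y.data if isinstance(y, Tensor) else np.asarray(y)


def tracking_loss(y, y_hat) -> Tensor:
    """Mean pixelwise BCE between masked-input target and reconstruction."""
    target = _target_array(y)
    y_hat = as_tensor(y_hat)
    if target.shape != y_hat.shape:
        raise ValueError(f"shape mismatch: {target.shape} vs {y_hat.shape}")
    return F.binary_cross_entropy(y_hat, target, EPS).mean()


def classification_loss(y, y_hat) -> Tensor:
    """BCE over class scores, averaged over the N_class entries (and any
    leading batch axes)."""
    target = _target_array(y)
    y_hat = as_tensor(y_hat)
    if target.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {target.shape} vs {y_hat.shape}")
    return F.binary_cross_entropy(y_hat, target, EPS).mean()


def cross_entropy_loss(y, y_hat) -> Tensor:
    """Positive-term cross-entropy, normalized by N_class as printed:
    -(1/N_class) sum_c y_c log(y_hat_c), averaged over any batch axes."""
    target = _target_array(y)
    y_hat = as_tensor(y_hat)
    if target.shape != y_hat.shape:
        raise ValueError(f"length mismatch: {target.shape} vs {y_hat.shape}")
    logp = F.log(F.clamp(y_hat, EPS, 1.0 - EPS))
    return -(as_tensor(target.astype(y_hat.data.dtype, copy=False)) * logp).mean()


def total_loss(l_track, l_cls, lambda_wt: float):
    """Weighted sum L_track + lambda_wt * L_cls."""
    if lambda_wt < 0:
        raise ValueError("lambda_wt must be non-negative")
    return l_track + lambda_wt * as_tensor(l_cls)
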