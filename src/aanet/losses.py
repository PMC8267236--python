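"""The deep-supervision composite loss: BCE, Dice, and the four-term total.

The per-head loss is ``alpha * L_BCE + L_Dice`` with ``alpha = 0.5``; the
network total combines the head groups as

    L_total = lambda1 * (L_down + L_up) + lambda2 * L_dual + L_result

with ``lambda1 = 0.4`` (encoder and decoder supervision) and
``lambda2 = 0.2`` (bottleneck attention head).  ``L_down``/``L_up`` are the
means over their four heads so the lambda weights are head-count invariant.

The Dice term is one minus the smoothed squared-sum Dice similarity
``2 * sum(T P) / (sum(T^2) + sum(P^2) + eps)`` — the similarity itself is
maximized at perfect overlap, so the loss orientation is ``1 - similarity``.
"""

from __future__ import annotations

import dataclasses
from typing import Dict, Tuple, Union

import numpy as np

from .brats_io import RegionTargets
from .network import SupervisionBundle
from .nn import Tensor, astensor
from .nn import tensor as F

#: clamp bound keeping log() finite on saturated probabilities
PROB_CLAMP = 1e-7

ArrayLike = Union[np.ndarray, Tensor]


@dataclasses.dataclass
class LossWeights:
    """Weights of the composite loss (all >= 0; epsilon > 0)."""

    alpha: float = 0.5       # BCE weight inside the per-head loss
    lambda1: float = 0.4     # encoder + decoder supervision weight
    lambda2: float = 0.2     # bottleneck (dual-attention) head weight
    epsilon: float = 1e-5    # Dice smoothing factor

    def __post_init__(self):
        if min(self.alpha, self.lambda1, self.lambda2) < 0:
            raise ValueError("loss weights must be non-negative")
        if self.epsilon <= 0:
            raise ValueError("epsilon must be positive")


def _check_shapes(pred: Tensor, target: Tensor) -> None:
    if pred.shape != target.shape:
        raise ValueError(f"prediction shape {pred.shape} != target shape {target.shape}")


def bce_loss(pred_prob: ArrayLike, target: ArrayLike) -> Tensor:
    """Mean binary cross-entropy over all elements, with probability clamping."""
    pred, target = astensor(pred_prob), astensor(target)
    _check_shapes(pred, target)
    p = F.clip(pred, PROB_CLAMP, 1.0 - PROB_CLAMP)
    return -(target * F.log(p) + (1.0 - target) * F.log(1.0 - p)).mean()


def dice_loss(pred_prob: ArrayLike, target: ArrayLike,
              epsilon: float = 1e-5) -> Tensor:
    """One minus the smoothed Dice similarity.

    For batched/channelled inputs (ndim >= 3) the similarity is computed per
    (sample, channel) over the spatial dims and averaged; flat inputs are
    treated as a single mask.
    """
    pred, target = astensor(pred_prob), astensor(target)
    _check_shapes(pred, target)
    if pred.ndim >= 3:
        axes = tuple(range(pred.ndim - 2, pred.ndim))
    else:
        axes = None
    inter = (pred * target).sum(axis=axes)
    denom = (pred * pred).sum(axis=axes) + (target * target).sum(axis=axes) + epsilon
    return (1.0 - 2.0 * inter / denom).mean()


def combined_loss(pred_prob: ArrayLike, target: ArrayLike,
                  weights: LossWeights = None) -> Tensor:
    """``alpha * BCE + Dice`` — the per-head segmentation loss."""
    w = weights or LossWeights()
    return (w.alpha * bce_loss(pred_prob, target)
            + dice_loss(pred_prob, target, w.epsilon))


def _target_array(target, like: Tensor) -> np.ndarray:
    if isinstance(target, RegionTargets):
        arr = target.stack()
    else:
        arr = np.asarray(target, dtype=np.float32)
    if arr.ndim == like.ndim - 1:
        arr = arr[None]
    return np.broadcast_to(arr, like.shape)


def total_loss(bundle: SupervisionBundle, target,
               weights: LossWeights = None) -> Tuple[Tensor, Dict[str, float]]:
    """The four-term deep-supervision total with a per-term breakdown.

    ``target`` may be a :class:`RegionTargets`, a (3, H, W) stack or a
    batched (B, 3, H, W) array.  Heads whose group weight is zero may be
    absent; a missing head under a positive weight is an error.
    """
    w = weights or LossWeights()
    tgt = _target_array(target, bundle.final_logits)

    def head_loss(logits: Tensor) -> Tensor:
        # accumulate the loss identities in double precision regardless of
        # the network's working dtype
        return combined_loss(F.sigmoid(F.cast(logits, np.float64)), tgt, w)

    def group_mean(heads, name: str, weight: float):
        if not heads:
            if weight > 0:
                raise ValueError(f"{name} heads missing but their weight is positive")
            return None
        losses = [head_loss(h) for h in heads]
        total = losses[0]
        for item in losses[1:]:
            total = total + item
        return total * (1.0 / len(losses))

    l_down = group_mean(bundle.eds_logits, "encoder supervision", w.lambda1)
    l_up = group_mean(bundle.us_logits, "decoder supervision", w.lambda1)
    l_dual = (head_loss(bundle.daf_logits) if bundle.daf_logits is not None
              else None)
    if l_dual is None and w.lambda2 > 0:
        raise ValueError("bottleneck head missing but lambda2 is positive")
    l_result = head_loss(bundle.final_logits)

    total = l_result
    if w.lambda1 > 0:
        total = total + w.lambda1 * (l_down + l_up)
    if w.lambda2 > 0:
        total = total + w.lambda2 * l_dual
    breakdown = {
        "L_down": float(l_down) if l_down is not None else 0.0,
        "L_up": float(l_up) if l_up is not None else 0.0,
        "L_dual": float(l_dual) if l_dual is not None else 0.0,
        "L_result": float(l_result),
        "L_total": float(total),
    }
    return total, breakdown
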