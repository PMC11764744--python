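"""Training loss and learning-rate schedule.

The composite objective is ``0.5 * BCE + Dice``.  BCE is the mean
per-pixel binary cross-entropy; the Dice loss uses squared-magnitude
normalisation with a smoothing term so an empty prediction against an
empty target costs nothing.  Both are defined on per-pixel foreground
probabilities; ``composite_loss_logits`` provides the numerically stable
autograd route used by the trainer (softplus-based BCE on logits).
"""

from __future__ import annotations

import numpy as np

from .nn import autograd as ag

__all__ = ["bce_loss", "dice_loss", "composite_loss", "poly_lr",
           "composite_loss_logits"]

DEFAULT_EPS = 1e-5
DEFAULT_CLIP = 1e-7


def _check_pair(p, g):
    p = np.asarray(p, dtype=np.float64)
    g = np.asarray(g, dtype=np.float64)
    if p.shape != g.shape:
        raise ValueError(f"shape mismatch: {p.shape} vs {g.shape}")
    return p, g


def bce_loss(p, g, clip: float = DEFAULT_CLIP) -> float:
    """Mean binary cross-entropy between probabilities ``p`` and binary
    ground truth ``g``; probabilities are clipped to [clip, 1-clip]."""
    p, g = _check_pair(p, g)
    p = np.clip(p, clip, 1.0 - clip)
    return float(-np.mean(g * np.log(p) + (1.0 - g) * np.log(1.0 - p)))


def dice_loss(p, g, eps: float = DEFAULT_EPS) -> float:
    """1 - (2*sum(p*g) + eps) / (sum(p^2) + sum(g^2) + eps), in [0, 1]."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    p, g = _check_pair(p, g)
    num = 2.0 * np.sum(p * g) + eps
    den = np.sum(p * p) + np.sum(g * g) + eps
    return float(1.0 - num / den)


def composite_loss(p, g, eps: float = DEFAULT_EPS,
                   clip: float = DEFAULT_CLIP, class_axis=None) -> float:
    """0.5 * BCE + Dice.  With ``class_axis`` set, the composite is
    computed per class slice and averaged over classes."""
    p, g = _check_pair(p, g)
    if class_axis is None:
        return 0.5 * bce_loss(p, g, clip) + dice_loss(p, g, eps)
    losses = [
        0.5 * bce_loss(pc, gc, clip) + dice_loss(pc, gc, eps)
        for pc, gc in zip(np.moveaxis(p, class_axis, 0),
                          np.moveaxis(g, class_axis, 0))
    ]
    return float(np.mean(losses))


def poly_lr(epoch: int, initial_lr: float = 1e-3, num_epochs: int = 150,
            power: float = 0.9) -> float:
    """Polynomial decay: lr(epoch) = initial_lr * (1 - epoch/num_epochs)^power."""
    if power <= 0:
        raise ValueError("power must be positive")
    if not 0 <= epoch <= num_epochs:
        raise ValueError(f"epoch must lie in [0, {num_epochs}], got {epoch}")
    return float(initial_lr * (1.0 - epoch / num_epochs) ** power)


def composite_loss_logits(logits, targets, eps: float = DEFAULT_EPS):
    """Autograd composite loss on logits (B, C, H, W) against binary
    targets of the same shape; per-class losses averaged over classes.

    BCE uses the softplus identity ``-[g log s(z) + (1-g) log(1-s(z))] =
    softplus(z) - g z``, which is stable for saturated logits.
    """
    targets = np.asarray(targets, dtype=np.float32)
    if logits.data.shape != targets.shape:
        raise ValueError(
            f"shape mismatch: logits {logits.data.shape} vs targets "
            f"{targets.shape}")
    n_classes = targets.shape[1]
    total = None
    for c in range(n_classes):
        z = ag.narrow(logits, 1, c, 1)
        g = ag.Tensor(targets[:, c:c + 1])
        bce = ag.reduce_mean(ag.softplus(z) - ag.mul(g, z))
        p = ag.sigmoid(z)
        num = ag.reduce_sum(ag.mul(p, g)) * 2.0 + eps
        den = ag.reduce_sum(ag.square(p)) + float(np.sum(targets[:, c] ** 2)) + eps
        dice = 1.0 - num / den
        loss_c = bce * 0.5 + dice
        total = loss_c if total is None else total + loss_c
    return total * (1.0 / n_classes)
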