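"""Adversarial and reconstruction objectives.

The adversarial term is the binary cross-entropy realization of the
conditional GAN objective over patch logits, with one-sided label
smoothing (real target 0.9) applied only when training the
discriminator.  The generator additionally minimizes a mean-absolute
reconstruction term weighted by ``L1_WEIGHT = 60``.
"""

from __future__ import annotations

from . import autograd as ag
from .autograd import Tensor

__all__ = ["L1_WEIGHT", "REAL_LABEL_SMOOTHING", "adversarial_objective", "l1_objective", "total_objective"]

L1_WEIGHT = 60.0
REAL_LABEL_SMOOTHING = 0.9


def adversarial_objective(
    scores_real,
    scores_fake,
    role: str,
    smoothing: float = REAL_LABEL_SMOOTHING,
) -> Tensor:
    """Patch-wise cross-entropy adversarial loss.

    ``role='discriminator'``: classify real pairs toward the smoothed
    positive target and fake pairs toward 0 (sum of the two mean terms).
    ``role='generator'``: drive fake scores toward the *unsmoothed*
    positive target 1.0 (``scores_real`` is ignored and may be None).
    """
    if role == "discriminator":
        return ag.add(
            ag.bce_with_logits(scores_real, smoothing),
            ag.bce_with_logits(scores_fake, 0.0),
        )
    if role == "generator":
        return ag.bce_with_logits(scores_fake, 1.0)
    raise ValueError(f"unknown role {role!r}")


def l1_objective(candidate, target) -> Tensor:
    """Mean absolute difference between candidate and target maps."""
    if not isinstance(candidate, Tensor):
        candidate = Tensor(candidate)
    if not isinstance(target, Tensor):
        target = Tensor(target)
    if candidate.shape != target.shape:
        raise ValueError("candidate/target shape mismatch")
    return ag.tmean(ag.tabs(ag.add(candidate, ag.scale(target, -1.0))))


def total_objective(adversarial, l1, l1_weight: float = L1_WEIGHT) -> Tensor:
    """Combined generator objective: adversarial + l1_weight * L1."""
    return ag.add(adversarial, ag.scale(l1, l1_weight))
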