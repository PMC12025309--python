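"""Hybrid Dice + binary cross-entropy objective with deep supervision.

The per-map hybrid loss is

    L(P, G) = 1 - 2 sum(P G) / (sum(P^2) + sum(G^2) + eps)          (Dice)
            - mean(G log P + (1 - G) log(1 - P))                     (BCE)

and the deeply supervised total sums weighted hybrid losses over the four
SLF maps and the four attentive maps plus the unweighted output loss, with
the empirical layer weights (0.4, 0.5, 0.7, 0.8) on both groups.

BCE is averaged (not summed) over voxels so magnitudes are independent of
resolution; probabilities are clipped to [1e-7, 1 - 1e-7] for stability.
All functions accept NumPy arrays (returning floats) or autodiff tensors
(returning scalar tensors on the tape).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._autodiff import tensor as T
from ._autodiff.tensor import Tensor

DICE_EPS = 1e-5
BCE_CLIP = 1e-7


@dataclass
class LossWeights:
    """Deep-supervision layer weights (level 1 -> 4, shallow to deep)."""

    w_slf: tuple[float, ...] = (0.4, 0.5, 0.7, 0.8)
    w_attn: tuple[float, ...] = (0.4, 0.5, 0.7, 0.8)

    def __post_init__(self):
        if len(self.w_slf) != 4 or len(self.w_attn) != 4:
            raise ValueError("expected 4 weights per group")
        if min(self.w_slf) < 0 or min(self.w_attn) < 0:
            raise ValueError("weights must be non-negative")


@dataclass
class LossBreakdown:
    """Per-component values of a deep-supervision loss evaluation."""

    per_slf: list[float]
    per_attn: list[float]
    out: float
    total: float
    total_tensor: object = field(default=None, repr=False, compare=False)


def _pair(p, g):
    pt = p if isinstance(p, Tensor) else Tensor(p)
    gt = g if isinstance(g, Tensor) else Tensor(np.asarray(g, dtype=np.float32))
    if pt.shape != gt.shape:
        raise ValueError(f"shape mismatch: prediction {pt.shape} vs ground truth {gt.shape}")
    keep = isinstance(p, Tensor) or isinstance(g, Tensor)
    return pt, gt, keep


def dice_loss(p, g, eps: float = DICE_EPS):
    """Soft Dice loss; 0 for a perfect prediction, ~1 for disjoint masks.

    The squared-sum denominator makes the loss exact on binary inputs; the
    smoothing term only disambiguates the empty-vs-empty case (loss -> 0).
    """
    pt, gt, keep = _pair(p, g)
    inter = T.tsum(pt * gt)
    # smoothing in numerator and denominator so empty-vs-empty -> loss 0
    denom = T.tsum(pt * pt) + T.tsum(gt * gt) + eps
    loss = 1.0 - (2.0 * inter + eps) / denom
    return loss if keep else float(loss.data)


def bce_loss(p, g, reduction: str = "mean"):
    """Binary cross-entropy (negative log-likelihood), voxel-averaged by default."""
    if reduction not in ("mean", "sum"):
        raise ValueError("reduction must be 'mean' or 'sum'")
    pt, gt, keep = _pair(p, g)
    pc = T.clip(pt, BCE_CLIP, 1.0 - BCE_CLIP)
    ll = gt * T.log(pc) + (1.0 - gt) * T.log(1.0 - pc)
    loss = -(T.tmean(ll) if reduction == "mean" else T.tsum(ll))
    return loss if keep else float(loss.data)


def output_loss(p, g, reduction: str = "mean"):
    """Hybrid loss: Dice + BCE."""
    pt, gt, keep = _pair(p, g)
    loss = dice_loss(pt, gt) + bce_loss(pt, gt, reduction)
    return loss if keep else float(loss.data)


def total_loss(prediction_set, g, weights: LossWeights | None = None,
               reduction: str = "mean") -> LossBreakdown:
    """Deeply supervised total: weighted SLF + attentive losses plus output loss.

    Returns a breakdown whose ``total`` equals the weighted recombination of
    its components; ``total_tensor`` carries the differentiable scalar.
    """
    if weights is None:
        weights = LossWeights()
    aux_slf = list(prediction_set.aux_slf)
    aux_attn = list(prediction_set.aux_attn)
    if len(aux_slf) != 4 or len(aux_attn) != 4:
        raise ValueError("prediction set must carry 4 + 4 auxiliary maps")

    if isinstance(g, Tensor):
        gt = g
    else:
        arr = g.data if hasattr(g, "data") else g   # LabelMask or ndarray
        gt = Tensor(np.asarray(arr, dtype=np.float32))
    per_slf, per_attn = [], []
    total_t = None

    def hybrid(p):
        pt = p if isinstance(p, Tensor) else Tensor(p)
        return dice_loss(pt, gt) + bce_loss(pt, gt, reduction)

    for w, p in zip(weights.w_slf, aux_slf):
        li = hybrid(p)
        per_slf.append(float(li.data))
        term = w * li
        total_t = term if total_t is None else total_t + term
    for w, p in zip(weights.w_attn, aux_attn):
        lj = hybrid(p)
        per_attn.append(float(lj.data))
        total_t = total_t + w * lj
    lout = hybrid(prediction_set.main)
    total_t = total_t + lout

    # reported total recombined in float64 so it matches its own components
    # exactly; the float32 tape scalar drives backprop
    out_f = float(lout.data)
    total_f = (sum(w * l for w, l in zip(weights.w_slf, per_slf))
               + sum(w * l for w, l in zip(weights.w_attn, per_attn)) + out_f)
    return LossBreakdown(per_slf=per_slf, per_attn=per_attn, out=out_f,
                         total=total_f, total_tensor=total_t)
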