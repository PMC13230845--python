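"""Grad-CAM on the interaction grid and per-channel-group input saliency.

Grad-CAM: forward to the logit, differentiate against the last convolutional
block's feature maps, weight each map by the spatial mean of its gradient,
sum, ReLU, bilinearly resize to the input grid, and min-max normalize.

Channel saliency: the gradient of the logit with respect to the input
tensor, aggregated per channel as the mean absolute gradient over the grid
(absolute values prevent sign cancellation), summed into five groups —
pair identities (16), compatibility, helix runs (diagonal + anti-diagonal),
position, structure — and normalized to shares that sum to 1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

from .featurize import GROUP_SIZES, FeaturizerConfig
from .model import InteractionCNN

SALIENCY_GROUPS = ("PairIDs", "C", "Runs", "Delta", "A")
_GROUP_OF = {"Base16": "PairIDs", "C": "C", "Hdiag": "Runs", "Hanti": "Runs",
             "Delta": "Delta", "A": "A"}


@dataclass
class GradCamMap:
    values: np.ndarray  # L_p x L_m in [0, 1]
    record_id: str = ""
    degenerate: bool = False  # raw map was identically zero


@dataclass
class SaliencyReport:
    shares: dict[str, float]
    n_samples: int
    subset: str = ""
    aggregation: str = "mean_abs_gradient"


def _logit_backward(model: InteractionCNN, X: np.ndarray) -> np.ndarray:
    """d(sum of logits)/d(input) in eval mode; batched over X."""
    logits = model.forward(X, train=False)
    return model.backward(np.ones_like(logits))


def grad_cam(model: InteractionCNN, x: np.ndarray,
             record_id: str = "") -> GradCamMap:
    """Grad-CAM heatmap for one featurized record (Ch x L_p x L_m)."""
    X = x[None] if x.ndim == 3 else x
    L_p, L_m = X.shape[2], X.shape[3]
    model.forward(X, train=False)
    fmap = model.feature_map  # 1 x C x h x w
    model.backward(np.ones(1, dtype=np.float64))
    grad = model.feature_grad
    weights = grad.mean(axis=(2, 3))  # 1 x C
    raw = np.maximum((weights[:, :, None, None] * fmap).sum(axis=1), 0.0)[0]
    hi = raw.max()
    if hi <= 0:
        return GradCamMap(values=np.zeros((L_p, L_m)), record_id=record_id,
                          degenerate=True)
    up = resize(raw.astype(np.float64), (L_p, L_m), order=1, mode="edge",
                anti_aliasing=False)
    lo, hi = up.min(), up.max()
    vals = (up - lo) / (hi - lo) if hi > lo else np.zeros_like(up)
    return GradCamMap(values=vals, record_id=record_id, degenerate=False)


def channel_saliency(model: InteractionCNN, x: np.ndarray,
                     fcfg: FeaturizerConfig) -> dict[str, float]:
    """Per-group saliency shares for one record; shares sum to 1.

    Ablated configurations report shares only over the present groups.
    """
    X = x[None] if x.ndim == 3 else x
    grad = _logit_backward(model, X)[0]           # Ch x L_p x L_m
    per_channel = np.abs(grad).mean(axis=(1, 2))  # mean |grad| per channel

    sums: dict[str, float] = {}
    pos = 0
    for g in fcfg.channel_mask:
        width = GROUP_SIZES[g]
        name = _GROUP_OF[g]
        sums[name] = sums.get(name, 0.0) + float(per_channel[pos:pos + width].sum())
        pos += width
    total = sum(sums.values())
    if total <= 0:
        # degenerate gradient: spread evenly over present groups
        return {g: 1.0 / len(sums) for g in sums}
    return {g: v / total for g, v in sums.items()}


def average_saliency(model: InteractionCNN, X: np.ndarray, labels,
                     fcfg: FeaturizerConfig,
                     split_by_label: bool = True) -> list[SaliencyReport]:
    """Arithmetic mean of per-sample shares, per class."""
    labels = np.asarray(labels)
    subsets = ([("positive", labels == 1), ("negative", labels == 0)]
               if split_by_label else [("all", np.ones(len(X), dtype=bool))])
    reports = []
    for name, sel in subsets:
        if not sel.any():
            raise ValueError(f"empty class for subset {name!r}")
        shares = [channel_saliency(model, X[i], fcfg) for i in np.where(sel)[0]]
        groups = shares[0].keys()
        mean = {g: float(np.mean([s[g] for s in shares])) for g in groups}
        reports.append(SaliencyReport(shares=mean, n_samples=int(sel.sum()),
                                      subset=name))
    return reports


def average_grad_cam(model: InteractionCNN, X: np.ndarray, labels,
                     split_by_label: bool = True) -> dict[str, np.ndarray]:
    """Element-wise mean of per-record normalized Grad-CAM maps, per class."""
    labels = np.asarray(labels)
    subsets = ([("positive", labels == 1), ("negative", labels == 0)]
               if split_by_label else [("all", np.ones(len(X), dtype=bool))])
    out: dict[str, np.ndarray] = {}
    for name, sel in subsets:
        if not sel.any():
            raise ValueError(f"empty class for subset {name!r}")
        maps = [grad_cam(model, X[i]).values for i in np.where(sel)[0]]
        out[name] = np.mean(maps, axis=0)
    return out
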