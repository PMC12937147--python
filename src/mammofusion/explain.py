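"""Grad-CAM saliency over the network's spatial stages.

For a chosen spatial stage A (default: the spatial-attention-refined map,
the last stage with spatial extent before global pooling), the channel
weights are the globally averaged gradients of the pre-sigmoid output logit
with respect to A, and the saliency map is ReLU of the weighted channel sum,
min-max normalised and bilinearly upsampled to the input resolution.
Per-branch maps (stages ``f_cc`` / ``f_mlo``) attribute the decision to one
view at a time.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from skimage.transform import resize as _sk_resize

from .data import PairedSample
from .model import MammoFusionNet

logger = logging.getLogger(__name__)

__all__ = ["SaliencyMap", "gradcam", "overlay", "SPATIAL_STAGES"]

#: stages with spatial extent that Grad-CAM may target
SPATIAL_STAGES = ("f_cc", "f_mlo", "f_fused", "f_attn", "f_refined")

_STAGE_VIEW = {"f_cc": "CC", "f_mlo": "MLO"}


@dataclass
class SaliencyMap:
    heatmap: np.ndarray        # (H, W) in [0, 1], input resolution
    target_stage: str
    view: str                  # {"CC", "MLO", "fused"}
    degenerate: bool = False   # all-zero gradients / activations


def gradcam(model: MammoFusionNet, sample: PairedSample,
            target_stage: str = "f_refined") -> SaliencyMap:
    """Gradient-weighted class activation map for one paired sample."""
    if target_stage not in SPATIAL_STAGES:
        raise ValueError(
            f"target_stage must be a spatial stage {SPATIAL_STAGES}: {target_stage!r}")
    model.eval()
    capture: dict = {}
    logit = model.forward_logit(sample.cc[None], sample.mlo[None], capture)
    if target_stage not in capture:
        raise ValueError(
            f"stage {target_stage!r} is not produced under this model config")
    act = capture[target_stage]
    logit.backward(np.ones_like(logit.data))
    grads = act.grad
    size = model.config.input_size
    view = _STAGE_VIEW.get(target_stage, "fused")
    if grads is None or not np.any(grads):
        logger.warning("gradcam: zero gradient at stage %s; degenerate map", target_stage)
        return SaliencyMap(np.zeros((size, size)), target_stage, view, degenerate=True)
    weights = grads.mean(axis=(1, 2))                       # (1, C)
    cam = np.maximum((act.data * weights[:, None, None, :]).sum(axis=-1)[0], 0.0)
    if cam.max() <= 0:
        logger.warning("gradcam: non-positive activation map; degenerate map")
        return SaliencyMap(np.zeros((size, size)), target_stage, view, degenerate=True)
    heat = _sk_resize(cam, (size, size), order=1, anti_aliasing=False,
                      preserve_range=True)
    heat = np.maximum(heat, 0.0)
    heat = (heat - heat.min()) / (heat.max() - heat.min())
    return SaliencyMap(heat, target_stage, view)


def overlay(image: np.ndarray, saliency: SaliencyMap, alpha: float = 0.4
            ) -> np.ndarray:
    """Alpha-blend the heatmap (jet colormap, red = high) over a grayscale
    image in [0, 1]; returns an (H, W, 3) float RGB array."""
    from matplotlib import cm

    img = np.asarray(image, dtype=np.float64)
    if img.max() > 1.0:
        img = img / 255.0
    heat = saliency.heatmap
    if heat.shape != img.shape:
        heat = _sk_resize(heat, img.shape, order=1, preserve_range=True)
    rgb_heat = cm.jet(np.clip(heat, 0, 1))[..., :3]
    base = np.stack([img] * 3, axis=-1)
    return np.clip((1 - alpha) * base + alpha * rgb_heat, 0.0, 1.0)
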