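"""Grad-CAM heatmaps and stitched slide-level activation maps.

Grad-CAM weights the final convolutional feature maps by the spatial
mean of the gradient of the target-class logit with respect to each map,
sums the weighted maps, rectifies, upsamples bilinearly to the input
size and max-normalizes.  The target layer is the last ReLU before
global average pooling — the only convolutional output feeding the
classification head in the truncated architecture.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from skimage.transform import resize

from .io_formats import GRADES, GradeCode
from .ensemble import EnsembleModel, predict_scores

TARGET_LAYER = "block4.relu"


@dataclasses.dataclass
class Heatmap:
    """Non-negative class-activation raster normalized to [0, 1]."""

    values: np.ndarray
    target_class: int
    layer: str = TARGET_LAYER

    def __post_init__(self) -> None:
        if self.values.min() < 0:
            raise ValueError("heatmap must be non-negative")
        vmax = self.values.max()
        if vmax > 0 and abs(vmax - 1.0) > 1e-9:
            raise ValueError("non-zero heatmap must be max-normalized")


def _prepare_input(model, image: np.ndarray) -> np.ndarray:
    """Accept a raw (H, W, 3) patch or an already-preprocessed NCHW/CHW
    array; raw patches get the training normalization and resize."""
    image = np.asarray(image)
    if image.ndim == 3 and image.shape[-1] == 3 and image.shape[0] != 3:
        x = image.astype(np.float64)
        if x.max() > 1.5:
            x = x / 255.0
        size = getattr(getattr(model, "spec", None), "input_size", None)
        if size and x.shape[:2] != (size, size):
            x = resize(x, (size, size), order=1, anti_aliasing=True)
        return np.moveaxis(x - 0.5, -1, 0)[None]
    if image.ndim == 3:
        return image[None].astype(np.float64)
    if image.ndim == 4:
        return image.astype(np.float64)
    raise ValueError(f"cannot interpret image of shape {image.shape}")


def grad_cam(model, image: np.ndarray, target_class: int) -> Heatmap:
    """Gradient-weighted class activation map for one input.

    The model must expose ``features_and_logits(x)`` and
    ``feature_gradients(dlogits)`` (gradients are taken w.r.t. the
    pre-softmax logit of ``target_class``).  Channel weights are the
    spatial means of those gradients; the map is
    ReLU(sum_k alpha_k A^k), upsampled bilinearly to the input's spatial
    size and normalized by its maximum (all-zero maps stay zero).
    """
    x = _prepare_input(model, image)
    feats, logits = model.features_and_logits(x)
    n_classes = logits.shape[1]
    if not 0 <= target_class < n_classes:
        raise ValueError(f"target_class {target_class} outside [0, {n_classes})")
    dlogits = np.zeros_like(logits)
    dlogits[:, target_class] = 1.0
    grads = model.feature_gradients(dlogits)
    alpha = grads.mean(axis=(2, 3))  # (N, K) spatial-mean channel weights
    cam = np.maximum(np.einsum("k,khw->hw", alpha[0], feats[0]), 0.0)
    out_hw = x.shape[2:]
    if cam.shape != out_hw:
        cam = resize(cam, out_hw, order=1, anti_aliasing=False)
        cam = np.maximum(cam, 0.0)
    vmax = cam.max()
    if vmax > 0:
        cam = cam / vmax
    return Heatmap(values=cam, target_class=target_class)


@dataclasses.dataclass
class SlideActivationMap:
    """Per-grade activation rasters at slide resolution.

    ``coverage`` counts contributing patches per pixel; pixels with zero
    coverage carry no information and are flagged absent rather than
    zero — use :meth:`masked` to retrieve a masked array.
    """

    maps: dict[GradeCode, np.ndarray]
    coverage: np.ndarray

    def masked(self, grade: GradeCode) -> np.ma.MaskedArray:
        return np.ma.masked_array(self.maps[grade], mask=self.coverage == 0)


def slide_activation_map(
    ensemble: EnsembleModel,
    slide: np.ndarray,
    origins: list[tuple[int, int]],
    patch_size: int,
    mode: str = "score",
) -> SlideActivationMap:
    """Stitch per-patch ensemble outputs into slide-resolution maps.

    Each patch window contributes either its scalar positive-class score
    (``mode="score"``) or its Grad-CAM map scaled by that score
    (``mode="gradcam"``) for every grade; overlapping contributions are
    averaged by per-pixel coverage count, so the result is independent
    of patch visiting order.
    """
    if not origins:
        raise ValueError("empty patch grid")
    if mode not in ("score", "gradcam"):
        raise ValueError(f"unknown mode {mode!r}")
    h, w = slide.shape[:2]
    acc = {g: np.zeros((h, w)) for g in GRADES}
    coverage = np.zeros((h, w), dtype=np.int64)
    for r, c in origins:
        if r < 0 or c < 0 or r + patch_size > h or c + patch_size > w:
            raise ValueError(f"patch origin {(r, c)} out of slide bounds")
        patch = slide[r : r + patch_size, c : c + patch_size]
        x = _prepare_input(ensemble.sub_models[GradeCode.G3], patch)
        scores = predict_scores(ensemble, x)
        for g in GRADES:
            if mode == "score":
                contrib = scores[g]
            else:
                cam = grad_cam(ensemble.sub_models[g], patch, target_class=1)
                contrib = resize(cam.values, (patch_size, patch_size), order=1) * scores[g]
            acc[g][r : r + patch_size, c : c + patch_size] += contrib
        coverage[r : r + patch_size, c : c + patch_size] += 1
    covered = coverage > 0
    for g in GRADES:
        acc[g][covered] /= coverage[covered]
    return SlideActivationMap(maps=acc, coverage=coverage)
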