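"""Instance-level attribution and slide heatmaps.

The attribution adapts Grad-CAM to bag models: for each instance j the
raw score is the positive part of the gradient of the bag logit with
respect to that instance's post-attention embedding, dotted with the
embedding itself — the direct analogue of channel-weighted activation
mapping when "spatial positions" are instances.  Raw scores are min-max
normalized per bag to [0, 1]; a constant raw vector normalizes to all
zeros.

Heatmaps paint each patch footprint with a diverging colormap value of
its activation (warm = high, cool = low); unpatched background stays
transparent, and overlapping footprints resolve to the pixelwise maximum
activation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import List, Optional, Tuple, Union

import numpy as np
from matplotlib import colormaps

from .data_model import Bag, PatchRecord
from .model import CamilModel, build_graph

ATTRIBUTION_LAYERS = ("encoder", "attention", "decoder")
DEFAULT_CMAP = "coolwarm"


@dataclass
class InstanceActivationMap:
    """Normalized per-instance activations plus their slide coordinates."""

    slide_id: str
    activations: np.ndarray  # (N,) in [0, 1]
    coords: List[PatchRecord]


def grid_coords(slide_id: str, n: int, patch_size: int = 16) -> List[PatchRecord]:
    """Synthetic raster-grid coordinates for bags without real positions."""
    cols = max(1, int(np.ceil(np.sqrt(n))))
    return [
        PatchRecord(slide_id, (i % cols) * patch_size, (i // cols) * patch_size, patch_size)
        for i in range(n)
    ]


def minmax_normalize(raw: np.ndarray) -> np.ndarray:
    """Min-max to [0, 1]; constant vectors map to all zeros."""
    raw = np.asarray(raw, dtype=np.float64)
    span = raw.max() - raw.min()
    if span <= 0:
        return np.zeros_like(raw)
    return (raw - raw.min()) / span


def instance_activations(
    model: CamilModel, bag: Bag, layer: str = "attention"
) -> InstanceActivationMap:
    """Grad-CAM style attribution of the bag logit to each instance.

    ``layer`` selects the embedding the gradient is taken at (encoder,
    attention or decoder output; default: post-attention).
    """
    if layer not in ATTRIBUTION_LAYERS:
        raise ValueError(f"layer must be one of {ATTRIBUTION_LAYERS}")
    for v in model.params.values():
        if not np.all(np.isfinite(v)):
            raise ValueError("model parameters contain non-finite values")
    p = model._param_tensors()
    logit, _, nodes = build_graph(bag.X, p, model.config.fusion_mode)
    logit.backward()
    node = nodes[layer]
    grad = node.grad if node.grad is not None else np.zeros_like(node.data)
    raw = np.maximum((grad * node.data).sum(axis=1), 0.0)
    coords = bag.coords if bag.coords is not None else grid_coords(bag.slide_id, bag.n_instances)
    return InstanceActivationMap(
        slide_id=bag.slide_id, activations=minmax_normalize(raw), coords=coords
    )


def render_heatmap(
    amap: InstanceActivationMap,
    slide_dims: Tuple[int, int],
    downsample: int = 1,
    cmap: str = DEFAULT_CMAP,
    base_image: Optional[np.ndarray] = None,
    overlay_alpha: float = 0.6,
) -> np.ndarray:
    """Reproject activations onto the slide as an RGBA uint8 raster.

    ``slide_dims`` is (width, height) in level-0 pixels; ``downsample``
    shrinks the output by an integer factor.  Each patch footprint is
    filled with the colormap value of its activation; where footprints
    overlap the maximum activation wins; background pixels get alpha 0
    (or the base image, when one is supplied for an overlay).
    """
    width, height = slide_dims
    if downsample < 1:
        raise ValueError("downsample must be a positive integer")
    out_w, out_h = max(1, width // downsample), max(1, height // downsample)
    act_canvas = np.full((out_h, out_w), -1.0)
    for rec, a in zip(amap.coords, amap.activations):
        if rec.x + rec.level_size > width or rec.y + rec.level_size > height:
            raise ValueError(
                f"patch at ({rec.x}, {rec.y}) size {rec.level_size} exceeds "
                f"slide bounds {width}x{height}"
            )
        x0, y0 = rec.x // downsample, rec.y // downsample
        s = max(1, int(np.ceil(rec.level_size / downsample)))
        x1, y1 = min(out_w, x0 + s), min(out_h, y0 + s)
        region = act_canvas[y0:y1, x0:x1]
        np.maximum(region, a, out=region)
    covered = act_canvas >= 0
    rgba = np.zeros((out_h, out_w, 4), dtype=np.uint8)
    mapper = colormaps[cmap]
    colors = (mapper(np.clip(act_canvas, 0.0, 1.0)) * 255).astype(np.uint8)
    rgba[covered] = colors[covered]
    if base_image is not None:
        base = np.asarray(base_image)
        if base.shape[0] != out_h or base.shape[1] != out_w:
            raise ValueError("base_image must match the downsampled slide dimensions")
        out = base.astype(np.float64).copy()
        out[covered] = (
            (1 - overlay_alpha) * out[covered] + overlay_alpha * colors[covered, :3]
        )
        blended = np.zeros((out_h, out_w, 4), dtype=np.uint8)
        blended[..., :3] = np.round(out).astype(np.uint8)
        blended[..., 3] = 255
        return blended
    return rgba


def activation_color(activation: float, cmap: str = DEFAULT_CMAP) -> np.ndarray:
    """RGBA uint8 colormap value of one activation (round-trip helper)."""
    return (np.asarray(colormaps[cmap](float(activation))) * 255).astype(np.uint8)


def write_activation_csv(amap: InstanceActivationMap, path: Union[str, Path]) -> Path:
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(("slide_id", "x", "y", "activation"))
        for rec, a in zip(amap.coords, amap.activations):
            writer.writerow((amap.slide_id, rec.x, rec.y, f"{a:.6f}"))
    return path
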