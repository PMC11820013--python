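"""Patch feature encoders behind a pluggable interface.

The production encoder is a frozen ImageNet-pretrained 18-layer residual
CNN whose global-average-pool output gives a 512-dimensional vector per
patch; it is an optional extra requiring torch/torchvision.  The
``toy_histogram`` encoder — concatenated per-channel intensity
histograms — is a fast, fully deterministic CPU encoder used throughout
the test bed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Sequence

import numpy as np

ENCODER_NAMES = ("pretrained_cnn", "toy_histogram")


@dataclass
class EncoderSpec:
    name: str = "toy_histogram"
    output_dim: int = 512
    normalize: bool = False

    def __post_init__(self) -> None:
        if self.name not in ENCODER_NAMES:
            raise ValueError(f"unknown encoder {self.name!r}; options: {ENCODER_NAMES}")
        if self.output_dim < 1:
            raise ValueError("output_dim must be >= 1")


def toy_histogram_encoder(patch: np.ndarray, output_dim: int = 512) -> np.ndarray:
    """Per-channel intensity histograms, L1-normalized per channel,
    concatenated and tiled/truncated to ``output_dim``.

    ``output_dim`` must be divisible by 3 (one equal block per RGB
    channel).  Deterministic and invariant to spatial rearrangements of
    the patch pixels (it sees only the per-channel intensity
    distribution).
    """
    patch = np.asarray(patch)
    if patch.ndim != 3 or patch.shape[2] != 3:
        raise ValueError(f"expected an RGB patch, got shape {patch.shape}")
    if output_dim % 3 != 0:
        raise ValueError(f"output_dim must be divisible by 3, got {output_dim}")
    bins = output_dim // 3
    if np.issubdtype(patch.dtype, np.integer):
        lo, hi = 0.0, 256.0
    else:
        lo, hi = 0.0, 1.0 + 1e-9
    blocks = []
    for c in range(3):
        hist, _ = np.histogram(patch[..., c].ravel(), bins=bins, range=(lo, hi))
        total = hist.sum()
        blocks.append(hist / total if total else hist.astype(float))
    return np.concatenate(blocks).astype(np.float32)


def _cnn_encode(patches: Sequence[np.ndarray], spec: EncoderSpec) -> np.ndarray:
    try:
        import torch
        import torchvision
    except ImportError as exc:  # pragma: no cover - exercised only without torch
        raise ImportError(
            "the pretrained_cnn encoder requires torch and torchvision "
            "(install the 'cnn' extra); use the toy_histogram encoder otherwise"
        ) from exc
    model = torchvision.models.resnet18(weights="IMAGENET1K_V1")
    model.fc = torch.nn.Identity()
    model.eval()
    mean = np.array([0.485, 0.456, 0.406])
    std = np.array([0.229, 0.224, 0.225])
    batch = np.stack([np.asarray(p, dtype=np.float64) / 255.0 for p in patches])
    batch = (batch - mean) / std
    with torch.no_grad():
        feats = model(torch.from_numpy(batch.transpose(0, 3, 1, 2)).float())
    return feats.numpy().astype(np.float32)


def encode_patches(patches: Sequence[np.ndarray], spec: EncoderSpec) -> np.ndarray:
    """Encode a list of same-sized RGB patches into an N x output_dim matrix.

    Row order follows input order; repeated runs on the same input are
    bit-identical (inference only, no augmentation).
    """
    patches = list(patches)
    if patches:
        shapes = {p.shape for p in map(np.asarray, patches)}
        if len(shapes) > 1:
            raise ValueError(f"patches have mixed shapes: {sorted(shapes)}")
    if spec.name == "toy_histogram":
        if not patches:
            out = np.zeros((0, spec.output_dim), dtype=np.float32)
        else:
            out = np.stack([toy_histogram_encoder(p, spec.output_dim) for p in patches])
    else:
        if not patches:
            out = np.zeros((0, spec.output_dim), dtype=np.float32)
        else:
            out = _cnn_encode(patches, spec)
            if out.shape[1] != spec.output_dim:
                raise ValueError(
                    f"encoder produced {out.shape[1]}-dim features, spec says {spec.output_dim}"
                )
    if spec.normalize and len(out):
        norms = np.linalg.norm(out, axis=1, keepdims=True)
        out = np.divide(out, norms, out=np.zeros_like(out), where=norms > 0)
    return out.astype(np.float32)
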