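"""Synthetic MIL bags and synthetic slide rasters — the download-free test bed.

Feature bags emulate the statistical structure the model is built for:
each bag holds N standard-Gaussian instances in ``feature_dim`` channels;
in a positive bag a small *witness* subset (``ceil(witness_rate * N)``
instances, default rate 0.1, mirroring the observation that tumor tissue
typically covers under 10% of a positive slide) receives a mean shift of
``effect_size`` on the first ``signal_channels`` channels.  Bag labels
therefore satisfy the MIL assumption by construction, and the recorded
instance labels provide ground truth the model never sees.

Synthetic slides are white canvases with saturated pink tissue blobs plus
an exact ground-truth tissue mask, used to test tiling and tissue
filtering against a known answer.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Tuple

import numpy as np
from skimage.draw import disk

from .data_model import Bag

TISSUE_RGB = (214, 61, 134)  # saturated H&E-like pink


@dataclass
class SynthConfig:
    n_bags: int = 200
    n_min: int = 20
    n_max: int = 60
    feature_dim: int = 512
    witness_rate: float = 0.1
    effect_size: float = 2.0
    signal_channels: int = 8
    positive_bag_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bags < 2:
            raise ValueError("need at least 2 bags")
        if not 1 <= self.n_min <= self.n_max:
            raise ValueError("need 1 <= n_min <= n_max")
        if not 0.0 < self.witness_rate <= 1.0:
            raise ValueError("witness_rate must lie in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if not 0 < self.signal_channels <= self.feature_dim:
            raise ValueError("signal_channels must lie in [1, feature_dim]")
        if not 0.0 < self.positive_bag_fraction < 1.0:
            raise ValueError("positive_bag_fraction must lie in (0, 1)")


def make_bags(cfg: SynthConfig) -> List[Bag]:
    """Generate seed-deterministic synthetic bags.

    Exactly ``round(n_bags * positive_bag_fraction)`` bags are positive,
    in a seed-shuffled order.  Signal lives on channels
    ``0..signal_channels-1``.  Features are float32 (the feature-store
    dtype).
    """
    rng = np.random.default_rng(cfg.seed)
    n_pos = int(round(cfg.n_bags * cfg.positive_bag_fraction))
    labels = np.zeros(cfg.n_bags, dtype=int)
    labels[:n_pos] = 1
    rng.shuffle(labels)
    bags: List[Bag] = []
    for i, y in enumerate(labels):
        n = int(rng.integers(cfg.n_min, cfg.n_max + 1))
        X = rng.standard_normal((n, cfg.feature_dim))
        inst = np.zeros(n, dtype=int)
        if y == 1:
            n_wit = int(np.ceil(cfg.witness_rate * n))
            wit = rng.choice(n, size=n_wit, replace=False)
            X[np.ix_(wit, np.arange(cfg.signal_channels))] += cfg.effect_size
            inst[wit] = 1
        bags.append(
            Bag(
                slide_id=f"synth_{i:04d}",
                X=X.astype(np.float32),
                y=int(y),
                instance_labels=inst,
            )
        )
    return bags


@dataclass
class SynthSlideConfig:
    width: int = 1024
    height: int = 768
    n_tissue_blobs: int = 6
    blob_radius_min: int = 40
    blob_radius_max: int = 120
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.width, self.height) < 1:
            raise ValueError("slide dimensions must be positive")
        if self.n_tissue_blobs < 0:
            raise ValueError("n_tissue_blobs must be >= 0")
        if not 1 <= self.blob_radius_min <= self.blob_radius_max:
            raise ValueError("need 1 <= blob_radius_min <= blob_radius_max")
        if self.n_tissue_blobs > 0 and 2 * self.blob_radius_max > min(self.width, self.height):
            raise ValueError("largest blob does not fit inside the canvas")


def make_slide(cfg: SynthSlideConfig) -> Tuple[np.ndarray, np.ndarray]:
    """Render a synthetic slide raster and its ground-truth tissue mask.

    Returns ``(image, mask)``: a (H, W, 3) uint8 RGB canvas, white with
    saturated pink disks, and the boolean union of the disks.
    Deterministic per seed; blobs always fit within the canvas.
    """
    rng = np.random.default_rng(cfg.seed)
    image = np.full((cfg.height, cfg.width, 3), 255, dtype=np.uint8)
    mask = np.zeros((cfg.height, cfg.width), dtype=bool)
    for _ in range(cfg.n_tissue_blobs):
        r = int(rng.integers(cfg.blob_radius_min, cfg.blob_radius_max + 1))
        cy = int(rng.integers(r, cfg.height - r + 1))
        cx = int(rng.integers(r, cfg.width - r + 1))
        rr, cc = disk((cy, cx), r, shape=mask.shape)
        mask[rr, cc] = True
    image[mask] = TISSUE_RGB
    return image, mask
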