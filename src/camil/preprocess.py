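"""Slide tiling and tissue filtering.

A slide raster is cut into non-overlapping square patches (default
256 x 256) at one or two magnifications (20x, 10x); patches whose tissue
area falls below a threshold (default 35%, strict "less than" is
discarded) are filtered out.

Tissue detection: the image is converted to HSV and the saturation
channel thresholded with Otsu's method computed per slide — H&E tissue is
strongly saturated (pink/purple) while glass background is near-white and
unsaturated.  When the saturation histogram is degenerate (e.g. an
all-white or fully stained patch) a fixed fallback threshold of 0.15 is
used instead, since Otsu needs two modes to separate.

Plain rasters declare their magnification; 10x is derived from a 20x base
raster by exact 2x2 block averaging.  Patch coordinates are always
reported in level-0 (base magnification) pixels.  Border tiles that do
not fully fit are dropped.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
from skimage.color import rgb2hsv
from skimage.filters import threshold_otsu

from .data_model import MAGNIFICATIONS, PatchRecord

_MAG_POWER = {"20x": 20, "10x": 10}
_FALLBACK_SAT_THRESHOLD = 0.15


@dataclass
class TilingConfig:
    patch_size: int = 256
    magnifications: Tuple[str, ...] = ("20x",)
    min_tissue_fraction: float = 0.35
    stride: Optional[int] = None  # None -> non-overlapping (= patch_size)

    def __post_init__(self) -> None:
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if self.stride is None:
            self.stride = self.patch_size
        if self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0.0 <= self.min_tissue_fraction <= 1.0:
            raise ValueError("min_tissue_fraction must lie in [0, 1]")
        for m in self.magnifications:
            if m not in MAGNIFICATIONS:
                raise ValueError(f"unsupported magnification {m!r}")


def _as_rgb(image: np.ndarray) -> np.ndarray:
    image = np.asarray(image)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError(f"expected an RGB (H, W, 3) raster, got shape {image.shape}")
    return image


def saturation_threshold(image: np.ndarray) -> float:
    """Per-slide Otsu threshold on the HSV saturation channel."""
    sat = rgb2hsv(_as_rgb(image))[..., 1]
    if float(sat.max() - sat.min()) < 1e-3:
        return _FALLBACK_SAT_THRESHOLD
    return float(threshold_otsu(sat))


def tissue_mask(image: np.ndarray, sat_threshold: Optional[float] = None) -> np.ndarray:
    """Boolean mask of tissue pixels (saturation above threshold)."""
    sat = rgb2hsv(_as_rgb(image))[..., 1]
    if sat_threshold is None:
        sat_threshold = saturation_threshold(image)
    return sat > sat_threshold


def tissue_fraction(patch: np.ndarray, sat_threshold: Optional[float] = None) -> float:
    """Fraction of a patch's pixels classified as tissue, in [0, 1].

    With no explicit threshold the patch's own Otsu threshold is used;
    :func:`tile_slide` always passes the slide-level threshold so that
    filtering is consistent across the slide.
    """
    mask = tissue_mask(patch, sat_threshold)
    return float(mask.mean())


def downsample2x(image: np.ndarray) -> np.ndarray:
    """Exact 2x2 block-average downsampling (trailing odd row/col dropped)."""
    image = _as_rgb(image)
    was_int = np.issubdtype(image.dtype, np.integer)
    img = image.astype(np.float64)
    h, w = img.shape[0] // 2 * 2, img.shape[1] // 2 * 2
    img = img[:h, :w]
    out = (img[0::2, 0::2] + img[1::2, 0::2] + img[0::2, 1::2] + img[1::2, 1::2]) / 4.0
    return np.round(out).astype(np.uint8) if was_int else out


def _level_image(image: np.ndarray, base_mag: str, target_mag: str) -> Tuple[np.ndarray, int]:
    """Return (raster at target magnification, level-0 scale factor)."""
    base, target = _MAG_POWER[base_mag], _MAG_POWER[target_mag]
    if target > base:
        raise ValueError(f"cannot tile at {target_mag} from a {base_mag} raster")
    factor = base // target
    out = image
    f = factor
    while f > 1:
        out = downsample2x(out)
        f //= 2
    return out, factor


def tile_slide(
    image: np.ndarray,
    slide_id: str,
    cfg: Optional[TilingConfig] = None,
    base_magnification: str = "20x",
) -> List[PatchRecord]:
    """Tile a slide raster into patch records with tissue fractions.

    Records lie on a regular grid per requested magnification; an image
    smaller than one patch at a requested magnification is an error.
    """
    cfg = cfg or TilingConfig()
    image = _as_rgb(image)
    records: List[PatchRecord] = []
    for mag in cfg.magnifications:
        level, factor = _level_image(image, base_magnification, mag)
        h, w = level.shape[:2]
        if h < cfg.patch_size or w < cfg.patch_size:
            raise ValueError(
                f"slide {slide_id!r} is {w}x{h} at {mag}, smaller than one "
                f"{cfg.patch_size}px patch"
            )
        thr = saturation_threshold(level)
        for y in range(0, h - cfg.patch_size + 1, cfg.stride):
            for x in range(0, w - cfg.patch_size + 1, cfg.stride):
                patch = level[y : y + cfg.patch_size, x : x + cfg.patch_size]
                frac = tissue_fraction(patch, thr)
                records.append(
                    PatchRecord(
                        slide_id=slide_id,
                        x=x * factor,
                        y=y * factor,
                        level_size=cfg.patch_size,
                        magnification=mag,
                        tissue_fraction=frac,
                    )
                )
    return records


def filter_patches(
    records: Sequence[PatchRecord], min_tissue_fraction: float = 0.35
) -> List[PatchRecord]:
    """Keep records with tissue_fraction >= threshold ("less than" is
    filtered out, strictly); input order preserved."""
    kept = []
    for r in records:
        if r.tissue_fraction is None:
            raise ValueError(f"record at ({r.x}, {r.y}) has no tissue_fraction")
        if r.tissue_fraction >= min_tissue_fraction:
            kept.append(r)
    return kept


def extract_patch(
    image: np.ndarray, record: PatchRecord, base_magnification: str = "20x"
) -> np.ndarray:
    """Cut the pixel data of one record back out of the slide raster."""
    level, factor = _level_image(_as_rgb(image), base_magnification, record.magnification)
    x, y, s = record.x // factor, record.y // factor, record.level_size
    return level[y : y + s, x : x + s]


MANIFEST_FIELDS = ("slide_id", "x", "y", "size", "magnification", "tissue_fraction")


def write_manifest(records: Sequence[PatchRecord], path: Union[str, Path]) -> Path:
    """Write a patch manifest CSV."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(MANIFEST_FIELDS)
        for r in records:
            writer.writerow(
                [r.slide_id, r.x, r.y, r.level_size, r.magnification,
                 "" if r.tissue_fraction is None else f"{r.tissue_fraction:.6f}"]
            )
    return path


def read_manifest(path: Union[str, Path]) -> List[PatchRecord]:
    records = []
    with Path(path).open() as fh:
        reader = csv.DictReader(fh)
        for row in reader:
            records.append(
                PatchRecord(
                    slide_id=row["slide_id"],
                    x=int(row["x"]),
                    y=int(row["y"]),
                    level_size=int(row["size"]),
                    magnification=row["magnification"],
                    tissue_fraction=float(row["tissue_fraction"]) if row["tissue_fraction"] else None,
                )
            )
    return records


def load_image(path: Union[str, Path]) -> np.ndarray:
    """Load a plain PNG/TIFF raster as an RGB uint8 array."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        import tifffile

        arr = tifffile.imread(path)
    else:
        from PIL import Image

        arr = np.asarray(Image.open(path).convert("RGB"))
    return _as_rgb(arr)
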