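"""Core data containers: patch records, bags and the HDF5 feature store.

A *bag* is one slide's worth of patch feature vectors together with the
slide-level binary label — the unit of weak supervision in multiple
instance learning.  Under the standard MIL assumption a bag is positive
iff it contains at least one positive instance; negative bags contain only
negative instances.  ``Bag.instance_labels`` carries synthetic ground
truth for evaluation only and is never consumed by the model, whose API
accepts just the feature matrix.

The on-disk feature store is a flat HDF5 file with one group per slide:

    /<slide_id>/features   float32, N x C
    /<slide_id>/coords     int64,   N x 2   (level-0 x, y of patch corner)
    /<slide_id>.attrs      label (int), magnification (str), patch_size (int)
    /.attrs                feature_dim (int)

Coordinates are 0-based level-0 pixel offsets of the patch top-left
corner; a patch occupies the half-open square [x, x+size) x [y, y+size).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Union

import h5py
import numpy as np

MAGNIFICATIONS = ("20x", "10x")
DEFAULT_FEATURE_DIM = 512


@dataclass
class PatchRecord:
    """One tissue patch: where it sits on the slide and how much tissue it holds."""

    slide_id: str
    x: int
    y: int
    level_size: int
    magnification: str = "20x"
    tissue_fraction: Optional[float] = None

    def __post_init__(self) -> None:
        if self.x < 0 or self.y < 0:
            raise ValueError(f"patch offsets must be non-negative, got ({self.x}, {self.y})")
        if self.level_size <= 0:
            raise ValueError(f"patch size must be positive, got {self.level_size}")
        if self.magnification not in MAGNIFICATIONS:
            raise ValueError(f"magnification must be one of {MAGNIFICATIONS}")
        if self.tissue_fraction is not None and not 0.0 <= self.tissue_fraction <= 1.0:
            raise ValueError(f"tissue_fraction must lie in [0, 1], got {self.tissue_fraction}")


@dataclass
class Bag:
    """One slide's instances plus its weak label.

    Parameters
    ----------
    slide_id : str
    X : (N, C) float array of instance features.
    y : slide label in {0, 1}.
    coords : optional list of N :class:`PatchRecord` mapping instances back
        to slide positions (absent for purely synthetic bags).
    instance_labels : optional (N,) binary array of per-instance ground
        truth.  Synthetic-data bookkeeping only — evaluation code may read
        it, the model never does.
    """

    slide_id: str
    X: np.ndarray
    y: int
    coords: Optional[List[PatchRecord]] = None
    instance_labels: Optional[np.ndarray] = field(default=None, repr=False)

    @property
    def n_instances(self) -> int:
        return int(self.X.shape[0])

    @property
    def n_channels(self) -> int:
        return int(self.X.shape[1])


def validate_bag(bag: Bag) -> Bag:
    """Check all bag invariants; return the bag unchanged if they hold.

    Raises
    ------
    ValueError
        On an empty bag, non-finite features, a label outside {0, 1}, a
        coords/feature length mismatch, or an instance-label assignment
        that contradicts the MIL assumption (a negative bag must contain
        only negative instances; a positive bag at least one positive).
    """
    X = np.asarray(bag.X)
    if X.ndim != 2 or X.shape[0] < 1:
        raise ValueError(f"empty or malformed bag: feature matrix shape {X.shape}")
    if not np.all(np.isfinite(X)):
        raise ValueError(f"non-finite features in bag {bag.slide_id!r}")
    if bag.y not in (0, 1):
        raise ValueError(f"bag label must be 0 or 1, got {bag.y!r}")
    if bag.coords is not None and len(bag.coords) != X.shape[0]:
        raise ValueError(
            f"bag {bag.slide_id!r}: {len(bag.coords)} coords for {X.shape[0]} instances"
        )
    if bag.instance_labels is not None:
        labels = np.asarray(bag.instance_labels)
        if labels.shape != (X.shape[0],):
            raise ValueError(f"instance_labels shape {labels.shape} != ({X.shape[0]},)")
        if not np.isin(labels, (0, 1)).all():
            raise ValueError("instance labels must be binary")
        any_pos = bool(labels.any())
        if bag.y == 0 and any_pos:
            raise ValueError(
                f"MIL contradiction in bag {bag.slide_id!r}: negative bag with a positive instance"
            )
        if bag.y == 1 and not any_pos:
            raise ValueError(
                f"MIL contradiction in bag {bag.slide_id!r}: positive bag with no positive instance"
            )
    return bag


def write_feature_store(bags: Sequence[Bag], path: Union[str, Path]) -> Path:
    """Write bags to an HDF5 feature store; returns the path.

    All bags must share the same channel count, which is recorded once as
    the root ``feature_dim`` attribute.  Features are stored as float32.
    Instance labels are deliberately NOT written — see
    :func:`write_instance_label_sidecar`.
    """
    bags = list(bags)
    if not bags:
        raise ValueError("cannot write an empty feature store")
    dims = {b.n_channels for b in bags}
    if len(dims) > 1:
        raise ValueError(f"bags have mixed channel counts: {sorted(dims)}")
    ids = [b.slide_id for b in bags]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate slide_id among bags")
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.attrs["feature_dim"] = int(dims.pop())
        for bag in bags:
            validate_bag(bag)
            grp = f.create_group(bag.slide_id)
            grp.create_dataset("features", data=np.asarray(bag.X, dtype=np.float32))
            if bag.coords is not None:
                coords = np.array([[r.x, r.y] for r in bag.coords], dtype=np.int64)
                grp.attrs["magnification"] = bag.coords[0].magnification
                grp.attrs["patch_size"] = int(bag.coords[0].level_size)
            else:
                coords = np.zeros((bag.n_instances, 2), dtype=np.int64)
                coords[:, 0] = np.arange(bag.n_instances)
                grp.attrs["magnification"] = "20x"
                grp.attrs["patch_size"] = 1
                grp.attrs["synthetic_coords"] = True
            grp.create_dataset("coords", data=coords)
            grp.attrs["label"] = int(bag.y)
    return path


def read_feature_store(
    path: Union[str, Path], slide_ids: Optional[Sequence[str]] = None
) -> List[Bag]:
    """Read bags back in deterministic (lexicographic slide_id) order."""
    path = Path(path)
    bags: List[Bag] = []
    with h5py.File(path, "r") as f:
        available = sorted(k for k in f.keys())
        if slide_ids is None:
            wanted = available
        else:
            missing = sorted(set(slide_ids) - set(available))
            if missing:
                raise KeyError(f"slide ids not in store: {missing}")
            wanted = sorted(slide_ids)
        for sid in wanted:
            grp = f[sid]
            X = grp["features"][...]
            coords_arr = grp["coords"][...]
            if coords_arr.shape[0] != X.shape[0]:
                raise ValueError(
                    f"store corrupt for {sid!r}: {coords_arr.shape[0]} coords, "
                    f"{X.shape[0]} feature rows"
                )
            if grp.attrs.get("synthetic_coords", False):
                coords = None
            else:
                mag = str(grp.attrs.get("magnification", "20x"))
                size = int(grp.attrs.get("patch_size", 256))
                coords = [
                    PatchRecord(sid, int(x), int(y), size, mag) for x, y in coords_arr
                ]
            bags.append(Bag(slide_id=sid, X=X, y=int(grp.attrs["label"]), coords=coords))
    return bags


def write_instance_label_sidecar(bags: Sequence[Bag], path: Union[str, Path]) -> Path:
    """Write ground-truth instance labels to a JSON sidecar, kept apart
    from the model-visible feature store."""
    import json

    payload = {
        b.slide_id: [int(v) for v in np.asarray(b.instance_labels)]
        for b in bags
        if b.instance_labels is not None
    }
    path = Path(path)
    path.write_text(json.dumps(payload, indent=0, sort_keys=True))
    return path


def attach_instance_labels(bags: Sequence[Bag], sidecar: Union[str, Path]) -> List[Bag]:
    """Re-attach sidecar instance labels (evaluation convenience)."""
    import json

    payload = json.loads(Path(sidecar).read_text())
    out = []
    for b in bags:
        if b.slide_id in payload:
            b.instance_labels = np.asarray(payload[b.slide_id], dtype=np.int64)
        out.append(b)
    return out
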