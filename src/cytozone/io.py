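"""Raster I/O for fields of view, masks and categorical ground truth.

A field of view (FOV) is a set of co-registered single-channel intensity
rasters, one per stain, keyed by *role* rather than acquisition order:

* ``nuclear``      -- DNA dye (Hoechst)
* ``cytoskeleton`` -- vimentin fibrils (V9 clone)
* ``cytoplasm``    -- diffuse cytoplasmic stain (anti-ENO1)
* ``antibody``     -- the test antibody whose distribution is quantified

Channels are stored as individual single-plane TIFFs with a JSON sidecar
mapping roles to files; categorical ground truth uses a fixed 5-class
taxonomy (see :data:`CLASS_LEGEND`).  All coordinates are row-major,
origin top-left, 0-based.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import tifffile

CHANNEL_ROLES = ("nuclear", "cytoskeleton", "cytoplasm", "antibody")

#: Fixed class-id convention for categorical ground-truth images.
CLASS_LEGEND: dict[int, str] = {
    0: "background",
    1: "target_subcellular",
    2: "target_nucleus",
    3: "other_subcellular",
    4: "other_nucleus",
}

N_CLASSES = 5


class ChannelShapeError(ValueError):
    """Channels of one FOV do not share identical dimensions."""


@dataclass
class FOV:
    """Named set of co-registered single-channel intensity rasters.

    Parameters
    ----------
    channels
        Mapping from role name to 2-D non-negative integer raster.
    bit_depth
        Declared container depth; intensities must be <= 2**bit_depth - 1.
    """

    channels: dict[str, np.ndarray]
    bit_depth: int = 16
    fov_id: str = "fov"

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("FOV requires at least one channel")
        shapes = {role: ch.shape for role, ch in self.channels.items()}
        first = next(iter(shapes.values()))
        bad = [r for r, s in shapes.items() if s != first]
        if bad:
            raise ChannelShapeError(
                f"channel shape mismatch: roles {sorted(bad)} differ from "
                f"{next(iter(shapes))} {first}"
            )
        if len(first) != 2:
            raise ValueError("channels must be single-plane 2-D rasters")
        limit = 2 ** self.bit_depth - 1
        for role, ch in self.channels.items():
            if not np.issubdtype(ch.dtype, np.integer):
                raise TypeError(f"channel {role!r} must be integer-valued")
            if ch.size and (ch.min() < 0 or ch.max() > limit):
                raise ValueError(
                    f"channel {role!r} exceeds declared {self.bit_depth}-bit range"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return next(iter(self.channels.values())).shape

    @property
    def height(self) -> int:
        return self.shape[0]

    @property
    def width(self) -> int:
        return self.shape[1]

    def channel(self, role: str) -> np.ndarray:
        try:
            return self.channels[role]
        except KeyError:
            raise KeyError(
                f"no channel with role {role!r}; present: {sorted(self.channels)}"
            ) from None


@dataclass
class GroundTruthImage:
    """Categorical per-pixel class image with the 5-class legend."""

    labels: np.ndarray
    legend: Mapping[int, str] = field(default_factory=lambda: dict(CLASS_LEGEND))

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            raise TypeError("class labels must be integral")
        present = np.unique(self.labels)
        if present.size and (present.min() < 0 or present.max() >= N_CLASSES):
            raise ValueError(f"illegal class ids {present[(present < 0) | (present >= N_CLASSES)]}")

    def class_counts(self) -> dict[int, int]:
        return {c: int(np.count_nonzero(self.labels == c)) for c in range(N_CLASSES)}


def _read_plane(path: Path) -> np.ndarray:
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a single-plane raster, got shape {arr.shape}")
    return arr


def read_fov(paths: Mapping[str, str | Path], fov_id: str = "fov") -> FOV:
    """Read one single-channel raster per role and assemble a FOV.

    Raises a hard error naming the offending roles when channel shapes
    disagree, and when any file holds more than one plane.
    """
    channels: dict[str, np.ndarray] = {}
    bit_depth = 16
    for role, p in paths.items():
        p = Path(p)
        if not p.exists():
            raise FileNotFoundError(f"channel {role!r}: {p} does not exist")
        arr = _read_plane(p)
        channels[role] = arr
        bit_depth = max(bit_depth, int(arr.dtype.itemsize) * 8) if arr.dtype.itemsize * 8 > 16 else bit_depth
    depths = {ch.dtype.itemsize * 8 for ch in channels.values()}
    bit_depth = max(depths)
    return FOV(channels=channels, bit_depth=bit_depth, fov_id=fov_id)


def write_fov(fov: FOV, directory: str | Path, stem: str | None = None) -> dict[str, Path]:
    """Write each channel as a single-plane TIFF plus a JSON role sidecar."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = stem or fov.fov_id
    dtype = np.uint16 if fov.bit_depth > 8 else np.uint8
    out: dict[str, Path] = {}
    for role, ch in fov.channels.items():
        p = directory / f"{stem}_{role}.tif"
        tifffile.imwrite(p, ch.astype(dtype))
        out[role] = p
    sidecar = directory / f"{stem}_channels.json"
    sidecar.write_text(
        json.dumps(
            {
                "fov_id": fov.fov_id,
                "bit_depth": fov.bit_depth,
                "channels": {r: p.name for r, p in out.items()},
            },
            indent=2,
        )
    )
    out["sidecar"] = sidecar
    return out


def read_fov_sidecar(sidecar: str | Path) -> FOV:
    """Re-assemble a FOV from the JSON sidecar written by :func:`write_fov`."""
    sidecar = Path(sidecar)
    meta = json.loads(sidecar.read_text())
    paths = {role: sidecar.parent / name for role, name in meta["channels"].items()}
    fov = read_fov(paths, fov_id=meta.get("fov_id", "fov"))
    fov.bit_depth = int(meta.get("bit_depth", fov.bit_depth))
    return fov


def write_mask(mask: np.ndarray, path: str | Path, binary_values: tuple[int, int] = (0, 255)) -> Path:
    """Write a binary or label mask losslessly.

    Binary (bool) masks are stored 8-bit using ``binary_values``; label
    masks are stored 16-bit.  Label counts beyond the 16-bit container
    raise an error.
    """
    path = Path(path)
    mask = np.asarray(mask)
    if mask.dtype == bool:
        lo, hi = binary_values
        arr = np.where(mask, np.uint8(hi), np.uint8(lo))
        tifffile.imwrite(path, arr)
        return path
    if not np.issubdtype(mask.dtype, np.integer):
        raise TypeError("mask dtype must be integral or bool")
    if mask.size and mask.max() > np.iinfo(np.uint16).max:
        raise OverflowError(
            f"label {int(mask.max())} exceeds 16-bit mask container (max 65535)"
        )
    if mask.size and mask.min() < 0:
        raise ValueError("labels must be non-negative")
    tifffile.imwrite(path, mask.astype(np.uint16))
    return path


def read_mask(path: str | Path, binary: bool = False) -> np.ndarray:
    """Read a mask written by :func:`write_mask`.

    With ``binary=True`` any nonzero pixel is foreground.
    """
    arr = _read_plane(Path(path))
    return arr > 0 if binary else arr.astype(np.int32)


def write_ground_truth(gt: GroundTruthImage, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, gt.labels.astype(np.uint8))
    legend_path = path.with_suffix(".legend.json")
    legend_path.write_text(json.dumps({int(k): v for k, v in gt.legend.items()}, indent=2))
    return path


def read_ground_truth(path: str | Path) -> GroundTruthImage:
    path = Path(path)
    labels = _read_plane(path).astype(np.int32)
    legend_path = path.with_suffix(".legend.json")
    legend = dict(CLASS_LEGEND)
    if legend_path.exists():
        legend = {int(k): v for k, v in json.loads(legend_path.read_text()).items()}
    return GroundTruthImage(labels=labels, legend=legend)
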