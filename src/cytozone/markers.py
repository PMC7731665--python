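"""Nucleus labelling and per-nucleus composite marker images.

Instance segmentation is reduced to semantic segmentation by building,
for every nucleus, a composite image in which that nucleus is marked
green, every other nucleus red, and the binarized structure channel
(cytoskeleton or cytoplasm) is carried alongside.  A per-pixel classifier
then only ever has to answer one question: which structure pixels belong
to *the* green nucleus.

Nuclear "boundary" classes are implemented as filled nuclear objects
rather than 1-px contours, which keeps class areas well defined and
conserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .io import CLASS_LEGEND, GroundTruthImage
from .preprocess import FG_STRUCTURE


@dataclass
class NucleusLabelMap:
    """Connected-component nucleus labels, consecutively numbered 1..n."""

    labels: np.ndarray
    n_nuclei: int
    areas: dict[int, int]

    def ids(self) -> list[int]:
        return list(range(1, self.n_nuclei + 1))


@dataclass
class CompositeMarkerImage:
    """Three binary planes: target nucleus (green), other nuclei (red),
    and the binarized structure channel."""

    target_id: int
    green_plane: np.ndarray
    red_plane: np.ndarray
    structure_plane: np.ndarray
    channel_role: str = "cytoskeleton"
    class_legend: dict[int, str] = field(default_factory=lambda: dict(CLASS_LEGEND))

    def __post_init__(self) -> None:
        g, r, s = (np.asarray(p, dtype=bool) for p in (self.green_plane, self.red_plane, self.structure_plane))
        if not (g.shape == r.shape == s.shape):
            raise ValueError("composite planes must share dimensions")
        if (g & r).any():
            raise ValueError("green and red nuclear planes overlap")
        if not g.any():
            raise ValueError("green (target) plane is empty")
        self.green_plane, self.red_plane, self.structure_plane = g, r, s

    @property
    def shape(self) -> tuple[int, int]:
        return self.green_plane.shape

    def to_planes(self) -> np.ndarray:
        """Stack as an (3, H, W) RGB-like binary array (R=other, G=target, B=structure)."""
        return np.stack([self.red_plane, self.green_plane, self.structure_plane]).astype(np.uint8)


def label_nuclei(binary_nuclear: np.ndarray, min_area: int = 50) -> NucleusLabelMap:
    """Label 8-connected nuclear objects, drop those below ``min_area``,
    and renumber survivors consecutively in raster-scan order."""
    mask = np.asarray(binary_nuclear, dtype=bool)
    raw, n = ndimage.label(mask, structure=FG_STRUCTURE)
    if n:
        sizes = np.bincount(raw.ravel())
        keep = np.flatnonzero(sizes >= min_area)
        keep = keep[keep > 0]
    else:
        keep = np.array([], dtype=int)
    if keep.size == 0:
        raise ValueError("no markers: no nuclear object survives the area filter")
    remap = np.zeros(n + 1, dtype=np.int32)
    remap[keep] = np.arange(1, keep.size + 1)  # raw labels are in raster order
    labels = remap[raw]
    areas = {int(new): int(sizes[old]) for new, old in enumerate(keep, start=1)}
    return NucleusLabelMap(labels=labels, n_nuclei=int(keep.size), areas=areas)


def make_composite(
    nuclei: NucleusLabelMap,
    structure: np.ndarray,
    target_id: int,
    channel_role: str = "cytoskeleton",
) -> CompositeMarkerImage:
    """Build the composite marker image for one target nucleus."""
    if target_id not in nuclei.areas:
        raise KeyError(f"unknown target_id {target_id}; valid ids 1..{nuclei.n_nuclei}")
    green = nuclei.labels == target_id
    red = (nuclei.labels > 0) & ~green
    return CompositeMarkerImage(
        target_id=target_id,
        green_plane=green,
        red_plane=red,
        structure_plane=np.asarray(structure, dtype=bool),
        channel_role=channel_role,
    )


def all_composites(
    nuclei: NucleusLabelMap, structure: np.ndarray, channel_role: str = "cytoskeleton"
) -> list[CompositeMarkerImage]:
    """One composite per nucleus; each nucleus is green in exactly one."""
    return [make_composite(nuclei, structure, t, channel_role) for t in nuclei.ids()]


def composite_to_classes(
    comp: CompositeMarkerImage,
    target_cell_pixels: np.ndarray,
    other_cell_pixels: np.ndarray,
    resolve_conflicts: bool = False,
) -> GroundTruthImage:
    """Rasterise a composite plus per-cell structure assignments into the
    5-class categorical image.

    Priority on overlaps (when ``resolve_conflicts``):
    green nucleus > red nuclei > target subcellular > other subcellular >
    background.  Without conflict resolution, overlapping target/other
    subcellular masks raise.
    """
    tgt = np.asarray(target_cell_pixels, dtype=bool)
    oth = np.asarray(other_cell_pixels, dtype=bool)
    if tgt.shape != comp.shape or oth.shape != comp.shape:
        raise ValueError("mask dimensions do not match the composite")
    if (tgt & oth).any() and not resolve_conflicts:
        raise ValueError("target and other subcellular masks overlap; enable priority resolution")
    labels = np.zeros(comp.shape, dtype=np.uint8)
    labels[oth] = 3
    labels[tgt] = 1
    labels[comp.red_plane] = 4
    labels[comp.green_plane] = 2
    return GroundTruthImage(labels=labels, legend=dict(comp.class_legend))


def classes_to_masks(gt: GroundTruthImage) -> dict[str, np.ndarray]:
    """Invert a categorical image back to the constituent binary masks."""
    lab = gt.labels
    return {
        "target_subcellular": lab == 1,
        "target_nucleus": lab == 2,
        "other_subcellular": lab == 3,
        "other_nucleus": lab == 4,
        "background": lab == 0,
    }
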