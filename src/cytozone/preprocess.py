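"""Histogram autothresholding and binary morphology.

Raw stain channels are reduced to binary structure masks with the three
classical histogram thresholds used for the nuclear / cytoskeleton /
cytoplasm channels respectively:

* Otsu (1979) -- maximises between-class variance,
* Tsai (1985) moment preservation ("Moments"),
* Doyle (1962) percentile ("Percentile").

All three operate on a 256-bin histogram regardless of bit depth, which
reproduces the discretisation of the classical ImageJ-style threshold
functions.  Foreground is *strictly greater than* the returned threshold
bin, so an all-foreground result is impossible by construction.

Connectivity conventions: foreground objects are 8-connected, background
(hole detection) is 4-connected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import ndimage


class DegenerateHistogramError(ValueError):
    """Histogram has fewer than two nonempty bins; no threshold exists."""


@dataclass
class Histogram:
    """Equal-width intensity histogram over the full container range."""

    counts: np.ndarray
    bin_edges: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        self.bin_edges = np.asarray(self.bin_edges, dtype=np.float64)
        if self.counts.ndim != 1 or self.n_bins < 2:
            raise ValueError("histogram needs >= 2 one-dimensional bins")
        if len(self.bin_edges) != self.n_bins + 1:
            raise ValueError("bin_edges must have n_bins + 1 entries")

    @property
    def n_bins(self) -> int:
        return len(self.counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def bin_width(self) -> float:
        return float(self.bin_edges[1] - self.bin_edges[0])

    def nonempty_bins(self) -> np.ndarray:
        return np.flatnonzero(self.counts)


def _infer_bit_depth(channel: np.ndarray) -> int:
    if channel.dtype == np.uint8:
        return 8
    if np.issubdtype(channel.dtype, np.integer):
        return 16
    raise TypeError("channel must be an integer raster")


def compute_histogram(channel: np.ndarray, n_bins: int = 256, bit_depth: int | None = None) -> Histogram:
    """Bin a channel into ``n_bins`` equal-width bins over [0, 2**depth - 1].

    For 16-bit data with 256 bins the bin index of a pixel is
    ``value // 256`` -- the classical 8-bit reduction.
    """
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ValueError("cannot histogram an empty raster")
    if bit_depth is None:
        bit_depth = _infer_bit_depth(channel)
    levels = 2**bit_depth
    if levels % n_bins:
        raise ValueError(f"n_bins={n_bins} must divide {levels} intensity levels")
    width = levels // n_bins
    idx = channel.astype(np.int64) // width
    if idx.min() < 0 or idx.max() >= n_bins:
        raise ValueError("intensities exceed the declared bit depth")
    counts = np.bincount(idx.ravel(), minlength=n_bins)
    edges = np.arange(n_bins + 1, dtype=np.float64) * width
    return Histogram(counts=counts, bin_edges=edges)


def _require_nondegenerate(hist: Histogram) -> None:
    if len(hist.nonempty_bins()) < 2:
        raise DegenerateHistogramError("degenerate histogram: fewer than two occupied bins")


def otsu_threshold(hist: Histogram) -> int:
    """Between-class-variance maximising threshold (bin index).

    Scans every candidate ``t``; background is ``bins <= t``, foreground
    ``bins > t``.  Ties are broken toward the lowest ``t``.
    """
    _require_nondegenerate(hist)
    counts = hist.counts.astype(np.float64)
    total = counts.sum()
    bins = np.arange(hist.n_bins, dtype=np.float64)
    w0 = np.cumsum(counts)[:-1]  # candidates t = 0 .. n_bins-2
    w1 = total - w0
    m0 = np.cumsum(counts * bins)[:-1]
    mu0 = np.divide(m0, w0, out=np.zeros_like(w0), where=w0 > 0)
    mu1 = np.divide(counts @ bins - m0, w1, out=np.zeros_like(w1), where=w1 > 0)
    var_between = w0 * w1 * (mu0 - mu1) ** 2
    var_between[(w0 == 0) | (w1 == 0)] = -np.inf
    return int(np.argmax(var_between))


def moments_threshold(hist: Histogram) -> int:
    """Tsai moment-preserving threshold (bin index).

    Solves for the two-level image whose first three gray-level moments
    equal the histogram's, then thresholds at the bin where the
    cumulative pixel fraction first reaches the below-threshold fraction
    ``p0``.
    """
    _require_nondegenerate(hist)
    counts = hist.counts.astype(np.float64)
    total = counts.sum()
    p = counts / total
    bins = np.arange(hist.n_bins, dtype=np.float64)
    m1 = p @ bins
    m2 = p @ bins**2
    m3 = p @ bins**3
    cd = m2 - m1 * m1  # variance; > 0 for nondegenerate histograms
    c0 = (-m2 * m2 + m1 * m3) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = max(c1 * c1 - 4.0 * c0, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    p0 = (z1 - m1) / (z1 - z0)  # fraction of pixels at the darker level
    cum = np.cumsum(p)
    # 1e-9 absorbs float noise when p0 falls exactly on a cumulative step
    reached = np.flatnonzero(cum >= p0 - 1e-9)
    return int(reached[0]) if reached.size else hist.n_bins - 2


def percentile_threshold(hist: Histogram, fraction: float = 0.5) -> int:
    """Doyle percentile threshold: smallest bin where the cumulative
    count reaches ``fraction`` of all pixels."""
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    _require_nondegenerate(hist)
    cum = np.cumsum(hist.counts)
    target = fraction * hist.total
    return int(np.flatnonzero(cum >= target - 1e-9)[0])


_THRESHOLD_FUNCS = {
    "otsu": otsu_threshold,
    "moments": moments_threshold,
    "percentile": percentile_threshold,
}


def binarize(
    channel: np.ndarray,
    method: str = "otsu",
    n_bins: int = 256,
    bit_depth: int | None = None,
    **params,
) -> np.ndarray:
    """Threshold a channel into a boolean mask (pixel bin > threshold bin)."""
    try:
        func = _THRESHOLD_FUNCS[method]
    except KeyError:
        raise ValueError(f"unknown threshold method {method!r}; choose from {sorted(_THRESHOLD_FUNCS)}") from None
    hist = compute_histogram(channel, n_bins=n_bins, bit_depth=bit_depth)
    t = func(hist, **params)
    width = hist.bin_width
    return (np.asarray(channel).astype(np.int64) // int(width)) > t


FG_STRUCTURE = np.ones((3, 3), dtype=bool)  # 8-connected foreground


def despeckle(mask: np.ndarray, min_size: int = 2) -> np.ndarray:
    """One round of speck removal: delete 8-connected foreground
    components smaller than ``min_size`` pixels.  Idempotent."""
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=FG_STRUCTURE)
    if n == 0:
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    keep = sizes >= min_size
    keep[0] = False
    return keep[labels]


def fill_holes(mask: np.ndarray) -> np.ndarray:
    """Fill background components (4-connected) not reaching the border."""
    mask = np.asarray(mask, dtype=bool)
    return ndimage.binary_fill_holes(mask)


def largest_component(mask: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component.

    Ties break toward the component whose first pixel occurs earliest in
    raster-scan order.  An empty mask is returned unchanged with a warning.
    """
    mask = np.asarray(mask, dtype=bool)
    labels, n = ndimage.label(mask, structure=FG_STRUCTURE)
    if n == 0:
        warnings.warn("largest_component: empty mask", stacklevel=2)
        return mask.copy()
    sizes = np.bincount(labels.ravel())
    sizes[0] = -1
    best = int(np.argmax(sizes))  # scipy labels in raster order of first pixel
    return labels == best


def median_filter_2d(channel: np.ndarray, radius: int = 1) -> np.ndarray:
    """Square-window median filter on an intensity raster (reflect padding)."""
    if radius < 1:
        raise ValueError("radius must be >= 1")
    return ndimage.median_filter(np.asarray(channel), size=2 * radius + 1, mode="reflect")
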