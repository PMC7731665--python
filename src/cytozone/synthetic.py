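"""Synthetic multichannel fluorescence scenes with known ground truth.

Scenes emulate a desk-scale confluent epithelial monolayer: elliptical
nuclei inside larger elliptical cytoplasm blobs, fibrillar cytoskeleton
drawn as smoothed random-walk polylines anchored in each cell (and
allowed to cross the nucleus), and a test-antibody channel planted as a
known non-negative mixture of the three structural signals plus Gaussian
noise:

    antibody = scale * (w_vim * S_vim + w_nuc * S_nuc + w_cyto * S_cyto) + noise

where each ``S`` is the blurred, unit-normalised clean structural
pattern.  Truth masks are emitted before blur and noise, so every
pipeline stage can be scored against exact geometry.  Generation is
fully deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line
from skimage.morphology import disk

from .io import FOV, GroundTruthImage
from .learn import TrainingConfig  # noqa: F401  (re-exported convenience)
from .markers import CompositeMarkerImage, composite_to_classes
from .segmentation import CellSegmentation


@dataclass
class SceneParams:
    """Geometry, intensity and noise settings for one synthetic FOV."""

    image_size: int = 256
    n_cells: int = 5
    nucleus_radius: tuple[float, float] = (11.0, 15.0)
    cell_radius: tuple[float, float] = (34.0, 44.0)
    axis_ratio: tuple[float, float] = (0.75, 0.95)
    fibrils_per_cell: int = 6
    fibril_length: tuple[int, int] = (30, 80)
    fibril_halfwidth: int = 1
    levels: dict = field(
        default_factory=lambda: {
            "nuclear": 30000, "cytoskeleton": 28000, "cytoplasm": 16000, "antibody": 20000,
        }
    )
    background_level: int = 300
    antibody_weights: tuple[float, float, float] = (0.85, 0.15, 0.25)  # (w_vim, w_nuc, w_cyto)
    noise_sd: float = 300.0
    blur_sigma: float = 0.8
    bit_depth: int = 16
    seed: int = 0
    max_place_tries: int = 2000

    def __post_init__(self) -> None:
        if self.n_cells < 1:
            raise ValueError("n_cells must be >= 1")
        for lo, hi in (self.nucleus_radius, self.cell_radius):
            if lo <= 0 or hi < lo:
                raise ValueError("radius ranges must be positive and ordered")
        if any(w < 0 or not np.isfinite(w) for w in self.antibody_weights):
            raise ValueError("antibody weights must be finite and non-negative")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SceneParams":
        d = dict(d)
        for key in ("nucleus_radius", "cell_radius", "axis_ratio", "fibril_length", "antibody_weights"):
            if key in d and isinstance(d[key], list):
                d[key] = tuple(d[key])
        return cls(**{k: v for k, v in d.items() if k in cls.__dataclass_fields__})


@dataclass
class SceneTruth:
    """Exact pre-blur, pre-noise geometry of a generated scene."""

    cells: list[CellSegmentation]
    nucleus_labels: np.ndarray
    nuc_mask: np.ndarray
    vim_mask: np.ndarray
    cyto_mask: np.ndarray
    clean_antibody: np.ndarray  # noise-free antibody expectation (float)
    params: SceneParams


def _ellipse_mask(shape, center, a, b, theta, rng_free=True) -> np.ndarray:
    rr, cc = draw_ellipse(center[0], center[1], a, b, shape=shape, rotation=theta)
    m = np.zeros(shape, dtype=bool)
    m[rr, cc] = True
    return m


def _place_cells(params: SceneParams, rng: np.random.Generator):
    """Sample non-overlapping cell ellipses (bounding-circle criterion).

    Largest-first greedy placement with full restarts; a fresh ellipse
    set is drawn on every restart so dead-end configurations are not
    kept.  Deterministic given the generator state.
    """
    size = params.image_size
    tries_per_cell = 50
    n_restarts = max(1, params.max_place_tries // (tries_per_cell * params.n_cells))
    for _ in range(n_restarts):
        shapes = sorted(
            (
                (a := rng.uniform(*params.cell_radius), a * rng.uniform(*params.axis_ratio),
                 rng.uniform(0, np.pi))
                for _ in range(params.n_cells)
            ),
            key=lambda s: -s[0],
        )
        if 2 * (shapes[0][0] + 2) >= size:
            raise RuntimeError("cell_radius too large for image_size")
        placed = []  # (center, a, b, theta)
        for a, b, theta in shapes:
            margin = a + 2
            for _ in range(tries_per_cell):
                cy = rng.uniform(margin, size - margin)
                cx = rng.uniform(margin, size - margin)
                if all(np.hypot(cy - p[0][0], cx - p[0][1]) > a + p[1] + 2 for p in placed):
                    placed.append(((cy, cx), a, b, theta))
                    break
            else:
                break  # restart with a fresh draw
        if len(placed) == params.n_cells:
            return placed
    raise RuntimeError(
        f"could not place {params.n_cells} non-overlapping cells in "
        f"{size}x{size} after {params.max_place_tries} tries; reduce n_cells or cell_radius"
    )


def _fibril_mask(params, rng, center, cell_mask) -> np.ndarray:
    """Smoothed random-walk polylines anchored near the cell centre."""
    shape = cell_mask.shape
    acc = np.zeros(shape, dtype=bool)
    for _ in range(params.fibrils_per_cell):
        length = int(rng.integers(params.fibril_length[0], params.fibril_length[1] + 1))
        # start near the nucleus so fibrils may cross it
        y = center[0] + rng.normal(0, 3)
        x = center[1] + rng.normal(0, 3)
        angle = rng.uniform(0, 2 * np.pi)
        pts = [(y, x)]
        step = 4.0
        for _ in range(max(length // int(step), 2)):
            angle += rng.normal(0, 0.35)
            y += step * np.sin(angle)
            x += step * np.cos(angle)
            pts.append((y, x))
        for (y0, x0), (y1, x1) in zip(pts[:-1], pts[1:]):
            r0, c0 = int(round(y0)), int(round(x0))
            r1, c1 = int(round(y1)), int(round(x1))
            r0 = np.clip(r0, 0, shape[0] - 1); c0 = np.clip(c0, 0, shape[1] - 1)
            r1 = np.clip(r1, 0, shape[0] - 1); c1 = np.clip(c1, 0, shape[1] - 1)
            rr, cc = draw_line(r0, c0, r1, c1)
            acc[rr, cc] = True
    if params.fibril_halfwidth > 0:
        acc = ndimage.binary_dilation(acc, structure=disk(params.fibril_halfwidth))
    return acc & cell_mask  # fibrils stay inside their cell


def _normalized_blur(mask: np.ndarray, sigma: float) -> np.ndarray:
    sig = ndimage.gaussian_filter(mask.astype(np.float64), sigma)
    peak = sig.max()
    return sig / peak if peak > 0 else sig


def generate_fov(params: SceneParams | None = None) -> tuple[FOV, SceneTruth]:
    """Generate one synthetic FOV plus its exact truth."""
    params = params or SceneParams()
    rng = np.random.default_rng(params.seed)
    size = params.image_size
    shape = (size, size)
    placed = _place_cells(params, rng)

    nucleus_labels = np.zeros(shape, dtype=np.int32)
    cells: list[CellSegmentation] = []
    vim_union = np.zeros(shape, dtype=bool)
    cyto_union = np.zeros(shape, dtype=bool)
    nuc_union = np.zeros(shape, dtype=bool)
    for i, (center, a, b, theta) in enumerate(placed, start=1):
        cell_mask = _ellipse_mask(shape, center, a, b, theta)
        na = rng.uniform(*params.nucleus_radius)
        nb = na * rng.uniform(*params.axis_ratio)
        jitter = (center[0] + rng.normal(0, 2), center[1] + rng.normal(0, 2))
        nuc_mask = _ellipse_mask(shape, jitter, na, nb, rng.uniform(0, np.pi)) & cell_mask
        fib = _fibril_mask(params, rng, jitter, cell_mask)
        nucleus_labels[nuc_mask] = i
        nuc_union |= nuc_mask
        vim_union |= fib
        cyto_union |= cell_mask
        cells.append(
            CellSegmentation(
                cell_id=i,
                nuc_mask=nuc_mask,
                cytoskeleton_mask=fib,
                cytoplasm_mask=cell_mask,
                whole_cell_mask=cell_mask,
                touches_border=bool(
                    cell_mask[0].any() or cell_mask[-1].any()
                    or cell_mask[:, 0].any() or cell_mask[:, -1].any()
                ),
            )
        )

    s_nuc = _normalized_blur(nuc_union, params.blur_sigma)
    s_vim = _normalized_blur(vim_union, params.blur_sigma)
    s_cyto = _normalized_blur(cyto_union, params.blur_sigma)
    w_vim, w_nuc, w_cyto = params.antibody_weights
    clean_ab = params.background_level + params.levels["antibody"] * (
        w_vim * s_vim + w_nuc * s_nuc + w_cyto * s_cyto
    )

    limit = 2**params.bit_depth - 1

    def to_channel(signal: np.ndarray) -> np.ndarray:
        noisy = signal + rng.normal(0, params.noise_sd, shape)
        return np.clip(np.round(noisy), 0, limit).astype(np.uint16)

    channels = {
        "nuclear": to_channel(params.background_level + params.levels["nuclear"] * s_nuc),
        "cytoskeleton": to_channel(params.background_level + params.levels["cytoskeleton"] * s_vim),
        "cytoplasm": to_channel(params.background_level + params.levels["cytoplasm"] * s_cyto),
        "antibody": to_channel(clean_ab),
    }
    fov = FOV(channels=channels, bit_depth=params.bit_depth, fov_id=f"synthetic_seed{params.seed}")
    truth = SceneTruth(
        cells=cells,
        nucleus_labels=nucleus_labels,
        nuc_mask=nuc_union,
        vim_mask=vim_union,
        cyto_mask=cyto_union,
        clean_antibody=clean_ab,
        params=params,
    )
    return fov, truth


def truth_composites(
    truth: SceneTruth, channel_role: str = "cytoskeleton"
) -> list[tuple[CompositeMarkerImage, GroundTruthImage]]:
    """Per-nucleus composite + categorical truth pairs for one scene.

    The structure plane is the exact truth mask for the requested
    channel; class-1/3 pixels are per-cell structure pixels outside any
    nucleus, so classes partition the frame.
    """
    attr = "cytoskeleton_mask" if channel_role == "cytoskeleton" else "cytoplasm_mask"
    structure = np.zeros(truth.nuc_mask.shape, dtype=bool)
    for cell in truth.cells:
        structure |= getattr(cell, attr)
    pairs = []
    for cell in truth.cells:
        green = cell.nuc_mask
        red = truth.nuc_mask & ~green
        comp = CompositeMarkerImage(
            target_id=cell.cell_id,
            green_plane=green,
            red_plane=red,
            structure_plane=structure,
            channel_role=channel_role,
        )
        tgt_px = getattr(cell, attr) & ~truth.nuc_mask
        oth_px = structure & ~getattr(cell, attr) & ~truth.nuc_mask
        gt = composite_to_classes(comp, tgt_px, oth_px)
        pairs.append((comp, gt))
    return pairs


def make_training_set(
    params: SceneParams | None = None,
    n_fovs: int = 2,
    seed: int = 0,
    channel_role: str = "cytoskeleton",
) -> list[tuple[CompositeMarkerImage, GroundTruthImage]]:
    """Composite/ground-truth training pairs from ``n_fovs`` fresh scenes."""
    if n_fovs < 1:
        raise ValueError("n_fovs must be >= 1")
    base = params or SceneParams()
    dataset = []
    for k in range(n_fovs):
        d = base.to_dict()
        d["seed"] = int(np.random.default_rng((seed, k)).integers(0, 2**31 - 1))
        _, truth = generate_fov(SceneParams.from_dict(d))
        dataset.extend(truth_composites(truth, channel_role=channel_role))
    return dataset
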