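"""Trainable per-pixel segmentation backend.

The backend is a 5-class multinomial softmax classifier over a per-pixel
feature stack built from the composite marker image: the raw binary
planes, Gaussian smoothings at two scales, Euclidean distance transforms
to the green and red nuclei, and the signed distance margin between
them.  It is trained with stochastic gradient descent using the
hyperparameter contract of the original pipeline: momentum 0.9, base
learning rate 1e-3, piecewise schedule dropping by a factor of 0.3 every
690 iterations, 2300 iterations total, cross-entropy loss with class
weights balanced by inverse pixel frequency, and train-time augmentation
(rotation, isotropic scale, x/y reflection).

Two independent backends are intended, one per structure channel,
because fibrillar (cytoskeleton) and diffuse (cytoplasm) foreground have
different pixel statistics; the backend interface hides which is in use.
Training is fully deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
from scipy import ndimage

from .io import CLASS_LEGEND, N_CLASSES, GroundTruthImage
from .markers import CompositeMarkerImage

AUGMENTATIONS = ("rotation", "scale", "reflect_x", "reflect_y")


@dataclass
class TrainingConfig:
    """SGD schedule and data-handling hyperparameters."""

    momentum: float = 0.9
    learning_rate: float = 1e-3
    lr_drop_period_iters: int = 690
    lr_drop_factor: float = 0.3
    schedule: str = "piecewise"
    total_iters: int = 2300
    class_weighting: str = "inverse_frequency"
    augmentation: tuple[str, ...] = AUGMENTATIONS
    n_augment: int = 2          # augmented copies added per training image
    batch_pixels: int = 1024
    seed: int = 0
    split: tuple[int, int, int] = (189, 24, 23)  # train/val/test image counts at full scale
    log_every: int = 100

    def __post_init__(self) -> None:
        for name in ("momentum", "learning_rate", "lr_drop_factor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("lr_drop_period_iters", "total_iters", "batch_pixels"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        unknown = set(self.augmentation) - set(AUGMENTATIONS)
        if unknown:
            raise ValueError(f"unknown augmentations {sorted(unknown)}")

    def lr_at(self, iteration: int) -> float:
        if self.schedule != "piecewise":
            return self.learning_rate
        return self.learning_rate * self.lr_drop_factor ** (iteration // self.lr_drop_period_iters)


def inverse_frequency_weights(class_counts: np.ndarray) -> np.ndarray:
    """Median-free inverse-pixel-frequency class weights.

    ``w_c`` is proportional to ``1 / count_c`` and normalised so the
    weights average to 1.  Every class must be present.
    """
    counts = np.asarray(class_counts, dtype=np.float64)
    missing = np.flatnonzero(counts == 0)
    if missing.size:
        names = [CLASS_LEGEND[int(c)] for c in missing]
        raise ValueError(f"class(es) absent from training set: {names}")
    w = 1.0 / counts
    return w * (len(w) / w.sum())


def composite_features(comp: CompositeMarkerImage) -> np.ndarray:
    """Per-pixel feature stack, shape (H*W, n_features)."""
    g = comp.green_plane.astype(np.float64)
    r = comp.red_plane.astype(np.float64)
    s = comp.structure_plane.astype(np.float64)
    diag = float(np.hypot(*comp.shape))
    d_green = ndimage.distance_transform_edt(~comp.green_plane) / diag
    if comp.red_plane.any():
        d_red = ndimage.distance_transform_edt(~comp.red_plane) / diag
    else:
        d_red = np.ones_like(d_green)
    feats = [
        g,
        r,
        s,
        ndimage.gaussian_filter(g, 2.0),
        ndimage.gaussian_filter(g, 6.0),
        ndimage.gaussian_filter(r, 2.0),
        ndimage.gaussian_filter(r, 6.0),
        ndimage.gaussian_filter(s, 2.0),
        d_green,
        d_red,
        d_red - d_green,
        s * (d_red - d_green),
    ]
    return np.stack([f.ravel() for f in feats], axis=1)


N_FEATURES = 12


def _augment_pair(
    comp: CompositeMarkerImage, gt: GroundTruthImage, rng: np.random.Generator, kinds: tuple[str, ...]
) -> tuple[CompositeMarkerImage, GroundTruthImage]:
    planes = [comp.green_plane, comp.red_plane, comp.structure_plane]
    labels = gt.labels

    def apply(fn):
        nonlocal planes, labels
        planes = [fn(p) for p in planes]
        labels = fn(labels)

    if "reflect_x" in kinds and rng.random() < 0.5:
        apply(lambda a: a[:, ::-1])
    if "reflect_y" in kinds and rng.random() < 0.5:
        apply(lambda a: a[::-1, :])
    if "rotation" in kinds:
        k = int(rng.integers(0, 4))
        if k:
            apply(lambda a: np.rot90(a, k))
    if "scale" in kinds:
        zoom = float(rng.uniform(0.8, 1.25))
        h, w = labels.shape

        def zoom_crop(a):
            out = ndimage.zoom(a.astype(np.uint8), zoom, order=0)
            canvas = np.zeros((h, w), dtype=out.dtype)
            ch, cw = min(h, out.shape[0]), min(w, out.shape[1])
            canvas[:ch, :cw] = out[:ch, :cw]
            return canvas

        apply(zoom_crop)
    green = planes[0].astype(bool)
    if not green.any():  # scaling may have pushed the target out of frame
        return comp, gt
    aug = CompositeMarkerImage(
        target_id=comp.target_id,
        green_plane=green,
        red_plane=planes[1].astype(bool) & ~green,
        structure_plane=planes[2].astype(bool),
        channel_role=comp.channel_role,
    )
    return aug, GroundTruthImage(labels=np.ascontiguousarray(labels))


@dataclass
class PixelSoftmaxBackend:
    """Feature-based softmax pixel classifier satisfying the backend protocol."""

    channel_role: str
    weights: np.ndarray  # (n_features + 1, 5), last row is the bias
    feat_mean: np.ndarray
    feat_std: np.ndarray
    config: TrainingConfig
    name: str = "trained"
    val_loss_log: list = field(default_factory=list)

    def _scores(self, comp: CompositeMarkerImage) -> np.ndarray:
        X = (composite_features(comp) - self.feat_mean) / self.feat_std
        return X @ self.weights[:-1] + self.weights[-1]

    def predict_classes(self, comp: CompositeMarkerImage) -> np.ndarray:
        """Full 5-class per-pixel prediction."""
        scores = self._scores(comp)
        return scores.argmax(axis=1).reshape(comp.shape).astype(np.uint8)

    def predict(self, comp: CompositeMarkerImage) -> np.ndarray:
        """Binary mask of predicted target-subcellular (class-1) pixels.

        Restricted to the structure foreground plane, which class-1
        pixels are a subset of by definition.
        """
        cls = self.predict_classes(comp)
        return (cls == 1) & comp.structure_plane

    def save(self, directory: str | Path) -> Path:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        np.savez(
            directory / "model.npz",
            weights=self.weights,
            feat_mean=self.feat_mean,
            feat_std=self.feat_std,
        )
        cfg = asdict(self.config)
        cfg["augmentation"] = list(self.config.augmentation)
        cfg["split"] = list(self.config.split)
        (directory / "model.json").write_text(
            json.dumps(
                {"channel_role": self.channel_role, "name": self.name, "config": cfg,
                 "val_loss_log": self.val_loss_log},
                indent=2,
            )
        )
        return directory

    @classmethod
    def load(cls, directory: str | Path) -> "PixelSoftmaxBackend":
        directory = Path(directory)
        meta = json.loads((directory / "model.json").read_text())
        arrs = np.load(directory / "model.npz")
        cfg = meta["config"]
        cfg["augmentation"] = tuple(cfg["augmentation"])
        cfg["split"] = tuple(cfg["split"])
        return cls(
            channel_role=meta["channel_role"],
            weights=arrs["weights"],
            feat_mean=arrs["feat_mean"],
            feat_std=arrs["feat_std"],
            config=TrainingConfig(**cfg),
            name=meta.get("name", "trained"),
            val_loss_log=meta.get("val_loss_log", []),
        )


def _weighted_ce_and_grad(
    X: np.ndarray, y: np.ndarray, W: np.ndarray, b: np.ndarray, class_w: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    scores = X @ W + b
    scores -= scores.max(axis=1, keepdims=True)
    exps = np.exp(scores)
    probs = exps / exps.sum(axis=1, keepdims=True)
    n = len(y)
    sample_w = class_w[y]
    loss = float(-(sample_w * np.log(probs[np.arange(n), y] + 1e-12)).mean())
    delta = probs.copy()
    delta[np.arange(n), y] -= 1.0
    delta *= sample_w[:, None] / n
    return loss, X.T @ delta, delta.sum(axis=0)


def train_backend(
    dataset: list[tuple[CompositeMarkerImage, GroundTruthImage]],
    config: TrainingConfig | None = None,
    channel_role: str | None = None,
    val_dataset: list[tuple[CompositeMarkerImage, GroundTruthImage]] | None = None,
) -> PixelSoftmaxBackend:
    """Train a per-pixel 5-class classifier on composite/ground-truth pairs.

    Reproducible given ``config.seed``; validation loss (when a
    validation set is supplied) is logged every ``config.log_every``
    iterations into the returned backend's ``val_loss_log``.
    """
    if not dataset:
        raise ValueError("training dataset is empty")
    cfg = config or TrainingConfig()
    role = channel_role or dataset[0][0].channel_role
    shapes = {comp.shape for comp, _ in dataset}
    if len(shapes) > 1:
        raise ValueError(f"training images must share dimensions; got {shapes}")
    rng = np.random.default_rng(cfg.seed)

    pairs = list(dataset)
    if cfg.n_augment and cfg.augmentation:
        for comp, gt in dataset:
            for _ in range(cfg.n_augment):
                pairs.append(_augment_pair(comp, gt, rng, cfg.augmentation))

    X = np.concatenate([composite_features(c) for c, _ in pairs], axis=0)
    y = np.concatenate([g.labels.ravel() for _, g in pairs], axis=0).astype(np.int64)
    counts = np.bincount(y, minlength=N_CLASSES)
    class_w = inverse_frequency_weights(counts)

    mean = X.mean(axis=0)
    std = X.std(axis=0)
    std[std == 0] = 1.0
    X = (X - mean) / std

    if val_dataset:
        Xv = np.concatenate([composite_features(c) for c, _ in val_dataset], axis=0)
        Xv = (Xv - mean) / std
        yv = np.concatenate([g.labels.ravel() for _, g in val_dataset], axis=0).astype(np.int64)

    n_feat = X.shape[1]
    W = np.zeros((n_feat, N_CLASSES))
    b = np.zeros(N_CLASSES)
    vW = np.zeros_like(W)
    vb = np.zeros_like(b)
    val_log: list[tuple[int, float]] = []
    npix = len(y)
    for it in range(cfg.total_iters):
        idx = rng.integers(0, npix, size=min(cfg.batch_pixels, npix))
        _, gW, gb = _weighted_ce_and_grad(X[idx], y[idx], W, b, class_w)
        lr = cfg.lr_at(it)
        vW = cfg.momentum * vW - lr * gW
        vb = cfg.momentum * vb - lr * gb
        W += vW
        b += vb
        if val_dataset and (it + 1) % cfg.log_every == 0:
            vloss, _, _ = _weighted_ce_and_grad(Xv, yv, W, b, class_w)
            val_log.append((it + 1, vloss))

    weights = np.vstack([W, b])
    return PixelSoftmaxBackend(
        channel_role=role,
        weights=weights,
        feat_mean=mean,
        feat_std=std,
        config=cfg,
        val_loss_log=val_log,
    )
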