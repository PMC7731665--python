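"""Segmentation scoring: IOU, mean IOU, rank correlation, benchmarking."""

from __future__ import annotations

import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats


def iou(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Intersection over union of two binary masks.

    Defined as 1.0 (with a warning flag) when both masks are empty:
    vacuous agreement, excludable by the caller.
    """
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError(f"mask shapes differ: {a.shape} vs {b.shape}")
    union = np.count_nonzero(a | b)
    if union == 0:
        warnings.warn("IOU of two empty masks, defined as 1.0", stacklevel=2)
        return 1.0
    return np.count_nonzero(a & b) / union


def mean_iou(pairs: Sequence[tuple[np.ndarray, np.ndarray]]) -> float:
    """Arithmetic mean of per-pair IOUs."""
    if not len(pairs):
        raise ValueError("empty pair list")
    return float(np.mean([iou(a, b) for a, b in pairs]))


def area_rank_correlation(areas_auto: Sequence[float], areas_manual: Sequence[float]) -> float:
    """Spearman rho (midrank ties) between two area series."""
    a = np.asarray(areas_auto, dtype=np.float64)
    b = np.asarray(areas_manual, dtype=np.float64)
    if len(a) != len(b):
        raise ValueError("area series must have equal lengths")
    if len(a) < 3:
        raise ValueError("need >= 3 paired areas")
    return float(stats.spearmanr(a, b).statistic)


def benchmark(
    masks_by_method: Mapping[str, Mapping[str, Sequence[np.ndarray]]],
    truths: Mapping[str, Sequence[np.ndarray]],
) -> pd.DataFrame:
    """Mean IOU per (method, region type) against a shared truth set.

    ``masks_by_method[method][region]`` and ``truths[region]`` are
    parallel mask lists; every method must cover every truth mask.
    """
    rows = []
    for method, per_region in masks_by_method.items():
        for region, truth_masks in truths.items():
            if region not in per_region:
                raise ValueError(f"method {method!r} missing region {region!r}")
            preds = per_region[region]
            if len(preds) != len(truth_masks):
                raise ValueError(
                    f"method {method!r}, region {region!r}: {len(preds)} masks for {len(truth_masks)} truths"
                )
            rows.append(
                {"method": method, "region": region,
                 "mean_iou": mean_iou(list(zip(preds, truth_masks))), "n": len(truth_masks)}
            )
    return pd.DataFrame(rows, columns=["method", "region", "mean_iou", "n"])
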