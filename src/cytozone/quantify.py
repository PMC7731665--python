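"""Zone intensity statistics, colocalization and group comparisons.

The primary readouts are mean pixel intensity (MPI) of the test-antibody
channel within each subcellular zone, MPI ratios between zones, and
Pearson colocalization between the antibody channel and the structural
channels, either per cell (within the whole-cell mask) or per FOV
(all matched pixels of the frame, background included).

Group comparisons use two-sided nonparametric tests: Mann-Whitney for
independent groups and Wilcoxon signed-rank for paired values, with
exact enumeration for small samples (n <= 10) and the normal
approximation with tie correction otherwise.  Multiple testing is
controlled with Benjamini-Hochberg q-values.
"""

from __future__ import annotations

from itertools import combinations, product

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import FOV
from .zones import ZoneSet

EXACT_N_MAX = 10


class EmptyZoneError(ValueError):
    pass


def mean_pixel_intensity(channel: np.ndarray, mask: np.ndarray) -> float:
    """Arithmetic mean of channel values over mask pixels."""
    channel = np.asarray(channel)
    mask = np.asarray(mask, dtype=bool)
    if channel.shape != mask.shape:
        raise ValueError("channel and mask shapes differ")
    if not mask.any():
        raise EmptyZoneError("empty zone")
    return float(channel[mask].mean())


def pixel_correlation(chan_a: np.ndarray, chan_b: np.ndarray, scope_mask: np.ndarray | None = None) -> float:
    """Pearson correlation of matched pixel intensities within a scope.

    ``scope_mask=None`` means whole-frame scope.  Returns NaN when either
    channel has zero variance within the scope (undefined correlation);
    use :func:`pixel_correlation_detail` for the reason.
    """
    r, _, _ = pixel_correlation_detail(chan_a, chan_b, scope_mask)
    return r


def pixel_correlation_detail(
    chan_a: np.ndarray, chan_b: np.ndarray, scope_mask: np.ndarray | None = None
) -> tuple[float, int, str | None]:
    """As :func:`pixel_correlation`, returning ``(r, n_pixels, reason)``."""
    a = np.asarray(chan_a, dtype=np.float64)
    b = np.asarray(chan_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("channel shapes differ")
    if scope_mask is None:
        av, bv = a.ravel(), b.ravel()
    else:
        scope_mask = np.asarray(scope_mask, dtype=bool)
        if scope_mask.shape != a.shape:
            raise ValueError("scope mask shape differs from channels")
        av, bv = a[scope_mask], b[scope_mask]
    n = av.size
    if n < 2:
        raise ValueError("correlation scope must contain >= 2 pixels")
    if av.std() == 0 or bv.std() == 0:
        return float("nan"), n, "zero variance"
    r = float(np.corrcoef(av, bv)[0, 1])
    return r, n, None


def build_quant_tables(
    fov: FOV,
    cells: list[ZoneSet],
    antibody_channel: np.ndarray | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-(cell, zone) MPI/area table and colocalization table.

    Colocalization rows pair the antibody channel with the cytoskeleton
    and nuclear channels, at cell scope (within each whole-cell mask)
    and once at FOV scope (all matched pixels of the frame).  Empty
    zones and zero-variance scopes appear as rows with an explicit
    ``reason`` instead of being dropped.
    """
    ab = fov.channel("antibody") if antibody_channel is None else np.asarray(antibody_channel)
    quant_rows = []
    for zs in cells:
        for name, mask in zs.zones.items():
            area = int(mask.sum())
            if area:
                mpi = mean_pixel_intensity(ab, mask)
                reason = None
            else:
                mpi, reason = float("nan"), "empty zone"
            quant_rows.append(
                {"fov_id": zs.fov_id, "cell_id": zs.cell_id, "zone": name,
                 "area_px": area, "mpi": mpi, "reason": reason}
            )
    quant = pd.DataFrame(quant_rows, columns=["fov_id", "cell_id", "zone", "area_px", "mpi", "reason"])

    coloc_rows = []
    pairs = [("antibody", "cytoskeleton"), ("antibody", "nuclear")]
    for zs in cells:
        whole = zs.zones["whole"]
        for ca, cb in pairs:
            r, n, reason = pixel_correlation_detail(fov.channel(ca), fov.channel(cb), whole)
            coloc_rows.append(
                {"fov_id": zs.fov_id, "scope": "cell", "cell_id": zs.cell_id,
                 "channel_pair": f"{ca}x{cb}", "r": r, "n_pixels": n, "reason": reason}
            )
    for ca, cb in pairs:
        r, n, reason = pixel_correlation_detail(fov.channel(ca), fov.channel(cb), None)
        coloc_rows.append(
            {"fov_id": fov.fov_id, "scope": "fov", "cell_id": -1,
             "channel_pair": f"{ca}x{cb}", "r": r, "n_pixels": n, "reason": reason}
        )
    coloc = pd.DataFrame(coloc_rows, columns=["fov_id", "scope", "cell_id", "channel_pair", "r", "n_pixels", "reason"])
    return quant, coloc


def mpi_ratio(table: pd.DataFrame, zone_a: str, zone_b: str) -> pd.DataFrame:
    """Per-cell ratio MPI(zone_a) / MPI(zone_b).

    Rows with a zero denominator are kept with NaN ratio and a flag
    rather than dropped.
    """
    for z in (zone_a, zone_b):
        if z not in set(table["zone"]):
            raise KeyError(f"zone {z!r} absent from table")
    wide = table.pivot_table(index=["fov_id", "cell_id"], columns="zone", values="mpi", aggfunc="first")
    a = wide[zone_a]
    b = wide[zone_b]
    ratio = a / b.where(b != 0)
    out = pd.DataFrame(
        {"ratio": ratio, "flag": np.where(b == 0, "zero denominator", None)},
        index=wide.index,
    ).reset_index()
    return out


def _mannwhitney_u(x: np.ndarray, y: np.ndarray) -> float:
    ranks = stats.rankdata(np.concatenate([x, y]))
    rx = ranks[: len(x)].sum()
    return float(rx - len(x) * (len(x) + 1) / 2)


def _exact_mannwhitney(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided exact p by full enumeration of group assignments.

    p = P(|U - mean(U)| >= |U_obs - mean(U)|) over all C(n, n_x)
    relabellings of the pooled sample; handles ties via midranks.
    """
    pooled = np.concatenate([x, y])
    n, nx = len(pooled), len(x)
    mu = nx * (n - nx) / 2
    u_obs = _mannwhitney_u(x, y)
    dev = abs(u_obs - mu)
    count = total = 0
    idx_all = np.arange(n)
    for pick in combinations(range(n), nx):
        sel = np.zeros(n, dtype=bool)
        sel[list(pick)] = True
        u = _mannwhitney_u(pooled[sel], pooled[~sel])
        total += 1
        if abs(u - mu) >= dev - 1e-12:
            count += 1
    return count / total


def _exact_wilcoxon(d: np.ndarray) -> float:
    """Two-sided exact signed-rank p by enumerating all sign patterns."""
    ranks = stats.rankdata(np.abs(d))
    w_obs = ranks[d > 0].sum()
    mu = ranks.sum() / 2
    dev = abs(w_obs - mu)
    count = 0
    n = len(d)
    for signs in product((0, 1), repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / 2**n


def compare_groups(values_a, values_b, test: str = "mann_whitney") -> float:
    """Two-sided nonparametric group comparison p-value.

    ``mann_whitney`` for independent samples, ``wilcoxon_paired`` for
    matched pairs (equal lengths required).  Exact enumeration when the
    larger sample has n <= 10, normal approximation with tie correction
    otherwise.  Identical paired samples give p = 1.0.
    """
    a = np.asarray(values_a, dtype=np.float64)
    b = np.asarray(values_b, dtype=np.float64)
    if test == "mann_whitney":
        if len(a) < 2 or len(b) < 2:
            raise ValueError("each group needs n >= 2")
        if max(len(a), len(b)) <= EXACT_N_MAX:
            return _exact_mannwhitney(a, b)
        return float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
    if test == "wilcoxon_paired":
        if len(a) != len(b):
            raise ValueError("paired test requires equal lengths")
        if len(a) < 2:
            raise ValueError("paired test needs n >= 2")
        d = a - b
        d = d[d != 0]
        if len(d) == 0:
            return 1.0
        if len(d) <= EXACT_N_MAX:
            return _exact_wilcoxon(d)
        return float(stats.wilcoxon(d, correction=False, mode="approx").pvalue)
    raise ValueError(f"unknown test {test!r}")


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, order-preserving."""
    p = np.asarray(p_values, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]
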