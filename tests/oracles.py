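"""Independent brute-force / closed-form oracles used to validate the
package implementations.  These deliberately avoid the code paths (and
where possible the libraries) used by the implementations themselves."""

from __future__ import annotations

from collections import deque
from itertools import combinations, product

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra


# ---------------------------------------------------------------- thresholds

def otsu_oracle(counts) -> int:
    """Exhaustive scan of between-class variance over all candidate bins."""
    counts = [float(c) for c in counts]
    n = len(counts)
    total = sum(counts)
    grand = sum(i * c for i, c in enumerate(counts))
    w0 = s0 = 0.0
    best_t, best_v = None, -1.0
    for t in range(n - 1):
        w0 += counts[t]
        s0 += t * counts[t]
        w1 = total - w0
        if w0 == 0 or w1 == 0:
            continue
        v = w0 * w1 * (s0 / w0 - (grand - s0) / w1) ** 2
        if v > best_v + 1e-9:  # strict improvement -> lowest t wins ties
            best_v, best_t = v, t
    return best_t


def moments_oracle(counts) -> int:
    """Tsai moment preservation via an explicit linear system + np.roots."""
    counts = np.asarray(counts, dtype=float)
    p = counts / counts.sum()
    g = np.arange(len(counts), dtype=float)
    m1, m2, m3 = (p * g).sum(), (p * g**2).sum(), (p * g**3).sum()
    # moments of a two-level image with levels z0 < z1 and fraction p0 at z0
    # satisfy z^2 + c1 z + c0 = 0 with coefficients from this linear system
    c0, c1 = np.linalg.solve(np.array([[1.0, m1], [m1, m2]]), np.array([-m2, -m3]))
    roots = np.sort(np.roots([1.0, c1, c0]).real)
    z0, z1 = roots
    p0 = (z1 - m1) / (z1 - z0)
    cum = 0.0
    for t in range(len(counts)):
        cum += p[t]
        if cum >= p0 - 1e-9:
            return t
    return len(counts) - 2


def percentile_oracle(counts, fraction=0.5) -> int:
    counts = np.asarray(counts, dtype=float)
    target = fraction * counts.sum()
    cum = 0.0
    for t in range(len(counts)):
        cum += counts[t]
        if cum >= target - 1e-9:
            return t
    raise AssertionError("unreachable")


# ---------------------------------------------------------------- morphology

_N8 = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
_N4 = [(-1, 0), (1, 0), (0, -1), (0, 1)]


def _components(mask, neigh):
    """Connected components by BFS, in raster-scan order of first pixel."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    seen = np.zeros_like(mask)
    comps = []
    for r in range(h):
        for c in range(w):
            if mask[r, c] and not seen[r, c]:
                q = deque([(r, c)])
                seen[r, c] = True
                comp = []
                while q:
                    y, x = q.popleft()
                    comp.append((y, x))
                    for dy, dx in neigh:
                        ny, nx = y + dy, x + dx
                        if 0 <= ny < h and 0 <= nx < w and mask[ny, nx] and not seen[ny, nx]:
                            seen[ny, nx] = True
                            q.append((ny, nx))
                comps.append(comp)
    return comps


def despeckle_oracle(mask, min_size=2):
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    for comp in _components(mask, _N8):
        if len(comp) >= min_size:
            for y, x in comp:
                out[y, x] = True
    return out


def fill_holes_oracle(mask):
    """Flood-fill background from the border (4-connectivity); the rest fills."""
    mask = np.asarray(mask, dtype=bool)
    h, w = mask.shape
    outside = np.zeros_like(mask)
    q = deque()
    for r in range(h):
        for c in (0, w - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                q.append((r, c))
    for c in range(w):
        for r in (0, h - 1):
            if not mask[r, c] and not outside[r, c]:
                outside[r, c] = True
                q.append((r, c))
    while q:
        y, x = q.popleft()
        for dy, dx in _N4:
            ny, nx = y + dy, x + dx
            if 0 <= ny < h and 0 <= nx < w and not mask[ny, nx] and not outside[ny, nx]:
                outside[ny, nx] = True
                q.append((ny, nx))
    return mask | ~outside


def largest_component_oracle(mask):
    comps = _components(mask, _N8)
    out = np.zeros_like(np.asarray(mask, dtype=bool))
    if not comps:
        return out
    best = max(comps, key=len)  # max() keeps the earliest on ties
    for y, x in best:
        out[y, x] = True
    return out


def label_oracle(mask):
    """Consecutive labels in raster-scan order of component first pixels."""
    out = np.zeros(np.asarray(mask).shape, dtype=np.int32)
    for i, comp in enumerate(_components(mask, _N8), start=1):
        for y, x in comp:
            out[y, x] = i
    return out


# ------------------------------------------------- geodesic assignment

def geodesic_assign_oracle(structure, nuc_labels, tie_decimals=6):
    """Per-pixel nearest-nucleus assignment via sparse-graph Dijkstra.

    8-connected moves cost 1 (axial) or sqrt(2) (diagonal), restricted to
    structure foreground plus nuclei; unreachable structure pixels use
    Euclidean distance to nucleus centroids.  Ties go to the lower label.
    """
    structure = np.asarray(structure, dtype=bool)
    nuc_labels = np.asarray(nuc_labels)
    h, w = structure.shape
    traversable = structure | (nuc_labels > 0)
    idx = -np.ones((h, w), dtype=int)
    nodes = np.argwhere(traversable)
    for i, (r, c) in enumerate(nodes):
        idx[r, c] = i
    rows, cols, vals = [], [], []
    for i, (r, c) in enumerate(nodes):
        for dy, dx in _N8:
            nr, nc = r + dy, c + dx
            if 0 <= nr < h and 0 <= nc < w and traversable[nr, nc]:
                rows.append(i)
                cols.append(idx[nr, nc])
                vals.append(np.hypot(dy, dx))
    n_nodes = len(nodes)
    graph = coo_matrix((vals, (rows, cols)), shape=(n_nodes, n_nodes))
    n_lab = int(nuc_labels.max())
    dist = np.full((n_lab, n_nodes), np.inf)
    for k in range(1, n_lab + 1):
        sources = [idx[r, c] for r, c in np.argwhere(nuc_labels == k)]
        if sources:
            d = dijkstra(graph, directed=False, indices=sources, min_only=True)
            dist[k - 1] = d
    dist = np.round(dist, tie_decimals)
    out = np.zeros((h, w), dtype=np.int32)
    cents = []
    for k in range(1, n_lab + 1):
        pix = np.argwhere(nuc_labels == k)
        cents.append(pix.mean(axis=0) if len(pix) else np.array([np.nan, np.nan]))
    for r, c in np.argwhere(structure):
        d = dist[:, idx[r, c]]
        if np.isfinite(d).any():
            out[r, c] = int(np.argmin(d)) + 1
        else:
            e = np.round([np.hypot(r - cy, c - cx) for cy, cx in cents], tie_decimals)
            out[r, c] = int(np.argmin(e)) + 1
    return out


# ----------------------------------------------------------------- metrics

def mpi_oracle(channel, mask):
    vals = [channel[r, c] for r, c in np.argwhere(np.asarray(mask, dtype=bool))]
    return sum(vals) / len(vals)


def pearson_oracle(x, y):
    x = np.asarray(x, float).ravel()
    y = np.asarray(y, float).ravel()
    n = len(x)
    sx, sy = x.sum(), y.sum()
    num = n * (x * y).sum() - sx * sy
    den = np.sqrt(n * (x**2).sum() - sx**2) * np.sqrt(n * (y**2).sum() - sy**2)
    return num / den


def midrank_oracle(v):
    v = np.asarray(v, float)
    ranks = np.empty(len(v))
    order = np.argsort(v, kind="stable")
    i = 0
    while i < len(v):
        j = i
        while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
            j += 1
        avg = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def spearman_oracle(a, b):
    return pearson_oracle(midrank_oracle(a), midrank_oracle(b))


def iou_oracle(a, b):
    a = np.asarray(a, bool)
    b = np.asarray(b, bool)
    inter = sum(1 for r, c in np.argwhere(a) if b[r, c])
    union = int(a.sum() + b.sum()) - inter
    return 1.0 if union == 0 else inter / union


def _u_statistic(x, y):
    """Mann-Whitney U of x by direct pair counting (0.5 per tie)."""
    u = 0.0
    for xi in x:
        for yj in y:
            if xi > yj:
                u += 1.0
            elif xi == yj:
                u += 0.5
    return u


def mannwhitney_exact_oracle(x, y):
    """Two-sided exact p over all group relabellings, by pair counting."""
    pooled = list(x) + list(y)
    n, nx = len(pooled), len(x)
    mu = nx * (n - nx) / 2
    dev = abs(_u_statistic(x, y) - mu)
    count = total = 0
    for pick in combinations(range(n), nx):
        xs = [pooled[i] for i in pick]
        ys = [pooled[i] for i in range(n) if i not in pick]
        total += 1
        if abs(_u_statistic(xs, ys) - mu) >= dev - 1e-12:
            count += 1
    return count / total


def wilcoxon_exact_oracle(diffs):
    """Two-sided exact signed-rank p over all sign patterns."""
    d = np.asarray(diffs, float)
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    ranks = midrank_oracle(np.abs(d))
    w_obs = sum(r for r, di in zip(ranks, d) if di > 0)
    mu = ranks.sum() / 2
    dev = abs(w_obs - mu)
    count = 0
    for signs in product((0, 1), repeat=len(d)):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if abs(w - mu) >= dev - 1e-12:
            count += 1
    return count / 2 ** len(d)


def bh_oracle(p):
    """Step-up q-values: q_(i) = min_{j >= i} m * p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    best = np.inf
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        best = min(best, m * p[i] / rank)
        q[i] = min(best, 1.0)
    return q


def median3_oracle(img):
    """Naive 3x3 windowed median with reflect padding."""
    img = np.asarray(img)
    pad = np.pad(img, 1, mode="symmetric")  # scipy's 'reflect' convention
    out = np.empty_like(img)
    h, w = img.shape
    for r in range(h):
        for c in range(w):
            out[r, c] = np.median(pad[r : r + 3, c : c + 3])
    return out
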