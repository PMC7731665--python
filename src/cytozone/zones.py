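"""Named subcellular zones and zone algebra.

Per cell the canonical zones are:

* ``whole``     -- the assembled whole-cell mask
* ``nuc``       -- nuclear mask clipped to the whole cell
* ``vim_hi``    -- high-cytoskeleton-signal zone clipped to the whole cell;
  deliberately *not* clipped to exclude the nucleus, so that fibrils
  crossing the nucleus remain part of the vim_hi zone
* ``cytoplasm`` -- whole minus nuc
* ``vim_lo``    -- cytoplasm minus vim_hi

Conservation holds by construction: ``area(nuc) + area(cytoplasm) =
area(whole)`` and ``area(vim_lo) + area(vim_hi ∩ cytoplasm) =
area(cytoplasm)``.

User-defined zones are evaluated with a small set algebra over zone
names supporting union (``∪``, ``|``, ``+``) and difference (``∖``,
``\\``, ``-``).  Mixed operators require explicit parentheses; a chain
of one operator evaluates left to right.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .io import FOV
from .preprocess import binarize, despeckle, fill_holes
from .segmentation import CellSegmentation, PipelineConfig

CANONICAL_ZONES = ("whole", "nuc", "vim_hi", "cytoplasm", "vim_lo")


@dataclass
class ZoneSet:
    """Dictionary of named binary zone masks for one cell (or one FOV)."""

    cell_id: int
    zones: dict[str, np.ndarray] = field(default_factory=dict)
    fov_id: str = "fov"

    def __post_init__(self) -> None:
        self.zones = {k: np.asarray(v, dtype=bool) for k, v in self.zones.items()}
        self._check()

    def _check(self) -> None:
        z = self.zones
        if "whole" not in z or not z["whole"].any():
            raise ValueError("zone set requires a nonempty 'whole' zone")
        whole = z["whole"]
        for name, m in z.items():
            if m.shape != whole.shape:
                raise ValueError(f"zone {name!r} shape mismatch")
            if name != "vim_hi" and (m & ~whole).any():
                raise ValueError(f"zone {name!r} escapes the whole-cell mask")
        if {"nuc", "cytoplasm"} <= z.keys():
            if z["nuc"].sum() + z["cytoplasm"].sum() != whole.sum():
                raise ValueError("nuc + cytoplasm areas do not conserve whole area")

    def area(self, name: str) -> int:
        return int(self.zones[name].sum())

    def names(self) -> list[str]:
        return list(self.zones)

    def add(self, name: str, mask: np.ndarray) -> None:
        self.zones[name] = np.asarray(mask, dtype=bool)


def derive_zones(cell: CellSegmentation, vimhi_fov_mask: np.ndarray, fov_id: str = "fov") -> ZoneSet:
    """Derive the canonical zone set for one segmented cell."""
    whole = cell.whole_cell_mask
    if not whole.any():
        raise ValueError("empty whole-cell mask")
    vimhi_fov_mask = np.asarray(vimhi_fov_mask, dtype=bool)
    if vimhi_fov_mask.shape != whole.shape:
        raise ValueError("vim_hi mask shape mismatch")
    nuc = cell.nuc_mask & whole
    vim_hi = vimhi_fov_mask & whole
    cytoplasm = whole & ~nuc
    vim_lo = cytoplasm & ~vim_hi
    return ZoneSet(
        cell_id=cell.cell_id,
        fov_id=fov_id,
        zones={"whole": whole, "nuc": nuc, "vim_hi": vim_hi, "cytoplasm": cytoplasm, "vim_lo": vim_lo},
    )


_TOKEN = re.compile(r"\s*(?:(?P<lpar>\()|(?P<rpar>\))|(?P<op>[∪∖|+\\-])|(?P<name>[A-Za-z_][A-Za-z0-9_]*))")

_UNION = {"∪", "|", "+"}
_DIFF = {"∖", "\\", "-"}


def _tokenize(expr: str) -> list[str]:
    tokens, pos = [], 0
    while pos < len(expr):
        m = _TOKEN.match(expr, pos)
        if not m or m.end() == pos:
            raise ValueError(f"cannot parse zone expression at: {expr[pos:]!r}")
        tokens.append(next(v for v in m.groupdict().values() if v))
        pos = m.end()
    return tokens


def zone_expression(zs: ZoneSet, expr: str) -> np.ndarray:
    """Evaluate a union/difference algebra over zone names.

    A chain with a single operator kind evaluates left to right; mixing
    union and difference at one level requires explicit parentheses.
    """
    tokens = _tokenize(expr)

    def parse(pos: int) -> tuple[np.ndarray, int]:
        def atom(p: int) -> tuple[np.ndarray, int]:
            if p >= len(tokens):
                raise ValueError("unexpected end of zone expression")
            t = tokens[p]
            if t == "(":
                val, p = parse(p + 1)
                if p >= len(tokens) or tokens[p] != ")":
                    raise ValueError("unbalanced parentheses in zone expression")
                return val, p + 1
            if t in _UNION | _DIFF or t == ")":
                raise ValueError(f"expected zone name, got {t!r}")
            if t not in zs.zones:
                raise KeyError(f"unknown zone name {t!r}; defined: {zs.names()}")
            return zs.zones[t].copy(), p + 1

        val, pos = atom(pos)
        seen_kind = None
        while pos < len(tokens) and tokens[pos] not in (")",):
            op = tokens[pos]
            kind = "union" if op in _UNION else "diff" if op in _DIFF else None
            if kind is None:
                raise ValueError(f"expected operator, got {op!r}")
            if seen_kind and kind != seen_kind:
                raise ValueError("mixed ∪ and ∖ require explicit parentheses")
            seen_kind = kind
            rhs, pos = atom(pos + 1)
            val = val | rhs if kind == "union" else val & ~rhs
        return val, pos

    result, end = parse(0)
    if end != len(tokens):
        raise ValueError("trailing tokens in zone expression")
    return result


def tissue_zones(fov: FOV, config: PipelineConfig | None = None) -> ZoneSet:
    """FOV-level zones for tissue mode: no cell decomposition.

    ``whole`` is the full frame; ``vim_hi`` and ``nuc`` come straight
    from the channel autothresholds.
    """
    cfg = config or PipelineConfig()
    whole = np.ones(fov.shape, dtype=bool)
    nuc = binarize(fov.channel("nuclear"), cfg.method_nuclear, n_bins=cfg.n_bins, bit_depth=fov.bit_depth)
    nuc = fill_holes(despeckle(nuc, cfg.despeckle_min_size))
    vim_hi = binarize(
        fov.channel("cytoskeleton"), cfg.method_cytoskeleton, n_bins=cfg.n_bins, bit_depth=fov.bit_depth
    )
    cytoplasm = whole & ~nuc
    vim_lo = cytoplasm & ~vim_hi
    return ZoneSet(
        cell_id=0,
        fov_id=fov.fov_id,
        zones={"whole": whole, "nuc": nuc, "vim_hi": vim_hi, "cytoplasm": cytoplasm, "vim_lo": vim_lo},
    )
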