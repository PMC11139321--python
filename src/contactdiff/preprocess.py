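"""Normalization to [-1, 1], sliding-window tiling, and stitch-by-averaging.

Balanced contact values are mapped to the network's [-1, 1] range by a
four-step transform: clip at ``maxV``, linear map [0, maxV] -> [1, 10],
log10 to [0, 1], then linear map to [-1, 1].  ``maxV`` is 0.05 at 5 kb and
0.08 at 1 kb by default, chosen near the smallest non-zero value on the
first two diagonals so the short-range pixels do not dominate the scale.

A chromosome matrix is covered by window x window tiles whose top-left
corner slides along the diagonal in fixed bin steps and rightwards in the
same steps, up to a genomic-distance cap (2 Mb by default) beyond which
pixels are out of scope.  Predicted tiles are stitched back by averaging
every covering tile's inverse-normalized value at each pixel.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, List, Optional, Sequence

import numpy as np

from .contact_io import ContactMatrix

__all__ = [
    "NormalizationSpec",
    "TilingParams",
    "Tile",
    "normalize_forward",
    "normalize_inverse",
    "make_tiles",
    "extract_tile",
    "stitch_tiles",
]

#: normalized level that a zero-contact (or missing) pixel maps to
ZERO_LEVEL = -1.0


@dataclass(frozen=True)
class NormalizationSpec:
    """Clipping ceiling and bin size for the four-step value transform."""

    maxV: float = 0.05
    resolution: int = 5000

    def __post_init__(self) -> None:
        if self.maxV <= 0:
            raise ValueError("maxV must be positive")

    @classmethod
    def default_for(cls, resolution: int) -> "NormalizationSpec":
        return cls(maxV=0.08 if resolution == 1000 else 0.05,
                   resolution=resolution)


@dataclass(frozen=True)
class TilingParams:
    """Sliding-window geometry for splitting a chromosome matrix."""

    window: int = 256
    diag_step: int = 50
    max_right_steps: int = 5
    max_distance: int = 2_000_000  # bp

    def __post_init__(self) -> None:
        if min(self.window, self.diag_step) < 1 or self.max_right_steps < 0:
            raise ValueError("window/diag_step must be positive")
        if self.max_distance < 1:
            raise ValueError("max_distance must be positive")

    @classmethod
    def default_for(cls, resolution: int) -> "TilingParams":
        if resolution == 1000:
            return cls(window=256, diag_step=100, max_right_steps=20)
        return cls(window=256, diag_step=50, max_right_steps=5)


@dataclass
class Tile:
    """A window x window normalized submatrix with its placement.

    ``row0``/``col0`` are the bin indices of the window's top-left corner;
    ``col0 = row0 + right_offset_steps * diag_step`` except for an anchored
    final column placement at the chromosome end.  ``values`` is filled by
    :func:`extract_tile` (or by a network); ``coverage`` flags pixels that
    are inside the chromosome and within the genomic-distance cap.
    """

    chrom: str
    window: int
    row0: int
    col0: int
    right_offset_steps: int
    values: Optional[np.ndarray] = None
    coverage: Optional[np.ndarray] = None
    padded: bool = False

    @property
    def row_range(self) -> range:
        return range(self.row0, self.row0 + self.window)

    @property
    def col_range(self) -> range:
        return range(self.col0, self.col0 + self.window)


# -- value transform -------------------------------------------------------


def normalize_forward(values: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    """Map balanced values (>= 0, NaN = missing) to [-1, 1].

    Missing pixels map to -1, the zero-contact image level.
    """
    v = np.asarray(values, dtype=np.float64)
    finite = np.isfinite(v)
    if np.any(v[finite] < 0):
        raise ValueError("balanced values must be non-negative")
    clipped = np.minimum(v, spec.maxV)
    scaled = 1.0 + 9.0 * clipped / spec.maxV         # [1, 10]
    logged = np.log10(scaled)                        # [0, 1]
    out = 2.0 * logged - 1.0                         # [-1, 1]
    return np.where(finite, out, ZERO_LEVEL)


def normalize_inverse(values: np.ndarray, spec: NormalizationSpec) -> np.ndarray:
    """Invert :func:`normalize_forward`; input is clipped to [-1, 1] first."""
    x = np.clip(np.asarray(values, dtype=np.float64), -1.0, 1.0)
    logged = (x + 1.0) / 2.0
    scaled = np.power(10.0, logged)
    return (scaled - 1.0) / 9.0 * spec.maxV


# -- tiling ----------------------------------------------------------------


def make_tiles(
    n_bins: int,
    params: TilingParams,
    resolution: int,
    chrom: str = "",
) -> List[Tile]:
    """Enumerate tile placements covering one chromosome.

    Diagonal anchors run over multiples of ``diag_step``; each anchor takes
    rightward offsets ``k = 0 .. max_right_steps`` whose windows fit in the
    chromosome.  A final anchor at ``n_bins - window`` (and, per anchor, a
    final column at ``n_bins - window``) is appended when the stepped grid
    cannot reach the chromosome end, so every in-scope pixel is covered.
    """
    w = params.window
    if n_bins < w:
        # chromosome shorter than one window: single padded placement
        tile = Tile(chrom=chrom, window=w, row0=0, col0=0,
                    right_offset_steps=0, padded=True)
        return [tile]

    max_dist_bins = params.max_distance // resolution
    last = n_bins - w
    diag_starts = list(range(0, last + 1, params.diag_step))
    if diag_starts[-1] != last:
        diag_starts.append(last)

    placements: List[Tile] = []
    seen = set()
    for r0 in diag_starts:
        cols = []
        for k in range(params.max_right_steps + 1):
            c0 = r0 + k * params.diag_step
            if c0 + w > n_bins:
                break
            cols.append((c0, k))
        # anchored final column: the stepped grid stops short of the end while
        # in-scope pixels (distance < cap) would be left uncovered
        reach = r0 + params.max_right_steps * params.diag_step
        if reach + w > n_bins and cols and cols[-1][0] < last:
            # anchored window still holds in-scope pixels iff its minimum
            # distance (last - r0 - w + 1) is below the cap
            if last - r0 < max_dist_bins + w - 1:
                cols.append((last, (last - r0) // params.diag_step))
        for c0, k in cols:
            key = (r0, c0)
            if key in seen:
                continue
            seen.add(key)
            placements.append(
                Tile(chrom=chrom, window=w, row0=r0, col0=c0,
                     right_offset_steps=k)
            )
    return placements


def _coverage_mask(tile: Tile, n_bins: int, max_dist_bins: int) -> np.ndarray:
    w = tile.window
    rows = tile.row0 + np.arange(w)[:, None]
    cols = tile.col0 + np.arange(w)[None, :]
    inside = (rows < n_bins) & (cols < n_bins)
    in_scope = np.abs(cols - rows) < max_dist_bins
    return inside & in_scope


def extract_tile(
    matrix: ContactMatrix,
    placement: Tile,
    spec: NormalizationSpec,
    params: TilingParams,
) -> Tile:
    """Fill a placement with normalized values from the sparse matrix.

    Symmetry is applied below the diagonal; out-of-chromosome pixels are set
    to -1 and flagged out of coverage.
    """
    w = placement.window
    n = matrix.n_bins
    dense = np.zeros((w, w), dtype=np.float64)

    r0, c0 = placement.row0, placement.col0
    # upper-triangle entries falling in [r0, r0+w) x [c0, c0+w), plus their
    # mirrors for the below-diagonal part of diagonal-straddling windows
    for (bi, bj) in ((matrix.bin1, matrix.bin2), (matrix.bin2, matrix.bin1)):
        sel = (bi >= r0) & (bi < r0 + w) & (bj >= c0) & (bj < c0 + w)
        dense[bi[sel] - r0, bj[sel] - c0] = matrix.value[sel]

    rows = r0 + np.arange(w)[:, None]
    cols = c0 + np.arange(w)[None, :]
    inside = (rows < n) & (cols < n)
    miss = np.zeros((w, w), dtype=bool)
    valid_r = np.clip(rows, 0, n - 1)
    valid_c = np.clip(cols, 0, n - 1)
    miss = matrix.missing[valid_r] | matrix.missing[valid_c]
    dense[miss] = np.nan

    values = normalize_forward(dense, spec)
    values[~inside] = ZERO_LEVEL

    max_dist_bins = params.max_distance // matrix.resolution
    coverage = _coverage_mask(placement, n, max_dist_bins)
    return Tile(
        chrom=placement.chrom,
        window=w,
        row0=r0,
        col0=c0,
        right_offset_steps=placement.right_offset_steps,
        values=values,
        coverage=coverage,
        padded=placement.padded or not inside.all(),
    )


def stitch_tiles(
    tiles: Sequence[Tile],
    n_bins: int,
    spec: NormalizationSpec,
    chrom: str = "",
    resolution: int = 5000,
    missing: Optional[np.ndarray] = None,
) -> ContactMatrix:
    """Average inverse-normalized tile predictions into a chromosome matrix.

    Averaging happens on the balanced (inverse-normalized) scale.  Pixels
    outside every tile's coverage are absent from the output; the result is
    stored upper-triangle.
    """
    if not tiles:
        raise ValueError("no tiles to stitch")
    w = tiles[0].window
    acc = np.zeros((n_bins, n_bins), dtype=np.float64)
    cnt = np.zeros((n_bins, n_bins), dtype=np.int64)
    for tile in tiles:
        if tile.window != w:
            raise ValueError("inconsistent tile window sizes")
        if tile.values is None or tile.coverage is None:
            raise ValueError("tile has no prediction values/coverage")
        pred = normalize_inverse(tile.values, spec)
        cov = tile.coverage
        r0, c0 = tile.row0, tile.col0
        rows = r0 + np.arange(w)[:, None]
        cols = c0 + np.arange(w)[None, :]
        rr = rows.repeat(w, axis=1)[cov]
        cc = cols.repeat(w, axis=0)[cov]
        np.add.at(acc, (rr, cc), pred[cov])
        np.add.at(cnt, (rr, cc), 1)
    covered = cnt > 0
    avg = np.zeros_like(acc)
    avg[covered] = acc[covered] / cnt[covered]
    # symmetrize: pixels may be covered on one side of the diagonal only
    iu, ju = np.triu_indices(n_bins)
    up_cov = covered[iu, ju]
    lo_cov = covered[ju, iu]
    both = up_cov & lo_cov & (iu != ju)
    vals = np.where(
        both,
        (avg[iu, ju] + avg[ju, iu]) / 2.0,
        np.where(up_cov, avg[iu, ju], avg[ju, iu]),
    )
    keep = (up_cov | lo_cov)
    if missing is not None:
        keep &= ~missing[iu] & ~missing[ju]
    keep &= vals > 0
    return ContactMatrix(
        chrom=chrom,
        resolution=resolution,
        n_bins=n_bins,
        bin1=iu[keep],
        bin2=ju[keep],
        value=vals[keep],
        missing=missing,
    )
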