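"""Loop-level evaluation: APA with corner scores, loop matching and recovery,
top-loop selection, CTCF motif-orientation classes, anchor/peak overlap,
enhancer-promoter labeling, and loop-pixel value extraction.

Loops are bin-indexed pixels ``(bin1 <= bin2)`` at a stated resolution with
an optional FDR used only for ranking.  Anchors derive from bins as
half-open intervals ``[bin * resolution, (bin + 1) * resolution)`` and may
be extended symmetrically (the 5-kb anchor +/- 5-kb extension gives the
15-kb loci used for ChIP-seq peak overlap).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .contact_io import ContactMatrix

__all__ = [
    "Loop",
    "LoopSet",
    "APAConfig",
    "APAResult",
    "read_bedpe",
    "write_bedpe",
    "read_bed",
    "match_loops",
    "recovery_fraction",
    "top_loops",
    "apa",
    "plot_apa",
    "classify_ctcf_orientation",
    "anchor_peak_overlap",
    "label_ep_loops",
    "extract_pixel_values",
]

CTCF_CLASSES = ("convergent", "divergent", "forward", "reverse", "unclassified")


@dataclass(frozen=True)
class Loop:
    """A single loop pixel."""

    chrom: str
    bin1: int
    bin2: int
    fdr: Optional[float] = None

    def __post_init__(self) -> None:
        if self.bin1 > self.bin2:
            raise ValueError("bin1 must be <= bin2")
        if self.fdr is not None and not 0 <= self.fdr <= 1:
            raise ValueError("fdr must be in [0, 1]")


@dataclass
class LoopSet:
    """Vectorized collection of loop pixels at one resolution."""

    chrom: np.ndarray
    bin1: np.ndarray
    bin2: np.ndarray
    resolution: int
    fdr: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        if self.fdr is not None:
            self.fdr = np.asarray(self.fdr, dtype=np.float64)
            if len(self.fdr) != len(self.bin1):
                raise ValueError("fdr must parallel loops")
        if np.any(self.bin1 > self.bin2):
            raise ValueError("loops must satisfy bin1 <= bin2")

    def __len__(self) -> int:
        return len(self.bin1)

    @property
    def distance(self) -> np.ndarray:
        """Genomic distance in bp per loop."""
        return (self.bin2 - self.bin1) * self.resolution

    def subset(self, mask: np.ndarray) -> "LoopSet":
        return LoopSet(
            chrom=self.chrom[mask],
            bin1=self.bin1[mask],
            bin2=self.bin2[mask],
            resolution=self.resolution,
            fdr=None if self.fdr is None else self.fdr[mask],
        )

    def filter_distance(self, min_bp: int, max_bp: int) -> "LoopSet":
        """Loops with genomic distance in [min_bp, max_bp], inclusive."""
        d = self.distance
        return self.subset((d >= min_bp) & (d <= max_bp))

    def anchors(self, extension: int = 0) -> pd.DataFrame:
        """Deduplicated anchor intervals (both sides), extended +/- extension.

        Intervals are half-open in bp, clipped at zero on the left.
        """
        res = self.resolution
        rows = []
        for side in ("bin1", "bin2"):
            b = getattr(self, side)
            rows.append(pd.DataFrame({
                "chrom": self.chrom,
                "start": b * res - extension,
                "end": (b + 1) * res + extension,
            }))
        df = pd.concat(rows, ignore_index=True)
        df["start"] = df["start"].clip(lower=0)
        return df.drop_duplicates(ignore_index=True)


def read_bedpe(path: str, resolution: int) -> LoopSet:
    """Read BEDPE loops (chrom1,start1,end1,chrom2,start2,end2[,fdr]).

    Anchor midpoints are mapped to bins at the stated resolution; anchors
    are reordered so bin1 <= bin2 (only cis loops are supported).
    """
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    if df.shape[1] < 6:
        raise ValueError("BEDPE needs at least 6 columns")
    if not (df[0] == df[3]).all():
        raise ValueError("only cis (same-chromosome) loops are supported")
    b1 = ((df[1] + df[2]) // 2 // resolution).to_numpy(dtype=np.int64)
    b2 = ((df[4] + df[5]) // 2 // resolution).to_numpy(dtype=np.int64)
    lo, hi = np.minimum(b1, b2), np.maximum(b1, b2)
    fdr = df[6].to_numpy(dtype=np.float64) if df.shape[1] > 6 else None
    return LoopSet(chrom=df[0].to_numpy(dtype=object), bin1=lo, bin2=hi,
                   resolution=resolution, fdr=fdr)


def write_bedpe(loops: LoopSet, path: str) -> None:
    res = loops.resolution
    cols = {
        0: loops.chrom, 1: loops.bin1 * res, 2: (loops.bin1 + 1) * res,
        3: loops.chrom, 4: loops.bin2 * res, 5: (loops.bin2 + 1) * res,
    }
    if loops.fdr is not None:
        cols[6] = loops.fdr
    pd.DataFrame(cols).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str) -> pd.DataFrame:
    """BED intervals; strand read from column 6 when present."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    out = pd.DataFrame({
        "chrom": df[0], "start": df[1].astype(np.int64),
        "end": df[2].astype(np.int64),
    })
    if df.shape[1] >= 6:
        out["strand"] = df[5]
    return out


# -- loop matching and recovery -------------------------------------------


def match_loops(reference: LoopSet, query: LoopSet, s: int) -> np.ndarray:
    """Per-reference flags: matched iff a query loop lies in the
    (2s+1) x (2s+1) pixel square centered on the reference pixel."""
    if reference.resolution != query.resolution:
        raise ValueError("resolution mismatch between loop sets")
    by_chrom: Dict[str, set] = {}
    for c, i, j in zip(query.chrom, query.bin1, query.bin2):
        by_chrom.setdefault(c, set()).add((int(i), int(j)))
    flags = np.zeros(len(reference), dtype=bool)
    for idx, (c, i, j) in enumerate(
        zip(reference.chrom, reference.bin1, reference.bin2)
    ):
        pool = by_chrom.get(c)
        if not pool:
            continue
        found = False
        for di in range(-s, s + 1):
            for dj in range(-s, s + 1):
                if (i + di, j + dj) in pool:
                    found = True
                    break
            if found:
                break
        flags[idx] = found
    return flags


def recovery_fraction(reference: LoopSet, query: LoopSet, s: int) -> float:
    """Fraction of reference loops matched by the query at extending size s."""
    if len(reference) == 0:
        raise ValueError("empty reference loop set")
    return float(match_loops(reference, query, s).mean())


def top_loops(loops: LoopSet, n: int) -> LoopSet:
    """The n loops with smallest FDR; deterministic lexicographic tie-break."""
    if loops.fdr is None:
        raise ValueError("top_loops requires FDR values")
    if n > len(loops):
        raise ValueError("n exceeds loop count")
    order = np.lexsort((loops.bin2, loops.bin1, loops.chrom.astype(str),
                        loops.fdr))
    return loops.subset(order[:n])


# -- aggregate peak analysis ----------------------------------------------


@dataclass(frozen=True)
class APAConfig:
    """Window/corner geometry and mode for aggregate peak analysis.

    ``mode="oe"`` expects an observed/expected matrix and uses all loops;
    ``mode="raw"`` expects balanced values with loops pre-filtered to the
    100 kb - 2 Mb distance band (both ends inclusive).
    """

    window: int = 11
    corner: int = 3
    mode: str = "oe"

    def __post_init__(self) -> None:
        if self.window % 2 == 0:
            raise ValueError("window must be odd")
        if not 1 <= self.corner <= (self.window - 1) // 2:
            raise ValueError("corner must fit beside the center")
        if self.mode not in ("oe", "raw"):
            raise ValueError("mode must be 'oe' or 'raw'")

    @classmethod
    def default_for(cls, resolution: int, mode: str = "oe") -> "APAConfig":
        if resolution == 1000:
            return cls(window=51, corner=15, mode=mode)
        return cls(window=11, corner=3, mode=mode)


@dataclass
class APAResult:
    """Averaged submatrix around loop pixels plus the four corner scores."""

    mean_submatrix: np.ndarray
    n_loops_used: int
    n_loops_skipped: int
    corner_scores: Dict[str, float]


def apa(matrix: ContactMatrix, loops: LoopSet, config: APAConfig) -> APAResult:
    """Average window x window blocks centered at loop pixels.

    Each corner score is the center pixel of the averaged block divided by
    the mean of that corner's corner x corner block.  Loops whose window
    leaves the matrix are skipped and counted.
    """
    w = config.window
    half = w // 2
    n = matrix.n_bins
    dense = matrix.to_dense(fill_missing=np.nan)
    use = loops
    if config.mode == "raw":
        use = loops.filter_distance(100_000, 2_000_000)
    acc = np.zeros((w, w))
    cnt = np.zeros((w, w))
    used = skipped = 0
    for c, i, j in zip(use.chrom, use.bin1, use.bin2):
        if c != matrix.chrom or i - half < 0 or j + half >= n \
                or i + half >= n or j - half < 0:
            skipped += 1
            continue
        block = dense[i - half:i + half + 1, j - half:j + half + 1]
        finite = np.isfinite(block)
        acc[finite] += block[finite]
        cnt += finite
        used += 1
    if used == 0:
        raise ValueError("no usable loops for APA")
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(cnt > 0, acc / cnt, np.nan)
    center = mean[half, half]
    cs = config.corner
    corners = {
        "lower_left": mean[w - cs:, :cs],
        "lower_right": mean[w - cs:, w - cs:],
        "upper_left": mean[:cs, :cs],
        "upper_right": mean[:cs, w - cs:],
    }
    scores = {
        name: float(center / np.nanmean(block))
        for name, block in corners.items()
    }
    return APAResult(mean_submatrix=mean, n_loops_used=used,
                     n_loops_skipped=skipped, corner_scores=scores)


def plot_apa(result: APAResult, path: str, title: str = "") -> None:
    """Heat map of the averaged APA block with corner scores annotated."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(4, 4))
    im = ax.imshow(result.mean_submatrix, cmap="Reds")
    fig.colorbar(im, ax=ax, shrink=0.8)
    w = result.mean_submatrix.shape[0]
    pos = {"upper_left": (0.05, 0.95), "upper_right": (0.95, 0.95),
           "lower_left": (0.05, 0.05), "lower_right": (0.95, 0.05)}
    for name, (x, y) in pos.items():
        ax.text(x, y, f"{result.corner_scores[name]:.2f}",
                transform=ax.transAxes, ha="left" if x < 0.5 else "right",
                va="top" if y > 0.5 else "bottom", fontsize=9)
    ax.set_title(title or f"APA (n={result.n_loops_used})")
    ax.set_xticks([0, w - 1])
    ax.set_yticks([0, w - 1])
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# -- interval overlap machinery -------------------------------------------


def _overlaps_any(
    q_chrom: np.ndarray, q_start: np.ndarray, q_end: np.ndarray,
    peaks: pd.DataFrame,
) -> np.ndarray:
    """Half-open interval overlap (>= 1 bp) of queries against a peak table.

    Sorted-scan: peaks sorted by start per chromosome with a running prefix
    maximum of ends; a query [s, e) overlaps iff some peak has start < e and
    end > s.
    """
    out = np.zeros(len(q_start), dtype=bool)
    for chrom, sub in peaks.groupby("chrom", sort=False):
        sel = np.flatnonzero(q_chrom == chrom)
        if len(sel) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        order = np.argsort(starts, kind="stable")
        starts, ends = starts[order], ends[order]
        prefix_max_end = np.maximum.accumulate(ends)
        k = np.searchsorted(starts, q_end[sel], side="left")
        has = k > 0
        hit = np.zeros(len(sel), dtype=bool)
        hit[has] = prefix_max_end[k[has] - 1] > q_start[sel[has]]
        out[sel] = hit
    return out


def anchor_peak_overlap(
    loops: LoopSet, peaks: pd.DataFrame, extension: int = 5000
) -> float:
    """Fraction of deduplicated, extended loop anchors overlapping >= 1 peak."""
    anchors = loops.anchors(extension=extension)
    if len(anchors) == 0:
        return 0.0
    hits = _overlaps_any(
        anchors["chrom"].to_numpy(dtype=object),
        anchors["start"].to_numpy(),
        anchors["end"].to_numpy(),
        peaks,
    )
    return float(hits.mean())


def label_ep_loops(
    loops: LoopSet,
    promoters: pd.DataFrame,
    enhancers: pd.DataFrame,
    extension: int = 5000,
) -> np.ndarray:
    """EP flag per loop: one extended anchor overlaps an enhancer and the
    other overlaps a promoter (in either orientation)."""
    res = loops.resolution
    flags = np.zeros(len(loops), dtype=bool)
    sides = []
    for b in (loops.bin1, loops.bin2):
        start = np.maximum(b * res - extension, 0)
        end = (b + 1) * res + extension
        in_e = _overlaps_any(loops.chrom, start, end, enhancers)
        in_p = _overlaps_any(loops.chrom, start, end, promoters)
        sides.append((in_e, in_p))
    (e1, p1), (e2, p2) = sides
    return (e1 & p2) | (p1 & e2)


def classify_ctcf_orientation(
    strand1: Optional[str], strand2: Optional[str]
) -> str:
    """Motif-orientation class from the resolved strands of the two anchors
    (upstream anchor first): forward-reverse is convergent, reverse-forward
    divergent, forward-forward forward, reverse-reverse reverse; anchors
    without a single resolved motif strand are unclassified."""
    table = {("+", "-"): "convergent", ("-", "+"): "divergent",
             ("+", "+"): "forward", ("-", "-"): "reverse"}
    return table.get((strand1, strand2), "unclassified")


def classify_loops_ctcf(
    loops: LoopSet, motifs: pd.DataFrame, extension: int = 0
) -> np.ndarray:
    """Orientation class per loop from a stranded motif interval table.

    An anchor's strand is resolved only if all overlapping motifs agree;
    anchors overlapping both strands (or none) leave the loop unclassified.
    """
    if "strand" not in motifs:
        raise ValueError("motif table needs a strand column")
    fwd = motifs[motifs["strand"] == "+"]
    rev = motifs[motifs["strand"] == "-"]
    res = loops.resolution
    resolved = []
    for b in (loops.bin1, loops.bin2):
        start = np.maximum(b * res - extension, 0)
        end = (b + 1) * res + extension
        has_f = _overlaps_any(loops.chrom, start, end, fwd)
        has_r = _overlaps_any(loops.chrom, start, end, rev)
        strand = np.where(has_f & ~has_r, "+",
                          np.where(has_r & ~has_f, "-", "?"))
        resolved.append(strand)
    s1, s2 = resolved
    return np.array([
        classify_ctcf_orientation(a if a != "?" else None,
                                  b if b != "?" else None)
        for a, b in zip(s1, s2)
    ])


def extract_pixel_values(loops: LoopSet, matrix: ContactMatrix) -> np.ndarray:
    """Balanced value at each loop pixel: 0 if no stored entry, NaN if either
    bin is missing."""
    n = matrix.n_bins
    if len(loops) and (loops.bin1.min() < 0 or loops.bin2.max() >= n):
        raise ValueError("loop bins out of matrix range")
    return np.array([matrix.get(i, j)
                     for i, j in zip(loops.bin1, loops.bin2)])
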