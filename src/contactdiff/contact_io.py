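"""Chromosome-scale contact matrices in the cool dialect.

A balanced contact matrix is stored sparsely as upper-triangle triplets
``(bin_i, bin_j, value)`` with 0-based bin indices over half-open genomic
intervals ``[start, start + resolution)``.  Balanced values follow the cool
convention ``value = raw_count * weight_i * weight_j``; bins whose balancing
weight is undefined (NaN) are *missing* and carry no entries.  Pixels between
two non-missing bins that have no stored entry are true zeros, distinct from
missing data.

On-disk format is a minimal single-resolution cool (HDF5) layout with
``chroms``, ``bins``, ``pixels`` and ``indexes`` groups, readable by standard
cool tooling; a COO triplet text format is provided as a fallback.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import h5py
import numpy as np

__all__ = [
    "ContactMatrix",
    "ExpectedProfile",
    "read_cool",
    "write_cool",
    "read_coo_text",
    "write_coo_text",
    "compute_expected",
    "observed_over_expected",
    "downsample_counts",
]


@dataclass
class ContactMatrix:
    """One chromosome's balanced contact values at a fixed bin size.

    Parameters
    ----------
    chrom : str
        Chromosome name.
    resolution : int
        Bin size in bp.
    n_bins : int
        Number of bins, ``ceil(chrom_length / resolution)``.
    bin1, bin2 : ndarray of int
        Upper-triangle bin indices, ``bin1 <= bin2``.
    value : ndarray of float
        Balanced contact frequency per entry (dimensionless, >= 0).
    raw : ndarray of int, optional
        Parallel raw counts, when known.
    weights : ndarray of float, optional
        Per-bin balancing weights (length ``n_bins``); NaN marks missing bins.
    missing : ndarray of bool, optional
        Explicit missing-bin mask; derived from ``weights`` when omitted.
    """

    chrom: str
    resolution: int
    n_bins: int
    bin1: np.ndarray
    bin2: np.ndarray
    value: np.ndarray
    raw: Optional[np.ndarray] = None
    weights: Optional[np.ndarray] = None
    missing: Optional[np.ndarray] = field(default=None)

    def __post_init__(self) -> None:
        self.bin1 = np.asarray(self.bin1, dtype=np.int64)
        self.bin2 = np.asarray(self.bin2, dtype=np.int64)
        self.value = np.asarray(self.value, dtype=np.float64)
        if self.raw is not None:
            self.raw = np.asarray(self.raw)
        if self.weights is not None:
            self.weights = np.asarray(self.weights, dtype=np.float64)
            if self.weights.shape != (self.n_bins,):
                raise ValueError("weights must have length n_bins")
        if self.missing is None:
            if self.weights is not None:
                self.missing = np.isnan(self.weights)
            else:
                self.missing = np.zeros(self.n_bins, dtype=bool)
        self.missing = np.asarray(self.missing, dtype=bool)
        self._validate()
        self._canonicalize()

    def _validate(self) -> None:
        if self.n_bins < 1:
            raise ValueError("n_bins must be >= 1")
        if not (len(self.bin1) == len(self.bin2) == len(self.value)):
            raise ValueError("triplet arrays must have equal length")
        if self.raw is not None and len(self.raw) != len(self.value):
            raise ValueError("raw counts must parallel values")
        if np.any(self.bin1 > self.bin2):
            raise ValueError("entries must be upper triangle (bin1 <= bin2)")
        if len(self.bin1) and (
            self.bin1.min() < 0 or self.bin2.max() >= self.n_bins
        ):
            raise ValueError("bin indices out of range")
        if not np.all(np.isfinite(self.value)) or np.any(self.value < 0):
            raise ValueError("balanced values must be finite and >= 0")
        if len(self.bin1) and (
            np.any(self.missing[self.bin1]) or np.any(self.missing[self.bin2])
        ):
            raise ValueError("missing bins must carry no entries")

    def _canonicalize(self) -> None:
        order = np.lexsort((self.bin2, self.bin1))
        self.bin1 = self.bin1[order]
        self.bin2 = self.bin2[order]
        self.value = self.value[order]
        if self.raw is not None:
            self.raw = self.raw[order]

    # -- queries ----------------------------------------------------------

    @property
    def n_entries(self) -> int:
        return len(self.value)

    def get(self, i: int, j: int) -> float:
        """Value at pixel (i, j); symmetric lookup; NaN if either bin missing."""
        if i > j:
            i, j = j, i
        if self.missing[i] or self.missing[j]:
            return float("nan")
        lo = np.searchsorted(self.bin1, i, side="left")
        hi = np.searchsorted(self.bin1, i, side="right")
        k = np.searchsorted(self.bin2[lo:hi], j, side="left") + lo
        if k < hi and self.bin2[k] == j:
            return float(self.value[k])
        return 0.0

    def to_dense(self, fill_missing: float = np.nan) -> np.ndarray:
        """Dense symmetric (n_bins, n_bins) array; missing bins filled."""
        m = np.zeros((self.n_bins, self.n_bins), dtype=np.float64)
        m[self.bin1, self.bin2] = self.value
        m[self.bin2, self.bin1] = self.value
        m[self.missing, :] = fill_missing
        m[:, self.missing] = fill_missing
        return m

    @classmethod
    def from_dense(
        cls,
        dense: np.ndarray,
        chrom: str,
        resolution: int,
        missing: Optional[np.ndarray] = None,
        weights: Optional[np.ndarray] = None,
    ) -> "ContactMatrix":
        """Build from a dense symmetric array (upper triangle is taken)."""
        n = dense.shape[0]
        iu, ju = np.triu_indices(n)
        vals = np.asarray(dense, dtype=np.float64)[iu, ju]
        if missing is None and weights is not None:
            missing = np.isnan(weights)
        if missing is None:
            missing = np.zeros(n, dtype=bool)
        keep = (
            (vals != 0)
            & np.isfinite(vals)
            & ~missing[iu]
            & ~missing[ju]
        )
        return cls(
            chrom=chrom,
            resolution=resolution,
            n_bins=n,
            bin1=iu[keep],
            bin2=ju[keep],
            value=vals[keep],
            weights=weights,
            missing=missing,
        )


@dataclass
class ExpectedProfile:
    """Mean balanced contact per diagonal offset (distance-decay profile)."""

    chrom: str
    resolution: int
    values: np.ndarray  # length n_bins; NaN where undefined

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)


# -- cool-dialect HDF5 I/O -------------------------------------------------


def write_cool(matrix: ContactMatrix, path: str) -> None:
    """Write a single-resolution cool (HDF5) file.

    Raw counts are stored when present (with the balancing weight column);
    otherwise balanced values are written directly as float counts with unit
    weights, so ``read_cool(write_cool(m))`` is the identity on entries.
    """
    if not np.all(np.isfinite(matrix.value)):
        raise ValueError("refusing to write non-finite values")
    n = matrix.n_bins
    res = matrix.resolution
    chrom_length = n * res
    with h5py.File(path, "w") as f:
        f.attrs["format"] = "HDF5::Cooler"
        f.attrs["format-version"] = 3
        f.attrs["bin-type"] = "fixed"
        f.attrs["bin-size"] = res
        f.attrs["nbins"] = n
        f.attrs["nchroms"] = 1
        f.attrs["nnz"] = matrix.n_entries
        f.attrs["generated-by"] = "contactdiff"
        g = f.create_group("chroms")
        g.create_dataset("name", data=np.array([matrix.chrom.encode()]))
        g.create_dataset("length", data=np.array([chrom_length], dtype=np.int64))
        starts = np.arange(n, dtype=np.int64) * res
        ends = np.minimum(starts + res, chrom_length)
        g = f.create_group("bins")
        g.create_dataset("chrom", data=np.zeros(n, dtype=np.int32))
        g.create_dataset("start", data=starts)
        g.create_dataset("end", data=ends)
        if matrix.weights is not None:
            weight = matrix.weights
        else:
            weight = np.ones(n, dtype=np.float64)
            weight[matrix.missing] = np.nan
        g.create_dataset("weight", data=weight)
        g = f.create_group("pixels")
        g.create_dataset("bin1_id", data=matrix.bin1)
        g.create_dataset("bin2_id", data=matrix.bin2)
        if matrix.raw is not None:
            g.create_dataset("count", data=np.asarray(matrix.raw, dtype=np.int64))
        else:
            g.create_dataset("count", data=matrix.value)
        g = f.create_group("indexes")
        g.create_dataset(
            "chrom_offset", data=np.array([0, n], dtype=np.int64)
        )
        bin1_offset = np.searchsorted(
            matrix.bin1, np.arange(n + 1), side="left"
        ).astype(np.int64)
        g.create_dataset("bin1_offset", data=bin1_offset)


def read_cool(
    path: str, chrom: str, resolution: int, balance: bool = True
) -> ContactMatrix:
    """Read one chromosome's matrix from a cool file.

    With ``balance=True`` (default) entries are ``count * w_i * w_j`` and bins
    with NaN weight enter the missing mask; with ``balance=False`` raw counts
    are returned as values and no bin is missing.
    """
    with h5py.File(path, "r") as f:
        res = int(f.attrs["bin-size"])
        if res != resolution:
            raise ValueError(
                f"requested resolution {resolution} but file stores {res}"
            )
        names = [x.decode() if isinstance(x, bytes) else str(x)
                 for x in f["chroms/name"][:]]
        if chrom not in names:
            raise ValueError(f"chromosome {chrom!r} not in file ({names})")
        cix = names.index(chrom)
        chrom_offset = f["indexes/chrom_offset"][:]
        b0, b1 = int(chrom_offset[cix]), int(chrom_offset[cix + 1])
        n = b1 - b0
        bin1_offset = f["indexes/bin1_offset"][:]
        p0, p1 = int(bin1_offset[b0]), int(bin1_offset[b1])
        bin1 = f["pixels/bin1_id"][p0:p1] - b0
        bin2 = f["pixels/bin2_id"][p0:p1] - b0
        count = f["pixels/count"][p0:p1]
        inside = bin2 < n  # drop trans pixels if any
        bin1, bin2, count = bin1[inside], bin2[inside], count[inside]
        has_weights = "weight" in f["bins"]
        weights = f["bins/weight"][b0:b1] if has_weights else None

    raw = count if np.issubdtype(count.dtype, np.integer) else None
    if not balance:
        return ContactMatrix(
            chrom=chrom,
            resolution=resolution,
            n_bins=n,
            bin1=bin1,
            bin2=bin2,
            value=count.astype(np.float64),
            raw=raw,
        )
    if weights is None:
        raise ValueError(
            "file has no balancing weights; pass balance=False for raw counts"
        )
    balanced = count * weights[bin1] * weights[bin2]
    keep = np.isfinite(balanced)
    return ContactMatrix(
        chrom=chrom,
        resolution=resolution,
        n_bins=n,
        bin1=bin1[keep],
        bin2=bin2[keep],
        value=balanced[keep],
        raw=raw[keep] if raw is not None else None,
        weights=weights,
    )


# -- COO text fallback -----------------------------------------------------


def write_coo_text(matrix: ContactMatrix, path: str) -> None:
    """Tab-separated ``bin1 bin2 value`` triplets with a small header."""
    with open(path, "w") as fh:
        fh.write(
            f"# chrom={matrix.chrom} resolution={matrix.resolution} "
            f"n_bins={matrix.n_bins}\n"
        )
        miss = np.flatnonzero(matrix.missing)
        fh.write("# missing=" + ",".join(map(str, miss)) + "\n")
        for i, j, v in zip(matrix.bin1, matrix.bin2, matrix.value):
            fh.write(f"{i}\t{j}\t{float(v)!r}\n")


def read_coo_text(path: str) -> ContactMatrix:
    chrom, resolution, n_bins, missing = "?", 0, 0, []
    b1, b2, vv = [], [], []
    with open(path) as fh:
        for line in fh:
            if line.startswith("#"):
                if "chrom=" in line:
                    for tok in line[1:].split():
                        k, _, v = tok.partition("=")
                        if k == "chrom":
                            chrom = v
                        elif k == "resolution":
                            resolution = int(v)
                        elif k == "n_bins":
                            n_bins = int(v)
                elif "missing=" in line:
                    body = line.split("=", 1)[1].strip()
                    missing = [int(x) for x in body.split(",") if x]
                continue
            i, j, v = line.split()
            b1.append(int(i))
            b2.append(int(j))
            vv.append(float(v))
    mask = np.zeros(n_bins, dtype=bool)
    mask[missing] = True
    return ContactMatrix(
        chrom=chrom,
        resolution=resolution,
        n_bins=n_bins,
        bin1=np.array(b1, dtype=np.int64),
        bin2=np.array(b2, dtype=np.int64),
        value=np.array(vv, dtype=np.float64),
        missing=mask,
    )


# -- expected profile and O/E ---------------------------------------------


def compute_expected(matrix: ContactMatrix) -> ExpectedProfile:
    """Mean balanced value per diagonal offset over non-missing bin pairs.

    Absent entries among non-missing pairs count as zero.  Offsets with no
    valid pair are NaN.
    """
    n = matrix.n_bins
    valid = (~matrix.missing).astype(np.float64)
    # number of valid (i, i+d) pairs per offset d = autocorrelation of mask
    pair_counts = np.correlate(valid, valid, mode="full")[n - 1:]
    offsets = matrix.bin2 - matrix.bin1
    sums = np.bincount(offsets, weights=matrix.value, minlength=n)
    with np.errstate(invalid="ignore", divide="ignore"):
        means = np.where(pair_counts > 0, sums / pair_counts, np.nan)
    return ExpectedProfile(matrix.chrom, matrix.resolution, means)


def observed_over_expected(
    matrix: ContactMatrix, expected: ExpectedProfile
) -> ContactMatrix:
    """Divide each value by the expected value at its diagonal offset.

    Entries at offsets where the expected value is zero or undefined are
    dropped (treated as missing data).
    """
    if (
        expected.chrom != matrix.chrom
        or expected.resolution != matrix.resolution
        or len(expected.values) < matrix.n_bins
    ):
        raise ValueError("expected profile does not match matrix")
    offs = matrix.bin2 - matrix.bin1
    exp = expected.values[offs]
    ok = np.isfinite(exp) & (exp > 0)
    return ContactMatrix(
        chrom=matrix.chrom,
        resolution=matrix.resolution,
        n_bins=matrix.n_bins,
        bin1=matrix.bin1[ok],
        bin2=matrix.bin2[ok],
        value=matrix.value[ok] / exp[ok],
        weights=matrix.weights,
        missing=matrix.missing,
    )


# -- read-level down-sampling ---------------------------------------------


def downsample_counts(
    matrix: ContactMatrix,
    fraction: float,
    seed: int,
    rescale_weights: bool = True,
) -> ContactMatrix:
    """Binomial thinning of raw counts, emulating read-pair down-sampling.

    Each raw count c is replaced by Binomial(c, fraction).  Balanced values
    are recomputed from the thinned counts; with ``rescale_weights`` (default)
    the balancing weights are multiplied by 1/sqrt(fraction) so the balanced
    scale stays depth-invariant, as re-balancing the thinned matrix would do.
    Deterministic given ``seed``.
    """
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    if matrix.raw is None:
        raise ValueError("downsampling requires raw counts")
    if fraction == 1.0:
        return matrix
    rng = np.random.default_rng(seed)
    new_raw = rng.binomial(np.asarray(matrix.raw, dtype=np.int64), fraction)
    if matrix.weights is not None:
        weights = matrix.weights.copy()
    else:
        weights = np.ones(matrix.n_bins)
        weights[matrix.missing] = np.nan
    if rescale_weights:
        weights = weights / np.sqrt(fraction)
    keep = new_raw > 0
    b1, b2, raw = matrix.bin1[keep], matrix.bin2[keep], new_raw[keep]
    return ContactMatrix(
        chrom=matrix.chrom,
        resolution=matrix.resolution,
        n_bins=matrix.n_bins,
        bin1=b1,
        bin2=b2,
        value=raw * weights[b1] * weights[b2],
        raw=raw,
        weights=weights,
        missing=matrix.missing,
    )
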