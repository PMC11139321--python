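import numpy as np
import pytest

from contactdiff.contact_io import ContactMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(
    rng: np.random.Generator,
    n_bins: int = 20,
    n_missing: int = 0,
    density: float = 0.5,
    with_raw: bool = False,
    chrom: str = "chrT",
    resolution: int = 5000,
) -> ContactMatrix:
    """A random sparse upper-triangle matrix for oracle comparisons."""
    missing = np.zeros(n_bins, dtype=bool)
    if n_missing:
        missing[rng.choice(n_bins, size=n_missing, replace=False)] = True
    iu, ju = np.triu_indices(n_bins)
    ok = ~missing[iu] & ~missing[ju]
    iu, ju = iu[ok], ju[ok]
    keep = rng.random(len(iu)) < density
    iu, ju = iu[keep], ju[keep]
    if with_raw:
        raw = rng.integers(1, 50, size=len(iu))
        weights = np.where(missing, np.nan, 0.01)
        value = raw * 0.01 * 0.01
        return ContactMatrix(
            chrom=chrom, resolution=resolution, n_bins=n_bins,
            bin1=iu, bin2=ju, value=value, raw=raw, weights=weights,
        )
    value = rng.uniform(0.0001, 0.05, size=len(iu))
    return ContactMatrix(
        chrom=chrom, resolution=resolution, n_bins=n_bins,
        bin1=iu, bin2=ju, value=value, missing=missing,
    )
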