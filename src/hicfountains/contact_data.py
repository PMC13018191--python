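"""Binned cis Hi-C contact maps: balancing, expected, observed/expected.

A :class:`ContactMap` holds one symmetric raw-count matrix per chromosome at a
single resolution, together with per-bin balancing weights (iterative
correction) and a bad-bin mask.  Coordinates are 0-based half-open throughout;
a genomic position maps to bin ``floor(pos / resolution)``.  Only
intra-chromosomal (cis) contacts are modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "ContactMap",
    "ExpectedProfile",
    "ice_balance",
    "expected_cis",
    "obs_over_exp",
]


@dataclass
class ContactMap:
    """Single-resolution cis contact map.

    Parameters
    ----------
    resolution
        Bin size in bp, > 0.
    chromsizes
        Ordered mapping of chromosome name to length in bp.
    counts
        Mapping of chromosome name to a symmetric nonnegative matrix of raw
        contact counts, one square matrix of side ``ceil(length/resolution)``
        per chromosome.
    weights
        Optional mapping of chromosome to per-bin balancing multipliers; NaN
        marks a bad bin.  ``None`` until :func:`ice_balance` is applied.
    """

    resolution: int
    chromsizes: dict[str, int]
    counts: dict[str, np.ndarray]
    weights: dict[str, np.ndarray] | None = None

    def __post_init__(self) -> None:
        if self.resolution <= 0:
            raise ValueError("resolution must be positive")
        for chrom, mat in self.counts.items():
            n = self.n_bins(chrom)
            if mat.shape != (n, n):
                raise ValueError(
                    f"{chrom}: counts shape {mat.shape} != ({n}, {n})"
                )

    @property
    def chromosomes(self) -> list[str]:
        return list(self.chromsizes)

    def n_bins(self, chrom: str) -> int:
        return -(-self.chromsizes[chrom] // self.resolution)

    @property
    def is_balanced(self) -> bool:
        return self.weights is not None

    def bad_bins(self, chrom: str) -> np.ndarray:
        """Boolean mask of bins excluded from balancing/analysis."""
        if self.weights is None:
            # Before balancing the only defensible definition is zero coverage.
            return self.counts[chrom].sum(axis=0) == 0
        return ~np.isfinite(self.weights[chrom])

    def balanced(self, chrom: str) -> np.ndarray:
        """Balanced matrix ``w_i * w_j * counts_ij``; NaN on bad bins."""
        if self.weights is None:
            raise ValueError("map is not balanced; run ice_balance first")
        w = self.weights[chrom]
        return w[:, None] * w[None, :] * self.counts[chrom]

    def bin_index(self, chrom: str, pos: int) -> int:
        if not 0 <= pos < self.chromsizes[chrom]:
            raise ValueError(f"position {pos} outside {chrom}")
        return pos // self.resolution


@dataclass
class ExpectedProfile:
    """Distance-decay expected: mean balanced contact per diagonal.

    ``values[chrom][s]`` is the mean balanced contact frequency over all valid
    bin pairs at separation ``s`` (in bins); NaN where no valid pair exists.
    ``n_valid`` counts the contributing pairs.
    """

    resolution: int
    values: dict[str, np.ndarray]
    n_valid: dict[str, np.ndarray] = field(default_factory=dict)


def _check_symmetric(mat: np.ndarray, chrom: str) -> None:
    if mat.shape[0] != mat.shape[1] or not np.allclose(
        mat, mat.T, equal_nan=True
    ):
        raise ValueError(f"{chrom}: counts matrix is not symmetric")


def ice_balance(
    cmap: ContactMap,
    tol: float = 1e-5,
    max_iter: int = 200,
    mad_max: float = 5.0,
) -> ContactMap:
    """Iterative correction to equal (unit) marginals.

    Bins whose raw coverage lies more than ``mad_max`` median absolute
    deviations below the median coverage of nonzero bins are flagged bad and
    get NaN weight; zero-coverage bins are always bad.  Convergence is reached
    when the maximum relative marginal deviation falls below ``tol``.  Weights
    are scaled so that every valid marginal of the balanced matrix equals 1.
    """
    weights: dict[str, np.ndarray] = {}
    any_valid = False
    for chrom, counts in cmap.counts.items():
        _check_symmetric(counts, chrom)
        if np.any(counts < 0):
            raise ValueError(f"{chrom}: negative counts")
        n = counts.shape[0]
        coverage = counts.sum(axis=0)
        bad = coverage == 0
        nz = coverage[~bad]
        if nz.size:
            med = np.median(nz)
            mad = np.median(np.abs(nz - med))
            if mad > 0:
                bad |= coverage < med - mad_max * mad
        w = np.ones(n)
        w[bad] = np.nan
        if not bad.all():
            mat = counts.astype(float).copy()
            mat[bad, :] = 0.0
            mat[:, bad] = 0.0
            b = np.ones(n)
            for _ in range(max_iter):
                marg = b * (mat @ b)
                marg_valid = marg[~bad]
                scale = marg_valid.mean()
                if scale == 0:
                    break
                dev = np.abs(marg_valid / scale - 1.0).max()
                if dev < tol:
                    break
                adj = np.where(marg > 0, marg / scale, 1.0)
                b /= adj
            # rescale to unit marginals
            marg = b * (mat @ b)
            m = marg[~bad].mean()
            if m > 0:
                b /= np.sqrt(m)
            w[~bad] = b[~bad]
            any_valid = True
        weights[chrom] = w
    if not any_valid:
        raise ValueError("all bins are bad; cannot balance")
    return replace(cmap, weights=weights)


def expected_cis(cmap: ContactMap) -> ExpectedProfile:
    """Per-chromosome mean balanced contact at each separation.

    Bad bins are excluded from every diagonal.  Raises if the map has no valid
    bin at all.
    """
    values: dict[str, np.ndarray] = {}
    n_valid: dict[str, np.ndarray] = {}
    total_valid = 0
    for chrom in cmap.chromosomes:
        bal = cmap.balanced(chrom)
        n = bal.shape[0]
        good = ~cmap.bad_bins(chrom)
        total_valid += int(good.sum())
        exp = np.full(n, np.nan)
        cnt = np.zeros(n, dtype=int)
        for s in range(n):
            diag = np.diagonal(bal, offset=s)
            ok = good[: n - s] & good[s:]
            if ok.any():
                exp[s] = diag[ok].mean()
                cnt[s] = int(ok.sum())
        values[chrom] = exp
        n_valid[chrom] = cnt
    if total_valid == 0:
        raise ValueError("no valid bins in map")
    return ExpectedProfile(cmap.resolution, values, n_valid)


def obs_over_exp(
    cmap: ContactMap, expected: ExpectedProfile, chrom: str
) -> np.ndarray:
    """Balanced matrix divided by expected at each separation.

    Entries on bad bins, or where the expected is zero or undefined, are NaN.
    """
    bal = cmap.balanced(chrom)
    exp = expected.values[chrom]
    n = bal.shape[0]
    if exp.shape[0] != n:
        raise ValueError("expected profile incompatible with map")
    sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
    denom = exp[sep]
    with np.errstate(divide="ignore", invalid="ignore"):
        oe = bal / denom
    oe[~np.isfinite(denom) | (denom == 0)] = np.nan
    return oe
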