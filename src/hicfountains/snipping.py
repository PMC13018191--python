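"""Window snipping, pileups, coarse-graining, and P(s) curves.

Windows are square, odd-sided obs/exp submatrices centered on the map
diagonal (or on given genomic positions): a "400 Kb window" at 10 Kb
resolution is realized as +/-20 bins around the center bin, i.e. 41x41.
Cells outside the chromosome are NaN, and NaN never propagates into any
mean (count-weighted NaN-means everywhere).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .contact_data import ContactMap, ExpectedProfile, expected_cis, obs_over_exp

__all__ = [
    "Snippet",
    "Pileup",
    "ContactFrequencyCurve",
    "window_halfwidth",
    "snip_windows",
    "snip_matrix",
    "average_pileup",
    "coarse_grain",
    "ps_curve",
]


@dataclass
class Snippet:
    chrom: str
    center_bin: int
    values: np.ndarray

    def __post_init__(self) -> None:
        side = self.values.shape[0]
        if self.values.shape != (side, side) or side % 2 == 0:
            raise ValueError("snippet must be square with odd side")


@dataclass
class Pileup:
    """Element-wise NaN-mean of equally shaped snippets."""

    values: np.ndarray
    n_obs: np.ndarray
    resolution: int | None = None


@dataclass
class ContactFrequencyCurve:
    """P(s) on log-spaced separation bins with its log-derivative."""

    separation_bp: np.ndarray
    ps: np.ndarray
    log_derivative: np.ndarray


def window_halfwidth(window_bp: int, resolution: int) -> int:
    """Half-width in bins; the snippet side is ``2*W + 1``."""
    if window_bp < 3 * resolution:
        raise ValueError("window must span at least 3 bins")
    return window_bp // (2 * resolution)


def snip_matrix(matrix: np.ndarray, center: int, halfwidth: int) -> np.ndarray:
    """Square window around a diagonal bin; out-of-range cells NaN."""
    n = matrix.shape[0]
    side = 2 * halfwidth + 1
    out = np.full((side, side), np.nan)
    lo = max(0, center - halfwidth)
    hi = min(n, center + halfwidth + 1)
    if lo < hi:
        out[
            lo - (center - halfwidth) : hi - (center - halfwidth),
            lo - (center - halfwidth) : hi - (center - halfwidth),
        ] = matrix[lo:hi, lo:hi]
    return out


def snip_windows(
    cmap: ContactMap,
    expected: ExpectedProfile,
    centers: list[tuple[str, int]] | str,
    window_bp: int,
) -> list[Snippet]:
    """Extract diagonal obs/exp windows at positions or at every bin.

    ``centers`` is either a list of ``(chrom, position_bp)`` tuples or the
    string ``"every-bin"``.  Each snippet is assigned to the genomic point of
    its center bin.
    """
    W = window_halfwidth(window_bp, cmap.resolution)
    oe = {c: obs_over_exp(cmap, expected, c) for c in cmap.chromosomes}
    if centers == "every-bin":
        centers = [
            (c, b * cmap.resolution)
            for c in cmap.chromosomes
            for b in range(cmap.n_bins(c))
        ]
    snippets = []
    for chrom, pos in centers:
        b = cmap.bin_index(chrom, pos)
        snippets.append(Snippet(chrom, b, snip_matrix(oe[chrom], b, W)))
    return snippets


def average_pileup(snippets: list[Snippet | np.ndarray]) -> Pileup:
    """Per-cell NaN-mean and non-NaN count across equally shaped snippets."""
    if not snippets:
        raise ValueError("no snippets to average")
    arrays = [s.values if isinstance(s, Snippet) else np.asarray(s) for s in snippets]
    shape = arrays[0].shape
    if any(a.shape != shape for a in arrays):
        raise ValueError("snippets have mixed shapes")
    stack = np.stack(arrays)
    n_obs = np.isfinite(stack).sum(axis=0)
    with np.errstate(invalid="ignore"):
        values = np.where(
            n_obs > 0, np.nansum(np.where(np.isfinite(stack), stack, 0.0), axis=0), np.nan
        )
    values = values / np.where(n_obs > 0, n_obs, 1)
    return Pileup(values=values, n_obs=n_obs)


def coarse_grain(matrix: np.ndarray, factor: int) -> np.ndarray:
    """NaN-mean over ``factor x factor`` blocks; trailing remainder truncated."""
    if factor < 1:
        raise ValueError("factor must be >= 1")
    if factor == 1:
        return matrix.copy()
    n = (matrix.shape[0] // factor) * factor
    m = (matrix.shape[1] // factor) * factor
    blocks = matrix[:n, :m].reshape(n // factor, factor, m // factor, factor)
    blocks = blocks.transpose(0, 2, 1, 3).reshape(n // factor, m // factor, -1)
    with np.errstate(invalid="ignore"):
        return np.nanmean(blocks, axis=2)


def ps_curve(
    cmap: ContactMap,
    log_ratio: float = 2 ** 0.125,
    smooth_bins: int = 3,
) -> ContactFrequencyCurve:
    """Contact probability versus separation and its log-derivative.

    Per-chromosome diagonal means are pooled (weighted by the number of valid
    bin pairs) into log-spaced separation bins with ratio ``log_ratio``
    (2^(1/8) by default); the derivative d log P / d log s is taken by finite
    differences and smoothed with a ``smooth_bins``-wide moving average.
    """
    expected = expected_cis(cmap)
    max_sep = max(v.shape[0] for v in expected.values.values())
    sums = np.zeros(max_sep)
    cnts = np.zeros(max_sep)
    for chrom, vals in expected.values.items():
        n = expected.n_valid[chrom]
        ok = np.isfinite(vals)
        sums[: vals.shape[0]][ok] += vals[ok] * n[ok]
        cnts[: vals.shape[0]][ok] += n[ok]

    edges = [1.0]
    while edges[-1] < max_sep:
        edges.append(max(edges[-1] * log_ratio, edges[-1] + 1))
    edges = np.array(edges)
    sep_bins = np.arange(1, max_sep)
    idx = np.searchsorted(edges, sep_bins, side="right") - 1

    ps, centers = [], []
    for k in range(len(edges) - 1):
        sel = sep_bins[idx == k]
        if sel.size == 0:
            continue
        c = cnts[sel].sum()
        if c == 0:
            continue
        ps.append(sums[sel].sum() / c)
        centers.append(np.exp(np.mean(np.log(sel))))
    ps = np.array(ps)
    centers = np.array(centers)
    pos = ps > 0
    if pos.sum() < 3:
        raise ValueError("fewer than 3 usable separation bins")
    logs = np.log(centers[pos])
    logp = np.log(ps[pos])
    deriv = np.gradient(logp, logs)
    if smooth_bins > 1:
        kernel = np.ones(smooth_bins) / smooth_bins
        deriv = np.convolve(deriv, kernel, mode="same")
    full_deriv = np.full(ps.shape, np.nan)
    full_deriv[pos] = deriv
    return ContactFrequencyCurve(
        separation_bp=centers * cmap.resolution,
        ps=ps,
        log_derivative=full_deriv,
    )
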