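"""Fountain quantification: protractor profiles, differential calls, enrichment.

The protractor measures the angular intensity profile of a pileup: each cell
is assigned to an angular sector by its direction about the center, measured
from one arm of the main diagonal (0 degrees) so that 90 degrees is the
perpendicular bisector where the fountain signal concentrates.  Sector means
are NaN-means over cells whose radius lies in ``[r_min, r_max]``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ProtractorProfile",
    "protractor",
    "differential_fountains",
    "randomized_enrichment",
    "enrichment_table",
]


@dataclass
class ProtractorProfile:
    """Per-sector mean obs/exp over a radial annulus of a pileup."""

    sector_edges_deg: np.ndarray  # len = n_sectors + 1, spans [0, 180]
    means: np.ndarray

    @property
    def sector_centers_deg(self) -> np.ndarray:
        return 0.5 * (self.sector_edges_deg[:-1] + self.sector_edges_deg[1:])


def protractor(
    pileup: np.ndarray,
    sector_deg: float = 10.0,
    r_min_bins: float = 3.0,
    r_max_bins: float | None = None,
) -> ProtractorProfile:
    """Angular intensity profile of a square pileup.

    Only the half-plane above the main diagonal is binned (the matrix is
    symmetric for Hi-C pileups); angles run from 0 (along the diagonal,
    toward larger coordinates) through 90 (perpendicular bisector) to 180
    (along the diagonal, toward smaller coordinates).
    """
    x = np.asarray(
        pileup.values if hasattr(pileup, "values") else pileup, dtype=float
    )
    if x.ndim != 2 or x.shape[0] != x.shape[1]:
        raise ValueError("pileup must be a square matrix")
    if sector_deg <= 0:
        raise ValueError("sector_deg must be positive")
    side = x.shape[0]
    c = (side - 1) / 2
    if r_max_bins is None:
        r_max_bins = c
    if r_max_bins <= r_min_bins:
        raise ValueError("r_max must exceed r_min")
    di = np.arange(side)[:, None] - c
    dj = np.arange(side)[None, :] - c
    r = np.hypot(di, dj)
    along = (di + dj) / math.sqrt(2.0)  # component along the diagonal arm
    perp = (dj - di) / math.sqrt(2.0)  # distance from the diagonal
    # folding the half-planes (|perp|) makes the profile exactly invariant
    # under transposition and mirror-symmetric for bisector-symmetric input
    angle = np.degrees(np.arctan2(np.abs(perp), along))

    n_sectors = int(round(180.0 / sector_deg))
    edges = np.linspace(0.0, 180.0, n_sectors + 1)
    sel = (r >= r_min_bins) & (r <= r_max_bins) & (r > 0)
    means = np.full(n_sectors, np.nan)
    # sector assignment closed symmetrically about 90 degrees so that
    # boundary cells mirror consistently
    frac = angle / sector_deg
    idx = np.where(angle <= 90.0, np.floor(frac), np.ceil(frac) - 1.0)
    idx = np.clip(idx.astype(int), 0, n_sectors - 1)
    # cells exactly on the bisector are their own mirror image and belong
    # to both central sectors
    on_bisector = np.isclose(angle, 90.0)
    for k in range(n_sectors):
        members = idx == k
        if np.isclose(edges[k], 90.0) or np.isclose(edges[k + 1], 90.0):
            members = members | on_bisector
        cells = x[sel & members]
        cells = cells[np.isfinite(cells)]
        if cells.size:
            means[k] = cells.mean()
    return ProtractorProfile(edges, means)


def differential_fountains(
    scores_a: pd.DataFrame,
    scores_b: pd.DataFrame,
    min_delta: float = 0.1,
    min_consistency: float = 1.0,
) -> pd.DataFrame:
    """Classify fountains as DOWN / SAME / UP between two conditions.

    ``scores_a`` and ``scores_b`` are per-fountain tables with one column per
    replicate (same index = same fountain set).  A fountain is DOWN when the
    mean score drops by more than ``min_delta`` (in correlation units) and at
    least ``min_consistency`` of all cross-replicate pairs agree in sign; UP
    symmetrically; otherwise SAME.
    """
    if not scores_a.index.equals(scores_b.index):
        raise ValueError("mismatched fountain sets")
    a = scores_a.to_numpy(dtype=float)
    b = scores_b.to_numpy(dtype=float)
    delta = b.mean(axis=1) - a.mean(axis=1)
    diffs = b[:, None, :] - a[:, :, None]  # all cross pairs
    frac_neg = (diffs < 0).mean(axis=(1, 2))
    frac_pos = (diffs > 0).mean(axis=(1, 2))
    cls = np.where(
        (delta < -min_delta) & (frac_neg >= min_consistency),
        "DOWN",
        np.where((delta > min_delta) & (frac_pos >= min_consistency), "UP", "SAME"),
    )
    return pd.DataFrame(
        {"class": cls, "delta": delta},
        index=scores_a.index,
    )


def _merge_intervals(starts: np.ndarray, ends: np.ndarray):
    order = np.argsort(starts)
    starts, ends = starts[order], ends[order]
    merged_s, merged_e = [], []
    for s, e in zip(starts, ends):
        if merged_e and s <= merged_e[-1]:
            merged_e[-1] = max(merged_e[-1], e)
        else:
            merged_s.append(s)
            merged_e.append(e)
    return np.array(merged_s), np.array(merged_e)


def _covered_fraction(bin_starts, bin_ends, el_starts, el_ends) -> np.ndarray:
    """Fraction of each [start, end) bin covered by the union of elements."""
    if len(el_starts) == 0:
        return np.zeros(len(bin_starts))
    ms, me = _merge_intervals(np.asarray(el_starts), np.asarray(el_ends))
    cum = np.concatenate([[0], np.cumsum(me - ms)])

    def covered(a, b):
        i = np.searchsorted(me, a, side="right")
        j = np.searchsorted(ms, b, side="left")
        if i >= j:
            return 0
        total = cum[j] - cum[i]
        total -= max(0, a - ms[i])
        total -= max(0, me[j - 1] - b)
        return total

    out = np.array(
        [covered(a, b) for a, b in zip(bin_starts, bin_ends)], dtype=float
    )
    return out / (np.asarray(bin_ends) - np.asarray(bin_starts))


def randomized_enrichment(
    fountains: pd.DataFrame,
    elements: pd.DataFrame,
    chromsizes: dict[str, int],
    resolution: int,
    n_rand: int = 1000,
    seed: int = 0,
    bad_bins: dict[str, np.ndarray] | None = None,
) -> dict:
    """Element enrichment at fountain-base bins against a randomized control.

    The observed statistic is the mean fraction of each fountain-base bin
    covered by the elements.  The null re-places the fountains uniformly over
    valid bins ``n_rand`` times, preserving per-chromosome counts.  The
    z-score and p-value come from a normal fit to the null sample.
    """
    if n_rand < 100:
        raise ValueError("n_rand must be >= 100")
    if len(fountains) == 0:
        raise ValueError("empty fountain set")
    if any(v <= 0 for v in chromsizes.values()):
        raise ValueError("zero-length genome")
    rng = np.random.default_rng(seed)
    el_by_chrom = (
        {c: g[["start", "end"]].to_numpy() for c, g in elements.groupby("chrom")}
        if len(elements)
        else {}
    )

    def stat(bins_by_chrom):
        fracs = []
        for chrom, bins in bins_by_chrom.items():
            if len(bins) == 0:
                continue
            starts = bins * resolution
            ends = np.minimum(starts + resolution, chromsizes[chrom])
            els = el_by_chrom.get(chrom, np.empty((0, 2)))
            fracs.append(_covered_fraction(starts, ends, els[:, 0], els[:, 1]))
        return float(np.concatenate(fracs).mean())

    obs_bins = {
        c: (g["start"].to_numpy() // resolution)
        for c, g in fountains.groupby("chrom")
    }
    counts = {c: len(b) for c, b in obs_bins.items()}
    observed = stat(obs_bins)

    valid = {}
    for chrom in counts:
        n = -(-chromsizes[chrom] // resolution)
        ok = np.ones(n, dtype=bool)
        if bad_bins and chrom in bad_bins:
            ok &= ~bad_bins[chrom]
        valid[chrom] = np.flatnonzero(ok)

    null = np.empty(n_rand)
    for t in range(n_rand):
        rand_bins = {
            c: rng.choice(valid[c], size=k, replace=True)
            for c, k in counts.items()
        }
        null[t] = stat(rand_bins)
    mu, sd = float(null.mean()), float(null.std(ddof=1))
    if sd > 0:
        z = (observed - mu) / sd
    else:
        z = 0.0 if observed == mu else float("inf") * np.sign(observed - mu)
    p = float(stats.norm.sf(z)) if np.isfinite(z) else (0.0 if z > 0 else 1.0)
    return {
        "observed": observed,
        "null_mean": mu,
        "null_sd": sd,
        "z": float(z),
        "p": p,
    }


def enrichment_table(
    fountains: pd.DataFrame,
    element_classes: dict[str, pd.DataFrame],
    chromsizes: dict[str, int],
    resolution: int,
    n_rand: int = 1000,
    seed: int = 0,
    bad_bins=None,
) -> pd.DataFrame:
    """One enrichment row per element class, with Benjamini-Hochberg FDR."""
    rows = []
    for name, els in element_classes.items():
        res = randomized_enrichment(
            fountains, els, chromsizes, resolution, n_rand, seed, bad_bins
        )
        res["element_class"] = name
        rows.append(res)
    df = pd.DataFrame(rows).set_index("element_class")
    p = df["p"].to_numpy()
    m = len(p)
    order = np.argsort(p)
    fdr = np.empty(m)
    running = 1.0
    for rank_pos in range(m - 1, -1, -1):
        i = order[rank_pos]
        running = min(running, p[i] * m / (rank_pos + 1))
        fdr[i] = running
    df["fdr"] = fdr
    return df
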