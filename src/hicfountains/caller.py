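"""Fountain calling on Hi-C contact maps.

A fountain is a contact enrichment that emanates from a single locus and
broadens with distance from the diagonal.  The caller scores every diagonal
obs/exp window against a reference fountain mask (Pearson correlation),
scores local map noise with a Scharr gradient, finds local maxima of the
fountain-score track with their topographic prominence, keeps peaks above
Li's minimum cross-entropy prominence threshold, and then applies five
filtration rules: proximity to bad bins (<50 Kb), negative mask correlation,
replicate consistency (+/-20 Kb), overlap with calls on a control map
(putative rearrangements/misassemblies), and the top 25% by Scharr noise
score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .contact_data import ContactMap, expected_cis, obs_over_exp
from .snipping import window_halfwidth

__all__ = [
    "FountainMask",
    "CallerParams",
    "build_mask",
    "wedge_values",
    "fountain_score",
    "scharr_noise_score",
    "score_track",
    "find_peaks",
    "li_threshold",
    "call_fountains",
]

SCHARR_X = np.array([[-3, 0, 3], [-10, 0, 10], [-3, 0, 3]], dtype=float)
SCHARR_Y = SCHARR_X.T

FILTER_FLAGS = (
    "badbin50",
    "negative_corr",
    "replicate20",
    "control_overlap",
    "scharr_top25",
)


@dataclass
class FountainMask:
    """Reference fountain template, same shape as the scored snippets."""

    values: np.ndarray
    provenance: str

    def __post_init__(self) -> None:
        v = self.values
        if v.ndim != 2 or v.shape[0] != v.shape[1] or v.shape[0] % 2 == 0:
            raise ValueError("mask must be square with odd side")
        if not np.all(np.isfinite(v)):
            raise ValueError("mask must be finite")
        if np.nanstd(v) == 0:
            raise ValueError("mask must be non-constant")


@dataclass
class CallerParams:
    """Thresholds and switches of the filtration pipeline (defaults as published)."""

    window_bp: int = 400_000
    badbin_dist_bp: int = 50_000
    replicate_offset_bp: int = 20_000
    scharr_top_frac: float = 0.25
    track_smooth_bins: int = 3
    # replicate re-detection threshold as a fraction of the final merged
    # prominence threshold; < 1 because each replicate holds only part of
    # the merged depth and its score track is correspondingly noisier
    replicate_redetect_frac: float = 0.8
    apply_li_threshold: bool = True
    filter_badbin: bool = True
    filter_negative: bool = True
    filter_replicates: bool = True
    filter_control: bool = True
    filter_scharr: bool = True


def wedge_values(
    side: int,
    half_angle_deg: float,
    r_min_bins: float = 0.0,
    center: float | None = None,
) -> np.ndarray:
    """Binary wedge about the perpendicular bisector of the main diagonal.

    Cell (i, j) is 1 when its offset vector from the center makes an angle of
    at most ``half_angle_deg`` with the off-diagonal direction (either side of
    the diagonal, so the pattern is symmetric) and its radius is at least
    ``r_min_bins``.  ``center`` defaults to the geometric middle, which is a
    lattice cell for odd sides.
    """
    if not 0 < half_angle_deg < 90:
        raise ValueError("half-angle must lie in (0, 90) degrees")
    c = (side - 1) / 2 if center is None else center
    di = np.arange(side)[:, None] - c
    dj = np.arange(side)[None, :] - c
    r = np.hypot(di, dj)
    # component along the anti-diagonal (perpendicular bisector) direction
    perp = np.abs(dj - di) / np.sqrt(2)
    with np.errstate(invalid="ignore"):
        cos_theta = np.where(r > 0, perp / r, 0.0)
    cos_lim = math.cos(math.radians(half_angle_deg))
    wedge = (cos_theta >= cos_lim - 1e-12) & (r >= r_min_bins) & (r > 0)
    return wedge.astype(float)


def build_mask(
    seed_snippets=None,
    wedge_params: tuple[int, float, float] | None = None,
) -> FountainMask:
    """Reference mask from seed snippets (NaN-mean) or synthetic wedge.

    ``wedge_params`` is ``(side, half_angle_deg, r_min_bins)``.
    """
    if seed_snippets is not None:
        arrays = [
            s.values if hasattr(s, "values") else np.asarray(s, dtype=float)
            for s in seed_snippets
        ]
        if not arrays:
            raise ValueError("empty seed list")
        if any(a.shape != arrays[0].shape for a in arrays):
            raise ValueError("seed snippets have mixed shapes")
        with np.errstate(invalid="ignore"):
            mean = np.nanmean(np.stack(arrays), axis=0)
        mean = np.where(np.isfinite(mean), mean, np.nanmean(mean))
        return FountainMask(mean, provenance="seed-average")
    if wedge_params is None:
        raise ValueError("provide seed snippets or wedge parameters")
    side, half_angle, r_min = wedge_params
    return FountainMask(
        wedge_values(side, half_angle, r_min),
        provenance=f"synthetic-wedge({half_angle},{r_min})",
    )


def fountain_score(snippet: np.ndarray, mask: np.ndarray | FountainMask) -> float:
    """Pearson correlation between snippet and mask over jointly finite cells.

    NaN when fewer than 3 joint cells remain or either argument is constant
    on the joint support.
    """
    m = mask.values if isinstance(mask, FountainMask) else np.asarray(mask)
    x = np.asarray(snippet, dtype=float).ravel()
    y = np.asarray(m, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("snippet and mask shapes differ")
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3:
        return float("nan")
    xs, ys = x[ok], y[ok]
    xs = xs - xs.mean()
    ys = ys - ys.mean()
    denom = math.sqrt((xs @ xs) * (ys @ ys))
    if denom == 0:
        return float("nan")
    return float(np.clip((xs @ ys) / denom, -1.0, 1.0))


def scharr_noise_score(snippet: np.ndarray) -> float:
    """Mean Scharr gradient magnitude over interior cells.

    NaN cells are replaced by the snippet's finite mean before convolution;
    smooth maps score near zero, noisy or sharp patterns score high.
    """
    x = np.asarray(snippet, dtype=float)
    if x.shape[0] < 3 or x.shape[1] < 3:
        raise ValueError("snippet smaller than 3x3")
    finite = np.isfinite(x)
    if not finite.any():
        return float("nan")
    filled = np.where(finite, x, x[finite].mean())
    gx = ndimage.convolve(filled, SCHARR_X, mode="nearest")
    gy = ndimage.convolve(filled, SCHARR_Y, mode="nearest")
    mag = np.hypot(gx, gy)
    return float(mag[1:-1, 1:-1].mean())


def _stack_diagonal_windows(matrix: np.ndarray, halfwidth: int) -> np.ndarray:
    """(n, side, side) stack of diagonal windows, NaN-padded at the edges."""
    n = matrix.shape[0]
    side = 2 * halfwidth + 1
    padded = np.full((n + 2 * halfwidth, n + 2 * halfwidth), np.nan)
    padded[halfwidth : halfwidth + n, halfwidth : halfwidth + n] = matrix
    s0, s1 = padded.strides
    from numpy.lib.stride_tricks import as_strided

    return as_strided(
        padded, shape=(n, side, side), strides=(s0 + s1, s0, s1)
    )


def score_track(
    cmap: ContactMap,
    mask: FountainMask,
    window_bp: int,
    with_scharr: bool = True,
) -> dict[str, pd.DataFrame]:
    """Per-bin fountain score and Scharr noise score for every chromosome.

    The noise score is the Scharr gradient of the variance-stabilized
    (Anscombe, ``2 sqrt(counts + 3/8)``) raw-count window after removing its
    smooth component with a short uniform filter: Poisson grain then has the
    same amplitude in every window regardless of enrichment, so the score
    singles out genuinely sharp features (misassembly blocks, edges) rather
    than well-covered biological structure.  Scores are NaN where the window
    has too few valid cells (e.g. on bad bins and chromosome edges).
    """
    W = window_halfwidth(window_bp, cmap.resolution)
    side = 2 * W + 1
    if mask.values.shape != (side, side):
        raise ValueError(
            f"mask side {mask.values.shape[0]} does not match window ({side})"
        )
    expected = expected_cis(cmap)
    mflat = mask.values.ravel()
    out = {}
    for chrom in cmap.chromosomes:
        oe = obs_over_exp(cmap, expected, chrom)
        stack = _stack_diagonal_windows(oe, W)
        n = oe.shape[0]
        X = stack.reshape(n, side * side)
        finite = np.isfinite(X)
        nx = finite.sum(axis=1)
        Xz = np.where(finite, X, 0.0)
        Mz = np.where(finite, mflat[None, :], 0.0)
        with np.errstate(invalid="ignore", divide="ignore"):
            mean_x = Xz.sum(1) / nx
            mean_m = Mz.sum(1) / nx
            sxx = (Xz**2).sum(1) - nx * mean_x**2
            smm = (Mz**2).sum(1) - nx * mean_m**2
            sxm = (Xz * Mz).sum(1) - nx * mean_x * mean_m
            r = sxm / np.sqrt(sxx * smm)
        r[(nx < 3) | ~(sxx > 0) | ~(smm > 0)] = np.nan
        r = np.clip(r, -1.0, 1.0)
        scharr = np.full(n, np.nan)
        if with_scharr:
            counts = cmap.counts[chrom].astype(float).copy()
            bad = cmap.bad_bins(chrom)
            counts[bad, :] = np.nan
            counts[:, bad] = np.nan
            cstack = _stack_diagonal_windows(counts, W)
            for b in range(n):
                win = cstack[b]
                finite = np.isfinite(win)
                if finite.sum() < 3:
                    continue
                t = 2.0 * np.sqrt(win + 0.375)
                t = np.where(finite, t, np.nanmean(t))
                # high-pass: keep bin-scale grain and sharp steps, drop the
                # smooth structure a genuine fountain contributes
                residual = t - ndimage.uniform_filter(t, size=5)
                scharr[b] = scharr_noise_score(residual)
        out[chrom] = pd.DataFrame(
            {"fountain_score": r, "scharr_score": scharr}
        )
    return out


def find_peaks(track: np.ndarray) -> pd.DataFrame:
    """Local maxima of a 1D signal with topographic prominence.

    NaNs split the signal into independent segments; segment ends act as
    bases.  Prominence is the peak height minus the higher of the minima on
    the paths to the nearest higher points (or segment ends) on both sides.
    Plateau peaks report the leftmost bin of the plateau.
    """
    x = np.asarray(track, dtype=float)
    if not np.isfinite(x).any():
        raise ValueError("all-NaN track")
    peaks, heights, proms = [], [], []
    finite = np.isfinite(x)
    boundaries = np.flatnonzero(np.diff(finite.astype(int)))
    starts = [0] if finite[0] else []
    starts += [b + 1 for b in boundaries if finite[b + 1]]
    ends = [b + 1 for b in boundaries if finite[b]]
    if finite[-1]:
        ends.append(len(x))
    for lo, hi in zip(starts, ends):
        seg = x[lo:hi]
        m = len(seg)
        i = 0
        while i < m:
            j = i
            while j + 1 < m and seg[j + 1] == seg[i]:
                j += 1
            left_ok = i > 0 and seg[i - 1] < seg[i]
            right_ok = j < m - 1 and seg[j + 1] < seg[i]
            if left_ok and right_ok:
                h = seg[i]
                lmin = h
                k = i - 1
                while k >= 0 and seg[k] <= h:
                    lmin = min(lmin, seg[k])
                    k -= 1
                rmin = h
                k = j + 1
                while k < m and seg[k] <= h:
                    rmin = min(rmin, seg[k])
                    k += 1
                peaks.append(lo + i)
                heights.append(h)
                proms.append(h - max(lmin, rmin))
            i = j + 1
    return pd.DataFrame(
        {"bin": np.array(peaks, dtype=int), "height": heights, "prominence": proms}
    )


def li_threshold(values, tol: float = 1e-8, max_iter: int = 200) -> float:
    """Li's minimum cross-entropy threshold for positive values.

    The classic fixed-point iteration
    ``t' = (mu_below - mu_above) / (ln mu_below - ln mu_above)``
    is run first; because that iteration can settle on a non-global fixed
    point for multimodal data, the returned threshold is the exact global
    minimizer of the cross entropy over all midpoints between consecutive
    sorted values (computed in closed form with prefix sums).  The result
    lies strictly between the two class means.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if v.size < 2 or np.unique(v).size < 2:
        raise ValueError("need at least 2 distinct values")
    if np.any(v <= 0):
        raise ValueError("Li threshold requires positive values")
    t = v.mean()
    for _ in range(max_iter):
        below = v[v <= t]
        above = v[v > t]
        if below.size == 0 or above.size == 0:
            break
        mu_b = below.mean()
        mu_a = above.mean()
        if mu_b == mu_a:
            break
        t_new = (mu_b - mu_a) / (math.log(mu_b) - math.log(mu_a))
        if abs(t_new - t) < tol:
            t = t_new
            break
        t = t_new

    # exact scan over all split points
    vs = np.sort(v)
    n = vs.size
    cum = np.cumsum(vs)
    k = np.arange(1, n)
    m1, m2 = cum[:-1], cum[-1] - cum[:-1]
    mu1 = m1 / k
    mu2 = m2 / (n - k)
    with np.errstate(invalid="ignore"):
        eta = -(m1 * np.log(mu1) + m2 * np.log(mu2))
    eta[mu2 == mu1] = np.inf
    # splits between equal values are not valid thresholds
    eta[vs[:-1] == vs[1:]] = np.inf
    best = int(np.argmin(eta))
    t_exact = 0.5 * (vs[best] + vs[best + 1])

    def cross_entropy(thr):
        b, a = v[v <= thr], v[v > thr]
        if b.size == 0 or a.size == 0:
            return np.inf
        return -(b.sum() * math.log(b.mean()) + a.sum() * math.log(a.mean()))

    return float(t if cross_entropy(t) < cross_entropy(t_exact) else t_exact)


def smooth_track(x: np.ndarray, k: int) -> np.ndarray:
    """NaN-aware moving average over ``k`` bins (k <= 1 is a no-op).

    Adjacent score-track bins share almost their whole window, so bin-level
    jitter creates a litter of micro local maxima; a short moving average
    removes them without touching real peaks.
    """
    if k <= 1:
        return x
    finite = np.isfinite(x)
    kernel = np.ones(k)
    num = np.convolve(np.where(finite, x, 0.0), kernel, mode="same")
    den = np.convolve(finite.astype(float), kernel, mode="same")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / den
    out[den == 0] = np.nan
    return out


def _peaks_by_chrom(track_by_chrom, smooth_bins=1, column="fountain_score"):
    out = {}
    for chrom, df in track_by_chrom.items():
        sig = smooth_track(df[column].to_numpy(), smooth_bins)
        out[chrom] = (
            find_peaks(sig)
            if np.isfinite(sig).any()
            else pd.DataFrame({"bin": [], "height": [], "prominence": []})
        )
    return out


def call_fountains(
    replicates: list[ContactMap],
    merged: ContactMap,
    mask: FountainMask,
    control: ContactMap | None = None,
    params: CallerParams | None = None,
) -> pd.DataFrame:
    """Full fountain-calling pipeline on a merged map with replicate support.

    Returns a BED6+ style table with one row per candidate surviving the
    prominence threshold, its scores, the set of filter flags raised, and
    ``passed`` (True iff no flag).  Flags are assigned independently; the
    Scharr top-25% filter is evaluated on the candidates surviving all other
    filters.
    """
    params = params or CallerParams()
    res = merged.resolution
    for rep in replicates:
        if rep.resolution != res or rep.chromsizes != merged.chromsizes:
            raise ValueError("replicate binning mismatch")

    smooth = params.track_smooth_bins
    tracks = score_track(merged, mask, params.window_bp)
    rep_peaks = []
    if params.filter_replicates and replicates:
        for rep in replicates:
            rtracks = score_track(rep, mask, params.window_bp, with_scharr=False)
            peaks = _peaks_by_chrom(rtracks, smooth)
            # a candidate must be DETECTED in the replicate: a local maximum
            # whose prominence clears the replicate's own Li threshold
            proms = np.concatenate(
                [p["prominence"].to_numpy() for p in peaks.values()]
            )
            proms = proms[proms > 0]
            if params.apply_li_threshold and np.unique(proms).size >= 2:
                thr = li_threshold(proms)
                peaks = {
                    c: p[p["prominence"] >= thr] for c, p in peaks.items()
                }
            rep_peaks.append(peaks)

    control_peaks: dict[str, pd.DataFrame] = {}
    if params.filter_control and control is not None:
        ctracks = score_track(control, mask, params.window_bp, with_scharr=False)
        control_peaks = _peaks_by_chrom(ctracks, smooth)

    rows = []
    all_proms = []
    for chrom, track in tracks.items():
        pk = find_peaks(
            smooth_track(track["fountain_score"].to_numpy(), smooth)
        )
        for _, p in pk.iterrows():
            rows.append(
                {
                    "chrom": chrom,
                    "bin": int(p["bin"]),
                    "fountain_score": float(p["height"]),
                    "prominence": float(p["prominence"]),
                    "scharr_score": float(
                        track["scharr_score"].iloc[int(p["bin"])]
                    ),
                }
            )
            if p["prominence"] > 0:
                all_proms.append(float(p["prominence"]))
    calls = pd.DataFrame(
        rows,
        columns=["chrom", "bin", "fountain_score", "prominence", "scharr_score"],
    )

    offset_bins = params.replicate_offset_bp // res
    flags = [set() for _ in range(len(calls))]
    for idx, row in calls.iterrows():
        chrom, b = row["chrom"], int(row["bin"])
        if params.filter_badbin:
            bad = np.flatnonzero(merged.bad_bins(chrom))
            if bad.size and np.abs(bad - b).min() * res < params.badbin_dist_bp:
                flags[idx].add("badbin50")
        if params.filter_negative and row["fountain_score"] < 0:
            flags[idx].add("negative_corr")
        if params.filter_replicates and rep_peaks:
            for peaks in rep_peaks:
                rb = peaks[chrom]["bin"].to_numpy(dtype=int)
                if rb.size == 0 or np.abs(rb - b).min() > offset_bins:
                    flags[idx].add("replicate20")
                    break

    # prominence threshold: Li's separation point, estimated on the
    # replicate-supported candidates so the cross-entropy split reflects
    # reproducible signal rather than the single-map noise bulk
    final_thr = None
    if params.apply_li_threshold:
        pool = [
            p
            for i, p in enumerate(calls["prominence"])
            if p > 0 and "replicate20" not in flags[i]
        ]
        if np.unique(pool).size >= 2:
            final_thr = li_threshold(pool)
            keep = calls["prominence"].to_numpy() >= final_thr
            calls = calls[keep].reset_index(drop=True)
            flags = [f for f, k in zip(flags, keep) if k]

    # replicate consistency at the final stringency: the fountain must be
    # DETECTED in every replicate — a peak within the offset window whose
    # prominence clears the same threshold the merged candidate had to clear
    if params.filter_replicates and rep_peaks and final_thr is not None:
        redetect = params.replicate_redetect_frac * final_thr
        for idx, row in calls.iterrows():
            chrom, b = row["chrom"], int(row["bin"])
            for peaks in rep_peaks:
                pk = peaks[chrom]
                near = pk[
                    (np.abs(pk["bin"] - b) <= offset_bins)
                    & (pk["prominence"] >= redetect)
                ]
                if not len(near):
                    flags[idx].add("replicate20")
                    break

    if params.filter_scharr and len(calls) > 1:
        # top fraction of the thresholded candidate set by noise score,
        # independent of the other flags
        scores = calls["scharr_score"].to_numpy()
        if np.isfinite(scores).any():
            cutoff = np.nanquantile(scores, 1 - params.scharr_top_frac)
            for i, s in enumerate(scores):
                if s > cutoff:
                    flags[i].add("scharr_top25")

    # control filter: candidates re-detected on the control map at the same
    # stringency mark condition-independent features — putative genomic
    # rearrangements and misassembly
    if params.filter_control and control_peaks:
        for chrom, pk in control_peaks.items():
            prom = pk["prominence"].to_numpy()
            if final_thr is not None:
                det = pk[prom >= final_thr]
            else:
                pos = prom[prom > 0]
                det = (
                    pk[prom >= li_threshold(pos)]
                    if np.unique(pos).size >= 2
                    else pk
                )
            cb = det["bin"].to_numpy(dtype=int)
            if cb.size == 0:
                continue
            for idx, row in calls.iterrows():
                if (
                    row["chrom"] == chrom
                    and np.abs(cb - int(row["bin"])).min() <= offset_bins
                ):
                    flags[idx].add("control_overlap")

    calls = calls.copy()
    calls["start"] = calls["bin"] * res
    calls["end"] = np.minimum(
        calls["start"] + res,
        calls["chrom"].map(merged.chromsizes).astype(int),
    )
    calls["name"] = [f"fountain_{i}" for i in range(len(calls))]
    calls["strand"] = "."
    calls["flags"] = [",".join(sorted(f)) if f else "." for f in flags]
    calls["passed"] = [not f for f in flags]
    return calls[
        [
            "chrom",
            "start",
            "end",
            "name",
            "fountain_score",
            "strand",
            "prominence",
            "scharr_score",
            "flags",
            "passed",
            "bin",
        ]
    ].reset_index(drop=True)
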