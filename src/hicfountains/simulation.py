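"""1D lattice simulation of loop extruders with facilitated loading.

Extruders (cohesins) live on a periodic 1D lattice, 1 site = 1 Kb.  Each
extruder occupies two leg sites and grows its loop by stepping both legs
outward.  Loading happens on empty adjacent site pairs with a background
probability per step, multiplied by an enrichment factor ``E`` when the pair
touches a loading platform (an enhancer).  Three mechanisms desynchronize
the two legs and thereby broaden the contact pattern from a hairpin into a
fountain:

``background``
    extruders also load everywhere else and collide with the platform-loaded
    ones;
``barriers``
    platform-only loading plus randomly positioned barriers around the
    platform that stall a crossing leg with probability ``p_stall`` per
    attempt (``p_stall = 0`` recovers the synchronized hairpin control);
``decoupled``
    platform-only loading with each leg stepping independently with
    probability ``p_step``.

Default parameters encode the best-fit regime: 2.5 Mb lattice, platforms
every 500 Kb, 10-fold loading enrichment, background density of one extruder
per 150 Kb and processivity (total loop growth per lifetime) of 150 Kb.

Contact maps are reconstructed from sampled loop configurations with an
analytic Gaussian-chain kernel: ``P(i,j) ~ (d_eff + offset) ** exponent``
where ``d_eff`` is the shortest path through the chain backbone plus
zero-length bridges at extruder (left, right) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from .quantify import protractor
from .snipping import Pileup, average_pileup, coarse_grain
from .caller import wedge_values, fountain_score

__all__ = [
    "SimParams",
    "ExtruderState",
    "step",
    "run",
    "steady_stats",
    "occupancy_fwhm",
    "align_occupancy",
    "contacts_from_loops",
    "simulated_oe_window",
    "simulated_average_fountain",
    "cross_section_widths",
    "pileup_wedge_score",
    "fit_metrics",
    "parameter_sweep",
]

PROCESSIVITY_KB = 150.0
BACKGROUND_SPACING_KB = 150.0


def _default_platforms() -> tuple[int, ...]:
    return (250, 750, 1250, 1750, 2250)


@dataclass
class SimParams:
    """Lattice extrusion configuration (1 site = 1 Kb).

    ``p_unload`` defaults to 2/processivity so that the mean total loop
    growth over an extruder lifetime is 150 Kb; ``p_load`` defaults to
    ``p_unload / 150`` which balances to one background extruder per 150 Kb.
    """

    L: int = 2500
    platforms: tuple[int, ...] = field(default_factory=_default_platforms)
    enrichment: float = 10.0
    p_unload: float = 2.0 / PROCESSIVITY_KB
    p_load: float = (2.0 / PROCESSIVITY_KB) / BACKGROUND_SPACING_KB
    p_step: float = 1.0
    mechanism: str = "background"
    barrier_halfwidth: int = 50
    p_stall: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("p_unload", "p_load", "p_step", "p_stall"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.enrichment < 1:
            raise ValueError("enrichment must be >= 1")
        if self.mechanism not in ("background", "barriers", "decoupled"):
            raise ValueError(f"unknown mechanism {self.mechanism!r}")
        if any(not 0 <= p < self.L for p in self.platforms):
            raise ValueError("platforms must lie within the lattice")

    def barrier_sites(self) -> np.ndarray:
        """Candidate barrier sites: every site within +/-barrier_halfwidth
        of a platform (platforms excluded)."""
        if self.mechanism != "barriers":
            return np.array([], dtype=int)
        sites = set()
        for p in self.platforms:
            for d in range(-self.barrier_halfwidth, self.barrier_halfwidth + 1):
                if d != 0:
                    sites.add((p + d) % self.L)
        return np.array(sorted(sites), dtype=int)


class ExtruderState:
    """Mutable extruder configuration on the periodic lattice.

    Leg positions are stored unwrapped (``left < right`` always); the
    occupancy array maps each lattice site to the extruder occupying it with
    a leg, or -1.
    """

    def __init__(self, L: int):
        self.L = L
        self.left: list[int] = []
        self.right: list[int] = []
        self.origin: list[str] = []  # "platform" | "background"
        self.occupancy = np.full(L, -1, dtype=int)

    @property
    def n(self) -> int:
        return len(self.left)

    def add(self, left: int, right: int, origin: str) -> None:
        k = self.n
        self.left.append(left)
        self.right.append(right)
        self.origin.append(origin)
        self.occupancy[left % self.L] = k
        self.occupancy[right % self.L] = k

    def remove(self, indices) -> None:
        keep = [k for k in range(self.n) if k not in set(indices)]
        for k in indices:
            self.occupancy[self.left[k] % self.L] = -1
            self.occupancy[self.right[k] % self.L] = -1
        self.left = [self.left[k] for k in keep]
        self.right = [self.right[k] for k in keep]
        self.origin = [self.origin[k] for k in keep]
        for new_k, k in enumerate(keep):
            self.occupancy[self.left[new_k] % self.L] = new_k
            self.occupancy[self.right[new_k] % self.L] = new_k

    def snapshot(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        return (
            np.array(self.left, dtype=int),
            np.array(self.right, dtype=int),
            np.array([o == "platform" for o in self.origin], dtype=bool),
        )

    def check_invariants(self) -> None:
        assert all(l < r for l, r in zip(self.left, self.right))
        occ = np.full(self.L, -1, dtype=int)
        for k, (l, r) in enumerate(zip(self.left, self.right)):
            for site in (l % self.L, r % self.L):
                assert occ[site] == -1, "two legs share a site"
                occ[site] = k
        assert np.array_equal(occ, self.occupancy)


def _platform_pairs(params: SimParams) -> list[tuple[int, int]]:
    pairs = []
    for p in params.platforms:
        pairs.append(((p - 1) % params.L, p))
        pairs.append((p, (p + 1) % params.L))
    return pairs


def step(
    state: ExtruderState,
    params: SimParams,
    rng: np.random.Generator,
    check: bool = False,
) -> ExtruderState:
    """Advance one time step in place: unload, load, then step legs.

    Simultaneous leg moves are resolved in order of increasing lattice site,
    re-checking occupancy, so legs can never cross or share a site.
    """
    L = params.L
    # (1) unloading
    if state.n:
        gone = np.flatnonzero(rng.random(state.n) < params.p_unload)
        if gone.size:
            state.remove(list(gone))

    # (2) loading
    platform_sites = set(params.platforms)
    p_plat = min(1.0, params.p_load * params.enrichment)
    for a, b in _platform_pairs(params):
        if (
            rng.random() < p_plat
            and state.occupancy[a] == -1
            and state.occupancy[b] == -1
        ):
            left_uw = a if b > a else a - L  # unwrapped, left < right
            state.add(left_uw, left_uw + 1, "platform")
    if params.mechanism == "background":
        k = rng.binomial(L, params.p_load)
        if k:
            for a in rng.integers(0, L, size=k):
                b = (a + 1) % L
                if a in platform_sites or b in platform_sites:
                    continue  # platform pairs handled above with weight E
                if state.occupancy[a] == -1 and state.occupancy[b] == -1:
                    state.add(a, a + 1, "background")

    # (3) stepping
    barrier = np.zeros(L, dtype=bool)
    if params.mechanism == "barriers":
        barrier[params.barrier_sites()] = True
    legs = []
    for k in range(state.n):
        legs.append((state.left[k] % L, k, "left"))
        legs.append((state.right[k] % L, k, "right"))
    legs.sort()
    for _, k, which in legs:
        if params.mechanism == "decoupled":
            if rng.random() >= params.p_step:
                continue
        elif params.p_step < 1.0 and rng.random() >= params.p_step:
            continue
        if which == "left":
            cur, tgt = state.left[k], state.left[k] - 1
        else:
            cur, tgt = state.right[k], state.right[k] + 1
        tgt_site = tgt % L
        if state.occupancy[tgt_site] != -1:
            continue  # blocked by any leg (including own partner on a ring)
        if barrier[tgt_site] and rng.random() < params.p_stall:
            continue
        state.occupancy[cur % L] = -1
        state.occupancy[tgt_site] = k
        if which == "left":
            state.left[k] = tgt
        else:
            state.right[k] = tgt
    if check:
        state.check_invariants()
    return state


def run(
    params: SimParams,
    burn_in: int = 1000,
    n_samples: int = 1000,
    interval: int = 10,
    collect_occupancy: bool = True,
):
    """Simulate and record configurations every ``interval`` steps.

    Returns ``(samples, occupancy)`` where samples is a list of
    ``(left, right, is_platform_origin)`` arrays and occupancy is the
    per-site leg count averaged over every post-burn-in step.
    """
    if n_samples < 1:
        raise ValueError("n_samples must be >= 1")
    if burn_in < 0:
        raise ValueError("burn_in must be >= 0")
    rng = np.random.default_rng(params.seed)
    state = ExtruderState(params.L)
    for _ in range(burn_in):
        step(state, params, rng)
    occ_sum = np.zeros(params.L)
    samples = []
    n_steps = 0
    for s in range(n_samples):
        for _ in range(interval):
            step(state, params, rng)
            if collect_occupancy:
                sites = np.array(
                    [x % params.L for x in state.left + state.right], dtype=int
                )
                np.add.at(occ_sum, sites, 1)
                n_steps += 1
        samples.append(state.snapshot())
    occupancy = occ_sum / max(n_steps, 1)
    return samples, occupancy


def _arc_intersects(l, r, a, b, L) -> np.ndarray:
    """Vectorized: does the extruder span [l, r] touch ring arc [a, b]?"""
    l = np.asarray(l)
    r = np.asarray(r)
    span = r - l
    return (((a - l) % L) <= span) | (((l - a) % L) <= (b - a))


def steady_stats(
    samples,
    fountain_region: tuple[int, int],
    L: int,
) -> dict:
    """Time-averaged extruder counts whose span intersects a region.

    ``fountain_region`` is (start_site, end_site) on the ring.  Counts are
    split by origin; density is total extruders per Kb of lattice.
    """
    if len(samples) == 0:
        raise ValueError("empty samples")
    a, b = fountain_region
    plat_counts, bg_counts, totals = [], [], []
    for left, right, is_plat in samples:
        if left.size == 0:
            plat_counts.append(0)
            bg_counts.append(0)
            totals.append(0)
            continue
        hit = _arc_intersects(left, right, a, b, L)
        plat_counts.append(int((hit & is_plat).sum()))
        bg_counts.append(int((hit & ~is_plat).sum()))
        totals.append(int(left.size))
    return {
        "platform_per_region": float(np.mean(plat_counts)),
        "background_per_region": float(np.mean(bg_counts)),
        "all_per_region": float(np.mean(plat_counts) + np.mean(bg_counts)),
        "density_per_kb": float(np.mean(totals) / L),
    }


def align_occupancy(
    occupancy: np.ndarray, platforms, halfwidth: int = 250
) -> np.ndarray:
    """Average the occupancy profile re-centered at each platform."""
    L = occupancy.shape[0]
    rows = []
    for p in platforms:
        idx = (np.arange(p - halfwidth, p + halfwidth + 1)) % L
        rows.append(occupancy[idx])
    return np.mean(rows, axis=0)


def occupancy_fwhm(
    aligned: np.ndarray,
    smooth_sites: int = 5,
    background_offsets: tuple[int, int] = (150, 240),
) -> float:
    """FWHM (Kb) of the platform-centered occupancy peak above background.

    The aligned profile is smoothed with a short moving average; the
    background level is the mean over offsets in ``background_offsets`` on
    both sides; half-max crossings are located by linear interpolation
    walking outward from the center.
    """
    c = aligned.shape[0] // 2
    kernel = np.ones(smooth_sites) / smooth_sites
    sm = np.convolve(aligned, kernel, mode="same")
    lo, hi = background_offsets
    bg_idx = np.concatenate([np.arange(c - hi, c - lo), np.arange(c + lo, c + hi)])
    bg_idx = bg_idx[(bg_idx >= 0) & (bg_idx < sm.shape[0])]
    background = sm[bg_idx].mean()
    search = min(lo, c) - 1
    peak = sm[c - search : c + search + 1].max() - background
    if peak <= 0:
        return float("nan")
    half = background + peak / 2.0

    # The top of the peak is structured (legs vacate the loading site at one
    # site per step), so the width is taken between the OUTERMOST
    # half-maximum crossings, scanning inward from the background zone.
    def crossing(direction: int) -> float:
        for d in range(search, 0, -1):
            cur = sm[c + direction * d]
            if cur >= half:
                outer = sm[c + direction * (d + 1)]
                frac = (half - outer) / (cur - outer) if cur > outer else 1.0
                return d + 1 - frac
        return 0.0

    return float(crossing(-1) + crossing(+1))


# -- contact reconstruction --------------------------------------------------

def _ring_dist(i: np.ndarray, j: np.ndarray, L: int) -> np.ndarray:
    d = np.abs(i - j)
    return np.minimum(d, L - d)


def contacts_from_loops(
    sample,
    L: int,
    exponent: float = -1.5,
    offset: int = 1,
) -> np.ndarray:
    """Contact probabilities from one loop configuration.

    ``P(i, j) = (d_eff(i, j) + offset) ** exponent`` with ``d_eff`` the
    shortest path in the graph of backbone edges (length 1 each, periodic)
    plus zero-length bridges between each extruder's two legs.  Computed
    exactly by min-plus composition through the small set of bridge
    endpoints.
    """
    if exponent >= 0:
        raise ValueError("exponent must be negative")
    left, right = np.asarray(sample[0]) % L, np.asarray(sample[1]) % L
    sites = np.arange(L)
    d_eff = _ring_dist(sites[:, None], sites[None, :], L).astype(float)
    if left.size:
        nodes = np.concatenate([left, right])
        m = nodes.size
        K = left.size
        D = _ring_dist(nodes[:, None], nodes[None, :], L).astype(float)
        for k in range(K):
            D[k, K + k] = 0.0
            D[K + k, k] = 0.0
        # Floyd-Warshall on the small endpoint graph
        for k in range(m):
            D = np.minimum(D, D[:, k : k + 1] + D[k : k + 1, :])
        A = _ring_dist(sites[:, None], nodes[None, :], L).astype(float)  # L x m
        M = np.min(A[:, :, None] + D[None, :, :], axis=1)  # L x m
        tmp = np.empty((L, L))
        for v in range(m):
            np.add.outer(M[:, v], A[:, v], out=tmp)
            np.minimum(d_eff, tmp, out=d_eff)
    else:
        pass
    return (d_eff + offset) ** exponent


def simulated_oe_window(
    samples,
    params: SimParams,
    window_bp: int = 200_000,
    exponent: float = -1.5,
    offset: int = 1,
) -> np.ndarray:
    """Platform-centered obs/exp window at lattice (1 Kb) resolution.

    Averages the contact kernel over samples, normalizes by the map's own
    distance decay (ring diagonals) and averages the ``window_bp`` windows
    around every platform (periodic wrap).
    """
    if len(samples) < 1:
        raise ValueError("need at least one sample")
    L = params.L
    mean_p = np.zeros((L, L))
    for sample in samples:
        mean_p += contacts_from_loops(sample, L, exponent, offset)
    mean_p /= len(samples)

    sep = _ring_dist(np.arange(L)[:, None], np.arange(L)[None, :], L)
    max_s = L // 2
    expected = np.zeros(max_s + 1)
    rows = np.arange(L)
    for s in range(max_s + 1):
        expected[s] = mean_p[rows, (rows + s) % L].mean()
    oe = mean_p / expected[sep]

    halfwidth = window_bp // 2000  # 1 Kb sites, +/- half the window
    snippets = []
    for p in params.platforms:
        idx = np.arange(p - halfwidth, p + halfwidth + 1) % L
        snippets.append(oe[np.ix_(idx, idx)])
    return average_pileup(snippets).values


def window_contact_ensemble(
    samples,
    params: SimParams,
    halfwidth: int,
    platform: int | None = None,
    exponent: float = -1.5,
    offset: int = 1,
) -> np.ndarray:
    """Ensemble-mean contact kernel in platform-centered windows.

    Exact (bridges outside the window are still used by the shortest paths)
    but much cheaper than the full-lattice map.  With ``platform=None`` the
    windows of every platform are averaged.
    """
    L = params.L
    platforms = params.platforms if platform is None else (platform,)
    side = 2 * halfwidth + 1
    idx_sets = [
        np.arange(p - halfwidth, p + halfwidth + 1) % L for p in platforms
    ]
    mean_p = np.zeros((side, side))
    tmp = np.empty((side, side))
    bases = [
        _ring_dist(idx[:, None], idx[None, :], L).astype(float)
        for idx in idx_sets
    ]
    for sample in samples:
        left, right = np.asarray(sample[0]) % L, np.asarray(sample[1]) % L
        if left.size:
            nodes = np.concatenate([left, right])
            m = nodes.size
            K = left.size
            D = _ring_dist(nodes[:, None], nodes[None, :], L).astype(float)
            for k in range(K):
                D[k, K + k] = 0.0
                D[K + k, k] = 0.0
            for k in range(m):
                D = np.minimum(D, D[:, k : k + 1] + D[k : k + 1, :])
        for idx, base in zip(idx_sets, bases):
            d_eff = base.copy()
            if left.size:
                A = _ring_dist(idx[:, None], nodes[None, :], L).astype(float)
                M = np.min(A[:, :, None] + D[None, :, :], axis=1)
                for v in range(m):
                    np.add.outer(M[:, v], A[:, v], out=tmp)
                    np.minimum(d_eff, tmp, out=d_eff)
            mean_p += (d_eff + offset) ** exponent
    return mean_p / (len(samples) * len(platforms))


def platform_window_pileup(
    samples,
    params: SimParams,
    window_bp: int = 200_000,
    factor: int = 10,
    exponent: float = -1.5,
    offset: int = 1,
) -> Pileup:
    """Coarse-grained platform pileup from the window-restricted kernel.

    Equivalent in content to :func:`simulated_average_fountain` but
    normalized by the window's own per-separation mean instead of the
    full-lattice P(s); an order of magnitude cheaper for long lattices.
    """
    halfwidth = window_bp // 2000
    win = window_contact_ensemble(
        samples, params, halfwidth, exponent=exponent, offset=offset
    )
    side = win.shape[0]
    sep = np.abs(np.arange(side)[:, None] - np.arange(side)[None, :])
    oe = np.empty_like(win)
    for s in range(side):
        mu = win[sep == s].mean()
        oe[sep == s] = win[sep == s] / mu if mu > 0 else np.nan
    values = coarse_grain(oe, factor)
    n_obs = np.full_like(values, float(len(samples)))
    return Pileup(values=values, n_obs=n_obs, resolution=factor * 1000)


def simulated_average_fountain(
    samples,
    params: SimParams,
    window_bp: int = 200_000,
    factor: int = 10,
    exponent: float = -1.5,
    offset: int = 1,
) -> Pileup:
    """Ensemble pileup of obs/exp windows at the loading platforms.

    200 Kb windows on the 1 Kb lattice coarse-grained by ``factor`` = 10
    give a 20x20 pileup at 10 Kb bins.
    """
    window = simulated_oe_window(samples, params, window_bp, exponent, offset)
    values = coarse_grain(window, factor)
    n_obs = np.full_like(values, float(len(samples)))
    return Pileup(values=values, n_obs=n_obs, resolution=factor * 1000)


def cross_section_widths(
    oe_window: np.ndarray,
    heights_kb,
    slab_halfwidth: int = 5,
) -> np.ndarray:
    """Width of the fountain per cross-section at given distances from the base.

    A contact (base - x, base + y) sits at height ``(x + y) / 2`` Kb from the
    base and at transverse position ``(y - x) / 2``.  For each requested
    height the function takes the slab of cells within ``slab_halfwidth`` of
    it and returns the standard deviation of the transverse position weighted
    by the obs/exp enrichment above baseline (clipped at zero).  Hairpins
    keep the width flat and near zero; desynchronized extrusion lets it grow
    with height.
    """
    side = oe_window.shape[0]
    c = (side - 1) // 2
    di = np.arange(side)[:, None] - c  # -x
    dj = np.arange(side)[None, :] - c  # +y
    height = (dj - di) / 2.0  # (x + y)/2 for cells with i<=c<=j
    trans = (dj + di) / 2.0  # (y - x)/2
    cone = (di <= 0) & (dj >= 0)  # both legs flank the base
    widths = []
    for h in heights_kb:
        sel = cone & (np.abs(height - h) <= slab_halfwidth)
        vals = oe_window[sel]
        t = np.rint(trans[sel]).astype(int)
        ok = np.isfinite(vals)
        vals, t = vals[ok], t[ok]
        if vals.size == 0:
            widths.append(float("nan"))
            continue
        # collapse the slab to a transverse intensity profile, remove its
        # baseline, and take the intensity-weighted standard deviation
        tt = np.arange(t.min(), t.max() + 1)
        prof = np.full(tt.shape, np.nan)
        for k, tv in enumerate(tt):
            cells = vals[t == tv]
            if cells.size:
                prof[k] = cells.mean()
        good = np.isfinite(prof)
        prof, tt = prof[good], tt[good]
        if prof.size == 0:
            widths.append(float("nan"))
            continue
        # ridge width: extent of the profile above half its peak enrichment.
        # (A loop also pinches together everything beyond its two legs, which
        # adds a wide low plateau to every cross-section; the half-maximum
        # cut isolates the ridge traced by the leg positions themselves.)
        baseline = np.median(prof)
        peak = prof.max() - baseline
        if peak <= 0:
            widths.append(float("nan"))
            continue
        widths.append(float((prof - baseline >= peak / 2.0).sum()))
    return np.array(widths)


def wedge_score_of_window(
    win: np.ndarray,
    half_angle_deg: float = 30.0,
    r_min_bins: float = 1.0,
) -> float:
    """Wedge correlation of a contact window, normalized per separation.

    Dividing each diagonal by its own window mean is a cheap local obs/exp;
    the Pearson correlation with a binary wedge mask then measures how
    fountain-like the window is.
    """
    side = win.shape[0]
    sep = np.abs(np.arange(side)[:, None] - np.arange(side)[None, :])
    oe = np.empty_like(win, dtype=float)
    for s in range(side):
        cells = win[sep == s]
        mu = cells.mean()
        oe[sep == s] = win[sep == s] / mu if mu > 0 else np.nan
    wedge = wedge_values(side, half_angle_deg, r_min_bins)
    return fountain_score(oe, wedge)


def window_wedge_score(
    samples,
    params: SimParams,
    halfwidth: int = 100,
    half_angle_deg: float = 30.0,
    r_min_bins: float = 1.0,
) -> float:
    """Wedge correlation of the platform-window ensemble kernel.

    Converges much faster than the full-lattice pileup for ensembles
    dominated by background loops.
    """
    win = window_contact_ensemble(samples, params, halfwidth)
    return wedge_score_of_window(win, half_angle_deg, r_min_bins)


def best_fit_measurements(
    seed: int,
    burn_in: int = 2000,
    n_samples: int = 2000,
    interval: int = 1000,
    region_bp: int = 400_000,
) -> dict:
    """Steady-state observables of the best-fit facilitated-loading regime.

    Runs the default parameters (2.5 Mb lattice, platforms every 500 Kb,
    10-fold enrichment, one background extruder per 150 Kb, 150 Kb
    processivity), then reports the time-averaged number of platform-origin
    extruders whose span touches a ``region_bp`` window centered on a
    platform, the same count for all extruders, the extruder density, and
    the FWHM (Kb) of the platform-aligned occupancy peak above background.
    """
    params = SimParams(seed=seed)
    samples, occupancy = run(
        params, burn_in=burn_in, n_samples=n_samples, interval=interval
    )
    half_region = region_bp // 2000  # sites on each side of the platform
    p0 = params.platforms[0]
    st = steady_stats(samples, (p0 - half_region, p0 + half_region), params.L)
    aligned = align_occupancy(occupancy, params.platforms)
    fwhm = occupancy_fwhm(aligned)
    return {
        "platform_extruders_per_fountain": st["platform_per_region"],
        "all_extruders_per_fountain": st["all_per_region"],
        "density_per_kb": st["density_per_kb"],
        "occupancy_fwhm_kb": fwhm,
        "n_samples": len(samples),
    }


def pileup_wedge_score(
    pileup: Pileup | np.ndarray,
    half_angle_deg: float = 30.0,
    r_min_bins: float = 1.0,
) -> float:
    """Pearson correlation of a pileup with a wedge mask of matching side."""
    values = pileup.values if isinstance(pileup, Pileup) else np.asarray(pileup)
    side = values.shape[0]
    wedge = wedge_values(side, half_angle_deg, r_min_bins, center=(side - 1) / 2)
    return fountain_score(values, wedge)


def fit_metrics(
    sim_pileup: Pileup | np.ndarray,
    ref_pileup: Pileup | np.ndarray,
    sector_deg: float = 10.0,
    r_min_bins: float = 2.0,
) -> dict:
    """Protractor MSE and shape Spearman between two pileups."""
    sim = sim_pileup.values if isinstance(sim_pileup, Pileup) else np.asarray(sim_pileup)
    ref = ref_pileup.values if isinstance(ref_pileup, Pileup) else np.asarray(ref_pileup)
    if sim.shape != ref.shape:
        raise ValueError("pileups must have the same shape (resample first)")
    prof_sim = protractor(sim, sector_deg, r_min_bins).means
    prof_ref = protractor(ref, sector_deg, r_min_bins).means
    ok = np.isfinite(prof_sim) & np.isfinite(prof_ref)
    if not ok.any():
        raise ValueError("all-NaN protractor overlap")
    mse = float(np.mean((prof_sim[ok] - prof_ref[ok]) ** 2))
    side = sim.shape[0]
    offdiag = ~np.eye(side, dtype=bool)
    xs, ys = sim[offdiag], ref[offdiag]
    both = np.isfinite(xs) & np.isfinite(ys)
    rho = stats.spearmanr(xs[both], ys[both]).statistic
    return {"protractor_mse": mse, "shape_spearman": float(rho)}


def parameter_sweep(
    grid: list[SimParams],
    ref: Pileup,
    burn_in: int = 1000,
    n_samples: int = 200,
    interval: int = 10,
    method: str = "window",
) -> pd.DataFrame:
    """Run each grid point, compare its average fountain to the reference.

    ``method="window"`` builds the pileup from platform-window kernels
    (cheap, all platforms pooled); ``method="full"`` uses the full-lattice
    obs/exp pipeline.  Returns one row per grid point with the parameters
    and fit metrics, sorted by protractor MSE ascending.
    """
    if not grid:
        raise ValueError("empty parameter grid")
    make = platform_window_pileup if method == "window" else simulated_average_fountain
    rows = []
    for params in grid:
        samples, _ = run(
            params, burn_in=burn_in, n_samples=n_samples, interval=interval,
            collect_occupancy=False,
        )
        pile = make(samples, params)
        metrics = fit_metrics(pile, ref)
        rows.append(
            {
                "enrichment": params.enrichment,
                "p_load": params.p_load,
                "p_unload": params.p_unload,
                "mechanism": params.mechanism,
                "seed": params.seed,
                **metrics,
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("protractor_mse")
        .reset_index(drop=True)
    )
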