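"""Synthetic Hi-C maps with implanted fountains and known ground truth.

The generator emulates the statistical structure the caller relies on: a
power-law distance decay ``(s + 1) ** exponent``, multiplicative wedge-shaped
fountain enrichments (so obs/exp inside a fountain has a constant target
level of ``1 + strength``), independent Poisson count noise per replicate at
a fixed total coverage, and randomly placed bad bins shared across
replicates.  Everything is a deterministic function of the spec seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contact_data import ContactMap

__all__ = [
    "FixtureSpec",
    "FixtureData",
    "default_fixture_spec",
    "place_fountains",
    "generate",
    "merge_replicates",
    "evaluate_calls",
    "CallEvaluation",
]

FOUNTAIN_COLUMNS = ["chrom", "pos", "strength", "half_angle_deg", "extent_bp"]
ARTIFACT_COLUMNS = ["chrom", "pos", "strength", "halfwidth_bp"]


@dataclass
class FixtureSpec:
    """Recipe for a synthetic multi-replicate cis Hi-C dataset.

    ``artifacts`` are misassembly-like features: sharp square blocks of
    enriched contacts on the diagonal.  Unlike fountains they are implanted
    in every map including the condition-independent control, mimicking
    genomic (assembly) rather than biological signal — the prey of the
    noise-score and control filters.
    """

    chrom_length_bp: int
    n_chroms: int = 1
    resolution: int = 10_000
    exponent: float = -1.5
    coverage: float = 5e6  # total counts per replicate, all chromosomes
    fountains: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=FOUNTAIN_COLUMNS)
    )
    artifacts: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=ARTIFACT_COLUMNS)
    )
    bad_bin_fraction: float = 0.01
    n_replicates: int = 2
    with_control: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coverage <= 0:
            raise ValueError("coverage must be positive")
        if len(self.fountains):
            if (self.fountains["strength"] < 0).any():
                raise ValueError("fountain strength must be >= 0")
            if (self.fountains["extent_bp"] > self.chrom_length_bp).any():
                raise ValueError("fountain extent exceeds chromosome length")

    @property
    def chromsizes(self) -> dict[str, int]:
        return {
            f"chr{i + 1}": self.chrom_length_bp for i in range(self.n_chroms)
        }


def place_fountains(
    chromsizes: dict[str, int],
    n: int,
    resolution: int,
    seed: int,
    strength: float = 1.0,
    half_angle_deg: float = 30.0,
    extent_bp: int = 200_000,
    min_edge_bp: int = 2_000_000,
    min_sep_bp: int = 2_000_000,
) -> pd.DataFrame:
    """Random non-overlapping fountain positions, away from chromosome ends."""
    rng = np.random.default_rng(seed)
    total = sum(chromsizes.values())
    rows = []
    remaining = n
    names = list(chromsizes)
    for ci, chrom in enumerate(names):
        share = (
            remaining
            if ci == len(names) - 1
            else int(round(n * chromsizes[chrom] / total))
        )
        share = min(share, remaining)
        placed = []
        attempts = 0
        while len(placed) < share and attempts < 10_000:
            attempts += 1
            pos = int(
                rng.integers(
                    min_edge_bp // resolution,
                    (chromsizes[chrom] - min_edge_bp) // resolution,
                )
            ) * resolution
            if all(abs(pos - q) >= min_sep_bp for q in placed):
                placed.append(pos)
        for pos in sorted(placed):
            rows.append(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "strength": strength,
                    "half_angle_deg": half_angle_deg,
                    "extent_bp": extent_bp,
                }
            )
        remaining -= len(placed)
    return pd.DataFrame(rows, columns=FOUNTAIN_COLUMNS)


def default_fixture_spec(
    seed: int = 0,
    n_fountains: int = 20,
    strength: float = 1.0,
    total_length_bp: int = 100_000_000,
    n_chroms: int = 4,
    coverage: float = 5e6,
    n_replicates: int = 2,
    n_artifacts: int = 20,
    artifact_strength: float = 4.0,
) -> FixtureSpec:
    """The standard test fixture: 100 Mb in 4 chromosomes at 10 Kb bins."""
    chrom_length = total_length_bp // n_chroms
    chromsizes = {f"chr{i + 1}": chrom_length for i in range(n_chroms)}
    fountains = (
        place_fountains(chromsizes, n_fountains, 10_000, seed, strength)
        if n_fountains
        else pd.DataFrame(columns=FOUNTAIN_COLUMNS)
    )
    artifacts = pd.DataFrame(columns=ARTIFACT_COLUMNS)
    if n_artifacts:
        # placed like fountains but from an independent seed stream; keep
        # them clear of the implanted fountains
        placed = place_fountains(
            chromsizes, n_artifacts, 10_000, seed + 104729, artifact_strength
        )
        keep = []
        for _, a in placed.iterrows():
            near = fountains[
                (fountains["chrom"] == a["chrom"])
                & ((fountains["pos"] - a["pos"]).abs() < 1_000_000)
            ]
            if not len(near):
                keep.append(
                    {
                        "chrom": a["chrom"],
                        "pos": int(a["pos"]),
                        "strength": artifact_strength,
                        "halfwidth_bp": 20_000,
                    }
                )
        artifacts = pd.DataFrame(keep, columns=ARTIFACT_COLUMNS)
    return FixtureSpec(
        chrom_length_bp=chrom_length,
        n_chroms=n_chroms,
        resolution=10_000,
        coverage=coverage,
        fountains=fountains,
        artifacts=artifacts,
        n_replicates=n_replicates,
        seed=seed,
    )


def _implant_wedge(
    expected: np.ndarray,
    base_bin: int,
    strength: float,
    half_angle_deg: float,
    extent_bins: float,
) -> None:
    """Multiply expected by (1 + strength) inside the fountain wedge.

    A cell belongs to the wedge when its offset from the base makes an angle
    of at most ``half_angle_deg`` with the perpendicular bisector of the
    diagonal and its distance from the diagonal (along the bisector) is at
    most ``extent_bins``.  The enrichment holds a central plateau over the
    inner half of the wedge angle and rolls off smoothly (cosine ramp) to
    the wedge edge and over the outer 20% of the radial extent, as real
    fountains fade into the background rather than ending in a step.
    """
    n = expected.shape[0]
    reach = int(math.ceil(extent_bins * math.sqrt(2))) + 1
    lo = max(0, base_bin - reach)
    hi = min(n, base_bin + reach + 1)
    di = np.arange(lo, hi)[:, None] - base_bin
    dj = np.arange(lo, hi)[None, :] - base_bin
    r = np.hypot(di, dj)
    perp = np.abs(dj - di) / math.sqrt(2.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        theta = np.degrees(np.arccos(np.clip(np.where(r > 0, perp / r, 0.0), -1, 1)))
    ang = np.clip((theta - half_angle_deg / 2.0) / (half_angle_deg / 2.0), 0.0, 1.0)
    ang_taper = 0.5 * (1.0 + np.cos(math.pi * ang))
    rad = np.clip((perp - 0.8 * extent_bins) / (0.2 * extent_bins), 0.0, 1.0)
    rad_taper = 0.5 * (1.0 + np.cos(math.pi * rad))
    # fountains are pinched near the diagonal: the enrichment switches on
    # over the first few bins of radius rather than starting at full height
    onset = 0.5 * (1.0 - np.cos(math.pi * np.clip(r / 8.0, 0.0, 1.0)))
    factor = 1.0 + strength * ang_taper * rad_taper * onset * (r > 0)
    block = expected[lo:hi, lo:hi]
    expected[lo:hi, lo:hi] = block * factor


@dataclass
class FixtureData:
    """Generated maps plus the ground truth that produced them."""

    replicates: list[ContactMap]
    truth: pd.DataFrame  # BED-like table of fountain base bins
    control: ContactMap | None = None


def _implant_block(
    expected: np.ndarray, base_bin: int, strength: float, halfwidth_bins: int
) -> None:
    """Sharp misassembly-like square enrichment on the diagonal."""
    n = expected.shape[0]
    lo = max(0, base_bin - halfwidth_bins)
    hi = min(n, base_bin + halfwidth_bins + 1)
    expected[lo:hi, lo:hi] *= 1.0 + strength


def generate(spec: FixtureSpec) -> FixtureData:
    """Build replicate ContactMaps, an optional control map, and the truth.

    Fountains go into the replicates only; artifacts and bad bins are shared
    by every map including the control (they model assembly features, not
    biology).  A fountain row may carry a ``replicate`` integer to implant it
    in a single replicate only (replicate-discordant decoys).  The truth
    table lists the replicate-shared fountains.
    """
    rng = np.random.default_rng(spec.seed)
    res = spec.resolution
    chromsizes = spec.chromsizes
    n_bins = {c: -(-l // res) for c, l in chromsizes.items()}

    # shared bad bins per chromosome
    bad = {}
    for chrom, n in n_bins.items():
        k = int(round(spec.bad_bin_fraction * n))
        bad[chrom] = (
            rng.choice(n, size=k, replace=False) if k else np.array([], dtype=int)
        )

    total_len = sum(chromsizes.values())
    base_expected = {}
    for chrom, n in n_bins.items():
        sep = np.abs(np.arange(n)[:, None] - np.arange(n)[None, :])
        base_expected[chrom] = (sep + 1.0) ** spec.exponent
        for _, a in spec.artifacts.iterrows():
            if a["chrom"] == chrom:
                _implant_block(
                    base_expected[chrom],
                    int(a["pos"]) // res,
                    float(a["strength"]),
                    int(a["halfwidth_bp"]) // res,
                )

    def expected_for(replicate: int | None) -> dict[str, np.ndarray]:
        out = {c: m.copy() for c, m in base_expected.items()}
        if replicate is None:
            return out  # control: artifacts only, no fountains
        for _, f in spec.fountains.iterrows():
            target = f.get("replicate", None)
            if target is not None and not (
                isinstance(target, float) and math.isnan(target)
            ):
                if int(target) != replicate:
                    continue
            _implant_wedge(
                out[f["chrom"]],
                int(f["pos"]) // res,
                float(f["strength"]),
                float(f["half_angle_deg"]),
                float(f["extent_bp"]) / res,
            )
        return out

    def sample_map(exp: dict[str, np.ndarray], stream: int) -> ContactMap:
        counts = {}
        map_rng = np.random.default_rng([spec.seed, stream])
        for chrom, lam in exp.items():
            cov_share = spec.coverage * chromsizes[chrom] / total_len
            # scale so the symmetric full-matrix total matches the coverage
            full_sum = 2.0 * np.triu(lam, 1).sum() + np.trace(lam)
            lam_scaled = lam * (cov_share / full_sum)
            upper = map_rng.poisson(np.triu(lam_scaled))
            mat = (upper + np.triu(upper, 1).T).astype(float)
            mat[bad[chrom], :] = 0.0
            mat[:, bad[chrom]] = 0.0
            counts[chrom] = mat
        return ContactMap(
            resolution=res, chromsizes=dict(chromsizes), counts=counts
        )

    replicates = [
        sample_map(expected_for(rep), rep) for rep in range(spec.n_replicates)
    ]
    control = (
        sample_map(expected_for(None), spec.n_replicates + 7)
        if spec.with_control
        else None
    )

    truth = spec.fountains.copy()
    if len(truth):
        shared = pd.Series(True, index=truth.index)
        if "replicate" in truth.columns:
            shared = truth["replicate"].isna()
        truth = truth[shared].reset_index(drop=True)
    truth_bed = pd.DataFrame(
        {
            "chrom": truth["chrom"] if len(truth) else [],
            "start": (truth["pos"] // res * res).astype(int) if len(truth) else [],
            "end": (truth["pos"] // res * res + res).astype(int) if len(truth) else [],
        }
    )
    return FixtureData(replicates=replicates, truth=truth_bed, control=control)


def merge_replicates(replicates: list[ContactMap]) -> ContactMap:
    """Sum raw counts across replicates into one merged map."""
    first = replicates[0]
    counts = {c: m.copy() for c, m in first.counts.items()}
    for rep in replicates[1:]:
        if rep.chromsizes != first.chromsizes or rep.resolution != first.resolution:
            raise ValueError("replicate binning mismatch")
        for c in counts:
            counts[c] += rep.counts[c]
    return ContactMap(
        resolution=first.resolution,
        chromsizes=dict(first.chromsizes),
        counts=counts,
    )


@dataclass
class CallEvaluation:
    precision: float
    recall: float
    n_matched: int
    n_called: int
    n_truth: int


def evaluate_calls(
    calls: pd.DataFrame,
    truth: pd.DataFrame,
    tol_bins: int,
    resolution: int,
) -> CallEvaluation:
    """Greedy one-to-one matching of called to true fountain bins.

    Pairs are matched closest-first within ``tol_bins``; precision is
    matched/called (NaN when nothing was called), recall is matched/truth.
    """
    if tol_bins < 0:
        raise ValueError("tolerance must be nonnegative")
    n_called = len(calls)
    n_truth = len(truth)
    pairs = []
    for chrom in truth["chrom"].unique() if n_truth else []:
        tb = (truth.loc[truth["chrom"] == chrom, "start"] // resolution).to_numpy()
        if n_called:
            cb = (
                calls.loc[calls["chrom"] == chrom, "start"] // resolution
            ).to_numpy()
        else:
            cb = np.array([], dtype=int)
        for ti, t in enumerate(tb):
            for ci, c in enumerate(cb):
                d = abs(int(t) - int(c))
                if d <= tol_bins:
                    pairs.append((d, chrom, ti, ci))
    pairs.sort()
    used_t, used_c, matched = set(), set(), 0
    for d, chrom, ti, ci in pairs:
        if (chrom, ti) in used_t or (chrom, ci) in used_c:
            continue
        used_t.add((chrom, ti))
        used_c.add((chrom, ci))
        matched += 1
    precision = matched / n_called if n_called else float("nan")
    recall = matched / n_truth if n_truth else float("nan")
    return CallEvaluation(precision, recall, matched, n_called, n_truth)
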