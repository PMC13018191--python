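"""Fountain scoring, peak prominence, Li thresholding, and the filter stack.

The prominence and threshold operations are checked against independent
brute-force oracles, and the Pearson score against both the closed formula
and scipy's implementation.
"""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from hicfountains import caller as cl
from hicfountains import contact_data as cd
from hicfountains import fixtures as fx


# -- independent oracles -----------------------------------------------------

def prominence_oracle(signal):
    """Brute-force topographic prominence: scan to the nearest higher point
    on each side, take the minimum on each path, prominence is height minus
    the higher of the two minima (segment ends act as bases)."""
    out = []
    m = len(signal)
    for i in range(m):
        j = i
        while j + 1 < m and signal[j + 1] == signal[i]:
            j += 1
        if not (i > 0 and signal[i - 1] < signal[i]):
            continue
        if not (j < m - 1 and signal[j + 1] < signal[i]):
            continue
        h = signal[i]
        side_mins = []
        for rng in (range(i - 1, -1, -1), range(j + 1, m)):
            lowest = h
            for k in rng:
                if signal[k] > h:
                    break
                lowest = min(lowest, signal[k])
            side_mins.append(lowest)
        out.append((i, h, h - max(side_mins)))
    return out


def cross_entropy(values, t):
    below, above = values[values <= t], values[values > t]
    if below.size == 0 or above.size == 0:
        return np.inf
    return -(below.sum() * np.log(below.mean()) + above.sum() * np.log(above.mean()))


def li_oracle_eta(values):
    """Minimum cross-entropy over all candidate midpoints (brute force)."""
    values = np.sort(np.asarray(values, dtype=float))
    mids = (values[:-1] + values[1:]) / 2
    return min(cross_entropy(values, t) for t in mids)


# -- masks -------------------------------------------------------------------

class TestBuildMask:
    def test_wedge_area_fraction(self):
        # fraction of nonzero cells must match the angular area of the
        # double wedge: 4*alpha of 360 degrees, counted by an independent
        # atan2-based predicate
        side, alpha = 41, 45.0
        mask = cl.build_mask(wedge_params=(side, alpha, 0.0))
        c = (side - 1) / 2
        count = 0
        for i in range(side):
            for j in range(side):
                di, dj = i - c, j - c
                r = np.hypot(di, dj)
                if r == 0:
                    continue
                theta = np.degrees(np.arcsin(min(1, abs(dj - di) / (np.sqrt(2) * r))))
                if 90 - theta <= alpha + 1e-9:
                    count += 1
        assert mask.values.sum() == count
        assert abs(mask.values.mean() - alpha / 90) < 0.05

    def test_seed_average(self):
        a = np.arange(9.0).reshape(3, 3)
        mask = cl.build_mask(seed_snippets=[a, a, a])
        np.testing.assert_allclose(mask.values, a)
        assert mask.provenance == "seed-average"

    def test_empty_seed_list(self):
        with pytest.raises(ValueError, match="empty seed"):
            cl.build_mask(seed_snippets=[])

    def test_invalid_half_angle(self):
        with pytest.raises(ValueError, match="half-angle"):
            cl.build_mask(wedge_params=(41, 95.0, 0.0))


class TestFountainScore:
    def test_affine_invariance(self, wedge_mask):
        rng = np.random.default_rng(0)
        snippet = 2.5 * wedge_mask.values + 0.3 + 0 * rng.normal(size=(41, 41))
        assert cl.fountain_score(snippet, wedge_mask) == pytest.approx(1.0)

    def test_negation_antisymmetry(self, wedge_mask):
        rng = np.random.default_rng(1)
        snippet = rng.normal(size=(41, 41))
        r = cl.fountain_score(snippet, wedge_mask)
        assert cl.fountain_score(-snippet, wedge_mask) == pytest.approx(-r)
        assert cl.fountain_score(-wedge_mask.values, wedge_mask) == pytest.approx(-1.0)

    def test_formula_oracle(self):
        rng = np.random.default_rng(2)
        snippet = rng.normal(size=(3, 3))
        mask = rng.normal(size=(3, 3))
        expected = stats.pearsonr(snippet.ravel(), mask.ravel()).statistic
        assert cl.fountain_score(snippet, mask) == pytest.approx(expected)

    def test_nan_cells_excluded(self):
        rng = np.random.default_rng(3)
        snippet = rng.normal(size=(4, 4))
        mask = rng.normal(size=(4, 4))
        snippet[0, 0] = np.nan
        keep = np.isfinite(snippet.ravel())
        expected = stats.pearsonr(
            snippet.ravel()[keep], mask.ravel()[keep]
        ).statistic
        assert cl.fountain_score(snippet, mask) == pytest.approx(expected)

    def test_degenerate_inputs_are_nan(self):
        assert np.isnan(cl.fountain_score(np.ones((3, 3)), np.eye(3)))
        few = np.full((3, 3), np.nan)
        few[0, 0] = 1.0
        assert np.isnan(cl.fountain_score(few, np.eye(3)))


class TestScharr:
    def test_constant_is_zero(self):
        assert cl.scharr_noise_score(np.full((5, 5), 7.0)) == 0.0

    def test_vertical_step_hand_convolution(self):
        snippet = np.array([[0, 0, 1], [0, 0, 1], [0, 0, 1]], dtype=float)
        # center: |Gx| = 3 + 10 + 3 = 16, Gy = 0
        assert cl.scharr_noise_score(snippet) == pytest.approx(16.0)

    def test_linearity_in_scale(self):
        rng = np.random.default_rng(4)
        snippet = rng.normal(size=(7, 7))
        s1 = cl.scharr_noise_score(snippet)
        assert cl.scharr_noise_score(3.0 * snippet) == pytest.approx(3.0 * s1)
        assert cl.scharr_noise_score(-2.0 * snippet) == pytest.approx(2.0 * s1)

    def test_too_small(self):
        with pytest.raises(ValueError, match="3x3"):
            cl.scharr_noise_score(np.ones((2, 2)))


class TestFindPeaks:
    def test_worked_example(self):
        pk = cl.find_peaks(np.array([0.0, 2.0, 1.0, 3.0, 0.0]))
        assert list(pk["bin"]) == [1, 3]
        np.testing.assert_allclose(pk["prominence"], [1.0, 3.0])

    def test_monotone_has_no_peaks(self):
        assert len(cl.find_peaks(np.arange(6.0))) == 0
        assert len(cl.find_peaks(-np.arange(6.0))) == 0

    def test_nan_splits_segments(self):
        x = np.array([0, 2, 0, np.nan, 0, 3, 0], dtype=float)
        pk = cl.find_peaks(x)
        assert list(pk["bin"]) == [1, 5]
        np.testing.assert_allclose(pk["prominence"], [2.0, 3.0])

    def test_plateau_reports_leftmost(self):
        pk = cl.find_peaks(np.array([0.0, 1.0, 1.0, 1.0, 0.0]))
        assert list(pk["bin"]) == [1]

    def test_all_nan_errors(self):
        with pytest.raises(ValueError, match="all-NaN"):
            cl.find_peaks(np.array([np.nan, np.nan]))

    def test_exhaustive_contour_oracle_short_signals(self):
        # every signal of length <= 7 over {0,1,2,3}
        for m in range(2, 8):
            for vals in itertools.product(range(4), repeat=m):
                signal = np.array(vals, dtype=float)
                got = [
                    (int(b), h, p)
                    for b, h, p in cl.find_peaks(signal).itertuples(index=False)
                ]
                assert got == prominence_oracle(signal), signal

    def test_contour_oracle_random_longer_signals(self):
        rng = np.random.default_rng(5)
        for _ in range(300):
            m = rng.integers(8, 13)
            signal = rng.integers(0, 4, size=m).astype(float)
            got = [
                (int(b), h, p)
                for b, h, p in cl.find_peaks(signal).itertuples(index=False)
            ]
            assert got == prominence_oracle(signal), signal


class TestLiThreshold:
    def test_bimodal_between_modes(self):
        v = np.array([1, 1, 1, 10, 10, 10], dtype=float)
        t = cl.li_threshold(v)
        assert 1 < t < 10
        # the returned threshold attains the brute-force minimum cross-entropy
        assert cross_entropy(v, t) == pytest.approx(li_oracle_eta(v))

    def test_all_equal_errors(self):
        with pytest.raises(ValueError):
            cl.li_threshold([2.0, 2.0, 2.0])

    def test_nonpositive_errors(self):
        with pytest.raises(ValueError, match="positive"):
            cl.li_threshold([-1.0, 2.0])

    def test_matches_brute_force_on_random_samples(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            v = np.concatenate(
                [
                    rng.lognormal(0.0, 0.4, size=rng.integers(10, 40)),
                    rng.lognormal(2.0, 0.3, size=rng.integers(5, 20)),
                ]
            )
            t = cl.li_threshold(v)
            eta_star = li_oracle_eta(v)
            assert cross_entropy(v, t) <= eta_star + 1e-6 * abs(eta_star)

    def test_two_gaussians_between_means(self):
        rng = np.random.default_rng(7)
        v = np.concatenate([rng.normal(2, 0.2, 50), rng.normal(9, 0.5, 50)])
        t = cl.li_threshold(v)
        assert 2 < t < 9
        assert cross_entropy(v, t) == pytest.approx(li_oracle_eta(v), rel=1e-3)

    def test_agrees_with_skimage_on_separation(self):
        # skimage iterates on the continuous criterion and can stop at a
        # different point of the gap; both must land strictly inside it
        from skimage.filters import threshold_li

        rng = np.random.default_rng(8)
        v = np.concatenate([rng.uniform(1, 2, 200), rng.uniform(8, 12, 100)])
        mine, theirs = cl.li_threshold(v), threshold_li(v)
        assert 2 < mine < 8 and 2 < theirs < 8
        assert (v <= mine).sum() == (v <= theirs).sum()


class TestSmoothTrack:
    def test_nan_aware(self):
        x = np.array([1.0, np.nan, 3.0])
        out = cl.smooth_track(x, 3)
        assert out[1] == pytest.approx(2.0)

    def test_noop_for_k1(self):
        x = np.array([1.0, 2.0])
        np.testing.assert_array_equal(cl.smooth_track(x, 1), x)


class TestCallFountains:
    @pytest.fixture(scope="class")
    def decoy_run(self, wedge_mask):
        spec = fx.default_fixture_spec(
            seed=5,
            n_fountains=10,
            total_length_bp=50_000_000,
            n_chroms=2,
            coverage=2.5e6,
            n_artifacts=0,
        )
        # two replicate-discordant decoys: implanted only in replicate 0 at
        # double strength so the merged map still shows them
        decoys = pd.DataFrame(
            {
                "chrom": ["chr1", "chr2"],
                "pos": [20_000_000, 5_000_000],
                "strength": [2.0, 2.0],
                "half_angle_deg": [30.0, 30.0],
                "extent_bp": [200_000, 200_000],
                "replicate": [0, 0],
            }
        )
        spec.fountains["replicate"] = np.nan
        spec.fountains = pd.concat([spec.fountains, decoys], ignore_index=True)
        data = fx.generate(spec)
        reps_b = [cd.ice_balance(r) for r in data.replicates]
        merged = cd.ice_balance(fx.merge_replicates(data.replicates))
        params = cl.CallerParams(filter_scharr=False, filter_control=False)
        calls = cl.call_fountains(reps_b, merged, wedge_mask, params=params)
        return spec, data, calls

    def test_decoys_flagged_replicate20(self, decoy_run):
        spec, data, calls = decoy_run
        decoy_bins = {("chr1", 2000), ("chr2", 500)}
        flagged = set()
        for _, row in calls.iterrows():
            for c, b in decoy_bins:
                if row["chrom"] == c and abs(row["bin"] - b) <= 2:
                    assert "replicate20" in row["flags"]
                    flagged.add((c, b))
        assert flagged == decoy_bins

    def test_consistent_fountains_pass(self, decoy_run):
        spec, data, calls = decoy_run
        passed = calls[calls["passed"]]
        ev = fx.evaluate_calls(passed, data.truth, 2, 10_000)
        assert ev.recall >= 0.8

    def test_replicate_binning_mismatch(self, wedge_mask, powerlaw_map):
        m = cd.ice_balance(powerlaw_map)
        other = cd.ContactMap(
            20_000, {"chrA": 100_000}, {"chrA": np.ones((5, 5))}
        )
        with pytest.raises(ValueError, match="mismatch"):
            cl.call_fountains([other], m, wedge_mask)


class TestFilterFlagsOnFixture:
    def test_badbin_flag_matches_distance_rule(self, e2e):
        merged = e2e["merged"]
        for _, row in e2e["calls"].iterrows():
            bad = np.flatnonzero(merged.bad_bins(row["chrom"]))
            d = np.abs(bad - row["bin"]).min() * merged.resolution
            assert (d < 50_000) == ("badbin50" in row["flags"])

    def test_negative_corr_flag_matches_sign(self, e2e):
        for _, row in e2e["calls"].iterrows():
            assert (row["fountain_score"] < 0) == (
                "negative_corr" in row["flags"]
            )

    def test_passed_iff_no_flags(self, e2e):
        for _, row in e2e["calls"].iterrows():
            assert row["passed"] == (row["flags"] == ".")
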