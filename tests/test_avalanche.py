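"""Peak detection, avalanche size/lifetime, and distribution estimation."""

import numpy as np
import pytest

from mregaval.avalanche import (
    Peak,
    avalanche_lifetime,
    avalanche_size,
    build_records,
    detect_peaks,
    estimate_distribution,
    filter_motion_peaks,
    peak_threshold,
)
from mregaval.motion import SpeedSeries, exclusion_mask
from mregaval.physio import CleanSeries


def series(values):
    return CleanSeries(values=np.asarray(values, dtype=float), fs_hz=10.0)


def oracle_detect(values, threshold, min_dist):
    """Independent brute-force reference: enumerate strict local maxima
    (plateaus -> leftmost sample), then greedily keep by descending value,
    earlier index first on ties."""
    T = len(values)
    cands = []
    for i in range(1, T - 1):
        if values[i] <= threshold:
            continue
        # previous strictly-different value
        j = i - 1
        while j >= 0 and values[j] == values[i]:
            j -= 1
        k = i + 1
        while k < T and values[k] == values[i]:
            k += 1
        left_ok = j >= 0 and values[j] < values[i] and values[i - 1] != values[i]
        right_ok = k < T and values[k] < values[i]
        if left_ok and right_ok:
            cands.append(i)
    chosen = []
    for i in sorted(cands, key=lambda i: (-values[i], i)):
        if all(abs(i - c) >= min_dist for c in chosen):
            chosen.append(i)
    return sorted(chosen)


class TestThreshold:
    def test_k_times_sd(self, rng):
        vals = rng.normal(0, 2.0, 200000)
        thr = peak_threshold(series(vals), 1.5)
        assert thr == pytest.approx(3.0, rel=0.02)

    def test_k_zero(self, rng):
        assert peak_threshold(series(rng.normal(size=100)), 0.0) == 0.0

    def test_standardized_series(self, rng):
        v = rng.normal(size=5000)
        v = (v - v.mean()) / v.std(ddof=1)
        assert peak_threshold(series(v), 1.5) == pytest.approx(1.5, abs=1e-9)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            peak_threshold(series(np.ones(10)), 1.5)


class TestDetectPeaks:
    def test_all_zero_no_peaks(self):
        assert detect_peaks(series(np.zeros(100)), 0.5) == []

    def test_greedy_min_distance_example(self):
        v = np.zeros(1000)
        v[100], v[130], v[600] = 5.0, 4.0, 3.0
        peaks = detect_peaks(series(v), threshold=1.0, min_dist=50)
        assert [p.index for p in peaks] == [100, 600]

    def test_equal_maxima_earlier_kept(self):
        v = np.zeros(100)
        v[40] = v[50] = 2.0
        peaks = detect_peaks(series(v), threshold=1.0, min_dist=50)
        assert [p.index for p in peaks] == [40]

    def test_peak_fields(self):
        v = np.zeros(100)
        v[30] = 2.5
        (p,) = detect_peaks(series(v), threshold=1.0)
        assert p.index == 30 and p.value == 2.5 and p.time_s == pytest.approx(3.0)

    def test_plateau_takes_leftmost(self):
        v = np.zeros(100)
        v[20:23] = 2.0
        peaks = detect_peaks(series(v), threshold=1.0, min_dist=5)
        assert [p.index for p in peaks] == [20]

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_bruteforce_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = np.round(rng.normal(size=500), 2)  # rounding induces ties/plateaus
        got = [p.index for p in detect_peaks(series(v), 0.8, min_dist=20)]
        assert got == oracle_detect(v, 0.8, 20)

    @pytest.mark.parametrize("seed", range(5))
    def test_minimum_distance_invariant(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=2000)
        idx = [p.index for p in detect_peaks(series(v), 0.5, min_dist=50)]
        gaps = np.diff(idx)
        assert (gaps >= 50).all()


class TestMotionFilter:
    def make_mask(self, T=2000, flag_at=1000):
        trans = np.zeros(T)
        trans[flag_at] = 0.5
        return exclusion_mask(
            SpeedSeries(trans, np.zeros(T)), pre=50, post=100,
            exclude_boundaries=False,
        )

    def test_empty_mask_keeps_all(self):
        mask = exclusion_mask(
            SpeedSeries(np.zeros(2000), np.zeros(2000)), exclude_boundaries=False
        )
        peaks = [Peak(100, 2.0, 10.0), Peak(500, 3.0, 50.0)]
        kept, rejected = filter_motion_peaks(peaks, mask)
        assert kept == peaks and rejected == []

    def test_peak_whose_crop_contains_motion_rejected(self):
        mask = self.make_mask()
        kept, rejected = filter_motion_peaks([Peak(950, 2.0, 95.0)], mask)
        assert kept == [] and len(rejected) == 1

    def test_peak_clear_of_motion_kept(self):
        mask = self.make_mask()
        kept, rejected = filter_motion_peaks([Peak(849, 2.0, 84.9)], mask)
        assert len(kept) == 1 and rejected == []


class TestLifetimeAndSize:
    def test_run_around_peak(self):
        v = [0.0, 0.2, 1.1, 2.0, 1.3, 0.9, 0.0]
        span = avalanche_lifetime(series(v), Peak(3, 2.0, 0.3), threshold=1.0)
        assert span == (2, 4)
        assert avalanche_size(series(v), span) == pytest.approx(4.4)

    def test_isolated_sample_lifetime_one(self):
        v = np.zeros(50)
        v[20] = 3.0
        span = avalanche_lifetime(series(v), Peak(20, 3.0, 2.0), 1.0)
        assert span == (20, 20)
        assert avalanche_size(series(v), span) == 3.0

    def test_run_clipped_at_series_start(self):
        v = np.array([2.0, 1.5, 1.2, 0.5])
        span = avalanche_lifetime(series(v), Peak(0, 2.0, 0.0), 1.0)
        assert span == (0, 2)

    def test_boundary_value_included(self):
        # "no value falls under the threshold": equality stays in the run
        v = np.array([0.0, 1.0, 2.0, 1.0, 0.0])
        span = avalanche_lifetime(series(v), Peak(2, 2.0, 0.2), 1.0)
        assert span == (1, 3)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_linear_scan_oracle(self, seed):
        rng = np.random.default_rng(seed)
        v = rng.normal(size=300)
        thr = 0.5
        for p in detect_peaks(series(v), thr, min_dist=10):
            span = avalanche_lifetime(series(v), p, thr)
            # oracle: maximal contiguous run of values >= thr containing p
            lo = p.index
            while lo > 0 and v[lo - 1] >= thr:
                lo -= 1
            hi = p.index
            while hi < v.size - 1 and v[hi + 1] >= thr:
                hi += 1
            assert span == (lo, hi)
            assert np.all(v[span[0] : span[1] + 1] >= thr)
            size = avalanche_size(series(v), span)
            assert size >= (span[1] - span[0] + 1) * thr
            assert size >= abs(p.value)

    def test_records_table(self):
        v = np.zeros(600)
        v[100], v[300] = 3.0, 2.5
        cs = series(v)
        peaks = detect_peaks(cs, 1.0)
        recs = build_records(cs, peaks, 1.0)
        assert [r.lifetime_samples for r in recs] == [1, 1]
        from mregaval.avalanche import records_to_table

        table = records_to_table(recs, component=2)
        assert list(table["peak_index"]) == [100, 300]
        assert (table["component"] == 2).all()


class TestDistribution:
    def sample_power_law(self, n, alpha=2.0, xmin=1.0, xmax=1000.0, seed=0):
        rng = np.random.default_rng(seed)
        u = rng.uniform(size=n)
        # inverse CDF of truncated pareto
        a = 1 - alpha
        return (xmin**a + u * (xmax**a - xmin**a)) ** (1 / a)

    def test_mle_recovers_exponent(self):
        x = self.sample_power_law(10_000)
        est = estimate_distribution(x, kind="size")
        # closed-form check of the MLE itself
        closed = 1 + x.size / np.sum(np.log(x / x.min()))
        assert est.exponent_mle == pytest.approx(closed, rel=1e-12)
        assert est.exponent_mle == pytest.approx(2.0, abs=0.05)

    def test_ls_exponent_near_mle_for_clean_power_law(self):
        x = self.sample_power_law(10_000)
        est = estimate_distribution(x)
        assert est.exponent_ls == pytest.approx(est.exponent_mle, abs=0.35)

    def test_scale_invariance(self):
        x = self.sample_power_law(5000, seed=3)
        a = estimate_distribution(x).exponent_mle
        b = estimate_distribution(x * 37.5).exponent_mle
        assert a == pytest.approx(b, rel=1e-9)

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError, match="at least 10"):
            estimate_distribution(np.arange(1, 10))

    def test_degenerate_equal_values_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            estimate_distribution(np.full(20, 3.0))

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            estimate_distribution(np.linspace(-1, 5, 20))

    def test_densities_normalized(self):
        x = self.sample_power_law(2000, seed=1)
        est = estimate_distribution(x)
        widths = np.diff(
            np.logspace(np.log10(x.min()), np.log10(x.max()), est.bin_centers.size + 1)
        )
        assert np.sum(est.densities * widths) == pytest.approx(1.0, abs=0.01)
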