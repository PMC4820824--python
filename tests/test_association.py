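"""Correlation dissection, conditional maps, contrasts, ACF and XCF."""

import numpy as np
import pandas as pd
import pytest

import seqbind as sb

from conftest import as_track, flat_grid


class TestPearson:
    def test_perfect_linear(self):
        x = as_track(np.arange(10.0))
        y = as_track(2 * np.arange(10.0) + 1)
        r, n = sb.pearson_correlation(x, y)
        assert r == pytest.approx(1.0)
        assert n == 10

    def test_independent_null(self, rng):
        x = as_track(rng.normal(size=100_000))
        y = as_track(rng.normal(size=100_000))
        r, _ = sb.pearson_correlation(x, y)
        assert abs(r) < 0.01

    def test_matches_two_pass_oracle(self, rng):
        xv, yv = rng.normal(size=500), rng.normal(size=500)
        r, _ = sb.pearson_correlation(as_track(xv), as_track(yv))
        mx, my = xv.mean(), yv.mean()
        oracle = ((xv - mx) * (yv - my)).sum() / np.sqrt(
            ((xv - mx) ** 2).sum() * ((yv - my) ** 2).sum()
        )
        assert r == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            sb.pearson_correlation(as_track([1.0, 1, 1]), as_track([1.0, 2, 3]))

    def test_undefined_bins_excluded(self):
        x = as_track([1.0, np.nan, 3, 4, 5])
        y = as_track([2.0, 7, 6, np.nan, 10])
        r, n = sb.pearson_correlation(x, y)
        assert n == 3


class TestPartial:
    def test_common_cause_removed(self, rng):
        n = 100_000
        z = rng.normal(size=n)
        x = as_track(z + rng.normal(size=n))
        y = as_track(z + rng.normal(size=n))
        zt = as_track(z)
        r_marg, _ = sb.pearson_correlation(x, y)
        r_part, _ = sb.partial_correlation(x, y, [zt])
        assert r_marg > 0.3
        assert abs(r_part) < 0.02

    def test_no_controls_reduces_to_pearson(self, rng):
        x = as_track(rng.normal(size=200))
        y = as_track(rng.normal(size=200))
        assert sb.partial_correlation(x, y, []) == sb.pearson_correlation(x, y)

    def test_formula_equals_residual_path(self, rng):
        for _ in range(5):
            base = rng.normal(size=300)
            x = as_track(base + rng.normal(size=300))
            y = as_track(0.5 * base + rng.normal(size=300))
            z = as_track(base + 0.3 * rng.normal(size=300))
            r1, _ = sb.partial_correlation(x, y, [z], method="formula")
            r2, _ = sb.partial_correlation(x, y, [z], method="residual")
            assert r1 == pytest.approx(r2, abs=1e-10)

    def test_degenerate_control_rejected(self, rng):
        xv = rng.normal(size=100)
        x = as_track(xv)
        y = as_track(rng.normal(size=100))
        with pytest.raises(ValueError):
            sb.partial_correlation(x, y, [as_track(2 * xv + 1)])


class TestConditionalMap:
    def make_features(self, gc, cpg):
        grid = flat_grid(len(gc))
        n = grid.n_bins
        return sb.FeatureTable(
            grid,
            np.asarray(gc, float),
            np.asarray(cpg, float),
            np.zeros(n),
            {},
            {},
            np.ones(n, dtype=bool),
        )

    def test_constant_signal_gives_unit_cells(self, rng):
        gc = rng.uniform(0.3, 0.6, 5000)
        cpg = rng.uniform(0.0, 0.1, 5000)
        ft = self.make_features(gc, cpg)
        cmap = sb.conditional_enrichment_map(
            ft, sb.SignalTrack(ft.grid, np.ones(5000)), min_count=10
        )
        vals = cmap.mean[~cmap.masked & (cmap.count > 0)]
        np.testing.assert_allclose(vals, 1.0)

    def test_counts_conserved(self, rng):
        gc = rng.uniform(0.2, 0.8, 3000)
        cpg = rng.uniform(0.0, 0.2, 3000)
        ft = self.make_features(gc, cpg)
        cmap = sb.conditional_enrichment_map(
            ft, sb.SignalTrack(ft.grid, rng.normal(1, 0.1, 3000)), min_count=5
        )
        assert cmap.count.sum() == 3000

    def test_gc_only_signal_constant_across_cpg(self, rng):
        n = 60_000
        gc = rng.uniform(0.3, 0.6, n)
        cpg = np.clip(0.05 + 0.2 * (gc - 0.45) + rng.normal(0, 0.02, n), 0, 0.5)
        sig = 1.0 + 2.0 * gc + rng.normal(0, 0.05, n)
        ft = self.make_features(gc, cpg)
        cmap = sb.conditional_enrichment_map(
            ft, sb.SignalTrack(ft.grid, sig), gc_res=0.05, cpg_res=0.02, min_count=100
        )
        for gi in range(cmap.mean.shape[0]):
            row = cmap.mean[gi]
            cnt = cmap.count[gi]
            ok = np.isfinite(row)
            if ok.sum() < 2:
                continue
            # within a GC row, cell means agree within a few standard errors
            se = 0.05 / np.sqrt(np.maximum(cnt[ok], 1)) + 2.0 * 0.05 / np.sqrt(12)
            spread = row[ok].max() - row[ok].min()
            assert spread < 2 * 2.0 * 0.05 + 6 * se.max()

    def test_mask_monotone_in_min_count(self, rng):
        gc = rng.uniform(0.3, 0.6, 2000)
        cpg = rng.uniform(0.0, 0.1, 2000)
        ft = self.make_features(gc, cpg)
        sig = sb.SignalTrack(ft.grid, np.ones(2000))
        m10 = sb.conditional_enrichment_map(ft, sig, min_count=10).masked
        m50 = sb.conditional_enrichment_map(ft, sig, min_count=50).masked
        assert not (m10 & ~m50).any()


class TestPeakFlank:
    def peaks(self):
        return pd.DataFrame(
            {"chrom": ["chrT", "chrT"], "start": [3000, 9000], "end": [4500, 10500]}
        )

    def test_uniform_signal(self, rng):
        n = 200
        sig = as_track(np.ones(n) + rng.normal(0, 1e-6, n))
        res = sb.peak_flank_contrast(self.peaks(), sig)
        assert res.fold == pytest.approx(1.0, abs=1e-4)
        assert 0 <= res.fraction_peak_higher <= 1

    def test_doubled_signal_inside_peaks(self, rng):
        n = 2000
        vals = 1.0 + 0.01 * rng.normal(size=n)
        grid = flat_grid(n)
        starts = np.arange(20, 1980, 100) * 150
        peaks = pd.DataFrame(
            {"chrom": "chrT", "start": starts, "end": starts + 10 * 150}
        )
        for s in starts:
            vals[s // 150 : s // 150 + 10] *= 2
        res = sb.peak_flank_contrast(peaks, sb.SignalTrack(grid, vals))
        assert res.fold == pytest.approx(2.0, rel=0.05)
        assert res.fraction_peak_higher == 1.0
        assert res.p_value < 0.05

    def test_flank_clipped_at_neighbouring_peak(self):
        # nearby peaks: flanks must stop at the neighbour
        n = 100
        vals = np.ones(n)
        grid = flat_grid(n)
        peaks = pd.DataFrame(
            {"chrom": ["chrT", "chrT"], "start": [3000, 4800], "end": [4500, 6000]}
        )
        vals[20:30] = 5.0  # peak 1 bins
        vals[32:40] = 9.0  # peak 2 bins
        res = sb.peak_flank_contrast(peaks, sb.SignalTrack(grid, vals))
        # interval-arithmetic oracle: peak1 flanks are [1500,3000) and
        # [4500,4800) (clipped at peak2), all background bins; peak2 flanks
        # are [4500,4800) and [6000,7200)
        row1 = res.per_peak.iloc[0]
        assert row1["peak_mean"] == pytest.approx(5.0)
        assert row1["flank_mean"] == pytest.approx(1.0)
        row2 = res.per_peak.iloc[1]
        assert row2["peak_mean"] == pytest.approx(9.0)
        assert row2["flank_mean"] == pytest.approx(1.0)

    def test_bookended_peaks_merge(self):
        sig = as_track(np.ones(100))
        peaks = pd.DataFrame(
            {"chrom": ["chrT", "chrT"], "start": [3000, 4500], "end": [4500, 6000]}
        )
        res = sb.peak_flank_contrast(peaks, sig)
        assert res.n_peaks == 1

    def test_merging_overlapping_peaks(self):
        n = 100
        sig = as_track(np.ones(n))
        peaks = pd.DataFrame(
            {"chrom": ["chrT", "chrT"], "start": [3000, 3600], "end": [3900, 4500]}
        )
        res = sb.peak_flank_contrast(peaks, sig)
        assert res.n_peaks == 1


class TestAutocorrelation:
    def test_iid_noise_hwhm_below_one_bin(self, rng):
        sig = as_track(rng.normal(size=50_000))
        res = sb.autocorrelation_hwhm(sig, max_lag=20)
        assert res.hwhm_bp <= 150

    def test_gaussian_bumps_closed_form(self, rng):
        # signal = sum of Gaussian bumps => autocorrelation Gaussian with
        # scale sigma*sqrt(2); HWHM = sigma*sqrt(2)*sqrt(2 ln 2)
        W, sigma_bp = 150, 600.0
        n = 40_000
        x = np.arange(n) * W
        centers = rng.choice(n * W, 600, replace=False)
        sig = np.zeros(n)
        for c in centers:
            lo = max(0, int((c - 5 * sigma_bp) // W))
            hi = min(n, int((c + 5 * sigma_bp) // W))
            sig[lo:hi] += np.exp(-0.5 * ((x[lo:hi] - c) / sigma_bp) ** 2)
        res = sb.autocorrelation_hwhm(as_track(sig), max_lag=30)
        expected = sigma_bp * np.sqrt(2.0) * np.sqrt(2 * np.log(2))
        assert res.hwhm_bp == pytest.approx(expected, abs=W)

    def test_boxcar_triangular_acf(self, rng):
        W = 150
        w_bins = 8  # boxcar width w => triangular ACF, HWHM = w/2
        n = 40_000
        sig = np.zeros(n)
        starts = rng.choice(n - w_bins, 400, replace=False)
        for s in starts:
            sig[s : s + w_bins] = 1.0
        res = sb.autocorrelation_hwhm(as_track(sig), max_lag=30)
        assert res.hwhm_bp == pytest.approx(w_bins * W / 2, abs=W)

    def test_no_crossing_flagged(self):
        sig = as_track(np.sin(np.arange(1000) / 5000.0))  # very slow trend
        res = sb.autocorrelation_hwhm(sig, max_lag=5)
        assert res.is_lower_bound


class TestCrossCorrelation:
    def test_self_correlation_peaks_at_zero(self, rng):
        a = as_track(rng.normal(size=5000))
        res = sb.cross_correlation(a, a, max_offset=10)
        assert res.argmax_bp == 0
        assert res.r_max == pytest.approx(1.0)

    def test_shift_detected(self, rng):
        v = rng.normal(size=5000)
        a = as_track(v)
        b = as_track(np.roll(v, 3))
        res = sb.cross_correlation(a, b, max_offset=10)
        assert res.argmax_bp == 3 * 150

    def test_independent_tracks_bounded(self, rng):
        n = 20_000
        a = as_track(rng.normal(size=n))
        b = as_track(rng.normal(size=n))
        res = sb.cross_correlation(a, b, max_offset=5)
        assert np.max(np.abs(res.r)) < 3 / np.sqrt(n)
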