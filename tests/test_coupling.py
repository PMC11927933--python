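"""Window scheme, weighted correlation, FC timeseries, and coupling statistics."""

import math

import numpy as np
import pytest

from dyncouple.bold import DEFAULT_NETWORKS, RoiTimeseries
from dyncouple.coupling import (
    FcSeries,
    adjusted_coupling,
    couple,
    cross_network_pairs,
    fc_timeseries,
    fisher_z,
    gaussian_taper,
    make_window_scheme,
    network_pairs,
    weighted_pearson,
)
from dyncouple.eeg import PowerSeries


class TestGaussianTaper:
    def test_half_maximum_at_half_fwhm_offset(self):
        w = gaussian_taper(60, 27.78)
        # center 29.5; offset 13.89 -> the discrete neighbours bracket 0.5
        assert w[43] > 0.5 > w[44]
        # unit continuous peak: discrete max is exactly the half-sample value
        # for even lengths, and exactly 1 for odd lengths
        sigma = 27.78 / (2 * np.sqrt(2 * np.log(2)))
        assert w.max() == pytest.approx(np.exp(-0.25 / (2 * sigma**2)))
        assert gaussian_taper(61, 27.78).max() == 1.0

    def test_huge_fwhm_approaches_uniform(self):
        w = gaussian_taper(5, 1e9)
        np.testing.assert_allclose(w, 1.0, atol=1e-12)

    def test_symmetry(self):
        w = gaussian_taper(60, 27.78)
        np.testing.assert_allclose(w, w[::-1], atol=1e-15)

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            gaussian_taper(60, 0.0)
        with pytest.raises(ValueError):
            gaussian_taper(1, 27.78)


class TestWindowScheme:
    def test_standard_run_yields_247_windows(self):
        scheme = make_window_scheme(306, 60, 1, 27.78, 1.8)
        assert scheme.n_windows == 247
        assert scheme.duration_seconds == pytest.approx(108.0)
        assert scheme.overlap_seconds == pytest.approx(106.2)

    def test_single_window_limit(self):
        assert make_window_scheme(60, 60, 1).n_windows == 1

    @pytest.mark.parametrize("n,length,step", [(100, 60, 2), (306, 60, 5)])
    def test_window_count_closed_form(self, n, length, step):
        scheme = make_window_scheme(n, length, step)
        assert scheme.n_windows == (n - length) // step + 1
        assert scheme.overlap_seconds == pytest.approx((length - step) * 1.8)

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError, match="shorter"):
            make_window_scheme(59, 60)


class TestWeightedPearson:
    def test_uniform_weights_match_plain_pearson(self, rng):
        # brute-force unweighted oracle on 1,000 random instances
        for _ in range(1000):
            n = int(rng.integers(3, 40))
            x = rng.standard_normal(n)
            y = rng.standard_normal(n)
            r_plain = np.corrcoef(x, y)[0, 1]
            r_w = weighted_pearson(x, y, np.ones(n))
            assert abs(r_w - r_plain) < 1e-12

    def test_perfect_linear_relations(self, rng):
        x = rng.standard_normal(30)
        w = rng.uniform(0.1, 2.0, 30)
        assert weighted_pearson(x, 2 * x + 3, w) == pytest.approx(1.0)
        assert weighted_pearson(x, -x, w) == pytest.approx(-1.0)

    def test_invariant_to_weight_rescaling(self, rng):
        x, y = rng.standard_normal((2, 50))
        w = rng.uniform(0.0, 1.0, 50)
        w[0] = 0.5
        assert weighted_pearson(x, y, w) == pytest.approx(
            weighted_pearson(x, y, 37.0 * w), abs=1e-14
        )

    def test_degenerate_inputs_rejected(self, rng):
        x = rng.standard_normal(10)
        with pytest.raises(ValueError, match="variance"):
            weighted_pearson(np.ones(10), x, np.ones(10))
        with pytest.raises(ValueError, match="weights"):
            weighted_pearson(x, x, -np.ones(10))


class TestFcTimeseries:
    @staticmethod
    def make_ts(values):
        labels = tuple(f"r{i}" for i in range(values.shape[1]))
        return RoiTimeseries(values, labels, 1.8)

    def test_duplicated_roi_gives_unit_correlation(self, rng):
        x = rng.standard_normal(306)
        ts = self.make_ts(np.column_stack([x, x]))
        scheme = make_window_scheme(306)
        fc = fc_timeseries(ts, scheme, [("r0", "r1")])[("r0", "r1")]
        np.testing.assert_allclose(fc.values, 1.0, atol=1e-10)
        assert fc.n_windows == 247

    def test_independent_noise_has_no_mean_coupling(self, rng):
        means = []
        scheme = make_window_scheme(306)
        for _ in range(30):
            ts = self.make_ts(rng.standard_normal((306, 2)))
            fc = fc_timeseries(ts, scheme, [("r0", "r1")])[("r0", "r1")]
            means.append(fc.values.mean())
        assert abs(np.mean(means)) < 0.1

    def test_weighted_and_plain_modes_differ(self, rng):
        ts = self.make_ts(rng.standard_normal((306, 2)))
        scheme = make_window_scheme(306)
        a = fc_timeseries(ts, scheme, [("r0", "r1")], weighted=True)
        b = fc_timeseries(ts, scheme, [("r0", "r1")], weighted=False)
        assert not np.allclose(a[("r0", "r1")].values, b[("r0", "r1")].values)

    def test_unknown_roi_rejected(self, rng):
        ts = self.make_ts(rng.standard_normal((306, 2)))
        with pytest.raises(KeyError, match="r9"):
            fc_timeseries(ts, make_window_scheme(306), [("r0", "r9")])


class TestFisherZ:
    def test_reference_values(self):
        assert fisher_z(0.0) == 0.0
        assert fisher_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert fisher_z(0.5) == pytest.approx(math.atanh(0.5))

    def test_odd_function(self, rng):
        for r in rng.uniform(-0.99, 0.99, 50):
            assert fisher_z(-r) == pytest.approx(-fisher_z(r))

    @pytest.mark.parametrize("r", [1.0, -1.0, 1.5])
    def test_out_of_range_rejected(self, r):
        with pytest.raises(ValueError):
            fisher_z(r)


class TestCouple:
    def test_identical_series_hits_fisher_error_path(self, rng):
        x = rng.standard_normal(247)
        with pytest.raises(ValueError, match="Fisher"):
            couple(x, x, lag_trs=0)

    @pytest.mark.parametrize("k", [0, 2, 5])
    def test_shifted_series_recovered_at_correct_lag(self, rng, k):
        base = rng.standard_normal(260)
        power = base[: 247]
        fc = np.roll(base, k)[:247] + rng.standard_normal(247) * 1e-6
        rs = {lag: couple(fc, power, lag_trs=lag).r for lag in range(6)}
        assert max(rs, key=rs.get) == k
        assert rs[k] > 0.999

    def test_null_coupling_width_matches_bartlett_oracle(self, rng):
        # Independent window-smoothed series have a wide null distribution:
        # var(r) ~ sum_k rho_a(k) rho_b(k) / n (Bartlett).  The empirical
        # null sd over seeds must match that closed form; smoothing by the
        # 60-epoch Gaussian taper inflates it far beyond the 1/sqrt(n)
        # naive width.
        from dyncouple.coupling import gaussian_taper

        w = gaussian_taper(60, 27.78)
        w = w / w.sum()
        rho = np.correlate(w, w, mode="full")
        rho = rho / rho.max()
        n_win = 247
        var_pred = np.sum(rho**2) / n_win
        rs = []
        for _ in range(300):
            a = np.convolve(rng.standard_normal(306), w, mode="valid")
            b = np.convolve(rng.standard_normal(306), w, mode="valid")
            rs.append(couple(a, b).r)
        sd = np.std(rs)
        assert 0.6 * np.sqrt(var_pred) < sd < 1.4 * np.sqrt(var_pred)
        # and far wider than the naive iid width
        assert sd > 3.0 / np.sqrt(n_win)

    def test_negative_lag_rejected(self, rng):
        a, b = rng.standard_normal((2, 247))
        with pytest.raises(ValueError, match="negative"):
            couple(a, b, lag_trs=-1)

    def test_insufficient_overlap_rejected(self, rng):
        a, b = rng.standard_normal((2, 12))
        with pytest.raises(ValueError, match="overlapping"):
            couple(a, b, lag_trs=5)

    def test_missing_windows_dropped_pairwise(self, rng):
        a, b = rng.standard_normal((2, 247))
        a[10:20] = np.nan
        rec = couple(a, b)
        assert rec.n_windows == 237

    def test_metadata_propagates(self, rng):
        fc = FcSeries(("vPCC", "lAG"), rng.uniform(-0.5, 0.5, 247))
        power = PowerSeries("alpha", rng.uniform(0.5, 1.5, 247), smoothed=True)
        rec = couple(fc, power, lag_trs=3)
        assert rec.pair == ("vPCC", "lAG")
        assert rec.band == "alpha"
        assert rec.lag_trs == 3
        assert rec.z == pytest.approx(math.atanh(rec.r))


class TestAdjustedCoupling:
    def test_arithmetic(self):
        assert adjusted_coupling(0.8, [0.2, 0.4]) == pytest.approx(0.5)
        assert adjusted_coupling(0.3, [0.0, 0.0]) == pytest.approx(0.3)

    def test_translation_invariance(self):
        base = adjusted_coupling(0.8, [0.2, 0.4])
        shifted = adjusted_coupling(0.8 + 0.7, [0.2 + 0.7, 0.4 + 0.7])
        assert shifted == pytest.approx(base)

    def test_empty_extra_set_rejected(self):
        with pytest.raises(ValueError):
            adjusted_coupling(0.5, [])


def test_network_pair_families():
    dmn = network_pairs(DEFAULT_NETWORKS, "DMN")
    extra = cross_network_pairs(DEFAULT_NETWORKS, "DMN", ("ECN", "SN"))
    assert len(dmn) == 10  # C(5, 2) within-DMN pairs
    assert len(extra) == 5 * 7  # DMN nodes x (ECN + SN) nodes
    assert all(a != b for a, b in dmn + extra)
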