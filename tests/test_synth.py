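"""Synthetic study generator: determinism, spectra, and ground-truth wiring."""

import dataclasses
import logging

import numpy as np
import pytest

from dyncouple import SimConfig
from dyncouple.coupling import fc_timeseries, make_window_scheme
from dyncouple.eeg import ALPHA_BAND, band_power_series
from dyncouple.synth import (
    null_config,
    simulate_bold,
    simulate_eeg,
    simulate_latent_state,
    simulate_study,
)

TARGET = ("vPCC", "lAG")


class TestLatentState:
    def test_fixed_seed_is_deterministic(self):
        a = simulate_latent_state(306, 0.02, 1.8, seed=1)
        b = simulate_latent_state(306, 0.02, 1.8, seed=1)
        np.testing.assert_array_equal(a, b)
        assert not np.array_equal(a, simulate_latent_state(306, 0.02, 1.8, seed=2))

    def test_standardised(self):
        s = simulate_latent_state(306, 0.02, 1.8, seed=3)
        assert abs(s.mean()) < 1e-12
        assert abs(s.std() - 1.0) < 1e-12

    @pytest.mark.parametrize("seed", [0, 7, 123])
    def test_power_concentrated_below_cutoff(self, seed):
        # periodogram oracle: fraction of spectral power below 0.02 Hz
        s = simulate_latent_state(306, 0.02, 1.8, seed=seed)
        freqs = np.fft.rfftfreq(306, d=1.8)
        pxx = np.abs(np.fft.rfft(s)) ** 2
        frac = pxx[freqs < 0.02].sum() / pxx.sum()
        assert frac > 0.9

    def test_rejects_degenerate_inputs(self):
        with pytest.raises(ValueError):
            simulate_latent_state(0, 0.02, 1.8, seed=1)
        with pytest.raises(ValueError, match="Nyquist"):
            simulate_latent_state(306, 0.5, 1.8, seed=1)  # above 1/(2*tr)


class TestSimulateBold:
    def test_same_seed_bit_identical(self):
        cfg = SimConfig()
        lat = simulate_latent_state(306, 0.02, 1.8, seed=1)
        a, _ = simulate_bold(lat, cfg, "active", "post", seed=9)
        b, _ = simulate_bold(lat, cfg, "active", "post", seed=9)
        np.testing.assert_array_equal(a.values, b.values)

    def test_true_rho_is_linear_in_latent(self):
        cfg = dataclasses.replace(SimConfig(), coupling_gain_bold=0.4)
        lat = simulate_latent_state(306, 0.02, 1.8, seed=2)
        _, truth = simulate_bold(lat, cfg, "active", "post", seed=3)
        rho = truth.true_rho[TARGET]
        if truth.n_rho_clipped == 0:
            r = np.corrcoef(rho, lat)[0, 1]
            assert r == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.abs(rho) < 1.0)

    def test_zero_effect_fc_uncoupled_from_latent(self):
        # Monte-Carlo: with no injected effect the windowed FC of the target
        # pair shows no systematic correlation with the latent state.
        cfg = null_config(SimConfig())
        scheme = make_window_scheme(306, tr=cfg.tr)
        w = scheme.taper / scheme.taper.sum()
        rs = []
        for seed in range(100):
            lat = simulate_latent_state(306, 0.02, 1.8, seed=seed)
            ts, _ = simulate_bold(lat, cfg, "active", "post", seed=seed + 500)
            fc = fc_timeseries(ts, scheme, [TARGET])[TARGET].values
            lat_w = np.convolve(lat, w, mode="valid")
            rs.append(np.corrcoef(fc, lat_w)[0, 1])
        assert abs(np.mean(rs)) < 0.1

    def test_extreme_effect_is_clipped_and_counted(self, caplog):
        cfg = dataclasses.replace(SimConfig(), coupling_gain_bold=2.0)
        lat = simulate_latent_state(306, 0.02, 1.8, seed=4)
        with caplog.at_level(logging.WARNING, logger="dyncouple.synth"):
            _, truth = simulate_bold(lat, cfg, "active", "post", seed=5)
        assert truth.n_rho_clipped > 0
        assert any("clipped" in rec.message for rec in caplog.records)
        assert np.all(np.abs(truth.true_rho[TARGET]) < 1.0)


class TestSimulateEeg:
    def test_gamma_zero_power_uncorrelated_with_latent(self):
        cfg = dataclasses.replace(SimConfig(), coupling_gain_alpha=0.0)
        rs = []
        for seed in range(100):
            lat = simulate_latent_state(306, 0.02, 1.8, seed=seed)
            eeg = simulate_eeg(lat, cfg, seed=seed + 1000)
            power = band_power_series(eeg, ALPHA_BAND).values
            rs.append(np.corrcoef(power, lat)[0, 1])
        assert abs(np.mean(rs)) < 0.03

    def test_gamma_half_power_tracks_latent(self):
        cfg = SimConfig()  # default gamma = 0.5
        rs = []
        for seed in range(100):
            lat = simulate_latent_state(306, 0.02, 1.8, seed=seed)
            eeg = simulate_eeg(lat, cfg, seed=seed + 2000)
            power = band_power_series(eeg, ALPHA_BAND).values
            rs.append(np.corrcoef(power, lat)[0, 1])
        assert np.mean(rs) > 0.5

    def test_noiseless_unmodulated_alpha_power_constant(self):
        # pure alpha generator: no background, no neighbouring rhythms
        cfg = dataclasses.replace(
            SimConfig(), coupling_gain_alpha=0.0, noise_sd=0.0,
            theta_amp=0.0, beta_amp=0.0,
        )
        lat = simulate_latent_state(306, 0.02, 1.8, seed=1)
        eeg = simulate_eeg(lat, cfg, seed=2)
        # raw (unnormalised) alpha power per epoch: constant up to the small
        # phase-dependent spectral leakage of the taper
        from dyncouple.eeg import multitaper_psd_array, band_mask

        freqs, psd = multitaper_psd_array(eeg.data[0], eeg.fs)
        p = psd[:, band_mask(freqs, ALPHA_BAND)].mean(axis=1)
        assert p.std() / p.mean() < 0.02

    def test_fixed_seed_bit_identical(self):
        cfg = SimConfig()
        lat = simulate_latent_state(306, 0.02, 1.8, seed=1)
        a = simulate_eeg(lat, cfg, seed=3)
        b = simulate_eeg(lat, cfg, seed=3)
        np.testing.assert_array_equal(a.data, b.data)

    def test_required_channels_present(self, default_eeg):
        for ch in ("P4", "P6", "P8", "PO4", "PO8", "O2"):
            assert ch in default_eeg.channel_labels
        assert default_eeg.n_samples == 450  # 250 Hz * 1.8 s


class TestSimulateStudy:
    def test_default_study_has_16_plus_16_subjects(self):
        design = simulate_study(SimConfig(seed=1, n_subjects_per_group=16)).design
        counts = design.groupby("group")["subject"].nunique()
        assert counts["active"] == 16 and counts["sham"] == 16
        assert set(design["session"]) == {"pre", "post"}

    def test_small_study_size(self, small_bundle):
        assert len(small_bundle.entries) == 2 * 2 * 2  # subjects x groups x sessions
        assert len(small_bundle.design) == 8

    def test_fixed_seed_reproducible(self, small_sim_config, small_bundle):
        again = simulate_study(small_sim_config)
        assert again.design.equals(small_bundle.design)
        key = ("A01", "post")
        np.testing.assert_array_equal(
            again.entries[key].eeg.data, small_bundle.entries[key].eeg.data
        )
        np.testing.assert_array_equal(
            again.entries[key].bold.values, small_bundle.entries[key].bold.values
        )

    def test_session_effect_signs(self, small_bundle):
        active_post = small_bundle.entries[("A01", "post")].truth
        sham_post = small_bundle.entries[("S01", "post")].truth
        pre = small_bundle.entries[("A01", "pre")].truth
        assert active_post.true_coupling_sign[TARGET] == 1
        assert sham_post.true_coupling_sign[TARGET] == -1
        assert pre.true_coupling_sign[TARGET] == 0


def test_config_rejects_fractional_samples_per_epoch():
    with pytest.raises(ValueError, match="integer number of samples"):
        SimConfig(eeg_fs=257.0)  # 257 * 1.8 is not an integer


def test_config_rejects_unknown_target_pair():
    with pytest.raises(ValueError, match="target pair"):
        SimConfig(target_pairs=(("vPCC", "nope"),))
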