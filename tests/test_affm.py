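"""Adaptive frequency filtering: spectra, gains, masks, fusion, training."""

import numpy as np
import pytest

from aftanet.affm import (FilterBank, forward_fft, filter_gains,
                          adaptive_mask, apply_filter, inverse_and_fuse,
                          affm_forward, AFFMLayer)
from aftanet.nn import Tensor, AdamW


class TestForwardFFT:
    def test_constant_signal_has_only_dc_energy(self):
        spec = forward_fft(np.full(16, 3.0))
        assert spec.P[0] == pytest.approx((16 * 3.0) ** 2)
        np.testing.assert_allclose(spec.P[1:], 0.0, atol=1e-20)

    def test_pure_fourier_mode_occupies_single_bin(self):
        n, k = 32, 5
        x = np.cos(2 * np.pi * k * np.arange(n) / n)
        spec = forward_fft(x)
        hot = np.flatnonzero(spec.P > 1e-12)
        assert hot.tolist() == [k]

    def test_parseval_identity(self):
        rng = np.random.default_rng(0)
        for n in (8, 15, 64):
            x = rng.normal(size=n)
            F = np.fft.fft(x)
            lhs = np.sum(x ** 2)
            rhs = np.sum(np.abs(F) ** 2) / n
            assert abs(lhs - rhs) / lhs < 1e-8

    def test_nonfinite_input_rejected(self):
        with pytest.raises(ValueError):
            forward_fft(np.array([1.0, np.nan]))


class TestFilterGains:
    def test_zero_weights_give_one_quarter_everywhere(self):
        bank = FilterBank(w_global=np.zeros(8), w_local=np.zeros(8))
        gg, gl, g = filter_gains(bank)
        np.testing.assert_allclose(gg, 0.5)
        np.testing.assert_allclose(g, 0.25)

    def test_saturated_weights_approach_one(self):
        bank = FilterBank(w_global=np.full(4, 50.0), w_local=np.full(4, 50.0))
        _, _, g = filter_gains(bank)
        np.testing.assert_allclose(g, 1.0, atol=1e-12)

    def test_monotone_in_each_weight(self):
        w = np.linspace(-3, 3, 9)
        bank_lo = FilterBank(w_global=w, w_local=np.zeros(9))
        bank_hi = FilterBank(w_global=w + 0.5, w_local=np.zeros(9))
        assert np.all(filter_gains(bank_hi)[2] > filter_gains(bank_lo)[2])

    def test_gains_strictly_inside_unit_interval(self):
        rng = np.random.default_rng(1)
        bank = FilterBank(w_global=rng.normal(size=16, scale=3),
                          w_local=rng.normal(size=16, scale=3))
        _, _, g = filter_gains(bank)
        assert np.all((g > 0) & (g < 1))


class TestAdaptiveMask:
    def test_direct_arithmetic_case(self):
        # P = [0,4,1,1], median 1, normalized ~ [0,4,1,1], theta=2 -> 0100
        spec = forward_fft(np.zeros(6))
        spec.P = np.array([0.0, 4.0, 1.0, 1.0])
        mask = adaptive_mask(spec, theta=2.0, epsilon=1e-12)
        np.testing.assert_array_equal(mask, [0, 1, 0, 0])

    def test_negative_threshold_keeps_everything(self):
        spec = forward_fft(np.random.default_rng(0).normal(size=32))
        np.testing.assert_array_equal(adaptive_mask(spec, theta=-1.0),
                                      np.ones(17))

    def test_uniform_power_all_pass_at_half_threshold(self):
        spec = forward_fft(np.zeros(8))
        spec.P = np.full(5, 7.0)
        np.testing.assert_array_equal(adaptive_mask(spec, theta=0.5),
                                      np.ones(5))

    def test_soft_mask_lies_in_unit_interval_and_tracks_hard(self):
        spec = forward_fft(np.random.default_rng(3).normal(size=64))
        soft = adaptive_mask(spec, theta=1.0, temperature=0.01)
        hard = adaptive_mask(spec, theta=1.0)
        assert np.all((soft >= 0) & (soft <= 1))
        # agreement away from the decision boundary; bins whose normalized
        # energy sits within the sigmoid's transition width may differ
        med = np.median(spec.P)
        far = np.abs(spec.P / (med + 1e-12) - 1.0) > 0.1
        np.testing.assert_allclose(soft[far], hard[far], atol=1e-3)

    def test_empty_spectrum_rejected(self):
        spec = forward_fft(np.zeros(4))
        spec.P = np.empty(0)
        with pytest.raises(ValueError):
            adaptive_mask(spec, theta=0.5)


class TestApplyFilterAndFuse:
    def test_identity_and_annihilation(self):
        spec = forward_fft(np.random.default_rng(0).normal(size=16))
        np.testing.assert_array_equal(
            apply_filter(spec, np.ones(9), np.ones(9)), spec.F)
        np.testing.assert_array_equal(
            apply_filter(spec, np.zeros(9), np.ones(9)), np.zeros(9))

    def test_linear_in_spectrum(self):
        rng = np.random.default_rng(1)
        s1, s2 = forward_fft(rng.normal(size=16)), forward_fft(rng.normal(size=16))
        mask = rng.random(9)
        g = rng.random(9)
        a, b = 2.0, -0.5
        combo = forward_fft(np.zeros(16))
        combo.F = a * s1.F + b * s2.F
        np.testing.assert_allclose(
            apply_filter(combo, mask, g),
            a * apply_filter(s1, mask, g) + b * apply_filter(s2, mask, g))

    def test_shape_mismatch_rejected(self):
        spec = forward_fft(np.zeros(16))
        with pytest.raises(ValueError):
            apply_filter(spec, np.ones(5), np.ones(9))

    def test_alpha_one_returns_input_exactly(self):
        x = np.random.default_rng(2).normal(size=20)
        F_hat = np.zeros(11, dtype=complex)
        np.testing.assert_array_equal(inverse_and_fuse(F_hat, x, 1.0), x)

    def test_alpha_zero_unit_filter_round_trips(self):
        x = np.random.default_rng(3).normal(size=20)
        spec = forward_fft(x)
        out = inverse_and_fuse(apply_filter(spec, np.ones(11), np.ones(11)),
                               x, 0.0)
        np.testing.assert_allclose(out, x, atol=1e-6)

    def test_ifft_fft_round_trip(self):
        x = np.random.default_rng(4).normal(size=33)
        np.testing.assert_allclose(np.fft.irfft(np.fft.rfft(x), n=33), x,
                                   atol=1e-8)


class TestAFFMForward:
    def _bank(self, n, **kw):
        bins = n // 2 + 1
        return FilterBank(w_global=np.zeros(bins), w_local=np.zeros(bins), **kw)

    def test_bypass_alpha_one_is_identity(self):
        H = np.random.default_rng(0).normal(size=(10, 3))
        bank = self._bank(10, alpha=1.0)
        np.testing.assert_array_equal(affm_forward(H, bank), H)

    def test_shape_preserved(self):
        H = np.random.default_rng(1).normal(size=(12, 5))
        out = affm_forward(H, self._bank(12, alpha=0.3))
        assert out.shape == H.shape

    def test_energy_non_expansion(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            x = rng.normal(size=24)
            spec = forward_fft(x)
            mask = rng.random(13)
            g = rng.random(13)
            x_hat = np.fft.irfft(apply_filter(spec, mask, g), n=24)
            assert np.sum(x_hat ** 2) <= np.sum(x ** 2) + 1e-12

    def test_linear_operator_when_mask_disabled_and_gains_fixed(self):
        # median-normalized energy is scale-invariant, so the hard mask is
        # too; with theta fixed the whole map is linear in H
        H = np.random.default_rng(3).normal(size=(16, 2))
        bank = self._bank(16, alpha=0.4, theta=-1.0)   # mask == all-ones
        a = 3.5
        np.testing.assert_allclose(affm_forward(a * H, bank),
                                   a * affm_forward(H, bank), atol=1e-10)

    def test_length_one_sequence_passes_through_with_warning(self, caplog):
        H = np.ones((1, 4))
        with caplog.at_level("WARNING"):
            out = affm_forward(H, self._bank(2), axis=-2)
        np.testing.assert_array_equal(out, H)
        assert "degenerate" in caplog.text


class TestAFFMLayer:
    def test_matches_functional_reference_in_eval(self):
        n, d = 12, 5
        H = np.random.default_rng(0).normal(size=(n, d))
        layer = AFFMLayer(n_ref_bins=n // 2 + 1, local_cutoff_fraction=0.0,
                          theta_init=0.8)
        bank = FilterBank(w_global=np.zeros(7), w_local=np.zeros(7),
                          theta=0.8, alpha=0.5)
        out, _ = layer.forward(Tensor(H), training=False)
        np.testing.assert_allclose(out.data, affm_forward(H, bank), atol=1e-10)

    def test_all_parameters_receive_gradients(self):
        layer = AFFMLayer(n_ref_bins=7, local_cutoff_fraction=0.0)
        H = Tensor(np.random.default_rng(1).normal(size=(12, 4)))
        out, gate = layer.forward(H, training=True)
        ((out * out).sum() + (gate * gate).sum()).backward()
        for name, p in layer.parameters().items():
            assert p.grad is not None and np.any(p.grad != 0), name

    def test_gate_is_mean_one_energy_profile(self):
        layer = AFFMLayer(n_ref_bins=9)
        H = Tensor(np.random.default_rng(2).normal(size=(16, 3)))
        _, gate = layer.forward(H, training=False)
        assert gate.shape == (16,)
        assert gate.data.mean() == pytest.approx(1.0, abs=1e-6)
        assert np.all(gate.data >= 0)

    def test_denoising_fit_suppresses_interference_bin(self):
        """200 gradient steps on clean+interference drive the gain at the
        interference bin strictly below the gain at the signal bin."""
        rng = np.random.default_rng(0)
        n, d = 32, 8
        t = np.arange(n)
        sig_bin, noise_bin = 3, 10
        clean = np.stack([np.sin(2 * np.pi * sig_bin * t / n
                                 + rng.uniform(0, 2 * np.pi))
                          for _ in range(d)], axis=1)
        interference = np.stack([0.8 * np.sin(2 * np.pi * noise_bin * t / n
                                              + rng.uniform(0, 2 * np.pi))
                                 for _ in range(d)], axis=1)
        noisy = clean + interference
        layer = AFFMLayer(n_ref_bins=n // 2 + 1, local_cutoff_fraction=0.0,
                          theta_init=-5.0)
        opt = AdamW(layer.parameters(), lr=0.05)
        for _ in range(200):
            out, _ = layer.forward(Tensor(noisy), training=True)
            diff = out - Tensor(clean)
            loss = (diff * diff).mean() + layer.theta_penalty()
            opt.zero_grad()
            loss.backward()
            opt.step()
        _, _, g = layer.gains_for(n)
        assert g.data[noise_bin] < g.data[sig_bin] - 0.5

    def test_invalid_construction_rejected(self):
        with pytest.raises(ValueError):
            AFFMLayer(n_ref_bins=0)
        with pytest.raises(ValueError):
            AFFMLayer(n_ref_bins=4, alpha_init=1.0)
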