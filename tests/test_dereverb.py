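"""WPE prediction filters and the late-reverberation post-filter."""

import numpy as np
import pytest

from ciderev.dereverb import (PostFilterConfig, PsdEstimate, WpeConfig,
                              late_reverb_postfilter, oracle_psd, wpe_dereverb)
from ciderev.spectral import SpectralFrames, StftConfig, analyze


def _frames_from_matrix(values, cfg=None):
    cfg = cfg or StftConfig()
    T = values.shape[0]
    return SpectralFrames(values, cfg,
                          original_length=(T - 1) * cfg.hop + cfg.window_length)


def _single_bin_ar(T=6000, delay=4, coef=0.8, bin_idx=5, seed=0):
    """x_t = d_t + coef * x_{t-delay} in one bin; oracle PSD |d|^2."""
    rng = np.random.default_rng(seed)
    d = (rng.normal(size=T) + 1j * rng.normal(size=T)) / np.sqrt(2)
    x = np.zeros(T, complex)
    for t in range(T):
        x[t] = d[t] + (coef * x[t - delay] if t >= delay else 0.0)
    cfg = StftConfig()
    vals = np.zeros((T, cfg.n_bins), complex)
    vals[:, bin_idx] = x
    lam = np.ones((T, cfg.n_bins))
    lam[:, bin_idx] = np.abs(d) ** 2
    return _frames_from_matrix(vals, cfg), PsdEstimate(lam), d


class TestWpe:
    def test_recovers_ar_coefficient(self):
        frames, lam, _ = _single_bin_ar()
        res = wpe_dereverb(frames, WpeConfig(delay=4, order=6), lam)
        g = res.filter.coefficients[5]
        assert g[0].real == pytest.approx(0.8, abs=1e-2)
        assert abs(g[0].imag) < 1e-2
        assert np.all(np.abs(g[1:]) < 5e-2)

    def test_white_noise_is_a_noop(self, rng):
        # no inter-frame correlation beyond the delay: nothing to predict
        T, cfg = 2000, StftConfig()
        vals = (rng.normal(size=(T, cfg.n_bins))
                + 1j * rng.normal(size=(T, cfg.n_bins)))
        frames = _frames_from_matrix(vals, cfg)
        res = wpe_dereverb(frames, WpeConfig(),
                           PsdEstimate(np.abs(vals) ** 2))
        rel = (np.linalg.norm(res.frames.values - vals)
               / np.linalg.norm(vals))
        assert rel < 0.05
        assert np.linalg.norm(res.filter.coefficients) < 1.0

    def test_gain_invariance_with_matched_psd(self):
        frames, lam, _ = _single_bin_ar(seed=2)
        cfg = WpeConfig(delay=4, order=6)
        out1 = wpe_dereverb(frames, cfg, lam).frames.values
        scaled = _frames_from_matrix(frames.values * 7.5, frames.config)
        lam2 = PsdEstimate(lam.values * 7.5 ** 2)
        out2 = wpe_dereverb(scaled, cfg, lam2).frames.values
        assert np.allclose(out2, 7.5 * out1, rtol=1e-10, atol=1e-10)

    def test_iterative_objective_non_increasing(self, sentences, ir_rt60_1):
        import scipy.signal
        wet = scipy.signal.fftconvolve(np.tile(sentences[0].samples, 2),
                                       ir_rt60_1.samples)
        res = wpe_dereverb(analyze(wet), WpeConfig(iterations=4))
        assert len(res.objective) == 4
        diffs = np.diff(res.objective)
        assert np.all(diffs <= 1e-8 * np.abs(res.objective[0]))

    def test_too_few_frames_raises(self):
        frames = _frames_from_matrix(
            np.zeros((10, StftConfig().n_bins), complex))
        with pytest.raises(ValueError, match="frames"):
            wpe_dereverb(frames, WpeConfig(delay=4, order=12))

    def test_psd_shape_mismatch_raises(self):
        frames, lam, _ = _single_bin_ar(T=500)
        with pytest.raises(ValueError, match="shape"):
            wpe_dereverb(frames, WpeConfig(),
                         PsdEstimate(lam.values[:-1]))

    def test_config_validation(self):
        for kwargs in ({"delay": 0}, {"order": 0}, {"iterations": 0},
                       {"psd_floor": 0.0}):
            with pytest.raises(ValueError):
                WpeConfig(**kwargs)


class TestOraclePsd:
    def test_zero_clean_gives_all_floor(self):
        frames = _frames_from_matrix(
            np.zeros((100, StftConfig().n_bins), complex))
        lam = oracle_psd(frames)
        assert np.all(lam.values > 0)
        assert np.ptp(lam.values) == 0.0

    def test_quadratic_scaling(self, rng):
        vals = rng.normal(size=(50, StftConfig().n_bins)) + 0j
        a = oracle_psd(_frames_from_matrix(vals)).values
        b = oracle_psd(_frames_from_matrix(3.0 * vals)).values
        assert np.allclose(b, 9.0 * a)


class TestPostFilter:
    def test_gains_bounded_for_any_input(self, rng):
        cfg = StftConfig()
        vals = (rng.normal(size=(300, cfg.n_bins))
                + 1j * rng.normal(size=(300, cfg.n_bins)))
        frames = _frames_from_matrix(vals, cfg)
        pf = PostFilterConfig(assumed_rt60=0.5, gain_floor=-12.0)
        out = late_reverb_postfilter(frames, pf).values
        floor = 10 ** (-12 / 20)
        ratio = np.abs(out) / np.maximum(np.abs(vals), 1e-300)
        assert np.all(ratio <= 1.0 + 1e-9)
        assert np.all(ratio >= floor - 1e-9)

    def test_no_removed_reverb_means_identity(self, rng):
        cfg = StftConfig()
        vals = rng.normal(size=(200, cfg.n_bins)) + 0j
        frames = _frames_from_matrix(vals, cfg)
        out = late_reverb_postfilter(
            frames, PostFilterConfig(assumed_rt60=1.0),
            reverb_psd=np.zeros_like(vals, dtype=float),
            reverb_span=(0.032, 0.128))
        assert np.allclose(out.values, vals)

    def test_config_validation(self):
        with pytest.raises(ValueError):
            PostFilterConfig(assumed_rt60=0.0)
        with pytest.raises(ValueError):
            PostFilterConfig(late_delay=0.0)
        with pytest.raises(ValueError):
            PostFilterConfig(gain_floor=3.0)

    def test_span_validation(self, rng):
        cfg = StftConfig()
        vals = rng.normal(size=(100, cfg.n_bins)) + 0j
        frames = _frames_from_matrix(vals, cfg)
        with pytest.raises(ValueError, match="reverb_span"):
            late_reverb_postfilter(frames, PostFilterConfig(),
                                   reverb_psd=np.abs(vals) ** 2,
                                   reverb_span=None)
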