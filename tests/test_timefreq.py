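"""Morlet wavelet power, baseline normalization, ROIs and flipping."""

import numpy as np
import pytest
from scipy.integrate import quad

from proctrl.preprocess import EpochSet
from proctrl.timefreq import (
    WaveletParams, morlet_mother, wavelet_kernel, cwt_power, condition_mean_energy,
    baseline_normalize, roi_band_timecourse, flip_hemispheres, min_usable_freq,
    TFRPower, ROISet,
)

SR = 250.0


def _epochs(data, ch_names=None):
    data = np.asarray(data, float)
    ch_names = ch_names or [f"ch{i}" for i in range(data.shape[1])]
    return EpochSet(data, SR, ch_names, -1.0, "cue")


class TestMotherWavelet:
    def test_value_at_zero(self):
        w = morlet_mother(0.0)
        assert w.real == pytest.approx(np.pi ** -0.5, abs=1e-12)
        assert w.imag == 0.0

    def test_envelope_even(self):
        t = np.linspace(-3, 3, 301)
        np.testing.assert_allclose(np.abs(morlet_mother(t)),
                                   np.abs(morlet_mother(-t)), rtol=1e-12)

    def test_energy_matches_closed_form(self):
        # integral of |w|^2 = (pi*f_b)^-1 * sqrt(pi*f_b/2) = 1/sqrt(2*pi*f_b)
        for f_b in (1.0, 2.0):
            num, _ = quad(lambda t: np.abs(morlet_mother(t, f_b)) ** 2, -20, 20)
            assert num == pytest.approx(1.0 / np.sqrt(2 * np.pi * f_b), abs=1e-6)


class TestCwtPower:
    def test_peak_frequency_recovery(self):
        t = np.arange(750) / SR
        sig = np.sin(2 * np.pi * 10.0 * t)
        eps = _epochs(sig[None, None, :])
        wp = WaveletParams(freqs=np.arange(4.0, 30.0))
        tfr = cwt_power(eps, wp)
        core = ~tfr.edge_mask
        mean_e = np.where(core, tfr.power[0, 0], np.nan)
        prof = np.nanmean(mean_e, axis=1)
        assert wp.freqs[np.nanargmax(prof)] == 10.0

    def test_zero_signal_zero_energy(self):
        tfr = cwt_power(_epochs(np.zeros((2, 1, 750))),
                        WaveletParams(freqs=np.arange(8.0, 20.0)))
        assert np.abs(tfr.power).max() == 0.0

    def test_amplitude_doubling_quadruples_energy(self):
        rng = np.random.default_rng(0)
        sig = rng.standard_normal((1, 1, 750))
        wp = WaveletParams(freqs=np.arange(8.0, 20.0))
        a = cwt_power(_epochs(sig), wp).power
        b = cwt_power(_epochs(2 * sig), wp).power
        np.testing.assert_allclose(b, 4 * a, rtol=1e-5)

    def test_too_low_frequency_errors_with_minimum(self):
        eps = _epochs(np.zeros((1, 1, 750)))
        wp = WaveletParams(freqs=np.array([0.3, 10.0]))
        with pytest.raises(ValueError, match="minimum usable frequency"):
            cwt_power(eps, wp)
        assert min_usable_freq(750, SR, wp) == pytest.approx(0.98, abs=0.01)

    def test_one_hz_runs_on_three_second_epochs(self):
        wp = WaveletParams(freqs=np.array([1.0, 10.0]))
        tfr = cwt_power(_epochs(np.zeros((1, 1, 750))), wp)
        assert tfr.edge_mask[0].mean() > 0.9  # 1 Hz almost fully edge-flagged
        assert tfr.edge_mask[1].mean() < 0.2

    def test_batched_condition_means_match_per_trial_path(self):
        rng = np.random.default_rng(1)
        data = rng.standard_normal((8, 2, 750))
        eps = _epochs(data)
        wp = WaveletParams(freqs=np.arange(9.0, 15.0))
        cond = np.array(["a", "b"] * 4, dtype=object)
        out = condition_mean_energy(eps, cond, wp)
        per = cwt_power(eps, wp).power
        for c in ("a", "b"):
            np.testing.assert_allclose(
                out[c].power, per[cond == c].mean(axis=0), rtol=2e-4)


class TestBaselineNormalize:
    def _flat_tfr(self, value):
        p = np.full((1, 2, 750), value)
        return TFRPower(p, np.array([10.0, 11.0]), -1.0 + np.arange(750) / SR,
                        ["a"], SR)

    def test_equal_to_baseline_gives_zero(self):
        out = baseline_normalize(self._flat_tfr(5.0))
        np.testing.assert_allclose(out.power, 0.0, atol=1e-12)

    def test_double_baseline_gives_plus_100(self):
        tfr = self._flat_tfr(3.0)
        post = tfr.times >= 0
        tfr.power[..., post] = 6.0
        out = baseline_normalize(tfr)
        np.testing.assert_allclose(out.power[..., post], 100.0, atol=1e-9)

    def test_degenerate_baseline_rejected(self):
        with pytest.raises(ValueError, match="baseline"):
            baseline_normalize(self._flat_tfr(0.0))

    def test_scale_invariance(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((6, 2, 750))
        wp = WaveletParams(freqs=np.arange(9.0, 15.0))
        cond = np.array(["x"] * 6, dtype=object)
        a = baseline_normalize(condition_mean_energy(_epochs(data), cond, wp)["x"], params=wp)
        b = baseline_normalize(condition_mean_energy(_epochs(7.5 * data), cond, wp)["x"], params=wp)
        np.testing.assert_allclose(a.power, b.power, rtol=1e-4, atol=1e-4)


class TestRoiTimecourse:
    def _tfr(self, power):
        n_ch, n_f, n_t = power.shape
        return TFRPower(power, 9.0 + np.arange(n_f), np.arange(n_t) / SR,
                        [f"c{i}" for i in range(n_ch)], SR)

    def test_single_electrode_single_bin_identity(self):
        rng = np.random.default_rng(3)
        p = rng.standard_normal((3, 4, 50))
        tfr = self._tfr(p)
        out = roi_band_timecourse(tfr, ["c1"], (10.0, 10.0))
        np.testing.assert_allclose(out, p[1, 1])

    def test_equal_channels_equal_mean(self):
        p = np.tile(np.arange(50.0), (4, 3, 1))
        out = roi_band_timecourse(self._tfr(p), ["c0", "c2"], (9.0, 11.0))
        np.testing.assert_allclose(out, p[0, 0])

    def test_matches_loop_oracle(self):
        rng = np.random.default_rng(4)
        p = rng.standard_normal((5, 6, 30))
        tfr = self._tfr(p)
        roi, band = ["c0", "c3", "c4"], (10.0, 12.0)
        out = roi_band_timecourse(tfr, roi, band)
        expect = np.zeros(30)
        n = 0
        for c in (0, 3, 4):
            for fi, f in enumerate(tfr.freqs):
                if band[0] <= f <= band[1]:
                    expect += p[c, fi]
                    n += 1
        np.testing.assert_allclose(out, expect / n, rtol=1e-12)

    def test_empty_band_raises(self):
        tfr = self._tfr(np.zeros((2, 3, 10)))
        with pytest.raises(ValueError, match="intersect"):
            roi_band_timecourse(tfr, ["c0"], (80.0, 90.0))


class TestFlipHemispheres:
    def test_double_flip_is_identity(self, montage):
        rng = np.random.default_rng(5)
        labels = montage.analysis_labels
        eps = _epochs(rng.standard_normal((4, len(labels), 20)), labels)
        which = np.array([True, False, True, False])
        out = flip_hemispheres(flip_hemispheres(eps, montage, which), montage, which)
        np.testing.assert_array_equal(out.data, eps.data)
        assert not out.flipped.any()

    def test_c3_value_moves_to_c4(self, montage):
        labels = montage.analysis_labels
        data = np.zeros((1, len(labels), 5))
        data[0, labels.index("C3")] = 1.0
        out = flip_hemispheres(_epochs(data, labels), montage, np.array([True]))
        assert out.data[0, labels.index("C4")].min() == 1.0
        assert out.data[0, labels.index("C3")].max() == 0.0

    def test_midline_untouched(self, montage):
        labels = montage.analysis_labels
        rng = np.random.default_rng(6)
        data = rng.standard_normal((2, len(labels), 8))
        out = flip_hemispheres(_epochs(data, labels), montage, np.array([True, True]))
        for lab in ("Fz", "Cz", "Pz"):
            np.testing.assert_array_equal(out.data[:, labels.index(lab)],
                                          data[:, labels.index(lab)])

    def test_lateralization_recovered_after_flip(self, montage):
        """Hand-locked lateralized pattern: flipping LHB trials aligns it."""
        labels = montage.analysis_labels
        rng = np.random.default_rng(7)
        n = 40
        hands = np.array(["right"] * (n // 2) + ["left"] * (n // 2))
        data = 0.1 * rng.standard_normal((n, len(labels), 10))
        # ipsilateral (same side as hand) C-electrode carries the signal
        for k, h in enumerate(hands):
            data[k, labels.index("C4" if h == "right" else "C3")] += 1.0
        eps = _epochs(data, labels)
        flipped = flip_hemispheres(eps, montage, hands == "left")
        li = (flipped.data[:, labels.index("C4")].mean()
              - flipped.data[:, labels.index("C3")].mean())
        li_rhb = (data[hands == "right", labels.index("C4")].mean()
                  - data[hands == "right", labels.index("C3")].mean())
        assert li == pytest.approx(li_rhb, abs=0.1)


class TestEnergyScaling:
    def test_white_noise_energy_linear_in_trials(self):
        rng = np.random.default_rng(8)
        wp = WaveletParams(freqs=np.arange(9.0, 15.0))
        totals, ns = [], [4, 8, 16, 32]
        for n in ns:
            data = rng.standard_normal((n, 1, 750))
            tfr = cwt_power(_epochs(data), wp)
            totals.append(tfr.power.sum())
        r = np.corrcoef(ns, totals)[0, 1]
        assert r ** 2 > 0.99


def test_default_roi_set_consistent(montage):
    rs = ROISet()
    for roi in rs.rois.values():
        for lab in roi:
            assert lab in montage.labels
    assert rs.bands["mu"] == (9.0, 14.0)
    assert rs.bands["beta"] == (15.0, 25.0)
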