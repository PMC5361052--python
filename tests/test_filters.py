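"""The five baseline-removal filters: oracles from designed transfer functions,
brute-force medians, spline exactness, and DWT energy accounting."""

import numpy as np
import numpy.testing as npt
import pytest
import pywt
from scipy.signal import freqz

import ecgbaseline as eb
from ecgbaseline.errors import (
    ContractError,
    InsufficientAnchorsError,
    InvalidParameterError,
)

FS = 512.0


def _cosine(freq, n=51200, fs=FS):
    return np.cos(2 * np.pi * freq * np.arange(n) / fs)


def _energy_ratio(out, sig, trim=2.0):
    r = eb.trim_boundaries(out, FS, trim)
    s = eb.trim_boundaries(sig, FS, trim)
    return float(np.sum(r ** 2) / np.sum(s ** 2))


@pytest.mark.parametrize("name", sorted(eb.FILTERS))
def test_length_preserved_and_time_measured(short_record, name):
    y = short_record.leads[0] + 0.3
    out = eb.apply_filter(name, y, FS, anchors=short_record.spline_anchors())
    assert out.x_hat.shape == y.shape
    assert out.elapsed >= 0.0


class TestButterworth:
    def test_dc_rejection(self):
        out = eb.butterworth_highpass(np.full(5120, 3.0), FS)
        assert np.abs(out.x_hat[512:-512]).max() < 1e-6 * 3.0

    def test_stopband_attenuation_matches_designed_response(self):
        # one decade below cutoff the order-2 high-pass falls 40 dB per pass;
        # forward+backward gives ~80 dB from the squared transfer function
        from ecgbaseline.filters import _butter_coeffs
        b, a = _butter_coeffs(2, 0.5, FS)
        _, h = freqz(b, a, worN=[2 * np.pi * 0.05 / FS])
        two_pass_db = 20 * np.log10(np.abs(h[0]) ** 2)
        assert abs(two_pass_db + 80.0) < 1.0
        measured = _energy_ratio(eb.butterworth_highpass(_cosine(0.05), FS).x_hat,
                                 _cosine(0.05), trim=5.0)
        assert 10 * np.log10(measured) < -60.0

    def test_passband_gain_unity_and_zero_phase(self):
        sig = _cosine(5.0, n=5120)
        out = eb.butterworth_highpass(sig, FS)
        interior = slice(1024, -1024)
        npt.assert_allclose(out.x_hat[interior], sig[interior], atol=0.01)
        # symmetric pulse stays symmetric under zero-phase filtering
        pulse = np.exp(-0.5 * ((np.arange(5120) - 2560) / 40.0) ** 2)
        filtered = eb.butterworth_highpass(pulse, FS).x_hat
        asymmetry = np.abs(filtered[:2560][::-1][:2000] - filtered[2561:2561 + 2000])
        assert asymmetry.max() < 1e-6 * np.abs(filtered).max()

    def test_linearity(self):
        rng = np.random.default_rng(0)
        x, y = rng.normal(size=(2, 4096))
        fa = eb.butterworth_highpass(2.0 * x + 0.5 * y, FS).x_hat
        fb = 2.0 * eb.butterworth_highpass(x, FS).x_hat \
            + 0.5 * eb.butterworth_highpass(y, FS).x_hat
        npt.assert_allclose(fa, fb, rtol=0, atol=1e-9 * np.abs(fb).max())

    def test_cutoff_beyond_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            eb.butterworth_highpass(np.zeros(100), FS, f_cut=300.0)


class TestMovingMedian:
    @staticmethod
    def _brute(y, n1, n2):
        def mm(v, w):
            half = w // 2
            return np.array([np.median(v[max(0, i - half): i + half + 1])
                             for i in range(len(v))])
        return y - mm(mm(y, n1), n2)

    def test_constant_removed_exactly(self):
        out = eb.moving_median_baseline(np.full(3000, 1.7), FS)
        npt.assert_array_equal(out.x_hat, 0.0)

    def test_matches_brute_force_double_median(self):
        rng = np.random.default_rng(1)
        y = rng.normal(size=60)
        out = eb.moving_median_baseline(y, fs=10.0, w1=0.5, w2=1.1)  # 5-, 11-sample
        npt.assert_array_equal(out.x_hat, self._brute(y, 5, 11))

    def test_sparse_impulse_train_untouched_in_interior(self):
        # impulses sparser than half the first window: medians see majority zeros
        y = np.zeros(60)
        y[10::12] = 1.0
        out = eb.moving_median_baseline(y, fs=10.0, w1=0.5, w2=1.1)
        npt.assert_array_equal(out.x_hat, self._brute(y, 5, 11))
        npt.assert_array_equal(out.x_hat[8:-8], y[8:-8])

    def test_pure_offset_removed_on_isoelectric_record(self, short_record):
        x = short_record.leads[0]
        out = eb.moving_median_baseline(x + 0.25, FS)
        base = eb.moving_median_baseline(x, FS)
        npt.assert_allclose(out.x_hat, base.x_hat, atol=1e-12)

    def test_refiltering_changes_little(self, short_record):
        once = eb.moving_median_baseline(short_record.leads[1] + 0.4, FS).x_hat
        twice = eb.moving_median_baseline(once, FS).x_hat
        assert np.sum((twice - once) ** 2) < 0.05 * np.sum(once ** 2)

    def test_window_longer_than_signal_rejected(self):
        with pytest.raises(InvalidParameterError):
            eb.moving_median_baseline(np.zeros(100), FS)


class TestSpline:
    def test_zero_anchor_values_leave_signal_untouched(self):
        rng = np.random.default_rng(2)
        y = rng.normal(size=2000)
        anchors = np.arange(100, 2000, 300)
        y[anchors] = 0.0
        out = eb.spline_baseline(y, FS, anchors)
        npt.assert_allclose(out.x_hat[anchors[0]:anchors[-1]],
                            y[anchors[0]:anchors[-1]], atol=1e-12)

    def test_reproduces_cubic_polynomial_exactly(self):
        t = np.arange(4000) / FS
        poly = 0.3 * t ** 3 - 1.2 * t ** 2 + 0.5 * t - 0.1
        anchors = np.arange(50, 4000, 350)
        out = eb.spline_baseline(poly, FS, anchors)
        interior = slice(anchors[0], anchors[-1])
        npt.assert_allclose(out.x_hat[interior], 0.0, atol=1e-9)

    def test_tracks_rendered_baseline_at_beat_rate_anchors(self, short_record,
                                                           spec_short):
        # anchors arrive at ~1 Hz, so the 0.5 Hz band edge sits at the anchor
        # Nyquist rate; most of the artifact is removed, a band-edge residual
        # remains
        b = eb.render(eb.draw_realization(spec_short, 3), spec_short)
        anchors = short_record.spline_anchors()
        out = eb.spline_baseline(b, FS, anchors)
        interior = slice(anchors[0], anchors[-1])
        assert np.mean(out.x_hat[interior] ** 2) < 0.15 * np.mean(b[interior] ** 2)

    def test_too_few_anchors_rejected(self):
        with pytest.raises(InsufficientAnchorsError):
            eb.spline_baseline(np.zeros(100), FS, [1, 2, 3])


class TestWaveletCancellation:
    def test_required_level_formula(self):
        assert eb.required_decomposition_level(512.0, 0.5) == 9

    def test_in_band_cosine_cancelled(self):
        sig = _cosine(0.2)
        out = eb.wavelet_cancellation(sig, FS)
        assert _energy_ratio(out.x_hat, sig) < 0.01

    def test_white_noise_loses_only_the_approximation_band(self):
        rng = np.random.default_rng(3)
        w = rng.normal(size=51200)
        out = eb.wavelet_cancellation(w, FS)
        ratio = np.sum(out.x_hat ** 2) / np.sum(w ** 2)
        assert abs(ratio - (1 - 0.5 / 256)) < 0.005

    def test_linearity(self):
        rng = np.random.default_rng(4)
        x, y = rng.normal(size=(2, 5120))
        fa = eb.wavelet_cancellation(3.0 * x - y, FS).x_hat
        fb = 3.0 * eb.wavelet_cancellation(x, FS).x_hat \
            - eb.wavelet_cancellation(y, FS).x_hat
        npt.assert_allclose(fa, fb, rtol=0, atol=1e-9 * np.abs(fb).max())

    def test_pad_and_trim_fallback_for_odd_lengths(self):
        sig = _cosine(0.2, n=5000)
        out = eb.wavelet_cancellation(sig, FS)
        assert out.x_hat.shape == sig.shape


class TestWaveletHighpass:
    def test_vaidyanathan_filter_bank_is_orthonormal(self):
        wav = eb.vaidyanathan_wavelet()
        h = np.asarray(wav.rec_lo)
        assert abs(h.sum() - np.sqrt(2)) < 1e-7
        assert abs((h ** 2).sum() - 1.0) < 1e-7
        for shift in range(1, len(h) // 2):
            assert abs(np.dot(h[:-2 * shift], h[2 * shift:])) < 1e-7
        rng = np.random.default_rng(5)
        v = rng.normal(size=512)
        coeffs = pywt.wavedec(v, wav, mode="periodization", level=3)
        npt.assert_allclose(pywt.waverec(coeffs, wav, mode="periodization"), v,
                            atol=1e-10)

    def test_constant_suppressed(self):
        out = eb.wavelet_highpass(np.ones(51200), FS)
        assert np.abs(out.x_hat).max() < 1e-2

    def test_detail_band_cosine_passes(self):
        sig = _cosine(5.0, n=5120)
        out = eb.wavelet_highpass(sig, FS)
        assert np.sum(out.x_hat ** 2) / np.sum(sig ** 2) > 0.95

    def test_deep_in_band_cosine_attenuated(self):
        sig = _cosine(0.05)
        out = eb.wavelet_highpass(sig, FS)
        assert np.sum(out.x_hat ** 2) / np.sum(sig ** 2) < 0.10

    def test_cutoff_above_subband_nyquist_rejected(self):
        with pytest.raises(InvalidParameterError):
            eb.wavelet_highpass(np.zeros(5120), FS, f_cut=1.5)


def test_every_filter_reduces_artifact_energy(short_record, spec_short):
    """On corrupted leads each method raises CC(clean, output) above no-filter."""
    anchors = short_record.spline_anchors()
    for snr_db in (-3.0, 3.0):
        improved = {name: [] for name in eb.FILTERS}
        baseline_cc = []
        for lead in (0, 5, 9):
            x = short_record.leads[lead]
            x_t = eb.trim_boundaries(x, FS)
            for seed in range(3):
                b = eb.render(eb.draw_realization(spec_short, 50 + seed), spec_short)
                b, _ = eb.scale_to_snr(b, x, snr_db)
                y = x + b
                y_t = eb.trim_boundaries(y, FS)
                baseline_cc.append(eb.correlation_coefficient(x_t, y_t))
                for name in eb.FILTERS:
                    out = eb.apply_filter(name, y, FS, anchors=anchors)
                    out_t = eb.trim_boundaries(out.x_hat, FS)
                    improved[name].append(eb.correlation_coefficient(x_t, out_t))
        for name, ccs in improved.items():
            assert np.median(ccs) > np.median(baseline_cc), name


def test_unknown_filter_name_rejected():
    with pytest.raises(InvalidParameterError):
        eb.apply_filter("fir", np.zeros(10), FS)
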