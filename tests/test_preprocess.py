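"""Preprocessing chain: despiking, baseline recovery, normalization, stability."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ramanstage import preprocess, synthetic
from ramanstage.datatypes import Spectrum
from ramanstage.preprocess import (
    PreprocessConfig,
    area_normalize,
    baseline_correct,
    despike,
    preprocess_set,
    resample,
)


def _gaussian_spectrum(center=1003.0, amp=1.0, fwhm=15.0):
    x = np.arange(300.0, 1801.0)
    sigma = fwhm / 2.3548200450309493
    return Spectrum(x, amp * np.exp(-0.5 * ((x - center) / sigma) ** 2))


class TestResample:
    def test_identity_on_own_axis(self):
        s = _gaussian_spectrum()
        out = resample(s, s.wavenumbers)
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_linear_ramp_exact_on_half_step(self):
        x = np.arange(300.0, 1801.0)
        s = Spectrum(x, 2.0 * x + 7.0, {"cell_id": "c0"})
        half = np.arange(300.0, 1800.01, 0.5)
        out = resample(s, half)
        np.testing.assert_allclose(out.intensities, 2.0 * half + 7.0, rtol=1e-12)
        assert out.meta == {"cell_id": "c0"}

    def test_no_extrapolation(self):
        s = _gaussian_spectrum()
        with pytest.raises(ValueError, match="beyond"):
            resample(s, (300.0, 1900.0, 1.0))


class TestDespike:
    def test_smooth_peak_not_flagged(self):
        s = _gaussian_spectrum()
        out, flagged = despike(s)
        assert flagged.size == 0
        np.testing.assert_array_equal(out.intensities, s.intensities)

    def test_injected_spike_localized_and_removed(self):
        """A 50x spike is flagged at exactly its channel and repaired to truth."""
        noise_sd = 0.02
        rng = np.random.default_rng(4)
        s = _gaussian_spectrum()
        truth = s.intensities.copy()
        noisy = truth + rng.normal(0, noise_sd, truth.size)
        spiked = noisy.copy()
        spiked[700] += 50.0
        out, flagged = despike(Spectrum(s.wavenumbers, spiked))
        assert list(flagged) == [s.wavenumbers[700]]
        # repaired output matches the spike-free signal within the noise level
        assert np.abs(out.intensities - noisy).max() < 3 * noise_sd
        # untouched channels are bit-identical
        mask = np.ones(truth.size, bool)
        mask[700] = False
        np.testing.assert_array_equal(out.intensities[mask], noisy[mask])

    def test_double_width_spike_both_channels_flagged(self):
        rng = np.random.default_rng(5)
        s = _gaussian_spectrum()
        y = s.intensities + rng.normal(0, 0.02, len(s))
        y[900] += 30.0
        y[901] += 22.0
        _, flagged = despike(Spectrum(s.wavenumbers, y))
        assert set(flagged) == {s.wavenumbers[900], s.wavenumbers[901]}

    def test_idempotent(self):
        rng = np.random.default_rng(6)
        s = _gaussian_spectrum()
        y = s.intensities + rng.normal(0, 0.02, len(s))
        y[[400, 1100]] += [40.0, 25.0]
        once, _ = despike(Spectrum(s.wavenumbers, y))
        twice, flagged2 = despike(once)
        assert flagged2.size == 0
        np.testing.assert_array_equal(once.intensities, twice.intensities)

    def test_too_few_channels_rejected(self):
        with pytest.raises(ValueError, match="5 channels"):
            despike(Spectrum([1.0, 2.0, 3.0], [0.0, 1.0, 0.0]))


class TestBaselineCorrect:
    def test_pure_linear_trend_removed(self):
        x = np.arange(300.0, 1801.0)
        line = 1.0 + 0.002 * (x - 300.0)
        corrected, baseline = baseline_correct(Spectrum(x, line))
        assert np.abs(corrected.intensities).max() < 0.01 * np.ptp(line)
        np.testing.assert_allclose(corrected.intensities + baseline, line, rtol=1e-9)

    def test_recovers_generator_baseline_within_5pct(self):
        """RMSE of the ALS estimate vs the known polynomial background < 5%."""
        cfg = synthetic.SyntheticConfig(n_per_class=8, spike_rate=0.0, seed=21)
        dataset, truths = synthetic.generate_dataset(cfg)
        sq_errs, means = [], []
        for i in range(len(dataset)):
            _, est = baseline_correct(dataset.spectrum(i))
            sq_errs.append(np.mean((est - truths[i].baseline) ** 2))
            means.append(truths[i].baseline.mean())
        rmse = np.sqrt(np.mean(sq_errs))
        assert rmse < 0.05 * np.mean(means)

    def test_lower_envelope_property(self):
        """Baseline sits at or below the signal on >= 90% of channels."""
        cfg = synthetic.SyntheticConfig(n_per_class=3, spike_rate=0.0, seed=22)
        dataset, _ = synthetic.generate_dataset(cfg)
        for i in range(len(dataset)):
            s = dataset.spectrum(i)
            _, est = baseline_correct(s)
            assert (est <= s.intensities).mean() >= 0.90

    def test_nonfinite_input_rejected(self):
        s = _gaussian_spectrum()
        s.intensities[10] = np.nan  # bypasses construction-time validation
        with pytest.raises(ValueError, match="finite"):
            baseline_correct(s)

    def test_polynomial_fallback_same_interface(self):
        cfg = PreprocessConfig(baseline_method="polynomial")
        x = np.arange(300.0, 1801.0)
        line = 2.0 + 0.001 * (x - 300.0)
        corrected, baseline = baseline_correct(Spectrum(x, line), cfg)
        assert np.abs(corrected.intensities).max() < 0.02 * np.ptp(line)


class TestAreaNormalize:
    def test_constant_closed_form(self):
        x = np.arange(300.0, 1801.0)
        out = area_normalize(Spectrum(x, np.full_like(x, 5.0)))
        np.testing.assert_allclose(out.intensities, 1.0 / 1500.0, rtol=1e-12)

    def test_idempotent(self):
        s = _gaussian_spectrum()
        once = area_normalize(s)
        twice = area_normalize(once)
        np.testing.assert_allclose(once.intensities, twice.intensities, rtol=1e-12)

    def test_zero_spectrum_rejected(self):
        x = np.arange(300.0, 1801.0)
        with pytest.raises(ValueError, match="nonpositive"):
            area_normalize(Spectrum(x, np.zeros_like(x)))

    @settings(deadline=None, max_examples=25, derandomize=True)
    @given(scale=st.floats(min_value=1e-6, max_value=1e6))
    def test_scale_invariance(self, scale):
        """normalize(c*x) == normalize(x) for any c > 0."""
        s = _gaussian_spectrum()
        a = area_normalize(s)
        b = area_normalize(s.with_intensities(scale * s.intensities))
        np.testing.assert_allclose(
            a.intensities, b.intensities,
            rtol=1e-9, atol=1e-12 * np.abs(a.intensities).max(),
        )


class TestPreprocessSet:
    def test_unit_integral_and_spike_metadata(self, small_clean):
        clean, details = small_clean
        for i in range(len(clean)):
            integral = np.trapezoid(clean.intensities[i], clean.wavenumbers)
            assert integral == pytest.approx(1.0, abs=1e-9)
        assert "n_spikes" in clean.meta.columns

    def test_spike_recall_at_least_95pct(self, small_dataset, small_clean):
        spectra_set, truths = small_dataset
        _, details = small_clean
        axis = spectra_set.wavenumbers
        hit = total = 0
        for i in range(len(spectra_set)):
            truth = truths[i]
            if not truth.spike_channels:
                continue
            qc = details[str(spectra_set.spectrum_ids[i])]
            flagged = set(np.searchsorted(axis, qc["spike_positions"]))
            total += len(truth.spike_channels)
            hit += len(set(truth.spike_channels) & flagged)
        assert total > 0
        assert hit / total >= 0.95

    def test_rerun_is_stable(self, small_clean):
        """Second pass through the chain changes nothing beyond 1e-6 relative."""
        clean, _ = small_clean
        again = preprocess_set(clean)
        drift = np.abs(again.intensities - clean.intensities).max()
        assert drift <= 1e-6 * np.abs(clean.intensities).max()

    def test_empty_set_rejected(self, small_dataset):
        spectra_set, _ = small_dataset
        empty = spectra_set.subset(np.zeros(len(spectra_set), dtype=bool))
        with pytest.raises(ValueError, match="empty"):
            preprocess_set(empty)

    def test_error_annotated_with_spectrum_id(self, small_dataset):
        spectra_set, _ = small_dataset
        bad = spectra_set.subset(np.arange(2))
        bad.intensities[1, :] = 0.0  # nonpositive integral downstream
        with pytest.raises(ValueError, match=str(bad.spectrum_ids[1])):
            preprocess_set(bad)


class TestConfigValidation:
    @pytest.mark.parametrize(
        "kwargs",
        [
            {"despike_threshold": 0.0},
            {"baseline_p": 0.0},
            {"baseline_p": 1.0},
            {"baseline_iters": 0},
            {"normalization_area": 0.0},
            {"baseline_method": "magic"},
        ],
    )
    def test_invalid_config_rejected(self, kwargs):
        with pytest.raises(ValueError):
            PreprocessConfig(**kwargs)
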