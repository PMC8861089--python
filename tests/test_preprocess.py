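import numpy as np
import pandas as pd
import pytest

from lipidfinger.errors import ValidationError
from lipidfinger.preprocess import (
    FeatureMatrix,
    average_spectra,
    bin_features,
    estimate_noise,
    exclude_spectra,
    pearson_qc,
    pick_peaks,
    preprocess_spectrum,
    resample,
    savgol_smooth,
    tic_normalize,
    tophat_baseline,
)
from lipidfinger.spectra_io import PeakList, Spectrum
from lipidfinger.synth import SynthConfig, simulate_experiment, simulate_spectrum


class TestResample:
    def test_uniform_spectrum_same_step_identical(self, flat_spectrum):
        out = resample(flat_spectrum, 0.01)
        np.testing.assert_allclose(out.intensity, flat_spectrum.intensity)

    def test_midpoint_is_arithmetic_mean(self):
        s = Spectrum(mz=[400.0, 400.2], intensity=[2.0, 4.0])
        out = resample(s, 0.1)
        assert out.intensity[1] == pytest.approx(3.0)

    def test_tic_integral_preserved_on_synthetic_spectrum(self):
        cfg = SynthConfig(noise_sd=0.0, seed=0)
        s = simulate_spectrum([(700.0, 5.0), (1200.0, 3.0)], cfg)
        out = resample(s, 0.017)
        tic_in = np.trapezoid(s.intensity, s.mz)  # trapezoid oracle
        tic_out = np.trapezoid(out.intensity, out.mz)
        assert abs(tic_out - tic_in) / tic_in < 1e-3

    def test_step_larger_than_span_rejected(self):
        s = Spectrum(mz=[400.0, 401.0], intensity=[1.0, 1.0])
        with pytest.raises(ValidationError):
            resample(s, 5.0)


class TestSavgol:
    def test_quadratic_signal_reproduced_exactly(self):
        mz = np.arange(400.0, 410.0, 0.01)
        y = 2.0 + 0.5 * (mz - 405) + 0.1 * (mz - 405) ** 2
        out = savgol_smooth(Spectrum(mz=mz, intensity=y))
        np.testing.assert_allclose(out.intensity, y, atol=1e-9)

    def test_zero_cycles_is_identity(self, flat_spectrum):
        out = savgol_smooth(flat_spectrum, cycles=0)
        np.testing.assert_array_equal(out.intensity, flat_spectrum.intensity)

    def test_noise_variance_reduced(self, rng):
        mz = np.arange(400.0, 450.0, 0.01)
        y = rng.normal(10.0, 1.0, mz.size)
        out = savgol_smooth(Spectrum(mz=mz, intensity=y))
        assert out.intensity.var() < y.var()

    def test_non_uniform_grid_rejected(self):
        s = Spectrum(mz=[400.0, 400.1, 400.5], intensity=[1.0, 1.0, 1.0])
        with pytest.raises(ValidationError, match="resample"):
            savgol_smooth(s)


def naive_opening(y, size):
    """Brute-force morphological opening oracle (erosion then dilation)."""
    n = len(y)
    half_lo = (size - 1) // 2
    half_hi = size - 1 - half_lo
    eroded = np.array([min(y[max(0, i - half_lo): min(n, i + half_hi + 1)]) for i in range(n)])
    return np.array([max(eroded[max(0, i - half_lo): min(n, i + half_hi + 1)]) for i in range(n)])


class TestTopHat:
    def test_constant_spectrum_fully_explained_by_baseline(self, flat_spectrum):
        residual, baseline = tophat_baseline(flat_spectrum)
        np.testing.assert_allclose(baseline.intensity, 3.0)
        np.testing.assert_allclose(residual.intensity, 0.0)

    def test_narrow_peak_on_offset(self, gaussian_factory):
        s = gaussian_factory([450.0], [10.0], offset=2.0)
        residual, baseline = tophat_baseline(s, min_width_frac=0.10)
        apex = np.argmax(s.intensity)
        assert baseline.intensity[apex] == pytest.approx(2.0, rel=1e-6)
        assert residual.intensity[apex] == pytest.approx(10.0, rel=0.01)

    def test_residual_non_negative_for_any_input(self, rng):
        mz = np.arange(400.0, 420.0, 0.01)
        s = Spectrum(mz=mz, intensity=rng.uniform(0, 5, mz.size))
        residual, _ = tophat_baseline(s)
        assert residual.intensity.min() >= 0.0

    def test_matches_naive_opening_oracle(self, rng):
        mz = np.arange(0.0, 2.0, 0.01)
        y = rng.uniform(0, 10, mz.size)
        s = Spectrum(mz=mz, intensity=y)
        _, baseline = tophat_baseline(s, min_width_frac=0.1)
        size = int(round(0.1 * (mz[-1] - mz[0]) / 0.01))
        size += 1 - size % 2
        np.testing.assert_allclose(baseline.intensity, naive_opening(y, size), atol=1e-8)


class TestTicNormalize:
    def test_sums_to_one(self, rng):
        mz = np.arange(400.0, 410.0, 0.01)
        s = Spectrum(mz=mz, intensity=rng.uniform(0, 5, mz.size))
        assert tic_normalize(s).tic == pytest.approx(1.0, abs=1e-12)

    def test_scale_invariance(self, flat_spectrum):
        scaled = flat_spectrum.with_(intensity=flat_spectrum.intensity * 7)
        np.testing.assert_allclose(
            tic_normalize(scaled).intensity, tic_normalize(flat_spectrum).intensity
        )

    def test_two_point_example(self):
        s = Spectrum(mz=[400.0, 401.0], intensity=[3.0, 1.0])
        np.testing.assert_allclose(tic_normalize(s).intensity, [0.75, 0.25])

    def test_zero_tic_flagged(self):
        s = Spectrum(mz=[400.0, 401.0], intensity=[0.0, 0.0])
        with pytest.raises(ValidationError, match="[Nn]ull"):
            tic_normalize(s)


class TestEstimateNoise:
    def test_recovers_known_sigma(self, rng):
        mz = np.arange(500.0, 520.0, 0.01)  # 2000 points, one window
        s = Spectrum(mz=mz, intensity=rng.normal(50.0, 2.0, mz.size))
        model = estimate_noise(s, window=20.0)
        assert model.level[0] == pytest.approx(2.0, rel=0.10)

    def test_all_zero_window_floors(self):
        s = Spectrum(mz=np.arange(500.0, 520.0, 0.01), intensity=np.zeros(2000))
        model = estimate_noise(s, window=20.0)
        assert np.all(model.level > 0)

    def test_robust_to_single_huge_peak(self, rng):
        mz = np.arange(500.0, 520.0, 0.01)
        base = rng.normal(10.0, 1.0, mz.size)
        clean = estimate_noise(Spectrum(mz=mz, intensity=base), window=20.0)
        spiked_y = base.copy()
        spiked_y[1000] += 1e4
        spiked = estimate_noise(Spectrum(mz=mz, intensity=spiked_y), window=20.0)
        assert abs(spiked.level[0] - clean.level[0]) / clean.level[0] < 0.20

    def test_floor_tracks_background_median(self, rng):
        mz = np.arange(500.0, 520.0, 0.01)
        s = Spectrum(mz=mz, intensity=rng.normal(7.0, 0.5, mz.size))
        model = estimate_noise(s, window=20.0)
        assert model.floor_at(510.0) == pytest.approx(7.0, abs=0.1)


class TestAverageSpectra:
    def test_single_spectrum_is_itself(self, flat_spectrum):
        out = average_spectra([flat_spectrum])
        np.testing.assert_array_equal(out.intensity, flat_spectrum.intensity)

    def test_two_spectra_pointwise_mean(self):
        a = Spectrum(mz=[400.0, 401.0], intensity=[0.0, 2.0])
        b = Spectrum(mz=[400.0, 401.0], intensity=[2.0, 0.0])
        np.testing.assert_allclose(average_spectra([a, b]).intensity, [1.0, 1.0])

    def test_mean_tic_linearity(self, rng):
        mz = np.arange(400.0, 401.0, 0.01)
        spectra = [Spectrum(mz=mz, intensity=rng.uniform(0, 5, mz.size)) for _ in range(4)]
        avg = average_spectra(spectra)
        assert avg.tic == pytest.approx(np.mean([s.tic for s in spectra]))

    def test_mismatched_grids_rejected(self):
        a = Spectrum(mz=[400.0, 401.0], intensity=[1.0, 1.0])
        b = Spectrum(mz=[400.0, 402.0], intensity=[1.0, 1.0])
        with pytest.raises(ValidationError):
            average_spectra([a, b])


class TestPickPeaks:
    def test_single_gaussian_high_snr_one_peak_at_true_mz(self):
        cfg = SynthConfig(noise_sd=0.02, baseline_amp=0.0, seed=3)
        s = simulate_spectrum([(700.0, 50.0)], cfg)  # SNR far above threshold
        noise = estimate_noise(s)
        peaks = pick_peaks(s, noise)
        strong = [p for p in peaks if p.snr > 10]
        assert len(strong) == 1
        assert strong[0].mz == pytest.approx(700.0, abs=0.01)

    def test_low_snr_peak_excluded(self, gaussian_factory, rng):
        mz = np.arange(400.0, 500.0, 0.01)
        sigma = 1.0
        y = rng.normal(0, sigma, mz.size)
        i = 5000
        y[i - 1 : i + 2] += [1.2, 2.5 * sigma, 1.2]  # apex SNR ~2.5
        noise = estimate_noise(Spectrum(mz=mz, intensity=np.abs(y)))
        peaks = pick_peaks(Spectrum(mz=mz, intensity=np.abs(y)), noise, snr_min=3.0)
        assert not any(abs(p.mz - mz[i]) < 0.05 for p in peaks)

    def test_two_peaks_separated_by_5_fwhm_resolved(self):
        cfg = SynthConfig(noise_sd=0.02, baseline_amp=0.0, seed=4)
        fwhm = 700.0 / cfg.resolution
        s = simulate_spectrum([(700.0, 50.0), (700.0 + 5 * fwhm, 50.0)], cfg)
        peaks = pick_peaks(s, estimate_noise(s))
        strong = [p for p in peaks if p.snr > 10]
        assert len(strong) == 2


class TestFeatureMatrix:
    def make_fm(self, values, groups=None):
        n = values.shape[1]
        groups = groups or ["g1"] * n
        samples = pd.DataFrame(
            dict(sample_id=[f"s{i}" for i in range(n)], group=groups,
                 bio_rep=list(range(1, n + 1)), tech_rep=[1] * n)
        )
        return FeatureMatrix(
            feature_mz=np.arange(1.0, values.shape[0] + 1), values=values, samples=samples
        )

    def test_bin_features_recovers_apex_for_identical_spectra(self, gaussian_factory):
        s = gaussian_factory([450.0, 470.0], [5.0, 2.0])
        noise_src = s.with_(intensity=s.intensity + 0.001)
        peaks = pick_peaks(noise_src, estimate_noise(noise_src), snr_min=3.0)
        strong = PeakList([p for p in peaks if p.snr > 10])
        s1 = s.with_(sample_id="a")
        fm = bin_features(strong, [s1])
        np.testing.assert_allclose(
            np.sort(fm.values[:, 0])[-2:], [2.0, 5.0], rtol=0.01
        )

    def test_empty_peaklist_zero_rows(self, flat_spectrum):
        fm = bin_features(PeakList([]), [flat_spectrum])
        assert fm.n_features == 0

    def test_spiked_log2fc_recovered_noiseless(self):
        cfg = SynthConfig(noise_sd=0.0, baseline_amp=0.0, tic_cv=0.0,
                          sigma_bio_log2=0.0, sigma_tech_log2=0.0,
                          n_bio=2, n_tech=1, seed=0)
        key = cfg.panel_keys()[0]
        cfg.group_effects = {"treated": {key: 1.0}}
        spectra, truth = simulate_experiment(cfg)
        mz0 = truth.lipids.loc[truth.lipids.key == key, "mz_theoretical"].iloc[0]
        avg = average_spectra(spectra)
        peaks = pick_peaks(avg, estimate_noise(avg))
        fm = bin_features(peaks, spectra)
        i = np.argmin(np.abs(fm.feature_mz - mz0))
        treated = fm.group_values("treated")[i].mean()
        vehicle = fm.group_values("vehicle")[i].mean()
        assert treated / vehicle == pytest.approx(2.0, rel=1e-6)

    def test_exclude_null_spectrum(self):
        values = np.array([[1.0, 0.0], [2.0, 0.0]])
        fm = self.make_fm(values)
        out = exclude_spectra(fm)
        assert out.n_samples == 1 and out.samples.sample_id[0] == "s0"

    def test_exclude_uncorrelated_spectrum(self, rng):
        base = rng.uniform(1, 10, 50)
        cols = [base * rng.normal(1, 0.02, 50) for _ in range(4)]
        cols.append(rng.permutation(base))  # fingerprint destroyed
        fm = self.make_fm(np.column_stack(cols))
        out = exclude_spectra(fm, min_corr=0.5)
        assert out.n_samples == 4 and "s4" not in set(out.samples.sample_id)

    def test_clean_replicates_untouched(self, rng):
        base = rng.uniform(1, 10, 50)
        cols = [base * rng.normal(1, 0.05, 50) for _ in range(5)]
        fm = self.make_fm(np.column_stack(cols))
        assert exclude_spectra(fm).n_samples == 5

    def test_all_excluded_is_hard_error(self):
        fm = self.make_fm(np.zeros((3, 2)))
        with pytest.raises(ValidationError):
            exclude_spectra(fm)

    def test_collapse_technical_averages(self):
        values = np.array([[1.0, 3.0, 10.0, 20.0]])
        samples = pd.DataFrame(
            dict(sample_id=list("abcd"), group=["g1"] * 4,
                 bio_rep=[1, 1, 2, 2], tech_rep=[1, 2, 1, 2])
        )
        fm = FeatureMatrix(feature_mz=[1.0], values=values, samples=samples)
        out = fm.collapse_technical()
        np.testing.assert_allclose(out.values, [[2.0, 15.0]])

    def test_tsv_round_trip(self, tmp_path):
        fm = self.make_fm(np.array([[1.0, 2.0], [3.0, 4.0]]))
        fm.to_tsv(tmp_path / "fm.tsv")
        back = FeatureMatrix.from_tsv(tmp_path / "fm.tsv", fm.samples)
        np.testing.assert_allclose(back.values, fm.values)


class TestPearsonQc:
    def test_identical_columns_r_one(self):
        fm = TestFeatureMatrix().make_fm(np.tile([[1.0], [5.0], [2.0]], (1, 3)))
        corr, summary = pearson_qc(fm)
        assert corr.iloc[0, 1] == pytest.approx(1.0)
        assert summary.mean_r[0] == pytest.approx(1.0)

    def test_negated_column_r_minus_one(self):
        col = np.array([1.0, 5.0, 2.0])
        fm = TestFeatureMatrix().make_fm(np.column_stack([col, 6.0 - col]))
        corr, _ = pearson_qc(fm)
        assert corr.iloc[0, 1] == pytest.approx(-1.0)

    def test_zero_variance_column_reported_missing(self):
        fm = TestFeatureMatrix().make_fm(
            np.column_stack([[1.0, 5.0, 2.0], [3.0, 3.0, 3.0]])
        )
        corr, _ = pearson_qc(fm)
        assert np.isnan(corr.iloc[0, 1])

    def test_default_synthetic_replicates_in_expected_regime(self):
        spectra, _ = simulate_experiment(SynthConfig(seed=11, n_bio=3, n_tech=3))
        processed = [preprocess_spectrum(s) for s in spectra]
        avg = average_spectra(processed)
        peaks = pick_peaks(avg, estimate_noise(avg))
        fm = bin_features(peaks, processed)
        _, summary = pearson_qc(fm)
        assert all(0.8 <= r <= 1.0 for r in summary.mean_r)


def test_pipeline_recovers_truth_with_stochastics_off():
    """Noise-free synthetic spectra round-trip the generator's ground truth."""
    cfg = SynthConfig(noise_sd=0.0, baseline_amp=0.0, tic_cv=0.0,
                      sigma_bio_log2=0.0, sigma_tech_log2=0.0,
                      n_bio=2, n_tech=1, seed=0)
    spectra, truth = simulate_experiment(cfg)
    processed = [preprocess_spectrum(s) for s in spectra]
    avg = average_spectra(processed)
    peaks = pick_peaks(avg, estimate_noise(avg), resolution=cfg.resolution)
    picked = np.array(peaks.mz)
    for mz0 in truth.lipids.mz_theoretical:
        err = np.min(np.abs(picked - mz0))
        assert err <= mz0 / (2 * cfg.resolution)
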