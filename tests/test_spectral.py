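"""Amplitude spectra, noise baselines, harmonic summation and ROI measures."""

from __future__ import annotations

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import fpvs
from fpvs import spectral
from fpvs.spectral import ROI_OT_BILATERAL, AmplitudeSpectrum, HarmonicSet

from conftest import ODDBALL_SET, quiet_config, short_schedule


def make_spectrum(values: np.ndarray, resolution: float = 0.1,
                  labels: tuple[str, ...] = ("ch0",)) -> AmplitudeSpectrum:
    """Wrap raw per-channel bin values in a spectrum object."""
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_samples = 2 * (values.shape[1] - 1)
    return AmplitudeSpectrum(
        resolution=resolution,
        amplitudes=values,
        channel_labels=labels,
        duration=1.0 / resolution,
        n_samples=n_samples,
    )


class TestAmplitudeSpectrum:
    def test_exact_bin_sinusoid_maps_to_its_amplitude(self):
        """2.5 µV at 6 Hz over 70 s at 256 Hz -> 2.5 µV at the 6 Hz bin."""
        fs, dur = 256.0, 70.0
        t = np.arange(round(fs * dur)) / fs
        ep = fpvs.Recording(fs, ("Oz",), (2.5 * np.sin(2 * np.pi * 6.0 * t))[None, :],
                            [], {})
        spec = fpvs.amplitude_spectrum(ep)
        assert spec.amplitudes[0, spec.bin_of(6.0)] == pytest.approx(2.5, abs=1e-9)

    def test_zero_input_zero_spectrum(self):
        ep = fpvs.Recording(256.0, ("Oz",), np.zeros((1, 1024)), [], {})
        assert np.all(fpvs.amplitude_spectrum(ep).amplitudes == 0)

    def test_resolution_is_inverse_duration(self):
        fs = 256.0
        n = round(70.83 * fs)  # 70.83 s segment
        ep = fpvs.Recording(fs, ("Oz",), np.zeros((1, n)), [], {})
        spec = fpvs.amplitude_spectrum(ep)
        assert spec.resolution == pytest.approx(1.0 / 70.83, rel=1e-4)
        assert round(spec.resolution, 4) == 0.0141

    def test_empty_input_rejected(self):
        ep = fpvs.Recording(256.0, ("Oz",), np.zeros((1, 0)), [], {})
        with pytest.raises(ValueError, match="empty"):
            fpvs.amplitude_spectrum(ep)

    def test_non_bin_frequency_rejected(self):
        ep = fpvs.Recording(256.0, ("Oz",), np.zeros((1, 256)), [], {})
        spec = fpvs.amplitude_spectrum(ep)
        with pytest.raises(ValueError, match="not an exact bin"):
            spec.bin_of(1.5)


def brute_force_noise(values: np.ndarray, center: int, per_side: int = 10):
    """Literal re-implementation of the noise rule for cross-checking:
    candidates at offsets +-2..+-(per_side+1), drop one largest and one
    smallest, return mean and sample sd."""
    cand = []
    for off in range(2, per_side + 2):
        cand.append(values[center - off])
        cand.append(values[center + off])
    cand.sort()
    used = cand[1:-1]
    arr = np.array(used)
    return float(arr.mean()), float(arr.std(ddof=1))


class TestEstimateNoise:
    def test_flat_spectrum(self):
        spec = make_spectrum(np.full(40, 3.5))
        est = fpvs.estimate_noise(spec, "ch0", 20)
        assert est.mean == pytest.approx(3.5)
        assert est.sd == 0.0
        assert len(est.used_offsets) == 18

    def test_known_candidate_values(self):
        """Candidates 1..20 µV -> mean of 2..19 = 10.5 µV."""
        values = np.zeros(40)
        center = 20
        offsets = list(range(2, 12))
        vals = iter(range(1, 21))
        for off in offsets:
            values[center - off] = next(vals)
        for off in offsets:
            values[center + off] = next(vals)
        spec = make_spectrum(values)
        est = fpvs.estimate_noise(spec, "ch0", center)
        assert est.mean == pytest.approx(10.5)

    def test_spike_at_center_and_adjacent_bins_ignored(self):
        values = np.full(40, 1.0)
        values[19:22] = 500.0
        spec = make_spectrum(values)
        est = fpvs.estimate_noise(spec, "ch0", 20)
        assert est.mean == pytest.approx(1.0)

    def test_edge_bin_rejected(self):
        spec = make_spectrum(np.ones(40))
        with pytest.raises(ValueError, match="neighbours"):
            fpvs.estimate_noise(spec, "ch0", 5)

    def test_matches_brute_force_on_random_spectra(self):
        """Exhaustive cross-check on 10^4 random 40-bin spectra."""
        rng = np.random.default_rng(123)
        for _ in range(10_000):
            values = rng.rayleigh(1.0, 40)
            spec = make_spectrum(values)
            est = fpvs.estimate_noise(spec, "ch0", 20)
            mean, sd = brute_force_noise(values, 20)
            assert est.mean == pytest.approx(mean, abs=0, rel=1e-12)
            assert est.sd == pytest.approx(sd, abs=1e-12)


class TestPerBinMeasures:
    def test_direct_arithmetic(self):
        """amp 5, noise mean 2, noise sd 1 -> SNR 2.5, SB 3 µV, z 3."""
        values = np.zeros(40)
        center = 20
        offsets = fpvs.spectral._candidate_offsets(10)
        # noise candidates alternating 1 and 3: mean 2 after trimming, sd 1+
        pattern = np.tile([1.0, 3.0], 10)
        values[center + offsets] = pattern
        values[center] = 5.0
        spec = make_spectrum(values)
        est = fpvs.estimate_noise(spec, "ch0", center)
        assert est.mean == pytest.approx(2.0)
        snr = fpvs.snr_at(spec, "ch0", center)
        sb = fpvs.subtract_at(spec, "ch0", center)
        z = fpvs.z_at(spec, "ch0", center)
        assert snr == pytest.approx(5.0 / est.mean)
        assert sb == pytest.approx(5.0 - est.mean)
        assert z == pytest.approx((5.0 - est.mean) / est.sd)

    def test_amplitude_equal_to_noise(self):
        values = np.full(40, 2.0)
        values[20] = 2.0
        spec = make_spectrum(values)
        assert fpvs.snr_at(spec, "ch0", 20) == pytest.approx(1.0)
        assert fpvs.subtract_at(spec, "ch0", 20) == pytest.approx(0.0)
        assert fpvs.z_at(spec, "ch0", 20) == 0.0

    def test_zero_noise_sd_flags_infinite_z(self):
        values = np.full(40, 1.0)
        values[20] = 2.0
        spec = make_spectrum(values)
        assert fpvs.z_at(spec, "ch0", 20) == np.inf

    @pytest.mark.parametrize("snr, percent", [(35.0, 3400.0), (3.0, 200.0)])
    def test_snr_percent_conversion(self, snr, percent):
        assert fpvs.snr_to_percent_increase(snr) == pytest.approx(percent)


class TestHarmonicSelection:
    def _high_snr_grand(self) -> AmplitudeSpectrum:
        """Grand average over channels of a low-noise 70 s study snippet."""
        cfg = quiet_config(noise_rms=0.3)
        sch = fpvs.default_schedule(seed=0, steady_duration=70.0)
        specs = []
        for subject in range(2):
            for cond in ("upright", "inverted"):
                rec = fpvs.simulate_recording(sch, cfg, cond, subject=subject)
                eps, _ = fpvs.preprocess_recording(rec)
                specs.append(fpvs.amplitude_spectrum(eps[0]))
        return fpvs.grand_average_spectrum(specs, collapse_channels=True)

    def test_injected_harmonics_recovered_exactly(self):
        """High-SNR grand average returns exactly harmonics 1-6, 8, 9."""
        grand = self._high_snr_grand()
        hset = fpvs.find_significant_harmonics(grand, 6.0 / 7.0)
        assert hset.indices == (1, 2, 3, 4, 5, 6, 8, 9)

    def test_harmonic_seven_never_selected(self):
        """The 6 Hz bin (oddball harmonic 7) is excluded by construction even
        though the base response there is enormous."""
        grand = self._high_snr_grand()
        b6 = grand.bin_of(6.0)
        assert fpvs.z_at(grand, "grand", b6) > 3.1  # base response is there
        hset = fpvs.find_significant_harmonics(grand, 6.0 / 7.0)
        assert 7 not in hset.indices

    def test_non_bin_fundamental_rejected(self):
        grand = self._high_snr_grand()
        with pytest.raises(ValueError, match="bin"):
            fpvs.find_significant_harmonics(grand, 0.91)

    def test_harmonic_set_rejects_excluded_multiples(self):
        with pytest.raises(ValueError, match="multiple"):
            HarmonicSet(6.0 / 7.0, (1, 2, 7))


class TestSumHarmonics:
    def test_single_harmonic_reduces_to_subtract_at(self, noise_free_epoch):
        spec = fpvs.amplitude_spectrum(noise_free_epoch)
        hset = HarmonicSet(6.0 / 7.0, (2,))
        resp = fpvs.sum_harmonics(spec, hset)
        b = spec.bin_of(2 * 6.0 / 7.0)
        assert resp.channel_value("P9") == pytest.approx(
            fpvs.subtract_at(spec, "P9", b)
        )

    def test_additivity_of_known_amplitudes(self):
        """Injected 0.3/0.2/0.1 µV at oddball harmonics 1-3 sum to 0.6 µV."""
        cfg = quiet_config()
        cfg = dataclasses.replace(
            cfg,
            base_response=None,
            oddball_response=fpvs.PeriodicResponseSpec(
                6.0 / 7.0,
                ((1, 0.3, 0.0), (2, 0.2, 0.5), (3, 0.1, 1.0)),
                {"Oz": 1.0},
            ),
        )
        rec = fpvs.simulate_recording(short_schedule(), cfg, "upright")
        from fpvs.preprocess import PreprocessConfig, crop_integer_cycles

        spec = fpvs.amplitude_spectrum(crop_integer_cycles(rec, PreprocessConfig()))
        resp = fpvs.sum_harmonics(spec, HarmonicSet(6.0 / 7.0, (1, 2, 3)))
        assert resp.channel_value("Oz") == pytest.approx(0.6, abs=1e-6)

    def test_flat_spectrum_sums_to_zero(self):
        spec = make_spectrum(np.full(80, 1.0), resolution=6.0 / 7.0 / 20)
        resp = fpvs.sum_harmonics(spec, HarmonicSet(6.0 / 7.0, (1,)))
        assert resp.summed_amplitude[0] == pytest.approx(0.0)

    def test_empty_set_rejected(self, noise_free_epoch):
        spec = fpvs.amplitude_spectrum(noise_free_epoch)
        with pytest.raises(ValueError, match="empty"):
            fpvs.sum_harmonics(spec, HarmonicSet(6.0 / 7.0, ()))


class TestROIs:
    def test_roi_of_one_channel_is_that_channel(self, noise_free_epoch):
        spec = fpvs.amplitude_spectrum(noise_free_epoch)
        resp = fpvs.sum_harmonics(spec, ODDBALL_SET)
        roi = fpvs.ROIDefinition("single", ("P10",))
        assert fpvs.roi_aggregate(resp, roi) == pytest.approx(
            resp.channel_value("P10")
        )

    def test_roi_mean_of_known_values(self):
        resp = fpvs.HarmonicResponse(
            harmonic_set=ODDBALL_SET,
            channel_labels=("P9", "P10", "PO11", "PO12"),
            summed_amplitude=np.array([0.6, 0.7, 0.62, 0.68]),
            snr=np.zeros((4, 8)),
            z=np.zeros((4, 8)),
        )
        assert fpvs.roi_aggregate(resp, ROI_OT_BILATERAL) == pytest.approx(0.65)

    def test_missing_channel_rejected(self):
        resp = fpvs.HarmonicResponse(
            ODDBALL_SET, ("P9",), np.array([0.5]), np.zeros((1, 8)), np.zeros((1, 8))
        )
        with pytest.raises(ValueError, match="missing"):
            fpvs.roi_aggregate(resp, ROI_OT_BILATERAL)

    def test_data_driven_roi_recovers_injected_peaks(self, noise_free_epoch):
        spec = fpvs.amplitude_spectrum(noise_free_epoch)
        resp = fpvs.sum_harmonics(spec, ODDBALL_SET)
        values = dict(zip(resp.channel_labels, resp.summed_amplitude))
        roi = fpvs.data_driven_roi(values, k=4)
        assert set(roi.channel_labels) == {"P9", "P10", "PO11", "PO12"}

    def test_data_driven_roi_k_equals_channel_count(self):
        values = {"A": 1.0, "B": 2.0}
        roi = fpvs.data_driven_roi(values, k=2, montage_order=("A", "B"))
        assert set(roi.channel_labels) == {"A", "B"}

    def test_data_driven_roi_tie_break_follows_montage_order(self):
        values = {"A": 1.0, "B": 2.0, "C": 1.0}
        roi = fpvs.data_driven_roi(values, k=2, montage_order=("A", "B", "C"))
        assert roi.channel_labels == ("B", "A")

    def test_data_driven_roi_k_too_large_rejected(self):
        with pytest.raises(ValueError, match="k="):
            fpvs.data_driven_roi({"A": 1.0}, k=2, montage_order=("A",))


class TestIndividualSignificance:
    def test_strong_injected_response_is_significant(self, noise_free_epoch):
        """With a 0.65 µV response over a weak noise floor, z far exceeds 3.1."""
        cfg = quiet_config(noise_rms=1.0)
        rec = fpvs.simulate_recording(short_schedule(seed=9), cfg, "upright")
        eps, _ = fpvs.preprocess_recording(rec)
        spec = fpvs.amplitude_spectrum(eps[0])
        z = fpvs.individual_significance(spec, ODDBALL_SET, ROI_OT_BILATERAL)
        assert z > 3.1

    def test_null_z_matches_independent_statistic_oracle(self):
        """The summed-harmonic z must behave exactly like the same statistic
        computed by direct Monte Carlo on exchangeable bins: comparable null
        quantiles, and (being t-like over 18 trimmed sums) a z > 3.1 rate of
        roughly 1%, far above the 0.1% a normal approximation suggests."""
        rng = np.random.default_rng(77)
        # pipeline: null spectra through individual_significance
        zs = []
        res = 6.0 / 7.0 / 30
        for _ in range(400):
            values = rng.rayleigh(0.05, 500)
            spec = make_spectrum(values, resolution=res, labels=("P9",))
            roi = fpvs.ROIDefinition("one", ("P9",))
            zs.append(fpvs.individual_significance(spec, ODDBALL_SET, roi))
        zs = np.array(zs)
        # oracle: same statistic assembled from scratch on fresh draws
        oracle = []
        offs = fpvs.spectral._candidate_offsets(10)
        for _ in range(4000):
            sums = rng.rayleigh(0.05, (8, len(offs) + 1)).sum(axis=0)
            signal, null = sums[0], np.sort(sums[1:])[1:-1]
            oracle.append((signal - null.mean()) / null.std(ddof=1))
        oracle = np.array(oracle)
        for q in (0.5, 0.9, 0.99):
            assert np.quantile(zs, q) == pytest.approx(
                np.quantile(oracle, q), abs=0.35
            )

    def test_harmonic_set_is_shared_not_refit(self, noise_free_epoch):
        """The set is an input fixed from grand-averaged data; applying it to
        any subject spectrum must not mutate it."""
        spec = fpvs.amplitude_spectrum(noise_free_epoch)
        before = ODDBALL_SET.indices
        fpvs.individual_significance(spec, ODDBALL_SET, ROI_OT_BILATERAL)
        assert ODDBALL_SET.indices == before

    def test_insufficient_neighbours_rejected(self):
        spec = make_spectrum(np.ones(30), resolution=6.0 / 7.0 / 3)
        with pytest.raises(ValueError, match="neighbour"):
            fpvs.individual_significance(
                spec, ODDBALL_SET, fpvs.ROIDefinition("one", ("ch0",))
            )


class TestInvariances:
    @given(st.floats(min_value=0.1, max_value=50.0))
    @settings(max_examples=10, deadline=None, derandomize=True)
    def test_scale_invariance(self, c):
        """Scaling the recording by c scales SB sums by c and leaves SNR and
        z unchanged."""
        rng = np.random.default_rng(31)
        values = rng.rayleigh(1.0, 200)
        spec1 = make_spectrum(values, resolution=6.0 / 7.0 / 15)
        spec2 = make_spectrum(values * c, resolution=6.0 / 7.0 / 15)
        hset = HarmonicSet(6.0 / 7.0, (1, 2, 3, 4))
        r1 = fpvs.sum_harmonics(spec1, hset)
        r2 = fpvs.sum_harmonics(spec2, hset)
        assert r2.summed_amplitude[0] == pytest.approx(
            c * r1.summed_amplitude[0], rel=1e-9
        )
        np.testing.assert_allclose(r2.snr, r1.snr, rtol=1e-9)
        np.testing.assert_allclose(r2.z, r1.z, rtol=1e-9)

    def test_base_rate_independence(self):
        """Scaling the base response leaves the oddball quantification
        untouched (harmonic 7 is excluded)."""
        sch = short_schedule()
        cfg = quiet_config()
        cfg_big = dataclasses.replace(cfg, base_response=cfg.base_response.scaled(10.0))
        from fpvs.preprocess import PreprocessConfig, crop_integer_cycles

        out = []
        for c in (cfg, cfg_big):
            rec = fpvs.simulate_recording(sch, c, "upright")
            spec = fpvs.amplitude_spectrum(
                crop_integer_cycles(rec, PreprocessConfig())
            )
            resp = fpvs.sum_harmonics(spec, ODDBALL_SET)
            out.append(fpvs.roi_aggregate(resp, ROI_OT_BILATERAL))
        assert out[1] == pytest.approx(out[0], rel=1e-6)

    def test_sqrt_n_noise_reduction_with_phase_locked_signal(self):
        """Averaging 16 epochs cuts noise RMS ~4x, signal unchanged."""
        fs, n = 256.0, 4096
        t = np.arange(n) / fs
        signal = 2.0 * np.sin(2 * np.pi * 8.0 * t)
        rng = np.random.default_rng(6)
        epochs = [
            fpvs.Recording(fs, ("Oz",),
                           (signal + rng.standard_normal(n))[None, :], [], {})
            for _ in range(16)
        ]
        avg = fpvs.average_time_domain(epochs)
        spec = fpvs.amplitude_spectrum(avg)
        assert spec.amplitudes[0, spec.bin_of(8.0)] == pytest.approx(2.0, rel=0.02)
        resid = avg.data[0] - signal
        assert resid.std() == pytest.approx(1.0 / 4.0, rel=0.25)

    def test_average_identities(self):
        ep = fpvs.Recording(256.0, ("Oz",),
                            np.random.default_rng(0).standard_normal((1, 64)), [], {})
        same = fpvs.average_time_domain([ep, ep])
        np.testing.assert_allclose(same.data, ep.data)
        neg = dataclasses.replace(ep, data=-ep.data, events=[])
        zero = fpvs.average_time_domain([ep, neg])
        np.testing.assert_allclose(zero.data, 0.0, atol=1e-12)

    def test_heterogeneous_epochs_rejected(self):
        a = fpvs.Recording(256.0, ("Oz",), np.zeros((1, 64)), [], {})
        b = fpvs.Recording(256.0, ("Oz",), np.zeros((1, 65)), [], {})
        with pytest.raises(ValueError, match="heterogeneous"):
            fpvs.average_time_domain([a, b])
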