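"""Epoch-averaged spectra, coherence, peak CKC and significance threshold."""

import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from ckc.epoching import EpochSpec, make_epochs, segment_epochs
from ckc.forward import GRAD, default_sensor_array
from ckc.simulate import SensorRecording, _tangential_orientation
from ckc.spectral import (CoherenceResult, SpectralError, attach_threshold,
                          coherence, epoch_spectra, peak_ckc, sensor_ckc,
                          significance_threshold, sum_recordings,
                          topography_table)

FS = 1000.0


def epochs_from_arrays(meg, ref, array):
    """Assemble an EpochSet directly from (K, C, N) MEG and (K, N) reference."""
    from ckc.epoching import EpochSet
    k = meg.shape[0]
    return EpochSet(meg=meg, ref=ref, starts=np.arange(k) * meg.shape[2],
                    sample_rate=FS, array=array, provenance={})


@pytest.fixture(scope="module")
def tiny_array():
    return default_sensor_array(4)  # 12 channels


class TestEpochSpectra:
    def test_bin_aligned_sinusoid_power_in_one_bin(self, tiny_array):
        n, k = 1000, 2
        t = np.arange(n) / FS
        x = np.sin(2 * np.pi * 5.0 * t)  # 5 Hz = bin 5 at 1 Hz resolution
        meg = np.tile(x, (k, tiny_array.n_channels, 1))
        est = epoch_spectra(epochs_from_arrays(meg, np.tile(x, (k, 1)),
                                               tiny_array))
        assert est.freqs[np.argmax(est.pxx[0])] == pytest.approx(5.0)
        assert est.pxx[0, 5] > 0.999 * est.pxx[0].sum()

    def test_identical_signals_give_equal_spectra(self, tiny_array, rng):
        meg = rng.standard_normal((3, tiny_array.n_channels, 500))
        ref = meg[:, 0, :]
        est = epoch_spectra(epochs_from_arrays(meg, ref, tiny_array))
        np.testing.assert_allclose(est.pxy[0], est.pyy, rtol=1e-10)
        np.testing.assert_allclose(est.pxx[0], est.pyy, rtol=1e-10)

    def test_white_noise_spectrum_flat(self, tiny_array, rng):
        k, n = 80, 500
        meg = rng.standard_normal((k, tiny_array.n_channels, n))
        est = epoch_spectra(epochs_from_arrays(meg, meg[:, 0, :], tiny_array))
        inner = est.pxx[1, 1:-1]  # skip DC and Nyquist (half-width bins)
        assert inner.mean() == pytest.approx(n, rel=0.05)
        # chi-squared spread around the mean: sd/mean ~ 1/sqrt(K)
        assert inner.std() / inner.mean() == pytest.approx(1 / np.sqrt(k),
                                                           rel=0.35)

    def test_single_epoch_rejected(self, tiny_array, rng):
        meg = rng.standard_normal((1, tiny_array.n_channels, 100))
        with pytest.raises(SpectralError):
            epoch_spectra(epochs_from_arrays(meg, meg[:, 0, :], tiny_array))


class TestCoherence:
    def test_self_coherence_is_one(self, tiny_array, rng):
        meg = rng.standard_normal((4, tiny_array.n_channels, 300))
        res = coherence(epoch_spectra(
            epochs_from_arrays(meg, meg[:, 2, :], tiny_array)))
        np.testing.assert_allclose(res.coh[2], 1.0, atol=1e-10)

    def test_independent_noise_bias_is_one_over_k(self, tiny_array, rng):
        k, n = 60, 600
        meg = rng.standard_normal((k, tiny_array.n_channels, n))
        ref = rng.standard_normal((k, n))
        res = coherence(epoch_spectra(epochs_from_arrays(meg, ref, tiny_array)))
        vals = res.coh[:, 1:-1].ravel()  # many independent bin-replicates
        se = vals.std(ddof=1) / np.sqrt(len(vals))
        assert abs(vals.mean() - 1 / k) < 3 * se + 1e-4

    def test_equal_variance_additive_noise_limit_half(self, tiny_array, rng):
        # Y = X + n with var(n) = var(x): coherence -> SNR/(1+SNR) = 0.5
        k, n = 200, 256
        x = rng.standard_normal((k, tiny_array.n_channels, n))
        ref = x[:, 0, :] + rng.standard_normal((k, n))
        res = coherence(epoch_spectra(epochs_from_arrays(x, ref, tiny_array)))
        assert res.coh[0, 1:-1].mean() == pytest.approx(0.5, abs=0.02)

    def test_zero_power_bin_flagged_undefined(self, tiny_array):
        meg = np.zeros((2, tiny_array.n_channels, 100))
        ref = np.ones((2, 100))
        res = coherence(epoch_spectra(epochs_from_arrays(meg, ref, tiny_array)))
        assert np.isnan(res.coh[0, 1])

    @given(data=hnp.arrays(np.float64, (3, 2, 32),
                           elements=st.floats(-1e3, 1e3)))
    @settings(max_examples=50, deadline=None)
    def test_coherence_bounded_for_arbitrary_finite_input(self, data):
        arr = default_sensor_array(1)  # 3 channels; use 2 of them
        meg = np.concatenate([data, data[:, :1, :]], axis=1)
        res = coherence(epoch_spectra(epochs_from_arrays(meg, data[:, 0, :],
                                                         arr)))
        finite = res.coh[np.isfinite(res.coh)]
        assert np.all(finite >= 0.0) and np.all(finite <= 1.0)

    def test_scale_invariance(self, tiny_array, rng):
        meg = rng.standard_normal((5, tiny_array.n_channels, 200))
        ref = rng.standard_normal((5, 200))
        base = coherence(epoch_spectra(epochs_from_arrays(meg, ref,
                                                          tiny_array)))
        scaled = coherence(epoch_spectra(epochs_from_arrays(
            meg * 3.7, ref * -0.002, tiny_array)))
        np.testing.assert_allclose(scaled.coh, base.coh, atol=1e-12)


class TestPeak:
    def make_result(self, coh, array):
        freqs = np.arange(coh.shape[1], dtype=float)
        return CoherenceResult(coh=coh, freqs=freqs, k=10, array=array)

    def test_unique_maximum_found(self, tiny_array):
        coh = np.full((tiny_array.n_channels, 8), 0.1)
        coh[3, 3] = 0.9  # a gradiometer channel
        res = peak_ckc(self.make_result(coh, tiny_array), stim_freq=3.0)
        assert res.peak_channel == 3
        assert res.peak_value == 0.9
        assert res.peak_pair == int(tiny_array.pair_index[3])

    def test_tie_breaks_to_lowest_channel_index(self, tiny_array):
        coh = np.full((tiny_array.n_channels, 8), 0.2)
        coh[4, 3] = coh[7, 3] = 0.8
        res = peak_ckc(self.make_result(coh, tiny_array), stim_freq=3.0)
        assert res.peak_channel == 4

    def test_magnetometers_excluded_by_default(self, tiny_array):
        coh = np.full((tiny_array.n_channels, 8), 0.1)
        mag = tiny_array.channel_set("magnetometer")[0]
        coh[mag, 3] = 0.99
        res = peak_ckc(self.make_result(coh, tiny_array), stim_freq=3.0)
        assert tiny_array.kind[res.peak_channel] == GRAD

    def test_off_grid_frequency_rejected_unless_snapped(self, tiny_array):
        coh = np.full((tiny_array.n_channels, 8), 0.1)
        with pytest.raises(SpectralError, match="bin grid"):
            peak_ckc(self.make_result(coh, tiny_array), stim_freq=3.3)
        res = peak_ckc(self.make_result(coh, tiny_array), stim_freq=3.3,
                       snap=True)
        assert res.stim_freq == 3.0

    def test_peak_channel_has_strong_leadfield_gain(self, leadfield32, grid4):
        """In a signal-dominated run the winning gradiometer is among the
        sensors the true source projects to most strongly."""
        from ckc.design import separate_design
        from ckc.simulate import default_ground_truth, synth_session
        design = separate_design("D2", n_bursts=2, burst_s=40.0)
        truth = default_ground_truth(grid4, gain=2.0, seed=1)
        rec, kins, _ = synth_session(design, truth, leadfield32)
        es = make_epochs(rec, kins["D2"], EpochSpec(), design.burst_schedule)
        res = sensor_ckc(es, 3.0)
        ori = _tangential_orientation(grid4.nodes[truth.source_nodes["D2"]])
        gains = np.abs(leadfield32.full[truth.source_nodes["D2"]] @ ori)
        grads = es.array.channel_set(GRAD)
        top10 = grads[np.argsort(gains[grads])[::-1][:10]]
        assert res.peak_channel in top10


class TestThreshold:
    def test_exponent_one_closed_form(self):
        assert significance_threshold(n_trials=2, n_sens=1) == \
            pytest.approx(0.95)
        assert significance_threshold(n_trials=2, n_sens=204) == \
            pytest.approx(1 - 0.05 / 204)

    def test_strictly_decreasing_in_effective_trials(self):
        grid = np.linspace(2.0, 400.0, 150)
        vals = [significance_threshold(n, n_sens=204) for n in grid]
        assert np.all(np.diff(vals) < 0)

    def test_alpha_and_overlap_divisor_exposed(self):
        t1 = significance_threshold(100, 204, alpha=0.01)
        t2 = significance_threshold(100, 204, alpha=0.05)
        assert t1 > t2
        # the literal reading divides the trial count by d
        t3 = significance_threshold(100, 204, d=5.0)
        assert t3 > t2

    def test_invalid_arguments_rejected(self):
        with pytest.raises(SpectralError):
            significance_threshold(1, 204)  # exponent undefined
        with pytest.raises(SpectralError):
            significance_threshold(100, 204, alpha=1.5)

    def test_attach_threshold_uses_gradiometer_count(self, tiny_array, rng):
        meg = rng.standard_normal((10, tiny_array.n_channels, 200))
        res = coherence(epoch_spectra(epochs_from_arrays(meg, meg[:, 0, :],
                                                         tiny_array)))
        out = attach_threshold(res)
        n_grad = len(tiny_array.channel_set(GRAD))
        assert out.threshold == pytest.approx(
            significance_threshold(10, n_grad))


class TestSumRecordings:
    def test_self_sum_leaves_coherence_unchanged(self, coupled_session):
        rec = coupled_session["recording"]
        doubled = sum_recordings([rec, rec])
        spec = EpochSpec(grad_reject=1e9, mag_reject=1e9)
        es1 = segment_epochs(rec, np.ones(rec.n_samples), spec,
                             coupled_session["design"].burst_schedule)
        es2 = segment_epochs(doubled, np.ones(rec.n_samples), spec,
                             coupled_session["design"].burst_schedule)
        ref = np.random.default_rng(0).standard_normal(es1.ref.shape)
        es1 = dataclasses.replace(es1, ref=ref)
        es2 = dataclasses.replace(es2, ref=ref)
        c1 = coherence(epoch_spectra(es1))
        c2 = coherence(epoch_spectra(es2))
        np.testing.assert_allclose(c1.coh, c2.coh, atol=1e-12)

    def test_misaligned_onsets_rejected(self, coupled_session, grid4,
                                        leadfield32):
        from ckc.design import separate_design
        from ckc.simulate import make_stimulus_train
        shifted = separate_design("D2", n_bursts=2, burst_s=40.0)
        shifted = dataclasses.replace(
            shifted, burst_schedule=((1.0, 40.0), (46.0, 40.0)),
            total_duration=86.0)
        t_shift = make_stimulus_train(shifted)
        rec = coupled_session["recording"]
        with pytest.raises(SpectralError, match="onset"):
            sum_recordings([rec, rec],
                           [coupled_session["train"], t_shift])


class TestTopography:
    def test_table_shape_and_peak(self, coupled_session, tmp_path):
        res = sensor_ckc(coupled_session["epochs"], 3.0)
        table = topography_table(res)
        assert len(table) == res.array.n_channels
        assert table["coherence"].max() == pytest.approx(res.peak_value)
        path = tmp_path / "topo.tsv"
        table.to_csv(path, sep="\t", index=False)
        import pandas as pd
        back = pd.read_csv(path, sep="\t")
        np.testing.assert_allclose(back["coherence"], table["coherence"])


class TestReferenceRobustness:
    def test_surrogate_reference_with_same_onsets(self, coupled_session,
                                                  grid4, leadfield32):
        """Replacing the measured acceleration with a surrogate periodic
        reference sharing the onsets changes peak CKC by < 0.05."""
        from ckc.simulate import hann_pulse_kernel, synth_acceleration
        es = coupled_session["epochs"]
        base = sensor_ckc(es, 3.0)
        surrogate = synth_acceleration(
            coupled_session["train"], "D2",
            kernel=hann_pulse_kernel(120.0), axis_gains=(1.0, 1.0, 4.0),
            noise_sd=0.0)
        es2 = make_epochs(coupled_session["recording"], surrogate, EpochSpec(),
                          coupled_session["design"].burst_schedule)
        alt = sensor_ckc(es2, 3.0)
        assert abs(alt.peak_value - base.peak_value) < 0.05

    def test_phase_randomized_surrogate_destroys_significance(self,
                                                              coupled_session,
                                                              rng):
        """Randomly circular-shifting each reference epoch scrambles the
        MEG-reference phase relation and should kill significance.

        (Plain pairing shuffles cannot: with a strictly periodic stimulus
        and a 3995 ms epoch step the onset phase is nearly constant across
        epochs, so swapping epochs preserves the phase lock.)
        """
        es = coupled_session["epochs"]
        hits = 0
        for _ in range(10):
            shifts = rng.integers(0, es.n_samples, size=es.k)
            ref = np.stack([np.roll(es.ref[k], s)
                            for k, s in enumerate(shifts)])
            res = sensor_ckc(dataclasses.replace(es, ref=ref), 3.0)
            hits += res.significant
        # the threshold is calibrated at alpha=0.05 per surrogate, so allow
        # binomial slack around the nominal 5% exceedance rate
        assert hits <= 2
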