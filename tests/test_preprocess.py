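"""Binning, dead-time discard, STA computation, shuffle surrogate test."""

import numpy as np
import pytest

from spikevar import (
    KernelSpec,
    SpikeRaster,
    StimulusSet,
    bin_spikes,
    compute_sta,
    draw_ground_truth,
    generate_stimulus,
    simulate_raster,
    sta_shuffle_test,
)
from spikevar.io import read_raster_csv, write_raster_csv


def _stim(amps, frozen=True):
    amps = np.atleast_2d(np.asarray(amps, dtype=float))
    k = amps.shape[0]
    return StimulusSet(
        amplitudes=amps,
        is_frozen=np.full(k, frozen),
        frozen_realization_id=np.where(np.full(k, frozen), 0, -1),
    )


class TestBinSpikes:
    def test_dead_time_discard_worked_example(self):
        # pulses at 0, 0.04, 0.08 s; spikes at 5, 15 and 55 ms; the 5 ms
        # spike falls in the 10 ms dead window and is discarded
        raster = bin_spikes(
            [np.array([0.005, 0.015, 0.055])],
            [np.array([0.0, 0.04, 0.08])],
            delta_t=0.04,
            dead_time=0.010,
        )
        assert raster.counts.tolist() == [[1, 1, 0]]
        assert raster.n_dropped_dead == 1

    def test_no_spikes_gives_zero_raster(self):
        raster = bin_spikes([np.array([])], [np.arange(5) * 0.04], 0.04, 0.01)
        assert raster.counts.sum() == 0 and raster.n_bins == 5

    def test_hundred_second_trial_at_25hz_gives_2500_bins(self):
        pulses = np.arange(0.0, 100.0, 0.04)
        raster = bin_spikes([np.array([1.0, 2.0])], [pulses], 0.04, 0.01)
        assert raster.n_bins == 2500

    def test_boundary_spike_belongs_to_later_bin(self):
        # half-open bins: a spike exactly on a pulse timestamp joins that
        # pulse's bin (and is then dead-time-discarded if dead_time > 0)
        raster = bin_spikes([np.array([0.04])], [np.array([0.0, 0.04])], 0.04, 0.0)
        assert raster.counts.tolist() == [[0, 1]]

    def test_count_conservation_with_out_of_range_spikes(self):
        rng = np.random.default_rng(0)
        spikes = [np.sort(rng.uniform(-0.5, 5.0, size=200)) for _ in range(3)]
        pulses = [np.arange(0.0, 4.0, 0.04)] * 3
        raster = bin_spikes(spikes, pulses, 0.04, 0.01)
        assert raster.n_spikes + raster.n_dropped_dead + raster.n_dropped_range == 600
        assert raster.n_dropped_range > 0

    def test_unequal_pulse_counts_rejected(self):
        with pytest.raises(ValueError, match="unequal pulse counts"):
            bin_spikes([np.array([]), np.array([])], [np.arange(3) * 0.04, np.arange(4) * 0.04])

    def test_nonincreasing_pulses_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            bin_spikes([np.array([])], [np.array([0.0, 0.0, 0.04])])

    def test_csv_roundtrip_is_identity(self, tmp_path):
        rng = np.random.default_rng(1)
        raster = SpikeRaster(
            counts=rng.poisson(0.5, size=(4, 20)),
            delta_t=0.04,
            is_frozen=np.array([True, False, True, False]),
            dead_time=0.01,
        )
        p = tmp_path / "raster.csv"
        write_raster_csv(raster, p)
        back = read_raster_csv(p)
        assert (back.counts == raster.counts).all()
        assert back.delta_t == raster.delta_t
        assert (back.is_frozen == raster.is_frozen).all()
        assert (back.trial_ids == raster.trial_ids).all()


class TestSTA:
    def test_constant_stimulus_taps(self):
        raster = SpikeRaster(counts=np.array([[0, 1, 0, 2, 1]]), delta_t=0.04)
        stim = _stim(np.full((1, 5), 7.0))
        assert np.allclose(compute_sta(raster, stim, m=3, center=False).taps, 7.0)
        assert np.allclose(compute_sta(raster, stim, m=3, center=True).taps, 0.0)

    def test_single_spike_taps_equal_stimulus_slice(self):
        counts = np.zeros((1, 6), dtype=int)
        counts[0, 4] = 1
        raster = SpikeRaster(counts=counts, delta_t=0.04)
        x = np.arange(6.0)
        sta = compute_sta(raster, _stim(x), m=3, center=False)
        # lag 0 = own bin (x_4), lag 1 = x_3, lag 2 = x_2
        assert np.allclose(sta.taps, [4.0, 3.0, 2.0])

    def test_zero_spikes_is_an_error(self):
        raster = SpikeRaster(counts=np.zeros((2, 5), dtype=int), delta_t=0.04)
        stim = _stim(np.random.default_rng(0).normal(size=(2, 5)), frozen=False)
        with pytest.raises(ValueError, match="STA undefined"):
            compute_sta(raster, stim, m=3)

    def test_filter_recovery_from_simulation(self):
        truth = draw_ground_truth(
            18, 2500, 25,
            phi_kernel=KernelSpec("matern", 0.0, length=5.0),
            rho_kernel=KernelSpec("ar1", 0.0, corr=0.9),
            seed=13,
        )
        stim = generate_stimulus(18, 2500, frozen_fraction=1.0, seed=13)
        raster = simulate_raster(truth, stim, seed=13)
        sta = compute_sta(raster, stim, m=25)
        assert np.corrcoef(sta.taps, truth.filter_k)[0, 1] > 0.9


class TestShuffleTest:
    def test_too_few_shuffles_rejected(self):
        raster = SpikeRaster(counts=np.ones((2, 50), dtype=int), delta_t=0.04)
        stim = _stim(np.random.default_rng(0).normal(size=(2, 50)), frozen=False)
        with pytest.raises(ValueError, match="at least 100"):
            sta_shuffle_test(raster, stim, m=5, n_shuffles=10)

    def test_null_calibration_mostly_insignificant(self):
        rng = np.random.default_rng(7)
        flags = []
        for run in range(20):
            counts = rng.poisson(0.3, size=(4, 300))
            raster = SpikeRaster(counts=counts, delta_t=0.04)
            stim = _stim(rng.normal(-800, 280, size=(4, 300)), frozen=False)
            res = sta_shuffle_test(raster, stim, m=5, n_shuffles=500, seed=run)
            flags.append(res.significant)
        assert sum(flags) <= 5  # false-positive rate stays near the nominal level

    def test_strong_filter_is_significant(self):
        truth = draw_ground_truth(
            8, 1000, 10,
            phi_kernel=KernelSpec("matern", 0.0, length=5.0),
            rho_kernel=KernelSpec("ar1", 0.0, corr=0.9),
            filter_norm=1.0 / 280.0,
            seed=21,
        )
        stim = generate_stimulus(8, 1000, frozen_fraction=1.0, seed=21)
        raster = simulate_raster(truth, stim, seed=21)
        res = sta_shuffle_test(raster, stim, m=10, n_shuffles=200, seed=21)
        assert res.significant
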