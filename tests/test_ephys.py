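"""Recording analysis: band split, detection, spectra, depth profile, success."""

import numpy as np
import pytest

from retroprobe import ephys as E
from retroprobe import synthetic as syn

FS = 20000.0


def _block_from_trace(traces, steps=None, stimuli=None):
    traces = np.atleast_2d(traces)
    electrodes = [
        E.ElectrodeInfo("S1", i, "lower" if i == 0 else "upper", 25.0 if i == 0 else 15.0)
        for i in range(traces.shape[0])
    ]
    return E.RecordingBlock(
        traces_uv=traces,
        fs_hz=FS,
        electrodes=electrodes,
        steps=steps or [E.DepthStep(0, 0.0, traces.shape[1] / FS)],
        stimuli=stimuli or [],
    )


class TestBandSplit:
    @pytest.mark.parametrize("freq,goes_to", [(5.0, "lfp"), (1000.0, "spike")])
    def test_sinusoids_route_to_their_band(self, freq, goes_to):
        t = np.arange(int(4 * FS)) / FS
        block = _block_from_trace(np.sin(2 * np.pi * freq * t))
        spike, lfp = E.split_bands(block)
        kept, removed = (lfp, spike) if goes_to == "lfp" else (spike, lfp)
        mid = slice(int(FS), int(3 * FS))  # ignore filter edges
        assert np.abs(kept[0, mid]).max() > 0.9
        assert np.abs(removed[0, mid]).max() < 0.1  # >= 20 dB down

    def test_low_sampling_rate_rejected(self):
        block = _block_from_trace(np.zeros(1000))
        block.fs_hz = 4000.0
        with pytest.raises(ValueError):
            E.split_bands(block)

    def test_offnominal_rate_warns(self):
        block = _block_from_trace(np.zeros(4000))
        block.fs_hz = 10000.0
        with pytest.warns(UserWarning):
            E.split_bands(block)


class TestSpikeDetection:
    def test_noiseless_planted_spikes_recovered_at_their_times(self):
        times = np.arange(10) * 0.4 + 0.2
        trace = np.zeros(int(4.5 * FS))
        tpl = syn._spike_template(FS) * 50.0
        for t0 in times:
            i = int(t0 * FS)
            trace[i : i + tpl.size] += tpl
        train = E.detect_spikes(trace, FS, threshold_k=4.0)
        assert len(train) == 10
        assert np.all(np.abs(train.times_s - times) < 5e-4)

    def test_refractory_merges_close_events(self):
        trace = np.zeros(int(FS))
        tpl = syn._spike_template(FS) * 50.0
        for t0 in (0.5, 0.5004):  # 0.4 ms apart
            i = int(t0 * FS)
            trace[i : i + tpl.size] += tpl
        assert len(E.detect_spikes(trace, FS, threshold_k=4.0)) == 1

    def test_pure_noise_rarely_crosses_high_threshold(self, rng):
        noise = rng.normal(0, 5.0, int(10 * FS))
        assert len(E.detect_spikes(noise, FS, threshold_k=6.0)) <= 1

    def test_invalid_threshold_rejected(self):
        with pytest.raises(ValueError):
            E.detect_spikes(np.zeros(100), FS, threshold_k=0.0)


class TestSpectrum:
    def test_pure_tone_peak_at_generating_frequency(self):
        t = np.arange(int(10 * FS)) / FS
        spec = E.amplitude_spectrum(np.sin(2 * np.pi * 3.3 * t), FS)
        assert spec.dominant_frequency_hz == pytest.approx(3.3, abs=0.1)
        assert spec.peaks[0][1] == pytest.approx(1.0, rel=1e-6)

    def test_two_tones_two_peaks(self):
        t = np.arange(int(10 * FS)) / FS
        x = np.sin(2 * np.pi * 3.3 * t) + 0.6 * np.sin(2 * np.pi * 7.0 * t)
        spec = E.amplitude_spectrum(x, FS)
        found = sorted(round(f, 1) for f, _ in spec.peaks[:2])
        assert found == [3.3, 7.0]

    def test_dc_only_trace_has_no_band_peak(self):
        spec = E.amplitude_spectrum(np.full(int(4 * FS), 3.0), FS)
        assert spec.peaks == [] or spec.dominant_frequency_hz is None

    def test_empty_trace_rejected(self):
        with pytest.raises(ValueError):
            E.amplitude_spectrum(np.empty(0), FS)

    @pytest.mark.parametrize("freq", [1.7, 4.4, 12.3, 19.0])
    def test_peak_within_one_bin_across_band(self, freq):
        t = np.arange(int(5 * FS)) / FS  # 0.2 Hz resolution
        spec = E.amplitude_spectrum(np.sin(2 * np.pi * freq * t), FS)
        assert abs(spec.dominant_frequency_hz - freq) <= 0.2


class TestDepthProfile:
    def test_generator_schedule_recovered(self, wt_recording):
        block, truth = wt_recording
        trains = E.detect_spikes_block(block, threshold_k=5.0)
        counts, shift = E.depth_activity_profile(block, trains)
        assert counts.shape == (4, 6)
        assert np.array_equal(shift.to_numpy(), truth.activation_step.astype(float))
        # monotone non-decreasing activation with electrode height
        assert (np.diff(shift.to_numpy()) >= 0).all()

    def test_all_noise_block_has_empty_profile(self, rng):
        block = _block_from_trace(
            rng.normal(0, 5, (2, int(2 * FS))),
            steps=[E.DepthStep(0, 0.0, 1.0), E.DepthStep(1, 1.0, 2.0)],
        )
        trains = E.detect_spikes_block(block, threshold_k=6.0)
        counts, shift = E.depth_activity_profile(block, trains)
        assert (counts.to_numpy() <= 3).all()
        assert shift.isna().all()

    def test_missing_annotations_rejected(self):
        block = _block_from_trace(np.zeros(1000))
        block.steps = []
        with pytest.raises(ValueError):
            E.depth_activity_profile(block, [E.SpikeTrain(np.empty(0), np.empty(0))])


class TestLfpPolarity:
    def test_reversal_matches_generator_truth(self, wt_recording):
        block, truth = wt_recording
        _, lfp = E.split_bands(block)
        last = block.steps[-1]
        i0, i1 = int(last.t_start_s * FS), int(last.t_stop_s * FS)
        events = [
            E.StimulusEvent(ev.onset_s - last.t_start_s, ev.duration_s)
            for ev in block.stimuli
            if last.t_start_s <= ev.onset_s < last.t_stop_s
        ]
        resp = E.lfp_stimulus_response(lfp[:, i0:i1], FS, events)
        assert np.array_equal(resp.polarity.to_numpy(), truth.lfp_polarity[:, -1])

    def test_zero_signal_reports_neutral(self):
        resp = E.lfp_stimulus_response(
            np.zeros((1, int(3 * FS))), FS, [E.StimulusEvent(1.0)]
        )
        assert resp.polarity.iloc[0] == 0
        assert resp.amplitude_uv.iloc[0] == 0.0

    def test_identical_repeats_average_to_single_response(self, rng):
        t = np.arange(int(6 * FS)) / FS
        one = np.exp(-(((t - 1.1) / 0.05) ** 2))
        x = one + np.exp(-(((t - 3.1) / 0.05) ** 2))  # same response at both onsets
        single = E.lfp_stimulus_response(x, FS, [E.StimulusEvent(1.0)])
        both = E.lfp_stimulus_response(x, FS, [E.StimulusEvent(1.0), E.StimulusEvent(3.0)])
        assert both.amplitude_uv.iloc[0] == pytest.approx(single.amplitude_uv.iloc[0], rel=1e-6)

    def test_no_events_rejected(self):
        with pytest.raises(ValueError):
            E.lfp_stimulus_response(np.zeros((1, 1000)), FS, [])


class TestSuccessClassifier:
    def _noiseless_block(self, planted):
        block, truth = syn.gen_recording(
            syn.InsertionProtocol(n_steps=3),
            syn.RecordingScenario(
                mode="WT", noise_sd_uv=0.0, stimuli=[], step_duration_s=4.0,
                planted_spike_times=planted, seed=0,
            ),
        )
        return block, truth

    def test_upper_spikes_in_last_step_is_success(self):
        block, truth = self._noiseless_block(
            {3: np.array([10.1, 10.5, 10.9, 11.3])}  # upper electrode, last step
        )
        trains = E.detect_spikes_block(block)
        assert E.classify_insertion_success(block, trains) == {"S1": True}
        assert truth.success == {"S1": True}

    def test_lower_only_activity_is_failure(self):
        block, truth = self._noiseless_block({0: np.linspace(0.2, 11.5, 40)})
        trains = E.detect_spikes_block(block)
        assert E.classify_insertion_success(block, trains) == {"S1": False}
        assert truth.success == {"S1": False}

    def test_empty_recording_is_failure(self):
        block, _ = self._noiseless_block({})
        trains = [E.SpikeTrain(np.empty(0), np.empty(0), c) for c in range(4)]
        assert E.classify_insertion_success(block, trains) == {"S1": False}

    def test_no_upper_electrodes_rejected(self):
        block = _block_from_trace(np.zeros((1, 1000)))
        with pytest.raises(ValueError):
            E.classify_insertion_success(block, [E.SpikeTrain(np.empty(0), np.empty(0))])
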