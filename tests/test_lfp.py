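"""De-spiked LFP extraction: transient removal, combined FIR + decimation,
blockwise/whole-file equivalence, container packaging."""

import numpy as np
import pytest

from ephyskit.data_io import EventSeries, read_raw_header, write_raw
from ephyskit.lfp import LfpExtractionConfig, despike, extract_lfp
from ephyskit.synth import biphasic_waveform, default_probe


def _contaminated(rate=5000.0, duration=10.0, n_spikes=40, seed=0):
    """Clean LFP-band background plus biphasic transients at known times."""
    rng = np.random.default_rng(seed)
    t = np.arange(int(duration * rate)) / rate
    clean = 30.0 * np.cos(2 * np.pi * 10.0 * t) + 15.0 * rng.standard_normal(t.size)
    wave = biphasic_waveform(rate, 1.5, amplitude=250.0)
    half = len(wave) // 2
    times = np.sort(rng.uniform(0.5, duration - 0.5, n_spikes))
    dirty = clean.copy()
    for s in times:
        i0 = int(round(s * rate)) - half
        dirty[i0 : i0 + len(wave)] += wave
    return clean, dirty, times, rate


def _window_mask(times, rate, n, window_ms=(-2.0, 4.0)):
    mask = np.zeros(n, dtype=bool)
    for s in times:
        a = int(round((s + window_ms[0] * 1e-3) * rate))
        b = int(round((s + window_ms[1] * 1e-3) * rate))
        mask[max(a, 0) : min(b, n)] = True
    return mask


class TestDespike:
    @pytest.mark.parametrize("method", ["interpolate", "spectral"])
    def test_outside_windows_bit_unchanged(self, method):
        clean, dirty, times, rate = _contaminated()
        out = despike(dirty, rate, [times], method=method)
        mask = _window_mask(times, rate, dirty.size)
        assert np.array_equal(out[0, ~mask], dirty[~mask])

    @pytest.mark.parametrize("method", ["interpolate", "spectral"])
    def test_rms_error_halved_in_spike_windows(self, method):
        # replacing the transient must bring the signal at least 50% closer
        # (in RMS) to the uncontaminated ground truth inside spike windows
        clean, dirty, times, rate = _contaminated()
        out = despike(dirty, rate, [times], method=method)
        mask = _window_mask(times, rate, dirty.size)
        err_before = np.sqrt(np.mean((dirty[mask] - clean[mask]) ** 2))
        err_after = np.sqrt(np.mean((out[0, mask] - clean[mask]) ** 2))
        assert err_after < 0.5 * err_before

    def test_none_method_identity(self):
        _, dirty, times, rate = _contaminated()
        assert np.array_equal(despike(dirty, rate, [times], method="none"), dirty[None, :])

    def test_spectral_deterministic_and_seeded(self):
        _, dirty, times, rate = _contaminated()
        a = despike(dirty, rate, [times], method="spectral", seed=1)
        b = despike(dirty, rate, [times], method="spectral", seed=1)
        c = despike(dirty, rate, [times], method="spectral", seed=2)
        assert np.array_equal(a, b)
        assert not np.array_equal(a, c)

    def test_spectral_blockwise_matches_whole(self):
        # the surrogate is keyed on absolute sample position, so splitting
        # the signal into blocks reproduces the whole-signal replacement
        _, dirty, times, rate = _contaminated(duration=4.0, n_spikes=15)
        whole = despike(dirty, rate, [times], method="spectral", seed=3)
        cut = dirty.size // 2
        t_cut = cut / rate
        left = despike(
            dirty[:cut], rate, [times[times < t_cut + 0.01]], method="spectral", seed=3
        )
        right = despike(
            dirty[cut:],
            rate,
            [times[times > t_cut - 0.01]],
            method="spectral",
            seed=3,
            t0=t_cut,
        )
        glued = np.concatenate([left[0], right[0]])
        # spans fully inside one block must match exactly; skip 10 ms at the cut
        guard = _window_mask(np.array([t_cut]), rate, dirty.size, (-10.0, 10.0))
        assert np.array_equal(glued[~guard], whole[0][~guard])

    def test_overlapping_windows_merged(self):
        rate = 1000.0
        x = np.zeros(1000)
        x[102:108] = 50.0
        out = despike(x, rate, [np.array([0.103, 0.105])], method="interpolate")
        assert np.abs(out[0, 95:115]).max() < 5.0

    def test_wrong_spike_list_length(self):
        with pytest.raises(ValueError, match="per channel"):
            despike(np.zeros((2, 100)), 1000.0, [np.array([0.05])])

    def test_unknown_method(self):
        with pytest.raises(ValueError, match="method"):
            despike(np.zeros(100), 1000.0, [np.empty(0)], method="magic")


class TestConfig:
    def test_band_validation(self):
        with pytest.raises(ValueError, match="band"):
            LfpExtractionConfig(band=(150.0, 0.5))
        with pytest.raises(ValueError, match="Nyquist"):
            LfpExtractionConfig(band=(0.5, 600.0), target_rate=1000.0)

    def test_window_validation(self):
        with pytest.raises(ValueError, match="pre < post"):
            LfpExtractionConfig(despike_window=(4.0, -2.0))


class TestExtractLfp:
    def test_output_rate_duration_and_channels(self, demo_container, demo_recording):
        assert demo_container.lfp_rate == 1000.0
        assert demo_container.n_channels == demo_recording.n_channels
        assert demo_container.n_samples == demo_recording.n_samples // 30
        assert demo_container.channel_labels == demo_recording.channel_labels

    def test_events_carried_over(self, demo_container, demo_events):
        labels = {e.label for e in demo_container.events}
        assert {e.label for e in demo_events} <= labels
        stim_in = next(e for e in demo_events if e.kind == "stimulus")
        stim_out = demo_container.event_series(stim_in.label)
        assert np.array_equal(stim_out.times, stim_in.times)

    def test_provenance_record_appended(self, demo_container, demo_recording):
        rec = demo_container.history[-1]
        assert rec.operation == "extract_lfp"
        assert rec.parameters["target_rate_hz"] == 1000.0
        assert rec.parameters["despike_method"] == "spectral"
        assert str(demo_recording.source_path) in rec.input_paths[0]

    def test_oscillation_amplitude_preserved(self, tmp_path):
        # a 10 Hz, 40 uV tone passes the 0.5-150 Hz chain unchanged
        rate = 30000.0
        t = np.arange(int(4.0 * rate)) / rate
        data = (40.0 * np.cos(2 * np.pi * 10.0 * t))[None, :]
        rec = read_raw_header(
            write_raw(data, rate, default_probe(1), tmp_path / "r")
        )
        c = extract_lfp(rec, [], LfpExtractionConfig(despike_method="none"))
        core = c.signals[0, 500:3500]
        t_out = np.arange(c.n_samples) / c.lfp_rate
        ref = 40.0 * np.cos(2 * np.pi * 10.0 * t_out)[500:3500]
        assert np.allclose(core, ref, atol=0.5)

    @pytest.mark.parametrize("method", ["none", "interpolate", "spectral"])
    def test_blockwise_equals_whole_file(self, tmp_path, rng, method):
        rate = 10000.0
        n = 40000
        data = rng.standard_normal((2, n)) * 20
        rec = read_raw_header(write_raw(data, rate, default_probe(2), tmp_path / "r"))
        spikes = EventSeries(
            "Spikes Channel AD01 |1|", "spike", np.sort(rng.uniform(0.2, 3.8, 25))
        )
        big = LfpExtractionConfig(despike_method=method, ram_budget=10**9)
        small = LfpExtractionConfig(despike_method=method, ram_budget=2 * n // 3)
        c1 = extract_lfp(rec, [spikes], big)
        c2 = extract_lfp(rec, [spikes], small)
        scale = np.abs(c1.signals).max()
        assert np.abs(c1.signals - c2.signals).max() <= 1e-6 * scale

    def test_non_integer_ratio_rejected(self, tmp_path, rng):
        rec = read_raw_header(
            write_raw(rng.standard_normal((1, 1000)), 2500.0, default_probe(1), tmp_path / "r")
        )
        with pytest.raises(ValueError, match="integer multiple"):
            extract_lfp(rec, [], LfpExtractionConfig(target_rate=1000.0))

    def test_despiking_removes_transient_power(self, tmp_path):
        clean, dirty, times, rate = _contaminated(rate=5000.0)
        rec = read_raw_header(
            write_raw(dirty[None, :], rate, default_probe(1), tmp_path / "r")
        )
        spikes = EventSeries("Spikes Channel AD01 |1|", "spike", times)
        raw_c = extract_lfp(rec, [spikes], LfpExtractionConfig(despike_method="none"))
        de_c = extract_lfp(
            rec, [spikes], LfpExtractionConfig(despike_method="interpolate")
        )
        # ground-truth LFP: the clean signal through the same chain
        rec2 = read_raw_header(
            write_raw(clean[None, :], rate, default_probe(1), tmp_path / "r2")
        )
        truth = extract_lfp(rec2, [], LfpExtractionConfig(despike_method="none"))
        sl = slice(500, -500)
        err_raw = np.sqrt(np.mean((raw_c.signals[0, sl] - truth.signals[0, sl]) ** 2))
        err_de = np.sqrt(np.mean((de_c.signals[0, sl] - truth.signals[0, sl]) ** 2))
        assert err_de < err_raw

    def test_int16_storage_preserved(self, demo_container):
        assert demo_container.storage_encoding == "int16"
        assert demo_container.storage_gains is not None
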