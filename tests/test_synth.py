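"""Synthetic ground-truth generation: schedules, Poisson trains, background,
waveform templates, recording assembly."""

import numpy as np
import pytest
from scipy import signal

from ephyskit.synth import (
    DEFAULT_CONDITION_DIRECTIONS,
    OscillationSpec,
    TrialSchedule,
    UnitSpec,
    assemble_recording,
    biphasic_waveform,
    condition_direction,
    default_probe,
    generate_demo_dataset,
    generate_lfp_background,
    generate_schedule,
    generate_spike_trains,
)


class TestConditions:
    def test_direction_parse(self):
        assert condition_direction("Stim On 0") == 0.0
        assert condition_direction("Stim On pi") == pytest.approx(np.pi)
        assert condition_direction("Stim On -1/2 pi") == pytest.approx(-np.pi / 2)
        assert len(DEFAULT_CONDITION_DIRECTIONS) == 8

    def test_unknown_label(self):
        with pytest.raises(ValueError):
            condition_direction("Stim On banana")


class TestSchedule:
    def test_counts_and_non_overlap(self):
        sch = TrialSchedule(n_repeats=3)
        events = generate_schedule(sch, seed=7)
        assert len(events) == 8
        all_onsets = np.sort(np.concatenate([e.times for e in events]))
        assert all_onsets.size == sch.n_trials
        # onsets are separated by at least stimulus + ITI
        assert np.all(np.diff(all_onsets) >= sch.stimulus_duration + sch.inter_trial_interval - 1e-9)
        for e in events:
            assert e.times.size == 3

    def test_deterministic(self):
        sch = TrialSchedule(n_repeats=2)
        a = generate_schedule(sch, seed=5)
        b = generate_schedule(sch, seed=5)
        for x, y in zip(a, b):
            assert np.array_equal(x.times, y.times)

    def test_min_duration_contains_schedule(self):
        sch = TrialSchedule(n_repeats=2)
        events = generate_schedule(sch, seed=1)
        last = max(e.times.max() for e in events)
        assert last + sch.stimulus_duration <= sch.min_duration


class TestSpikeTrains:
    def test_homogeneous_rate_recovery(self):
        unit = UnitSpec("AD01", 1, base_rate=25.0)
        trains = generate_spike_trains([unit], [], 0.5, duration=200.0, seed=3)
        rate = trains[0].times.size / 200.0
        # Poisson SE at 25 Hz over 200 s is ~0.35 Hz; allow 4 SE
        assert rate == pytest.approx(25.0, abs=1.5)

    def test_tuning_modulates_counts(self):
        sch = TrialSchedule(n_repeats=40, stimulus_duration=0.5, inter_trial_interval=0.3)
        events = generate_schedule(sch, seed=11)
        unit = UnitSpec("AD01", 1, base_rate=30.0, preferred_direction=0.0, kappa=2.0)
        duration = sch.min_duration
        trains = generate_spike_trains([unit], events, 0.5, duration, seed=4)
        times = trains[0].times

        def count_in(label):
            ev = next(e for e in events if e.label == label)
            return sum(
                np.count_nonzero((times >= t) & (times < t + 0.5)) for t in ev.times
            )

        pref = count_in("Stim On 0")
        anti = count_in("Stim On pi")
        # expected ratio exp(2*(1-(-1))) = e^4 ~ 55; require strong separation
        assert pref > 5 * max(anti, 1)

    def test_phase_locking_concentrates_phases(self):
        unit = UnitSpec("AD01", 1, base_rate=40.0, phase_lock=(10.0, 3.0, 0.0))
        trains = generate_spike_trains([unit], [], 0.5, duration=120.0, seed=9)
        phases = (2 * np.pi * 10.0 * trains[0].times) % (2 * np.pi)
        plv = np.abs(np.mean(np.exp(1j * phases)))
        # von Mises conc 3 -> PLV = I1(3)/I0(3) ~ 0.81
        assert plv > 0.6

    def test_zero_rate_unit_is_silent(self):
        trains = generate_spike_trains(
            [UnitSpec("AD01", 1, base_rate=0.0)], [], 0.5, 10.0, seed=0
        )
        assert trains[0].times.size == 0

    def test_schedule_beyond_duration_rejected(self):
        sch = TrialSchedule(n_repeats=2)
        events = generate_schedule(sch, seed=0)
        with pytest.raises(ValueError, match="duration"):
            generate_spike_trains(
                [UnitSpec("AD01", 1, base_rate=10.0)], events, 0.5, 2.0, seed=0
            )


class TestBackground:
    def test_std_normalization(self):
        bg = generate_lfp_background(3, 10.0, 1000.0, noise_std=50.0, seed=2)
        assert bg.shape == (3, 10000)
        assert np.allclose(bg.std(axis=1), 50.0, rtol=0.02)

    def test_pink_spectrum_slope(self):
        bg = generate_lfp_background(1, 60.0, 1000.0, spectral_exponent=1.0, seed=4)
        f, p = signal.welch(bg[0], fs=1000.0, nperseg=4096)
        sel = (f >= 2) & (f <= 100)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.25)

    def test_oscillation_peak_and_gains(self):
        osc = OscillationSpec(freq=10.0, amplitude=40.0, channel_gains=[1.0, 0.0])
        bg = generate_lfp_background(
            2, 20.0, 1000.0, oscillations=[osc], noise_std=5.0, seed=1
        )
        f, p = signal.welch(bg, fs=1000.0, nperseg=2048, axis=1)
        i10 = np.argmin(np.abs(f - 10.0))
        # the driven channel shows a sharp peak over its spectral neighborhood;
        # the zero-gain channel shows none (compare to flanking 1/f bins)
        flank0 = 0.5 * (p[0, i10 - 4] + p[0, i10 + 4])
        flank1 = 0.5 * (p[1, i10 - 4] + p[1, i10 + 4])
        assert p[0, i10] > 50 * flank0
        assert p[1, i10] < 5 * flank1

    def test_envelope_window(self):
        osc = OscillationSpec(freq=8.0, amplitude=100.0, envelope=(2.0, 4.0))
        bg = generate_lfp_background(
            1, 6.0, 1000.0, oscillations=[osc], noise_std=1.0, seed=3
        )
        assert bg[0, 2500] != pytest.approx(bg[0, 500], abs=1)  # crude presence check
        assert np.std(bg[0, 2000:4000]) > 10 * np.std(bg[0, :1000])

    def test_rate_too_low_for_oscillation(self):
        with pytest.raises(ValueError, match="4x"):
            generate_lfp_background(
                1, 1.0, 100.0, oscillations=[OscillationSpec(freq=40.0, amplitude=1.0)]
            )


class TestWaveform:
    def test_biphasic_shape(self):
        w = biphasic_waveform(30000.0, 1.5, amplitude=100.0)
        assert w.min() == pytest.approx(-100.0)
        assert w.max() > 0  # rebound present
        assert abs(w.min()) > abs(w.max())  # trough dominates

    def test_net_negative_area(self):
        # extracellular spikes have non-cancelling lobes; the template must
        # carry net area so it has low-frequency spectral content
        w = biphasic_waveform(30000.0, 1.5)
        assert w.sum() < -0.1 * np.abs(w).sum() / len(w) * len(w) * 0.1
        assert w.sum() < 0

    def test_duration_sets_length(self):
        assert len(biphasic_waveform(30000.0, 1.5)) == 45
        assert len(biphasic_waveform(10000.0, 2.0)) == 20


class TestAssembly:
    def test_spikes_added_at_times_with_neighbor_leak(self):
        rate = 10000.0
        bg = np.zeros((3, 10000))
        unit = UnitSpec("AD02", 1, base_rate=1.0, amplitude_uv=80.0)
        from ephyskit.data_io import EventSeries

        trains = [EventSeries(unit.label, "spike", np.array([0.3, 0.7]))]
        data, truth = assemble_recording(
            bg, rate, trains, [unit], default_probe(3), neighbor_gain=0.3
        )
        assert data[0].any() is np.False_  # channel above untouched
        assert data[1].min() == pytest.approx(-80.0)
        assert data[2].min() == pytest.approx(-24.0)  # 0.3 leak
        i = int(round(0.3 * rate))
        assert np.abs(data[1, i - 30 : i + 30]).max() == pytest.approx(80.0)
        assert truth["units"][0]["n_spikes"] == 2
        assert truth["units"][0]["amplitude_uv"] == 80.0

    def test_default_amplitude_tracks_background_rms(self, rng):
        bg = rng.standard_normal((1, 20000)) * 10.0
        from ephyskit.data_io import EventSeries

        unit = UnitSpec("AD01", 1, base_rate=1.0)
        trains = [EventSeries(unit.label, "spike", np.array([1.0]))]
        _, truth = assemble_recording(bg, 10000.0, trains, [unit], default_probe(1))
        rms = float(np.sqrt(np.mean(bg**2)))
        assert truth["units"][0]["amplitude_uv"] == pytest.approx(5 * rms, rel=1e-9)

    def test_unknown_unit_channel(self):
        unit = UnitSpec("ZZ99", 1, base_rate=1.0)
        with pytest.raises(KeyError, match="ZZ99"):
            assemble_recording(np.zeros((1, 100)), 1000.0, [], [unit], default_probe(1))


class TestDemoDataset:
    def test_files_written_and_reproducible(self, demo_dataset, tmp_path):
        for key in ("header", "events", "probe", "ground_truth"):
            assert demo_dataset[key].exists()
        truth = demo_dataset["truth"]
        assert truth["seed"] == 20240917
        assert len(truth["units"]) == 4
        # same seed regenerates byte-identical raw payload
        again = generate_demo_dataset(
            tmp_path, seed=20240917, n_channels=4, schedule=TrialSchedule(n_repeats=2)
        )
        a = demo_dataset["header"].with_suffix(".dat").read_bytes()
        b = again["header"].with_suffix(".dat").read_bytes()
        assert a == b

    def test_events_carry_schedule_and_spikes(self, demo_events):
        kinds = {e.kind for e in demo_events}
        assert kinds == {"stimulus", "spike"}
        stim = [e for e in demo_events if e.kind == "stimulus"]
        assert len(stim) == 8
        assert all(e.times.size == 2 for e in stim)
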