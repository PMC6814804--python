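"""Synthetic multichannel extracellular recordings with known ground truth.

Emulates a linear-probe visual-cortex experiment: Poisson-spiking units with
von Mises direction tuning, biphasic spike waveforms superimposed on a 1/f
LFP background with oscillatory bursts, a trial schedule of direction
conditions, and optional spike-phase locking to a background oscillation.
Every generator is deterministic given its seed, and the injected rates,
tuning and locking are returned as a ground-truth bundle so downstream
estimators can be validated by parameter recovery.

This is a statistical emulation, not a biophysical one: no conductance
models, no electrode drift, no bursting.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Sequence

import numpy as np

from ephyskit.data_io import (
    ChannelInfo,
    EventSeries,
    make_spike_label,
    write_events,
    write_probe_geometry,
    write_raw,
)

DEFAULT_CONDITION_DIRECTIONS: dict[str, float] = {
    "Stim On -3/4 pi": -0.75 * np.pi,
    "Stim On -1/2 pi": -0.50 * np.pi,
    "Stim On -1/4 pi": -0.25 * np.pi,
    "Stim On 0": 0.0,
    "Stim On 1/4 pi": 0.25 * np.pi,
    "Stim On 1/2 pi": 0.50 * np.pi,
    "Stim On 3/4 pi": 0.75 * np.pi,
    "Stim On pi": np.pi,
}

_DIRECTION_RE = re.compile(r"Stim On (-?)(?:(\d+)/(\d+) )?pi$|Stim On (-?\d+(?:\.\d+)?)$")


def condition_direction(label: str) -> float:
    """Motion direction (radians) encoded in a condition label like
    ``"Stim On -1/4 pi"`` or ``"Stim On 0"``."""
    if label in DEFAULT_CONDITION_DIRECTIONS:
        return DEFAULT_CONDITION_DIRECTIONS[label]
    m = _DIRECTION_RE.match(label)
    if m is None:
        raise ValueError(f"cannot parse a direction from condition label {label!r}")
    if m.group(4) is not None:
        return float(m.group(4))
    sign = -1.0 if m.group(1) == "-" else 1.0
    frac = 1.0 if m.group(2) is None else float(m.group(2)) / float(m.group(3))
    return sign * frac * np.pi


@dataclass(frozen=True)
class UnitSpec:
    """Ground-truth description of one simulated unit.

    Firing is an inhomogeneous Poisson process: ``base_rate`` outside
    stimulation, and during a stimulus of direction theta

        rate = base_rate * exp(kappa * (cos(theta - preferred_direction) - 1))

    (a von Mises tuning profile peaking at ``preferred_direction``).
    ``phase_lock``, when set to ``(freq_hz, concentration, preferred_phase)``,
    additionally concentrates spikes at the given phase of a cosine
    oscillation ``cos(2*pi*freq*t)`` in the LFP background.
    """

    channel: str
    cell_number: int
    base_rate: float
    preferred_direction: float = 0.0
    kappa: float = 0.0
    amplitude_uv: float | None = None  # None -> 5x background RMS at assembly
    waveform_ms: float = 1.5
    phase_lock: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if self.cell_number < 1:
            raise ValueError("cell_number must be >= 1")
        if not np.isfinite(self.base_rate) or self.base_rate < 0:
            raise ValueError(f"base_rate must be finite and >= 0, got {self.base_rate}")
        if self.kappa < 0:
            raise ValueError("kappa must be >= 0")
        if not 0 < self.waveform_ms < 5:
            raise ValueError("waveform duration must be under 5 ms")

    @property
    def label(self) -> str:
        return make_spike_label(self.channel, self.cell_number)

    def rate_for_direction(self, theta: float) -> float:
        return self.base_rate * np.exp(
            self.kappa * (np.cos(theta - self.preferred_direction) - 1.0)
        )


@dataclass(frozen=True)
class TrialSchedule:
    """Block design: every condition repeated ``n_repeats`` times, stimuli of
    ``stimulus_duration`` s separated by ``inter_trial_interval`` s."""

    condition_labels: tuple[str, ...] = tuple(DEFAULT_CONDITION_DIRECTIONS)
    n_repeats: int = 4
    stimulus_duration: float = 0.5
    inter_trial_interval: float = 1.0
    t_start: float = 1.0

    def __post_init__(self) -> None:
        if self.n_repeats < 1:
            raise ValueError("n_repeats must be >= 1")
        if self.stimulus_duration <= 0 or self.inter_trial_interval < 0:
            raise ValueError("durations must be positive")
        object.__setattr__(self, "condition_labels", tuple(self.condition_labels))

    @property
    def n_trials(self) -> int:
        return len(self.condition_labels) * self.n_repeats

    @property
    def min_duration(self) -> float:
        """Recording length needed to contain the full schedule."""
        period = self.stimulus_duration + self.inter_trial_interval
        return self.t_start + self.n_trials * period


def generate_schedule(schedule: TrialSchedule, seed: int) -> list[EventSeries]:
    """Randomly interleave condition presentations on a regular grid.

    Returns one stimulus EventSeries per condition, ``n_repeats`` onsets
    each; onsets are non-overlapping by construction and deterministic for
    a given seed.
    """
    rng = np.random.default_rng(seed)
    order = np.repeat(np.arange(len(schedule.condition_labels)), schedule.n_repeats)
    rng.shuffle(order)
    period = schedule.stimulus_duration + schedule.inter_trial_interval
    onsets = schedule.t_start + np.arange(order.size) * period
    out = []
    for ci, label in enumerate(schedule.condition_labels):
        out.append(
            EventSeries(label=label, kind="stimulus", times=onsets[order == ci])
        )
    return out


def _stimulus_rate_profile(
    unit: UnitSpec,
    schedule_events: Sequence[EventSeries],
    stimulus_duration: float,
    directions: dict[str, float] | None,
) -> list[tuple[float, float, float]]:
    """(onset, offset, rate) windows during which the unit's rate differs."""
    windows = []
    for ev in schedule_events:
        theta = (
            directions[ev.label] if directions is not None else condition_direction(ev.label)
        )
        rate = unit.rate_for_direction(theta)
        for t in ev.times:
            windows.append((t, t + stimulus_duration, rate))
    windows.sort()
    return windows


def generate_spike_trains(
    units: Sequence[UnitSpec],
    schedule_events: Sequence[EventSeries],
    stimulus_duration: float,
    duration: float,
    seed: int,
    directions: dict[str, float] | None = None,
) -> list[EventSeries]:
    """Inhomogeneous Poisson spike trains by thinning, one per unit.

    The candidate process runs at ``base_rate`` (the tuning profile's
    maximum); candidates are kept with probability rate(t)/base_rate, where
    rate(t) follows the unit's von Mises tuning during stimulus windows and
    equals ``base_rate`` elsewhere. Units with ``phase_lock`` are further
    thinned by a von Mises acceptance profile on the oscillation phase
    ``2*pi*f*t``, which preserves locking without changing the preferred
    direction.
    """
    for ev in schedule_events:
        if ev.times.size and ev.times[-1] + stimulus_duration > duration + 1e-9:
            raise ValueError(
                f"schedule extends to {ev.times[-1] + stimulus_duration:g} s but "
                f"duration is only {duration:g} s"
            )
    rng = np.random.default_rng(seed)
    out = []
    for unit in units:
        if unit.base_rate == 0:
            out.append(EventSeries(label=unit.label, kind="spike", times=np.empty(0)))
            continue
        n_cand = rng.poisson(unit.base_rate * duration)
        cand = np.sort(rng.uniform(0, duration, size=n_cand))
        rate = np.full(cand.size, unit.base_rate)
        for t0, t1, r in _stimulus_rate_profile(
            unit, schedule_events, stimulus_duration, directions
        ):
            in_win = (cand >= t0) & (cand < t1)
            rate[in_win] = r
        keep = rng.uniform(size=cand.size) < rate / unit.base_rate
        times = cand[keep]
        if unit.phase_lock is not None:
            freq, conc, pref_phase = unit.phase_lock
            phase = 2 * np.pi * freq * times
            accept = np.exp(conc * (np.cos(phase - pref_phase) - 1.0))
            times = times[rng.uniform(size=times.size) < accept]
        out.append(EventSeries(label=unit.label, kind="spike", times=times))
    return out


@dataclass(frozen=True)
class OscillationSpec:
    """A shared sinusoidal component of the LFP background.

    ``envelope`` is either None (always on), an ``(on, off)`` window in
    seconds, or a callable of the time vector returning a gain envelope.
    ``channel_gains`` scales the component per channel (default: all 1),
    which is how coherent channel groups are built.
    """

    freq: float
    amplitude: float
    envelope: tuple[float, float] | Callable[[np.ndarray], np.ndarray] | None = None
    channel_gains: Sequence[float] | None = None


def generate_lfp_background(
    n_channels: int,
    duration: float,
    rate: float,
    spectral_exponent: float = 1.0,
    oscillations: Sequence[OscillationSpec] = (),
    seed: int = 0,
    noise_std: float = 50.0,
) -> np.ndarray:
    """1/f^exponent Gaussian background plus shared oscillatory bursts.

    Noise is generated independently per channel by spectral shaping and
    scaled to ``noise_std`` (µV). Each oscillation is ``amplitude *
    cos(2*pi*f*t)`` times its envelope, added to every channel with its
    per-channel gain, so channels sharing a component are coherent at that
    frequency. Requires ``rate >= 4 * max oscillation frequency``.
    """
    for osc in oscillations:
        if rate < 4 * osc.freq:
            raise ValueError(
                f"sampling rate {rate:g} Hz is below 4x the {osc.freq:g} Hz "
                f"oscillation; raise the rate to avoid aliasing"
            )
    rng = np.random.default_rng(seed)
    n = int(round(duration * rate))
    t = np.arange(n) / rate

    white = rng.standard_normal((n_channels, n))
    if spectral_exponent == 0:
        noise = white * noise_std
    else:
        spec = np.fft.rfft(white, axis=1)
        f = np.fft.rfftfreq(n, d=1 / rate)
        shaping = np.zeros_like(f)
        shaping[1:] = f[1:] ** (-spectral_exponent / 2.0)
        noise = np.fft.irfft(spec * shaping[None, :], n=n, axis=1)
        std = noise.std(axis=1, keepdims=True)
        std[std == 0] = 1.0
        noise = noise / std * noise_std

    for osc in oscillations:
        wave = osc.amplitude * np.cos(2 * np.pi * osc.freq * t)
        if isinstance(osc.envelope, tuple):
            on, off = osc.envelope
            wave = wave * ((t >= on) & (t < off))
        elif callable(osc.envelope):
            wave = wave * osc.envelope(t)
        gains = (
            np.ones(n_channels)
            if osc.channel_gains is None
            else np.asarray(osc.channel_gains, dtype=float)
        )
        if gains.shape != (n_channels,):
            raise ValueError("channel_gains must have one entry per channel")
        noise += gains[:, None] * wave[None, :]
    return noise


def biphasic_waveform(rate: float, duration_ms: float = 1.5, amplitude: float = 1.0) -> np.ndarray:
    """Difference-of-Gaussians extracellular spike template: a sharp negative
    trough followed by a slower, smaller positive rebound, peak |value| =
    amplitude. The rebound does not cancel the trough, so the template has
    net (negative) area — like a physiological extracellular action
    potential, its spectrum extends down to low frequencies."""
    n = max(3, int(round(duration_ms * 1e-3 * rate)))
    t = np.linspace(0, duration_ms, n)  # ms
    trough_t, rebound_t = 0.35 * duration_ms, 0.62 * duration_ms
    w = -np.exp(-(((t - trough_t) / (0.10 * duration_ms)) ** 2)) + 0.35 * np.exp(
        -(((t - rebound_t) / (0.18 * duration_ms)) ** 2)
    )
    return amplitude * w / np.abs(w).max()


def assemble_recording(
    background: np.ndarray,
    rate: float,
    spike_trains: Sequence[EventSeries],
    units: Sequence[UnitSpec],
    channels: Sequence[ChannelInfo],
    neighbor_gain: float = 0.3,
) -> tuple[np.ndarray, dict]:
    """Superimpose each unit's waveform on its home channel at its spike
    times, with a scaled copy on the next channel down the probe.

    The neighbor leakage reproduces the duplicate-unit scenario in which a
    spike sorter detects the same neuron on two adjacent contacts. Returns
    the assembled signal and a ground-truth bundle (per-unit rates, tuning,
    locking, amplitudes).
    """
    data = np.array(background, dtype=np.float64, copy=True)
    n_ch, n = data.shape
    if n_ch != len(channels):
        raise ValueError("background rows must match channel count")
    labels = [c.label for c in channels]
    duration = n / rate
    truth_units = []
    trains = {ev.label: ev for ev in spike_trains}
    for unit in units:
        if unit.channel not in labels:
            raise KeyError(f"unit channel {unit.channel!r} not in probe {labels}")
        ch = labels.index(unit.channel)
        amp = (
            unit.amplitude_uv
            if unit.amplitude_uv is not None
            else 5.0 * float(np.sqrt(np.mean(background[ch] ** 2)))
        )
        wave = biphasic_waveform(rate, unit.waveform_ms, amp)
        half = len(wave) // 2
        train = trains.get(unit.label)
        times = train.times if train is not None else np.empty(0)
        if times.size and times[-1] > duration:
            raise ValueError(
                f"spike at {times[-1]:g} s beyond recording duration {duration:g} s"
            )
        for t in times:
            i0 = int(round(t * rate)) - half
            a, b = max(i0, 0), min(i0 + len(wave), n)
            if a >= b:
                continue
            seg = wave[a - i0 : b - i0]
            data[ch, a:b] += seg
            if ch + 1 < n_ch and neighbor_gain:
                data[ch + 1, a:b] += neighbor_gain * seg
        truth_units.append(
            {
                "label": unit.label,
                "channel": unit.channel,
                "cell_number": unit.cell_number,
                "base_rate_hz": unit.base_rate,
                "preferred_direction_rad": unit.preferred_direction,
                "kappa": unit.kappa,
                "amplitude_uv": amp,
                "waveform_ms": unit.waveform_ms,
                "phase_lock": list(unit.phase_lock) if unit.phase_lock else None,
                "n_spikes": int(times.size),
            }
        )
    truth = {"neighbor_gain": neighbor_gain, "rate_hz": rate, "units": truth_units}
    return data, truth


# ---------------------------------------------------------------------------
# turnkey dataset
# ---------------------------------------------------------------------------


def default_probe(n_channels: int = 32, pitch_um: float = 100.0) -> list[ChannelInfo]:
    """Linear probe with ``n_channels`` contacts, labels AD01..ADnn."""
    return [
        ChannelInfo(
            label=f"AD{i + 1:02d}",
            position=(0.0, 0.0, -i * pitch_um * 1e-6),
            group="probe0",
        )
        for i in range(n_channels)
    ]


def generate_demo_dataset(
    outdir: str | Path,
    seed: int,
    n_channels: int = 8,
    sampling_rate: float = 30_000.0,
    schedule: TrialSchedule | None = None,
    units: Sequence[UnitSpec] | None = None,
    oscillations: Sequence[OscillationSpec] | None = None,
    spectral_exponent: float = 1.0,
    noise_std: float = 50.0,
    sample_encoding: str = "int16",
    gain_uv_per_count: float = 0.195,
) -> dict:
    """Generate and write a complete synthetic dataset to ``outdir``.

    Produces raw payload + header, an event TSV (stimulus onsets and spike
    trains), a probe-geometry TSV and a ground-truth JSON. Returns a dict of
    the file paths plus the truth bundle.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(seed)
    sub = rng.integers(0, 2**31 - 1, size=3)

    if schedule is None:
        schedule = TrialSchedule()
    channels = default_probe(n_channels)
    if units is None:
        prefs = np.linspace(-np.pi, np.pi, 5)[:4]
        units = [
            UnitSpec(
                channel=channels[(2 * i) % n_channels].label,
                cell_number=1 + (2 * i) // n_channels,
                base_rate=15.0,
                preferred_direction=float(prefs[i % 4]),
                kappa=2.0,
                phase_lock=(10.0, 1.5, 0.0) if i == 0 else None,
            )
            for i in range(min(4, n_channels))
        ]
    if oscillations is None:
        oscillations = [
            OscillationSpec(freq=10.0, amplitude=30.0),
            OscillationSpec(
                freq=22.0,
                amplitude=20.0,
                channel_gains=[1.0 if i < n_channels // 2 else 0.1 for i in range(n_channels)],
            ),
        ]

    duration = schedule.min_duration + 1.0
    sched_events = generate_schedule(schedule, int(sub[0]))
    trains = generate_spike_trains(
        units, sched_events, schedule.stimulus_duration, duration, int(sub[1])
    )
    background = generate_lfp_background(
        n_channels,
        duration,
        sampling_rate,
        spectral_exponent=spectral_exponent,
        oscillations=oscillations,
        seed=int(sub[2]),
        noise_std=noise_std,
    )
    data, truth = assemble_recording(background, sampling_rate, trains, units, channels)

    header = write_raw(
        data,
        sampling_rate,
        channels,
        outdir / "raw",
        sample_encoding=sample_encoding,
        gains=gain_uv_per_count if sample_encoding == "int16" else 1.0,
    )
    events_path = write_events(list(sched_events) + list(trains), outdir / "events.tsv")
    probe_path = write_probe_geometry(channels, outdir / "probe.tsv")
    truth["schedule"] = {
        "condition_labels": list(schedule.condition_labels),
        "n_repeats": schedule.n_repeats,
        "stimulus_duration_s": schedule.stimulus_duration,
        "inter_trial_interval_s": schedule.inter_trial_interval,
    }
    truth["seed"] = seed
    truth_path = outdir / "ground_truth.json"
    truth_path.write_text(json.dumps(truth, indent=1))
    return {
        "header": header,
        "events": events_path,
        "probe": probe_path,
        "ground_truth": truth_path,
        "truth": truth,
    }
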