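"""Cut continuous LFP and spike trains into condition-labeled trials.

Trials are fixed windows ``[w0, w1)`` (seconds, half-open) around stimulus
onsets; t = 0 is the onset. The onset sample is ``floor(t_event * rate)``
and the window is realized in samples as
``[onset + round(w0*rate), onset + round(w1*rate))``, so every trial has
the same length. Spikes are re-expressed relative to each onset; a spike
exactly at ``w1`` is excluded, one at ``w0`` included.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from ephyskit.data_io import ChannelInfo, EventSeries, LfpContainer


@dataclass
class TrialSet:
    """Epoched signal tensor plus per-trial relative spike times.

    data : trials x channels x samples (µV)
    time : sample times relative to onset, seconds
    conditions : per-trial condition label
    spikes : unit label -> list (per trial) of relative spike-time arrays
    bad_trials : boolean flags; flagged trials are excluded by analyses
    onsets : absolute onset time of each trial in the source recording
    """

    data: np.ndarray
    time: np.ndarray
    conditions: list[str]
    window: tuple[float, float]
    rate: float
    channels: list[ChannelInfo]
    spikes: dict[str, list[np.ndarray]] = field(default_factory=dict)
    bad_trials: np.ndarray = None  # type: ignore[assignment]
    onsets: np.ndarray = None  # type: ignore[assignment]
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be trials x channels x samples")
        n_trials = self.data.shape[0]
        if len(self.conditions) != n_trials:
            raise ValueError("need one condition label per trial")
        if self.bad_trials is None:
            self.bad_trials = np.zeros(n_trials, dtype=bool)
        else:
            self.bad_trials = np.asarray(self.bad_trials, dtype=bool)
        if self.onsets is None:
            self.onsets = np.full(n_trials, np.nan)
        else:
            self.onsets = np.asarray(self.onsets, dtype=np.float64)
        expected = int(round((self.window[1] - self.window[0]) * self.rate))
        if self.time.size != expected or self.data.shape[2] != expected:
            raise ValueError(
                f"window {self.window} at {self.rate:g} Hz implies "
                f"{expected} samples, got time={self.time.size}, "
                f"data={self.data.shape[2]}"
            )
        w0, w1 = self.window
        for unit, per_trial in self.spikes.items():
            if len(per_trial) != n_trials:
                raise ValueError(f"unit {unit!r}: need one spike list per trial")
            for times in per_trial:
                if times.size and (times[0] < w0 or times[-1] >= w1):
                    raise ValueError(
                        f"unit {unit!r} has spikes outside the window {self.window}"
                    )

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def channel_labels(self) -> list[str]:
        return [c.label for c in self.channels]

    @property
    def units(self) -> list[str]:
        return list(self.spikes)

    def good_trials(self) -> np.ndarray:
        return np.flatnonzero(~self.bad_trials)

    def trials_of(self, condition: str, good_only: bool = True) -> np.ndarray:
        """Indices of trials with the given condition label."""
        mask = np.array([c == condition for c in self.conditions])
        if good_only:
            mask &= ~self.bad_trials
        return np.flatnonzero(mask)

    def select(self, trial_indices: Sequence[int]) -> "TrialSet":
        idx = np.asarray(trial_indices, dtype=int)
        return TrialSet(
            data=self.data[idx],
            time=self.time,
            conditions=[self.conditions[i] for i in idx],
            window=self.window,
            rate=self.rate,
            channels=list(self.channels),
            spikes={u: [per[i] for i in idx] for u, per in self.spikes.items()},
            bad_trials=self.bad_trials[idx],
            onsets=self.onsets[idx],
        )


def import_epochs(
    container: LfpContainer,
    event_labels: Sequence[str],
    window: tuple[float, float] = (-0.5, 1.0),
) -> TrialSet:
    """Epoch a container around the onsets of the named event series.

    One trial per event occurrence whose full window lies inside the
    recording; onsets too close to an edge are dropped and counted in
    ``meta['n_dropped']``. All spike series in the container are carried
    along with times re-expressed relative to each onset.
    """
    w0, w1 = float(window[0]), float(window[1])
    if not w0 < w1:
        raise ValueError(f"window must satisfy w0 < w1, got {window}")
    rate = container.lfp_rate
    i_w0 = int(round(w0 * rate))
    i_w1 = int(round(w1 * rate))
    n_len = i_w1 - i_w0
    n_sig = container.n_samples

    known = [e.label for e in container.events]
    for lab in event_labels:
        if lab not in known:
            raise KeyError(f"no event series {lab!r} in container; known: {known}")

    entries = []  # (onset_time, label)
    for lab in event_labels:
        for t in container.event_series(lab).times:
            entries.append((float(t), lab))
    entries.sort()

    kept, dropped = [], 0
    for t, lab in entries:
        onset = int(np.floor(t * rate))
        i0, i1 = onset + i_w0, onset + i_w1
        if i0 < 0 or i1 > n_sig:
            dropped += 1
        else:
            kept.append((t, lab, i0, i1))
    if not kept:
        raise ValueError(
            f"no trials survive: all {len(entries)} onsets are within "
            f"{window} s of a recording edge"
        )

    data = np.stack([container.signals[:, i0:i1] for _, _, i0, i1 in kept])
    time = (np.arange(n_len) + i_w0) / rate
    spikes: dict[str, list[np.ndarray]] = {}
    for ev in container.spike_series():
        per_trial = []
        for t, _, _, _ in kept:
            rel = ev.times - t
            per_trial.append(rel[(rel >= w0) & (rel < w1)])
        spikes[ev.label] = per_trial

    return TrialSet(
        data=data,
        time=time,
        conditions=[lab for _, lab, _, _ in kept],
        window=(w0, w1),
        rate=rate,
        channels=list(container.channels),
        spikes=spikes,
        onsets=np.array([t for t, _, _, _ in kept]),
        meta={"n_dropped": dropped, "n_selected": len(entries)},
    )


def baseline_correct(
    trials: TrialSet,
    baseline: tuple[float, float] = (-0.5, -0.1),
    mode: str = "subtract_mean",
) -> TrialSet:
    """Baseline-correct every trial/channel over ``baseline`` ``[b0, b1)`` s.

    ``subtract_mean`` removes the baseline mean; ``zscore`` scales by the
    baseline standard deviation as well. Trials with zero baseline variance
    under ``zscore`` are flagged bad (counted in ``meta['n_zero_sigma']``)
    and left unscaled.
    """
    if mode not in ("subtract_mean", "zscore"):
        raise ValueError(f"mode must be 'subtract_mean' or 'zscore', got {mode!r}")
    b0, b1 = baseline
    w0, w1 = trials.window
    if not (w0 <= b0 < b1 <= w1):
        raise ValueError(f"baseline {baseline} outside trial window {trials.window}")
    mask = (trials.time >= b0) & (trials.time < b1)
    if not mask.any():
        raise ValueError(f"baseline {baseline} contains no samples")

    data = trials.data.copy()
    base = data[:, :, mask]
    mu = base.mean(axis=2, keepdims=True)
    data -= mu
    bad = trials.bad_trials.copy()
    n_zero = 0
    if mode == "zscore":
        sd = base.std(axis=2, keepdims=True)
        zero = sd[:, :, 0] == 0
        zero_trials = zero.any(axis=1)
        sd[sd == 0] = 1.0
        data /= sd
        n_zero = int(zero_trials.sum())
        bad |= zero_trials
    meta = dict(trials.meta)
    meta.update({"baseline": (b0, b1), "baseline_mode": mode, "n_zero_sigma": n_zero})
    return TrialSet(
        data=data,
        time=trials.time,
        conditions=list(trials.conditions),
        window=trials.window,
        rate=trials.rate,
        channels=list(trials.channels),
        spikes=trials.spikes,
        bad_trials=bad,
        onsets=trials.onsets,
        meta=meta,
    )


def trials_to_container(trials: TrialSet) -> LfpContainer:
    """Concatenate trials back into a continuous container.

    Trial k occupies samples ``[k*L, (k+1)*L)``; a stimulus event series per
    condition marks each trial's onset and spikes are restored to absolute
    times, so re-epoching with the same window reproduces the trial set.
    """
    n_trials, n_ch, L = trials.data.shape
    signals = trials.data.transpose(1, 0, 2).reshape(n_ch, n_trials * L)
    rate = trials.rate
    w0 = trials.window[0]
    onsets = np.arange(n_trials) * L / rate - w0
    events: list[EventSeries] = []
    for cond in dict.fromkeys(trials.conditions):
        t_cond = onsets[[i for i, c in enumerate(trials.conditions) if c == cond]]
        events.append(EventSeries(label=cond, kind="stimulus", times=t_cond))
    for unit, per_trial in trials.spikes.items():
        abs_times = np.concatenate(
            [rel + onsets[i] for i, rel in enumerate(per_trial)]
        ) if per_trial else np.empty(0)
        events.append(EventSeries(label=unit, kind="spike", times=abs_times))
    return LfpContainer(
        signals=signals,
        lfp_rate=rate,
        channels=list(trials.channels),
        events=events,
    )
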