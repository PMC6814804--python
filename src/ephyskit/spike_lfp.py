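"""Spike-LFP measures: spike-triggered average and spike-field coherence.

The spike-triggered average (STA) is the mean LFP snippet centered on a
unit's spikes, normalized by spike count. Spike-field coherence follows the
Fries estimator: the power spectrum of the STA divided by the mean power
spectrum of the individual spike-triggered snippets, in percent —

    SFC(f) = 100 * P_STA(f) / mean_i P_snippet_i(f)

so perfectly phase-locked spikes give 100% and N spikes at independent
phases give ~100/N % in expectation. Spectra use a single Hann taper over
the snippet window; the frequency resolution is 1 / window length.

Spikes whose full window does not fit inside the recording (or their trial)
are dropped, not zero-padded, and counted in the result.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.signal as sps

from ephyskit.data_io import LfpContainer
from ephyskit.epochs import TrialSet

DEFAULT_WINDOW = (-0.150, 0.150)


@dataclass
class StaResult:
    """Spike-triggered average per channel with bootstrap confidence band."""

    sta: np.ndarray  # channels x lags, µV
    lags: np.ndarray  # seconds, lag 0 at the center
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_spikes: int
    n_dropped: int
    unit_id: str
    channel_labels: list[str]

    def channel(self, label: str) -> np.ndarray:
        return self.sta[self.channel_labels.index(label)]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.sta.T, index=self.lags, columns=self.channel_labels)


@dataclass
class SfcResult:
    """Fries spike-field coherence per channel, percent in [0, 100]."""

    sfc: np.ndarray  # channels x frequencies
    frequencies: np.ndarray  # Hz
    snippet_window: tuple[float, float]
    n_spikes: int
    n_dropped: int
    unit_id: str
    channel_labels: list[str]
    n_clipped: int = 0  # values numerically outside [0, 100] before clipping
    n_zero_denominator: int = 0

    def channel(self, label: str) -> np.ndarray:
        return self.sfc[self.channel_labels.index(label)]

    def peak_frequency(self, channel: str | None = None) -> float:
        row = self.sfc.mean(axis=0) if channel is None else self.channel(channel)
        return float(self.frequencies[int(np.argmax(row))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.sfc.T, index=self.frequencies, columns=self.channel_labels
        )


def _collect_snippets(
    obj: TrialSet | LfpContainer, unit: str, window: tuple[float, float]
) -> tuple[np.ndarray, int, float, list[str]]:
    """Spike-triggered snippets (spikes x channels x lags) from a trial set
    or a continuous container; returns (snippets, n_dropped, rate, labels)."""
    w0, w1 = window
    if not w0 < w1:
        raise ValueError(f"window must satisfy w0 < w1, got {window}")

    if isinstance(obj, LfpContainer):
        rate = obj.lfp_rate
        i0 = int(round(w0 * rate))
        i1 = int(round(w1 * rate))
        times = obj.event_series(unit).times
        n = obj.n_samples
        snippets, dropped = [], 0
        for t in times:
            c = int(round(t * rate))
            a, b = c + i0, c + i1
            if a < 0 or b > n:
                dropped += 1
            else:
                snippets.append(obj.signals[:, a:b])
        labels = obj.channel_labels
    elif isinstance(obj, TrialSet):
        rate = obj.rate
        i0 = int(round(w0 * rate))
        i1 = int(round(w1 * rate))
        if unit not in obj.spikes:
            raise KeyError(f"unknown unit {unit!r}; known units: {obj.units}")
        tw0 = obj.window[0]
        L = obj.data.shape[2]
        snippets, dropped = [], 0
        for ti in obj.good_trials():
            for r in obj.spikes[unit][ti]:
                c = int(round((r - tw0) * rate))
                a, b = c + i0, c + i1
                if a < 0 or b > L:
                    dropped += 1
                else:
                    snippets.append(obj.data[ti, :, a:b])
        labels = obj.channel_labels
    else:
        raise TypeError(f"expected TrialSet or LfpContainer, got {type(obj).__name__}")

    if not snippets:
        raise ValueError(
            f"unit {unit!r}: no spike has its full {window} s window inside "
            f"the data ({dropped} dropped)"
        )
    return np.stack(snippets), dropped, rate, labels


def spike_triggered_average(
    obj: TrialSet | LfpContainer,
    unit: str,
    window: tuple[float, float] = DEFAULT_WINDOW,
    ci_level: float = 0.95,
    n_boot: int = 500,
    seed: int = 0,
) -> StaResult:
    """Average LFP around each spike of ``unit``, on every channel.

    The STA is the snippet sum divided by the usable spike count; the
    confidence band is a seeded percentile bootstrap over spikes.
    """
    snippets, dropped, rate, labels = _collect_snippets(obj, unit, window)
    n_spikes = snippets.shape[0]
    sta = snippets.mean(axis=0)
    i0 = int(round(window[0] * rate))
    lags = (np.arange(snippets.shape[2]) + i0) / rate

    rng = np.random.default_rng(seed)
    alpha = (1 - ci_level) / 2
    boots = np.empty((n_boot,) + sta.shape)
    for b in range(n_boot):
        pick = rng.integers(0, n_spikes, size=n_spikes)
        boots[b] = snippets[pick].mean(axis=0)
    ci_low = np.quantile(boots, alpha, axis=0)
    ci_high = np.quantile(boots, 1 - alpha, axis=0)

    return StaResult(
        sta=sta,
        lags=lags,
        ci_low=ci_low,
        ci_high=ci_high,
        n_spikes=n_spikes,
        n_dropped=dropped,
        unit_id=unit,
        channel_labels=list(labels),
    )


def spike_field_coherence(
    obj: TrialSet | LfpContainer,
    unit: str,
    window: tuple[float, float] = DEFAULT_WINDOW,
    max_freq: float = 50.0,
) -> SfcResult:
    """Fries spike-field coherence of ``unit`` against every channel.

    Both the STA spectrum and the per-snippet spectra use the same Hann
    taper over the snippet window, making the estimator invariant to
    uniform rescaling of the LFP. Frequencies are reported up to
    ``max_freq`` (display cap, default 50 Hz).
    """
    snippets, dropped, rate, labels = _collect_snippets(obj, unit, window)
    n_spikes = snippets.shape[0]
    if n_spikes < 2:
        raise ValueError("spike-field coherence needs at least 2 usable spikes")
    L = snippets.shape[2]
    taper = sps.windows.hann(L, sym=False)

    sta = snippets.mean(axis=0)
    p_sta = np.abs(np.fft.rfft(sta * taper, axis=1)) ** 2
    p_snip = (np.abs(np.fft.rfft(snippets * taper, axis=2)) ** 2).mean(axis=0)

    freqs = np.fft.rfftfreq(L, d=1 / rate)
    zero_den = p_snip <= 0
    denom = np.where(zero_den, 1.0, p_snip)
    sfc = 100.0 * p_sta / denom
    sfc[zero_den] = 0.0

    clipped = int(np.count_nonzero((sfc < 0) | (sfc > 100 + 1e-6)))
    sfc = np.clip(sfc, 0.0, 100.0)

    keep = freqs <= max_freq
    return SfcResult(
        sfc=sfc[:, keep],
        frequencies=freqs[keep],
        snippet_window=tuple(window),
        n_spikes=n_spikes,
        n_dropped=dropped,
        unit_id=unit,
        channel_labels=list(labels),
        n_clipped=clipped,
        n_zero_denominator=int(zero_den[:, keep].sum()),
    )
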