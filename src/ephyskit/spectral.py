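"""LFP frequency analysis.

Welch power spectra, complex Morlet wavelet time-frequency maps with
baseline z-scoring, and all-pairs magnitude-squared coherence (MSC) from
Welch cross- and auto-spectra.

The Morlet wavelet is parameterized by a cycles count (default 7): at
frequency f its Gaussian envelope has standard deviation
sigma_t = cycles / (2*pi*f), fixing the time-frequency trade-off. The
default frequency grid is logarithmic from 2 to 90 Hz (40 points).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.signal as sps


def default_wavelet_frequencies(
    fmin: float = 2.0, fmax: float = 90.0, n: int = 40
) -> np.ndarray:
    return np.geomspace(fmin, fmax, n)


def welch_psd(
    block: np.ndarray,
    rate: float,
    segment_length: float = 1.0,
    overlap: float = 0.5,
) -> tuple[np.ndarray, np.ndarray]:
    """Welch power spectral density per channel (Hann windows, averaged
    periodograms). Returns ``(frequencies, psd)`` with psd in units²/Hz;
    integrating psd over frequency recovers the signal variance (Parseval).
    """
    block = np.atleast_2d(np.asarray(block, dtype=np.float64))
    if not np.all(np.isfinite(block)):
        raise ValueError("welch_psd requires finite samples")
    nper = int(round(segment_length * rate))
    if nper > block.shape[1]:
        raise ValueError(
            f"segment of {segment_length} s ({nper} samples) exceeds the "
            f"signal length ({block.shape[1]} samples)"
        )
    nover = int(round(nper * overlap))
    f, psd = sps.welch(
        block, fs=rate, window="hann", nperseg=nper, noverlap=nover, axis=1
    )
    return f, psd


@dataclass
class TfMap:
    """Time-frequency power map (frequencies x times) for one signal."""

    power: np.ndarray
    frequencies: np.ndarray
    times: np.ndarray
    normalization: str = "raw"  # or "zscore"
    flagged_rows: list[int] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.power, index=self.frequencies, columns=self.times)


def morlet_tf(
    signal: np.ndarray,
    rate: float,
    frequencies: np.ndarray | None = None,
    cycles: float = 7.0,
    times: np.ndarray | None = None,
) -> TfMap:
    """Complex Morlet wavelet decomposition of a single trial signal.

    Power at (f, t) is the squared magnitude of the convolution with a
    zero-mean complex Morlet wavelet of ``cycles`` cycles at f. Frequencies
    above Nyquist raise; frequencies below one cycle per epoch are rejected
    because the wavelet would not fit the data.
    """
    x = np.asarray(signal, dtype=np.float64).ravel()
    if frequencies is None:
        frequencies = default_wavelet_frequencies()
    frequencies = np.sort(np.asarray(frequencies, dtype=float))
    n = x.size
    epoch_len = n / rate
    if np.any(frequencies >= rate / 2):
        raise ValueError(
            f"wavelet frequencies up to {frequencies.max():g} Hz exceed the "
            f"Nyquist frequency {rate / 2:g} Hz"
        )
    if np.any(frequencies < 1.0 / epoch_len):
        raise ValueError(
            f"lowest frequency {frequencies.min():g} Hz is below one cycle "
            f"per {epoch_len:g} s epoch"
        )
    power = np.empty((frequencies.size, n))
    for i, f in enumerate(frequencies):
        sigma_t = cycles / (2 * np.pi * f)
        half = int(np.ceil(4 * sigma_t * rate))
        tw = np.arange(-half, half + 1) / rate
        wav = np.exp(2j * np.pi * f * tw) * np.exp(-(tw**2) / (2 * sigma_t**2))
        wav -= wav.mean()  # zero mean: no DC leakage
        wav /= np.sqrt(np.sum(np.abs(wav) ** 2))  # unit energy
        conv = sps.fftconvolve(x.astype(complex), wav, mode="same")
        power[i] = np.abs(conv) ** 2
    if times is None:
        times = np.arange(n) / rate
    return TfMap(power=power, frequencies=frequencies, times=np.asarray(times))


def baseline_zscore_tf(tfmap: TfMap, baseline: tuple[float, float]) -> TfMap:
    """Z-score each frequency row against the ``[b0, b1)`` baseline period.

    Rows with zero baseline variance are set to 0 and listed in
    ``flagged_rows``.
    """
    b0, b1 = baseline
    t = tfmap.times
    if b0 < t[0] - 1e-12 or b1 > t[-1] + 1.0 / max(len(t), 1):
        raise ValueError(f"baseline {baseline} outside map times [{t[0]:g}, {t[-1]:g}]")
    mask = (t >= b0) & (t < b1)
    if not mask.any():
        raise ValueError(f"baseline {baseline} contains no time bins")
    base = tfmap.power[:, mask]
    mu = base.mean(axis=1, keepdims=True)
    sd = base.std(axis=1, keepdims=True)
    flagged = np.flatnonzero(sd[:, 0] == 0)
    sd[sd == 0] = 1.0
    z = (tfmap.power - mu) / sd
    z[flagged] = 0.0
    return TfMap(
        power=z,
        frequencies=tfmap.frequencies,
        times=t,
        normalization="zscore",
        flagged_rows=list(flagged),
    )


@dataclass
class CoherenceMatrix:
    """All-pairs magnitude-squared coherence (channels x channels x freqs)."""

    msc: np.ndarray
    frequencies: np.ndarray
    channel_labels: list[str]

    def at_frequency(self, freq: float) -> np.ndarray:
        """The NxN coherence slice at the frequency bin nearest ``freq`` —
        the per-frequency display of the coherence matrix."""
        i = int(np.argmin(np.abs(self.frequencies - freq)))
        return self.msc[:, :, i]

    def pair(self, lab1: str, lab2: str) -> np.ndarray:
        i = self.channel_labels.index(lab1)
        j = self.channel_labels.index(lab2)
        return self.msc[i, j]

    def to_frame(self, freq: float) -> pd.DataFrame:
        return pd.DataFrame(
            self.at_frequency(freq),
            index=self.channel_labels,
            columns=self.channel_labels,
        )


def nxn_coherence(
    block: np.ndarray,
    rate: float,
    segment_length: float = 1.0,
    overlap: float = 0.5,
    channel_labels: list[str] | None = None,
) -> CoherenceMatrix:
    """Magnitude-squared coherence between all channel pairs.

    MSC(f) = |S_xy(f)|² / (S_xx(f) S_yy(f)) with the cross- and
    auto-spectra estimated by Welch averaging (Hann windows). Needs at
    least 2 averaging segments — with a single segment the estimator is
    degenerate at 1 everywhere.
    """
    block = np.atleast_2d(np.asarray(block, dtype=np.float64))
    n_ch, n = block.shape
    nper = int(round(segment_length * rate))
    step = nper - int(round(nper * overlap))
    n_segs = (n - nper) // step + 1 if n >= nper else 0
    if n_segs < 2:
        raise ValueError(
            f"coherence needs >= 2 averaging segments; got {n_segs} "
            f"({segment_length} s segments on {n / rate:g} s of data)"
        )
    win = sps.windows.hann(nper, sym=False)
    segs = np.stack(
        [block[:, k * step : k * step + nper] * win for k in range(n_segs)], axis=1
    )  # ch x seg x nper
    spec = np.fft.rfft(segs, axis=2)
    # cross-spectral matrix averaged over segments
    s = np.einsum("isf,jsf->ijf", spec, np.conj(spec)) / n_segs
    auto = np.real(np.einsum("iif->if", s))
    auto_safe = np.where(auto <= 0, 1.0, auto)
    msc = np.abs(s) ** 2 / (auto_safe[:, None, :] * auto_safe[None, :, :])
    bad = auto <= 0
    msc[bad[:, None, :] | bad[None, :, :]] = 0.0
    msc = np.clip((msc + msc.transpose(1, 0, 2)) / 2, 0.0, 1.0)
    for i in range(n_ch):
        msc[i, i, :] = 1.0
    freqs = np.fft.rfftfreq(nper, d=1 / rate)
    if channel_labels is None:
        channel_labels = [f"ch{i}" for i in range(n_ch)]
    return CoherenceMatrix(msc=msc, frequencies=freqs, channel_labels=list(channel_labels))
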