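"""Continuous-signal conditioning.

DC-offset removal, linear-phase (symmetric FIR, zero net group delay)
band-pass/band-stop/notch/low/high-pass filtering, polyphase resampling, and
bad-channel / bad-segment masking.

Filters are windowed-sinc designs (Kaiser window), with the order chosen
from the requested transition width and stop-band attenuation. Signals are
reflect-padded by one filter length before convolution so short epochs do
not show start-up transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from fractions import Fraction

import numpy as np
import scipy.signal as sps

_FILTER_KINDS = ("bandpass", "bandstop", "notch", "lowpass", "highpass")


@dataclass(frozen=True)
class FilterSpec:
    """Linear-phase FIR filter description.

    Parameters
    ----------
    kind : one of bandpass, bandstop, notch, lowpass, highpass
    edges : cutoff frequencies in Hz (two for band filters, one for
        lowpass/highpass, the mains frequency for notch)
    transition_width : Hz; width of each transition band. Defaults to a
        quarter of the lowest edge, floored at 0.5 Hz.
    attenuation : stop-band attenuation in dB (default 60).
    notch_bandwidth : full stop-band width of a notch, Hz (default 2).
    """

    kind: str
    edges: tuple[float, ...]
    transition_width: float | None = None
    attenuation: float = 60.0
    notch_bandwidth: float = 2.0

    def __post_init__(self) -> None:
        if self.kind not in _FILTER_KINDS:
            raise ValueError(f"filter kind must be one of {_FILTER_KINDS}, got {self.kind!r}")
        edges = tuple(float(e) for e in (self.edges if np.iterable(self.edges) else (self.edges,)))
        object.__setattr__(self, "edges", edges)
        n_expected = 1 if self.kind in ("lowpass", "highpass", "notch") else 2
        if len(edges) != n_expected:
            raise ValueError(f"{self.kind} filter needs {n_expected} edge(s), got {edges}")
        if any(e <= 0 for e in edges):
            raise ValueError(f"filter edges must be > 0, got {edges}")
        if n_expected == 2 and not edges[0] < edges[1]:
            raise ValueError(f"band edges must satisfy low < high, got {edges}")

    def band_edges(self) -> tuple[float, ...]:
        """Edges actually used for design (a notch expands to a narrow band)."""
        if self.kind == "notch":
            f0 = self.edges[0]
            half = self.notch_bandwidth / 2
            return (max(f0 - half, 1e-6), f0 + half)
        return self.edges

    def effective_transition(self) -> float:
        if self.transition_width is not None:
            return float(self.transition_width)
        return max(0.5, 0.25 * min(self.band_edges()))


def design_fir(spec: FilterSpec, rate: float) -> np.ndarray:
    """Design the symmetric FIR taps for ``spec`` at sampling rate ``rate``."""
    edges = spec.band_edges()
    nyq = rate / 2
    if any(e >= nyq for e in edges):
        raise ValueError(f"filter edges {edges} must lie strictly below Nyquist {nyq:g} Hz")
    width = spec.effective_transition()
    ntaps, beta = sps.kaiserord(spec.attenuation, width / nyq)
    ntaps |= 1  # Type-I (odd) so every response, incl. highpass/bandstop, is valid
    pass_zero = spec.kind in ("lowpass", "bandstop", "notch")
    cutoff = list(edges)
    return sps.firwin(ntaps, cutoff, window=("kaiser", beta), pass_zero=pass_zero, fs=rate)


def apply_filter(block: np.ndarray, rate: float, spec: FilterSpec) -> np.ndarray:
    """Zero-phase filter ``block`` (channels x samples).

    The symmetric FIR is applied with reflect padding of one filter length
    and the (integer) group delay compensated, so in-band sinusoids come out
    amplitude-preserved with no phase shift.
    """
    block = np.atleast_2d(np.asarray(block, dtype=np.float64))
    taps = design_fir(spec, rate)
    return _fir_zero_phase(block, taps)


def _fir_zero_phase(block: np.ndarray, taps: np.ndarray) -> np.ndarray:
    n = block.shape[1]
    pad = len(taps)
    if n == 0:
        return block.copy()
    pad = min(pad, n - 1) if n > 1 else 0
    if pad:
        padded = np.concatenate(
            [block[:, pad:0:-1], block, block[:, -2 : -2 - pad : -1]], axis=1
        )
    else:
        padded = block
    out = sps.oaconvolve(padded, taps[None, :], mode="same", axes=1)
    return out[:, pad : pad + n]


def remove_dc(
    block: np.ndarray,
    rate: float | None = None,
    window: tuple[float, float] | None = None,
) -> np.ndarray:
    """Subtract the per-channel mean computed over ``window`` ``[t0, t1)``
    seconds (default: the whole signal)."""
    block = np.atleast_2d(np.asarray(block, dtype=np.float64))
    if block.shape[0] == 0 or block.shape[1] == 0:
        raise ValueError("cannot remove DC from an empty signal block")
    if window is None:
        mean = block.mean(axis=1, keepdims=True)
    else:
        if rate is None:
            raise ValueError("rate is required when a window is given")
        i0 = int(np.floor(window[0] * rate))
        i1 = int(np.floor(window[1] * rate))
        if not (0 <= i0 < i1 <= block.shape[1]):
            raise ValueError(f"DC window {window} outside signal of {block.shape[1]} samples")
        mean = block[:, i0:i1].mean(axis=1, keepdims=True)
    return block - mean


def resample_signal(block: np.ndarray, rate_in: float, rate_out: float) -> np.ndarray:
    """Polyphase resampling with built-in anti-alias low-pass.

    Output length is ``floor(n_samples * rate_out / rate_in)``; content below
    the output Nyquist is preserved.
    """
    if rate_out <= 0:
        raise ValueError(f"rate_out must be > 0, got {rate_out}")
    block = np.atleast_2d(np.asarray(block, dtype=np.float64))
    if rate_out == rate_in:
        return block.copy()
    frac = Fraction(rate_out / rate_in).limit_denominator(10_000)
    out = sps.resample_poly(block, frac.numerator, frac.denominator, axis=1)
    n_out = int(np.floor(block.shape[1] * rate_out / rate_in))
    return out[:, :n_out]


@dataclass
class BadMask:
    """Channels and time segments to exclude from analysis.

    Segments are ``[t0, t1)`` in seconds; overlapping or touching segments
    are merged on construction.
    """

    bad_channels: list[str] = field(default_factory=list)
    bad_segments: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        segs = sorted((float(a), float(b)) for a, b in self.bad_segments)
        for a, b in segs:
            if not a < b:
                raise ValueError(f"bad segment [{a}, {b}) is empty or inverted")
        merged: list[tuple[float, float]] = []
        for a, b in segs:
            if merged and a <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], b))
            else:
                merged.append((a, b))
        self.bad_segments = merged
        self.bad_channels = list(dict.fromkeys(self.bad_channels))

    def overlaps(self, t0: float, t1: float) -> bool:
        """True if the half-open interval [t0, t1) intersects any bad segment."""
        return any(a < t1 and t0 < b for a, b in self.bad_segments)


def apply_bad_mask(obj, mask: BadMask):
    """Exclude bad channels/segments from a container or trial set.

    Returns ``(filtered, report)``: a copy with bad channels dropped (and,
    for trial sets, trials overlapping bad segments flagged bad), plus a
    report of what was excluded.
    """
    from ephyskit.data_io import LfpContainer
    from ephyskit.epochs import TrialSet

    labels = obj.channel_labels
    unknown = [c for c in mask.bad_channels if c not in labels]
    if unknown:
        raise KeyError(f"unknown channel(s) {unknown}; known channels: {labels}")
    keep = [i for i, lab in enumerate(labels) if lab not in mask.bad_channels]

    report = {
        "n_bad_channels": len(labels) - len(keep),
        "n_channels_kept": len(keep),
        "n_bad_segments": len(mask.bad_segments),
    }

    if isinstance(obj, LfpContainer):
        out = LfpContainer(
            signals=obj.signals[keep],
            lfp_rate=obj.lfp_rate,
            channels=[obj.channels[i] for i in keep],
            events=list(obj.events),
            history=list(obj.history),
            unit=obj.unit,
            storage_encoding=obj.storage_encoding,
        )
        bad_secs = sum(
            max(0.0, min(b, obj.duration) - max(a, 0.0)) for a, b in mask.bad_segments
        )
        report["bad_seconds"] = bad_secs
        return out, report

    if isinstance(obj, TrialSet):
        bad_trials = obj.bad_trials.copy()
        w0, w1 = obj.window
        n_newly_bad = 0
        for i, onset in enumerate(obj.onsets):
            if mask.overlaps(onset + w0, onset + w1) and not bad_trials[i]:
                bad_trials[i] = True
                n_newly_bad += 1
        out = TrialSet(
            data=obj.data[:, keep, :],
            time=obj.time,
            conditions=list(obj.conditions),
            window=obj.window,
            rate=obj.rate,
            channels=[obj.channels[i] for i in keep],
            spikes=obj.spikes,
            bad_trials=bad_trials,
            onsets=obj.onsets,
        )
        report["n_trials_flagged_bad"] = n_newly_bad
        return out, report

    raise TypeError(f"apply_bad_mask does not support {type(obj).__name__}")
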