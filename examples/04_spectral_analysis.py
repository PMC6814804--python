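"""LFP frequency analysis: Welch PSD, Morlet time-frequency, coherence.

The demo background carries a 10 Hz oscillation on every channel and a
22 Hz component confined to the first half of the probe, so the coherence
matrix at 22 Hz shows a channel block.

Run after example 01:  python examples/04_spectral_analysis.py
"""

from pathlib import Path

import numpy as np

from ephyskit import (
    baseline_zscore_tf,
    import_epochs,
    morlet_tf,
    nxn_coherence,
    read_lfp_container,
    welch_psd,
)

container = read_lfp_container(Path("example_output/dataset/lfp.bst"))

# Welch PSD of the whole recording: the 10 Hz line stands out.
f, psd = welch_psd(container.signals, container.lfp_rate, segment_length=2.0)
ch0 = psd[0]
print("channel", container.channel_labels[0], "PSD peaks (Hz):",
      [round(float(f[i]), 1) for i in np.argsort(ch0)[-3:][::-1]])

# Morlet time-frequency map of one trial, z-scored to the pre-stimulus
# baseline.
stim_labels = [e.label for e in container.events if e.kind == "stimulus"]
trials = import_epochs(container, stim_labels, window=(-0.5, 1.0))
tf = morlet_tf(trials.data[0, 0], trials.rate, times=trials.time)
z = baseline_zscore_tf(tf, baseline=(-0.5, -0.1))
fi, ti = np.unravel_index(np.abs(z.power).argmax(), z.power.shape)
print(f"largest baseline deviation: {z.power[fi, ti]:+.1f} sd at "
      f"{z.frequencies[fi]:.1f} Hz, t = {z.times[ti]:.2f} s")

# N x N magnitude-squared coherence across the probe.
m = nxn_coherence(
    container.signals, container.lfp_rate,
    segment_length=2.0, channel_labels=container.channel_labels,
)
print("\ncoherence at 22 Hz (first half of the probe shares the component):")
print(m.to_frame(22.0).round(2).to_string())
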