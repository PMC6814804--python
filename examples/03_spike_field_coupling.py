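"""Spike-LFP coupling: spike-triggered average and spike-field coherence.

The demo simulator phase-locks its first unit to the shared 10 Hz
oscillation, so the STA shows a 10 Hz ripple and the Fries SFC peaks at
10 Hz on that unit but not on an unlocked one.

Run after example 01:  python examples/03_spike_field_coupling.py
"""

from pathlib import Path

from ephyskit import (
    import_epochs,
    read_lfp_container,
    spike_field_coherence,
    spike_triggered_average,
)

container = read_lfp_container(Path("example_output/dataset/lfp.bst"))
stim_labels = [e.label for e in container.events if e.kind == "stimulus"]
trials = import_epochs(container, stim_labels, window=(-0.5, 1.0))

for unit in trials.units[:2]:
    sta = spike_triggered_average(trials, unit, window=(-0.15, 0.15), seed=0)
    sfc = spike_field_coherence(trials, unit, window=(-0.15, 0.15))
    home = unit.split()[2]  # channel label inside "Spikes Channel <ch> |n|"
    print(f"{unit}: {sta.n_spikes} usable spikes ({sta.n_dropped} at edges)")
    print(f"  STA range on {home}: "
          f"[{sta.channel(home).min():.1f}, {sta.channel(home).max():.1f}] uV")
    print(f"  SFC peak {sfc.channel(home).max():.1f}% at "
          f"{sfc.peak_frequency(home):.1f} Hz "
          f"(resolution {sfc.frequencies[1] - sfc.frequencies[0]:.2f} Hz)")

# Continuous-signal variant: the same estimators accept a container
# directly and use absolute spike times.
unit = trials.units[0]
sfc_cont = spike_field_coherence(container, unit, window=(-0.15, 0.15))
print(f"\nwhole-recording SFC peak for {unit}: "
      f"{sfc_cont.peak_frequency():.1f} Hz")
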