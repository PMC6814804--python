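"""Epoch a recording and run the spike metrics.

Cuts [-0.5, 1.0) s trials around every stimulus onset, then computes a
raster, a PSTH with bootstrap confidence band, a direction tuning curve,
and the noise-correlation matrix with duplicate-unit flagging.

Run after example 01:  python examples/02_epochs_and_spike_metrics.py
"""

from pathlib import Path

from ephyskit import (
    import_epochs,
    noise_correlation,
    psth,
    raster,
    read_lfp_container,
    tuning_curve,
)

container = read_lfp_container(Path("example_output/dataset/lfp.bst"))

stim_labels = [e.label for e in container.events if e.kind == "stimulus"]
trials = import_epochs(container, stim_labels, window=(-0.5, 1.0))
print(f"{trials.n_trials} trials ({trials.meta['n_dropped']} dropped at edges), "
      f"units: {trials.units}")

unit = trials.units[0]

# Raster: one row of relative spike times per trial.
rows = raster(trials, unit)
print(f"\nraster for {unit}: first three trials "
      f"{[list(r.round(3)) for r in rows[:3]]}")

# PSTH: rate conserves the total spike count exactly.
p = psth(trials, unit, bin_width=0.050, seed=0)
print(f"PSTH peak {p.rate.max():.1f} spikes/s at "
      f"t = {p.bin_centers[p.rate.argmax()]:.3f} s; "
      f"conserved count {p.total_spikes():.0f}")

# Tuning: mean count per direction during the stimulus.
tc = tuning_curve(trials, unit, stim_labels, count_window=(0.0, 0.5), seed=0)
print("\ntuning curve:")
print(tc.to_frame().to_string(index=False))
print(f"preferred condition: {tc.preferred_condition()}")

# Noise correlations: pairs above r = 0.8 are duplicate candidates
# (the simulator leaks each waveform onto the neighboring contact).
m = noise_correlation(trials, count_window=(0.0, 0.5))
print("\nnoise-correlation matrix:")
print(m.to_frame().round(2).to_string())
for a, b, r in m.flags:
    print(f"duplicate candidate: {a} ~ {b} (r = {r:.2f})")
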