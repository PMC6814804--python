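"""Synthesize a ground-truth probe recording and convert it to LFP.

Generates a 30 kHz, 8-channel recording with tuned, phase-locked units and
coherent background oscillations, then runs the de-spiked LFP converter and
inspects the resulting single-file container.

Run:  python examples/01_synthesize_and_convert.py
"""

from pathlib import Path

from ephyskit import (
    LfpExtractionConfig,
    extract_lfp,
    generate_demo_dataset,
    read_events,
    read_lfp_container,
    read_raw_header,
    write_lfp_container,
)

outdir = Path("example_output/dataset")

# 1. Synthesize: raw payload + sidecar header, events TSV, probe geometry,
#    and a ground-truth JSON describing every injected unit.
res = generate_demo_dataset(outdir, seed=42, n_channels=8)
print("ground truth units:")
for u in res["truth"]["units"]:
    print(
        f"  {u['label']}: base {u['base_rate_hz']} Hz, "
        f"preferred {u['preferred_direction_rad'] / 3.141592653589793:+.2f} pi, "
        f"kappa {u['kappa']}, {u['n_spikes']} spikes"
    )

# 2. Lazy raw handle: nothing but the header is read here.
rec = read_raw_header(res["header"])
print(f"\nraw: {rec.n_channels} ch x {rec.n_samples} samples "
      f"at {rec.sampling_rate:g} Hz ({rec.duration:.1f} s)")

# 3. Convert: de-spike around every sorted spike, band-pass 0.5-150 Hz,
#    decimate 30 kHz -> 1 kHz, carry all events along.
events = read_events(res["events"])
cfg = LfpExtractionConfig(band=(0.5, 150.0), despike_method="spectral", seed=0)
container = extract_lfp(rec, events, cfg)
path = write_lfp_container(container, outdir / "lfp.bst")

raw_bytes = res["header"].with_suffix(".dat").stat().st_size
print(f"\ncontainer: {container.n_channels} ch at {container.lfp_rate:g} Hz, "
      f"{len(container.events)} event series")
print(f"sizes: raw {raw_bytes / 1e6:.1f} MB -> container "
      f"{path.stat().st_size / 1e6:.2f} MB "
      f"({raw_bytes / path.stat().st_size:.0f}x smaller)")

# 4. Containers are self-describing: provenance rides along.
back = read_lfp_container(path)
for rec_ in back.history:
    print(f"history: {rec_.operation} {rec_.parameters}")
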