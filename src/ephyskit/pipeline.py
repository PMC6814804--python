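"""Reproducible, provenance-logged batch pipelines.

A pipeline spec (YAML or JSON) is an ordered list of stages, each naming a
registered operation and its parameters, plus a global seed, input file
references and an output directory. Execution is strictly headless: every
stage appends one provenance record (operation, input files, parameters,
timestamp, package version) to a line-delimited log, and identical
spec + seed re-runs produce identical output content.

The global seed is split per stage by stable hashing of the stage id, so
inserting a stage does not shift the randomness of the ones downstream.
Output digests (written to ``digests.json``) hash result content only —
provenance timestamps are excluded — which is what the reproducibility
guarantee is stated over.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
import yaml

from ephyskit.data_io import (
    ProvenanceRecord,
    read_events,
    read_raw_header,
    write_lfp_container,
)
from ephyskit.epochs import baseline_correct, import_epochs
from ephyskit.lfp import LfpExtractionConfig, extract_lfp
from ephyskit.spectral import morlet_tf, nxn_coherence, welch_psd
from ephyskit.spike_lfp import spike_field_coherence, spike_triggered_average
from ephyskit.spike_metrics import noise_correlation, psth, tuning_curve
from ephyskit.synth import generate_demo_dataset


@dataclass
class Stage:
    operation: str
    params: dict = field(default_factory=dict)
    id: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            self.id = self.operation


@dataclass
class PipelineSpec:
    stages: list[Stage]
    seed: int = 0
    inputs: dict = field(default_factory=dict)  # name -> file path
    outdir: str | Path = "pipeline_out"

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineSpec":
        stages = [
            Stage(operation=s["operation"], params=dict(s.get("params", {})), id=s.get("id", ""))
            for s in d.get("stages", [])
        ]
        return cls(
            stages=stages,
            seed=int(d.get("seed", 0)),
            inputs=dict(d.get("inputs", {})),
            outdir=d.get("outdir", "pipeline_out"),
        )

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def stage_seed(global_seed: int, stage_id: str) -> int:
    """Stable per-stage seed below 2**31, independent of stage position."""
    h = hashlib.sha256(f"{global_seed}:{stage_id}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2**31)


# ---------------------------------------------------------------------------
# stage registry
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class _OpInfo:
    run: Callable
    requires: tuple[str, ...]
    provides: tuple[str, ...]


def _write_tsv(df, path: Path) -> None:
    df.to_csv(path, sep="\t", float_format="%.10g")


def _default_unit(ctx: dict, params: dict) -> str:
    if "unit" in params:
        return params["unit"]
    units = [e.label for e in ctx["container"].spike_series()]
    if not units:
        raise ValueError("no spike series available to analyze")
    return units[0]


def _op_synth(ctx: dict, params: dict, seed: int, outdir: Path) -> list[str]:
    from ephyskit.synth import TrialSchedule

    sched_keys = {"condition_labels", "n_repeats", "stimulus_duration", "inter_trial_interval"}
    sched_params = {k: params[k] for k in sched_keys if k in params}
    schedule = TrialSchedule(**sched_params) if sched_params else None
    other = {k: v for k, v in params.items() if k not in sched_keys}
    res = generate_demo_dataset(outdir / "synth", seed=seed, schedule=schedule, **other)
    ctx["raw_header"] = res["header"]
    ctx["events_path"] = res["events"]
    ctx["truth"] = res["truth"]
    return [str(res["header"]), str(res["events"])]


def _op_extract(ctx: dict, params: dict, seed: int, outdir: Path) -> list[str]:
    header = Path(ctx.get("raw_header") or ctx["inputs"]["raw_header"])
    events_path = Path(ctx.get("events_path") or ctx["inputs"]["events"])
    rec = read_raw_header(header)
    events = read_events(events_path)
    cfg = LfpExtractionConfig(
        band=tuple(params.get("band", (0.5, 150.0))),
        notch=params.get("notch"),
        target_rate=params.get("target_rate", 1000.0),
        despike_method=params.get("despike_method", "spectral"),
        seed=seed,
    )
    container = extract_lfp(rec, events, cfg)
    out = outdir / "lfp_container.bst"
    write_lfp_container(container, out)
    ctx["container"] = container
    ctx["container_path"] = out
    return [str(header), str(events_path)]


def _op_epoch(ctx: dict, params: dict, seed: int, outdir: Path) -> list[str]:
    container = ctx["container"]
    labels = params.get("event_labels") or [
        e.label for e in container.events if e.kind == "stimulus"
    ]
    window = tuple(params.get("window", (-0.5, 1.0)))
    trials = import_epochs(container, labels, window)
    if "baseline" in params:
        trials = baseline_correct(
            trials,
            tuple(params["baseline"]),
            params.get("baseline_mode", "subtract_mean"),
        )
    ctx["trials"] = trials
    return [str(ctx.get("container_path", ""))]


def _op_psth(ctx: dict, params: dict, seed: int, outdir: Path) -> list[str]:
    unit = _default_unit(ctx, params)
    res = psth(
        ctx["trials"],
        unit,
        bin_width=params.get("bin_width", 0.010),
        n_boot=params.get("n_boot", 1000),
        seed=seed,
    )
    _write_tsv(res.to_frame(), outdir / f"psth_{_slug(unit)}.tsv")
    ctx[f"psth:{unit}"] = res
    return []


def _op_tuning(ctx: dict, params: dict, seed: int, outdir: Path) -> list[str]:
    unit = _default_unit(ctx, params)
    order = params.get("condition_order") or [
        e.label for e in ctx["container"].events if e.kind == "stimulus"
    ]
    res = tuning_curve(
        ctx["trials"],
        unit,
        order,
        count_window=tuple(params.get("count_window", (0.0, 0.3))),
        n_boot=params.get("n_boot", 1000),
        seed=seed,
    )
    _write_tsv(res.to_frame(), outdir / f"tuning_{_slug(unit)}.tsv")
    ctx[f"tuning:{unit}"] = res
    return []


def _op_noisecorr(ctx: dict, params: dict, seed: int, outdir: Path) -> list[str]:
    res = noise_correlation(
        ctx["trials"],
        count_window=tuple(params.get("count_window", (0.0, 0.3))),
        center=params.get("center", "per_condition_mean"),
        duplicate_threshold=params.get("duplicate_threshold", 0.8),
    )
    _write_tsv(res.to_frame(), outdir / "noise_correlation.tsv")
    ctx["noisecorr"] = res
    return []


def _op_sta(ctx: dict, params: dict, seed: int, outdir: Path) -> list[str]:
    unit = _default_unit(ctx, params)
    res = spike_triggered_average(
        ctx["trials"],
        unit,
        window=tuple(params.get("window", (-0.150, 0.150))),
        n_boot=params.get("n_boot", 500),
        seed=seed,
    )
    _write_tsv(res.to_frame(), outdir / f"sta_{_slug(unit)}.tsv")
    ctx[f"sta:{unit}"] = res
    return []


def _op_sfc(ctx: dict, params: dict, seed: int, outdir: Path) -> list[str]:
    unit = _default_unit(ctx, params)
    res = spike_field_coherence(
        ctx["trials"],
        unit,
        window=tuple(params.get("window", (-0.150, 0.150))),
        max_freq=params.get("max_freq", 50.0),
    )
    _write_tsv(res.to_frame(), outdir / f"sfc_{_slug(unit)}.tsv")
    ctx[f"sfc:{unit}"] = res
    return []


def _op_tf(ctx: dict, params: dict, seed: int, outdir: Path) -> list[str]:
    trials = ctx["trials"]
    ch = params.get("channel", trials.channel_labels[0])
    ci = trials.channel_labels.index(ch)
    ti = int(params.get("trial", 0))
    freqs = params.get("frequencies")
    tfmap = morlet_tf(
        trials.data[ti, ci],
        trials.rate,
        frequencies=np.asarray(freqs) if freqs else None,
        cycles=params.get("cycles", 7.0),
        times=trials.time,
    )
    if "baseline" in params:
        from ephyskit.spectral import baseline_zscore_tf

        tfmap = baseline_zscore_tf(tfmap, tuple(params["baseline"]))
    _write_tsv(tfmap.to_frame(), outdir / f"tf_{_slug(ch)}_trial{ti}.tsv")
    ctx[f"tf:{ch}:{ti}"] = tfmap
    return []


def _op_coherence(ctx: dict, params: dict, seed: int, outdir: Path) -> list[str]:
    trials = ctx["trials"]
    ti = int(params.get("trial", 0))
    res = nxn_coherence(
        trials.data[ti],
        trials.rate,
        segment_length=params.get("segment_length", 0.5),
        overlap=params.get("overlap", 0.5),
        channel_labels=trials.channel_labels,
    )
    freq = params.get("display_frequency", 40.0)
    _write_tsv(res.to_frame(freq), outdir / f"coherence_{freq:g}hz_trial{ti}.tsv")
    ctx[f"coherence:{ti}"] = res
    return []


def _op_welch(ctx: dict, params: dict, seed: int, outdir: Path) -> list[str]:
    import pandas as pd

    container = ctx["container"]
    f, psd = welch_psd(
        container.signals,
        container.lfp_rate,
        segment_length=params.get("segment_length", 1.0),
        overlap=params.get("overlap", 0.5),
    )
    df = pd.DataFrame(psd.T, index=f, columns=container.channel_labels)
    _write_tsv(df, outdir / "welch_psd.tsv")
    ctx["welch"] = (f, psd)
    return []


def _slug(text: str) -> str:
    return "".join(c if c.isalnum() else "_" for c in text).strip("_")


OP_REGISTRY: dict[str, _OpInfo] = {
    "synth": _OpInfo(_op_synth, requires=(), provides=("raw_header", "events_path")),
    "extract_lfp": _OpInfo(
        _op_extract, requires=("raw_header", "events_path"), provides=("container",)
    ),
    "epoch": _OpInfo(_op_epoch, requires=("container",), provides=("trials",)),
    "psth": _OpInfo(_op_psth, requires=("trials",), provides=()),
    "tuning": _OpInfo(_op_tuning, requires=("trials", "container"), provides=()),
    "noisecorr": _OpInfo(_op_noisecorr, requires=("trials",), provides=()),
    "sta": _OpInfo(_op_sta, requires=("trials",), provides=()),
    "sfc": _OpInfo(_op_sfc, requires=("trials",), provides=()),
    "tf": _OpInfo(_op_tf, requires=("trials",), provides=()),
    "coherence": _OpInfo(_op_coherence, requires=("trials",), provides=()),
    "welch": _OpInfo(_op_welch, requires=("container",), provides=()),
}


# ---------------------------------------------------------------------------
# validation and execution
# ---------------------------------------------------------------------------


def validate_spec(spec: PipelineSpec) -> list[str]:
    """Dry-run check: unresolved stage names, missing input files, and
    stage-to-stage dataflow mismatches. Returns a list of problems (empty
    when the spec is runnable); nothing is executed."""
    problems = []
    available = set(spec.inputs)
    if {"raw_header", "events"} <= set(spec.inputs):
        available |= {"raw_header", "events_path"}
    for name, path in spec.inputs.items():
        if not Path(path).exists():
            problems.append(f"input {name!r}: file not found: {path}")
    for i, st in enumerate(spec.stages):
        info = OP_REGISTRY.get(st.operation)
        if info is None:
            problems.append(
                f"stage {i} ({st.id}): unknown operation {st.operation!r}; "
                f"registered: {sorted(OP_REGISTRY)}"
            )
            continue
        missing = [r for r in info.requires if r not in available]
        if missing:
            problems.append(
                f"stage {i} ({st.id}): operation {st.operation!r} needs "
                f"{missing} which no earlier stage provides"
            )
        available |= set(info.provides)
    return problems


def run_pipeline(spec: PipelineSpec) -> tuple[dict, list[ProvenanceRecord]]:
    """Execute the stages in order.

    Appends one provenance record per stage to ``<outdir>/provenance.jsonl``
    and a content-digest manifest to ``<outdir>/digests.json``. A failing
    stage aborts with its name; artifacts written by earlier stages are left
    on disk. Returns the artifact context and the provenance records.
    """
    problems = validate_spec(spec)
    if problems:
        raise ValueError("invalid pipeline spec:\n" + "\n".join(problems))
    outdir = Path(spec.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    log_path = outdir / "provenance.jsonl"
    ctx: dict = {"inputs": dict(spec.inputs)}
    records: list[ProvenanceRecord] = []
    with open(log_path, "a") as log:
        for st in spec.stages:
            seed = stage_seed(spec.seed, st.id)
            info = OP_REGISTRY[st.operation]
            try:
                inputs = info.run(ctx, st.params, seed, outdir)
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline stage {st.id!r} ({st.operation}) failed: {exc}"
                ) from exc
            rec = ProvenanceRecord(
                operation=st.operation,
                input_paths=[p for p in inputs if p],
                parameters={**st.params, "stage_seed": seed},
            )
            records.append(rec)
            log.write(json.dumps(rec.to_dict()) + "\n")
            log.flush()

    digests = {}
    for path in sorted(outdir.glob("*.tsv")):
        digests[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()
    if "container" in ctx:
        digests["lfp_container.bst"] = ctx["container"].content_digest()
    (outdir / "digests.json").write_text(json.dumps(digests, indent=1))
    ctx["digests"] = digests
    return ctx, records
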