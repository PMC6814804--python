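"""Core data types and file formats.

Conventions used throughout the package:

* time is expressed in seconds (double precision) from recording start,
* sample indices are 0-based, and every time window is half-open ``[t0, t1)``,
* the raw payload is little-endian, sample-major interleaved (one frame of
  all channels per time point), described by a JSON sidecar header,
* events travel as TSV tables, probe geometry as TSV, and extracted LFP as
  a self-describing single binary container file.
"""

from __future__ import annotations

import hashlib
import json
import struct
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

RAW_FORMAT_NAME = "ephyskit-raw"
RAW_FORMAT_VERSION = 1
CONTAINER_MAGIC = b"EPHYSLFP"
CONTAINER_VERSION = 1

_DTYPES = {"int16": np.int16, "float32": np.float32}

SPIKE_LABEL_PREFIX = "Spikes Channel "


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ChannelInfo:
    """One recording channel: unique label, optional 3-D position (meters),
    and the probe/array group it belongs to."""

    label: str
    position: tuple[float, float, float] | None = None
    group: str = ""

    def __post_init__(self) -> None:
        if not self.label:
            raise ValueError("channel label must be non-empty")
        if self.position is not None:
            pos = tuple(float(v) for v in self.position)
            if len(pos) != 3 or not all(np.isfinite(pos)):
                raise ValueError(
                    f"channel {self.label!r}: position must be a finite "
                    f"3-vector, got {self.position!r}"
                )
            object.__setattr__(self, "position", pos)


@dataclass
class RawRecording:
    """Lazy handle to a continuous multichannel recording.

    No signal payload is held in memory; :func:`read_raw_segment` pages
    windows in on demand via a memory map.
    """

    source_path: Path
    sampling_rate: float
    channels: list[ChannelInfo]
    n_samples: int
    sample_encoding: str  # "int16" or "float32"
    gains: np.ndarray  # physical units per count, one per channel
    unit: str = "uV"

    def __post_init__(self) -> None:
        self.source_path = Path(self.source_path)
        if self.sampling_rate <= 0:
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if self.sample_encoding not in _DTYPES:
            raise ValueError(
                f"sample_encoding must be one of {sorted(_DTYPES)}, "
                f"got {self.sample_encoding!r}"
            )
        labels = [c.label for c in self.channels]
        if len(set(labels)) != len(labels):
            raise ValueError("channel labels must be unique")
        self.gains = np.asarray(self.gains, dtype=np.float64)
        if self.gains.shape != (len(self.channels),):
            raise ValueError(
                f"need one gain per channel: {self.gains.shape} vs "
                f"{len(self.channels)} channels"
            )

    @property
    def n_channels(self) -> int:
        return len(self.channels)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_samples / self.sampling_rate

    @property
    def channel_labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def _memmap(self) -> np.memmap:
        dtype = _DTYPES[self.sample_encoding]
        return np.memmap(
            self.source_path,
            dtype=np.dtype(dtype).newbyteorder("<"),
            mode="r",
            shape=(self.n_samples, self.n_channels),
        )


@dataclass
class EventSeries:
    """Labeled, sorted event times: experimental markers or one unit's
    spike train.

    Spike series follow the labeling grammar
    ``"Spikes Channel <channel-label> |<cell-number>|"`` so that every unit
    is identified by its home electrode and within-channel cell index.
    """

    label: str
    kind: str  # "stimulus", "behavioral" or "spike"
    times: np.ndarray
    channel: str | None = None
    cell: int | None = None

    def __post_init__(self) -> None:
        if self.kind not in ("stimulus", "behavioral", "spike"):
            raise ValueError(f"unknown event kind {self.kind!r}")
        times = np.unique(np.asarray(self.times, dtype=np.float64))
        if times.size and times[0] < 0:
            raise ValueError(f"event series {self.label!r} has negative times")
        self.times = times
        if self.kind == "spike":
            chan, cell = parse_spike_label(self.label)
            if self.channel is None:
                self.channel = chan
            if self.cell is None:
                self.cell = cell
            if (self.channel, self.cell) != (chan, cell):
                raise ValueError(
                    f"spike label {self.label!r} disagrees with unit fields "
                    f"({self.channel!r}, {self.cell!r})"
                )

    @property
    def unit_id(self) -> tuple[str, int] | None:
        if self.kind == "spike":
            return (self.channel, self.cell)
        return None

    @property
    def n_events(self) -> int:
        return int(self.times.size)


def make_spike_label(channel: str, cell: int) -> str:
    """Format the normative per-unit label, e.g. ``Spikes Channel AD01 |1|``."""
    return f"{SPIKE_LABEL_PREFIX}{channel} |{int(cell)}|"


def parse_spike_label(label: str) -> tuple[str, int]:
    """Parse ``"Spikes Channel <chan> |<cell>|"`` into (channel, cell)."""
    if not label.startswith(SPIKE_LABEL_PREFIX) or not label.endswith("|"):
        raise ValueError(
            f"spike label {label!r} does not follow the grammar "
            f"'{SPIKE_LABEL_PREFIX}<channel> |<cell>|'"
        )
    body = label[len(SPIKE_LABEL_PREFIX) : -1]
    chan, sep, cell = body.rpartition(" |")
    if not sep or not chan or not cell.isdigit():
        raise ValueError(f"cannot parse channel/cell from spike label {label!r}")
    return chan, int(cell)


@dataclass
class ProvenanceRecord:
    """One logged processing step: what ran, on which files, with which
    parameters, when, and under which package version."""

    operation: str
    input_paths: list[str] = field(default_factory=list)
    parameters: dict = field(default_factory=dict)
    timestamp: str = ""
    software_version: str = ""

    def __post_init__(self) -> None:
        if not self.operation:
            raise ValueError("provenance operation must be non-empty")
        if not self.timestamp:
            self.timestamp = datetime.now(timezone.utc).isoformat()
        else:
            datetime.fromisoformat(self.timestamp)  # validates
        if not self.software_version:
            from ephyskit import __version__

            self.software_version = __version__
        self.input_paths = [str(p) for p in self.input_paths]

    def to_dict(self) -> dict:
        return {
            "timestamp": self.timestamp,
            "operation": self.operation,
            "input_paths": list(self.input_paths),
            "parameters": dict(self.parameters),
            "software_version": self.software_version,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ProvenanceRecord":
        return cls(
            operation=d["operation"],
            input_paths=list(d.get("input_paths", [])),
            parameters=dict(d.get("parameters", {})),
            timestamp=d.get("timestamp", ""),
            software_version=d.get("software_version", ""),
        )


@dataclass
class LfpContainer:
    """Down-sampled LFP plus everything needed to analyze it: signals,
    channel metadata, all experimental and spike events, and the processing
    history. Persists as a single binary file."""

    signals: np.ndarray  # channels x samples, physical units
    lfp_rate: float
    channels: list[ChannelInfo]
    events: list[EventSeries] = field(default_factory=list)
    history: list[ProvenanceRecord] = field(default_factory=list)
    unit: str = "uV"
    storage_encoding: str = "float32"  # payload dtype on disk
    storage_gains: np.ndarray | None = None  # per-channel gain for int16 storage

    def __post_init__(self) -> None:
        self.signals = np.atleast_2d(np.asarray(self.signals))
        if self.signals.shape[0] != len(self.channels):
            raise ValueError(
                f"signal rows ({self.signals.shape[0]}) must match channel "
                f"count ({len(self.channels)})"
            )
        if self.lfp_rate <= 0:
            raise ValueError("lfp_rate must be > 0")
        dur = self.duration
        for ev in self.events:
            if ev.times.size and ev.times[-1] > dur + 1e-12:
                raise ValueError(
                    f"event series {ev.label!r} has time {ev.times[-1]:g} s "
                    f"beyond the signal duration {dur:g} s"
                )

    @property
    def n_channels(self) -> int:
        return self.signals.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signals.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.lfp_rate

    @property
    def channel_labels(self) -> list[str]:
        return [c.label for c in self.channels]

    def spike_series(self) -> list[EventSeries]:
        return [e for e in self.events if e.kind == "spike"]

    def event_series(self, label: str) -> EventSeries:
        for e in self.events:
            if e.label == label:
                return e
        raise KeyError(
            f"no event series {label!r}; known: {[e.label for e in self.events]}"
        )

    def content_digest(self) -> str:
        """SHA-256 over signals, events and channel metadata.

        The processing history is excluded on purpose: it carries wall-clock
        timestamps, and two runs of the same pipeline must agree on content.
        """
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.signals, dtype=np.float32).tobytes())
        h.update(json.dumps(_channels_to_json(self.channels)).encode())
        for ev in sorted(self.events, key=lambda e: e.label):
            h.update(ev.label.encode())
            h.update(ev.kind.encode())
            h.update(np.ascontiguousarray(ev.times).tobytes())
        return h.hexdigest()


# ---------------------------------------------------------------------------
# raw binary + sidecar header
# ---------------------------------------------------------------------------


def _channels_to_json(channels: Sequence[ChannelInfo]) -> list[dict]:
    out = []
    for c in channels:
        d: dict = {"label": c.label, "group": c.group}
        if c.position is not None:
            d["position"] = list(c.position)
        out.append(d)
    return out


def _channels_from_json(items: Iterable[dict]) -> list[ChannelInfo]:
    return [
        ChannelInfo(
            label=d["label"],
            position=tuple(d["position"]) if d.get("position") else None,
            group=d.get("group", ""),
        )
        for d in items
    ]


def read_raw_header(header_path: str | Path) -> RawRecording:
    """Parse a sidecar header and return a lazy recording handle.

    The header declares the sampling rate, channel list, sample encoding and
    the payload file; the payload itself is not loaded. The declared sample
    count is checked against the payload byte size.
    """
    header_path = Path(header_path)
    if not header_path.exists():
        raise FileNotFoundError(f"header file not found: {header_path}")
    with open(header_path) as fh:
        try:
            meta = json.load(fh)
        except json.JSONDecodeError as exc:
            raise ValueError(f"header {header_path} is not valid JSON: {exc}") from exc

    for key in ("sampling_rate_hz", "channels", "dtype", "payload", "n_samples"):
        if key not in meta:
            raise ValueError(f"header {header_path} is missing field {key!r}")

    dtype = meta["dtype"]
    if dtype not in _DTYPES:
        raise ValueError(f"header field 'dtype' must be one of {sorted(_DTYPES)}, got {dtype!r}")

    channels = _channels_from_json(meta["channels"])
    gains = np.array([float(c.get("gain", 1.0)) for c in meta["channels"]])
    payload = header_path.parent / meta["payload"]
    if not payload.exists():
        raise FileNotFoundError(f"payload file not found: {payload}")

    n_samples = int(meta["n_samples"])
    itemsize = np.dtype(_DTYPES[dtype]).itemsize
    expected = n_samples * len(channels) * itemsize
    actual = payload.stat().st_size
    if expected != actual:
        raise ValueError(
            f"header declares n_samples={n_samples} x {len(channels)} channels "
            f"x {itemsize} B = {expected} bytes, but payload {payload.name} "
            f"has {actual} bytes"
        )

    return RawRecording(
        source_path=payload,
        sampling_rate=float(meta["sampling_rate_hz"]),
        channels=channels,
        n_samples=n_samples,
        sample_encoding=dtype,
        gains=gains,
        unit=meta.get("unit", "uV"),
    )


def _resolve_channel_indices(
    rec: RawRecording, channel_subset: Sequence[str] | None
) -> np.ndarray:
    labels = rec.channel_labels
    if channel_subset is None:
        return np.arange(len(labels))
    idx = []
    for lab in channel_subset:
        if lab not in labels:
            raise KeyError(f"unknown channel {lab!r}; known channels: {labels}")
        idx.append(labels.index(lab))
    return np.asarray(idx)


def read_raw_segment(
    rec: RawRecording,
    t0: float,
    t1: float,
    channel_subset: Sequence[str] | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Load the window ``[t0, t1)`` (seconds) in physical units.

    Returns ``(block, time)`` where ``block`` is channels x samples and
    ``time`` the sample times in seconds. Covers the half-open sample range
    ``[floor(t0*rate), floor(t1*rate))``; memory use is proportional to the
    window, not the file.
    """
    if not (0 <= t0 < t1 <= rec.duration + 1e-12):
        raise ValueError(
            f"window [{t0}, {t1}) outside recording [0, {rec.duration:g}) s"
        )
    i0 = int(np.floor(t0 * rec.sampling_rate))
    i1 = int(np.floor(t1 * rec.sampling_rate))
    i1 = min(i1, rec.n_samples)
    idx = _resolve_channel_indices(rec, channel_subset)
    mm = rec._memmap()
    block = np.asarray(mm[i0:i1, idx], dtype=np.float64).T
    block *= rec.gains[idx][:, None]
    time = np.arange(i0, i1, dtype=np.float64) / rec.sampling_rate
    return block, time


def write_raw(
    data: np.ndarray,
    sampling_rate: float,
    channels: Sequence[ChannelInfo],
    path: str | Path,
    sample_encoding: str = "float32",
    gains: np.ndarray | float = 1.0,
    unit: str = "uV",
) -> Path:
    """Write ``data`` (channels x samples, physical units) as payload ``.dat``
    plus sidecar header ``.json``; returns the header path.

    For int16 encoding samples are stored as ``round(value / gain)`` counts.
    """
    data = np.atleast_2d(np.asarray(data))
    if not np.all(np.isfinite(data)):
        raise ValueError("signal values must be finite")
    if sample_encoding not in _DTYPES:
        raise ValueError(f"sample_encoding must be one of {sorted(_DTYPES)}")
    path = Path(path)
    gains = np.broadcast_to(np.asarray(gains, dtype=np.float64), (data.shape[0],))

    header_path = path.with_suffix(".json")
    payload_path = path.with_suffix(".dat")
    _write_raw_payload(data, payload_path, sample_encoding, gains)
    write_raw_header(
        header_path,
        payload_path.name,
        sampling_rate,
        channels,
        data.shape[1],
        sample_encoding,
        gains,
        unit,
    )
    return header_path


def write_raw_header(
    header_path: str | Path,
    payload_name: str,
    sampling_rate: float,
    channels: Sequence[ChannelInfo],
    n_samples: int,
    sample_encoding: str,
    gains: np.ndarray,
    unit: str = "uV",
) -> Path:
    header_path = Path(header_path)
    chan_json = _channels_to_json(channels)
    for d, g in zip(chan_json, np.asarray(gains, dtype=float)):
        d["gain"] = float(g)
    meta = {
        "format": RAW_FORMAT_NAME,
        "version": RAW_FORMAT_VERSION,
        "sampling_rate_hz": float(sampling_rate),
        "n_samples": int(n_samples),
        "dtype": sample_encoding,
        "unit": unit,
        "payload": payload_name,
        "channels": chan_json,
    }
    with open(header_path, "w") as fh:
        json.dump(meta, fh, indent=1)
    return header_path


def _write_raw_payload(
    data: np.ndarray, payload_path: Path, sample_encoding: str, gains: np.ndarray
) -> None:
    counts = data / gains[:, None]
    if sample_encoding == "int16":
        counts = np.clip(np.rint(counts), -32768, 32767)
    dtype = np.dtype(_DTYPES[sample_encoding]).newbyteorder("<")
    with open(payload_path, "wb") as fh:
        counts.T.astype(dtype).tofile(fh)


# ---------------------------------------------------------------------------
# event tables
# ---------------------------------------------------------------------------

_EVENT_COLUMNS = ["label", "kind", "time_s", "channel", "cell"]


def write_events(events: Sequence[EventSeries], path: str | Path) -> Path:
    """Write event series to a TSV with columns label, kind, time_s, channel, cell."""
    rows = []
    for ev in events:
        for t in ev.times:
            rows.append(
                {
                    "label": ev.label,
                    "kind": ev.kind,
                    "time_s": repr(float(t)),
                    "channel": ev.channel or "",
                    "cell": "" if ev.cell is None else int(ev.cell),
                }
            )
    path = Path(path)
    pd.DataFrame(rows, columns=_EVENT_COLUMNS).to_csv(path, sep="\t", index=False)
    return path


def read_events(path: str | Path) -> list[EventSeries]:
    """Read an event TSV back into a list of :class:`EventSeries`.

    Times are sorted and de-duplicated per series; malformed rows raise with
    their (1-based, header-inclusive) row number.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("label", "kind", "time_s") if c not in df.columns]
    if missing:
        raise ValueError(f"event table {path} is missing columns {missing}")

    grouped: dict[tuple[str, str], list[float]] = {}
    order: list[tuple[str, str]] = []
    for i, row in enumerate(df.itertuples(index=False), start=2):
        try:
            t = float(row.time_s)
            if not np.isfinite(t):
                raise ValueError
        except ValueError:
            raise ValueError(
                f"{path}, row {i}: cannot parse time_s={row.time_s!r}"
            ) from None
        if row.kind not in ("stimulus", "behavioral", "spike"):
            raise ValueError(f"{path}, row {i}: unknown kind {row.kind!r}")
        key = (row.label, row.kind)
        if key not in grouped:
            grouped[key] = []
            order.append(key)
        grouped[key].append(t)

    out = []
    for label, kind in order:
        out.append(EventSeries(label=label, kind=kind, times=np.array(grouped[(label, kind)])))
    return out


# ---------------------------------------------------------------------------
# probe geometry
# ---------------------------------------------------------------------------


def write_probe_geometry(channels: Sequence[ChannelInfo], path: str | Path) -> Path:
    rows = []
    for c in channels:
        x, y, z = c.position if c.position is not None else (np.nan, np.nan, np.nan)
        rows.append({"label": c.label, "x": x, "y": y, "z": z, "group": c.group})
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
    return path


def read_probe_geometry(path: str | Path) -> list[ChannelInfo]:
    df = pd.read_csv(path, sep="\t", keep_default_na=True)
    out = []
    for row in df.itertuples(index=False):
        pos = None
        if np.isfinite(row.x) and np.isfinite(row.y) and np.isfinite(row.z):
            pos = (float(row.x), float(row.y), float(row.z))
        group = "" if not isinstance(row.group, str) else row.group
        out.append(ChannelInfo(label=str(row.label), position=pos, group=group))
    return out


# ---------------------------------------------------------------------------
# LFP container (single binary file)
# ---------------------------------------------------------------------------


def write_lfp_container(container: LfpContainer, path: str | Path) -> Path:
    """Serialize a container to one binary file.

    Layout: 8-byte magic, uint32 format version, uint64 metadata length, a
    JSON metadata block (rate, channels, events, history, storage encoding),
    then the sample-major little-endian payload. int16 storage keeps the
    per-channel gain in the metadata so physical values survive the trip.
    """
    path = Path(path)
    enc = container.storage_encoding
    if enc not in _DTYPES:
        raise ValueError(f"storage_encoding must be one of {sorted(_DTYPES)}")
    if enc == "int16":
        gains = container.storage_gains
        if gains is None:
            peak = np.abs(container.signals).max(axis=1)
            gains = np.where(peak > 0, peak / 32000.0, 1.0)
        gains = np.asarray(gains, dtype=np.float64)
        payload = np.clip(
            np.rint(container.signals / gains[:, None]), -32768, 32767
        ).T.astype(np.dtype(np.int16).newbyteorder("<"))
    else:
        gains = np.ones(container.n_channels)
        payload = container.signals.T.astype(np.dtype(np.float32).newbyteorder("<"))

    meta = {
        "version": CONTAINER_VERSION,
        "lfp_rate_hz": float(container.lfp_rate),
        "n_samples": int(container.n_samples),
        "unit": container.unit,
        "dtype": enc,
        "gains": [float(g) for g in gains],
        "channels": _channels_to_json(container.channels),
        "events": [
            {
                "label": ev.label,
                "kind": ev.kind,
                "times": [float(t) for t in ev.times],
            }
            for ev in container.events
        ],
        "history": [rec.to_dict() for rec in container.history],
    }
    blob = json.dumps(meta).encode("utf-8")
    with open(path, "wb") as fh:
        fh.write(CONTAINER_MAGIC)
        fh.write(struct.pack("<I", CONTAINER_VERSION))
        fh.write(struct.pack("<Q", len(blob)))
        fh.write(blob)
        payload.tofile(fh)
    return path


def read_lfp_container(path: str | Path) -> LfpContainer:
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != CONTAINER_MAGIC:
            raise ValueError(
                f"{path} is not an LFP container (bad magic {magic!r}; "
                f"expected {CONTAINER_MAGIC!r} version {CONTAINER_VERSION})"
            )
        (version,) = struct.unpack("<I", fh.read(4))
        if version != CONTAINER_VERSION:
            raise ValueError(
                f"{path}: unsupported container version {version}; "
                f"expected {CONTAINER_VERSION}"
            )
        (meta_len,) = struct.unpack("<Q", fh.read(8))
        meta = json.loads(fh.read(meta_len).decode("utf-8"))
        dtype = np.dtype(_DTYPES[meta["dtype"]]).newbyteorder("<")
        n_ch = len(meta["channels"])
        counts = np.fromfile(fh, dtype=dtype).reshape(meta["n_samples"], n_ch).T

    gains = np.asarray(meta["gains"], dtype=np.float64)
    signals = counts.astype(np.float64) * gains[:, None]
    events = [
        EventSeries(label=d["label"], kind=d["kind"], times=np.array(d["times"]))
        for d in meta["events"]
    ]
    history = [ProvenanceRecord.from_dict(d) for d in meta["history"]]
    return LfpContainer(
        signals=signals,
        lfp_rate=meta["lfp_rate_hz"],
        channels=_channels_from_json(meta["channels"]),
        events=events,
        history=history,
        unit=meta.get("unit", "uV"),
        storage_encoding=meta["dtype"],
        storage_gains=gains if meta["dtype"] == "int16" else None,
    )


def predicted_container_size(container: LfpContainer) -> int:
    """Closed-form size prediction: metadata block plus payload bytes."""
    itemsize = np.dtype(_DTYPES[container.storage_encoding]).itemsize
    payload = container.n_samples * container.n_channels * itemsize
    # regenerate the metadata blob to measure the header exactly
    import io

    tmp = io.BytesIO()
    n = len(
        json.dumps(
            {
                "version": CONTAINER_VERSION,
                "lfp_rate_hz": float(container.lfp_rate),
                "n_samples": int(container.n_samples),
                "unit": container.unit,
                "dtype": container.storage_encoding,
                "gains": [1.0] * container.n_channels,
                "channels": _channels_to_json(container.channels),
                "events": [
                    {"label": e.label, "kind": e.kind, "times": [float(t) for t in e.times]}
                    for e in container.events
                ],
                "history": [r.to_dict() for r in container.history],
            }
        ).encode()
    )
    del tmp
    return 8 + 4 + 8 + n + payload
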