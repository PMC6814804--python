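"""I/O layer: sidecar headers, lazy paged reads, event tables, containers."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ephyskit.data_io import (
    ChannelInfo,
    EventSeries,
    LfpContainer,
    ProvenanceRecord,
    make_spike_label,
    parse_spike_label,
    predicted_container_size,
    read_events,
    read_lfp_container,
    read_probe_geometry,
    read_raw_header,
    read_raw_segment,
    write_events,
    write_lfp_container,
    write_probe_geometry,
    write_raw,
)


def _channels(n, with_pos=False):
    return [
        ChannelInfo(
            f"AD{i + 1:02d}",
            position=(0.0, 0.0, -1e-4 * i) if with_pos else None,
            group="probe0",
        )
        for i in range(n)
    ]


# ---------------------------------------------------------------------------
# raw binary + header
# ---------------------------------------------------------------------------


class TestRawRoundTrip:
    def test_int16_bit_exact(self, tmp_path, rng):
        gain = 0.195
        counts = rng.integers(-1000, 1000, size=(3, 500))
        data = counts * gain
        header = write_raw(data, 30000.0, _channels(3), tmp_path / "rec",
                           sample_encoding="int16", gains=gain)
        rec = read_raw_header(header)
        block, t = read_raw_segment(rec, 0, rec.duration)
        assert np.array_equal(block, counts * gain)
        assert rec.sampling_rate == 30000.0
        assert rec.n_samples == 500

    def test_float32_tolerance(self, tmp_path, rng):
        data = rng.standard_normal((2, 400)) * 100
        header = write_raw(data, 1000.0, _channels(2), tmp_path / "rec",
                           sample_encoding="float32")
        block, _ = read_raw_segment(read_raw_header(header), 0, 0.4)
        assert np.allclose(block, data, rtol=1e-6, atol=1e-4)

    def test_gain_converts_counts_to_physical(self, tmp_path):
        data = np.array([[0.195, 0.39, -0.585]])
        header = write_raw(data, 1000.0, _channels(1), tmp_path / "rec",
                           sample_encoding="int16", gains=0.195)
        block, _ = read_raw_segment(read_raw_header(header), 0, 0.003)
        assert np.allclose(block[0], np.array([1, 2, -3]) * 0.195)

    def test_empty_recording(self, tmp_path):
        header = write_raw(np.empty((2, 0)), 1000.0, _channels(2), tmp_path / "rec")
        rec = read_raw_header(header)
        assert rec.n_samples == 0
        assert rec.duration == 0.0

    def test_header_metadata_round_trip(self, tmp_path, rng):
        data = rng.standard_normal((4, 100))
        header = write_raw(data, 2500.0, _channels(4, with_pos=True), tmp_path / "rec")
        rec = read_raw_header(header)
        assert rec.channel_labels == ["AD01", "AD02", "AD03", "AD04"]
        assert rec.channels[2].position == (0.0, 0.0, -2e-4)
        assert rec.channels[0].group == "probe0"


class TestHeaderValidation:
    def test_duration_from_byte_arithmetic(self, tmp_path, rng):
        # 2 channels, int16: payload of 4000 bytes -> 1000 samples -> 1 s at 1 kHz
        data = rng.integers(-5, 5, size=(2, 1000)).astype(float)
        header = write_raw(data, 1000.0, _channels(2), tmp_path / "rec",
                           sample_encoding="int16")
        rec = read_raw_header(header)
        assert (tmp_path / "rec.dat").stat().st_size == 4000
        assert rec.n_samples == 1000
        assert rec.duration == pytest.approx(1.0)

    def test_payload_size_mismatch_names_both_numbers(self, tmp_path, rng):
        data = rng.standard_normal((2, 100))
        header = write_raw(data, 1000.0, _channels(2), tmp_path / "rec")
        meta = json.loads(header.read_text())
        meta["n_samples"] = 150
        header.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="150") as exc:
            read_raw_header(header)
        assert str(2 * 150 * 4) in str(exc.value)  # declared bytes
        assert str(2 * 100 * 4) in str(exc.value)  # actual bytes

    def test_missing_field(self, tmp_path, rng):
        header = write_raw(rng.standard_normal((1, 10)), 1000.0, _channels(1),
                           tmp_path / "rec")
        meta = json.loads(header.read_text())
        del meta["sampling_rate_hz"]
        header.write_text(json.dumps(meta))
        with pytest.raises(ValueError, match="sampling_rate_hz"):
            read_raw_header(header)


class TestPagedReads:
    def test_full_window_equals_one_shot(self, tmp_path, rng):
        data = rng.standard_normal((3, 256))
        rec = read_raw_header(write_raw(data, 128.0, _channels(3), tmp_path / "r"))
        block, t = read_raw_segment(rec, 0, rec.duration)
        assert block.shape == (3, 256)
        assert t[0] == 0.0

    @settings(deadline=None, derandomize=True, max_examples=25)
    @given(
        n=st.integers(16, 200),
        split=st.floats(0.1, 0.9),
        data_seed=st.integers(0, 2**16),
    )
    def test_adjacent_windows_compose(self, tmp_path_factory, n, split, data_seed):
        tmp_path = tmp_path_factory.mktemp("paged")
        local = np.random.default_rng(data_seed)
        data = local.standard_normal((2, n))
        rate = 100.0
        rec = read_raw_header(write_raw(data, rate, _channels(2), tmp_path / "r"))
        tm = (n / rate) * split
        b1, _ = read_raw_segment(rec, 0, tm)
        b2, _ = read_raw_segment(rec, tm, n / rate)
        whole, _ = read_raw_segment(rec, 0, n / rate)
        assert np.array_equal(np.concatenate([b1, b2], axis=1), whole)

    def test_channel_subset_and_unknown_label(self, tmp_path, rng):
        data = rng.standard_normal((3, 50))
        rec = read_raw_header(write_raw(data, 50.0, _channels(3), tmp_path / "r"))
        block, _ = read_raw_segment(rec, 0, 1.0, channel_subset=["AD03", "AD01"])
        assert np.allclose(block, data[[2, 0]], rtol=1e-6, atol=1e-5)
        with pytest.raises(KeyError, match="AD01"):
            read_raw_segment(rec, 0, 1.0, channel_subset=["nope"])

    def test_window_outside_recording(self, tmp_path, rng):
        rec = read_raw_header(
            write_raw(rng.standard_normal((1, 100)), 100.0, _channels(1), tmp_path / "r")
        )
        with pytest.raises(ValueError):
            read_raw_segment(rec, 0, 2.0)
        with pytest.raises(ValueError):
            read_raw_segment(rec, -0.5, 0.5)


# ---------------------------------------------------------------------------
# events
# ---------------------------------------------------------------------------


class TestEvents:
    def test_spike_label_grammar(self):
        assert parse_spike_label("Spikes Channel AD01 |1|") == ("AD01", 1)
        assert make_spike_label("AD07", 3) == "Spikes Channel AD07 |3|"
        with pytest.raises(ValueError):
            parse_spike_label("Channel AD01 |1|")

    def test_round_trip(self, tmp_path):
        events = [
            EventSeries("Stim On 0", "stimulus", np.array([1.5, 0.25, 3.75])),
            EventSeries("Spikes Channel AD01 |1|", "spike",
                        np.array([0.1001, 0.5002, 2.3])),
        ]
        read_back = read_events(write_events(events, tmp_path / "ev.tsv"))
        assert [e.label for e in read_back] == [e.label for e in events]
        assert [e.kind for e in read_back] == ["stimulus", "spike"]
        # sorted on read, preserved to 1e-9 s
        assert np.allclose(read_back[0].times, [0.25, 1.5, 3.75], atol=1e-9)
        assert read_back[1].unit_id == ("AD01", 1)

    def test_times_sorted_and_deduplicated(self):
        ev = EventSeries("x", "stimulus", np.array([2.0, 1.0, 2.0]))
        assert np.array_equal(ev.times, [1.0, 2.0])

    def test_malformed_row_reports_row_number(self, tmp_path):
        path = tmp_path / "bad.tsv"
        path.write_text("label\tkind\ttime_s\tchannel\tcell\na\tstimulus\t1.0\t\t\nb\tstimulus\toops\t\t\n")
        with pytest.raises(ValueError, match="row 3"):
            read_events(path)


# ---------------------------------------------------------------------------
# container
# ---------------------------------------------------------------------------


def _make_container(rng, n_ch=3, n_s=2000, with_events=True):
    events = []
    if with_events:
        events = [
            EventSeries("Stim On 0", "stimulus", np.array([0.5, 1.2])),
            EventSeries("Spikes Channel AD01 |1|", "spike", np.array([0.11, 0.92, 1.5])),
        ]
    return LfpContainer(
        signals=rng.standard_normal((n_ch, n_s)) * 40,
        lfp_rate=1000.0,
        channels=_channels(n_ch, with_pos=True),
        events=events,
        history=[ProvenanceRecord(operation="synthesize", parameters={"seed": 1})],
    )


class TestContainer:
    def test_round_trip(self, tmp_path, rng):
        c = _make_container(rng)
        c2 = read_lfp_container(write_lfp_container(c, tmp_path / "c.bst"))
        assert np.allclose(c2.signals, c.signals, rtol=1e-6, atol=1e-4)
        assert c2.lfp_rate == c.lfp_rate
        assert [e.label for e in c2.events] == [e.label for e in c.events]
        assert np.allclose(c2.events[1].times, c.events[1].times)
        assert c2.channels[1].position == c.channels[1].position
        assert c2.history[0].operation == "synthesize"
        assert c2.history[0].parameters == {"seed": 1}

    def test_zero_events_round_trip(self, tmp_path, rng):
        c = _make_container(rng, with_events=False)
        c2 = read_lfp_container(write_lfp_container(c, tmp_path / "c.bst"))
        assert c2.events == []

    def test_corrupt_magic_names_format(self, tmp_path, rng):
        p = write_lfp_container(_make_container(rng), tmp_path / "c.bst")
        raw = bytearray(p.read_bytes())
        raw[:4] = b"XXXX"
        p.write_bytes(bytes(raw))
        with pytest.raises(ValueError, match="EPHYSLFP"):
            read_lfp_container(p)

    def test_size_matches_prediction(self, tmp_path, rng):
        c = _make_container(rng, n_ch=4, n_s=5000)
        p = write_lfp_container(c, tmp_path / "c.bst")
        assert abs(p.stat().st_size - predicted_container_size(c)) <= 0.05 * p.stat().st_size

    @settings(deadline=None, derandomize=True, max_examples=15)
    @given(n_ch=st.integers(1, 4), n_s=st.integers(10, 400), seed=st.integers(0, 2**16))
    def test_round_trip_property(self, tmp_path_factory, n_ch, n_s, seed):
        tmp_path = tmp_path_factory.mktemp("cont")
        local = np.random.default_rng(seed)
        c = _make_container(local, n_ch=n_ch, n_s=n_s, with_events=False)
        c2 = read_lfp_container(write_lfp_container(c, tmp_path / "c.bst"))
        assert np.allclose(c2.signals, c.signals, rtol=1e-6, atol=1e-4)

    def test_event_beyond_duration_rejected(self, rng):
        with pytest.raises(ValueError, match="beyond"):
            LfpContainer(
                signals=rng.standard_normal((1, 100)),
                lfp_rate=1000.0,
                channels=_channels(1),
                events=[EventSeries("late", "stimulus", np.array([5.0]))],
            )

    def test_content_digest_ignores_history(self, rng):
        c = _make_container(rng)
        d1 = c.content_digest()
        c.history.append(ProvenanceRecord(operation="later"))
        assert c.content_digest() == d1


class TestProbeGeometry:
    def test_round_trip(self, tmp_path):
        chans = _channels(4, with_pos=True)
        back = read_probe_geometry(write_probe_geometry(chans, tmp_path / "p.tsv"))
        assert [c.label for c in back] == [c.label for c in chans]
        assert back[3].position == pytest.approx(chans[3].position)
        assert back[0].group == "probe0"


class TestProvenance:
    def test_timestamp_validated(self):
        with pytest.raises(ValueError):
            ProvenanceRecord(operation="x", timestamp="not-a-date")
        rec = ProvenanceRecord(operation="filter", input_paths=["a.dat"])
        back = ProvenanceRecord.from_dict(rec.to_dict())
        assert back.operation == "filter"
        assert back.timestamp == rec.timestamp

    def test_operation_required(self):
        with pytest.raises(ValueError):
            ProvenanceRecord(operation="")
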