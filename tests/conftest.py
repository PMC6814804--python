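"""Shared fixtures: a small synthetic probe dataset and containers/trials
derived from it, generated once per session."""

from __future__ import annotations

import numpy as np
import pytest

from ephyskit.data_io import read_events, read_raw_header
from ephyskit.epochs import import_epochs
from ephyskit.lfp import LfpExtractionConfig, extract_lfp
from ephyskit.synth import TrialSchedule, generate_demo_dataset


@pytest.fixture(scope="session")
def demo_dataset(tmp_path_factory):
    """Small 4-channel, 30 kHz probe recording: 8 conditions x 2 repeats."""
    outdir = tmp_path_factory.mktemp("demo")
    return generate_demo_dataset(
        outdir,
        seed=20240917,
        n_channels=4,
        schedule=TrialSchedule(n_repeats=2),
    )


@pytest.fixture(scope="session")
def demo_recording(demo_dataset):
    return read_raw_header(demo_dataset["header"])


@pytest.fixture(scope="session")
def demo_events(demo_dataset):
    return read_events(demo_dataset["events"])


@pytest.fixture(scope="session")
def demo_container(demo_recording, demo_events):
    return extract_lfp(
        demo_recording, demo_events, LfpExtractionConfig(despike_method="spectral")
    )


@pytest.fixture(scope="session")
def demo_trials(demo_container):
    labels = [e.label for e in demo_container.events if e.kind == "stimulus"]
    return import_epochs(demo_container, labels, (-0.5, 1.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
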