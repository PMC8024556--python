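"""Shared fixtures: small synthetic recordings generated at test time."""

import numpy as np
import pytest

from microsleep import (
    SimConfig,
    filter_recording,
    generate_recording,
    rasterize_events,
)


@pytest.fixture(scope="session")
def short_cfg() -> SimConfig:
    """Two minutes of simulated MWT — enough for I/O and windowing tests."""
    return SimConfig(duration_s=120.0, seed=11)


@pytest.fixture(scope="session")
def short_recording(short_cfg):
    return generate_recording(short_cfg, rec_id="fix000")


@pytest.fixture(scope="session")
def long_recording():
    """One full 40-min recording at the default study conditions."""
    cfg = SimConfig(seed=19)
    return generate_recording(cfg, rec_id="fix40m"), cfg


@pytest.fixture(scope="session")
def prepared_pair(short_recording):
    """Conditioned recording + per-sample label track."""
    rec, events = short_recording
    filt = filter_recording(rec)
    track = rasterize_events(events, rec.n_samples, rec.fs)
    return filt, track


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
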