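import numpy as np
import pytest
from hypothesis import settings

import semgforce as sf

settings.register_profile("repro", derandomize=True, deadline=None)
settings.load_profile("repro")


@pytest.fixture(scope="session")
def default_recording():
    """Default-condition synthetic recording: 60 actions, 4 levels, 6 channels."""
    cfg = sf.SimConfig(seed=123)
    rec, truth = sf.generate_recording(cfg)
    return cfg, rec, truth


@pytest.fixture(scope="session")
def default_segments(default_recording):
    _, rec, _ = default_recording
    spans = sf.detect_actions(rec)
    return sf.trim_segments(spans, rec)


@pytest.fixture(scope="session")
def default_table(default_recording, default_segments):
    _, rec, _ = default_recording
    wcfg = sf.WindowConfig.from_ms(200, 0.5, rec.fs)
    return sf.extract_table(default_segments, rec, wcfg)


@pytest.fixture(scope="session")
def planted_run():
    """Scaled recording with exactly two informative channels (P1, P2)."""
    cfg = sf.SimConfig(
        seed=42,
        actions_per_level=5,
        n_actions=20,
        channel_gains=(1.0, 0.9, 0.0, 0.0, 0.0, 0.0),
    )
    rec, truth = sf.generate_recording(cfg)
    segments = sf.trim_segments(sf.detect_actions(rec), rec)
    wcfg = sf.WindowConfig.from_ms(200, 0.5, rec.fs)
    table = sf.extract_table(segments, rec, wcfg)
    return cfg, rec, truth, table


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
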