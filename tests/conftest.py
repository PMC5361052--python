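import numpy as np
import pytest
from hypothesis import settings

import ecgbaseline as eb

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")

# Per-lead ST levels (mV) used by the shared fixtures: mixed elevations and
# depressions of clinically relevant magnitude.
ST_LEVELS = np.array([0.2, -0.1, 0.05, -0.3, 0.15, -0.25,
                      0.1, 0.3, -0.05, 0.2, -0.2, 0.12])


@pytest.fixture(scope="session")
def template():
    return eb.make_beat_template(ST_LEVELS, seed=123)


@pytest.fixture(scope="session")
def short_record(template):
    """10 s, 12-lead clean record (5120 samples at 512 Hz)."""
    return eb.synthesize_record(template, eb.RRModel(), duration=10.0, seed=7)


@pytest.fixture(scope="session")
def spec_short(short_record):
    return eb.BaselineSpec(fs=short_record.fs, n_samples=short_record.n_samples)


@pytest.fixture(scope="session")
def realization_short(spec_short):
    return eb.draw_realization(spec_short, seed=42)
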