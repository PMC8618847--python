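import numpy as np
import pytest

from bsound import synthetic


@pytest.fixture(scope="session")
def short_recording():
    """12-s synthetic recording with clear bursts, shared across tests."""
    cfg = synthetic.SynthConfig(duration_s=12.0, events_per_min=40.0,
                                snr_db=20.0, seed=7)
    rec, ann = synthetic.generate(cfg)
    return rec, ann, cfg


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
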