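import numpy as np
import pytest

import clockwave as cw


@pytest.fixture
def noiseless_colony():
    """Deterministic traveling-wave colony (no noise, no spikes)."""
    cfg = cw.ColonySimConfig(seed=11, noise_model="none", duration_min=2880)
    truth = cw.simulate_phase_field(cfg)
    movie = cw.render_luminescence(truth, cfg)
    return cfg, truth, movie


@pytest.fixture
def cosine_trace():
    """Pure zero-mean cosine, 5-min sampling over 48 h, period 160 min."""
    t = 5.0 * np.arange(577)
    return cw.TimeSeries(t, np.cos(2 * np.pi * t / 160.0), label="cos160")
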