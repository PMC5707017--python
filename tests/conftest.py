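import numpy as np
import pytest

import furawave as fw


@pytest.fixture
def flat_trace():
    """Noise-free flat trace at ratio 1.0, 600 s at 3-s sampling."""
    t = np.arange(0, 601, 3.0)
    return fw.RatioTrace(times=t, values=np.ones_like(t), roi_id="flat",
                         stimulus_time=120.0)


@pytest.fixture
def clean_config():
    """Noise-free single-spike cohort with a deterministic 120-s latency."""
    return fw.CohortConfig(
        n_cells=4, noise_sd=0.0, responder_prob=1.0, max_spikes=1,
        latency_mean=120.0, latency_sd=0.0, stimulus_time=300.0, seed=11,
    )


@pytest.fixture
def oscillating_cohort():
    """Small noise-free cohort with sustained spike trains."""
    cfg = fw.CohortConfig(n_cells=5, noise_sd=0.0, responder_prob=1.0,
                          stimulus_time=300.0, seed=7)
    return fw.simulate_cohort(cfg, condition="train")
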