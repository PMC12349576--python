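import numpy as np
import pytest

import ssvepnet as sv


@pytest.fixture(scope="session")
def stim():
    return sv.StimulusSet()


@pytest.fixture(scope="session")
def bank():
    return sv.design_filter_bank(sv.FilterBankSpec(), 250.0)


@pytest.fixture(scope="session")
def noiseless_epochs(stim):
    """A small noiseless subject: 2 trials per class."""
    cfg = sv.SynthConfig(snr_db=np.inf, trials_per_class=2, seed=11)
    return sv.generate_subject(stim, cfg, "NL", np.random.default_rng(11))


@pytest.fixture(scope="session")
def small_window_batch(stim, bank):
    """A tiny labelled batch of filter-bank windows at +10 dB, P=64."""
    cfg = sv.SynthConfig(snr_db=10.0, trials_per_class=4, seed=21)
    es = sv.generate_subject(stim, cfg, "WB", np.random.default_rng(21))
    x = sv.downsample(es.data, 1000, 250)
    ws = sv.WindowSpec(d_samples=64)
    rng = np.random.default_rng(22)
    windows, labels = sv.harvest_windows(x, es.labels, ws, 4, rng, bank=bank)
    return windows, labels
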