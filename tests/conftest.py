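import numpy as np
import pytest

import tdiquant as tq


@pytest.fixture(scope="session")
def default_sim():
    """One default-noise synthetic strip with ground truth (seeded)."""
    return tq.simulate(seed=42)


@pytest.fixture(scope="session")
def noiseless_sim():
    """A noiseless, jitter-free strip: speckle and background noise off."""
    wave = tq.make_waveform(tq.WaveformParams(jitter_frac=0.0), seed=7)
    rp = tq.RenderParams(speckle_sd=0.0, background_noise_sd=0.0)
    return tq.render_strip(wave, rp)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
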