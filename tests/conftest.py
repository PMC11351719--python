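import pytest

import avcond as av


@pytest.fixture(scope="session")
def layout():
    return av.default_layout()


@pytest.fixture(scope="session")
def default_schedule():
    return av.generate_schedule(av.DesignConfig(seed=11))


@pytest.fixture(scope="session")
def noiseless_session(layout, default_schedule):
    """One noiseless session with attenuation and injection planted."""
    cfg = av.DesignConfig(seed=11)
    effects = av.default_effects(layout, srate=500.0, noise_sd=0.0,
                                 white_sd=0.0)
    epochs = av.simulate_session(default_schedule, layout, effects, seed=2,
                                 config=cfg)
    return epochs, effects


@pytest.fixture(scope="session")
def noisy_session(layout, default_schedule):
    """One realistic-noise session (all defaults)."""
    cfg = av.DesignConfig(seed=11)
    effects = av.default_effects(layout, srate=500.0)
    epochs = av.simulate_session(default_schedule, layout, effects, seed=3,
                                 config=cfg)
    return epochs, effects
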