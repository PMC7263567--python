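import pytest

from epimech.synth import SynthConfig, default_config, generate_scene


@pytest.fixture(scope="session")
def config():
    return default_config()


@pytest.fixture(scope="session")
def noiseless_config(config):
    presets = {name: p.replace(noise_sd=0.0, period_jitter_frac=0.0)
               for name, p in config.presets.items()}
    return SynthConfig(seed=0, presets=presets)


@pytest.fixture(scope="session")
def mosaic_scene(noiseless_config):
    """One noiseless F-actin mosaic (control + mutant clone), with truth."""
    return generate_scene(noiseless_config, "mutant", 16, seed=2)


@pytest.fixture(scope="session")
def control_scene(noiseless_config):
    return generate_scene(noiseless_config, "control", 16, seed=1)
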