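import numpy as np
import pytest
from dataclasses import replace

from ecgbeats.synthetic import BeatClass, default_config, generate_beat, generate_dataset


@pytest.fixture(scope="session")
def config():
    return default_config(seed=1)


@pytest.fixture(scope="session")
def noiseless_config(config):
    """Default morphology, but no measurement noise, wander, amplitude
    jitter, ST jitter or heart modes: the fully deterministic geometry."""
    classes = {
        lab: replace(m, st_sd=0.0, amp_jitter_frac=0.0, modes=())
        for lab, m in config.classes.items()
    }
    return replace(config, noise_sd=0.0, baseline_amp=0.0, classes=classes)


@pytest.fixture(scope="session")
def nor_beat(noiseless_config):
    return generate_beat(BeatClass.NOR, noiseless_config, 0)


@pytest.fixture(scope="session")
def beats_by_class(config):
    return {lab: generate_beat(lab, config, 7) for lab in BeatClass}


@pytest.fixture(scope="session")
def nor_population(config):
    """1000 default NOR beats on per-beat substreams of one root seed."""
    return [
        generate_beat(BeatClass.NOR, config,
                      np.random.default_rng(np.random.SeedSequence(entropy=1, spawn_key=(0, i))))
        for i in range(1000)
    ]
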