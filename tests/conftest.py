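import numpy as np
import pytest

from biaslab import GeneratorConfig, generate_dataset, make_phantom


@pytest.fixture(scope="session")
def phantom32():
    return make_phantom(32, 2.0, "class1", seed=1)


@pytest.fixture(scope="session")
def phantom32_class2():
    return make_phantom(32, 2.0, "class2", seed=1)


@pytest.fixture(scope="session")
def clean_stack32():
    """600 noiseless CTF-free projections at uniform poses (box 32)."""
    cfg = GeneratorConfig(n_particles=600, box=32, snr=np.inf, with_ctf=False,
                          seed=3, phantom_seed=1)
    stack, volumes = generate_dataset(cfg)
    return stack, volumes["class1"]


@pytest.fixture(scope="session")
def noisy_stack32():
    """Realistic small dataset: SNR 0.1, CTF on, box 32."""
    cfg = GeneratorConfig(n_particles=200, box=32, snr=0.1, seed=4, phantom_seed=1)
    stack, volumes = generate_dataset(cfg)
    return stack, volumes["class1"]
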