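import numpy as np
import pytest

from seqforge import gan_core, seqdata


@pytest.fixture(scope="session")
def tata_pwm():
    """Sharp 6-position PWM (column max 0.97) around the TATAAT box."""
    return seqdata.pwm_from_consensus("TATAAT", p_max=0.97, name="tata")


@pytest.fixture(scope="session")
def small_gan():
    """A tiny untrained generator/critic pair (L=12) for structural tests."""
    gcfg = gan_core.GeneratorConfig(seq_len=12, channels=8, n_res_blocks=2, latent_dim=16)
    ccfg = gan_core.CriticConfig(seq_len=12, channels=8, n_res_blocks=2)
    return gan_core.build_generator(gcfg, seed=0), gan_core.build_critic(ccfg, seed=0)


@pytest.fixture(scope="session")
def background_seqs():
    spec = seqdata.SyntheticDatasetSpec(n_sequences=50, length=30, seed=123)
    return seqdata.simulate_dataset(spec).sequences


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)
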