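import numpy as np
import pytest

from gevescan import synth


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_sim():
    """One small but complete endogenization scenario shared across tests."""
    return synth.simulate_endogenization(
        host=synth.HostModel(length=400_000, gc=0.28, repeat_fraction=0.4),
        insert=synth.InsertModel(length=120_000, gc=0.37, n_genes=40),
        decay=synth.DecayModel(),
        read_model=synth.ReadSimModel(depth=15.0, read_length_mean=6_000, read_length_sd=2_000),
        seed=7,
    )


def random_dna(rng, length, gc=0.5):
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=length, p=p)])
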