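import numpy as np
import pytest

from plmfuse.synthetic import FamilySimConfig, simulate_family


@pytest.fixture
def tiny_fasta(tmp_path):
    path = tmp_path / "tiny.fasta"
    path.write_text(">q\nACDE\n>h\nGHIK\n")
    return path


@pytest.fixture
def clean_family():
    """Noise-free family: embeddings carry the labels exactly."""
    config = FamilySimConfig(L=40, n_homologs=5, sub_rate=0.2, indel_rate=0.1,
                             sigma=0.0, D=16, seed=7)
    return simulate_family(config, "clean", 0)


@pytest.fixture
def noisy_family():
    config = FamilySimConfig(L=40, n_homologs=10, sub_rate=0.2, indel_rate=0.1,
                             sigma=2.0, D=16, seed=11)
    return simulate_family(config, "noisy", 1)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
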