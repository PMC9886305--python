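import numpy as np
import pytest

from metacpi.encoders import ChemicalEncoderConfig, ProteinEncoderConfig
from metacpi.model import ModelConfig
from metacpi.msa import AlignedFamily
from metacpi.synthetic import GeneratorConfig, generate_dataset
from metacpi.training import distill_corpus


@pytest.fixture(scope="session")
def small_dataset():
    """Shared 12-family synthetic dataset (kept small for unit tests)."""
    return generate_dataset(GeneratorConfig(n_families=12, members_per_family=4,
                                            n_molecules=20, pairs_per_family=20,
                                            seed=11))


@pytest.fixture(scope="session")
def small_corpus(small_dataset):
    return distill_corpus([sf.family for sf in small_dataset.families])


@pytest.fixture(scope="session")
def tiny_model_config(small_corpus):
    return ModelConfig(
        protein=ProteinEncoderConfig(vocab_size=len(small_corpus.vocab),
                                     embedding_dim=16, n_layers=2, n_heads=2,
                                     max_positions=64),
        chemical=ChemicalEncoderConfig(embedding_dim=16),
        attention_dim=16)


@pytest.fixture
def toy_family():
    return AlignedFamily(
        family_id="TOY",
        member_ids=["m1", "m2", "m3", "m4"],
        aligned_rows=["ACDEFGHIKLMN",
                      "ACDEFGHIKLMN",
                      "ACDEFGHIKLMN",
                      "ACDEFGHIKLMN"])


@pytest.fixture
def rng():
    return np.random.default_rng(0)
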