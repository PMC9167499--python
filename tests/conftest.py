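"""Shared fixtures: small synthetic corpora and pretrained tables.

Session-scoped so the (deterministic) corpus generation and embedding
pretraining run once per test session.
"""

import numpy as np
import pytest

from multitok.config import EmbeddingTrainConfig, pretrain_tables
from multitok.encoder import EncoderConfig
from multitok.synthetic import generate_smiles
from multitok.tokenize import TokenizerSpec, learn_bpe_vocabulary


@pytest.fixture(scope="session")
def smiles_corpus() -> list[str]:
    return generate_smiles(80, seed=42)


@pytest.fixture(scope="session")
def bpe_vocab(smiles_corpus):
    return learn_bpe_vocabulary(smiles_corpus, 60, corpus_tag="fixture")


@pytest.fixture(scope="session")
def compound_specs(bpe_vocab):
    return [TokenizerSpec(kind="ecfp", radius=1),
            TokenizerSpec(kind="bpe", vocabulary=bpe_vocab)]


@pytest.fixture(scope="session")
def small_config():
    return EncoderConfig(dimension=16, heads=2, layers=2, dropout=0.1,
                         max_len=128)


@pytest.fixture(scope="session")
def tables(smiles_corpus, compound_specs, small_config):
    return pretrain_tables(smiles_corpus, compound_specs,
                           EmbeddingTrainConfig(epochs=3),
                           small_config.dimension, seed=7)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
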