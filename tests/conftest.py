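import numpy as np
import pytest

from idiomkit.curation import IdrRecord
from idiomkit.fim import encode_corpus
from idiomkit.fixtures import CorpusSpec, synth_idr_corpus
from idiomkit.model import DecoderLM, ModelConfig
from idiomkit.trainer import TrainConfig, pretrain


@pytest.fixture(scope="session")
def toy_config() -> ModelConfig:
    return ModelConfig(n_layers=2, n_heads=2, d_model=32, max_len=96)


@pytest.fixture(scope="session")
def toy_model(toy_config) -> DecoderLM:
    """Small randomly initialized model (float64, untrained)."""
    return DecoderLM(toy_config, seed=11)


@pytest.fixture(scope="session")
def idp_records():
    """400 synthetic context-free IDR records, median length 60."""
    seqs = synth_idr_corpus(
        CorpusSpec(n_sequences=400, median_length=60, max_length=120, seed=7)
    )
    return [IdrRecord(f"s{i}", "", s, "", 1, len(s)) for i, s in enumerate(seqs)]


@pytest.fixture(scope="session")
def pretrained_tiny(idp_records) -> DecoderLM:
    """A briefly pre-trained tiny model shared across sampler/RL tests."""
    corpus = encode_corpus(idp_records, max_len=130)
    model = DecoderLM(
        ModelConfig(n_layers=2, n_heads=4, d_model=64, max_len=160, dtype="float32"),
        seed=5,
    )
    pretrain(model, corpus, TrainConfig.desk(total_steps=120, seed=5))
    return model
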