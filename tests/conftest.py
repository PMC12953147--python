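"""Shared fixtures: the reference synthetic corpus and trained checkpoints.

The heavyweight artifacts (the simulated author panel and the two trained
models) are session-scoped so the conditioning, neutrality and evaluation
tests all reuse a single training run.
"""

from __future__ import annotations

import numpy as np
import pytest

import traitlm as T
from traitlm.synthetic_data import (
    SyntheticConfig,
    participants_to_records,
    sample_participants,
    train_heldout_split,
)

REF_SEED = 0


@pytest.fixture(scope="session")
def ref_config() -> SyntheticConfig:
    """The reference study conditions: 5 traits, beta=1, 200 authors x 10
    messages."""
    return SyntheticConfig(seed=REF_SEED)


@pytest.fixture(scope="session")
def ref_participants(ref_config):
    return sample_participants(ref_config)


@pytest.fixture(scope="session")
def ref_records(ref_participants):
    return participants_to_records(ref_participants)


@pytest.fixture(scope="session")
def ref_split(ref_records, ref_config):
    return train_heldout_split(ref_records, ref_config)


@pytest.fixture(scope="session")
def null_participants():
    """Same panel shape with beta=0: no trait-language coupling."""
    return sample_participants(SyntheticConfig(seed=REF_SEED, beta=0.0))


@pytest.fixture(scope="session")
def ref_vocab(ref_records):
    return T.Vocabulary.from_corpus([r.tokens for r in ref_records])


@pytest.fixture(scope="session")
def ref_model_cfg(ref_vocab):
    return T.ModelConfig(vocab_size=len(ref_vocab))


@pytest.fixture(scope="session")
def ref_adapter_cfg(ref_config):
    return T.AdapterConfig(latent_size=ref_config.t)


@pytest.fixture(scope="session")
def trained_checkpoint(ref_split, ref_vocab, ref_model_cfg, ref_adapter_cfg, ref_config):
    """The conditioned model trained on the reference fixture."""
    train, _ = ref_split
    msgs = T.records_to_messages(train, ref_vocab)
    return T.train_adapter(
        msgs, ref_model_cfg, ref_adapter_cfg, T.TrainConfig(seed=REF_SEED),
        ref_vocab, trait_names=ref_config.trait_names,
    )


@pytest.fixture(scope="session")
def unconditioned_checkpoint(ref_split, ref_vocab, ref_model_cfg, ref_adapter_cfg):
    """Matched control: identical data, architecture and seed, but every
    trait profile zeroed, so conditioning carries no information."""
    train, _ = ref_split
    msgs = [
        T.ScoredMessage(m.tokens, np.zeros(m.scores.shape))
        for m in T.records_to_messages(train, ref_vocab)
    ]
    return T.train_adapter(
        msgs, ref_model_cfg, ref_adapter_cfg, T.TrainConfig(seed=REF_SEED), ref_vocab
    )


@pytest.fixture(scope="session")
def heldout_messages(ref_split, ref_vocab):
    _, held = ref_split
    return T.records_to_messages(held, ref_vocab)


@pytest.fixture
def tiny_model_cfg():
    """A minimal but non-degenerate architecture for unit tests."""
    return T.ModelConfig(
        vocab_size=12, num_layers=2, hidden_size=16, num_heads=4,
        num_kv_heads=2, head_dim=4, max_sequence_length=16,
    )
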