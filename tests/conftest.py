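import numpy as np
import pytest

import rnalm as R


@pytest.fixture(scope="session")
def base_tokenizer():
    """Base-only vocabulary: one nucleotide per token, EOS id 0."""
    return R.BPETokenizer(
        merges=[], vocab=["<eos>", "A", "C", "G", "T"], base_symbols=["A", "C", "G", "T"]
    )


@pytest.fixture(scope="session")
def small_corpus():
    return R.generate_markov_corpus(R.uniform_markov_spec(40, 60, seed=11))


@pytest.fixture(scope="session")
def trained_tokenizer(small_corpus):
    return R.train_bpe(small_corpus, vocab_size=24)


@pytest.fixture(scope="session")
def tiny_config():
    return R.ModelConfig(n_layers=2, d_model=32, n_heads=2, context_len=32, vocab_size=8, seed=5)


@pytest.fixture(scope="session")
def tiny_model(tiny_config):
    return R.build_model(tiny_config)


@pytest.fixture(scope="session")
def hairpins():
    return R.generate_hairpin_corpus(30, stem_len=12, loop_len=5, seed=3)


class ToyModel:
    """Drop-in model with hand-set next-token distributions for sampler oracles.

    ``table`` maps a conditioning token id (or None for the start state) to a
    probability vector over the vocabulary; unseen contexts fall back to the
    start distribution.
    """

    def __init__(self, table, vocab_size, context_len=16):
        from rnalm.model import ModelConfig

        self.config = ModelConfig(
            n_layers=1, d_model=2, n_heads=1, context_len=context_len, vocab_size=vocab_size
        )
        self.table = {k: np.asarray(v, dtype=float) for k, v in table.items()}

    def forward(self, ids):
        ids = np.asarray(ids)
        B, L = ids.shape
        out = np.empty((B, L, self.config.vocab_size))
        for b in range(B):
            for t in range(L):
                key = int(ids[b, t])
                p = self.table.get(key, self.table[None])
                out[b, t] = np.log(np.maximum(p, 1e-300))
        return out


@pytest.fixture
def toy_model_factory():
    return ToyModel
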