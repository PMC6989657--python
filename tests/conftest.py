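import numpy as np
import pytest

from phenocnn import GeneratorConfig, generate_corpus


@pytest.fixture(scope="session")
def small_corpus():
    """A small labelled corpus with a clear token signal (shared, read-only)."""
    cfg = GeneratorConfig(
        n_notes=80,
        n_phenotypes=2,
        vocab_size=400,
        zipf_alpha=0.97,
        signal_tokens_per_phenotype=3,
        signal_rate=0.3,
        sentences_per_note=(4, 8),
        words_per_sentence=(4, 9),
        label_prevalences=(0.3, 0.2),
        singleton_rate=0.02,
        seed=7,
    )
    return generate_corpus(cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
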