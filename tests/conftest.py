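import numpy as np
import pytest

from vqnorm import (
    CohortSpec,
    ScaleModel,
    TokenizerConfig,
    TransformerConfig,
    Volume3D,
    train_tokenizer,
)


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def tiny_cohort_spec(**overrides) -> CohortSpec:
    """A fast-to-render cohort: 16^3 grid, 4 regions, small n."""
    defaults = dict(
        n_subjects=12,
        grid_shape=(16, 16, 16),
        n_rois=4,
        scales={"total": ScaleModel(0.3, 2.0, 12.9), "social": ScaleModel(0.3, 1.5, 5.0)},
        seed=0,
    )
    defaults.update(overrides)
    return CohortSpec(**defaults)


@pytest.fixture(scope="session")
def trained_toy_tokenizer():
    """Tokenizer trained on a handful of structured 16^3 volumes."""
    rng = np.random.default_rng(5)
    base = rng.uniform(0.2, 0.8, size=(16, 16, 16))
    vols = [Volume3D(np.clip(base + rng.normal(0, 0.02, base.shape), 0, None)) for _ in range(8)]
    config = TokenizerConfig(vocabulary_size=8, embedding_dim=8, hidden=32, epochs=10, seed=6)
    tok, report = train_tokenizer(vols, config)
    return tok, report, vols
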