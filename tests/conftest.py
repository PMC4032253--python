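import numpy as np
import pytest

from plastinet import ExperimentConfig, generate_memory_set


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_memories():
    """A small hetero-associative memory set for structural tests."""
    return generate_memory_set(M=5, m=20, n=24, k=4, l=5, seed=7)


@pytest.fixture
def tiny_block_config():
    """A scaled-down block-learning configuration for fast pipeline tests."""
    return ExperimentConfig(
        mode="multi", m=150, n=150, k=12, l=12,
        c_a=0.08, c_p=1.0, f1c=0.0, p_elim=1.0,
        lambda_=0.9, kappa=0.1,
        n_blocks=3, M_per_block=3, replay_steps=3,
        auto_c=0.5, n_iter=2, eval_stride=1, seed=11,
    )
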