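import numpy as np
import pytest

from comprec import GenParams, generate_dataset, partition_sequence_space


@pytest.fixture(scope="session")
def partition_l4():
    return partition_sequence_space(4, seed=11)


@pytest.fixture(scope="session")
def small_train(partition_l4):
    return generate_dataset(
        partition_l4.train_pool, N=400, alpha=0.5, mu=0.0, role="train", seed=7
    )


@pytest.fixture(scope="session")
def small_test(partition_l4):
    return generate_dataset(
        partition_l4.test_pool, N=400, alpha=0.5, mu=0.0, role="test", seed=8
    )


@pytest.fixture(scope="session")
def noisy_train(partition_l4):
    return generate_dataset(
        partition_l4.train_pool, N=400, alpha=0.5, mu=0.2, role="train", seed=9
    )
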