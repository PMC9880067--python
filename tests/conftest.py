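import numpy as np
import pytest

import genesieve as gs


@pytest.fixture
def tiny_matrix() -> gs.ExpressionMatrix:
    rng = np.random.default_rng(7)
    return gs.ExpressionMatrix(
        tuple(f"g{i}" for i in range(6)),
        tuple(f"s{j}" for j in range(8)),
        rng.normal(5.0, 1.0, size=(6, 8)),
    )


@pytest.fixture
def tiny_labels(tiny_matrix) -> gs.ClassLabels:
    sids = tiny_matrix.sample_ids
    return gs.ClassLabels({s: ("A" if j < 4 else "B") for j, s in enumerate(sids)},
                          positive_class="A")


@pytest.fixture(scope="session")
def benchmark_dataset() -> gs.SyntheticDataset:
    """The default 2000-gene, 28+22-sample recovery benchmark."""
    return gs.generate(gs.benchmark_config())
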