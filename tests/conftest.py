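import numpy as np
import pytest

from mirlink import (
    AssociationDataset,
    SyntheticSpec,
    TrainConfig,
    generate_planted_dataset,
)


@pytest.fixture
def tiny_ds() -> AssociationDataset:
    """4 miRNAs x 3 diseases with 5 known associations."""
    A = np.array(
        [
            [1, 0, 1],
            [0, 1, 0],
            [1, 1, 0],
            [0, 0, 0],
        ]
    )
    return AssociationDataset(
        [f"mir-{i}" for i in range(4)], [f"dz-{j}" for j in range(3)], A
    )


@pytest.fixture(scope="session")
def planted():
    """Default planted synthetic world (dataset, true propensity matrix)."""
    return generate_planted_dataset(SyntheticSpec())


@pytest.fixture
def quick_cfg() -> TrainConfig:
    """A deliberately tiny training configuration for structural tests."""
    return TrainConfig(
        latent_dim=8,
        epochs=2,
        batch_size=64,
        learning_rate=1e-3,
        hidden_widths=(32, 16, 8),
        d_h=8,
        attn_rank=4,
    )
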