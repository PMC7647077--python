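import numpy as np
import pandas as pd
import pytest

from netten.datasets import ExpressionDataset, NetworkTensor
from netten.simulate import (
    CoefficientProfile,
    NoiseSpec,
    generate_dataset,
    generate_network_tensor,
)


@pytest.fixture(scope="session")
def small_truth():
    """Tiny varying-coefficient dataset with one edge of each profile kind."""
    profiles = {
        (0, 0): CoefficientProfile("constant", baseline=1.5, shifted=1.5),
        (1, 1): CoefficientProfile("step", baseline=0.0, shifted=2.0),
        (2, 2): CoefficientProfile("sigmoid", baseline=-1.0, shifted=1.0),
    }
    return generate_dataset(60, 4, 3, profiles, NoiseSpec(sigma=0.05, seed=11), seed=5)


@pytest.fixture(scope="session")
def small_dataset(small_truth) -> ExpressionDataset:
    return small_truth.to_expression_dataset()


@pytest.fixture(scope="session")
def planted_stack():
    """Noiseless planted rank-2 tensor stack with a linear response."""
    return generate_network_tensor(60, 30, 15, 2, response_map="linear", seed=3)


@pytest.fixture()
def toy_tensor() -> NetworkTensor:
    """Hand-sized 3-target x 3-regulator x 4-sample tensor with known sparsity."""
    coeffs = np.zeros((3, 3, 4))
    coeffs[0, 1, 0] = 1.0  # g0 <- g1 in sample s0 only
    coeffs[1, 2, :] = -0.5  # g1 <- g2 everywhere
    coeffs[2, 0, 2] = 2.0  # g2 <- g0 in sample s2
    return NetworkTensor(
        coefficients=coeffs,
        intercepts=np.zeros((3, 4)),
        target_ids=["g0", "g1", "g2"],
        regulator_ids=["g0", "g1", "g2"],
        sample_ids=["s0", "s1", "s2", "s3"],
        modulator=np.array([-1.0, -0.3, 0.3, 1.0]),
    )


@pytest.fixture()
def toy_expression(toy_tensor) -> ExpressionDataset:
    rng = np.random.default_rng(0)
    values = pd.DataFrame(
        rng.standard_normal((3, 4)),
        index=toy_tensor.target_ids,
        columns=toy_tensor.sample_ids,
    )
    roles = pd.Series("both", index=values.index)
    return ExpressionDataset(values=values, roles=roles,
                             modulator=toy_tensor.modulator)
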