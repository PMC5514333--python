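import numpy as np
import pytest

from gomultiloc import (
    LabelSpace,
    MultiLabelDataset,
    GOSubspace,
    SyntheticConfig,
    generate,
)


@pytest.fixture(scope="session")
def small_truth():
    """A small seeded synthetic cohort with planted signal."""
    return generate(SyntheticConfig(n=60, c=4, omega=40, s=3, seed=7))


@pytest.fixture(scope="session")
def recovery_truth():
    """The signal-recovery benchmark cohort (strong planted signal)."""
    return generate(
        SyntheticConfig(n=200, c=4, omega=100, s=5, lam0=0.5, dlam=3.0, seed=0)
    )


@pytest.fixture
def toy_dataset():
    """Three proteins, two labels, linearly separable signal features.

    P1 is cytoplasmic, P3 nuclear, P2 both; feature 0 marks cytoplasm,
    feature 1 marks nucleus, feature 2 is constant background.
    """
    subspace = GOSubspace(["GO:0000001", "GO:0000002", "GO:0000003"])
    labelspace = LabelSpace(("cytoplasm", "nucleus"))
    X = np.array([[3, 0, 1], [3, 3, 1], [0, 3, 1]])
    Y = np.array([[1, -1], [1, 1], [-1, 1]])
    return MultiLabelDataset(["P1", "P2", "P3"], X, Y, subspace, labelspace)
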