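import numpy as np
import pandas as pd
import pytest

from ecvnet import PipelineConfig, SampleLabels, TPMMatrix
from ecvnet import simulate as sim


@pytest.fixture(scope="session")
def config():
    return PipelineConfig(seed=1)


@pytest.fixture(scope="session")
def knockdown_cohort():
    """One knocked-down regulator, 11 cases vs 9 controls, 30 genes."""
    truth = sim.knockdown_scenario(30, 0.06, 5, 0.0, seed=11)
    counts, labels = sim.simulate_counts(truth, 11, 9, seed=101)
    return truth, counts, labels


def make_tpm(values: np.ndarray, genes, samples) -> TPMMatrix:
    """Normalize arbitrary nonnegative values into a valid TPM matrix."""
    frame = pd.DataFrame(values, index=list(genes), columns=list(samples))
    frame = frame / frame.sum(axis=0) * 1e6
    return TPMMatrix(frame, column_sum_rtol=1e-9)


def make_labels(n_case: int, n_control: int) -> SampleLabels:
    ids = [f"case{i:02d}" for i in range(n_case)] + \
          [f"ctrl{i:02d}" for i in range(n_control)]
    return SampleLabels(pd.Series(["case"] * n_case + ["control"] * n_control,
                                  index=ids, name="group"))


@pytest.fixture
def tpm_factory():
    return make_tpm


@pytest.fixture
def labels_factory():
    return make_labels
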