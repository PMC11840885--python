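import numpy as np
import pandas as pd
import pytest

from dietsub import InterventionSpec, crossfit_nuisances, validate_dataset
from dietsub import simulation as sim


class FixedExposureA:
    """Exposure-A model with one fixed pmf shared by every record."""

    def __init__(self, pmf, support):
        self.pmf = np.asarray(pmf, dtype=float)
        self.support = np.asarray(support, dtype=int)
        self.descriptor = {"backend": "fixed"}

    def pmf_matrix(self, data, a=None):
        return np.tile(self.pmf, (data.n, 1))


class FixedExposureB:
    """Exposure-B model with one fixed pmf per conditioning level of A."""

    def __init__(self, pmf_by_a, support):
        # pmf_by_a: mapping a -> pmf over support
        self.pmf_by_a = {int(k): np.asarray(v, dtype=float) for k, v in pmf_by_a.items()}
        self.support = np.asarray(support, dtype=int)
        self.descriptor = {"backend": "fixed"}

    def pmf_matrix(self, data, a=None):
        A = np.broadcast_to(np.asarray(data.A if a is None else a), (data.n,))
        return np.stack([self.pmf_by_a[int(ai)] for ai in A])


class ConstantOutcome:
    """Outcome model predicting a single constant."""

    def __init__(self, value):
        self.value = float(value)
        self.descriptor = {"backend": "constant"}

    def predict(self, data, a=None, b=None):
        return np.full(data.n, self.value)


@pytest.fixture(scope="session")
def spec3():
    return InterventionSpec(x=3)


@pytest.fixture(scope="session")
def study1_small():
    return sim.generate_study1(2000, 42)


@pytest.fixture(scope="session")
def study1_nuisances(study1_small):
    specs = sim.scenario_specs(1, "correct")
    return crossfit_nuisances(
        study1_small, specs["outcome"], specs["expA"], specs["expB"]
    )


@pytest.fixture(scope="session")
def toy_dataset():
    table = pd.DataFrame(
        {
            "L": [0, 1, 0],
            "A": [2, 0, 1],
            "B": [1, 5, 6],
            "C": [0, 1, 2],
            "Y": [0, 1, 0],
        }
    )
    return validate_dataset(table, {"L": "L", "A": "A", "B": "B", "C": "C", "Y": "Y"})
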