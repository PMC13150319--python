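import numpy as np
import pytest

from widenedpipe import BranchRecord, Dataset, SimConfig, simulate_dataset


@pytest.fixture
def three_records():
    """A tiny hand-built dataset with wide, valid values."""
    return Dataset(
        records=[
            BranchRecord("Acer_rubrum", 500, 510, 45.0, 22.0, 300.0, 12.0),
            BranchRecord("Quercus_alba", 1200, 1180, 60.5, 30.25, 520.0, 8.5),
            BranchRecord("Pinus_edulis", 80, 83, 18.0, 12.0, 95.0, 20.0),
        ],
        provenance="hand-built",
    )


@pytest.fixture
def null_dataset():
    """Default-condition synthetic null (no furcation), fixed seed."""
    return simulate_dataset(SimConfig(seed=11))


@pytest.fixture
def noiseless_dataset():
    """Deterministic no-furcation limit: exact widening, exact isometry."""
    return simulate_dataset(SimConfig(seed=5, sigma_d=0.0, sigma_n=0.0))
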