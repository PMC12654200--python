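import numpy as np
import pandas as pd
import pytest

from ftirfp import SpectraSet, SyntheticConfig, aggregate_replicates, generate_cohort
from ftirfp.synthetic import separable_config


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort (30 replicate spectra) plus its ground truth."""
    return generate_cohort(SyntheticConfig(seed=11))


@pytest.fixture(scope="session")
def donor_set(default_cohort):
    """Donor-level (replicate-averaged) spectra of the default cohort."""
    spectra, _ = default_cohort
    return aggregate_replicates(spectra)


@pytest.fixture(scope="session")
def separable_donor_set():
    """Donor-level spectra of a separable-by-construction cohort."""
    spectra, _ = generate_cohort(separable_config(seed=5))
    return aggregate_replicates(spectra)


def make_set(grid, matrix, donors=None, groups=None, replicates=None) -> SpectraSet:
    """Assemble a SpectraSet from raw arrays with minimal metadata."""
    matrix = np.atleast_2d(np.asarray(matrix, dtype=float))
    n = matrix.shape[0]
    donors = donors or [f"D{i:02d}" for i in range(n)]
    groups = groups or ["UNKNOWN"] * n
    replicates = replicates or ["r1"] * n
    meta = pd.DataFrame(
        {"donor_id": donors, "replicate_id": replicates, "group": groups}
    )
    return SpectraSet(np.asarray(grid, dtype=float), matrix, meta)
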