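import numpy as np
import pandas as pd
import pytest

from popkit.genotypes import BandMatrix
from popkit.simulate import SimulationConfig, simulate_dataset


@pytest.fixture(scope="session")
def study_dataset():
    """Default study-scale panel: 82 accessions, 59 markers, 3 pops."""
    return simulate_dataset(SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def small_dataset():
    """Small panel for fast MCMC/association tests."""
    cfg = SimulationConfig(
        n_accessions=40, n_markers=30, n_pops=2, differentiation=0.8,
        admixture_concentration=0.05, missing_rate=0.0, seed=7,
    )
    return simulate_dataset(cfg)


def band_matrix_from_array(values: np.ndarray, prefix: str = "M") -> BandMatrix:
    """Helper: wrap a 0/1/-9 array, one marker per band."""
    n, L = values.shape
    cols = [f"{prefix}{j + 1:03d}_1" for j in range(L)]
    ids = [f"A{i + 1:03d}" for i in range(n)]
    return BandMatrix(pd.DataFrame(values, index=ids, columns=cols))
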