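import numpy as np
import pandas as pd
import pytest

from divscan import SimulationConfig, simulate_dataset
from divscan.genotypes import GenotypeMatrix


@pytest.fixture(scope="session")
def default_dataset():
    """One default-parameter simulation shared by read-only tests."""
    return simulate_dataset(SimulationConfig(seed=1))


@pytest.fixture(scope="session")
def small_config():
    """Reduced cohort for fast per-test simulations."""
    return SimulationConfig(
        n_scaffolds=4, windows_per_scaffold=10, snps_per_window=15.0, seed=3
    )


def make_matrix(calls, groups=None, scaffold="scaffold_1", start_pos=100):
    """Build a GenotypeMatrix from a (sites x samples) list of call codes."""
    calls = np.asarray(calls, dtype=np.int8)
    n_sites, n_samples = calls.shape
    samples = [f"s{i}" for i in range(n_samples)]
    if groups is None:
        half = n_samples // 2
        groups = {s: ("control" if i < half else "heat") for i, s in enumerate(samples)}
    else:
        groups = dict(zip(samples, groups))
    sites = pd.DataFrame(
        {
            "scaffold": scaffold,
            "pos": np.arange(start_pos, start_pos + n_sites),
            "ref": "A",
            "alt": "G",
        }
    )
    return GenotypeMatrix(sites=sites, calls=calls, samples=samples, groups=groups)
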