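import numpy as np
import pandas as pd
import pytest

from neuro17q import (CNProfile, SimulationConfig, simulate_cohort,
                      simulate_dependency_screen)


def pytest_addoption(parser):
    parser.addoption(
        "--bell-expr", default=None,
        help="Path to the processed tumor-cohort expression TSV (log2 scale) "
             "for the optional external-data correlation checks.")
    parser.addoption(
        "--depmap-dir", default=None,
        help="Directory with DepMap 19Q3 exports for the optional external "
             "screen reproduction.")


@pytest.fixture(scope="session")
def cohort():
    """Default-condition synthetic cohort, shared across tests."""
    config = SimulationConfig(seed=11)
    return config, simulate_cohort(config)


@pytest.fixture(scope="session")
def dependency_screen():
    """2000-gene screen with 40 planted MNA-essential genes."""
    config = SimulationConfig(seed=7, n_genes=2000)
    screen, truth = simulate_dependency_screen(config)
    return config, screen, truth


def make_profile(sample_id="S1", chrom="chr17", log2=None, cn=None,
                 bin_size=1_000_000):
    """Small CNProfile builder for hand-constructed cases."""
    log2 = np.asarray(log2, dtype=float)
    n = len(log2)
    bins = pd.DataFrame({
        "chromosome": chrom,
        "start": np.arange(n) * bin_size,
        "end": (np.arange(n) + 1) * bin_size,
        "log2_ratio": log2,
        "cn": cn if cn is not None else np.nan,
    })
    return CNProfile(sample_id=sample_id, bins=bins)
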