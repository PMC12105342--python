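import numpy as np
import pandas as pd
import pytest

import miteomics as m


@pytest.fixture(scope="session")
def small_sim():
    """300-gene simulated experiment shared by cheap tests."""
    return m.simulate_counts(m.SimulationConfig(n_genes=300, seed=11))


@pytest.fixture(scope="session")
def small_em(small_sim):
    return m.ExpressionMatrix(small_sim.counts, small_sim.sample_groups,
                              small_sim.lengths)


@pytest.fixture(scope="session")
def calibration_sim():
    """The reference recovery experiment: 2000 genes, effect 3, dispersion 0.1."""
    cfg = m.SimulationConfig(n_genes=2000, effect_log2fc=3.0,
                             baseline_mean=100.0, dispersion=0.1, seed=2024)
    return m.simulate_counts(cfg)


@pytest.fixture(scope="session")
def calibration_profiles(calibration_sim):
    sim = calibration_sim
    em = m.ExpressionMatrix(sim.counts, sim.sample_groups, sim.lengths)
    return m.stage_profiles(em)


@pytest.fixture(scope="session")
def planted_proteome():
    return m.simulate_proteome(n_background=500, n_cpr=5, n_cpap=5, n_cph=5,
                               seed=77)


def toy_em(counts: np.ndarray, lengths, groups) -> m.ExpressionMatrix:
    """Build a tiny ExpressionMatrix from raw arrays."""
    genes = [f"g{i}" for i in range(counts.shape[0])]
    samples = [f"s{i}" for i in range(counts.shape[1])]
    return m.ExpressionMatrix(
        pd.DataFrame(counts, index=genes, columns=samples),
        pd.Series(groups, index=samples),
        pd.Series(lengths, index=genes),
    )
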