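import numpy as np
import pandas as pd
import pytest

from filamix import ExpressionMatrix, SimulationParams, simulate_dataset


@pytest.fixture(scope="session")
def small_sim():
    """A small noisy simulated experiment with ground truth (session-wide)."""
    params = SimulationParams(n_genes=400, noise_cv=0.1, seed=11)
    return simulate_dataset(params)


@pytest.fixture
def toy_matrix():
    """Hand-built 4-gene x 9-sample matrix (one condition, 3 replicates)."""
    rng = np.random.default_rng(3)
    genes = ["g1", "g2", "g3", "g4"]
    cols = [f"P_{t}_{r}" for t in ("F", "V", "Ht") for r in (1, 2, 3)]
    values = pd.DataFrame(
        rng.uniform(100, 1000, size=(4, 9)), index=genes, columns=cols)
    annotation = pd.DataFrame(
        {"product": "p", "category": ["Other", "Unknown", "Photosynthesis",
                                      "N2 fixation"]},
        index=genes)
    return ExpressionMatrix(values, annotation)
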