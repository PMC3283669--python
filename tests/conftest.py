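import numpy as np
import pandas as pd
import pytest

from regulon_shift import ExpressionMatrix, SimulationConfig, simulate_study


@pytest.fixture(scope="session")
def small_study():
    """A modest synthetic study shared by read-only tests."""
    return simulate_study(SimulationConfig(n_genes=300, seed=11))


@pytest.fixture()
def gaussian_matrix():
    """Null expression matrix: 4 strains x 1 phase x 3 reps, no strain effect."""
    rng = np.random.default_rng(7)
    genes = [f"g{i}" for i in range(200)]
    cols = {
        f"{strain}.log.{rep}": 8 + 0.3 * rng.standard_normal(len(genes))
        for strain in ("wt", "gis1", "rph1", "gis1rph1")
        for rep in (1, 2, 3)
    }
    return ExpressionMatrix(pd.DataFrame(cols, index=genes))
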