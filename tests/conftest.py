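import numpy as np
import pandas as pd
import pytest

import grainqtl as gq
from grainqtl.containers import GeneticMap


@pytest.fixture(scope="session")
def study():
    """One default-scale simulated study shared across tests (seed 11)."""
    return gq.simulate_study(gq.study_config(), seed=11)


@pytest.fixture(scope="session")
def small_map():
    """3 chromosomes x 10 markers, 10 cM spacing."""
    rows = [
        (f"C{c}M{j + 1:02d}", str(c), float(j * 10))
        for c in (1, 2, 3)
        for j in range(10)
    ]
    return GeneticMap(pd.DataFrame(rows, columns=["marker", "chromosome", "cm"]))


@pytest.fixture()
def rng():
    return np.random.default_rng(7)
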